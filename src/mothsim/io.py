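"""Result/trajectory serialization and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig, config_to_dict
from .experiment import ResultsTable

__all__ = ["RunManifest", "write_outputs", "read_results"]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a campaign bit-for-bit."""

    config_hash: str
    master_seed: int
    software_version: str
    created_at: str
    results_path: str
    trajectory_paths: dict[str, str]


def _config_hash(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_outputs(results: ResultsTable, trajectories: dict[str, pd.DataFrame] | None,
                  out_dir: str | Path, config: RunConfig | None = None,
                  seed: int = 0) -> RunManifest:
    """Write results CSV, optional trajectory CSVs and a manifest JSON.

    Re-running the same campaign with the manifest's seed reproduces the
    CSVs byte-identically (the manifest's own timestamp is informational).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = out / "results.csv"
    results.df.to_csv(results_path, index=False, float_format="%.10g")
    traj_paths: dict[str, str] = {}
    for name, frame in (trajectories or {}).items():
        p = out / f"trajectory_{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        traj_paths[name] = str(p)
    manifest = RunManifest(
        config_hash=_config_hash(config) if config is not None else "",
        master_seed=seed,
        software_version=__version__,
        created_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        results_path=str(results_path),
        trajectory_paths=traj_paths,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


def read_results(path: str | Path) -> ResultsTable:
    """Load a results CSV written by :func:`write_outputs`."""
    return ResultsTable(pd.read_csv(path))
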