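"""Assemble the full statistical comparison report for one campaign."""

from __future__ import annotations

import itertools
from dataclasses import asdict

import numpy as np

from .experiment import ResultsTable
from .stats import (ContingencyTable, dunn_test, fisher_exact_rxc,
                    g2_goodness_of_fit, pairwise_fisher, scheirer_ray_hare)

__all__ = ["benchmark_report"]


def _success_table(results: ResultsTable) -> ContingencyTable:
    """Models x levels table of success counts (among started navigators).

    With a single treatment level the table degenerates to one column; the
    comparison then falls back to models x {success, failure} counts.
    """
    models = results.models
    levels = results.levels
    if len(levels) >= 2:
        counts = np.zeros((len(models), len(levels)), dtype=np.int64)
        for i, m in enumerate(models):
            for j, lv in enumerate(levels):
                counts[i, j] = results.counts(m, lv)[2]
        return ContingencyTable(counts, tuple(models),
                                tuple(f"{lv:g}" for lv in levels))
    lv = levels[0]
    counts = np.zeros((len(models), 2), dtype=np.int64)
    for i, m in enumerate(models):
        _, started, succ = results.counts(m, lv)
        counts[i] = (succ, started - succ)
    return ContingencyTable(counts, tuple(models), ("success", "failure"))


def benchmark_report(results: ResultsTable, n_mc: int = 100_000,
                     rng: np.random.Generator | None = None) -> dict:
    """The three-step success-rate comparison plus the rank analysis of tau.

    1. overall models x levels Fisher exact test on success counts;
    2. pairwise model Fisher (2x2 success/failure, pooled over levels) with
       Holm-Bonferroni adjustment;
    3. per-level G-squared goodness of fit of success counts across models
       against uniformity;
    then Scheirer-Ray-Hare on tau (model x level) with Dunn post-hoc
    comparisons of the models.
    """
    if rng is None:
        rng = np.random.default_rng()
    models = results.models
    levels = results.levels
    report: dict = {}

    overall = _success_table(results)
    rep = fisher_exact_rxc(overall, n_mc=n_mc, rng=rng)
    report["fisher_overall"] = asdict(rep)

    pair_tables = {}
    for m1, m2 in itertools.combinations(models, 2):
        cells = []
        for m in (m1, m2):
            succ = sum(results.counts(m, lv)[2] for lv in levels)
            started = sum(results.counts(m, lv)[1] for lv in levels)
            cells.append([succ, started - succ])
        pair_tables[(m1, m2)] = np.array(cells)
    report["fisher_pairwise"] = [asdict(r)
                                 for r in pairwise_fisher(pair_tables)]

    report["g2_per_level"] = {}
    for lv in levels:
        observed = [results.counts(m, lv)[2] for m in models]
        if sum(observed) == 0:
            continue
        rep = g2_goodness_of_fit(observed)
        report["g2_per_level"][f"{lv:g}"] = asdict(rep)

    tau_rows = results.df[results.df["success"]]
    if len(tau_rows) >= 3 and tau_rows["model"].nunique() >= 2:
        srh = scheirer_ray_hare(tau_rows["tau"].to_numpy(),
                                tau_rows["model"].to_numpy(),
                                tau_rows["level"].to_numpy())
        report["srh_tau"] = {k: asdict(v) for k, v in srh.items()}
        groups, labels = [], []
        for m in models:
            vals = tau_rows.loc[tau_rows["model"] == m, "tau"].to_numpy()
            if vals.size:
                groups.append(vals)
                labels.append(m)
        if len(groups) >= 2:
            report["dunn_tau"] = [asdict(r)
                                  for r in dunn_test(groups, labels)]
    return report
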