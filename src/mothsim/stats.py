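"""Nonparametric benchmarking statistics.

The benchmark compares navigator cohorts with the test family standard in
behavioral ecology: contingency tests on success counts (G-squared goodness
of fit, r x c Fisher exact with Monte-Carlo estimation, pairwise Fisher with
Holm-Bonferroni adjustment) and rank tests on the efficiency ratio tau
(Scheirer-Ray-Hare two-way rank ANOVA, Dunn's pairwise post-hoc test).  All
procedures are implemented from their standard definitions; ties are
handled with mid-ranks throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ContingencyTable", "TestReport", "g2_goodness_of_fit",
           "fisher_exact_rxc", "fisher_exact_2x2", "holm_bonferroni",
           "pairwise_fisher", "scheirer_ray_hare", "dunn_test",
           "enumerate_fisher_exact"]


@dataclass(frozen=True)
class ContingencyTable:
    """Integer count matrix with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class TestReport:
    """Outcome of one statistical procedure."""

    method: str
    statistic: float
    df: float
    p_value: float
    adjusted_p: float | None = None
    labels: tuple[str, ...] = ()
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ------------------------------------------------------------------ G-squared


def g2_goodness_of_fit(observed, expected=None) -> TestReport:
    """Likelihood-ratio (G-squared) goodness-of-fit test.

    ``G2 = 2 * sum O * ln(O / E)`` over cells with O > 0, df = k - 1,
    p from the upper chi-square tail.  ``expected=None`` tests against the
    uniform distribution.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    if (obs < 0).any():
        raise ValueError("observed counts must be >= 0")
    if expected is None:
        exp = np.full_like(obs, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float).ravel()
        if exp.shape != obs.shape:
            raise ValueError("observed and expected must have the same length")
    if (exp <= 0).any():
        raise ValueError("expected counts must be > 0")
    if not math.isclose(obs.sum(), exp.sum(), rel_tol=1e-6, abs_tol=0.5):
        raise ValueError("observed and expected totals must agree")
    mask = obs > 0
    g2 = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    df = obs.size - 1
    p = float(sps.chi2.sf(g2, df))
    return TestReport("G2 goodness of fit", g2, df, p)


# ------------------------------------------------------------ Fisher's exact


def _log_table_prob(table: np.ndarray, lgam_margins: float,
                    log_nfac: float) -> float:
    """Log hypergeometric probability of a table given its margins."""
    return lgam_margins - log_nfac - float(
        np.sum([math.lgamma(v + 1.0) for v in table.ravel()]))


def _margin_lgamma(table: np.ndarray) -> tuple[float, float]:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    lg = (sum(math.lgamma(r + 1.0) for r in rows)
          + sum(math.lgamma(c + 1.0) for c in cols))
    return lg, math.lgamma(table.sum() + 1.0)


def fisher_exact_2x2(table) -> TestReport:
    """Two-sided Fisher exact test on a 2x2 table (full enumeration).

    Sums the probabilities of all hypergeometric tables with the observed
    margins whose probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    r0, r1 = t.sum(axis=1)
    c0, _c1 = t.sum(axis=0)
    n = t.sum()
    if r0 == 0 or r1 == 0 or c0 == 0 or _c1 == 0:
        return TestReport("Fisher exact 2x2", 0.0, 1, 1.0,
                          labels=("degenerate margins",))
    lo, hi = max(0, c0 - r1), min(r0, c0)
    ks = np.arange(lo, hi + 1)
    logp = (sps.hypergeom.logpmf(ks, n, r0, c0))
    obs_logp = float(sps.hypergeom.logpmf(t[0, 0], n, r0, c0))
    p = float(np.exp(logp[logp <= obs_logp + 1e-9]).sum())
    return TestReport("Fisher exact 2x2", float(t[0, 0]), 1, min(p, 1.0))


def enumerate_fisher_exact(table) -> float:
    """Exact two-sided Fisher p on a small r x c table by full enumeration.

    Brute-force oracle: walks every non-negative integer matrix with the
    observed margins.  Feasible only for small totals (N <= ~30).
    """
    t = np.asarray(table, dtype=np.int64)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    lg_m, log_nfac = _margin_lgamma(t)
    obs_logp = _log_table_prob(t, lg_m, log_nfac)
    r, c = t.shape
    total = 0.0

    def rec(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            cand = np.vstack(acc + [last])
            logp = _log_table_prob(cand, lg_m, log_nfac)
            if logp <= obs_logp + 1e-9:
                total += math.exp(logp)
            return
        for combo in _compositions(rows[i], remaining_cols):
            rec(i + 1, remaining_cols - combo, acc + [combo])

    def _compositions(total_row: int, caps: np.ndarray):
        # all ways to split total_row over len(caps) cells with cell <= cap
        if len(caps) == 1:
            if 0 <= total_row <= caps[0]:
                yield np.array([total_row])
            return
        for first in range(0, min(total_row, caps[0]) + 1):
            for rest in _compositions(total_row - first, caps[1:]):
                yield np.concatenate(([first], rest))

    rec(0, cols.copy(), [])
    return min(total, 1.0)


def fisher_exact_rxc(table, n_mc: int = 100_000,
                     rng: np.random.Generator | None = None) -> TestReport:
    """Two-sided Fisher exact test for an r x c table.

    2x2 tables are solved exactly; larger tables get a Monte-Carlo estimate
    of the exact p: the proportion of margin-preserving tables whose
    hypergeometric probability does not exceed the observed one.  Sampling
    draws each row from the multivariate hypergeometric distribution of the
    remaining column totals, which yields the uniform-margins null.  The
    estimate uses the (count + 1) / (n_mc + 1) convention and reports its
    binomial standard error.
    """
    ct = table if isinstance(table, ContingencyTable) else ContingencyTable(
        np.asarray(table))
    t = ct.counts
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if (rows == 0).any() or (cols == 0).any():
        return TestReport("Fisher exact r x c", 0.0, df, 1.0,
                          labels=("degenerate margins",))
    if t.shape == (2, 2):
        rep = fisher_exact_2x2(t)
        return TestReport("Fisher exact 2x2", rep.statistic, df, rep.p_value)
    if rng is None:
        rng = np.random.default_rng()
    lg_m, log_nfac = _margin_lgamma(t)
    obs_logp = _log_table_prob(t, lg_m, log_nfac)
    hits = 0
    r = t.shape[0]
    for _ in range(n_mc):
        remaining = cols.copy()
        logp = lg_m - log_nfac
        for i in range(r - 1):
            draw = rng.multivariate_hypergeometric(remaining, rows[i])
            logp -= sum(math.lgamma(v + 1.0) for v in draw)
            remaining -= draw
        logp -= sum(math.lgamma(v + 1.0) for v in remaining)
        if logp <= obs_logp + 1e-9:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return TestReport("Fisher exact r x c (Monte Carlo)", float(hits), df,
                      p, stderr=se)


# ----------------------------------------------------------- Holm-Bonferroni


def holm_bonferroni(p_values) -> list[float]:
    """Holm's step-down adjustment; returns adjusted p in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


def pairwise_fisher(tables: dict[tuple[str, str], np.ndarray]
                    ) -> list[TestReport]:
    """Pairwise 2x2 Fisher tests with Holm-Bonferroni adjusted p-values."""
    keys = list(tables)
    raw = [fisher_exact_2x2(tables[k]) for k in keys]
    adj = holm_bonferroni([r.p_value for r in raw])
    return [TestReport(r.method, r.statistic, r.df, r.p_value,
                       adjusted_p=a, labels=k)
            for r, a, k in zip(raw, adj, keys)]


# --------------------------------------------------------- rank-based tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def scheirer_ray_hare(values, factor_a, factor_b) -> dict[str, TestReport]:
    """Scheirer-Ray-Hare nonparametric two-way ANOVA on ranks.

    Jointly mid-ranks all observations, computes the two-way sums of squares
    on the ranks, and scales each effect by ``MS_total = SS_total / (N - 1)``
    (which carries the tie correction): ``H = SS_effect / MS_total`` is
    referred to the chi-square distribution with the effect's df.  Returns
    reports for 'A', 'B' and 'interaction' (the latter NaN when any cell has
    fewer than 2 observations or a factor has a single level).
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    ranks = _midranks(y)
    n = y.size
    grand = ranks.mean()
    ss_total = float(np.sum((ranks - grand) ** 2))
    ms_total = ss_total / (n - 1)
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)

    def _ss_factor(f, levels) -> float:
        ss = 0.0
        for lv in levels:
            sel = ranks[f == lv]
            ss += sel.size * (sel.mean() - grand) ** 2
        return ss

    ss_a = _ss_factor(fa, a_levels)
    ss_b = _ss_factor(fb, b_levels)
    ss_cells = 0.0
    min_cell = np.inf
    for la in a_levels:
        for lb in b_levels:
            sel = ranks[(fa == la) & (fb == lb)]
            min_cell = min(min_cell, sel.size)
            if sel.size:
                ss_cells += sel.size * (sel.mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b

    reports: dict[str, TestReport] = {}
    for name, ss, df in (("A", ss_a, len(a_levels) - 1),
                         ("B", ss_b, len(b_levels) - 1),
                         ("interaction", ss_ab,
                          (len(a_levels) - 1) * (len(b_levels) - 1))):
        if df <= 0 or (name == "interaction" and min_cell < 2):
            reports[name] = TestReport(f"SRH {name}", math.nan, max(df, 0),
                                       math.nan)
            continue
        h = ss / ms_total if ms_total > 0 else 0.0
        reports[name] = TestReport(f"SRH {name}", h, df,
                                   float(sps.chi2.sf(h, df)))
    return reports


def dunn_test(groups: list[np.ndarray], labels: list[str] | None = None,
              adjust: bool = True) -> list[TestReport]:
    """Dunn's rank-sum post-hoc test for all group pairs.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with the tie term ``T = sum(t^3 - t)`` over tie groups; two-sided normal
    p-values, Holm-adjusted by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    reports = []
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw_ps = []
    zs = []
    for i, j in pairs:
        denom = math.sqrt(var_base * (1.0 / groups[i].size
                                      + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * float(sps.norm.sf(abs(z)))
        zs.append(z)
        raw_ps.append(min(p, 1.0))
    adj = holm_bonferroni(raw_ps) if adjust else [None] * len(raw_ps)
    for (i, j), z, p, a in zip(pairs, zs, raw_ps, adj):
        reports.append(TestReport("Dunn", z, math.nan, p, adjusted_p=a,
                                  labels=(labels[i], labels[j])))
    return reports
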