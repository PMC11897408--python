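"""Normality-gated two-sample testing and hierarchical summaries.

The workflow mirrors common practice in quantitative cell biology: each
sample is checked for normality with the Shapiro-Wilk test; if both
samples pass at alpha, an unpaired two-tailed Welch t test is used,
otherwise a two-tailed Mann-Whitney U test. Count contrasts (e.g.
fraction of cells with big cytoplasmic foci) use a two-sided Fisher exact
test. All tests are two-tailed at alpha = 0.05 by default and no
multiple-testing correction is applied (comparisons are reported
per-figure, one at a time).

The Mann-Whitney p-value is exact by full enumeration of all
C(n_a + n_b, n_a) group assignments (mid-ranks for ties) when
n_a + n_b <= 12, and a tie-corrected, continuity-corrected normal
approximation otherwise. The Fisher two-sided p follows the
probability-mass rule: the sum of hypergeometric probabilities of all
tables (at fixed margins) no more probable than the observed one.

Replicate structure is summarized hierarchically: per-experiment means
("triangles") plus an overall mean +/- s.e.m. on a declared basis —
either across experiments or across all units — since the two bases
answer different questions and are not interchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsConfig",
    "TestResult",
    "HierarchicalSummary",
    "choose_test",
    "welch_t",
    "mann_whitney_u",
    "fisher_exact",
    "summarize_hierarchical",
]


@dataclass
class StatsConfig:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class TestResult:
    test: str  # "welch_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    df: float | None = None
    shapiro_p_a: float | None = None
    shapiro_p_b: float | None = None
    gate: str | None = None  # "both_normal" | "not_normal"


@dataclass
class HierarchicalSummary:
    experiment_means: dict[str, float]
    overall_mean: float
    sem: float
    basis: str  # "experiments" | "units"
    n_experiments: int
    n_units: int
    single_group: bool = False  # n = 1 on the chosen basis; sem reported as 0


def welch_t(sample_a, sample_b) -> TestResult:
    """Two-tailed unpaired t test with Welch's correction.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with Welch-Satterthwaite
    degrees of freedom. Both samples constant with equal means gives
    t = 0, p = 1; constant with unequal means is undefined and raises.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, 1.0, df=float(a.size + b.size - 2))
        raise ValueError(
            "both samples have zero variance with unequal means; "
            "t statistic undefined"
        )
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("welch_t", float(t), min(p, 1.0), df=float(df))


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration over all group assignments of the pooled (mid-ranked)
    data for n_a + n_b <= 12; otherwise the normal approximation with tie
    correction and continuity correction. The reported statistic is
    U = R_a - n_a(n_a+1)/2 for the first sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("mann_whitney_u requires n >= 1 per sample")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)

    if n_a + n_b <= 12:
        # enumerate every split of the pooled ranks into groups of size n_a
        m_obs = min(u_obs, n_a * n_b - u_obs)
        total = 0
        extreme = 0
        for comb in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(comb)], n_a, n_b)
            total += 1
            if min(u, n_a * n_b - u) <= m_obs + 1e-9:
                extreme += 1
        p = extreme / total
        return TestResult("mann_whitney_u", u_obs, p)

    mean_u = n_a * n_b / 2.0
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:  # all values tied
        return TestResult("mann_whitney_u", u_obs, 1.0)
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    p = 2.0 * float(sps.norm.sf(max(z, 0.0)))
    return TestResult("mann_whitney_u", u_obs, min(p, 1.0))


def choose_test(sample_a, sample_b, cfg: StatsConfig | None = None) -> TestResult:
    """Shapiro-Wilk gate: both samples normal at alpha -> Welch t, else
    Mann-Whitney U; always two-tailed. Requires n >= 3 per sample (the
    normality test is undefined below that)."""
    cfg = cfg or StatsConfig()
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("choose_test requires n >= 3 per sample")
    pa = _shapiro_p(a)
    pb = _shapiro_p(b)
    if pa > cfg.alpha and pb > cfg.alpha:
        res = welch_t(a, b)
        gate = "both_normal"
    else:
        res = mann_whitney_u(a, b)
        gate = "not_normal"
    res.shapiro_p_a = pa
    res.shapiro_p_b = pb
    res.gate = gate
    return res


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: treat as non-normal, use the rank test
    with np.errstate(all="ignore"):
        return float(sps.shapiro(x).pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (sample odds ratio, p). p is the sum of hypergeometric
    probabilities, at the observed margins, of every table no more
    probable than the observed one (probability-mass rule).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.rint(t)):
            raise ValueError("table entries must be non-negative integers")
        t = np.rint(t).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise ValueError("a margin of the table is zero; the test is undefined")
    rv = sps.hypergeom(n, c1, r1)  # X = top-left entry at fixed margins
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = rv.pmf(a)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return odds, min(p, 1.0)


def summarize_hierarchical(
    groups: dict[str, "np.ndarray | list[float]"], basis: str = "experiments"
) -> HierarchicalSummary:
    """Per-experiment means plus an overall mean +/- s.e.m.

    ``basis="experiments"`` summarizes over the experiment means (the
    triangles of a superplot); ``basis="units"`` pools every unit. With a
    single element on the chosen basis the s.e.m. is reported as 0 and
    flagged.
    """
    if basis not in ("experiments", "units"):
        raise ValueError("basis must be 'experiments' or 'units'")
    if not groups:
        raise ValueError("at least one experiment required")
    exp_means = {k: float(np.mean(v)) for k, v in groups.items()}
    units = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    if basis == "experiments":
        vals = np.array(list(exp_means.values()))
    else:
        vals = units
    n = vals.size
    sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return HierarchicalSummary(
        experiment_means=exp_means,
        overall_mean=float(vals.mean()),
        sem=sem,
        basis=basis,
        n_experiments=len(groups),
        n_units=int(units.size),
        single_group=n == 1,
    )
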