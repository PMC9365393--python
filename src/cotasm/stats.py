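"""Nonparametric inference layer for interface-size comparisons.

Interface areas are right-skewed and left-bounded by the minimum-area
cutoff, so all A/B comparisons use rank tests: Wilcoxon rank-sum for
independent groups, one-tailed Wilcoxon signed-rank for paired first/last
comparisons, Dunn's test with Holm-Bonferroni correction for multi-group
comparisons, and Fisher's exact test for early/late contingency tables.
Effect sizes are reported as r = |Z|/sqrt(n) with Z recovered from the p
value. Stratum-preserving bootstrap resampling (with the add-one
finite-sampling correction) gives the age- and operon-stratified area
difference probabilities, and binomial proportions carry Jeffreys
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

DEFAULT_SEED = 20220728


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect_size: float
    n: int
    tails: str            # "one" | "two"
    method: str
    extra: dict = field(default_factory=dict)


@dataclass
class BootstrapResult:
    B: int
    point_estimates: np.ndarray
    p: float
    strata: dict[str, int]   # stratum label -> size
    observed: float


@dataclass
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def fraction(self) -> float:
        return self.successes / self.trials


def effect_size_r(p_value: float, tails: str, n: int) -> float:
    """r = |Z|/sqrt(n), Z being the standard-normal quantile of the p value."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError("p value must lie in (0, 1]; p = 0 means underflow")
    if n < 1:
        raise ValueError("sample size must be positive")
    q = p_value / 2.0 if tails == "two" else p_value
    z = abs(sps.norm.isf(q))
    return float(z / np.sqrt(n))


def wilcoxon_rank_sum(a, b, tails: str = "two",
                      alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U comparison of two independent samples.

    Exact enumeration for small samples (n_a + n_b <= 12, no ties), else
    the tie-corrected normal approximation with continuity correction.
    The effect size is r = |Z|/sqrt(n_a + n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    n = a.size + b.size
    if tails == "two":
        alternative = "two-sided"
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(a.size * b.size / 2.0, 1.0, 0.0, n, tails,
                          "wilcoxon_rank_sum")
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    p = float(min(1.0, res.pvalue))
    return TestResult(float(res.statistic), p,
                      effect_size_r(p, tails, n), n, tails,
                      f"wilcoxon_rank_sum[{method}]")


def wilcoxon_signed_rank(diffs, tails: str = "one",
                         alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test on paired differences (one-tailed default).

    Zero differences are dropped before ranking; exact null distribution
    when n <= 20 without ties, else tie-corrected normal approximation.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero")
    if tails == "two":
        alternative = "two-sided"
    has_ties = np.unique(np.abs(diffs)).size < diffs.size
    method = "exact" if (diffs.size <= 20 and not has_ties) else "approx"
    res = sps.wilcoxon(diffs, alternative=alternative, method=method,
                       correction=(method == "approx"))
    p = float(min(1.0, res.pvalue))
    return TestResult(float(res.statistic), p,
                      effect_size_r(p, tails, diffs.size),
                      int(diffs.size), tails,
                      f"wilcoxon_signed_rank[{method}]")


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def dunn_holm(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Dunn's test of multiple comparisons with Holm-adjusted p values.

    Pooled-rank z statistics with tie correction, one TestResult per group
    pair; the raw two-sided p is kept in ``extra['p_raw']``.
    """
    if len(groups) < 3:
        raise ValueError("Dunn's test needs at least three groups")
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("empty group")
    pooled = np.concatenate([arrays[k] for k in labels])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank, start = {}, 0
    for k in labels:
        nk = arrays[k].size
        mean_rank[k] = ranks[start:start + nk].mean()
        start += nk
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    results, raw_ps, pairs = [], [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ki, kj = labels[i], labels[j]
            ni, nj = arrays[ki].size, arrays[kj].size
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (mean_rank[ki] - mean_rank[kj]) / se if se > 0 else 0.0
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            raw_ps.append(p_raw)
            pairs.append((ki, kj, z, ni + nj))
    adjusted = holm_adjust(raw_ps)
    for (ki, kj, z, n_pair), p_raw, p_adj in zip(pairs, raw_ps, adjusted):
        p_eff = max(min(p_adj, 1.0), np.finfo(float).tiny)
        results.append(
            TestResult(float(z), float(p_adj),
                       effect_size_r(p_eff, "two", n_pair),
                       n_pair, "two", "dunn_holm",
                       extra={"pair": (ki, kj), "p_raw": p_raw})
        )
    return results


def fisher_exact_or(table, alternative: str = "two-sided") -> dict:
    """Fisher's exact test and sample odds ratio for a 2x2 count table.

    ``table`` is ((a, b), (c, d)). The odds ratio is the sample OR
    (a*d)/(b*c) - infinite or zero cells are flagged; the relative risk
    a/(a+b) over c/(c+d) is also returned. ``alternative`` selects the
    tail ("two-sided", "greater", "less").
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    zero_cell = (b == 0 or c == 0 or a == 0 or d == 0)
    if b * c == 0:
        odds_ratio = float("inf") if a * d > 0 else float("nan")
    else:
        odds_ratio = (a * d) / (b * c)
    rr = float("nan")
    if (a + b) > 0 and (c + d) > 0 and c > 0:
        rr = (a / (a + b)) / (c / (c + d))
    return {
        "odds_ratio": odds_ratio,
        "p_value": float(p),
        "relative_risk": rr,
        "zero_cell": zero_cell,
        "n": a + b + c + d,
    }


def stratified_bootstrap(
    values,
    strata,
    B: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> BootstrapResult:
    """Stratum-preserving bootstrap of the mean paired area difference.

    Within each stratum, subunits are resampled with replacement; the
    point estimate of a resample is the pooled mean difference. The
    probability that the difference is not greater than zero uses the
    add-one finite-sampling correction, p = (1 + #{estimates <= 0})/(B+1),
    so p is floored at 1/(B+1).
    """
    if B < 1:
        raise ValueError("need at least one resample")
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    if values.size != strata.size or values.size == 0:
        raise ValueError("values and strata must be equal-length, non-empty")
    rng = np.random.default_rng(seed)
    groups = {lab: values[strata == lab] for lab in np.unique(strata)}
    if any(g.size == 0 for g in groups.values()):
        raise ValueError("empty stratum")
    estimates = np.empty(B)
    for bi in range(B):
        parts = [g[rng.integers(0, g.size, g.size)] for g in groups.values()]
        estimates[bi] = np.concatenate(parts).mean()
    p = (1 + int(np.sum(estimates <= 0.0))) / (B + 1)
    return BootstrapResult(
        B=B, point_estimates=estimates, p=float(p),
        strata={str(k): int(v.size) for k, v in groups.items()},
        observed=float(values.mean()),
    )


def jeffreys_ci(x: int, n: int, level: float = 0.68) -> BinomialCI:
    """Jeffreys binomial interval: Beta(x+1/2, n-x+1/2) quantiles.

    Boundary rule: the lower limit is 0 when x = 0 and the upper limit is
    1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n with n >= 1")
    alpha = (1.0 - level) / 2.0
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha, x + 0.5, n - x + 0.5))
    upper = 1.0 if x == n else float(
        sps.beta.ppf(1.0 - alpha, x + 0.5, n - x + 0.5))
    return BinomialCI(x, n, level, lower, upper)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def ols_slope(x, y) -> dict:
    """Least-squares slope with Pearson r, for the separation regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "pearson_r": float(res.rvalue), "p_value": float(res.pvalue),
            "n": int(x.size)}
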