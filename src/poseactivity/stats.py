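"""Univariate statistics: rank tests, effect sizes, correlations, multiplicity.

Conventions follow common reporting practice for small two-group designs:

* Mann-Whitney U is reported as ``min(U1, U2)`` with a standardized
  statistic ``Z = (U - n1 n2 / 2) / sigma_U`` using the tie-corrected
  normal approximation, and an effect size ``r = |Z| / sqrt(N)``.
* Spearman correlations carry Fisher-z confidence intervals with
  ``SE = 1 / sqrt(n - 3)`` and a t-approximation p value (n - 2 df).
* Across all movement outcomes, Benjamini-Hochberg step-up adjustment
  controls the false discovery rate; an anatomically structured
  sensitivity analysis applies Bonferroni correction within five body
  domains (head alone, each limb's four regions), i.e. alpha / m per
  domain with strict-inequality significance.
* Wilson score intervals summarize classification proportions and the
  Hanley-McNeil normal approximation gives AUC intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .landmarks import DOMAINS, STAT_REGIONS


@dataclass
class GroupTestResult:
    region: str
    u: float
    z: float
    r: float
    p_raw: float
    p_fdr: float | None
    direction: str  # "risk>control" | "control>risk" | "n.s."


@dataclass
class CorrelationResult:
    region: str
    rho: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class DomainCorrection:
    domain: str
    m: int
    alpha_adj: float
    outcomes: dict[str, bool]  # region -> significant at alpha_adj


def shapiro_gate(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """Choose the test family from per-group Shapiro-Wilk normality tests.

    Returns ``"nonparametric"`` if any group deviates from normality at
    ``alpha``, else ``"parametric"``.
    """
    for name, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
        if sps.shapiro(values).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def mann_whitney(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    """Mann-Whitney U with midranks, tie-corrected Z, and min-U reporting.

    ``a`` is the first (here: risk) group.  Direction is taken from the
    mean ranks and reported as ``n.s.`` when the raw two-sided p >= 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = r2 - n2 * (n2 + 1) / 2
    u = min(u1, u2)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2
    if sigma2 <= 0:  # all values tied
        z = 0.0
    else:
        z = (u - mu) / np.sqrt(sigma2)
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    r_eff = effect_size_r(z, n)
    mean_rank1, mean_rank2 = r1 / n1, r2 / n2
    if p >= 0.05:
        direction = "n.s."
    else:
        direction = "risk>control" if mean_rank1 > mean_rank2 else "control>risk"
    return GroupTestResult("", float(u), float(z), r_eff, p, None, direction)


def effect_size_r(z: float, n: int) -> float:
    """Rank-test effect size r = |Z| / sqrt(N)."""
    if n < 2:
        raise ValueError("N must be >= 2")
    return float(abs(z) / np.sqrt(n))


def u_from_mean_ranks(mean_rank1: float, n1: int, mean_rank2: float, n2: int) -> float:
    """Recover min(U1, U2) from printed per-group mean ranks.

    Validates the rank-sum identity n1*mr1 + n2*mr2 = N(N+1)/2 (to within
    rounding of printed two-decimal ranks).
    """
    n = n1 + n2
    total = n1 * mean_rank1 + n2 * mean_rank2
    if abs(total - n * (n + 1) / 2) > 0.5 * n:
        raise ValueError(
            f"inconsistent mean ranks: rank sum {total} != N(N+1)/2 = {n * (n + 1) / 2}")
    u1 = n1 * mean_rank1 - n1 * (n1 + 1) / 2
    u2 = n2 * mean_rank2 - n2 * (n2 + 1) / 2
    return float(min(u1, u2))


def spearman_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> CorrelationResult:
    """Spearman rho with Fisher-z CI (SE = 1/sqrt(n-3)) and t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    n = len(x)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    zcrit = sps.norm.ppf(0.5 + conf / 2)
    half = zcrit / np.sqrt(n - 3)
    return CorrelationResult(
        "", rho, float(np.tanh(z - half)), float(np.tanh(z + half)), float(res.pvalue)
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    if p_values.min() < 0 or p_values.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


def domain_bonferroni(
    p_by_region: dict[str, float], alpha: float = 0.05,
    domains: dict[str, tuple[str, ...]] | None = None,
) -> list[DomainCorrection]:
    """Domain-wise Bonferroni correction over the five anatomical families.

    Each domain uses alpha_adj = alpha / m where m is the number of
    outcomes in the domain (the single-outcome head domain is therefore
    uncorrected); significance is strict: p < alpha_adj.
    """
    domains = domains or DOMAINS
    assigned: dict[str, str] = {}
    for name, members in domains.items():
        for region in members:
            if region in assigned:
                raise ValueError(f"region {region!r} assigned to multiple domains")
            assigned[region] = name
    unassigned = set(p_by_region) - set(assigned)
    if unassigned:
        raise ValueError(f"regions assigned to no domain: {sorted(unassigned)}")
    out = []
    for name, members in domains.items():
        present = [m for m in members if m in p_by_region]
        if not present:
            continue
        m = len(members)
        alpha_adj = alpha / m
        flags = {region: bool(p_by_region[region] < alpha_adj) for region in present}
        out.append(DomainCorrection(name, m, alpha_adj, flags))
    return out


def pooled_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def chi2_2x2(counts: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table (no continuity correction by default)."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    return chi2, 1, float(sps.chi2.sf(chi2, 1))


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    z = sps.norm.ppf(0.5 + conf / 2)
    phat = k / n
    denom = 1 + z**2 / n
    center = phat + z**2 / (2 * n)
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    # boundary cases are exact: [0, .] for k=0 and [., 1] for k=n
    low = 0.0 if k == 0 else min(max((center - half) / denom, 0.0), 1.0)
    high = 1.0 if k == n else min(max((center + half) / denom, 0.0), 1.0)
    return float(low), float(high)


def hanley_mcneil_ci(
    auc: float, n1: int, n2: int, conf: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation AUC interval using the Q1/Q2 variance formula."""
    if not 0 <= auc <= 1:
        raise ValueError("AUC must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one case per class")
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = np.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.5 + conf / 2)
    return float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


# ---------------------------------------------------------------------------
# Table-level drivers over the feature table


def group_differences(
    features: pd.DataFrame, regions: tuple[str, ...] = STAT_REGIONS
) -> pd.DataFrame:
    """Mann-Whitney comparisons (risk vs control) across regions, BH-adjusted."""
    results = []
    risk = features[features["group"] == "risk"]
    control = features[features["group"] == "control"]
    for region in regions:
        res = mann_whitney(risk[region].to_numpy(), control[region].to_numpy())
        res.region = region
        results.append(res)
    p_fdr = bh_adjust([r.p_raw for r in results])
    rows = []
    for res, adj in zip(results, p_fdr):
        res.p_fdr = float(adj)
        rows.append(
            {"region": res.region, "U": res.u, "Z": res.z, "r": res.r,
             "p_raw": res.p_raw, "p_fdr": res.p_fdr, "direction": res.direction}
        )
    return pd.DataFrame(rows)


def conners_correlations(
    features: pd.DataFrame, regions: tuple[str, ...] = STAT_REGIONS, conf: float = 0.95
) -> pd.DataFrame:
    """Spearman correlations of regional indices with the teacher rating.

    Uncorrected for multiplicity, matching the exploratory convention for
    this table.
    """
    rows = []
    score = features["conners_score"].to_numpy()
    for region in regions:
        res = spearman_ci(features[region].to_numpy(), score, conf)
        rows.append(
            {"region": region, "rho": res.rho, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p": res.p}
        )
    return pd.DataFrame(rows)


def spearman_matrix(
    features: pd.DataFrame, regions: tuple[str, ...] = STAT_REGIONS
) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix across regional indices."""
    sub = features[list(regions)]
    if (sub.nunique() <= 1).any():
        bad = sub.columns[(sub.nunique() <= 1)].tolist()
        raise ValueError(f"zero-variance columns: {bad}")
    mat = sub.corr(method="spearman")
    np.fill_diagonal(mat.values, 1.0)
    return mat


def normality_census(features: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk gate per movement outcome (17 regions + global)."""
    from .landmarks import GLOBAL_INDEX, REGIONS

    rows = []
    for col in list(REGIONS) + [GLOBAL_INDEX]:
        by_group = {
            g: features.loc[features["group"] == g, col].to_numpy()
            for g in ("risk", "control")
        }
        rows.append({"outcome": col, "family": shapiro_gate(by_group, alpha)})
    return pd.DataFrame(rows)
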