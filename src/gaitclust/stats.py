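"""Assumption-dispatched group comparisons, effect sizes and correlations.

Continuous variables: normality (Shapiro-Wilk per group) and variance
homogeneity (Levene, median-centred) decide between one-way ANOVA with
Tukey HSD and Kruskal-Wallis with Dunn's post-hoc (Holm-adjusted).
Eta-squared accompanies both branches (rank-based on the Kruskal-Wallis
branch).  Categorical variables: Pearson chi-squared with Cramer's V.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decomposition import eta_squared_1d


@dataclass
class ComparisonResult:
    variable: str
    groups: list
    test_used: str            # anova | kruskal_wallis | chi_squared
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_size_name: str     # eta_squared | cramers_v
    posthoc: list = field(default_factory=list)  # (pair, p, significant)
    assumption_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def check_assumptions(groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per group and Levene (median-centred) across groups."""
    clean = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(clean):
        if len(g) < 3:
            raise ValueError(f"group {i} has fewer than 3 observations")
    shapiro_ps = []
    for g in clean:
        if np.ptp(g) == 0:
            shapiro_ps.append(0.0)  # constant sample: certainly non-normal
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_ps.append(float(sps.shapiro(g).pvalue))
    normal = all(p > alpha for p in shapiro_ps)
    lev_p = float(sps.levene(*clean, center="median").pvalue)
    return {
        "normal": normal,
        "homoscedastic": lev_p > alpha,
        "shapiro_p": shapiro_ps,
        "levene_p": lev_p,
    }


def eta_squared(values, labels) -> float:
    """Classical eta-squared: between-group SS over total SS."""
    return eta_squared_1d(np.asarray(values, float), np.asarray(labels))


def rank_eta_squared(h_stat: float, n: int, k: int) -> float:
    """Rank-based eta-squared for a Kruskal-Wallis H statistic."""
    if n <= k:
        raise ValueError("need n > k")
    return float(np.clip((h_stat - k + 1) / (n - k), 0.0, 1.0))


def _dunn_posthoc(groups: dict, alpha: float, adjust: str = "holm") -> list:
    """Dunn's rank-sum pairwise z tests with tie correction.

    p-values are Holm-adjusted by default (``adjust=None`` for unadjusted).
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    start = 0
    for g in names:
        size = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + size].mean())
        start += size
    pairs, raw_p = [], []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pairs.append((a, b))
        raw_p.append(2.0 * sps.norm.sf(abs(z)))
    if adjust:
        adj = multipletests(raw_p, method=adjust)[1]
    else:
        adj = np.asarray(raw_p)
    return [(pair, float(p), bool(p < alpha)) for pair, p in zip(pairs, adj)]


def compare_groups(
    values, labels, alpha: float = 0.05, variable: str = ""
) -> ComparisonResult:
    """Omnibus comparison of a continuous variable across groups.

    Dispatch: if every group passes Shapiro-Wilk and Levene passes, one-way
    ANOVA with Tukey HSD post-hoc; otherwise Kruskal-Wallis with Dunn's
    post-hoc (Holm-adjusted).  Post-hoc tests run only when the omnibus
    p-value is below ``alpha``.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    names = [g for g in np.unique(labels)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    groups = {g: values[labels == g] for g in names}
    assumptions = check_assumptions(list(groups.values()), alpha)
    k, n = len(names), len(values)

    if assumptions["normal"] and assumptions["homoscedastic"]:
        stat, p = sps.f_oneway(*groups.values())
        df = k - 1
        es = eta_squared(values, labels)
        posthoc = []
        if p < alpha:
            res = sps.tukey_hsd(*groups.values())
            for i, j in itertools.combinations(range(k), 2):
                pv = float(res.pvalue[i, j])
                posthoc.append(((names[i], names[j]), pv, bool(pv < alpha)))
        return ComparisonResult(
            variable=variable, groups=names, test_used="anova",
            statistic=float(stat), df=float(df), p_value=float(p),
            effect_size=es, effect_size_name="eta_squared",
            posthoc=posthoc, assumption_log=assumptions,
        )

    stat, p = sps.kruskal(*groups.values())
    es = rank_eta_squared(float(stat), n, k)
    posthoc = _dunn_posthoc(groups, alpha) if p < alpha else []
    return ComparisonResult(
        variable=variable, groups=names, test_used="kruskal_wallis",
        statistic=float(stat), df=float(k - 1), p_value=float(p),
        effect_size=es, effect_size_name="eta_squared",
        posthoc=posthoc, assumption_log=assumptions,
    )


def cramers_v(table: np.ndarray, variable: str = "") -> ComparisonResult:
    """Pearson chi-squared (no continuity correction) with Cramer's V.

    V = sqrt(chi2 / (N * (min(r, c) - 1))).  Warns when any expected count
    is below 5; raises on zero margins.
    """
    table = np.asarray(table, float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{variable or 'table'}: expected count below 5; chi-squared "
            "approximation may be poor",
            stacklevel=2,
        )
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return ComparisonResult(
        variable=variable,
        groups=[f"col{j}" for j in range(table.shape[1])],
        test_used="chi_squared",
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        effect_size=v,
        effect_size_name="cramers_v",
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
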