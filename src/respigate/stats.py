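"""Study statistics: repeated-measures ANOVA (Wilks), Bonferroni pairwise
comparisons, ordinal Krippendorff's alpha and Bland--Altman agreement.

The repeated-measures ANOVA uses the multivariate approach: with k
conditions measured on n subjects, form the k-1 within-subject difference
variables, compute the one-sample Hotelling statistic
``T2 = n * dbar' S^-1 dbar``, and report

* Wilks' lambda  ``L = 1 / (1 + T2 / (n - 1))``,
* ``F = T2 * (n - k + 1) / ((n - 1)(k - 1))`` on (k-1, n-k+1) df,
* partial eta squared ``1 - L``.

Krippendorff's alpha for ordinal data is computed from the coincidence
matrix with the rank distance
``delta2(c, k) = (sum_{g=c..k} n_g - (n_c + n_k) / 2)^2``;
``alpha = 1 - D_o / D_e``. Missing entries are handled by the
pairable-values rule (units with fewer than two ratings drop out).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from respigate.synthetic import CONDITIONS


@dataclass
class RmAnovaResult:
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    p_bonf: float
    ci_low: float
    ci_high: float


@dataclass
class AgreementResult:
    alpha: float
    metric: str
    n_raters: int
    n_items: int


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def _condition_matrix(table: pd.DataFrame | np.ndarray,
                      conditions: tuple[str, ...] = CONDITIONS
                      ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Extract the n x k value matrix (complete cases only)."""
    if isinstance(table, pd.DataFrame):
        cols = [c for c in conditions if c in table.columns]
        if len(cols) < 2:
            raise ValueError(
                f"condition table must contain columns {conditions}, "
                f"got {list(table.columns)}"
            )
        y = table[cols].to_numpy(dtype=float)
        names = tuple(cols)
    else:
        y = np.asarray(table, dtype=float)
        names = tuple(conditions[: y.shape[1]])
    y = y[~np.isnan(y).any(axis=1)]
    return y, names


def rm_anova_wilks(table: pd.DataFrame | np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA, multivariate (Wilks' lambda) form."""
    y, _ = _condition_matrix(table)
    n, k = y.shape
    if n <= k - 1:
        raise ValueError(f"need more than k-1={k - 1} subjects, got {n}")
    d = y[:, :-1] - y[:, 1:]                 # n x (k-1) difference variables
    dbar = d.mean(axis=0)
    s = np.cov(d, rowvar=False, ddof=1).reshape(k - 1, k - 1)
    if np.allclose(d, 0.0):
        # no within-subject differences at all: no condition effect
        t2 = 0.0
    else:
        try:
            sol = np.linalg.solve(s, dbar)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular covariance of within-subject differences -- the "
                "metric is degenerate across conditions"
            ) from exc
        t2 = float(n * dbar @ sol)
    lam = 1.0 / (1.0 + t2 / (n - 1))
    df1, df2 = k - 1, n - k + 1
    f_stat = t2 * df2 / ((n - 1) * df1)
    p = float(sps.f.sf(f_stat, df1, df2)) if f_stat > 0 else 1.0
    return RmAnovaResult(wilks_lambda=lam, F=f_stat, df1=df1, df2=df2, p=p,
                         partial_eta_sq=1.0 - lam)


def bonferroni_pairwise(table: pd.DataFrame | np.ndarray,
                        alpha: float = 0.05) -> list[PairwiseResult]:
    """Paired-t pairwise comparisons, Bonferroni corrected, both orders.

    Each of the 3 condition pairs (and its mirror) reports the paired mean
    difference X - Y, its SE, ``p_bonf = min(1, 3 p)`` and the
    Bonferroni-adjusted 95% CI (coverage 1 - alpha/3).
    """
    y, names = _condition_matrix(table)
    n, k = y.shape
    if n < 2:
        raise ValueError(f"need >= 2 subjects for pairwise tests, got {n}")
    m = k * (k - 1) // 2
    tcrit = sps.t.ppf(1.0 - alpha / (2 * m), n - 1)
    results: list[PairwiseResult] = []
    for i, j in combinations(range(k), 2):
        d = y[:, i] - y[:, j]
        mean_diff = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if sd == 0.0:
            p = 1.0 if mean_diff == 0.0 else 0.0
        else:
            p = float(sps.ttest_rel(y[:, i], y[:, j]).pvalue)
        p_bonf = min(1.0, m * p)
        half = tcrit * se
        for (a_name, b_name), sign in (((names[i], names[j]), 1.0),
                                       ((names[j], names[i]), -1.0)):
            md = sign * mean_diff
            results.append(PairwiseResult(
                pair=(a_name, b_name), mean_diff=md, se=se, p_bonf=p_bonf,
                ci_low=md - half, ci_high=md + half,
            ))
    return results


def krippendorff_alpha_ordinal(ratings: pd.DataFrame | np.ndarray,
                               levels: list | None = None) -> AgreementResult:
    """Krippendorff's alpha for ordinal data from the coincidence matrix.

    ``ratings`` is items x raters; missing entries (NaN) are allowed and
    handled by the pairable-values rule. ``levels`` fixes the ordered
    category set; by default the observed values (sorted) are used.
    """
    if isinstance(ratings, pd.DataFrame):
        values = ratings.to_numpy(dtype=float)
        n_raters = ratings.shape[1]
    else:
        values = np.asarray(ratings, dtype=float)
        n_raters = values.shape[1]
    n_items = values.shape[0]

    observed = values[~np.isnan(values)]
    if levels is None:
        levels = sorted(set(observed.tolist()))
    levels = list(levels)
    level_pos = {v: i for i, v in enumerate(levels)}
    L = len(levels)

    # coincidence matrix over pairable values
    o = np.zeros((L, L))
    any_pairable = False
    for u in range(n_items):
        vals = values[u][~np.isnan(values[u])]
        m_u = len(vals)
        if m_u < 2:
            continue
        any_pairable = True
        idx = [level_pos[v] for v in vals]
        for a in range(m_u):
            for b in range(m_u):
                if a != b:
                    o[idx[a], idx[b]] += 1.0 / (m_u - 1)
    if not any_pairable:
        raise ValueError("no item has two or more ratings: nothing is pairable")

    n_c = o.sum(axis=1)
    n_tot = n_c.sum()
    if L == 1:
        return AgreementResult(alpha=1.0, metric="ordinal",
                               n_raters=n_raters, n_items=n_items)

    # ordinal distance on the marginal distribution
    cum = np.cumsum(n_c)
    delta2 = np.zeros((L, L))
    for c in range(L):
        for k in range(c + 1, L):
            span = cum[k] - (cum[c - 1] if c > 0 else 0.0)
            d = span - (n_c[c] + n_c[k]) / 2.0
            delta2[c, k] = delta2[k, c] = d * d

    d_o = float((o * delta2).sum())
    d_e = float((np.outer(n_c, n_c) * delta2).sum() / (n_tot - 1))
    if d_e == 0.0:
        # all coincidences in one category: perfect agreement
        alpha = 1.0
    else:
        alpha = 1.0 - d_o / d_e
    return AgreementResult(alpha=alpha, metric="ordinal",
                           n_raters=n_raters, n_items=n_items)


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need >= 2 paired values")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd)


def one_sided_mean_test(values: np.ndarray, threshold: float,
                        direction: str = "greater") -> float:
    """One-sample t-test of the mean against a threshold, one-sided.

    Used e.g. to test whether cohort phase cross-correlations exceed 0.5
    (strong correlation). Zero-variance samples are degenerate: p is 0
    when every value is strictly on the alternative side, 1 when strictly
    on the null side and 0.5 when all values equal the threshold.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if v.std(ddof=1) == 0.0:
        if v[0] == threshold:
            return 0.5
        on_alt = v[0] > threshold if direction == "greater" else v[0] < threshold
        return 0.0 if on_alt else 1.0
    res = sps.ttest_1samp(v, threshold, alternative=direction)
    return float(res.pvalue)


def relative_difference_percent(difference: float, reference: float) -> float:
    """A mean difference as a percentage of a reference mean.

    E.g. a 1.4 ml gated-vs-ungated backward-flow difference against a
    15.8 ml reference volume is an 8.9% relative difference.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * difference / reference


__all__ = [
    "RmAnovaResult", "PairwiseResult", "AgreementResult", "BlandAltmanResult",
    "rm_anova_wilks", "bonferroni_pairwise", "krippendorff_alpha_ordinal",
    "bland_altman", "one_sided_mean_test", "relative_difference_percent",
]
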