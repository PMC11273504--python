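"""Correlation, regression-equivalence, and kappa agreement statistics.

Cohen's kappa is implemented from the confusion-matrix formulas so the
asymptotic variance can be audited term by term.  With cell proportions
p_ij, marginals p_i. and p_.j, and agreement weights w_ij (identity
weights for the unweighted statistic, linear Cicchetti-Allison weights
w_ij = 1 - |i-j|/(C-1) for the weighted one):

    p_o = sum_ij w_ij p_ij          observed (weighted) agreement
    p_e = sum_ij w_ij p_i. p_.j     chance agreement
    kappa = (p_o - p_e) / (1 - p_e)

The non-null asymptotic variance (Fleiss, Cohen & Everitt, 1969), with
row/column weight averages wbar_i. = sum_j p_.j w_ij and
wbar_.j = sum_i p_i. w_ij, is

    n var = [ sum_ij p_ij (w_ij (1-p_e) - (wbar_i. + wbar_.j)(1-p_o))^2
              - (p_o p_e - 2 p_e + p_o)^2 ] / (1-p_e)^4

used for the 95% CI, and the null-hypothesis variance (kappa = 0)

    n var0 = [ sum_ij p_i. p_.j (w_ij - (wbar_i. + wbar_.j))^2 - p_e^2 ]
             / (1-p_e)^2

used for the z-test.  Identity weights reduce both to the standard
unweighted forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateAgreementError, DomainError, UndefinedCorrelationError

__all__ = [
    "AgreementResult",
    "RegressionResult",
    "pearson_r",
    "spearman_rho",
    "cohen_kappa",
    "interpret_kappa",
    "regress_pair",
    "confusion_matrix",
]

CLASS_ORDER = ("low", "medium", "high")


@dataclass
class AgreementResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_value: float  # z-test of H0: kappa = 0
    interpretation: str  # low / fair-good / high
    confusion: pd.DataFrame
    weighting: str  # none / linear / quadratic
    n: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    slope_ci95: tuple[float, float]
    slope_ci_contains_1: bool
    p_value: float
    n: int


def _check_vectors(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise DomainError(f"need n >= {min_n}, got {x.size}")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-approximation p-value."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Rank correlation using average (mid) ranks for ties, two-sided p."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def confusion_matrix(a, b, categories=CLASS_ORDER) -> pd.DataFrame:
    """Counts of ordered (a, b) label pairs with a fixed category order."""
    a = pd.Series(list(a))
    b = pd.Series(list(b))
    if len(a) != len(b):
        raise DomainError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    seen = set(a) | set(b)
    unknown = seen - set(categories)
    if unknown:
        raise DomainError(f"labels outside the category set {list(categories)}: {sorted(unknown)}")
    cat = pd.CategoricalDtype(categories=list(categories), ordered=True)
    m = pd.crosstab(a.astype(cat), b.astype(cat), dropna=False)
    return m.reindex(index=categories, columns=categories, fill_value=0)


def _weight_matrix(c: int, weighting: str) -> np.ndarray:
    i, j = np.indices((c, c))
    if weighting == "none":
        return (i == j).astype(float)
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (c - 1)
    if weighting == "quadratic":
        return 1.0 - ((i - j) / (c - 1)) ** 2
    raise DomainError(f"unknown weighting {weighting!r}")


def kappa_from_confusion(table: np.ndarray | pd.DataFrame, weighting: str = "none"):
    """(kappa, se, se0, n) from a square confusion matrix of counts."""
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DomainError(f"confusion matrix must be square, got {m.shape}")
    n = m.sum()
    if n < 2:
        raise DomainError("need at least 2 paired labels")
    c = m.shape[0]
    if c < 2:
        raise DomainError("need at least 2 categories")
    p = m / n
    pi = p.sum(axis=1)  # row marginals (rater a)
    pj = p.sum(axis=0)  # column marginals (rater b)
    w = _weight_matrix(c, weighting)
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if pe >= 1.0 - 1e-12:
        raise DegenerateAgreementError(
            "chance agreement is 1 (both raters constant on the same label); kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)

    wbar_i = w @ pj  # row-wise expected weight
    wbar_j = pi @ w  # column-wise expected weight
    cross = wbar_i[:, None] + wbar_j[None, :]
    # non-null variance (CI)
    term = (w * (1 - pe) - cross * (1 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    # null variance (z-test of kappa = 0)
    term0 = (w - cross) ** 2
    var0 = ((np.outer(pi, pj) * term0).sum() - pe**2) / (n * (1 - pe) ** 2)
    return float(kappa), float(np.sqrt(max(var, 0.0))), float(np.sqrt(max(var0, 0.0))), int(n)


def cohen_kappa(a, b, weighting: str = "none", categories=CLASS_ORDER) -> AgreementResult:
    """Chance-corrected agreement between two label vectors.

    ``weighting="none"`` is classical Cohen's kappa; ``"linear"`` gives
    partial credit for near-miss disagreements on the ordered scale.
    Returns the point estimate, asymptotic SE, 95% CI, and the z-test
    against kappa = 0.
    """
    confusion = confusion_matrix(a, b, categories)
    kappa, se, se0, n = kappa_from_confusion(confusion.to_numpy(), weighting)
    z = kappa / se0 if se0 > 0 else np.inf * np.sign(kappa)
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return AgreementResult(
        kappa=kappa,
        se=se,
        ci95=ci,
        p_value=p,
        interpretation=interpret_kappa(kappa),
        confusion=confusion,
        weighting=weighting,
        n=n,
    )


def interpret_kappa(kappa: float) -> str:
    """Agreement band: < 0.40 low, 0.40-0.75 fair-good (closed interval),
    > 0.75 high."""
    if kappa > 1:
        raise DomainError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0.40:
        return "low"
    if kappa <= 0.75:
        return "fair-good"
    return "high"


def regress_pair(x, y) -> RegressionResult:
    """Simple OLS of y on x with a t-based 95% CI on the slope and a flag
    for whether the CI contains 1 (regression-equivalence check)."""
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("slope undefined: x has zero variance")
    n = x.size
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        slope_ci95=(float(lo), float(hi)),
        slope_ci_contains_1=bool(lo <= 1.0 <= hi),
        p_value=float(res.pvalue),
        n=n,
    )
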