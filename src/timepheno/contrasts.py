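"""Phenotype-wise statistical contrasts of the tumor immune microenvironment.

Immune-cell fractions and per-sample features (TMB, mutation rates,
neoantigen counts, checkpoint-gene expression) are compared between
phenotype pairs with two-sided Mann-Whitney U tests, annotated with the
conventional star scheme.  Clinical category structure is tested with
chi-square (Fisher's exact on sparse 2x2 tables), and the CD8-CYT
relationship with Spearman's rank correlation.  No multiplicity correction
is applied across a panel by default; a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .phenotyping import LABELS, PhenotypeAssignment

logger = logging.getLogger(__name__)

#: strict upper p-value bounds for star annotations
STAR_THRESHOLDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (0.05, "*"),
)

EXACT_MAX_PRODUCT = 400  # exact Mann-Whitney when n1*n2 <= this and data are tie-free


class ContrastError(ValueError):
    pass


@dataclass
class ContrastResult:
    feature: str
    pair: tuple[str, str]
    statistic: float
    p_value: float
    n1: int
    n2: int
    annotation: str
    method: str


def star_annotation(p: float) -> str:
    """Map a p-value onto the star scheme (strict '<' at every boundary)."""
    if not 0 <= p <= 1:
        raise ContrastError(f"p-value outside [0, 1]: {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "NS"


def _mw_asymptotic_p(u1: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided normal approximation for U with tie-corrected variance,
    continuity correction and a fourth-cumulant Edgeworth refinement.

    The Edgeworth term (the null U distribution is symmetric, so the first
    correction involves only its excess kurtosis) shrinks the worst-case
    error against exact enumeration from ~1e-2 to ~5e-4 at group sizes
    around 10-20.
    """
    m, n = x.size, y.size
    big_n = m + n
    mu = m * n / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    var = m * n / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    g2 = -6 / 5 * (m * m + n * n + m * n + m + n) / (m * n * (big_n + 1))
    u_big = max(u1, m * n - u1)
    z = (u_big - 0.5 - mu) / sd
    sf = stats.norm.sf(z) + stats.norm.pdf(z) * g2 / 24 * (z**3 - 3 * z)
    return float(min(1.0, max(0.0, 2.0 * sf)))


def mann_whitney(
    x,
    y,
    feature: str = "",
    pair: tuple[str, str] = ("A", "B"),
    method: str = "auto",
) -> ContrastResult:
    """Two-sided Mann-Whitney U test between two groups.

    ``method='auto'`` uses exact null enumeration when n1*n2 <= 400 and the
    pooled data are tie-free, and the normal approximation (tie-corrected
    variance, continuity correction, Edgeworth kurtosis term) otherwise.
    Missing values are dropped before testing.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContrastError(f"empty group in contrast {feature!r} {pair}")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if method == "auto":
        method = "exact" if (x.size * y.size <= EXACT_MAX_PRODUCT and tie_free) else "asymptotic"
    if method == "exact":
        if not tie_free:
            raise ContrastError("exact enumeration is undefined under ties")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u1, p = float(res.statistic), float(min(res.pvalue, 1.0))
    elif method == "asymptotic":
        ranks = stats.rankdata(pooled)
        u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
        p = _mw_asymptotic_p(u1, x, y)
    else:
        raise ContrastError(f"unknown method {method!r}")
    return ContrastResult(
        feature=feature,
        pair=pair,
        statistic=u1,
        p_value=p,
        n1=int(x.size),
        n2=int(y.size),
        annotation=star_annotation(p),
        method=f"mann-whitney-{method}",
    )


def spearman(x, y) -> float:
    """Spearman's rank correlation (mid-rank Pearson on ranks).

    Pairwise-complete; returns NaN (flagged missing) when either vector is
    constant, where the coefficient is undefined.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 3:
        raise ContrastError("spearman needs n >= 3 pairwise-complete observations")
    if df["x"].nunique() == 1 or df["y"].nunique() == 1:
        return float("nan")
    return float(stats.spearmanr(df["x"], df["y"]).statistic)


def contingency_test(
    table, exclude_unknown: bool = True, unknown_label: str = "unknown"
) -> tuple[float, float, str]:
    """Test independence of a contingency table of counts.

    Chi-square by default; Fisher's exact when the table is 2x2 and any
    expected cell count is below 5.  If ``table`` is a labelled DataFrame and
    ``exclude_unknown`` is set, rows/columns labelled ``unknown`` are dropped
    before testing.  Returns (statistic, p, method).
    """
    if isinstance(table, pd.DataFrame):
        if exclude_unknown:
            table = table.loc[
                [r for r in table.index if str(r).lower() != unknown_label],
                [c for c in table.columns if str(c).lower() != unknown_label],
            ]
        counts = table.to_numpy()
    else:
        counts = np.asarray(table)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ContrastError("need a table with >= 2 rows and >= 2 columns after exclusion")
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.number):
        raise ContrastError("counts must be non-negative numbers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ContrastError("degenerate table: a row or column margin is zero")
    expected = stats.contingency.expected_freq(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        stat, p = stats.fisher_exact(counts, alternative="two-sided")
        return float(stat), float(p), "fisher-exact"
    chi2 = stats.chi2_contingency(counts, correction=False)
    return float(chi2.statistic), float(chi2.pvalue), "chi-square"


def contrast_panel(
    features: pd.DataFrame,
    assignment: PhenotypeAssignment,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney contrasts of every feature across all three phenotype pairs.

    ``features`` is samples x features (an ``ImmuneFractionTable.data`` or
    ``SampleFeatureTable.data``).  Features missing in a group (all-NaN) are
    skipped with a log entry.  Returns a tidy table; ``bh_correct`` adds a
    Benjamini-Hochberg column without changing the star annotations.
    """
    common = features.index.intersection(assignment.labels.index)
    if len(common) == 0:
        raise ContrastError("no samples shared between features and assignment")
    feats = features.loc[common]
    labels = assignment.labels.loc[common]
    rows = []
    for feature in feats.columns:
        for a, b in combinations(LABELS, 2):
            x = feats.loc[labels == a, feature].dropna()
            y = feats.loc[labels == b, feature].dropna()
            if x.empty or y.empty:
                logger.info("contrast_panel: skipping %r for pair (%s, %s): empty group", feature, a, b)
                continue
            rows.append(mann_whitney(x, y, feature=feature, pair=(a, b)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_correct and not out.empty:
        out["adjusted_p"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
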