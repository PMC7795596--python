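"""Cytolytic activity (CYT) scoring.

CYT is the per-sample geometric mean of GZMA and PRF1 expression in TPM — a
bulk-transcriptome proxy for the killing capacity of cytotoxic T and NK
cells.  RSEM estimated abundances are converted to TPM by renormalizing each
sample to proportions and multiplying by 1e6.

Microarray cohorts distributed as per-gene z-scores cannot feed a geometric
mean (values are signed), so a rank-based surrogate is provided: the mean of
the two genes' within-cohort fractional ranks.  It is invariant to any
per-gene monotone transform and preserves the cohort ordering that the
percentile-based phenotyping consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TPM_TOTAL, ExpressionMatrix

GZMA = "GZMA"
PRF1 = "PRF1"
DEFAULT_PSEUDOCOUNT = 0.01


class ScoringError(ValueError):
    pass


@dataclass
class CytScores:
    """Per-sample CYT values plus the provenance needed to interpret them."""

    values: pd.Series  # indexed by sample id, finite and >= 0
    pseudocount: float
    source_scale: str  # "tpm" or "rank_based"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ScoringError("CYT values must be finite and non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def rsem_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalize RSEM estimated abundances to TPM (columns sum to 1e6).

    The conversion is invariant to positive per-column rescaling, so
    unnormalized exports are accepted.
    """
    if expr.scale != "rsem":
        raise ScoringError(f"rsem_to_tpm expects scale='rsem', got {expr.scale!r}")
    values = expr.data.to_numpy(dtype=float)
    colsums = values.sum(axis=0)
    zero = colsums <= 0
    if zero.any():
        sample = expr.data.columns[int(np.argmax(zero))]
        raise ScoringError(f"sample {sample!r} has all-zero expression; cannot form TPM")
    tpm = values / colsums * TPM_TOTAL
    return ExpressionMatrix(pd.DataFrame(tpm, index=expr.data.index, columns=expr.data.columns), "tpm")


def _require_genes(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    for gene in (GZMA, PRF1):
        if gene not in expr.data.index:
            raise ScoringError(f"gene {gene!r} missing from the expression matrix")
    return expr.data.loc[GZMA].to_numpy(float), expr.data.loc[PRF1].to_numpy(float)


def cyt_score(expr: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> CytScores:
    """Geometric mean of GZMA and PRF1 TPM, with a small pseudocount.

    Computed in log space; a zero product (possible only at pseudocount 0)
    yields CYT = 0 exactly.
    """
    if expr.scale != "tpm":
        raise ScoringError(
            f"cyt_score is defined on TPM; got scale={expr.scale!r} "
            "(convert with rsem_to_tpm, or use rank_based_cyt for z-score/log2 data)"
        )
    if pseudocount < 0:
        raise ScoringError("pseudocount must be >= 0")
    gzma, prf1 = _require_genes(expr)
    a = gzma + pseudocount
    b = prf1 + pseudocount
    positive = (a > 0) & (b > 0)
    logs = 0.5 * (np.log(np.where(positive, a, 1.0)) + np.log(np.where(positive, b, 1.0)))
    cyt = np.where(positive, np.exp(logs), 0.0)
    return CytScores(pd.Series(cyt, index=expr.data.columns), pseudocount, "tpm")


def rank_based_cyt(expr: ExpressionMatrix) -> CytScores:
    """Rank surrogate for CYT on z-score or log2 cohorts.

    Per sample: the mean of GZMA's and PRF1's within-cohort fractional
    mid-ranks (rank / n), a value in (0, 1].  The sample ranking — the only
    thing percentile phenotyping uses — is unchanged by any strictly
    increasing per-gene transform.
    """
    if expr.scale not in ("zscore", "log2"):
        raise ScoringError(f"rank_based_cyt expects scale in ('zscore','log2'), got {expr.scale!r}")
    if expr.n_samples < 2:
        raise ScoringError("rank_based_cyt needs at least 2 samples")
    gzma, prf1 = _require_genes(expr)
    n = expr.n_samples
    frac = (stats.rankdata(gzma) + stats.rankdata(prf1)) / (2 * n)
    return CytScores(pd.Series(frac, index=expr.data.columns), 0.0, "rank_based")
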