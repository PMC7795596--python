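"""Two-group differential expression and volcano categorization.

Per gene: log2 fold change (difference of group means on a log-like scale),
Welch's t statistic with its two-sided p, and a Benjamini-Hochberg adjusted
p across all genes tested.  TPM input is transformed with log2(x + 1) first;
z-score and log2 cohorts are used as-is.  Genes with zero variance in both
groups have no defined t statistic: they are flagged, given p = 1 when the
means also agree, and excluded from the ranked list that feeds pre-ranked
GSEA.  The ranking metric is the t score (descending), ties broken
lexicographically by symbol.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05


class DgeError(ValueError):
    pass


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise DgeError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _log_like(expr: ExpressionMatrix) -> pd.DataFrame:
    if expr.scale in ("log2", "zscore"):
        return expr.data
    if expr.scale == "tpm":
        return np.log2(expr.data + 1.0)
    raise DgeError(
        f"differential expression needs a log-like scale; got {expr.scale!r} "
        "(convert rsem with scoring.rsem_to_tpm first)"
    )


def differential_expression(
    expr: ExpressionMatrix, labels: pd.Series, pair: tuple[str, str]
) -> pd.DataFrame:
    """Welch-t differential expression of ``pair[0]`` versus ``pair[1]``.

    Returns a gene-indexed DataFrame with columns ``log2_fold_change``,
    ``t_score``, ``p_value``, ``adjusted_p``, ``degenerate`` and
    ``volcano_class``.  Swapping the pair negates log2FC and t and leaves
    p-values unchanged.
    """
    a_label, b_label = pair
    labels = labels.loc[labels.index.intersection(expr.data.columns)]
    a_ids = labels.index[labels == a_label]
    b_ids = labels.index[labels == b_label]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise DgeError(f"both groups need >= 3 samples; got {len(a_ids)} vs {len(b_ids)} for {pair}")
    data = _log_like(expr)
    a = data.loc[:, a_ids].to_numpy(float)
    b = data.loc[:, b_ids].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mean_a - mean_b
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    # zero variance in both groups: t undefined; identical distributions get
    # the conventional (0, 1)
    equal_means = degenerate & (log2_fc == 0)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    if degenerate.any():
        logger.info("differential_expression: %d degenerate-variance genes flagged", int(degenerate.sum()))
    out = pd.DataFrame(
        {
            "log2_fold_change": log2_fc,
            "t_score": t,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=data.index,
    )
    ok = ~out["degenerate"]
    adjusted = np.full(len(out), np.nan)
    adjusted[ok.to_numpy()] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["adjusted_p"] = adjusted
    out["volcano_class"] = volcano_classify(out)
    return out


def volcano_classify(
    results: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_adjusted: bool = False,
) -> pd.Series:
    """Classify genes as up / down / ns at |FC| > ``fc_threshold`` (linear
    scale) and p < ``p_threshold``; ``use_adjusted`` switches the p column."""
    if fc_threshold <= 0:
        raise DgeError("fc_threshold must be positive (linear-scale fold change)")
    log_fc = math.log2(fc_threshold)
    p = results["adjusted_p"] if use_adjusted else results["p_value"]
    lfc = results["log2_fold_change"]
    cls = np.where(
        (lfc > log_fc) & (p < p_threshold),
        "up",
        np.where((lfc < -log_fc) & (p < p_threshold), "down", "ns"),
    )
    return pd.Series(cls, index=results.index, name="volcano_class")


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Ranked gene list (t score descending, alphabetical tie-break) for GSEA.

    Degenerate-variance genes are excluded.  Returns columns
    ``gene``, ``score``.
    """
    ok = results.loc[~results["degenerate"]]
    if ok.empty:
        raise DgeError("no genes left to rank")
    ties = ok["t_score"].duplicated(keep=False)
    if ties.any():
        logger.info("rank_genes: %d tied t-scores broken alphabetically", int(ties.sum()))
    ordered = ok.sort_index(kind="mergesort").sort_values(
        "t_score", ascending=False, kind="mergesort"
    )
    return pd.DataFrame({"gene": ordered.index, "score": ordered["t_score"].to_numpy()}).reset_index(
        drop=True
    )


def write_rnk(ranked: pd.DataFrame, path) -> None:
    """Write a GSEA ``.rnk`` file (gene TAB score, ranked)."""
    ranked.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


def read_rnk(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["gene"].duplicated().any():
        raise DgeError(f"{path}: duplicate genes in .rnk file")
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
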