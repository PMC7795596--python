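"""Pre-ranked gene-set enrichment analysis (GSEA), implemented from scratch.

Given a gene list ranked by a signed score (here: the Welch t score from the
differential-expression stage) and a collection of gene sets, the classic
weighted Kolmogorov-Smirnov running-sum statistic is computed per set:
walking down the ranking, membership hits increment the sum proportionally
to |score|^p (p = ``weight_exponent``, default 1) normalized by the set's
total weight, and misses decrement it by 1/(N - Nh).  The enrichment score
(ES) is the signed maximum deviation of this walk from zero, and the leading
edge is the run of member genes up to (for ES >= 0) or after (for ES < 0)
the extremum.

Significance uses a gene-set permutation null: ``n_perm`` uniformly random
same-size sets are scored against the same ranking.  NES divides ES by the
mean magnitude of same-sign null ES values; the nominal p is the same-sign
null tail fraction; the FDR q is the standard sign-stratified ratio of null
to observed NES tail fractions, clipped to [0, 1] and monotone-corrected so
a more extreme NES never carries a larger q.  With a fixed seed all outputs
are bit-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NES_THRESHOLD = 1.7
Q_THRESHOLD = 0.01
DEFAULT_N_PERM = 1000


class GseaError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_hits: int
    n_dropped: int = 0  # set members absent from the ranked list
    flags: tuple[str, ...] = field(default_factory=tuple)


def _validate_ranking(genes, scores) -> tuple[np.ndarray, np.ndarray]:
    genes = np.asarray(genes, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if genes.size != scores.size or genes.size == 0:
        raise GseaError("genes and scores must be equal-length and non-empty")
    if len(set(genes)) != genes.size:
        raise GseaError("ranked list contains duplicate genes")
    if not np.isfinite(scores).all():
        raise GseaError("scores must be finite")
    if (np.diff(scores) > 0).any():
        raise GseaError("scores must be sorted non-increasing")
    return genes, scores


def _signed_extremum(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Pick the deviation of larger magnitude; ties resolve positive."""
    return np.where(hi >= -lo, hi, lo)


def enrichment_score(
    genes, scores, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, full running sum, and leading edge for one gene set.

    ``genes``/``scores`` form the ranked list (scores non-increasing); only
    set members present in the list count as hits (absent members are simply
    ignored here; the driver logs them).
    """
    genes, scores = _validate_ranking(genes, scores)
    hit = np.isin(genes, list(gene_set))
    n, n_hits = genes.size, int(hit.sum())
    if n_hits == 0:
        raise GseaError("gene set has empty intersection with the ranked list")
    if n_hits == n:
        raise GseaError("gene set covers the whole ranked list; ES undefined")
    weights = np.abs(scores) ** weight_exponent
    total = weights[hit].sum()
    if total == 0:  # all member scores are exactly 0: fall back to equal weights
        weights = np.ones(n)
        total = float(n_hits)
    increments = np.where(hit, weights / total, -1.0 / (n - n_hits))
    running = np.cumsum(increments)
    hi, lo = running.max(), running.min()
    es = float(_signed_extremum(np.array(lo), np.array(hi)))
    if es >= 0:
        peak = int(np.argmax(running))
        leading = genes[: peak + 1][hit[: peak + 1]]
    else:
        peak = int(np.argmin(running))
        leading = genes[peak + 1 :][hit[peak + 1 :]]
    return es, running, tuple(leading)


def _es_batch(scores: np.ndarray, positions: np.ndarray, weight_exponent: float) -> np.ndarray:
    """ES for many same-size gene sets given by their (row-sorted) positions.

    The running sum is piecewise: it rises only at hits, so its extrema lie at
    hit positions (after the hit) and just before hits; evaluating those
    candidates reproduces the full walk's signed maximum deviation.
    """
    n = scores.size
    m, k = positions.shape
    w = np.abs(scores[positions]) ** weight_exponent
    cumw = np.cumsum(w, axis=1)
    total = cumw[:, -1][:, None]
    degenerate = total[:, 0] == 0
    if degenerate.any():
        idx = np.arange(1, k + 1, dtype=float)
        cumw = np.where(degenerate[:, None], idx, cumw)
        w = np.where(degenerate[:, None], 1.0, w)
        total = np.where(degenerate[:, None], float(k), total)
    miss = n - k
    ranks = np.arange(k)
    dev_at = cumw / total - (positions - ranks) / miss
    dev_before = (cumw - w) / total - (positions - ranks) / miss
    hi = dev_at.max(axis=1)
    lo = np.minimum(dev_before.min(axis=1), 0.0)
    return _signed_extremum(lo, hi)


def permutation_null(
    scores,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Null ES sample from uniformly random same-size gene sets."""
    scores = np.asarray(scores, dtype=float)
    if n_perm < 1:
        raise GseaError("n_perm must be >= 1")
    if not 1 <= set_size < scores.size:
        raise GseaError(f"set_size must lie in [1, {scores.size - 1}], got {set_size}")
    u = rng.random((n_perm, scores.size))
    positions = np.sort(np.argpartition(u, set_size - 1, axis=1)[:, :set_size], axis=1)
    return _es_batch(scores, positions, weight_exponent)


def _nes_one(es: float, nulls: np.ndarray) -> float:
    if es == 0:
        return 0.0
    same = nulls[nulls > 0] if es > 0 else nulls[nulls < 0]
    if same.size == 0:
        return float("nan")
    return float(es / np.abs(same).mean())


def normalize_and_fdr(
    observed: dict[str, float], nulls: dict[str, np.ndarray]
) -> pd.DataFrame:
    """NES, nominal p and FDR q for each set from its permutation null.

    Null ES are normalized per set by the same same-sign means as the
    observed ES, pooled across sets, and the q of each set is the ratio of
    the pooled-null to observed tail fractions on its own sign, clipped to
    [0, 1] and made monotone in |NES|.
    """
    names = list(observed)
    if set(names) - set(nulls):
        raise GseaError("every observed set needs a null sample")
    nes, p_nom, flags = {}, {}, {name: [] for name in names}
    pooled_null_nes = []
    for name in names:
        es, null = observed[name], np.asarray(nulls[name], float)
        pos, neg = null[null > 0], null[null < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        null_nes = np.concatenate(
            [pos / mean_pos if pos.size else pos, neg / mean_neg if neg.size else neg]
        )
        pooled_null_nes.append(null_nes)
        if es == 0:
            nes[name], p_nom[name] = 0.0, 1.0
            continue
        same = pos if es > 0 else neg
        if same.size == 0:
            nes[name] = np.nan
            p_nom[name] = 1.0 / (null.size + 1)
            flags[name].append("no-same-sign-null")
            continue
        nes[name] = es / np.abs(same).mean()
        p_nom[name] = float((np.abs(same) >= abs(es)).mean())
    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.array([])
    obs_nes = np.array([nes[name] for name in names], dtype=float)
    q = np.full(len(names), np.nan)
    pos_pool, neg_pool = pooled[pooled > 0], pooled[pooled < 0]
    obs_pos, obs_neg = obs_nes[obs_nes > 0], obs_nes[obs_nes < 0]
    for i, v in enumerate(obs_nes):
        if not np.isfinite(v):
            continue
        if v == 0:
            q[i] = 1.0
            continue
        if v > 0:
            null_tail = (pos_pool >= v).mean() if pos_pool.size else 0.0
            obs_tail = (obs_pos >= v).mean()
        else:
            null_tail = (neg_pool <= v).mean() if neg_pool.size else 0.0
            obs_tail = (obs_neg <= v).mean()
        q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    # monotone correction: a more extreme |NES| never has a larger q
    order = np.argsort(-np.abs(np.nan_to_num(obs_nes)))
    running = np.inf
    for i in order[::-1]:  # least extreme -> most extreme, take running min
        if np.isfinite(q[i]):
            running = min(running, q[i])
            q[i] = running
    return pd.DataFrame(
        {
            "set_name": names,
            "es": [observed[n] for n in names],
            "nes": obs_nes,
            "p_nominal": [p_nom[n] for n in names],
            "fdr_q": q,
            "flags": [";".join(flags[n]) for n in names],
        }
    )


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_sets: dict,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Run pre-ranked GSEA over a gene-set collection.

    ``ranked`` has columns ``gene`` and ``score`` sorted non-increasing (as
    produced by :func:`timepheno.dge.rank_genes` or read from a ``.rnk``
    file).  Sets are processed in collection order with a single seeded
    generator, so a fixed seed gives bit-identical results.  Sets whose
    intersection with the list is below ``min_size`` are reported with a
    ``skipped`` flag and NaN statistics.
    """
    if rng is None:
        if seed is None:
            raise GseaError("provide a seed (or an explicit rng) for the permutation null")
        rng = np.random.default_rng(seed)
    genes, scores = _validate_ranking(ranked["gene"].to_numpy(), ranked["score"].to_numpy(float))
    observed: dict[str, float] = {}
    nulls: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    skipped_rows = []
    for name, members in gene_sets.items():
        members = set(members)
        hits = members & set(genes)
        dropped = len(members) - len(hits)
        if dropped:
            logger.info("gsea: set %r: %d members absent from the ranked list", name, dropped)
        if len(hits) < min_size or len(hits) >= genes.size:
            skipped_rows.append(
                {
                    "set_name": name, "es": np.nan, "nes": np.nan, "p_nominal": np.nan,
                    "fdr_q": np.nan, "n_hits": len(hits), "n_dropped": dropped,
                    "leading_edge": "", "flags": "skipped",
                }
            )
            continue
        es, _, leading = enrichment_score(genes, scores, hits, weight_exponent)
        observed[name] = es
        nulls[name] = permutation_null(scores, len(hits), n_perm, rng, weight_exponent)
        meta[name] = {"n_hits": len(hits), "n_dropped": dropped, "leading_edge": ";".join(leading)}
    if observed:
        table = normalize_and_fdr(observed, nulls)
        for col in ("n_hits", "n_dropped", "leading_edge"):
            table[col] = [meta[n][col] for n in table["set_name"]]
    else:
        table = pd.DataFrame(
            columns=["set_name", "es", "nes", "p_nominal", "fdr_q", "flags",
                     "n_hits", "n_dropped", "leading_edge"]
        )
    if skipped_rows:
        table = pd.concat([table, pd.DataFrame(skipped_rows)], ignore_index=True)
    return table


def significant_sets(
    results: pd.DataFrame,
    nes_threshold: float = NES_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Filter to |NES| > ``nes_threshold`` and FDR q < ``q_threshold``."""
    keep = (results["nes"].abs() > nes_threshold) & (results["fdr_q"] < q_threshold)
    return results.loc[keep.fillna(False)]
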