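"""Immunofunctional phenotype calibration and assignment.

Samples are partitioned into three phenotypes from two per-sample quantities:
the CD8+ T-cell fraction (from immune deconvolution) and the cytolytic
activity score CYT:

* **HTI** (hot T-cell infiltrated): CYT above its cohort cutoff — high CYT
  alone defines the group, regardless of CD8;
* **CTI** (cold T-cell infiltrated): CD8 above its cutoff but CYT below;
* **NI** (non-inflamed): both below.

Cutoffs are empirical cohort quantiles: retaining the top ``x`` fraction
means cutting at quantile ``1 - x`` (linear interpolation between order
statistics) with a strict ``>`` membership test, so ties at the cutoff fall
below it.  Cutoffs are always calibrated on the cohort being classified,
never transferred between cohorts.  Realized top-fractions (strictly-above
counts / n) are returned for audit: on tie-free data they match the request
to within 1/n, while point masses (e.g. zero-inflated CD8 fractions) pull
them below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABELS = ("HTI", "CTI", "NI")

DEFAULT_CD8_TOP_FRACTION = 0.85
DEFAULT_CYT_TOP_FRACTION = 0.40  # TCGA-like; microarray z-score cohorts used 0.08


class PhenotypingError(ValueError):
    pass


@dataclass
class PhenotypeThresholds:
    cd8_top_fraction: float
    cyt_top_fraction: float
    cd8_cutoff_value: float
    cyt_cutoff_value: float

    def __post_init__(self) -> None:
        for name in ("cd8_top_fraction", "cyt_top_fraction"):
            f = getattr(self, name)
            if not 0 < f < 1:
                raise PhenotypingError(f"{name} must lie in (0, 1), got {f}")
        if not (np.isfinite(self.cd8_cutoff_value) and np.isfinite(self.cyt_cutoff_value)):
            raise PhenotypingError("cutoff values must be finite")


@dataclass
class PhenotypeAssignment:
    labels: pd.Series  # one of LABELS per sample
    thresholds: PhenotypeThresholds
    group_counts: dict[str, int] = field(default_factory=dict)
    realized_cd8_top_fraction: float | None = None
    realized_cyt_top_fraction: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise PhenotypingError(f"labels outside {LABELS}: {bad}")
        if not self.group_counts:
            self.group_counts = {lab: int((self.labels == lab).sum()) for lab in LABELS}
        if sum(self.group_counts.values()) != len(self.labels):
            raise PhenotypingError("group counts do not sum to n")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def percentile_cutoff(values, top_fraction: float) -> float:
    """Cutoff retaining the top ``top_fraction`` of a cohort.

    Linear-interpolation empirical quantile at probability
    ``1 - top_fraction``; membership downstream is strict ``>``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise PhenotypingError("need a 1-d vector with n >= 2")
    if not 0 < top_fraction < 1:
        raise PhenotypingError(f"top_fraction must lie in (0, 1), got {top_fraction}")
    if not np.isfinite(arr).all():
        raise PhenotypingError("values must be finite")
    if arr.max() == arr.min():
        warnings.warn(
            "constant vector: every value ties at the cutoff, so the strict '>' "
            "membership test selects zero samples",
            stacklevel=2,
        )
    return float(np.quantile(arr, 1.0 - top_fraction))


def classify_samples(cd8, cyt, thresholds: PhenotypeThresholds) -> PhenotypeAssignment:
    """Assign HTI / CTI / NI given fixed cutoffs (exhaustive and exclusive)."""
    cd8 = pd.Series(cd8) if not isinstance(cd8, pd.Series) else cd8
    cyt = pd.Series(cyt) if not isinstance(cyt, pd.Series) else cyt
    if len(cd8) != len(cyt) or not cd8.index.equals(cyt.index):
        raise PhenotypingError("cd8 and cyt vectors must be aligned to the same samples")
    hot = cyt.to_numpy() > thresholds.cyt_cutoff_value
    cold = ~hot & (cd8.to_numpy() > thresholds.cd8_cutoff_value)
    labels = np.where(hot, "HTI", np.where(cold, "CTI", "NI"))
    return PhenotypeAssignment(pd.Series(labels, index=cd8.index), thresholds)


def calibrate_and_classify(
    cd8,
    cyt,
    cd8_top_fraction: float = DEFAULT_CD8_TOP_FRACTION,
    cyt_top_fraction: float = DEFAULT_CYT_TOP_FRACTION,
) -> PhenotypeAssignment:
    """Calibrate both cutoffs on this cohort, classify, and audit.

    The realized top-fractions (strictly-above counts / n) are recorded so the
    effect of ties and point masses on the nominal percentile is inspectable.
    """
    cd8 = pd.Series(cd8) if not isinstance(cd8, pd.Series) else cd8
    cyt = pd.Series(cyt) if not isinstance(cyt, pd.Series) else cyt
    thresholds = PhenotypeThresholds(
        cd8_top_fraction=cd8_top_fraction,
        cyt_top_fraction=cyt_top_fraction,
        cd8_cutoff_value=percentile_cutoff(cd8.to_numpy(), cd8_top_fraction),
        cyt_cutoff_value=percentile_cutoff(cyt.to_numpy(), cyt_top_fraction),
    )
    assignment = classify_samples(cd8, cyt, thresholds)
    n = len(cd8)
    assignment.realized_cd8_top_fraction = float((cd8.to_numpy() > thresholds.cd8_cutoff_value).sum() / n)
    assignment.realized_cyt_top_fraction = float((cyt.to_numpy() > thresholds.cyt_cutoff_value).sum() / n)
    return assignment
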