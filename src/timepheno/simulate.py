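"""Synthetic-cohort generator with the statistical structure the pipeline assumes.

Each sample draws a latent phenotype (HTI / CTI / NI with TCGA-like
proportions 0.40 / 0.46 / 0.14), and all observables depend on it:

* a shared per-sample "immune activity" factor couples the CD8 fraction and
  the two cytolytic genes, giving the CD8-CYT rank correlation (target
  ~0.5) observed in bulk cohorts;
* the CD8 fraction is a zero-inflated Beta (the zero mass concentrates in
  non-inflamed samples), the remaining immune mass is spread over the other
  21 cell types by a Dirichlet draw;
* GZMA / PRF1 are lognormal on TPM with phenotype-ordered means
  (HTI > CTI >= NI), so the CYT score reproduces the intended ordering;
* background genes are lognormal on TPM (Gaussian in log2); planted gene
  sets are shifted by a configured log2 effect in their target phenotypes
  (an interferon-response-like set up in HTI, estrogen-response-like sets up
  in CTI and NI), and the GMT also carries unplanted random sets;
* survival is exponential with phenotype-specific hazards (default hazard
  ratio 0.5 for HTI vs NI) under an independent uniform censoring horizon;
* TMB / mutation-rate / neoantigen / checkpoint features are lognormal (or
  Poisson for counts) with a configurable HTI shift.

Everything is driven by one seeded generator: a fixed seed gives
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    TPM_TOTAL,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ImmuneFractionTable,
    SampleFeatureTable,
    write_clinical_table,
    write_expression_matrix,
    write_feature_table,
    write_fraction_table,
    write_gmt,
)
from .phenotyping import LABELS

OTHER_CELL_TYPES = (
    "B_naive", "B_memory", "Plasma", "CD4_naive", "CD4_memory_resting",
    "CD4_memory_activated", "Tfh", "Treg", "Tgd", "NK_resting", "NK_activated",
    "Monocytes", "M0", "M1", "M2", "DC_resting", "DC_activated",
    "Mast_resting", "Mast_activated", "Eosinophils", "Neutrophils",
)

FEATURE_COLUMNS = (
    "TMB", "non_silent_mutation_rate", "silent_mutation_rate",
    "snv_neoantigens", "indel_neoantigens",
    "HLA_A", "PD1", "PDL1", "PDL2", "IDO1",
)


class SimulationError(ValueError):
    pass


def _default_planted_sets() -> dict:
    return {
        "IFN_RESPONSE_LIKE": (("HTI",), 1.0),
        "ESTROGEN_RESPONSE_EARLY_LIKE": (("CTI", "NI"), 1.0),
        "ESTROGEN_RESPONSE_LATE_LIKE": (("CTI", "NI"), 1.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Proportions follow the TCGA-like phenotype split; hazard, effect-size and
    noise defaults are generator choices documented in the methods note, not
    estimates from any real cohort.
    """

    n_samples: int = 1000
    # (HTI, CTI, NI)
    phenotype_proportions: tuple[float, float, float] = (0.40, 0.46, 0.14)
    cd8_zero_mass: float = 0.15
    cd8_zero_scale: dict = field(default_factory=lambda: {"HTI": 0.1, "CTI": 0.2, "NI": 1.0})
    cd8_beta_params: dict = field(
        default_factory=lambda: {"HTI": (6.0, 14.0), "CTI": (5.0, 15.0), "NI": (1.5, 20.0)}
    )
    # per-phenotype (mean, sd) of log2 GZMA / log2 PRF1 TPM; means ordered HTI > CTI >= NI
    cyt_log2_params: dict = field(
        default_factory=lambda: {"HTI": (6.0, 0.8), "CTI": (3.5, 0.8), "NI": (3.0, 0.8)}
    )
    # loading of the shared immune-activity factor on log2 GZMA/PRF1 and on the
    # CD8 Beta quantile (calibrated once to a CD8-CYT Spearman of ~0.5)
    latent_coupling: float = 0.6
    cd8_coupling: float = 0.6
    n_genes: int = 2000
    planted_sets: dict = field(default_factory=_default_planted_sets)
    planted_set_size: int = 40
    n_background_sets: int = 20
    background_set_size: int = 40
    noise_sd_log2: float = 1.0
    # per-month exponential hazards; HTI vs NI hazard ratio 0.5 by default
    hazard_rates: dict = field(default_factory=lambda: {"HTI": 0.004, "CTI": 0.006, "NI": 0.008})
    pfs_hazard_multiplier: float = 1.5
    censoring_horizon_months: float = 180.0
    feature_shift_log2: float = 0.5  # HTI shift of TMB/neoantigen/checkpoint features
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.phenotype_proportions, float)
        if props.size != 3 or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise SimulationError("phenotype_proportions must be 3 non-negative values summing to 1")
        if not 0 <= self.cd8_zero_mass < 1:
            raise SimulationError("cd8_zero_mass must lie in [0, 1)")
        for name in ("hazard_rates", "cd8_beta_params", "cyt_log2_params", "cd8_zero_scale"):
            d = getattr(self, name)
            if set(d) != set(LABELS):
                raise SimulationError(f"{name} must have exactly the keys {LABELS}")
        if any(h < 0 for h in self.hazard_rates.values()):
            raise SimulationError("hazard rates must be >= 0")
        needed = self.planted_set_size * len(self.planted_sets)
        if self.n_genes < needed + self.background_set_size:
            raise SimulationError(
                f"n_genes={self.n_genes} too small for {len(self.planted_sets)} planted sets "
                f"of size {self.planted_set_size}"
            )


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # scale=tpm; includes GZMA and PRF1 rows
    fractions: ImmuneFractionTable
    clinical: ClinicalTable
    features: SampleFeatureTable
    true_labels: pd.Series
    gene_sets: GeneSetCollection
    config: SimulationConfig


def _per_label(d: dict, labels: np.ndarray, idx: int | None = None) -> np.ndarray:
    if idx is None:
        return np.array([d[lab] for lab in labels], float)
    return np.array([d[lab][idx] for lab in labels], float)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under ``config`` (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    labels = rng.choice(list(LABELS), size=n, p=config.phenotype_proportions)
    u = rng.standard_normal(n)  # shared immune-activity factor

    # --- cytolytic genes (log2 TPM, lognormal) ------------------------------
    c = config.latent_coupling
    mu = _per_label(config.cyt_log2_params, labels, 0)
    sd = _per_label(config.cyt_log2_params, labels, 1)
    resid = np.sqrt(max(0.0, 1.0 - c * c))
    log2_gzma = mu + sd * (c * u + resid * rng.standard_normal(n))
    log2_prf1 = mu + sd * (c * u + resid * rng.standard_normal(n))

    # --- immune fractions ----------------------------------------------------
    zero_mass = config.cd8_zero_mass * _per_label(config.cd8_zero_scale, labels)
    is_zero = rng.random(n) < zero_mass
    k = config.cd8_coupling
    quantile = stats.norm.cdf(k * u + np.sqrt(1 - k * k) * rng.standard_normal(n))
    alpha = _per_label(config.cd8_beta_params, labels, 0)
    beta = _per_label(config.cd8_beta_params, labels, 1)
    cd8 = np.where(is_zero, 0.0, stats.beta.ppf(quantile, alpha, beta))
    others = rng.dirichlet(np.full(len(OTHER_CELL_TYPES), 2.0), size=n) * (1 - cd8)[:, None]
    fraction_df = pd.DataFrame(others, index=sample_ids, columns=list(OTHER_CELL_TYPES))
    fraction_df.insert(3, "CD8T", cd8)

    # --- expression matrix (log2 -> TPM) ------------------------------------
    gene_names, set_members = [], {}
    for set_name in config.planted_sets:
        members = [f"{set_name}_{i:03d}" for i in range(1, config.planted_set_size + 1)]
        set_members[set_name] = members
        gene_names.extend(members)
    n_background = config.n_genes - len(gene_names)
    background = [f"BG_{i:05d}" for i in range(1, n_background + 1)]
    gene_names.extend(background)

    base = rng.uniform(2.0, 8.0, size=len(gene_names))
    log2_expr = base[:, None] + config.noise_sd_log2 * rng.standard_normal((len(gene_names), n))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for set_name, (targets, effect) in config.planted_sets.items():
        rows = [gene_index[g] for g in set_members[set_name]]
        in_target = np.isin(labels, list(targets))
        log2_expr[np.ix_(rows, np.where(in_target)[0])] += effect

    linear = np.vstack([2.0 ** log2_gzma, 2.0 ** log2_prf1, 2.0 ** log2_expr])
    linear = linear / linear.sum(axis=0) * TPM_TOTAL
    expr_df = pd.DataFrame(linear, index=["GZMA", "PRF1", *gene_names], columns=sample_ids)
    expression = ExpressionMatrix(expr_df, "tpm")

    # --- gene sets (planted + unplanted random background sets) -------------
    gene_sets: GeneSetCollection = {
        name: frozenset(members) for name, members in set_members.items()
    }
    for i in range(1, config.n_background_sets + 1):
        picks = rng.choice(background, size=min(config.background_set_size, len(background)), replace=False)
        gene_sets[f"RANDOM_SET_{i:02d}"] = frozenset(picks)

    # --- clinical table with survival ----------------------------------------
    hazards = _per_label(config.hazard_rates, labels)
    clinical_df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clinical_df["age_years"] = np.clip(rng.normal(58, 12, n).round(1), 25, 90)
    er_pos = {"HTI": 0.67, "CTI": 0.81, "NI": 0.69}
    pgr_pos = {"HTI": 0.60, "CTI": 0.68, "NI": 0.62}
    her2_pos = {"HTI": 0.16, "CTI": 0.18, "NI": 0.15}
    def status(prob_pos: dict, p_unknown: float) -> np.ndarray:
        p = _per_label(prob_pos, labels)
        draw = rng.random(n)
        out = np.where(draw < p, "positive", "negative")
        return np.where(rng.random(n) < p_unknown, "unknown", out)
    clinical_df["er_status"] = status(er_pos, 0.04)
    clinical_df["pgr_status"] = status(pgr_pos, 0.04)
    clinical_df["her2_status"] = status(her2_pos, 0.10)
    clinical_df["grade"] = rng.choice(["1", "2", "3"], size=n, p=(0.15, 0.40, 0.45))
    clinical_df["stage"] = rng.choice(["I/II", "III/IV", "unknown"], size=n, p=(0.72, 0.25, 0.03))
    clinical_df["histology"] = rng.choice(
        ["ductal", "lobular", "other"], size=n, p=(0.72, 0.18, 0.10)
    )
    for endpoint, mult in (("OS", 1.0), ("PFS", config.pfs_hazard_multiplier)):
        h = hazards * mult
        event_time = np.where(h > 0, rng.exponential(1.0, n) / np.where(h > 0, h, 1.0), np.inf)
        censor_time = rng.uniform(0, config.censoring_horizon_months, n)
        clinical_df[f"{endpoint}_months"] = np.minimum(event_time, censor_time).round(2)
        clinical_df[f"{endpoint}_event"] = (event_time <= censor_time).astype(int)
    recurred = clinical_df["PFS_event"] == 1
    rec_kind = np.where(rng.random(n) < 0.7, "distant", "local")
    clinical_df["recurrence_type"] = np.where(recurred, rec_kind, "none")
    clinical = ClinicalTable(clinical_df)

    # --- per-sample features --------------------------------------------------
    shift = np.where(labels == "HTI", config.feature_shift_log2, 0.0)
    feat = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    feat["TMB"] = 2.0 ** (rng.normal(0.5, 0.8, n) + shift)
    feat["non_silent_mutation_rate"] = 2.0 ** (rng.normal(0.3, 0.8, n) + shift)
    feat["silent_mutation_rate"] = 2.0 ** (rng.normal(-0.7, 0.8, n) + shift)
    feat["snv_neoantigens"] = rng.poisson(2.0 ** (rng.normal(4.0, 0.8, n) + shift)).astype(float)
    feat["indel_neoantigens"] = rng.poisson(2.0 ** (rng.normal(1.5, 0.8, n) + shift)).astype(float)
    for col in ("HLA_A", "PD1", "PDL1", "PDL2", "IDO1"):
        feat[col] = 2.0 ** (rng.normal(5.0, 1.0, n) + shift)
    features = SampleFeatureTable(feat)

    return SyntheticCohort(
        expression=expression,
        fractions=ImmuneFractionTable(fraction_df),
        clinical=clinical,
        features=features,
        true_labels=pd.Series(labels, index=sample_ids, name="phenotype"),
        gene_sets=gene_sets,
        config=config,
    )


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with every phenotype effect removed.

    Labels are still drawn, but expression, fractions, features and hazards no
    longer depend on them — the calibration regime for type-I-error checks.
    """
    shared_cd8 = config.cd8_beta_params["CTI"]
    shared_cyt = config.cyt_log2_params["CTI"]
    mean_hazard = float(np.mean(list(config.hazard_rates.values())))
    return dataclasses.replace(
        config,
        cd8_zero_scale={lab: 1.0 for lab in LABELS},
        cd8_beta_params={lab: shared_cd8 for lab in LABELS},
        cyt_log2_params={lab: shared_cyt for lab in LABELS},
        planted_sets={
            name: (targets, 0.0) for name, (targets, _) in config.planted_sets.items()
        },
        hazard_rates={lab: mean_hazard for lab in LABELS},
        feature_shift_log2=0.0,
    )


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort with no label effect anywhere (see :func:`null_config`)."""
    return simulate_cohort(null_config(config))


def separable_config(n_samples: int = 1000, seed: int = 0) -> SimulationConfig:
    """Noiseless-separation conditions: disjoint CYT and CD8 supports per label.

    With cutoff fractions taken from the realized label counts,
    ``calibrate_and_classify`` recovers the true labels exactly.
    """
    return SimulationConfig(
        n_samples=n_samples,
        cd8_zero_mass=0.0,
        # tight Beta supports: NI mean ~0.048, CTI ~0.33, HTI ~0.50 with
        # negligible overlap at these concentrations
        cd8_beta_params={"HTI": (5000.0, 5000.0), "CTI": (3300.0, 6700.0), "NI": (480.0, 9520.0)},
        cyt_log2_params={"HTI": (12.0, 0.01), "CTI": (4.0, 0.01), "NI": (3.0, 0.01)},
        latent_coupling=0.0,
        cd8_coupling=0.0,
        seed=seed,
    )


def worked_fixture() -> SyntheticCohort:
    """Tiny deterministic cohort (12 samples, 30 genes) for hand checks.

    GZMA/PRF1 TPM pairs are perfect-square products, so CYT at pseudocount 0
    is an integer geometric mean; with cutoff fractions (cd8_top=0.5,
    cyt_top=0.25) the classification is 3 HTI (S03, S11, S12), 4 CTI
    (S07-S10) and 5 NI.  A 5-gene planted set (``PSET``) is elevated in the
    HTI samples.  No randomness: byte-stable across runs.
    """
    sample_ids = [f"S{i:02d}" for i in range(1, 13)]
    gzma = np.array([1, 4, 400, 1, 4, 9, 4, 16, 9, 16, 2500, 900], float)
    prf1 = np.array([4, 9, 900, 9, 16, 16, 25, 25, 25, 36, 400, 1600], float)
    cd8 = np.arange(1, 13) / 20.0  # 0.05 .. 0.60
    true = np.array(
        ["NI", "NI", "HTI", "NI", "NI", "NI", "CTI", "CTI", "CTI", "CTI", "HTI", "HTI"]
    )

    pset_genes = [f"PSET_{c}" for c in "ABCDE"]
    is_hti = true == "HTI"
    rows = {"GZMA": gzma, "PRF1": prf1}
    jitter = np.arange(12) * 0.5  # deterministic within-group spread
    for j, g in enumerate(pset_genes):
        rows[g] = np.where(is_hti, 100.0 + 10 * j, 10.0 + j) + jitter
    for k in range(1, 23):
        rows[f"BG{k:02d}"] = 40.0 + k + np.arange(12)
    filler = TPM_TOTAL - np.sum(list(rows.values()), axis=0)
    rows["FILLER"] = filler
    expr = ExpressionMatrix(pd.DataFrame(rows, index=sample_ids).T, "tpm")

    others = np.repeat(((1 - cd8) / len(OTHER_CELL_TYPES))[:, None], len(OTHER_CELL_TYPES), axis=1)
    fr = pd.DataFrame(others, index=sample_ids, columns=list(OTHER_CELL_TYPES))
    fr.insert(3, "CD8T", cd8)

    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clin["age_years"] = np.linspace(40, 73, 12).round(0)
    clin["er_status"] = ["positive", "negative"] * 6
    clin["pgr_status"] = ["positive"] * 6 + ["negative"] * 6
    clin["her2_status"] = ["negative"] * 10 + ["positive"] * 2
    clin["OS_months"] = np.arange(12, 132, 10).astype(float)
    clin["OS_event"] = [1, 0] * 6
    feats = pd.DataFrame(
        {"TMB": np.linspace(0.5, 6.0, 12)}, index=pd.Index(sample_ids, name="sample_id")
    )
    return SyntheticCohort(
        expression=expr,
        fractions=ImmuneFractionTable(fr),
        clinical=ClinicalTable(clin),
        features=SampleFeatureTable(feats),
        true_labels=pd.Series(true, index=sample_ids, name="phenotype"),
        gene_sets={"PSET": frozenset(pset_genes)},
        config=SimulationConfig(n_samples=12, seed=0),
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write the five tables plus GMT and a manifest (config, seed, checksums)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort.expression, out / "expression.tsv")
    write_fraction_table(cohort.fractions, out / "fractions.tsv")
    write_clinical_table(cohort.clinical, out / "clinical.tsv")
    write_feature_table(cohort.features, out / "features.tsv")
    write_gmt(cohort.gene_sets, out / "gene_sets.gmt")
    cohort.true_labels.to_frame().to_csv(out / "true_labels.tsv", sep="\t", index_label="sample_id")
    files = ["expression.tsv", "fractions.tsv", "clinical.tsv", "features.tsv",
             "gene_sets.gmt", "true_labels.tsv"]
    manifest = {
        "config": dataclasses.asdict(cohort.config),
        "seed": cohort.config.seed,
        "checksums": {
            f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
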