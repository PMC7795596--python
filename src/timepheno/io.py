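"""Reading, validation and alignment of cohort input tables.

Five table kinds feed the pipeline: a gene-by-sample expression matrix
(cBioPortal ``data_mrna`` dialect: ``Hugo_Symbol`` first column, optional
``Entrez_Gene_Id`` ignored), a 22-cell-type immune-fraction table
(CIBERSORT-style relative fractions), a clinical table with receptor status
and survival endpoints, a per-sample numeric feature table (TMB, neoantigen
counts, checkpoint-gene expression), and a GMT gene-set collection.

All tables are tab-delimited text.  Parsed tables are wrapped in small
dataclasses that validate the invariants the downstream modules rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_SCALES = ("rsem", "tpm", "log2", "zscore")
TPM_TOTAL = 1e6
#: canonical name of the CD8 T-cell column after cell-type canonicalization
CD8_COLUMN = "CD8T"

STATUS_LEVELS = ("negative", "positive", "unknown")
RECURRENCE_LEVELS = ("distant", "local", "none", "unknown")
ENDPOINTS = ("OS", "PFS", "BCSS", "RFS_distant", "RFS_local")


class CohortIOError(ValueError):
    """Raised when an input table violates its format or invariants."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise CohortIOError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a declared scale.

    ``data`` is a genes x samples DataFrame; ``scale`` is one of
    ``rsem`` (non-negative estimated abundances), ``tpm`` (columns sum to
    1e6), ``log2`` or ``zscore``.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise CohortIOError(
                f"unknown expression scale {self.scale!r}; expected one of {EXPRESSION_SCALES}"
            )
        if self.data.size == 0:
            raise CohortIOError("empty expression matrix")
        _check_unique(self.data.index, "gene symbols")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise CohortIOError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale in ("rsem", "tpm") and (values < 0).any():
            raise CohortIOError(f"negative values are invalid on scale={self.scale}")
        if self.scale == "tpm":
            sums = values.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                worst = self.data.columns[int(np.argmax(np.abs(sums - TPM_TOTAL)))]
                raise CohortIOError(
                    f"TPM columns must sum to 1e6; sample {worst!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - TPM_TOTAL))]:.6g}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)


@dataclass
class CollapseReport:
    """Audit of duplicate-gene collapsing performed while reading."""

    collapsed_symbols: dict[str, int] = field(default_factory=dict)
    n_rows_in: int = 0
    n_rows_out: int = 0


@dataclass
class ImmuneFractionTable:
    """Per-sample relative fractions over 22 immune cell types (rows sum to 1)."""

    data: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise CohortIOError("empty fraction table")
        _check_unique(self.data.index, "sample ids")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise CohortIOError("non-finite immune fraction")
        if (values < 0).any() or (values > 1).any():
            raise CohortIOError("immune fractions must lie in [0, 1]")
        sums = values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-3):
            worst = self.data.index[int(np.argmax(np.abs(sums - 1)))]
            raise CohortIOError(
                f"fraction rows must sum to 1 (relative-fraction mode); "
                f"sample {worst!r} sums to {sums[np.argmax(np.abs(sums - 1))]:.4f}"
            )
        if CD8_COLUMN not in self.data.columns:
            raise CohortIOError(
                f"no {CD8_COLUMN!r} column after canonicalization; "
                f"columns: {list(self.data.columns)[:6]}..."
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cd8(self) -> pd.Series:
        return self.data[CD8_COLUMN]

    def subset_samples(self, sample_ids) -> "ImmuneFractionTable":
        return ImmuneFractionTable(self.data.loc[list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations and survival endpoints.

    Receptor statuses are closed enums {negative, positive, unknown}; blank or
    unrecognized entries are mapped to ``unknown`` rather than dropped, because
    contingency analyses exclude them explicitly per analysis.  Endpoints are
    stored as paired ``<endpoint>_months`` / ``<endpoint>_event`` columns.
    """

    data: pd.DataFrame  # samples x clinical columns

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        for col in ("er_status", "pgr_status", "her2_status"):
            if col in self.data.columns:
                bad = set(self.data[col].dropna()) - set(STATUS_LEVELS)
                if bad:
                    raise CohortIOError(f"{col} has values outside {STATUS_LEVELS}: {bad}")
        for ep in self.endpoints:
            t = self.data[f"{ep}_months"]
            e = self.data[f"{ep}_event"]
            if (t.dropna() < 0).any():
                raise CohortIOError(f"negative {ep} time")
            if not set(e.dropna().unique()) <= {0, 1}:
                raise CohortIOError(f"{ep} event flags must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def endpoints(self) -> list[str]:
        return [
            ep
            for ep in ENDPOINTS
            if f"{ep}_months" in self.data.columns and f"{ep}_event" in self.data.columns
        ]

    def endpoint_records(self, endpoint: str) -> pd.DataFrame:
        """Complete-case (time, event) records for one endpoint."""
        if endpoint not in self.endpoints:
            raise CohortIOError(f"endpoint {endpoint!r} not present; have {self.endpoints}")
        df = self.data[[f"{endpoint}_months", f"{endpoint}_event"]].dropna()
        df.columns = ["time_months", "event"]
        return df.astype({"event": int})

    def subset_samples(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass
class SampleFeatureTable:
    """Per-sample numeric features (TMB, mutation rates, neoantigen counts,
    checkpoint-gene expression).  Missing values stay as NaN, never dropped."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        non_numeric = [c for c in self.data.columns if not pd.api.types.is_numeric_dtype(self.data[c])]
        if non_numeric:
            raise CohortIOError(f"non-numeric feature columns: {non_numeric}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, sample_ids) -> "SampleFeatureTable":
        return SampleFeatureTable(self.data.loc[list(sample_ids)])


GeneSetCollection = dict[str, frozenset]


def _load_cell_type_map() -> dict[str, str]:
    with resources.files("timepheno.data").joinpath("cell_types.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["source_name"], df["canonical_name"]))


def canonicalize_cell_types(columns) -> list[str]:
    """Map CIBERSORT-style cell-type names onto canonical short names.

    Unrecognized names pass through unchanged so that already-canonical
    tables round-trip.
    """
    mapping = _load_cell_type_map()
    return [mapping.get(c, c) for c in columns]


def read_expression_matrix(path, scale: str) -> tuple[ExpressionMatrix, CollapseReport]:
    """Read a tab-delimited gene x sample matrix.

    First column holds gene symbols (``Hugo_Symbol``); an optional
    ``Entrez_Gene_Id`` column is ignored.  Duplicate gene symbols are
    collapsed to the row with maximal variance across samples, and the
    collapse is reported alongside the matrix.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise CohortIOError(f"{path}: empty expression matrix")
    gene_col = df.columns[0]
    genes = df[gene_col]
    df = df.drop(columns=[gene_col])
    if df.columns[0] == "Entrez_Gene_Id":
        df = df.drop(columns=["Entrez_Gene_Id"])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortIOError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {genes.iat[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise CohortIOError(
            f"{path}: missing value at gene {genes.iat[r]!r}, sample {df.columns[c]!r}"
        )
    numeric.index = genes.values
    report = CollapseReport(n_rows_in=len(numeric))
    if genes.duplicated().any():
        audit = pd.DataFrame(
            {"sym": genes.to_numpy(), "var": numeric.var(axis=1, ddof=0).to_numpy()}
        )
        keep_pos = audit.groupby("sym", sort=False)["var"].idxmax()
        for sym, count in genes.value_counts()[lambda s: s > 1].items():
            report.collapsed_symbols[sym] = int(count)
        numeric = numeric.iloc[np.sort(keep_pos.to_numpy())]
        logger.info("collapsed %d duplicated gene symbols", len(report.collapsed_symbols))
    report.n_rows_out = len(numeric)
    return ExpressionMatrix(numeric, scale), report


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    out = expr.data.copy()
    out.insert(0, "Hugo_Symbol", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, tab-separated symbols."""
    collection: GeneSetCollection = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CohortIOError(f"{path}: empty GMT file")
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise CohortIOError(f"{path}: line {i} has {len(fields)} fields; need name, description, >=1 gene")
        name = fields[0]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise CohortIOError(f"{path}: line {i} ({name!r}) lists no genes")
        if name in collection:
            raise CohortIOError(f"{path}: duplicate gene-set name {name!r} at line {i}")
        collection[name] = genes
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_fraction_table(path) -> ImmuneFractionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = canonicalize_cell_types(df.columns)
    return ImmuneFractionTable(df)


def write_fraction_table(table: ImmuneFractionTable, path) -> None:
    table.data.to_csv(path, sep="\t", float_format="%.10g")


_STATUS_SYNONYMS = {
    "positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "0": "negative",
}


def _normalize_status(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    return s.map(_STATUS_SYNONYMS).fillna("unknown")


def read_clinical_table(path, column_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read a tab-delimited clinical table.

    ``column_map`` renames source columns onto the canonical schema
    (``sample_id``, ``age_years``, ``er_status``, ``pgr_status``,
    ``her2_status``, ``grade``, ``stage``, ``histology``,
    ``recurrence_type``, ``<EP>_months``/``<EP>_event``).
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    if "sample_id" not in df.columns:
        raise CohortIOError(f"{path}: no sample_id column (use column_map to rename)")
    df = df.set_index("sample_id")
    for col in ("er_status", "pgr_status", "her2_status"):
        if col in df.columns:
            df[col] = _normalize_status(df[col])
    if "recurrence_type" in df.columns:
        rec = df["recurrence_type"].astype(str).str.strip().str.lower()
        df["recurrence_type"] = rec.where(rec.isin(RECURRENCE_LEVELS), "unknown")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_feature_table(path, column_map: dict[str, str] | None = None) -> SampleFeatureTable:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    if "sample_id" not in df.columns:
        raise CohortIOError(f"{path}: no sample_id column")
    df = df.set_index("sample_id")
    df = df.apply(pd.to_numeric, errors="coerce")
    return SampleFeatureTable(df)


def write_feature_table(table: SampleFeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


@dataclass
class AlignedCohort:
    """Tables restricted to the sample-id intersection, in one shared order."""

    sample_ids: list[str]
    expression: ExpressionMatrix | None = None
    fractions: ImmuneFractionTable | None = None
    clinical: ClinicalTable | None = None
    features: SampleFeatureTable | None = None
    drop_log: dict[str, int] = field(default_factory=dict)


def align_cohort(
    expression: ExpressionMatrix | None = None,
    fractions: ImmuneFractionTable | None = None,
    clinical: ClinicalTable | None = None,
    features: SampleFeatureTable | None = None,
) -> AlignedCohort:
    """Restrict all supplied tables to their common samples, in a shared order.

    The shared order is the expression matrix's sample order restricted to the
    intersection (or the first supplied table's order if expression is absent),
    which makes the operation idempotent.
    """
    tables = {
        "expression": expression,
        "fractions": fractions,
        "clinical": clinical,
        "features": features,
    }
    present = {k: v for k, v in tables.items() if v is not None}
    if not present:
        raise CohortIOError("align_cohort needs at least one table")
    id_sets = {k: set(v.sample_ids) for k, v in present.items()}
    common = set.intersection(*id_sets.values())
    if not common:
        raise CohortIOError("no sample ids shared by all supplied tables")
    first = next(iter(present.values()))
    order = [s for s in first.sample_ids if s in common]
    drop_log = {k: len(ids) - len(common) for k, ids in id_sets.items() if len(ids) > len(common)}
    for name, n in drop_log.items():
        logger.info("align_cohort: dropped %d samples from %s", n, name)
    return AlignedCohort(
        sample_ids=order,
        expression=expression.subset_samples(order) if expression is not None else None,
        fractions=fractions.subset_samples(order) if fractions is not None else None,
        clinical=clinical.subset_samples(order) if clinical is not None else None,
        features=features.subset_samples(order) if features is not None else None,
        drop_log=drop_log,
    )
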