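"""End-to-end orchestration from a single structured (YAML) config.

Stages: read + align inputs -> CYT scoring -> phenotype calibration ->
immune-microenvironment contrasts -> differential expression (+ ``.rnk``)
per configured pair -> pre-ranked GSEA -> survival panel.  Every output
table is tab-delimited; the run manifest records the full config, its hash
and the seed, which together suffice to re-execute the run.  Stochastic
stages (the GSEA permutation null) are bit-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import contrasts, dge, gsea, io, phenotyping, scoring, survival

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


DEFAULTS = {
    "scoring": {"pseudocount": scoring.DEFAULT_PSEUDOCOUNT},
    "phenotyping": {
        "cd8_top_fraction": phenotyping.DEFAULT_CD8_TOP_FRACTION,
        "cyt_top_fraction": phenotyping.DEFAULT_CYT_TOP_FRACTION,
    },
    "dge": {"pairs": [["HTI", "NI"], ["HTI", "CTI"], ["CTI", "NI"]]},
    "gsea": {
        "enabled": True,
        "n_perm": gsea.DEFAULT_N_PERM,
        "nes_threshold": gsea.NES_THRESHOLD,
        "q_threshold": gsea.Q_THRESHOLD,
    },
    "survival": {"endpoints": None},
}


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    return config


def _merged(config: dict) -> dict:
    out = {k: dict(v) for k, v in DEFAULTS.items()}
    for key, value in config.items():
        if key in out and isinstance(value, dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> dict:
    """Check paths, fractions and seed requirements before any compute."""
    cfg = _merged(config)
    inputs = cfg.get("inputs") or {}
    if "expression" not in inputs or "scale" not in inputs:
        raise PipelineError("config needs inputs.expression and inputs.scale")
    for key in ("expression", "fractions", "clinical", "features", "gene_sets"):
        path = inputs.get(key)
        if path is not None and not Path(path).exists():
            raise PipelineError(f"inputs.{key}: file not found: {path}")
    for key in ("cd8_top_fraction", "cyt_top_fraction"):
        f = cfg["phenotyping"][key]
        if not 0 < f < 1:
            raise PipelineError(f"phenotyping.{key} must lie in (0, 1)")
    if cfg["gsea"].get("enabled", True) and inputs.get("gene_sets"):
        if cfg["gsea"].get("seed") is None:
            raise PipelineError("gsea.seed is mandatory when the GSEA stage runs")
    if "output_dir" not in cfg:
        raise PipelineError("config needs output_dir")
    return cfg


def run_pipeline(config: dict) -> Path:
    """Execute all configured stages; returns the output directory.

    Aborts with the failing stage's name; outputs written so far are listed
    in ``partial_manifest.json``.
    """
    cfg = validate_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "setup"

    def emit(name: str) -> Path:
        written.append(name)
        return out / name

    try:
        stage = "cohort_io"
        inputs = cfg["inputs"]
        expr, collapse = io.read_expression_matrix(inputs["expression"], inputs["scale"])
        fractions = io.read_fraction_table(inputs["fractions"]) if inputs.get("fractions") else None
        clinical = (
            io.read_clinical_table(inputs["clinical"], inputs.get("clinical_column_map"))
            if inputs.get("clinical") else None
        )
        features = (
            io.read_feature_table(inputs["features"], inputs.get("feature_column_map"))
            if inputs.get("features") else None
        )
        gene_sets = io.read_gmt(inputs["gene_sets"]) if inputs.get("gene_sets") else None
        cohort = io.align_cohort(expr, fractions, clinical, features)
        expr = cohort.expression

        stage = "scoring"
        if expr.scale == "rsem":
            expr = scoring.rsem_to_tpm(expr)
        if expr.scale == "tpm":
            cyt = scoring.cyt_score(expr, cfg["scoring"]["pseudocount"])
        else:
            cyt = scoring.rank_based_cyt(expr)
        cyt.values.rename("cyt").to_frame().to_csv(
            emit("cyt_scores.tsv"), sep="\t", index_label="sample_id"
        )

        stage = "phenotyping"
        if cohort.fractions is None:
            raise PipelineError("phenotyping needs an immune-fraction table")
        assignment = phenotyping.calibrate_and_classify(
            cohort.fractions.cd8,
            cyt.values,
            cfg["phenotyping"]["cd8_top_fraction"],
            cfg["phenotyping"]["cyt_top_fraction"],
        )
        pheno_table = assignment.labels.rename("phenotype").to_frame()
        pheno_table["cd8"] = cohort.fractions.cd8
        pheno_table["cyt"] = cyt.values
        pheno_table.to_csv(emit("phenotypes.tsv"), sep="\t", index_label="sample_id")
        with open(emit("phenotype_audit.json"), "w") as fh:
            json.dump(
                {
                    "thresholds": dataclasses.asdict(assignment.thresholds),
                    "group_counts": assignment.group_counts,
                    "realized_cd8_top_fraction": assignment.realized_cd8_top_fraction,
                    "realized_cyt_top_fraction": assignment.realized_cyt_top_fraction,
                    "collapsed_gene_symbols": collapse.collapsed_symbols,
                },
                fh, indent=2,
            )

        stage = "time_contrasts"
        if cohort.fractions is not None:
            contrasts.contrast_panel(cohort.fractions.data, assignment).to_csv(
                emit("contrasts_fractions.tsv"), sep="\t", index=False
            )
        if cohort.features is not None:
            contrasts.contrast_panel(cohort.features.data, assignment).to_csv(
                emit("contrasts_features.tsv"), sep="\t", index=False
            )

        stage = "dge"
        rankings = {}
        for a, b in cfg["dge"]["pairs"]:
            results = dge.differential_expression(expr, assignment.labels, (a, b))
            tag = f"{a}_vs_{b}"
            results.to_csv(emit(f"dge_{tag}.tsv"), sep="\t", index_label="gene")
            ranked = dge.rank_genes(results)
            dge.write_rnk(ranked, emit(f"dge_{tag}.rnk"))
            rankings[tag] = ranked

        stage = "gsea"
        if gene_sets is not None and cfg["gsea"].get("enabled", True):
            for tag, ranked in rankings.items():
                table = gsea.gsea_preranked(
                    ranked, gene_sets,
                    n_perm=cfg["gsea"]["n_perm"],
                    seed=cfg["gsea"]["seed"],
                )
                table.to_csv(emit(f"gsea_{tag}.tsv"), sep="\t", index=False)

        stage = "survival"
        if cohort.clinical is not None and cohort.clinical.endpoints:
            panel = survival.survival_panel(
                cohort.clinical, assignment, endpoints=cfg["survival"]["endpoints"]
            )
            panel.to_csv(emit("survival_panel.tsv"), sep="\t", index=False)

        stage = "manifest"
        config_blob = json.dumps(cfg, sort_keys=True, default=str)
        with open(emit("run_manifest.json"), "w") as fh:
            json.dump(
                {
                    "config": cfg,
                    "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
                    "seed": cfg["gsea"].get("seed"),
                    "outputs": written,
                    "aligned_samples": len(cohort.sample_ids),
                    "drop_log": cohort.drop_log,
                },
                fh, indent=2,
            )
    except Exception as exc:
        with open(out / "partial_manifest.json", "w") as fh:
            json.dump({"failed_stage": stage, "error": str(exc), "outputs": written}, fh, indent=2)
        raise PipelineError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
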