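"""End-to-end orchestration of the radiogenomics analysis.

Sequences the stages — synthetic cohort (or supplied feature/count
tables) -> multi-view fusion subtyping -> PRF cascade -> differential
expression and co-expression modules -> pathway-feature association
network -> expression classifier -> external validation — writing each
stage's outputs plus a manifest into a run directory.  A single global
seed fans out to per-stage seeds by stable hashing of stage names, so
stage RNG streams are decoupled and reruns with the same configuration
are bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, classifier, coexpression, expression, fusion, synthetic
from .radiomics.registry import MultiViewFeatureTable
from .survival import SurvivalData

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "n_patients",
    "n_validation_patients",
    "n_genes",
    "texture_effect_sd",
    "affected_feature_fraction",
    "subtype2_log_hazard",
    "censoring_rate",
    "radius_mm",
    "bin_width",
    "consensus_reps",
    "consensus_fraction",
    "k_range",
    "beta",
    "min_module_size",
    "cut_height",
    "top_variable_genes",
    "pair_fdr",
    "top_pairs_per_prf",
    "cv_folds",
    "features_csv",
    "counts_tsv",
    "survival_csv",
}


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with the study's defaults."""

    seed: int = 0
    out_dir: str = "runs/run"
    n_patients: int = 30
    n_validation_patients: int = 150
    n_genes: int = 2000
    texture_effect_sd: float = 1.5
    affected_feature_fraction: float = 0.3
    subtype2_log_hazard: float = float(np.log(1.0 / 0.146))
    censoring_rate: float = 0.3
    radius_mm: float = 10.0
    bin_width: float = 25.0
    consensus_reps: int = 1000
    consensus_fraction: float = 0.8
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    beta: float = 8.0
    min_module_size: int = 30
    cut_height: float = 0.98
    top_variable_genes: int | None = 5000
    pair_fdr: float = 0.05
    top_pairs_per_prf: int = 5
    cv_folds: int = 10
    features_csv: str | None = None
    counts_tsv: str | None = None
    survival_csv: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.consensus_fraction <= 1):
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.consensus_reps < 1:
            raise ValueError("consensus_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def manifest_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("hccfusion")
    root.addHandler(handler)
    try:
        _run_stages(config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _run_stages(config: PipelineConfig, out: Path) -> None:
    manifest = {
        "config": dataclasses.asdict(config),
        "parameter_hash": config.manifest_hash(),
        "stages": [],
    }

    # --- stage: cohort ------------------------------------------------------
    if config.features_csv:
        features = MultiViewFeatureTable.read_csv(config.features_csv, standardized=True)
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        survival = SurvivalData.from_frame(pd.read_csv(config.survival_csv))
        cohort = None
    else:
        cohort_cfg = synthetic.CohortConfig(
            n_patients=config.n_patients,
            seed=stage_seed(config.seed, "synth"),
            texture_effect_sd=config.texture_effect_sd,
            affected_feature_fraction=config.affected_feature_fraction,
            n_genes=config.n_genes,
            subtype2_log_hazard=config.subtype2_log_hazard,
            censoring_rate=config.censoring_rate,
        )
        cohort = synthetic.generate_cohort(cohort_cfg)
        cohort.save(out / "cohort")
        features = cohort.features.zscore()
        counts = cohort.counts
        survival = cohort.survival
    manifest["stages"].append("cohort")

    # --- stage: fusion subtyping -------------------------------------------
    fifs_seed = stage_seed(config.seed, "fifs")
    views = {v: features.view(v).to_numpy() for v in features.data.columns.levels[0]}
    cons = fusion.consensus_select_k(
        views,
        k_range=config.k_range,
        n_reps=config.consensus_reps,
        fraction=config.consensus_fraction,
        seed=fifs_seed,
    )
    fused = fusion.fuse_views(views, patient_ids=features.patients)
    labels = fusion.spectral_cluster(fused, cons.chosen_k, seed=fifs_seed)
    subtype = fusion.assign_subtypes(labels, survival, patient_ids=features.patients)
    fused.to_frame().to_csv(out / "fused_network.csv")
    subtype.rename_axis("patient_id").to_frame().to_csv(out / "subtypes.csv")
    sil = fusion.silhouette_from_similarity(fused, labels)
    manifest["chosen_k"] = cons.chosen_k
    manifest["silhouette"] = sil
    manifest["stages"].append("fifs")

    # --- stage: PRF cascade --------------------------------------------------
    prf_table = association.identify_prfs(features, subtype.to_numpy(), survival)
    prf_table.to_csv(out / "prf_table.csv", index=False)
    prfs = association.prf_values(features, prf_table)
    manifest["n_prfs"] = int(len(prf_table))
    manifest["stages"].append("prf")

    # --- stage: DE + modules --------------------------------------------------
    de = expression.differential_expression(counts, subtype.to_numpy(), reference="FIFS1")
    de.table.to_csv(out / "de_table.csv", index=False)
    norm = expression.normalize_counts(counts)
    log_expr = np.log2(norm + 1.0)
    cx_params = coexpression.CoexpressionParams(
        beta=config.beta,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        top_variable_genes=config.top_variable_genes,
    )
    filtered = coexpression.filter_variable_genes(
        log_expr, cx_params.top_variable_genes
    )
    adjacency = coexpression.signed_adjacency(filtered, cx_params)
    tom = coexpression.tom_similarity(adjacency)
    modules = coexpression.detect_modules(tom, cx_params)
    modules.to_frame().to_csv(out / "modules.csv", index=False)
    manifest["n_modules"] = int(len(modules.modules))
    manifest["stages"].append("modules")

    # --- stage: association network -------------------------------------------
    result_pairs = pd.DataFrame(columns=["module", "pathway", "prf", "r", "p", "q"])
    gene_table = pd.DataFrame(columns=["gene", "prf", "pathway", "module", "r", "p"])
    if modules.modules and len(prf_table):
        eigengenes, _ve = coexpression.module_eigengenes(filtered, modules)
        module_flags = association.filter_prf_modules(
            eigengenes, subtype.to_numpy(), survival, prfs
        )
        module_flags.to_csv(out / "module_filter.csv", index=False)
        selected = module_flags.loc[module_flags["selected"], "module"]
        if len(selected):
            sets = expression.GeneSetCollection(
                {m: modules.modules[m] for m in selected}, source="modules"
            )
            scores = expression.ssgsea_scores(log_expr, sets)
            pairs = association.pathway_feature_pairs(
                scores, prfs, pathway_modules={m: m for m in selected},
                fdr=config.pair_fdr,
            )
            result_pairs = pairs
            net = association.build_association_network(
                pairs, top_n=config.top_pairs_per_prf
            )
            association.write_network(
                net, graphml_path=out / "association.graphml",
                sif_path=out / "association.sif",
            )
            gene_table = association.prf_related_genes(
                log_expr, pairs, prfs, sets, modules
            )
    result_pairs.to_csv(out / "pathway_feature_pairs.csv", index=False)
    gene_table.to_csv(out / "prf_related_genes.csv", index=False)
    manifest["n_pairs"] = int(len(result_pairs))
    manifest["stages"].append("association")

    # --- stage: classifier -----------------------------------------------------
    module_gene_ids = [g for genes in modules.modules.values() for g in genes]
    try:
        cands = classifier.candidate_genes(de, module_gene_ids)
    except ValueError as exc:
        logger.warning("classifier skipped: %s", exc)
        cands = []
    if cands:
        model = classifier.train_nsc(
            log_expr.loc[cands],
            subtype.to_numpy(),
            folds=config.cv_folds,
            seed=stage_seed(config.seed, "classify"),
        )
        model.to_json(out / "nsc_model.json")
        model.cv_profile.to_csv(out / "nsc_cv_profile.csv", index=False)
        manifest["n_candidate_genes"] = len(cands)
        manifest["n_signature_genes"] = len(model.active_genes)
        manifest["nsc_threshold"] = model.threshold
        manifest["nsc_cv_error"] = float(model.cv_profile["cv_error"].min())

        # external validation on an independent synthetic cohort
        if cohort is not None:
            val_cfg = synthetic.CohortConfig(
                n_patients=config.n_validation_patients,
                seed=stage_seed(config.seed, "validate"),
                texture_effect_sd=config.texture_effect_sd,
                affected_feature_fraction=config.affected_feature_fraction,
                n_genes=config.n_genes,
                subtype2_log_hazard=config.subtype2_log_hazard,
                censoring_rate=config.censoring_rate,
            )
            val = synthetic.generate_cohort(val_cfg)
            val_expr = np.log2(expression.normalize_counts(val.counts) + 1.0)
            predicted, _scores = classifier.predict_nsc(model, val_expr)
            predicted.rename_axis("patient_id").to_frame().to_csv(
                out / "validation_predictions.csv"
            )
            immune = expression.GeneSetCollection(
                {
                    "immune_module": [
                        g
                        for g, m in val.truth["gene_module"].items()
                        if m == "immune"
                    ]
                },
                source="synthetic",
            )
            report = classifier.validate_external(
                predicted, val.survival, immune, val_expr
            )
            manifest["validation_logrank_p"] = report["logrank_p"]
    manifest["stages"].append("classifier")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
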