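"""End-to-end orchestration: one config, one seed, one machine-readable report.

Stage order mirrors the analysis narrative: (simulate) -> CIMP subtyping ->
paired differential methylation / expression -> cis (and optionally trans)
regulation -> specificity cascade -> diagnostic evaluation.  All thresholds
live in :class:`PipelineConfig` with the standard defaults (SD > 0.2 /
normal mean < 0.05 probe selection; FDR < 0.05 with |delta beta| > 0.2 and
|log2FC| > 1 calls; |r| > 0.3 correlation gate; 0.1 blood and pan-cancer
caps; >10% missing removal; panel of 6).  A single master seed derives the
per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cimp import call_cimp, consensus_cluster, select_cimp_cpgs, survival_by_group, associate_clinical
from .data_model import BetaMatrix, drop_sex_chromosomes
from .diagnostic import (
    cross_cancer_specificity,
    evaluate,
    fit_logistic,
    training_frame,
)
from .differential import filter_missing, gene_meth_status, knn_impute, paired_de, paired_dm, region_distribution
from .differential import log_cpm
from .regulation import cis_correlation, trans_correlation
from .screen import run_cascade
from .synthetic import CohortBundle, SimConfig, generate_bundle, read_bundle, write_bundle

logger = logging.getLogger(__name__)

# fixed offsets deriving stage seeds from the master seed
_SEED_CONSENSUS = 11
_SEED_IMPUTE = 23
_SEED_TEST_BUNDLE = 104_729


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus the input source (simulate or a bundle
    directory written by :func:`methmark.synthetic.write_bundle`)."""

    seed: int = 0
    simulate: SimConfig | None = None
    bundle_dir: str | None = None
    outdir: str | None = None

    # preprocessing
    max_missing: float = 0.10
    knn_k: int = 10

    # CIMP
    sd_min: float = 0.2
    normal_max: float = 0.05
    cimp_margin: float = 0.15
    consensus_k: int | None = None
    consensus_k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    consensus_resamples: int = 250
    consensus_item_frac: float = 0.8
    consensus_selection: str = "pac"

    # differential
    dm_alpha: float = 0.05
    dm_delta: float = 0.2
    de_alpha: float = 0.05
    de_fc_min: float = 1.0

    # regulation
    r_min: float = 0.3
    corr_alpha: float = 0.05
    run_trans: bool = True

    # cascade
    panel_size: int = 6
    stage1_alpha: float = 0.05
    stage1_delta: float = 0.2
    stage1_test: str = "wilcoxon"
    blood_cap: float | None = 0.1
    pan_cap: float = 0.1

    # diagnostic model
    ridge: float = 1e-8
    decision_threshold: float = 0.5
    test_bundle_seed: int | None = None  # default: seed + fixed offset

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if d.get("simulate") is not None and not isinstance(d["simulate"], SimConfig):
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "consensus_k_range" in d and d["consensus_k_range"] is not None:
            d["consensus_k_range"] = tuple(d["consensus_k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        problems = []
        if self.simulate is None and self.bundle_dir is None:
            problems.append("either a simulate block or bundle_dir is required")
        if self.simulate is not None and self.bundle_dir is not None:
            problems.append("simulate and bundle_dir are mutually exclusive")
        for name in ("max_missing", "dm_alpha", "de_alpha", "corr_alpha", "r_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must lie in [0, 1], got {v}")
        if self.panel_size < 1:
            problems.append("panel_size must be >= 1")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))


def _prepare_paired(bundle: CohortBundle, cfg: PipelineConfig) -> tuple[BetaMatrix, BetaMatrix]:
    """Combined filter/impute of the patient-paired tumor+normal matrix."""
    tumor = bundle.paired_tumor()
    normal = bundle.adjacent_normal
    combined = BetaMatrix(
        pd.concat([tumor.values, normal.values], axis=1),
        pd.concat([tumor.sample_meta.loc[tumor.sample_ids], normal.sample_meta.loc[normal.sample_ids]]),
    )
    combined = drop_sex_chromosomes(combined, bundle.annotation)
    combined = filter_missing(combined, cfg.max_missing)
    combined = knn_impute(combined, k=cfg.knn_k, seed=cfg.seed + _SEED_IMPUTE)
    return (
        combined.subset_samples(tumor.sample_ids),
        combined.subset_samples(normal.sample_ids),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the JSON-serializable report.

    Identical (config, seed) pairs produce identical reports (timestamps
    excluded by construction: none are recorded).
    """
    cfg = config
    cfg.validate()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs ---------------------------------------------------------
    if cfg.simulate is not None:
        bundle = generate_bundle(cfg.simulate, seed=cfg.seed)
        if outdir:
            write_bundle(bundle, outdir / "bundle")
    else:
        bundle = read_bundle(cfg.bundle_dir)
    ann = bundle.annotation

    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
    }

    # ---- CIMP subtyping -------------------------------------------------
    tumor_auto = filter_missing(drop_sex_chromosomes(bundle.hcc_tumor, ann), cfg.max_missing)
    normal_auto = filter_missing(drop_sex_chromosomes(bundle.adjacent_normal, ann), cfg.max_missing)
    selected = select_cimp_cpgs(
        tumor_auto, normal_auto, ann, sd_min=cfg.sd_min, normal_max=cfg.normal_max
    )
    cimp_report: dict = {"n_selected_probes": len(selected)}
    cimp_patients: list[str] = []
    if len(selected) >= 2 and tumor_auto.n_samples >= 3:
        sel_matrix = knn_impute(
            tumor_auto.subset_probes(selected), k=cfg.knn_k, seed=cfg.seed + _SEED_IMPUTE
        )
        consensus = consensus_cluster(
            sel_matrix,
            k_range=cfg.consensus_k_range,
            n_resamples=cfg.consensus_resamples,
            item_frac=cfg.consensus_item_frac,
            seed=cfg.seed + _SEED_CONSENSUS,
            k=cfg.consensus_k,
            selection=cfg.consensus_selection,
        )
        cimp_label = call_cimp(consensus, sel_matrix, margin=cfg.cimp_margin)
        patient_of = bundle.hcc_tumor.sample_meta["patient_id"]
        assignments = consensus.assignments.rename(index=patient_of.to_dict())
        cimp_report.update(
            {
                "k": consensus.k,
                "cluster_sizes": {
                    int(k): int(v)
                    for k, v in consensus.assignments.value_counts().sort_index().items()
                },
                "pac_by_k": consensus.pac,
                "cdf_area_by_k": consensus.cdf_area,
                "cimp_cluster": cimp_label,
            }
        )
        if cimp_label is not None:
            cimp_patients = sorted(assignments.index[assignments == cimp_label])
            cimp_report["cimp_patients"] = cimp_patients
            cimp_report["cimp_fraction"] = len(cimp_patients) / len(assignments)
            groups = pd.Series(
                np.where(assignments == cimp_label, "CIMP", "non-CIMP"),
                index=assignments.index,
            )
            surv = survival_by_group(groups, bundle.clinical)
            cimp_report["logrank_p_cimp_vs_rest"] = surv.test.p_value
            assoc = associate_clinical(assignments, bundle.clinical)
            cimp_report["n_clinical_associations_p_lt_05"] = (
                int((assoc["p_value"] < 0.05).sum()) if len(assoc) else 0
            )
            if outdir:
                assoc.to_csv(outdir / "clinical_associations.csv", index=False)
        if outdir:
            consensus.assignments.to_csv(outdir / "cimp_assignments.csv")
            consensus.consensus_matrix.to_csv(outdir / "consensus_matrix.tsv", sep="\t")
    else:
        logger.warning("CIMP stage skipped: too few selected probes or samples")
    report["cimp"] = cimp_report

    # ---- differential methylation / expression -------------------------
    tumor_paired, normal_paired = _prepare_paired(bundle, cfg)
    dm = paired_dm(tumor_paired, normal_paired, alpha=cfg.dm_alpha, delta=cfg.dm_delta)
    paired_patients = set(bundle.paired_patients())
    expr_meta = bundle.expression.meta()
    expr_paired_samples = expr_meta.index[
        expr_meta["patient_id"].isin(paired_patients)
    ]
    de = paired_de(
        bundle.expression.subset_samples(expr_paired_samples),
        alpha=cfg.de_alpha,
        fc_min=cfg.de_fc_min,
    )
    gene_status = gene_meth_status(dm, ann)
    regions = region_distribution(dm, ann)
    report["differential"] = {
        "n_probes_tested": int(dm.table["p"].notna().sum()),
        "n_hyper": len(dm.hyper_probes),
        "n_hypo": len(dm.hypo_probes),
        "n_genes_dm_high": int((gene_status["status"] == "DM-high").sum()),
        "n_genes_dm_low": int((gene_status["status"] == "DM-low").sum()),
        "n_genes_dm_both": int((gene_status["status"] == "both").sum()),
        "n_de_high": len(de.de_high_genes),
        "n_de_low": len(de.de_low_genes),
        "region_distribution": regions,
    }
    if outdir:
        dm.table.to_csv(outdir / "dm_results.tsv", sep="\t")
        de.table.to_csv(outdir / "de_results.tsv", sep="\t")
        gene_status.to_csv(outdir / "gene_meth_status.tsv", sep="\t")
        (outdir / "region_distribution.json").write_text(json.dumps(regions, indent=1))

    # ---- regulation -----------------------------------------------------
    expr_log = log_cpm(bundle.expression.counts)
    cis = cis_correlation(
        tumor_auto, expr_log, expr_meta, ann, r_min=cfg.r_min, alpha=cfg.corr_alpha
    )
    report["regulation"] = {
        "n_cis_records": len(cis.records),
        "n_genes_tested": len(cis.gene_class),
        "class_fractions_all": cis.class_fractions(),
        "class_fractions_de": cis.class_fractions(de.de_genes),
    }
    if outdir:
        cis.records.to_csv(outdir / "cis_records.tsv", sep="\t")
        cis.gene_class.to_csv(outdir / "cis_gene_class.tsv", sep="\t")

    if cfg.run_trans:
        dm_de_genes = gene_status.index[
            gene_status["status"].isin(["DM-high", "DM-low", "both"])
        ].intersection(de.de_genes)
        trans_probes = [
            p
            for g in dm_de_genes
            for p in ann.promoter_probes(g)
            if p in tumor_auto.probe_ids and dm.table.loc[p, "call"] != "ns"
        ]
        report["regulation"]["n_dm_de_genes"] = int(len(dm_de_genes))
        report["regulation"]["n_trans_probes"] = len(set(trans_probes))
        if trans_probes and len(de.de_genes):
            trans_beta = knn_impute(
                tumor_auto.subset_probes(sorted(set(trans_probes))),
                k=cfg.knn_k,
                seed=cfg.seed + _SEED_IMPUTE,
            )
            trans = trans_correlation(
                trans_beta,
                expr_log.loc[expr_log.index.intersection(de.de_genes)],
                expr_meta,
                ann,
                r_min=cfg.r_min,
                alpha=cfg.corr_alpha,
                dm_status=gene_status["status"],
            )
            report["regulation"]["trans_mean_frac_negative"] = float(
                trans.probe_summary["frac_negative"].mean()
            )
            if outdir:
                trans.r.to_csv(outdir / "trans_r.tsv", sep="\t")
                trans.probe_summary.to_csv(outdir / "trans_probe_summary.tsv", sep="\t")

    # ---- specificity cascade -------------------------------------------
    panel, audit = run_cascade(
        dm,
        de,
        ann,
        tumor_auto,
        normal_auto,
        bundle.blood,
        bundle.other_cancers,
        panel_size=cfg.panel_size,
        stage1_alpha=cfg.stage1_alpha,
        stage1_delta=cfg.stage1_delta,
        stage1_test=cfg.stage1_test,
        blood_cap=cfg.blood_cap,
        pan_cap=cfg.pan_cap,
    )
    report["cascade"] = {
        "stages": audit.summary(),
        "panel": panel.table.reset_index().to_dict(orient="records"),
    }
    if outdir:
        panel.table.to_csv(outdir / "marker_panel.tsv", sep="\t")
        (outdir / "cascade_audit.json").write_text(json.dumps(audit.summary(), indent=1))

    # ---- diagnostic model ----------------------------------------------
    diag_report: dict = {}
    if len(panel):
        X_tr, y_tr = training_frame(tumor_paired, normal_paired, panel.probes)
        model = fit_logistic(X_tr, y_tr, ridge=cfg.ridge)
        model.decision_threshold = cfg.decision_threshold
        train_eval = evaluate(model, X_tr, y_tr, cohort_label="training(paired)")
        diag_report["training"] = _eval_dict(train_eval)
        if cfg.simulate is not None:
            test_seed = (
                cfg.test_bundle_seed
                if cfg.test_bundle_seed is not None
                else cfg.seed + _SEED_TEST_BUNDLE
            )
            test_bundle = generate_bundle(
                cfg.simulate, seed=test_seed, structure_seed=cfg.seed
            )
            X_te, y_te = training_frame(
                test_bundle.hcc_tumor, test_bundle.adjacent_normal, panel.probes
            )
            test_eval = evaluate(model, X_te, y_te, cohort_label="independent")
            diag_report["independent"] = _eval_dict(test_eval)
            cross = cross_cancer_specificity(model, test_bundle.other_cancers)
        else:
            cross = cross_cancer_specificity(model, bundle.other_cancers)
        diag_report["cross_cancer"] = {
            "per_cohort": cross.to_dict(orient="records"),
            "median_frac_positive": cross.attrs.get("median_frac_positive"),
            "overall_frac_positive": cross.attrs.get("overall_frac_positive"),
        }
        if outdir:
            model.to_json(outdir / "diagnostic_model.json")
            cross.to_csv(outdir / "cross_cancer_specificity.csv", index=False)
    else:
        logger.warning("empty marker panel; diagnostic stage skipped")
    report["diagnostic"] = diag_report

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
    return report


def _eval_dict(res) -> dict:
    return {
        "cohort": res.cohort_label,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "auc": res.auc,
        "tp": res.tp,
        "fp": res.fp,
        "tn": res.tn,
        "fn": res.fn,
    }


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
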