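"""Multi-cohort synthetic methylation / expression / clinical data.

The generator emulates the statistical structure the downstream pipeline
assumes in a hepatocellular-carcinoma-style study design:

* a probe universe with genomic context (promoter CpG-island probes with low
  baseline beta ~0.03, gene-body and open-sea probes ~0.7 — the familiar
  bimodal beta landscape), sampled from Beta distributions parameterized by
  (mean, concentration) per context stratum;
* a target tumor cohort with a patient-matched adjacent-normal subset, a
  healthy-blood cohort, and K other cancer types each with tumor and normal
  samples, all sharing one probe universe and annotation manifest;
* planted effects with a ground-truth ledger: background hyper/hypomethylated
  probes, tumor-specific hypermethylated marker probes, pan-cancer
  hypermethylated decoys, blood-high decoys, paired-cohort-only artifacts,
  a CIMP subgroup (concerted promoter-CGI hypermethylation in a small
  patient fraction with worse survival), variably methylated promoter probes
  that carry the subtype signal, negatively (and positively) cis-regulated
  genes, and down/up-regulated genes;
* negative-binomial expression counts whose log-mean tracks promoter
  methylation for the cis-regulated genes;
* exponential survival with a hazard multiplier for CIMP patients, uniform
  censoring, and cluster-enriched clinical covariates.

Everything is driven by one :class:`SimConfig` and one integer seed;
identical (config, seed) yields an identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import (
    AnnotationTable,
    BetaMatrix,
    ClinicalTable,
    CountMatrix,
    read_annotation,
    read_beta_matrix,
    read_clinical,
    read_counts,
    write_annotation,
    write_beta_matrix,
    write_clinical,
    write_counts,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortBundle",
    "generate_bundle",
    "generate_expression",
    "generate_survival",
    "generate_clustered_beta",
    "write_bundle",
    "read_bundle",
]


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Cohort sizes mirror the target-study ratios at reduced scale:
    100 tumors with 30 patient-matched normals, 50 blood donors, and ten
    other cancer types with 40 tumor / 20 normal samples each.
    """

    # probe universe / cohorts
    n_probes: int = 20_000
    n_genes: int = 3_000
    n_hcc: int = 100
    n_paired_normal: int = 30
    n_blood: int = 50
    n_other_cancers: int = 10
    n_other_tumor: int = 40
    n_other_normal: int = 20
    n_sex_probes: int = 200

    # background beta distributions (mean, shared concentration)
    promoter_cgi_mean: float = 0.03
    body_mean: float = 0.70
    opensea_mean: float = 0.70
    concentration: float = 30.0
    missing_rate: float = 0.01

    # planted differential methylation
    n_dm_hyper: int = 500
    n_dm_hypo: int = 1_500
    dm_delta: float = 0.4

    # planted diagnostic markers and decoys (all in promoters of DE-low genes)
    n_specific_markers: int = 6
    marker_delta: float = 0.4
    n_pan_cancer: int = 20
    pan_level: float = 0.5
    pan_min_types: int = 3
    pan_max_types: int = 6
    pan_normal_prob: float = 0.5
    n_blood_high: int = 20
    blood_high_level: float = 0.5
    n_pair_artifact: int = 20

    # CIMP structure
    n_cimp_probes: int = 300
    cimp_variable_frac: float = 0.4
    cimp_variable_amp: float = 0.5
    cimp_shift: float = 0.4
    cimp_fraction: float = 0.05

    # expression
    n_de_low: int = 150
    n_de_high: int = 100
    de_log2fc: float = 2.0
    n_cis_negative: int = 100
    n_cis_positive: int = 30
    cis_slope_log2: float = -4.0
    cis_base_beta: float = 0.30
    cis_concentration: float = 8.0
    nb_dispersion: float = 0.1
    expr_log2_mean: float = 9.0
    expr_log2_sd: float = 1.0
    libsize_log2_sd: float = 0.15

    # survival / clinical
    hazard_ratio_cimp: float = 3.0
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_rate: float = 0.2
    stage3_prob_cimp: float = 0.6
    stage3_prob_other: float = 0.25
    male_prob: float = 0.7
    hcv_prob_cimp: float = 0.5
    hcv_prob_other: float = 0.2
    hbv_prob: float = 0.3

    def validate(self) -> None:
        if self.n_probes < 4 * self.n_genes + self.n_sex_probes:
            raise ValueError("n_probes too small for 4 probes per gene plus sex probes")
        n_marker_like = (
            self.n_specific_markers
            + self.n_pan_cancer
            + self.n_blood_high
            + self.n_pair_artifact
        )
        if n_marker_like > 2 * self.n_de_low:
            raise ValueError("not enough DE-low promoter probes for planted markers/decoys")
        n_gene_classes = (
            self.n_de_low + self.n_de_high + self.n_cis_negative + self.n_cis_positive
        )
        if n_gene_classes > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")
        n_neutral = self.n_genes - n_gene_classes
        if self.n_dm_hyper + self.n_cimp_probes > 2 * n_neutral:
            raise ValueError("not enough neutral promoter probes for dm_hyper + cimp probes")
        if self.n_paired_normal > self.n_hcc:
            raise ValueError("n_paired_normal cannot exceed n_hcc")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth ledger, keyed by probe / gene / patient identifiers."""

    dm_hyper_probes: frozenset[str]
    dm_hypo_probes: frozenset[str]
    cimp_patients: frozenset[str]
    cimp_probes: frozenset[str]
    specific_marker_probes: frozenset[str]
    pan_cancer_probes: frozenset[str]
    blood_high_probes: frozenset[str]
    pair_artifact_probes: frozenset[str]
    cis_negative_genes: frozenset[str]
    cis_positive_genes: frozenset[str]
    de_low_genes: frozenset[str]
    de_high_genes: frozenset[str]
    cis_driver_probes: dict[str, str]  # gene -> promoter probe coupled to expression
    hazard_ratio_cimp: float

    def __post_init__(self) -> None:
        if self.specific_marker_probes & self.pan_cancer_probes:
            raise ValueError("specific markers and pan-cancer decoys must be disjoint")
        if not self.specific_marker_probes <= self.dm_hyper_probes:
            raise ValueError("specific markers must be planted hypermethylated")

    def to_json(self, path) -> None:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = sorted(v) if isinstance(v, frozenset) else v
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = d[f.name]
            kwargs[f.name] = frozenset(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class CohortBundle:
    """The complete multi-cohort collection plus its planted ground truth."""

    annotation: AnnotationTable
    hcc_tumor: BetaMatrix
    adjacent_normal: BetaMatrix
    blood: BetaMatrix
    other_cancers: dict[str, dict[str, BetaMatrix]]  # type -> {"tumor","normal"}
    expression: CountMatrix
    clinical: ClinicalTable
    truth: GroundTruth
    config: SimConfig

    def paired_patients(self) -> list[str]:
        return sorted(self.adjacent_normal.patients().dropna().unique())

    def paired_tumor(self) -> BetaMatrix:
        """Tumor samples of patients that also have an adjacent normal."""
        patients = set(self.paired_patients())
        keep = [
            s
            for s in self.hcc_tumor.sample_ids
            if self.hcc_tumor.sample_meta.loc[s, "patient_id"] in patients
        ]
        return self.hcc_tumor.subset_samples(keep)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _probe_id(i: int) -> str:
    return f"cg{i:08d}"


def _build_annotation(cfg: SimConfig) -> tuple[AnnotationTable, dict]:
    """Deterministic manifest layout: 4 probes per gene (TSS200 and TSS1500
    island probes, two body probes), a block of sex-chromosome probes, and
    intergenic open-sea probes.  A handful of TSS1500 probes carry a second
    (Body) gene annotation to exercise the primary-gene convention."""
    genes = [f"GENE{g:04d}" for g in range(cfg.n_genes)]
    rows = []
    layout = {
        "tss200": {},  # gene -> probe
        "tss1500": {},
        "body": {},  # gene -> [probes]
        "intergenic": [],
        "sex": [],
    }
    i = 0
    pos = {}
    n_multi = min(50, cfg.n_genes - 1)
    for g_idx, gene in enumerate(genes):
        chrom = str((g_idx % 22) + 1)
        base_pos = pos.get(chrom, 0) + 100_000
        pos[chrom] = base_pos
        specs = [
            ("TSS200", "Island", -100, "tss200"),
            ("TSS1500", "Island", -800, "tss1500"),
            ("Body", "N_Shore", 2_000, "body"),
            ("Body", "OpenSea", 5_000, "body"),
        ]
        for region, cgi, dtss, slot in specs:
            pid = _probe_id(i)
            gene_symbols = (gene,)
            region_classes = (region,)
            if slot == "tss1500" and g_idx < n_multi:
                gene_symbols = (gene, genes[g_idx + 1])
                region_classes = (region, "Body")
            rows.append(
                {
                    "probe_id": pid,
                    "chromosome": chrom,
                    "position": base_pos + dtss + 2_000,
                    "gene_symbols": gene_symbols,
                    "region_classes": region_classes,
                    "cgi_relation": cgi,
                    "distance_to_tss": dtss,
                }
            )
            if slot == "body":
                layout["body"].setdefault(gene, []).append(pid)
            else:
                layout[slot][gene] = pid
            i += 1
    for k in range(cfg.n_sex_probes):
        pid = _probe_id(i)
        rows.append(
            {
                "probe_id": pid,
                "chromosome": "X" if k % 2 == 0 else "Y",
                "position": 50_000 + 1_000 * k,
                "gene_symbols": (),
                "region_classes": (),
                "cgi_relation": "OpenSea",
                "distance_to_tss": None,
            }
        )
        layout["sex"].append(pid)
        i += 1
    while i < cfg.n_probes:
        pid = _probe_id(i)
        rows.append(
            {
                "probe_id": pid,
                "chromosome": str((i % 22) + 1),
                "position": 10_000_000 + 500 * i,
                "gene_symbols": (),
                "region_classes": (),
                "cgi_relation": "OpenSea",
                "distance_to_tss": None,
            }
        )
        layout["intergenic"].append(pid)
        i += 1
    df = pd.DataFrame(rows).set_index("probe_id")
    return AnnotationTable(df), layout


def _sample_beta(rng: np.random.Generator, mean: np.ndarray, conc: np.ndarray) -> np.ndarray:
    m = np.clip(mean, 0.001, 0.999)
    return rng.beta(m * conc, (1.0 - m) * conc)


def _meta_frame(sample_ids, cohort_id, tissue_type, cancer_type, patient_ids):
    return pd.DataFrame(
        {
            "cohort_id": cohort_id,
            "tissue_type": tissue_type,
            "cancer_type": cancer_type,
            "patient_id": patient_ids,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_bundle(
    config: SimConfig | None = None, seed: int = 0, structure_seed: int | None = None
) -> CohortBundle:
    """Generate the full multi-cohort bundle with planted ground truth.

    All randomness descends from one ``numpy.random.SeedSequence(seed)``;
    identical (config, seed) pairs yield identical bundles.

    ``structure_seed`` separates the structural assignment (which probes and
    genes carry planted effects, which patients are CIMP) from the noise
    draws: two bundles with the same structure seed but different seeds are
    independent cohorts from the same underlying biology — the shape of an
    independent validation dataset.  By default the structure follows the
    main seed.
    """
    cfg = config or SimConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    r_assign, r_beta, r_expr, r_surv, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    if structure_seed is not None:
        r_assign = np.random.default_rng(np.random.SeedSequence(structure_seed).spawn(1)[0])

    ann, layout = _build_annotation(cfg)
    probe_index = ann.probe_ids
    probe_pos = {p: k for k, p in enumerate(probe_index)}
    genes = [f"GENE{g:04d}" for g in range(cfg.n_genes)]

    # ---- gene classes ----------------------------------------------------
    shuffled = list(genes)
    r_assign.shuffle(shuffled)
    cur = 0

    def take(n):
        nonlocal cur
        out = shuffled[cur : cur + n]
        cur += n
        return out

    de_low = take(cfg.n_de_low)
    de_high = take(cfg.n_de_high)
    cis_neg = take(cfg.n_cis_negative)
    cis_pos = take(cfg.n_cis_positive)
    neutral = shuffled[cur:]

    # ---- probe classes ---------------------------------------------------
    de_low_promoters = [layout["tss200"][g] for g in de_low] + [
        layout["tss1500"][g] for g in de_low
    ]
    r_assign.shuffle(de_low_promoters)
    k = 0

    def take_probes(pool, n):
        nonlocal k
        out = pool[k : k + n]
        k += n
        return out

    specific = take_probes(de_low_promoters, cfg.n_specific_markers)
    pan = take_probes(de_low_promoters, cfg.n_pan_cancer)
    blood_high = take_probes(de_low_promoters, cfg.n_blood_high)
    pair_artifact = take_probes(de_low_promoters, cfg.n_pair_artifact)

    neutral_promoters = [layout["tss200"][g] for g in neutral] + [
        layout["tss1500"][g] for g in neutral
    ]
    r_assign.shuffle(neutral_promoters)
    dm_hyper_bg = neutral_promoters[: cfg.n_dm_hyper]
    cimp_probes = neutral_promoters[cfg.n_dm_hyper : cfg.n_dm_hyper + cfg.n_cimp_probes]

    hypo_pool = [p for g in neutral for p in layout["body"][g]] + layout["intergenic"]
    r_assign.shuffle(hypo_pool)
    dm_hypo = hypo_pool[: cfg.n_dm_hypo]

    cis_drivers = {g: layout["tss200"][g] for g in cis_neg + cis_pos}

    # ---- patients and samples -------------------------------------------
    width = max(4, len(str(cfg.n_hcc)))
    patients = [f"P{j:0{width}d}" for j in range(cfg.n_hcc)]
    paired = sorted(str(p) for p in r_assign.choice(patients, size=cfg.n_paired_normal, replace=False))
    cimp_n = max(1, round(cfg.cimp_fraction * cfg.n_hcc))
    cimp_patients = sorted(str(p) for p in r_assign.choice(patients, size=cimp_n, replace=False))

    tumor_samples = [f"{p}-T" for p in patients]
    normal_samples = [f"{p}-N" for p in paired]
    blood_samples = [f"BLOOD{j:04d}" for j in range(cfg.n_blood)]
    cancer_types = [f"OC{j:02d}" for j in range(cfg.n_other_cancers)]

    # ---- base probe means and concentrations ----------------------------
    base_mean = np.full(len(probe_index), cfg.opensea_mean)
    promoter_island = (
        ann.promoter_mask() & (ann.df["cgi_relation"] == "Island")
    ).to_numpy()
    body_mask = ann.df["region_classes"].map(lambda rc: bool(rc) and rc[0] == "Body")
    base_mean[promoter_island] = cfg.promoter_cgi_mean
    base_mean[body_mask.to_numpy()] = cfg.body_mean
    base_mean[[probe_pos[p] for p in layout["sex"]]] = 0.5
    driver_rows = [probe_pos[p] for p in cis_drivers.values()]
    base_mean[driver_rows] = cfg.cis_base_beta

    conc = np.full(len(probe_index), cfg.concentration)

    def rows(probes):
        return [probe_pos[p] for p in probes]

    # ---- HCC tumor cohort ------------------------------------------------
    mean_t = np.tile(base_mean[:, None], (1, cfg.n_hcc))
    hyper_all = list(specific) + list(pan) + list(blood_high) + list(dm_hyper_bg)
    mean_t[rows(dm_hyper_bg)] += cfg.dm_delta
    mean_t[rows(specific) + rows(pan) + rows(blood_high)] += cfg.marker_delta
    paired_cols = [patients.index(p) for p in paired]
    mean_t[np.ix_(rows(pair_artifact), paired_cols)] += cfg.marker_delta
    mean_t[rows(dm_hypo)] -= cfg.dm_delta
    # variably methylated promoter probes carrying the subtype signal
    var_rows = rows(cimp_probes)
    bern = r_beta.random((len(var_rows), cfg.n_hcc)) < cfg.cimp_variable_frac
    mean_t[var_rows] += bern * cfg.cimp_variable_amp
    # CIMP patients: concerted hypermethylation of all promoter-CGI probes
    cimp_cols = [patients.index(p) for p in cimp_patients]
    mean_t[np.ix_(np.nonzero(promoter_island)[0], cimp_cols)] += cfg.cimp_shift

    conc_t = np.tile(conc[:, None], (1, cfg.n_hcc))
    conc_t[driver_rows] = cfg.cis_concentration
    tumor_vals = _sample_beta(r_beta, mean_t, conc_t)

    # ---- adjacent normals (patient-matched, no planted shifts) ----------
    mean_n = np.tile(base_mean[:, None], (1, cfg.n_paired_normal))
    normal_vals = _sample_beta(r_beta, mean_n, np.tile(conc[:, None], (1, cfg.n_paired_normal)))

    # ---- blood -----------------------------------------------------------
    mean_b = np.tile(base_mean[:, None], (1, cfg.n_blood))
    mean_b[rows(blood_high)] = cfg.blood_high_level
    blood_vals = _sample_beta(r_beta, mean_b, np.tile(conc[:, None], (1, cfg.n_blood)))

    # ---- other cancers ---------------------------------------------------
    # each pan-cancer decoy is elevated in a few other cancer types
    pan_plan: dict[str, list[tuple[str, str]]] = {p: [] for p in pan}
    for p in pan:
        n_types = int(r_assign.integers(cfg.pan_min_types, cfg.pan_max_types + 1))
        n_types = min(n_types, len(cancer_types))
        chosen = r_assign.choice(cancer_types, size=n_types, replace=False)
        for t in chosen:
            pan_plan[p].append((t, "tumor"))
            if r_assign.random() < cfg.pan_normal_prob:
                pan_plan[p].append((t, "normal"))

    other: dict[str, dict[str, BetaMatrix]] = {}
    other_vals: dict[tuple[str, str], np.ndarray] = {}
    for t in cancer_types:
        for tissue, n in (("tumor", cfg.n_other_tumor), ("normal", cfg.n_other_normal)):
            mean_o = np.tile(base_mean[:, None], (1, n))
            for p, targets in pan_plan.items():
                if (t, tissue) in targets:
                    mean_o[probe_pos[p]] = cfg.pan_level
            other_vals[(t, tissue)] = _sample_beta(
                r_beta, mean_o, np.tile(conc[:, None], (1, n))
            )

    # ---- expression (from the unmasked beta values) ---------------------
    truth = GroundTruth(
        dm_hyper_probes=frozenset(hyper_all + list(pair_artifact)),
        dm_hypo_probes=frozenset(dm_hypo),
        cimp_patients=frozenset(cimp_patients),
        cimp_probes=frozenset(cimp_probes),
        specific_marker_probes=frozenset(specific),
        pan_cancer_probes=frozenset(pan),
        blood_high_probes=frozenset(blood_high),
        pair_artifact_probes=frozenset(pair_artifact),
        cis_negative_genes=frozenset(cis_neg),
        cis_positive_genes=frozenset(cis_pos),
        de_low_genes=frozenset(de_low),
        de_high_genes=frozenset(de_high),
        cis_driver_probes=dict(sorted(cis_drivers.items())),
        hazard_ratio_cimp=cfg.hazard_ratio_cimp,
    )

    tumor_df = pd.DataFrame(tumor_vals, index=probe_index, columns=tumor_samples)
    normal_df = pd.DataFrame(normal_vals, index=probe_index, columns=normal_samples)
    expression = _generate_expression_from_values(
        tumor_df, normal_df, patients, paired, genes, truth, cfg, r_expr
    )

    # ---- survival / clinical --------------------------------------------
    clinical = generate_survival(patients, cimp_patients, cfg, rng=r_surv)

    # ---- missingness (MCAR), then wrap ----------------------------------
    def mask(vals):
        if cfg.missing_rate > 0:
            m = r_miss.random(vals.shape) < cfg.missing_rate
            vals = vals.copy()
            vals[m] = np.nan
        return vals

    hcc_tumor = BetaMatrix(
        pd.DataFrame(mask(tumor_vals), index=probe_index, columns=tumor_samples),
        _meta_frame(tumor_samples, "hcc", "tumor", "HCC", patients),
    )
    adjacent_normal = BetaMatrix(
        pd.DataFrame(mask(normal_vals), index=probe_index, columns=normal_samples),
        _meta_frame(normal_samples, "hcc", "normal", "HCC", paired),
    )
    blood = BetaMatrix(
        pd.DataFrame(mask(blood_vals), index=probe_index, columns=blood_samples),
        _meta_frame(blood_samples, "blood", "blood", "none", [None] * cfg.n_blood),
    )
    for t in cancer_types:
        other[t] = {}
        for tissue, n in (("tumor", cfg.n_other_tumor), ("normal", cfg.n_other_normal)):
            ids = [f"{t}-{tissue[0].upper()}{j:03d}" for j in range(n)]
            other[t][tissue] = BetaMatrix(
                pd.DataFrame(mask(other_vals[(t, tissue)]), index=probe_index, columns=ids),
                _meta_frame(ids, t, tissue, t, [None] * n),
            )

    return CohortBundle(
        annotation=ann,
        hcc_tumor=hcc_tumor,
        adjacent_normal=adjacent_normal,
        blood=blood,
        other_cancers=other,
        expression=expression,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )


def _generate_expression_from_values(
    tumor_beta: pd.DataFrame,
    normal_beta: pd.DataFrame,
    patients: list[str],
    paired: list[str],
    genes: list[str],
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Negative-binomial counts; cis-regulated genes couple their log2 mean
    to the realized beta of their promoter driver probe."""
    tumor_samples = [f"{p}-T" for p in patients]
    normal_samples = [f"{p}-N" for p in paired]
    samples = tumor_samples + normal_samples
    n_genes, n_samples = len(genes), len(samples)

    base = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, size=n_genes)
    lib = rng.normal(0.0, cfg.libsize_log2_sd, size=n_samples)
    log2_mu = base[:, None] + lib[None, :]

    gene_pos = {g: i for i, g in enumerate(genes)}
    tumor_cols = np.arange(len(tumor_samples))
    low_rows = [gene_pos[g] for g in sorted(truth.de_low_genes)]
    high_rows = [gene_pos[g] for g in sorted(truth.de_high_genes)]
    log2_mu[np.ix_(low_rows, tumor_cols)] -= cfg.de_log2fc
    log2_mu[np.ix_(high_rows, tumor_cols)] += cfg.de_log2fc

    beta_all = pd.concat([tumor_beta, normal_beta], axis=1)[samples]
    for g, probe in truth.cis_driver_probes.items():
        slope = (
            cfg.cis_slope_log2
            if g in truth.cis_negative_genes
            else -cfg.cis_slope_log2
        )
        b = beta_all.loc[probe].to_numpy(dtype=float)
        b = np.nan_to_num(b, nan=cfg.cis_base_beta)
        log2_mu[gene_pos[g]] += slope * (b - cfg.cis_base_beta)

    mu = np.power(2.0, log2_mu)
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    meta = _meta_frame(
        samples,
        "hcc",
        ["tumor"] * len(tumor_samples) + ["normal"] * len(normal_samples),
        "HCC",
        patients + paired,
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


def generate_expression(bundle: CohortBundle, config: SimConfig | None = None, seed: int = 0) -> CountMatrix:
    """Regenerate the expression counts for an existing bundle.

    Uses the bundle's recorded beta values (missing entries fall back to the
    cis baseline), so correlations follow the same planted structure as the
    bundle's own expression matrix.
    """
    cfg = config or bundle.config
    rng = np.random.default_rng(seed)
    patients = sorted(bundle.hcc_tumor.patients().dropna().unique())
    paired = bundle.paired_patients()
    genes = list(bundle.expression.gene_ids)
    return _generate_expression_from_values(
        bundle.hcc_tumor.values,
        bundle.adjacent_normal.values,
        patients,
        paired,
        genes,
        bundle.truth,
        cfg,
        rng,
    )


def _uniform_censor_bound(lam: float, rate: float) -> float:
    """Upper bound c of the U(0, c) censoring time achieving an expected
    censoring fraction ``rate`` against Exp(lam) event times."""
    def frac_censored(c):
        return (1.0 - np.exp(-lam * c)) / (lam * c) - rate

    return brentq(frac_censored, 1e-9, 1e9)


def generate_survival(
    patient_ids,
    cimp_patients,
    config: SimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClinicalTable:
    """Exponential survival with a CIMP hazard multiplier, uniform censoring,
    and cluster-enriched clinical covariates (stage, sex, race, viral status)."""
    cfg = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    patient_ids = list(patient_ids)
    cimp = set(cimp_patients)
    n = len(patient_ids)
    is_cimp = np.array([p in cimp for p in patient_ids])

    hazard = cfg.baseline_hazard * np.where(is_cimp, cfg.hazard_ratio_cimp, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_max = _uniform_censor_bound(cfg.baseline_hazard, cfg.censoring_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    p3 = np.where(is_cimp, cfg.stage3_prob_cimp, cfg.stage3_prob_other)
    u = rng.random(n)
    rest = 1.0 - p3
    stage = np.where(
        u < p3, "III", np.where(u < p3 + 0.5 * rest, "I", np.where(u < p3 + 0.85 * rest, "II", "IV"))
    )
    sex = np.where(rng.random(n) < cfg.male_prob, "male", "female")
    race = rng.choice(["white", "asian", "black", "other"], size=n, p=[0.5, 0.3, 0.15, 0.05])
    ph = np.where(is_cimp, cfg.hcv_prob_cimp, cfg.hcv_prob_other)
    uv = rng.random(n)
    viral = np.where(uv < ph, "HCV", np.where(uv < ph + cfg.hbv_prob, "HBV", "none"))

    df = pd.DataFrame(
        {
            "survival_time": np.round(time, 1),
            "event": event,
            "stage": stage,
            "sex": sex,
            "race": race,
            "viral_status": viral,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return ClinicalTable(df)


def generate_clustered_beta(
    n_probes: int = 100,
    cluster_sizes: tuple[int, ...] = (20, 20, 20),
    seed: int = 0,
    low: float = 0.2,
    high: float = 0.8,
    concentration: float = 60.0,
) -> tuple[BetaMatrix, pd.Series]:
    """Beta matrix with planted, well-separated sample clusters.

    Each cluster gets an independent random high/low pattern over probes, so
    clusters are roughly equidistant; noise is Beta around the pattern mean.
    Returns the matrix and the true cluster label per sample.
    """
    rng = np.random.default_rng(seed)
    patterns = rng.random((len(cluster_sizes), n_probes)) < 0.5
    means = np.where(patterns, high, low)
    cols, labels = [], []
    vals = []
    for c, size in enumerate(cluster_sizes):
        m = np.tile(means[c][:, None], (1, size))
        vals.append(_sample_beta(rng, m, np.full_like(m, concentration)))
        cols += [f"S{c}_{j:03d}" for j in range(size)]
        labels += [c + 1] * size
    values = pd.DataFrame(np.hstack(vals), index=[_probe_id(i) for i in range(n_probes)], columns=cols)
    meta = _meta_frame(cols, "sim", "tumor", "HCC", cols)
    return BetaMatrix(values, meta), pd.Series(labels, index=cols, name="cluster")


# ---------------------------------------------------------------------------
# bundle persistence (the plain-text exchange layout used by the CLI)
# ---------------------------------------------------------------------------


def write_bundle(bundle: CohortBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(bundle.annotation, out / "annotation.csv")
    write_beta_matrix(bundle.hcc_tumor, out / "hcc_tumor.tsv", out / "hcc_tumor.meta.csv")
    write_beta_matrix(
        bundle.adjacent_normal, out / "adjacent_normal.tsv", out / "adjacent_normal.meta.csv"
    )
    write_beta_matrix(bundle.blood, out / "blood.tsv", out / "blood.meta.csv")
    for t, cohorts in bundle.other_cancers.items():
        for tissue, bm in cohorts.items():
            stem = f"other_{t}_{tissue}"
            write_beta_matrix(bm, out / f"{stem}.tsv", out / f"{stem}.meta.csv")
    write_counts(bundle.expression, out / "expression.tsv", out / "expression.meta.csv")
    write_clinical(bundle.clinical, out / "clinical.csv")
    bundle.truth.to_json(out / "truth.json")
    (out / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=1, sort_keys=True)
    )


def read_bundle(indir) -> CohortBundle:
    d = Path(indir)
    cfg = SimConfig.from_dict(json.loads((d / "sim_config.json").read_text()))
    other: dict[str, dict[str, BetaMatrix]] = {}
    for f in sorted(d.glob("other_*_tumor.tsv")):
        t = f.name[len("other_") : -len("_tumor.tsv")]
        other[t] = {
            tissue: read_beta_matrix(
                d / f"other_{t}_{tissue}.tsv", d / f"other_{t}_{tissue}.meta.csv"
            )
            for tissue in ("tumor", "normal")
        }
    return CohortBundle(
        annotation=read_annotation(d / "annotation.csv"),
        hcc_tumor=read_beta_matrix(d / "hcc_tumor.tsv", d / "hcc_tumor.meta.csv"),
        adjacent_normal=read_beta_matrix(
            d / "adjacent_normal.tsv", d / "adjacent_normal.meta.csv"
        ),
        blood=read_beta_matrix(d / "blood.tsv", d / "blood.meta.csv"),
        other_cancers=other,
        expression=read_counts(d / "expression.tsv", d / "expression.meta.csv"),
        clinical=read_clinical(d / "clinical.csv"),
        truth=GroundTruth.from_json(d / "truth.json"),
        config=cfg,
    )
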