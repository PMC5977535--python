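"""Missing-data handling and paired differential methylation / expression.

Call semantics follow the usual dual-gate convention: a probe is
differentially methylated only when FDR < alpha AND |delta beta| > delta
(defaults 0.05 / 0.2); a gene is differentially expressed only when
FDR < alpha AND |log2 fold change| > 1.  "More than 10% missing" removal
and both effect-size gates use strict inequalities.

Differential expression operates on median-ratio-normalized log2 CPM with a
paired t-test per gene — a deliberately transparent pipeline with the same
thresholds and call labels (DE-high / DE-low) as moderated NB frameworks,
chosen so every step here is directly verifiable against hand computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics.pairwise import nan_euclidean_distances

from .data_model import (
    AnnotationTable,
    BetaMatrix,
    CountMatrix,
    PROMOTER_CLASSES,
    paired_sample_table,
)
from .stats_core import bh_fdr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# missing data
# ---------------------------------------------------------------------------


def filter_missing(matrix: BetaMatrix, max_missing_frac: float = 0.10) -> BetaMatrix:
    """Drop probes whose missing fraction strictly exceeds the threshold."""
    frac = matrix.missing_fraction()
    keep = matrix.probe_ids[(frac <= max_missing_frac).to_numpy()]
    dropped = matrix.n_probes - len(keep)
    if dropped:
        logger.info("filter_missing: removed %d probes (> %.0f%% missing)", dropped, 100 * max_missing_frac)
    return matrix.subset_probes(keep)


def knn_impute(
    matrix: BetaMatrix, k: int = 10, pool_size: int = 2000, seed: int = 0
) -> BetaMatrix:
    """Probe-wise k-nearest-neighbor imputation.

    Each missing cell becomes the mean, at that sample, of the k probes
    nearest by Euclidean distance over the shared observed samples.
    Neighbor candidates are fully observed probes; for large matrices the
    candidate pool is subsampled to ``pool_size`` (seeded), which keeps the
    distance computation linear in the number of probes.  Observed values
    are never altered and imputed values are clipped to [0, 1].
    """
    values = matrix.values
    arr = values.to_numpy(dtype=float).copy()
    row_missing = np.isnan(arr).any(axis=1)
    if not row_missing.any():
        return BetaMatrix(values.copy(), matrix.sample_meta)
    if np.isnan(arr).all(axis=1).any():
        bad = values.index[np.isnan(arr).all(axis=1)][:5].tolist()
        raise ValueError(f"probes with no observed values cannot be imputed: {bad}")

    complete = np.nonzero(~np.isnan(arr).any(axis=1))[0]
    if len(complete) == 0:
        raise ValueError("knn_impute needs at least one fully observed probe")
    if len(complete) < k:
        logger.warning("knn_impute: only %d complete candidate probes (< k=%d)", len(complete), k)
    if len(complete) > pool_size:
        rng = np.random.default_rng(seed)
        complete = np.sort(rng.choice(complete, size=pool_size, replace=False))
    pool = arr[complete]

    target_idx = np.nonzero(row_missing)[0]
    k_eff = min(k, len(complete))
    chunk = 1024
    for start in range(0, len(target_idx), chunk):
        idx = target_idx[start : start + chunk]
        d = nan_euclidean_distances(arr[idx], pool)
        nearest = np.argpartition(d, kth=k_eff - 1, axis=1)[:, :k_eff]
        fill = pool[nearest].mean(axis=1)  # (chunk, n_samples)
        block = arr[idx]
        mask = np.isnan(block)
        block[mask] = fill[mask]
        arr[idx] = block
    arr = np.clip(arr, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(arr, index=values.index, columns=values.columns), matrix.sample_meta)


# ---------------------------------------------------------------------------
# paired differential methylation
# ---------------------------------------------------------------------------


@dataclass
class DMResult:
    """Per-probe paired differential methylation calls."""

    table: pd.DataFrame  # mean_tumor, mean_normal, delta_beta, n_pairs, t, p, fdr, call
    alpha: float
    delta: float

    def called(self, call: str) -> pd.Index:
        return self.table.index[self.table["call"] == call]

    @property
    def hyper_probes(self) -> pd.Index:
        return self.called("hyper")

    @property
    def hypo_probes(self) -> pd.Index:
        return self.called("hypo")


def _match_pairs(tumor: BetaMatrix, normal: BetaMatrix) -> tuple[list[str], list[str]]:
    meta = pd.concat([tumor.meta(), normal.meta()])
    pairs = paired_sample_table(meta)
    paired_samples = set(pairs["tumor_sample"]) | set(pairs["normal_sample"])
    unpaired = [s for s in list(tumor.sample_ids) + list(normal.sample_ids) if s not in paired_samples]
    if unpaired:
        raise ValueError(f"unpaired samples present: {unpaired[:10]}")
    return list(pairs["tumor_sample"]), list(pairs["normal_sample"])


def _paired_t_rows(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise paired t on a matrix of differences (NaN = missing pair).

    Returns (t, p, n).  Rows with < 2 complete pairs get p = NaN; rows with
    zero-variance differences get (0, 1) when the shift is zero and
    (inf, 0) otherwise — flagged calls, never silent NaN.
    """
    n = (~np.isnan(diffs)).sum(axis=1)
    mean = np.full(len(diffs), np.nan)
    sd = np.full(len(diffs), np.nan)
    ok = n >= 2
    with np.errstate(invalid="ignore"):
        mean[n > 0] = np.nanmean(diffs[n > 0], axis=1)
        sd[ok] = np.nanstd(diffs[ok], axis=1, ddof=1)
    t = np.full(len(diffs), np.nan)
    p = np.full(len(diffs), np.nan)
    regular = ok & (sd > 0)
    t[regular] = mean[regular] / (sd[regular] / np.sqrt(n[regular]))
    p[regular] = 2.0 * sps.t.sf(np.abs(t[regular]), df=n[regular] - 1)
    degen = ok & (sd == 0)
    zero = degen & (mean == 0)
    t[zero], p[zero] = 0.0, 1.0
    const = degen & (mean != 0)
    t[const] = np.sign(mean[const]) * np.inf
    p[const] = 0.0
    return t, p, n


def paired_dm(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    alpha: float = 0.05,
    delta: float = 0.2,
) -> DMResult:
    """Paired t-test per probe on patient-matched tumor/normal beta values.

    Pairs are matched through patient_id; any sample without a partner is an
    error.  Missing values are handled pairwise-complete per probe; probes
    with fewer than 2 complete pairs are excluded from the FDR family and
    called 'ns'.  BH adjustment runs across all tested probes.
    """
    t_cols, n_cols = _match_pairs(tumor, normal)
    if len(t_cols) < 3:
        raise ValueError("paired_dm needs >= 3 patient-matched pairs")
    shared = tumor.probe_ids.intersection(normal.probe_ids)
    T = tumor.values.loc[shared, t_cols].to_numpy(dtype=float)
    N = normal.values.loc[shared, n_cols].to_numpy(dtype=float)
    diffs = T - N
    t, p, n = _paired_t_rows(diffs)

    fdr = np.full(len(shared), np.nan)
    tested = ~np.isnan(p)
    fdr[tested] = bh_fdr(p[tested])

    mean_t = np.nanmean(T, axis=1)
    mean_n = np.nanmean(N, axis=1)
    delta_beta = np.nanmean(diffs, axis=1)

    call = np.full(len(shared), "ns", dtype=object)
    sig = tested & (fdr < alpha)
    call[sig & (delta_beta > delta)] = "hyper"
    call[sig & (delta_beta < -delta)] = "hypo"

    table = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "delta_beta": delta_beta,
            "n_pairs": n,
            "t": t,
            "p": p,
            "fdr": fdr,
            "call": call,
        },
        index=shared,
    )
    return DMResult(table=table, alpha=alpha, delta=delta)


# ---------------------------------------------------------------------------
# paired differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame  # log2fc, t, p, fdr, call
    alpha: float
    fc_min: float

    def called(self, call: str) -> pd.Index:
        return self.table.index[self.table["call"] == call]

    @property
    def de_low_genes(self) -> pd.Index:
        return self.called("DE-low")

    @property
    def de_high_genes(self) -> pd.Index:
        return self.called("DE-high")

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]


def median_ratio_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample scaling factors by the median-of-ratios method, normalized
    to geometric mean 1.  The reference profile is the geometric mean across
    samples over genes expressed everywhere."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = libsize.index[libsize == 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    rate = counts / libsize
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 10:
        logger.warning("median_ratio_factors: %d all-positive genes; factors may be noisy", int(positive.sum()))
    ref = np.exp(np.log(rate[positive]).mean(axis=1))
    factors = (rate[positive].T / ref).T.median(axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on median-ratio-scaled library sizes."""
    eff_lib = counts.sum(axis=0) * median_ratio_factors(counts)
    return np.log2(counts / eff_lib * 1e6 + prior)


def paired_de(
    counts: CountMatrix,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    prior: float = 0.5,
) -> DEResult:
    """Paired differential expression on log2 CPM.

    Genes with all-zero counts are dropped (logged).  log2fc is the mean
    paired log2-CPM difference (tumor - normal); calls require FDR < alpha
    and |log2fc| > fc_min.
    """
    t_cols, n_cols = _match_pairs_counts(counts)
    if len(t_cols) < 3:
        raise ValueError("paired_de needs >= 3 patient-matched pairs")
    sub = counts.counts[t_cols + n_cols]
    nonzero = sub.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("paired_de: dropped %d all-zero genes", int((~nonzero).sum()))
    sub = sub[nonzero]
    logc = log_cpm(sub, prior=prior)
    diffs = logc[t_cols].to_numpy() - logc[n_cols].to_numpy()
    t, p, _ = _paired_t_rows(diffs)
    fdr = np.full(len(sub), np.nan)
    tested = ~np.isnan(p)
    fdr[tested] = bh_fdr(p[tested])
    log2fc = diffs.mean(axis=1)
    call = np.full(len(sub), "ns", dtype=object)
    sig = tested & (fdr < alpha)
    call[sig & (log2fc > fc_min)] = "DE-high"
    call[sig & (log2fc < -fc_min)] = "DE-low"
    table = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "fdr": fdr, "call": call}, index=sub.index
    )
    return DEResult(table=table, alpha=alpha, fc_min=fc_min)


def _match_pairs_counts(counts: CountMatrix) -> tuple[list[str], list[str]]:
    pairs = paired_sample_table(counts.meta())
    paired_samples = set(pairs["tumor_sample"]) | set(pairs["normal_sample"])
    unpaired = [s for s in counts.sample_ids if s not in paired_samples]
    if unpaired:
        raise ValueError(f"unpaired samples present: {unpaired[:10]}")
    return list(pairs["tumor_sample"]), list(pairs["normal_sample"])


# ---------------------------------------------------------------------------
# CpG -> gene status and genomic-context summaries
# ---------------------------------------------------------------------------


def gene_meth_status(dm: DMResult, ann: AnnotationTable) -> pd.DataFrame:
    """Promoter-methylation status per primary gene.

    A gene is DM-high when at least one of its promoter probes is called
    hyper, DM-low when at least one is hypo, 'both' with one of each, and
    'none' when it has promoter probes but no calls.  The probe-to-gene map
    uses the first listed gene only.
    """
    probes = dm.table.index.intersection(ann.probe_ids)
    sub = ann.df.loc[probes]
    primary = sub["gene_symbols"].map(lambda g: g[0] if g else None)
    is_prom = sub["region_classes"].map(lambda rc: bool(rc) and rc[0] in PROMOTER_CLASSES)
    calls = dm.table.loc[probes, "call"]
    rows = {}
    frame = pd.DataFrame({"gene": primary, "promoter": is_prom, "call": calls})
    frame = frame[frame["gene"].notna() & frame["promoter"]]
    for gene, grp in frame.groupby("gene", sort=True):
        hyper = grp.index[grp["call"] == "hyper"].tolist()
        hypo = grp.index[grp["call"] == "hypo"].tolist()
        if hyper and hypo:
            status = "both"
        elif hyper:
            status = "DM-high"
        elif hypo:
            status = "DM-low"
        else:
            status = "none"
        rows[gene] = {
            "status": status,
            "hyper_probes": ";".join(hyper),
            "hypo_probes": ";".join(hypo),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


_TSS_BINS = [-np.inf, -1500, -500, -50, 50, 500, 1500, np.inf]
_TSS_LABELS = ["<-1500", "-1500..-500", "-500..-50", "-50..50", "50..500", "500..1500", ">1500"]


def region_distribution(dm: DMResult, ann: AnnotationTable) -> dict:
    """Counts/fractions of hyper vs hypo calls by genomic context.

    Strata at the CpG level: Promoter, CGI, Promoter & CGI, and the whole
    genome; plus per-CGI-relation bins and signed distance-to-TSS bins.
    Gene-level strata count primary genes with at least one called promoter
    probe in the stratum (genes with both directions count in both).
    """
    called = dm.table[dm.table["call"] != "ns"]
    probes = called.index.intersection(ann.probe_ids)
    sub = ann.df.loc[probes]
    calls = called.loc[probes, "call"]
    promoter = sub["region_classes"].map(lambda rc: any(c in PROMOTER_CLASSES for c in rc))
    island = sub["cgi_relation"] == "Island"

    def tally(mask) -> dict:
        c = calls[np.asarray(mask, dtype=bool)]
        n_hyper = int((c == "hyper").sum())
        n_hypo = int((c == "hypo").sum())
        total = n_hyper + n_hypo
        return {
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "frac_hyper": n_hyper / total if total else np.nan,
            "frac_hypo": n_hypo / total if total else np.nan,
        }

    cpg_strata = {
        "Promoter": tally(promoter),
        "CGI": tally(island),
        "Promoter&CGI": tally(promoter & island),
        "WholeGenome": tally(np.ones(len(calls), dtype=bool)),
    }
    cgi_bins = {
        rel: tally(sub["cgi_relation"] == rel) for rel in sorted(sub["cgi_relation"].unique())
    }
    dtss = pd.to_numeric(sub["distance_to_tss"], errors="coerce")
    tss_bins = {}
    binned = pd.cut(dtss, bins=_TSS_BINS, labels=_TSS_LABELS)
    for label in _TSS_LABELS:
        tss_bins[label] = tally((binned == label).to_numpy())

    status = gene_meth_status(dm, ann)

    def gene_tally(status_frame: pd.DataFrame) -> dict:
        n_hyper = int(status_frame["status"].isin(["DM-high", "both"]).sum())
        n_hypo = int(status_frame["status"].isin(["DM-low", "both"]).sum())
        total = n_hyper + n_hypo
        return {
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "frac_hyper": n_hyper / total if total else np.nan,
            "frac_hypo": n_hypo / total if total else np.nan,
        }

    gene_strata = {"Promoter": gene_tally(status[status["status"] != "none"])}
    return {
        "cpg_strata": cpg_strata,
        "cgi_relation": cgi_bins,
        "tss_distance": tss_bins,
        "gene_strata": gene_strata,
    }
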