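"""Cis and trans methylation-expression correlation (eQTM-style).

Cis: Pearson correlation between each promoter probe and the expression of
its own primary gene across matched tumor samples.  Trans: the full grid of
selected probes against the expression of differentially expressed genes.
A record is significant when |r| > r_min AND FDR < alpha (defaults 0.3 /
0.05); the sign is recorded separately, and genes aggregate to
negative / positive / both / none classes over their promoter probes.

Expression enters on the log2-normalized scale so r is stable under library
scaling.  FDR families are per analysis: all cis tests together, all trans
tests together; degenerate records (constant probe or gene) are flagged and
excluded from the family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import AnnotationTable, BetaMatrix, PROMOTER_CLASSES
from .stats_core import bh_fdr

logger = logging.getLogger(__name__)


def match_tumor_samples(
    beta: BetaMatrix, expr_meta: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Patient-matched (methylation sample, expression sample) tumor pairs."""
    bm_meta = beta.meta()
    bm_tumor = bm_meta[bm_meta["tissue_type"] == "tumor"].dropna(subset=["patient_id"])
    ex_tumor = expr_meta[expr_meta["tissue_type"] == "tumor"].dropna(subset=["patient_id"])
    by_patient = {p: s for s, p in ex_tumor["patient_id"].items()}
    meth_cols, expr_cols = [], []
    for s, p in bm_tumor["patient_id"].items():
        if p in by_patient:
            meth_cols.append(s)
            expr_cols.append(by_patient[p])
    return meth_cols, expr_cols


def _row_standardize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score rows; returns (z, constant_row_mask)."""
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mean) / sd, constant


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


@dataclass
class CisResult:
    records: pd.DataFrame  # probe_id index; gene, r, p, fdr, sign
    gene_class: pd.DataFrame  # gene index; class, n_negative, n_positive
    r_min: float
    alpha: float

    def class_fractions(self, genes=None) -> dict[str, float]:
        """Fractions of negative / positive / both / none gene classes over
        an arbitrary gene subset (default: all tested genes)."""
        gc = self.gene_class
        if genes is not None:
            gc = gc.loc[gc.index.intersection(pd.Index(genes))]
        n = len(gc)
        if n == 0:
            return {c: float("nan") for c in ("negative", "positive", "both", "none")}
        return {c: float((gc["class"] == c).mean()) for c in ("negative", "positive", "both", "none")}


def cis_correlation(
    beta: BetaMatrix,
    expr_log: pd.DataFrame,
    expr_meta: pd.DataFrame,
    ann: AnnotationTable,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> CisResult:
    """Correlate each promoter probe with its primary gene's expression.

    ``expr_log`` is genes x samples log2-normalized expression; samples are
    matched to the tumor methylation samples through patient ids (>= 3
    matches required).  Missing beta values are handled pairwise-complete
    per probe.  Returns one record per (promoter probe, primary gene) pair
    plus per-gene classes.
    """
    meth_cols, expr_cols = match_tumor_samples(beta, expr_meta)
    n = len(meth_cols)
    if n < 3:
        raise ValueError("cis_correlation needs >= 3 patient-matched tumor samples")

    primary = ann.df["gene_symbols"].map(lambda g: g[0] if g else None)
    is_prom = ann.df["region_classes"].map(lambda rc: bool(rc) and rc[0] in PROMOTER_CLASSES)
    candidates = ann.probe_ids[
        (is_prom & primary.notna() & primary.isin(expr_log.index)).to_numpy()
    ]
    candidates = candidates.intersection(beta.probe_ids)
    genes = primary.loc[candidates]

    B = beta.values.loc[candidates, meth_cols].to_numpy(dtype=float)
    E = expr_log.loc[genes, expr_cols].to_numpy(dtype=float)

    r = np.full(len(candidates), np.nan)
    p = np.full(len(candidates), np.nan)
    complete = ~np.isnan(B).any(axis=1)
    # vectorized path for complete probes
    if complete.any():
        Bz, b_const = _row_standardize(B[complete])
        Ez, e_const = _row_standardize(E[complete])
        rr = (Bz * Ez).mean(axis=1)
        rr[b_const | e_const] = np.nan
        r[complete] = rr
        with np.errstate(invalid="ignore"):
            p[complete] = np.where(np.isnan(rr), np.nan, _r_to_p(rr, n))
    # pairwise-complete path for probes with missing cells
    for i in np.nonzero(~complete)[0]:
        x, y = B[i], E[i]
        ok = ~np.isnan(x)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            continue
        r[i], p[i] = sps.pearsonr(x[ok], y[ok])

    tested = ~np.isnan(p)
    n_degen = int((~tested).sum())
    if n_degen:
        logger.info("cis_correlation: %d degenerate records excluded from FDR", n_degen)
    fdr = np.full(len(candidates), np.nan)
    fdr[tested] = bh_fdr(p[tested])
    sign = np.full(len(candidates), "ns", dtype=object)
    sig = tested & (np.abs(r) > r_min) & (fdr < alpha)
    sign[sig & (r < 0)] = "negative"
    sign[sig & (r > 0)] = "positive"

    records = pd.DataFrame(
        {"gene": genes.to_numpy(), "r": r, "p": p, "fdr": fdr, "sign": sign},
        index=candidates,
    )
    records.index.name = "probe_id"

    rows = {}
    for gene, grp in records.groupby("gene", sort=True):
        n_neg = int((grp["sign"] == "negative").sum())
        n_pos = int((grp["sign"] == "positive").sum())
        if n_neg and n_pos:
            cls = "both"
        elif n_neg:
            cls = "negative"
        elif n_pos:
            cls = "positive"
        else:
            cls = "none"
        rows[gene] = {"class": cls, "n_negative": n_neg, "n_positive": n_pos}
    gene_class = pd.DataFrame.from_dict(rows, orient="index")
    gene_class.index.name = "gene"
    return CisResult(records=records, gene_class=gene_class, r_min=r_min, alpha=alpha)


@dataclass
class TransResult:
    r: pd.DataFrame  # probes x genes
    fdr: pd.DataFrame
    sign: pd.DataFrame  # "negative" / "positive" / "ns" / "self" / "degenerate"
    probe_summary: pd.DataFrame  # per probe: n significant negative/positive, fractions
    r_min: float
    alpha: float


def trans_correlation(
    beta: BetaMatrix,
    expr_log: pd.DataFrame,
    expr_meta: pd.DataFrame,
    ann: AnnotationTable,
    r_min: float = 0.3,
    alpha: float = 0.05,
    exclude_self: bool = True,
    dm_status: pd.Series | None = None,
) -> TransResult:
    """Correlation grid: selected probes x expression of selected genes.

    ``beta`` should already be restricted to the probes of interest
    (typically promoter probes of DM-and-DE genes) and complete (impute
    first); ``expr_log`` rows are typically the DE genes.  Self pairs
    (probe against its own primary gene) are the cis question and are
    excluded from the FDR family by default.  ``dm_status`` (gene ->
    DM-high/DM-low) is attached to the probe summary when provided, to
    support the hyper->negative / hypo->positive trans contrast.
    """
    if beta.n_probes == 0:
        raise ValueError("trans_correlation: empty probe set (no DM∩DE probes upstream?)")
    if len(expr_log) == 0:
        raise ValueError("trans_correlation: empty gene set (no DE genes upstream?)")
    meth_cols, expr_cols = match_tumor_samples(beta, expr_meta)
    n = len(meth_cols)
    if n < 3:
        raise ValueError("trans_correlation needs >= 3 patient-matched tumor samples")

    B = beta.values.loc[:, meth_cols].to_numpy(dtype=float)
    if np.isnan(B).any():
        raise ValueError("trans_correlation requires complete beta values; impute first")
    E = expr_log.loc[:, expr_cols].to_numpy(dtype=float)

    Bz, b_const = _row_standardize(B)
    Ez, e_const = _row_standardize(E)
    R = (Bz @ Ez.T) / n
    P = _r_to_p(R, n)

    probes = beta.probe_ids
    genes = expr_log.index
    degenerate = b_const[:, None] | e_const[None, :]

    primary = ann.df["gene_symbols"].map(lambda g: g[0] if g else None)
    probe_gene = primary.reindex(probes)
    self_pair = probe_gene.to_numpy()[:, None] == genes.to_numpy()[None, :]

    family = ~degenerate
    if exclude_self:
        family &= ~self_pair
    flat_fdr = np.full(R.shape, np.nan)
    flat_fdr[family] = bh_fdr(P[family])

    sign = np.full(R.shape, "ns", dtype=object)
    sig = family & (np.abs(R) > r_min) & (flat_fdr < alpha)
    sign[sig & (R < 0)] = "negative"
    sign[sig & (R > 0)] = "positive"
    sign[degenerate] = "degenerate"
    if exclude_self:
        sign[self_pair] = "self"

    n_neg = (sign == "negative").sum(axis=1)
    n_pos = (sign == "positive").sum(axis=1)
    n_tested = family.sum(axis=1)
    summary = pd.DataFrame(
        {
            "meth_gene": probe_gene.to_numpy(),
            "n_tested": n_tested,
            "n_negative": n_neg,
            "n_positive": n_pos,
            "frac_negative": np.where(n_tested > 0, n_neg / np.maximum(n_tested, 1), np.nan),
            "frac_positive": np.where(n_tested > 0, n_pos / np.maximum(n_tested, 1), np.nan),
        },
        index=probes,
    )
    if dm_status is not None:
        summary["meth_gene_dm_status"] = summary["meth_gene"].map(dm_status)

    return TransResult(
        r=pd.DataFrame(R, index=probes, columns=genes),
        fdr=pd.DataFrame(flat_fdr, index=probes, columns=genes),
        sign=pd.DataFrame(sign, index=probes, columns=genes),
        probe_summary=summary,
        r_min=r_min,
        alpha=alpha,
    )
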