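"""The tumor-specificity screening cascade for diagnostic CpG markers.

Four sequential filters followed by information-gain ranking:

* stage 0 — hypermethylated promoter probes whose primary gene is
  down-regulated (DM hyper ∩ DE-low) in the paired cohorts;
* stage 1 — hypermethylation must replicate in the full (unpaired) tumor
  cohort against all normals (rank-sum test with BH plus the delta-beta
  gate, in the hyper direction);
* stage 2 — probes more methylated in healthy blood than in tumors are
  removed, with an additional absolute blood-mean cap so survivors are
  genuinely unmethylated in healthy people;
* stage 3 — probes whose mean beta exceeds a cap in the tumor OR normal
  samples of ANY other cancer type are removed (tumor-type specificity);
* ranking — per-probe information gain of tumor-vs-normal labels, top
  ``panel_size`` probes form the panel.

Every stage appends an audit row with its rule, counts, and the measured
quantity per probe, so the cascade narrative (a -> b -> c -> panel) is
fully reconstructible.  Cohort means use observed values only; a probe with
no observed value in a required cohort fails that stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import AnnotationTable, BetaMatrix, PROMOTER_CLASSES
from .differential import DEResult, DMResult
from .stats_core import bh_fdr, info_gain

logger = logging.getLogger(__name__)


@dataclass
class StageAudit:
    name: str
    rule: str
    n_in: int
    n_out: int
    detail: pd.DataFrame  # per-probe measured quantities and pass/fail


@dataclass
class CascadeAudit:
    stages: list[StageAudit] = field(default_factory=list)

    def add(self, stage: StageAudit) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError("cascade audit: stage input does not match previous output")
        self.stages.append(stage)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def summary(self) -> dict:
        return {
            s.name: {"rule": s.rule, "n_in": s.n_in, "n_out": s.n_out} for s in self.stages
        }


@dataclass
class MarkerPanel:
    table: pd.DataFrame  # probe_id index: gene, info_gain, rank

    @property
    def probes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _probe_means(bm: BetaMatrix, probes) -> pd.Series:
    present = [p for p in probes if p in bm.probe_ids]
    means = bm.values.loc[present].mean(axis=1)  # nan-aware via pandas
    return means.reindex(probes)


def stage0_candidates(
    dm: DMResult, de: DEResult, ann: AnnotationTable
) -> tuple[list[str], pd.DataFrame]:
    """Hyper-called promoter probes whose primary gene is DE-low."""
    if len(dm.table) == 0 or len(de.table) == 0:
        raise ValueError("stage0 requires non-empty DM and DE results")
    hyper = dm.hyper_probes
    sub = ann.df.reindex(hyper.intersection(ann.probe_ids))
    primary = sub["gene_symbols"].map(lambda g: g[0] if g else None)
    is_prom = sub["region_classes"].map(lambda rc: bool(rc) and rc[0] in PROMOTER_CLASSES)
    de_low = set(de.de_low_genes)
    keep = is_prom & primary.map(lambda g: g in de_low)
    detail = pd.DataFrame(
        {
            "gene": primary,
            "promoter": is_prom,
            "gene_de_low": primary.map(lambda g: g in de_low),
            "passed": keep,
        }
    )
    return sorted(sub.index[keep.to_numpy(dtype=bool)]), detail


def stage1_cohort_hyper(
    candidates,
    hcc_all: BetaMatrix,
    normal_all: BetaMatrix,
    alpha: float = 0.05,
    delta: float = 0.2,
    test: str = "wilcoxon",
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates whose hypermethylation replicates in the full cohorts.

    Per probe, tumor vs normal observed values are compared with a
    Wilcoxon rank-sum test (or Welch t with ``test="t"``); BH runs within
    the candidate family; the probe passes with FDR < alpha AND mean
    difference > delta in the hyper direction.
    """
    overlap = set(hcc_all.sample_ids) & set(normal_all.sample_ids)
    if overlap:
        raise ValueError(f"tumor/normal cohorts share sample ids: {sorted(overlap)[:5]}")
    candidates = list(candidates)
    if not candidates:
        return [], pd.DataFrame(columns=["delta_mean", "p", "fdr", "passed"])
    # absent probes (e.g. removed by the missingness filter in one cohort)
    # become all-NaN rows and therefore fail the stage
    T = hcc_all.values.reindex(candidates).to_numpy(dtype=float)
    N = normal_all.values.reindex(candidates).to_numpy(dtype=float)
    p = np.full(len(candidates), np.nan)
    dmean = np.full(len(candidates), np.nan)
    for i in range(len(candidates)):
        t_obs = T[i][~np.isnan(T[i])]
        n_obs = N[i][~np.isnan(N[i])]
        if len(t_obs) == 0 or len(n_obs) == 0:
            continue  # no observed values in a required cohort -> fails
        dmean[i] = t_obs.mean() - n_obs.mean()
        if test == "wilcoxon":
            p[i] = sps.mannwhitneyu(t_obs, n_obs, alternative="two-sided").pvalue
        elif test == "t":
            p[i] = sps.ttest_ind(t_obs, n_obs, equal_var=False).pvalue
        else:
            raise ValueError(f"unknown stage-1 test {test!r}")
    tested = ~np.isnan(p)
    fdr = np.full(len(candidates), np.nan)
    fdr[tested] = bh_fdr(p[tested])
    passed = tested & (fdr < alpha) & (dmean > delta)
    detail = pd.DataFrame(
        {"delta_mean": dmean, "p": p, "fdr": fdr, "passed": passed}, index=candidates
    )
    return [c for c, ok in zip(candidates, passed) if ok], detail


def stage2_blood_filter(
    probes,
    hcc_all: BetaMatrix,
    blood: BetaMatrix,
    blood_cap: float | None = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Remove probes at least as methylated in blood as in tumors.

    Keeps probes with mean beta(blood) < mean beta(tumor); with
    ``blood_cap`` set (default 0.1) the blood mean must additionally stay
    at or below the cap, so survivors are lowly methylated in healthy
    people.  ``blood_cap=None`` gives the comparison-only behavior.
    """
    probes = list(probes)
    if not probes:
        return [], pd.DataFrame(columns=["mean_blood", "mean_tumor", "passed"])
    mb = _probe_means(blood, probes)
    mt = _probe_means(hcc_all, probes)
    passed = (mb < mt) & mb.notna() & mt.notna()
    if blood_cap is not None:
        passed &= mb <= blood_cap
    detail = pd.DataFrame({"mean_blood": mb, "mean_tumor": mt, "passed": passed})
    return sorted(detail.index[passed]), detail


def stage3_pan_cancer_filter(
    probes,
    other_cancers: dict[str, dict[str, BetaMatrix]],
    cap: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Remove probes with mean beta > cap in tumor OR normal samples of any
    other cancer type."""
    probes = list(probes)
    if not other_cancers:
        raise ValueError("stage3 requires at least one other cancer cohort")
    for t, cohorts in other_cancers.items():
        for tissue, bm in cohorts.items():
            if bm.n_samples == 0:
                raise ValueError(f"other cancer cohort {t}/{tissue} has zero samples")
    if not probes:
        return [], pd.DataFrame(columns=["max_other_mean", "worst_cohort", "passed"])
    means = {}
    for t, cohorts in sorted(other_cancers.items()):
        for tissue, bm in sorted(cohorts.items()):
            means[f"{t}/{tissue}"] = _probe_means(bm, probes)
    mdf = pd.DataFrame(means)
    max_mean = mdf.max(axis=1)
    worst = mdf.idxmax(axis=1)
    passed = (max_mean <= cap) & max_mean.notna()
    detail = pd.DataFrame(
        {"max_other_mean": max_mean, "worst_cohort": worst, "passed": passed}
    )
    return sorted(detail.index[passed]), detail


def rank_by_info_gain(
    probes,
    hcc_all: BetaMatrix,
    normal_all: BetaMatrix,
    panel_size: int = 6,
    ann: AnnotationTable | None = None,
) -> tuple[MarkerPanel, pd.DataFrame]:
    """Rank probes by information gain of tumor-vs-normal labels.

    Scores are computed on observed values over the combined cohorts;
    ordering is by descending gain with a deterministic tie-break on probe
    id.  The full ranking is returned alongside the top-``panel_size``
    panel.
    """
    probes = list(probes)
    scores = {}
    labels = np.concatenate(
        [np.ones(hcc_all.n_samples, dtype=int), np.zeros(normal_all.n_samples, dtype=int)]
    )
    for p in probes:
        x = np.concatenate(
            [
                hcc_all.values.loc[p].to_numpy(dtype=float),
                normal_all.values.loc[p].to_numpy(dtype=float),
            ]
        )
        scores[p] = info_gain(x, labels)
    ranking = pd.DataFrame({"info_gain": pd.Series(scores)})
    # descending gain, stable tie-break on probe id
    ranking = ranking.sort_index(kind="mergesort").sort_values(
        by="info_gain", ascending=False, kind="mergesort"
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    if ann is not None:
        primary = ann.df["gene_symbols"].map(lambda g: g[0] if g else None)
        ranking.insert(0, "gene", primary.reindex(ranking.index))
    panel = MarkerPanel(table=ranking.head(panel_size).copy())
    return panel, ranking


def run_cascade(
    dm: DMResult,
    de: DEResult,
    ann: AnnotationTable,
    hcc_all: BetaMatrix,
    normal_all: BetaMatrix,
    blood: BetaMatrix,
    other_cancers: dict[str, dict[str, BetaMatrix]],
    panel_size: int = 6,
    stage1_alpha: float = 0.05,
    stage1_delta: float = 0.2,
    stage1_test: str = "wilcoxon",
    blood_cap: float | None = 0.1,
    pan_cap: float = 0.1,
) -> tuple[MarkerPanel, CascadeAudit]:
    """Compose stage 0 -> 1 -> 2 -> 3 -> information-gain ranking.

    Deterministic given inputs and configuration; the audit records every
    stage's rule and per-probe diagnostics.
    """
    audit = CascadeAudit()

    s0, d0 = stage0_candidates(dm, de, ann)
    audit.add(
        StageAudit(
            "stage0_dm_de",
            "hyper promoter probes of DE-low primary genes (paired cohorts)",
            n_in=len(dm.hyper_probes),
            n_out=len(s0),
            detail=d0,
        )
    )

    s1, d1 = stage1_cohort_hyper(
        s0, hcc_all, normal_all, alpha=stage1_alpha, delta=stage1_delta, test=stage1_test
    )
    audit.add(
        StageAudit(
            "stage1_cohort_hyper",
            f"{stage1_test} FDR<{stage1_alpha} and mean difference>{stage1_delta} "
            "in full tumor vs normal cohorts",
            n_in=len(s0),
            n_out=len(s1),
            detail=d1,
        )
    )

    s2, d2 = stage2_blood_filter(s1, hcc_all, blood, blood_cap=blood_cap)
    cap_txt = f" and blood mean<={blood_cap}" if blood_cap is not None else ""
    audit.add(
        StageAudit(
            "stage2_blood",
            f"blood mean < tumor mean{cap_txt}",
            n_in=len(s1),
            n_out=len(s2),
            detail=d2,
        )
    )

    s3, d3 = stage3_pan_cancer_filter(s2, other_cancers, cap=pan_cap)
    audit.add(
        StageAudit(
            "stage3_pan_cancer",
            f"mean beta <= {pan_cap} in tumor and normal samples of every other cancer type",
            n_in=len(s2),
            n_out=len(s3),
            detail=d3,
        )
    )

    panel, ranking = rank_by_info_gain(
        s3, hcc_all, normal_all, panel_size=panel_size, ann=ann
    )
    audit.add(
        StageAudit(
            "info_gain_ranking",
            f"top {panel_size} probes by information gain (tumor vs normal)",
            n_in=len(s3),
            n_out=len(panel),
            detail=ranking,
        )
    )
    counts = " -> ".join(str(s.n_out) for s in audit.stages)
    logger.info("cascade counts: %d -> %s", audit.stages[0].n_in, counts)
    return panel, audit
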