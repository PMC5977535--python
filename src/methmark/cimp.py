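"""CIMP subtyping: informative-probe selection, consensus k-means
clustering, methylator-phenotype calling, and clinical/survival association.

The clustering follows the Monti resampling scheme: repeatedly subsample
items, run k-means, and record how often each co-sampled pair lands in the
same cluster.  The consensus matrix (co-clustered / co-sampled counts) is
then cut hierarchically into k groups.  The number of clusters can be fixed
or chosen automatically; the default selector minimizes the proportion of
ambiguous clustering (PAC — the mass of consensus entries away from 0 and
1), with the consensus-CDF areas and their increments also reported for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data_model import AnnotationTable, BetaMatrix, ClinicalTable
from .stats_core import SurvivalCurve, TestResult, fisher_exact_2x2, km_estimate, logrank_test

logger = logging.getLogger(__name__)


def select_cimp_cpgs(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    ann: AnnotationTable,
    sd_min: float = 0.2,
    normal_max: float = 0.05,
) -> list[str]:
    """Promoter probes that vary across tumors (SD > sd_min) while staying
    unmethylated in normal tissue (mean beta < normal_max).

    Missing values are ignored per probe.  Raising ``sd_min`` can only
    shrink the selection.
    """
    if tumor.n_samples == 0 or normal.n_samples == 0:
        raise ValueError("select_cimp_cpgs requires non-empty tumor and normal cohorts")
    shared = tumor.probe_ids.intersection(normal.probe_ids)
    promoter = ann.promoter_mask()
    promoter = promoter.reindex(shared).fillna(False)
    t_sd = tumor.values.loc[shared].std(axis=1, ddof=1)
    n_mean = normal.values.loc[shared].mean(axis=1)
    keep = promoter & (t_sd > sd_min) & (n_mean < normal_max)
    return sorted(shared[keep.to_numpy(dtype=bool)])


@dataclass
class ConsensusResult:
    k: int
    assignments: pd.Series  # sample -> cluster label in 1..k
    consensus_matrix: pd.DataFrame  # samples x samples, for the chosen k
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    cimp_cluster: int | None = None

    def cluster_members(self, label: int) -> list[str]:
        return sorted(self.assignments.index[self.assignments == label])


def _consensus_for_k(
    X: np.ndarray, k: int, n_resamples: int, item_frac: int, rng: np.random.Generator, n_init: int
) -> np.ndarray:
    n = X.shape[0]
    size = max(k + 1, int(round(item_frac * n)))
    co_cluster = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(X[idx])
        same = labels[:, None] == labels[None, :]
        co_cluster[np.ix_(idx, idx)] += same
        co_sampled[np.ix_(idx, idx)] += 1
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "consensus: %d sample pairs never co-sampled (consensus set to 0); "
            "raise n_resamples",
            int(never.sum()) // 2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    return (consensus + consensus.T) / 2.0


def _cdf_area(consensus: np.ndarray) -> float:
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    if len(vals) == 0:
        return 0.0
    # area under the empirical CDF over [0, 1]
    cdf = np.arange(1, len(vals) + 1) / len(vals)
    xs = np.concatenate([[0.0], vals, [1.0]])
    ys = np.concatenate([[0.0], cdf, [1.0]])
    return float(np.sum(np.diff(xs) * ys[:-1]))


def _pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    vals = consensus[np.triu_indices_from(consensus, k=1)]
    if len(vals) == 0:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_cluster(
    matrix: BetaMatrix | pd.DataFrame,
    k_range=(2, 3, 4, 5, 6),
    n_resamples: int = 250,
    item_frac: float = 0.8,
    seed: int = 0,
    k: int | None = None,
    selection: str = "pac",
    n_init: int = 10,
) -> ConsensusResult:
    """Monti-style consensus k-means over the samples (columns) of a beta
    matrix restricted to informative probes.

    Per resample, ``item_frac`` of the samples are drawn without replacement
    and clustered with k-means (k-means++ initialization, ``n_init``
    restarts); consensus(i, j) = co-clustered / co-sampled.  The final
    assignment cuts average-linkage hierarchical clustering of
    1 - consensus at k.  ``k`` pins the cluster number; otherwise it is
    chosen over ``k_range`` by ``selection``: "pac" (minimize the proportion
    of ambiguous consensus entries; near-ties resolve toward the largest
    crisp k, since merging true clusters can also be stable) or
    "delta-area" (largest increment of the consensus-CDF area).  The whole
    procedure is deterministic given the seed.
    """
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("consensus_cluster requires a complete matrix; impute first")
    X = values.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    ks = [k] if k is not None else sorted(set(k_range))
    for kk in ks:
        if not 2 <= kk <= n - 1:
            raise ValueError(f"k={kk} outside [2, n_samples-1]")

    rng = np.random.default_rng(seed)
    matrices: dict[int, np.ndarray] = {}
    for kk in ks:
        matrices[kk] = _consensus_for_k(X, kk, n_resamples, item_frac, rng, n_init)

    areas = {kk: _cdf_area(m) for kk, m in matrices.items()}
    deltas = {}
    prev = 0.0
    for kk in ks:
        deltas[kk] = areas[kk] - prev
        prev = areas[kk]
    pacs = {kk: _pac(m) for kk, m in matrices.items()}

    if k is not None:
        chosen = k
    elif selection == "pac":
        # finest stable partition: the largest k whose PAC is within epsilon
        # of the minimum (merging true clusters can also be stable, so ties
        # at low PAC are resolved toward more clusters)
        eps = 0.01
        best = min(pacs.values())
        chosen = max(kk for kk in ks if pacs[kk] <= best + eps)
    elif selection == "delta-area":
        chosen = max(ks, key=lambda kk: (deltas[kk], -kk))
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    cons = matrices[chosen]
    dist = 1.0 - cons
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=chosen, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance, for determinism
    relabel, next_label = {}, 1
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = next_label
            next_label += 1
        labels[i] = relabel[c]

    samples = values.columns
    return ConsensusResult(
        k=chosen,
        assignments=pd.Series(labels, index=samples, name="cluster"),
        consensus_matrix=pd.DataFrame(cons, index=samples, columns=samples),
        cdf_area=areas,
        delta_area=deltas,
        pac=pacs,
    )


def call_cimp(
    result: ConsensusResult, matrix: BetaMatrix | pd.DataFrame, margin: float = 0.15
) -> int | None:
    """Label of the methylator-phenotype cluster, or None.

    The CIMP call goes to the cluster with the highest mean beta over the
    selected probes, provided that mean exceeds the grand mean by
    ``margin``.  margin = 0 degenerates to the plain argmax.
    """
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    grand = float(np.nanmean(values.to_numpy(dtype=float)))
    means = {}
    for label in sorted(result.assignments.unique()):
        cols = result.assignments.index[result.assignments == label]
        means[label] = float(np.nanmean(values[cols].to_numpy(dtype=float)))
    top = max(means, key=lambda c: means[c])
    if means[top] - grand > margin:
        result.cimp_cluster = int(top)
        return int(top)
    result.cimp_cluster = None
    return None


CLINICAL_COVARIATES = ("stage", "sex", "race", "viral_status")


def associate_clinical(
    assignments: pd.Series, clinical: ClinicalTable, covariates=CLINICAL_COVARIATES
) -> pd.DataFrame:
    """Fisher exact association of each cluster with each covariate level.

    ``assignments`` maps patient id -> cluster.  For every (cluster, level)
    pair a 2x2 table (in-cluster vs out x level vs not) is tested.
    Patients without clinical rows are excluded (logged); covariates with a
    single observed level are skipped with a warning.
    """
    clin = clinical.df
    common = assignments.index.intersection(clin.index)
    dropped = len(assignments) - len(common)
    if dropped:
        logger.info("associate_clinical: %d patients lack clinical data", dropped)
    assignments = assignments.loc[common]
    clin = clin.loc[common]
    rows = []
    for cov in covariates:
        levels = [l for l in clin[cov].astype(str).unique() if l != "NA"]
        if len(levels) < 2:
            logger.warning("associate_clinical: covariate %s has one level, skipped", cov)
            continue
        for cluster in sorted(assignments.unique()):
            in_c = assignments == cluster
            for level in sorted(levels):
                has = clin[cov].astype(str) == level
                a = int((in_c & has).sum())
                b = int((in_c & ~has).sum())
                c = int((~in_c & has).sum())
                d = int((~in_c & ~has).sum())
                res = fisher_exact_2x2([[a, b], [c, d]])
                rows.append(
                    {
                        "cluster": cluster,
                        "covariate": cov,
                        "level": level,
                        "n_in_with": a,
                        "n_in_without": b,
                        "n_out_with": c,
                        "n_out_without": d,
                        "odds_ratio": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SurvivalComparison:
    curves: dict[str, SurvivalCurve]
    test: TestResult
    n_per_group: dict[str, int]


def survival_by_group(
    groups: pd.Series, clinical: ClinicalTable, stage_filter: str | None = None
) -> SurvivalComparison:
    """Kaplan-Meier curves per group plus the log-rank contrast.

    ``groups`` maps patient id -> group label (e.g. CIMP / non-CIMP or the
    cluster number).  ``stage_filter`` restricts the contrast to one stage
    (e.g. "III") before testing.
    """
    clin = clinical.df
    common = groups.index.intersection(clin.index)
    groups = groups.loc[common]
    clin = clin.loc[common]
    if stage_filter is not None:
        keep = clin["stage"].astype(str) == stage_filter
        groups, clin = groups[keep], clin[keep]
    if groups.nunique() < 2:
        raise ValueError("survival_by_group needs >= 2 non-empty groups after filtering")
    times = clin["survival_time"].to_numpy(dtype=float)
    events = clin["event"].to_numpy(dtype=int)
    curves = {
        str(g): km_estimate(times[groups == g], events[groups == g])
        for g in sorted(groups.unique(), key=str)
    }
    test = logrank_test(times, events, groups.astype(str).to_numpy())
    n_per_group = {str(g): int((groups == g).sum()) for g in sorted(groups.unique(), key=str)}
    return SurvivalComparison(curves=curves, test=test, n_per_group=n_per_group)
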