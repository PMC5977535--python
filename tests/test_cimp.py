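import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methmark.cimp import (
    associate_clinical,
    call_cimp,
    consensus_cluster,
    select_cimp_cpgs,
    survival_by_group,
)
from methmark.data_model import ClinicalTable
from methmark.synthetic import SimConfig, generate_clustered_beta, generate_survival

from conftest import toy_annotation, toy_beta


class TestSelectCimpCpgs:
    def test_constant_matrix_selects_nothing(self):
        ann = toy_annotation()
        probes = list(ann.probe_ids)
        tumor = toy_beta(np.full((6, 5), 0.5), probes, [f"T{i}" for i in range(5)])
        normal = toy_beta(np.full((6, 3), 0.02), probes, [f"N{i}" for i in range(3)], tissue="normal")
        assert select_cimp_cpgs(tumor, normal, ann) == []

    def test_threshold_logic(self):
        ann = toy_annotation()
        probes = list(ann.probe_ids)
        rng = np.random.default_rng(0)
        tvals = np.full((6, 40), 0.05)
        # cgA (promoter): high tumor SD
        tvals[0] = np.where(rng.random(40) < 0.5, 0.9, 0.05)
        # cgB (body): same variance but not a promoter
        tvals[1] = tvals[0]
        tumor = toy_beta(tvals, probes, [f"T{i}" for i in range(40)])
        nvals = np.full((6, 10), 0.02)
        normal = toy_beta(nvals, probes, [f"N{i}" for i in range(10)], tissue="normal")
        assert select_cimp_cpgs(tumor, normal, ann) == ["cgA"]
        # same probe excluded once the normal mean rises above the cap
        nvals2 = nvals.copy()
        nvals2[0] = 0.2
        normal2 = toy_beta(nvals2, probes, [f"N{i}" for i in range(10)], tissue="normal")
        assert select_cimp_cpgs(tumor, normal2, ann) == []

    def test_monotone_in_sd_min(self, small_bundle):
        from methmark.data_model import drop_sex_chromosomes
        from methmark.differential import filter_missing

        tumor = filter_missing(drop_sex_chromosomes(small_bundle.hcc_tumor, small_bundle.annotation))
        normal = filter_missing(drop_sex_chromosomes(small_bundle.adjacent_normal, small_bundle.annotation))
        loose = set(select_cimp_cpgs(tumor, normal, small_bundle.annotation, sd_min=0.1))
        tight = set(select_cimp_cpgs(tumor, normal, small_bundle.annotation, sd_min=0.3))
        assert tight <= loose

    def test_recovers_planted_variable_promoters(self, default_bundle):
        from methmark.data_model import drop_sex_chromosomes
        from methmark.differential import filter_missing

        b = default_bundle
        tumor = filter_missing(drop_sex_chromosomes(b.hcc_tumor, b.annotation))
        normal = filter_missing(drop_sex_chromosomes(b.adjacent_normal, b.annotation))
        sel = set(select_cimp_cpgs(tumor, normal, b.annotation))
        recovered = len(sel & b.truth.cimp_probes) / len(b.truth.cimp_probes)
        assert recovered >= 0.9
        # nothing outside promoters sneaks in
        body = {p for p in sel if b.annotation.record(p).region_classes[0] == "Body"}
        assert not body

    def test_empty_cohort_rejected(self):
        ann = toy_annotation()
        tumor = toy_beta(np.zeros((6, 0)), list(ann.probe_ids), [])
        normal = toy_beta(np.full((6, 2), 0.02), list(ann.probe_ids), ["N0", "N1"], tissue="normal")
        with pytest.raises(ValueError):
            select_cimp_cpgs(tumor, normal, ann)


class TestConsensusCluster:
    def test_well_separated_blobs_ari_one(self):
        bm, labels = generate_clustered_beta(n_probes=80, cluster_sizes=(15, 15, 15), seed=2)
        res = consensus_cluster(bm, k_range=(2, 3, 4), n_resamples=100, seed=3)
        assert res.k == 3
        assert adjusted_rand_score(labels.values, res.assignments.values) == 1.0
        cm = res.consensus_matrix.to_numpy()
        same = labels.values[:, None] == labels.values[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert cm[same & off].mean() > 0.95
        assert cm[~same].mean() < 0.05

    def test_duplicated_samples_consensus_one(self):
        rng = np.random.default_rng(4)
        base = rng.random(30)
        vals = np.column_stack([base, base, base + 0.3, base + 0.3]).clip(0, 1)
        bm = toy_beta(vals, [f"cg{i}" for i in range(30)], ["A1", "A2", "B1", "B2"])
        res = consensus_cluster(bm, k_range=(2,), n_resamples=100, item_frac=0.9, seed=5)
        cm = res.consensus_matrix
        assert cm.loc["A1", "A2"] == pytest.approx(1.0)
        assert cm.loc["B1", "B2"] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        bm, _ = generate_clustered_beta(n_probes=40, cluster_sizes=(10, 10), seed=6)
        r1 = consensus_cluster(bm, k_range=(2, 3), n_resamples=50, seed=7)
        r2 = consensus_cluster(bm, k_range=(2, 3), n_resamples=50, seed=7)
        pd.testing.assert_frame_equal(r1.consensus_matrix, r2.consensus_matrix)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        assert r1.k == r2.k

    def test_k_out_of_range_rejected(self):
        bm, _ = generate_clustered_beta(n_probes=20, cluster_sizes=(4, 4), seed=8)
        with pytest.raises(ValueError):
            consensus_cluster(bm, k_range=(9,), n_resamples=10, seed=0)

    def test_missing_values_rejected(self):
        vals = np.full((5, 6), 0.4)
        vals[0, 0] = np.nan
        bm = toy_beta(vals, [f"cg{i}" for i in range(5)], [f"S{i}" for i in range(6)])
        with pytest.raises(ValueError, match="impute"):
            consensus_cluster(bm, k_range=(2,), n_resamples=10, seed=0)


class TestCallCimp:
    def _result_with_clusters(self, values, assignments):
        from methmark.cimp import ConsensusResult

        samples = list(values.columns)
        return ConsensusResult(
            k=len(set(assignments)),
            assignments=pd.Series(assignments, index=samples),
            consensus_matrix=pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples),
            cdf_area={},
            delta_area={},
            pac={},
        )

    def test_hypermethylated_cluster_called(self):
        vals = pd.DataFrame(
            np.column_stack([np.full((10, 4), 0.1), np.full((10, 2), 0.7)]),
            index=[f"cg{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(6)],
        )
        res = self._result_with_clusters(vals, [1, 1, 1, 1, 2, 2])
        assert call_cimp(res, vals) == 2
        assert res.cimp_cluster == 2

    def test_no_hypermethylated_cluster_none(self):
        vals = pd.DataFrame(
            np.full((10, 6), 0.3), index=[f"cg{i}" for i in range(10)], columns=[f"S{i}" for i in range(6)]
        )
        res = self._result_with_clusters(vals, [1, 1, 1, 2, 2, 2])
        assert call_cimp(res, vals) is None

    def test_zero_margin_always_argmax(self):
        vals = pd.DataFrame(
            np.column_stack([np.full((5, 3), 0.30), np.full((5, 3), 0.31)]),
            index=[f"cg{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(6)],
        )
        res = self._result_with_clusters(vals, [1, 1, 1, 2, 2, 2])
        assert call_cimp(res, vals, margin=0.0) == 2


class TestClinicalAssociation:
    def _clinical(self, n, stage3_idx):
        df = pd.DataFrame(
            {
                "survival_time": np.linspace(10, 1000, n),
                "event": 1,
                "stage": ["III" if i in stage3_idx else "I" for i in range(n)],
                "sex": ["male" if i % 2 else "female" for i in range(n)],
                "race": "asian",
                "viral_status": "none",
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )
        return ClinicalTable(df)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        cluster = pd.Series([2 if i < 40 else 1 for i in range(n)], index=[f"P{i}" for i in range(n)])
        stage3 = {i for i in range(40) if rng.random() < 0.8} | {
            i for i in range(40, n) if rng.random() < 0.2
        }
        res = associate_clinical(cluster, self._clinical(n, stage3))
        row = res[(res["cluster"] == 2) & (res["covariate"] == "stage") & (res["level"] == "III")]
        assert float(row["p_value"].iloc[0]) < 0.01

    def test_single_level_covariate_skipped(self):
        cluster = pd.Series([1, 1, 2, 2], index=[f"P{i}" for i in range(4)])
        res = associate_clinical(cluster, self._clinical(4, set()), covariates=("race",))
        assert len(res) == 0

    def test_null_covariate_not_enriched(self):
        rng = np.random.default_rng(10)
        n = 200
        cluster = pd.Series(rng.integers(1, 3, n), index=[f"P{i}" for i in range(n)])
        stage3 = {i for i in range(n) if rng.random() < 0.3}
        res = associate_clinical(cluster, self._clinical(n, stage3))
        sub = res[(res["covariate"] == "stage") & (res["level"] == "III")]
        assert (sub["p_value"] > 0.001).all()


class TestSurvivalByGroup:
    def test_planted_hazard_detected_and_stage_filter(self):
        cfg = SimConfig(hazard_ratio_cimp=4.0, censoring_rate=0.1, stage3_prob_cimp=0.5, stage3_prob_other=0.5)
        pats = [f"P{i}" for i in range(300)]
        cimp = set(pats[:100])
        clin = generate_survival(pats, cimp, cfg, seed=12)
        groups = pd.Series(["CIMP" if p in cimp else "rest" for p in pats], index=pats)
        comp = survival_by_group(groups, clin)
        assert comp.test.p_value < 1e-4
        assert set(comp.curves) == {"CIMP", "rest"}
        comp3 = survival_by_group(groups, clin, stage_filter="III")
        assert comp3.n_per_group["CIMP"] < comp.n_per_group["CIMP"]
        assert comp3.test.p_value < 0.05

    def test_single_group_rejected(self):
        clin = generate_survival([f"P{i}" for i in range(10)], [], SimConfig(), seed=0)
        groups = pd.Series(["g"] * 10, index=[f"P{i}" for i in range(10)])
        with pytest.raises(ValueError):
            survival_by_group(groups, clin)
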