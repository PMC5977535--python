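import logging

import numpy as np
import pandas as pd
import pytest

from methmark.data_model import AnnotationTable, BetaMatrix, CpGAnnotation
from methmark.differential import paired_de, paired_dm
from methmark.pipeline import PipelineConfig, _prepare_paired
from methmark.synthetic import SimConfig, generate_bundle

logging.getLogger("methmark").setLevel(logging.ERROR)


def small_sim_config(**overrides) -> SimConfig:
    """Scaled-down study conditions for fast unit tests."""
    base = dict(
        n_probes=2_000,
        n_genes=300,
        n_hcc=40,
        n_paired_normal=15,
        n_blood=20,
        n_other_cancers=3,
        n_other_tumor=15,
        n_other_normal=8,
        n_sex_probes=40,
        n_dm_hyper=60,
        n_dm_hypo=120,
        n_specific_markers=4,
        n_pan_cancer=6,
        n_blood_high=6,
        n_pair_artifact=6,
        n_cimp_probes=60,
        n_de_low=30,
        n_de_high=20,
        n_cis_negative=20,
        n_cis_positive=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_sim_config(), seed=42)


@pytest.fixture(scope="session")
def small_paired(small_bundle):
    return _prepare_paired(small_bundle, PipelineConfig(bundle_dir="unused"))


@pytest.fixture(scope="session")
def small_dm(small_paired):
    tumor, normal = small_paired
    return paired_dm(tumor, normal)


@pytest.fixture(scope="session")
def small_de(small_bundle):
    meta = small_bundle.expression.meta()
    paired = set(small_bundle.paired_patients())
    samples = meta.index[meta["patient_id"].isin(paired)]
    return paired_de(small_bundle.expression.subset_samples(samples))


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the full default study conditions, shared across tests."""
    return generate_bundle(SimConfig(), seed=7)


def toy_annotation() -> AnnotationTable:
    """Six-probe manifest covering promoters, body, multi-gene and sex probes."""
    return AnnotationTable.from_records(
        [
            CpGAnnotation("cgA", "1", 100, ("G1",), ("TSS200",), "Island", -100),
            CpGAnnotation("cgB", "1", 200, ("G1",), ("Body",), "OpenSea", 2000),
            CpGAnnotation("cgC", "7", 300, ("G2", "G1"), ("TSS1500", "Body"), "Island", -900),
            CpGAnnotation("cgD", "X", 400, ("G3",), ("TSS200",), "N_Shore", -50),
            CpGAnnotation("cgE", "Y", 500, (), (), "OpenSea", None),
            CpGAnnotation("cgF", "2", 600, ("G4",), ("3UTR",), "S_Shelf", 9000),
        ]
    )


def toy_beta(values: np.ndarray, probes, samples, tissue="tumor", patients=None) -> BetaMatrix:
    meta = pd.DataFrame(
        {
            "cohort_id": "toy",
            "tissue_type": tissue if isinstance(tissue, list) else [tissue] * len(samples),
            "cancer_type": "HCC",
            "patient_id": patients if patients is not None else list(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), meta)
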