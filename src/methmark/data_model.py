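"""Domain containers and file I/O for 450K-style methylation cohorts.

The central objects are:

* :class:`AnnotationTable` — per-probe genomic context (gene, gene-region
  class, CpG-island relation, distance to TSS) mirroring the columns of the
  HumanMethylation450 manifest that the analysis actually uses.
* :class:`BetaMatrix` — probes x samples methylation fractions (beta values
  in [0, 1], NaN for missing) plus per-sample metadata (cohort, tissue type,
  cancer type, patient id).
* :class:`CountMatrix` — genes x samples raw RNA-seq read counts with the
  same metadata layout.
* :class:`ClinicalTable` — per-patient survival and covariates.

File formats are plain text: beta and count matrices are TSV with the
feature id in the first column and ``NA`` for missing beta values; metadata,
annotation and clinical tables are CSV.  Coordinates are 1-based.  Missing
is a first-class value distinct from 0; every statistic downstream declares
its missing policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGION_CLASSES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})
#: gene-region classes treated as "promoter": within 1500 bp upstream of the TSS
PROMOTER_CLASSES = frozenset({"TSS1500", "TSS200"})
CGI_RELATIONS = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)
TISSUE_TYPES = frozenset({"tumor", "normal", "blood"})
SEX_CHROMOSOMES = frozenset({"X", "Y"})

META_COLUMNS = ["cohort_id", "tissue_type", "cancer_type", "patient_id"]


class DataFormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGAnnotation:
    """Genomic context of a single CpG probe.

    ``gene_symbols`` and ``region_classes`` are parallel: probe i is in
    region ``region_classes[j]`` of gene ``gene_symbols[j]``.  Multi-gene
    probes are resolved downstream by the primary-gene convention (first
    listed gene).
    """

    probe_id: str
    chromosome: str
    position: int
    gene_symbols: tuple[str, ...] = ()
    region_classes: tuple[str, ...] = ()
    cgi_relation: str = "OpenSea"
    distance_to_tss: int | None = None

    def __post_init__(self) -> None:
        if len(self.gene_symbols) != len(self.region_classes):
            raise ValueError(
                f"{self.probe_id}: gene_symbols and region_classes must be parallel"
            )
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1")
        bad = set(self.region_classes) - REGION_CLASSES
        if bad:
            raise ValueError(f"{self.probe_id}: unknown region classes {sorted(bad)}")
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValueError(f"{self.probe_id}: unknown CGI relation {self.cgi_relation}")

    @property
    def primary_gene(self) -> str | None:
        return self.gene_symbols[0] if self.gene_symbols else None


class AnnotationTable:
    """Vectorized view over a set of :class:`CpGAnnotation` records.

    Internally a DataFrame indexed by probe id with object columns
    ``gene_symbols`` / ``region_classes`` holding tuples.
    """

    def __init__(self, df: pd.DataFrame):
        required = {
            "chromosome",
            "position",
            "gene_symbols",
            "region_classes",
            "cgi_relation",
            "distance_to_tss",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise DataFormatError(f"duplicate probe ids in annotation: {dups}")
        self.df = df

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CpGAnnotation]) -> "AnnotationTable":
        rows = [
            {
                "probe_id": r.probe_id,
                "chromosome": r.chromosome,
                "position": r.position,
                "gene_symbols": tuple(r.gene_symbols),
                "region_classes": tuple(r.region_classes),
                "cgi_relation": r.cgi_relation,
                "distance_to_tss": r.distance_to_tss,
            }
            for r in records
        ]
        df = pd.DataFrame(rows).set_index("probe_id")
        return cls(df)

    # -- accessors ---------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.df.index

    def record(self, probe_id: str) -> CpGAnnotation:
        row = self.df.loc[probe_id]
        dtss = row["distance_to_tss"]
        return CpGAnnotation(
            probe_id=probe_id,
            chromosome=str(row["chromosome"]),
            position=int(row["position"]),
            gene_symbols=tuple(row["gene_symbols"]),
            region_classes=tuple(row["region_classes"]),
            cgi_relation=row["cgi_relation"],
            distance_to_tss=None if pd.isna(dtss) else int(dtss),
        )

    def records(self) -> Iterator[CpGAnnotation]:
        for pid in self.df.index:
            yield self.record(pid)

    @property
    def primary_gene(self) -> pd.Series:
        """First listed gene per probe (None for intergenic probes)."""
        return self.df["gene_symbols"].map(lambda g: g[0] if g else None)

    def promoter_mask(self, primary_only: bool = False) -> pd.Series:
        """Boolean Series: probe lies in the promoter (TSS1500/TSS200).

        With ``primary_only`` the region class is taken with respect to the
        first listed gene only; otherwise a promoter annotation to any gene
        qualifies.
        """
        if primary_only:
            return self.df["region_classes"].map(
                lambda rc: bool(rc) and rc[0] in PROMOTER_CLASSES
            )
        return self.df["region_classes"].map(
            lambda rc: any(c in PROMOTER_CLASSES for c in rc)
        )

    def promoter_probes(self, gene: str) -> list[str]:
        """Probes annotated as TSS1500/TSS200 for ``gene`` (any position in
        the gene list).  Unknown genes yield an empty list."""
        out = []
        for pid, genes, regions in zip(
            self.df.index, self.df["gene_symbols"], self.df["region_classes"]
        ):
            for g, rc in zip(genes, regions):
                if g == gene and rc in PROMOTER_CLASSES:
                    out.append(pid)
                    break
        return out

    def autosomal_probes(self) -> pd.Index:
        chrom = self.df["chromosome"].astype(str)
        return self.df.index[~chrom.isin(SEX_CHROMOSOMES)]

    def subset(self, probe_ids: Sequence[str]) -> "AnnotationTable":
        return AnnotationTable(self.df.loc[list(probe_ids)])


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _validate_meta(meta: pd.DataFrame, sample_ids: pd.Index, what: str) -> None:
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise DataFormatError(f"{what}: sample metadata missing {sorted(missing_cols)}")
    if meta.index.has_duplicates:
        raise DataFormatError(f"{what}: duplicate sample ids in metadata")
    absent = [s for s in sample_ids if s not in meta.index]
    if absent:
        raise DataFormatError(f"{what}: samples without metadata: {absent[:5]}")
    bad = set(meta.loc[list(sample_ids), "tissue_type"]) - TISSUE_TYPES
    if bad:
        raise DataFormatError(f"{what}: unknown tissue_type values {sorted(bad)}")


@dataclass
class BetaMatrix:
    """Probes x samples beta values with per-sample metadata.

    ``values``: float DataFrame, index = probe ids, columns = sample ids,
    NaN = missing.  ``sample_meta``: DataFrame indexed by sample id with
    columns cohort_id, tissue_type, cancer_type, patient_id (patient_id may
    be NaN for unmatched samples, e.g. blood donors).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise DataFormatError(f"duplicate probe ids: {dups}")
        if v.columns.has_duplicates:
            raise DataFormatError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"beta value {arr[i, j]!r} out of [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        _validate_meta(self.sample_meta, v.columns, "beta matrix")

    # -- accessors ---------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta(self) -> pd.DataFrame:
        """Metadata rows aligned to the sample columns."""
        return self.sample_meta.loc[self.values.columns]

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.sample_meta)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        return BetaMatrix(self.values[ids], self.sample_meta.loc[ids])

    def patients(self) -> pd.Series:
        return self.meta()["patient_id"]


@dataclass
class CountMatrix:
    """Genes x samples raw read counts with sample metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise DataFormatError("duplicate gene ids in count matrix")
        arr = c.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataFormatError(
                f"negative count at gene {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataFormatError("counts must be integral")
        _validate_meta(self.sample_meta, c.columns, "count matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def meta(self) -> pd.DataFrame:
        return self.sample_meta.loc[self.counts.columns]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.sample_meta.loc[ids])


STAGES = ("I", "II", "III", "IV", "NA")
VIRAL_STATUSES = ("HBV", "HCV", "none", "NA")


@dataclass
class ClinicalTable:
    """Per-patient survival time (days), event flag and covariates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        required = {"survival_time", "event", "stage", "sex", "race", "viral_status"}
        missing = required - set(df.columns)
        if missing:
            raise DataFormatError(f"clinical table missing columns {sorted(missing)}")
        if df.index.has_duplicates:
            raise DataFormatError("duplicate patient ids in clinical table")
        if (df["survival_time"] < 0).any():
            raise DataFormatError("negative survival_time")
        if not df["event"].isin([0, 1]).all():
            raise DataFormatError("event must be 0 or 1")
        bad = set(df["stage"].astype(str)) - set(STAGES)
        if bad:
            raise DataFormatError(f"unknown stage values {sorted(bad)}")
        bad = set(df["viral_status"].astype(str)) - set(VIRAL_STATUSES)
        if bad:
            raise DataFormatError(f"unknown viral_status values {sorted(bad)}")

    @property
    def patient_ids(self) -> pd.Index:
        return self.df.index


# ---------------------------------------------------------------------------
# elementary methylation arithmetic
# ---------------------------------------------------------------------------


def compute_beta(m, u, offset: float = 100.0):
    """Beta value from methylated/unmethylated intensities: M / (U + M + offset).

    The offset (default 100, the standard Illumina stabilizer) keeps the
    value strictly below 1 and damps low-intensity noise.  Accepts scalars
    or arrays; negative intensities are rejected.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    beta = m / (u + m + offset)
    return float(beta) if beta.ndim == 0 else beta


def drop_sex_chromosomes(matrix: BetaMatrix, ann: AnnotationTable) -> BetaMatrix:
    """Remove probes on chromosomes X and Y; the sample set is unchanged."""
    unannotated = [p for p in matrix.probe_ids if p not in ann]
    if unannotated:
        raise ValueError(
            f"{len(unannotated)} probes without annotation, e.g. {unannotated[:5]}"
        )
    chrom = ann.df.loc[matrix.probe_ids, "chromosome"].astype(str)
    keep = matrix.probe_ids[~chrom.isin(SEX_CHROMOSOMES)]
    if len(keep) == 0:
        logger.warning("drop_sex_chromosomes: no autosomal probes remain")
    return matrix.subset_probes(keep)


def promoter_probes(ann: AnnotationTable, gene: str) -> list[str]:
    """Probe ids whose region class for ``gene`` is TSS1500 or TSS200."""
    return ann.promoter_probes(gene)


def paired_sample_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Patients with both a tumor and a normal sample in ``meta``.

    Returns a DataFrame with columns patient_id, tumor_sample, normal_sample
    (first sample of each tissue type per patient, in metadata order).
    """
    rows = []
    with_patient = meta.dropna(subset=["patient_id"])
    for pid, grp in with_patient.groupby("patient_id", sort=True):
        tumors = grp.index[grp["tissue_type"] == "tumor"]
        normals = grp.index[grp["tissue_type"] == "normal"]
        if len(tumors) and len(normals):
            rows.append(
                {"patient_id": pid, "tumor_sample": tumors[0], "normal_sample": normals[0]}
            )
    return pd.DataFrame(rows, columns=["patient_id", "tumor_sample", "normal_sample"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NA_VALUES = ["NA", ""]


def _read_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, dtype=str, keep_default_na=False, na_values=[""])
    if "sample_id" not in meta.columns:
        raise DataFormatError(f"{meta_path}: metadata needs a sample_id column")
    return meta.set_index("sample_id")


def read_beta_matrix(path, meta_path) -> BetaMatrix:
    values = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    values.index = values.index.astype(str)
    try:
        return BetaMatrix(values.astype(float), _read_meta(meta_path))
    except DataFormatError as e:
        raise DataFormatError(f"{path}: {e}") from e


def write_beta_matrix(bm: BetaMatrix, path, meta_path) -> None:
    out = bm.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    meta = bm.meta().copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def read_counts(path, meta_path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    try:
        return CountMatrix(counts.astype(np.int64), _read_meta(meta_path))
    except (DataFormatError, ValueError) as e:
        raise DataFormatError(f"{path}: {e}") from e


def write_counts(cm: CountMatrix, path, meta_path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    meta = cm.meta().copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def _join_tuple(t: tuple) -> str:
    return ";".join(t)


def read_annotation(path) -> AnnotationTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    required = {
        "probe_id",
        "chromosome",
        "position",
        "gene_symbols",
        "region_classes",
        "cgi_relation",
        "distance_to_tss",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: annotation missing columns {sorted(missing)}")
    df = df.set_index("probe_id")
    df["position"] = df["position"].astype(int)
    df["gene_symbols"] = df["gene_symbols"].map(
        lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ()
    )
    df["region_classes"] = df["region_classes"].map(
        lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ()
    )
    df["distance_to_tss"] = pd.to_numeric(df["distance_to_tss"], errors="coerce")
    try:
        return AnnotationTable(df)
    except (DataFormatError, ValueError) as e:
        raise DataFormatError(f"{path}: {e}") from e


def write_annotation(ann: AnnotationTable, path) -> None:
    out = ann.df.copy()
    out["gene_symbols"] = out["gene_symbols"].map(_join_tuple)
    out["region_classes"] = out["region_classes"].map(_join_tuple)
    out["distance_to_tss"] = out["distance_to_tss"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.index.name = "probe_id"
    out.to_csv(path)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[""])
    if "patient_id" not in df.columns:
        raise DataFormatError(f"{path}: clinical table needs a patient_id column")
    df = df.set_index("patient_id")
    df["survival_time"] = df["survival_time"].astype(float)
    df["event"] = df["event"].astype(int)
    try:
        return ClinicalTable(df)
    except DataFormatError as e:
        raise DataFormatError(f"{path}: {e}") from e


def write_clinical(ct: ClinicalTable, path) -> None:
    out = ct.df.copy()
    out.index.name = "patient_id"
    out.to_csv(path)
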