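"""Reading, validation and filtering of genus count tables, sample metadata
and clinical tables.

The canonical on-disk formats are plain TSV: a count table with genus ids
in the first column and sample ids in the header; a sample metadata table
with columns sample_id, patient_id, sample_type; and a clinical table keyed
by patient_id.  A dense BIOM-style JSON reader is provided for convenience.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenusCountTable",
    "ClinicalTable",
    "read_count_table",
    "read_biom_json",
    "read_clinical_table",
    "filter_taxa",
    "detection_limit_fraction",
    "split_triplets",
    "SAMPLE_TYPES",
]

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("tumour", "normal", "stool")

# accepted aliases, case-insensitive ("T"/"VN"/"S" follow the figure-caption
# shorthand for tumour / visually normal / stool swabs)
_TYPE_ALIASES = {
    "tumour": "tumour",
    "tumor": "tumour",
    "t": "tumour",
    "normal": "normal",
    "visually_normal": "normal",
    "vn": "normal",
    "stool": "stool",
    "s": "stool",
}

CLINICAL_ENUMS = {
    "gender": {"male", "female"},
    "localisation": {"right", "transverse", "left", "rectosigmoideum", "rectum"},
    "grade": {"NA_in_situ", "1", "2", "3"},
    "ajcc": {"0", "I", "II", "III", "IV"},
    "pT": {"pTis", "pT1", "pT2", "pT3", "pT4"},
    "pN": {"pN0", "pN1", "pN2"},
    "M": {"M0", "M1"},
    "msi": {"MSI", "MSS", "NA"},
    "braf": {"wt", "mut", "NA"},
    "kras": {"wt", "mut", "NA"},
    "nras": {"wt", "mut", "NA"},
}


def normalise_sample_type(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _TYPE_ALIASES:
        raise ValueError(
            f"unknown sample_type {value!r}; expected one of {sorted(set(_TYPE_ALIASES))}"
        )
    return _TYPE_ALIASES[key]


@dataclass
class GenusCountTable:
    """Integer genus x sample count matrix joined to per-sample metadata.

    ``counts``: DataFrame (genus x sample, non-negative integers).
    ``sample_meta``: DataFrame indexed by sample_id with columns
    patient_id, sample_type in {tumour, normal, stool}.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate genus ids")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.asarray(arr, dtype=float) % 1 == 0):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        meta = self.sample_meta
        missing = set(c.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        meta = meta.loc[list(c.columns)].copy()
        meta["sample_type"] = [normalise_sample_type(t) for t in meta["sample_type"]]
        dup = meta.groupby(["patient_id", "sample_type"]).size()
        bad = dup[dup > 1]
        if len(bad):
            raise ValueError(f"patient has duplicate sample types: {bad.index.tolist()}")
        depths = arr.sum(axis=0)
        if (depths == 0).any():
            zero = list(c.columns[depths == 0])
            raise ValueError(f"zero-depth samples: {zero}")
        self.sample_meta = meta

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of_type(self, sample_type: str) -> list[str]:
        st = normalise_sample_type(sample_type)
        return list(self.sample_meta.index[self.sample_meta["sample_type"] == st])

    def subset_samples(self, sample_ids) -> "GenusCountTable":
        ids = list(sample_ids)
        return GenusCountTable(self.counts[ids], self.sample_meta.loc[ids])

    def subset_genera(self, genus_ids) -> "GenusCountTable":
        return GenusCountTable(self.counts.loc[list(genus_ids)], self.sample_meta)

    def write(self, counts_path, meta_path) -> None:
        self.counts.rename_axis("genus_id").to_csv(counts_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates with enumerated category labels."""

    data: pd.DataFrame  # indexed by patient_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate patient ids in clinical table")
        for col, allowed in CLINICAL_ENUMS.items():
            if col not in df.columns:
                continue
            vals = set(df[col].dropna().astype(str))
            bad = vals - allowed
            if bad:
                raise ValueError(f"invalid {col} labels: {sorted(bad)}")

    def for_patients(self, patient_ids) -> pd.DataFrame:
        return self.data.loc[[p for p in patient_ids if p in self.data.index]]


def read_count_table(path, meta_path) -> GenusCountTable:
    """Read a genus x sample TSV/CSV count table plus sample metadata."""
    sep = "," if str(path).endswith(".csv") else "\t"
    counts = pd.read_csv(path, sep=sep, index_col=0)
    msep = "," if str(meta_path).endswith(".csv") else "\t"
    meta = pd.read_csv(meta_path, sep=msep, index_col=0, dtype=str)
    for col in ("patient_id", "sample_type"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    return GenusCountTable(counts, meta)


def read_biom_json(path, meta_path) -> GenusCountTable:
    """Read a dense BIOM-style JSON table (rows = genera, columns = samples)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValueError("only dense BIOM-JSON tables are supported")
    genus_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = pd.DataFrame(doc["data"], index=genus_ids, columns=sample_ids)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return GenusCountTable(counts, meta)


def read_clinical_table(path) -> ClinicalTable:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"])
    return ClinicalTable(df)


def filter_taxa(
    table: GenusCountTable, min_samples: int = 3, min_reads: int = 9
) -> GenusCountTable:
    """Keep a genus iff some sample type has >= ``min_samples`` samples each
    carrying >= ``min_reads`` reads of it (contamination guard).

    Idempotent, and monotone in the sample set: adding samples can only
    keep more genera.
    """
    keep = np.zeros(len(table.genus_ids), dtype=bool)
    for st in SAMPLE_TYPES:
        ids = table.samples_of_type(st)
        if not ids:
            continue
        hits = (table.counts[ids] >= min_reads).sum(axis=1)
        keep |= (hits >= min_samples).to_numpy()
    removed = int((~keep).sum())
    frac = removed / max(len(keep), 1)
    logger.info("filter_taxa removed %d/%d genera (%.1f%%)", removed, len(keep), 100 * frac)
    if keep.sum() == 0:
        warnings.warn("taxa filter removed every genus")
    out = GenusCountTable(table.counts.loc[keep], table.sample_meta)
    return out


def detection_limit_fraction(min_reads: int = 9, min_depth: int = 2968) -> float:
    """Relative-abundance detection limit implied by a read threshold, as a
    percentage of the shallowest sample's depth, rounded to one decimal."""
    if min_depth <= 0:
        raise ValueError("min_depth must be positive")
    return round(100.0 * min_reads / min_depth, 1)


def split_triplets(table: GenusCountTable) -> tuple[GenusCountTable, GenusCountTable]:
    """Split into the triplet subtable (patients with tumour+normal+stool)
    and the duplet subtable (patients with tumour+normal only)."""
    have = table.sample_meta.groupby("patient_id")["sample_type"].agg(frozenset)
    triplet_pat = set(have.index[have == frozenset(SAMPLE_TYPES)])
    duplet_pat = set(have.index[have == frozenset(("tumour", "normal"))])
    meta = table.sample_meta
    trip_ids = list(meta.index[meta["patient_id"].isin(triplet_pat)])
    dup_ids = list(meta.index[meta["patient_id"].isin(duplet_pat)])
    trip = table.subset_samples(trip_ids) if trip_ids else _empty_like(table)
    dup = table.subset_samples(dup_ids) if dup_ids else _empty_like(table)
    return trip, dup


def _empty_like(table: GenusCountTable) -> GenusCountTable:
    t = object.__new__(GenusCountTable)
    t.counts = table.counts.iloc[:, 0:0]
    t.sample_meta = table.sample_meta.iloc[0:0]
    return t


def triplet_patients(table: GenusCountTable) -> list[str]:
    """Patients contributing all three sample types, in stable order."""
    have = table.sample_meta.groupby("patient_id", sort=False)["sample_type"].agg(frozenset)
    return [p for p, s in have.items() if s == frozenset(SAMPLE_TYPES)]
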