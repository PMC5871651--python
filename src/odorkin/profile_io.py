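"""Readers and writers for peak tables, metadata, pedigrees and results.

File conventions
----------------
* Peak table: wide CSV, first column ``sample_id``, remaining columns one
  per compound (e.g. retention-time labels like ``RT31.70``); values are
  non-negative chromatographic areas in arbitrary units, absence = 0.
* Metadata: CSV ``sample_id,individual_id,sex,group,age,rank`` with one
  row per sample; rank may be empty (e.g. for males).
* Pedigree: CSV ``id,mother,father``; empty field = unknown parent.
* All files UTF-8 with header; decimal point "."; floats serialized at
  12 significant digits so write-read round-trips are exact for display
  purposes.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable

__all__ = [
    "PeakTable",
    "IndividualMetadata",
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "write_metadata",
    "read_pedigree",
    "write_pedigree",
    "write_manifest",
]

FLOAT_FMT = "%.12g"


class DataFormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class PeakTable:
    """Samples-by-compounds matrix of non-negative peak areas."""

    sample_ids: list[str]
    compound_ids: list[str]
    areas: np.ndarray  # shape (n_samples, n_compounds)
    is_blank: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.compound_ids)):
            raise DataFormatError(
                f"area matrix shape {self.areas.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.compound_ids)} compounds"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise DataFormatError("duplicate compound ids")
        bad = np.argwhere(~np.isfinite(self.areas) | (self.areas < 0))
        if bad.size:
            i, j = bad[0]
            raise DataFormatError(
                f"negative or non-numeric area at sample {self.sample_ids[i]!r}, "
                f"compound {self.compound_ids[j]!r}"
            )
        if self.is_blank is None:
            self.is_blank = np.zeros(len(self.sample_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.compound_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "PeakTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            compound_ids=[str(c) for c in df.columns],
            areas=df.to_numpy(dtype=float),
            **kw,
        )

    def subset_compounds(self, keep: list[str]) -> "PeakTable":
        idx = [self.compound_ids.index(c) for c in keep]
        return PeakTable(list(self.sample_ids), list(keep), self.areas[:, idx],
                         is_blank=None if self.is_blank is None else self.is_blank.copy())

    def subset_samples(self, keep: list[str]) -> "PeakTable":
        idx = [self.sample_ids.index(s) for s in keep]
        blanks = None if self.is_blank is None else self.is_blank[idx]
        return PeakTable(list(keep), list(self.compound_ids), self.areas[idx], is_blank=blanks)


@dataclass
class IndividualMetadata:
    """Per-individual attributes plus the sample -> individual map."""

    individuals: pd.DataFrame  # index individual_id; columns sex, group, age, rank
    sample_map: pd.Series = field(default=None)  # index sample_id -> individual_id

    def individuals_of(self, sample_ids: list[str]) -> list[str]:
        return [self.sample_map[s] for s in sample_ids]

    def subset(self, individual_ids: list[str]) -> "IndividualMetadata":
        keep = self.individuals.loc[individual_ids]
        smap = self.sample_map[self.sample_map.isin(individual_ids)]
        return IndividualMetadata(keep, smap)


def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise DataFormatError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataFormatError(f"{path}: duplicate sample ids {dups}")
    body = df.set_index("sample_id")
    try:
        areas = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: non-numeric peak area ({exc})") from exc
    if np.isnan(areas).any():
        i, j = np.argwhere(np.isnan(areas))[0]
        raise DataFormatError(
            f"{path}: missing/non-numeric area at row {body.index[i]!r}, column {body.columns[j]!r}"
        )
    neg = np.argwhere(areas < 0)
    if neg.size:
        i, j = neg[0]
        raise DataFormatError(
            f"{path}: negative area at row {body.index[i]!r}, column {body.columns[j]!r}"
        )
    return PeakTable.from_frame(body)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, float_format=FLOAT_FMT)


def read_metadata(path: str | Path, peaks: PeakTable | None = None) -> IndividualMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str, "sex": str, "group": str})
    required = ["sample_id", "individual_id", "sex", "group", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    if "rank" not in df.columns:
        df["rank"] = np.nan
    if df["sample_id"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate sample ids")
    bad_sex = sorted(set(df["sex"]) - {"F", "M"})
    if bad_sex:
        raise DataFormatError(f"{path}: sex values outside {{F,M}}: {bad_sex}")
    if (df["age"] <= 0).any():
        raise DataFormatError(f"{path}: non-positive ages")
    ranks = df["rank"].astype(float)
    out_of_range = ranks.notna() & ((ranks < 0) | (ranks > 1))
    if out_of_range.any():
        vals = sorted(ranks[out_of_range].unique())
        raise DataFormatError(f"{path}: rank values outside [0,1]: {vals}")
    # per-individual attributes must be consistent across their samples
    per_ind = df.groupby("individual_id")[["sex", "group", "age", "rank"]].nunique(dropna=False)
    inconsistent = per_ind[(per_ind > 1).any(axis=1)].index.tolist()
    if inconsistent:
        raise DataFormatError(f"{path}: inconsistent attributes for individuals {inconsistent}")
    individuals = (
        df.drop_duplicates("individual_id")
        .set_index("individual_id")[["sex", "group", "age", "rank"]]
        .astype({"age": float, "rank": float})
    )
    sample_map = df.set_index("sample_id")["individual_id"]
    if peaks is not None:
        orphans = sorted(set(peaks.sample_ids) - set(sample_map.index))
        if orphans:
            raise DataFormatError(f"{path}: peak-table samples without metadata: {orphans}")
    return IndividualMetadata(individuals, sample_map)


def write_metadata(meta: IndividualMetadata, path: str | Path) -> None:
    rows = []
    for sample_id, ind in meta.sample_map.items():
        rec = meta.individuals.loc[ind]
        rows.append(
            {
                "sample_id": sample_id,
                "individual_id": ind,
                "sex": rec["sex"],
                "group": rec["group"],
                "age": rec["age"],
                "rank": "" if pd.isna(rec["rank"]) else rec["rank"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return PedigreeTable.from_frame(df)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, *, inputs: dict[str, str] | None = None,
                   parameters: dict | None = None, seed: int | None = None,
                   timings: dict[str, float] | None = None) -> dict:
    """Write a JSON run manifest capturing inputs, parameters and versions."""
    from . import __version__

    manifest = {
        "tool": "odorkin",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)} for name, p in (inputs or {}).items()
        },
        "parameters": parameters or {},
        "timings_s": timings or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
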