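"""Core in-memory containers shared by every analysis stage.

A peak table is a samples x mass-peaks matrix of nonnegative intensities with a
units tag; sample metadata is a plain :class:`pandas.DataFrame` keyed by sample
id; distance matrices get a thin validated wrapper so that symmetric/zero-diagonal
invariants are checked once, at construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: recognised units tags for a peak table
UNITS = ("counts", "ppbV", "ratio")

#: metadata columns every sample table must carry
META_COLUMNS = ("role", "species", "strain", "replicate", "location", "season", "matrix")

_PEAK_LABEL_RE = re.compile(r"^ms(\d+(?:\.\d+)?)$")


def peak_label(mz: float) -> str:
    """Format an m/z value as a peak-column label, e.g. ``ms61.0295``."""
    return f"ms{mz:.4f}"


def label_to_mz(label: str) -> float:
    """Parse the m/z value out of a ``ms<mz>`` column label."""
    m = _PEAK_LABEL_RE.match(str(label))
    if m is None:
        raise ValueError(f"not a peak label: {label!r}")
    return float(m.group(1))


@dataclass
class PeakTable:
    """Samples x peaks intensity matrix.

    ``data`` has sample ids as index and ``ms<mz>`` labels as columns;
    ``units`` records what the numbers mean (raw ion count rates, headspace
    concentrations in ppbV, or ratios to the sample mean).
    """

    data: pd.DataFrame
    units: str = "ppbV"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated peak labels: {dupes}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicated sample ids in peak table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def peaks(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mz(self) -> np.ndarray:
        """m/z values parsed from the column labels, in column order."""
        return np.array([label_to_mz(c) for c in self.data.columns])

    def subset_peaks(self, peaks: Sequence[str]) -> "PeakTable":
        return PeakTable(self.data.loc[:, list(peaks)], units=self.units)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        return PeakTable(self.data.loc[list(sample_ids)], units=self.units)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, units: str = "ppbV") -> "PeakTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        df.index.name = "sample"
        df.index = df.index.astype(str)
        return cls(df.astype(float), units=units)


def validate_meta(meta: pd.DataFrame, table: PeakTable | None = None) -> pd.DataFrame:
    """Check a sample-metadata frame and (optionally) its alignment to a table."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if meta.index.duplicated().any():
        raise ValueError("duplicated sample ids in metadata")
    bad_roles = set(meta["role"]) - {"sample", "blank"}
    if bad_roles:
        raise ValueError(f"unknown roles in metadata: {sorted(bad_roles)}")
    if table is not None:
        if list(meta.index) != list(table.data.index):
            raise ValueError("metadata rows are not aligned to the peak table")
    return meta


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    meta = meta.set_index(meta.columns[0])
    meta.index.name = "sample"
    meta.index = meta.index.astype(str)
    return validate_meta(meta)


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.insert(0, "sample", out.index)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labelled objects."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicated ids in distance matrix")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def reorder(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = [str(i) for i in ids]
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        out = self.to_frame()
        out.insert(0, "id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))
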