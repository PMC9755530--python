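"""Reading, validating, and writing reflection tables.

Unmerged input is one row per observed reflection: Miller index
``(h, k, l)``, an image identifier, the integrated intensity ``I`` and
its uncertainty ``sigma_I``, plus arbitrary numeric metadata columns
(detector position, rotation angle, wavelength, Ewald offset,
resolution, ...).  Supported formats are MTZ (via gemmi) and a plain
CSV dialect: comma-separated, UTF-8, header row, ``.`` decimal point,
required columns ``h,k,l,image,I,SigI`` — every remaining numeric
column is treated as metadata.

Merged output is one row per unique reflection with posterior mean
amplitude ``F`` and standard deviation ``SigF``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReflectionTable",
    "MergedTable",
    "ValidationError",
    "FormatError",
    "read_reflections",
    "read_many",
    "write_merged",
    "read_merged",
    "standardize_metadata",
    "apply_standardization",
]

#: internal column names
_CORE = ["h", "k", "l", "image_id", "dataset_id", "intensity", "sigma_I"]

#: CSV header names accepted for the required columns
_CSV_REQUIRED = {"h": "h", "k": "k", "l": "l", "image": "image_id",
                 "I": "intensity", "SigI": "sigma_I"}


class FormatError(ValueError):
    """A required column or structural element of the input is missing."""


class ValidationError(ValueError):
    """Input rows violate a table invariant (e.g. non-positive sigma)."""


@dataclass
class ReflectionTable:
    """Unmerged observations plus named metadata columns.

    ``df`` holds integer ``h,k,l,image_id,dataset_id`` and float
    ``intensity, sigma_I`` columns followed by the metadata columns.
    ``image_id`` is re-indexed to a contiguous 0-based range at
    construction.
    """

    df: pd.DataFrame
    metadata_columns: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in _CORE if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        for c in self.metadata_columns:
            if c not in self.df.columns:
                raise FormatError(f"metadata column not found: {c!r}")
        bad = int((self.df["sigma_I"].to_numpy() <= 0).sum())
        if bad:
            raise ValidationError(
                f"sigma_I must be strictly positive; {bad} offending row(s)")
        # contiguous 0-based image ids (per full table)
        codes, _ = pd.factorize(self.df["image_id"], sort=True)
        self.df = self.df.copy()
        self.df["image_id"] = codes.astype(np.int64)
        for c in ("h", "k", "l", "dataset_id"):
            self.df[c] = self.df[c].astype(np.int64)
        if ((self.df[["h", "k", "l"]].to_numpy() == 0).all(axis=1)).any():
            raise ValidationError("Miller index (0,0,0) is unphysical")

    def __len__(self):
        return len(self.df)

    @property
    def n_images(self) -> int:
        return int(self.df["image_id"].max()) + 1 if len(self.df) else 0

    def miller(self) -> np.ndarray:
        return self.df[["h", "k", "l"]].to_numpy()

    def subset(self, mask) -> "ReflectionTable":
        return ReflectionTable(self.df.loc[mask].reset_index(drop=True),
                               list(self.metadata_columns))


@dataclass
class MergedTable:
    """Posterior amplitude summaries, one row per unique reflection.

    Columns: ``h,k,l`` (ASU index), ``F``, ``SigF``, ``n_obs``,
    ``friedel_branch`` in {``plus``, ``minus``, ``merged``},
    ``dataset_id``; ``dspacing`` (Å) is carried when available.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = ["h", "k", "l", "F", "SigF", "n_obs",
                    "friedel_branch", "dataset_id"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"merged table missing column(s): {missing}")
        if len(self.df) == 0:
            raise ValidationError("merged table must not be empty")
        F = self.df["F"].to_numpy(float)
        S = self.df["SigF"].to_numpy(float)
        if not (np.isfinite(F).all() and np.isfinite(S).all()):
            raise ValidationError("F/SigF must be finite")
        if (F <= 0).any() or (S <= 0).any():
            raise ValidationError("F and SigF must be strictly positive")
        key = self.df[["h", "k", "l", "friedel_branch", "dataset_id"]]
        if key.duplicated().any():
            raise ValidationError(
                "duplicate (asu_index, friedel_branch, dataset_id) rows")

    def __len__(self):
        return len(self.df)


# ---------------------------------------------------------------------------
# reading

def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        return format
    return "mtz" if str(path).lower().endswith(".mtz") else "csv"


def read_reflections(path, format: str | None = None,
                     dataset_id: int = 0) -> ReflectionTable:
    """Read one unmerged reflection file (MTZ or CSV dialect).

    All numeric columns beyond the required set become metadata,
    preserved by name and row order.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for name in _CSV_REQUIRED:
            if name not in df.columns:
                raise FormatError(f"missing required column: {name!r}")
        meta = [c for c in df.columns
                if c not in _CSV_REQUIRED and c != "dataset_id"]
        df = df.rename(columns=_CSV_REQUIRED)
    elif fmt == "mtz":
        import gemmi
        mtz = gemmi.read_mtz_file(str(path))
        data = np.asarray(mtz, dtype=np.float64)
        cols = [c.label for c in mtz.columns]
        df = pd.DataFrame(data, columns=cols)
        mapping = {"H": "h", "K": "k", "L": "l", "BATCH": "image_id",
                   "I": "intensity", "SIGI": "sigma_I"}
        for name in mapping:
            if name not in df.columns:
                raise FormatError(f"missing required MTZ column: {name!r}")
        meta = [c for c in cols if c not in mapping]
        df = df.rename(columns=mapping)
        df["image_id"] = df["image_id"].round().astype(np.int64)
    else:
        raise FormatError(f"unknown format: {fmt!r}")
    if "dataset_id" not in df.columns:
        df["dataset_id"] = int(dataset_id)
    df["dataset_id"] = df["dataset_id"].astype(np.int64)
    meta = [c for c in meta if pd.api.types.is_numeric_dtype(df[c])]
    return ReflectionTable(df.reset_index(drop=True), meta)


def read_many(paths, format: str | None = None) -> ReflectionTable:
    """Read several files into one table; ``dataset_id`` follows input
    file order (joint multi-dataset merging, e.g. dark vs. 2 ms)."""
    tables = [read_reflections(p, format=format, dataset_id=i)
              for i, p in enumerate(paths)]
    if len(tables) > 1:
        for i, t in enumerate(tables):
            t.df["dataset_id"] = np.int64(i)
    common = set(tables[0].metadata_columns)
    for t in tables[1:]:
        common &= set(t.metadata_columns)
    meta = [c for c in tables[0].metadata_columns if c in common]
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return ReflectionTable(df, meta)


# ---------------------------------------------------------------------------
# writing

def write_merged(merged: MergedTable, path, format: str | None = None,
                 cell=(79.0, 79.0, 38.0, 90.0, 90.0, 90.0),
                 spacegroup: str = "P 1") -> None:
    """Write a merged table.

    CSV keeps the full column set.  MTZ uses standard types (H for
    indices, F/Q for amplitude and its sigma); with separate Friedel
    branches the layout is paired F(+)/F(-) columns (types G/L), one
    row per ASU index.
    """
    if len(merged) == 0:
        raise ValidationError("refusing to write an empty merged table")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        # %.17g guarantees float64 round-trips bit-exactly through text
        merged.df.to_csv(path, index=False, float_format="%.17g")
        return
    if fmt != "mtz":
        raise FormatError(f"unknown format: {fmt!r}")
    import gemmi
    df = merged.df
    anomalous = set(df["friedel_branch"]) >= {"plus", "minus"}
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.find_spacegroup_by_name(spacegroup)
    mtz.set_cell_for_all(gemmi.UnitCell(*cell))
    if anomalous:
        plus = df[df["friedel_branch"] == "plus"]
        minus = df[df["friedel_branch"] == "minus"]
        both = plus.merge(minus, on=["h", "k", "l", "dataset_id"],
                          suffixes=("_plus", "_minus"))
        mtz.add_dataset("merged")
        for label, typ in [("F(+)", "G"), ("SIGF(+)", "L"),
                           ("F(-)", "G"), ("SIGF(-)", "L")]:
            mtz.add_column(label, typ)
        data = np.column_stack([
            both[["h", "k", "l"]].to_numpy(float),
            both["F_plus"], both["SigF_plus"],
            both["F_minus"], both["SigF_minus"]])
    else:
        mtz.add_dataset("merged")
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        data = np.column_stack([df[["h", "k", "l"]].to_numpy(float),
                                df["F"], df["SigF"]])
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def read_merged(path, format: str | None = None) -> MergedTable:
    """Read back a CSV merged table written by :func:`write_merged`."""
    fmt = _infer_format(path, format)
    if fmt != "csv":
        raise FormatError("read_merged supports the CSV dialect")
    return MergedTable(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# metadata standardization

def standardize_metadata(table: ReflectionTable, columns=None):
    """Z-score selected metadata columns.

    Returns ``(X, centers, spreads)`` where ``X`` is the rows × d design
    matrix, ``centers`` the per-column means, ``spreads`` the per-column
    population standard deviations.  A zero-variance column is centered
    and its spread recorded as 1, so held-out rows can be transformed
    with the training statistics via :func:`apply_standardization`.
    """
    if columns is None:
        columns = list(table.metadata_columns)
    for c in columns:
        if c not in table.df.columns:
            raise KeyError(f"unknown metadata column: {c!r}")
        if not pd.api.types.is_numeric_dtype(table.df[c]):
            raise KeyError(f"metadata column not numeric: {c!r}")
    M = table.df[list(columns)].to_numpy(np.float64)
    centers = M.mean(axis=0)
    spreads = M.std(axis=0)  # population sd
    spreads = np.where(spreads == 0.0, 1.0, spreads)
    return (M - centers) / spreads, centers, spreads


def apply_standardization(df: pd.DataFrame, columns, centers, spreads):
    """Transform rows (e.g. held-out data) with stored training statistics."""
    M = df[list(columns)].to_numpy(np.float64)
    return (M - np.asarray(centers)) / np.asarray(spreads)
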