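"""Localization-table and summary I/O.

Localizations live in flat CSV tables, one row per detected fluorophore
emission.  Two dialects are supported:

``native``
    columns ``x_nm,y_nm,frame[,photons,precision_nm]``
``thunderstorm``
    columns ``x [nm]``, ``y [nm]``, ``frame`` — the interoperability surface
    for tables exported by common SMLM reconstruction software.

Coordinates are nanometres, origin at the ROI lower-left corner, y increasing
upward; frame indices are 0-based.  Files are written with 2-decimal fixed
formatting, so a write/read round trip preserves coordinates to 0.01 nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("native", "thunderstorm")

_THUNDERSTORM_MAP = {"x [nm]": "x_nm", "y [nm]": "y_nm", "frame": "frame"}


class FormatError(ValueError):
    """A localization table does not match the declared dialect."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned ROI rectangle in nm; origin at lower-left."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError("ROI width/height must be non-negative")

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6


@dataclass(frozen=True)
class FieldMetadata:
    """Provenance/grouping metadata for one imaged field."""

    subject: str = ""
    condition: str = ""
    imaging_day: str = ""
    field_id: str = ""
    frames_acquired: int = 3000


@dataclass
class LocalizationField:
    """One imaged ROI's localizations — the atomic input of the pipeline."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    frame: np.ndarray
    roi: Rect
    photons: Optional[np.ndarray] = None
    precision_nm: Optional[np.ndarray] = None
    metadata: FieldMetadata = field(default_factory=FieldMetadata)

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.frame = np.asarray(self.frame, dtype=int)
        n = self.x_nm.size
        if self.y_nm.size != n or self.frame.size != n:
            raise ValueError("x, y and frame must have equal length")
        if np.any(self.frame < 0):
            raise ValueError("frame indices must be non-negative")
        for name in ("photons", "precision_nm"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, v)

    def __len__(self) -> int:
        return int(self.x_nm.size)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x_nm, self.y_nm])

    def with_metadata(self, **kwargs) -> "LocalizationField":
        return replace(self, metadata=replace(self.metadata, **kwargs))

    def allclose(self, other: "LocalizationField", atol: float = 0.005) -> bool:
        """Equality up to the declared on-disk precision (0.01 nm)."""
        if len(self) != len(other):
            return False
        if not (
            np.allclose(self.x_nm, other.x_nm, atol=atol)
            and np.allclose(self.y_nm, other.y_nm, atol=atol)
            and np.array_equal(self.frame, other.frame)
        ):
            return False
        for name in ("photons", "precision_nm"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.allclose(a, b, atol=atol):
                return False
        return True


def _empty_field(roi: Rect, metadata: FieldMetadata) -> LocalizationField:
    return LocalizationField(
        np.empty(0), np.empty(0), np.empty(0, dtype=int), roi, metadata=metadata
    )


def read_localizations(
    path,
    dialect: str = "native",
    roi: Optional[Rect] = None,
    metadata: Optional[FieldMetadata] = None,
) -> LocalizationField:
    """Read a localization table.

    Rows with non-finite coordinates are dropped, with the dropped count
    logged.  A file containing only a header yields an empty field (with a
    warning logged).  If ``roi`` is omitted it is taken as the bounding box
    of the data anchored at the origin.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header)")
    if dialect == "thunderstorm":
        missing = [c for c in _THUNDERSTORM_MAP if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        df = df.rename(columns=_THUNDERSTORM_MAP)
    else:
        missing = [c for c in ("x_nm", "y_nm", "frame") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    metadata = metadata or FieldMetadata(field_id=path.stem)
    if df.empty:
        logger.warning("%s: empty localization table", path)
        return _empty_field(roi or Rect(0, 0, 0, 0), metadata)

    finite = np.isfinite(df["x_nm"].to_numpy(float)) & np.isfinite(
        df["y_nm"].to_numpy(float)
    )
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) with non-finite coordinates", path, n_bad)
        df = df.loc[finite]

    x = df["x_nm"].to_numpy(float)
    y = df["y_nm"].to_numpy(float)
    if roi is None:
        roi = Rect(0.0, 0.0, float(x.max(initial=0.0)), float(y.max(initial=0.0)))
    return LocalizationField(
        x_nm=x,
        y_nm=y,
        frame=df["frame"].to_numpy(int),
        roi=roi,
        photons=df["photons"].to_numpy(float) if "photons" in df.columns else None,
        precision_nm=(
            df["precision_nm"].to_numpy(float) if "precision_nm" in df.columns else None
        ),
        metadata=metadata,
    )


def write_localizations(field: LocalizationField, path, dialect: str = "native") -> None:
    """Write a localization table with deterministic column order/formatting."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    cols = {"x_nm": field.x_nm, "y_nm": field.y_nm, "frame": field.frame}
    if dialect == "native":
        if field.photons is not None:
            cols["photons"] = field.photons
        if field.precision_nm is not None:
            cols["precision_nm"] = field.precision_nm
    df = pd.DataFrame(cols)
    if dialect == "thunderstorm":
        inv = {v: k for k, v in _THUNDERSTORM_MAP.items()}
        df = df.rename(columns=inv)
    try:
        df.to_csv(path, index=False, float_format="%.2f")
    except OSError as exc:
        raise OSError(f"cannot write localization table to {path}: {exc}") from exc


SUMMARY_COLUMNS = [
    "subject",
    "condition",
    "imaging_day",
    "field_id",
    "n_localizations",
    "n_clusters_retained",
    "clusters_per_20um2",
    "median_diameter_nm",
    "mean_inner_density",
    "pct_free",
    "n_sub_small",
    "n_small",
    "n_medium",
    "n_large",
    "n_very_large",
]


def summary_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-field summary rows into a keyed table.

    Keys (subject, condition, imaging_day, field_id) must be unique.
    """
    df = pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS)
    keys = ["subject", "condition", "imaging_day", "field_id"]
    if df.duplicated(subset=keys).any():
        dup = df.loc[df.duplicated(subset=keys), keys].iloc[0].tolist()
        raise ValueError(f"duplicate field summary key: {dup}")
    return df


def write_summary(table: pd.DataFrame, path) -> None:
    """Write a field-summary table as TSV (deterministic formatting)."""
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.4f")
    except OSError as exc:
        raise OSError(f"cannot write summary table to {path}: {exc}") from exc


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
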