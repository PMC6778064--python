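"""Per-cluster morphometry: 2D PCA shape, outlier rejection, size classes.

The diameter estimator is deliberately simple and documented: after a single
outlier-rejection pass, the cluster's *mean diameter* is the mean of the two
principal-axis extents (max minus min of member projections on each principal
axis).  The *inner density* is the raw number of localizations in the cluster
— "fluorescent flashes" — counted before outlier removal, so that the density
filter and the conservation invariant operate on the original partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class SizeClass(str, Enum):
    SUB_SMALL = "SUB_SMALL"  # below the smallest aggregate bin (< 20 nm)
    SMALL = "SMALL"          # [20, 100) nm
    MEDIUM = "MEDIUM"        # [100, 300) nm
    LARGE = "LARGE"          # [300, 500) nm
    VERY_LARGE = "VERY_LARGE"  # >= 500 nm


AGGREGATE_CLASSES = (
    SizeClass.SMALL,
    SizeClass.MEDIUM,
    SizeClass.LARGE,
    SizeClass.VERY_LARGE,
)


@dataclass(frozen=True)
class SizeBinning:
    """Half-open diameter bins [lo, hi) with boundaries in nm.

    Defaults reproduce the aggregate classes used for striatal α-synuclein
    profiling: small 20–100 nm, medium 100–300 nm, large 300–500 nm, very
    large ≥ 500 nm; anything under 20 nm is sub-small (monomer scale).
    """

    boundaries_nm: Tuple[float, ...] = (20.0, 100.0, 300.0, 500.0)

    def __post_init__(self) -> None:
        b = self.boundaries_nm
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("boundaries must be 4 strictly increasing values")

    def classify(self, diameter_nm: float) -> SizeClass:
        if not (math.isfinite(diameter_nm) and diameter_nm >= 0):
            raise ValueError(f"diameter must be finite and >= 0, got {diameter_nm}")
        b = self.boundaries_nm
        if diameter_nm < b[0]:
            return SizeClass.SUB_SMALL
        if diameter_nm < b[1]:
            return SizeClass.SMALL
        if diameter_nm < b[2]:
            return SizeClass.MEDIUM
        if diameter_nm < b[3]:
            return SizeClass.LARGE
        return SizeClass.VERY_LARGE


@dataclass
class Cluster:
    """Morphometry of one cluster of localizations."""

    id: int
    member_indices: np.ndarray
    centroid_nm: Tuple[float, float]
    axes: np.ndarray  # (2, 2) rows = major, minor unit vectors
    extent_major_nm: float
    extent_minor_nm: float
    n_localizations: int  # the inner density (all members, pre outlier removal)
    size_class: SizeClass
    retained: bool = True

    @property
    def mean_diameter_nm(self) -> float:
        return (self.extent_major_nm + self.extent_minor_nm) / 2.0


def pca_shape(points) -> Tuple[np.ndarray, np.ndarray, Tuple[float, float]]:
    """Principal-axis shape of a 2D point set.

    Returns ``(centroid, axes, (extent_major, extent_minor))`` where axes are
    orthonormal eigenvectors of the coordinate covariance (rows: major then
    minor) and an extent is max − min of the projections onto that axis.
    A degenerate (isotropic) covariance is resolved by taking the axis closer
    to +x as major; axis signs are fixed so each axis has non-negative x
    (ties: non-negative y).
    """
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) == 0:
        raise ValueError("expected a non-empty (n, 2) point array")
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    if len(xy) == 1:
        axes = np.array([[1.0, 0.0], [0.0, 1.0]])
        return centroid, axes, (0.0, 0.0)

    cov = centered.T @ centered / (len(xy) - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if math.isclose(evals[0], evals[1], rel_tol=1e-12, abs_tol=1e-12):
        # isotropic: major = axis closer to +x
        major, minor = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    else:
        major, minor = evecs[:, 1], evecs[:, 0]
    axes = np.vstack([_fix_sign(major), _fix_sign(minor)])
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return centroid, axes, (float(extents[0]), float(extents[1]))


def _fix_sign(v: np.ndarray) -> np.ndarray:
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        return -v
    return v


def remove_outliers(points, outlier_sd: float) -> np.ndarray:
    """Single-pass principal-axis outlier rejection.

    Drops points whose projection onto either principal axis of the input set
    lies more than ``outlier_sd`` standard deviations from the projection
    mean.  Never returns an empty set: if every point would be dropped, the
    point closest to the centroid is kept.
    """
    if not outlier_sd > 0:
        raise ValueError("outlier_sd must be positive")
    xy = np.asarray(points, dtype=float)
    if len(xy) <= 2 or math.isinf(outlier_sd):
        return xy.copy()
    centroid, axes, _ = pca_shape(xy)
    proj = (xy - centroid) @ axes.T
    sd = proj.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # no spread along an axis -> nothing to reject there
    keep = np.all(np.abs(proj - proj.mean(axis=0)) <= outlier_sd * sd, axis=1)
    if not keep.any():
        keep[np.argmin(np.linalg.norm(xy - centroid, axis=1))] = True
    return xy[keep]


def measure_cluster(
    points,
    binning: SizeBinning,
    outlier_sd: float = 2.5,
    cluster_id: int = 0,
    member_indices: Optional[np.ndarray] = None,
) -> Cluster:
    """Morphometry of one cluster: PCA shape on outlier-filtered members.

    ``n_localizations`` counts *all* members (inner density); the diameter and
    size class come from the outlier-filtered point set.
    """
    xy = np.asarray(points, dtype=float)
    if len(xy) == 0:
        raise ValueError("a cluster needs at least one member")
    filtered = remove_outliers(xy, outlier_sd)
    centroid, axes, (ext_maj, ext_min) = pca_shape(filtered)
    diameter = (ext_maj + ext_min) / 2.0
    if member_indices is None:
        member_indices = np.arange(len(xy))
    return Cluster(
        id=cluster_id,
        member_indices=np.asarray(member_indices, dtype=int),
        centroid_nm=(float(centroid[0]), float(centroid[1])),
        axes=axes,
        extent_major_nm=ext_maj,
        extent_minor_nm=ext_min,
        n_localizations=len(xy),
        size_class=binning.classify(diameter),
    )


def measure_clusters(
    xy: np.ndarray,
    labels: np.ndarray,
    binning: SizeBinning,
    outlier_sd: float = 2.5,
) -> list:
    """Measure every cluster in a labelling (free points ignored)."""
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = []
    for cid in range(labels.max(initial=-1) + 1):
        idx = np.flatnonzero(labels == cid)
        if idx.size:
            out.append(
                measure_cluster(
                    xy[idx], binning, outlier_sd, cluster_id=cid, member_indices=idx
                )
            )
    return out


def size_distribution(clusters: Iterable[Cluster], binning: SizeBinning) -> dict:
    """Counts of retained clusters per size class.

    Sub-small micro-clusters are reported separately and excluded from the
    four aggregate bins.
    """
    counts = {cls: 0 for cls in SizeClass}
    for c in clusters:
        if c.retained:
            counts[c.size_class] += 1
    return {
        "sub_small": counts[SizeClass.SUB_SMALL],
        "small": counts[SizeClass.SMALL],
        "medium": counts[SizeClass.MEDIUM],
        "large": counts[SizeClass.LARGE],
        "very_large": counts[SizeClass.VERY_LARGE],
    }


def clusters_to_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """One row per cluster, for TSV export."""
    rows = [
        {
            "cluster_id": c.id,
            "centroid_x_nm": c.centroid_nm[0],
            "centroid_y_nm": c.centroid_nm[1],
            "extent_major_nm": c.extent_major_nm,
            "extent_minor_nm": c.extent_minor_nm,
            "mean_diameter_nm": c.mean_diameter_nm,
            "n_localizations": c.n_localizations,
            "size_class": c.size_class.value,
            "retained": c.retained,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "centroid_x_nm",
            "centroid_y_nm",
            "extent_major_nm",
            "extent_minor_nm",
            "mean_diameter_nm",
            "n_localizations",
            "size_class",
            "retained",
        ],
    )
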