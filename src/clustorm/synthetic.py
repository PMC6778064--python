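"""Synthetic localization fields and stereology phantoms with ground truth.

The generator emulates, at the localization level, a striatal dSTORM field:

* dense protein *aggregates* — discs (or truncated Gaussians) of 20 to >500 nm
  diameter emitting tens to hundreds of localizations each;
* a dispersed *monomer* population — point-like single proteins that blink a
  handful of times (default: 1 + Poisson(6) localizations, mean 7) and whose
  apparent footprint is set by the localization precision (default σ = 8 nm,
  which puts the apparent PCA diameter near 23 nm);
* homogeneous Poisson *background* localizations.

No camera/PSF/frame-level simulation is attempted: generation is directly at
the localization level, in 2D.  Every localization carries a ground-truth
source label so downstream stages can be tested as parameter recovery.

The module also builds 3D phantoms (cell populations, fiber networks) used to
validate the stereology estimators by Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .io import FieldMetadata, LocalizationField, Rect
from .laws import DistributionLaw, shifted_poisson

_PROFILES = ("uniform_disc", "gaussian")


@dataclass(frozen=True)
class SyntheticFieldConfig:
    """Parameters of one synthetic dSTORM field.

    Lengths in nm, rates per µm².  ``effect_multipliers`` is the
    (density_multiplier, free_fraction_shift_pp) pair consumed by
    :func:`generate_condition_pair` for treatment scenarios.
    """

    roi_width_nm: float
    roi_height_nm: float
    n_aggregates: int
    aggregate_diameter_law: Optional[DistributionLaw]
    aggregate_density_law: Optional[DistributionLaw]
    aggregate_profile: str = "uniform_disc"
    n_monomers: int = 0
    locs_per_monomer_law: DistributionLaw = field(
        default_factory=lambda: shifted_poisson(1, 6.0)
    )
    localization_precision_nm: float = 8.0
    background_rate_per_um2: float = 0.5
    condition_label: str = ""
    imaging_day: str = "d0"
    effect_multipliers: Tuple[float, float] = (1.0, 0.0)
    frames_acquired: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_width_nm <= 0 or self.roi_height_nm <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.n_aggregates < 0 or self.n_monomers < 0:
            raise ValueError("counts must be non-negative")
        if self.localization_precision_nm < 0:
            raise ValueError("localization precision must be non-negative")
        if self.background_rate_per_um2 < 0:
            raise ValueError("background rate must be non-negative")
        if self.aggregate_profile not in _PROFILES:
            raise ValueError(f"aggregate_profile must be one of {_PROFILES}")
        if self.n_aggregates > 0:
            if self.aggregate_diameter_law is None or self.aggregate_density_law is None:
                raise ValueError("aggregate laws required when n_aggregates > 0")
            if self.aggregate_diameter_law.support_min <= 0:
                raise ValueError("aggregate diameter law must have support above 0")
        if self.locs_per_monomer_law.support_min < 1:
            raise ValueError("locs-per-monomer law must guarantee counts >= 1")
        if self.effect_multipliers[0] <= 0:
            raise ValueError("density multiplier must be positive")

    @property
    def roi(self) -> Rect:
        return Rect(0.0, 0.0, self.roi_width_nm, self.roi_height_nm)

    @property
    def area_um2(self) -> float:
        return self.roi.area_um2

    def expected_free_fraction(self) -> Optional[float]:
        """Expected % of localizations not emitted by aggregates."""
        agg = (
            self.n_aggregates * self.aggregate_density_law.mean
            if self.n_aggregates
            else 0.0
        )
        free = (
            self.n_monomers * self.locs_per_monomer_law.mean
            + self.background_rate_per_um2 * self.area_um2
        )
        total = agg + free
        if total == 0:
            return None
        return 100.0 * free / total


# ground-truth source kinds
SOURCE_AGGREGATE = 0
SOURCE_MONOMER = 1
SOURCE_BACKGROUND = 2


@dataclass
class GroundTruth:
    """Per-localization provenance plus per-aggregate truth."""

    source_kind: np.ndarray  # SOURCE_* per localization
    source_id: np.ndarray  # aggregate/monomer index, -1 for background
    aggregate_centers_nm: np.ndarray  # (n_agg, 2)
    aggregate_diameters_nm: np.ndarray
    aggregate_loc_counts: np.ndarray

    @property
    def free_fraction_pct(self) -> Optional[float]:
        """% of localizations whose source is not an aggregate.

        ``None`` (no data) for an empty field.
        """
        n = self.source_kind.size
        if n == 0:
            return None
        return 100.0 * float(np.mean(self.source_kind != SOURCE_AGGREGATE))


def _clip_to_roi(xy: np.ndarray, roi: Rect) -> np.ndarray:
    # jittered localizations falling outside the ROI are clipped to the
    # boundary rather than discarded, preserving configured counts
    xy[:, 0] = np.clip(xy[:, 0], roi.x0, roi.x0 + roi.width)
    xy[:, 1] = np.clip(xy[:, 1], roi.y0, roi.y0 + roi.height)
    return xy


def _disc_points(rng, center, diameter, n) -> np.ndarray:
    r = (diameter / 2.0) * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _gaussian_disc_points(rng, center, diameter, n) -> np.ndarray:
    # isotropic Gaussian (sd = diameter/4) truncated at the radius
    sd, radius = diameter / 4.0, diameter / 2.0
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.normal(0.0, sd, size=(2 * (n - got) + 8, 2))
        ok = cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]
        take = min(len(ok), n - got)
        out[got : got + take] = ok[:take]
        got += take
    return center + out


def generate_field(
    config: SyntheticFieldConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[LocalizationField, GroundTruth]:
    """Draw one synthetic field.  Identical (config, seed) ⇒ identical output.

    Aggregate centers are uniform over the ROI; each aggregate emits its drawn
    localization count from its spatial profile truncated at its radius; each
    monomer emits K ~ locs_per_monomer_law localizations at its position; all
    localizations are jittered by the localization precision and clipped to
    the ROI.  Background is a homogeneous Poisson process.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    roi = config.roi

    xs: List[np.ndarray] = []
    kinds: List[np.ndarray] = []
    ids: List[np.ndarray] = []

    # aggregates
    if config.n_aggregates:
        centers = np.column_stack(
            [
                rng.uniform(roi.x0, roi.x0 + roi.width, config.n_aggregates),
                rng.uniform(roi.y0, roi.y0 + roi.height, config.n_aggregates),
            ]
        )
        diameters = config.aggregate_diameter_law.sample(rng, config.n_aggregates)
        if np.any(diameters > min(roi.width, roi.height)):
            raise ValueError(
                "drawn aggregate diameter exceeds the smaller ROI dimension"
            )
        if np.any(diameters <= 0):
            raise ValueError("aggregate diameter law produced non-positive value")
        counts = config.aggregate_density_law.sample_counts(rng, config.n_aggregates)
        for i in range(config.n_aggregates):
            if counts[i] == 0:
                continue
            if config.aggregate_profile == "uniform_disc":
                pts = _disc_points(rng, centers[i], diameters[i], counts[i])
            else:
                pts = _gaussian_disc_points(rng, centers[i], diameters[i], counts[i])
            xs.append(pts)
            kinds.append(np.full(counts[i], SOURCE_AGGREGATE))
            ids.append(np.full(counts[i], i))
    else:
        centers = np.empty((0, 2))
        diameters = np.empty(0)
        counts = np.empty(0, dtype=int)

    # monomers
    if config.n_monomers:
        mono_pos = np.column_stack(
            [
                rng.uniform(roi.x0, roi.x0 + roi.width, config.n_monomers),
                rng.uniform(roi.y0, roi.y0 + roi.height, config.n_monomers),
            ]
        )
        ks = config.locs_per_monomer_law.sample_counts(rng, config.n_monomers)
        xs.append(np.repeat(mono_pos, ks, axis=0))
        kinds.append(np.full(ks.sum(), SOURCE_MONOMER))
        ids.append(np.repeat(np.arange(config.n_monomers), ks))

    # background: homogeneous Poisson
    n_bg = int(rng.poisson(config.background_rate_per_um2 * config.area_um2))
    if n_bg:
        bg = np.column_stack(
            [
                rng.uniform(roi.x0, roi.x0 + roi.width, n_bg),
                rng.uniform(roi.y0, roi.y0 + roi.height, n_bg),
            ]
        )
        xs.append(bg)
        kinds.append(np.full(n_bg, SOURCE_BACKGROUND))
        ids.append(np.full(n_bg, -1))

    if xs:
        xy = np.concatenate(xs)
        kind = np.concatenate(kinds).astype(int)
        sid = np.concatenate(ids).astype(int)
    else:
        xy = np.empty((0, 2))
        kind = np.empty(0, dtype=int)
        sid = np.empty(0, dtype=int)

    if config.localization_precision_nm > 0 and len(xy):
        xy = xy + rng.normal(0.0, config.localization_precision_nm, size=xy.shape)
    xy = _clip_to_roi(xy, roi)
    frames = rng.integers(0, config.frames_acquired, size=len(xy))

    fld = LocalizationField(
        x_nm=xy[:, 0],
        y_nm=xy[:, 1],
        frame=frames,
        roi=roi,
        metadata=FieldMetadata(
            condition=config.condition_label,
            imaging_day=config.imaging_day,
            frames_acquired=config.frames_acquired,
        ),
    )
    truth = GroundTruth(
        source_kind=kind,
        source_id=sid,
        aggregate_centers_nm=centers,
        aggregate_diameters_nm=diameters,
        aggregate_loc_counts=counts,
    )
    return fld, truth


# ---------------------------------------------------------------------------
# condition pairs (placebo-vs-treatment style designs)
# ---------------------------------------------------------------------------


@dataclass
class LabeledField:
    """One generated field tagged with its arm / subject / imaging day."""

    field: LocalizationField
    truth: GroundTruth
    condition: str
    subject: str
    imaging_day: str
    field_id: str


def treated_config(
    base: SyntheticFieldConfig,
    effect: Optional[Tuple[float, float]] = None,
) -> SyntheticFieldConfig:
    """Derive the treated-arm configuration from the reference one.

    The density multiplier rescales the mean of the aggregate density law;
    the free-fraction shift (percentage points) is achieved by solving for
    the monomer count that moves the *expected* free fraction from the
    reference value f₀ to f₀ + shift:  with A the expected aggregate
    localizations (after the multiplier), B the expected background and μ the
    mean localizations per monomer, the target free total F satisfies
    F = t/(1−t)·A, so n_monomers = max(0, round((F − B)/μ)).
    """
    m, shift = effect if effect is not None else base.effect_multipliers
    if m <= 0:
        raise ValueError("density multiplier must be positive")
    if base.n_aggregates and base.aggregate_density_law is not None:
        new_density = base.aggregate_density_law.scaled_mean(m)
        agg_locs = base.n_aggregates * new_density.mean
    else:
        new_density = base.aggregate_density_law
        agg_locs = 0.0
    mu = base.locs_per_monomer_law.mean
    bg = base.background_rate_per_um2 * base.area_um2
    f0 = base.expected_free_fraction()
    f0 = 0.0 if f0 is None else f0 / 100.0
    t = min(max(f0 + shift / 100.0, 0.0), 0.99)
    if agg_locs > 0:
        target_free = t / (1.0 - t) * agg_locs
    else:
        target_free = base.n_monomers * mu + bg
    n_mono = max(0, int(round((target_free - bg) / mu)))
    return replace(
        base,
        aggregate_density_law=new_density,
        n_monomers=n_mono,
        effect_multipliers=(1.0, 0.0),
    )


def generate_condition_pair(
    base: SyntheticFieldConfig,
    effect: Optional[Tuple[float, float]] = None,
    n_fields_per_arm: int = 1,
    seed: int = 0,
    *,
    n_subjects_per_arm: int = 1,
    reference_label: str = "placebo",
    treated_label: str = "treated",
) -> List[LabeledField]:
    """Generate a two-arm field collection with a known treatment effect.

    Fields are split evenly over subjects within each arm; the j-th field of
    every subject (both arms) shares an imaging day ``d<j>``, so the per-day
    density filter always finds reference clusters.
    """
    if n_fields_per_arm < 1:
        raise ValueError("n_fields_per_arm must be >= 1")
    if n_subjects_per_arm < 1 or n_fields_per_arm % n_subjects_per_arm:
        raise ValueError("n_fields_per_arm must be a multiple of n_subjects_per_arm")
    ref_cfg = replace(base, condition_label=reference_label)
    trt_cfg = replace(treated_config(base, effect), condition_label=treated_label)

    per_subj = n_fields_per_arm // n_subjects_per_arm
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_fields_per_arm)
    out: List[LabeledField] = []
    k = 0
    for label, cfg in ((reference_label, ref_cfg), (treated_label, trt_cfg)):
        for s in range(n_subjects_per_arm):
            subject = f"{label}_m{s}"
            for j in range(per_subj):
                day = f"d{j}"
                cfg_j = replace(cfg, imaging_day=day)
                fld, truth = generate_field(
                    cfg_j, rng=np.random.default_rng(children[k])
                )
                fld = fld.with_metadata(
                    subject=subject, field_id=f"{subject}_f{j}", imaging_day=day
                )
                out.append(
                    LabeledField(fld, truth, label, subject, day, f"{subject}_f{j}")
                )
                k += 1
    return out


# ---------------------------------------------------------------------------
# stereology phantoms
# ---------------------------------------------------------------------------


@dataclass
class CellPhantom:
    """A known population of point-like cells in a box (µm units)."""

    volume_um: Tuple[float, float, float]
    centroids_um: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.centroids_um = np.asarray(self.centroids_um, dtype=float).reshape(-1, 3)
        dims = np.asarray(self.volume_um, dtype=float)
        if np.any(dims <= 0):
            raise ValueError("phantom volume dimensions must be positive")
        if len(self.centroids_um) and (
            np.any(self.centroids_um < 0) or np.any(self.centroids_um > dims)
        ):
            raise ValueError("centroids must lie inside the volume")

    @property
    def n_true(self) -> int:
        return len(self.centroids_um)


@dataclass
class FiberPhantom:
    """A fiber network as straight 3D segments in a reference box (µm).

    Segments may extend beyond the box (they are generated in a padded
    region so the process is homogeneous up to the walls); the true length
    density ``lv_um_per_um3`` counts only length clipped to the box.
    """

    volume_um: Tuple[float, float, float]
    segments_um: np.ndarray  # (n, 2, 3) endpoints
    lv_um_per_um3: float
    isotropic: bool = True

    def __post_init__(self) -> None:
        self.segments_um = np.asarray(self.segments_um, dtype=float).reshape(-1, 2, 3)


def generate_cell_phantom(
    volume_um: Tuple[float, float, float], n_cells: int, seed: int = 0
) -> CellPhantom:
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    dims = np.asarray(volume_um, dtype=float)
    pts = rng.uniform(0.0, 1.0, size=(n_cells, 3)) * dims
    return CellPhantom(tuple(dims), pts)


def _clipped_lengths(segments: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Per-segment length inside [0, dims] (exact slab clipping)."""
    if len(segments) == 0:
        return np.empty(0)
    a, b = segments[:, 0, :], segments[:, 1, :]
    d = b - a
    t0 = np.zeros(len(segments))
    t1 = np.ones(len(segments))
    for k in range(3):
        dk = d[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            tl = np.where(dk != 0, (0.0 - a[:, k]) / dk, -np.inf)
            th = np.where(dk != 0, (dims[k] - a[:, k]) / dk, np.inf)
        lo = np.minimum(tl, th)
        hi = np.maximum(tl, th)
        inside = (dk != 0) | ((a[:, k] >= 0) & (a[:, k] <= dims[k]))
        lo = np.where(dk == 0, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(dk == 0, np.where(inside, np.inf, -np.inf), hi)
        t0 = np.maximum(t0, lo)
        t1 = np.minimum(t1, hi)
    frac = np.clip(t1 - t0, 0.0, 1.0)
    return frac * np.linalg.norm(d, axis=1)


def _clipped_length(segments: np.ndarray, dims: np.ndarray) -> float:
    """Total segment length inside [0, dims]."""
    return float(np.sum(_clipped_lengths(np.asarray(segments), np.asarray(dims))))


def generate_fiber_phantom(
    volume_um: Tuple[float, float, float],
    target_lv_um_per_um3: float,
    segment_length_law: DistributionLaw,
    isotropic: bool = True,
    seed: int = 0,
    batch: int = 512,
) -> FiberPhantom:
    """Grow a homogeneous fiber phantom until the clipped length density
    reaches the target (within one segment, i.e. well under 1%).

    Segment midpoints are uniform over the box padded by the maximal segment
    length, keeping intensity homogeneous up to the walls.  Isotropic
    orientation draws directions uniformly on the sphere; otherwise fibers
    run along +z (a deliberately anisotropic phantom).
    """
    if target_lv_um_per_um3 < 0:
        raise ValueError("target length density must be non-negative")
    dims = np.asarray(volume_um, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("phantom volume dimensions must be positive")
    vol = float(np.prod(dims))
    if target_lv_um_per_um3 > 0 and segment_length_law.mean <= 0:
        raise ValueError("segment length law must have positive mean")
    rng = np.random.default_rng(seed)
    segs: List[np.ndarray] = []
    total_inside = 0.0
    target_len = target_lv_um_per_um3 * vol
    pad = segment_length_law.mean * 4 + 1.0
    while total_inside < target_len:
        lengths = np.abs(segment_length_law.sample(rng, batch))
        # uniform midpoints over the padded box
        mid = rng.uniform(0.0, 1.0, size=(batch, 3)) * (dims + 2 * pad) - pad
        if isotropic:
            v = rng.normal(size=(batch, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
        else:
            v = np.tile(np.array([0.0, 0.0, 1.0]), (batch, 1))
        half = (lengths / 2.0)[:, None] * v
        new = np.stack([mid - half, mid + half], axis=1)
        adds = _clipped_lengths(new, dims)
        cum = total_inside + np.cumsum(adds)
        cut = int(np.searchsorted(cum, target_len) + 1)
        cut = min(cut, batch)
        segs.append(new[:cut])
        total_inside = float(cum[cut - 1])
    segments = np.concatenate(segs) if segs else np.empty((0, 2, 3))
    lv = total_inside / vol
    return FiberPhantom(tuple(dims), segments, lv, isotropic=isotropic)
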