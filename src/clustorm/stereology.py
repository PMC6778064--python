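"""Design-based stereology: the optical fractionator and the space-ball probe.

Optical fractionator
    The total particle number in a reference space is estimated from counts
    in a systematic-uniform-random sample of counting frames::

        N̂ = ΣQ⁻ · (1/ssf) · (1/asf) · (1/tsf)

    with section sampling fraction ssf = section thickness / section spacing,
    area sampling fraction asf = counting-frame area / grid-cell area, and
    thickness sampling fraction tsf = dissector height / mean measured
    section thickness.  The bundled default design follows a mouse SNpc
    protocol: 30 µm sections every 180 µm, 220 × 220 µm grid, 85 × 85 µm
    frame, dissector spanning the measured thickness (tsf = 1).

Space-ball (hemispherical surface probe)
    Fiber length density is estimated from transections of an isotropic
    curved probe surface::

        L_V = 2 · ΣI / ΣS

    where ΣI is the total number of fiber–surface intersections and ΣS the
    total probe surface area (2πr² per hemisphere, curved surface only — the
    flat face is excluded).  A hemisphere's curved surface presents the same
    mean projected area to every direction, which is what makes the
    estimator orientation-robust; a flat probe of equal area is biased for
    anisotropic fibers (see :func:`simulate_planar_probe`).  Default design:
    10 µm radius hemispheres on a 250 µm grid; results are reported in nm of
    fiber per µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .synthetic import CellPhantom, FiberPhantom


@dataclass
class FractionatorDesign:
    """Sampling fractions and raw counts for an optical-fractionator run."""

    section_thickness_um: float = 30.0
    section_spacing_um: float = 180.0
    grid_x_um: float = 220.0
    grid_y_um: float = 220.0
    frame_x_um: float = 85.0
    frame_y_um: float = 85.0
    dissector_height_um: Optional[float] = None  # default: measured thickness
    q_counts: Sequence[int] = field(default_factory=list)
    measured_thickness_um: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.section_thickness_um, self.section_spacing_um) <= 0:
            raise ValueError("section thickness and spacing must be positive")
        if min(self.grid_x_um, self.grid_y_um, self.frame_x_um, self.frame_y_um) <= 0:
            raise ValueError("grid and frame dimensions must be positive")
        if self.frame_x_um > self.grid_x_um or self.frame_y_um > self.grid_y_um:
            raise ValueError("counting frame cannot exceed the grid cell")
        if self.section_spacing_um < self.section_thickness_um:
            raise ValueError("section spacing must be >= section thickness")
        if any(q < 0 for q in self.q_counts):
            raise ValueError("counts must be non-negative")

    @property
    def ssf(self) -> float:
        return self.section_thickness_um / self.section_spacing_um

    @property
    def asf(self) -> float:
        return (self.frame_x_um * self.frame_y_um) / (self.grid_x_um * self.grid_y_um)

    @property
    def tsf(self) -> float:
        if not self.measured_thickness_um:
            return 1.0
        tbar = float(np.mean(self.measured_thickness_um))
        h = self.dissector_height_um if self.dissector_height_um is not None else tbar
        return h / tbar


def optical_fractionator(design: FractionatorDesign) -> float:
    """Estimate the total particle number from a fractionator design."""
    if not design.q_counts:
        raise ValueError("need at least one counting site")
    total_q = float(np.sum(design.q_counts))
    return total_q / (design.ssf * design.asf * design.tsf)


@dataclass
class SpaceballDesign:
    """Hemispherical-probe array parameters and raw intersection counts."""

    probe_radius_um: float = 10.0
    probe_spacing_um: float = 250.0
    intersections: Sequence[int] = field(default_factory=list)
    n_probes: Optional[int] = None
    section_volume_um3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.probe_radius_um <= 0 or self.probe_spacing_um <= 0:
            raise ValueError("probe radius and spacing must be positive")
        if any(i < 0 for i in self.intersections):
            raise ValueError("intersection counts must be non-negative")

    @property
    def probe_surface_um2(self) -> float:
        """Curved (counting) surface of one hemisphere."""
        return 2.0 * math.pi * self.probe_radius_um**2


def spaceball_length_density(
    design: SpaceballDesign, units: str = "nm_per_um3"
) -> float:
    """Length density L_V = 2·ΣI/ΣS from hemispherical-probe counts."""
    n = design.n_probes if design.n_probes is not None else len(design.intersections)
    if n < 1:
        raise ValueError("need at least one probe site")
    total_i = float(np.sum(design.intersections))
    lv_um = 2.0 * total_i / (n * design.probe_surface_um2)  # µm / µm³
    if units == "um_per_um3":
        return lv_um
    if units == "nm_per_um3":
        return lv_um * 1e3
    raise ValueError("units must be 'um_per_um3' or 'nm_per_um3'")


def total_length_um(design: SpaceballDesign) -> float:
    """Total fiber length in the sampled section, L = L_V × section volume."""
    if design.section_volume_um3 is None:
        raise ValueError("section_volume_um3 required for a length total")
    return spaceball_length_density(design, "um_per_um3") * design.section_volume_um3


# ---------------------------------------------------------------------------
# simulated sampling of phantoms (closes the Monte-Carlo validation loop)
# ---------------------------------------------------------------------------


def simulate_fractionator(
    phantom: CellPhantom,
    design: FractionatorDesign,
    rng: np.random.Generator,
) -> FractionatorDesign:
    """Sample a cell phantom with a systematic-uniform-random fractionator.

    Sections tile z with the design spacing and a uniform random phase;
    counting frames tile x-y with the grid period and a uniform random phase.
    A cell (nucleolus-proxy point) is counted iff it falls inside a section
    slab and inside a frame; frame membership uses half-open intervals, the
    point-particle form of the forbidden-line rule (two exclusion edges).
    Returns a copy of the design with per-section counts filled in.
    """
    dims = np.asarray(phantom.volume_um, dtype=float)
    if design.section_thickness_um > dims[2]:
        raise ValueError("section thickness exceeds phantom depth")
    pts = phantom.centroids_um
    z0 = rng.uniform(0.0, design.section_spacing_um)
    gx = rng.uniform(0.0, design.grid_x_um)
    gy = rng.uniform(0.0, design.grid_y_um)

    if len(pts) == 0:
        n_sections = max(1, int(math.ceil(dims[2] / design.section_spacing_um)))
        return _with_counts(design, [0] * n_sections)

    zmod = np.mod(pts[:, 2] - z0, design.section_spacing_um)
    in_section = zmod < design.section_thickness_um
    xmod = np.mod(pts[:, 0] - gx, design.grid_x_um)
    ymod = np.mod(pts[:, 1] - gy, design.grid_y_um)
    in_frame = (xmod < design.frame_x_um) & (ymod < design.frame_y_um)
    counted = in_section & in_frame

    section_index = ((pts[:, 2] - z0) // design.section_spacing_um).astype(int)
    n_sections = max(1, int(math.ceil((dims[2] - z0) / design.section_spacing_um)) + 1)
    counts = [0] * n_sections
    for idx in section_index[counted]:
        counts[max(0, int(idx))] += 1
    return _with_counts(design, counts)


def _with_counts(design: FractionatorDesign, counts: List[int]) -> FractionatorDesign:
    return FractionatorDesign(
        section_thickness_um=design.section_thickness_um,
        section_spacing_um=design.section_spacing_um,
        grid_x_um=design.grid_x_um,
        grid_y_um=design.grid_y_um,
        frame_x_um=design.frame_x_um,
        frame_y_um=design.frame_y_um,
        dissector_height_um=design.dissector_height_um,
        q_counts=counts,
        measured_thickness_um=[design.section_thickness_um] * len(counts),
    )


def sphere_segment_intersections(
    segments: np.ndarray,
    center: np.ndarray,
    radius: float,
    hemisphere: str = "lower",
) -> int:
    """Exact count of segment crossings of a (hemi)sphere surface.

    Solves the line–sphere quadratic per segment and keeps roots with
    parameter t ∈ [0, 1]; for a hemisphere, only crossings on the counted
    half (z below the center for ``lower``) are kept.  Endpoints lying
    inside the sphere produce no crossing, as they should for a surface
    probe.
    """
    segs = np.asarray(segments, dtype=float).reshape(-1, 2, 3)
    if len(segs) == 0:
        return 0
    a = segs[:, 0, :] - center
    d = segs[:, 1, :] - segs[:, 0, :]
    A = np.einsum("ij,ij->i", d, d)
    B = 2.0 * np.einsum("ij,ij->i", a, d)
    C = np.einsum("ij,ij->i", a, a) - radius**2
    disc = B * B - 4 * A * C
    ok = np.flatnonzero((disc > 0) & (A > 0))
    if ok.size == 0:
        return 0
    sq = np.sqrt(disc[ok])
    roots = np.stack(
        [(-B[ok] - sq) / (2 * A[ok]), (-B[ok] + sq) / (2 * A[ok])], axis=1
    )
    z = segs[ok, 0, 2, None] + roots * d[ok, 2, None]
    valid = (roots >= 0.0) & (roots <= 1.0)
    if hemisphere == "lower":
        valid &= z <= center[2]
    elif hemisphere == "upper":
        valid &= z >= center[2]
    elif hemisphere != "full":
        raise ValueError("hemisphere must be 'lower', 'upper' or 'full'")
    return int(np.count_nonzero(valid))


def _probe_grid(
    dims: np.ndarray, spacing: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Systematic x-y probe positions with random phase, margin from walls."""
    ox = rng.uniform(0.0, spacing)
    oy = rng.uniform(0.0, spacing)
    xs = np.arange(ox, dims[0], spacing)
    ys = np.arange(oy, dims[1], spacing)
    centers = [
        (x, y)
        for x in xs
        for y in ys
        if margin <= x <= dims[0] - margin and margin <= y <= dims[1] - margin
    ]
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def simulate_spaceball(
    phantom: FiberPhantom,
    design: SpaceballDesign,
    rng: np.random.Generator,
) -> SpaceballDesign:
    """Sample a fiber phantom with an array of hemispherical probes.

    Probes sit with their flat face on the section top surface, dome pointing
    down into the tissue; only curved-surface crossings are counted.  Probe
    centers keep one radius clear of the phantom's side walls so the probe
    lies entirely in the reference space.
    """
    dims = np.asarray(phantom.volume_um, dtype=float)
    r = design.probe_radius_um
    if r > dims[2]:
        raise ValueError("probe radius exceeds the section thickness")
    if 2 * r >= min(dims[0], dims[1]):
        raise ValueError("probe does not fit inside the phantom footprint")
    centers_xy = _probe_grid(dims, design.probe_spacing_um, r, rng)
    z_top = dims[2]

    segs = phantom.segments_um
    counts = []
    lo = segs.min(axis=1)  # per-segment bounding boxes
    hi = segs.max(axis=1)
    for cx, cy in centers_xy:
        c = np.array([cx, cy, z_top])
        near = (
            (lo[:, 0] <= cx + r)
            & (hi[:, 0] >= cx - r)
            & (lo[:, 1] <= cy + r)
            & (hi[:, 1] >= cy - r)
            & (lo[:, 2] <= z_top)
            & (hi[:, 2] >= z_top - r)
        )
        counts.append(
            sphere_segment_intersections(segs[near], c, r, hemisphere="lower")
        )
    return SpaceballDesign(
        probe_radius_um=r,
        probe_spacing_um=design.probe_spacing_um,
        intersections=counts,
        section_volume_um3=float(np.prod(dims)),
    )


def simulate_planar_probe(
    phantom: FiberPhantom,
    design: SpaceballDesign,
    rng: np.random.Generator,
    depth_um: Optional[float] = None,
) -> float:
    """Length-density estimate from *flat* disc probes of equal total area.

    Horizontal discs of area 2πr² (matching the hemisphere's curved surface)
    are placed at a fixed depth; L_V is estimated with the same 2·ΣI/ΣS
    formula.  For isotropic fibers this is unbiased, but for anisotropic
    fibers it is not — vertical fibers are counted twice too often and
    in-plane fibers never — which is the classical argument for curved
    probes.
    """
    dims = np.asarray(phantom.volume_um, dtype=float)
    r_eff = math.sqrt(2.0) * design.probe_radius_um  # disc area = 2πr²
    depth = dims[2] / 2.0 if depth_um is None else depth_um
    centers_xy = _probe_grid(dims, design.probe_spacing_um, r_eff, rng)
    z = dims[2] - depth
    segs = phantom.segments_um
    total_i = 0
    for cx, cy in centers_xy:
        a, b = segs[:, 0, :], segs[:, 1, :]
        dz = b[:, 2] - a[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (z - a[:, 2]) / dz
        crossing = (dz != 0) & (t >= 0) & (t <= 1)
        px = a[:, 0] + t * (b[:, 0] - a[:, 0])
        py = a[:, 1] + t * (b[:, 1] - a[:, 1])
        inside = crossing & ((px - cx) ** 2 + (py - cy) ** 2 <= r_eff**2)
        total_i += int(np.count_nonzero(inside))
    area = len(centers_xy) * math.pi * r_eff**2
    if area == 0:
        raise ValueError("no planar probes fit the phantom")
    return 2.0 * total_i / area  # µm / µm³


def simulate_probe_sampling(phantom, design, seed: int = 0):
    """Dispatch phantom sampling to the matching probe simulator."""
    rng = np.random.default_rng(seed)
    if isinstance(phantom, CellPhantom) and isinstance(design, FractionatorDesign):
        return simulate_fractionator(phantom, design, rng)
    if isinstance(phantom, FiberPhantom) and isinstance(design, SpaceballDesign):
        return simulate_spaceball(phantom, design, rng)
    raise TypeError("phantom/design combination not supported")
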