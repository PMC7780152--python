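"""Synthetic 3D phantoms of vascularized endocrine tissue with ground truth.

Phantoms emulate the structures the quantification pipeline assumes:
tubular capillary networks at a controlled volume fraction, thicker
smooth-muscle-coated (α-SMA+) artery tubes, insulin+ islet spheroids
containing a dense internal capillary plexus, nuclei rendered as
Gaussian blobs, and cell populations (macrophages, fibroblasts,
pericytes, β cells, proliferating subsets) placed at controlled
distances from the vessel surface. Channels are blurred by an isotropic
Gaussian PSF and degraded with additive Gaussian noise (clipped at 0).

Tubes are rasterized by an exact point-to-axis distance test per voxel
centre, restricted to the segment's axial extent, i.e. as true finite
cylinders — so the analytic volume πr²L is the ground truth against
which rasterization and the downstream pipeline are checked. True
metrics in :class:`GroundTruth` always come from the analytic geometry,
never from the rendered image.

Identical (spec, seed) pairs produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import DEFAULT_SPACING_UM, VoxelGrid

NUCLEI_CHANNEL = "nuclei"


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

@dataclass
class Tube:
    """Finite cylinder from ``p0_um`` to ``p1_um`` (zyx order, μm)."""

    p0_um: tuple[float, float, float]
    p1_um: tuple[float, float, float]
    radius_um: float

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1_um, self.p0_um)))

    @property
    def volume_um3(self) -> float:
        return float(np.pi * self.radius_um**2 * self.length_um)


def rasterize_tube(
    mask: np.ndarray, tube: Tube, spacing_um: Sequence[float]
) -> None:
    """OR a finite cylinder into ``mask`` using exact voxel-centre tests."""
    sp = np.asarray(spacing_um, float)
    shape = np.asarray(mask.shape)
    p0 = np.asarray(tube.p0_um, float)
    p1 = np.asarray(tube.p1_um, float)
    r = float(tube.radius_um)
    lo = np.maximum(0, np.floor((np.minimum(p0, p1) - r) / sp)).astype(int)
    hi = np.minimum(shape - 1, np.ceil((np.maximum(p0, p1) + r) / sp)).astype(int)
    if np.any(lo > hi):
        return
    grids = np.meshgrid(
        *(np.arange(lo[i], hi[i] + 1) * sp[i] for i in range(3)), indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        inside = np.linalg.norm(pts - p0, axis=1) <= r
    else:
        t = (pts - p0) @ v / vv
        closest = p0 + np.outer(t, v)
        radial = np.linalg.norm(pts - closest, axis=1)
        inside = (t >= 0.0) & (t <= 1.0) & (radial <= r)
    sub = mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    sub |= inside.reshape(sub.shape)


def rasterize_ball(
    mask: np.ndarray, center_um: Sequence[float], radius_um: float,
    spacing_um: Sequence[float],
) -> None:
    rasterize_tube(mask, Tube(tuple(center_um), tuple(center_um), radius_um), spacing_um)


def _segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (used for overlap rejection)."""
    p0, p1, q0, q1 = (np.asarray(a, float) for a in (p0, p1, q0, q1))
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Random capillary network hitting an exact analytic volume fraction.

    Straight non-overlapping segments are placed fully inside the domain
    until their cumulative analytic volume Σ πr²L reaches
    ``target_volume_fraction`` of the domain volume (the final segment is
    trimmed to land on the target exactly).
    """

    target_volume_fraction: float
    radius_um_range: tuple[float, float] = (2.5, 4.0)
    segment_length_um_range: tuple[float, float] = (30.0, 70.0)
    max_attempts: int = 20000


@dataclass
class IsletSpec:
    """Insulin+ spheroid with an internal capillary plexus."""

    center_um: tuple[float, float, float]
    radius_um: float
    plexus_fraction: float = 0.05
    plexus_radius_um: float = 2.2
    plexus_segment_length_um: tuple[float, float] = (10.0, 25.0)


@dataclass
class CellPopulationSpec:
    """A cell type placed at a controlled distance from the vessel surface.

    ``distance_band_um = (d_min, d_max)`` places cells uniformly among
    voxels whose centre-to-nearest-vessel-voxel distance lies in the
    band; ``None`` means uniform anywhere in tissue (outside vessels).
    ``in_islet`` restricts placement to islet interiors.
    """

    name: str
    markers: tuple[str, ...]
    count: int
    distance_band_um: tuple[float, float] | None = None
    in_islet: bool = False
    proliferating_fraction: float = 0.0
    cell_radius_um: float = 3.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (60, 100, 100)
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    vessels: list[Tube] = field(default_factory=list)
    vessel_network: NetworkSpec | None = None
    arteries: list[Tube] = field(default_factory=list)
    islets: list[IsletSpec] = field(default_factory=list)
    cell_populations: list[CellPopulationSpec] = field(default_factory=list)
    foreground: float = 200.0
    background: float = 10.0
    marker_foreground: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    psf_sigma_um: float = 0.0
    seed: int = 0
    vessel_marker: str = "Emcn"
    artery_marker: str = "aSMA"
    islet_marker: str = "insulin"
    proliferation_marker: str = "Ki67"
    nuclei_sigma_um: float = 2.0
    min_cell_separation_um: float = 9.0

    def validate(self) -> None:
        extent = min(s * sp for s, sp in zip(self.shape, self.spacing_um))
        for tube in list(self.vessels) + list(self.arteries):
            if not (0 < tube.radius_um < extent / 2):
                raise ValueError(f"tube radius {tube.radius_um} outside (0, {extent / 2})")
        for islet in self.islets:
            if not (0 < islet.radius_um < extent / 2):
                raise ValueError(f"islet radius {islet.radius_um} outside (0, {extent / 2})")
        for pop in self.cell_populations:
            if pop.count < 0:
                raise ValueError(f"negative count for population {pop.name!r}")
            if not (0 <= pop.proliferating_fraction <= 1):
                raise ValueError(f"proliferating_fraction of {pop.name!r} not in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")


@dataclass
class GroundTruth:
    """Analytic truth emitted alongside each phantom."""

    vessel_mask: np.ndarray
    artery_mask: np.ndarray
    islet_labels: np.ndarray
    cells: pd.DataFrame
    true_metrics: dict
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def place_cells_at_distance(
    vessel_mask: np.ndarray,
    spacing_um: Sequence[float],
    n: int,
    d_min: float,
    d_max: float,
    seed: int | np.random.Generator = 0,
    min_separation_um: float = 0.0,
    allowed_mask: np.ndarray | None = None,
    existing_um: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``n`` voxel-centre positions with vessel distance in [d_min, d_max].

    Distance is the anisotropic Euclidean distance from the voxel centre
    to the nearest vessel voxel centre (0 inside the vessel mask), the
    same definition the interactome uses, so planted distances are exact
    by construction. Reproducible under ``seed``.

    Returns an ``(n, 3)`` array of centroids in μm (zyx).
    """
    if d_min > d_max:
        raise ValueError(f"require d_min <= d_max, got ({d_min}, {d_max})")
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any() and np.isfinite(d_max):
        raise ValueError("vessel mask is empty; finite distance band is infeasible")
    sp = np.asarray([float(s) for s in spacing_um])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = ndimage.distance_transform_edt(~vessel_mask, sampling=sp)
    candidates = (dist >= d_min) & (dist <= d_max)
    if allowed_mask is not None:
        candidates &= np.asarray(allowed_mask, bool)
    idx = np.argwhere(candidates)
    if len(idx) < n:
        raise ValueError(
            f"infeasible distance band [{d_min}, {d_max}] μm: "
            f"{len(idx)} candidate voxels for {n} cells"
        )
    order = rng.permutation(len(idx))
    chosen: list[np.ndarray] = []
    blockers = [] if existing_um is None or len(existing_um) == 0 else [np.asarray(existing_um, float)]
    for i in order:
        pos = idx[i] * sp
        if min_separation_um > 0 and (chosen or blockers):
            others = np.concatenate([np.asarray(chosen).reshape(-1, 3)] + blockers) \
                if chosen else blockers[0]
            if np.linalg.norm(others - pos, axis=1).min() < min_separation_um:
                continue
        chosen.append(pos)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(
            f"could only place {len(chosen)}/{n} cells in band [{d_min}, {d_max}] μm "
            f"with separation {min_separation_um} μm"
        )
    return np.asarray(chosen)


def _random_network(
    shape: Sequence[int],
    spacing_um: Sequence[float],
    spec: NetworkSpec,
    rng: np.random.Generator,
    existing: list[Tube] | None = None,
) -> list[Tube]:
    """Non-overlapping random segments summing to the exact target volume."""
    sp = np.asarray(spacing_um, float)
    extent = np.asarray(shape) * sp
    domain_volume = float(np.prod(extent))
    target = spec.target_volume_fraction * domain_volume
    tubes: list[Tube] = []
    others = list(existing or [])
    total = 0.0
    clearance = float(sp.max())
    attempts = 0
    while total < target and attempts < spec.max_attempts:
        attempts += 1
        r = float(rng.uniform(*spec.radius_um_range))
        length = float(rng.uniform(*spec.segment_length_um_range))
        remaining = target - total
        length = min(length, remaining / (np.pi * r**2))
        if length < 2 * r:
            # too short to look tubular: finish with a thinner radius
            r = max(spec.radius_um_range[0] * 0.8, np.sqrt(remaining / (np.pi * 2 * r)))
            length = remaining / (np.pi * r**2)
        margin = r + clearance
        if np.any(extent - 2 * margin <= 0):
            raise ValueError("domain too small for requested tube radii")
        p0 = rng.uniform(margin, extent - margin)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p1 = p0 + direction * length
        if np.any(p1 < margin) or np.any(p1 > extent - margin):
            continue
        ok = True
        for other in tubes + others:
            gap = _segment_segment_distance(p0, p1, other.p0_um, other.p1_um)
            if gap < r + other.radius_um + clearance:
                ok = False
                break
        if not ok:
            continue
        tubes.append(Tube(tuple(p0), tuple(p1), r))
        total += np.pi * r**2 * length
    if total < target * 0.999:
        raise ValueError(
            f"could not reach target volume fraction {spec.target_volume_fraction} "
            f"(achieved {total / domain_volume:.4%}) in {spec.max_attempts} attempts"
        )
    return tubes


def _plexus_tubes(
    islet: IsletSpec, rng: np.random.Generator
) -> list[Tube]:
    """Random chords inside an islet sphere forming its capillary plexus."""
    center = np.asarray(islet.center_um, float)
    inner = islet.radius_um - islet.plexus_radius_um - 1.0
    if inner <= 0:
        return []
    target = islet.plexus_fraction * (4.0 / 3.0) * np.pi * islet.radius_um**3
    tubes: list[Tube] = []
    total = 0.0
    attempts = 0
    while total < target and attempts < 5000:
        attempts += 1
        r = islet.plexus_radius_um
        length = float(rng.uniform(*islet.plexus_segment_length_um))
        length = min(length, (target - total) / (np.pi * r**2))
        if length <= r:
            break
        # random start point and direction, both endpoints inside the sphere
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p0 = center + u * (inner * rng.uniform(0, 0.8) ** (1 / 3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p1 = p0 + direction * length
        if np.linalg.norm(p1 - center) > inner:
            continue
        ok = all(
            _segment_segment_distance(p0, p1, t.p0_um, t.p1_um) >= r + t.radius_um
            for t in tubes
        )
        if not ok:
            continue
        tubes.append(Tube(tuple(p0), tuple(p1), r))
        total += np.pi * r**2 * length
    return tubes


def _paint_nucleus(
    channel: np.ndarray, center_um: np.ndarray, sigma_um: float,
    amplitude: float, spacing_um: np.ndarray,
) -> None:
    """Add a 3D Gaussian blob (a nucleus) at a physical position."""
    lo = np.maximum(0, np.floor((center_um - 4 * sigma_um) / spacing_um)).astype(int)
    hi = np.minimum(np.asarray(channel.shape) - 1,
                    np.ceil((center_um + 4 * sigma_um) / spacing_um)).astype(int)
    grids = np.meshgrid(
        *(np.arange(lo[i], hi[i] + 1) * spacing_um[i] for i in range(3)), indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    blob = amplitude * np.exp(-d2 / (2.0 * sigma_um**2))
    channel[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += blob


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render a phantom volume and its analytic ground truth.

    The returned :class:`~gland3d.grid.VoxelGrid` has one channel per
    marker referenced by the spec plus a nuclei channel; every placed
    cell carries a nucleus blob. ``GroundTruth.true_metrics`` holds the
    analytic vessel volume fraction, artery count, tube diameters and
    per-population counts/fractions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing_um, float)
    shape = tuple(int(s) for s in spec.shape)
    domain_volume_um3 = float(np.prod(np.asarray(shape) * sp))

    # --- vasculature ------------------------------------------------------
    capillaries = list(spec.vessels)
    if spec.vessel_network is not None:
        capillaries += _random_network(shape, sp, spec.vessel_network, rng,
                                       existing=list(spec.arteries))
    plexus: list[Tube] = []
    islet_labels = np.zeros(shape, dtype=np.int32)
    for i, islet in enumerate(spec.islets, start=1):
        ball = np.zeros(shape, bool)
        rasterize_ball(ball, islet.center_um, islet.radius_um, sp)
        islet_labels[ball] = i
        plexus += _plexus_tubes(islet, rng)

    vessel_mask = np.zeros(shape, dtype=bool)
    for tube in capillaries + plexus:
        rasterize_tube(vessel_mask, tube, sp)
    artery_mask = np.zeros(shape, dtype=bool)
    for tube in spec.arteries:
        rasterize_tube(artery_mask, tube, sp)

    # --- channels ---------------------------------------------------------
    markers: list[str] = []

    def _register(name: str) -> None:
        if name not in markers:
            markers.append(name)

    _register(spec.vessel_marker)
    if spec.arteries:
        _register(spec.artery_marker)
    if spec.islets:
        _register(spec.islet_marker)
    for pop in spec.cell_populations:
        for m in pop.markers:
            _register(m)
        if pop.proliferating_fraction > 0:
            _register(spec.proliferation_marker)

    def _fg(marker: str) -> float:
        return float(spec.marker_foreground.get(marker, spec.foreground))

    channels = {m: np.full(shape, spec.background, dtype=np.float64) for m in markers}
    channels[NUCLEI_CHANNEL] = np.full(shape, spec.background, dtype=np.float64)
    channels[spec.vessel_marker][vessel_mask] = _fg(spec.vessel_marker)
    if spec.arteries:
        channels[spec.artery_marker][artery_mask] = _fg(spec.artery_marker)
    if spec.islets:
        channels[spec.islet_marker][islet_labels > 0] = _fg(spec.islet_marker)

    # --- cells ------------------------------------------------------------
    dist_field = ndimage.distance_transform_edt(~vessel_mask, sampling=sp) \
        if vessel_mask.any() else np.full(shape, np.inf)
    occupied = vessel_mask | artery_mask
    cell_rows = []
    placed_all: list[np.ndarray] = []
    cell_id = 0
    for pop in spec.cell_populations:
        if pop.count == 0:
            continue
        allowed = ~occupied
        if pop.in_islet:
            allowed &= islet_labels > 0
        if pop.distance_band_um is not None:
            d_min, d_max = pop.distance_band_um
            if d_min <= 0:
                allowed = allowed | vessel_mask  # surface placement permitted
        else:
            d_min, d_max = 0.0, np.inf
        pop_rng = np.random.default_rng(rng.integers(0, 2**31))
        existing = np.concatenate(placed_all) if placed_all else None
        try:
            centroids = place_cells_at_distance(
                vessel_mask, sp, pop.count, d_min, d_max,
                seed=pop_rng, min_separation_um=spec.min_cell_separation_um,
                allowed_mask=allowed, existing_um=existing,
            )
        except ValueError as exc:
            raise ValueError(f"population {pop.name!r}: {exc}") from exc
        placed_all.append(centroids)
        proliferating = pop_rng.random(pop.count) < pop.proliferating_fraction
        for c, prolif in zip(centroids, proliferating):
            cell_id += 1
            idx = tuple(np.round(c / sp).astype(int))
            body = np.zeros(shape, bool)
            rasterize_ball(body, c, pop.cell_radius_um, sp)
            body &= ~vessel_mask
            for m in pop.markers:
                channels[m][body] = _fg(m)
            if prolif:
                channels[spec.proliferation_marker][body] = _fg(spec.proliferation_marker)
            _paint_nucleus(channels[NUCLEI_CHANNEL], c, spec.nuclei_sigma_um,
                           _fg(NUCLEI_CHANNEL), sp)
            cell_rows.append({
                "cell_id": cell_id,
                "type": pop.name,
                "centroid_z_um": c[0], "centroid_y_um": c[1], "centroid_x_um": c[2],
                "distance_to_vessel_um": float(dist_field[idx]),
                "proliferating": bool(prolif),
                "in_islet": bool(islet_labels[idx] > 0),
            })
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "type", "centroid_z_um", "centroid_y_um", "centroid_x_um",
                 "distance_to_vessel_um", "proliferating", "in_islet"],
    )

    # --- optics + noise ---------------------------------------------------
    names = markers + [NUCLEI_CHANNEL]
    data = np.stack([channels[m] for m in names])
    if spec.psf_sigma_um > 0:
        sigma_vox = tuple(spec.psf_sigma_um / s for s in sp)
        for i in range(len(data)):
            data[i] = ndimage.gaussian_filter(data[i], sigma=sigma_vox)
    if spec.noise_sd > 0:
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, size=data.shape), 0.0, None)

    grid = VoxelGrid(data=data, spacing_um=tuple(sp), channel_names=names)

    # --- analytic truth ---------------------------------------------------
    cap_volume = sum(t.volume_um3 for t in capillaries + plexus)
    true_metrics: dict = {
        "vessel_volume_fraction": cap_volume / domain_volume_um3,
        "artery_count": len(spec.arteries),
        "mean_artery_diameter_um": (
            float(np.mean([2 * t.radius_um for t in spec.arteries])) if spec.arteries else 0.0
        ),
        "mean_capillary_diameter_um": (
            float(np.mean([2 * t.radius_um for t in capillaries])) if capillaries else 0.0
        ),
        "islet_count": len(spec.islets),
        "domain_volume_um3": domain_volume_um3,
    }
    for pop in spec.cell_populations:
        sub = cells[cells["type"] == pop.name]
        true_metrics[f"count_{pop.name}"] = int(len(sub))
        if pop.proliferating_fraction > 0 and len(sub):
            true_metrics[f"proliferating_fraction_{pop.name}"] = float(sub["proliferating"].mean())
    truth = GroundTruth(
        vessel_mask=vessel_mask, artery_mask=artery_mask, islet_labels=islet_labels,
        cells=cells, true_metrics=true_metrics, spacing_um=tuple(sp),
    )
    return grid, truth
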