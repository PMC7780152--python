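"""Surface segmentation, shape statistics and nuclei-seeded cell segmentation.

Mirrors the interactive surface-reconstruction workflow used on
immunolabelled gland volumes: background subtraction, Gaussian
smoothing, (manual or Otsu) thresholding, 26-connected component
labelling with per-component shape statistics, removal of small
high-sphericity components as noise, and nuclei-seeded segmentation of
cells with per-marker mean intensities and rule-based phenotyping.

Sphericity is the standard dimensionless shape score

.. math:: \\psi = \\pi^{1/3} (6V)^{2/3} / A

with volume :math:`V` from voxel counts and surface area :math:`A`
from a marching-cubes boundary mesh; :math:`\\psi = 1` for a ball and
decreases with elongation and surface roughness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

COMPONENT_COLUMNS = (
    "label", "voxel_count", "volume_um3", "surface_area_um2",
    "sphericity", "elongation",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
)

CELL_COLUMNS_BASE = (
    "cell_id", "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "nucleus_volume_um3", "territory_volume_um3",
)


def _sigma_voxels(sigma_um: float, spacing_um: Sequence[float]) -> tuple[float, ...]:
    """Convert an isotropic physical smoothing scale to per-axis voxel sigmas."""
    return tuple(float(sigma_um) / float(s) for s in spacing_um)


def subtract_background(
    channel: np.ndarray, spacing_um: Sequence[float], scale_um: float
) -> np.ndarray:
    """Remove slowly varying background at scale ``scale_um`` (μm).

    Output is ``input - gaussian(input, scale_um)`` clipped at zero, so a
    flat field maps to ~0 while structures much smaller than ``scale_um``
    keep their contrast.
    """
    if scale_um <= 0:
        raise ValueError(f"scale_um must be > 0, got {scale_um}")
    channel = np.asarray(channel, dtype=float)
    background = ndimage.gaussian_filter(channel, sigma=_sigma_voxels(scale_um, spacing_um))
    return np.clip(channel - background, 0.0, None)


# ---------------------------------------------------------------------------
# Connected components with shape statistics
# ---------------------------------------------------------------------------

def _component_surface_area(mask: np.ndarray, spacing_um: Sequence[float]) -> float:
    """Surface area (μm²) of a binary solid from a marching-cubes mesh."""
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing_um))
    return float(measure.mesh_surface_area(verts, faces))


def _elongation(mask: np.ndarray, spacing_um: Sequence[float]) -> float:
    """Principal-axis elongation: sqrt of largest/smallest inertia eigenvalue ratio."""
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing_um)
    if len(coords) < 2:
        return 1.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.linalg.eigvalsh(cov)
    smallest = max(eig[0], 1e-12)
    return float(np.sqrt(eig[-1] / smallest))


@dataclass
class ComponentSet:
    """Binary mask plus labelled 26-connected components with shape stats.

    ``components`` holds one row per label (labels contiguous from 1):
    voxel count, volume (μm³), marching-cubes surface area (μm²),
    sphericity ψ, principal-axis elongation and the centroid in μm.
    """

    mask: np.ndarray
    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    components: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(COMPONENT_COLUMNS)))

    def __len__(self) -> int:
        return len(self.components)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @classmethod
    def from_mask(cls, mask: np.ndarray, spacing_um: Sequence[float]) -> "ComponentSet":
        """Label a binary mask (26-connectivity) and compute shape statistics."""
        mask = np.asarray(mask).astype(bool)
        spacing = tuple(float(s) for s in spacing_um)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        voxel_vol = float(np.prod(spacing))
        rows = []
        slices = ndimage.find_objects(labels)
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            sub = labels[sl] == lab
            count = int(sub.sum())
            volume = count * voxel_vol
            area = _component_surface_area(sub, spacing)
            sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
            elong = _elongation(sub, spacing)
            zyx = np.argwhere(sub).astype(float)
            offset = np.array([s.start for s in sl], dtype=float)
            centroid = (zyx.mean(axis=0) + offset) * np.asarray(spacing)
            rows.append((lab, count, volume, area, sphericity, elong, *centroid))
        df = pd.DataFrame(rows, columns=list(COMPONENT_COLUMNS))
        return cls(mask=mask, labels=labels, spacing_um=spacing, components=df)  # type: ignore[arg-type]


def segment_surface(
    channel: np.ndarray,
    spacing_um: Sequence[float],
    smooth_sigma_um: float = 1.5,
    threshold: float | str = "auto",
) -> ComponentSet:
    """Smooth, threshold and label a marker channel into a surface.

    ``threshold`` is either a number (manual — preferred when comparing
    groups, with the same value applied to every sample) or ``"auto"``
    for Otsu's method on the smoothed histogram. Components use
    26-connectivity. Empty foreground yields a valid empty
    :class:`ComponentSet`.
    """
    channel = np.asarray(channel, dtype=float)
    if np.isnan(channel).any():
        raise ValueError("channel contains NaN")
    smoothed = channel
    if smooth_sigma_um > 0:
        smoothed = ndimage.gaussian_filter(channel, sigma=_sigma_voxels(smooth_sigma_um, spacing_um))
    if threshold == "auto":
        if np.ptp(smoothed) == 0:
            return ComponentSet.from_mask(np.zeros_like(channel, bool), spacing_um)
        thr = float(filters.threshold_otsu(smoothed))
    else:
        thr = float(threshold)  # type: ignore[arg-type]
    mask = smoothed > thr
    return ComponentSet.from_mask(mask, spacing_um)


def filter_noise_components(
    cs: ComponentSet,
    max_volume_um3: float = 500.0,
    min_sphericity: float = 0.8,
) -> ComponentSet:
    """Drop small high-sphericity components regarded as noise.

    Removes exactly the components with ``volume < max_volume_um3`` AND
    ``sphericity >= min_sphericity``; everything else is retained and
    relabelled contiguously from 1.
    """
    if max_volume_um3 <= 0:
        raise ValueError("max_volume_um3 must be > 0")
    if not (0 < min_sphericity <= 1):
        raise ValueError("min_sphericity must be in (0, 1]")
    df = cs.components
    drop = df[(df["volume_um3"] < max_volume_um3) & (df["sphericity"] >= min_sphericity)]["label"]
    keep_mask = cs.mask.copy()
    for lab in drop:
        keep_mask[cs.labels == lab] = False
    return ComponentSet.from_mask(keep_mask, cs.spacing_um)


# ---------------------------------------------------------------------------
# Nuclei-seeded cell segmentation
# ---------------------------------------------------------------------------

def segment_cells(
    nuclei_channel: np.ndarray,
    spacing_um: Sequence[float],
    marker_channels: dict[str, np.ndarray] | None = None,
    membrane_channel: np.ndarray | None = None,
    nucleus_sigma_um: float = 2.0,
    min_separation_um: float = 6.0,
    threshold: float | str = "auto",
    max_cell_radius_um: float = 8.0,
) -> pd.DataFrame:
    """Detect nuclei and segment per-cell territories around them.

    Nuclei are detected as local maxima of the Gaussian-smoothed nuclei
    channel above an automatic (Otsu) or manual threshold. Each nucleus
    seeds a watershed on the membrane channel when one is given,
    otherwise territories are nearest-seed regions, in both cases bounded
    by ``max_cell_radius_um``. Per-cell mean marker intensities are
    measured over the territory.

    Returns
    -------
    pandas.DataFrame
        One row per cell: id, centroid (μm), nucleus volume, territory
        volume, one ``I_<marker>`` column per marker, and placeholder
        ``phenotype`` / ``distance_to_vessel_um`` columns.
    """
    nuclei = np.asarray(nuclei_channel, dtype=float)
    spacing = np.asarray([float(s) for s in spacing_um])
    marker_channels = marker_channels or {}

    smoothed = ndimage.gaussian_filter(nuclei, sigma=_sigma_voxels(nucleus_sigma_um, spacing))
    if threshold == "auto":
        thr = float(filters.threshold_otsu(smoothed)) if np.ptp(smoothed) > 0 else np.inf
    else:
        thr = float(threshold)  # type: ignore[arg-type]
    # suppression radius at half the expected separation so anisotropic
    # diagonals between distinct nuclei are not merged
    min_dist_vox = max(1, int(round(0.5 * min_separation_um / float(spacing.min()))))
    peaks = peak_local_max(
        smoothed, min_distance=min_dist_vox, threshold_abs=thr, exclude_border=False
    )

    columns = list(CELL_COLUMNS_BASE) + [f"I_{m}" for m in marker_channels] + [
        "phenotype", "region", "distance_to_vessel_um"
    ]
    if len(peaks) == 0:
        warnings.warn("no nuclei detected; returning empty cell table", stacklevel=2)
        return pd.DataFrame(columns=columns)

    # seed label volume and bounded territories
    seeds = np.zeros(nuclei.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        seeds[tuple(p)] = i
    dist_to_seed, indices = ndimage.distance_transform_edt(
        seeds == 0, sampling=spacing, return_indices=True
    )
    nearest = seeds[tuple(indices)]
    within = dist_to_seed <= max_cell_radius_um
    if membrane_channel is not None:
        membrane = ndimage.gaussian_filter(
            np.asarray(membrane_channel, float), sigma=_sigma_voxels(nucleus_sigma_um, spacing)
        )
        territories = sk_seg.watershed(membrane, markers=seeds, mask=within)
    else:
        territories = np.where(within, nearest, 0)

    # nucleus extent: smoothed signal above threshold, assigned to nearest seed
    nuc_fg = smoothed > (thr if np.isfinite(thr) else 0)
    voxel_vol = float(np.prod(spacing))
    n = len(peaks)
    ids = np.arange(1, n + 1)
    terr_counts = np.bincount(territories.ravel(), minlength=n + 1)[1:]
    nuc_counts = np.bincount(np.where(nuc_fg, territories, 0).ravel(), minlength=n + 1)[1:]
    marker_means = {}
    for m, ch in marker_channels.items():
        means = ndimage.mean(np.asarray(ch, float), labels=territories, index=ids)
        marker_means[m] = np.where(terr_counts > 0, np.nan_to_num(means), 0.0)
    df = pd.DataFrame({
        "cell_id": ids,
        "centroid_z_um": peaks[:, 0] * spacing[0],
        "centroid_y_um": peaks[:, 1] * spacing[1],
        "centroid_x_um": peaks[:, 2] * spacing[2],
        "nucleus_volume_um3": nuc_counts * voxel_vol,
        "territory_volume_um3": terr_counts * voxel_vol,
    })
    for m in marker_channels:
        df[f"I_{m}"] = marker_means[m]
    df["phenotype"] = "unclassified"
    df["region"] = "all"
    df["distance_to_vessel_um"] = np.nan
    return df[columns]


# ---------------------------------------------------------------------------
# Marker phenotyping
# ---------------------------------------------------------------------------

BANDS = ("neg", "pos", "lo", "hi")


@dataclass
class PhenotypeRule:
    """Marker-band rule, e.g. ``{"CD31": "pos", "Emcn": "hi"}``.

    A cell satisfies the rule iff every marker's mean intensity falls in
    the stated band relative to that marker's thresholds
    ``(t_pos, t_hi)``: neg: < t_pos; pos: ≥ t_pos; lo: ∈ [t_pos, t_hi);
    hi: ≥ t_hi. Rules are evaluated in declared priority order; the
    first match labels the cell.
    """

    label: str
    bands: dict[str, str]

    def __post_init__(self) -> None:
        for marker, band in self.bands.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r} for marker {marker!r}")

    def matches(self, intensities: dict[str, float], thresholds: dict[str, tuple[float, float]]) -> bool:
        for marker, band in self.bands.items():
            value = intensities[marker]
            t_pos, t_hi = thresholds[marker]
            ok = {
                "neg": value < t_pos,
                "pos": value >= t_pos,
                "lo": t_pos <= value < t_hi,
                "hi": value >= t_hi,
            }[band]
            if not ok:
                return False
        return True


def default_marker_thresholds(
    cells: pd.DataFrame, markers: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Per-marker (t_pos, t_hi): Otsu over cell intensities; t_hi = median above t_pos."""
    thresholds = {}
    for marker in markers:
        vals = cells[f"I_{marker}"].to_numpy(float)
        if len(vals) == 0 or np.ptp(vals) == 0:
            t_pos = float(vals.max()) + 1.0 if len(vals) else 1.0
        else:
            t_pos = float(filters.threshold_otsu(vals))
        above = vals[vals >= t_pos]
        t_hi = float(np.median(above)) if len(above) else t_pos
        if t_hi <= t_pos:
            t_hi = t_pos * 1.000001 + 1e-9
        thresholds[marker] = (t_pos, t_hi)
    return thresholds


def classify_phenotypes(
    cells: pd.DataFrame,
    rules: Sequence[PhenotypeRule],
    thresholds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Assign each cell the first matching rule's label, else "unclassified".

    ``thresholds`` maps marker → (t_pos, t_hi); when omitted it is
    derived from the table itself via :func:`default_marker_thresholds`.
    """
    markers = sorted({m for r in rules for m in r.bands})
    for marker in markers:
        if f"I_{marker}" not in cells.columns:
            raise KeyError(f"unknown marker {marker!r}: no column I_{marker}")
    if thresholds is None:
        thresholds = default_marker_thresholds(cells, markers)
    else:
        for marker in markers:
            if marker not in thresholds:
                raise KeyError(f"no thresholds for marker {marker!r}")
            t_pos, t_hi = thresholds[marker]
            if not t_pos < t_hi:
                raise ValueError(f"require t_pos < t_hi for {marker!r}, got {(t_pos, t_hi)}")

    out = cells.copy()
    labels = []
    for _, row in out.iterrows():
        intensities = {m: float(row[f"I_{m}"]) for m in markers}
        label = "unclassified"
        for rule in rules:
            if rule.matches(intensities, thresholds):
                label = rule.label
                break
        labels.append(label)
    out["phenotype"] = labels
    return out
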