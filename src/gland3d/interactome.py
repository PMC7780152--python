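"""Distance-transform cell–vessel interactome.

Each cell's distance to the vascular surface is read from the exact
anisotropic Euclidean distance transform of the vessel mask (0 inside a
vessel, distance in μm outside). A cell belongs to the interactome of a
vessel subset when its distance to that subset is **≤ 18 μm**
(inclusive, configurable). Interaction matrices tabulate, per
(vessel subset × cell type), how many cells of each type lie within the
threshold; comparing matrices between conditions (young vs aged) yields
gained/lost/stable interactions.

Distances are measured from the cell centroid to the nearest vessel
voxel; the field is interpolated trilinearly at off-grid centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_MAX_DISTANCE_UM = 18.0
DEFAULT_PRESENCE_MIN_FRACTION = 0.1

MATRIX_COLUMNS = ("subset", "cell_type", "n_within", "n_total", "fraction", "present")


@dataclass
class DistanceField:
    """Per-voxel distance (μm) to the nearest vessel voxel; 0 inside vessels."""

    distance_um: np.ndarray
    spacing_um: tuple[float, float, float]

    def at(self, centroids_um: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the field at physical positions (zyx μm)."""
        centroids_um = np.atleast_2d(np.asarray(centroids_um, float))
        sp = np.asarray(self.spacing_um)
        coords = (centroids_um / sp).T
        shape = np.asarray(self.distance_um.shape, float)
        if np.any(coords < -0.5) or np.any(coords > shape[:, None] - 0.5):
            raise ValueError("centroid outside grid bounds")
        return ndimage.map_coordinates(self.distance_um, coords, order=1, mode="nearest")


def distance_to_vessels(
    vessel_mask: np.ndarray, spacing_um: Sequence[float]
) -> DistanceField:
    """Exact anisotropic Euclidean distance transform of the vessel complement.

    An empty vessel mask yields a field of +∞ with a warning.
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    sp = tuple(float(s) for s in spacing_um)
    if not vessel_mask.any():
        warnings.warn("empty vessel mask: distance field is infinite", stacklevel=2)
        return DistanceField(np.full(vessel_mask.shape, np.inf), sp)
    dist = ndimage.distance_transform_edt(~vessel_mask, sampling=sp)
    return DistanceField(dist, sp)


def annotate_cell_distances(cells: pd.DataFrame, dist_field: DistanceField) -> pd.DataFrame:
    """Fill ``distance_to_vessel_um`` for each cell from the distance field."""
    out = cells.copy()
    if len(out) == 0:
        if "distance_to_vessel_um" not in out.columns:
            out["distance_to_vessel_um"] = pd.Series(dtype=float)
        return out
    centroids = out[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy(float)
    out["distance_to_vessel_um"] = dist_field.at(centroids)
    return out


def interactome_membership(
    cells: pd.DataFrame, max_distance_um: float = DEFAULT_MAX_DISTANCE_UM
) -> pd.DataFrame:
    """Flag cells within the interactome (distance ≤ threshold, inclusive)."""
    if "distance_to_vessel_um" not in cells.columns:
        raise KeyError("cells have no distance_to_vessel_um column; annotate first")
    out = cells.copy()
    out["interactome_member"] = out["distance_to_vessel_um"] <= max_distance_um
    return out


@dataclass
class InteractionMatrix:
    """Vessel-subset × cell-type interaction table for one condition.

    ``table`` is long-format with columns ``subset, cell_type, n_within,
    n_total, fraction, present``; an interaction is *present* when the
    within-threshold fraction reaches ``presence_min_fraction``.
    """

    table: pd.DataFrame
    threshold_um: float = DEFAULT_MAX_DISTANCE_UM
    presence_min_fraction: float = DEFAULT_PRESENCE_MIN_FRACTION
    condition: str = ""

    def pivot(self, value: str = "fraction") -> pd.DataFrame:
        return self.table.pivot(index="subset", columns="cell_type", values=value)

    def present_pairs(self) -> set[tuple[str, str]]:
        t = self.table
        return set(map(tuple, t.loc[t["present"], ["subset", "cell_type"]].to_numpy()))


def build_interactome(
    cells: pd.DataFrame,
    vessel_subsets: Mapping[str, np.ndarray],
    spacing_um: Sequence[float],
    threshold_um: float = DEFAULT_MAX_DISTANCE_UM,
    presence_min_fraction: float = DEFAULT_PRESENCE_MIN_FRACTION,
    condition: str = "",
    type_column: str = "type",
) -> InteractionMatrix:
    """Tabulate cells within ``threshold_um`` of each vessel subset, by cell type.

    Each subset gets its own distance field, so one cell can belong to
    several subsets' interactomes. Subsets with empty masks are omitted
    with a warning; cell types with zero cells yield (0, 0, 0.0) rows
    flagged absent.
    """
    cell_types = sorted(cells[type_column].unique()) if len(cells) else []
    rows = []
    for subset_name, mask in vessel_subsets.items():
        mask = np.asarray(mask, bool)
        if not mask.any():
            warnings.warn(f"vessel subset {subset_name!r} is empty; row omitted", stacklevel=2)
            continue
        dist_field = distance_to_vessels(mask, spacing_um)
        annotated = annotate_cell_distances(cells, dist_field)
        member = annotated["distance_to_vessel_um"] <= threshold_um
        for cell_type in cell_types:
            of_type = annotated[type_column] == cell_type
            n_total = int(of_type.sum())
            n_within = int((of_type & member).sum())
            fraction = n_within / n_total if n_total else 0.0
            rows.append((subset_name, cell_type, n_within, n_total, fraction,
                         n_total > 0 and fraction >= presence_min_fraction))
    table = pd.DataFrame(rows, columns=list(MATRIX_COLUMNS))
    return InteractionMatrix(table=table, threshold_um=threshold_um,
                             presence_min_fraction=presence_min_fraction,
                             condition=condition)


def differential_interactome(
    m_young: InteractionMatrix, m_aged: InteractionMatrix
) -> pd.DataFrame:
    """Classify every (subset, cell type) pair as gained / lost / stable.

    *Gained* interactions are present only in the aged condition, *lost*
    only in the young one. The two matrices must share their subset and
    cell-type vocabularies and threshold.
    """
    ty, ta = m_young.table, m_aged.table
    vocab_y = set(map(tuple, ty[["subset", "cell_type"]].to_numpy()))
    vocab_a = set(map(tuple, ta[["subset", "cell_type"]].to_numpy()))
    if vocab_y != vocab_a:
        raise ValueError("interaction matrices have different subset/cell-type vocabularies")
    if m_young.threshold_um != m_aged.threshold_um:
        raise ValueError("interaction matrices use different distance thresholds")
    present_y = m_young.present_pairs()
    present_a = m_aged.present_pairs()
    rows = []
    for subset, cell_type in sorted(vocab_y):
        key = (subset, cell_type)
        if key in present_a and key not in present_y:
            status = "gained"
        elif key in present_y and key not in present_a:
            status = "lost"
        else:
            status = "stable"
        rows.append((subset, cell_type, status))
    return pd.DataFrame(rows, columns=["subset", "cell_type", "status"])
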