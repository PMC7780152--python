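"""Per-islet/per-gland scalar quantifications and group statistics.

Area fractions (insulin+/CXCR4+ "β-cell mass", VEGFA coverage),
positive-cell fractions (Ki67+ β cells over all β cells), counts per
tissue volume (macrophages, fibroblasts per mm³), follicle density,
ordinal expression binning for qualitative heatmaps, Pearson
correlation, and the group tests used throughout: a two-tailed
equal-variance Student's t-test for two groups and one-way ANOVA with
Tukey's multiple-comparison test for more than two. P < 0.05 is the
conventional significance level; data are summarized as mean ± s.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .segmentation import ComponentSet
from .vessels import UM3_PER_MM3

EXPRESSION_LEVELS = ("none", "low", "medium", "high", "very_high")
UM2_PER_MM2 = 1e6


# ---------------------------------------------------------------------------
# Scalar quantifications
# ---------------------------------------------------------------------------

def area_fraction(marker_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Percent of the region's voxels that are marker-positive.

    This is the construction behind "β-cell mass": insulin- or
    CXCR4-stained volume divided by the islet volume, ×100. Same for
    VEGFA coverage per islet.
    """
    marker = np.asarray(marker_mask, bool)
    region = np.asarray(region_mask, bool)
    denom = int(region.sum())
    if denom == 0:
        raise ValueError("empty region mask")
    return 100.0 * float((marker & region).sum()) / denom


def positive_fraction(
    cells: pd.DataFrame,
    numerator: Mapping[str, bool] | str,
    denominator: Mapping[str, bool] | str | None = None,
) -> float:
    """Percent of denominator cells that also satisfy the numerator rule.

    Rules are either a phenotype label (matched against the
    ``phenotype``/``type`` column) or a mapping of boolean columns, e.g.
    ``{"proliferating": True}``. Returns NaN (flagged undefined) when
    the denominator is empty.
    """

    def _select(rule) -> pd.Series:
        if rule is None:
            return pd.Series(True, index=cells.index)
        if isinstance(rule, str):
            col = "phenotype" if "phenotype" in cells.columns else "type"
            sel = cells[col] == rule
            if "type" in cells.columns and not sel.any():
                sel = sel | (cells["type"] == rule)
            return sel
        sel = pd.Series(True, index=cells.index)
        for column, value in rule.items():
            if column not in cells.columns:
                raise KeyError(f"unknown column {column!r}")
            sel &= cells[column] == value
        return sel

    den = _select(denominator)
    n_den = int(den.sum())
    if n_den == 0:
        return float("nan")
    num = _select(numerator) & den
    return 100.0 * int(num.sum()) / n_den


def count_per_volume(
    cells: pd.DataFrame,
    cell_type: str,
    tissue_mask: np.ndarray,
    spacing_um: Sequence[float],
    type_column: str = "type",
) -> float:
    """Cells of a given type per mm³ of tissue."""
    tissue = np.asarray(tissue_mask, bool)
    voxel_vol = float(np.prod([float(s) for s in spacing_um]))
    volume_mm3 = tissue.sum() * voxel_vol / UM3_PER_MM3
    if volume_mm3 == 0:
        raise ValueError("empty tissue mask")
    n = int((cells[type_column] == cell_type).sum()) if len(cells) else 0
    return n / volume_mm3


def follicle_density(
    follicles: ComponentSet,
    gland_mask: np.ndarray,
    spacing_um: Sequence[float],
    mode: str = "volume",
) -> float:
    """Follicle count per gland measure (per mm³, or per mm² in single-slice mode)."""
    gland = np.asarray(gland_mask, bool)
    if not gland.any():
        raise ValueError("empty gland mask")
    sp = [float(s) for s in spacing_um]
    if mode == "volume":
        measure = gland.sum() * float(np.prod(sp)) / UM3_PER_MM3
    elif mode == "area":
        measure = gland.sum() * sp[1] * sp[2] / UM2_PER_MM2
    else:
        raise ValueError(f"mode must be 'volume' or 'area', got {mode!r}")
    return follicles.n_components / measure


def bin_expression(mean_intensity: float, edges: Sequence[float]) -> str:
    """Map a mean intensity to an ordinal level for qualitative heatmaps.

    Half-open bins over 4 strictly ascending edges: none [0, e1),
    low [e1, e2), medium [e2, e3), high [e3, e4), very_high [e4, ∞).
    """
    edges = [float(e) for e in edges]
    if len(edges) != 4 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"edges must be 4 strictly ascending thresholds, got {edges}")
    idx = int(np.searchsorted(edges, mean_intensity, side="right"))
    return EXPRESSION_LEVELS[idx]


def default_expression_edges(intensities: Sequence[float]) -> list[float]:
    """Quantile (20/40/60/80%) edges over the positive intensities."""
    vals = np.asarray(intensities, float)
    vals = vals[vals > 0]
    if len(vals) == 0:
        return [1.0, 2.0, 3.0, 4.0]
    edges = list(np.quantile(vals, [0.2, 0.4, 0.6, 0.8]))
    for i in range(1, 4):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] * (1 + 1e-9) + 1e-12
    return edges


def expression_heatmap(
    mean_intensities: pd.DataFrame, edges: Mapping[str, Sequence[float]] | None = None
) -> pd.DataFrame:
    """Ordinal (marker × region) heatmap of expression levels.

    ``mean_intensities`` has markers as rows and regions as columns;
    per-marker edges default to intensity quantiles.
    """
    out = pd.DataFrame(index=mean_intensities.index, columns=mean_intensities.columns,
                       dtype=object)
    for marker in mean_intensities.index:
        row = mean_intensities.loc[marker]
        marker_edges = (edges or {}).get(marker) or default_expression_edges(row.to_numpy(float))
        out.loc[marker] = [bin_expression(v, marker_edges) for v in row]
    return out


def plot_expression_heatmap(levels: pd.DataFrame, path=None):
    """Render an ordinal heatmap (grey→dark green→light green→yellow→red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["#bdbdbd", "#1b5e20", "#8bc34a", "#ffeb3b", "#d32f2f"])
    codes = levels.apply(lambda col: col.map(EXPRESSION_LEVELS.index))
    fig, ax = plt.subplots(figsize=(1 + 0.6 * levels.shape[1], 1 + 0.4 * levels.shape[0]))
    ax.imshow(codes.to_numpy(int), cmap=cmap, vmin=0, vmax=4, aspect="auto")
    ax.set_xticks(range(levels.shape[1]), levels.columns, rotation=45, ha="right")
    ax.set_yticks(range(levels.shape[0]), levels.index)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p between paired per-islet values.

    Zero variance in either vector is flagged by returning (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Result of a two-group t-test or multi-group ANOVA + Tukey HSD."""

    metric: str
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    test: str                       # "t-test" or "anova+tukey"
    statistic: float                # t for 2 groups, F for > 2
    p_value: float
    tukey: pd.DataFrame | None = None   # pairwise group1, group2, p_adj
    significant: bool = False

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n": None, "mean": self.means[g], "sd": self.sds[g]}
            for g in self.groups
        ]
        return pd.DataFrame(rows)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]], metric: str = "", alpha: float = 0.05
) -> GroupComparison:
    """Compare group means the way the quantifications are analysed.

    Two groups: two-tailed unpaired Student's t-test (equal variance;
    see :func:`welch_t` for the unequal-variance alternative). More than
    two: one-way ANOVA with Tukey's HSD pairwise p-values. Each group
    needs at least 2 values.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(values_by_group[g], float) for g in groups}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}

    if len(groups) == 2:
        t, p = sps.ttest_ind(arrays[groups[0]], arrays[groups[1]], equal_var=True)
        return GroupComparison(metric, groups, means, sds, "t-test",
                               float(t), float(p), None, bool(p < alpha))

    f, p = sps.f_oneway(*arrays.values())
    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[g] * len(arrays[g]) for g in groups])
    hsd = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    pairs = list(combinations(hsd.groupsunique, 2))
    tukey = pd.DataFrame({
        "group1": [p[0] for p in pairs],
        "group2": [p[1] for p in pairs],
        "p_adj": np.asarray(hsd.pvalues, float),
        "reject": np.asarray(hsd.reject, bool),
    })
    return GroupComparison(metric, groups, means, sds, "anova+tukey",
                           float(f), float(p), tukey, bool(p < alpha))


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unequal-variance (Welch) two-tailed t-test, available behind a flag."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
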