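"""End-to-end quantification run: volume in, tables + run report out.

Thin orchestration over the library modules; every threshold it uses is
echoed into a JSON run report so that group comparisons can be rerun
with identical settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import morphology

from . import interactome as inter
from . import segmentation as seg
from . import vessels
from .config import PipelineConfig
from .grid import QuantTable, RegionMask, VoxelGrid, write_mask, write_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    vessel_components: seg.ComponentSet
    artery_components: seg.ComponentSet | None
    cells: pd.DataFrame
    metrics: vessels.VesselMetrics
    table: QuantTable
    report: dict = field(default_factory=dict)


def default_tissue_mask(grid: VoxelGrid, nuclei_channel: str = "nuclei") -> np.ndarray:
    """Convex hull of the nuclei-channel foreground, as the gland outline.

    Falls back to the whole grid when the nuclei channel is absent or
    empty.
    """
    if not grid.has_channel(nuclei_channel):
        return np.ones(grid.shape, bool)
    nuc = grid.channel(nuclei_channel)
    if np.ptp(nuc) == 0:
        return np.ones(grid.shape, bool)
    from skimage import filters

    fg = nuc > filters.threshold_otsu(nuc)
    if not fg.any():
        return np.ones(grid.shape, bool)
    return morphology.convex_hull_image(fg)


def run_pipeline(
    grid: VoxelGrid,
    config: PipelineConfig,
    regions: RegionMask | None = None,
    tissue_mask: np.ndarray | None = None,
    sample_id: str = "sample",
    group: str = "",
) -> PipelineResult:
    """Quantify one volume: vessels, arteries, diameters, cells, interactome."""
    cfg = config
    report: dict = {"sample_id": sample_id, "config": cfg.to_dict()}
    table = QuantTable()

    if tissue_mask is None:
        tissue_mask = default_tissue_mask(grid, cfg.nuclei_channel)

    # --- vessels ---------------------------------------------------------
    vessel_raw = grid.channel(cfg.vessel_channel)
    vessel_bs = seg.subtract_background(vessel_raw, grid.spacing_um, cfg.background_scale_um)
    vessel_cs = seg.segment_surface(
        vessel_bs, grid.spacing_um, cfg.smooth_sigma_um, cfg.vessel_threshold
    )
    vessel_cs = seg.filter_noise_components(
        vessel_cs, cfg.noise_max_volume_um3, cfg.noise_min_sphericity
    )
    density = vessels.vessel_density(vessel_cs.mask, tissue_mask)
    table.add("vessel_density", density, "fraction", sample_id, group)

    mean_diam = float("nan")
    if vessel_cs.mask.any():
        mean_diam, per_region_d = vessels.estimate_diameters(
            vessel_cs.mask, grid.spacing_um,
            n_regions=cfg.diameter_n_regions,
            region_size_um=cfg.diameter_region_size_um,
            seed=cfg.seed,
        )
        table.add("mean_capillary_diameter", mean_diam, "um", sample_id, group)
        report["capillary_diameters_um"] = per_region_d

    # --- arteries --------------------------------------------------------
    artery_cs = None
    metrics = vessels.VesselMetrics(
        vessel_density=density, mean_capillary_diameter_um=mean_diam
    )
    if grid.has_channel(cfg.artery_channel):
        asma_bs = seg.subtract_background(
            grid.channel(cfg.artery_channel), grid.spacing_um, cfg.background_scale_um
        )
        asma_cs = seg.segment_surface(
            asma_bs, grid.spacing_um, cfg.smooth_sigma_um, cfg.vessel_threshold
        )
        artery_cs = vessels.detect_arteries(
            asma_cs, cfg.artery_min_length_um, cfg.artery_min_radius_um,
            cfg.artery_min_elongation,
        )
        metrics.artery_count = artery_cs.n_components
        metrics.artery_density_per_mm3 = vessels.artery_density(
            artery_cs.n_components, tissue_mask, grid.spacing_um
        )
        table.add("artery_count", metrics.artery_count, "count", sample_id, group)
        table.add("artery_density", metrics.artery_density_per_mm3, "per_mm3",
                  sample_id, group)
        if artery_cs.mask.any():
            metrics.mean_artery_diameter_um, _ = vessels.estimate_diameters(
                artery_cs.mask, grid.spacing_um,
                n_regions=cfg.diameter_n_regions,
                region_size_um=cfg.diameter_region_size_um,
                seed=cfg.seed,
            )
            table.add("mean_artery_diameter", metrics.mean_artery_diameter_um, "um",
                      sample_id, group)

    # --- per-region densities -------------------------------------------
    if regions is not None:
        for name, value in vessels.region_restricted_density(vessel_cs.mask, regions).items():
            metrics.per_region[name] = vessels.VesselMetrics(vessel_density=value)
            table.add("vessel_density", value, "fraction", sample_id, group, region=name)

    # --- cells + interactome --------------------------------------------
    cells = pd.DataFrame()
    if grid.has_channel(cfg.nuclei_channel) and np.ptp(grid.channel(cfg.nuclei_channel)) > 0:
        marker_channels = {
            name: grid.channel(name) for name in grid.channel_names
            if name != cfg.nuclei_channel
        }
        cells = seg.segment_cells(
            grid.channel(cfg.nuclei_channel), grid.spacing_um,
            marker_channels=marker_channels,
        )
        if len(cells) and vessel_cs.mask.any():
            dist_field = inter.distance_to_vessels(vessel_cs.mask, grid.spacing_um)
            cells = inter.annotate_cell_distances(cells, dist_field)
            cells = inter.interactome_membership(cells, cfg.interactome_max_distance_um)
        table.add("cell_count", len(cells), "count", sample_id, group)

    report["n_vessel_components"] = vessel_cs.n_components
    report["vessel_density"] = density
    return PipelineResult(
        vessel_components=vessel_cs, artery_components=artery_cs, cells=cells,
        metrics=metrics, table=table, report=report,
    )


def save_result(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write tables, masks and the JSON run report under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.table, out / "quantifications.csv")
    if len(result.cells):
        result.cells.to_csv(out / "cells.csv", index=False)
    write_mask(result.vessel_components.mask, out / "vessel_mask.tif")
    if result.artery_components is not None:
        write_mask(result.artery_components.mask, out / "artery_mask.tif")
    with open(out / "run_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=float)
    return out
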