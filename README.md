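# gland3d

3D quantification of vasculature and perivascular cell niches in
multiplex fluorescence volumes of endocrine glands (pancreas, adrenal,
thyroid, ovary, testis, pituitary).

Deep confocal / light-sheet imaging of immunolabelled gland sections
produces multi-channel voxel volumes in which blood vessels (Emcn,
Endoglin, CD31, Caveolin-1, VE-Cadherin), arteries (α-SMA), islets
(insulin), nuclei and many cell-type markers can be segmented and
measured. Studies of vascular ageing and angiocrine signalling in these
tissues rely on a small set of standard quantities, which this package
computes as an open, scriptable, fully tested pipeline:

- **vessel density** — vessel volume / tissue volume, optionally
  restricted to regions (islet vs non-islet) or to phenotype subsets
  (e.g. CD31⁺Emcn^hi capillaries);
- **artery counts per mm³** — thick elongated α-SMA⁺ tubes
  distinguished from stromal α-SMA signal by skeleton length, interior
  radius and elongation;
- **capillary / artery diameters** — from *n* = 7 randomly sampled
  sub-regions, as twice the interior Euclidean-distance-transform value
  along the vessel skeleton;
- **cell–vessel interactomes** — per-cell distance to the vascular
  surface from an exact anisotropic Euclidean distance transform; a
  cell is in a vessel subset's interactome when its distance is
  **≤ 18 μm** (inclusive); interaction matrices (vessel subset ×
  cell type) and young-vs-aged differential interactomes
  (gained / lost / stable);
- **cell segmentation and phenotyping** — nuclei-seeded territories,
  per-cell marker means, rule-based phenotypes
  (neg / pos / lo / hi bands, e.g. CD31⁺Emcn^hi vs CD31⁺Emcn^lo);
- **per-islet metrics** — β-cell mass as insulin⁺ (or CXCR4⁺) area
  fraction of the islet, VEGFA coverage, Ki67⁺ β-cell fractions,
  counts per mm³, follicle density, ordinal expression heatmaps;
- **group statistics** — two-tailed Student's *t*-test for two groups,
  one-way ANOVA with Tukey's HSD for more, Pearson correlation;
  results as mean ± s.d. with *P* < 0.05 significance.

Because raw gland volumes are large and hosted interactively, the
package ships a first-class **synthetic phantom generator**
(`gland3d.phantom`) that renders tubular capillary networks at an exact
analytic volume fraction, α-SMA⁺ artery tubes, insulin⁺ islet
spheroids with internal capillary plexi, Gaussian-blob nuclei and cell
populations planted at controlled distances from the vessel surface —
with full ground truth. Every quantification is validated against this
analytic truth.

## Core definitions

With voxel spacing (dz, dy, dx) in μm (default 0.82 × 0.69 × 0.69 μm,
matching confocal acquisition of thick sections):

- vessel density ρ = Σ vessel voxels / Σ tissue voxels (dimensionless);
- artery density = artery count / tissue volume, per mm³ (10⁹ μm³);
- sphericity ψ = π^⅓ (6V)^⅔ / A, with V from voxel counts and A from a
  marching-cubes boundary mesh; small components with ψ ≥ 0.8 and
  V < 500 μm³ are removed as segmentation noise;
- distance field D(x) = 0 inside the vessel mask, else the exact
  anisotropic Euclidean distance (μm) to the nearest vessel voxel;
  interactome membership ⇔ D(cell centroid) ≤ 18 μm.

## Worked example

```python
import numpy as np
from gland3d import (CellPopulationSpec, NetworkSpec, PhantomSpec,
                     PipelineConfig, generate_phantom, run_pipeline)

spec = PhantomSpec(
    shape=(60, 100, 100),                       # (z, y, x) voxels
    vessel_network=NetworkSpec(target_volume_fraction=0.02),
    cell_populations=[
        CellPopulationSpec("macrophage", ("CD68",), 30, distance_band_um=(0, 18)),
    ],
    seed=7,
)
grid, truth = generate_phantom(spec)

cfg = PipelineConfig(vessel_threshold="auto", smooth_sigma_um=0.5)
result = run_pipeline(grid, cfg, tissue_mask=np.ones(grid.shape, bool))

print(f"planted vessel volume fraction: {truth.true_metrics['vessel_volume_fraction']:.4f}")
print(f"measured vessel density:        {result.metrics.vessel_density:.4f}")
print(f"mean capillary diameter:        {result.metrics.mean_capillary_diameter_um:.2f} um")
print(f"cells segmented:                {len(result.cells)}")
members = result.cells["interactome_member"].sum()
print(f"cells within 18 um of vessels:  {members}/{len(result.cells)}")
```

prints

```
planted vessel volume fraction: 0.0200
measured vessel density:        0.0199
mean capillary diameter:        5.70 um
cells segmented:                30
cells within 18 um of vessels:  29/30
```

The planted 2 % vessel fraction is recovered to 0.5 %, all 30 planted
macrophages are found, and the capillary diameter matches the
generator's 2.5–4 μm tube radii. One planted cell sits exactly at the
18 μm band edge; measured against the *segmented* (rather than true)
vessel surface its distance lands marginally above the threshold —
distances are always reported against the mask the pipeline actually
produced.

Command-line equivalents:

```bash
gland3d phantom --spec spec.yaml --out phantom.ome.tif --truth truth/
gland3d run --config cfg.yaml --input phantom.ome.tif --out results/
```

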