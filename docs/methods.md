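# Methods

This note documents the models, conventions and numerical choices
behind `gland3d`, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Coordinate and unit conventions

Volumes are stored as `(channel, z, y, x)` arrays; masks as
`(z, y, x)`. Voxel indices are 0-based and a voxel's physical position
is `index × spacing` (voxel-centre convention). All physical quantities
are micrometre-based (μm, μm², μm³); densities per mm³ use
1 mm³ = 10⁹ μm³. The default spacing is (dz, dy, dx) =
(0.82, 0.69, 0.69) μm — the z-interval and in-plane pixel size of
single-cell-resolution confocal acquisition of thick gland sections.
All smoothing scales and kernels are specified in μm and converted
per-axis by the spacing, so anisotropic stacks are handled uniformly.

When OME metadata and user configuration disagree, configuration wins
and a warning is logged; when neither provides a spacing, the default
above is used.

## Surface segmentation

The vessel-surface reconstruction follows the interactive workflow it
replaces: (1) background subtraction — the channel minus a Gaussian
estimate of the local background at a scale (default 20 μm) well above
the structures of interest, clipped at zero; (2) Gaussian smoothing
(default 1.5 μm); (3) thresholding — either a fixed manual value or
Otsu's method on the smoothed histogram. When groups are compared the
threshold must be fixed and identical across samples; the realized
threshold is recorded in the JSON run report. (4) 26-connected
component labelling with shape statistics; (5) noise removal.

Per-component statistics: volume V = voxel count × voxel volume;
surface area A from a marching-cubes mesh of the padded component at
iso-level 0.5 (spacing-aware); sphericity ψ = π^⅓ (6V)^⅔ / A;
elongation as the square root of the ratio of extreme inertia-tensor
eigenvalues of the voxel point cloud. ψ → 1 with resolution for balls
(rasterized balls of radius ≥ 8 voxels score ψ ≥ 0.9 — marching-cubes
meshes of digital spheres carry a few percent of excess area) and
decreases strictly with elongation at fixed volume.

The noise filter removes exactly the components with
V < `max_volume_um3` (default 500 μm³) **and** ψ ≥ `min_sphericity`
(default 0.8): small bright blobs are segmentation noise, whereas
genuine vessels are large or elongated. Both criteria are applied
because a size cut alone would delete capillary fragments and a shape
cut alone would delete islet spheroid-like objects; both defaults are
configuration-exposed and logged.

## Cell segmentation and phenotyping

Nuclei are detected as local maxima of the nuclei channel smoothed at
the nucleus scale (default σ = 2 μm) above an Otsu or manual
threshold, with a suppression radius of half the expected inter-nucleus
separation. Each nucleus seeds a territory: a watershed on the
(smoothed) membrane channel when one exists, otherwise the
nearest-seed region, in both cases bounded by `max_cell_radius_um`
(default 8 μm). Per-cell marker intensities are territory means. Note
that territory means dilute compact marker signal; when phenotyping on
small cytoplasmic markers, either reduce `max_cell_radius_um` toward
the cell-body radius or set thresholds on the per-cell intensity
distribution rather than on raw channel levels.

Phenotype rules are ordered marker-band conjunctions over bands
neg (< t_pos), pos (≥ t_pos), lo ([t_pos, t_hi)), hi (≥ t_hi); all
band comparisons are inclusive at their lower edge. The first matching
rule labels the cell; unmatched cells are "unclassified". Default
thresholds per marker: t_pos by Otsu over the per-cell intensities,
t_hi as the median of the above-t_pos intensities — both overridable,
and overriding is recommended for group contrasts.

## Vascular metrics

**Vessel density** is the voxel-measure ratio (vessel ∩ tissue)/tissue.
The tissue mask defaults to the convex hull of the nuclei-channel
foreground when no ROI is supplied (glands are outlined, not
algorithmically defined, in the workflow this replaces). The ratio is
invariant to uniform spacing rescaling and monotone under vessel
dilation.

**Arteries** are α-SMA⁺ components that pass three tubularity
thresholds: skeleton length ≥ 50 μm, mean interior radius ≥ 3 μm and
elongation = length/(2 × mean radius) ≥ 2. The original criterion is
qualitative ("tubular shape"), so these defaults are explicit,
configuration-exposed choices; counts on phantoms are exact when tubes
clear the thresholds with ≥ 20 % margin. Skeletons come from 3D
thinning; skeleton length is the sum of 26-adjacent voxel-pair
distances in physical units. scikit-image 0.26's Lee thinning can
erode certain highly symmetric tubes completely; when that happens the
implementation falls back to the local-maximum ridge of the interior
distance transform for the radius and the principal-axis extent for
the length. Note that thinning retracts skeleton ends by roughly one
radius, so a tube of length L yields a skeleton of ≈ L − 2r; length
thresholds should be set accordingly.

**Diameters** replace manual caliper measurements with a deterministic
estimator: `n_regions` (default 7) cubic sub-blocks of side
`region_size_um` (default 50 μm) are sampled at seeded-random
positions, resampled when vessel-free; within each block the mask is
skeletonized and the local radius read from the interior EDT at
skeleton voxels; the block diameter is twice the mean radius and the
estimate is the mean over blocks. On axis-aligned and 45°-oblique
cylinders the estimator is accurate within one in-plane voxel
(±1.38 μm at default spacing).

## Interactome

The distance field is the exact anisotropic Euclidean distance
transform of the vessel-mask complement (`scipy.ndimage`,
`sampling=spacing`): 0 on vessel voxels, the distance in μm to the
nearest vessel voxel elsewhere; it matches a brute-force all-pairs
search to machine precision. Cell distances are trilinear
interpolations of this field at the centroid. Distance is measured
centroid-to-nearest-vessel-voxel — the boundary-vs-centroid choice is
not specified in the workflow this reimplements; the centroid is
deterministic and is recorded in output metadata.

Membership uses the inclusive rule distance ≤ 18 μm (configurable).
Interaction matrices tabulate (n_within, n_total, fraction) per
(vessel subset × cell type); each subset gets its own distance field,
so a cell may belong to several subsets' interactomes. An interaction
is "present" when its fraction reaches `presence_min_fraction`
(default 0.1 — the qualitative presence criterion of published
interactome maps is not quantified, so the cut is explicit and
configurable). Differential interactomes classify each pair as gained
(present in aged only), lost (present in young only) or stable.

## Per-islet quantifications and statistics

β-cell mass is implemented as the insulin⁺ (or CXCR4⁺) area fraction
of the islet region (×100), the islet being the referent denominator;
the same construction gives VEGFA coverage. Proliferation fractions
are segmented-cell count ratios (Ki67⁺ β / all β), undefined (NaN,
flagged) when the denominator is empty. Counts per volume divide by
tissue volume in mm³; follicle density supports per-mm² (single-slice)
and per-mm³ modes. Ordinal expression heatmaps bin mean intensities
into none/low/medium/high/very_high by half-open bins over four
strictly ascending edges; default edges are the 20/40/60/80 %
quantiles of the positive intensities per marker (published heatmaps
do not quantify their bins). Counts "per islet (f.u.)" in the source
workflow use an undefined fluorescence normalization; this package
reports raw per-islet counts with islet volume alongside instead.

Group comparison: exactly two groups → two-tailed unpaired Student's
t-test with pooled variance (the unequal-variance Welch test is
available behind a flag); more than two → one-way ANOVA with Tukey HSD
pairwise p-values (statsmodels); each group needs n ≥ 2. For two
groups, ANOVA satisfies F = t² and identical p. Identical groups give
t = 0, p = 1. The test suite verifies all p-values against hand-coded
closed forms (pooled-variance t, sums-of-squares F, studentized-range
Tukey) to 1e-10. Pearson correlation requires n ≥ 3 and flags
zero-variance input as undefined.

## Synthetic phantoms

The generator renders what the analysis assumes, with analytic ground
truth:

- **Tubes** are finite cylinders rasterized by an exact point-to-axis
  test per voxel centre (radial distance ≤ r within the axial extent),
  so the analytic volume is exactly πr²L, with no end caps. Random
  networks place non-overlapping segments (lengths 30–70 μm, radii
  2.5–4 μm by default) fully inside the domain and trim the final
  segment so the cumulative analytic volume hits the target fraction
  exactly. Rasterized volumes track the analytic value to a few
  percent for radii ≥ 3 voxels in generic pose; axis-aligned tubes at
  resonant lattice phases can deviate more — an inherent property of
  digital sampling, not of the estimators.
- **Islets** are insulin⁺ spheres with an internal plexus of thinner
  tubes at a target fraction of the islet volume (default 5 %).
- **Cells** are placed on voxel centres whose EDT distance to the
  vessel mask lies in a requested band (or uniformly in tissue), with
  a global minimum separation (default 9 μm ≥ 4σ of the nucleus blob)
  so nuclei remain individually detectable; the planted distance is
  exact under the same centroid-to-voxel definition the interactome
  uses. Each cell carries a Gaussian nucleus (σ = 2 μm) and a 3 μm
  marker sphere; proliferating subsets are seeded Bernoulli draws, and
  the realized fraction is recorded as truth.
- **Optics**: isotropic Gaussian PSF blur and additive Gaussian noise
  clipped at zero. Depth-dependent PSF, spectral bleed-through,
  Poisson photon statistics, vessel curvature/branching and tissue
  deformation are deliberately not modelled — so passing recovery
  tests demonstrates correctness of the measurement chain on its own
  assumptions, not robustness to every real-microscopy artefact.

Identical (spec, seed) pairs yield bit-identical phantoms; all
stochastic placement flows from one documented generator.

## Problem sizes and determinism

The validation suite uses phantoms of roughly 0.6–2.4 million voxels
(e.g. 60×100×100 for volume-fraction recovery, 60×200×200 for artery
counting) — large enough for radii ≥ 3 voxels and tube lengths that
clear the artery thresholds with margin, while keeping the whole suite
in the tens of seconds. The acceptance script derives every sub-seed
from its single `--seed` argument; distance-oracle checks run on
16–24³ volumes where the all-pairs search is feasible.

## Known limitations

- Thresholding after background subtraction biases thin-tube volumes
  when the threshold is far from the half-amplitude of the local
  foreground; fixed manual thresholds shared across samples (as the
  reproduced workflow prescribes) make group *contrasts* robust even
  when absolute volumes carry this bias.
- The artery criterion is a numeric proxy for a qualitative judgement;
  absolute counts on real data depend on its thresholds.
- Cell territories are geometric (bounded nearest-seed/watershed), not
  membrane-accurate; marker means on territories dilute compact
  signal.
- The 18 μm rule is applied to centroid distance; a membrane-distance
  variant would shift memberships by up to one cell radius.
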