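"""Surface/cell segmentation, shape statistics and phenotyping."""

import numpy as np
import pandas as pd
import pytest

from gland3d import (ComponentSet, PhenotypeRule, classify_phenotypes,
                     filter_noise_components, segment_cells, segment_surface,
                     subtract_background)

from conftest import SPACING, make_ball_mask, make_cylinder_mask


class TestBackgroundSubtraction:
    def test_flat_field_maps_to_zero(self):
        flat = np.full((16, 24, 24), 37.0)
        out = subtract_background(flat, SPACING, 20.0)
        assert np.abs(out).max() < 1.0

    def test_tube_contrast_preserved_ramp_suppressed(self):
        shape = (20, 40, 120)
        sp = (1.0, 1.0, 1.0)
        ramp = np.broadcast_to(np.linspace(0, 100, shape[2]), shape).copy()
        tube = make_cylinder_mask(shape, sp, (10, 20, 20), (10, 20, 100), 3.0)
        img = ramp + 200.0 * tube
        out = subtract_background(img, sp, 20.0)
        # tube contrast within 10 % of the planted 200
        inside = out[tube].mean()
        assert inside == pytest.approx(200.0, rel=0.10)
        # ramp suppressed by > 90 % away from the tube
        bg = out[~tube & (np.arange(shape[0])[:, None, None] < 5)]
        assert bg.mean() < 0.1 * ramp.mean()

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((4, 4, 4)), SPACING, 0.0)


class TestSegmentSurface:
    def test_noiseless_cylinder_volume_within_5pct(self, cylinder_phantom):
        grid, _ = cylinder_phantom
        cs = segment_surface(grid.channel("Emcn"), grid.spacing_um,
                             smooth_sigma_um=0.0, threshold=105.0)
        assert cs.n_components == 1
        analytic = np.pi * 5.0**2 * 31.0
        assert cs.components.loc[0, "volume_um3"] == pytest.approx(analytic, rel=0.05)

    def test_all_zero_channel_gives_empty_set(self):
        cs = segment_surface(np.zeros((8, 8, 8)), SPACING, 0.0, threshold=0.5)
        assert cs.n_components == 0
        assert not cs.mask.any()

    def test_connectivity_merges_bridged_spheres(self):
        sp = (1.0, 1.0, 1.0)
        img = np.zeros((20, 20, 50))
        img[make_ball_mask(img.shape, sp, (10, 10, 12), 5)] = 100
        img[make_ball_mask(img.shape, sp, (10, 10, 38), 5)] = 100
        cs = segment_surface(img, sp, 0.0, threshold=50)
        assert cs.n_components == 2
        img[9:12, 9:12, 12:39] = 100  # bridge
        cs2 = segment_surface(img, sp, 0.0, threshold=50)
        assert cs2.n_components == 1

    def test_nan_rejected(self):
        bad = np.zeros((4, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            segment_surface(bad, SPACING, 0.0, threshold=0.5)

    def test_otsu_auto_threshold_recovers_bimodal_mask(self, cylinder_phantom):
        grid, truth = cylinder_phantom
        cs = segment_surface(grid.channel("Emcn"), grid.spacing_um, 0.0, "auto")
        jaccard = (cs.mask & truth.vessel_mask).sum() / (cs.mask | truth.vessel_mask).sum()
        assert jaccard >= 0.95


class TestShapeStatistics:
    def test_sphericity_of_rasterized_ball_approaches_one(self):
        sp = (1.0, 1.0, 1.0)
        for radius in (8, 12):
            mask = make_ball_mask((30, 30, 30), sp, (15, 15, 15), radius)
            cs = ComponentSet.from_mask(mask, sp)
            assert cs.components.loc[0, "sphericity"] >= 0.9

    def test_sphericity_decreases_with_elongation_at_fixed_volume(self):
        # cylinders of equal volume, increasing aspect ratio
        sp = (1.0, 1.0, 1.0)
        volume = np.pi * 6.0**2 * 24.0
        psis = []
        for r in (6.0, 4.0, 2.5):
            length = volume / (np.pi * r**2)
            mask = make_cylinder_mask(
                (40, 40, int(length) + 20), sp, (20, 20, 5), (20, 20, 5 + length), r
            )
            cs = ComponentSet.from_mask(mask, sp)
            psis.append(cs.components.loc[0, "sphericity"])
        assert psis[0] > psis[1] > psis[2]

    def test_component_voxel_counts_partition_the_mask(self):
        sp = SPACING
        mask = make_ball_mask((24, 24, 48), sp, (9, 8, 8), 3.0)
        mask |= make_ball_mask((24, 24, 48), sp, (9, 8, 25), 4.0)
        cs = ComponentSet.from_mask(mask, sp)
        assert cs.components["voxel_count"].sum() == mask.sum()
        assert list(cs.components["label"]) == [1, 2]


class TestNoiseFilter:
    def _mixed_set(self):
        sp = (1.0, 1.0, 1.0)
        mask = make_cylinder_mask((30, 30, 80), sp, (15, 15, 5), (15, 15, 75), 3.0)
        mask |= make_ball_mask((30, 30, 80), sp, (8, 8, 40), 3.0)  # tiny ball ~113 μm³
        return ComponentSet.from_mask(mask, sp)

    def test_removes_small_high_sphericity_keeps_tube(self):
        cs = self._mixed_set()
        assert cs.n_components == 2
        out = filter_noise_components(cs, max_volume_um3=500.0, min_sphericity=0.8)
        assert out.n_components == 1
        assert out.components.loc[0, "sphericity"] < 0.8  # the tube survived

    def test_large_ball_above_volume_cut_is_retained(self):
        sp = (1.0, 1.0, 1.0)
        mask = make_ball_mask((30, 30, 30), sp, (15, 15, 15), 8.0)  # ~2145 μm³
        out = filter_noise_components(ComponentSet.from_mask(mask, sp), 500.0, 0.8)
        assert out.n_components == 1

    def test_empty_set_passes_through(self):
        cs = ComponentSet.from_mask(np.zeros((6, 6, 6), bool), SPACING)
        out = filter_noise_components(cs, 500.0, 0.8)
        assert out.n_components == 0

    def test_bad_thresholds_rejected(self):
        cs = self._mixed_set()
        with pytest.raises(ValueError):
            filter_noise_components(cs, -1.0, 0.8)
        with pytest.raises(ValueError):
            filter_noise_components(cs, 500.0, 1.5)


class TestSegmentCells:
    def test_two_separated_nuclei_found_within_one_voxel(self):
        from gland3d.phantom import _paint_nucleus

        sp = np.asarray(SPACING)
        nuc = np.full((30, 40, 40), 10.0)
        truth = np.array([[10.0, 10.0, 10.0], [14.0, 18.0, 20.0]])
        for c in truth:
            _paint_nucleus(nuc, c, 2.0, 200.0, sp)
        cells = segment_cells(nuc, sp)
        assert len(cells) == 2
        got = cells[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
        got = got[np.argsort(got[:, 0])]
        assert np.abs(got - truth).max() <= sp.max()

    def test_planted_nucleus_count_recovered_exactly(self):
        from gland3d import CellPopulationSpec, PhantomSpec, Tube, generate_phantom

        spec = PhantomSpec(
            shape=(50, 80, 80),
            vessels=[Tube((20.5, 27.6, 5), (20.5, 27.6, 50), 3.0)],
            cell_populations=[
                CellPopulationSpec("macrophage", ("CD68",), 40, distance_band_um=(0, 25))
            ],
            seed=13,
        )
        grid, truth = generate_phantom(spec)
        cells = segment_cells(grid.channel("nuclei"), grid.spacing_um,
                              marker_channels={"CD68": grid.channel("CD68")})
        assert len(cells) == len(truth.cells) == 40

    def test_empty_nuclei_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            cells = segment_cells(np.zeros((10, 10, 10)), SPACING)
        assert len(cells) == 0


class TestPhenotyping:
    def _cells(self):
        return pd.DataFrame({
            "cell_id": [1, 2, 3, 4],
            "I_CD31": [50.0, 50.0, 0.0, 10.0],
            "I_Emcn": [90.0, 30.0, 0.0, 20.0],
        })

    THRESH = {"CD31": (20.0, 40.0), "Emcn": (25.0, 60.0)}

    def test_emcn_hi_vs_lo_split(self):
        rules = [
            PhenotypeRule("CD31+Emcn-hi", {"CD31": "pos", "Emcn": "hi"}),
            PhenotypeRule("CD31+Emcn-lo", {"CD31": "pos", "Emcn": "lo"}),
        ]
        out = classify_phenotypes(self._cells(), rules, self.THRESH)
        assert list(out["phenotype"]) == [
            "CD31+Emcn-hi", "CD31+Emcn-lo", "unclassified", "unclassified"
        ]

    def test_zero_intensity_cell_unclassified(self):
        out = classify_phenotypes(self._cells(), [PhenotypeRule("ec", {"CD31": "pos"})],
                                  self.THRESH)
        assert out.loc[2, "phenotype"] == "unclassified"

    def test_value_exactly_at_t_pos_is_positive(self):
        cells = pd.DataFrame({"cell_id": [1], "I_CD31": [20.0]})
        out = classify_phenotypes(cells, [PhenotypeRule("ec", {"CD31": "pos"})],
                                  {"CD31": (20.0, 40.0)})
        assert out.loc[0, "phenotype"] == "ec"

    def test_priority_order_first_match_wins(self):
        cells = pd.DataFrame({"cell_id": [1], "I_CD31": [50.0]})
        rules = [PhenotypeRule("first", {"CD31": "pos"}),
                 PhenotypeRule("second", {"CD31": "hi"})]
        out = classify_phenotypes(cells, rules, {"CD31": (20.0, 40.0)})
        assert out.loc[0, "phenotype"] == "first"

    def test_unknown_marker_raises(self):
        with pytest.raises(KeyError, match="Vimentin"):
            classify_phenotypes(self._cells(),
                                [PhenotypeRule("x", {"Vimentin": "neg"})], self.THRESH)

    def test_band_semantics(self):
        rule = PhenotypeRule("x", {"m": "lo"})
        th = {"m": (10.0, 20.0)}
        assert not rule.matches({"m": 5.0}, th)
        assert rule.matches({"m": 10.0}, th)
        assert rule.matches({"m": 19.999}, th)
        assert not rule.matches({"m": 20.0}, th)
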