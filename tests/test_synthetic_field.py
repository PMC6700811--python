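"""Simulator contracts: determinism, design balance, truth conservation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import idcpheno as ip
from idcpheno.io import pixels_in_polygon
from idcpheno.synthetic_field import latent_to_class


def _cfg(**kw):
    base = dict(n_trials=2, entries_per_trial=6, seed=5)
    base.update(kw)
    return ip.FieldSimConfig(**base)


class TestConfigValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="residual_sd"):
            _cfg(residual_sd=-0.1)

    def test_non_decreasing_coverage_rejected(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            _cfg(class_coverage_means=(0.2, 0.25, 0.1, 0.05, 0.01))

    def test_color_mix_must_sum_to_one(self):
        bad = ((0.5, 0.4, 0.2),) + ip.FieldSimConfig().class_color_mix[1:]
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(class_color_mix=bad)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="n_blocks"):
            _cfg(n_blocks=1)

    def test_rgb_mean_outside_range_rejected(self):
        with pytest.raises(ValueError, match="0,255"):
            _cfg(soil_rgb_mean=(300.0, 100.0, 50.0))

    def test_config_file_round_trip(self, tmp_path):
        cfg = _cfg(seed=99)
        cfg.to_file(tmp_path / "sim.cfg")
        assert ip.FieldSimConfig.from_file(tmp_path / "sim.cfg") == cfg


class TestSimulateScores:
    def test_degenerate_noise_gives_grand_mean_class(self):
        cfg = _cfg(entry_effect_sd=0.0, block_effect_sd=0.0, residual_sd=0.0,
                   rater_sd=0.0)
        sim = ip.simulate_scores(cfg)
        expected = int(latent_to_class(cfg.grand_mean))
        assert (sim.plots["true_score"] == expected).all()
        assert (sim.plots["visual_score"] == expected).all()

    def test_same_seed_identical_tables(self):
        s1, s2 = ip.simulate_scores(_cfg()), ip.simulate_scores(_cfg())
        pd.testing.assert_frame_equal(s1.plots, s2.plots)

    def test_latent_recomputable_from_drawn_effects(self):
        # residual_sd = 0: latent must equal grand mean + entry + block
        # effect exactly, recomputed from the reported effect tables
        cfg = _cfg(residual_sd=0.0)
        sim = ip.simulate_scores(cfg)
        ee = sim.entry_effects.set_index(["trial_id", "entry_id"])["effect"]
        be = sim.block_effects.set_index(["trial_id", "block_id"])["effect"]
        for _, row in sim.plots.iterrows():
            expected = (sim.grand_mean
                        + ee[(row["trial_id"], row["entry_id"])]
                        + be[(row["trial_id"], row["block_id"])])
            assert row["latent"] == pytest.approx(expected, abs=1e-12)

    def test_entry_effect_shared_across_blocks(self):
        # with residual off, the within-entry latent difference between the
        # two blocks equals the block-effect difference for every entry
        cfg = _cfg(residual_sd=0.0)
        sim = ip.simulate_scores(cfg)
        be = sim.block_effects.set_index(["trial_id", "block_id"])["effect"]
        wide = sim.plots.pivot_table(index=["trial_id", "entry_id"],
                                     columns="block_id", values="latent")
        for (trial, _entry), row in wide.iterrows():
            delta = be[(trial, 2)] - be[(trial, 1)]
            assert row[2] - row[1] == pytest.approx(delta, abs=1e-12)

    def test_design_balance(self):
        sim = ip.simulate_scores(_cfg(n_blocks=3))
        counts = sim.plots.groupby(["trial_id", "block_id", "entry_id"]).size()
        assert (counts == 1).all()


class TestRenderField:
    def test_determinism_bit_identical(self, small_config):
        a = ip.simulate_field(small_config)
        b = ip.simulate_field(small_config)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[2].truth_raster, b[2].truth_raster)
        assert [g.wkt for g in a[1].geometries] == [g.wkt for g in b[1].geometries]
        pd.testing.assert_frame_equal(a[2].plots, b[2].plots)

    def test_truth_raster_shape_matches_raster(self, small_field):
        raster, _, truth, _ = small_field
        assert truth.truth_raster.shape == raster.shape

    def test_every_polygon_has_truth_record(self, small_field):
        _, polys, truth, _ = small_field
        assert set(polys.plot_ids()) == set(truth.plots["plot_id"])

    def test_conservation_green_yellow_brown_vs_canopy(self, small_field):
        raster, polys, truth, _ = small_field
        tr = truth.truth_raster
        recs = truth.plots.set_index("plot_id")
        for rec, geom in zip(polys.records, polys.geometries):
            rr, cc = pixels_in_polygon(geom, raster.transform, raster.shape)
            labels = tr[rr, cc]
            n_canopy = int((labels > 0).sum())
            assert n_canopy == recs.loc[rec["plot_id"], "n_canopy"]

    def test_realized_coverage_within_binomial_error(self):
        # a high-severity plot with >= 2000 bbox pixels: realized canopy
        # fraction within 3 binomial standard errors of the class mean
        cfg = _cfg(entry_effect_sd=0.0, block_effect_sd=0.0, residual_sd=0.0,
                   grand_mean=5.0, plot_px=(56, 40))
        _, _, truth, _ = ip.simulate_field(cfg)
        p = cfg.class_coverage_means[4]
        n = 56 * 40
        se = np.sqrt(p * (1 - p) / n)
        frac = truth.plots["realized_coverage"]
        assert ((frac - p).abs() <= 3 * se + 1e-12).all()

    def test_zero_coverage_renders_soil_only(self):
        cfg = _cfg(entry_effect_sd=0.0, block_effect_sd=0.0, residual_sd=0.0,
                   grand_mean=5.0,
                   class_coverage_means=(0.4, 0.3, 0.2, 0.1, 0.0))
        _, _, truth, _ = ip.simulate_field(cfg)
        assert truth.truth_raster.max() == 0

    def test_truth_color_mix_matches_configuration(self):
        # green share of canopy pixels across class-1 plots ~ configured mix
        cfg = _cfg(entry_effect_sd=0.0, block_effect_sd=0.0, residual_sd=0.0,
                   grand_mean=1.0, n_trials=3, entries_per_trial=8)
        _, polys, truth, _ = ip.simulate_field(cfg)
        tr = truth.truth_raster
        n_green = int((tr == 1).sum())
        n_canopy = int((tr > 0).sum())
        p = cfg.class_color_mix[0][0]
        se = np.sqrt(p * (1 - p) / n_canopy)
        assert n_green / n_canopy == pytest.approx(p, abs=4 * se)

    def test_polygons_georeferenced_with_raster(self, small_field):
        raster, polys, _, _ = small_field
        t = raster.transform
        xmin = t.origin_x
        xmax = t.origin_x + raster.shape[1] * t.pixel_width
        ymax = t.origin_y
        ymin = t.origin_y - raster.shape[0] * t.pixel_height
        for geom in polys.geometries:
            gx0, gy0, gx1, gy1 = geom.bounds
            assert xmin <= gx0 < gx1 <= xmax
            assert ymin <= gy0 < gy1 <= ymax
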