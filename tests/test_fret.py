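"""Bleed-through correction, FRET-index recovery, and linescan profiles."""

import numpy as np
import pytest

from junctionmech import fret
from junctionmech import synthetic as syn
from junctionmech.stats import kruskal_dunn


def constant_imageset(donor, acceptor, fret_value, shape=(16, 16)):
    return fret.FretImageSet(
        donor=np.full(shape, float(donor)),
        acceptor=np.full(shape, float(acceptor)),
        fret=np.full(shape, float(fret_value)),
    )


FULL_MASK = np.ones((16, 16), dtype=int)


class TestSubtractBackground:
    def test_constant_subtraction(self):
        images = fret.subtract_background(constant_imageset(250, 250, 250),
                                          "constant", 100.0)
        assert np.all(images.donor == 150.0)
        assert np.all(images.fret == 150.0)

    def test_oversubtraction_clamps_to_zero(self):
        images = fret.subtract_background(constant_imageset(50, 50, 50),
                                          "constant", 100.0)
        assert np.all(images.donor == 0.0)

    def test_percentile_recovers_generator_background(self):
        truth = syn.FretTruth(transfer_fractions=(0.3, 0.1), background_level=100.0)
        images, _ = syn.gen_fret_imageset(truth)
        subtracted = fret.subtract_background(images, "percentile", 5.0)
        # most pixels are pure background, so the 5th percentile estimate is
        # within 2 counts of the true level and background pixels land at ~0
        estimated = float(np.percentile(images.donor, 5.0))
        assert estimated == pytest.approx(100.0, abs=2.0)
        assert np.all(subtracted.donor[images.donor == 100.0] < 2.0)

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            fret.subtract_background(constant_imageset(1, 1, 1), "percentile", 0.0)


class TestEstimateSbt:
    def test_noise_free_exact(self):
        truth = syn.FretTruth(transfer_fractions=(0.2, 0.4), sbt_donor_true=0.3,
                              sbt_acceptor_true=0.0, background_level=0.0)
        d_img, d_mask = syn.gen_fret_imageset(syn.donor_only_truth(truth))
        a_img, a_mask = syn.gen_fret_imageset(syn.acceptor_only_truth(truth))
        sbt = fret.estimate_sbt(d_img, d_mask, a_img, a_mask)
        assert sbt.sbt_donor == pytest.approx(0.3, abs=1e-9)
        assert sbt.sbt_acceptor == pytest.approx(0.0, abs=1e-9)
        assert sbt.n_rois_used == 4

    def test_poisson_noise_within_five_percent(self):
        truth = syn.FretTruth(
            transfer_fractions=tuple([0.0] * 10), sbt_donor_true=0.25,
            sbt_acceptor_true=0.15, background_level=0.0, noise_model="poisson",
            seed=11,
        )
        geometry = syn.JunctionGeometry(
            shape=(128, 64),
            segments=tuple(((12 * i + 6, 8), (12 * i + 6, 56), 5) for i in range(10)),
        )
        d_img, d_mask = syn.gen_fret_imageset(syn.donor_only_truth(truth), geometry)
        a_img, a_mask = syn.gen_fret_imageset(syn.acceptor_only_truth(truth), geometry)
        sbt = fret.estimate_sbt(d_img, d_mask, a_img, a_mask)
        assert sbt.sbt_donor == pytest.approx(0.25, rel=0.05)
        assert sbt.sbt_acceptor == pytest.approx(0.15, rel=0.05)

    def test_zero_denominator_names_roi(self):
        bad = constant_imageset(0, 10, 10)
        with pytest.raises(fret.DegenerateRoiError, match="ROI 1"):
            fret.estimate_sbt(bad, FULL_MASK, constant_imageset(0, 10, 10), FULL_MASK)


class TestCorrectedFretAndIndex:
    def test_hand_arithmetic(self):
        images = constant_imageset(donor=200, acceptor=150, fret_value=100)
        sbt = fret.SbtCoefficients(sbt_donor=0.3, sbt_acceptor=0.1)
        cfret = fret.corrected_fret(images, sbt, FULL_MASK)
        assert cfret == pytest.approx(25.0, abs=1e-12)
        assert fret.fret_index(cfret, images, FULL_MASK) == pytest.approx(
            25.0 / 150.0, abs=1e-9)

    def test_zero_sbt_returns_fret_mean(self):
        images = constant_imageset(200, 150, 100)
        sbt = fret.SbtCoefficients(0.0, 0.0)
        assert fret.corrected_fret(images, sbt, FULL_MASK) == pytest.approx(100.0)

    def test_donor_only_control_self_consistency(self):
        truth = syn.FretTruth(transfer_fractions=(0.0,), sbt_donor_true=0.35,
                              sbt_acceptor_true=0.12, background_level=0.0)
        geometry = syn.JunctionGeometry(segments=(((16, 8), (16, 56), 5),))
        d_img, d_mask = syn.gen_fret_imageset(syn.donor_only_truth(truth), geometry)
        a_img, a_mask = syn.gen_fret_imageset(syn.acceptor_only_truth(truth), geometry)
        sbt = fret.estimate_sbt(d_img, d_mask, a_img, a_mask)
        cfret = fret.corrected_fret(d_img, sbt, d_mask == 1)
        assert abs(cfret) < 1e-9

    def test_empty_roi_raises(self):
        images = constant_imageset(1, 1, 1)
        with pytest.raises(fret.DegenerateRoiError):
            fret.corrected_fret(images, fret.SbtCoefficients(0, 0),
                                np.zeros((16, 16), dtype=bool))


class TestQuantifyJunctions:
    def _experiment(self, transfers, seed=0, noise="none"):
        truth = syn.FretTruth(transfer_fractions=transfers, noise_model=noise,
                              seed=seed)
        geometry = syn.JunctionGeometry(
            shape=(32 * len(transfers), 64),
            segments=tuple(((32 * i + 16, 8), (32 * i + 16, 56), 5)
                           for i in range(len(transfers))),
        )
        images, mask = syn.gen_fret_imageset(truth, geometry)
        d_img, d_mask = syn.gen_fret_imageset(syn.donor_only_truth(truth), geometry)
        a_img, a_mask = syn.gen_fret_imageset(syn.acceptor_only_truth(truth), geometry)
        return truth, (d_img, d_mask, a_img, a_mask), (images, mask)

    def test_noise_free_matches_closed_form(self):
        truth, controls, sensor = self._experiment((0.1, 0.25, 0.5))
        table = fret.quantify_junctions(*controls, {"sensor": [sensor]},
                                        background=truth.background_level)
        expected = [e * truth.donor_expression / truth.acceptor_expression
                    for e in truth.transfer_fractions]
        np.testing.assert_allclose(table["fret_index"], expected, atol=1e-6)

    def test_index_monotone_in_transfer(self):
        truth, controls, sensor = self._experiment((0.2, 0.4))
        table = fret.quantify_junctions(*controls, {"s": [sensor]},
                                        background=truth.background_level)
        idx = table.sort_values("roi_id")["fret_index"].to_numpy()
        assert idx[0] < idx[1]

    def test_global_rescaling_invariance(self):
        truth, controls, sensor = self._experiment((0.3,))
        d_img, d_mask, a_img, a_mask = controls
        images, mask = sensor

        def scale(s, factor):
            return fret.FretImageSet(s.donor * factor, s.acceptor * factor,
                                     s.fret * factor)

        base = fret.quantify_junctions(d_img, d_mask, a_img, a_mask,
                                       {"s": [(images, mask)]}, background=100.0)
        scaled = fret.quantify_junctions(
            scale(d_img, 3.0), d_mask, scale(a_img, 3.0), a_mask,
            {"s": [(scale(images, 3.0), mask)]}, background=300.0)
        assert scaled["fret_index"].iloc[0] == pytest.approx(
            base["fret_index"].iloc[0], rel=1e-9)

    def test_null_groups_rarely_significant_and_power(self):
        # two groups with identical truth: Kruskal-Wallis should be quiet;
        # a genuinely higher transfer fraction should raise the median index
        null_hits = 0
        power_hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            _, controls, sensor_a = self._experiment(
                (0.3, 0.3, 0.3), seed=3 * seed, noise="poisson")
            _, _, sensor_b = self._experiment(
                (0.3, 0.3, 0.3), seed=3 * seed + 1, noise="poisson")
            _, _, sensor_c = self._experiment(
                (0.45, 0.45, 0.45), seed=3 * seed + 2, noise="poisson")
            table = fret.quantify_junctions(
                *controls,
                {"a": [sensor_a], "b": [sensor_b], "c": [sensor_c]},
                background=100.0)
            by_group = {g: sub["fret_index"].to_numpy()
                        for g, sub in table.groupby("group")}
            if kruskal_dunn({"a": by_group["a"], "b": by_group["b"]}).p_omnibus > 0.05:
                null_hits += 1
            if np.median(by_group["c"]) > np.median(by_group["a"]):
                power_hits += 1
        assert null_hits >= 0.9 * n_seeds
        assert power_hits == n_seeds


class TestLinescan:
    def test_gaussian_band_peaks_at_midline(self):
        rows = np.arange(64)
        image = np.tile(np.exp(-0.5 * ((rows - 32.0) / 3.0) ** 2)[:, None], (1, 64))
        profile = fret.linescan(image, (8, 30), (56, 30), width=3)
        peak = profile.loc[profile["intensity"].idxmax(), "distance_um"]
        assert abs(peak) <= 1.0

    def test_flat_image_constant_profile(self):
        profile = fret.linescan(np.full((32, 32), 7.0), (4, 16), (28, 16), width=5)
        np.testing.assert_allclose(profile["intensity"], 7.0, atol=1e-9)

    def test_width_one_equals_pixel_sampling_on_axis_line(self):
        rng = np.random.default_rng(2)
        image = rng.uniform(0, 100, size=(20, 20))
        profile = fret.linescan(image, (5, 3), (5, 17), width=1)
        np.testing.assert_allclose(profile["intensity"],
                                   image[5, 3:18], atol=1e-9)

    def test_distances_centered_on_midpoint(self):
        profile = fret.linescan(np.zeros((32, 32)), (0, 16), (30, 16), width=1,
                                pixel_size_um=0.5)
        d = profile["distance_um"].to_numpy()
        assert d[0] == pytest.approx(-d[-1])

    def test_segment_outside_bounds_raises(self):
        with pytest.raises(ValueError, match="outside"):
            fret.linescan(np.zeros((16, 16)), (2, 2), (20, 2), width=1)
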