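"""Morphometrics: segmentation, shape, enrichment, protrusions, foci."""
import numpy as np
import pytest

from cardionuc import morpho
from cardionuc.errors import SegmentationError
from cardionuc.images import Focus, generate_nucleus_image
from cardionuc.morpho import (RingGeometry, bootstrap_ci, detect_foci,
                              detect_protrusion, nuclear_dimensions,
                              perinuclear_enrichment, score_cohort,
                              segment_nucleus)
from cardionuc.presets import generate_image_cohort, image_preset


class TestSegmentation:
    def test_noiseless_ellipse_dice(self, clean_nucleus_image):
        channels, _ = clean_nucleus_image
        mask = segment_nucleus(channels["chromatin"])
        spec = image_preset("WT_mouse")
        a, b = spec.nucleus_semi_axes
        ny, nx = mask.shape
        y = (np.arange(ny) - (ny - 1) / 2) * 0.1
        x = (np.arange(nx) - (nx - 1) / 2) * 0.1
        Y, X = np.meshgrid(y, x, indexing="ij")
        truth = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.99

    def test_background_only_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SegmentationError):
            segment_nucleus(rng.normal(0.02, 0.005, (200, 200)))

    def test_deterministic_on_identical_input(self, clean_nucleus_image):
        channels, _ = clean_nucleus_image
        a = segment_nucleus(channels["chromatin"])
        b = segment_nucleus(channels["chromatin"])
        assert np.array_equal(a, b)


class TestDimensions:
    def test_circle_aspect_ratio_unity(self):
        spec = image_preset("WT_mouse", noise_sd=0.0,
                            nucleus_semi_axes=(3.5, 3.5))
        channels, _ = generate_nucleus_image(spec)
        dims = nuclear_dimensions(segment_nucleus(channels["chromatin"]))
        assert dims["aspect_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_known_ellipse_aspect_ratio(self):
        spec = image_preset("WT_mouse", noise_sd=0.0,
                            nucleus_semi_axes=(7.0, 3.5))
        channels, _ = generate_nucleus_image(spec)
        dims = nuclear_dimensions(segment_nucleus(channels["chromatin"]))
        assert dims["aspect_ratio"] == pytest.approx(2.0, abs=0.05)
        assert dims["nuclear_length"] == pytest.approx(14.0, rel=0.03)

    def test_rotation_invariance_sweep(self):
        """AR unbiased to < 2% across a 12-angle sweep of the same ellipse."""
        errs = []
        for ang in np.linspace(0.0, 165.0, 12):
            spec = image_preset("WT_mouse", noise_sd=0.0,
                                orientation=np.deg2rad(ang))
            channels, truth = generate_nucleus_image(spec)
            ar = nuclear_dimensions(segment_nucleus(channels["chromatin"]))["aspect_ratio"]
            errs.append(abs(ar - truth.aspect_ratio) / truth.aspect_ratio)
        assert max(errs) < 0.02

    def test_rotated_matches_unrotated(self):
        """A 37-degree rotation leaves the AR estimate within 0.02 of truth
        (pixelation biases the axis-aligned and rotated cases in opposite
        directions, so each is checked against the analytic value)."""
        base = image_preset("WT_mouse", noise_sd=0.0)
        rot = image_preset("WT_mouse", noise_sd=0.0, orientation=np.deg2rad(37))
        truth = base.nucleus_semi_axes[0] / base.nucleus_semi_axes[1]
        ar0 = nuclear_dimensions(segment_nucleus(
            generate_nucleus_image(base)[0]["chromatin"]))["aspect_ratio"]
        ar37 = nuclear_dimensions(segment_nucleus(
            generate_nucleus_image(rot)[0]["chromatin"]))["aspect_ratio"]
        assert abs(ar0 - truth) < 0.02
        assert abs(ar37 - truth) < 0.02

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 25] = True
        with pytest.raises(ValueError):
            nuclear_dimensions(mask)


class TestEnrichment:
    def test_uniform_tubulin_ratio_one(self, clean_nucleus_image):
        channels, _ = clean_nucleus_image
        mask = segment_nucleus(channels["chromatin"])
        out = perinuclear_enrichment(np.ones_like(channels["tubulin"]), mask)
        assert out["enrichment_overall"] == pytest.approx(1.0, abs=0.02)
        assert out["enrichment_tips"] == pytest.approx(1.0, abs=0.02)
        assert out["enrichment_sides"] == pytest.approx(1.0, abs=0.02)

    def test_recovers_generated_factor(self):
        spec = image_preset("csDNKASH", noise_sd=0.0)
        spec.tubulin.enrichment_factor = 2.0
        spec.tubulin.tip_boost = 0.0
        channels, _ = generate_nucleus_image(spec)
        mask = segment_nucleus(channels["chromatin"])
        out = perinuclear_enrichment(channels["tubulin"], mask)
        assert out["enrichment_overall"] == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("factor", [1.0, 1.5, 2.0, 3.0])
    def test_recovery_sweep_with_noise(self, factor):
        """|estimate - truth| < 0.15 at SNR >= 10 across the factor sweep."""
        spec = image_preset("csDNKASH", noise_sd=0.1, seed=int(factor * 10))
        spec.tubulin.enrichment_factor = factor
        spec.tubulin.tip_boost = 0.0
        channels, _ = generate_nucleus_image(spec)
        mask = segment_nucleus(channels["chromatin"])
        out = perinuclear_enrichment(channels["tubulin"], mask)
        assert abs(out["enrichment_overall"] - factor) < 0.15

    def test_tip_boost_raises_tip_over_side_ratio(self):
        spec = image_preset("WT_mouse", noise_sd=0.0)   # tip_boost 0.4
        channels, _ = generate_nucleus_image(spec)
        mask = segment_nucleus(channels["chromatin"])
        out = perinuclear_enrichment(channels["tubulin"], mask)
        assert out["enrichment_tips"] > out["enrichment_sides"]

    def test_empty_cytoplasmic_band_rejected(self, clean_nucleus_image):
        channels, _ = clean_nucleus_image
        mask = segment_nucleus(channels["chromatin"])
        rings = RingGeometry(pn_ring_width=1.0, cyt_inner_offset=14.0,
                             cyt_outer_offset=16.0)
        with pytest.raises(ValueError):
            perinuclear_enrichment(channels["tubulin"], mask, rings)

    def test_invalid_rings_rejected(self):
        with pytest.raises(ValueError):
            RingGeometry(pn_ring_width=3.0, cyt_inner_offset=2.0).validate()


class TestProtrusion:
    def test_clean_ellipsoid_negative(self, clean_nucleus_image):
        channels, _ = clean_nucleus_image
        mask = segment_nucleus(channels["chromatin"])
        present, area = detect_protrusion(channels["chromatin"], mask)
        assert not present
        assert area == 0.0

    def test_planted_tip_protrusion_detected(self, protrusion_image):
        channels, truth = protrusion_image
        mask = segment_nucleus(channels["chromatin"])
        present, area = detect_protrusion(channels["chromatin"], mask)
        assert present
        assert area == pytest.approx(truth.protrusion_area, rel=0.25)

    def test_side_blob_excluded_by_tip_sectors(self):
        spec = image_preset("N195K", noise_sd=0.0)
        channels, _ = generate_nucleus_image(spec)
        chrom = channels["chromatin"].copy()
        ny, nx = chrom.shape
        y = (np.arange(ny) - (ny - 1) / 2) * 0.1
        x = (np.arange(nx) - (nx - 1) / 2) * 0.1
        Y, X = np.meshgrid(y, x, indexing="ij")
        blob = X ** 2 + (Y - 2.9) ** 2 <= 0.8 ** 2   # on the nuclear side
        chrom[blob] = 1.0
        mask = segment_nucleus(chrom)
        present, _ = detect_protrusion(chrom, mask)
        assert not present

    def test_cohort_prevalence_within_binomial_interval(self):
        """Detected prevalence consistent with the planted Bernoulli rate."""
        from scipy import stats
        n = 120
        imgs = generate_image_cohort("N195K", n, seed=31)
        table, summary = score_cohort(imgs, mode="protrusion", seed=31)
        lo = stats.binom.ppf(0.025, n, 0.20) / n
        hi = stats.binom.ppf(0.975, n, 0.20) / n
        assert lo <= summary["prevalence"] <= hi


class TestFoci:
    def _image(self, foci, noise=0.02, seed=1):
        spec = image_preset("N195K", foci=foci, noise_sd=noise, seed=seed)
        return generate_nucleus_image(spec)

    def test_no_foci_counts_zero(self):
        channels, _ = self._image([])
        mask = segment_nucleus(channels["chromatin"])
        count, areas = detect_foci(channels["foci"], mask)
        assert count == 0 and areas == []

    def test_three_in_ring_foci_counted_with_areas(self):
        foci = [Focus(center=(6.8, 0.0)), Focus(center=(0.0, 3.4)),
                Focus(center=(-6.9, 0.5))]
        channels, _ = self._image(foci)
        mask = segment_nucleus(channels["chromatin"])
        count, areas = detect_foci(channels["foci"], mask)
        assert count == 3
        for a in areas:
            assert a == pytest.approx(np.pi * 0.25 ** 2, rel=0.3)

    def test_focus_two_microns_outside_excluded(self):
        channels, _ = self._image([Focus(center=(6.2 + 2.5, 0.0))])
        mask = segment_nucleus(channels["chromatin"])
        count, _ = detect_foci(channels["foci"], mask)
        assert count == 0

    def test_nuclear_mode_restricts_to_interior(self):
        foci = [Focus(center=(0.0, 0.0)), Focus(center=(6.8, 0.0))]
        channels, _ = self._image(foci)
        mask = segment_nucleus(channels["chromatin"])
        count, _ = detect_foci(channels["foci"], mask, mode="nuclear")
        assert count == 1


class TestScalingInvariance:
    def test_metrics_invariant_to_global_intensity_scale(self, protrusion_image):
        channels, _ = protrusion_image
        scaled = {k: v * 7.3 for k, v in channels.items()}
        for ch in (channels, scaled):
            mask = segment_nucleus(ch["chromatin"])
            enr = perinuclear_enrichment(ch["tubulin"], mask)
            pres, _ = detect_protrusion(ch["chromatin"], mask)
            if ch is channels:
                ref = (enr["enrichment_overall"], pres)
        assert enr["enrichment_overall"] == pytest.approx(ref[0], rel=1e-9)
        assert pres == ref[1]


class TestCohortScoring:
    def test_protrusion_free_cohort_zero_prevalence(self):
        spec = image_preset("WT_mouse", noise_sd=0.0)
        channels, truth = generate_nucleus_image(spec)
        imgs = [(channels, truth)] * 5
        table, summary = score_cohort(imgs, mode="protrusion", seed=0)
        assert summary["prevalence"] == 0.0
        assert summary["ci_low"] == 0.0 and summary["ci_high"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            score_cohort([], mode="protrusion")

    def test_bootstrap_ci_brackets_mean(self):
        values = np.array([0, 0, 1, 0, 1, 1, 0, 0, 1, 0], float)
        lo, hi = bootstrap_ci(values, seed=2)
        assert lo <= values.mean() <= hi
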