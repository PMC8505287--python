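"""Generators: exact counts, regime structure, reproducibility, rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ihcspatial import (InvalidSpecError, PatternSpec, PointPattern,
                        RenderSpec, Window, clark_evans_ratio, field_rng,
                        generate_cohort, generate_pattern, render_field,
                        uniformity_index)
from ihcspatial.stains import DAB_OD

from conftest import make_pattern


class TestGeneratePattern:
    def test_coincident_points_are_identical(self, px_window):
        p = generate_pattern(PatternSpec("coincident", 100, seed=1), px_window)
        assert p.n == 100
        assert np.unique(p.coords, axis=0).shape[0] == 1

    def test_zero_points_gives_empty_pattern(self, px_window):
        p = generate_pattern(PatternSpec("csr", 0, seed=1), px_window)
        assert p.n == 0

    def test_csr_first_moments_match_uniform_law(self, unit_window):
        # mean of U(0,1) is 1/2 with SE (1/sqrt(12))/sqrt(n)
        p = generate_pattern(PatternSpec("csr", 10_000, seed=7), unit_window)
        tol = 3.0 * (1.0 / np.sqrt(12.0)) / 100.0
        assert abs(p.x.mean() - 0.5) < tol
        assert abs(p.y.mean() - 0.5) < tol

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            PatternSpec("csr", -5)
        with pytest.raises(InvalidSpecError):
            PatternSpec("unknown_regime", 10)
        with pytest.raises(InvalidSpecError):
            PatternSpec("thomas_cluster", 10)  # missing cluster parameters
        with pytest.raises(InvalidSpecError):
            PatternSpec("jittered_lattice", 10, jitter=1.5)

    def test_same_seed_is_bitwise_identical(self, px_window):
        for regime in ("csr", "thomas_cluster", "jittered_lattice", "coincident"):
            a = make_pattern(regime, 120, px_window, seed=9)
            b = make_pattern(regime, 120, px_window, seed=9)
            np.testing.assert_array_equal(a.coords, b.coords)

    @given(
        regime=st.sampled_from(["csr", "thomas_cluster", "jittered_lattice", "coincident"]),
        n=st.integers(min_value=0, max_value=300),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_patterns_have_exact_count_inside_window(self, regime, n, seed):
        window = Window(800.0, 600.0)
        p = make_pattern(regime, n, window, seed=seed)
        assert p.n == n
        if n:
            assert window.contains(p.x, p.y).all()

    def test_hard_core_min_distance_respected(self, px_window):
        p = generate_pattern(
            PatternSpec("csr", 80, min_distance=40.0, seed=3), px_window)
        from scipy.spatial.distance import pdist

        assert pdist(p.coords).min() >= 40.0

    def test_clark_evans_ordering_of_regimes(self, px_window):
        """Thomas clusters aggregate (R < 1); near-regular lattices disperse (R > 1)."""
        for seed in range(20):
            thomas = make_pattern("thomas_cluster", 150, px_window, seed=seed)
            lattice = make_pattern("jittered_lattice", 150, px_window, seed=seed)
            assert clark_evans_ratio(thomas) < 1.0
            assert clark_evans_ratio(lattice) > 1.0

    def test_csr_passes_quadrat_uniformity_at_expected_rate(self, px_window):
        """Chi-square quadrat counts reject a true CSR pattern ~5% of the time."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 300
        edges = np.linspace(0, 1000, 6)
        for _ in range(n_rep):
            p = generate_pattern(PatternSpec("csr", 250), px_window, rng=rng)
            counts, *_ = np.histogram2d(p.x, p.y, bins=[edges, edges])
            rejections += stats.chisquare(counts.ravel()).pvalue < 0.05
        # binomial(300, 0.05) three-sigma band
        assert 0.01 <= rejections / n_rep <= 0.09


class TestRenderField:
    def test_zero_nuclei_zero_noise_is_uniform_background(self):
        w = Window(63, 63)
        empty = PointPattern(np.empty(0), np.empty(0), w)
        out = render_field(empty, None, RenderSpec(shape=(64, 64)))
        assert np.all(out.image.pixels == 255.0)
        assert not out.dab_mask.any() and not out.nuclei_mask.any()

    def test_dab_only_nucleus_has_od_parallel_to_dab_vector(self):
        w = Window(63, 63)
        one = PointPattern([32.0], [32.0], w)
        spec = RenderSpec(shape=(64, 64), hematoxylin_amplitude=0.0)
        out = render_field(one, None, spec)
        od = -np.log10(out.image.pixels[32, 32] / 255.0)
        cosine = od @ DAB_OD / np.linalg.norm(od)
        assert cosine == pytest.approx(1.0, abs=1e-12)
        assert out.dab_mask[32, 32]

    def test_non_unit_stain_vector_rejected(self):
        with pytest.raises(InvalidSpecError):
            RenderSpec(dab_od=(0.5, 0.5, 0.5))

    def test_render_is_deterministic_under_seed(self, px_window):
        w = Window(127, 127)
        pts = generate_pattern(PatternSpec("csr", 20, seed=4), w)
        spec = RenderSpec(shape=(128, 128), noise_sd=3.0, seed=11)
        a = render_field(pts, None, spec)
        b = render_field(pts, None, spec)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    def test_centers_outside_image_bounds_rejected(self):
        w = Window(200, 200)
        pts = PointPattern([150.0], [10.0], w)
        with pytest.raises(InvalidSpecError):
            render_field(pts, None, RenderSpec(shape=(64, 64)))


class TestGenerateCohort:
    def test_study_shape_150_fields_per_group(self, px_window):
        spec = PatternSpec("csr", 50)
        cohort = generate_cohort(spec, spec, px_window, seed=0)
        df = cohort.to_frame()
        assert len(df) == 300
        assert (df.groupby("group").size() == 150).all()
        assert df.groupby(["group", "sample_id"]).size().eq(10).all()

    def test_cohort_deterministic_and_fields_independently_replayable(self, px_window):
        spec = PatternSpec("csr", 60)
        a = generate_cohort(spec, spec, px_window, n_samples_per_group=2,
                            n_fields_per_sample=3, seed=5)
        b = generate_cohort(spec, spec, px_window, n_samples_per_group=2,
                            n_fields_per_sample=3, seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.pattern.coords, rb.pattern.coords)
        # replay one field from its keyed stream without the rest of the cohort
        rec = a.fields[4]  # group 0, sample 1, field 1
        rng = field_rng(5, 0, 1, 1)
        n = int(rng.poisson(60))
        replay = generate_pattern(PatternSpec("csr", n), px_window, rng=rng)
        np.testing.assert_array_equal(rec.pattern.coords, replay.coords)

    def test_fixed_count_distribution(self, px_window):
        spec = PatternSpec("csr", 77)
        cohort = generate_cohort(spec, spec, px_window, n_samples_per_group=2,
                                 n_fields_per_sample=2, seed=1,
                                 count_distribution="fixed")
        assert all(rec.pattern.n == 77 for rec in cohort)

    def test_matched_regime_contrast_detected_with_high_power(self, px_window):
        """Clustered arm vs CSR arm: the uniformity-index t-test should
        essentially always separate the documented default effect size."""
        spec_a = PatternSpec("thomas_cluster", 150,
                             parent_intensity=8.0 / px_window.area,
                             offspring_spread=0.03 * px_window.shorter_side)
        spec_b = PatternSpec("csr", 150)
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            cohort = generate_cohort(spec_a, spec_b, px_window, seed=900 + rep)
            means = {}
            for rec in cohort:
                means.setdefault((rec.group, rec.sample_id), []).append(
                    uniformity_index(rec.pattern).index)
            ga = [np.mean(v) for (g, _), v in means.items() if g == "A"]
            gb = [np.mean(v) for (g, _), v in means.items() if g == "B"]
            pval = stats.ttest_ind(ga, gb).pvalue
            hits += pval < 0.05
        assert hits / n_rep > 0.9
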