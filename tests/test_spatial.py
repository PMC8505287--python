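"""Ripley K, CSR envelopes, pattern classification and the uniformity index."""

import math

import numpy as np
import pytest

from ihcspatial import (KFunctionResult, PatternSpec, PointPattern, R_HEX,
                        RipleyKAnalysis, UndefinedStatisticError, Window,
                        classify_pattern, csr_envelope, default_d_grid,
                        generate_pattern, hexagonal_lattice, ripley_k,
                        uniformity_index)

from conftest import make_pattern


def brute_force_k(pattern: PointPattern, d_grid) -> np.ndarray:
    """Independent O(n^2) oracle: literal evaluation of
    K(d) = |W|/(n(n-1)) * sum over ordered pairs of 1(dist <= d)."""
    n = pattern.n
    out = []
    for d in d_grid:
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dist = math.hypot(pattern.x[i] - pattern.x[j],
                                  pattern.y[i] - pattern.y[j])
                if dist <= d:
                    count += 1
        out.append(pattern.window.area * count / (n * (n - 1)))
    return np.asarray(out)


class TestRipleyK:
    def test_two_points_hand_computed(self):
        w = Window(100.0, 100.0)
        p = PointPattern([10.0, 10.0], [10.0, 15.0], w)  # distance 5
        k = ripley_k(p, np.array([1.0, 4.9, 5.0, 20.0]))
        np.testing.assert_allclose(k, [0.0, 0.0, 10000.0, 10000.0])

    def test_coincident_points_saturate_at_window_area(self, px_window):
        p = generate_pattern(PatternSpec("coincident", 50, seed=1), px_window)
        k = ripley_k(p, np.array([0.5, 10.0, 100.0]))
        np.testing.assert_allclose(k, px_window.area)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, px_window):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        p = generate_pattern(PatternSpec("csr", n, seed=seed), px_window)
        grid = default_d_grid(px_window, n_steps=12)
        np.testing.assert_array_equal(ripley_k(p, grid), brute_force_k(p, grid))

    def test_invariant_under_rotation_and_translation(self, px_window):
        p = generate_pattern(PatternSpec("csr", 80, seed=2), px_window)
        grid = default_d_grid(px_window)
        k = ripley_k(p, grid)
        np.testing.assert_allclose(ripley_k(p.rotated90(), grid), k)
        # in-window translation leaves all pairwise distances unchanged
        shrunk = PointPattern(p.x * 0.5, p.y * 0.5, px_window)
        shifted = PointPattern(shrunk.x + 200.0, shrunk.y + 300.0, px_window)
        np.testing.assert_allclose(ripley_k(shifted, grid), ripley_k(shrunk, grid))

    def test_k_is_nondecreasing(self, csr_pattern):
        k = ripley_k(csr_pattern, default_d_grid(csr_pattern.window))
        assert (np.diff(k) >= 0).all()

    def test_too_few_points_rejected(self, px_window):
        p = PointPattern([1.0], [1.0], px_window)
        with pytest.raises(UndefinedStatisticError):
            ripley_k(p, np.array([1.0]))

    def test_grid_validation(self, px_window, csr_pattern):
        with pytest.raises(ValueError):
            ripley_k(csr_pattern, np.array([0.0, 1.0]))       # non-positive start
        with pytest.raises(ValueError):
            ripley_k(csr_pattern, np.array([5.0, 4.0]))       # not ascending
        with pytest.raises(ValueError):
            ripley_k(csr_pattern, np.array([600.0]))          # beyond half window

    def test_translation_correction_unbiased_under_csr(self, unit_window):
        """E[K(d)] = pi d^2 for a homogeneous process; the translation-
        corrected estimator should hit it closely even near the boundary."""
        grid = np.array([0.05, 0.10])
        ks = [ripley_k(generate_pattern(PatternSpec("csr", 300, seed=s), unit_window),
                       grid, edge_correction="translation")
              for s in range(40)]
        np.testing.assert_allclose(np.mean(ks, axis=0), np.pi * grid**2, rtol=0.05)


class TestEnvelope:
    def test_order_statistics_bracket_the_mean(self, px_window):
        env = csr_envelope(100, px_window, default_d_grid(px_window),
                           n_sim=50, seed=3)
        assert (env.lower <= env.k0_mean).all()
        assert (env.k0_mean <= env.upper).all()

    def test_standard_rank_is_third_extreme_for_100_sims(self, px_window):
        env = csr_envelope(50, px_window, default_d_grid(px_window, n_steps=5),
                           n_sim=100, seed=4)
        assert env.rank == 3

    def test_same_seed_gives_identical_envelopes(self, px_window):
        grid = default_d_grid(px_window)
        a = csr_envelope(80, px_window, grid, n_sim=30, seed=9)
        b = csr_envelope(80, px_window, grid, n_sim=30, seed=9)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)
        np.testing.assert_array_equal(a.k0_mean, b.k0_mean)

    def test_rejects_degenerate_inputs(self, px_window):
        grid = default_d_grid(px_window)
        with pytest.raises(UndefinedStatisticError):
            csr_envelope(1, px_window, grid)
        with pytest.raises(ValueError):
            csr_envelope(10, px_window, grid, n_sim=1)

    def test_envelope_width_shrinks_with_point_count(self, unit_window):
        """The Monte-Carlo K envelope tightens as n grows (more pairs per
        pattern average out); compare mean widths over replicates."""
        grid = default_d_grid(unit_window, n_steps=10)
        widths = {}
        rng = np.random.default_rng(10)
        for n in (50, 500):
            vals = []
            for _ in range(50):
                env = csr_envelope(n, unit_window, grid, n_sim=50, rng=rng)
                vals.append(np.mean(env.upper - env.lower))
            widths[n] = np.mean(vals)
        assert widths[500] < widths[50]


class TestClassification:
    def _result(self, px_window, k_obs, lo=None, hi=None):
        grid = default_d_grid(px_window, n_steps=10)
        k0 = np.pi * grid**2
        return KFunctionResult(
            d=grid, k_obs=k_obs, k0_mean=k0,
            env_lo=k0 * 0.8 if lo is None else lo,
            env_hi=k0 * 1.2 if hi is None else hi,
            n_points=100, window=px_window, n_sim=100)

    def test_observed_equal_to_null_mean_is_random(self, px_window):
        grid = default_d_grid(px_window, n_steps=10)
        res = self._result(px_window, np.pi * grid**2)
        assert res.verdict.label == "random"

    def test_sustained_excess_is_clustered_and_deficit_is_avoidance(self, px_window):
        grid = default_d_grid(px_window, n_steps=10)
        k0 = np.pi * grid**2
        assert self._result(px_window, k0 * 1.5).verdict.label == "clustered"
        assert self._result(px_window, k0 * 0.5).verdict.label == "avoidance"
        both = k0.copy() * 1.5
        both[5:] = k0[5:] * 0.5
        assert self._result(px_window, both).verdict.label == "mixed"

    def test_short_excursions_do_not_trigger_a_call(self, px_window):
        grid = default_d_grid(px_window, n_steps=10)
        k0 = np.pi * grid**2
        spiky = k0.copy()
        spiky[4] *= 1.5  # one grid point above: chance excursion
        res = self._result(px_window, spiky)
        assert res.verdict.label == "random"
        assert res.verdict.frac_above == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_regime_fixtures_classified_correctly(self, seed, px_window):
        thomas = make_pattern("thomas_cluster", 200, px_window, seed=seed)
        res = RipleyKAnalysis(thomas).fit(n_sim=100, seed=1000 + seed)
        assert res.verdict.label == "clustered"
        lattice = make_pattern("jittered_lattice", 100, px_window, seed=seed)
        res = RipleyKAnalysis(lattice).fit(n_sim=100, seed=2000 + seed)
        assert res.verdict.label == "avoidance"

    def test_summary_mentions_verdict(self, px_window):
        pat = make_pattern("csr", 100, px_window, seed=6)
        res = RipleyKAnalysis(pat).fit(n_sim=20, seed=7)
        text = res.summary()
        assert res.verdict.label in text and "100" in text


class TestUniformityIndex:
    def test_maximal_clustering_scores_zero(self, px_window):
        p = generate_pattern(PatternSpec("coincident", 100, seed=1), px_window)
        assert uniformity_index(p).index == 0.0

    def test_regular_array_scores_one(self):
        hex400 = hexagonal_lattice(20, 20, spacing=10.0)
        assert uniformity_index(hex400).index == pytest.approx(1.0, abs=0.03)

    def test_csr_sits_at_the_clark_evans_null(self, unit_window):
        """Under CSR the NN ratio is ~1, so the index is ~1/R_hex ~= 0.465."""
        vals = [uniformity_index(
            generate_pattern(PatternSpec("csr", 1000, seed=s), unit_window)).index
            for s in range(50)]
        assert np.mean(vals) == pytest.approx(1.0 / R_HEX, abs=0.02)

    def test_undefined_below_two_points(self, px_window):
        res = uniformity_index(PointPattern([5.0], [5.0], px_window))
        assert not res.defined
        assert math.isnan(res.index)

    def test_regime_ordering_on_matched_counts(self, px_window):
        """coincident < clustered < random < near-regular, every seed."""
        for seed in range(20):
            co = uniformity_index(make_pattern("coincident", 150, px_window, seed)).index
            th = uniformity_index(make_pattern("thomas_cluster", 150, px_window, seed)).index
            cs = uniformity_index(make_pattern("csr", 150, px_window, seed)).index
            la = uniformity_index(make_pattern("jittered_lattice", 150, px_window, seed)).index
            assert co < th < cs < la

    def test_index_bounded_in_unit_interval(self, px_window):
        for seed in range(10):
            for regime in ("csr", "thomas_cluster", "jittered_lattice"):
                idx = uniformity_index(make_pattern(regime, 120, px_window, seed)).index
                assert 0.0 <= idx <= 1.0

    def test_donnelly_correction_raises_expected_distance(self, px_window):
        p = make_pattern("csr", 50, px_window, seed=3)
        plain = uniformity_index(p)
        corrected = uniformity_index(p, nn_correction="donnelly")
        assert corrected.expected_nn_distance > plain.expected_nn_distance
        assert corrected.index < plain.index
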