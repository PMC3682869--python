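"""Running-sum statistic, Brownian-bridge max p-values, moments, Z-scores."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from wordbridge import bridge_max_sf, bridge_moments, running_sum, z_score
from wordbridge.rankstat import _series_sf, _series_sf_vec
from wordbridge.wordstats import LogScoreSet


def profile_of(values, word="W"):
    return running_sum(LogScoreSet(word=word, scores=np.asarray(values, float)))


class TestRunningSum:
    def test_toy_example(self):
        prof = profile_of([2.0, 0.0, 1.0])
        assert np.allclose(prof.r, [0, 1, 0, 0])
        assert prof.D == pytest.approx(1.0)
        assert prof.es_index == 1
        assert prof.direction == "down"
        assert not prof.degenerate

    def test_constant_scores_degenerate(self):
        prof = profile_of([1.5] * 10)
        assert np.allclose(prof.r, 0.0)
        assert prof.D == 0.0
        assert prof.degenerate

    def test_starts_and_ends_at_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            prof = profile_of(rng.exponential(size=int(rng.integers(2, 500))))
            assert prof.r[0] == 0.0
            assert abs(prof.r[-1]) < 1e-9

    def test_reversal_mirrors_profile(self):
        """Reversing the gene order keeps D and maps es_index to u - es_index."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            ls = rng.normal(size=50)
            fwd = profile_of(ls)
            rev = profile_of(ls[::-1])
            assert rev.D == pytest.approx(fwd.D, rel=1e-12)
            assert rev.es_index == 50 - fwd.es_index
            assert rev.direction != fwd.direction

    def test_es_index_ties_take_smallest_rank(self):
        # two ranks attain |r| = 1: index 1 (r=+1) and later ones
        prof = profile_of([2.0, 1.0, 0.0])
        assert prof.es_index == 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            profile_of([1.0])


class TestBridgeMaxSf:
    def test_deep_tail(self):
        # x = D/(sigma*sqrt(t)) = 5
        assert bridge_max_sf(D=5.0 * 10, sigma=1.0, t=100) < 1e-10

    def test_median_of_kolmogorov_distribution(self):
        assert _series_sf(0.82757) == pytest.approx(0.5, abs=1e-4)

    def test_value_at_one(self):
        assert _series_sf(1.0) == pytest.approx(sps.kstwobign.sf(1.0), abs=1e-10)
        assert _series_sf(1.0) == pytest.approx(0.27, abs=5e-4)

    def test_matches_independent_series_oracle(self):
        xs = np.linspace(0.05, 4.0, 80)
        ours = np.array([_series_sf(x) for x in xs])
        assert np.allclose(ours, sps.kstwobign.sf(xs), atol=1e-10)

    def test_vectorized_matches_scalar(self):
        xs = np.concatenate([np.linspace(0.0, 3.0, 50), [0.049, 0.05, 0.051]])
        vec = _series_sf_vec(xs)
        scal = np.array([_series_sf(x) for x in xs])
        assert np.allclose(vec, scal, atol=1e-12)
        assert vec[-3] == 1.0 and scal[-3] == 1.0  # below the series guard

    def test_series_guard_region(self):
        assert bridge_max_sf(D=0.01, sigma=1.0, t=100) == 1.0

    def test_strictly_decreasing_in_D(self):
        # over the range where sf is representable away from 0 and 1
        Ds = np.linspace(5.0, 25.0, 40)
        vals = [bridge_max_sf(D, 1.0, 100) for D in Ds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bridge_max_sf(1.0, 0.0, 100)
        with pytest.raises(ValueError):
            bridge_max_sf(1.0, 1.0, 1)
        with pytest.raises(ValueError):
            bridge_max_sf(-1.0, 1.0, 100)


class TestBridgeMoments:
    def test_unit_time_closed_forms(self):
        mean, var = bridge_moments(1)
        assert mean == pytest.approx(math.sqrt(math.pi / 2) * math.log(2), rel=1e-12)
        assert mean == pytest.approx(0.86873, abs=1e-5)
        assert var == pytest.approx(0.0678, abs=1e-4)
        # independent check against the reference distribution's moments
        assert mean == pytest.approx(sps.kstwobign.mean(), rel=1e-9)
        assert var == pytest.approx(sps.kstwobign.var(), rel=1e-6)

    def test_sqrt_t_scaling(self):
        m1, _ = bridge_moments(1)
        m100, _ = bridge_moments(100)
        assert m100 == pytest.approx(10 * m1, rel=1e-12)

    def test_variance_closed_form_t4(self):
        _, var = bridge_moments(4)
        expected = 4 * math.pi**2 / 12 - (math.sqrt(2 * math.pi) * math.log(2)) ** 2
        assert var == pytest.approx(expected, rel=1e-12)

    def test_against_numerical_integration(self):
        """Closed forms equal integrals of the bridge-max distribution."""
        mean, var = bridge_moments(1)
        num_mean, _ = integrate.quad(sps.kstwobign.sf, 0, 10)
        num_m2, _ = integrate.quad(lambda x: 2 * x * sps.kstwobign.sf(x), 0, 10)
        assert mean == pytest.approx(num_mean, abs=1e-3)
        assert var == pytest.approx(num_m2 - num_mean**2, abs=1e-3)

    def test_positive_variance(self):
        for t in (1, 2, 10, 1000):
            assert bridge_moments(t)[1] > 0


class TestZScore:
    def test_centered_at_expected_max(self):
        mean, _ = bridge_moments(50)
        assert z_score(D=2.0 * mean, sigma=2.0, t=50) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above_mean(self):
        mean, var = bridge_moments(1)
        assert z_score(D=mean + math.sqrt(var), sigma=1.0, t=1) == pytest.approx(1.0)

    def test_decreasing_in_sigma(self):
        assert z_score(5.0, 2.0, 100) < z_score(5.0, 1.0, 100)

    def test_degenerate_sigma(self):
        assert z_score(0.0, 0.0, 100) == 0.0

    def test_scale_invariance(self):
        """Multiplying all log-scores by c > 0 leaves Z unchanged."""
        rng = np.random.default_rng(2)
        ls = rng.exponential(size=80)
        for c in (0.1, 3.0, 250.0):
            p1 = profile_of(ls)
            p2 = profile_of(c * ls)
            z1 = z_score(p1.D, p1.sigma, 80)
            z2 = z_score(p2.D, p2.sigma, 80)
            assert z2 == pytest.approx(z1, rel=1e-9)


class TestBridgeCalibration:
    def test_permutation_null_matches_analytic_sf_at_large_t(self):
        """Analytic sf agrees with the permutation null of D/(sigma*sqrt(t)).

        The running sum over t genes is a discrete bridge whose maximum
        undershoots the continuous bridge max by O(1/sqrt(t)); at t=1000
        the analytic survival function evaluated at the empirical
        10/50/90% permutation quantiles is within 0.04 of nominal.
        """
        rng = np.random.default_rng(5)
        t = 1000
        ls = rng.exponential(size=t)
        sigma = ls.std()
        perm = rng.permuted(np.tile(ls, (4000, 1)), axis=1)
        cs = np.cumsum(perm - perm.mean(axis=1, keepdims=True), axis=1)
        x = np.abs(cs).max(axis=1) / (sigma * math.sqrt(t))
        for q, nominal in [(0.1, 0.9), (0.5, 0.5), (0.9, 0.1)]:
            sf = _series_sf(float(np.quantile(x, q)))
            assert sf == pytest.approx(nominal, abs=0.04)

    def test_discrete_grid_deviation_shrinks_with_t(self):
        """The median-quantile deviation decreases as the list grows."""
        rng = np.random.default_rng(6)
        devs = []
        for t in (100, 400, 1600):
            ls = rng.normal(size=t)
            perm = rng.permuted(np.tile(ls, (3000, 1)), axis=1)
            cs = np.cumsum(perm - perm.mean(axis=1, keepdims=True), axis=1)
            x = np.abs(cs).max(axis=1) / (ls.std() * math.sqrt(t))
            devs.append(abs(_series_sf(float(np.median(x))) - 0.5))
        assert devs[2] < devs[0]
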