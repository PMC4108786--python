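import math

import numpy as np
import pytest

from slgraph.preprocess import BandDefinition
from slgraph.sl import (
    SLParams,
    critical_distance,
    derive_params,
    embed,
    sl_matrix,
    sl_pair,
)

ALPHA = BandDefinition("alpha", 8.0, 13.0)
THETA = BandDefinition("theta", 4.0, 8.0)

from oracles import sl_pair_bruteforce  # noqa: E402


class TestDeriveParams:
    def test_theta_lag_at_512hz(self):
        p = derive_params(THETA, 512.0, 0.01, 4096)
        assert p.lag == round(512 / (3 * 8)) == 21

    def test_alpha_embedding_dimension(self):
        p = derive_params(ALPHA, 512.0, 0.01, 4096)
        assert p.m == math.floor(3 * 13 / 8) + 1 == 5

    def test_theiler_and_search_windows(self):
        p = derive_params(ALPHA, 512.0, 0.01, 4096)
        assert p.w1 == 2 * p.lag * (p.m - 1)
        assert p.w1 < p.w2

    def test_short_epoch_with_large_pref_rejected(self):
        with pytest.raises(ValueError):
            derive_params(ALPHA, 512.0, 0.5, 80)

    def test_depends_only_on_inputs(self):
        a = derive_params(ALPHA, 512.0, 0.01, 4096)
        b = derive_params(ALPHA, 512.0, 0.01, 4096)
        assert a == b


class TestEmbed:
    def test_worked_example(self):
        vecs = embed(np.array([1.0, 2, 3, 4, 5]), m=2, lag=2)
        np.testing.assert_array_equal(vecs, [[1, 3], [2, 4], [3, 5]])

    def test_m_one_returns_samples(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(embed(x, 1, 3).ravel(), x)

    @pytest.mark.parametrize("m,lag", [(2, 1), (3, 4), (5, 7)])
    def test_count_matches_formula(self, rng, m, lag):
        x = rng.standard_normal(100)
        assert embed(x, m, lag).shape == (100 - (m - 1) * lag, m)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.zeros(5), m=3, lag=3)


class TestCriticalDistance:
    def params(self, p_ref=0.1):
        return SLParams(lag=1, m=2, w1=1, w2=30, p_ref=p_ref)

    def test_constant_series_radius_zero(self):
        emb = np.zeros((20, 2))
        assert critical_distance(emb, 5, self.params()) == 0.0

    def test_pref_covering_all_candidates_gives_max(self, rng):
        emb = rng.standard_normal((20, 2))
        p = SLParams(lag=1, m=2, w1=1, w2=30, p_ref=0.999999)
        i = 10
        cand = [j for j in range(20) if 1 < abs(i - j) <= 30]
        dmax = max(np.linalg.norm(emb[j] - emb[i]) for j in cand)
        assert critical_distance(emb, i, p) == pytest.approx(dmax)

    def test_matches_sorted_quantile(self, rng):
        emb = rng.standard_normal((50, 2))
        p = self.params(p_ref=0.13)
        i = 25
        cand = [j for j in range(50) if p.w1 < abs(i - j) <= p.w2]
        d = sorted(np.linalg.norm(emb[j] - emb[i]) for j in cand)
        k = math.ceil(p.p_ref * len(cand))
        assert critical_distance(emb, i, p) == pytest.approx(d[k - 1])

    def test_empty_candidate_set_rejected(self):
        emb = np.zeros((4, 2))
        with pytest.raises(ValueError, match="empty"):
            critical_distance(emb, 0, SLParams(lag=1, m=2, w1=5, w2=6, p_ref=0.1))


class TestSLPair:
    def test_identical_series_give_exactly_one(self, rng):
        p = SLParams(lag=2, m=3, w1=4, w2=60, p_ref=0.05)
        x = rng.standard_normal(200)
        assert sl_pair(x, x, p) == 1.0

    def test_length_mismatch_rejected(self, rng):
        p = SLParams(lag=1, m=2, w1=1, w2=20, p_ref=0.1)
        with pytest.raises(ValueError, match="mismatch"):
            sl_pair(rng.standard_normal(50), rng.standard_normal(60), p)

    def test_symmetry_exact(self, rng):
        p = SLParams(lag=1, m=2, w1=2, w2=40, p_ref=0.05)
        x, y = rng.standard_normal((2, 150))
        assert sl_pair(x, y, p) == sl_pair(y, x, p)

    @pytest.mark.parametrize("case", range(20))
    def test_matches_bruteforce_enumeration(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(120, 300))
        p = SLParams(
            lag=int(rng.integers(1, 4)),
            m=int(rng.integers(2, 5)),
            w1=int(rng.integers(1, 6)),
            w2=int(rng.integers(20, 80)),
            p_ref=float(rng.uniform(0.02, 0.2)),
        )
        # correlated pair so recurrences genuinely coincide
        shared = rng.standard_normal(n)
        x = 0.7 * shared + 0.3 * rng.standard_normal(n)
        y = 0.7 * shared + 0.3 * rng.standard_normal(n)
        assert sl_pair(x, y, p) == pytest.approx(sl_pair_bruteforce(x, y, p), abs=1e-12)

    def test_coupling_monotonicity(self):
        rng = np.random.default_rng(7)
        p = SLParams(lag=1, m=3, w1=4, w2=200, p_ref=0.05)
        means = []
        for c in (0.0, 0.5, 0.95):
            vals = []
            for _ in range(10):
                s = rng.standard_normal(600)
                x = np.sqrt(c) * s + np.sqrt(1 - c) * rng.standard_normal(600)
                y = np.sqrt(c) * s + np.sqrt(1 - c) * rng.standard_normal(600)
                vals.append(sl_pair(x, y, p))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_bounded_in_unit_interval(self, rng):
        p = SLParams(lag=1, m=2, w1=2, w2=50, p_ref=0.05)
        for _ in range(5):
            v = sl_pair(rng.standard_normal(200), rng.standard_normal(200), p)
            assert 0.0 <= v <= 1.0


class TestSLMatrix:
    def test_two_identical_channels(self, rng):
        p = SLParams(lag=1, m=2, w1=2, w2=50, p_ref=0.05)
        x = rng.standard_normal(200)
        m = sl_matrix(np.vstack([x, x]), p)
        assert m.values[0, 1] == 1.0
        np.testing.assert_array_equal(np.diag(m.values), [1.0, 1.0])

    def test_independent_channels_near_pref(self, rng):
        p = SLParams(lag=1, m=2, w1=2, w2=400, p_ref=0.05)
        vals = []
        for _ in range(10):
            m = sl_matrix(rng.standard_normal((3, 800)), p)
            iu = np.triu_indices(3, 1)
            vals.extend(m.values[iu])
        assert abs(np.mean(vals) - 0.05) < 0.02

    def test_shared_source_beats_independent(self, rng):
        p = SLParams(lag=1, m=3, w1=4, w2=300, p_ref=0.05)
        t = np.arange(800) / 100.0
        coupled, independent = [], []
        for _ in range(8):
            shared = np.sin(2 * np.pi * 7.0 * t + rng.uniform(0, 2 * np.pi))
            a = 0.8 * shared + 0.6 * rng.standard_normal(800)
            b = 0.8 * shared + 0.6 * rng.standard_normal(800)
            coupled.append(sl_pair(a, b, p))
            independent.append(
                sl_pair(rng.standard_normal(800), rng.standard_normal(800), p)
            )
        assert np.mean(coupled) > np.mean(independent)

    def test_single_channel_rejected(self, rng):
        p = SLParams(lag=1, m=2, w1=1, w2=20, p_ref=0.1)
        with pytest.raises(ValueError, match="2 channels"):
            sl_matrix(rng.standard_normal((1, 100)), p)
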