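import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fixent import (
    EntropyConfig,
    EntropyProfile,
    FixationSegment,
    fuzzy_entropy,
    grid_entropy,
    increment_entropy,
    phase_entropy,
    profile_fixation,
    sample_entropy,
    shannon,
    spectral_entropy,
)
from fixent.entropy import MetricUndefined

from conftest import random_sequences
from oracles import (
    oracle_fuzzy,
    oracle_griden,
    oracle_incren,
    oracle_phasen,
    oracle_sampen,
    oracle_specen,
)

CFG = EntropyConfig()

#: x whose 40 SODP points put an exactly equal cumulative slope (7*pi)
#: in each of the 4 sectors: an Eulerian walk over increment sign states
#: with unit steps (boundary angles pi/2, pi, 3*pi/2, 2*pi and diagonal
#: angles pi/4, 5*pi/4, 7*pi/4).
UNIFORM_SECTOR_INCREMENTS = (
    [0] + [1] * 21 + [-1] * 3 + [0, 1, -1] * 3 + [0, -1] * 3 + [0]
)
UNIFORM_SECTOR_X = np.concatenate([[0.0], np.cumsum(UNIFORM_SECTOR_INCREMENTS)])


class TestShannon:
    def test_certainty_is_zero(self):
        assert shannon([1.0]) == 0.0

    def test_uniform_closed_form(self):
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_base_two_closed_form(self):
        assert shannon([0.5, 0.25, 0.25], log_base="2") == pytest.approx(1.5)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            shannon([1.2, -0.2])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nonnegative_and_bounded(self, weights):
        p = np.array(weights) / sum(weights)
        h = shannon(p)
        assert -1e-12 <= h <= math.log(len(p)) + 1e-12


class TestOracleEquivalence:
    """Each vectorized metric equals its independent loop-based twin."""

    SEQS = random_sequences(60, seed=2024)

    @pytest.mark.parametrize("name,fast,naive", [
        ("fuzz", fuzzy_entropy, lambda x: oracle_fuzzy(list(x))),
        ("incr", increment_entropy, lambda x: oracle_incren(list(x))),
        ("samp", sample_entropy, lambda x: oracle_sampen(list(x))),
        ("phas", phase_entropy, lambda x: oracle_phasen(list(x))),
        ("spec", spectral_entropy, lambda x: oracle_specen(list(x))),
    ])
    def test_metric_matches_oracle(self, name, fast, naive):
        checked = 0
        for x in self.SEQS:
            try:
                got = fast(x, CFG)
            except MetricUndefined:
                with pytest.raises(ValueError):
                    naive(x)
                continue
            assert got == pytest.approx(naive(x), abs=1e-9)
            checked += 1
        assert checked >= 50

    def test_grid_matches_oracle(self):
        for x in self.SEQS:
            grid, gdr = grid_entropy(x, CFG)
            o_grid, o_gdr = oracle_griden(list(x))
            assert grid == pytest.approx(o_grid, abs=1e-12)
            assert gdr == pytest.approx(o_gdr, abs=1e-12)


class TestAnalyticLimits:
    def test_ramp_fuzzy_is_zero(self):
        assert fuzzy_entropy(np.linspace(0, 1, 40), CFG) == pytest.approx(0, abs=1e-12)

    def test_ramp_increment_is_zero(self):
        # exactly representable ramp: all increments identical in floats
        assert increment_entropy(np.arange(40.0), CFG) == 0.0

    def test_alternating_increment_is_log_two(self):
        x = np.tile([0.0, 1.0], 10)
        assert increment_entropy(x, CFG) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_counted_sample_entropy(self):
        # (1,2,1,2,1,2,1,2): B=12 matched pairs at m=1, A=9 at m=2
        x = np.tile([1.0, 2.0], 4)
        assert sample_entropy(x, CFG) == pytest.approx(-math.log(9 / 12), abs=1e-12)

    def test_concentrated_poincare_closed_form(self):
        # min-max normalization pins some coordinate to 0 and some to 1,
        # so for N >= 3 a non-constant signal always fills >= 2 cells;
        # the most concentrated case is 3 points in the corner cell and
        # the single range-setting transition elsewhere:
        # counts (3, 1)/4 -> GridEn = H(3/4, 1/4), GDR = 2/9
        x = np.array([0.2, 0.2, 0.2, 0.2, 1.0])
        grid, gdr = grid_entropy(x, CFG)
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert grid == pytest.approx(expected, abs=1e-12)
        assert gdr == pytest.approx(2 / 9)

    def test_uniform_nine_cell_poincare(self):
        # 10 samples traversing a de Bruijn-like path: the 9 Poincare
        # points land in all 9 cells of the 3x3 grid exactly once
        levels = {0: 0.1, 1: 0.5, 2: 0.9}
        path = [0, 0, 1, 0, 2, 1, 1, 2, 2, 0]
        x = np.array([levels[v] for v in path])
        grid, gdr = grid_entropy(x, CFG)
        assert gdr == 1.0
        assert grid == pytest.approx(math.log(9), abs=1e-12)

    def test_monotone_sodp_single_sector(self):
        # accelerating monotone rise: all increments positive -> all SODP
        # points in the first quadrant
        x = np.cumsum(np.linspace(0.1, 1.0, 20))
        assert phase_entropy(x, CFG) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sector_sums_reach_maximum(self):
        assert phase_entropy(UNIFORM_SECTOR_X, CFG) == pytest.approx(1.0, abs=1e-12)

    def test_bin_aligned_sinusoid_spectral_zero(self):
        n = 64
        x = np.sin(2 * np.pi * 8 * np.arange(n) / n)
        assert spectral_entropy(x, CFG) == pytest.approx(0.0, abs=1e-9)

    def test_flat_spectrum_reaches_log_bin_count(self):
        rng = np.random.default_rng(6)
        n = 64
        coeffs = np.zeros(n // 2 + 1, dtype=complex)
        coeffs[1:-1] = np.exp(2j * np.pi * rng.random(n // 2 - 1))
        coeffs[-1] = 1.0  # Nyquist bin must be real
        x = np.fft.irfft(coeffs, n=n)
        assert spectral_entropy(x, CFG) == pytest.approx(math.log(n // 2), abs=1e-9)


class TestAffineInvariance:
    METRICS = [fuzzy_entropy, increment_entropy, sample_entropy,
               phase_entropy, spectral_entropy]

    @pytest.mark.parametrize("a,b", [(3.7, 0.0), (0.25, -11.0), (120.0, 4.4)])
    def test_all_metrics_invariant(self, a, b):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(0, 0.1, 50) + 0.05 * np.sin(np.arange(50) / 3)
            y = a * x + b
            for metric in self.METRICS:
                assert metric(y, CFG) == pytest.approx(metric(x, CFG), abs=1e-8)
            gx, rx = grid_entropy(x, CFG)
            gy, ry = grid_entropy(y, CFG)
            assert gy == pytest.approx(gx, abs=1e-8)
            assert ry == pytest.approx(rx, abs=1e-8)


class TestBounds:
    def test_bounds_on_random_signals(self):
        cfg = CFG
        for x in random_sequences(40, seed=99):
            try:
                s = sample_entropy(x, cfg)
                assert s >= 0  # A <= B always under Chebyshev distance
            except MetricUndefined:
                pass
            p = phase_entropy(x, cfg)
            assert 0 <= p <= 1 + 1e-12
            g, gdr = grid_entropy(x, cfg)
            assert 0 <= g <= math.log(cfg.grid_n ** 2) + 1e-12
            assert 0 < gdr <= 1
            sp = spectral_entropy(x, cfg)
            assert 0 <= sp <= math.log(len(x) // 2) + 1e-12

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_sample_entropy_match_counts_nested(self, seed):
        # every (m+1)-template match implies the corresponding m-match
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        try:
            assert sample_entropy(x, CFG) >= 0
        except MetricUndefined:
            pass


class TestDegenerate:
    @pytest.mark.parametrize("metric", [
        fuzzy_entropy, sample_entropy, spectral_entropy,
        lambda x, c: grid_entropy(x, c)[0],
    ])
    def test_constant_signal_undefined(self, metric):
        with pytest.raises(MetricUndefined):
            metric(np.ones(30), CFG)

    def test_origin_only_sodp_undefined(self):
        with pytest.raises(MetricUndefined):
            phase_entropy(np.ones(30), CFG)


class TestProfile:
    @staticmethod
    def _seg(x, fid=0):
        return FixationSegment(x=np.asarray(x, float), pre_context=np.zeros(30),
                               post_context=np.zeros(30), fixation_id=fid)

    def test_constant_fixation_invalid(self):
        prof = profile_fixation(self._seg(np.ones(40)))
        assert not prof.valid

    def test_ramp_fixation_invalid_via_zero_entropies(self):
        prof = profile_fixation(self._seg(np.arange(40.0)))
        assert prof.fuzz == pytest.approx(0, abs=1e-12)
        assert prof.incr == 0.0
        assert not prof.valid

    def test_zero_value_marks_invalid(self):
        prof = EntropyProfile(fixation_id=0, fuzz=1, incr=1, samp=0.0,
                              grid=1, gdr=0.5, phas=0.5, spec=1)
        prof.refresh_validity()
        assert not prof.valid

    def test_healthy_fixation_valid(self):
        rng = np.random.default_rng(21)
        prof = profile_fixation(self._seg(rng.normal(0, 0.05, 60)))
        assert prof.valid
        assert all(np.isfinite(v) for v in prof.values().values())

    def test_batch_valid_count_matches_planted_degenerates(self):
        rng = np.random.default_rng(22)
        segs = []
        for i in range(90):
            segs.append(self._seg(rng.normal(0, 0.05, 50), fid=i))
        for i in range(10):  # planted degenerate: constant trajectories
            segs.append(self._seg(np.full(50, 3.3), fid=90 + i))
        profs = [profile_fixation(s) for s in segs]
        assert sum(p.valid for p in profs) == 90

    def test_context_excluded_from_metrics(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 0.05, 60)
        a = profile_fixation(self._seg(x))
        b = profile_fixation(FixationSegment(
            x=x, pre_context=np.full(30, 50.0), post_context=np.full(30, -50.0)))
        assert a.values() == b.values()
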