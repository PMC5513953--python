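"""Templates, DTW alignment, and the four signal-quality indices."""

import numpy as np
import pytest

from dusqa.beats import CycleEnvelope
from dusqa.template_sqi import (
    Template,
    build_templates,
    dtw_align,
    dtw_cost_and_path,
    initial_template,
    logistic_weight,
    segment_sqis,
    score_beats,
    sqi1_direct,
    sqi2_linear,
    sqi3_dtw,
    sqi4_wdtw,
    update_template,
)


def _norm(x):
    return (x - np.mean(x)) / np.std(x)


def _cycle(values, onset=0):
    return CycleEnvelope(np.asarray(values, dtype=float), onset)


def _triangle(L):
    half = L // 2
    return _norm(np.concatenate([np.linspace(0, 1, half),
                                 np.linspace(1, 0, L - half)]))


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive enumeration of all monotone warping paths
# ---------------------------------------------------------------------------

def brute_force_dtw(seq, ref, weights=None):
    """Minimum weighted cost and argmin path over *all* complete paths (DFS)."""
    n, m = len(seq), len(ref)
    lags = np.arange(max(n, m), dtype=float)
    w = np.ones_like(lags) if weights is None else np.asarray(weights(lags))

    def cell(i, j):
        return w[abs(i - j)] * (seq[i] - ref[j]) ** 2

    best = [np.inf, None]

    def dfs(i, j, cost, path):
        cost = cost + cell(i, j)
        path = path + [(i, j)]
        if i == n - 1 and j == m - 1:
            if cost < best[0]:
                best[0], best[1] = cost, path
            return
        if i + 1 < n:
            dfs(i + 1, j, cost, path)
        if j + 1 < m:
            dfs(i, j + 1, cost, path)
        if i + 1 < n and j + 1 < m:
            dfs(i + 1, j + 1, cost, path)

    dfs(0, 0, 0.0, [])
    return best[0], best[1]


def path_cost(path, seq, ref, weights=None):
    n, m = len(seq), len(ref)
    lags = np.arange(max(n, m), dtype=float)
    w = np.ones_like(lags) if weights is None else np.asarray(weights(lags))
    return sum(w[abs(i - j)] * (seq[i] - ref[j]) ** 2 for i, j in path)


class TestDTW:
    def test_identity_alignment(self):
        x = np.array([0.0, 1.0, 3.0, 2.0, 0.5])
        cost, path = dtw_cost_and_path(x, x)
        assert cost == 0.0
        assert path == [(i, i) for i in range(x.size)]
        assert np.array_equal(dtw_align(x, x), x)

    def test_repeated_element_recovers_reference(self):
        ref = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        seq = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        cost, _ = dtw_cost_and_path(seq, ref)
        assert cost == 0.0
        assert np.array_equal(dtw_align(seq, ref), ref)

    def test_dp_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            n, m = rng.integers(2, 7, size=2)
            seq = rng.standard_normal(n)
            ref = rng.standard_normal(m)
            cost, path = dtw_cost_and_path(seq, ref)
            bf_cost, _ = brute_force_dtw(seq, ref)
            assert cost == pytest.approx(bf_cost, abs=1e-12)
            # DP path must itself be optimal
            assert path_cost(path, seq, ref) == pytest.approx(bf_cost, abs=1e-12)

    def test_weighted_dp_matches_enumeration(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 7, size=2)
            seq = rng.standard_normal(n)
            ref = rng.standard_normal(m)
            wfun = logistic_weight(int(m), 0.5)
            cost, path = dtw_cost_and_path(seq, ref, wfun)
            bf_cost, _ = brute_force_dtw(seq, ref, wfun)
            assert cost == pytest.approx(bf_cost, abs=1e-12)

    def test_logistic_weight_penalty_structure(self):
        """Weights grow with phase lag; g steepens the penalty around L/2."""
        L = 50
        d = np.arange(L, dtype=float)
        for g in (0.0, 0.02, 0.1, 1.0):
            w = logistic_weight(L, g)(d)
            assert np.all(np.diff(w) >= 0)          # monotone in lag
            assert np.all((0 < w) & (w <= 1))
        # larger g raises the penalty on lags beyond the midpoint and relaxes
        # it below (the logistic pivots at L/2)
        w_lo, w_hi = (logistic_weight(L, g)(d) for g in (0.02, 0.5))
        assert np.all(w_hi[d > L / 2 + 1] >= w_lo[d > L / 2 + 1])
        assert np.all(w_hi[d < L / 2 - 1] <= w_lo[d < L / 2 - 1])

    def test_large_g_blocks_long_range_warping(self, rng):
        """With a steep phase penalty the optimal path hugs the diagonal."""
        ref = np.sin(np.linspace(0, 4 * np.pi, 40))
        seq = np.roll(ref, 12)  # strong warp needed for a perfect match
        _, path_free = dtw_cost_and_path(seq, ref)
        _, path_pen = dtw_cost_and_path(seq, ref, logistic_weight(40, 5.0))
        lag_free = max(abs(i - j) for i, j in path_free)
        lag_pen = max(abs(i - j) for i, j in path_pen)
        assert lag_pen <= lag_free

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            dtw_cost_and_path(np.array([1.0]), np.array([1.0, 2.0]))


class TestTemplates:
    def test_mean_of_identical_cycles(self):
        tri = _triangle(100)
        cycles = [_cycle(tri) for _ in range(5)]
        t = initial_template(cycles)
        assert t.valid and t.L == 100 and t.support_count == 5
        assert np.allclose(t.values, tri)

    def test_length_is_mean_btbi(self):
        cycles = [_cycle(np.ones(400)), _cycle(np.ones(420)), _cycle(np.ones(380))]
        assert initial_template(cycles).L == 400

    def test_single_cycle_invalid(self):
        assert not initial_template([_cycle(np.ones(100))]).valid

    def test_update_keeps_matching_cycles(self):
        tri = _triangle(100)
        t = initial_template([_cycle(tri) for _ in range(4)])
        out = update_template(t, [_cycle(tri) for _ in range(4)])
        assert out.valid and out.support_count == 4
        assert np.allclose(out.values, t.values)

    def test_invalid_window_falls_back_to_previous(self, rng):
        tri = _triangle(100)
        prev = initial_template([_cycle(tri) for _ in range(3)])
        t = initial_template([_cycle(tri) for _ in range(2)])
        # 1 of 10 cycles correlates (10% < 20%) -> invalid, use previous
        cycles = [_cycle(tri)] + [_cycle(rng.standard_normal(100)) for _ in range(9)]
        out = update_template(t, cycles, neighbors=(prev, None))
        assert out.valid
        assert np.allclose(out.values, prev.values)

    def test_boundary_20_percent_inclusive(self, rng):
        tri = _triangle(100)
        t = initial_template([_cycle(tri) for _ in range(2)])
        noise = [_cycle(rng.standard_normal(100)) for _ in range(8)]
        out = update_template(t, [_cycle(tri), _cycle(tri)] + noise)
        assert out.valid  # exactly 2 of 10 at r = 1.0 >= 0.6

    def test_both_neighbors_invalid_gives_templateless_window(self, rng):
        t = initial_template([_cycle(rng.standard_normal(100)) for _ in range(2)])
        out = update_template(t, [_cycle(rng.standard_normal(100))
                                  for _ in range(10)], neighbors=(None, None))
        assert not out.valid
        assert sqi1_direct(_cycle(np.ones(100)), out) == 0.0


class TestSQIs:
    def setup_method(self):
        self.tri = _triangle(100)
        self.t = Template(values=self.tri, L=100, window_index=0,
                          valid=True, support_count=5)

    def test_self_correlation_is_one_for_all_four(self):
        c = _cycle(self.tri)
        assert sqi1_direct(c, self.t) == pytest.approx(1.0)
        assert sqi2_linear(c, self.t) == pytest.approx(1.0)
        assert sqi3_dtw(c, self.t) == pytest.approx(1.0)
        assert sqi4_wdtw(c, self.t) == pytest.approx(1.0)

    def test_negative_correlation_clipped_to_zero(self):
        c = _cycle(-self.tri)
        assert sqi1_direct(c, self.t) == 0.0
        assert sqi2_linear(c, self.t) == 0.0

    def test_sqi1_zero_padding_matches_closed_form(self):
        c = _cycle(self.tri[:80])
        padded = np.concatenate([self.tri[:80], np.zeros(20)])
        expected = np.corrcoef(padded, self.tri)[0, 1]
        assert sqi1_direct(c, self.t) == pytest.approx(max(expected, 0.0), abs=1e-12)

    def test_sqi2_resampling_round_trip(self):
        upsampled = np.interp(np.linspace(0, 1, 200), np.linspace(0, 1, 100), self.tri)
        assert sqi2_linear(_cycle(upsampled), self.t) > 0.99

    def test_sqi2_null_distribution_centred_near_zero(self, rng):
        t50 = Template(values=_triangle(50), L=50, window_index=0, valid=True)
        raw = []
        for _ in range(300):
            x = rng.standard_normal(50)
            r = np.corrcoef(np.interp(np.linspace(0, 1, 50),
                                      np.linspace(0, 1, 50), x), t50.values)[0, 1]
            raw.append(r)
        assert abs(np.mean(raw)) < 0.1

    def test_g_zero_reduces_wdtw_to_dtw(self, rng):
        for _ in range(10):
            c = _cycle(rng.standard_normal(80))
            assert sqi4_wdtw(c, self.t, g=0.0) == pytest.approx(
                sqi3_dtw(c, self.t), abs=1e-12)

    def test_warping_never_hurts_in_median(self, rng):
        """sqi3 >= sqi2 >= sqi1 in the median over random cycles."""
        t50 = Template(values=_triangle(50), L=50, window_index=0, valid=True)
        s1, s2, s3 = [], [], []
        for _ in range(200):
            c = _cycle(rng.standard_normal(40))
            s1.append(sqi1_direct(c, t50))
            s2.append(sqi2_linear(c, t50))
            s3.append(sqi3_dtw(c, t50))
        assert np.median(s3) >= np.median(s2) >= np.median(s1)

    def test_zero_variance_cycle_scores_zero(self):
        c = _cycle(np.zeros(100))
        assert sqi1_direct(c, self.t) == 0.0


class TestSegmentSQIs:
    def test_median_over_beats(self):
        tri = _triangle(100)
        t = Template(values=tri, L=100, window_index=0, valid=True)
        # three beats: two perfect, one noise -> median = 1.0 for sqi1
        rng = np.random.default_rng(1)
        cycles = [_cycle(tri, 0), _cycle(tri, 110), _cycle(rng.standard_normal(100), 220)]
        sqis = score_beats(cycles, [t], fs=4000.0)
        med = segment_sqis(0, 400, sqis)
        assert med[0] == pytest.approx(np.median([s.sqi1 for s in sqis]))

    def test_no_beats_scores_zero(self):
        assert segment_sqis(0, 100, []) == (0.0, 0.0, 0.0, 0.0)

    def test_beats_use_their_own_window_template(self):
        """Two windows with orthogonal templates: scores follow the assignment."""
        fs = 4000.0
        win = int(15 * fs)
        up = _norm(np.linspace(0, 1, 100))
        osc = _norm(np.sin(np.linspace(0, 6 * np.pi, 100)))
        cycles = ([_cycle(up, k * 110) for k in range(60)]
                  + [_cycle(osc, win + k * 110) for k in range(60)])
        templates = build_templates(cycles, fs, n_windows=2)
        sqis = score_beats(cycles, templates, fs)
        first = [s.sqi1 for s in sqis if s.window_index == 0]
        second = [s.sqi1 for s in sqis if s.window_index == 1]
        assert np.min(first) > 0.99 and np.min(second) > 0.99
        # cross-check: the other window's template would not match
        cross = sqi1_direct(_cycle(up), templates[1])
        assert cross < 0.5
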