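import numpy as np
import pytest

from ela.lsa import (local_similarity, ls_magnitude, ls_score_cutoff,
                     permutation_pvalue_ls, screen_pairs, theoretical_pvalue)
from ela.normalize import rank_normal_transform


def brute_force_ls(zx, zy, max_delay=0):
    """Exhaustive enumeration over all offsets and intervals (test oracle).

    Implements the same tie-break chain as the dynamic program: higher score,
    positive over negative, smaller |delay| (negative offset first), earliest
    start, shortest segment.
    """
    zx = np.asarray(zx, float)
    zy = np.asarray(zy, float)
    n = zx.size
    candidates = []
    for d in range(-max_delay, max_delay + 1):
        i0, i1 = max(0, -d), n - 1 - max(0, d)
        prod = zx[i0:i1 + 1] * zy[i0 + d:i1 + d + 1]
        L = prod.size
        for a in range(L):
            seg = 0.0
            for b in range(a, L):
                # left-to-right running sum: the same rounding sequence as a
                # sequential accumulator, so scores are bit-identical
                seg += float(prod[b])
                for score, sign in ((seg, "+"), (-seg, "-")):
                    if score >= 0:
                        candidates.append((
                            (-score, 0 if sign == "+" else 1, abs(d),
                             0 if d < 0 else 1, i0 + a, b - a),
                            (score, sign, (i0 + a + 1, i0 + b + 1), d),
                        ))
    # the empty segment (score 0) is always available
    candidates.append(((0.0, 0, 0, 1, 0, 0), (0.0, "+", (1, 1), 0)))
    key, (score, sign, interval, d) = min(candidates, key=lambda c: c[0])
    ls = score / n if sign == "+" else -score / n
    return ls, sign, interval, d


class TestLocalSimilarity:
    def test_self_products_take_whole_series(self):
        ls, sign, interval, d = local_similarity([1, -1, 2], [1, -1, 2])
        assert (ls, sign, interval, d) == (2.0, "+", (1, 3), 0)

    def test_antisymmetric_pair(self):
        ls, sign, interval, d = local_similarity([1, -1, 2], [-1, 1, -2])
        assert (ls, sign, interval, d) == (-2.0, "-", (1, 3), 0)

    def test_partial_segment_optimum(self):
        # products (1, -2, 3, -1, 2): best |segment sum| = 4 on positions 3..5
        ls, sign, interval, d = local_similarity([1, 2, 3, 1, 2],
                                                 [1, -1, 1, -1, 1])
        assert ls == pytest.approx(0.8)
        assert sign == "+" and interval == (3, 5) and d == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            local_similarity([1, 2], [1, 2, 3])

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError, match="max_delay"):
            local_similarity([1, 2, 3], [1, 2, 3], max_delay=3)

    @pytest.mark.parametrize("max_delay", [0, 1, 2])
    def test_dp_equals_brute_force(self, rng, max_delay):
        for _ in range(120):
            n = int(rng.integers(4, 16))
            zx = rng.standard_normal(n)
            zy = rng.standard_normal(n)
            assert local_similarity(zx, zy, max_delay) == \
                brute_force_ls(zx, zy, max_delay)

    def test_symmetry_at_zero_delay(self, rng):
        for _ in range(50):
            zx, zy = rng.standard_normal((2, 20))
            assert local_similarity(zx, zy) == local_similarity(zy, zx)

    def test_scale_quadratic_in_common_factor(self, rng):
        zx, zy = rng.standard_normal((2, 30))
        ls1 = local_similarity(zx, zy)[0]
        ls2 = local_similarity(2.5 * zx, 2.5 * zy)[0]
        assert ls2 == pytest.approx(2.5 ** 2 * ls1)

    def test_magnitude_shortcut_matches_dp(self, rng):
        for max_delay in (0, 1, 3):
            for _ in range(30):
                zx, zy = rng.standard_normal((2, 25))
                assert ls_magnitude(zx, zy, max_delay) == pytest.approx(
                    abs(local_similarity(zx, zy, max_delay)[0]), abs=1e-12
                )

    def test_all_zero_series_is_flat_zero(self):
        ls, sign, interval, d = local_similarity(np.zeros(5), np.zeros(5))
        assert (ls, sign, interval, d) == (0.0, "+", (1, 1), 0)


class TestTheoreticalPvalue:
    def test_zero_score_gives_one(self):
        assert theoretical_pvalue(0.0, 120) == 1.0

    def test_monotone_nonincreasing_in_score(self):
        ps = [theoretical_pvalue(ls, 120) for ls in np.arange(0, 1.5, 0.01)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-8

    def test_more_delays_cannot_reduce_p(self):
        for ls in (0.2, 0.3, 0.4):
            p0 = theoretical_pvalue(ls, 100, max_delay=0)
            p1 = theoretical_pvalue(ls, 100, max_delay=1)
            p3 = theoretical_pvalue(ls, 100, max_delay=3)
            assert p0 <= p1 <= p3

    def test_matches_permutation_at_observed_score(self, null_pair):
        zx, zy = null_pair(50)
        obs = ls_magnitude(zx.z, zy.z)
        p_theo = theoretical_pvalue(obs, 50)
        p_perm = permutation_pvalue_ls(zx.z, zy.z, n_perm=20_000, seed=11,
                                       observed=obs)
        se = np.sqrt(p_perm * (1 - p_perm) / 20_000)
        assert abs(p_theo - p_perm) <= 3 * max(se, 1e-4)

    def test_type_one_error_calibration_n120(self, rng):
        """Empirical rejection of 'p <= alpha' under the Gaussian null."""
        n, reps = 120, 2000
        rejections = {0.05: 0, 0.01: 0}
        for _ in range(reps):
            zx = rank_normal_transform(rng.standard_normal(n)).z
            zy = rank_normal_transform(rng.standard_normal(n)).z
            p = theoretical_pvalue(ls_magnitude(zx, zy), n)
            for alpha in rejections:
                rejections[alpha] += p <= alpha
        for alpha, count in rejections.items():
            rate = count / reps
            band = 3 * np.sqrt(alpha * (1 - alpha) / reps)
            assert abs(rate - alpha) <= band, (alpha, rate)

    def test_cutoff_inversion_is_stable(self):
        cut = ls_score_cutoff(120, p_cut=0.001)
        assert theoretical_pvalue(cut, 120) <= 0.001
        assert theoretical_pvalue(cut - 0.01, 120) > 0.001

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            theoretical_pvalue(0.5, 1)


class TestPermutationPvalue:
    def test_floor_for_perfect_association(self):
        t = np.linspace(0, 4 * np.pi, 40)
        zx = rank_normal_transform(np.sin(t) + 0.01 * np.cos(3 * t)).z
        p = permutation_pvalue_ls(zx, zx, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_same_seed_reproduces(self, null_pair):
        zx, zy = null_pair(30)
        p1 = permutation_pvalue_ls(zx.z, zy.z, n_perm=500, seed=42)
        p2 = permutation_pvalue_ls(zx.z, zy.z, n_perm=500, seed=42)
        assert p1 == p2

    def test_null_p_approximately_uniform(self, rng):
        """KS-style sanity: permutation p under the null is near-uniform."""
        n, reps = 30, 400
        pvals = np.empty(reps)
        for i in range(reps):
            zx = rank_normal_transform(rng.standard_normal(n)).z
            zy = rank_normal_transform(rng.standard_normal(n)).z
            pvals[i] = permutation_pvalue_ls(zx, zy, n_perm=200, seed=int(i))
        grid = np.linspace(0.05, 0.95, 10)
        ecdf = np.array([(pvals <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 4 * np.sqrt(0.25 / reps) + 1 / 200

    def test_minimum_permutations_enforced(self, null_pair):
        zx, zy = null_pair(20)
        with pytest.raises(ValueError):
            permutation_pvalue_ls(zx.z, zy.z, n_perm=50)


def _normalize_matrix(data):
    return {
        f"F{i:02d}": rank_normal_transform(row, f"F{i:02d}")
        for i, row in enumerate(data)
    }


class TestScreenPairs:
    def test_null_factors_yield_no_survivors(self, rng):
        hits = 0
        for _ in range(3):
            normalized = _normalize_matrix(rng.standard_normal((10, 120)))
            hits += len(screen_pairs(normalized))
        assert hits == 0

    def test_planted_pair_survives_with_wide_interval(self, rng):
        data = rng.standard_normal((21, 120))
        data[1] = data[0] + 0.2 * rng.standard_normal(120)
        normalized = _normalize_matrix(data)
        survivors = screen_pairs(normalized)
        assert {(s.x_id, s.y_id) for s in survivors} == {("F00", "F01")}
        s = survivors[0]
        assert s.span > 60 and s.sign == "+" and s.delay == 0
        assert s.p <= 0.001 and s.q <= 0.05

    def test_span_filter_excludes_short_association(self, rng):
        # correlated only on the first 30% of timepoints
        n = 120
        data = rng.standard_normal((6, n))
        data[1, :36] = data[0, :36] + 0.05 * rng.standard_normal(36)
        normalized = _normalize_matrix(data)
        pair = local_similarity(normalized["F00"], normalized["F01"])
        span = pair[2][1] - pair[2][0] + 1
        survivors = screen_pairs(normalized)
        if span <= 0.5 * n:
            assert ("F00", "F01") not in {(s.x_id, s.y_id) for s in survivors}
        # the reported interval matches the exhaustive oracle
        assert pair == brute_force_ls(normalized["F00"].z, normalized["F01"].z)

    def test_needs_two_factors(self, rng):
        normalized = _normalize_matrix(rng.standard_normal((1, 50)))
        with pytest.raises(ValueError, match="two factors"):
            screen_pairs(normalized)

    def test_perm_method_agrees_on_survivor_set(self, rng):
        data = rng.standard_normal((8, 80))
        data[1] = data[0] + 0.15 * rng.standard_normal(80)
        normalized = _normalize_matrix(data)
        theo = screen_pairs(normalized, p_method="theo")
        perm = screen_pairs(normalized, p_method="perm", n_perm=2000, seed=3)
        assert {(s.x_id, s.y_id) for s in theo} == \
            {(s.x_id, s.y_id) for s in perm} == {("F00", "F01")}
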