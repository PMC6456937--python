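import itertools
import math

import numpy as np
import pytest

from ela.liquid import (classify_la_type, la_permutation_test, la_score,
                        scan_all_mediators, scan_mediators)
from ela.lsa import PairAssociation, local_similarity
from ela.normalize import rank_normal_transform
from ela.simulate import simulate_mediated_triplet


class TestLaScore:
    def test_odd_symmetry_cancels(self):
        assert la_score([1, -1], [1, -1], [1, -1]) == 0.0

    def test_direct_arithmetic(self):
        assert la_score([1, 1, -1], [1, -1, -1], [3, 0, 3]) == 2.0

    def test_three_way_symmetry_machine_precision(self, rng):
        for _ in range(200):
            x, y, z = rng.standard_normal((3, 37))
            ref = la_score(x, y, z)
            assert la_score(z, y, x) == ref
            assert la_score(y, x, z) == ref
            assert la_score(x, z, y) == ref

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            la_score([1, 2], [1, 2], [1, 2, 3])

    def test_null_mean_near_zero(self, rng):
        """E[LA] = 0 under independence: mean over many null triplets."""
        reps, m = 10_000, 120
        x = rng.standard_normal((reps, m))
        y = rng.standard_normal((reps, m))
        z = rng.standard_normal((reps, m))
        las = np.mean(x * y * z, axis=1)
        se = las.std() / math.sqrt(reps)
        assert abs(las.mean()) <= 4 * se


class TestLaPermutationTest:
    def test_degenerate_mediator_gives_p_one(self, rng):
        x, y = rng.standard_normal((2, 30))
        assert la_permutation_test(x, y, np.zeros(30), n_perm=200, seed=0) == 1.0

    def test_same_seed_reproduces(self, rng):
        x, y, z = rng.standard_normal((3, 40))
        args = dict(n_perm=500, seed=7)
        assert la_permutation_test(x, y, z, **args) == \
            la_permutation_test(x, y, z, **args)

    def test_matches_exhaustive_enumeration_at_m6(self, rng):
        x, y, z = rng.standard_normal((3, 6))
        obs = abs(la_score(x, y, z))
        xy = x * y
        exact_stats = [
            abs(np.dot(xy, z[list(perm)]) / 6)
            for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean([s >= obs - 1e-12 for s in exact_stats])
        p_sampled = la_permutation_test(x, y, z, n_perm=20_000, seed=5)
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_sampled - p_exact) <= 3 * se + 1e-4

    def test_invariant_under_joint_permutation(self, rng):
        x, y, z = rng.standard_normal((3, 50))
        perm = rng.permutation(50)
        p1 = la_permutation_test(x, y, z, n_perm=500, seed=9)
        p2 = la_permutation_test(x[perm], y[perm], z[perm], n_perm=500, seed=9)
        assert p1 == p2

    def test_one_sided_counts_upper_tail(self, rng):
        z, y = rng.standard_normal((2, 120))
        x = -z * y + 0.3 * rng.standard_normal(120)  # strongly negative LA
        p_two = la_permutation_test(x, y, z, n_perm=1000, seed=2)
        p_one = la_permutation_test(x, y, z, n_perm=1000, seed=2, one_sided=True)
        assert p_two <= 0.01 and p_one > 0.5

    def test_minimum_permutations(self, rng):
        x, y, z = rng.standard_normal((3, 20))
        with pytest.raises(ValueError):
            la_permutation_test(x, y, z, n_perm=10)


class TestClassifyLaType:
    @pytest.mark.parametrize("ls,la,expected", [
        ("+", "+", "A"), ("-", "+", "B"), ("+", "-", "C"), ("-", "-", "D"),
    ])
    def test_mapping_is_the_documented_bijection(self, ls, la, expected):
        assert classify_la_type(ls, la) == expected

    def test_all_four_types_hit(self):
        types = {classify_la_type(a, b)
                 for a in "+-" for b in "+-"}
        assert types == {"A", "B", "C", "D"}

    def test_zero_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_la_type("0", "+")

    def test_conditional_correlation_matches_types_a_and_b(self, rng):
        """Simulated data split at the mediator's median reproduces the
        sign structure that defines types A and B."""
        n = 4000
        # type A: X, Y correlate positively only where Z is high
        z = rng.standard_normal(n)
        y = rng.standard_normal(n)
        x = np.where(z > 0, y, rng.standard_normal(n)) + 0.5 * rng.standard_normal(n)
        la = la_score(x - x.mean(), y, z)
        r_hi = np.corrcoef(x[z > 0], y[z > 0])[0, 1]
        r_all = np.corrcoef(x, y)[0, 1]
        assert la > 0 and r_hi > 0 and r_all > 0
        assert classify_la_type("+", "+") == "A"
        # type B: X, Y correlate negatively only where Z is low
        x2 = np.where(z < 0, -y, rng.standard_normal(n)) + 0.5 * rng.standard_normal(n)
        la2 = la_score(x2 - x2.mean(), y, z)
        assert la2 > 0 and np.corrcoef(x2, y)[0, 1] < 0
        assert classify_la_type("-", "+") == "B"


def _normalized_community(data):
    return {
        f"F{i:02d}": rank_normal_transform(row, f"F{i:02d}")
        for i, row in enumerate(data)
    }


def _planted_pair_assoc(normalized, x_id, y_id):
    ls, _, (a, b), d = local_similarity(normalized[x_id], normalized[y_id])
    return PairAssociation(x_id=x_id, y_id=y_id, ls=ls, interval_start=a,
                           interval_end=b, delay=d, p=1e-4, q=1e-3)


class TestScanMediators:
    def _community_with_triplet(self, seed, n_null=20):
        x, y, z, _ = simulate_mediated_triplet(120, "A", beta=1.0,
                                               noise_sd=0.5, seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        data = np.vstack([x, y, z, rng.standard_normal((n_null, 120))])
        return _normalized_community(data)

    def test_planted_mediator_found_among_nulls(self):
        hits = 0
        for seed in range(10):
            normalized = self._community_with_triplet(seed)
            pair = _planted_pair_assoc(normalized, "F00", "F01")
            found = scan_mediators(pair, normalized, n_perm=1000, seed=seed)
            if [t.z_id for t in found] == ["F02"]:
                assert found[0].la_type == "A"
                hits += 1
        assert hits >= 9

    def test_candidates_exclude_the_pair_itself(self, rng):
        normalized = _normalized_community(rng.standard_normal((6, 60)))
        pair = _planted_pair_assoc(normalized, "F01", "F03")
        scanned = scan_mediators(pair, normalized, n_perm=200, seed=0,
                                 return_all=True)
        assert {t.z_id for t in scanned} == {"F00", "F02", "F04", "F05"}
        assert all(t.z_id not in ("F01", "F03") for t in scanned)

    def test_effect_cutoff_semantics(self):
        normalized = self._community_with_triplet(3)
        pair = _planted_pair_assoc(normalized, "F00", "F01")
        loose = scan_mediators(pair, normalized, n_perm=1000, seed=3)
        strict = scan_mediators(pair, normalized, n_perm=1000, seed=3,
                                la_effect_cut=0.8)
        assert {t.z_id for t in strict} <= {t.z_id for t in loose}
        assert all(abs(t.la) >= 0.8 for t in strict)
        # a triplet below the cutoff never survives the stricter scan
        below = [t for t in loose if abs(t.la) < 0.8]
        assert all(t.z_id not in {s.z_id for s in strict} for t in below)

    def test_pooled_family_spans_all_pairs(self, rng):
        data = rng.standard_normal((8, 80))
        data[1] = data[0] + 0.2 * rng.standard_normal(80)
        data[3] = data[2] + 0.2 * rng.standard_normal(80)
        normalized = _normalized_community(data)
        pairs = [_planted_pair_assoc(normalized, "F00", "F01"),
                 _planted_pair_assoc(normalized, "F02", "F03")]
        _, n_tested = scan_all_mediators(pairs, normalized, n_perm=200, seed=1)
        assert n_tested == 2 * (8 - 2)


class TestEffectRecovery:
    def test_la_increases_with_coupling_strength(self):
        """Monte-Carlo averaged |LA| is strictly increasing in beta for the
        multiplicative mediation model x = beta * z * y + noise."""
        betas = [0.0, 0.25, 0.5, 1.0]
        means = []
        for beta in betas:
            scores = []
            for seed in range(60):
                x, y, z, truth = simulate_mediated_triplet(
                    120, "A", beta=beta, noise_sd=1.0, seed=seed, baseline=0.0
                )
                zx = rank_normal_transform(x).z
                zy = rank_normal_transform(y).z
                zz = rank_normal_transform(z).z
                scores.append(la_score(zx, zy, zz))
            means.append(np.mean(scores))
        assert all(b > a for a, b in zip(means, means[1:]))
        # sign matches the planted type-A pattern (positive LA)
        assert means[-1] > 0
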