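"""Differential counts: normalisation, dispersion, exact test, BH, calls."""

import math

import numpy as np
import pandas as pd
import pytest

from g4access.differential import CountMatrix, DifferentialResult, bh_adjust, \
    call_differential, estimate_dispersion, log_cpm, nb_exact_test, \
    run_differential, size_factors
from g4access.simulate import draw_counts


def _matrix(mat, conditions=("A", "A", "A", "B", "B", "B")):
    mat = np.asarray(mat)
    samples = [f"s{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=[f"r{i}" for i in range(mat.shape[0])],
                      columns=samples)
    return CountMatrix(df, dict(zip(samples, conditions)))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(10, 500, size=100)
        f = size_factors(np.column_stack([col, col, col]))
        assert f == pytest.approx(np.ones(3))

    def test_doubled_sample_gives_factor_ratio_two(self, rng):
        col = rng.integers(10, 500, size=100)
        f = size_factors(np.column_stack([col, 2 * col]))
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_sample_factor_one(self, rng):
        f = size_factors(rng.integers(1, 100, size=(60, 1)))
        assert f == pytest.approx([1.0])

    def test_fallback_to_totals_with_sparse_matrix(self, rng):
        # zeros everywhere leave <50 usable regions
        mat = rng.integers(0, 2, size=(60, 2)) * rng.integers(1, 50, (60, 2))
        mat[0] = [100, 300]
        f = size_factors(mat)
        totals = mat.sum(axis=0)
        assert f[1] / f[0] == pytest.approx(totals[1] / totals[0])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive total"):
            size_factors(np.zeros((10, 2)))


class TestLogCpm:
    def test_zero_count_in_million_read_library(self):
        counts = np.array([[0], [1_000_000]])
        vals = log_cpm(counts, np.ones(1))
        assert vals[0, 0] == pytest.approx(-1.0, abs=1e-3)

    def test_scale_invariance_at_large_counts(self):
        base = np.array([[4000.0], [996_000.0]])
        v1 = log_cpm(base, np.ones(1))
        v2 = log_cpm(2 * base, np.ones(1))
        assert v1[0, 0] == pytest.approx(v2[0, 0], abs=1e-3)

    def test_monotone_in_count(self):
        counts = np.array([[10, 20], [1000, 1000]])
        vals = log_cpm(counts, np.ones(2))
        assert vals[0, 0] < vals[0, 1]

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_cpm(np.ones((2, 1)), np.zeros(1))


class TestEstimateDispersion:
    def test_poisson_counts_estimate_near_zero(self, rng):
        counts = rng.poisson(200, size=(10_000, 6))
        disp = estimate_dispersion(counts, ["A"] * 3 + ["B"] * 3)
        assert disp.mean() <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        phi = 0.4
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + 200), size=(10_000, 6))
        disp = estimate_dispersion(counts, ["A"] * 3 + ["B"] * 3)
        assert 0.3 <= disp.mean() <= 0.5

    def test_constant_counts_floored_and_pool_dominated(self, rng):
        counts = rng.poisson(100, size=(200, 6))
        counts[0] = 50  # zero variance within both conditions
        disp = estimate_dispersion(counts, ["A"] * 3 + ["B"] * 3)
        assert disp[0] >= 1e-6
        assert disp[0] == disp.min()  # only the shared pool term remains

    def test_unreplicated_design_warns_and_returns_zero(self, rng):
        counts = rng.poisson(50, size=(20, 2))
        with pytest.warns(UserWarning, match="replicates"):
            disp = estimate_dispersion(counts, ["A", "B"])
        assert (disp == 0).all()


class TestNbExactTest:
    def test_equal_split_gives_p_one(self):
        p, lfc = nb_exact_test([5], [5])
        assert p == 1.0 and lfc == 0.0

    def test_extreme_split_matches_closed_form(self):
        p, _ = nb_exact_test([100], [0])
        assert p == pytest.approx(2 * 0.5 ** 100, rel=1e-9)

    def test_log2fc_prior_count(self):
        _, lfc = nb_exact_test([5], [20])
        assert lfc == pytest.approx(math.log2(20.5 / 5.5), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nb_exact_test([-1], [3])

    @pytest.mark.parametrize("dispersion", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, dispersion, rng):
        """Full enumeration of conditional split probabilities, written
        with scalar lgamma arithmetic independent of the implementation."""
        def nb_logpmf(x, r, mu):
            if r == math.inf:
                return x * math.log(mu) - mu - math.lgamma(x + 1)
            p = r / (r + mu)
            return (math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1)
                    + r * math.log(p) + x * math.log(1 - p))

        for _ in range(25):
            n_a, n_b = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            a = rng.integers(0, 40, size=n_a)
            b = rng.integers(0, 40, size=n_b)
            total = int(a.sum() + b.sum())
            if total == 0 or total > 200:
                continue
            frac = n_a / (n_a + n_b)
            if dispersion == 0:
                logs = [math.lgamma(total + 1) - math.lgamma(i + 1)
                        - math.lgamma(total - i + 1)
                        + i * math.log(frac) + (total - i) * math.log(1 - frac)
                        for i in range(total + 1)]
            else:
                ra, rb = n_a / dispersion, n_b / dispersion
                mu_a = total * frac
                logs = [nb_logpmf(i, ra, mu_a)
                        + nb_logpmf(total - i, rb, total - mu_a)
                        for i in range(total + 1)]
            z = max(logs)
            probs = [math.exp(v - z) for v in logs]
            norm = sum(probs)
            obs = probs[int(a.sum())]
            expected = min(sum(q for q in probs if q <= obs * (1 + 1e-9))
                           / norm, 1.0)
            p, _ = nb_exact_test(a, b, dispersion=dispersion)
            assert p == pytest.approx(expected, abs=1e-12)


class TestBhAdjust:
    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_hand_step_up_on_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, size=m)
            order = np.argsort(p)
            q_sorted = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                running = min(running, p[order[rank - 1]] * m / rank)
                q_sorted[rank - 1] = running
            expected = np.empty(m)
            expected[order] = q_sorted
            assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_monotone_along_sorted_p(self, rng):
        p = rng.uniform(0, 1, size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDifferential:
    def _result(self, fdr, lfc):
        return DifferentialResult("r", lfc, 5.0, fdr / 2, fdr,
                                  "increased" if lfc > 0 else "reduced")

    def test_dar_threshold(self):
        (r,) = call_differential([self._result(0.05, 0.5)])
        assert r.is_significant_dar and not r.is_significant_deg

    def test_deg_needs_both_fdr_and_lfc(self):
        (r,) = call_differential([self._result(0.01, 1.0)])
        assert not r.is_significant_deg
        (r,) = call_differential([self._result(0.01, 2.5)])
        assert r.is_significant_deg

    def test_neither_above_thresholds(self):
        (r,) = call_differential([self._result(0.2, 3.0)])
        assert not r.is_significant_dar and not r.is_significant_deg


class TestEndToEndRecovery:
    def test_planted_effects_recovered_with_correct_signs(self, rng):
        n, n_true = 600, 30
        mu = np.full(n, 200.0)
        lfc = np.zeros(n)
        lfc[:n_true // 2] = 2.0
        lfc[n_true // 2:n_true] = -2.0
        cols = []
        for j in range(6):
            mean = mu * np.power(2.0, lfc) if j >= 3 else mu
            cols.append(draw_counts(mean, 0.1, rng))
        res = run_differential(_matrix(np.column_stack(cols)))
        flagged = {r.region_id for r in res if r.is_significant_dar}
        true_ids = {f"r{i}" for i in range(n_true)}
        assert len(flagged & true_ids) >= 0.7 * n_true
        null_fp = len(flagged - true_ids) / (n - n_true)
        assert null_fp <= 0.02
        for r in res:
            if r.region_id in flagged & true_ids:
                planted = lfc[int(r.region_id[1:])]
                assert np.sign(r.log2fc) == np.sign(planted)
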