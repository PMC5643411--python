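"""Clone-size spectra, power-law MLE, diversity indices, subsampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from umitcr.repstats import (
    AbundanceDistribution,
    fit_power_law,
    gini,
    inverse_simpson,
    remove_shared,
    sample_power_law,
    search_annotated_cdr3,
    shannon_entropy,
    size_spectrum,
    subsample,
    top_k_queries,
)

D = AbundanceDistribution.from_sizes

sizes_strategy = st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=60)


class TestSpectrum:
    def test_proportions(self):
        spec = size_spectrum(D([1, 1, 1, 2]))
        assert spec.to_dict("records") == [
            {"abundance": 1, "proportion": 0.75},
            {"abundance": 2, "proportion": 0.25},
        ]

    def test_mostly_singletons(self):
        spec = size_spectrum(D([1] * 95 + [2] * 4 + [10]))
        assert spec.loc[spec.abundance == 1, "proportion"].item() == 0.95

    def test_empty_distribution_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            size_spectrum(D([]))


class TestPowerLaw:
    def test_closed_form_estimator_hand_value(self):
        # 1 + 5 / (4 ln 2 + ln 4) on sizes [1,1,1,1,2]
        fit = fit_power_law(D([1, 1, 1, 1, 2]), x_min=1, method="approx")
        assert fit.exponent == pytest.approx(1 + 5 / (6 * math.log(2)), rel=1e-12)
        assert fit.exponent == pytest.approx(2.2022, abs=1e-4)

    @pytest.mark.parametrize("b,tol", [(2.0, 0.05), (3.0, 0.05)])
    def test_exact_mle_recovers_the_exponent(self, b, tol):
        sample = sample_power_law(b, 20_000, rng=7)
        fit = fit_power_law(sample, x_min=1)
        assert abs(fit.exponent - b) < tol
        assert fit.n_tail == 20_000
        assert 0 <= fit.ks_distance <= 1

    def test_degenerate_tail_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law(D([3, 3, 3]), x_min=3)

    def test_automatic_x_min_avoids_a_distorted_head(self):
        rng = np.random.default_rng(3)
        body = np.ones(1500, dtype=np.int64)  # excess singleton mass
        tail = sample_power_law(2.5, 4000, rng=rng).sizes
        fit = fit_power_law(D(np.concatenate([body, tail])))
        # above the distorted head the sample is exactly zeta-distributed,
        # so KS minimization must move the cutoff off the singletons
        assert fit.x_min > 1
        assert fit.ks_distance < 0.05
        assert abs(fit.exponent - 2.5) < 0.25


class TestDiversityClosedForms:
    def test_gini_zero_for_equal_clones(self):
        assert gini(D([5, 5, 5, 5])) == pytest.approx(0.0)

    def test_gini_hand_value(self):
        assert gini(D([1, 1, 1, 97])) == pytest.approx(0.72)

    def test_shannon_of_k_equal_clones_is_ln_k(self):
        assert shannon_entropy(D([7] * 4)) == pytest.approx(math.log(4))
        assert shannon_entropy(D([3])) == 0.0
        assert shannon_entropy(D([1, 1, 2])) == pytest.approx(1.0397, abs=1e-4)
        assert shannon_entropy(D([7] * 4), base="bits") == pytest.approx(2.0)

    def test_inverse_simpson_closed_forms(self):
        assert inverse_simpson(D([9] * 6)) == pytest.approx(6.0)
        assert inverse_simpson(D([42])) == pytest.approx(1.0)
        assert inverse_simpson(D([1, 1, 2])) == pytest.approx(8 / 3)

    @given(sizes_strategy)
    @settings(max_examples=40, derandomize=True)
    def test_indices_invariant_under_relabeling(self, sizes):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(sizes))
        for fn in (gini, shannon_entropy, inverse_simpson):
            assert fn(D(sizes)) == pytest.approx(fn(D(shuffled)))

    @given(sizes_strategy)
    @settings(max_examples=40, derandomize=True)
    def test_index_ranges(self, sizes):
        d = D(sizes)
        assert 0 <= gini(d) < 1
        assert -1e-12 <= shannon_entropy(d) <= math.log(d.n_clones) + 1e-9
        assert 1 - 1e-9 <= inverse_simpson(d) <= d.n_clones + 1e-9

    def test_uniform_distribution_is_the_diversity_extreme(self):
        rng = np.random.default_rng(5)
        n, total = 20, 400
        uniform = D([total // n] * n)
        for _ in range(30):
            # random composition of `total` into n positive parts
            cuts = np.sort(rng.choice(np.arange(1, total), size=n - 1, replace=False))
            parts = np.diff(np.concatenate([[0], cuts, [total]]))
            other = D(parts)
            assert gini(uniform) <= gini(other) + 1e-12
            assert shannon_entropy(uniform) >= shannon_entropy(other) - 1e-12
            assert inverse_simpson(uniform) >= inverse_simpson(other) - 1e-9


class TestSubsample:
    def test_exact_depth_and_absent_zero_clones(self):
        d = D([100, 1])
        sub = subsample(d, 50, rng=0)
        assert sub.n_molecules == 50
        assert all(sub.sizes >= 1)

    def test_full_depth_returns_everything(self):
        d = D([4, 3, 2])
        sub = subsample(d, 9, rng=0)
        assert sorted(sub.sizes) == [2, 3, 4]

    def test_single_molecule(self):
        sub = subsample(D([5, 5]), 1, rng=0)
        assert sub.n_clones == 1 and sub.n_molecules == 1

    def test_depth_beyond_repertoire_is_an_error(self):
        with pytest.raises(ValueError):
            subsample(D([3]), 4)

    def test_expected_share_is_hypergeometric(self):
        d = D([500, 500])
        shares = []
        for seed in range(200):
            sub = subsample(d, 100, rng=seed)
            full = np.zeros(2)
            full[: sub.n_clones] = np.sort(sub.sizes)[::-1]
            shares.append(max(sub.sizes) / 100)
        # mean share of the larger draw ~ E[max(X, 100-X)]; X ~ Hypergeom
        assert 0.5 <= float(np.mean(shares)) < 0.56


class TestOverlapAndSearch:
    def test_disjoint_sets_untouched(self):
        naive = {"A": 5, "B": 1}
        assert remove_shared(naive, [{"C"}, {"D"}]) == naive

    def test_naive_subset_of_memory_empties(self):
        assert remove_shared({"A": 1}, [{"A", "B"}]) == {}

    def test_shared_clone_removed_abundances_kept(self):
        assert remove_shared({"A": 5, "B": 1}, [{"A"}]) == {"B": 1}

    def test_search_matrix_matches_linear_scan(self):
        reps = {
            "naive": {"CASSF": 2, "CGGGF": 1},
            "memory": {"CASSF": 7},
        }
        queries = ["CASSF", "CGGGF", "CAAAF"]
        matrix = search_annotated_cdr3(reps, queries)
        for q in queries:
            for name, rep in reps.items():
                assert matrix.loc[q, name] == rep.get(q, 0)
        top = top_k_queries(matrix, 1)
        assert list(top.index) == ["CASSF"]
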