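"""Hill numbers, coverage, rarefaction/extrapolation, similarity indices and
the ecotype-specificity permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stenella.diversity import (
    AbundanceVector,
    chao1,
    coverage_at_size,
    coverage_re_curves,
    diversity_at_coverage,
    diversity_at_size,
    ecotype_specificity_test,
    hill_asymptotic,
    hill_observed,
    horn_morisita,
    rarefied_richness,
    rarefied_richness_bruteforce,
    rarefied_shannon_bruteforce,
    sample_coverage,
    _bootstrap_assemblage,
)

counts_strategy = st.lists(st.integers(1, 12), min_size=1, max_size=25)


class TestHillObserved:
    def test_uniform_assemblage_all_orders(self):
        a = AbundanceVector.from_counts([5] * 10)
        for q in (0, 1, 2):
            assert hill_observed(a, q) == pytest.approx(10.0)

    def test_nine_one_hand_arithmetic(self):
        a = AbundanceVector.from_counts([9, 1])
        assert hill_observed(a, 0) == 2
        assert hill_observed(a, 2) == pytest.approx(1 / 0.82)

    def test_single_category(self):
        a = AbundanceVector.from_counts([7])
        for q in (0, 1, 2):
            assert hill_observed(a, q) == pytest.approx(1.0)

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            hill_observed(AbundanceVector.from_counts([3]), 3)

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_weakly_decreasing_in_q(self, counts):
        a = AbundanceVector.from_counts(counts)
        d0, d1, d2 = (hill_observed(a, q) for q in (0, 1, 2))
        assert d0 + 1e-9 >= d1 >= d2 - 1e-9


class TestAsymptotics:
    def test_no_singletons_chao1_equals_observed(self):
        a = AbundanceVector.from_counts([3, 4, 5])
        assert chao1(a) == a.s_obs

    def test_chao1_hand_formula(self):
        a = AbundanceVector.from_counts([3, 3, 2, 1, 1])  # S=5, n=10, f1=2, f2=1
        assert chao1(a) == pytest.approx(6.8)

    def test_saturated_sample_asymptotic_near_observed(self):
        # large per-category counts: the O(1/x) entropy bias correction is small
        a = AbundanceVector.from_counts([100] * 8)
        for q in (0, 1, 2):
            est, unreliable = hill_asymptotic(a, q)
            assert est == pytest.approx(hill_observed(a, q), rel=0.02)
            assert not unreliable

    def test_all_singletons_flagged(self):
        a = AbundanceVector.from_counts([1] * 6)
        _, unreliable = hill_asymptotic(a, 0)
        assert unreliable

    def test_q0_asymptotic_at_least_observed(self):
        a = AbundanceVector.from_counts([5, 2, 1, 1, 1])
        est, _ = hill_asymptotic(a, 0)
        assert est >= hill_observed(a, 0)

    def test_chao1_recovers_zipf_richness_within_bootstrap_ci(self):
        """On Zipf assemblages (S=200, n=2000) the Chao1 +/- bootstrap CI
        covers the true richness in most replicates."""
        rng = np.random.default_rng(0)
        S, n = 200, 2000
        p = 1.0 / np.arange(1, S + 1)
        p /= p.sum()
        hits = 0
        reps = 25
        for _ in range(reps):
            counts = rng.multinomial(n, p)
            a = AbundanceVector.from_counts(counts[counts > 0])
            est = chao1(a)
            probs = _bootstrap_assemblage(a)
            boots = []
            for _ in range(150):
                c = rng.multinomial(a.n, probs)
                boots.append(chao1(AbundanceVector.from_counts(c[c > 0])))
            se = np.std(boots, ddof=1)
            hits += est - 1.96 * se <= S <= est + 1.96 * se
        assert hits / reps >= 0.8


class TestCoverage:
    def test_no_singletons_full_coverage(self):
        assert sample_coverage(AbundanceVector.from_counts([2, 3, 4])) == 1.0

    def test_hand_formula(self):
        a = AbundanceVector.from_counts([3, 3, 2, 1, 1])
        assert sample_coverage(a) == pytest.approx(0.82)

    def test_all_singletons_zero_coverage(self):
        assert sample_coverage(AbundanceVector.from_counts([1] * 5)) == pytest.approx(0.0)

    @given(counts_strategy, st.integers(1, 30))
    @settings(max_examples=40, deadline=None)
    def test_coverage_nondecreasing_in_m(self, counts, m):
        a = AbundanceVector.from_counts(counts)
        m = min(m, 2 * a.n - 1)
        if m >= 1:
            assert coverage_at_size(a, m + 1) >= coverage_at_size(a, m) - 1e-9


class TestRarefactionExtrapolation:
    def test_endpoint_identity(self):
        a = AbundanceVector.from_counts([4, 3, 2, 1])
        for q in (0, 1, 2):
            assert diversity_at_size(a, q, a.n) == pytest.approx(hill_observed(a, q), rel=1e-9)

    def test_single_individual(self):
        a = AbundanceVector.from_counts([5, 3, 2])
        assert diversity_at_size(a, 0, 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [[3, 2, 1], [5, 4, 1, 1], [2, 2, 2, 2]])
    @pytest.mark.parametrize("m", [2, 4, 6])
    def test_q0_matches_exhaustive_subsampling(self, counts, m):
        """Expected richness under subsampling equals the brute-force average
        over every subsample (oracle, n <= 12)."""
        a = AbundanceVector.from_counts(counts)
        m = min(m, a.n)
        assert rarefied_richness(a, m) == pytest.approx(
            rarefied_richness_bruteforce(a, m), rel=1e-9
        )

    @pytest.mark.parametrize("counts,m", [([3, 2, 1], 3), ([4, 2], 4), ([2, 2, 1], 2)])
    def test_q1_interior_between_bruteforce_bounds(self, counts, m):
        """The exact hypergeometric expectation of subsample entropy matches
        enumeration (compared on the entropy scale, then exponentiated)."""
        a = AbundanceVector.from_counts(counts)
        ours = np.log(diversity_at_size(a, 1, m))
        brute = np.log(rarefied_shannon_bruteforce(a, m))
        assert ours == pytest.approx(brute, abs=1e-9)

    @given(counts_strategy)
    @settings(max_examples=30, deadline=None)
    def test_q0_curve_nondecreasing(self, counts):
        a = AbundanceVector.from_counts(counts)
        grid = range(1, min(2 * a.n, 40))
        vals = [diversity_at_size(a, 0, m) for m in grid]
        assert all(b >= a_ - 1e-9 for a_, b in zip(vals, vals[1:]))

    def test_re_curves_structure_and_ci(self):
        a = AbundanceVector.from_counts([8, 5, 4, 3, 2, 2, 1, 1, 1])
        curves = coverage_re_curves(a, n_boot=100, seed=3)
        for q in (0, 1, 2):
            rec = curves[q]
            assert np.all(rec["lo"] <= rec["diversity"] + 1e-9)
            assert np.all(rec["diversity"] <= rec["hi"] + 1e-9)
            # observed endpoint present
            at_n = rec["m"] == a.n
            assert rec["diversity"][at_n][0] == pytest.approx(hill_observed(a, q), rel=1e-9)

    def test_diversity_at_target_coverage(self):
        a = AbundanceVector.from_counts([8, 5, 4, 3, 2, 2, 1, 1, 1])
        d = diversity_at_coverage(a, 0, 0.9025)
        assert 1.0 <= d <= hill_asymptotic(a, 0)[0] + 1e-9
        with pytest.raises(ValueError):
            diversity_at_coverage(a, 0, 0.999999, m_max=2 * a.n)


class TestSimilarityIndices:
    def test_identical_assemblages(self):
        a = AbundanceVector.from_counts([5, 3, 2])
        b = AbundanceVector({"c0": 10, "c1": 6, "c2": 4})  # same proportions
        res = horn_morisita(a, b)
        assert res["horn"] == pytest.approx(1.0)
        assert res["morisita_horn"] == pytest.approx(1.0)

    def test_disjoint_assemblages(self):
        a = AbundanceVector({"x": 5, "y": 5})
        b = AbundanceVector({"u": 5, "v": 5})
        res = horn_morisita(a, b)
        assert res["horn"] == pytest.approx(0.0, abs=1e-12)
        assert res["morisita_horn"] == pytest.approx(0.0, abs=1e-12)

    def test_half_overlap_hand_arithmetic(self):
        a = AbundanceVector({"c1": 5, "c2": 5})
        b = AbundanceVector({"c2": 5, "c3": 5})
        assert horn_morisita(a, b)["morisita_horn"] == pytest.approx(0.5)

    @given(counts_strategy, st.integers(2, 7))
    @settings(max_examples=30, deadline=None)
    def test_morisita_horn_scale_invariance(self, counts, k):
        a = AbundanceVector.from_counts(counts)
        b = AbundanceVector.from_counts(list(reversed(counts)))
        scaled = AbundanceVector.from_counts([k * c for c in counts])
        r1 = horn_morisita(a, b)["morisita_horn"]
        r2 = horn_morisita(scaled, b)["morisita_horn"]
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestSpecificityTest:
    @staticmethod
    def disjoint_table(n_cat=10, size=5):
        table = {}
        for i in range(n_cat):
            eco = "coastal" if i % 2 == 0 else "offshore"
            table[f"cat{i}"] = {eco: size, ("offshore" if eco == "coastal" else "coastal"): 0}
        return table

    def test_fully_disjoint_maximal_specificity(self):
        res = ecotype_specificity_test(self.disjoint_table(), n_perm=500, seed=0)
        assert res["observed"] == 1.0
        assert res["p_value"] <= 5 / 501

    def test_all_shared_minimal_specificity(self):
        table = {f"cat{i}": {"coastal": 3, "offshore": 3} for i in range(8)}
        res = ecotype_specificity_test(table, n_perm=300, seed=1)
        assert res["observed"] == 0.0

    def test_type_one_error_controlled(self):
        """Randomly labeled repertoires are not flagged: p > 0.05 in >= 93%
        of null simulations."""
        ok = 0
        sims = 60
        for s in range(sims):
            rng = np.random.default_rng(900 + s)
            table = {}
            for i in range(12):
                size = int(rng.integers(2, 8))
                k = rng.binomial(size, 0.5)
                table[f"c{i}"] = {"coastal": int(k), "offshore": int(size - k)}
            if len({e for v in table.values() for e, c in v.items() if c > 0}) < 2:
                continue
            res = ecotype_specificity_test(table, n_perm=199, seed=s)
            ok += res["p_value"] > 0.05
        assert ok / sims >= 0.93

    def test_quantile_rule_available(self):
        res = ecotype_specificity_test(self.disjoint_table(), n_perm=300, seed=2, rule="quantile")
        assert res["p_value"] <= 0.05

    def test_single_ecotype_errors(self):
        table = {"a": {"coastal": 3}, "b": {"coastal": 2}}
        with pytest.raises(ValueError):
            ecotype_specificity_test(table)
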