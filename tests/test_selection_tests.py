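"""Group Wilcoxon tests, BH correction, per-ASV binomial selection tests."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from homesite.selection_tests import (
    asv_selection_binomial,
    asv_selection_table,
    benjamini_hochberg,
    enrichment_chisq,
    genotype_dependence,
)
from homesite.selection_tests import test_group_nonzero as group_nonzero  # alias: not a test


class TestGroupNonzero:
    def test_symmetric_values_give_p_one(self):
        result = group_nonzero([-2.0, 2.0, -1.0, 1.0])
        assert result.p_wilcoxon == pytest.approx(1.0)

    def test_exact_p_for_five_positive_values(self):
        """All-positive n=5: two-sided exact p = 2/2^5 = 0.0625."""
        result = group_nonzero([1.0, 2.0, 3.0, 4.0, 5.0])
        assert result.p_wilcoxon == pytest.approx(0.0625)
        assert result.n == 5 and result.median == 3.0

    def test_signed_rank_enumeration_oracle(self):
        """Exact p matches brute-force enumeration of all sign assignments."""
        values = np.array([0.8, -1.5, 2.3, 3.1, -0.4, 1.9])
        result = group_nonzero(values)
        ranks = np.argsort(np.argsort(np.abs(values))) + 1
        w_obs = ranks[values > 0].sum()
        n = len(values)
        w_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        mean_w = n * (n + 1) / 4
        p_exact = sum(1 for w in w_all if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12) / 2**n
        assert result.p_wilcoxon == pytest.approx(p_exact)

    def test_large_sample_shifted_mean_detected(self):
        rng = np.random.default_rng(0)
        hits = sum(
            group_nonzero(rng.normal(0.5, 1.0, 200)).p_wilcoxon < 0.001 for _ in range(40)
        )
        assert hits >= 38  # >= 95% of seeds

    def test_all_zero_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = group_nonzero([0.0, 0.0, 0.0])
        assert result.p_wilcoxon == 1.0

    def test_zeros_dropped_before_ranking(self):
        with_zeros = group_nonzero([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        without = group_nonzero([1.0, 2.0, 3.0, 4.0, 5.0])
        assert with_zeros.p_wilcoxon == pytest.approx(without.p_wilcoxon)


class TestBenjaminiHochberg:
    @staticmethod
    def hand_step_up(pvalues):
        """Independent oracle: literal BH step-up with monotonicity pass."""
        p = list(pvalues)
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            q[i] = min(prev, p[i] * m / rank_from_top)
            prev = q[i]
        return q

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            np.testing.assert_allclose(benjamini_hochberg(p), self.hand_step_up(p), atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-4, 1.0, 100)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([1.5])


def binomial_tail_oracle(k: int, n: int) -> float:
    """Independent oracle: exact one-sided tail sum at p0 = 1/2 via Fractions."""
    return float(sum(Fraction(math.comb(n, j)) for j in range(k, n + 1)) / Fraction(2**n))


class TestAsvSelectionBinomial:
    def test_all_mice_above_expected(self):
        obs = np.full(10, 0.3)
        record = asv_selection_binomial(obs, expected_relabund=0.1, direction="positive")
        assert record.n_successes == 10
        assert record.p_binomial == pytest.approx(2**-10)

    def test_half_above(self):
        obs = np.array([0.3] * 5 + [0.05] * 5)
        record = asv_selection_binomial(obs, expected_relabund=0.1)
        assert record.p_binomial == pytest.approx(binomial_tail_oracle(5, 10))

    def test_matches_tail_oracle_up_to_n_30(self):
        for n in range(3, 31):
            for k in range(0, n + 1):
                obs = np.concatenate([np.full(k, 2.0), np.full(n - k, 0.5)])
                record = asv_selection_binomial(obs, expected_relabund=1.0)
                assert record.p_binomial == pytest.approx(binomial_tail_oracle(k, n)), (k, n)

    def test_ties_count_as_failures(self):
        obs = np.array([0.1, 0.1, 0.1, 0.2])
        record = asv_selection_binomial(obs, expected_relabund=0.1, direction="positive")
        assert record.n_successes == 1
        record = asv_selection_binomial(obs, expected_relabund=0.1, direction="negative")
        assert record.n_successes == 0

    def test_too_few_mice_is_error(self):
        with pytest.raises(ValueError, match="minimum"):
            asv_selection_binomial([0.1, 0.2], expected_relabund=0.05)

    def test_table_matches_single_record_path(self):
        rng = np.random.default_rng(4)
        obs = pd.DataFrame(rng.random((6, 8)), index=[f"a{i}" for i in range(6)])
        expected = pd.Series(rng.random(6), index=obs.index)
        table = asv_selection_table(obs, expected)
        for row in table.itertuples():
            single = asv_selection_binomial(
                obs.loc[row.asv_id], expected[row.asv_id], direction=row.direction
            )
            assert row.p_binomial == pytest.approx(single.p_binomial)
            assert row.n_successes == single.n_successes
        # BH applied within each direction family
        pos = table[table.direction == "positive"]
        np.testing.assert_allclose(
            pos["q_bh"], benjamini_hochberg(pos["p_binomial"])
        )


class TestGenotypeDependence:
    @staticmethod
    def _records(asv_ids, pvalues):
        return pd.DataFrame(
            {
                "asv_id": asv_ids,
                "direction": "positive",
                "p_binomial": pvalues,
            }
        )

    def test_identical_cage_deviations_not_dependent(self):
        wt = self._records(["a1"], [0.01])
        ko = self._records(["a1"], [0.5])
        dev = pd.DataFrame(
            {
                "asv_id": ["a1"] * 6,
                "genotype": ["WT"] * 3 + ["Rag1KO"] * 3,
                "cage_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
                "deviation": [0.05, 0.04, 0.06, 0.05, 0.04, 0.06],
            }
        )
        out = genotype_dependence(wt, ko, dev)
        assert out.loc[0, "flagged"]
        assert out.loc[0, "p_ranksum"] == pytest.approx(1.0)
        assert not out.loc[0, "genotype_dependent"]

    def test_complete_separation_three_vs_three(self):
        """Exact rank-sum p for 3v3 complete separation is 2/C(6,3) = 0.1."""
        wt = self._records(["a1"], [0.01])
        ko = self._records(["a1"], [0.9])
        dev = pd.DataFrame(
            {
                "asv_id": ["a1"] * 6,
                "genotype": ["WT"] * 3 + ["Rag1KO"] * 3,
                "cage_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
                "deviation": [0.04, 0.05, 0.06, -0.01, 0.00, -0.02],
            }
        )
        out = genotype_dependence(wt, ko, dev)
        assert out.loc[0, "p_ranksum"] == pytest.approx(0.1)

    def test_concordant_asvs_not_flagged(self):
        wt = self._records(["a1", "a2"], [0.01, 0.8])
        ko = self._records(["a1", "a2"], [0.02, 0.7])
        dev = pd.DataFrame(
            {
                "asv_id": ["a1", "a1", "a1", "a1"],
                "genotype": ["WT", "WT", "Rag1KO", "Rag1KO"],
                "cage_id": ["c1", "c2", "c3", "c4"],
                "deviation": [0.1, 0.2, 0.1, 0.2],
            }
        )
        out = genotype_dependence(wt, ko, dev)
        assert not out["flagged"].any()
        assert not out["genotype_dependent"].any()

    def test_too_few_cages_skipped_with_reason(self):
        wt = self._records(["a1"], [0.01])
        ko = self._records(["a1"], [0.9])
        dev = pd.DataFrame(
            {
                "asv_id": ["a1"] * 3,
                "genotype": ["WT", "WT", "Rag1KO"],
                "cage_id": ["c1", "c2", "c3"],
                "deviation": [0.04, 0.05, -0.01],
            }
        )
        out = genotype_dependence(wt, ko, dev)
        assert out.loc[0, "skip_reason"] is not None
        assert np.isnan(out.loc[0, "p_ranksum"])

    def test_mixed_directions_rejected(self):
        records = pd.DataFrame(
            {"asv_id": ["a", "a"], "direction": ["positive", "negative"], "p_binomial": [0.1, 0.1]}
        )
        with pytest.raises(ValueError, match="direction"):
            genotype_dependence(records, records, pd.DataFrame())


class TestEnrichmentChisq:
    def test_balanced_table_p_one(self):
        result = enrichment_chisq([10, 10], [20, 20])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        """Table ((20,5),(5,20)): all expected cells 12.5, chi2 = 4*(7.5^2)/12.5 = 18."""
        result = enrichment_chisq([20, 5], [25, 25])
        assert result.statistic == pytest.approx(18.0)
        assert result.p_value == pytest.approx(2.209e-5, rel=1e-3)

    def test_fisher_when_expected_small(self):
        result = enrichment_chisq([3, 0], [4, 4], method="auto")
        assert result.method == "fisher"

    def test_monotone_in_effect_size(self):
        """Stronger native-vs-non-native selection imbalance -> smaller p."""
        pvals = [
            enrichment_chisq([sel_nat, 5], [40, 40]).p_value for sel_nat in (10, 20, 30)
        ]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="zero-margin"):
            enrichment_chisq([0, 0], [10, 10])

    def test_selected_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chisq([21, 5], [20, 20])
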