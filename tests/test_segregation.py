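"""Polysomic gamete model, expected ratios, chi-square and tabulations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polydose import (
    AllelicConfiguration,
    CrossSpec,
    InfeasibleCrossError,
    chi_square_gof,
    expected_phenotype_ratio,
    format_ratio,
    gamete_frequencies,
    offspring_distribution,
    ploidy_tabulation,
    segregation_table,
)
from polydose.exceptions import DegenerateDataError

A = AllelicConfiguration.from_string


def enumerate_gametes(parent, g):
    """Oracle: explicit enumeration of all C(ploidy, g) allele subsets."""
    alleles = [1] * parent.n_dominant + [0] * parent.n_recessive
    counts = {}
    total = 0
    for combo in itertools.combinations(range(parent.ploidy), g):
        k = sum(alleles[i] for i in combo)
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: Fraction(v, total) for k, v in counts.items()}


class TestGameteFrequencies:
    @pytest.mark.parametrize(
        "parent,g,expected",
        [
            ("Aaaa", 2, {1: Fraction(1, 2), 0: Fraction(1, 2)}),
            ("AAaa", 2, {2: Fraction(1, 6), 1: Fraction(4, 6), 0: Fraction(1, 6)}),
            ("aa", 1, {0: Fraction(1)}),
        ],
    )
    def test_enumerated_examples(self, parent, g, expected):
        dist = gamete_frequencies(A(parent), g)
        assert dict(dist.mass) == expected

    def test_exhaustive_enumeration_oracle_up_to_octoploid(self):
        for ploidy in range(1, 9):
            for na in range(ploidy + 1):
                parent = AllelicConfiguration(ploidy, na)
                for g in range(1, ploidy + 1):
                    dist = gamete_frequencies(parent, g)
                    assert dict(dist.mass) == enumerate_gametes(parent, g)

    @settings(derandomize=True, max_examples=100)
    @given(
        ploidy=st.integers(1, 8),
        data=st.data(),
    )
    def test_masses_sum_to_one_exactly(self, ploidy, data):
        na = data.draw(st.integers(0, ploidy))
        g = data.draw(st.integers(1, ploidy))
        dist = gamete_frequencies(AllelicConfiguration(ploidy, na), g)
        assert sum(dist.mass.values()) == 1
        lo, hi = max(0, g - (ploidy - na)), min(g, na)
        assert set(dist.mass) <= set(range(lo, hi + 1))

    def test_allele_swap_mirrors_distribution(self):
        for ploidy in range(2, 7):
            for na in range(ploidy + 1):
                for g in range(1, ploidy + 1):
                    d1 = gamete_frequencies(AllelicConfiguration(ploidy, na), g).mass
                    d2 = gamete_frequencies(
                        AllelicConfiguration(ploidy, ploidy - na), g
                    ).mass
                    assert {g - k: v for k, v in d2.items()} == dict(d1)

    def test_infeasible_gamete_ploidy(self):
        with pytest.raises(InfeasibleCrossError):
            gamete_frequencies(A("Aa"), 3)

    def test_monte_carlo_sampling_matches_exact_masses(self):
        """10^5 hypergeometric draws agree within 3 binomial standard errors."""
        rng = np.random.default_rng(12345)
        parent = A("AAaa")
        n = 100_000
        draws = rng.hypergeometric(parent.n_dominant, parent.n_recessive, 2, size=n)
        exact = gamete_frequencies(parent, 2).as_floats()
        for k, p in exact.items():
            freq = (draws == k).mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * se


class TestOffspringDistribution:
    def test_diploid_by_tetraploid_triploid_progeny(self):
        dist = offspring_distribution(CrossSpec(A("aa"), A("Aaaa"), 3))
        assert dist == {0: Fraction(1, 2), 1: Fraction(1, 2)}

    def test_homozygous_tetraploid_gives_uniform_heterozygotes(self):
        dist = offspring_distribution(CrossSpec(A("aa"), A("AAAA"), 3))
        assert dist == {2: Fraction(1)}

    def test_pentaploids_from_unreduced_gamete_all_carry_a_dominant_copy(self):
        dist = offspring_distribution(CrossSpec(A("AAaa"), A("aa"), 5))
        assert dist.get(0, Fraction(0)) == 0

    def test_explicit_gamete_override(self):
        # force an unreduced 2n gamete from the diploid side
        dist = offspring_distribution(
            CrossSpec(A("aa"), A("AAaa"), 4, female_gamete=2)
        )
        assert dist == {0: Fraction(1, 6), 1: Fraction(4, 6), 2: Fraction(1, 6)}

    def test_infeasible_allocation_reported(self):
        with pytest.raises(InfeasibleCrossError, match="tried"):
            offspring_distribution(CrossSpec(A("aa"), A("Aaaa"), 8))

    def test_classical_diploid_mendel_ratios(self):
        assert expected_phenotype_ratio(CrossSpec(A("Aa"), A("Aa"), 2)) == (3, 1)
        assert expected_phenotype_ratio(CrossSpec(A("Aa"), A("aa"), 2)) == (1, 1)


class TestExpectedRatio:
    @pytest.mark.parametrize(
        "female,male,progeny,ratio",
        [
            ("aa", "Aaaa", 2, (1, 3)),
            ("aa", "Aaaa", 3, (1, 1)),
            ("aa", "Aaaa", 4, (3, 1)),
            ("aa", "AAaa", 2, (1, 1)),
            ("aa", "AAaa", 3, (5, 1)),
            ("aa", "AAAA", 3, (1, 0)),
            ("AAaa", "aa", 5, (1, 0)),
        ],
    )
    def test_per_class_ratios(self, female, male, progeny, ratio):
        assert expected_phenotype_ratio(CrossSpec(A(female), A(male), progeny)) == ratio


class TestChiSquare:
    @pytest.mark.parametrize(
        "observed,ratio,chi2",
        [
            ((5, 5), (1, 1), 0.00),
            ((4, 5), (1, 3), 1.81),
            ((10, 0), (5, 1), 2.00),
        ],
    )
    def test_published_hand_values(self, observed, ratio, chi2):
        test = chi_square_gof(observed, ratio)
        assert round(test.chi2, 2) == chi2
        assert test.df == 1
        assert 0 <= test.p <= 1

    def test_no_continuity_correction(self):
        # Yates would give ((|4-2.25|-0.5)^2/2.25 + ...) ~ 0.93, not 1.81
        assert chi_square_gof((4, 5), (1, 3)).chi2 == pytest.approx(49 / 27, abs=1e-12)

    def test_zero_expectation_class_with_zero_observed_is_degenerate(self):
        test = chi_square_gof((7, 0), (1, 0))
        assert test.chi2 == 0.0 and test.p == 1.0
        assert "degenerate_class" in test.flags

    def test_observation_in_zero_expectation_class_is_infinite(self):
        test = chi_square_gof((7, 1), (1, 0))
        assert math.isinf(test.chi2) and test.p == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi_square_gof((0, 0), (1, 1))
        with pytest.raises(ValueError):
            chi_square_gof((3, 4), (0, 0))


class TestSegregationTable:
    def records(self):
        return [
            {"cross": "c1", "female_genotype": "AAaa", "male_genotype": "aa",
             "progeny_ploidy": 3, "observed_red": 66, "observed_white": 14},
            {"cross": "c1", "female_genotype": "AAaa", "male_genotype": "aa",
             "progeny_ploidy": 2, "observed_red": 0, "observed_white": 0},
        ]

    def test_observed_ratio_formatting(self):
        table = segregation_table(self.records())
        row = table[table["ploidy_class"] == "3x"].iloc[0]
        assert row["observed_ratio"] == "4.71:1"
        assert row["expected_ratio"] == "5:1"

    def test_empty_class_rows_use_placeholders(self):
        table = segregation_table(self.records())
        row = table[table["ploidy_class"] == "2x"].iloc[0]
        assert row["observed_ratio"] == "/"
        assert row["expected_ratio"] == "/"
        assert math.isnan(row["chi2"]) and math.isnan(row["p"])

    def test_total_row_pools_expected_counts(self):
        table = segregation_table(self.records())
        total = table[table["ploidy_class"] == "Total"].iloc[0]
        # only the 3x class contributes: expected (66.67, 13.33)
        assert total["observed_red"] == 66 and total["observed_white"] == 14
        assert total["chi2"] == pytest.approx(0.04, abs=5e-3)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            segregation_table([{"cross": "x"}])

    @pytest.mark.parametrize(
        "red,white,text",
        [(66, 14, "4.71:1"), (4, 5, "1:1.25"), (2, 0, "1:0"), (0, 3, "0:1"),
         (5, 5, "1:1"), (0, 0, "/"), (20, 30, "1:1.5")],
    )
    def test_ratio_formatter(self, red, white, text):
        assert format_ratio(red, white) == text


class TestPloidyTabulation:
    def test_percentages(self):
        table = ploidy_tabulation({"x": {2: 1, 3: 50}})
        by = table.set_index("ploidy")["percent"]
        assert by[3] == 98.04 and by[2] == 1.96

    def test_single_class_is_100(self):
        table = ploidy_tabulation({"x": {3: 5}})
        assert table["percent"].tolist() == [100.0]

    def test_even_split(self):
        table = ploidy_tabulation({"x": {2: 1, 3: 1}})
        assert table["percent"].tolist() == [50.0, 50.0]

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateDataError):
            ploidy_tabulation({"x": {}})
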