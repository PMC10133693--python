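"""Aggregation arithmetic, prevalence estimators, intervals and CIs."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta

from varprev.cohort_io import ALL, CountUnit, read_classification_table
from varprev.filtering import join_classification, select_disease_causing
from varprev.prevalence import (
    AggregateCounts,
    aggregate,
    aggregate_maf,
    carriers_from_counts,
    confidence_interval,
    display_frequency,
    display_prevalence,
    population_af,
    prevalence_carrier_method,
    prevalence_hardy_weinberg,
    prevalence_interval,
    round_sig,
    stratify_complement,
)

from .conftest import AMCARELAB_TSV, GNOMAD_TSV


def _disease_causing(table, path):
    return select_disease_causing(
        join_classification(table, read_classification_table(path)))


@pytest.fixture
def gnomad_agg(gnomad_table):
    selected = _disease_causing(gnomad_table, GNOMAD_TSV)
    return aggregate(selected, ALL, cohort_individuals=125780)


class TestAggregate:
    def test_gnomad_totals(self, gnomad_agg):
        assert (gnomad_agg.n_variants, gnomad_agg.total_allele_count,
                gnomad_agg.total_homozygotes) == (6, 470, 3)

    def test_clinical_exome_totals(self, amcarelab_table):
        selected = _disease_causing(amcarelab_table, AMCARELAB_TSV)
        agg = aggregate(selected, ALL, cohort_individuals=45392)
        assert (agg.n_variants, agg.total_allele_count) == (15, 34)
        assert agg.unit is CountUnit.INDIVIDUALS

    def test_single_row_sums_equal_row(self, gnomad_table):
        selected = _disease_causing(gnomad_table, GNOMAD_TSV)[:1]
        agg = aggregate(selected, ALL, cohort_individuals=125780)
        assert agg.total_allele_count == selected[0].counts[ALL].allele_count

    def test_mixed_units_rejected(self, gnomad_table, amcarelab_table):
        a = _disease_causing(gnomad_table, GNOMAD_TSV)
        b = _disease_causing(amcarelab_table, AMCARELAB_TSV)
        with pytest.raises(ValueError, match="mixed count units"):
            aggregate(a + b, ALL, cohort_individuals=1)


class TestCarriersFromCounts:
    @pytest.mark.parametrize("ac, hom, expected", [
        (470, 3, 467),   # each homozygote: two alleles, one individual
        (65, 0, 65),
        (2, 1, 1),
    ])
    def test_allele_units(self, ac, hom, expected):
        agg = AggregateCounts(ALL, 1, ac, hom, 125780)
        assert carriers_from_counts(agg) == expected

    def test_individual_units_pass_through(self):
        agg = AggregateCounts(ALL, 15, 34, 0, 45392, unit=CountUnit.INDIVIDUALS)
        assert carriers_from_counts(agg) == 34


class TestAggregateMaf:
    def test_gnomad_value(self, gnomad_agg):
        assert display_frequency(aggregate_maf(gnomad_agg)) == "0.00186"

    def test_chinamap_value(self):
        agg = AggregateCounts(ALL, 2, 2, 0, 10588)
        assert round_sig(aggregate_maf(agg), 3) == 0.0000944

    def test_zero_counts(self):
        agg = AggregateCounts(ALL, 0, 0, 0, 1000)
        assert aggregate_maf(agg) == 0.0

    def test_individual_units_rejected(self):
        agg = AggregateCounts(ALL, 1, 34, 0, 45392, unit=CountUnit.INDIVIDUALS)
        with pytest.raises(ValueError):
            aggregate_maf(agg)


class TestCarrierMethod:
    @pytest.mark.parametrize("ac, hom, n, unit, expected", [
        (470, 3, 125780, CountUnit.ALLELES, "371.3"),    # pooled gnomAD
        (65, 0, 113261, CountUnit.ALLELES, "57.4"),      # non-African
        (34, 0, 45392, CountUnit.INDIVIDUALS, "74.9"),   # clinical exomes
        (2, 0, 10588, CountUnit.ALLELES, "18.9"),        # ChinaMAP
    ])
    def test_headline_prevalences(self, ac, hom, n, unit, expected):
        agg = AggregateCounts(ALL, 1, ac, hom, n, unit=unit)
        est = prevalence_carrier_method(agg)
        assert display_prevalence(est.prevalence_per_100k) == expected

    def test_ci_contains_point_estimate(self, gnomad_agg):
        est = prevalence_carrier_method(gnomad_agg)
        assert est.ci_low <= est.prevalence_per_100k <= est.ci_high

    def test_inconsistent_summary_rejected(self):
        agg = AggregateCounts(ALL, 1, 30, 0, 10)
        with pytest.raises(ValueError, match="exceed"):
            prevalence_carrier_method(agg)

    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(0.01, 1.0), carriers=st.integers(0, 400))
    def test_penetrance_scaling_is_exactly_linear(self, k, carriers):
        agg = AggregateCounts(ALL, 1, carriers, 0, 10000)
        full = prevalence_carrier_method(agg, penetrance=1.0)
        scaled = prevalence_carrier_method(agg, penetrance=k)
        assert scaled.prevalence_per_100k == k * full.prevalence_per_100k
        assert scaled.ci_high == k * full.ci_high


class TestHardyWeinbergMethod:
    def test_boundaries(self):
        assert prevalence_hardy_weinberg(0.0).prevalence_per_100k == 0.0
        assert prevalence_hardy_weinberg(1.0).prevalence_per_100k == 100000.0

    def test_agrees_with_carrier_method_to_second_order(self):
        maf = 0.0018564
        hwe = prevalence_hardy_weinberg(maf).prevalence_per_100k
        direct = 1e5 * (1 - (1 - maf) ** 2)  # closed-form oracle
        assert hwe == pytest.approx(direct, rel=1e-12)
        carrier = 1e5 * 2 * maf
        assert abs(carrier - hwe) / hwe <= maf

    @settings(derandomize=True, max_examples=100)
    @given(maf=st.floats(1e-8, 0.1))
    def test_relative_gap_bounded_by_maf(self, maf):
        # carrier method ~ 2q, HWE = 2q - q^2: they differ by the q^2 term
        hwe = prevalence_hardy_weinberg(maf).prevalence_per_100k
        carrier = 1e5 * 2 * maf
        assert abs(carrier - hwe) / hwe <= maf * (1 + 1e-9)


class TestStratifyComplement:
    def test_cohort_size_subtraction(self):
        total = AggregateCounts(ALL, 6, 470, 3, 125748)
        sub = AggregateCounts("African/African-American", 1, 402, 3, 12487)
        comp = stratify_complement(total, sub)
        assert comp.cohort_individuals == 113261
        assert comp.population == "non-African/African-American"

    def test_derived_complement_differs_from_reported_split(self):
        # the exact complement has 68 alleles; the published split reports 65
        # (undocumented extra exclusions) — the engine must not hide that.
        total = AggregateCounts(ALL, 6, 470, 3, 125748)
        sub = AggregateCounts("African", 1, 402, 3, 12487)
        comp = stratify_complement(total, sub)
        assert comp.total_allele_count == 68
        assert carriers_from_counts(comp) == 68
        assert comp.total_allele_count != 65

    def test_empty_subpopulation_leaves_total(self):
        total = AggregateCounts(ALL, 6, 470, 3, 125748)
        sub = AggregateCounts("none", 0, 0, 0, 1)
        comp = stratify_complement(total, sub)
        assert comp.total_allele_count == 470 and comp.total_homozygotes == 3

    def test_negative_difference_rejected(self):
        total = AggregateCounts(ALL, 1, 10, 0, 100)
        sub = AggregateCounts("big", 1, 20, 0, 50)
        with pytest.raises(ValueError, match="exceeds total"):
            stratify_complement(total, sub)

    @settings(derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_conservation_exact(self, data):
        ac_t = data.draw(st.integers(0, 10000))
        hom_t = data.draw(st.integers(0, ac_t // 2))
        n_t = data.draw(st.integers(2, 10 ** 6))
        ac_s = data.draw(st.integers(0, ac_t))
        hom_s = data.draw(st.integers(max(0, hom_t - (ac_t - ac_s) // 2),
                                      min(hom_t, ac_s // 2)))
        n_s = data.draw(st.integers(1, n_t - 1))
        total = AggregateCounts(ALL, 2, ac_t, hom_t, n_t)
        sub = AggregateCounts("sub", 1, ac_s, hom_s, n_s)
        comp = stratify_complement(total, sub)
        assert sub.total_allele_count + comp.total_allele_count == total.total_allele_count
        assert sub.total_homozygotes + comp.total_homozygotes == total.total_homozygotes
        assert sub.cohort_individuals + comp.cohort_individuals == total.cohort_individuals


class TestPopulationAf:
    def test_african_aggregate_frequency(self):
        assert round_sig(402 / (2 * 12487), 2) == 0.016

    def test_per_variant_frequency_from_cohort_n(self, gnomad_table):
        selected = _disease_causing(gnomad_table, GNOMAD_TSV)
        v50m = [v for v in selected if v.record.protein.canonical == "p.V50M"][0]
        v50m.counts[ALL].cohort_individuals = 125748
        assert round_sig(population_af(v50m, ALL), 3) == 0.000103

    def test_zero_allele_count(self, gnomad_table):
        selected = _disease_causing(gnomad_table, GNOMAD_TSV)
        v = selected[0]
        v.counts[ALL].allele_count = 0
        v.counts[ALL].cohort_individuals = None
        assert population_af(v, ALL) == 0.0


class TestConfidenceInterval:
    def test_zero_successes_has_zero_lower_bound(self):
        low, high = confidence_interval(0, 100)
        assert low == 0.0 and high > 0

    # Clopper-Pearson oracle via Beta quantiles, computed independently and
    # frozen; Wilson endpoints must sit within the known Wilson/exact gap
    # (small absolute gap at the lower end for tiny counts, <3% at the upper).
    @pytest.mark.parametrize("carriers, n, cp_low, cp_high", [
        (2, 10588, 2.2877, 68.2178),
        (467, 125780, 338.4228, 406.4632),
    ])
    def test_wilson_matches_exact_binomial_oracle(self, carriers, n, cp_low, cp_high):
        a = 0.025
        assert beta.ppf(a, carriers, n - carriers + 1) * 1e5 == pytest.approx(cp_low, abs=1e-3)
        assert beta.ppf(1 - a, carriers + 1, n - carriers) * 1e5 == pytest.approx(cp_high, abs=1e-3)
        w_low, w_high = confidence_interval(carriers, n, 0.95)
        assert abs(w_low - cp_low) <= max(3.0, 0.02 * cp_low)
        assert abs(w_high - cp_high) <= max(3.0, 0.02 * cp_high)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            confidence_interval(1, 10, 1.5)
        with pytest.raises(ValueError):
            confidence_interval(11, 10, 0.95)


class TestPrevalenceInterval:
    def _est(self, prev_100k):
        agg = AggregateCounts(ALL, 1, 0, 0, 100000)
        e = prevalence_carrier_method(agg)
        e.prevalence_per_100k = prev_100k
        return e

    def test_min_max_envelope(self):
        iv = prevalence_interval([("ChinaMAP", self._est(18.9)),
                                  ("Amcarelab", self._est(74.9))])
        assert (iv.low, iv.high) == (18.9, 74.9)
        assert iv.databases == ["ChinaMAP", "Amcarelab"]

    def test_three_estimates(self):
        iv = prevalence_interval([("a", self._est(18.9)), ("b", self._est(57.4)),
                                  ("c", self._est(74.9))])
        assert (iv.low, iv.high) == (18.9, 74.9)

    def test_single_estimate_degenerate(self):
        iv = prevalence_interval([("only", self._est(42.0))])
        assert iv.low == iv.high == 42.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prevalence_interval([])


class TestDisplayRounding:
    @pytest.mark.parametrize("value, expected", [
        (371.2831928764509, "371.3"),
        (57.38956922506423, "57.4"),
        (18.889308651303363, "18.9"),
        (74.90306661966866, "74.9"),
    ])
    def test_prevalence_one_decimal(self, value, expected):
        assert display_prevalence(value) == expected

    def test_rounding_never_feeds_back(self):
        # recompute from full precision, re-round: same display string
        agg = AggregateCounts(ALL, 6, 470, 3, 125780)
        est1 = prevalence_carrier_method(agg)
        est2 = prevalence_carrier_method(agg)
        assert display_prevalence(est1.prevalence_per_100k) == \
               display_prevalence(est2.prevalence_per_100k) == "371.3"
        assert est1.prevalence_per_100k == est2.prevalence_per_100k
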