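"""Collapsing burden statistics against independent oracles.

The exact one-sided Fisher test is checked against brute-force
enumeration of the hypergeometric tail; the one-sided chi-square
against the textbook Pearson formula computed from first principles.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csburden import (
    AnnotatedVariant,
    CollapsedCounts,
    InputFormatError,
    chisq_one_sided,
    collapse_carriers,
    fisher_one_sided,
    odds_ratio,
    stratified_burden,
)
from csburden.burden import allele_counts, format_row, render_table


# --- independent oracles ----------------------------------------------------

def binom(n, k):
    return math.comb(n, k)


def fisher_enumeration_oracle(a, n1, c, n2):
    """Sum hypergeometric point masses over the enrichment tail.

    P(A >= a) where A ~ Hypergeom(N=n1+n2, K=a+c carriers, n=n1 draws),
    enumerated term by term with exact integer binomials.
    """
    N, K = n1 + n2, a + c
    total = binom(N, n1)
    lo, hi = max(a, 0), min(K, n1)
    return sum(binom(K, x) * binom(N - K, n1 - x) for x in range(lo, hi + 1)) / total


def pearson_chi2_oracle(a, n1, c, n2):
    """Textbook Pearson statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    b, d = n1 - a, n2 - c
    N = n1 + n2
    return N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------

counts_small = st.tuples(
    st.integers(1, 30), st.integers(1, 30)
).flatmap(
    lambda nn: st.tuples(
        st.integers(0, nn[0]), st.just(nn[0]), st.integers(0, nn[1]), st.just(nn[1])
    )
)


class TestFisherOneSided:
    def test_single_case_carrier_closed_form(self):
        # with one carrier total, P(case draws it) = n1 / (n1 + n2)
        p = fisher_one_sided(CollapsedCounts(1, 574, 0, 828))
        assert p == pytest.approx(574 / 1402)
        assert round(p, 2) == 0.41

    def test_no_case_carriers_gives_total_mass(self):
        assert fisher_one_sided(CollapsedCounts(0, 574, 5, 828)) == pytest.approx(1.0)

    @given(counts_small)
    def test_matches_enumeration_oracle(self, tbl):
        a, n1, c, n2 = tbl
        assert fisher_one_sided(CollapsedCounts(a, n1, c, n2)) == pytest.approx(
            fisher_enumeration_oracle(a, n1, c, n2), abs=1e-12
        )

    def test_monotone_decreasing_in_case_carriers(self):
        # more case carriers at fixed margins -> stronger enrichment
        ps = [fisher_one_sided(CollapsedCounts(a, 50, 10 - a, 80)) for a in range(11)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    @given(counts_small)
    def test_p_in_unit_interval(self, tbl):
        a, n1, c, n2 = tbl
        p = fisher_one_sided(CollapsedCounts(a, n1, c, n2))
        assert 0 < p <= 1


class TestChisqOneSided:
    def test_proportional_table_gives_half(self):
        assert chisq_one_sided(CollapsedCounts(5, 100, 5, 100)) == pytest.approx(0.5)

    @given(counts_small)
    def test_matches_textbook_statistic(self, tbl):
        from scipy.stats import chi2

        a, n1, c, n2 = tbl
        if a + c == 0 or (n1 - a) + (n2 - c) == 0:
            return  # degenerate margin handled separately
        stat = pearson_chi2_oracle(a, n1, c, n2)
        p_two = chi2.sf(stat, 1)
        expected = p_two / 2 if a / n1 > c / n2 else 1 - p_two / 2
        assert chisq_one_sided(CollapsedCounts(a, n1, c, n2)) == pytest.approx(expected)

    @given(counts_small)
    def test_cohort_transposition_flips_p(self, tbl):
        a, n1, c, n2 = tbl
        counts = CollapsedCounts(a, n1, c, n2)
        if a + c == 0 or counts.b + counts.d == 0:
            return
        p = chisq_one_sided(counts)
        p_t = chisq_one_sided(counts.transpose_cohorts())
        assert p + p_t == pytest.approx(1.0)

    def test_zero_margin_warns_not_raises(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert chisq_one_sided(CollapsedCounts(0, 10, 0, 10)) == 1.0


class TestOddsRatio:
    def test_dmis_stratum_point_estimate(self):
        or_, ci = odds_ratio(CollapsedCounts(8, 574, 3, 828))
        assert round(or_, 1) == 3.9
        lo, hi = ci
        assert lo == pytest.approx(1.03, abs=0.01)  # Woolf log-OR interval
        assert hi == pytest.approx(14.71, abs=0.01)

    def test_null_stratum_point_estimate(self):
        or_, _ = odds_ratio(CollapsedCounts(8, 574, 11, 828))
        assert round(or_, 1) == 1.0

    def test_equal_rates_equal_cohorts_give_exactly_one(self):
        or_, _ = odds_ratio(CollapsedCounts(7, 100, 7, 100))
        assert or_ == 1.0

    def test_zero_cell_is_undefined_not_infinite(self):
        assert odds_ratio(CollapsedCounts(1, 574, 0, 828)) == (None, None)
        assert odds_ratio(CollapsedCounts(0, 574, 1, 828)) == (None, None)

    @given(counts_small)
    def test_transposed_or_is_reciprocal(self, tbl):
        a, n1, c, n2 = tbl
        counts = CollapsedCounts(a, n1, c, n2)
        or_, _ = odds_ratio(counts)
        or_t, _ = odds_ratio(counts.transpose_cohorts())
        if or_ is not None:
            assert or_t == pytest.approx(1.0 / or_)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputFormatError):
            CollapsedCounts(5, 4, 0, 10)


def _mkvar(i, consequence="missense", cadd=25.0):
    return AnnotatedVariant(
        chrom="15", pos=48_700_000 + i, ref="A", alt="C", gene="FBN1",
        consequence=consequence, cadd=cadd, protein_pos=10,
    )


class TestCollapseCarriers:
    def test_subject_with_two_variants_counts_once(self):
        v1, v2 = _mkvar(1), _mkvar(2)
        genotypes = {"S1": {v1.variant_id, v2.variant_id}, "S2": set()}
        counts = collapse_carriers([v1, v2], genotypes, ["S1", "S2"], ["C1"])
        assert counts == CollapsedCounts(1, 2, 0, 1)

    def test_unassigned_subject_is_error(self):
        v = _mkvar(1)
        with pytest.raises(InputFormatError, match="no cohort"):
            collapse_carriers([v], {"ghost": {v.variant_id}}, ["S1"], ["C1"])

    def test_overlapping_cohorts_rejected(self):
        with pytest.raises(InputFormatError):
            collapse_carriers([], {}, ["S1"], ["S1"])

    @given(st.data())
    def test_matches_brute_force_any(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        n_sub, n_var = 12, 6
        variants = [_mkvar(i) for i in range(n_var)]
        matrix = rng.integers(0, 2, size=(n_sub, n_var))
        subjects = [f"S{i}" for i in range(n_sub)]
        cases, controls = subjects[:7], subjects[7:]
        genotypes = {
            s: {variants[j].variant_id for j in range(n_var) if matrix[i, j]}
            for i, s in enumerate(subjects)
        }
        qualifying = data.draw(st.sets(st.integers(0, n_var - 1)))
        q_variants = [variants[j] for j in sorted(qualifying)]
        counts = collapse_carriers(q_variants, genotypes, cases, controls)
        cols = sorted(qualifying)
        expected_a = int(matrix[:7, cols].any(axis=1).sum()) if cols else 0
        expected_c = int(matrix[7:, cols].any(axis=1).sum()) if cols else 0
        assert (counts.a, counts.c) == (expected_a, expected_c)

    def test_allele_counts_tally_per_carrier(self):
        v = _mkvar(1)
        genotypes = {"S1": {v.variant_id}, "S2": {v.variant_id}, "C1": set()}
        assert allele_counts([v], genotypes, ["S1", "S2"], ["C1"]) == (2, 0)


class TestStratifiedBurden:
    def test_reference_inventory_rows(self, reference_dataset):
        ds = reference_dataset
        rows = {
            r.stratum: r
            for r in stratified_burden(ds.variants, ds.genotypes, ds.cases, ds.controls)
        }
        total = rows["Total"]
        assert (total.n_variants, total.counts.a, total.counts.c) == (30, 16, 14)
        low = rows["CADD score < 20"]
        assert (low.n_variants, low.counts.a, low.counts.c) == (19, 8, 11)
        dmis = rows["CADD score >= 20"]
        assert (dmis.n_variants, dmis.counts.a, dmis.counts.c) == (11, 8, 3)

    def test_empty_variant_set_yields_zero_rows(self):
        rows = stratified_burden([], {"S1": set(), "C1": set()}, ["S1"], ["C1"])
        assert all(r.n_variants == 0 and r.p_value is None for r in rows)

    def test_small_expected_counts_force_exact_test(self, reference_dataset):
        ds = reference_dataset
        rows = {
            r.stratum: r
            for r in stratified_burden(
                ds.variants, ds.genotypes, ds.cases, ds.controls, test="chisq"
            )
        }
        # D-mis stratum has min expected cell 4.5 < 5 -> Fisher despite config
        assert rows["CADD score >= 20"].test == "fisher_one_sided"
        # Total stratum has all expected cells >= 5 -> configured chi-square
        assert rows["Total"].test == "chisq_one_sided"


class TestRendering:
    def test_degenerate_or_renders_dash(self):
        from csburden.burden import BurdenRow

        row = BurdenRow("Splicing", 1, CollapsedCounts(1, 574, 0, 828),
                        None, None, 0.409, "fisher_one_sided", indent=True)
        rendered = format_row(row)
        assert rendered["OR (95% CI)"] == "–"
        assert rendered["P value"] == "0.41"

    def test_table_contains_all_strata(self, reference_dataset):
        ds = reference_dataset
        rows = stratified_burden(ds.variants, ds.genotypes, ds.cases, ds.controls)
        text = render_table(rows)
        for label in ("Total", "Frameshift", "Splicing", "CADD score >= 20"):
            assert label in text
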