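"""Tests for pileup, variant calling, Wilson intervals, spectrum, asymmetry
and region comparison."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from duplexmt.consensus import ConsensusRead, Segment
from duplexmt.reference import RegionAnnotation
from duplexmt.stats import (
    COLLAPSED_CLASSES,
    DIRECTIONAL_CLASSES,
    VariantCall,
    base_exposures,
    build_pileup,
    call_variants,
    compare_groups,
    de_novo_calls,
    fold_change,
    mutation_frequency,
    region_compare,
    region_frequency,
    region_mask,
    spectrum,
    strand_asymmetry,
    two_proportion_pvalue,
    welch_ttest,
    wilson_interval,
)
from tests.conftest import make_toy_genome


def make_read(start, bases):
    key = ("A" * 24, ((start, False), (start, True)))
    return ConsensusRead(
        level="DCS", segments=(Segment(start, bases),),
        coordinates=key[1], family_sizes=(3, 3), source_keys=(key[0],),
        family_key=key,
    )


def synthetic_pileup(genome, coverage, variants):
    """Pileup with uniform single-segment reads plus variant reads.

    ``variants``: list of (position, alt, n_mutant). The total depth at each
    covered position is ``coverage``.
    """
    reads = []
    muts = {}
    for pos, alt, k in variants:
        muts.setdefault(pos, []).extend([alt] * k)
    for i in range(coverage):
        seq = list(genome.sequence)
        for pos, alts in muts.items():
            if i < len(alts):
                seq[pos - 1] = alts[i]
        reads.append(make_read(1, "".join(seq)))
    return build_pileup(reads, genome)


class TestBuildPileup:
    def test_counts_and_wrap(self):
        g = make_toy_genome("ACGTACGTAC")
        reads = [make_read(9, "ACAC")]  # wraps: 9,10,1,2
        p = build_pileup(reads, g)
        assert p.total_bases == 4
        assert p.counts[8, 0] == 1  # pos 9 = A
        assert p.counts[0, 0] == 1  # pos 1 = A
        assert p.counts[1, 1] == 1  # pos 2 = C

    def test_n_bases_ignored(self):
        g = make_toy_genome("ACGTACGTAC")
        p = build_pileup([make_read(1, "ANGT")], g)
        assert p.total_bases == 3
        assert p.depth[1] == 0

    def test_out_of_range_segment_errors(self):
        g = make_toy_genome("ACGTACGTAC")
        with pytest.raises(ValueError, match="outside"):
            build_pileup([make_read(11, "ACGT")], g)


class TestCallVariants:
    def test_flags_and_exclusion(self):
        g = make_toy_genome("ACGTACGTAC" * 3)
        p = synthetic_pileup(g, 1000, [(5, "G", 20), (7, "C", 5), (9, "T", 950)])
        calls = call_variants(p, g)
        by_pos = {c.position: c for c in calls}
        assert by_pos[5].clonality == pytest.approx(0.02)
        assert by_pos[5].is_clonal and not by_pos[5].is_homoplasmic
        assert by_pos[7].clonality == pytest.approx(0.005)
        assert not by_pos[7].is_clonal
        assert by_pos[9].is_clonal and by_pos[9].is_homoplasmic
        dn = de_novo_calls(calls)
        assert [c.position for c in dn] == [7]

    def test_boundary_is_strict_greater(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 100, [(5, "G", 1)])
        # clonality exactly 1% is NOT clonal (cutoff is strict >)
        call = call_variants(p, g, clonality_cutoff=0.01)[0]
        assert call.clonality == pytest.approx(0.01)
        assert not call.is_clonal

    def test_indels_reported(self):
        g = make_toy_genome("ACGTACGTAC")
        p = synthetic_pileup(g, 10, [])
        p.add_indel(4, "+AC", 2)
        calls = call_variants(p, g)
        assert len(calls) == 1
        c = calls[0]
        assert c.is_indel and c.alt == "+AC" and c.mutant_count == 2

    def test_region_annotation(self):
        g = make_toy_genome("ACGTACGTAC" * 6)
        ann = [RegionAnnotation("d", 55, 5, "control")]
        p = synthetic_pileup(g, 200, [(3, "C", 1), (30, "A", 1)])
        calls = call_variants(p, g, annotations=ann)
        by_pos = {c.position: c for c in calls}
        assert by_pos[3].region_class == "control"
        assert by_pos[30].region_class == "intergenic"


class TestWilsonInterval:
    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 10_000))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_bounds_clamped(self):
        lo, hi = wilson_interval(0, 10)
        assert lo == 0.0
        lo, hi = wilson_interval(10, 10)
        assert hi == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 4)

    def test_confidence_widens(self):
        lo95, hi95 = wilson_interval(5, 100, 0.95)
        lo99, hi99 = wilson_interval(5, 100, 0.99)
        assert lo99 < lo95 and hi99 > hi95


class TestMutationFrequency:
    def test_unique_sites_over_total_bases(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 500, [(5, "G", 2), (30, "A", 1)])
        calls = de_novo_calls(call_variants(p, g))
        est = mutation_frequency(calls, p)
        assert est.k == 2  # two unique sites, not three molecules
        assert est.n == p.total_bases
        assert est.frequency == pytest.approx(2 / p.total_bases)
        assert est.lower <= est.frequency <= est.upper

    def test_count_molecules_mode(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 500, [(5, "G", 2)])
        calls = de_novo_calls(call_variants(p, g))
        est = mutation_frequency(calls, p, count_molecules=True)
        assert est.k == 2

    def test_indels_not_in_substitution_frequency(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 500, [])
        p.add_indel(4, "-2", 1)
        calls = de_novo_calls(call_variants(p, g))
        est = mutation_frequency(calls, p)
        assert est.k == 0

    def test_empty_pileup_errors(self):
        g = make_toy_genome("ACGT")
        with pytest.raises(ValueError):
            mutation_frequency([], build_pileup([], g))


class TestSpectrum:
    def test_class_structure(self):
        assert len(DIRECTIONAL_CLASSES) == 12
        assert len(COLLAPSED_CLASSES) == 6
        # each collapsed class holds complementary members
        from duplexmt.reference import complement

        for (a, b), (c, d) in COLLAPSED_CLASSES:
            assert (complement(a), complement(b)) == (c, d)

    def test_exposure_normalization(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 100, [(1, "G", 1)])  # A->G at an A position
        calls = de_novo_calls(call_variants(p, g))
        table = spectrum(calls, p)
        exp = base_exposures(p)
        row = table.directional.loc["A>G"]
        assert row["sites"] == 1
        assert row["exposure"] == exp["A"]
        assert row["frequency"] == pytest.approx(1 / exp["A"])

    def test_proportions_sum_to_one(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 100, [(1, "G", 1), (2, "T", 1), (3, "A", 1)])
        p.add_indel(50, "+A", 1)
        calls = de_novo_calls(call_variants(p, g))
        table = spectrum(calls, p)
        total = table.collapsed["proportion"].sum() + table.indel_proportion
        assert total == pytest.approx(1.0)

    def test_indel_frequency_per_total_bases(self):
        g = make_toy_genome("ACGTACGTAC" * 10)
        p = synthetic_pileup(g, 100, [])
        p.add_indel(50, "+A", 1)
        calls = de_novo_calls(call_variants(p, g))
        table = spectrum(calls, p)
        assert table.indel_sites == 1
        assert table.indel_frequency == pytest.approx(1 / p.total_bases)


class TestTwoProportion:
    def test_agrees_with_exact_binomial_at_spec_example(self):
        # 20 vs 5 events on equal exposures: conditional exact test
        n = 100_000
        p_z = two_proportion_pvalue(20, n, 5, n)
        p_exact = sps.binomtest(20, 25, 0.5).pvalue
        assert p_z < 0.05 and p_exact < 0.05
        assert abs(p_z - p_exact) < 0.005

    def test_no_events_p_one(self):
        assert two_proportion_pvalue(0, 100, 0, 100) == 1.0

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            two_proportion_pvalue(1, 0, 1, 10)


class TestStrandAsymmetry:
    def test_ratio_and_missing(self):
        g = make_toy_genome("ACGTACGTAC" * 100)  # equal base composition
        p = synthetic_pileup(g, 200, [(3, "A", 1)])  # one G->A
        calls = de_novo_calls(call_variants(p, g))
        table = strand_asymmetry(calls, p)
        row = table.loc["C>T/G>A"]
        assert row["sites_2"] == 1 and row["sites_1"] == 0
        assert row["ratio"] == 0.0  # zero numerator frequency, defined ratio
        # rows with zero events on both sides have p = 1
        assert table.loc["A>C/T>G", "p_value"] == 1.0

    def test_reciprocal_imbalance_detected(self):
        g = make_toy_genome("ACGTACGTAC" * 100)
        # 20 G->A sites versus 5 C->T sites
        variants = [(3 + 10 * i, "A", 1) for i in range(20)]
        variants += [(2 + 10 * i, "T", 1) for i in range(5)]
        p = synthetic_pileup(g, 200, variants)
        calls = de_novo_calls(call_variants(p, g))
        table = strand_asymmetry(calls, p)
        row = table.loc["C>T/G>A"]
        assert row["sites_1"] == 5 and row["sites_2"] == 20
        exp = base_exposures(p)
        want = (5 / exp["C"]) / (20 / exp["G"])
        assert row["ratio"] == pytest.approx(want)
        assert row["p_value"] < 0.05


class TestRegions:
    def _ann(self):
        return [RegionAnnotation("d", 55, 5, "control")]

    def test_region_mask_wraps(self):
        g = make_toy_genome("ACGTACGTAC" * 6)
        mask = region_mask(g, self._ann(), "control")
        assert mask[54] and mask[59] and mask[0] and mask[4]
        assert not mask[5] and not mask[53]
        assert (~mask == region_mask(g, self._ann(), "non_control")).all()

    def test_region_frequency(self):
        g = make_toy_genome("ACGTACGTAC" * 6)
        p = synthetic_pileup(g, 100, [(1, "G", 1), (30, "A", 1)])
        calls = de_novo_calls(call_variants(p, g))
        ctrl = region_frequency(calls, p, self._ann(), "control")
        rest = region_frequency(calls, p, self._ann(), "non_control")
        assert ctrl.k == 1 and rest.k == 1
        assert ctrl.n == 100 * 11 and rest.n == 100 * 49

    def test_region_compare_identical_fold_one(self):
        g = make_toy_genome("ACGTACGTAC" * 6)
        samples = []
        for _ in range(3):
            p = synthetic_pileup(g, 100, [(1, "G", 1), (30, "C", 1),
                                          (60, "C", 1), (20, "A", 1)])
            calls = de_novo_calls(call_variants(p, g))
            samples.append((calls, p))
        # same counts per sample; compare control vs control (identical)
        res = region_compare(samples, self._ann(), "control", "control")
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_region_compare_needs_two_samples(self):
        g = make_toy_genome("ACGTACGTAC" * 6)
        p = synthetic_pileup(g, 10, [])
        with pytest.raises(ValueError, match="at least 2"):
            region_compare([([], p)], self._ann())

    def test_fold_change_delta_method(self):
        f, sd = fold_change(2e-5, 2e-6, 1e-5, 1e-6)
        assert f == pytest.approx(2.0)
        want = 2.0 * math.sqrt(0.1**2 + 0.1**2)
        assert sd == pytest.approx(want)

    def test_fold_change_zero_denominator(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.1, 0.0, 0.0)

    def test_welch_ttest_matches_scipy(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5]
        want = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert welch_ttest(a, b) == pytest.approx(want)

    def test_welch_requires_two_per_group(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])

    def test_compare_groups(self):
        young = [3e-6, 4e-6, 4.5e-6]
        aged = [1.8e-5, 2.0e-5, 1.9e-5]
        fold, fold_sd, p = compare_groups(aged, young)
        assert fold == pytest.approx(np.mean(aged) / np.mean(young))
        assert p < 0.01
        assert fold_sd > 0
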