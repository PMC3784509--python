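"""Tests for the circular reference model, regions, and the genetic code."""

import numpy as np
import pytest

from duplexmt.reference import (
    BASES,
    GeneticCodeTable,
    ReferenceGenome,
    RegionAnnotation,
    VERTEBRATE_MITO_CODE,
    classify_substitution,
    complement,
    decode_bases,
    encode_bases,
    expected_nonsynonymous_fraction,
    load_reference,
    region_of,
    reverse_complement,
    strand_base_counts,
)
from tests.conftest import make_toy_genome


class TestEncoding:
    def test_roundtrip(self):
        s = "ACGTNACGT"
        assert decode_bases(encode_bases(s)) == s

    def test_codes(self):
        assert encode_bases("ACGTN").tolist() == [0, 1, 2, 3, 4]

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            encode_bases("ACGX")


class TestComplement:
    def test_complement(self):
        assert complement("A") == "T"
        assert complement("G") == "C"
        assert complement("N") == "N"

    def test_reverse_complement(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AAC") == "GTT"

    def test_double_reverse_complement_is_identity(self):
        s = "ACGGTTAACGT"
        assert reverse_complement(reverse_complement(s)) == s


class TestReferenceGenome:
    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ReferenceGenome(name="bad", sequence="ACGTX")

    def test_wrap(self):
        g = make_toy_genome("ACGTACGTAC")
        assert g.wrap(1) == 1
        assert g.wrap(10) == 10
        assert g.wrap(11) == 1
        assert g.wrap(0) == 10
        assert g.wrap(-1) == 9

    def test_base_at_wraps(self):
        g = make_toy_genome("ACGT")
        assert g.base_at(1) == "A"
        assert g.base_at(5) == "A"
        assert g.base_at(4) == "T"

    def test_fetch_wraps_origin(self):
        g = make_toy_genome("ACGTACGTAC")
        assert g.fetch(9, 4) == "ACAC"

    def test_fetch_equals_rotated_linear(self):
        # wrap correctness: fetching across the origin equals fetching the
        # same stretch from a rotated copy of the genome
        g = make_toy_genome("ACGTTGCAAC")
        rot = make_toy_genome(g.sequence[5:] + g.sequence[:5])
        assert g.fetch(6, 8) == rot.fetch(1, 8)

    def test_load_single_record_enforced(self, tmp_path):
        p = tmp_path / "multi.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="exactly one"):
            load_reference(p)

    def test_load_uppercases(self, tmp_path):
        p = tmp_path / "lc.fa"
        p.write_text(">a\nacgt\n")
        assert load_reference(p).sequence == "ACGT"


class TestPackagedReference:
    def test_length(self, genome):
        assert genome.length == 16569

    def test_base_composition_l_strand_is_c_rich(self, genome):
        counts = strand_base_counts(genome)
        assert sum(counts.values()) == genome.length
        # the light strand carries far more C than G
        assert counts["C"] > 2 * counts["G"]

    def test_annotations_cover_13_protein_genes(self, annotations):
        genes = [a for a in annotations if a.region_class == "protein_coding"]
        assert len(genes) == 13
        l_strand = [g for g in genes if g.coding_strand == "L"]
        assert [g.label for g in l_strand] == ["MT-ND6"]

    def test_control_region_wraps_origin(self, annotations):
        ctrl = [a for a in annotations if a.region_class == "control"]
        assert len(ctrl) == 1
        assert ctrl[0].start == 16024 and ctrl[0].end == 576

    def test_all_genes_are_clean_orfs(self, genome, annotations):
        code = VERTEBRATE_MITO_CODE
        for gene in annotations:
            if gene.region_class != "protein_coding":
                continue
            n = gene.span(genome.length)
            sense = genome.fetch(gene.start, n)
            if gene.coding_strand == "L":
                sense = reverse_complement(sense)
            # no internal stop in any complete codon
            for i in range(0, (n // 3 - 1) * 3, 3):
                assert not code.is_stop(sense[i : i + 3]), (gene.label, i)


class TestRegionAnnotation:
    def test_contains_simple(self):
        a = RegionAnnotation("x", 10, 20, "tRNA")
        assert a.contains(10) and a.contains(20) and not a.contains(21)

    def test_contains_wrapping(self):
        a = RegionAnnotation("dloop", 55, 5, "control")
        assert a.contains(55) and a.contains(60) and a.contains(1)
        assert a.contains(5) and not a.contains(6) and not a.contains(54)

    def test_span_wrapping(self):
        a = RegionAnnotation("dloop", 55, 5, "control")
        assert a.span(60) == 11

    def test_positions_wrap_in_order(self):
        a = RegionAnnotation("dloop", 58, 2, "control")
        assert a.positions(60).tolist() == [58, 59, 60, 1, 2]


class TestRegionOf:
    def test_precedence_and_fallback(self, toy_genome, toy_annotations):
        assert region_of(toy_genome, toy_annotations, 12) == "protein_coding"
        assert region_of(toy_genome, toy_annotations, 60) == "control"
        assert region_of(toy_genome, toy_annotations, 3) == "control"  # wraps
        assert region_of(toy_genome, toy_annotations, 30) == "intergenic"

    def test_out_of_range(self, toy_genome, toy_annotations):
        with pytest.raises(ValueError):
            region_of(toy_genome, toy_annotations, 0)
        with pytest.raises(ValueError):
            region_of(toy_genome, toy_annotations, 61)

    def test_dloop_positions_on_packaged(self, genome, annotations):
        assert region_of(genome, annotations, 16300) == "control"
        assert region_of(genome, annotations, 300) == "control"
        assert region_of(genome, annotations, 576) == "control"
        assert region_of(genome, annotations, 3400) == "protein_coding"


class TestGeneticCode:
    def test_vertebrate_mito_deviations(self):
        code = VERTEBRATE_MITO_CODE
        assert code.translate("ATA") == "M"  # Ile in the standard code
        assert code.translate("TGA") == "W"  # stop in the standard code
        assert code.is_stop("AGA") and code.is_stop("AGG")
        assert code.is_stop("TAA") and code.is_stop("TAG")

    def test_custom_code_must_be_complete(self):
        with pytest.raises(ValueError):
            GeneticCodeTable({"AAA": "K"})


def _oracle_classify(genome, gene, code, pos, alt):
    """Independent classification: rebuild the full mutant gene sequence and
    translate both versions codon by codon."""
    n = gene.span(genome.length)
    positions = [int(p) for p in gene.positions(genome.length)]
    sense = list(genome.fetch(gene.start, n))
    mut = list(sense)
    mut[positions.index(pos)] = alt
    if gene.coding_strand == "L":
        sense = list(reverse_complement("".join(sense)))
        mut = list(reverse_complement("".join(mut)))
    labels = []
    for i in range(0, (n // 3) * 3, 3):
        c0 = "".join(sense[i : i + 3])
        c1 = "".join(mut[i : i + 3])
        if code.is_stop(c0):
            continue
        if c0 != c1:
            labels.append(
                "synonymous" if code.translate(c0) == code.translate(c1)
                else "nonsynonymous"
            )
    return labels[0] if labels else "noncoding"


class TestClassifySubstitution:
    def test_alt_equal_ref_rejected(self, toy_genome, toy_annotations, standard_code):
        ref = toy_genome.base_at(12)
        with pytest.raises(ValueError):
            classify_substitution(
                toy_genome, toy_annotations, standard_code, 12, ref
            )

    def test_non_canonical_alt_rejected(self, toy_genome, toy_annotations,
                                        standard_code):
        with pytest.raises(ValueError):
            classify_substitution(toy_genome, toy_annotations, standard_code, 12, "N")

    def test_noncoding_positions(self, toy_genome, toy_annotations, standard_code):
        ref = toy_genome.base_at(30)
        alt = "A" if ref != "A" else "G"
        assert classify_substitution(
            toy_genome, toy_annotations, standard_code, 30, alt
        ) == "noncoding"

    def test_stop_codon_positions_are_noncoding(self, toy_genome, toy_annotations,
                                                standard_code):
        # positions 16-18 are the TAA stop of the toy gene
        for pos in (16, 17, 18):
            ref = toy_genome.base_at(pos)
            alt = "C" if ref != "C" else "G"
            assert classify_substitution(
                toy_genome, toy_annotations, standard_code, pos, alt
            ) == "noncoding"

    def test_matches_oracle_on_packaged_genes(self, genome, annotations,
                                              standard_code):
        rng = np.random.default_rng(42)
        genes = [a for a in annotations if a.region_class == "protein_coding"]
        checked = 0
        for gene in genes:
            positions = gene.positions(genome.length)
            for pos in rng.choice(positions, size=20, replace=False):
                pos = int(pos)
                # skip positions inside overlapping genes: the oracle is
                # single-gene, the implementation applies the any-gene rule
                if sum(g.contains(pos) for g in genes) > 1:
                    continue
                ref = genome.base_at(pos)
                for alt in BASES:
                    if alt == ref:
                        continue
                    got = classify_substitution(
                        genome, annotations, standard_code, pos, alt
                    )
                    want = _oracle_classify(genome, gene, standard_code, pos, alt)
                    assert got == want, (gene.label, pos, ref, alt)
                    checked += 1
        assert checked > 500

    def test_any_gene_rule_at_overlap(self, genome, annotations, standard_code):
        # ATP8/ATP6 overlap: positions belong to both reading frames; a call
        # is nonsynonymous when either frame changes protein
        atp8 = next(a for a in annotations if a.label == "MT-ATP8")
        atp6 = next(a for a in annotations if a.label == "MT-ATP6")
        overlap = [
            p for p in range(atp6.start, atp8.end + 1)
            if atp8.contains(p) and atp6.contains(p)
        ]
        assert overlap, "annotation should contain the ATP8/ATP6 overlap"
        for pos in overlap[:6]:
            ref = genome.base_at(pos)
            for alt in BASES:
                if alt == ref:
                    continue
                got = classify_substitution(
                    genome, annotations, standard_code, pos, alt
                )
                in8 = _oracle_classify(genome, atp8, standard_code, pos, alt)
                in6 = _oracle_classify(genome, atp6, standard_code, pos, alt)
                labels = {x for x in (in8, in6) if x != "noncoding"}
                want = (
                    "nonsynonymous" if "nonsynonymous" in labels
                    else ("synonymous" if labels else "noncoding")
                )
                assert got == want


class TestExpectedNonsynonymousFraction:
    def test_toy_gene_exact(self, toy_genome, toy_annotations, standard_code):
        # Toy gene codons: ATG (Met), GCA (Ala); stop TAA excluded.
        # Enumerate by hand over the 6 coding positions x 3 alts = 18 subs.
        n_ns = n_syn = 0
        for pos in range(10, 16):
            ref = toy_genome.base_at(pos)
            for alt in BASES:
                if alt == ref:
                    continue
                lab = _oracle_classify(
                    toy_genome, toy_annotations[0], standard_code, pos, alt
                )
                if lab == "nonsynonymous":
                    n_ns += 1
                elif lab == "synonymous":
                    n_syn += 1
        want = n_ns / (n_ns + n_syn)
        got = expected_nonsynonymous_fraction(
            toy_genome, toy_annotations, standard_code
        )
        assert got == pytest.approx(want)

    def test_requires_protein_annotations(self, toy_genome):
        with pytest.raises(ValueError):
            expected_nonsynonymous_fraction(toy_genome, [])
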