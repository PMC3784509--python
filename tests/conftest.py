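"""Shared fixtures: packaged reference data, toy genomes, and a pipeline
runner helper."""

from __future__ import annotations

import pytest

from duplexmt.reference import (
    GeneticCodeTable,
    ReferenceGenome,
    RegionAnnotation,
    packaged_annotations,
    packaged_reference,
)


@pytest.fixture(scope="session")
def genome() -> ReferenceGenome:
    return packaged_reference()


@pytest.fixture(scope="session")
def annotations() -> list[RegionAnnotation]:
    return list(packaged_annotations())


def make_toy_genome(sequence: str, name: str = "toy") -> ReferenceGenome:
    return ReferenceGenome(name=name, sequence=sequence.upper())


# A 60-bp toy genome with one 30-codon-free protein gene on the forward
# strand (positions 10..27: three codons + stop would not fit; keep it
# simple: gene of 2 codons + stop).
#
#   positions 1-9   : padding (noncoding)
#   positions 10-18 : gene "G1" (+): ATG GCA TAA  (Met-Ala-stop)
#   positions 19-60 : padding
TOY_SEQ = "ACGTACGTA" + "ATGGCATAA" + "GGGTTTAACCCGTACTCGATCGATCGGCTAGCTAACGTAGCT"
assert len(TOY_SEQ) == 60


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    return make_toy_genome(TOY_SEQ)


@pytest.fixture()
def toy_annotations() -> list[RegionAnnotation]:
    return [
        RegionAnnotation(
            label="G1", start=10, end=18, region_class="protein_coding",
            coding_strand="H",
        ),
        RegionAnnotation(
            label="CTRL", start=55, end=5, region_class="control",
            coding_strand=".",
        ),
    ]


@pytest.fixture()
def standard_code() -> GeneticCodeTable:
    from duplexmt.reference import VERTEBRATE_MITO_CODE

    return VERTEBRATE_MITO_CODE
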