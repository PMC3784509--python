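"""Circular mitochondrial reference model, region annotation, and the
vertebrate mitochondrial genetic code.

Conventions
-----------
* The reference sequence is always the light strand (L-strand), the C-rich
  strand of human mtDNA, stored 5'->3' as deposited in GenBank-style records.
* Coordinates are 1-based inclusive and wrap modulo the genome length: the
  base "after" position L is position 1. Region annotations may span the
  origin (``end < start``), as the D-loop (bp 16024-576) does.
* ``coding_strand`` of an annotation follows mitochondrial usage: ``H`` marks
  genes of the heavy-strand transcription unit, whose sense sequence is read
  directly off the L-strand reference; ``L`` marks genes of the light-strand
  unit (ND6 and eight tRNAs), whose sense sequence is the reverse complement.
* Substitutions are always expressed on the L-strand: an event written
  G->T means the reference L-strand base G was replaced by T; the same
  physical event seen from the H-strand is C->A.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: vertebrate mitochondrial code (NCBI translation table 2):
#: ATA=Met, TGA=Trp, AGA/AGG=Stop
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

STOP = "*"


def complement(base: str) -> str:
    """Complement of a base (or base string), preserving N."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneticCodeTable:
    """Mapping of the 64 codons to amino-acid symbols, stops as ``*``.

    Defaults to the vertebrate mitochondrial code. A custom mapping may be
    supplied for testing toy codes.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        if mapping is None:
            mapping = dict(_MITO_TABLE.forward_table)
            for codon in _MITO_TABLE.stop_codons:
                mapping[codon] = STOP
        if len(mapping) != 64:
            raise ValueError(f"genetic code must map 64 codons, got {len(mapping)}")
        self.mapping = dict(mapping)

    def translate(self, codon: str) -> str:
        return self.mapping[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP


VERTEBRATE_MITO_CODE = GeneticCodeTable()


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular reference genome stored as its L-strand sequence."""

    name: str
    sequence: str
    circular: bool = True
    _codes: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        bad = sorted(set(self.sequence) - set(BASES))
        if bad:
            positions = [i + 1 for i, b in enumerate(self.sequence) if b in bad][:10]
            raise ValueError(
                f"non-ACGT characters {bad} in reference "
                f"(first positions: {positions})"
            )
        codes = encode_bases(self.sequence)
        object.__setattr__(self, "_codes", codes)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """Sequence as uint8 codes A=0 C=1 G=2 T=3 (read-only view)."""
        return self._codes

    def wrap(self, pos: int) -> int:
        """Map any integer onto a valid 1-based position on the circle."""
        return (pos - 1) % self.length + 1

    def base_at(self, pos: int) -> str:
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """``length`` bases starting at 1-based ``start``, wrapping the origin."""
        if length < 0:
            raise ValueError("length must be non-negative")
        return decode_bases(self.fetch_codes(start, length))

    def fetch_codes(self, start: int, length: int) -> np.ndarray:
        idx = (np.arange(start - 1, start - 1 + length)) % self.length
        return self._codes[idx]


_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES + "N"):
    _ENCODE_LUT[ord(_b)] = _i
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class RegionAnnotation:
    """One annotated region; ``end < start`` denotes an origin-spanning region."""

    label: str
    start: int
    end: int
    region_class: str  # protein_coding | rRNA | tRNA | control
    coding_strand: str = "H"  # H: sense on the reference; L: sense on its complement
    reading_frame_offset: int = 0

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def span(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> np.ndarray:
        """1-based positions of the region in sense order on the L-strand."""
        n = self.span(genome_length)
        return (np.arange(self.start - 1, self.start - 1 + n) % genome_length) + 1


def load_reference(fasta_path) -> ReferenceGenome:
    """Load a single-record FASTA as a circular reference genome.

    Lowercase input is uppercased; more than one record, or characters
    outside ACGT, raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record, found {len(records)} in {fasta_path}"
        )
    rec = records[0]
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper())


def load_annotations(tsv_path) -> list[RegionAnnotation]:
    """Read a BED-like annotation TSV (1-based inclusive, header line).

    Columns: label, start, end, region_class, coding_strand, frame.
    """
    anns: list[RegionAnnotation] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["label", "start", "end", "region_class", "coding_strand", "frame"]
        if header != expected:
            raise ValueError(f"annotation header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            label, start, end, rclass, strand, frame = line.rstrip("\n").split("\t")
            anns.append(
                RegionAnnotation(
                    label=label,
                    start=int(start),
                    end=int(end),
                    region_class=rclass,
                    coding_strand=strand,
                    reading_frame_offset=int(frame),
                )
            )
    return anns


def packaged_reference() -> ReferenceGenome:
    """The packaged 16,569-bp synthetic human-mtDNA surrogate reference.

    Built from a real human mitochondrial genome (GenBank NC_001807.4) with
    two control-region poly-C bases removed so that every gene sits at the
    standard rCRS coordinates; see scripts/make_surrogate_reference.py. It is
    a synthetic surrogate: coding content is real, the exact sequence is not
    the rCRS.
    """
    path = importlib.resources.files("duplexmt.data") / "mito_surrogate.fa"
    return load_reference(str(path))


def packaged_annotations() -> list[RegionAnnotation]:
    """Standard 37-gene + D-loop human mtDNA annotation (rCRS coordinates)."""
    path = importlib.resources.files("duplexmt.data") / "mito_annotation.tsv"
    return load_annotations(str(path))


def region_of(
    genome: ReferenceGenome, annotations: Sequence[RegionAnnotation], pos: int
) -> str:
    """Region class containing ``pos`` (wrap-aware); ``intergenic`` if none.

    Protein-coding regions take precedence over overlapping RNA annotations.
    """
    if not (1 <= pos <= genome.length):
        raise ValueError(f"position {pos} outside 1..{genome.length}")
    hits = [a for a in annotations if a.contains(pos)]
    if not hits:
        return "intergenic"
    for cls in ("protein_coding", "control", "rRNA", "tRNA"):
        if any(a.region_class == cls for a in hits):
            return cls
    return hits[0].region_class


@functools.lru_cache(maxsize=256)
def _gene_sense_index(
    genome: ReferenceGenome, gene: RegionAnnotation
) -> tuple[str, dict[int, int]]:
    """Cached (sense sequence, position -> sense offset) for one gene."""
    n = gene.span(genome.length)
    positions = gene.positions(genome.length)
    sense = genome.fetch(gene.start, n)
    if gene.coding_strand == "L":
        sense = reverse_complement(sense)
        positions = positions[::-1]
    return sense, {int(p): i for i, p in enumerate(positions)}


def _codon_context(
    genome: ReferenceGenome, gene: RegionAnnotation, pos: int
) -> tuple[str, int] | None:
    """(sense codon, 0-based offset of ``pos`` within it) for ``pos`` in ``gene``.

    Returns ``None`` for positions in the trailing incomplete codon. The gene
    sense sequence is the L-strand slice for H-unit genes, its reverse
    complement for L-unit genes.
    """
    sense, index = _gene_sense_index(genome, gene)
    n = len(sense)
    k = index[pos] - gene.reading_frame_offset
    if k < 0:
        return None
    codon_idx, within = divmod(k, 3)
    lo = gene.reading_frame_offset + codon_idx * 3
    if lo + 3 > n:
        return None  # trailing incomplete codon (completed by polyadenylation)
    return sense[lo : lo + 3], within


def classify_substitution(
    genome: ReferenceGenome,
    annotations: Sequence[RegionAnnotation],
    code: GeneticCodeTable,
    pos: int,
    alt: str,
) -> str:
    """Classify an L-strand substitution as synonymous/nonsynonymous/noncoding.

    A position overlapped by several protein-coding genes is nonsynonymous if
    the change is nonsynonymous in ANY gene context; nonsense changes count as
    nonsynonymous. Positions inside a terminal stop codon carry no amino-acid
    meaning and are treated as noncoding. rRNA/tRNA/control positions are
    noncoding.
    """
    alt = alt.upper()
    if alt not in BASES:
        raise ValueError(f"alt base {alt!r} is not one of {BASES}")
    ref = genome.base_at(pos)
    if alt == ref:
        raise ValueError(f"alt equals the reference base {ref} at position {pos}")
    labels = []
    for gene in annotations:
        if gene.region_class != "protein_coding" or not gene.contains(pos):
            continue
        ctx = _codon_context(genome, gene, pos)
        if ctx is None:
            continue
        codon, within = ctx
        if code.is_stop(codon):
            continue  # terminal stop codon: excluded from coding accounting
        alt_sense = alt if gene.coding_strand == "H" else complement(alt)
        new_codon = codon[:within] + alt_sense + codon[within + 1 :]
        labels.append(
            "synonymous"
            if code.translate(new_codon) == code.translate(codon)
            else "nonsynonymous"
        )
    if not labels:
        return "noncoding"
    return "nonsynonymous" if "nonsynonymous" in labels else "synonymous"


def expected_nonsynonymous_fraction(
    genome: ReferenceGenome,
    annotations: Sequence[RegionAnnotation],
    code: GeneticCodeTable = VERTEBRATE_MITO_CODE,
) -> float:
    """Fraction of all possible coding point substitutions that change protein.

    Enumerates the three alternative bases at every protein-coding position,
    classifies each with the same rules as :func:`classify_substitution`
    (any-gene rule at overlaps, stop/partial codons excluded), and returns
    nonsynonymous / (nonsynonymous + synonymous): the non-synonymous fraction
    expected if mutations strike coding sites uniformly at random.
    """
    genes = [a for a in annotations if a.region_class == "protein_coding"]
    if not genes:
        raise ValueError("no protein_coding annotations supplied")
    coding_positions: set[int] = set()
    for gene in genes:
        coding_positions.update(int(p) for p in gene.positions(genome.length))
    n_ns = n_syn = 0
    for pos in coding_positions:
        ref = genome.base_at(pos)
        for alt in BASES:
            if alt == ref:
                continue
            label = classify_substitution(genome, genes, code, pos, alt)
            if label == "nonsynonymous":
                n_ns += 1
            elif label == "synonymous":
                n_syn += 1
    return n_ns / (n_ns + n_syn)


def strand_base_counts(genome: ReferenceGenome) -> dict[str, int]:
    """Counts of A, C, G, T on the L-strand; they sum to the genome length."""
    counts = np.bincount(genome.codes, minlength=4)
    return {b: int(counts[i]) for i, b in enumerate(BASES)}
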