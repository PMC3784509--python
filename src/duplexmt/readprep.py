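"""Raw read validation, duplex-tag extraction, and tag-family grouping.

A raw read is ``<12-bp tag><fixed spacer><insert...>``. The two tag halves of
a pair are concatenated in read order into the 24-nt duplex key; the two
strands of one parental molecule yield keys with mutually swapped halves.
Validation rejects pairs whose tag halves contain non-canonical bases
(``ambiguous_tag``), whose spacer does not match exactly (``bad_spacer``), or
which are too short (``too_short``); rejection is a counted outcome, not an
error. After tag and spacer removal a further ``trim_bases`` bases are
trimmed from each read start to drop end-repair/ligation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from duplexmt.reference import BASES

REJECT_BAD_SPACER = "bad_spacer"
REJECT_AMBIGUOUS_TAG = "ambiguous_tag"
REJECT_TOO_SHORT = "too_short"

_CANONICAL = set(BASES)


@dataclass(frozen=True)
class DuplexTagKey:
    """24-nt concatenated duplex tag in read order."""

    tag: str

    @property
    def half_length(self) -> int:
        return len(self.tag) // 2

    def mate_key(self) -> "DuplexTagKey":
        """Key of the opposite-strand family: the two halves swapped."""
        h = self.half_length
        return DuplexTagKey(self.tag[h:] + self.tag[:h])

    @property
    def orientation(self) -> str:
        """Nominal orientation label; mate keys get the opposite label."""
        return "alpha_beta" if self.tag <= self.mate_key().tag else "beta_alpha"


@dataclass(frozen=True)
class Rejection:
    reason: str  # bad_spacer | ambiguous_tag | too_short


#: mapping of one read: (1-based leftmost reference position, is_reverse)
ReadMapping = tuple[int, bool]


@dataclass
class PreparedReadPair:
    """A validated pair: duplex key plus technical-base-free sequences.

    ``read1``/``read2`` are reference-oriented once mappings are attached
    (as in SAM); straight from FASTQ they are in sequencing orientation.
    """

    qname: str
    key: DuplexTagKey
    read1: str
    read2: str
    mapping: tuple[ReadMapping, ReadMapping] | None = None


def validate_and_extract(
    read1: str,
    read2: str,
    spacer: str,
    tag_length: int = 12,
    trim_bases: int = 4,
    qname: str = "",
) -> PreparedReadPair | Rejection:
    """Validate a raw pair and excise tag, spacer and trim bases.

    The spacer must match exactly at its expected offset in both reads; each
    tag half may contain only canonical bases.
    """
    tech = tag_length + len(spacer) + trim_bases
    if len(read1) < tech + 1 or len(read2) < tech + 1:
        return Rejection(REJECT_TOO_SHORT)
    halves = []
    for read in (read1, read2):
        read = read.upper()
        half = read[:tag_length]
        if set(half) - _CANONICAL:
            return Rejection(REJECT_AMBIGUOUS_TAG)
        if read[tag_length : tag_length + len(spacer)] != spacer:
            return Rejection(REJECT_BAD_SPACER)
        halves.append(half)
    key = DuplexTagKey(halves[0] + halves[1])
    return PreparedReadPair(
        qname=qname,
        key=key,
        read1=read1.upper()[tech:],
        read2=read2.upper()[tech:],
    )


def iter_fastq_pairs(path1, path2) -> Iterator[tuple[str, str, str]]:
    """Yield (qname, seq1, seq2) from a pair of FASTQ files."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for rec1, rec2 in zip(f1, f2):
            if rec1.name != rec2.name:
                raise ValueError(
                    f"FASTQ files out of sync: {rec1.name!r} vs {rec2.name!r}"
                )
            yield rec1.name, rec1.sequence, rec2.sequence


@dataclass
class PairAlignment:
    """Reference-oriented trimmed sequences and mappings of one pair."""

    seq1: str
    seq2: str
    map1: ReadMapping
    map2: ReadMapping


def load_alignments(
    sam_path, reference_name: str | None = None
) -> tuple[dict[str, PairAlignment], int]:
    """Read pair alignments from SAM/BAM keyed by query name.

    Returns (alignments, n_off_target) where off-target counts pairs that are
    unmapped or mapped to a different reference.
    """
    firsts: dict[str, tuple[str, int, bool]] = {}
    seconds: dict[str, tuple[str, int, bool]] = {}
    off_target = set()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped or (
                reference_name is not None and rec.reference_name != reference_name
            ):
                off_target.add(rec.query_name)
                continue
            entry = (rec.query_sequence, rec.reference_start + 1, rec.is_reverse)
            (firsts if rec.is_read1 else seconds)[rec.query_name] = entry
    out: dict[str, PairAlignment] = {}
    for name, (s1, p1, r1) in firsts.items():
        if name in off_target or name not in seconds:
            off_target.add(name)
            continue
        s2, p2, r2 = seconds[name]
        out[name] = PairAlignment(seq1=s1, seq2=s2, map1=(p1, r1), map2=(p2, r2))
    return out, len(off_target)


#: grouping key of a family: (24-nt tag, ((pos1, rev1), (pos2, rev2)))
FamilyKey = tuple[str, tuple[ReadMapping, ReadMapping]]


def mate_family_key(key: FamilyKey) -> FamilyKey:
    """Family key of the opposite-strand family of the same molecule.

    The tag halves swap and read1/read2 mappings swap: the strand-mate's
    read1 sequences what our read2 sequenced.
    """
    tag, (m1, m2) = key
    h = len(tag) // 2
    return (tag[h:] + tag[:h], (m2, m1))


@dataclass
class ReadFamily:
    """Reads sharing one duplex tag key and mapping coordinates."""

    key: FamilyKey
    members: list[PreparedReadPair] = field(default_factory=list)

    @property
    def tag(self) -> str:
        return self.key[0]

    @property
    def coordinates(self) -> tuple[ReadMapping, ReadMapping]:
        return self.key[1]

    @property
    def size(self) -> int:
        return len(self.members)


def group_families(
    pairs: Iterable[PreparedReadPair],
) -> tuple[dict[FamilyKey, ReadFamily], int]:
    """Partition mapped pairs into tag families.

    Family identity is the 24-nt key together with both reads' mapped
    coordinates and orientations. Pairs without a mapping are excluded and
    counted. Returns (families, n_unmapped).
    """
    families: dict[FamilyKey, ReadFamily] = {}
    unmapped = 0
    for pair in pairs:
        if pair.mapping is None:
            unmapped += 1
            continue
        key: FamilyKey = (pair.key.tag, pair.mapping)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = ReadFamily(key=key)
        fam.members.append(pair)
    return families, unmapped
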