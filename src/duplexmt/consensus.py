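"""Single-strand and duplex consensus building, end clipping, near-tag
deduplication, and nuclear-pseudogene (NUMT) decoy filtering.

The single-strand consensus (SSCS) collapses a tag family position by
position: a position is undefined (``N``) unless covered by at least
``min_family`` reads with the modal base reaching the ``agreement`` fraction
(default three reads, 70%; exactly 70% passes). The duplex consensus (DCS)
keeps a base only where the two strand-mate SSCS agree with defined bases —
the step that removes strand-specific first-round PCR/damage errors.
Consensus reads live in genome space as one segment per mate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from duplexmt.reference import (
    ReferenceGenome,
    decode_bases,
    encode_bases,
)
from duplexmt.readprep import (
    FamilyKey,
    PreparedReadPair,
    ReadFamily,
    ReadMapping,
    group_families,
    mate_family_key,
)

__all__ = [
    "ReadFamily",
    "ConsensusRead",
    "Segment",
    "build_sscs",
    "build_dcs",
    "pair_strand_mates",
    "clip_ends",
    "dedup_near_tags",
    "dedup_families",
    "AlignmentScoring",
    "numt_filter",
]

_N = 4  # code of the undefined base


@dataclass(frozen=True)
class Segment:
    """A genome-forward consensus stretch: 1-based start + ACGTN bases."""

    start: int
    bases: str

    def positions(self, genome_length: int) -> np.ndarray:
        return (np.arange(self.start - 1, self.start - 1 + len(self.bases))
                % genome_length) + 1


@dataclass(frozen=True)
class ConsensusRead:
    """An SSCS or DCS: per-mate genome-space segments with N = undefined."""

    level: str  # SSCS | DCS
    segments: tuple[Segment, ...]
    coordinates: tuple[ReadMapping, ReadMapping]
    family_sizes: tuple[int, ...]
    source_keys: tuple[str, ...]
    family_key: FamilyKey | None = None

    @property
    def sequence(self) -> str:
        """All segment bases concatenated (N marks undefined positions)."""
        return "".join(seg.bases for seg in self.segments)

    @property
    def defined_bases(self) -> int:
        return sum(len(seg.bases) - seg.bases.count("N") for seg in self.segments)


def _column_consensus(
    mat: np.ndarray, min_family: int, agreement: float
) -> np.ndarray:
    """Per-column modal-base consensus of an (n_reads, length) code matrix.

    N (code 4) entries contribute neither to coverage nor to the tally; ties
    for the modal base never pass an agreement threshold > 0.5 and yield N
    otherwise.
    """
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    coverage = counts.sum(axis=0)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == top).sum(axis=0) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(coverage > 0, top / np.maximum(coverage, 1), 0.0)
    ok = (coverage >= min_family) & (frac >= agreement) & ~tie
    out = np.where(ok, modal, np.uint8(_N)).astype(np.uint8)
    return out


def _stack_reads(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-or-ragged-length reads into a code matrix, N-padded."""
    length = max(len(s) for s in seqs)
    mat = np.full((len(seqs), length), _N, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode_bases(s)
    return mat


def build_sscs(
    family: ReadFamily, min_family: int = 3, agreement: float = 0.7
) -> ConsensusRead | None:
    """Collapse one tag family into its single-strand consensus.

    Returns None when no position is defined (e.g. families smaller than
    ``min_family``): such families carry no usable sequence.
    """
    if not family.members:
        raise ValueError("cannot build a consensus from an empty family")
    segments = []
    any_defined = False
    for mate_idx, (pos, _reverse) in enumerate(family.coordinates):
        seqs = [
            (m.read1 if mate_idx == 0 else m.read2) for m in family.members
        ]
        cons = _column_consensus(_stack_reads(seqs), min_family, agreement)
        if (cons != _N).any():
            any_defined = True
        segments.append(Segment(start=pos, bases=decode_bases(cons)))
    if not any_defined:
        return None
    return ConsensusRead(
        level="SSCS",
        segments=tuple(segments),
        coordinates=family.coordinates,
        family_sizes=(family.size,),
        source_keys=(family.tag,),
        family_key=family.key,
    )


def pair_strand_mates(
    sscs_reads: Iterable[ConsensusRead],
) -> tuple[list[tuple[ConsensusRead, ConsensusRead]], int]:
    """Group SSCS with their opposite-strand mates.

    Two SSCS are mates when their 24-nt keys have swapped halves and their
    read1/read2 mappings are swapped. Returns (pairs, n_unpaired).
    """
    groups: dict[FamilyKey, list[ConsensusRead]] = {}
    for read in sscs_reads:
        if read.family_key is None:
            raise ValueError("SSCS lacks its family key; cannot pair strand mates")
        canon = min(read.family_key, mate_family_key(read.family_key))
        groups.setdefault(canon, []).append(read)
    pairs: list[tuple[ConsensusRead, ConsensusRead]] = []
    unpaired = 0
    for canon in groups:
        members = sorted(groups[canon], key=lambda r: r.family_key)
        if len(members) == 2:
            pairs.append((members[0], members[1]))
        else:
            unpaired += len(members)
    return pairs, unpaired


def build_dcs(a: ConsensusRead, b: ConsensusRead) -> ConsensusRead:
    """Duplex consensus of two strand-mate SSCS.

    Position-wise: identical defined bases are kept, anything else becomes N.
    Symmetric in its arguments.
    """
    if a.family_key is None or b.family_key is None:
        raise ValueError("both SSCS must carry family keys")
    if mate_family_key(a.family_key) != b.family_key:
        raise ValueError(
            "SSCS are not strand mates: keys/coordinates do not correspond"
        )
    # canonical orientation so build_dcs(a, b) == build_dcs(b, a)
    if b.family_key < a.family_key:
        a, b = b, a
    b_by_start = {seg.start: seg for seg in b.segments}
    segments = []
    for seg in a.segments:
        other = b_by_start.get(seg.start)
        if other is not None and len(other.bases) == len(seg.bases):
            x = encode_bases(seg.bases)
            y = encode_bases(other.bases)
            merged = np.where((x == y) & (x != _N), x, np.uint8(_N))
        else:  # general fallback: per-position dictionary intersection
            merged = _merge_general(seg, b.segments)
        segments.append(Segment(start=seg.start, bases=decode_bases(merged)))
    return ConsensusRead(
        level="DCS",
        segments=tuple(segments),
        coordinates=a.coordinates,
        family_sizes=a.family_sizes + b.family_sizes,
        source_keys=a.source_keys + b.source_keys,
        family_key=a.family_key,
    )


def _merge_general(seg: Segment, other_segments: tuple[Segment, ...]) -> np.ndarray:
    lookup: dict[int, int] = {}
    for o in other_segments:
        codes = encode_bases(o.bases)
        for i, c in enumerate(codes):
            lookup[o.start + i] = int(c)
    x = encode_bases(seg.bases)
    out = np.full(len(x), _N, dtype=np.uint8)
    for i, c in enumerate(x):
        if c != _N and lookup.get(seg.start + i, _N) == int(c):
            out[i] = c
    return out


def clip_ends(read: ConsensusRead, n: int = 5) -> ConsensusRead:
    """Set the first and last ``n`` defined positions of each segment to N.

    Mirrors soft-clipping read ends to suppress alignment artifacts; a
    segment with at most ``2n`` defined positions becomes entirely undefined.
    """
    if n < 0:
        raise ValueError("clip length must be non-negative")
    if n == 0:
        return read
    segments = []
    for seg in read.segments:
        codes = encode_bases(seg.bases)
        defined = np.nonzero(codes != _N)[0]
        if len(defined) <= 2 * n:
            codes[defined] = _N
        else:
            codes[defined[:n]] = _N
            codes[defined[-n:]] = _N
        segments.append(Segment(start=seg.start, bases=decode_bases(codes)))
    return replace(read, segments=tuple(segments))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("tags must have equal length")
    return sum(x != y for x, y in zip(a, b))


def dedup_near_tags(
    families: Sequence[ReadFamily],
    max_distance: int = 3,
    keep: str = "none",
) -> list[ReadFamily]:
    """Remove families with near-identical tags at one coordinate key.

    Families whose 24-nt keys differ by fewer than ``max_distance`` bases are
    linked; every family in a linked component of size > 1 is removed
    (``keep="none"``, the literal reading) or the largest family per
    component is retained (``keep="largest"``).
    """
    if keep not in ("none", "largest"):
        raise ValueError("keep must be 'none' or 'largest'")
    fams = sorted(families, key=lambda f: f.tag)
    n = len(fams)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if hamming(fams[i].tag, fams[j].tag) < max_distance:
                adj[i].append(j)
                adj[j].append(i)
    retained: list[ReadFamily] = []
    seen = [False] * n
    for i in range(n):
        if seen[i]:
            continue
        comp = [i]
        seen[i] = True
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    comp.append(v)
                    stack.append(v)
        if len(comp) == 1:
            retained.append(fams[comp[0]])
        elif keep == "largest":
            retained.append(max((fams[c] for c in comp), key=lambda f: f.size))
    return retained


def dedup_families(
    families: Sequence[ReadFamily],
    max_distance: int = 3,
    keep: str = "none",
) -> list[ReadFamily]:
    """Apply near-tag dedup within each coordinate group.

    Near-identical tags arise from tag-base errors within one molecule's
    descendants, which share their mapping coordinates, so families are
    compared only against others with the same coordinate key.
    """
    groups: dict[tuple, list[ReadFamily]] = {}
    for fam in families:
        groups.setdefault(fam.coordinates, []).append(fam)
    retained: list[ReadFamily] = []
    for coords in sorted(groups):
        retained.extend(dedup_near_tags(groups[coords], max_distance, keep))
    return retained


@dataclass(frozen=True)
class AlignmentScoring:
    """Local-alignment scoring for the NUMT decoy comparison."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def _defined_runs(read: ConsensusRead) -> list[str]:
    runs = []
    for seg in read.segments:
        for run in seg.bases.split("N"):
            if run:
                runs.append(run)
    return runs


def numt_filter(
    mutant_read: ConsensusRead,
    mito_genome: ReferenceGenome,
    decoys: Sequence[str],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> bool:
    """Keep/remove decision for a mutation-bearing consensus read.

    The read's defined stretches are locally aligned against the (doubled,
    wrap-aware) mitochondrial reference and against each nuclear decoy; the
    read is removed (returns False) when any decoy outscores the
    mitochondrial reference — the signature of a nuclear mitochondrial
    pseudogene rather than a true mtDNA molecule.
    """
    runs = _defined_runs(mutant_read)
    if not runs or not decoys:
        return True
    aligner = scoring.aligner()
    mito_seq = mito_genome.sequence + mito_genome.sequence  # circular wrap
    mito_score = sum(aligner.score(mito_seq, run) for run in runs)
    for decoy in decoys:
        decoy_score = sum(aligner.score(decoy.upper(), run) for run in runs)
        if decoy_score > mito_score:
            return False
    return True
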