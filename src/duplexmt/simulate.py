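"""Seeded simulator for duplex-tagged paired-end mtDNA libraries.

Each simulated double-stranded fragment receives a random 12-bp tag on each
end (the alpha and beta ends). Amplifying the two parental strands produces
two read families per fragment: reads whose 24-nt concatenated key is
``alpha+beta`` derive from one parental strand, ``beta+alpha`` reads from the
other. Four error classes are injected, each recorded in a ground-truth
ledger:

* ``true_mutation`` / ``clonal_variant`` — present on both parental strands,
  hence in every read of both families covering the site;
* ``damage`` — a first-round PCR/damage error confined to one parental
  strand, hence present in every read of exactly one family (the class that
  duplex consensus is designed to remove; default spectrum is concentrated
  on G->T on the damaged strand, mimicking 8-oxo-dG);
* ``late_pcr`` — arises at a random duplication step and propagates to the
  corresponding subset of one family;
* ``sequencing`` — independent per read per base.

All genomic coordinates in the ledger are 1-based L-strand positions; the
seed fully determines every output byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from duplexmt.reference import (
    BASES,
    ReferenceGenome,
    complement,
    decode_bases,
    encode_bases,
)

DEFAULT_SPACER = "TGACT"
_QUAL_CHAR = "I"  # constant placeholder quality; the pipeline is identity-based


@dataclass
class SimulationConfig:
    """Parameters of one simulated duplex library.

    ``family_size_distribution`` is ``("poisson_shifted", mean)`` — sizes are
    ``1 + Poisson(mean - 1)`` — or ``("fixed", k)``. ``clonal_variants`` are
    ``(position, alt, fraction)`` triples applied independently per fragment;
    ``injected_true_mutations`` are ``(position, alt)`` pairs each placed on
    exactly one randomly chosen covering fragment (both strands), for
    single-molecule sensitivity experiments; ``injected_margin`` keeps the
    injected position at least that many bases away from both ends of a read
    window, so downstream start-trimming and end-clipping cannot silently
    erase the one molecule the experiment depends on.
    """

    genome: ReferenceGenome
    n_fragments: int
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    read_length: int = 101
    tag_length: int = 12
    spacer: str = DEFAULT_SPACER
    trim_bases: int = 4
    family_size_distribution: tuple[str, float] = ("poisson_shifted", 6.0)
    true_mutation_frequency: float = 0.0
    damage_error_rate: float = 0.0
    damage_spectrum: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("G", "T"): 1.0}
    )
    late_pcr_error_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    clonal_variants: list[tuple[int, str, float]] = field(default_factory=list)
    injected_true_mutations: list[tuple[int, str]] = field(default_factory=list)
    injected_margin: int = 10
    seed: int = 0

    @property
    def insert_read_length(self) -> int:
        """Bases of genomic insert carried by each raw read (before trimming)."""
        return self.read_length - self.tag_length - len(self.spacer)

    def validate(self) -> None:
        for name in (
            "true_mutation_frequency",
            "damage_error_rate",
            "late_pcr_error_rate",
            "sequencing_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length < self.tag_length + len(self.spacer) + 1:
            raise ValueError("read_length must exceed tag + spacer length")
        if set(self.spacer) - set(BASES):
            raise ValueError("spacer must contain only ACGT")
        for pos, alt, fraction in self.clonal_variants:
            if not 0.0 < fraction <= 1.0:
                raise ValueError(
                    f"clonal variant fraction must be in (0,1], got {fraction}"
                )
            if alt not in BASES:
                raise ValueError(f"clonal variant alt {alt!r} not a canonical base")
            if self.genome.base_at(pos) == alt:
                raise ValueError(f"clonal variant at {pos} equals the reference")
        for pos, alt in self.injected_true_mutations:
            if alt.upper() not in BASES:
                raise ValueError(f"injected alt {alt!r} not a canonical base")
            if self.genome.base_at(pos) == alt.upper():
                raise ValueError(
                    f"injected mutation at {pos} equals the reference base"
                )
        kind, _param = self.family_size_distribution
        if kind not in ("poisson_shifted", "fixed"):
            raise ValueError(f"unknown family size distribution {kind!r}")
        dist_sum = sum(self.damage_spectrum.values())
        if self.damage_spectrum and not math.isclose(dist_sum, 1.0, rel_tol=1e-9):
            raise ValueError("damage_spectrum probabilities must sum to 1")


@dataclass(frozen=True)
class SimEvent:
    """One injected event; positions and alleles are 1-based L-strand."""

    event_class: str  # true_mutation | clonal_variant | damage | late_pcr | sequencing
    position: int
    ref: str
    alt: str
    fragment: int
    strand: str  # alpha | beta | both
    reads: tuple[str, ...]  # affected read ids, "frag<i>:<ab|ba>:<j>/<mate>"


class SimTruth:
    """Ledger of every injected event."""

    def __init__(self, events: list[SimEvent] | None = None):
        self.events: list[SimEvent] = events or []

    def add(self, event: SimEvent) -> None:
        self.events.append(event)

    def by_class(self, event_class: str) -> list[SimEvent]:
        return [e for e in self.events if e.event_class == event_class]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("event_class\tposition\tref\talt\tfragment\tstrand\treads\n")
            for e in self.events:
                fh.write(
                    f"{e.event_class}\t{e.position}\t{e.ref}\t{e.alt}\t"
                    f"{e.fragment}\t{e.strand}\t{','.join(e.reads)}\n"
                )

    def __len__(self) -> int:
        return len(self.events)


_FAM_NAMES = ("ab", "ba")


class SimulatedLibrary:
    """In-memory simulated library: read matrices plus provenance arrays.

    Row ``i`` of ``r1``/``r2`` holds the insert portion (length
    ``insert_read_length``) of read pair ``i`` in L-strand orientation; the
    raw sequenced read is reconstructed on FASTQ export (tag + spacer +
    insert, reverse-complemented for the mate that sequenced the H-strand).
    """

    def __init__(self, config, r1, r2, pair_fragment, pair_family, pair_member,
                 frag_start, frag_len, tag_a, tag_b, truth):
        self.config = config
        self.r1 = r1
        self.r2 = r2
        self.pair_fragment = pair_fragment
        self.pair_family = pair_family  # 0 = ab (alpha strand), 1 = ba (beta strand)
        self.pair_member = pair_member
        self.frag_start = frag_start  # 0-based leftmost fragment position
        self.frag_len = frag_len
        self.tag_a = tag_a
        self.tag_b = tag_b
        self.truth = truth

    @property
    def n_pairs(self) -> int:
        return len(self.pair_fragment)

    def qname(self, i: int) -> str:
        return (
            f"frag{self.pair_fragment[i]}:{_FAM_NAMES[self.pair_family[i]]}"
            f":{self.pair_member[i]}"
        )

    def pair_tags(self, i: int) -> tuple[str, str]:
        """(read1 tag half, read2 tag half) for pair ``i``."""
        f = self.pair_fragment[i]
        a = decode_bases(self.tag_a[f])
        b = decode_bases(self.tag_b[f])
        return (a, b) if self.pair_family[i] == 0 else (b, a)

    def pair_layout(self, i: int):
        """Mapping of the pair's trimmed reads.

        Returns ((pos1, rev1), (pos2, rev2)) with 1-based leftmost positions
        of the trimmed insert portions. The forward mate covers
        ``start+trim .. start+R-1``; the reverse mate covers
        ``start+L-R .. start+L-1-trim``.
        """
        cfg = self.config
        G = cfg.genome.length
        R = cfg.insert_read_length
        t = cfg.trim_bases
        f = self.pair_fragment[i]
        start, L = int(self.frag_start[f]), int(self.frag_len[f])
        fwd = (start + t) % G + 1
        rev = (start + L - R) % G + 1
        if self.pair_family[i] == 0:  # ab: read1 forward, read2 reverse
            return (fwd, False), (rev, True)
        return (rev, True), (fwd, False)

    # ------------------------------------------------------------------ IO

    def write_fastq(self, path1, path2) -> None:
        """Write the raw tagged reads as a standard 4-line FASTQ pair."""
        cfg = self.config
        sp = cfg.spacer
        qual = _QUAL_CHAR * cfg.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                name = self.qname(i)
                t1, t2 = self.pair_tags(i)
                s1 = decode_bases(self.r1[i])
                s2 = decode_bases(self.r2[i])
                if self.pair_family[i] == 0:
                    s2 = _revcomp_str(s2)
                else:
                    s1 = _revcomp_str(s1)
                f1.write(f"@{name}\n{t1}{sp}{s1}\n+\n{qual}\n")
                f2.write(f"@{name}\n{t2}{sp}{s2}\n+\n{qual}\n")

    def write_sam(self, path) -> None:
        """Ground-truth alignments of the trimmed reads as a SAM file."""
        cfg = self.config
        R = cfg.insert_read_length
        t = cfg.trim_bases
        tlen = R - t
        cigar = f"{tlen}M"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{cfg.genome.name}\tLN:{cfg.genome.length}\n")
            ref = cfg.genome.name
            for i in range(self.n_pairs):
                name = self.qname(i)
                (p1, rev1), (p2, rev2) = self.pair_layout(i)
                s1 = decode_bases(self.r1[i][t:] if not rev1 else self.r1[i][:-t])
                s2 = decode_bases(self.r2[i][t:] if not rev2 else self.r2[i][:-t])
                flag1 = 0x1 | 0x2 | 0x40 | (0x10 if rev1 else 0) | (0x20 if rev2 else 0)
                flag2 = 0x1 | 0x2 | 0x80 | (0x10 if rev2 else 0) | (0x20 if rev1 else 0)
                q = _QUAL_CHAR * tlen
                fh.write(
                    f"{name}\t{flag1}\t{ref}\t{p1}\t60\t{cigar}\t=\t{p2}\t0\t{s1}\t{q}\n"
                    f"{name}\t{flag2}\t{ref}\t{p2}\t60\t{cigar}\t=\t{p1}\t0\t{s2}\t{q}\n"
                )


def _revcomp_str(seq: str) -> str:
    return complement(seq)[::-1]


def inject_clonal_variants(
    genome: ReferenceGenome,
    clonal_variants: Sequence[tuple[int, str, float]],
    rng: np.random.Generator,
):
    """Per-fragment template chooser for clonal/inherited heteroplasmies.

    Returns a callable mapping a fragment's covered positions to the list of
    (position, alt) substitutions its template molecule carries; each variant
    is present with its configured fraction, independently per fragment.
    """
    validated = []
    for pos, alt, fraction in clonal_variants:
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"clonal variant fraction must be in (0,1], got {fraction}")
        validated.append((pos, alt.upper(), fraction))

    def choose(covered: set[int]) -> list[tuple[int, str]]:
        chosen = []
        for pos, alt, fraction in validated:
            if pos in covered and rng.random() < fraction:
                chosen.append((pos, alt))
        return chosen

    return choose


def _draw_family_sizes(config: SimulationConfig, rng, n: int) -> np.ndarray:
    kind, param = config.family_size_distribution
    if kind == "fixed":
        return np.full(n, int(param), dtype=np.int32)
    # shifted Poisson: minimum family size 1, mean = param
    lam = max(param - 1.0, 0.0)
    return 1 + rng.poisson(lam, size=n).astype(np.int32)


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Generate a duplex library with ground truth; seed-deterministic."""
    config.validate()
    genome = config.genome
    G = genome.length
    R = config.insert_read_length
    rng = np.random.default_rng(config.seed)
    n = config.n_fragments
    truth = SimTruth()

    if n == 0:
        if config.injected_true_mutations:
            raise ValueError(
                "no simulated fragment covers injected position "
                f"{config.injected_true_mutations[0][0]}: n_fragments is 0"
            )
        empty = np.zeros((0, R), dtype=np.uint8)
        zi = np.zeros(0, dtype=np.int32)
        return SimulatedLibrary(
            config, empty, empty.copy(), zi, zi.copy().astype(np.uint8), zi.copy(),
            zi.copy(), zi.copy(), np.zeros((0, config.tag_length), dtype=np.uint8),
            np.zeros((0, config.tag_length), dtype=np.uint8), truth,
        )

    starts = rng.integers(0, G, size=n).astype(np.int64)
    lengths = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
    ).astype(np.int64)
    if (lengths < R).any() and config.fragment_length_sd == 0:
        raise ValueError(
            f"fragment length {config.fragment_length_mean} shorter than the "
            f"{R}-base insert a read carries after tag and spacer"
        )
    if config.fragment_length_mean < R:
        raise ValueError(
            f"fragment_length_mean {config.fragment_length_mean} shorter than the "
            f"{R}-base insert a read carries after tag and spacer"
        )
    lengths = np.maximum(lengths, R)
    tag_a = rng.integers(0, 4, size=(n, config.tag_length)).astype(np.uint8)
    tag_b = rng.integers(0, 4, size=(n, config.tag_length)).astype(np.uint8)
    sizes = _draw_family_sizes(config, rng, 2 * n).reshape(n, 2)

    # assign each injected single-molecule mutation to one covering fragment
    injected_by_fragment: dict[int, list[tuple[int, str]]] = {}
    for pos, alt in config.injected_true_mutations:
        p0 = (pos - 1) % G
        covering = [
            f
            for f in range(n)
            if _fragment_columns(
                int(starts[f]), int(lengths[f]), R, G, p0, config.injected_margin
            )
        ]
        if not covering:
            raise ValueError(
                f"no simulated fragment covers injected position {pos} with "
                f"margin {config.injected_margin}"
            )
        frag = covering[int(rng.integers(0, len(covering)))]
        injected_by_fragment.setdefault(frag, []).append((pos, alt.upper()))

    clonal_chooser = inject_clonal_variants(genome, config.clonal_variants, rng)

    damage_classes = list(config.damage_spectrum.keys())
    damage_probs = np.array(list(config.damage_spectrum.values()), dtype=float)

    r1_blocks: list[np.ndarray] = []
    r2_blocks: list[np.ndarray] = []
    pair_fragment: list[np.ndarray] = []
    pair_family: list[np.ndarray] = []
    pair_member: list[np.ndarray] = []

    for f in range(n):
        start, L = int(starts[f]), int(lengths[f])
        w1 = genome.codes[(start + np.arange(R)) % G]
        w2 = genome.codes[(start + L - R + np.arange(R)) % G]
        covered = _covered_positions(start, L, R, G)

        # --- template-level events (per fragment, both strands) -----------
        both_strand: list[tuple[int, int]] = []  # (0-based pos, alt code)
        for pos, alt in clonal_chooser(covered):
            p0 = (pos - 1) % G
            both_strand.append((p0, BASES.index(alt)))
            truth.add(
                SimEvent("clonal_variant", pos, genome.base_at(pos), alt, f,
                         "both", _family_reads(f, sizes[f])))
        n_true = rng.binomial(len(covered), config.true_mutation_frequency) \
            if config.true_mutation_frequency > 0 else 0
        if n_true:
            cov_list = sorted(covered)
            for p0 in rng.choice(len(cov_list), size=n_true, replace=False):
                p0 = cov_list[int(p0)]
                ref = genome.sequence[p0]
                alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                both_strand.append((p0, BASES.index(alt)))
                truth.add(SimEvent("true_mutation", p0 + 1, ref, alt, f, "both",
                                   _family_reads(f, sizes[f])))
        for pos, alt in injected_by_fragment.get(f, ()):
            p0 = (pos - 1) % G
            both_strand.append((p0, BASES.index(alt)))
            truth.add(SimEvent("true_mutation", pos, genome.base_at(pos), alt, f,
                               "both", _family_reads(f, sizes[f])))

        # --- strand-specific damage (first-round errors) ------------------
        strand_events: list[list[tuple[int, int]]] = [[], []]
        if config.damage_error_rate > 0:
            cov_list = sorted(covered)
            for strand_idx, strand_name in ((0, "alpha"), (1, "beta")):
                n_dmg = rng.binomial(len(cov_list), config.damage_error_rate)
                if not n_dmg:
                    continue
                hit = rng.choice(len(cov_list), size=n_dmg, replace=False)
                for h in hit:
                    p0 = cov_list[int(h)]
                    src, dst = damage_classes[
                        int(rng.choice(len(damage_classes), p=damage_probs))
                    ]
                    ref = genome.sequence[p0]
                    strand_base = ref if strand_idx == 0 else complement(ref)
                    if strand_base != src:
                        continue  # the lesion's target base is absent here
                    alt = dst if strand_idx == 0 else complement(dst)
                    strand_events[strand_idx].append((p0, BASES.index(alt)))
                    truth.add(SimEvent(
                        "damage", p0 + 1, ref, alt, f, strand_name,
                        _family_reads(f, sizes[f], only=strand_idx)))

        # --- materialise reads --------------------------------------------
        for fam in (0, 1):
            size = int(sizes[f, fam])
            t1 = np.tile(w1, (size, 1))
            t2 = np.tile(w2, (size, 1))
            for p0, altc in both_strand + strand_events[fam]:
                for mat, wstart in ((t1, start), (t2, start + L - R)):
                    col = (p0 - wstart) % G
                    if col < R:
                        mat[:, col] = altc
            # late PCR errors: one lineage split per event
            if config.late_pcr_error_rate > 0 and size >= 1:
                n_late = rng.binomial(size * 2 * R, config.late_pcr_error_rate)
                for _ in range(n_late):
                    mate = int(rng.integers(0, 2))
                    col = int(rng.integers(0, R))
                    k_max = max(1, math.ceil(math.log2(size))) if size > 1 else 1
                    k = int(rng.integers(1, k_max + 1))
                    subset = max(1, round(size * 2.0 ** (-k)))
                    rows = rng.choice(size, size=subset, replace=False)
                    mat = t1 if mate == 0 else t2
                    wstart = start if mate == 0 else start + L - R
                    p0 = (wstart + col) % G
                    cur = int(mat[rows[0], col])
                    altc = (cur + int(rng.integers(1, 4))) % 4
                    mat[rows, col] = altc
                    fam_name = _FAM_NAMES[fam]
                    reads = tuple(
                        f"frag{f}:{fam_name}:{int(r)}/{mate + 1}" for r in sorted(rows)
                    )
                    truth.add(SimEvent(
                        "late_pcr", p0 + 1, genome.sequence[p0], BASES[altc], f,
                        "alpha" if fam == 0 else "beta", reads))
            # sequencing errors: independent per read per base
            if config.sequencing_error_rate > 0:
                n_seq = rng.binomial(size * 2 * R, config.sequencing_error_rate)
                if n_seq:
                    flat = rng.choice(size * 2 * R, size=n_seq, replace=False)
                    for idx in flat:
                        mate, rem = divmod(int(idx), size * R)
                        row, col = divmod(rem, R)
                        mat = t1 if mate == 0 else t2
                        wstart = start if mate == 0 else start + L - R
                        p0 = (wstart + col) % G
                        cur = int(mat[row, col])
                        altc = (cur + int(rng.integers(1, 4))) % 4
                        mat[row, col] = altc
                        truth.add(SimEvent(
                            "sequencing", p0 + 1, genome.sequence[p0], BASES[altc],
                            f, "alpha" if fam == 0 else "beta",
                            (f"frag{f}:{_FAM_NAMES[fam]}:{row}/{mate + 1}",)))
            # mate orientation: ab reads1 from window1; ba reads1 from window2
            if fam == 0:
                r1_blocks.append(t1)
                r2_blocks.append(t2)
            else:
                r1_blocks.append(t2)
                r2_blocks.append(t1)
            pair_fragment.append(np.full(size, f, dtype=np.int32))
            pair_family.append(np.full(size, fam, dtype=np.uint8))
            pair_member.append(np.arange(size, dtype=np.int32))

    return SimulatedLibrary(
        config,
        np.vstack(r1_blocks),
        np.vstack(r2_blocks),
        np.concatenate(pair_fragment),
        np.concatenate(pair_family),
        np.concatenate(pair_member),
        starts.astype(np.int64),
        lengths.astype(np.int64),
        tag_a,
        tag_b,
        truth,
    )


def _fragment_columns(
    start: int, L: int, R: int, G: int, p0: int, margin: int = 0
) -> bool:
    """Whether 0-based genomic position ``p0`` is covered by either window,
    optionally at least ``margin`` bases from both window ends."""
    return (
        margin <= ((p0 - start) % G) < R - margin
        or margin <= ((p0 - (start + L - R)) % G) < R - margin
    )


def _covered_positions(start: int, L: int, R: int, G: int) -> set[int]:
    pos = set(((start + np.arange(R)) % G).tolist())
    pos.update(((start + L - R + np.arange(R)) % G).tolist())
    return pos


def _family_reads(f: int, sizes, only: int | None = None) -> tuple[str, ...]:
    reads = []
    for fam in (0, 1):
        if only is not None and fam != only:
            continue
        for j in range(int(sizes[fam])):
            for mate in (1, 2):
                reads.append(f"frag{f}:{_FAM_NAMES[fam]}:{j}/{mate}")
    return tuple(reads)
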