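"""Pileup, variant calling with a clonality cutoff, and the downstream
mutation statistics: de-novo frequency with Wilson intervals, the 12/6-class
substitution spectrum, L-strand reciprocal-pair asymmetry, and region
(D-loop versus coding) comparisons.

Frequency definition: inherited or clonally expanded variants are excluded
with a clonality cutoff (a variant present in more than 1% of molecules at a
position is not a de-novo event), each (position, alt) is scored once
regardless of how many molecules carry it, and the de-novo frequency is the
number of such unique variants divided by the total number of duplex
consensus bases sequenced. Spectrum frequencies divide each class's unique
sites by the number of times that class's wild-type base was sequenced;
indels are scored independently per total bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from duplexmt.consensus import ConsensusRead
from duplexmt.reference import (
    BASES,
    ReferenceGenome,
    RegionAnnotation,
    complement,
    encode_bases,
    region_of,
)

#: the 12 directional L-strand substitution classes
DIRECTIONAL_CLASSES: list[tuple[str, str]] = [
    (x, y) for x in BASES for y in BASES if x != y
]

#: the 6 complement-collapsed classes, named by both directional members
COLLAPSED_CLASSES: list[tuple[tuple[str, str], tuple[str, str]]] = []
_seen = set()
for _x, _y in DIRECTIONAL_CLASSES:
    pair = tuple(sorted([(_x, _y), (complement(_x), complement(_y))]))
    if pair not in _seen:
        _seen.add(pair)
        COLLAPSED_CLASSES.append(pair)  # type: ignore[arg-type]


def class_label(ref: str, alt: str) -> str:
    return f"{ref}>{alt}"


def collapsed_label(pair) -> str:
    (a, b), (c, d) = pair
    return f"{a}>{b}/{c}>{d}"


class Pileup:
    """Per-position base counts over DCS reads, L-strand orientation."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.counts = np.zeros((genome.length, 4), dtype=np.int64)
        self.indels: dict[tuple[int, str], int] = {}

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_bases(self) -> int:
        return int(self.counts.sum())

    def add_indel(self, pos: int, descriptor: str, count: int = 1) -> None:
        """Record an indel event, e.g. ``+AC`` or ``-3``, at a 1-based pos."""
        key = (pos, descriptor)
        self.indels[key] = self.indels.get(key, 0) + count


def build_pileup(
    dcs_reads: Iterable[ConsensusRead], genome: ReferenceGenome
) -> Pileup:
    """Tally every defined DCS base into a wrap-aware positional pileup."""
    pileup = Pileup(genome)
    G = genome.length
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    for read in dcs_reads:
        for seg in read.segments:
            if not (1 <= seg.start <= G):
                raise ValueError(
                    f"segment start {seg.start} outside reference 1..{G}"
                )
            codes = encode_bases(seg.bases)
            defined = codes != 4
            if not defined.any():
                continue
            idx = (seg.start - 1 + np.nonzero(defined)[0]) % G
            pos_chunks.append(idx)
            code_chunks.append(codes[defined])
    if pos_chunks:
        np.add.at(
            pileup.counts,
            (np.concatenate(pos_chunks), np.concatenate(code_chunks)),
            1,
        )
    return pileup


@dataclass(frozen=True)
class VariantCall:
    """One substitution or indel observed in the duplex consensus pileup."""

    position: int
    ref: str
    alt: str  # single base, or indel descriptor like "+AC" / "-3"
    mutant_count: int
    depth: int
    region_class: str = "unknown"
    clonality_cutoff: float = 0.01
    homoplasmy_cutoff: float = 0.90

    @property
    def clonality(self) -> float:
        return self.mutant_count / self.depth if self.depth else 0.0

    @property
    def is_clonal(self) -> bool:
        return self.clonality > self.clonality_cutoff

    @property
    def is_homoplasmic(self) -> bool:
        return self.clonality > self.homoplasmy_cutoff

    @property
    def is_indel(self) -> bool:
        return len(self.alt) != 1 or self.alt not in BASES


def call_variants(
    pileup: Pileup,
    genome: ReferenceGenome,
    clonality_cutoff: float = 0.01,
    homoplasmy_cutoff: float = 0.90,
    annotations: Sequence[RegionAnnotation] | None = None,
) -> list[VariantCall]:
    """Emit one call per (position, alt) with at least one mutant molecule.

    Calls above the clonality cutoff are flagged clonal (inherited/expanded)
    and are excluded from de-novo statistics by :func:`de_novo_calls`; calls
    above the homoplasmy cutoff are additionally flagged homoplasmic.
    """
    calls: list[VariantCall] = []
    ref_codes = genome.codes
    counts = pileup.counts
    depth = pileup.depth
    nz_pos, nz_base = np.nonzero(counts)
    for p, b in zip(nz_pos, nz_base):
        if b == ref_codes[p]:
            continue
        pos = int(p) + 1
        calls.append(
            VariantCall(
                position=pos,
                ref=BASES[ref_codes[p]],
                alt=BASES[b],
                mutant_count=int(counts[p, b]),
                depth=int(depth[p]),
                region_class=(
                    region_of(genome, annotations, pos) if annotations else "unknown"
                ),
                clonality_cutoff=clonality_cutoff,
                homoplasmy_cutoff=homoplasmy_cutoff,
            )
        )
    for (pos, descriptor), count in sorted(pileup.indels.items()):
        p = (pos - 1) % genome.length
        calls.append(
            VariantCall(
                position=pos,
                ref=BASES[ref_codes[p]],
                alt=descriptor,
                mutant_count=count,
                depth=int(depth[p]),
                region_class=(
                    region_of(genome, annotations, pos) if annotations else "unknown"
                ),
                clonality_cutoff=clonality_cutoff,
                homoplasmy_cutoff=homoplasmy_cutoff,
            )
        )
    return calls


def de_novo_calls(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Calls below the clonality cutoff: the de-novo mutation set."""
    return [c for c in calls if not c.is_clonal]


def wilson_interval(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clamped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = 0.0 if k == 0 else max(0.0, (centre - half) / denom)
    hi = 1.0 if k == n else min(1.0, (centre + half) / denom)
    return lo, hi


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: float
    lower: float
    upper: float
    k: int
    n: int


def mutation_frequency(
    calls: Sequence[VariantCall],
    pileup: Pileup,
    confidence: float = 0.95,
    count_molecules: bool = False,
) -> FrequencyEstimate:
    """De-novo point-mutation frequency with a Wilson confidence interval.

    ``calls`` must already be the de-novo substitution set; each unique
    (position, alt) counts once (or, with ``count_molecules``, by its mutant
    molecule count) against the total DCS bases sequenced.
    """
    n = pileup.total_bases
    if n == 0:
        raise ValueError("pileup contains no sequenced bases")
    subs = [c for c in calls if not c.is_indel]
    k = sum(c.mutant_count for c in subs) if count_molecules else len(subs)
    lo, hi = wilson_interval(min(k, n), n, confidence)
    return FrequencyEstimate(frequency=k / n, lower=lo, upper=hi, k=k, n=n)


def base_exposures(pileup: Pileup) -> dict[str, int]:
    """Times each wild-type base was sequenced: reference-matching counts."""
    ref_codes = pileup.genome.codes
    out = {}
    for i, b in enumerate(BASES):
        mask = ref_codes == i
        out[b] = int(pileup.counts[mask, i].sum())
    return out


@dataclass
class SpectrumTable:
    """Counts, exposures and frequencies of the substitution classes."""

    directional: pd.DataFrame  # index: "X>Y"; columns: sites, exposure, frequency
    collapsed: pd.DataFrame  # index: "X>Y/X'>Y'"; + proportion
    indel_sites: int
    indel_frequency: float
    indel_proportion: float
    total_sites: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.collapsed.to_csv(fh, sep="\t")
            fh.write(
                f"\nindel_sites\t{self.indel_sites}\n"
                f"indel_frequency\t{self.indel_frequency}\n"
            )


def spectrum(calls: Sequence[VariantCall], pileup: Pileup) -> SpectrumTable:
    """Substitution spectrum of a de-novo call set.

    Directional class frequency = unique X->Y sites / times X was sequenced
    at X-reference positions; collapsed classes pool complementary pairs.
    Indels are events per total sequenced bases. Proportions are of all
    de-novo mutations (6 collapsed classes + indels) and sum to 1.
    """
    exposures = base_exposures(pileup)
    sites = {cls: 0 for cls in DIRECTIONAL_CLASSES}
    indel_sites = 0
    for c in calls:
        if c.is_indel:
            indel_sites += 1
        else:
            sites[(c.ref, c.alt)] += 1
    rows = []
    for x, y in DIRECTIONAL_CLASSES:
        n_exp = exposures[x]
        rows.append(
            {
                "class": class_label(x, y),
                "sites": sites[(x, y)],
                "exposure": n_exp,
                "frequency": sites[(x, y)] / n_exp if n_exp else float("nan"),
            }
        )
    directional = pd.DataFrame(rows).set_index("class")
    total_bases = pileup.total_bases
    total_sites = sum(sites.values()) + indel_sites
    rows = []
    for pair in COLLAPSED_CLASSES:
        (a, b), (c2, d) = pair
        n_sites = sites[(a, b)] + sites[(c2, d)]
        n_exp = exposures[a] + exposures[c2]
        rows.append(
            {
                "class": collapsed_label(pair),
                "sites": n_sites,
                "exposure": n_exp,
                "frequency": n_sites / n_exp if n_exp else float("nan"),
                "proportion": n_sites / total_sites if total_sites else 0.0,
            }
        )
    collapsed = pd.DataFrame(rows).set_index("class")
    return SpectrumTable(
        directional=directional,
        collapsed=collapsed,
        indel_sites=indel_sites,
        indel_frequency=indel_sites / total_bases if total_bases else float("nan"),
        indel_proportion=indel_sites / total_sites if total_sites else 0.0,
        total_sites=total_sites,
    )


def two_proportion_pvalue(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test; p = 1 when no events at all."""
    if n1 == 0 or n2 == 0:
        raise ValueError("exposures must be positive")
    if k1 + k2 == 0:
        return 1.0
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * sps.norm.sf(abs(z)))


def strand_asymmetry(
    calls: Sequence[VariantCall], pileup: Pileup
) -> pd.DataFrame:
    """L-strand asymmetry of the six reciprocal substitution pairs.

    For each pair (X->Y vs comp(X)->comp(Y), both counted on the L-strand),
    reports each member's frequency normalized by its own source-base
    exposure, the frequency ratio, and a two-proportion test p-value. A
    member with zero exposure is reported as missing (NaN), not zero.
    """
    exposures = base_exposures(pileup)
    sites = {cls: 0 for cls in DIRECTIONAL_CLASSES}
    for c in calls:
        if not c.is_indel:
            sites[(c.ref, c.alt)] += 1
    rows = []
    for pair in COLLAPSED_CLASSES:
        (a, b), (c2, d) = pair
        k1, n1 = sites[(a, b)], exposures[a]
        k2, n2 = sites[(c2, d)], exposures[c2]
        f1 = k1 / n1 if n1 else float("nan")
        f2 = k2 / n2 if n2 else float("nan")
        ratio = f1 / f2 if (n1 and n2 and f2 > 0) else float("nan")
        p = two_proportion_pvalue(k1, n1, k2, n2) if (n1 and n2) else float("nan")
        rows.append(
            {
                "pair": collapsed_label(pair),
                "class_1": class_label(a, b),
                "sites_1": k1,
                "exposure_1": n1,
                "frequency_1": f1,
                "class_2": class_label(c2, d),
                "sites_2": k2,
                "exposure_2": n2,
                "frequency_2": f2,
                "ratio": ratio,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("pair")


def region_mask(
    genome: ReferenceGenome,
    annotations: Sequence[RegionAnnotation],
    region: str,
) -> np.ndarray:
    """Boolean per-position mask; ``non_control`` is everything outside the
    control region (the coding side of the D-loop split)."""
    mask = np.zeros(genome.length, dtype=bool)
    for ann in annotations:
        if ann.region_class == "control":
            idx = ann.positions(genome.length) - 1
            mask[idx] = True
    if region == "control":
        return mask
    if region == "non_control":
        return ~mask
    out = np.zeros(genome.length, dtype=bool)
    for ann in annotations:
        if ann.region_class == region:
            out[ann.positions(genome.length) - 1] = True
    return out


def region_frequency(
    calls: Sequence[VariantCall],
    pileup: Pileup,
    annotations: Sequence[RegionAnnotation],
    region: str,
    confidence: float = 0.95,
) -> FrequencyEstimate:
    """De-novo substitution frequency restricted to one region."""
    mask = region_mask(pileup.genome, annotations, region)
    n = int(pileup.counts[mask].sum())
    if n == 0:
        raise ValueError(f"region {region!r} has no sequenced bases")
    k = sum(1 for c in calls if not c.is_indel and mask[c.position - 1])
    lo, hi = wilson_interval(min(k, n), n, confidence)
    return FrequencyEstimate(frequency=k / n, lower=lo, upper=hi, k=k, n=n)


def fold_change(
    mean1: float, sd1: float, mean2: float, sd2: float
) -> tuple[float, float]:
    """Ratio mean1/mean2 with first-order (delta-method) uncertainty."""
    if mean2 == 0:
        raise ValueError("cannot form a fold change against a zero mean")
    f = mean1 / mean2
    if mean1 == 0:
        return f, float("nan")
    sd = abs(f) * math.sqrt((sd1 / mean1) ** 2 + (sd2 / mean2) ** 2)
    return f, sd


def welch_ttest(values1: Sequence[float], values2: Sequence[float]) -> float:
    """Two-sample two-tailed Welch t-test on per-sample frequencies."""
    if len(values1) < 2 or len(values2) < 2:
        raise ValueError(
            "t-test requires at least two samples per group "
            f"(got {len(values1)} and {len(values2)})"
        )
    if np.allclose(values1, values2[0]) and np.allclose(values2, values2[0]):
        return 1.0  # all observations identical: no evidence of difference
    res = sps.ttest_ind(values1, values2, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


@dataclass
class RegionComparison:
    region1: str
    region2: str
    per_sample: pd.DataFrame  # columns: sample, region, frequency, k, n
    mean1: float
    mean2: float
    fold: float
    fold_sd: float
    p_value: float


def region_compare(
    samples: Sequence[tuple[Sequence[VariantCall], Pileup]],
    annotations: Sequence[RegionAnnotation],
    region1: str = "control",
    region2: str = "non_control",
    confidence: float = 0.95,
) -> RegionComparison:
    """Compare de-novo frequencies between two regions across samples.

    Each sample contributes one frequency per region; the two sets of
    per-sample frequencies are compared with a two-tailed Welch t-test, and
    the fold change carries delta-method-propagated uncertainty.
    """
    if len(samples) < 2:
        raise ValueError(
            f"region comparison requires at least 2 samples, got {len(samples)}"
        )
    rows = []
    freqs: dict[str, list[float]] = {region1: [], region2: []}
    for i, (calls, pileup) in enumerate(samples):
        for region in (region1, region2):
            est = region_frequency(calls, pileup, annotations, region, confidence)
            freqs[region].append(est.frequency)
            rows.append(
                {
                    "sample": i,
                    "region": region,
                    "frequency": est.frequency,
                    "k": est.k,
                    "n": est.n,
                }
            )
    mean1 = float(np.mean(freqs[region1]))
    mean2 = float(np.mean(freqs[region2]))
    sd1 = float(np.std(freqs[region1], ddof=1))
    sd2 = float(np.std(freqs[region2], ddof=1))
    fold, fold_sd = fold_change(mean1, sd1, mean2, sd2)
    p = welch_ttest(freqs[region1], freqs[region2])
    return RegionComparison(
        region1=region1,
        region2=region2,
        per_sample=pd.DataFrame(rows),
        mean1=mean1,
        mean2=mean2,
        fold=fold,
        fold_sd=fold_sd,
        p_value=p,
    )


def compare_groups(
    freqs1: Sequence[float], freqs2: Sequence[float]
) -> tuple[float, float, float]:
    """(fold change, fold sd, Welch p) between two groups of per-sample
    frequencies, e.g. aged versus young."""
    mean1, mean2 = float(np.mean(freqs1)), float(np.mean(freqs2))
    sd1 = float(np.std(freqs1, ddof=1))
    sd2 = float(np.std(freqs2, ddof=1))
    f, fsd = fold_change(mean1, sd1, mean2, sd2)
    return f, fsd, welch_ttest(freqs1, freqs2)
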