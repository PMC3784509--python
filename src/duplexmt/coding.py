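"""Coding-consequence annotation of de-novo variants and group comparison of
externally supplied pathogenicity scores.

Each de-novo substitution is classified synonymous / nonsynonymous /
noncoding under the vertebrate mitochondrial genetic code (any-gene rule at
overlapping reading frames); the observed nonsynonymous fraction is
nonsynonymous / (nonsynonymous + synonymous). Pathogenicity scores are never
computed here — they come from an external two-column TSV keyed by variant —
and group score distributions are compared with a two-sided Wilcoxon
rank-sum (Mann-Whitney) test: exact enumeration for small samples, a
tie-corrected continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as sps

from duplexmt.reference import (
    GeneticCodeTable,
    ReferenceGenome,
    RegionAnnotation,
    VERTEBRATE_MITO_CODE,
    classify_substitution,
)
from duplexmt.stats import VariantCall

#: combined sample size below which the rank-sum test enumerates exactly
EXACT_RANKSUM_MAX_N = 20


def variant_key(call: VariantCall) -> str:
    """Canonical key used to join external score tables: ``POS:REF>ALT``."""
    return f"{call.position}:{call.ref}>{call.alt}"


@dataclass(frozen=True)
class ConsequenceAnnotatedCall:
    """A de-novo call plus its coding consequence.

    ``gene`` is None exactly when the consequence is noncoding; a
    pathogenicity score may only accompany nonsynonymous calls.
    """

    call: VariantCall
    consequence: str  # synonymous | nonsynonymous | noncoding
    gene: str | None = None
    pathogenicity_score: float | None = None

    def __post_init__(self):
        if self.consequence not in ("synonymous", "nonsynonymous", "noncoding"):
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if (self.gene is None) != (self.consequence == "noncoding"):
            raise ValueError(
                "gene must be present iff the call is coding "
                f"(consequence={self.consequence!r}, gene={self.gene!r})"
            )
        if self.pathogenicity_score is not None:
            if self.consequence != "nonsynonymous":
                raise ValueError(
                    "pathogenicity scores apply only to nonsynonymous calls"
                )
            if not 0.0 <= self.pathogenicity_score <= 1.0:
                raise ValueError(
                    f"score {self.pathogenicity_score} outside [0, 1]"
                )


def _containing_gene(
    annotations: Sequence[RegionAnnotation], pos: int
) -> str | None:
    for ann in annotations:
        if ann.region_class == "protein_coding" and ann.contains(pos):
            return ann.label
    return None


def annotate_consequences(
    calls: Sequence[VariantCall],
    genome: ReferenceGenome,
    annotations: Sequence[RegionAnnotation],
    code: GeneticCodeTable = VERTEBRATE_MITO_CODE,
    scores: Mapping[str, float] | None = None,
) -> list[ConsequenceAnnotatedCall]:
    """Classify de-novo substitution calls by coding consequence.

    Indel calls are ignored (consequence classification is substitution-only
    here). A position outside the genome raises. ``scores`` joins an external
    pathogenicity table by :func:`variant_key`; scores attached to anything
    but a nonsynonymous call are an error by construction.
    """
    out: list[ConsequenceAnnotatedCall] = []
    for call in calls:
        if call.is_indel:
            continue
        if not 1 <= call.position <= genome.length:
            raise ValueError(
                f"call position {call.position} outside 1..{genome.length}"
            )
        consequence = classify_substitution(
            genome, annotations, code, call.position, call.alt
        )
        gene = (
            _containing_gene(annotations, call.position)
            if consequence != "noncoding"
            else None
        )
        score = None
        if scores is not None and consequence == "nonsynonymous":
            score = scores.get(variant_key(call))
        out.append(
            ConsequenceAnnotatedCall(
                call=call, consequence=consequence, gene=gene,
                pathogenicity_score=score,
            )
        )
    return out


def observed_nonsynonymous_fraction(
    annotated: Sequence[ConsequenceAnnotatedCall],
) -> float | None:
    """nonsynonymous / (nonsynonymous + synonymous); None when no coding
    calls exist (e.g. everything fell in tRNA/rRNA/control regions)."""
    n_ns = sum(1 for a in annotated if a.consequence == "nonsynonymous")
    n_syn = sum(1 for a in annotated if a.consequence == "synonymous")
    if n_ns + n_syn == 0:
        return None
    return n_ns / (n_ns + n_syn)


def load_scores(path) -> dict[str, float]:
    """Read an external two-column score TSV: variant key, score in [0, 1].

    Lines starting with ``#`` are comments; the key format is ``POS:REF>ALT``.
    """
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            key, raw = fields
            score = float(raw)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            scores[key] = score
    return scores


def compare_score_distributions(
    scores_group1: Sequence[float], scores_group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two score lists.

    Returns (U statistic of group 1, p-value). Exact enumeration when the
    combined sample size is below ``EXACT_RANKSUM_MAX_N`` and the pooled
    scores are tie-free; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    if not scores_group1 or not scores_group2:
        raise ValueError("both score lists must be nonempty")
    pooled = list(scores_group1) + list(scores_group2)
    has_ties = len(set(pooled)) < len(pooled)
    method = (
        "exact" if (len(pooled) < EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        scores_group1,
        scores_group2,
        alternative="two-sided",
        method=method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)
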