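"""End-to-end orchestration: one configuration drives simulate (optional),
read preparation, consensus building, mutation statistics and consequence
annotation, with per-stage reconciliation counts and a machine-readable JSON
summary. Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

import duplexmt
from duplexmt.coding import (
    annotate_consequences,
    load_scores,
    observed_nonsynonymous_fraction,
    variant_key,
)
from duplexmt.consensus import (
    ConsensusRead,
    build_dcs,
    build_sscs,
    clip_ends,
    dedup_families,
    numt_filter,
    pair_strand_mates,
)
from duplexmt.readprep import (
    PreparedReadPair,
    Rejection,
    group_families,
    iter_fastq_pairs,
    load_alignments,
    validate_and_extract,
)
from duplexmt.reference import (
    ReferenceGenome,
    RegionAnnotation,
    encode_bases,
    load_annotations,
    load_reference,
    packaged_annotations,
    packaged_reference,
)
from duplexmt.simulate import DEFAULT_SPACER, SimulationConfig, simulate_library
from duplexmt.stats import (
    Pileup,
    build_pileup,
    call_variants,
    de_novo_calls,
    mutation_frequency,
    region_frequency,
    spectrum,
    strand_asymmetry,
)

logger = logging.getLogger("duplexmt")

MODES = ("simulate", "process", "full")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the counts so far."""

    def __init__(self, stage: str, counts: dict[str, int], cause: Exception):
        super().__init__(
            f"stage {stage!r} failed: {cause}\nreconciliation so far: {counts}"
        )
        self.stage = stage
        self.counts = dict(counts)


@dataclass
class RunConfig:
    """All stage parameters plus file paths; defaults match the published
    protocol (tag 12, trim 4, min family 3, agreement 0.70, clip 5, dedup
    distance 3, clonality cutoff 0.01, homoplasmy cutoff 0.90, confidence
    0.95)."""

    mode: str = "full"  # simulate | process | full
    output_dir: str = "duplexmt_run"
    seed: int = 0
    # inputs (None -> packaged surrogate reference/annotations)
    reference_path: str | None = None
    annotation_path: str | None = None
    decoy_paths: list[str] = field(default_factory=list)
    scores_path: str | None = None
    fastq1: str | None = None  # required in process mode
    fastq2: str | None = None
    sam: str | None = None
    # read preparation
    tag_length: int = 12
    spacer: str = DEFAULT_SPACER
    trim_bases: int = 4
    # consensus
    min_family: int = 3
    agreement: float = 0.70
    clip_bases: int = 5
    dedup_distance: int = 3
    dedup_keep: str = "none"
    # statistics
    clonality_cutoff: float = 0.01
    homoplasmy_cutoff: float = 0.90
    confidence: float = 0.95
    # simulation parameters (keys of SimulationConfig except genome/seed and
    # the read-structure fields shared above)
    simulation: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "process":
            missing = [
                k for k in ("fastq1", "fastq2", "sam") if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(
                    f"process mode requires input paths: missing {missing}"
                )
        if not 0 < self.agreement <= 1:
            raise ValueError(f"agreement must be in (0,1], got {self.agreement}")
        if self.min_family < 1:
            raise ValueError("min_family must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def simulation_config(self, genome: ReferenceGenome) -> SimulationConfig:
        sim = dict(self.simulation)
        if "n_fragments" not in sim:
            raise ValueError(
                "simulation.n_fragments is required in simulate/full mode "
                "(set it under 'simulation:' in the YAML config)"
            )
        fsd = sim.get("family_size_distribution")
        if isinstance(fsd, (list, tuple)):
            sim["family_size_distribution"] = (str(fsd[0]), float(fsd[1]))
        if "clonal_variants" in sim:
            sim["clonal_variants"] = [
                (int(p), str(a).upper(), float(f))
                for p, a, f in sim["clonal_variants"]
            ]
        if "injected_true_mutations" in sim:
            sim["injected_true_mutations"] = [
                (int(p), str(a).upper()) for p, a in sim["injected_true_mutations"]
            ]
        return SimulationConfig(
            genome=genome,
            seed=self.seed,
            tag_length=self.tag_length,
            spacer=self.spacer,
            trim_bases=self.trim_bases,
            **sim,
        )


@dataclass
class RunSummary:
    """Counts, headline statistics and provenance of one pipeline run."""

    counts: dict[str, int]
    discards: dict[str, int]
    statistics: dict[str, Any]
    parameters: dict[str, Any]
    seed: int
    version: str = duplexmt.__version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def check_reconciliation(self) -> None:
        """Assert inputs = outputs + discards at every stage."""
        c, d = self.counts, self.discards
        checks = [
            ("read pairs", c["pairs_in"],
             c["pairs_prepared"] + d["bad_spacer"] + d["ambiguous_tag"]
             + d["too_short"]),
            ("prepared pairs", c["pairs_prepared"],
             c["pairs_mapped"] + d["unmapped_or_off_target"]),
            ("families", c["families"],
             c["families_after_dedup"] + d["dedup_near_tag"]),
            ("SSCS input", c["families_after_dedup"],
             c["sscs"] + d["sscs_insufficient"]),
            ("SSCS pairing", c["sscs"], 2 * c["dcs"] + d["sscs_unpaired"]),
            ("NUMT filter", c["dcs"], c["dcs_kept"] + d["numt"]),
        ]
        for name, lhs, rhs in checks:
            if lhs != rhs:
                raise AssertionError(
                    f"reconciliation failure at {name}: {lhs} != {rhs}"
                )


def _load_inputs(
    config: RunConfig,
) -> tuple[ReferenceGenome, list[RegionAnnotation], list[str]]:
    genome = (
        load_reference(config.reference_path)
        if config.reference_path
        else packaged_reference()
    )
    annotations = (
        load_annotations(config.annotation_path)
        if config.annotation_path
        else packaged_annotations()
    )
    decoys = []
    for path in config.decoy_paths:
        decoys.append(load_reference(path).sequence)
    return genome, list(annotations), decoys


def _mismatch_rate_raw(
    prepared: Sequence[PreparedReadPair], genome: ReferenceGenome
) -> tuple[int, int]:
    """(mismatches, bases) of mapped trimmed reads against the reference."""
    G = genome.length
    codes = genome.codes
    mismatches = 0
    bases = 0
    for pair in prepared:
        if pair.mapping is None:
            continue
        for seq, (pos, _rev) in zip((pair.read1, pair.read2), pair.mapping):
            read = encode_bases(seq)
            ref = codes[(pos - 1 + np.arange(len(read))) % G]
            defined = read != 4
            mismatches += int(((read != ref) & defined).sum())
            bases += int(defined.sum())
    return mismatches, bases


def consensus_mismatches(
    reads: Sequence[ConsensusRead], genome: ReferenceGenome
) -> tuple[int, int]:
    """(mismatches, defined bases) of consensus reads against the reference."""
    G = genome.length
    codes = genome.codes
    mismatches = 0
    bases = 0
    for read in reads:
        for seg in read.segments:
            seq = encode_bases(seg.bases)
            ref = codes[(seg.start - 1 + np.arange(len(seq))) % G]
            defined = seq != 4
            mismatches += int(((seq != ref) & defined).sum())
            bases += int(defined.sum())
    return mismatches, bases


def _read_has_mismatch(read: ConsensusRead, genome: ReferenceGenome) -> bool:
    m, _ = consensus_mismatches([read], genome)
    return m > 0


def write_variant_tsv(calls, path, genome_name: str) -> None:
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tCOUNT\tDEPTH\tCLONALITY\tREGION\tFLAGS\n")
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            flags = []
            if c.is_clonal:
                flags.append("clonal")
            if c.is_homoplasmic:
                flags.append("homoplasmic")
            if c.is_indel:
                flags.append("indel")
            fh.write(
                f"{genome_name}\t{c.position}\t{c.ref}\t{c.alt}\t"
                f"{c.mutant_count}\t{c.depth}\t{c.clonality:.6g}\t"
                f"{c.region_class}\t{','.join(flags) or '.'}\n"
            )


def write_vcf(calls, path, genome: ReferenceGenome) -> None:
    """Strict-VCF export of the substitution calls (indels skipped: the
    internal descriptors do not carry the anchored alleles VCF requires)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={genome.length}>\n")
        fh.write(
            '##INFO=<ID=COUNT,Number=1,Type=Integer,'
            'Description="Mutant molecule count">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="DCS depth">\n'
            '##INFO=<ID=CLONALITY,Number=1,Type=Float,'
            'Description="Mutant fraction of molecules">\n'
            '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">\n'
            '##FILTER=<ID=clonal,Description="Above the clonality cutoff">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            if c.is_indel:
                continue
            filt = "clonal" if c.is_clonal else "PASS"
            fh.write(
                f"{genome.name}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t"
                f"COUNT={c.mutant_count};DP={c.depth};"
                f"CLONALITY={c.clonality:.6g};REGION={c.region_class}\n"
            )


def run_full(config: RunConfig) -> RunSummary:
    """Execute the configured stages and write every artifact.

    simulate mode stops after writing FASTQ/SAM/truth; process mode consumes
    existing FASTQ+SAM; full mode chains both. Raises :class:`StageError`
    naming the failed stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_yaml(outdir / "resolved_config.yaml")
    counts: dict[str, int] = {}
    discards: dict[str, int] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    genome, annotations, decoys = _load_inputs(config)

    fastq1, fastq2, sam = config.fastq1, config.fastq2, config.sam
    if config.mode in ("simulate", "full"):
        try:
            stage("simulate")
            sim_cfg = config.simulation_config(genome)
            library = simulate_library(sim_cfg)
            fastq1 = str(outdir / "reads_1.fastq")
            fastq2 = str(outdir / "reads_2.fastq")
            sam = str(outdir / "alignments.sam")
            library.write_fastq(fastq1, fastq2)
            library.write_sam(sam)
            library.truth.write_tsv(outdir / "truth.tsv")
            counts["simulated_fragments"] = len(library.frag_start)
            counts["simulated_pairs"] = library.n_pairs
            counts["truth_events"] = len(library.truth)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError("simulate", counts, exc) from exc
    if config.mode == "simulate":
        summary = RunSummary(
            counts=counts, discards=discards,
            statistics={}, parameters=config.to_dict(), seed=config.seed,
        )
        summary.write(outdir / "summary.json")
        return summary

    # ---- read preparation -------------------------------------------------
    try:
        stage("read_prep")
        alignments, _ = load_alignments(sam, genome.name)
        prepared: list[PreparedReadPair] = []
        discards.update(bad_spacer=0, ambiguous_tag=0, too_short=0)
        n_in = 0
        for qname, s1, s2 in iter_fastq_pairs(fastq1, fastq2):
            n_in += 1
            res = validate_and_extract(
                s1, s2, spacer=config.spacer, tag_length=config.tag_length,
                trim_bases=config.trim_bases, qname=qname,
            )
            if isinstance(res, Rejection):
                discards[res.reason] += 1
                continue
            aln = alignments.get(qname)
            if aln is not None:
                res.read1, res.read2 = aln.seq1, aln.seq2
                res.mapping = (aln.map1, aln.map2)
            prepared.append(res)
        counts["pairs_in"] = n_in
        counts["pairs_prepared"] = len(prepared)
        mapped = [p for p in prepared if p.mapping is not None]
        counts["pairs_mapped"] = len(mapped)
        discards["unmapped_or_off_target"] = len(prepared) - len(mapped)
    except Exception as exc:
        raise StageError("read_prep", counts, exc) from exc

    # ---- consensus --------------------------------------------------------
    try:
        stage("consensus")
        families, _ = group_families(mapped)
        counts["families"] = len(families)
        fam_list = [families[k] for k in sorted(families)]
        retained = dedup_families(
            fam_list, max_distance=config.dedup_distance, keep=config.dedup_keep
        )
        counts["families_after_dedup"] = len(retained)
        discards["dedup_near_tag"] = len(fam_list) - len(retained)
        sscs = []
        for fam in retained:
            cons = build_sscs(
                fam, min_family=config.min_family, agreement=config.agreement
            )
            if cons is not None:
                sscs.append(cons)
        counts["sscs"] = len(sscs)
        discards["sscs_insufficient"] = len(retained) - len(sscs)
        pairs, unpaired = pair_strand_mates(sscs)
        counts["dcs"] = len(pairs)
        discards["sscs_unpaired"] = unpaired
        dcs = [clip_ends(build_dcs(a, b), n=config.clip_bases) for a, b in pairs]
        kept = []
        n_numt = 0
        for read in dcs:
            if decoys and _read_has_mismatch(read, genome):
                if not numt_filter(read, genome, decoys):
                    n_numt += 1
                    continue
            kept.append(read)
        counts["dcs_kept"] = len(kept)
        discards["numt"] = n_numt
        raw_mm, raw_bases = _mismatch_rate_raw(mapped, genome)
        sscs_mm, sscs_bases = consensus_mismatches(sscs, genome)
        dcs_mm, dcs_bases = consensus_mismatches(kept, genome)
        counts["dcs_defined_bases"] = dcs_bases
    except Exception as exc:
        raise StageError("consensus", counts, exc) from exc

    # ---- statistics -------------------------------------------------------
    try:
        stage("mutation_stats")
        pileup = build_pileup(kept, genome)
        calls = call_variants(
            pileup, genome,
            clonality_cutoff=config.clonality_cutoff,
            homoplasmy_cutoff=config.homoplasmy_cutoff,
            annotations=annotations,
        )
        de_novo = de_novo_calls(calls)
        write_variant_tsv(calls, outdir / "variants.tsv", genome.name)
        write_vcf(calls, outdir / "variants.vcf", genome)
        statistics: dict[str, Any] = {
            "mismatch_rates": {
                "raw": raw_mm / raw_bases if raw_bases else None,
                "sscs": sscs_mm / sscs_bases if sscs_bases else None,
                "dcs": dcs_mm / dcs_bases if dcs_bases else None,
            },
            "n_calls": len(calls),
            "n_de_novo": len(de_novo),
            "n_clonal": sum(1 for c in calls if c.is_clonal),
            "n_homoplasmic": sum(1 for c in calls if c.is_homoplasmic),
        }
        if pileup.total_bases:
            est = mutation_frequency(de_novo, pileup, config.confidence)
            statistics["frequency"] = {
                "value": est.frequency, "lower": est.lower, "upper": est.upper,
                "k": est.k, "n": est.n,
            }
            spec_table = spectrum(de_novo, pileup)
            spec_table.to_tsv(outdir / "spectrum.tsv")
            statistics["spectrum"] = {
                cls: {
                    "sites": int(row["sites"]),
                    "frequency": (
                        None if np.isnan(row["frequency"])
                        else float(row["frequency"])
                    ),
                    "proportion": float(row["proportion"]),
                }
                for cls, row in spec_table.collapsed.iterrows()
            }
            asym = strand_asymmetry(de_novo, pileup)
            asym.to_csv(outdir / "asymmetry.tsv", sep="\t")
            statistics["asymmetry"] = {
                pair: {
                    "ratio": None if np.isnan(row["ratio"]) else float(row["ratio"]),
                    "p_value": (
                        None if np.isnan(row["p_value"]) else float(row["p_value"])
                    ),
                }
                for pair, row in asym.iterrows()
            }
            regions = {}
            with open(outdir / "regions.tsv", "w") as fh:
                fh.write("region\tk\tn\tfrequency\tlower\tupper\n")
                for region in ("control", "non_control"):
                    try:
                        r = region_frequency(
                            de_novo, pileup, annotations, region, config.confidence
                        )
                    except ValueError:
                        continue
                    regions[region] = {
                        "frequency": r.frequency, "lower": r.lower,
                        "upper": r.upper, "k": r.k, "n": r.n,
                    }
                    fh.write(
                        f"{region}\t{r.k}\t{r.n}\t{r.frequency:.6g}\t"
                        f"{r.lower:.6g}\t{r.upper:.6g}\n"
                    )
            statistics["regions"] = regions
    except Exception as exc:
        raise StageError("mutation_stats", counts, exc) from exc

    # ---- coding impact ----------------------------------------------------
    try:
        stage("coding_impact")
        scores = load_scores(config.scores_path) if config.scores_path else None
        annotated = annotate_consequences(
            de_novo, genome, annotations, scores=scores
        )
        with open(outdir / "consequences.tsv", "w") as fh:
            fh.write("variant\tconsequence\tgene\tscore\n")
            for a in annotated:
                fh.write(
                    f"{variant_key(a.call)}\t{a.consequence}\t"
                    f"{a.gene or '.'}\t"
                    f"{'.' if a.pathogenicity_score is None else a.pathogenicity_score}\n"
                )
        frac = observed_nonsynonymous_fraction(annotated)
        statistics["nonsynonymous_fraction"] = frac
        statistics["n_nonsynonymous"] = sum(
            1 for a in annotated if a.consequence == "nonsynonymous"
        )
        statistics["n_synonymous"] = sum(
            1 for a in annotated if a.consequence == "synonymous"
        )
    except Exception as exc:
        raise StageError("coding_impact", counts, exc) from exc

    with open(outdir / "discards.tsv", "w") as fh:
        fh.write("reason\tcount\n")
        for reason in sorted(discards):
            fh.write(f"{reason}\t{discards[reason]}\n")

    summary = RunSummary(
        counts=counts, discards=discards, statistics=statistics,
        parameters=config.to_dict(), seed=config.seed,
    )
    summary.check_reconciliation()
    summary.write(outdir / "summary.json")
    return summary
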