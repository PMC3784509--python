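"""Compute a substitution spectrum, strand asymmetry and region comparison
from simulated samples.

Simulates three independent "samples" with a uniform true-mutation load
using the library API directly (rather than the one-shot pipeline), then
pools the calls to build the 6-class spectrum, tests reciprocal-pair
asymmetry, and compares the control region (D-loop) against the rest of
the genome across samples.

Run:  python examples/03_spectrum_and_regions.py
"""

import tempfile
from pathlib import Path

from duplexmt.consensus import (
    build_dcs,
    build_sscs,
    clip_ends,
    dedup_families,
    pair_strand_mates,
)
from duplexmt.readprep import (
    PreparedReadPair,
    group_families,
    iter_fastq_pairs,
    load_alignments,
    validate_and_extract,
)
from duplexmt.reference import packaged_annotations, packaged_reference
from duplexmt.simulate import SimulationConfig, simulate_library
from duplexmt.stats import (
    Pileup,
    build_pileup,
    call_variants,
    de_novo_calls,
    mutation_frequency,
    region_compare,
    spectrum,
    strand_asymmetry,
)

genome = packaged_reference()
annotations = packaged_annotations()


def simulate_sample(seed: int):
    """Simulate one duplex library and return (de-novo calls, pileup)."""
    cfg = SimulationConfig(
        genome=genome,
        n_fragments=3000,
        seed=seed,
        family_size_distribution=("fixed", 3),
        true_mutation_frequency=5e-5,
    )
    lib = simulate_library(cfg)
    with tempfile.TemporaryDirectory() as tmp:
        fq1, fq2, sam = (Path(tmp) / n for n in ("r1.fq", "r2.fq", "a.sam"))
        lib.write_fastq(fq1, fq2)
        lib.write_sam(sam)
        aligns, _ = load_alignments(sam, genome.name)
        prepared = []
        for qname, s1, s2 in iter_fastq_pairs(fq1, fq2):
            res = validate_and_extract(s1, s2, cfg.spacer, qname=qname)
            if isinstance(res, PreparedReadPair) and qname in aligns:
                a = aligns[qname]
                res.read1, res.read2 = a.seq1, a.seq2
                res.mapping = (a.map1, a.map2)
                prepared.append(res)
    families, _ = group_families(prepared)
    retained = dedup_families([families[k] for k in sorted(families)])
    sscs = [c for c in (build_sscs(f) for f in retained) if c]
    pairs, _ = pair_strand_mates(sscs)
    dcs = [clip_ends(build_dcs(a, b)) for a, b in pairs]
    pileup = build_pileup(dcs, genome)
    # shallow demo depth: a single molecule exceeds 1% clonality, so keep
    # all calls by disabling the cutoff
    calls = de_novo_calls(
        call_variants(pileup, genome, clonality_cutoff=1.0,
                      annotations=annotations)
    )
    return calls, pileup


samples = [simulate_sample(seed) for seed in (100, 101, 102)]
for i, (calls, pileup) in enumerate(samples):
    est = mutation_frequency(calls, pileup)
    print(f"sample {i}: {est.k} de-novo sites / {est.n:,} DCS bases "
          f"-> {est.frequency:.3g} [{est.lower:.3g}, {est.upper:.3g}]")

# pool calls and pileups across samples for the spectrum and asymmetry
pooled_calls = [c for calls, _ in samples for c in calls]
pooled_pileup = Pileup(genome=genome)
for _, pileup in samples:
    pooled_pileup.counts += pileup.counts

print(f"\npooled de-novo calls: {len(pooled_calls)}")
table = spectrum(pooled_calls, pooled_pileup)
print("\ncollapsed substitution spectrum:")
print(table.collapsed[["sites", "frequency", "proportion"]])

print("\nreciprocal-pair strand asymmetry:")
print(strand_asymmetry(pooled_calls, pooled_pileup)[
    ["sites_1", "sites_2", "ratio", "p_value"]])

res = region_compare(samples, annotations)
print(f"\nD-loop vs rest: fold {res.fold:.2f} +- {res.fold_sd:.2f}, "
      f"p = {res.p_value:.3f}")
print(res.per_sample)
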