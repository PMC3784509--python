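# duplexmt

Duplex-sequencing consensus calling and somatic mitochondrial DNA mutation
analysis.

`duplexmt` implements the tag-based duplex consensus workflow for detecting
ultra-rare somatic point mutations in mitochondrial DNA, together with the
downstream statistics used to characterise mtDNA mutagenesis, and a seeded
simulator with a complete ground-truth ledger for validating the whole chain.

## What it does

Duplex sequencing attaches a random 12-bp double-stranded tag to each end of
every DNA fragment before PCR. All reads descending from one parental strand
share a 24-nt tag key; the two strands of one molecule yield keys with
mutually swapped halves. Collapsing each tag family position by position
gives a **single-strand consensus sequence (SSCS)**, which removes sequencing
and late-PCR errors; requiring the two strand-mate SSCS to agree gives the
**duplex consensus sequence (DCS)**, which additionally removes first-round
PCR and single-strand DNA-damage artifacts, leaving only true double-stranded
mutations.

The package covers:

* **Reference model** — circular 1-based coordinates wrapping the origin,
  L-strand orientation, region annotations (D-loop control region, 13
  protein genes, rRNAs, tRNAs), the vertebrate mitochondrial genetic code,
  and exhaustive enumeration of the expected non-synonymous fraction
  (~75.7 % for the packaged reference).
* **Simulator** — seeded duplex libraries with four distinct error classes
  (true mutations, clonal heteroplasmies, single-strand damage, late-PCR
  errors, sequencing errors), FASTQ/SAM export, and a truth ledger naming
  every introduced event and the reads that carry it.
* **Read preparation** — tag/spacer validation, technical-base trimming, tag
  family grouping by 24-nt key and mapping coordinates.
* **Consensus** — SSCS (default: families of ≥3 reads, ≥70 % per-position
  agreement), strand-mate pairing, DCS, 5-nt end clipping, near-tag family
  deduplication (Hamming distance < 3 at one coordinate key), and
  local-alignment filtering of nuclear-pseudogene (NUMT) look-alikes against
  user-supplied decoys.
* **Statistics** — DCS pileup; variant calls with a clonality cutoff (>1 %
  of molecules → inherited/clonal, excluded from de-novo counts; >90 % →
  homoplasmic); de-novo frequency = unique mutated sites ÷ total DCS bases
  with Wilson 95 % intervals; 12-class directional and 6-class collapsed
  substitution spectra normalised by wild-type base exposure; L-strand
  reciprocal-pair asymmetry; D-loop versus coding-region comparison with
  Welch t-tests and delta-method fold-change uncertainty.
* **Coding impact** — synonymous/non-synonymous classification under the
  vertebrate mitochondrial code (any-gene rule in overlapping reading
  frames), observed non-synonymous fraction, and Wilcoxon rank-sum
  comparison of externally supplied pathogenicity scores.

## Quick start

Simulate a library, process it end-to-end, and read the JSON summary:

```bash
duplexmt full --out run --seed 7 --config examples/full_run.yaml
cat run/summary.json
```

Or drive everything from Python:

```python
from duplexmt.pipeline import RunConfig, run_full

cfg = RunConfig(
    mode="full", output_dir="run", seed=7,
    simulation={
        "n_fragments": 5000,
        "family_size_distribution": ["poisson_shifted", 6.0],
        "sequencing_error_rate": 1e-3,
        "damage_error_rate": 1e-4,
        "true_mutation_frequency": 1e-5,
    },
)
summary = run_full(cfg)
print(summary.statistics["frequency"])
```

Every run writes `summary.json` (counts, headline statistics, parameter
echo), `variants.tsv` (+ strict-VCF export), `spectrum.tsv`,
`asymmetry.tsv`, `regions.tsv`, `consequences.tsv`, a `discards.tsv` audit
of every filter, and the resolved YAML config. Identical config + seed gives
identical outputs.

CLI subcommands: `sim`, `prep`, `consensus`, `call`, `spectrum`,
`asymmetry`, `regions`, `consequences`, `full`; see `duplexmt --help`.

## Packaged reference

`duplexmt.data` ships a **synthetic** 16,569-bp human-mtDNA surrogate
reference (derived from the GenBank NC_001807.4 mitochondrial sequence with
two control-region poly-C bases removed so every gene sits at standard rCRS
coordinates) plus the standard 37-gene + D-loop annotation. It is intended
for simulation and testing; for real data supply your own reference FASTA
and annotation TSV (`--reference`, `--annotations`). See
`scripts/make_surrogate_reference.py` for its provenance.

## Examples and tests

Narrative walk-throughs live in `examples/`; run them directly, e.g.
`python examples/01_simulate_and_recover.py`. The test suite, including the
acceptance criteria, runs with `pytest`. The standalone acceptance runner
writes its results as JSON:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

## Documentation

`docs/methods.md` describes the full method: tag handling, consensus rules,
filters, estimators and statistical tests, with the exact default
parameters.
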