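# Methods

This note defines the algorithms, estimators and conventions implemented in
`duplexmt`, with their default parameters. All defaults are echoed into every
run's `summary.json` and `resolved_config.yaml`.

## Coordinates and strands

The reference is a circular genome stored as its **L-strand** (the C-rich
strand of human mtDNA) 5'→3'. Coordinates are 1-based inclusive and wrap
modulo the genome length: the base after position *L* is position 1. Region
annotations may span the origin (`end < start`), as the control region
(D-loop, bp 16024–576) does. Every substitution is expressed on the
L-strand: `G>T` means the reference L-strand base G was replaced by T; the
identical physical event read off the H-strand would be written `C>A`.

Annotations carry a `coding_strand` flag: `H`-unit genes are read directly
off the reference; `L`-unit genes (ND6 and eight tRNAs) are read off its
reverse complement. When a position falls in several annotations, class
precedence is protein_coding > control > rRNA > tRNA; positions in none are
`intergenic`.

## Read structure and preparation

A raw read is `<12-bp tag><fixed spacer><insert>`. For a read pair, the two
tag halves concatenated in read order form the 24-nt duplex key; the two
strands of one parental molecule produce keys with mutually swapped halves
(and swapped read-1/read-2 mapping coordinates). Validation rejects —
counted, never silently dropped — pairs with:

* `ambiguous_tag`: non-ACGT bases in either tag half;
* `bad_spacer`: spacer not matching exactly at its expected offset;
* `too_short`: insufficient length for tag + spacer + trim + 1 base.

After removing tag and spacer, a further **4 bases** (`trim_bases`) are
trimmed from each read start to drop end-repair/ligation artifacts. Families
group pairs by (24-nt key, read-1 mapping, read-2 mapping); both position
and orientation must match.

## Consensus building

**SSCS** (single-strand consensus): each tag family is collapsed per
position. A position is defined only if covered by at least `min_family = 3`
reads (N bases count toward neither coverage nor the tally) and the modal
base reaches `agreement = 0.70` of the coverage (exactly 70 % passes; ties
give N). Families whose consensus defines no position are discarded and
counted.

**Near-tag deduplication**: within one coordinate key, families whose
24-nt keys differ by fewer than `dedup_distance = 3` bases are linked into
components; every family in a component of size > 1 is removed (default), or
the largest per component is kept (`--dedup-keep-largest`). Tag errors arise
within one molecule's descendants, which share coordinates, so families at
different coordinates are never compared.

**DCS** (duplex consensus): two SSCS are strand mates when their keys have
swapped halves and swapped mate mappings. The DCS keeps a base only where
both strand mates have identical defined bases; disagreement or an undefined
base on either strand yields N. This is the step that removes strand-specific
first-round PCR and DNA-damage errors.

**End clipping**: the first and last `clip = 5` *defined* positions of each
DCS segment are set to N, suppressing alignment-edge artifacts.

**NUMT filter**: a DCS read carrying at least one mismatch has its defined
stretches locally aligned (match +2, mismatch −3, gap open −5, extend −2)
against the doubled (wrap-aware) mitochondrial reference and against each
supplied nuclear decoy sequence; the read is removed when any decoy
outscores the mitochondrial reference — the signature of a nuclear
mitochondrial pseudogene. With no decoys supplied the filter is a no-op.

## Variant calling and mutation frequency

All defined DCS bases are tallied into a positional pileup. Every
(position, non-reference base) with at least one molecule yields a call with
its **clonality** = mutant molecules ÷ depth:

* clonality > `0.01` → flagged clonal (inherited or clonally expanded),
  excluded from de-novo statistics;
* clonality > `0.90` → additionally flagged homoplasmic.

Both cutoffs are strict inequalities. The **de-novo point-mutation
frequency** is the number of unique de-novo (position, alt) sites divided by
the total number of DCS bases sequenced, with a Wilson score 95 % interval.
Counting unique sites (not molecules) avoids double-counting clonal
expansion below the cutoff; a molecule-count mode is available. Indels are
recorded as separate events and reported per total bases, never mixed into
the substitution frequency.

## Spectrum, asymmetry, regions

* **Spectrum**: 12 directional classes `X>Y`, each normalised by its
  exposure — the number of times wild-type base X was sequenced at
  X-reference positions; 6 collapsed classes pool complementary pairs.
  Class proportions (6 collapsed classes + indels) sum to 1.
* **Strand asymmetry**: for each reciprocal pair (e.g. `G>A` vs `C>T`, both
  on the L-strand), the ratio of exposure-normalised frequencies and a
  two-sided pooled two-proportion z-test. Zero exposure reports a missing
  value, not zero.
* **Regions**: de-novo frequency restricted to the control region
  (D-loop) versus everything else, each with Wilson intervals. Across ≥2
  samples, regions (or groups, e.g. aged vs young) are compared with a
  two-tailed Welch t-test on per-sample frequencies; fold changes carry
  first-order (delta-method) uncertainty.

## Coding impact

De-novo substitutions are classified under the vertebrate mitochondrial
genetic code (NCBI table 2: ATA→Met, TGA→Trp, AGA/AGG→stop). A position in
several overlapping reading frames is non-synonymous if the change is
non-synonymous in **any** frame; positions in terminal stop codons or in
trailing incomplete codons (completed by polyadenylation in vivo) are
excluded from coding accounting. The observed non-synonymous fraction is
non-synonymous ÷ (non-synonymous + synonymous); the expected fraction under
uniform mutation is computed by exhaustively enumerating the three
alternative bases at every protein-coding position (≈ 75.7 % for the
packaged reference). Externally supplied pathogenicity scores (two-column
TSV keyed `POS:REF>ALT`, scores in [0, 1]) are joined to non-synonymous
calls only, and group score distributions are compared with a two-sided
Wilcoxon rank-sum (Mann–Whitney) test — exact enumeration when the pooled
sample is tie-free and smaller than 20, otherwise the tie-corrected normal
approximation with continuity correction.

## Simulator

The simulator draws fragments uniformly on the circle with Gaussian lengths
(default mean 300 bp, sd 30), assigns each fragment two random 12-bp tags,
and emits, per strand-family, `1 + Poisson(mean − 1)` read pairs (or a fixed
size). Reads are 101 bp: 12-bp tag + 5-bp spacer + 84-bp insert. Five error
classes are introduced at their proper stage, every event recorded in a
truth ledger with the reads that carry it:

* **true mutations** (per-base rate, or explicitly injected single
  molecules) — on both parental strands: survive to DCS;
* **clonal variants** — per-fragment Bernoulli at a configured fraction:
  population-level heteroplasmies;
* **damage** — on one parental strand only (default spectrum G>T):
  reaches the SSCS of one strand, removed by DCS;
* **late PCR errors** — on a random sub-lineage (a 2^−k fraction) of one
  family: mostly removed at SSCS, always by DCS;
* **sequencing errors** — per read per base: removed at SSCS.

Injected single-molecule mutations are placed at least `injected_margin = 10`
bases from both ends of a read window so trimming and clipping cannot
silently erase the one molecule a sensitivity experiment depends on.

Given the same configuration and seed, the simulator, the pipeline and every
output file are byte-identical.

## Reconciliation

At every stage, inputs = outputs + discards: FASTQ pairs →
prepared/rejected; prepared → mapped/off-target; families →
retained/deduplicated; retained → SSCS/insufficient; SSCS → DCS
pairs/unpaired; DCS → kept/NUMT-removed. `summary.json` carries all counts
and the pipeline asserts the identities before writing it.
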