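# Methods

## The measurement problem

A mutation-accumulation (MA) panel propagates lines by single-seed
descent so that drift, not selection, decides the fate of new mutations;
resequencing after several generations and counting de novo variants
gives a direct rate estimate. For plant organelle genomes two
complications dominate. First, organelle genomes are present in many
copies per cell, so a new mutation is observed as a heteroplasmic read
fraction that drifts between generations through transmission
bottlenecks; a variant caught mid-sorting is "part of a mutation" in
frequency mass. Second, the read counts are contaminated: long
homopolymers carry locus-specific sequencing-error rates far above
baseline, and the nuclear genome of *Arabidopsis thaliana* contains a
large, nearly identical copy of mitochondrial DNA (numt) whose reads
carry the mitochondrial reference allele and depress observed variant
frequencies.

## Rate model

Rates are per base pair per generation:

μ = V / (G·N), with

- V — Σ of heteroplasmic frequencies over called SNVs/MNVs (an MNV
  counts once at its frequency), or the raw count for indels. Indels are
  unweighted because homopolymer sequencing error makes their frequency
  estimates unreliable; the indel rate is therefore biased upward by
  heteroplasmic indels counted at weight 1, and downward by multiple
  hits at one locus.
- G — genome length minus one copy of each excluded large repeat.
  Repeats that interconvert by recombination would double-count
  variants; removing one copy from both calling and the denominator
  keeps the rate consistent.
- N — homozygous generations summed over lines (7 per line carried to
  the eighth generation, 6 for lines that died one generation early; the
  heterozygous founder generation does not accumulate mutator-regime
  mutations).

With zero observations, setting the Poisson zero-probability e^(−μGN)
to α = 0.05 gives the upper bound μ = ln(1/α)/(G·N). A companion
"single-variant" rate 1/(G·N) reports what one homoplasmic variant
would have implied.

Per-class spectrum rates divide each class's frequency-weighted count by
the matching pair count (A:T or G:C) of the reduced genome, so genome
composition does not masquerade as mutational bias. Classes are
strand-symmetric (A→G and T→C are one class, AT>GC); six classes cover
all substitutions.

## Calling cascade

1. **Candidate gates.** Allele frequency ≥ 20% (min_freq), depth ≥ 50×
   (min_depth), per (position, allele). The high frequency cutoff
   suppresses vegetative (somatic) mutations and mapping noise.
2. **Wild-type background.** A candidate must be ≥ 3-fold (bg_fold) the
   mean frequency of the *same allele* across all WT control lines. The
   per-allele (rather than summed non-reference) background is the
   stricter reading and prevents a real variant in one WT line from
   masking a different allele; the WT mean is self-inclusive when WT
   lines are called (an option excludes the focal line). This rule is
   what absorbs homopolymer error: every line, control or mutator, sees
   the same inflated locus error, so a 3-fold excess demands a real
   signal.
3. **Repeat exclusion** drops calls in excluded repeat copies.
4. **Artefact exclusion.** Structural rearrangements between small
   repeats, and the numt, produce mismapped reads that mimic variants.
   Screening is by exact match: the call's alt-containing context (20 bp
   flank each side, flank_k) searched in supplied artefact junction
   sequences on either strand. Exact matching is deterministic and
   dependency-free; users of real data can pre-screen with a similarity
   search and pass the hits as a blocklist.
5. **Numt correction** (mitochondrial SNVs): expected nuclear-derived
   reads = nuclear coverage × numt copy number at the locus, kept as a
   real number; subtracted from the reference-allele count (floored at
   zero) and from the total depth before recomputing frequency, capped
   at 1.0. The correction can only raise a frequency. Nuclear coverage
   is estimated as (total read bases − organelle-mapped bases) / nuclear
   genome size. Thresholds are applied to the *raw* frequency, before
   correction, matching the cascade order above.
6. **MNV merge.** Adjacent same-line substitutions merge into one MNV at
   the mean of member frequencies; an insertion co-located with a
   substitution merges into a replacement-type MNV (one base pair
   replaced by a dinucleotide). Members leave the SNV pool so nothing is
   double-counted.
7. **Homoplasmy labels.** Plastid ≥ 0.98; mitochondrial > 0.90 strictly,
   on the corrected frequency, reflecting that the numt correction is
   approximate.

Indel alleles are keyed by left-aligned position at the start of their
repeat run and by inserted sequence / deleted length (`ins:SEQ`,
`del:N`); left-alignment is a convention choice and context assignment
is invariant to shifts within the run.

## Synthetic experiments

The generator emulates the pipeline's inputs downstream of read mapping
(per-site count tables), not reads. Default study conditions: a 50 kb
mitochondrial + 20 kb plastid reference pair (scaled-down stand-ins;
AT fraction 0.55 / 0.65 so the plastid is homopolymer-rich), 22 mutator
lines (18 × 7 + 4 × 6 generations, N = 150) and 20 control lines in
three founder families each, mean depth 500× (negative binomial,
size 50), base error 0.2%.

- **Mutation input.** Per generation, each class contributes
  Poisson(rate × G) SNVs at uniform eligible sites. Class rates default
  to the observed per-genome scale and spectrum of the mutator regime
  (plastid strongly AT→GC-biased, ~3.9 × 10⁻⁶ total; mitochondrial
  transition-balanced, ~9 × 10⁻⁷). Homopolymer indels arrive per locus
  (run ≥ 5 bp) at 2 × 10⁻³ (mito) / 6 × 10⁻³ (plastid) per generation,
  sized so a panel accumulates indel counts in proportion to the real
  experiment's per-genome counts; direction is deletion-biased at A/T
  runs and insertion-biased at G/C runs; lengths 1/2/3 bp at 0.9/0.08/
  0.02. MNVs arrive at ~1 per panel.
- **Heteroplasmy dynamics.** New mutations enter at frequency 0.5
  (initial_frequency; a convention for germline transmission — exposed
  in config) and drift by per-generation binomial resampling with
  bottleneck sizes 8 (mitochondrial) and 3 (plastid). The sizes are
  order-of-magnitude choices set so the simulated panels reproduce the
  observed sorting contrast — most surviving plastid variants fixed or
  lost within the experiment, mitochondrial sorting slower — not
  estimates of the real bottlenecks.
- **Error model.** Substitution miscalls per alt base at e/3.
  At a homopolymer of length L the locus error is
  e × 5 × (L − 4)^1, capped at 0.4, split 60:40 between del:1 and
  single-base insertion miscalls (and applied to substitutions across
  the run). This is a deliberately simple stand-in for the observed
  length-dependent error inflation; it reproduces the one property the
  cascade must survive — all lines share elevated, length-dependent
  locus error — without modelling the sequencing chemistry.
- **Numt contamination.** Mitochondrial tables gain Poisson(copies ×
  nuclear coverage) reference reads over numt intervals (one interval
  covering 20% of the genome, nuclear coverage 20×), and per-line read
  statistics are emitted so the caller re-derives coverage the same way
  it would from mapping summaries.

What the generator does **not** model: read-level artefacts (mapping
bias, strand effects, base-quality structure), true structural
rearrangements (artefact screening is tested with constructed junction
sequences), circular-genome coordinates (runs spanning the origin are
not merged), selection during propagation, and multiple independent hits
at one site within a line (collisions are resampled). Passing tests
therefore demonstrate the cascade's logic and calibration under a
faithful count-level error structure, not robustness to every real-data
pathology upstream of the counts.

## Statistical tests

- **Synonymous permutation test.** Holding the number and mutation class
  of CDS substitutions fixed per genome, each permutation re-places them
  uniformly on CDS sites whose reference pair matches the class (the alt
  base then being determined by class and strand), sums synonymous
  outcomes across genomes, and the one-tailed p is the fraction of
  10,000 permutations with at least the observed synonymous count.
  Placement is uniform over eligible sites, not weighted by degeneracy —
  the only reading that preserves the spectrum. The plain frequency is
  reported (no (b+1)/(n+1) correction); p = 0 is flagged as < 1/n_perm.
  Multi-exon genes concatenate segments in annotation order for codon
  phase; translation uses the standard genetic code, which plant
  organelle genes follow.
- **Overdispersion.** Cameron–Trivedi score test,
  z = Σ[(yᵢ−ȳ)² − yᵢ]/(ȳ√(2n)), one-sided against var = mean(1+α),
  α > 0, with an auxiliary intercept-only regression t as cross-check.
  Simulated calibration at n = 22, Poisson(5): type-I ≈ 0.04 at the
  nominal 0.05 (slightly conservative, as expected from the −ȳ/n bias
  of the squared-deviation term); power ≈ 0.9 against variance = 3 ×
  mean.
- **Two-sample count comparison** (nuclear SNV counts per line): the
  test is genuinely arguable at this panel size, so the utility exposes
  a conditional-binomial (Poisson), Welch t, and Mann–Whitney choice.

## Numerical and design notes

- Coordinates are 1-based inclusive throughout; excluded-repeat and numt
  intervals are half-open [start, end); BED input converts from 0-based.
- Zero-depth sites contribute frequency 0 to the WT background; a
  background of 0 leaves only the frequency/depth gates (a fold rule
  over zero is vacuous).
- Numt correction with total' ≤ 0 is skipped and flagged uncorrectable.
- Dinucleotide arrays are reported leftmost-phase with full units only;
  a trailing partial unit extends the span, not the count. Minimum 3
  units by default (not dictated by the emulated study; exposed).
- Homopolymer minimum length is 5 bp for the genome survey and context
  assignment, configurable (the survey cutoff is a free parameter, so
  A/T:G/C abundance ratios are reported as functions of it).
- All randomness descends from one root seed via spawned generator
  streams; identical config + seed gives byte-identical outputs.

## Problem sizes

The standing experiments run on the 50 + 20 kb pair: 50 replicates for
the wild-type null and recovery checks (≈ 2 and ≈ 5 minutes), 200
truth-level replicates for weighted-rate recovery, 2,000 replicates for
dispersion calibration, 10,000 permutations for the synonymous test.
The acceptance script uses 10/12 replicates for the two count-level
experiments to keep a full run near two minutes; the test suite runs the
larger versions.

## Known limitations

- The artefact screen is exact-match only; diverged junction copies
  require external pre-screening on real data.
- Indel frequency uses base-count depth at the anchor position, which
  slightly underestimates frequency when indel-supporting reads are not
  counted in depth.
- The WT upper bound assumes a single homoplasmic variant (weight 1).
- Genomes are treated as linear; origin-spanning repeats are unmerged.
- The weighted SNV estimator is unbiased for the planted rate ×
  initial frequency (frequency mass), which is the quantity drift
  conserves; it cannot distinguish event rate from initial frequency.
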