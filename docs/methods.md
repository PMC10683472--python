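# Methods

## Problem setting

A thiopeptide biosynthetic pathway accepts a precursor peptide whose core
region carries a randomized insert between fixed, required residues
(Ser-Trp upstream; Ser-Ser-Ser-Cys-Ala plus a short linker downstream in
the bundled template). Display selections read out, for each encoded
variant, whether the full enzymatic cascade matured it into a macrocyclic
thiopeptide (selection pool) or left a linear/shunt product (antiselection
pool). The package models this workflow end to end so that library-design
questions — *which degenerate codons should occupy which insert
positions?* — can be answered by a learned substrate-fitness model instead
of exhaustive experiments.

## Codon algebra

IUPAC ambiguity symbols are expanded exactly (Cartesian product of the
three per-symbol base sets) and translated with the standard genetic code
via Biopython's codon table. Two conventions are fixed throughout:

* **Diversity counts distinct stop-free amino-acid sequences.** Stop codons
  are excluded rather than treated as a 21st letter, and diversity is the
  exact integer product over positions of distinct non-stop amino acids.
  This convention reproduces the standard printed values (20^11 for
  `(nnk)11`, 7 × 20^9 × 15 for `dsk-(nnk)9-nnu`).
* **Sampling is multiplicity-weighted.** A peptide is sampled by drawing a
  concrete codon uniformly from each position's expansion and rejecting
  stop draws, which equals a weighted draw over non-stop amino acids
  (Ser has probability 3/31 at an `nnk` position). This models translation
  of a uniformly synthesized degenerate oligo, not a uniform draw over
  distinct amino acids.

Designs are written lower-case (`u` ≡ `t`, so RNA-style `nnu` is accepted);
concrete sequences are upper-case.

## The rule oracle (synthetic ground truth)

The simulator and the test suite need a ground-truth fitness function
standing in for the real enzymatic pathway. The oracle is a logistic of
summed position-residue weights,

    fitness(insert) = σ( s · ( Σ_i w[off(i)][aa_i] + b ) ),

where `off(i)` is the distance of position `i` to the nearest insert
boundary, clamped at 6 classes. Weight scale decays geometrically with the
offset (`boundary_scale · decay^off`, defaults 3.0 and 0.2), planting the
empirically motivated structure that residues adjacent to the modification
sites dominate substrate fitness. Defaults: sharpness `s = 8`, bias
`b = −0.15`, seed 7; optional pairwise interaction terms are off by
default.

Two constructional details matter:

* Raw weight draws are clipped to ±2 and the Ala weight at offset 0 is
  pinned to the strongest penalty (−2 before scaling). An alanine directly
  at a modification-adjacent boundary therefore ablates maturation, which
  is what makes a *virtual Ala scan* single out the boundary positions —
  without the pin, Ala could land near the neutral point of the boundary
  weight distribution and the scan would report boundary restriction as
  free even though boundary weights dominate every other readout.
* Sharpness and scales were chosen, by direct numerical calculation of
  E[max(p, 1−p)] over library-sampled peptides, so that the Bayes accuracy
  of the induced Bernoulli labeling exceeds 0.98. The margin is therefore a
  property of the planted problem, fixed before any classifier exists, and
  a well-trained classifier can reach ≥0.95 held-out accuracy without the
  label noise capping it.

Under these defaults a random `(nnk)` library has mean fitness ≈0.21 at
any insert length, and oracle scores concentrate near 0 and 1.

## Campaign simulator

Desk-scale stand-in for the experimental display selections (the real
campaigns start from ~6 × 10^12 molecules; the simulator defaults to
2 × 10^4 variants, a scale chosen so round summaries have low Monte-Carlo
noise while a six-round paired campaign runs in seconds):

1. **Pool generation** draws DNA variants codon-by-codon uniformly from
   the design expansion. Amber stops are allowed at the DNA level; such
   variants are *damaged* — they never mature and are rejected by the
   preprocessor, mirroring translation artifacts removed experimentally by
   affinity purification. For `(nnk)8`, the damaged fraction is
   1 − (31/32)^8 ≈ 0.22.
2. **A round** matures each copy with probability
   `time_factor × oracle(insert)` (the time factor models shortened
   enzymatic incubation; default 1.0). Selection keeps matured copies,
   antiselection the complement; kept + discarded equals the input count
   exactly. Survivors are resampled (multinomial) to the amplification
   target with per-base PCR point mutations (default 10^−4 per base per
   round; at that rate multi-hit copies are negligible and each mutated
   copy receives one substitution).
3. **FASTQ emission** writes Phred+33 reads, one per copy or capped at a
   configured sequencing depth; per-base qualities are clipped normals
   (mean 37, sd 3) and, optionally, bases are miscalled at the error rate
   their own quality implies. With errors off and qualities above the
   filter threshold, emission is lossless by construction.

Round summaries report unbound-recovery fraction (matured/total), the
copy-weighted mean oracle fitness of the surviving pool (damaged variants
count as 0), and unique-variant counts. Under any non-constant oracle,
selection's mean fitness and recovery rise round over round while
antiselection's fall — the simulator's analog of the experimentally
observed enrichment/depletion trajectories.

## Preprocessing

Reads with any base below Phred 30 are discarded whole (the strictest
reading of a "low-confidence base call" filter, and deterministic). The
surviving read is translated in frame 0; the upstream flank anchors the
frame and the downstream flank is matched at every allowed insert length
(fewest mismatches wins, ties to the shortest length — with the bundled
template a shifted downstream match cannot be mismatch-free, so zero-error
reads parse uniquely). Rejections are tallied by reason (`truncated`,
`template_mismatch`, `stop_in_insert`, `ambiguous_residue`) rather than
raised; the fixed-residue mismatch tolerance defaults to 0 and is
configurable. Counts aggregate per unique insert *before* the
selection/antiselection cross-filter removes shared inserts from both
pools; survivors get label 1 (selection) or 0 (antiselection) and a seeded
shuffle assigns disjoint train/validation/test splits (80/10/10).

## Classifier

Inserts are one-hot encoded over 21 channels (20 residues + pad) inside
the fixed core flanks. Variable-length inserts are **center-padded**
between the flanks: both insert boundaries abut modification sites, so
center padding keeps both boundary coordinates fixed across lengths (right
padding would move one of them).

The network is a stack of same-padding conv1d + ReLU layers followed by a
flattened dense head producing one logit; training minimizes binary
cross-entropy with Adam (lr 10^−3, batch 256) under an explicit seed, so
two runs with the same seed and data produce identical weights.
Predictions deduplicate their input batch, so identical inserts always
receive bit-identical probabilities; across different batch shapes,
float32 BLAS reductions may differ at the 10^−8 level, which is the
honest meaning of "batch-size invariant" here. The decision threshold is
0.5 with ties resolved toward label 0.

Two configurations are bundled:

* **Default** (12 conv layers × 600 channels, kernel 3): 11,936,401
  trainable parameters, matching the published architecture's two stated
  facts (12 convolutional layers, ≈1.2 × 10^7 parameters, here within
  0.6%). Kernel sizes and channel widths are not published; they are
  declared defaults, all configurable.
* **Reduced** (3 × 48): the desk-scale training configuration. On 10^5
  oracle-labeled peptides it reaches ≈0.98 held-out accuracy in well under
  a minute on one CPU — close to the 0.982 Bayes limit of the noisy-label
  construction.

The published model's optimizer, epochs, batch size, and regularization
are not stated in text; the defaults here are declared choices, not
inferences. The encoder covers the core flanks plus insert only (no
leader), also a declared convention.

## Design scoring and search

`E` is the Monte-Carlo mean of the predictor over n = 10^4 sampled
peptides by default (an exhaustive expectation is available for designs
with D ≤ 10^4 and is used as a cross-check in tests; Monte-Carlo remains
the single production code path). The score

    M = E × (log10 D / log10 D_ref)^γ,  D_ref = 20^L,
    γ_long = 0.5, γ_short = 2.0

is a declared functional form satisfying the properties the published
description states — strictly increasing in both E and D, with the
short-insert mode penalizing diversity deficits more than the long-insert
mode — while the published exact forms live in supplementary material not
reproduced here; both exponents are configurable so an alternative form
can be substituted.

Searches evaluate every candidate with the same base seed (common random
numbers), which removes sampling noise from candidate comparisons and
makes rankings reproducible; whether the original grid search shared
samples across candidates is unstated, so common random numbers are this
implementation's declared choice. Ties rank by higher E, then
lexicographic codon listing. Mixed-length libraries are assembled from a
per-length design map (equimolar by default) with total diversity summed
over lengths.

## Enrichment analytics

Library-fitness trajectories average predictions over the *unique* inserts
of each round (unweighted, since preprocessing deduplicates; an
abundance-weighted option exists because it is a defensible alternative
the published text does not disambiguate). Family calling replaces
embedding-based visualization with a deterministic, testable procedure:
greedy seeding from the most abundant unassigned insert, membership within
a Hamming radius of the seed, equal lengths only, count-weighted majority
consensus with `x` below 50%.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real experiment — paired
campaigns from a shared pool, round-over-round enrichment driven by a
per-peptide maturation probability, stop-codon damage, PCR drift,
quality-scored reads — with a planted, essentially additive fitness rule.
It does not emulate epistasis beyond optional pairwise terms, batch
effects, display-chemistry artifacts, abundance-dependent sequencing bias,
or the scale of real libraries (10^4–10^5 variants versus 10^12
molecules). Passing tests therefore demonstrate that the pipeline is
correct and that the model-guided design loop recovers planted structure;
they do not certify accuracy on real selection data, which depends on the
real pathway's landscape.

## Numerical conventions and degenerate inputs

Exact integer arithmetic for diversity (Python ints; no overflow).
Designs whose every expansion at some position is a stop raise an error.
`M` is defined as 0 for D = 1 (log-normalized diversity vanishes) and
rejects D < 1. Evaluation seeds are independent of model state; all
stochastic stages (sampling, simulation, splitting, training, emission)
take explicit seeds, and the pipeline derives per-stage seeds from one run
seed. Problem sizes used by the acceptance script: 10^5 labeled peptides
(15,000 held out), 2 × 10^4-variant six-round campaigns, 10^4-peptide
design evaluations — sizes at which every reported property is stable
across seeds.

## Known limitations

* The scoring function's exact published form (supplementary material) is
  not reproduced; only its stated qualitative properties are guaranteed.
* Zero-shot length generalization is supported by the encoder but not
  quantified; predictions at lengths absent from training are flagged by
  the caller's bookkeeping, not corrected.
* The preprocessor assumes pre-merged, in-frame reads beginning at the
  upstream flank (the simulator emits exactly that); adapter trimming,
  paired-end merging and UMI handling are out of scope.
* Training the full 12 × 600 architecture on CPU is possible but slow;
  the default exists to mirror the published architecture's stated scale,
  while desk-scale work uses the reduced configuration.
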