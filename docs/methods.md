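# Methods

## Overview

`meatid` models an amplicon-sequencing authentication assay for meat
products: a universal mammalian primer pair amplifies a 186-bp fragment of
the mitochondrial 16S rRNA gene from whatever species are present in a DNA
extract; the product is sequenced as 2×300 bp paired-end reads; reads are
assigned to a panel of mitochondrial references; and the per-genus share of
coverage depth is the composition estimate from which contamination and
mislabelling are called. The package implements every stage as testable
library code, with a simulator standing in for the sequencer so the whole
chain can be validated end to end under known ground truth.

## Reference panel and in-silico PCR

Real assays align against complete mitochondrial genomes, so the synthetic
panel emulates genomes, not amplicons: each reference is a random sequence
(default 2,000 bp — long enough that normalising depth by reference length
is genuinely exercised, short enough for exhaustive oracles) carrying
exactly one amplicon: the forward primer site
`GACGAGAAGACCCTATTGGAGC`, a 146-bp variable insert, and the reverse
complement of the reverse primer `TCCGAGGTCRCCCCAACC`, for a 186-bp product
including both primer-binding regions. The degenerate base R (A/G) is
concretised per reference, so a panel exercises both resolutions. The
variable insert descends from a single ancestral sequence mutated at
`between_genus_divergence` (default 0.15 substitutions/site) per genus and
`within_genus_divergence` (default 0.01) per species; primer sites are
never mutated, so amplifiability is a construction invariant rather than a
probabilistic outcome. The default study panel holds the nine meat species
of the validation design (pig, cattle, sheep, goat, chicken, turkey, duck,
ostrich, kangaroo), one species per genus, genus being the reporting unit
throughout.

In-silico PCR scans both strands for forward-site/reverse-complement-site
pairs within a maximum product length, IUPAC-aware on the primer side only
(templates are concrete DNA). Mismatch tolerance defaults to 0; references
without a site pair are reported as non-amplifiable rather than raising.
Coordinates everywhere are 0-based half-open on the forward strand.

## Read simulation

Each sample is a mixture design: species with DNA proportions summing
to 1. Read pairs draw their source reference multinomially with those
proportions — DNA proportion is taken as read proportion. The study itself
observed systematic per-species amplification bias (e.g. beef
over-represented against kangaroo) but published no bias model, so the
simulator's per-species amplification-efficiency multiplier defaults
to 1.0; bias experiments are possible, but no unpublished parameter is
asserted by default.

Because the 186-bp insert is shorter than the 300-bp read, read 1 is the
full insert followed by the reverse complement of the reverse Nextera
adapter tail and then uniform random filler; read 2 mirrors this from the
3' end. Substitution errors are i.i.d. per base (`error_rate`; the
validation configuration uses 0, the generic default 0.002 ≈ a MiSeq
substitution rate); indels are not modelled — MiSeq indel rates are an
order of magnitude below substitution rates and no indel data were
available to calibrate against. Mean base quality decays linearly from 37
to 25 across cycles with Gaussian noise (σ = 2, clipped to [2, 40]);
qualities model the instrument's confidence profile and are independent of
the realised errors. Read ids encode sample, pair index and true source
accession, so ground truth survives FASTQ round-trips.

The validation sample sheet mirrors the study design: nine pure controls
in duplicate (18 samples) plus five 1:1 and eight 9:1 two-species mixtures
in triplicate (39 samples; the 9:1 pork/beef mixture appears twice by
design), at 10,000 pairs per sample.

## Read QC

Three stages, mirroring common k-mer-based amplicon practice. Adapter
trimming is right-trim-only: the leftmost position whose k-mer (default
k = 21) exactly matches any adapter k-mer triggers removal to the read
end — appropriate because read-through adapters always sit 3' of the
insert. Quality trimming is the Mott-style cumulative algorithm on the
right end: remove the suffix maximising Σ(threshold − Qᵢ) (threshold
Q20), trimming only when the best score is positive and resolving ties in
favour of the longer read. Pairs where either mate falls below 50 bp are
dropped whole, preserving pair integrity. The exact parameter values of
the original pipeline's trimmer are unpublished; the defaults here are
standard practice and all are exposed in `QCParams`. The chain is
idempotent and never reorders pairs — both properties are tested.

## Classification

Each pair is assigned to the single best reference under an affine-gap
local alignment score (match +1, mismatch −1, gap open −2, gap
extend −1; a gap of length L costs open + (L−1)·extend), mates scored
jointly and required to hit the same reference in a proper
forward/reverse orientation; discordant or sub-threshold pairs (below
`min_score_frac` = 0.6 of the maximum attainable score) are counted
unassigned, never dropped. Ties break to the lexicographically smallest
accession, making runs bitwise reproducible.

The seeded mode shortlists references through an exact 15-mer index with
tiled seeds and scores candidate diagonals by gapless Kadane extension.
Two exactness arguments make the fast path safe: (i) a full-length
perfect gapless hit attains the Smith–Waterman maximum, so nothing can
beat it and an equal-scoring competitor would lose the tie-break; and
(ii) if a read occurs exactly anywhere on a reference, every tiled seed
hits that diagonal, so absence of a perfect seeded diagonal proves
absence of a perfect occurrence. When no perfect pair exists, full
Smith–Waterman runs on the shortlisted references. The Smith–Waterman
itself is vectorised by rows with a prefix-max formulation of the
horizontal-gap state, exact whenever gap-open ≥ gap-extend in penalty
(asserted): chaining two adjacent gaps then never beats one longer gap.
An exhaustive mode aligns everything against everything and is the
in-package cross-check; an independent plain-Python Gotoh implementation
in the test suite is the external oracle.

Coverage accumulates aligned bases (matched + mismatched columns,
excluding gaps) per reference; `avg_fold` divides by full reference
length, and breadth (`pct_covered`) is the union of hit intervals. The
composition statistic normalises genus-summed average fold to 100% over
genera with non-zero fold — the only reading of the assay's depth-share
definition under which per-genus percentages sum to ~100, which the
published per-sample figures do. Whether breadth of coverage entered the
original spreadsheet computation is not stated; it is reported here but
deliberately kept out of the percentage.

## Calling rules

Contamination: top genus percentage strictly below 98. The strictness
matters at the boundary — a documented worked case at 97.9% is called
contaminated, so comparisons are at full precision and display rounding
plays no role. Non-dominant genera split at 2% into substantive and
trace contaminants; the 2% floor reflects observed cross-contamination
and database-stringency noise in pure controls. Mislabelling (declared
genus ≠ dominant genus) is deliberately a separate flag: a declared-beef
sample that is ≥98% pork is mislabelled yet "uncontaminated" under the
purity rule, and conflating the two would hide exactly the fraud case
the assay exists for.

## Statistics

* **Proportion test.** χ² = n(k/n − p₀)²/(p₀(1−p₀)), df = 1, upper-tail
  p. No Yates continuity correction and p₀ = 0.5: with correction the
  pure-control count (1 of 18) gives p ≈ 4.1×10⁻⁴, while without it the
  computation reproduces every one of the twelve published survey
  p-values at printed precision — the uncorrected test against one half
  is the only combination consistent with all of them.
* **Contingency.** Pearson chi-square from marginal expected counts;
  Cramér's V = √(χ²/(n_obs·min(r−1, c−1))). The published V for the 2×3
  group table computes to 0.62510, which truncates (not rounds) to the
  published two-decimal figure; the verification table treats it as
  truncated. The published CI on V was produced by an unstated method,
  so the package's CI is its own: a row-wise multinomial bootstrap
  (10,000 resamples, fixed seed, percentile interval, degenerate
  resamples dropped) — deterministic, and not claimed to reproduce the
  published interval.
* **Far tails.** Survival probabilities come from the regularized upper
  incomplete gamma function Q(df/2, x/2), accurate in relative terms
  down to p ≈ 10⁻¹⁸ and beyond, cross-checked against the normal-tail
  identity χ²₁ sf(x) = 2(1 − Φ(√x)).
* **Deviation descriptives.** Percentage deviation is expected −
  observed, sign preserved. Summary statistics (min, max, median, mean,
  SD, variance) are computed on absolute deviations with the sample
  (n−1) denominator — the convention under which the published summary's
  variance equals its SD squared; the per-sample deviations behind the
  published table are in an unavailable appendix, so only the
  convention, not the values, is reproduced. n = 1 yields SD 0 with a
  degenerate flag.

## What the simulation shows — and what it cannot

The simulator provides exactly what the validation experiment needs:
known mixtures, error and quality structure, adapter read-through, and
ground truth per read. Passing the recovery checks (all 13 mixture
designs recovered within 3 multinomial standard errors at n = 10,000;
39/39 mixtures flagged, 18/18 pure controls clean) demonstrates that the
pipeline's quantification and calling logic are correct and unbiased
under its own assumptions. It does **not** demonstrate robustness to
what real data add: PCR amplification bias between species (the dominant
deviation source in the real validation, up to ~24 percentage points),
chimeras, indels, cross-genus read mis-mapping in conserved regions of
real mitogenomes, or database incompleteness. Quantities that depend on
the unavailable raw data — the published deviation summary values, raw
read counts, per-sample retail compositions and the retail-only
contingency results — are out of reach at desk scale and are covered
instead by convention and consistency checks.

## Problem sizes and runtime choices

The validation experiment runs 57 samples × 10,000 pairs (the package's
study-scale configuration) in a few minutes on one core; unit tests use
reduced panels (250–800 bp references) so that exhaustive
dynamic-programming oracles stay feasible; the law-of-large-numbers
check uses 10⁵ pairs. Bootstrap replicates default to 10,000 in library
calls and are reduced in tests where only determinism and bracketing are
asserted.

## Known limitations

Substitution-only error model; single amplicon per reference assumed by
the simulator (the PCR scanner itself handles multi-site templates);
best-hit-only assignment with no fractional multi-mapping; taxonomy
fixed at genus reporting; no attempt to model primer-binding
thermodynamics or amplification efficiency beyond an optional constant
multiplier.
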