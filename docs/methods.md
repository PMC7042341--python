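# Methods

## Problem and model

Apoptotic tumor cells expose caspase-cleaved protein fragments that can be
cross-presented as non-mutated neoantigens. The pipeline identifies such
fragments from quantitative SILAC GeLC-MS comparisons of apoptotic vs live
cells, designs an overlapping-peptide panel to interrogate patient T cells,
deconvolves pool-level responses to single peptides, and relates response
levels to overall survival. Each stage is a deterministic function of its
inputs plus a seeded generator for synthetic studies.

## SILAC quantitation and fragment calling

**Isotope shifts.** Heavy labels are 13C6-lysine and 13C6-15N4-arginine, so
a tryptic peptide with `k` labeled lysines and `r` labeled arginines shifts
by `k·6Δc + r·(6Δc + 4Δn)` with Δc = 1.003355 Da (13C−12C) and
Δn = 0.997035 Da (15N−14N). The five shift classes relevant to tryptic
peptides with at most one missed cleavage round to 6.02, 10.01, 12.04,
16.03 and 20.02 Da.

**Pair matching** (`match_pairs`) pairs centroided, singly charged peaks
whose m/z difference lies within a tolerance (default 0.05 Da) of a nominal
shift, greedily by smallest |difference − nominal| with ties broken by lower
light m/z. Greedy matching is a heuristic: on adversarial "chained" spectra
(three peaks mutually separated by near-nominal shifts) it can orphan a
matchable pair. Peptide maps with realistic peak spacing do not produce such
chains, and the property tests compare greedy output against the exhaustive
optimum on spectra with ≥ 50 Da base-peak separation.

**Ratios and orientation.** The apoptotic/live ratio is heavy/light in the
forward experiment and light/heavy in the label-swapped reverse replicate.
A detection with no live-channel partner is reported at the cap (default
100) with a `capped` flag — quant tables print such one-channel detections
as exactly 100, and they are treated as capped rather than as measured
ratios.

**Gel sections.** The SDS-PAGE lane is modeled as 16 half-open [lo, hi) kDa
sections spanning 5–250 kDa. Only the section count and range are
instrument-reported, so the default breakpoints are 17 log-spaced values
(overridable); log spacing mirrors the near-log migration of molecular
weight in gradient gels. Masses below 5 kDa fall into the lowest band
(they run at the gel bottom); masses ≥ 250 kDa are out of range.

**Classification.** FRAGMENTED iff `mwexp_hi < mwcal` (strict) **and**
apoptotic-enriched (`ratio > 1` or capped); the MW rule dominates the
fold-change thresholds, since a fragment's abundance ratio can sit near 1
while its migration is unambiguous. Otherwise UPREGULATED iff ratio > 2,
DOWNREGULATED iff ratio < 0.5 (a symmetric 2-fold no-change window; the
upstream convention only states the >2-fold "up" threshold, and a symmetric
window is the standard choice that still leaves a non-empty "no change"
class), else UNCHANGED. Replicate concordance intersects FRAGMENTED
accessions across orientations, matching by accession because gene symbols
are transcribed inconsistently between replicate tables.

## Epitope design

Each MS-identified peptide (minimum 6 residues) expands by ±20 flanking
residues, clipped to the protein; overlapping or adjacent expanded intervals
on one protein are merged before tiling to avoid synthesizing duplicate
20-mers. Regions are tiled into 20-mers stepping by 8 (overlap 12); if the
last stepped tile stops short of the region end, one extra tile is
right-anchored at the end — keeping every synthesized peptide full-length —
so a region of length R yields `(R−20)/8 + 1` tiles when 8 divides R−20 and
`⌊(R−20)/8⌋ + 2` otherwise. Regions shorter than 20 yield one flagged short
tile rather than being dropped. Tile ids are `accession_start`, stable
across runs so pool designs are reproducible.

## Pool matrix

Each peptide goes into exactly two of N pools (default 12) with no pool pair
reused, so at most C(N,2) peptides are supported and any single responding
peptide is identified by its positive pool pair. The constructor assigns
tiles (optionally seed-permuted) along a canonical pair sequence in which
*every prefix* keeps pool sizes within one of each other: for even N the
round-robin 1-factorization of K_N taken matching by matching, for odd N a
Walecki Hamiltonian-cycle decomposition with each cycle emitted as its
even-indexed matching, the closing edge, then the odd-indexed matching. A
naive greedy "least-loaded unused pair" rule does not have this property
(it can strand the last pools with only loaded partners and overshoot by
two), which is why the sequence is constructed rather than searched. For 37
peptides in 12 pools this gives ten pools of 6 and two of 7.

Deconvolution returns all tiles whose both pools are positive and flags the
call ambiguous when that candidate set is not the unique minimal explanation
— some positive pool has no candidate covering it, or a candidate is
redundant (removing it still covers all positives, so several subsets
explain the data). Ambiguity is reported, never resolved silently;
confirming single peptides is downstream wet-lab work.

## Response statistics

Net response = max(stimulated% − unstimulated%, 0). A measurement counts as
a response when net ≥ floor; the floor defaults to 0.01 percentage points —
the upstream assay convention never quantifies its responder cut-off, so
the floor is explicit, configurable and logged. Magnitude is the arithmetic
mean of net responses across patients per (pool, subset, cytokine,
timepoint) with pairwise exclusion of missing cells. Responder fold change
between treatment stages is the ratio of responder percentages, with +inf
and NaN sentinels for x/0 and 0/0. The dual IFN-γ⁺TNF-α⁺ channel is an
independent measurement, not derived from the single-cytokine channels.
Supporting comparisons are the pooled-variance two-sample t test (Welch by
flag; zero-variance degenerate inputs resolve to t=0, p=1 on equal means
and ±inf, p=0 otherwise) and one-way ANOVA, via scipy.

## Survival

Patients split at the cohort median of a response level; ties go LOW
(strict exceedance, so "HIGH" always means strictly above the median), and
an all-equal cohort is all LOW with a warning. Kaplan–Meier estimation and
the Mantel–Cox log-rank test (two-sided, χ² with 1 df) are delegated to
`lifelines`; tests cross-check the statistic against a direct
hypergeometric O−E/V implementation and a hand-evaluated example
(χ² = 49/17). Zero total variance returns a NaN sentinel rather than a
fabricated p-value. Note that a subject censored after the last event still
enlarges every earlier risk set, so appending one changes the statistic;
only the *position* of late censoring times relative to event times is
irrelevant.

## Synthetic data

The generator emulates the study's structure, not its raw instrument
output. One global seed fans out into independent named streams (proteome,
fragmentation, SILAC, evidence, cohort) so stages can be regenerated in
isolation.

- **Proteome**: 200 proteins by default, uniform residue composition,
  lengths uniform in 100–900 residues.
- **Fragmentation**: 8% of proteins are truly fragmented; cleavage falls
  after a random aspartate (uniform site if none) — a deliberately minimal
  caspase emulation, sufficient to produce MW-shifted fragments without
  modeling DEVD-motif specificity. The shorter side is the fragment; sites
  are resampled until the fragment (computed with standard average residue
  masses + 18.02 Da water, via pyteomics) lands at least one gel section
  below the intact protein and can hold an evidence peptide (≥ 25
  residues). Class fractions: 30% up, 50% down, remainder unchanged.
- **SILAC tables**: true ratios per class (UP uniform-log 2.2–20, DOWN
  0.05–0.45, UNCHANGED 1, FRAGMENTED 2–30) times independent lognormal
  noise (σ = 0.25) per orientation; fragmented proteins are one-channel
  singletons (capped at 100) with probability 0.3 per orientation. MWexp
  ranges come from the same gel-boundary config the classifier uses, so
  truth and observation are consistent by construction.
- **Cohort**: 14 patients, timepoints T0/T1/T2, 2 subsets × 3 cytokines ×
  12 pools. Background ~N(0.02, 0.005)%; pools containing an immunogenic
  tile add a stage effect with true means 0.02 / 0.15 / 0.40% (T0/T1/T2)
  times lognormal noise (σ = 0.35). PD-1-within-specific means are
  20 / 45 / 18% (rise after chemotherapy, fall under PD-1 blockade),
  SD 5. Survival is exponential with baseline hazard 1/30 per month
  (low-responder median OS ≈ 21 months, in the range of advanced NSCLC
  cohorts); patients above the cohort median of CD8 IFN-γ net response at
  T2 get the hazard divided by 3. Censoring is an independent exponential
  at 0.2× the baseline hazard.

What passing tests show — and do not show. The generator's ratios are
exactly lognormal around class-typical values and its responses exactly
stage-ordered, so recovery results (fragment-call F1 ≥ 0.9 at default
noise, 100% noise-free label-swap concordance, T0 < T1 < T2 magnitude
ordering in ≥ 95% of replicates, log-rank power ≥ 80% at hazard ratio 3
with n = 60 and type-I error ≤ 7% at hazard ratio 1) validate the
*implementation* under its assumed error model. Real spectra add isotope
envelopes, charge states, shared peptides and ratio compression; real
cohorts add inter-patient heterogeneity and informative dropout — none of
which the generator models, so these numbers are not predictions of
performance on real data.

## Problem sizes and numerical choices

The test suite exercises 200-protein proteomes, 60-replicate magnitude
sweeps and 500-replicate log-rank power/size studies at n = 60 patients —
sizes chosen so the full suite runs in well under a minute while the
Monte-Carlo margins (e.g. power ≈ 0.96 vs the 0.80 bound) stay far from
their thresholds. Coordinates are 1-based inclusive everywhere on disk;
gel sections are half-open [lo, hi); MWcal is compared against `mwexp_hi`
with strict `<`; ratio and percentage validations are closed intervals.
Quant parsers accept thousands separators ("51,854") so printed tables can
be transcribed verbatim.
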