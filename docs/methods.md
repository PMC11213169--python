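# Methods

## Scope and model

`ragdel` classifies somatic deletions by the recombination-signal-sequence
(RSS) evidence at their breakpoints and compares the burden of putatively
RAG-mediated deletions between two patient exposure groups.  The package
assumes its input is a final, pre-filtered deletion callset (VAF > 0.10);
read alignment, SV calling and caller consensus are upstream concerns.
Internally every coordinate is 0-based half-open, and a deletion's removed
segment is `[left_bp, right_bp)`.

One deliberate interface choice: in VCF input, POS is interpreted as the
*first deleted base* (1-based) and END as the last, i.e. the deleted
segment is `[POS-1, END)` in internal coordinates.  Callers that emit a
padding base at POS should be converted, or the TSV/BEDPE readers used.

## Motif scoring

A position-weight matrix (PWM) assigns window `x` the log-odds score
`s(x) = Σ_i log2 p_i(x_i)/b(x_i)` in bits, with background
`b = (A 0.3, C 0.2, G 0.2, T 0.3)` — the same composition the synthetic
genome is drawn from, so scan false-positive rates on synthetic data equal
their analytic values.  `N` bases contribute zero (neither reward nor
penalty).

Match p-values are exact: per-position score contributions are discretised
to 1e-3-bit bins and the distribution of the discretised window score under
the background is built by convolution; the p-value of a window is the tail
mass at the window's own discretised score, so the table and a brute-force
enumeration of all 4^w windows agree bin for bin (tested exhaustively for
the heptamer).  The 1e-3-bit step leaves discretisation error orders of
magnitude below the 1e-4 decision threshold's sensitivity even at width 39.

The full RSS matrix is the heptamer, a 12- or 23-column spacer equal to the
background (hence contributing exactly zero to any score), and the nonamer.
Both spacer variants are scanned and either may satisfy "full RSS".
Scanning covers both strands; reverse-strand tables are built from the
reverse-complemented matrix, so asymmetric backgrounds would be handled
correctly too.

Default matrices place probability 0.8 on each consensus base
(`CACAGTG`, `ACAAAAACC`) and 0.0667 elsewhere; experimentally derived
matrices can be supplied as MEME-minimal files and override the defaults.
With these defaults the scan threshold p < 1e-4 admits only the exact
consensus heptamer (p = 4.3e-5) — a single mismatch costs
log2(0.8/0.0667) ≈ 3.6 bits and fails — while the composed full RSS
tolerates roughly four mismatches across its sixteen informative positions.

## Breakpoint annotation

* **Flanks.**  ±50 bp windows around each breakpoint (±200 bp for decay
  profiles).  For deletions shorter than twice the flank the interior
  extents are clipped at the segment midpoint (left side receives the ceil
  half) so one motif instance can never satisfy both breakpoints; clipped
  and contig-truncated windows are flagged.
* **Offsets.**  A hit's offset is the signed junction-relative coordinate
  of its match base nearest the junction: the first interior base is +1,
  the first exterior base −1; a junction-straddling match counts as +1
  (interior preferred).  This makes "motif internal to the breakpoint" a
  sign test and the decay profile a band count.
* **Hit collapsing.**  Overlapping hits of one motif at one breakpoint are
  collapsed to the best (lowest p, then smallest |offset|, then interior),
  because the analysis counts deletions with *a* motif, not hit
  multiplicity.
* **Classes.**  full RSS at both breakpoints → `full_both`; at exactly one
  → `full_one`; otherwise `heptamer_only`, then `nonamer_only`, then
  `none`.  Heptamer evidence outranks nonamer evidence when both are
  present without a full RSS, reflecting the heptamer's greater specificity.
  `full_both`/`full_one` constitute "putatively RAG-mediated".  Per-motif
  indicator columns (heptamer/nonamer/full at one/both breakpoints) are
  emitted alongside so weaker-evidence tabulations need no reclassification.
* **Target status.**  A deletion is `ig_tcr` if either breakpoint lies
  within 1000 bp (inclusive) of a locus; the buffer boundary is inclusive
  because "within ±1000 bp" reads naturally that way and the convention
  must be fixed for testability.  Chromosomes absent from the locus set are
  off-target (logged).
* **Orientation.**  Excision-circle geometry: an interior heptamer is
  correctly oriented if its CAC end faces the junction — + strand at the
  left breakpoint, − strand at the right.  Exterior hits have undefined
  orientation (None, not False).  When a side has no stand-alone heptamer
  hit, the heptamer part of a full-RSS hit is used.

## Junctions

With an observed junction insert, the longest prefix matching the deleted
sequence past the left breakpoint and the longest suffix matching the
deleted sequence before the right breakpoint are stripped (exact matching
only — no mismatch tolerance, since any tolerance would need an arbitrary
parameter), the breakpoints are shifted accordingly (left-aligned
canonical form), and remaining bases are the NTN.  Empty inserts are
classified by the longest exact shared flank suffix (microhomology,
capped at 25 bp — far beyond biological expectation) or as blunt.  Absent
inserts are `unresolved` and excluded from NTN denominators.  NTN rates
are tabulated by evidence group — full RSS at both breakpoints, at one,
and everything else — over off-target deletions.

## De novo k-mer discovery

Canonical k-mers (a k-mer and its reverse complement are one entry) are
counted once per sequence (ZOOPS) over both strands, k = 5..12 (default 7).
The background is a seeded 10× dinucleotide-shuffled copy of the target set
(Altschul–Erickson Eulerian-path shuffle; each target is shuffled in its
canonical orientation, making discovery exactly invariant to
reverse-complementing the input).  Enrichment is the exact one-sided
hypergeometric test of the target presence count conditional on the total;
this remains calibrated although the background frequency is itself
estimated, where a binomial with plug-in background (offered as an option)
is measurably anti-conservative near Bonferroni thresholds.  Soft-masked
(lowercase) bases become `N` and contribute no k-mers.  No PWM refinement
or mismatch-tolerant merging is attempted: exact k-mer presence is the
deliverable, which is why discovery benchmarks use consensus-planted
cohorts — a PWM-sampled instance is an exact 7-mer match only ~30% of the
time, which measures the sampler, not the search.

## Cohort statistics

* Pearson chi-square on 2×2 tables, 1 df, **without** Yates continuity
  correction — with correction the 89/131 vs 19/72 table gives p ≈ 0.002
  rather than the 0.001-level the uncorrected statistic yields, so the
  convention matters and is fixed here.
* Two-sided Fisher p as the sum of hypergeometric probabilities of all
  tables (fixed margins) no more probable than the observed — the
  convention of mainstream statistics libraries; stated explicitly because
  two-sided Fisher has competing definitions.  Verified against brute-force
  enumeration in the tests.
* Crude OR = ad/bc with the Woolf log-scale 95% CI; zero cells take the
  Haldane–Anscombe 0.5 correction and are flagged.
* Bootstrap CIs resample *deletions* (not patients) within a group —
  percentile method, B = 10,000, seed recorded — matching per-deletion
  proportion bar plots.
* Wilcoxon rank-sum: exact for combined n ≤ 20 without ties, otherwise the
  tie-corrected normal approximation without continuity correction (so
  identical groups give p = 1).
* Age associations are OLS slopes with t-test p-values.
* The multilevel model is a random-intercept logistic regression of the
  per-deletion outcome (putatively RAG-mediated, or full-RSS-at-both) on
  exposure group, over off-target deletions.  It is fitted by maximum
  likelihood with fixed-order Gauss–Hermite quadrature (41 nodes) — at
  this cohort's cluster sizes (≤ ~40 observations) and intercept SDs
  (≤ ~2) fixed-order GH is accurate far below the Wald-CI resolution, and
  it is simple and deterministic; the implementation reproduces lme4's
  `glmer` (nAGQ = 25) to ≈1e-3 in the log-OR in the test suite.  The CI is
  Wald on the log-odds scale.  Complete separation of exposure × outcome
  triggers a refit with a weak ridge penalty (λ = 0.5 on the fixed
  effects) and a `separated` flag; the estimate is then a regularised one
  and should be read as such.

## Synthetic cohort generator

The generator emulates the study conditions; its defaults are fixed and
not tuning knobs:

| parameter | default | provenance |
|---|---|---|
| patients | 18 high / 17 low | cohort design |
| deletions per patient | NB(mean 22 high / 10 low, dispersion 8), min 3 | group totals land near 220/91 off-target deletions; per-patient medians ~12, range ~5–40 |
| P(on-target) | 0.45 | ~45% of deletions touch Ig/TCR loci |
| off-target P(RAG) | 0.41 / 0.21 | the headline group contrast |
| on-target P(RAG) | 0.93 | on-target deletions are overwhelmingly RSS-positive |
| P(full at both \| RAG) | 0.23 | ≈ (full-both %) / (RAG %) in the high group |
| interior offset | geometric, mean 15 bp, truncated so the motif fits the 50 bp flank | rapid positional decay; planted evidence stays recoverable |
| 23-nt spacer fraction | 0.3 | exercises both full-RSS variants |
| P(NTN) by class | 0.92 / 0.79 / 0.65 | full-both / full-one / non-RAG |
| NTN length | geometric, mean 4 bp | typical TdT additions |
| P(junction unresolved) | 0.05 | callsets rarely report every insert |
| genome | 4 × 1.5 Mb, A/T 0.3 C/G 0.2; six 25 kb loci | scaled-down; composition matches the scan background |
| deletion length | log-uniform 1 kb–1 Mb (off-target), 1–100 kb (on-target) | most somatic SVs are < 1 Mb |

Design points that matter for interpreting results:

* **Planted instances are functional sites.**  RSS sequences are sampled
  from the PWMs but conditioned (rejection sampling) on passing the
  scanner's own p < 1e-4 threshold: planted sites represent sequences RAG
  actually used, and an instance too weak to ever be detected is not a
  meaningful "planted" site.  Unconditioned sampling would silently drop
  ~20% of planted motifs below the detection threshold and decouple
  recovered from planted fractions.  A `consensus_planting` switch plants
  exact consensus for exact-value tests.
* **Breakpoint spacing.**  Distinct rearrangements use distinct RSS sites:
  breakpoints are kept far enough apart that no scan window (50 bp for
  classification, 200 bp for decay) can contain another breakpoint's
  planted motif — 300 bp clearance around off-target breakpoints, 150 bp
  among on-target ones.  Planted motif footprints never overlap.
* **Canonical junctions.**  Planted NTN bases are resampled so the first
  and last never equal their templated neighbours; the planted junction is
  already in maximally-stripped form, so junction resolution recovers the
  planted NTN length exactly.
* **Determinism.**  One `numpy` Generator seeded from the config drives
  everything; identical config + seed gives byte-identical FASTA, VCF and
  truth tables.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: real RSS matrices estimated from physiological
junctions (defaults are consensus-weighted stand-ins), sequence repeats and
GC heterogeneity (uniform background instead), caller breakpoint
uncertainty beyond templated-insert shifts, inter-deletion dependence
within a patient beyond the shared count distribution, and any non-deletion
SV class.  Recovered-vs-planted agreement validates the pipeline's
machinery, not the biological truth of any particular real callset.

## Numerical and degenerate-input conventions

* Score discretisation 1e-3 bits; p-value lookups use the discretised
  score, so DP and enumeration cannot disagree by more than a bin.
* Scan of a sequence shorter than the motif returns no hits (not an
  error); flanks truncated at contig ends are flagged.
* Tie-breaks are fixed everywhere (hit collapsing order; left/right
  midpoint split for short deletions; interior-preferred straddling
  offsets) so outputs are reproducible across platforms.
* `patient_summaries` errors on orphan patient ids; patients with zero
  off-target deletions yield NaN proportions and are excluded (logged)
  from proportion summaries.
* The bootstrap, the generator, de novo discovery and the pipeline all
  take explicit seeds; the run manifest records parameters, seeds and
  input checksums, and a rerun from the same manifest is byte-identical.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the full 35-patient study
conditions throughout (a cohort simulates and annotates in ~1 s): 100
replicate cohorts for the chi-square power check, 200 model-simulated
cohorts for mixed-model OR recovery, 100 null simulations for de novo
calibration, and 5 pooled cohorts for the reported synthetic recovery
percentages.  These sizes give Monte-Carlo error well inside the stated
tolerances (3 binomial SDs; 10% on the mean OR) while keeping a full run
in minutes on one CPU.

## Known limitations

* The mixed-model Wald CI is symmetric on the log scale; strongly
  asymmetric profile-likelihood-style intervals (as published alongside
  some of the reference odds ratios) are not reproduced, only the point
  estimate is.
* Heptamer-only and nonamer-only classes are scan-threshold-driven; at
  p < 1e-4 with the default matrices the stand-alone heptamer class
  effectively requires a consensus match.
* Exact-match k-mer discovery understates the frequency of degenerate
  motif instances relative to mismatch-tolerant tools; ranks, not target
  frequencies, are the comparable output.
* The orientation metric includes scan false positives (randomly
  oriented), so even a perfectly oriented cohort scores slightly below
  100% — ~96–98% at the default false-positive floor.
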