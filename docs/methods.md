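# Methods

This note documents the models, parameters and numerical choices behind
`msatpipe`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Assay model

The assay amplifies 11 microsatellite loci in two multiplex PCR groups
(6 + 5), each locus labeled FAM, HEX or NED and analyzed against a
co-injected ROX size ladder. The bundled panel (`data/panel.json`) records
for each marker its group, dye, analysis window (bp), repeat unit (1 or 2)
and expected product range, plus the analysis parameters: minimum peak
half-width per group (4 / 2 points), mono cut-off 0.95, and per-dye range
filters. Two design rules are validated: same-dye products within a group
must be ≥ 40 nt apart, and every window must lie inside the ladder's
usable interpolation range.

**Range-filter semantics.** Each dye/group filter interval occupies the
gap *between* the two same-dye marker windows of that group (e.g. group-1
FAM: 146–194, between the Bat25 and D3S3623 windows). Peaks inside the
interval (closed at both ends) are excluded before marker assignment.
This is the mechanism that removes HEX→FAM bleed-through replicas of
D6S262 (~167–184 bp) which would otherwise sit between the FAM marker
windows; artifacts outside every window are additionally ignored by
window-based marker assignment.

## Synthetic-data generator

The simulator emulates the statistical structure of multiplexed
microsatellite electropherograms; its defaults define the study
conditions used throughout the tests.

* **Genotypes.** Dinucleotide allele frequencies are triangular over the
  marker's template lattice (window interior, repeat-unit spacing), giving
  high heterozygosity as appropriate for these polymorphic loci.
  Bat25/Bat26 are quasimonomorphic: modal template alleles 126 / 121 bp
  (apparent 127 / 122 after adenylation, matching the published control
  profile) at probability 0.98 per chromosome, with rare variants at −3
  and +2 bp.
* **Stutter.** Each allele carries a geometric stutter ladder at −k·unit
  with height ratio r^k, r drawn per amplification from Uniform(0.85, 0.97)
  for mononucleotide and Uniform(0.30, 0.60) for dinucleotide repeats,
  truncated below 1% of the main peak. The mono upper bound keeps the
  second stutter below the 0.95 cut-off (0.97² < 0.95), so stable samples
  never call more than two alleles, while the first stutter occasionally
  exceeds it — reproducing the observed run-to-run mono ambiguity. These
  ratios are simulator choices; the source assay publishes none.
* **Adenylation.** Fraction 1.0 of product carries the non-templated +A
  (the tailed-primer design intent), so apparent sizes sit on a
  +1-shifted lattice which the default bins absorb.
* **Amplification inequality.** Per-allele lognormal height factor
  (σ = 0.08 in log space) on a 1200 FU per-copy base height; homozygotes
  render as one double-height product.
* **Instrument.** Mobility `m(L) = 9000 − 10⁶/(L + 100)` (strictly
  increasing, invertible on 35–500 nt; ≈ 21 scans/bp at 120 bp). Every
  rendered fragment — sample and ladder alike — receives independent
  migration noise of SD 0.08 bp-equivalent. Peaks are Gaussian pulses of
  σ = 4.2 scans (half-width at half height ≈ 4.9 points, passing both
  group minima). The FAM channel receives β = 0.05 of the HEX signal
  (bleed-through); one-scan spikes (Poisson rate 0.5/channel), broad
  nonspecific products placed uniformly outside the group's marker windows
  (rate 0.4/dye), a flat baseline of 80 FU and white noise of SD 5 FU
  complete the model. All draws flow through one `numpy.random.Generator`.

**What the simulator does not model:** saturation/off-scale peak shapes
(a clip threshold exists but defaults off), spectral calibration matrices
beyond the single β coefficient, inter-run mobility drift (the ladder
would cancel its common mode anyway), and template-quality effects such as
degraded lysates. Passing tests therefore demonstrate correctness of the
analysis chain under a clean, explicit noise model — not robustness to
every failure mode of real instruments.

## Detection, sizing, calling — numerical choices

* Despiking replaces points > 8 robust σ above their 3-point median (and
  > 20% above their own magnitude) with the median; a one-scan impulse
  cannot be a real peak at σ ≈ 4 scans.
* Baseline is a morphological opening (running min, then max) with an
  801-scan window, then a moving-average smooth; the window exceeds the
  ~300-scan span of a dense mononucleotide stutter comb so the baseline
  cannot ride its valleys.
* Apexes come from `scipy.signal.find_peaks` (height 50 FU, prominence
  25 FU) with parabolic sub-scan refinement on a 5-point-smoothed copy;
  half-width is measured at the *absolute* half height with linear
  interpolation (prominence-relative widths collapse when a spike rides a
  peak's flank).
* Ladder matching scores candidate monotone assignments by the RMS
  residual of a single reciprocal-law least-squares fit (candidate subsets
  are pre-ranked by a cheap cubic-fit residual); best RMS above 2 bp is a
  ladder failure. With `strict=False`, a deficit of up to two apexes is
  absorbed by dropping ladder fragments and flagging the fit partial.
* Local Southern solves `L = c/(m − m0) + L0` in closed form through each
  3-standard group (degenerate collinear groups raise an error) and
  averages the two predictions; fragments without two matched standards on
  each side are flagged unsized, never extrapolated. Sizes are reported to
  0.01 bp; scan indices are 0-based.
* Binning: nearest integer center within ±0.5 bp, exact ties to the lower
  center. Dinucleotide stutter rejection threshold 0.8 (configurable):
  a true heterozygote one repeat apart keeps a near-1 ratio (the minor
  allele also accumulates the major's stutter) while typical stutter
  (≤ 0.6) is removed. The mono cut-off comparison is strict (> 0.95): a
  ratio of exactly 0.95 is not an additional allele. Height ties for
  allele 1 break toward the smaller size.

## QC statistics

%CV uses the sample (n−1) standard deviation; an allele observed once is
reported missing, not zero. Percent deviation counts alleles (two per
marker per sample, homozygotes included) against expected bins —
dinucleotide exactly, mononucleotide with a +1 nt tolerance — so a
nonspecific peak displacing a true allele counts that expected allele as
miscalled. The overall value is the observation-weighted mean of the
per-day values. Control-sample tracking attributes deviations on runs
whose control was concordant to sample integrity, otherwise to process.

Because the replicate study applies independent 0.08 bp noise to the
query *and* the four interpolating standards, the sized-length SD per
allele is 0.106–0.124 bp (Monte-Carlo of the sizing math alone), i.e.
expected per-allele CVs of roughly 0.05–0.11% across the control's
alleles. The maximum over all identified alleles is a noisy order
statistic — secondary mononucleotide calls appear in only a handful of
runs, and a CV estimated from 2–5 observations has 30–70% relative error —
so individual replicate studies scatter around the ~0.11% level; the
fixed-seed study in the acceptance test realizes 0.11%.

## Downstream analyses

MSI: per-marker stability against a reference profile (mono: any allele
shifted by ≥ 3 bp for Bat25 / ≥ 4 bp for Bat26 from every reference
allele, with +1 normal; dinucleotide: any novel bin), and an overall
status over the five NCI loci (≥ 2 unstable → MSI-H, 1 → MSI-L, 0 → MSS)
following the standard workshop convention — the per-marker output is the
assay-faithful result, the status a labeled convention. LOH uses the
community-standard bin-matched height-ratio statistic with strict 0.5/2.0
bounds (the assay motivates marker placement near MMR genes but fixes no
formula); a normal homozygote or missing tumor height is uninformative
rather than called. Lineage consistency requires each child pair to split
one-from-each-parent; for trace-derived profiles the assessment defaults
are best restricted to the nine dinucleotide markers, since
quasimonomorphic mono calls carry inherent ±1 nt ambiguity.

## Problem sizes

The test suite simulates full traces of ~7,400 scans × 4 channels;
replicate QC uses 23 runs, the end-to-end concordance study 100 subjects ×
2 groups, and the mono-allele ceiling study 100 amplifications — sizes
chosen so the whole suite completes in well under a minute while keeping
every statistic's expected sampling error far below the asserted margins.

## Known limitations

* The "advanced" detector of commercial software is proprietary; ours is a
  documented stand-in sharing its tunable parameters.
* Bins default to the adenylation-shifted lattice; `bins_from_observations`
  seeds them from reference runs instead, but no inter-run correction
  factor is applied before binning (a hook exists, off by default).
* ABIF ingestion is a best-effort adapter (Biopython's reader, DATA1–4 tag
  mapping); the canonical interchange format is plain TSV/CSV/JSON.
* LOH makes no attempt at tumor-purity modeling; MSI thresholds apply to
  the two mono markers only and treat all dinucleotide novelty equally.
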