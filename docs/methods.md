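# Methods

## The index

RNA integrity is read out from RT-qPCR alone: two nested amplicons of
different length are amplified from the same transcript (bacterial
glutamine synthetase, *glnA*, in the default panel), and the cycle
thresholds of the long and short assays are combined as

    R_amp = (M - Ct_long) / (M - Ct_short),        M = 35 cycles

where M is the number of cycles the reaction is run. Intact RNA gives
equal Cts and an index of exactly 1; as damage accumulates the long
amplicon — the larger target for any damage event — loses template
faster, its Ct rises faster, and the index falls toward 0. Unlike a
plain ΔCt, the index is *not* invariant under a common Ct shift, so it
also responds to overall template abundance context; the package tests
pin this property down rather than hiding it.

Conventions at the boundaries:

- Cts at or above M, and not-detected wells, are **clamped to M** before
  the ratio. A censored long amplicon therefore yields exactly 0.
- A censored **short** amplicon makes the denominator 0; the index is the
  distinguished value `UNDEFINED` (a fully censored pair carries no
  integrity information), never 0 and never an exception.
- Ratios above 1 arise when the short assay's amplification efficiency
  lags the long one's (the default panel reproduces this with its 120 nt
  assay at efficiency 0.80). They are reported unclamped with the flag
  `OVER_UNITY` because the artifact is informative about efficiency
  mismatch.
- M belongs to the index, not to the assay: reference assays in the
  default panel run 40 cycles, but the index always uses the pair's
  35-cycle cap.

## Censoring and aggregation

Input tables are long CSV (one well per row); replicates are aggregated
per (sample, assay) after dropping wells that failed melt-curve QC.
Censored wells (not detected, or Ct above the cap) are handled by
policy: `cap` replaces them with M and keeps them in the mean, `exclude`
drops them. The default is role-based — `cap` for ratio-pair assays (so
an undetected long amplicon drives the index to its degraded limit) and
`exclude` for reference transcripts (so quantification never invents a
Ct). Both policies count censored wells.

## The degradation simulator

Every statistical property of the package is testable without
instrument data because plates are generated by a mechanistic model:

- **Damage** is a Poisson process along the template at rate λ events
  per nucleotide. A region of length L escapes with probability
  exp(−λL). Two mechanisms are distinguished: `strand_break` (heat,
  ribonucleases — fragments visible to electrophoresis) and
  `blocking_lesion` (UV-style intramolecular crosslinks — strands stay
  intact). Both abolish amplification across the region, so they share
  the survival form for qPCR and differ **only** in electrophoretic
  visibility. This single assumption generates the package's central
  contrast: an electrophoresis-based score is blind to blocking lesions
  while the amplification-based index is not.
- **Kinetics**: losing templates costs ΔCt = ln(1/survival)/ln(1+E)
  cycles for an assay of efficiency E (E = 1 means one cycle per
  halving).
- **Noise**: Gaussian on Ct, sd 0.15 cycles by default (a typical
  technical-replicate spread), one deterministic stream per
  (seed, level, assay, replicate). Cts reaching the assay cap are
  censored to not-detected.
- **Surrogate electrophoretic score**: `pseudo_rin = 1 + 9·exp(−p·L23S)`
  with p the *strand-break* rate only and L23S the large-subunit rRNA
  length (2900 nt; the 16S is 1500 nt, about half). It is synthetic by
  construction and contractual only in (a) monotone decline under strand
  breaks and (b) blindness to blocking lesions; it is never compared
  numerically to any vendor score, whose algorithm is proprietary.
- **Pool**: rRNA is taken as 82.5% of total RNA mass (midpoint of the
  80–85% typical of prokaryotic extracts). Substrate competition between
  rRNA and mRNA during nuclease digestion, sequence specificity,
  secondary-structure protection and fragment-length electropherograms
  are *not* modeled; passing tests therefore say nothing about those
  effects in real extracts.

Default panel: glnA 380/170/120 nt (efficiencies 0.95/0.95/0.80, cap
35), amoA 491 nt and 16S 143 nt reference assays (cap 40); pairs 380/170
(the recommended default) and 380/120. Demo scenarios run a
0/10/45/90-minute series with per-level rates in the 0–6·10⁻³ events/nt
range — illustrative intensities chosen so consecutive levels are
separated by several noise standard deviations, not calibrated to any
instrument.

## Evaluation statistics

- **Kendall tau-b** between each integrity index and each reference
  transcript's Ct, computed by direct O(n²) pair counting in integer
  arithmetic (series are short; exact reproducibility beats speed).
  P-values: full permutation enumeration at n ≤ 8 (two-sided, on the
  integer numerator, ties handled naturally), tie-corrected normal
  approximation otherwise. A constant index (e.g. the surrogate score
  under blocking lesions) has no rank information: tau is `UNDEFINED`
  and never counted significant. Significance is p ≤ α with α = 0.05;
  no multiple-testing correction is applied across the grid.
  Note that a perfectly monotone 4-point series has an exact two-sided
  p of 2/4! ≈ 0.083 — single short series cannot reach significance,
  which is why correlation grids pool experiments.
- **One-way ANOVA across degradation levels**, with Tukey HSD run *only*
  when the ANOVA p ≤ α (conditional testing); unequal group sizes use
  the Tukey–Kramer form via the studentized-range distribution. Results
  are summarized as a compact letter display built by the
  insert-and-absorb algorithm; the invariant — two levels share a letter
  iff their adjusted p exceeds α — is property-tested on random
  p-matrices. Letter identity is arbitrary (Latin letters); only the
  sharing relation is contractual. Group values are per-replicate index
  values (replicate r of the long assay paired with replicate r of the
  short).

## Normalization

Along a series, ΔCt (vs the undegraded reference t0) is regressed on
ΔR_amp **through the origin** — the model has no intercept, so the
corrected Ct,

    corrected Ct = Ct − α · (R_amp − R_amp_t0),

equals the observed Ct at the reference by construction. α is reported
per transcript and per mechanism and is not pooled across mechanisms by
default (both dependencies are real: the demo fits differ by transcript
by ~4× and vary across treatments). A positive fitted α is reported
with an `anomalous` flag rather than rejected. Diagnostics: r² about
the origin, residual sd (dof = n−1 over n non-reference points; a
single-point fit has slope but no dispersion estimate), and a t-based
95% interval on α. The interval assumes independent errors on the
degradation points relative to a well-determined reference baseline; if
the reference is itself a single noisy triplicate its error is shared
across all deltas and the plain interval undercovers. Correction is
only guaranteed to shrink degradation error when the Ct–index relation
is in fact linear; the misspecified (nonlinear) case is reported
without any improvement claim.

## Rate recovery

For simulated data the per-nt rate inverts in closed form,
λ = ΔCt·ln(1+E)/L per assay, exactly on noiseless plates. On noisy
plates the package pools all uncensored assays by weighted least
squares against the known baselines (weights x_a = L_a/ln(1+E_a)):
λ̂ = Σ x_a·ΔCt_a / Σ x_a². The 10%-accuracy property is stated for
λL ≥ 0.3 with L the *shortest* amplicon in the panel, i.e. every assay
carries at least 0.3/ln(1+E) cycles of signal; a single short assay at
the threshold has noise comparable to the band and cannot meet it
alone.

## Determinism and problem sizes

One integer seed governs everything; outputs contain no wall-clock
content, so a fixed seed reproduces every artifact byte for byte (the
demo is tested for this). The shipped validation suite uses series of
4 levels × 3 replicates × 5 assays, 500-fixture coverage checks for the
normalization interval, 1000 random vectors for the tau-b oracle, and
200 random fixtures for the letter display — sizes chosen so the whole
suite completes in well under a minute while estimates remain
statistically sharp.

## Known limitations

- The index detects damage only between the primer sites of the long
  amplicon; damage elsewhere on the transcript is invisible, whereas a
  fragment-based electrophoretic score sees any break. The simulator
  encodes this asymmetry but real RNA adds mechanisms (oxidative base
  destruction, mixed damage) outside the dichotomy.
- λ-vs-time calibrations for heat/UV/nuclease treatments are
  illustrative; no fit to instrument trajectories is attempted.
- Normalization validity is within-series; cross-environment
  comparisons and housekeeping-gene schemes are out of scope.
- Efficiency-corrected quantification (Pfaffl-type) and absolute copy
  number are out of scope; efficiencies enter only the simulator and
  the rate estimator.
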