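# Methods

This note documents the models, defaults and design choices behind
`pnetquant`, and what the synthetic generators do and do not emulate.

## Spectral-count quantification

Quantification is the normalized spectral abundance factor,
NSAF_N = (S_N/L_N) / Σ_i (S_i/L_i), computed per sample over the proteins
retained by the unique-peptide filter, then rescaled to ppm (×10⁶). A
sample with no nonzero count has no defined profile and is rejected
explicitly rather than returned as zeros. Because NSAF is a closed
composition, profiles are invariant to rescaling a sample's counts and
always sum to 1 (machine precision); both properties are tested.

The unique-peptide cutoff defaults to 2 (the conventional two-peptide
identification rule); it is a parameter because the boundary between
"at least two" and "more than two" peptides is ambiguous in common usage.

## Paired differential expression

The emulated design is deeply paired (tumor and adjacent pancreas from the
same patient, n = 4 pairs), so significance comes from a two-sided paired
t-test on log2(ppm + pseudocount) across pairs. The pseudocount (default
1 ppm) keeps zero counts finite; it is small relative to the ppm weight of
a single spectral count (~5–10 ppm at the default depth) so it compresses
nothing else. The test choice and the transform are configurable because
spectral-count practice varies; the paired t on log abundance is the
simplest test consistent with a paired design and a volcano plot drawn in
(log2 fold change, −log10 p).

Degenerate t statistics are resolved by symmetry: all-zero pair
differences give p = 1 (no evidence); constant nonzero differences give
p = 0 (off-scale evidence, rendered as +inf on the −log10 axis).

The Tu/Nor ratio is the ratio of condition means of ppm. When one
condition has zero mean the ratio is reported at the cap (default 500,
matching the ">500" display convention) with an explicit flag, and the
record is classed `tumor_only`/`para_only`; log2 fold change derives from
the capped ratio so it stays finite. Classification defaults are
min_fold = 2 and max_p = 0.05; the structural one-condition classes pass
through the same p threshold, because at shallow depth a protein can be
absent from one condition by sampling chance alone — the capped ratio is
not evidence by itself. Thresholds are parameters, not constants.

No multiple-testing correction is applied to the per-protein p-values (the
classification stage reproduces a raw-p volcano convention); a
Benjamini-Hochberg column can be added downstream by the caller if needed.

## Exact small-sample tests

`exact_stats` is implemented from first principles because every printed
association p-value in the validation tables depends on the precise
two-sided definition:

- **Fisher exact (2×2):** conditioning on both margins, the two-sided p
  sums hypergeometric point probabilities of all tables no more probable
  than the observed one (minimum-likelihood definition), with a 1e-7
  relative tolerance against floating-point ties. This definition — and
  not tail doubling — reproduces the printed 0.002 for the
  demethylation × expression table. The sample odds ratio is reported with
  zero-cell degeneracy flagged.
- **Pearson chi-square (r×c):** no continuity correction; expected counts
  from margins; undefined on a zero margin. On 2×2 it equals the closed
  form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), which is asserted in tests.
- **Mann-Whitney U:** midrank ties; the two-sided p is the null
  probability that |U − n1·n2/2| reaches the observed deviation. For
  tie-free data the exact null distribution of U comes from the classic
  rank-sum counting recurrence (cached per sample-size pair, used up to
  combined n = 60); tied data enumerate all C(n1+n2, n1) labelings up to
  combined n = 20; beyond that, a tie-corrected, continuity-corrected
  normal approximation. The permutation definition reproduces the printed
  band-ratio p = 0.0095 (2 of 210 labelings); note that other common
  two-sided conventions give 0.013 on the same data. The continuity
  correction keeps the asymptotic branch within 0.01 of exact at
  n = 20 + 20, which is tested.

## Assay validation rules

Band ratios are target/loading-control per lane, displayed at 2 decimals
(fold differences at 1 decimal) to match reporting convention, with full
precision available via `precision=None`. A zero control intensity is an
error, never a silent 0 or infinity. The published 10-lane UCH-L1 table is
bundled as a reference dataset; its raw intensity columns are partially
garbled in the available source, so the printed ratios are treated as
authoritative and the bundled intensities merely reproduce them. The
published worked example (8.3-fold) uses the two full-precision lane
ratios 0.342 and 0.041 as printed.

IHC positivity: below 20% stained tumor cells is negative (the weak "(±)"
category merges into negative); exactly 20% is positive, the complement of
the stated rule. MSP records require at least one band; both bands
together are a legal hemi-/heterogeneous methylation state, projected to
(methylation_present, demethylation_present).

## Survival analysis

Cohort rules are owned by this package; estimation is delegated to
lifelines (product-limit estimator, k-sample log-rank, Cox partial
likelihood with Efron tie handling and Wald intervals — the standard
modern defaults). Tests pin the delegation to hand oracles: the
product-limit estimate against hand arithmetic and the empirical survival
function, the log-rank statistic against a hand-accumulated O−E table, and
the Cox log-likelihood against the hand-enumerated risk-set product on a
4-subject example.

Endpoint coding: follow-up runs from surgery; OS events are deaths of
disease; DFS events are recurrence or death of disease (alive-with-disease
or dead-of-disease at last contact). Deaths of unknown cause, subjects
with unknown status and subjects without follow-up are excluded with a
logged count. Concurrent marker status is present iff both markers are
IHC-positive; subjects with either marker unscored are excluded from
concurrent-status analyses — their status is not imputable and explicit
exclusion is the only auditable choice.

The cross-sectional report tests each categorical feature against marker
status with Fisher (2×2) or chi-square (r×c) and each continuous feature
(age, size) with the exact Mann-Whitney test; deaths of unknown cause are
excluded only from the outcome rows. Row counts always equal the eligible
subjects for that row.

## Synthetic data

The generators emulate the study conditions, not any particular dataset:

- **Spectral experiment** (defaults: 3476 proteins, 4 pairs, 2×10⁵
  expected counts/sample — a plausible total for deeply fractionated
  runs): log-normal protein lengths (median 400 aa) and baseline
  abundances (σ_ln = 1.5); planted fractions 6.3% up and 1.8% down shifted
  4-fold (effect_log2fc = 2) in tumors; per-sample log-normal biological
  noise (sd 0.35 on log2, ~25% CV for paired adjacent tissue); Poisson
  counts at a depth jittered ±20% per sample (negative binomial behind the
  `overdispersion` switch — with 4 pairs the analysis cannot identify
  overdispersion, so Poisson is the default); unique-peptide counts
  Poisson in the square root of the mean count, so the two-peptide filter
  preferentially removes the shallowest profiles.
- **Cohort** (default n = 306): category frequencies set to the published
  clinicopathological summary proportions; marker positivity drawn
  independently per marker (0.60 × 0.465 ≈ 28% concurrent); exponential
  death and recurrence times with hazards multiplied by the spec's true
  hazard ratios for concurrent-positive subjects; uniform administrative
  censoring; statuses derived consistently (death before censoring → DOD
  at the death time; recurrence before censoring → AWD censored
  administratively; otherwise DFS), with configurable fractions of
  unfollowed and death-of-unknown-cause subjects.
- **Western blot / MSP:** lognormal lane ratios with a configurable tumor
  shift; MSP calls with a configurable odds ratio linking demethylation to
  expression (invalid double-negative draws default to fully methylated).

What passing tests show — and do not. The planted-effect recovery
criterion (sensitivity ≥ 0.8, FDP ≤ 0.2 at the defaults, measured over
planted proteins that survive the identification filter, with direction
counted) holds under Poisson counting noise with modest biological
variation; real spectral-count data carry overdispersion, shared-peptide
ambiguity and batch structure that this model deliberately omits, so the
measured operating characteristics are an upper bound, not a field
estimate. One real compositional property does appear and is worth
knowing: because NSAF is closed-sum, planting ~6% of the proteome 4-fold
up depresses every other protein's apparent abundance by ~19%, so null
proteins drift toward down-calls; at the defaults the down-direction false
calls are noticeably more frequent than up-direction ones. The null
calibration checks (type-I error of the paired test, log-rank and the
exact tests at ~5%) are run at sizes where the discrete tests are not
overwhelmingly conservative; Fisher's exact test sits below nominal by
construction on small tables.

Problem sizes in the test suite and acceptance script (3476-protein
experiments, 1000-replicate null calibrations, five 500-subject cohorts
for hazard-ratio recovery) were chosen so each check carries adequate
statistical resolution while the whole suite runs in well under a minute
of compute per heavy check.

## Known limitations

- The differential stage models spectral counts only; intensity-based
  quantification, match-between-runs and peptide-level inference are out
  of scope.
- Identification-level FDR control is assumed upstream (the pipeline
  starts from an exported count table).
- The Cox interface takes an arbitrary numeric covariate frame; it does
  not build model matrices from the clinical table automatically.
- Recurrence in the cross-sectional report is derived from outcome status
  (alive-with-disease/dead-of-disease vs disease-free), which conflates
  recurrence with death when recurrence dates are unavailable — the same
  compromise a status-only registry forces.
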