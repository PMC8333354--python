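# Methods

`nirspain` implements an fNIRS analysis pipeline for a cold-pressor
(thermal-pain) paradigm in fibromyalgia, together with a synthetic cohort
generator that reproduces the statistical structure the analysis assumes.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data do and do not establish
about real recordings.

## The measurement model

Continuous-wave fNIRS records light intensity at two wavelengths (760 and
850 nm) for each source-detector channel. The pipeline converts intensity
to oxyhemoglobin concentration change in four steps:

1. **Channel quality control.** The coefficient of variation
   CV = 100 · SD/mean of the *raw* intensity is computed per channel and
   wavelength (sample SD, ddof = 1). A channel is excluded when the CV at
   either wavelength strictly exceeds 7.5 % or is undefined (non-positive
   mean). QC runs before filtering because the band-pass would remove
   exactly the variance the rule is meant to catch. Whether the original
   protocol computed the CV on whole recordings or per-trial segments is
   not documented; whole-recording CV is used here.
2. **Optical density.** ΔOD(t) = −log10(I(t)/Ī) with Ī the channel's
   whole-recording mean intensity. Mean-referencing only shifts the series
   by a constant, and every downstream feature is invariant to a constant
   shift entering both the series and its baseline.
3. **Band-pass.** Zero-phase (forward-backward) Butterworth, order 3 per
   pass, 0.01–0.2 Hz. Zero-phase filtering preserves peak timing, which
   matters because peak latency is an endpoint. The passband retains ≥ 99 %
   of in-band sinusoid amplitude and suppresses cardiac/respiratory bands
   to < 0.1 % (verified by FFT in the test suite).
4. **Modified Beer–Lambert law (MBLL).** Per time point, solve
   E · (ΔHbO, ΔHbR)ᵀ = (ΔOD_λ / (L · DPF_λ))_λ with optode separation
   L = 3 cm and differential pathlength factors 7.25 (760 nm) and 6.38
   (850 nm). The extinction matrix E uses the standard published
   tabulation for HbO/HbR at these wavelengths. Concentrations are
   reported on the study's numeric scale (labelled mM in its tables even
   though the magnitudes are physiologically micromolar); the required
   scaling is folded into the shipped extinction constants so that
   unit-scale concentrations produce realistic optical densities (a
   0.35-unit response gives ΔOD ≈ 0.005, keeping clean-channel intensity
   CVs well below the exclusion threshold). Both the DPF pair and the
   extinction matrix are configurable.

The MBLL chain is linear; "filter then convert" and "convert then filter"
agree to numerical tolerance (property-tested).

## Paradigm and features

The paradigm is 60 s rest, immersion of the right hand at 25 °C (innocuous,
primary stimulus) for up to 30 s, 2 min rest, immersion at 5 °C (noxious,
secondary stimulus), 2 min rest. The 30 s before the primary onset define
the per-subject baseline (its mean HbO serves both stimuli). Channels are
averaged, unweighted, into four ROIs — left PFC (channels 1–9, 11, 12),
right PFC (9, 10, 12–20), right MC (21–30), left MC (31–40); channels 9
and 12 belong to both prefrontal ROIs. An ROI whose members were all
rejected is reported missing rather than raising.

Three measures are computed per subject × ROI × stimulus:

* **peak latency** — time from onset to the maximum HbO sample in the
  search window; ties resolve to the earliest sample, and a maximum on the
  window's last sample is flagged;
* **Δ-HbO** — that maximum minus the baseline;
* **Δ-HbO\*** — the mean HbO over the 15 s after stimulus end minus the
  baseline, stored signed (post − baseline). The mean over the window is
  used rather than the single sample at +15 s for robustness at 3.91 Hz;
  the instantaneous variant is available behind a switch.

**Peak-search window.** The search runs from stimulus onset to stimulus
end by default. Extending it through the 15 s post-stimulus window (the
`peak_search="post_end"` option) would make Δ-HbO ≥ Δ-HbO* a mathematical
identity, because a maximum over a superset window can never be below the
mean over a subwindow — yet the reference group summaries this package is
calibrated against contain a cell with Δ-HbO* above Δ-HbO (control left
PFC at 5 °C: 0.53 vs 0.49). The stimulus-period window is the only reading
consistent with those summaries, and matches the definition of the maximum
as the amplitude "of each thermal stimulus".

Percent-change contrasts (100·(post − pre)/pre) are reported rounded
half-up to two decimals alongside the raw value, matching the convention of
the published within-group contrasts.

## Group statistics

* **Characterization** — Mann–Whitney U (tie-corrected, two-sided) for
  continuous variables, Fisher's exact test for binary categoricals.
* **GEE** — one model per ROI per outcome:
  `outcome ~ group * temperature` with exchangeable working correlation,
  subject clusters (two observations each) and robust sandwich covariance
  (statsmodels). Sum-to-zero coding makes each df = 1 Wald χ² a
  Type-III-style main effect, mirroring the SPSS layout of the reference
  table. Cramér's V = √(χ²/(n·df)) is computed with n = number of
  subjects. An optional Bonferroni flag adjusts over a user-stated family
  (e.g. the four ROIs); the original family is not documented, so raw and
  adjusted p are both reported.
* **Spearman** — mid-rank correlations with two-tailed p, flagged at 0.05
  and 0.01; constant inputs yield flagged undefined cells.
* **Severity GLM** — Gaussian GLM of a clinical score on the left and
  right PFC Δ-HbO* with intercept; per-coefficient Wald χ² (df 1) and 95 %
  CI; collinear predictors (|r| > 0.999) are refused.
* **Sample size** — smallest N whose omnibus regression F test reaches the
  target power, with noncentrality λ = f²·N and df = (u, N−u−1), then an
  attrition inflation (ceil(N·1.1)). The "effect size 0.6" convention is
  ambiguous between Cohen's f and f²; f² is the default (it reproduces a
  base N of 20 for two predictors at α = 0.05, power 0.80) and f is
  selectable.

## Screening

The empirical ROC is built over all attained score values; AUC is the
trapezoidal area and equals the normalized Mann–Whitney U statistic (ties
count one half; verified exhaustively in tests). Orientation
`low_positive` (positive when score ≤ cutoff) is the default for the
group screen because fibromyalgia shows lower Δ-HbO*, which reconciles
negative published cutoffs with positive group means. The Youden-optimal
cutoff maximizes J = sensitivity + specificity − 1, with ties broken
toward higher sensitivity and then the smaller absolute cutoff, and is
reported at the attained score value (not a midpoint). The default AUC
confidence interval is Hanley–McNeil; a seeded stratified percentile
bootstrap is available ("exact binomial" is not a well-defined interval
for an AUC).

The within-patient severity screen dichotomizes a clinical score at its
median (a package convention — the original rule is not documented; the
quantile is configurable and the choice is flagged in the output) and
evaluates Δ-HbO* as a classifier of the high-severity label, with
sensitivity/specificity reported at fixed cutoffs (−0.175 left PFC,
−0.205 right PFC by default). Because the reference rank correlation
between left-PFC Δ-HbO* and central-sensitization scores is positive
(0.60), the severity screen defaults to `high_positive` orientation.

## The synthetic cohort generator

The generator's defaults *are* the study conditions: 22 fibromyalgia and
19 control subjects, 40 channels at 3.91 Hz, the paradigm above, and per
(ROI × temperature) feature distributions with the reference group means
and SDs reconstructed as SD = SE·√n from the published standard errors.
Fibromyalgia immersion durations are sampled uniformly on [10, 30] s
(early pain withdrawal — a stand-in, since per-subject durations are not
published); controls hold the full 30 s.

**Why calibration, not simple kernels.** The reference summaries describe
*processed* data: channel-averaged, band-passed signals. A naive
gamma-shaped transient has ~85 % of its energy below the 0.01 Hz high-pass
edge, so its filtered features would bear little relation to its nominal
parameters. The generator therefore works backwards from the measurement
model. Each ROI × stimulus response is a linear combination of
zero-integral basis shapes — a gamma-variate rise/exponential-decay
transient (peak carrier), a raised-cosine bump confined to the
post-stimulus window (Δ-HbO* carrier), and one baseline-corrective shape
per ROI — and the coefficients are solved from the feature definitions
themselves, evaluated on the *band-passed* bases: peak value at the
realized in-window maximum, post-window mean, and a filtered
baseline-window mean pinned at zero. Zero-integral shapes (each lobe
paired with an opposite-sign compensating lobe placed outside every
measurement window) keep high-pass ringing out of the baseline and
peak-search windows. Because midline channels 9 and 12 mix the two
prefrontal responses, the PFC pair is calibrated jointly against the
measured (channel-averaged) mixtures. The kernel's internal peak placement
is nudged until the realized filtered maximum lands on the drawn latency
sample. In the noiseless limit the full pipeline therefore returns the
drawn values to machine/sample precision, which is what makes
recovery-based validation exact rather than approximate.

**Draw model.** Within one response, the two amplitude measures share a
single Gaussian latent (they summarize one transient); homologous
left/right responses are rank-correlated at 0.80, the reference
correlation between the two prefrontal Δ-HbO* values — this also removes
physically incoherent draws in which a large left response leaks through
the midline channels and swamps a tiny right one. Floors keep every draw
band-limited-realizable: Δ-HbO ≥ 0.15 (a flat or downward deflection has
no meaningful peak), Δ-HbO* ≥ −0.25, latency within [1 s, duration − 3 s].
The amplitude floors are re-centered by their closed-form truncation
shifts so the configured cell means are preserved exactly; the latency
clamp shifts means by < 0.1 s at the defaults. Draws whose realized
maximum cannot be brought within the filter's smoothing scale (2.5 s) of
the drawn latency are rejected and redrawn; at the default parameters this
affects ~0.3 % of draws.

A deliberately simple primitive, `response_kernel`, is also exposed: the
monotone rise/decay transient that hits raw (unfiltered) targets exactly
and raises a constraint error when the requested post-window mean is not
reachable on a decay limb.

**Noise and artifacts.** Channel-level noise is synthesized in the
concentration domain: cardiac (0.02 units at 1.1 Hz), respiratory (0.01 at
0.25 Hz), Mayer waves (0.008 at 0.1 Hz — inside the analysis band),
white noise (SD 0.015), and a per-channel linear drift (slope
N(0, 10⁻⁴ units/s)); each oscillation gets a random phase and ±5 %
frequency jitter per channel. Amplitudes are a fixed package choice of
realistic magnitude (roughly 2–5 % of a typical response peak).
Deoxyhemoglobin is the conventional −1/3-scaled mirror of the clean HbO
with independent noise; it exists so the two-wavelength MBLL system is
well-posed, and is not analyzed. Intensities are produced by the exact
MBLL inverse. Motion artifacts (multiplicative gain drift or additive
spikes, scaled to a target CV) can be injected per channel to exercise the
QC rule; the default cohort rate is zero.

**Clinical scores.** Severity scores (central sensitization and
disability-due-to-pain totals) are drawn through a Gaussian copula on the
left-PFC Δ-HbO* latent with Spearman targets 0.60 (CSI), 0.40 (pain
disability) and 0.64 between the two scores (Gaussian correlations via
r = 2·sin(πρ/6)). Both groups use the same copula; only the score means
and SDs differ. Demographics (age, BMI, years of study, analgesic use)
are drawn from the reference group summaries for the characterization
table.

**What the synthetic data do not emulate.** No photon transport or head
geometry; no scalp coupling or short-separation channels; no motion
correction beyond channel rejection; Gaussian marginals where real scores
are bounded and skewed; noise stationarity. Passing recovery tests
demonstrates that the pipeline measures what it claims on signals with the
assumed structure — not that real recordings have that structure.

## Numerical choices and degenerate inputs

* Windows are half-open sample sets [start, stop), defined once
  (`paradigm.window_indices`) and shared by the generator and extractor.
* Peak ties resolve to the earliest sample; boundary maxima are flagged.
* CV exactly at the threshold is retained (the exclusion rule is a strict
  inequality).
* Zero/negative intensities, singular extinction matrices, empty classes,
  degenerate severity splits, collinear GLM predictors, and windows
  outside the recording raise typed errors naming the offending unit.
* The pipeline aborts with a stage-tagged error (e.g. when QC rejects all
  channels) and writes a manifest with a config hash and per-stage counts;
  identical seeds give byte-identical outputs.

## Problem sizes used in validation

Recovery checks simulate 200 subjects per group (48 cell-mean comparisons;
verified across eight independent seeds with no comparison outside 3
standard errors). The severity-screen consistency check uses 500
replicates of n = 22. The Monte-Carlo cross-check of the sample-size
routine uses 50 000 simulated regressions. These sizes make the checks
decisive while keeping a full run of the suite under a couple of minutes.

## Known limitations

* The latency of a response whose drawn peak amplitude sits near the floor
  is reproduced only to the calibration tolerance (2.5 s), not to the
  sample; amplitude measures are always exact.
* Reconstructing SDs as SE·√n assumes the published SEs are simple
  per-group standard errors.
* The severity screen's median split is a convention, not a reproduction
  of the original dichotomization.
* Published screening point values (cutoff tables and their
  sensitivity/specificity pairs) are internally inconsistent at the source
  and are not asserted; only distribution-level consistency is tested.
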