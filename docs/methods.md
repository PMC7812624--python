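# Methods

This note documents the models, parameters and numerical choices behind
`dyadsync`, what the synthetic cohorts do and do not emulate, and the
limitations a user should keep in mind.

## Signal model and preprocessing

Optical density uses the natural-log convention, ΔOD = −ln(I/Ī) with the
per-channel temporal mean as baseline, making every downstream quantity
invariant to source power and coupling efficiency. The modified
Beer–Lambert inversion uses the Gratzer/Prahl molar extinction tabulation
at 760/850 nm (base-10 values scaled by ln 10 to match the natural-log OD),
3 cm source–detector separation, and a differential pathlength factor of
6.0 for adults and 5.5 for children applied identically at both
wavelengths. Concentrations are reported in µM of relative change; their
absolute scale is irrelevant to coherence, which is scale-invariant.

Motion correction zeroes discrete-wavelet (Daubechies-5) detail
coefficients farther than `iqr_alpha` = 1.5 interquartile ranges from their
level median. The wavelet family and threshold are configurable; spikes
concentrate in few large detail coefficients, so this attenuates transients
by an order of magnitude while leaving smooth hemodynamics nearly untouched
(verified on constructed fixtures, interior of the series; boundary
extension distorts the outer ~samples, which the cone-of-influence
exclusion later discards anyway).

Channel quality control automates the visual "clear heart band" criterion:
a channel is retained only if Welch power in 0.6–1.5 Hz is at least
`power_ratio_min` = 0.2 of broadband (0.01–3 Hz) power at **both**
wavelengths. Whole channels, not single wavelengths, are excluded, because
the Beer–Lambert inversion needs both wavelengths.

The band-pass is a 2nd-order Butterworth (12 dB/octave) with corners
0.01/0.5 Hz, applied forward–backward (`sosfiltfilt`). Zero-phase filtering
doubles the magnitude roll-off but removes frequency-dependent lag, which
would otherwise bias between-partner coherence phase; the acceptance tests
compare measured gains against the analytic squared response.

## Wavelet coherence

Morlet wavelet with ω₀ = 6, dyadic scale grid with δj = 1/12, base scale
s₀ = 2/fs, Fourier period = 4π/(ω₀ + √(2+ω₀²))·s ≈ 1.033·s. Smoothing
follows the standard coherence recipe: per-scale Gaussian in time with
σ = √2·s (the Morlet decorrelation length) and a boxcar over 0.6
decorrelation lengths in scale (7 points at δj = 1/12). Both smoothings are
linear convolutions (zero-padded FFT); edge attenuation cancels between
numerator and denominator, and self-coherence is exactly 1. The cone of
influence excludes periods above ff/√2 × (time to the nearest edge).

Band-epoch averaging takes the unweighted mean of retained (in-band,
in-COI) cells in consecutive windows of ⌊30·fs⌋ samples. With 30 s at
7.81 Hz an epoch is 234 samples, so a nominal 240-s recording (1874
samples) yields exactly 8 epochs; defining epochs by ⌊duration/30⌋ seconds
instead would give 7 for a 239.95-s series, contradicting the 8 × 16
design, so the sample-block rule is used. An epoch with no retained cell is
missing, and channels masked in either partner produce missing rows that
propagate to the model frame.

For cohort-scale surrogate computations the scale grid is restricted to
1.2× the analysis band's period range (period ~5.6–20 s) and run in single
precision; this reproduces the full-grid in-band epoch means to ~1e-7
while being several times faster. The full 2–64 s grid remains the default
for the public single-pair API. The surrogate machinery also caches the
coherence of each *distinct* (child, mother) pairing — coherence does not
depend on which draw selected a pairing — so 100 or 1000 draws cost the
same as the number of available non-partner mothers.

## Surrogate controls

Random-pair: each child is paired with mothers drawn uniformly **with
replacement** from all non-partner mothers (1000 draws from ~39 candidates
force replacement). The chance-synchrony reference is the per-cell mean
over draws, not a quantile (a quantile option exists). All recordings are
truncated to the cohort-minimum length so every pairing shares one epoch
grid. Phase randomisation replaces positive-frequency Fourier phases of the
mother's series (configurable to child or both) with i.i.d. uniform draws,
leaving DC and Nyquist bins real; amplitude spectra are preserved to
machine precision, hence so is the circular autocorrelation.

## Conversation coding

Turns merge consecutive same-speaker utterances separated by ≤ 3000 ms;
speaker changes within the gap window are alternations, longer pauses break
the chain without alternation credit, and a partner onset before the
current offset records an overlap of that duration. Composites are equally
weighted means of sub-code counts with the explicitly negative sub-codes
(irrelevant, noncontingent) signed negative, so that higher always means
more cohesive; the signs are a documented convention, switchable by
preprocessing the counts. Counts (not rates) enter the composites; the
turn-taking composite is one value per dyad over the 4 minutes, so its
interaction with time crosses a dyad-constant score with the epoch index.
ICC uses the two-way random-effects absolute-agreement single-rater form
ICC(2,1), reported with its mean squares; kappa uses linear disagreement
weights. Both are validated against independent ANOVA/confusion-matrix
computations and cross-checked against pingouin and scikit-learn.

## Beta mixed model

Response y ∈ (0,1): y ~ Beta(µφ, (1−µ)φ), logit(µ) = Xβ + z'b_i, with
b_i ~ N(0, diag(σ²)) per dyad — a random intercept plus an *uncorrelated*
random slope for each fixed effect added along the ladder (the `||`
convention). Exact 0/1 responses are compressed by y ← (y(n−1)+0.5)/n.
Continuous predictors are z-standardised over included rows; epoch time
enters as a z-standardised linear covariate.

Estimation maximises the Laplace-approximated marginal likelihood
(observed-Hessian inner Newton with per-group step halving; adaptive
15-node Gauss–Hermite quadrature when the intercept is the only random
effect, which agrees with Laplace to <1e-2 on all parameters in the test
suite). The outer optimiser is L-BFGS-B on (β, log φ, log σ) with two
starting points (method-of-moments and near-zero variances); log σ is
bounded in [−7, 2.5]. Standard errors come from the numerically
differentiated observed information; headline p-values come only from
likelihood-ratio tests of nested ML fits, with degrees of freedom equal to
the parameter-count difference. The fixed-effects-only limit is verified
against an independent beta-regression MLE (statsmodels) to 1e-3.

The ladder is: M0 intercept (+dyad intercept); M1 +turn-taking; M2 +time;
M3 +turn-taking × time; M4–M7 add turn duration, relevance, intrusiveness
and contingency each to M3 and are compared against M3. The pairing
analysis stacks original values against each child's surrogate *mean* with
a child-level random intercept and tests pairing, time and pairing × time
successively. Interaction follow-ups compute link-scale trends
β_focal + β_int·m at the early/late (or median-split) moderator means with
delta-method standard errors; on the link scale these are exact linear
functions of the fixed effects.

A note on random slopes of dyad-constant covariates: a slope for a
covariate that does not vary within dyads is only weakly identified (it is
a variance inflation indexed by the covariate); the ladder includes it to
mirror the declared model structure, and its variance often estimates near
the boundary. This mirrors the behaviour of standard mixed-model software
under the same specification.

## Synthetic cohorts

Each subject's HbO per channel is κ-weighted shared narrowband signal
(0.06–0.15 Hz) plus √(1−κ²)-weighted private narrowband noise (so band
coherence tracks κ), plus cardiac (mother ~1.0 Hz, child ~1.2 Hz, var
0.18 µM²), respiration (0.25 Hz — deliberately outside the analysis band),
slow drift (< 0.008 Hz), white noise and Poisson motion spikes; amplitudes
(band 0.4, cardiac 0.6, resp 0.2, drift 1.0, white 0.1, spikes ~5 µM) were
chosen so that raw signals are physiology-dominated and the cardiac QC
ratio sits well above threshold, as in usable real recordings. κ varies
per epoch: the cohort generator sets each dyad's coupling slope to
`behavior_link` × the dyad's standardised turn-taking target, so high-turn
dyads gain coherence over epochs. HbR is −0.5 × HbO plus independent noise
(weaker ground-truth coupling for the HbR replication path). Intensities
come from the forward Beer–Lambert model with the same constants the
pipeline inverts, and an optional cohort-shared 0.1 Hz "Mayer-wave"
component (default off; 0.4 µM in the confound experiments) elevates
coherence in true and random pairs alike — the scenario the random-pair
control exists to expose. Conversations are alternating-renewal utterance
sequences (gaps 200–700 ms, occasional >3-s pauses, occasional overlaps)
whose tempo is tuned to a per-dyad turn-taking target.

What the generator does **not** emulate: photon transport and layered head
optics, spatially structured (ROI-specific) coupling, serially dependent
epoch-level autocorrelation beyond the smoothing kernel, non-stationary
physiology, or realistic conversational semantics. Passing tests therefore
certify the pipeline's correctness and statistical calibration under the
declared generative model, not fidelity to any particular empirical
dataset.

## Problem sizes used in the test suite and acceptance script

Cohort-level checks use 20 dyads × 240 s with 100 surrogate draws over 20
seeds (the draw-caching makes draw count immaterial); parameter recovery
uses 50 replicates of 40 dyads × 128 observations; LRT calibration uses
500 null replicates at 12 dyads × 16 observations with a within-dyad
covariate (testing a between-dyad covariate with 12 clusters is a known
small-sample failure mode of the likelihood-ratio test and is documented,
not asserted); interaction power uses 20 cohorts of 20 dyads × 32
observations with a true link-scale interaction of 0.08. The acceptance
script runs a 12-dyad end-to-end cohort. These sizes are the package's
validation design; larger studies simply scale the same code.

## Known limitations

* The per-channel → ROI map (channels 1–4, 5–8, 9–12, 13–16 → dlPFC-L,
  dlPFC-R, TPJ-L, TPJ-R) is a declared convention, overridable in the
  montage, since probe geometry alone does not fix a numbering.
* No short-separation regression or superficial-signal GLM; systemic
  confounds are addressed only through the surrogate controls.
* Laplace approximation can bias variance components at very small cluster
  counts; the AGQ path covers only intercept-only structures.
* SNIRF support is read-only and minimal (continuous-wave, one data block).
* No multiple-testing correction across channels is applied anywhere, by
  design of the analysis being implemented.
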