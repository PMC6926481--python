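# Methods

This note documents the models, numerical conventions and design choices
behind `chromaclock`, in the spirit of a software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Photometry

**Pigment templates.** Spectral sensitivities use the Govardovskii et al.
(2000) vitamin-A1 template: the α-band
`S(x) = 1/(e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D)` with
`x = λmax/λ`, `A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104` and
`a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940)`, plus the UV β-band
(amplitude 0.26, peak `189 + 0.315·λmax`, bandwidth `−40.5 + 0.195·λmax`).
The β-band is included by default: mouse UV-cone stimuli live in the
region where the β-bands of the longer-wavelength pigments are
non-negligible. λmax is restricted to the template's published validity
range, 330–600 nm. Default opsin set: S 365, L 556 (the human L-opsin
knocked into the red-cone line), melanopsin 480, rod 498 nm.

**Lens transmission.** Pre-receptoral filtering is a configurable
wavelength→fraction table. The shipped mouse default is a logistic curve
(midpoint 345 nm, 25 % short-wavelength floor) approximating the mouse
lens's substantial UV transmission; it is an explicit approximation, and
an identity lens is provided so that no numerical contract depends on the
exact curve. Corrected templates are renormalized to peak 1.

**Quadrature.** All effective photon fluxes are trapezoidal integrals of
flux density × normalized sensitivity on a shared 1-nm grid over
300–780 nm (sub-0.1 % error for these smooth integrands; verified against
a 0.05-nm refinement in the tests).

**Metamer solver.** Primaries are spectra at unit drive with per-primary
drive bounds [0, 1]. Equality constraints (receptor → target log10 flux)
are solved exactly in *linear* flux space: minimum-norm particular
solution plus the constraint null space. With three primaries and
melanopsin+rod constraints the null space is one-dimensional; because the
L/S contrast `log10(L(w)/S(w))` is a Möbius function of the null-space
coordinate, it is monotone there, and the maximal-contrast designs sit at
the feasible-interval endpoints — the solver therefore returns exact
bound-limited optima, which the tests confirm against an independent
1e-3-resolution grid-search oracle. Ties between endpoints break toward
the lower null-space coordinate. Residual tolerance on each equality is
1e-9 log units; infeasible targets raise a descriptive error naming the
violated bound.

μ(L,S), the mean cone log-illuminance, is defined as the arithmetic mean
of log10 L and log10 S flux ("average illuminance" on the log scale; the
log-of-mean alternative differs by less than rounding for near-balanced
stimuli). Along the one free color direction of a 3-primary rig μ(L,S) is
strictly monotone, so a blue/yellow *pair* cannot additionally be
μ-equalized with three primaries; instead `"mu"` may be supplied as an
additional (nonlinear) equality target, located by bracketed root-finding,
which pins a *single* stimulus of given cone illuminance — this is how
"dim"/"bright" intermediate-color stimuli are designed. Decoupling μ from
contrast in a pair requires a fourth primary.

**Synthetic primaries.** Gaussian profiles, default 20 nm FWHM, peaks
385/460/630 nm, total flux 1e15 photons/cm²/s per primary at unit drive.
The total flux is a unit convention chosen so that targets around 12.7 log
photons/cm²/s sit comfortably inside the drive bounds of all three
primaries.

## 2. Light schedules

Timelines are uniform 1-minute grids of per-opsin log10 flux, a
cone-opponent color coordinate (log10 L − log10 S, optionally
white-referenced), and a block label per sample. Darkness is encoded by a
finite sentinel (5.0 log photons/cm²/s) rather than −∞ so that log
arithmetic never propagates invalid values; the simulator's drive floor
lies far above it.

**Solar elevation** is a sinusoid in hour angle, calibrated so elevation
crosses +6° at `noon ± photoperiod/2` and −4° one twilight-duration
(default 60 min) later — the civil-twilight window that the naturalistic
paradigm spans. A full ephemeris adds nothing at the fidelity of the
paradigm.

**Twilight maps.** Between −4° and +6° the melanopsin/rod ("intensity")
channel ramps linearly at 0.25 log units/degree (2.5 log units across the
window) from a day plateau of 13.5 log photons/cm²/s; the color
coordinate ramps monotonically by 0.6 units, bluer at lower sun. Above
and below the window both clamp. Cone channels sit at intensity ± color/2.
The ramp endpoints and slopes are configuration knobs; the analysis
pipeline depends only on monotonicity and the clamps.

**Clouds.** Log-flux attenuation follows a stationary AR(1) process
(correlation time 30 min, mean 0.45, SD 0.28 log units), reflected at
zero and capped at 1.2 log units, drawn with an independent seed per
simulated day so no two days share a cloud pattern. The cap admits the
>10-fold dimming episodes characteristic of heavy overcast; reflection
and capping bias the lag-τc autocorrelation slightly below the latent
process's 1/e. Attenuation applies to the intensity channels only — the
twilight color trace is identical on clear and cloudy days, which is the
physical fact the paradigm exploits.

**Naturalistic paradigm.** Seven clear-sky baseline days (16:8, labelled
`baseline`, excluded from analysis) entrain the simulated animal, followed
by five interleaved epochs of: 3 cloudy natural days → 24 h constant dim
(intermediate color, night-floor intensity) → the matched intensity-only
block → 24 h constant dim. Each intensity-only block copies its partner
natural block's intensity channels bin-for-bin and pins the color at the
day value, so the paired comparison shares cloud realisations exactly.
Interleaving (rather than running all natural blocks first) keeps the
within-subject contrast orthogonal to slow drifts across the recording;
in early sequential designs such drift dominated the paired comparison
even when the two conditions' light input was provably identical.

## 3. Behavior simulator

A single circadian phase `φ ∈ [0,1)` (0 = activity onset) evolves as

    dφ/dt = 1/τ(D) + A·g(φ)·D,   τ(D) = τ₀ + k_τ·D,   g(φ) = −sin 2πφ,

integrated by forward Euler on the schedule grid (1 min). `g` delays in
the early subjective night and advances in the late subjective night —
the minimal shape with the correct resetting asymmetry. A continuous
velocity-modulation model was chosen over discrete PRC pulses because the
paradigms are long-duration exposures; three parameters then carry all
required phenomena: period aftereffects (k_τ), entrainment and jet-lag
dynamics (A), and chromatic modulation (w_c, below).

**Drive.** `D = max(0, max(0, (log₁₀mel + log₁₀rod)/2 − floor) + w_c·c)`
with `c` the color coordinate. The chromatic term is added for the
cone-functional ("redcone") genotype only and *unconditionally* — a
day-like color raises the clock's light-level estimate even when the
achromatic flux is at the floor. This is what makes the fixed-day-color
control condition informative: its nights read as weak day.

**Activity.** Poisson counts per bin at rate `rate_active` while
`φ < α(D) = clip(α₀ − α_slope·D, 0.05, 0.95)` and `rate_rest` otherwise;
optional negative masking divides the rate by `1 + masking_gain·D`
(disabled by default — no directional claim requires it).

**Default parameters** (units; rationale):

| parameter | default | meaning |
|---|---|---|
| τ₀ | 23.6 h | nocturnal mouse free-run in darkness |
| k_τ | 0.3 h/drive | period lengthening with light intensity |
| A | 0.01 cycles/h/drive | phase-response amplitude |
| w_c | 0.5 /color unit | chromatic drive weight (0 for coneless) |
| floor | 12.5 log photons | dim-light threshold of the drive |
| α₀, α_slope | 0.5, 0.03/drive | active fraction and its compression |
| rate_active, rate_rest | 20, 1 counts/10 min | emission rates |

Two of these deserve comment. The *floor* sits ~1 log unit below the
clear-sky day plateau, so cloud episodes (up to 1.2 log units) can push
daytime flux beneath it: intensity then becomes an ambiguous day/night
cue, which is precisely the regime in which chromatic information should
matter, and the regime the naturalistic paradigm was designed to probe.
The *phase-response amplitude* is set high enough that entrainment
stability is governed by zeitgeber contrast (which the twilight color cue
improves) rather than by the proximity of the mean period τ(D̄) to 24 h (a
competing, biologically incidental effect that dominates at small A).

A known consequence of velocity modulation: in constant light the realized
free-running period is `T = τ(D)/√(1 − (A·D·τ)²)`, slightly longer than
τ(D). At the defaults the inflation stays below one 10-min periodogram bin
for drives D ≤ 0.3, the regime used by the parameter-recovery tests; at
higher constant drives the measured period is genuinely longer than
τ₀ + k_τ·D (and the model approaches phase-locking near A·D·τ ≈ 1).
Directional comparisons (yellow vs blue, strong vs weak drive) are
monotone in D throughout the usable range and unaffected.

**What the generator does and does not emulate.** It reproduces, by
construction: intensity-dependent period lengthening, entrainment and
re-entrainment, intensity-dependent α compression, chromatic modulation of
drive in cone-functional animals and its absence in coneless ones, and
Poisson-like count noise. It does not model: SCN network or molecular
dynamics, sleep states, light-history adaptation, wheel blocking or other
recording artifacts, inter-individual parameter variability (one
parameter set per simulation), or pupil dynamics. Passing tests therefore
certify the analysis pipeline and the stated direction-of-effect logic,
not quantitative agreement with any animal cohort.

## 4. Rhythm analysis

**χ²-periodogram.** For each candidate period (stepping by one data bin
across 20–28 h) the record is truncated to K complete cycles and folded;
the Sokolove–Bushell statistic `Q_P = K·Σ_h(X̄_h−X̄)² / (Σ_i(X_i−X̄)²/n)`
is compared with the χ²(P−1) quantile at level 0.001. The best period is
the significant candidate maximizing Q_P (ties break toward the larger
Q_P neighborhood mean). This normalization is the one under which white
noise is calibrated to χ²(P−1) — the tests verify both the null
calibration and that a noiseless 24-h square wave is recovered exactly.
Constant records and records shorter than two cycles of the longest
candidate are rejected, never silently scored.

**α.** Fold at the estimated period (integer bins); α is the fraction of
folded-profile bins above the folded-profile mean.

**Phase markers.** Onset = start of the first 30-min window with *every*
bin strictly above the daily mean, scanning forward from the day's
reference time; offset = start of the first 90-min window strictly below
the mean after onset; windows may extend into the following day. Days
with no qualifying window report missing markers — they are excluded from
means, never interpolated. (The alternative "window mean above daily
mean" criterion is exposed as the brute-force oracle's parameterization
but not the default.) Midpoints are circular on the 24-h clock; shift
curves unwrap the daily series and subtract the mean of the five pre-shift
days, making the pre-shift baseline exactly zero.

**Waveforms.** Days are smoothed by a centered circular 2-h running mean,
averaged, mean-subtracted and divided by the maximum (peak ≡ 1);
zero-variance profiles raise an error. Crossing markers are the upward and
downward mean crossings of this smoothed waveform. Marker detection on raw
bins (30/90-min rule) and on smoothed waveforms (crossing rule) are both
provided; the paradigm-level analysis uses raw bins for per-day markers
and the smoothed waveform for mean-profile summaries.

**IS/IV.** Computed on acquisition bins (10-min PIR ⇒ 144 bins/day;
hourly rebinning is available but the tests pin the acquisition-bin mode).
IV uses successive differences i = 2..n, the standard definition. Both
statistics are affine-invariant; degenerate (zero-variance) inputs raise.

**Day–day correlation.** Mean Pearson r over all C(D,2) unordered day
pairs; pairs containing a zero-variance day are excluded and counted
(10 diurnal analysis days ⇒ 45 pairs, 5 constant-routine days ⇒ 10).

**Epoch selection.** Days are half-open 24-h windows anchored at the
schedule's block labels: the last 48 h of each 3-day block (10 diurnal
days per condition over 5 epochs) and the full 24-h dim epochs (5
constant-routine days per condition). The night window for the
percent-outside-night measure is the 8-h (projected) night of the 16:8
schedule, 20:00–04:00 schedule time by default.

**Exact 2×2 test.** Two-sided Fisher exact p (sum of hypergeometric point
probabilities not exceeding the observed table's), delegated to
`scipy.stats.fisher_exact` and cross-checked in the tests against a full
enumeration written directly from the hypergeometric pmf.

## 5. Problem sizes and reproducibility

Simulations run at 1-min resolution; the test and acceptance workloads use
14-day constant-light records, 28-day jet-lag records and the 47-day
naturalistic paradigm, with 20 seeds per condition for direction-of-effect
comparisons and 100–1000 replicates for Monte-Carlo calibration checks —
sizes at which every statistic is stable while the whole suite runs in
well under a minute on one core. All randomness flows through explicit
integer seeds (one per simulated day for clouds, one per simulation for
emission); rerunning any generator or the full pipeline with the same
configuration and seeds is byte-identical, and run manifests record seeds
and output checksums.

## 6. Known limitations

- The lens curve and twilight ramp shapes are declared approximations;
  analyses depending on their exact values (none in this package) would
  need measured tables.
- The metamer solver's general-position case handles one free color
  direction (n primaries, n−1 equality constraints, or n−2 plus the μ
  root-find); richer multi-primary optimization (e.g. 5-primary rigs with
  inequality spectra constraints) is out of scope.
- The oscillator is a single phase variable: it cannot express relative
  coordination, splitting, or aftereffects that outlast the driving light
  by design.
- IS/IV on short (2-day) segments are noisy; the pipeline pools days
  across epochs exactly so that these statistics are computed at the
  sample sizes for which they are meaningful.
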