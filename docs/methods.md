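# Methods

This note documents the models, estimators, parameter defaults and design
choices behind `pfcsync`, and what the synthetic-data validation does and
does not demonstrate about real recordings.

## Signal model and conditioning

All spectral and phase analyses operate on a regularly sampled LFP
(`LFPSignal`, µV). Analysis filters are Butterworth throughout and applied
**zero-phase** (forward–backward, `sosfiltfilt`): a causal filter's
frequency-dependent group delay would systematically rotate spike phases
and bias locking estimates, so zero-phase filtering is non-negotiable for
this pipeline even where a causal filter would do for power estimates. The
squared magnitude response this implies is accounted for in the filter
tests.

Instantaneous phase is the argument of the Hilbert analytic signal, with
the cosine convention (phase 0 at the oscillation peak, range (−π, π]).
The first and last 2 s of every phase series are flagged as filter edge
transients and excluded from spike-phase assignment (`EDGE_EXCLUDE_S`).

The sliding-band decomposition uses 3 Hz-wide 2nd-order band-passes on a
1 Hz grid of centers from 2 to 70 Hz, covering delta through gamma. The
grid step and range are package choices; the band width and filter order
are the analysis definition. Bands that would touch 0 Hz are clipped at
0.25 Hz (with a warning) rather than silently extended — a band-pass with a
0 Hz corner is unstable.

`decimate` keeps every (fs/target)-th sample and demands an integer ratio;
anti-alias filtering is the caller's responsibility (or `antialias=True`,
a 4th-order low-pass at 0.4·target — order chosen as the standard
compromise between rolloff and ringing).

## Spectral estimation and the group test

Welch PSDs use 2 s Hann windows with 90% overlap, density scaling (the
integral over frequency approximates the variance; verified to 5% by the
Parseval tests). A 2 s window natively gives 0.5 Hz bins; adjacent native
bin pairs are averaged onto a 1 Hz grid, on which band membership is
evaluated with inclusive bounds (theta 4–7.5 Hz therefore contains the
bins at 4, 5, 6, 7 Hz). Both grids are retained on the `PSD` object.
The alpha (8–12) and mu (10–12) bands overlap and are each reported.

Band energy is the *mean* power across the band's bins, so values are
comparable across bands of different width. The session (animal) is the
statistical unit; per band, session energies are compared across groups
with the Mann–Whitney U test (U = min(U_a, U_b), midrank ties). The p-value
is exact — full enumeration of group assignments — whenever n_a+n_b ≤ 20
and no ties are present, otherwise a normal approximation with tie and
continuity corrections (delegated to `scipy.stats.mannwhitneyu`; the test
suite verifies exactness against an independent brute-force enumeration of
all 6435 assignments at sizes 8 vs 7). Two-sided p-values throughout; no
multiple-comparison correction is applied across the six bands by default.

## Pairwise synchrony

The cross-correlogram histograms (target − reference) lags with 1 ms bins
over ±500 ms (configurable; the bin edges place 0 on an edge so the toy
examples enumerate exactly). The synchrony statistic is the integrated
area: the sum of correlogram mass in all bins fully inside [−w, +w] for
window half-lengths w ∈ {5, 10, 20, 50, 100, 200, 500} ms, spanning
monosynaptic to slow-oscillation timescales. Default normalization is
counts **per reference spike**, so the statistic is comparable across pairs
with different rates; raw counts are retained for oracle tests and for
comparison against the closed-form chance level
E[area] = r_ref·r_tgt·T·2w of independent stationary Poisson trains.
No shift-predictor or jitter correction is applied by default.

Group curves are summarized by the mean across pairs with a percentile
bootstrap CI: the resampling unit is the **pair** (2000 resamples, 95%
level, seeded). Elementwise coverage of this CI, measured over simulated
experiments with 30 Gaussian pairs, is ~93.5% — the familiar slight
undercoverage of the percentile method at moderate n, within the 93–97%
acceptance band.

## UP/DOWN states

The slow alternation between depolarized (UP) and hyperpolarized (DOWN)
cortical states under urethane anesthesia is tracked through the <3 Hz
zero-phase low-passed LFP. Each cycle is split into peak-centred
half-cycles by the sign of the filtered trace (equivalently cos(phase) ≥ 0),
and the half-cycle class with the higher pooled population firing rate is
labeled UP. Anchoring the label to firing rather than raw polarity makes
the segmentation invariant to electrode/reference polarity conventions;
with no spikes the positive-signal class is labeled UP with a warning.
State-restricted synchrony curves require **both** members of a spike pair
to lie inside the requested state (a reference-only mode is available),
and the restriction partitions pair counts exactly (UP–UP + DOWN–DOWN +
cross-state = total).

## Phase locking

Per unit and band center: spike phases by nearest-sample lookup (at
500 Hz, worst-case 1 ms → 0.04 rad error at 70 Hz's period — negligible;
no interpolation), then the mean resultant vector length
R = |⟨e^{iθ}⟩| and mean angle. Centers with fewer than 30 valid spike
phases are reported invalid (R = NaN): raw R is positively biased at small
n (E[R] ≈ √(π/4n) for uniform phases), and a transparent threshold serves
group contrasts better than bias-corrected estimators here. Population
profiles are mean ± SEM of R across units with valid estimates at each
center. The Rayleigh large-sample null quantile √(−ln α / n) is provided
for flatness checks; no per-center hypothesis test between groups is
computed — the group contrast is descriptive (mean ± SEM), matching how
such profiles are reported.

## Synthetic data: what it emulates

Each session's LFP is the sum of

- a 1/f^α Gaussian background (α = 1, σ = 30 µV), generated by spectral
  shaping of white noise (rFFT magnitudes × f^(−α/2), phases untouched,
  weights normalized so the output variance is σ² in expectation — an
  exactly controllable spectrum);
- a slow oscillation (1 Hz, 150 µV) standing in for the urethane slow
  state alternation;
- a theta component (6 Hz; 40 µV for vehicle, ×0.6 for the pcp group,
  with per-session log-normal amplitude jitter of σ = 0.2 so sessions are
  exchangeable but not identical).

Units are inhomogeneous Poisson with von Mises intensity
λ(t) = r·exp(κ·cos(θ_slow(t) − μ))/I₀(κ), sampled exactly by thinning
against the ceiling r·e^κ/I₀(κ). The I₀ normalization makes the
time-averaged rate equal r for a uniformly sweeping phase, and the
expected resultant length is the Bessel ratio I₁(κ)/I₀(κ) — the closed
form all locking validation is checked against (0.698 at κ = 2). DOWN
half-cycles multiply the intensity by the gate ratio (default 0.3).
Base rate 0.9 Hz with log-normal per-unit jitter (σ = 0.4) reflects the
low-rate regular-spiking regime of putative pyramidal cells; the default
common-input coincidence rates (0.01 Hz vehicle, 0.05 Hz pcp per pair,
2 ms Gaussian jitter per spike) lift realized mean rates to roughly 0.95
and 1.15 Hz. Group defaults — 8 vehicle vs 7 pcp sessions, κ = 0.5 vs 2.0,
theta factor 0.6 — encode the modeled effect directions: lower pcp theta
power, higher pcp pair synchrony, stronger pcp low-frequency locking. The
theta amplitude factor and κ contrast are free modeling choices (the
underlying effect sizes are not available in physical units), fixed once
in the defaults.

Waveform templates are biphasic half-sines (initial phase 0.64 ms,
after-hyperpolarization 0.87 ms, per-unit truncated-normal jitter at
σ = 0.30/0.34 ms) sampled at 40 kHz, which the waveform-feature extractor
recovers to sub-sample precision via interpolated zero crossings.

Determinism: session k draws from `SeedSequence([seed, k])`, so identical
configs give bit-identical datasets while per-session streams stay
independent.

**What passing does not show.** The generator has stationary sinusoidal
rhythms, Poissonian spiking and instantaneous common input. Real
urethane recordings have non-stationary state episodes, bursting and
refractoriness, conduction and synaptic delays (asymmetric correlograms),
volume-conduction artifacts and spike-sorting contamination. Validation
here demonstrates that the estimators recover known parameters under the
stated model — not that the model captures cortical dynamics.

## Numerical and degenerate-input choices

- Exactly coincident spike times are merged (thinning: 10⁻⁷ s; injected
  coincidences: 10⁻⁴ s, about one sample period of a sorted recording) so
  spike trains stay strictly increasing and correlograms avoid
  zero-interval artifacts.
- All-zero signals raise for phase extraction (phase undefined); empty
  angle sets raise for the resultant vector; an empty band raises for band
  energy; complete ties return p = 1 (zero rank variance).
- A single pair collapses the bootstrap CI to the point estimate with a
  warning rather than fabricating width.
- Jittered common-input spikes falling outside [0, T) are dropped and do
  not count toward the realized injected total.

## Problem sizes used in validation

The shipped validation runs at desk scale, chosen as the smallest sizes at
which the checked quantities are statistically decisive: 120 s sessions at
500 Hz for experiment-level replicates (50–100 replicates for detection
power), 600 s single pairs for coincidence recovery (50 seeds), 500
simulated experiments for bootstrap coverage, 50 seeds × 12 unmodulated
units for locking-profile flatness, and exhaustive enumeration (6435
assignments) wherever the permutation space is small enough to avoid Monte
Carlo noise altogether.
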