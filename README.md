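# pfcsync

Spike/LFP synchrony analysis for two-group extracellular recordings, built
around the question of how subchronic NMDA-antagonist treatment changes
prefrontal cortical dynamics: reduced theta-band power together with
*increased* pairwise spike synchrony and stronger locking of single units to
low-frequency oscillations. The package implements the full analysis chain
as a tested, reusable library plus CLI, and ships a synthetic-data generator
with known ground truth so every stage can be validated end to end.

It is aimed at systems-neurophysiology users who have continuous LFP traces
(float32 + JSON sidecar) and sorted single-unit spike trains (CSV), and want
reproducible group-level statistics rather than one-off scripts.

## What it computes

- **Band-power group comparison** — Welch periodograms (2 s Hann windows,
  90% overlap), band energies as the mean power over the bins of each band
  (delta 0.5–3.5, theta 4–7.5, alpha 8–12, mu 10–12, beta 13–30, gamma
  30–70 Hz), compared across groups per session with the Mann–Whitney *U*
  test for equal medians (exact for ≤20 sessions without ties).
- **Cross-correlogram synchrony curves** — for each simultaneously recorded
  unit pair, the area under the cross-correlogram integrated over symmetric
  lag windows of varying half-length *w*; group means carry 95% percentile
  bootstrap confidence bands resampled at the pair level.
- **Spike-phase locking profiles** — the LFP is band-pass filtered with a
  3 Hz-wide window sliding along the frequency axis (zero-phase 2nd-order
  Butterworth), instantaneous phase is taken from the Hilbert analytic
  signal, and locking per band is the mean resultant vector length
  R = |⟨e^{iθ}⟩| of spike phases; population profiles are mean ± SEM across
  units.
- **UP/DOWN-state control** — states are segmented from the <3 Hz low-pass
  LFP (half-cycles labeled by pooled population firing rate, so the result
  is electrode-polarity-proof) and synchrony curves are recomputed from
  state-restricted spike pairs.
- **Unit metrics** — firing rates, biphasic waveform phase durations
  (sub-sample zero-crossing interpolation), autocorrelograms, and a
  putative-pyramidal screen (low rate, broad initial waveform phase).
- **Synthetic experiments** — 1/f background + slow oscillation + group-
  dependent theta LFPs; inhomogeneous Poisson units with von Mises phase
  modulation, λ(t) = r·exp(κ·cos(θ(t)−μ))/I₀(κ), whose expected resultant
  length is the Bessel ratio I₁(κ)/I₀(κ); UP/DOWN rate gating; and injected
  near-coincident common-input spikes per pair, all with recorded ground
  truth.

## Worked example

Run the default synthetic experiment (8 vehicle vs 7 "pcp" sessions, 120 s
each, 6 units per session) through every stage:

```python
import numpy as np
from pfcsync import SyntheticConfig, RunConfig, run_pipeline

cfg = RunConfig(synthetic=SyntheticConfig(), seed=1,
                output_dir="demo_run", n_boot=2000)
report = run_pipeline(cfg)

theta = [r for r in report.band_comparisons if r["band"] == "theta"][0]
print(theta["median_vehicle"], theta["median_pcp"], theta["U"], theta["p"])
```

which prints (abridged to the headline numbers):

```
theta band: median vehicle=228.2 uV^2/Hz, median pcp=97.2 uV^2/Hz, U=0, p=0.0003
gamma band: median vehicle=1.74 uV^2/Hz, median pcp=1.73 uV^2/Hz, p=0.9551
synchrony vehicle: mean area at w=50 ms = 0.1344 [95% CI 0.1251, 0.1430] (120 pairs)
synchrony pcp:     mean area at w=50 ms = 0.2585 [95% CI 0.2419, 0.2756] (105 pairs)
locking vehicle: mean R over 2-4 Hz centers = 0.295 (48 units)
locking pcp:     mean R over 2-4 Hz centers = 0.353 (42 units)
```

Reading the output: the generator scales the pcp theta amplitude by 0.6
(power factor 0.36), and the theta comparison recovers that as a large
median drop with U = 0 (complete separation); gamma, where the groups are
identical by construction, stays null. The pcp group receives five times
the common-input coincidence rate, which the synchrony curves show as
non-overlapping CI bands, and its stronger slow-oscillation locking
(κ = 2 vs 0.5) appears as elevated low-frequency resultant lengths.

The same run from the shell:

```bash
pfcsync simulate --out data/ --seed 1
pfcsync psd     --in data/ --out psd_report.csv
pfcsync xcorr   --in data/ --out xcorr_run/ --boot 2000 --seed 1
pfcsync locking --in data/ --out locking_run/
pfcsync run     --in data/ --out full_run/ --seed 1        # all stages
```

All outputs are CSV/JSON; `report.json` embeds the resolved configuration
and a payload hash, and reruns with the same config and seed are
bit-identical.

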