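"""Per-unit descriptive metrics: firing rate, waveform shape, autocorrelogram.

Used for putative-pyramidal screening (low firing rate, broad initial
waveform phase) and for the autocorrelogram control that rules out
sorting artifacts as the source of group synchrony differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeTrain:
    """Sorted single-unit spike times for one session.

    Invariants: times strictly increasing, finite, within [0, duration).
    """

    times: np.ndarray
    unit_id: str
    duration: float
    session_id: str = "s0"
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: spike times must be 1-d")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise ValueError(f"unit {self.unit_id}: non-finite spike times")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"unit {self.unit_id}: spike times not strictly increasing"
            )
        if not self.duration > 0:
            raise ValueError(f"unit {self.unit_id}: duration must be positive")
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= self.duration):
            raise ValueError(
                f"unit {self.unit_id}: spike times outside [0, duration)"
            )

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Waveform:
    """Mean spike waveform (uV) at sampling rate fs."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 16:
            raise ValueError("waveform must have at least 16 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")


@dataclass(frozen=True)
class WaveformFeatures:
    """Durations (ms) of the two waveform phases.

    ``initial_wave_duration``: width of the dominant first phase between its
    bounding zero crossings. ``second_phase_duration``: width of the
    subsequent opposite-polarity phase (after-hyperpolarization).
    """

    initial_wave_duration: float
    second_phase_duration: float


@dataclass
class Correlogram:
    """Histogram of spike-pair lags on uniform bins symmetric about 0.

    ``counts`` may be raw pair counts or counts per reference spike,
    recorded in ``normalization``.
    """

    lag_bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    normalization: str = "raw"
    n_reference: int = 0

    @property
    def lag_centers(self) -> np.ndarray:
        return 0.5 * (self.lag_bin_edges[:-1] + self.lag_bin_edges[1:])


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count / duration (Hz)."""
    return train.n_spikes / train.duration


def _interp_zero(s: np.ndarray, i: int, j: int) -> float:
    """Fractional index of the zero crossing between samples i and j=i+1."""
    if s[i] == 0.0:
        return float(i)
    if s[j] == 0.0:
        return float(j)
    return i + s[i] / (s[i] - s[j])


def waveform_features(wf: Waveform) -> WaveformFeatures:
    """Extract the two phase durations from a biphasic mean waveform.

    The dominant extremum defines the first phase; its bounding zero
    crossings (linear interpolation between samples, sub-sample precision)
    give the initial wave duration. The immediately following
    opposite-polarity excursion bounded by the next zero crossing gives the
    second-phase duration. Raises ``ValueError`` when a bounding crossing or
    the opposite phase does not exist (e.g. monophasic pulses).
    """
    s = wf.samples
    m = int(np.argmax(np.abs(s)))
    sgn = np.sign(s[m])
    rel = s * sgn  # first phase is positive in `rel`

    # left bounding crossing of the first phase
    i = m
    while i > 0 and rel[i - 1] > 0:
        i -= 1
    if i == 0 and rel[0] > 0:
        raise ValueError("no zero crossing before the dominant extremum")
    x_l = _interp_zero(rel, i - 1, i) if rel[i] > 0 else float(i)

    # right bounding crossing
    j = m
    n = rel.size
    while j < n - 1 and rel[j + 1] > 0:
        j += 1
    if j == n - 1 and rel[n - 1] > 0:
        raise ValueError("no zero crossing after the dominant extremum")
    x_r = _interp_zero(rel, j, j + 1) if rel[j] > 0 else float(j)

    # second phase: opposite-polarity excursion starting at x_r
    k = int(np.ceil(x_r))
    while k < n and rel[k] == 0:
        k += 1
    if k >= n or rel[k] > 0:
        raise ValueError("no opposite-polarity second phase after the "
                         "initial wave")
    e = k
    while e < n - 1 and rel[e + 1] < 0:
        e += 1
    if e == n - 1 and rel[n - 1] < 0:
        raise ValueError("second phase does not return to zero")
    x_r2 = _interp_zero(rel, e, e + 1) if rel[e] < 0 else float(e)

    ms = 1000.0 / wf.fs
    return WaveformFeatures(
        initial_wave_duration=(x_r - x_l) * ms,
        second_phase_duration=(x_r2 - x_r) * ms,
    )


def _pair_lags(reference: np.ndarray, target: np.ndarray,
               max_lag: float) -> np.ndarray:
    """All (target - reference) lags with |lag| <= max_lag."""
    if reference.size == 0 or target.size == 0:
        return np.empty(0)
    lo = np.searchsorted(target, reference - max_lag, side="left")
    hi = np.searchsorted(target, reference + max_lag, side="right")
    chunks = [target[l:h] - t for t, l, h in zip(reference, lo, hi) if h > l]
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def _make_edges(bin_width: float, max_lag: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_lag < bin_width:
        raise ValueError("max_lag must be at least one bin width")
    n_half = int(np.ceil(max_lag / bin_width - 1e-9))
    return np.arange(-n_half, n_half + 1) * bin_width


def autocorrelogram(train: SpikeTrain, bin_width: float = 0.010,
                    max_lag: float = 0.5) -> Correlogram:
    """Histogram of all pairwise same-train lags, zero-lag self-pairs excluded.

    Symmetric about 0 by construction (each ordered pair contributes +d and
    -d). Defaults (10 ms bins, +/-500 ms) resolve both burst structure and
    slow-oscillation modulation.
    """
    edges = _make_edges(bin_width, max_lag)
    lags = _pair_lags(train.times, train.times, edges[-1])
    lags = lags[lags != 0.0]  # drop self-pairs; exact dups are excluded by invariant
    counts, _ = np.histogram(lags, bins=edges)
    return Correlogram(lag_bin_edges=edges, counts=counts.astype(float),
                       bin_width=bin_width, normalization="raw",
                       n_reference=train.n_spikes)


def screen_putative_pyramidal(rate: float, features: WaveformFeatures,
                              max_rate: float = 3.0,
                              min_initial_ms: float = 0.3) -> bool:
    """Putative pyramidal screen: low rate and broad initial waveform phase."""
    return bool(rate <= max_rate
                and features.initial_wave_duration >= min_initial_ms)
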