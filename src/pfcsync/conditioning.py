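"""Filtering, decimation and analytic-signal phase extraction for LFP traces.

The local field potential (LFP) enters every downstream analysis either as a
raw voltage series (spectral estimation) or as a narrow-band instantaneous
phase (spike-phase locking, UP/DOWN segmentation). All analysis filters are
Butterworth and applied zero-phase (forward-backward) by default: phase-locking
estimates are meaningless with a phase-distorting filter. The first and last
``EDGE_EXCLUDE_S`` seconds of every phase series are flagged as edge-transient
regions and excluded from spike-phase assignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

#: Seconds flagged as filter edge transient at each end of a PhaseSeries.
EDGE_EXCLUDE_S = 2.0

#: Lower clip (Hz) for degenerate narrow bands that would touch 0 Hz.
MIN_BAND_LOW_HZ = 0.25


@dataclass
class LFPSignal:
    """Regularly sampled extracellular voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in microvolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    channel_id : str
        Free-form channel label.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_id: str = "lfp"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("LFPSignal needs a 1-d series of at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFPSignal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal extent in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class PhaseSeries:
    """Instantaneous phase (and envelope) of a narrow-band signal.

    Phase follows the cosine convention: phase 0 at the oscillation peak,
    values in (-pi, pi]. ``edge_s`` seconds at each end are considered
    filter-transient and invalid for spike-phase assignment.
    """

    phase: np.ndarray
    fs: float
    band: tuple[float, float] | None = None
    amplitude: np.ndarray | None = None
    t0: float = 0.0
    edge_s: float = EDGE_EXCLUDE_S

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if self.amplitude.shape != self.phase.shape:
                raise ValueError("amplitude and phase must have equal length")

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def valid_window(self) -> tuple[float, float]:
        """(start, stop) in seconds of the edge-trimmed valid region."""
        return (self.t0 + self.edge_s, self.t0 + self.duration - self.edge_s)


def _design_butter(kind: str, order: int, cutoffs, fs: float):
    kinds = {"lowpass", "highpass", "bandpass"}
    if kind not in kinds:
        raise ValueError(f"kind must be one of {sorted(kinds)}, got {kind!r}")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    wn = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if kind == "bandpass":
        if wn.size != 2 or not wn[0] < wn[1]:
            raise ValueError("bandpass needs two increasing cutoffs")
    elif wn.size != 1:
        raise ValueError(f"{kind} needs exactly one cutoff")
    nyq = fs / 2.0
    if np.any(wn <= 0) or np.any(wn >= nyq):
        raise ValueError(
            f"cutoffs must lie strictly inside (0, {nyq}) Hz, got {wn.tolist()}"
        )
    return sps.butter(order, wn if wn.size > 1 else wn[0], btype=kind,
                      fs=fs, output="sos")


def butterworth_filter(signal: LFPSignal, kind: str, order: int, cutoffs,
                       zero_phase: bool = True) -> LFPSignal:
    """Butterworth-filter an LFP trace.

    With ``zero_phase`` the filter runs forward and backward (squared
    magnitude response, zero phase delay); otherwise a single causal pass.
    Output has the same length and sampling rate as the input.
    """
    sos = _design_butter(kind, order, cutoffs, signal.fs)
    if zero_phase:
        out = sps.sosfiltfilt(sos, signal.samples)
    else:
        out = sps.sosfilt(sos, signal.samples)
    return LFPSignal(out, signal.fs, t0=signal.t0, channel_id=signal.channel_id)


def decimate(signal: LFPSignal, target_fs: float,
             antialias: bool = False, antialias_order: int = 4) -> LFPSignal:
    """Downsample by an integer factor, keeping every (fs/target_fs)-th sample.

    The caller is expected to have applied anti-alias filtering already
    (e.g. a 200 Hz low-pass before 40 kHz -> 5 kHz decimation); pass
    ``antialias=True`` to request a Butterworth low-pass at 0.4*target_fs
    before picking samples.
    """
    ratio = signal.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or target_fs <= 0:
        raise ValueError(
            f"target_fs must divide fs evenly: fs={signal.fs}, target={target_fs}"
        )
    step = int(round(ratio))
    sig = signal
    if antialias and step > 1:
        sig = butterworth_filter(sig, "lowpass", antialias_order,
                                 0.4 * target_fs, zero_phase=True)
    return LFPSignal(sig.samples[::step].copy(), target_fs,
                     t0=signal.t0, channel_id=signal.channel_id)


def instantaneous_phase(signal: LFPSignal,
                        band: tuple[float, float] | None = None,
                        edge_s: float = EDGE_EXCLUDE_S) -> PhaseSeries:
    """Instantaneous phase of a (narrow-band) signal via the analytic signal.

    Phase 0 corresponds to the peak of a cosine. The input should already be
    band-limited; this function does not filter.
    """
    x = signal.samples
    if not np.any(x):
        raise ValueError("instantaneous phase is undefined for an all-zero signal")
    n = x.size
    analytic = sps.hilbert(x, N=next_fast_len(n))[:n]
    return PhaseSeries(
        phase=np.angle(analytic),
        fs=signal.fs,
        band=band,
        amplitude=np.abs(analytic),
        t0=signal.t0,
        edge_s=edge_s,
    )


def sliding_band_decompose(signal: LFPSignal, centers, width: float = 3.0,
                           order: int = 2,
                           edge_s: float = EDGE_EXCLUDE_S) -> list[PhaseSeries]:
    """Decompose an LFP into narrow-band phase series along a center grid.

    Each center c yields the band (c - width/2, c + width/2), filtered with a
    zero-phase second-order Butterworth band-pass and converted to phase via
    the analytic signal. Bands that would touch 0 Hz are clipped at
    ``MIN_BAND_LOW_HZ`` (a warning is issued) rather than silently extended.
    """
    if width <= 0:
        raise ValueError("band width must be positive")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    nyq = signal.fs / 2.0
    out: list[PhaseSeries] = []
    for c in centers:
        lo, hi = c - width / 2.0, c + width / 2.0
        if hi >= nyq:
            raise ValueError(f"band ({lo}, {hi}) Hz exceeds Nyquist {nyq} Hz")
        if lo < MIN_BAND_LOW_HZ:
            warnings.warn(
                f"band ({lo:.2f}, {hi:.2f}) Hz touches 0 Hz; "
                f"clipping low edge to {MIN_BAND_LOW_HZ} Hz",
                stacklevel=2,
            )
            lo = MIN_BAND_LOW_HZ
        filtered = butterworth_filter(signal, "bandpass", order, (lo, hi),
                                      zero_phase=True)
        ps = instantaneous_phase(filtered, band=(lo, hi), edge_s=edge_s)
        out.append(ps)
    return out
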