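"""Cross-correlogram synchrony curves, bootstrap CIs and UP/DOWN analysis.

The pairwise synchrony statistic is the area under the cross-correlogram
integrated over symmetric lag windows of varying half-length: near-coincident
common input concentrates mass near zero lag, so the area at short windows
rises above the chance level expected for independent trains. Group curves
carry percentile bootstrap confidence bands resampled at the pair level.

UP/DOWN states (the alternating depolarized/silent cortical states under
urethane anesthesia) are segmented from the <3 Hz low-pass LFP: the trace is
split into peak-centred half-cycles by the sign of the filtered signal, and
the half-cycle class with the higher pooled population firing rate is
labeled UP, which makes the labeling robust to electrode polarity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .conditioning import LFPSignal, butterworth_filter
from .units import Correlogram, SpikeTrain, _make_edges, _pair_lags

#: Default window half-lengths (s): monosynaptic to slow-oscillation scales.
DEFAULT_WINDOWS: tuple[float, ...] = (
    0.005, 0.010, 0.020, 0.050, 0.100, 0.200, 0.500)


@dataclass
class SynchronyCurve:
    """Integrated correlogram area as a function of window half-length."""

    window_half_lengths: np.ndarray
    area: np.ndarray
    normalization: str = "raw"
    pair_id: str | None = None
    n_pairs: int = 1

    def __post_init__(self) -> None:
        self.window_half_lengths = np.asarray(self.window_half_lengths, float)
        self.area = np.asarray(self.area, float)
        if self.window_half_lengths.shape != self.area.shape:
            raise ValueError("windows and area must have equal length")


@dataclass
class CIBand:
    """Elementwise percentile bootstrap confidence band."""

    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("CI lower bound exceeds upper bound")


@dataclass
class StateSegments:
    """Ordered, non-overlapping (start, end, state) intervals, states in
    {"UP", "DOWN"}, alternating."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end, prev_state = None, None
        for s, e, st in self.intervals:
            if st not in ("UP", "DOWN"):
                raise ValueError(f"unknown state {st!r}")
            if e <= s:
                raise ValueError("empty or inverted interval")
            if prev_end is not None and s < prev_end - 1e-12:
                raise ValueError("overlapping intervals")
            if prev_state is not None and st == prev_state:
                raise ValueError("states must alternate")
            prev_end, prev_state = e, st

    def arrays(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of all intervals with the given state."""
        sel = [(s, e) for s, e, st in self.intervals if st == state]
        if not sel:
            return np.empty(0), np.empty(0)
        a = np.asarray(sel, float)
        return a[:, 0], a[:, 1]

    def total_duration(self, state: str) -> float:
        starts, ends = self.arrays(state)
        return float(np.sum(ends - starts))


def in_state(times, segments: StateSegments, state: str) -> np.ndarray:
    """Boolean mask: which times fall inside intervals of the given state.

    Intervals are half-open [start, end)."""
    times = np.asarray(times, float)
    starts, ends = segments.arrays(state)
    if starts.size == 0:
        return np.zeros(times.shape, dtype=bool)
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = idx >= 0
    out = np.zeros(times.shape, dtype=bool)
    out[ok] = times[ok] < ends[idx[ok]]
    return out


def cross_correlogram(reference: SpikeTrain, target: SpikeTrain,
                      bin_width: float = 0.001, max_lag: float = 0.5,
                      normalization: str = "per_reference_spike") -> Correlogram:
    """Histogram of (target - reference) spike-time lags over +/- max_lag.

    ``per_reference_spike`` divides counts by the reference spike count so
    areas are comparable across pairs with different rates; ``raw`` keeps
    integer pair counts. Trains must come from the same session.
    """
    if reference.session_id != target.session_id:
        raise ValueError(
            f"cross-session correlogram: {reference.session_id} vs "
            f"{target.session_id}"
        )
    if normalization not in ("raw", "per_reference_spike"):
        raise ValueError(f"unknown normalization {normalization!r}")
    edges = _make_edges(bin_width, max_lag)
    lags = _pair_lags(reference.times, target.times, edges[-1])
    counts, _ = np.histogram(lags, bins=edges)
    counts = counts.astype(float)
    if normalization == "per_reference_spike" and reference.n_spikes > 0:
        counts = counts / reference.n_spikes
    return Correlogram(lag_bin_edges=edges, counts=counts,
                       bin_width=bin_width, normalization=normalization,
                       n_reference=reference.n_spikes)


def integrated_area(cc: Correlogram, window_half_lengths=DEFAULT_WINDOWS,
                    pair_id: str | None = None) -> SynchronyCurve:
    """Sum of correlogram mass in all bins fully inside [-w, +w] per window."""
    windows = np.asarray(window_half_lengths, float)
    max_edge = cc.lag_bin_edges[-1]
    if np.any(windows > max_edge + 1e-12):
        raise ValueError("integration window exceeds correlogram lag range")
    area = np.empty(windows.size)
    lo_e, hi_e = cc.lag_bin_edges[:-1], cc.lag_bin_edges[1:]
    for k, w in enumerate(windows):
        inside = (lo_e >= -w - 1e-12) & (hi_e <= w + 1e-12)
        area[k] = cc.counts[inside].sum()
    return SynchronyCurve(window_half_lengths=windows, area=area,
                          normalization=cc.normalization, pair_id=pair_id)


def expected_chance_area(rate_ref: float, rate_tgt: float, duration: float,
                         window_half_length: float,
                         normalization: str = "raw") -> float:
    """Chance-level integrated area for independent stationary Poisson trains.

    Raw expectation: rate_ref * rate_tgt * duration * 2w; per-reference-spike
    normalization divides by the expected reference count.
    """
    raw = rate_ref * rate_tgt * duration * 2.0 * window_half_length
    if normalization == "per_reference_spike":
        n_ref = rate_ref * duration
        return raw / n_ref if n_ref > 0 else 0.0
    return raw


def bootstrap_group_curves(curves: list[SynchronyCurve], n_boot: int = 2000,
                           level: float = 0.95, seed: int = 0
                           ) -> tuple[SynchronyCurve, CIBand]:
    """Group mean synchrony curve with a pair-level percentile bootstrap CI.

    Pairs (curves) are resampled with replacement ``n_boot`` times; the CI is
    the percentile band of the resampled means at each window length.
    Deterministic under ``seed``. A single pair collapses the CI to the point
    estimate with a warning.
    """
    if not curves:
        raise ValueError("need at least one synchrony curve")
    windows = curves[0].window_half_lengths
    mat = np.vstack([c.area for c in curves])
    for c in curves:
        if not np.array_equal(c.window_half_lengths, windows):
            raise ValueError("curves must share the same window grid")
    mean_curve = SynchronyCurve(windows, mat.mean(axis=0),
                                normalization=curves[0].normalization,
                                n_pairs=len(curves))
    n = mat.shape[0]
    if n < 2:
        warnings.warn("single pair: CI collapses to the point estimate",
                      stacklevel=2)
        band = CIBand(mean_curve.area.copy(), mean_curve.area.copy(),
                      level=level, n_boot=n_boot, seed=seed)
        return mean_curve, band
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = mat[idx].mean(axis=1)  # (n_boot, n_windows)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    return mean_curve, CIBand(lower, upper, level=level, n_boot=n_boot,
                              seed=seed)


def segment_up_down(lfp: LFPSignal, session_spikes: list[SpikeTrain],
                    cutoff_hz: float = 3.0, order: int = 2) -> StateSegments:
    """Segment the recording into UP/DOWN states from the <3 Hz LFP.

    The LFP is low-pass filtered (zero-phase Butterworth), split into
    peak-centred half-cycles by the sign of the filtered trace, and the
    half-cycle class with the higher pooled population firing rate is
    labeled UP. With no spikes the positive-signal class (instantaneous
    phase in (-pi/2, pi/2]) is labeled UP and a warning is issued.
    """
    filtered = butterworth_filter(lfp, "lowpass", order, cutoff_hz,
                                  zero_phase=True)
    pos = filtered.samples >= 0
    # run-length segmentation of the boolean series
    change = np.flatnonzero(np.diff(pos.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [pos.size]])
    seg_start = lfp.t0 + bounds[:-1] / lfp.fs
    seg_end = lfp.t0 + bounds[1:] / lfp.fs
    seg_pos = pos[bounds[:-1]]

    all_spikes = (np.sort(np.concatenate([t.times for t in session_spikes]))
                  if session_spikes else np.empty(0))
    if all_spikes.size == 0:
        warnings.warn("no spikes in session: UP labeled by phase convention "
                      "(filtered LFP >= 0)", stacklevel=2)
        up_is_pos = True
    else:
        t_pos = float(np.sum((seg_end - seg_start)[seg_pos]))
        t_neg = float(np.sum((seg_end - seg_start)[~seg_pos]))
        # count spikes inside positive segments
        ps, pe = seg_start[seg_pos], seg_end[seg_pos]
        idx = np.searchsorted(ps, all_spikes, side="right") - 1
        ok = idx >= 0
        n_pos = int(np.sum(all_spikes[ok] < pe[idx[ok]]))
        n_neg = all_spikes.size - n_pos
        rate_pos = n_pos / t_pos if t_pos > 0 else 0.0
        rate_neg = n_neg / t_neg if t_neg > 0 else 0.0
        up_is_pos = rate_pos >= rate_neg
    intervals = [
        (float(s), float(e), "UP" if (p == up_is_pos) else "DOWN")
        for s, e, p in zip(seg_start, seg_end, seg_pos)
    ]
    return StateSegments(intervals)


def restrict_train(train: SpikeTrain, segments: StateSegments,
                   state: str) -> SpikeTrain:
    """Copy of a train keeping only spikes inside intervals of one state."""
    mask = in_state(train.times, segments, state)
    return SpikeTrain(times=train.times[mask], unit_id=train.unit_id,
                      duration=train.duration, session_id=train.session_id,
                      group=train.group)


def state_restricted_curves(reference: SpikeTrain, target: SpikeTrain,
                            segments: StateSegments, state: str,
                            bin_width: float = 0.001, max_lag: float = 0.5,
                            windows=DEFAULT_WINDOWS,
                            normalization: str = "per_reference_spike",
                            both_in_state: bool = True) -> SynchronyCurve:
    """Synchrony curve from spike pairs restricted to one UP/DOWN state.

    With ``both_in_state`` (default) both pair members must lie inside
    intervals of the requested state; otherwise only the reference spike is
    restricted.
    """
    ref = restrict_train(reference, segments, state)
    tgt = restrict_train(target, segments, state) if both_in_state else target
    cc = cross_correlogram(ref, tgt, bin_width=bin_width, max_lag=max_lag,
                           normalization=normalization)
    return integrated_area(cc, windows,
                           pair_id=f"{reference.unit_id}-{target.unit_id}")
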