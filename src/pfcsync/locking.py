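"""Spike-LFP phase locking: resultant vector profiles across sliding bands.

For each unit the LFP is decomposed into 3 Hz-wide bands sliding along the
frequency axis; each spike is assigned the instantaneous phase of each band
component at its time, and locking per band is summarized by the mean
resultant vector length R = |mean(e^{i*theta})| in [0, 1] (0 = no locking,
1 = all spikes at one phase). Group population profiles are mean +/- SEM of
R across units.

Centers with fewer than ``min_spikes`` valid spike phases are reported with
R = NaN: the raw resultant length is positively biased at small n
(E[R] ~ n^{-1/2} for uniform phases), so small-n estimates would inflate
apparent locking.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .conditioning import LFPSignal, PhaseSeries, sliding_band_decompose
from .units import SpikeTrain

#: Default sliding-band center grid (Hz): 1 Hz steps, 2-70 Hz.
DEFAULT_CENTERS: np.ndarray = np.arange(2.0, 71.0, 1.0)

#: Minimum spike count for a valid resultant-length estimate.
DEFAULT_MIN_SPIKES = 30


@dataclass
class LockingProfile:
    """Per-unit resultant length and mean angle across band centers.

    Invalid centers (n_spikes < min_spikes) carry R = NaN.
    """

    unit_id: str
    centers: np.ndarray
    R: np.ndarray
    mean_angle: np.ndarray
    n_spikes: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        valid = np.isfinite(self.R)
        if np.any((self.R[valid] < 0) | (self.R[valid] > 1 + 1e-12)):
            raise ValueError("R must lie in [0, 1]")


@dataclass
class PopulationProfile:
    """Across-unit mean and SEM of R per band center for one group."""

    group: str
    centers: np.ndarray
    mean_R: np.ndarray
    sem_R: np.ndarray
    n_units: int
    n_valid: np.ndarray = None  # units contributing per center


def spike_phases(train: SpikeTrain, phase: PhaseSeries) -> np.ndarray:
    """Phase of the band component at each spike time (nearest sample).

    Spikes inside the flagged filter-edge regions or outside the series
    extent are dropped. Returns an empty array for an empty train.
    """
    if train.n_spikes == 0:
        return np.empty(0)
    lo, hi = phase.valid_window()
    t = train.times
    keep = (t >= lo) & (t < hi)
    idx = np.round((t[keep] - phase.t0) * phase.fs).astype(int)
    idx = idx[(idx >= 0) & (idx < phase.n_samples)]
    return phase.phase[idx]


def resultant_vector(angles) -> tuple[float, float]:
    """Mean resultant vector of a set of angles: (length R, mean angle).

    R = |mean(e^{i*theta})| in [0, 1]; the mean angle is the argument of the
    mean vector. Raises on empty input.
    """
    angles = np.asarray(angles, float)
    if angles.size == 0:
        raise ValueError("resultant vector undefined for empty angle set")
    z = np.exp(1j * angles).mean()
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_null_r(n: int, alpha: float = 0.05) -> float:
    """Approximate (1-alpha) null quantile of R for n uniform phases.

    Large-sample Rayleigh approximation: R_crit = sqrt(-ln(alpha)/n).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    return float(np.sqrt(-np.log(alpha) / n))


def session_locking_profiles(lfp: LFPSignal, trains: list[SpikeTrain],
                             centers=DEFAULT_CENTERS, width: float = 3.0,
                             min_spikes: int = DEFAULT_MIN_SPIKES,
                             ) -> list[LockingProfile]:
    """Locking profiles for all units of one session.

    The sliding-band decomposition of the session LFP is computed once and
    shared across units.
    """
    centers = np.asarray(centers, float)
    bands = sliding_band_decompose(lfp, centers, width=width)
    profiles = []
    for train in trains:
        R = np.full(centers.size, np.nan)
        ang = np.full(centers.size, np.nan)
        n = np.zeros(centers.size, dtype=int)
        for k, ps in enumerate(bands):
            phases = spike_phases(train, ps)
            n[k] = phases.size
            if phases.size >= min_spikes:
                R[k], ang[k] = resultant_vector(phases)
        if not np.any(np.isfinite(R)):
            warnings.warn(f"unit {train.unit_id}: no center reached "
                          f"min_spikes={min_spikes}; empty profile",
                          stacklevel=2)
        profiles.append(LockingProfile(unit_id=train.unit_id, centers=centers,
                                       R=R, mean_angle=ang, n_spikes=n,
                                       group=train.group))
    return profiles


def locking_profile(train: SpikeTrain, lfp: LFPSignal,
                    centers=DEFAULT_CENTERS, width: float = 3.0,
                    min_spikes: int = DEFAULT_MIN_SPIKES) -> LockingProfile:
    """Locking profile of a single unit against its session LFP."""
    return session_locking_profiles(lfp, [train], centers=centers,
                                    width=width, min_spikes=min_spikes)[0]


def population_profile(profiles: list[LockingProfile],
                       group: str) -> PopulationProfile:
    """Mean and SEM of R across units, per center, for valid estimates only."""
    if not profiles:
        raise ValueError("need at least one locking profile")
    centers = profiles[0].centers
    for p in profiles:
        if not np.array_equal(p.centers, centers):
            raise ValueError("profiles must share a common center grid")
    mat = np.vstack([p.R for p in profiles])
    valid = np.isfinite(mat)
    n_valid = valid.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_R = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    sem = np.where(n_valid >= 1, sem, np.nan)
    return PopulationProfile(group=group, centers=centers, mean_R=mean_R,
                             sem_R=sem, n_units=len(profiles),
                             n_valid=n_valid)
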