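"""Welch power spectral density, band energies and the group band comparison.

The group contrast follows the recording-study design: per animal (session)
one LFP, per band one energy value (mean spectral power across the band's
bins), compared across treatment groups with the Mann-Whitney U test for
equal medians. Band definitions: delta 0.5-3.5, theta 4-7.5, alpha 8-12,
mu 10-12, beta 13-30, gamma 30-70 Hz (inclusive bounds; alpha and mu overlap
by construction and are both reported).

Welch parameters default to 2 s Hann windows with 90% overlap. A 2 s window
natively yields 0.5 Hz bins; adjacent native bin pairs are averaged onto a
1 Hz grid (the grid on which band membership is evaluated), and both grids
are kept on the PSD object.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .conditioning import LFPSignal


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"need 0 <= low < high, got ({self.low}, {self.high})")


#: The six canonical bands, inclusive bounds in Hz.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.5, 3.5),
    FrequencyBand("theta", 4.0, 7.5),
    FrequencyBand("alpha", 8.0, 12.0),
    FrequencyBand("mu", 10.0, 12.0),
    FrequencyBand("beta", 13.0, 30.0),
    FrequencyBand("gamma", 30.0, 70.0),
)


@dataclass
class PSD:
    """One-sided Welch power spectral density (uV^2/Hz).

    ``freqs``/``power`` are the 1 Hz aggregated grid used for band energies;
    ``native_freqs``/``native_power`` retain the native resolution
    (1/window_s Hz). Density normalization: the integral of power over
    frequency approximates the signal variance.
    """

    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    overlap_frac: float
    taper: str
    native_df: float
    native_freqs: np.ndarray = field(repr=False, default=None)
    native_power: np.ndarray = field(repr=False, default=None)

    def total_power(self, native: bool = True) -> float:
        """Integral of the PSD over frequency (~ signal variance)."""
        if native and self.native_freqs is not None:
            return float(np.trapezoid(self.native_power, self.native_freqs))
        return float(np.trapezoid(self.power, self.freqs))


@dataclass
class GroupComparison:
    """Per-band two-group comparison of session band energies."""

    band: FrequencyBand
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    U: float
    p_two_sided: float
    median_a: float
    median_b: float
    group_a: str = "vehicle"
    group_b: str = "pcp"


def welch_psd(signal: LFPSignal, window_s: float = 2.0,
              overlap_frac: float = 0.9, taper: str = "hann") -> PSD:
    """Welch PSD with tapered overlapping segments.

    Raises if the window is longer than the signal or the overlap fraction is
    not in [0, 1).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    nperseg = int(round(window_s * signal.fs))
    if nperseg > signal.n_samples:
        raise ValueError(
            f"window of {window_s} s ({nperseg} samples) exceeds signal "
            f"length {signal.n_samples}"
        )
    noverlap = int(round(overlap_frac * nperseg))
    f, p = sps.welch(signal.samples, fs=signal.fs, window=taper,
                     nperseg=nperseg, noverlap=noverlap,
                     detrend="constant", scaling="density")
    native_df = f[1] - f[0]
    # Aggregate native bins onto a 1 Hz grid when the native resolution
    # divides 1 Hz evenly (e.g. 0.5 Hz bins from a 2 s window -> pairs).
    n_agg = int(round(1.0 / native_df)) if native_df < 1.0 else 1
    if n_agg > 1 and abs(n_agg * native_df - 1.0) < 1e-9:
        n_keep = f.size // n_agg
        freqs = f[: n_keep * n_agg : n_agg]
        power = p[: n_keep * n_agg].reshape(n_keep, n_agg).mean(axis=1)
    else:
        freqs, power = f, p
    return PSD(freqs=freqs, power=power, window_s=window_s,
               overlap_frac=overlap_frac, taper=taper, native_df=native_df,
               native_freqs=f, native_power=p)


def band_energy(psd: PSD, band: FrequencyBand) -> float:
    """Mean spectral power across bins with low <= f <= high (inclusive)."""
    mask = (psd.freqs >= band.low) & (psd.freqs <= band.high)
    if not np.any(mask):
        raise ValueError(f"band {band.name} ({band.low}-{band.high} Hz) "
                         "contains no PSD bins")
    return float(psd.power[mask].mean())


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U test for equal medians; returns (U, two-sided p).

    U = min(U_a, U_b) with midrank tie handling. The p-value is exact (full
    enumeration of group assignments) when nA+nB <= 20 and there are no
    ties, otherwise a normal approximation with tie and continuity
    correction. Complete ties (zero rank variance) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n_ab = a.size * b.size
    if np.ptp(pooled) == 0:
        # every assignment yields the same rank sum
        return n_ab / 2.0, 1.0
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, n_ab - u_a)
    return u, float(min(res.pvalue, 1.0))


def compare_band_energies(sessions, bands=DEFAULT_BANDS,
                          groups: tuple[str, str] = ("vehicle", "pcp"),
                          window_s: float = 2.0, overlap_frac: float = 0.9,
                          taper: str = "hann") -> list[GroupComparison]:
    """Per-band group comparison of session band energies.

    Parameters
    ----------
    sessions : iterable of (group_label, LFPSignal)
        One LFP per session (animal); the session is the statistical unit.
    groups : (str, str)
        The two group labels, (a, b); typically ("vehicle", "pcp").

    Returns one :class:`GroupComparison` per band.
    """
    sessions = list(sessions)
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to compare groups")
    ga, gb = groups
    lfps_a = [lfp for g, lfp in sessions if g == ga]
    lfps_b = [lfp for g, lfp in sessions if g == gb]
    if not lfps_a or not lfps_b:
        raise ValueError(f"need at least one session per group {groups}")
    psds_a = [welch_psd(s, window_s, overlap_frac, taper) for s in lfps_a]
    psds_b = [welch_psd(s, window_s, overlap_frac, taper) for s in lfps_b]
    out = []
    for band in bands:
        ea = np.array([band_energy(p, band) for p in psds_a])
        eb = np.array([band_energy(p, band) for p in psds_b])
        u, p = mann_whitney_u(ea, eb)
        out.append(GroupComparison(
            band=band, group_a_values=ea, group_b_values=eb, U=u,
            p_two_sided=p, median_a=float(np.median(ea)),
            median_b=float(np.median(eb)), group_a=ga, group_b=gb,
        ))
    return out
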