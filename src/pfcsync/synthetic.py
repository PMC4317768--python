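"""Two-group synthetic sessions with known ground truth.

Emulates urethane-anesthesia-like recordings: each session carries one LFP
(1/f background + slow <1.5 Hz UP/DOWN oscillation + theta component whose
amplitude differs by group) and a population of low-rate units whose spikes
are inhomogeneous Poisson with von Mises phase modulation around the slow
oscillation, rate-gated during DOWN states. Unit pairs receive injected
near-coincident common-input spikes, at a higher rate in the "pcp" group.

Everything is deterministic under the config seed: per-session streams are
derived from ``SeedSequence([seed, session_index])``, so identical configs
produce bit-identical datasets.

Group defaults mirror the modeled study design: 8 vehicle vs 7 pcp sessions,
base rate 0.9 Hz with common-input injection lifting mean rates to roughly
0.95 (vehicle) and 1.15 Hz (pcp), theta at 6 Hz (4-7.5 Hz band) with the pcp
amplitude scaled by 0.6, and stronger slow-oscillation locking in the pcp
group (kappa 2.0 vs 0.5).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.special import i0

from .conditioning import LFPSignal, PhaseSeries
from .synchrony import StateSegments
from .units import SpikeTrain, Waveform


def _wrap(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, float)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic two-group experiment.

    Amplitudes in uV, rates in Hz, durations in seconds.
    ``theta_amp_pcp_factor`` scales the pcp theta amplitude relative to
    vehicle (power scales with amplitude squared). ``theta_amp_jitter`` and
    ``rate_jitter`` are log-normal sigmas of per-session amplitude and
    per-unit rate variation. ``updown_gate_ratio`` multiplies unit intensity
    inside DOWN half-cycles of the slow oscillation.
    """

    n_vehicle_sessions: int = 8
    n_pcp_sessions: int = 7
    duration: float = 120.0
    fs: float = 500.0
    background_exponent: float = 1.0
    background_sigma: float = 30.0
    slow_osc_freq: float = 1.0
    slow_osc_amp: float = 150.0
    theta_freq: float = 6.0
    theta_amp_vehicle: float = 40.0
    theta_amp_pcp_factor: float = 0.6
    theta_amp_jitter: float = 0.2
    base_rate: float = 0.9
    rate_jitter: float = 0.4
    kappa_vehicle: float = 0.5
    kappa_pcp: float = 2.0
    preferred_phase: float = 0.0
    updown_gate_ratio: float = 0.3
    n_units_per_session: int = 6
    coincidence_rate_vehicle: float = 0.01
    coincidence_rate_pcp: float = 0.05
    coincidence_jitter: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vehicle_sessions < 1 or self.n_pcp_sessions < 1:
            raise ValueError("need at least one session per group")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be strictly positive")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be strictly positive")
        if not 0 < self.theta_amp_pcp_factor <= 1:
            raise ValueError("theta_amp_pcp_factor must be in (0, 1]")
        if self.kappa_vehicle < 0 or self.kappa_pcp < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 <= self.updown_gate_ratio <= 1:
            raise ValueError("updown_gate_ratio must be in [0, 1]")
        if self.coincidence_jitter < 0:
            raise ValueError("coincidence_jitter must be >= 0")
        for name in ("background_sigma", "slow_osc_amp", "theta_amp_vehicle",
                     "theta_amp_jitter", "rate_jitter",
                     "coincidence_rate_vehicle", "coincidence_rate_pcp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.slow_osc_freq <= 0 or self.theta_freq <= 0:
            raise ValueError("oscillation frequencies must be positive")

    def theta_amp(self, group: str) -> float:
        _check_group(group)
        if group == "pcp":
            return self.theta_amp_vehicle * self.theta_amp_pcp_factor
        return self.theta_amp_vehicle

    def kappa(self, group: str) -> float:
        _check_group(group)
        return self.kappa_pcp if group == "pcp" else self.kappa_vehicle

    def coincidence_rate(self, group: str) -> float:
        _check_group(group)
        return (self.coincidence_rate_pcp if group == "pcp"
                else self.coincidence_rate_vehicle)


def _check_group(group: str) -> None:
    if group not in ("vehicle", "pcp"):
        raise ValueError(f"group must be 'vehicle' or 'pcp', got {group!r}")


@dataclass
class SessionData:
    """One synthetic session: LFP, spike trains, pairs and its ground truth."""

    session_id: str
    group: str
    lfp: LFPSignal
    trains: list[SpikeTrain]
    pairs: list[tuple[str, str]]
    waveforms: dict[str, Waveform]
    true_up_segments: StateSegments | None
    theta_amp: float
    slow_phase_offset: float
    pair_injected: dict[tuple[str, str], int]
    unit_rates: dict[str, float]


@dataclass
class SyntheticDataset:
    """All sessions of a synthetic experiment plus the generating config."""

    config: SyntheticConfig
    sessions: list[SessionData]

    def ground_truth(self) -> dict:
        return {
            "config": asdict(self.config),
            "sessions": [
                {
                    "session_id": s.session_id,
                    "group": s.group,
                    "theta_amp": s.theta_amp,
                    "slow_phase_offset": s.slow_phase_offset,
                    "unit_rates": dict(s.unit_rates),
                    "pair_injected": {f"{a}|{b}": int(c)
                                      for (a, b), c in s.pair_injected.items()},
                }
                for s in self.sessions
            ],
        }


# ---------------------------------------------------------------------------
# LFP generation


def _shaped_background(n: int, fs: float, exponent: float, sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian background via spectral shaping of white noise.

    White noise is shaped in the frequency domain with weights f^(-alpha/2)
    (random phases preserved); weights are normalized so the output variance
    equals sigma^2 in expectation. alpha = 0 reduces to white noise.
    """
    if sigma == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if exponent == 0:
        return sigma * white
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = f[1:] ** (-exponent / 2.0)
    # expected output variance = mean of w^2 over the full (two-sided) spectrum
    mult = np.full(f.size, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    mean_w2 = float(np.sum(w ** 2 * mult) / n)
    shaped = np.fft.irfft(np.fft.rfft(white) * w, n=n)
    return sigma * shaped / np.sqrt(mean_w2)


def _gen_lfp(config: SyntheticConfig, group: str, seed,
             theta_amp: float | None = None
             ) -> tuple[LFPSignal, dict]:
    _check_group(group)
    rng = np.random.default_rng(seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    amp = config.theta_amp(group) if theta_amp is None else theta_amp
    phi_slow = float(rng.uniform(-np.pi, np.pi))
    phi_theta = float(rng.uniform(-np.pi, np.pi))
    samples = _shaped_background(n, config.fs, config.background_exponent,
                                 config.background_sigma, rng)
    samples = samples + config.slow_osc_amp * np.cos(
        2 * np.pi * config.slow_osc_freq * t + phi_slow)
    samples = samples + amp * np.cos(
        2 * np.pi * config.theta_freq * t + phi_theta)
    lfp = LFPSignal(samples, config.fs, channel_id=f"{group}-lfp")
    truth = {"theta_amp": amp, "slow_phase_offset": phi_slow,
             "theta_phase_offset": phi_theta}
    return lfp, truth


def gen_lfp(config: SyntheticConfig, group: str, seed) -> LFPSignal:
    """Synthetic LFP: 1/f^alpha background + slow oscillation + theta.

    The theta amplitude is ``theta_amp_vehicle`` for the vehicle group and
    ``theta_amp_vehicle * theta_amp_pcp_factor`` for pcp. Deterministic
    under ``seed``.
    """
    return _gen_lfp(config, group, seed)[0]


def slow_phase_series(config: SyntheticConfig, phase_offset: float,
                      n_samples: int | None = None) -> PhaseSeries:
    """Analytic phase of the slow oscillation (ground truth, no filtering)."""
    n = (int(round(config.duration * config.fs))
         if n_samples is None else n_samples)
    t = np.arange(n) / config.fs
    phase = _wrap(2 * np.pi * config.slow_osc_freq * t + phase_offset)
    return PhaseSeries(phase=phase, fs=config.fs,
                       band=(0.0, 1.5 * config.slow_osc_freq), edge_s=0.0)


def true_up_segments(config: SyntheticConfig,
                     phase_offset: float) -> StateSegments:
    """Ground-truth UP/DOWN segments: UP where cos(slow phase) >= 0."""
    phase = slow_phase_series(config, phase_offset)
    mask = np.cos(phase.phase) >= 0
    return _mask_to_segments(mask, config.fs)


def _mask_to_segments(up_mask: np.ndarray, fs: float,
                      t0: float = 0.0) -> StateSegments:
    change = np.flatnonzero(np.diff(up_mask.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [up_mask.size]])
    intervals = [
        (t0 + b0 / fs, t0 + b1 / fs, "UP" if up_mask[b0] else "DOWN")
        for b0, b1 in zip(bounds[:-1], bounds[1:])
    ]
    return StateSegments(intervals)


# ---------------------------------------------------------------------------
# Spike generation


def _merge_close(times: np.ndarray, tol: float) -> np.ndarray:
    """Sorted times with successive values closer than ``tol`` merged."""
    if times.size == 0:
        return times
    keep = np.concatenate([[True], np.diff(times) >= tol])
    return times[keep]


def gen_locked_spikes(phase: PhaseSeries, base_rate: float, kappa: float,
                      preferred_phase: float = 0.0,
                      gate: StateSegments | None = None,
                      gate_ratio: float = 1.0, seed=0,
                      duration: float | None = None,
                      unit_id: str = "u0", session_id: str = "s0",
                      group: str = "") -> SpikeTrain:
    """Inhomogeneous Poisson train with von Mises phase modulation.

    Intensity lambda(t) = base_rate * exp(kappa*cos(phase(t) - mu)) / I0(kappa),
    multiplied by ``gate_ratio`` inside DOWN segments when a gate is given.
    The I0 normalization makes the time-averaged intensity equal base_rate
    when phase sweeps uniformly and no gate is applied. Sampled by thinning
    (rejection) against the ceiling base_rate * e^kappa / I0(kappa), which is
    exact. Exactly coincident accepted candidates are merged to keep spike
    times strictly increasing.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be strictly positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    T = phase.duration if duration is None else float(duration)
    if T > phase.duration + 1e-9:
        raise ValueError(
            f"phase series ({phase.duration:.3f} s) shorter than requested "
            f"duration ({T:.3f} s)"
        )
    rng = np.random.default_rng(seed)
    bessel = float(i0(kappa))
    lam_max = base_rate * np.exp(kappa) / bessel
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    idx = np.minimum(np.round(cand * phase.fs).astype(int),
                     phase.n_samples - 1)
    lam = base_rate * np.exp(kappa * np.cos(phase.phase[idx]
                                            - preferred_phase)) / bessel
    if gate is not None:
        from .synchrony import in_state
        down = in_state(cand, gate, "DOWN")
        lam = np.where(down, lam * gate_ratio, lam)
    accept = rng.uniform(0.0, lam_max, size=n_cand) < lam
    times = _merge_close(cand[accept], 1e-7)
    return SpikeTrain(times=times, unit_id=unit_id, duration=T,
                      session_id=session_id, group=group)


def gen_synchronous_pair(trainA_rate: float, trainB_rate: float,
                         coincidence_rate: float, jitter: float,
                         duration: float, seed=0,
                         min_isi: float = 1e-4,
                         session_id: str = "s0"
                         ) -> tuple[SpikeTrain, SpikeTrain, int]:
    """Two Poisson trains sharing a common jittered event stream.

    Each common event (Poisson at ``coincidence_rate``) inserts one spike in
    each train at the event time plus independent Gaussian jitter of SD
    ``jitter``. Returns (trainA, trainB, realized injected count); an event
    whose jittered spike lands outside [0, duration) in either train does
    not count as injected.
    """
    if trainA_rate < 0 or trainB_rate < 0 or coincidence_rate < 0:
        raise ValueError("rates must be >= 0")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    base_a = rng.uniform(0, duration, size=rng.poisson(trainA_rate * duration))
    base_b = rng.uniform(0, duration, size=rng.poisson(trainB_rate * duration))
    events = rng.uniform(0, duration, size=rng.poisson(coincidence_rate
                                                       * duration))
    add_a = events + rng.normal(0.0, jitter, size=events.size)
    add_b = events + rng.normal(0.0, jitter, size=events.size)
    ok = ((add_a >= 0) & (add_a < duration)
          & (add_b >= 0) & (add_b < duration))
    injected = int(np.sum(ok))
    ta = _merge_close(np.sort(np.concatenate([base_a, add_a[ok]])), min_isi)
    tb = _merge_close(np.sort(np.concatenate([base_b, add_b[ok]])), min_isi)
    a = SpikeTrain(ta, unit_id="pairA", duration=duration,
                   session_id=session_id)
    b = SpikeTrain(tb, unit_id="pairB", duration=duration,
                   session_id=session_id)
    return a, b, injected


def inject_coincidences(trainA: SpikeTrain, trainB: SpikeTrain, rate: float,
                        jitter: float, seed=0,
                        event_times: np.ndarray | None = None,
                        min_isi: float = 1e-4
                        ) -> tuple[SpikeTrain, SpikeTrain, int, np.ndarray]:
    """Add common-input spikes to an existing pair of trains.

    Events are Poisson at ``rate`` over the trains' duration unless explicit
    ``event_times`` are given (e.g. restricted to UP states). Each event adds
    one independently jittered spike to each train. Returns the new trains,
    the realized injected count and the event times used.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    duration = trainA.duration
    rng = np.random.default_rng(seed)
    if event_times is None:
        event_times = rng.uniform(0, duration,
                                  size=rng.poisson(rate * duration))
    event_times = np.asarray(event_times, float)
    add_a = event_times + rng.normal(0.0, jitter, size=event_times.size)
    add_b = event_times + rng.normal(0.0, jitter, size=event_times.size)
    ok = ((add_a >= 0) & (add_a < duration)
          & (add_b >= 0) & (add_b < duration))
    injected = int(np.sum(ok))
    ta = _merge_close(np.sort(np.concatenate([trainA.times, add_a[ok]])),
                      min_isi)
    tb = _merge_close(np.sort(np.concatenate([trainB.times, add_b[ok]])),
                      min_isi)
    a = replace(trainA, times=ta)
    b = replace(trainB, times=tb)
    return a, b, injected, event_times


# ---------------------------------------------------------------------------
# Waveform templates


def make_biphasic_waveform(initial_ms: float = 0.64, second_ms: float = 0.87,
                           amp_initial: float = -120.0,
                           amp_second: float = 45.0, fs: float = 40000.0,
                           pad_ms: float = 0.3) -> Waveform:
    """Biphasic template: a half-sine first phase followed by an
    opposite-polarity half-sine after-hyperpolarization, zero-padded."""
    n_pad = int(round(pad_ms * fs / 1000.0))
    n_total = int(round((2 * pad_ms + initial_ms + second_ms) * fs / 1000.0))
    t = np.arange(n_total) / fs * 1000.0  # ms
    t1, t2 = pad_ms, pad_ms + initial_ms
    t3 = t2 + second_ms
    s = np.zeros(n_total)
    in1 = (t >= t1) & (t < t2)
    s[in1] = amp_initial * np.sin(np.pi * (t[in1] - t1) / initial_ms)
    in2 = (t >= t2) & (t < t3)
    s[in2] = amp_second * np.sin(np.pi * (t[in2] - t2) / second_ms)
    if n_total < 16:
        s = np.concatenate([s, np.zeros(16 - n_total)])
    return Waveform(samples=s, fs=fs)


# ---------------------------------------------------------------------------
# Full experiment


def gen_experiment(config: SyntheticConfig) -> SyntheticDataset:
    """Generate all sessions of a two-group experiment.

    Session k draws its random stream from SeedSequence([config.seed, k]),
    so streams are independent yet fully reproducible. Each session holds
    one LFP, ``n_units_per_session`` von-Mises/gated units locked to the
    slow oscillation, and all within-session unit pairs with injected
    common-input coincidences.
    """
    groups = (["vehicle"] * config.n_vehicle_sessions
              + ["pcp"] * config.n_pcp_sessions)
    sessions: list[SessionData] = []
    for k, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        session_id = f"session_{k:03d}"
        amp = config.theta_amp(group)
        if config.theta_amp_jitter > 0:
            amp *= float(np.exp(config.theta_amp_jitter
                                * rng.standard_normal()))
        lfp, truth = _gen_lfp(config, group, rng, theta_amp=amp)
        phase = slow_phase_series(config, truth["slow_phase_offset"])
        gate = (true_up_segments(config, truth["slow_phase_offset"])
                if config.updown_gate_ratio < 1 else None)
        kappa = config.kappa(group)
        trains, waveforms, unit_rates = [], {}, {}
        for u in range(config.n_units_per_session):
            unit_id = f"{session_id}_u{u:02d}"
            rate = config.base_rate
            if config.rate_jitter > 0:
                rate *= float(np.exp(config.rate_jitter
                                     * rng.standard_normal()))
            train = gen_locked_spikes(
                phase, rate, kappa,
                preferred_phase=config.preferred_phase, gate=gate,
                gate_ratio=config.updown_gate_ratio, seed=rng,
                unit_id=unit_id, session_id=session_id, group=group)
            trains.append(train)
            unit_rates[unit_id] = rate
            d1 = max(0.25, 0.64 + 0.3036 * rng.standard_normal())
            d2 = max(0.30, 0.87 + 0.34 * rng.standard_normal())
            waveforms[unit_id] = make_biphasic_waveform(
                initial_ms=d1, second_ms=d2)
        pairs = list(combinations([t.unit_id for t in trains], 2))
        pair_injected: dict[tuple[str, str], int] = {}
        c_rate = config.coincidence_rate(group)
        by_id = {t.unit_id: i for i, t in enumerate(trains)}
        for a_id, b_id in pairs:
            ia, ib = by_id[a_id], by_id[b_id]
            trains[ia], trains[ib], n_inj, _ = inject_coincidences(
                trains[ia], trains[ib], c_rate, config.coincidence_jitter,
                seed=rng)
            pair_injected[(a_id, b_id)] = n_inj
        sessions.append(SessionData(
            session_id=session_id, group=group, lfp=lfp, trains=trains,
            pairs=pairs, waveforms=waveforms, true_up_segments=gate,
            theta_amp=amp, slow_phase_offset=truth["slow_phase_offset"],
            pair_injected=pair_injected, unit_rates=unit_rates))
    return SyntheticDataset(config=config, sessions=sessions)
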