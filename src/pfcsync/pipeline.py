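"""End-to-end orchestration: data I/O, run configuration and the pipeline.

Session directory layout (written by the simulator, read by every stage)::

    <root>/ground_truth.json          # only for synthetic data
    <root>/session_000/lfp.f32        # little-endian float32 samples
    <root>/session_000/lfp.json       # {fs_hz, n_samples, units, group, ...}
    <root>/session_000/spikes.csv     # unit_id,time_s
    <root>/session_000/waveforms.csv  # unit_id,fs_hz,sample_idx,uv (optional)

``run_pipeline`` executes the enabled stages in dependency order
(spectral, unit metrics, pair synchrony, phase locking), writes one CSV per
stage plus a machine-readable ``report.json``, and is deterministic under a
fixed config and seed (the report embeds a hash of its own payload).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import locking as lk
from . import spectral as sp
from . import synchrony as sy
from . import units as un
from .conditioning import LFPSignal
from .synthetic import SyntheticConfig, SyntheticDataset, gen_experiment
from .units import SpikeTrain, Waveform

log = logging.getLogger("pfcsync")


# ---------------------------------------------------------------------------
# Session I/O


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write a synthetic dataset to the session directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in dataset.sessions:
        d = out / s.session_id
        d.mkdir(exist_ok=True)
        (d / "lfp.f32").write_bytes(
            np.asarray(s.lfp.samples, dtype="<f4").tobytes())
        meta = {"fs_hz": s.lfp.fs, "n_samples": int(s.lfp.n_samples),
                "units": "uV", "group": s.group, "session_id": s.session_id,
                "t0": s.lfp.t0}
        (d / "lfp.json").write_text(json.dumps(meta, indent=1))
        rows = [(t.unit_id, time) for t in s.trains for time in t.times]
        pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
            d / "spikes.csv", index=False)
        wrows = [(uid, wf.fs, i, v)
                 for uid, wf in s.waveforms.items()
                 for i, v in enumerate(wf.samples)]
        if wrows:
            pd.DataFrame(
                wrows, columns=["unit_id", "fs_hz", "sample_idx", "uv"]
            ).to_csv(d / "waveforms.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth(), indent=1))


def read_session(session_dir) -> tuple[LFPSignal, list[SpikeTrain],
                                       dict[str, Waveform]]:
    """Read one session directory into validated objects.

    Hard errors: missing sidecar or ``fs_hz`` key, sample-count mismatch
    between ``lfp.f32`` and the sidecar, unsorted spike times (the error
    names the offending unit).
    """
    d = Path(session_dir)
    sidecar = d / "lfp.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"{sidecar}: sidecar lacks required key 'fs_hz'")
    samples = np.frombuffer((d / "lfp.f32").read_bytes(), dtype="<f4")
    n_expected = int(meta.get("n_samples", samples.size))
    if samples.size != n_expected:
        raise ValueError(
            f"{d / 'lfp.f32'}: {samples.size} samples but sidecar declares "
            f"{n_expected}")
    lfp = LFPSignal(samples.astype(float), float(meta["fs_hz"]),
                    t0=float(meta.get("t0", 0.0)),
                    channel_id=str(meta.get("session_id", d.name)))
    group = str(meta.get("group", ""))
    session_id = str(meta.get("session_id", d.name))
    duration = lfp.duration
    trains: list[SpikeTrain] = []
    spikes_csv = d / "spikes.csv"
    if spikes_csv.exists():
        df = pd.read_csv(spikes_csv)
        for uid, sub in df.groupby("unit_id", sort=True):
            trains.append(SpikeTrain(
                times=sub["time_s"].to_numpy(float), unit_id=str(uid),
                duration=duration, session_id=session_id, group=group))
    waveforms: dict[str, Waveform] = {}
    wf_csv = d / "waveforms.csv"
    if wf_csv.exists():
        wdf = pd.read_csv(wf_csv)
        for uid, sub in wdf.groupby("unit_id", sort=True):
            sub = sub.sort_values("sample_idx")
            waveforms[str(uid)] = Waveform(sub["uv"].to_numpy(float),
                                           float(sub["fs_hz"].iloc[0]))
    return lfp, trains, waveforms


def read_dataset(root) -> list[dict]:
    """Read every ``session_*`` directory under ``root``.

    Returns a list of dicts with keys session_id, group, lfp, trains,
    waveforms.
    """
    root = Path(root)
    dirs = sorted(p for p in root.iterdir()
                  if p.is_dir() and p.name.startswith("session_"))
    if not dirs:
        raise FileNotFoundError(f"no session_* directories under {root}")
    out = []
    for d in dirs:
        lfp, trains, waveforms = read_session(d)
        meta = json.loads((d / "lfp.json").read_text())
        out.append({"session_id": str(meta.get("session_id", d.name)),
                    "group": str(meta.get("group", "")), "lfp": lfp,
                    "trains": trains, "waveforms": waveforms})
    return out


def _dataset_to_records(dataset: SyntheticDataset) -> list[dict]:
    return [{"session_id": s.session_id, "group": s.group, "lfp": s.lfp,
             "trains": s.trains, "waveforms": s.waveforms}
            for s in dataset.sessions]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run.

    Either ``synthetic`` (a :class:`SyntheticConfig`) or ``input_dir`` must
    be set. The global ``seed`` drives both the simulator and the bootstrap.
    """

    output_dir: str = "pfcsync_run"
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    seed: int = 0
    # stage toggles
    run_spectral: bool = True
    run_units: bool = True
    run_xcorr: bool = True
    run_locking: bool = True
    run_updown: bool = False
    save_data: bool = False
    # spectral parameters
    window_s: float = 2.0
    overlap_frac: float = 0.9
    # correlogram parameters
    bin_width: float = 0.001
    max_lag: float = 0.5
    windows: tuple = sy.DEFAULT_WINDOWS
    normalization: str = "per_reference_spike"
    n_boot: int = 2000
    ci_level: float = 0.95
    # locking parameters
    center_lo: float = 2.0
    center_hi: float = 70.0
    center_step: float = 1.0
    band_width: float = 3.0
    min_spikes: int = lk.DEFAULT_MIN_SPIKES
    # unit screening
    max_rate: float = 3.0
    min_initial_ms: float = 0.3
    log_level: str = "INFO"

    def centers(self) -> np.ndarray:
        return np.arange(self.center_lo, self.center_hi + 1e-9,
                         self.center_step)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = list(self.windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if isinstance(syn, dict):
            d["synthetic"] = SyntheticConfig(**syn)
        if "windows" in d and d["windows"] is not None:
            d["windows"] = tuple(float(w) for w in d["windows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))


# ---------------------------------------------------------------------------
# Pipeline


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _payload_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunReport:
    """Machine-readable pipeline result with provenance."""

    config: dict
    seed: int
    band_comparisons: list = field(default_factory=list)
    unit_table: list = field(default_factory=list)
    synchrony: dict = field(default_factory=dict)
    updown_synchrony: dict = field(default_factory=dict)
    locking: dict = field(default_factory=dict)
    payload_hash: str = ""

    def payload(self) -> dict:
        return {"config": self.config, "seed": self.seed,
                "band_comparisons": self.band_comparisons,
                "unit_table": self.unit_table,
                "synchrony": self.synchrony,
                "updown_synchrony": self.updown_synchrony,
                "locking": self.locking}


def _stage_spectral(records, cfg: RunConfig, out: Path) -> list[dict]:
    comps = sp.compare_band_energies(
        [(r["group"], r["lfp"]) for r in records],
        window_s=cfg.window_s, overlap_frac=cfg.overlap_frac)
    rows = [{"band": c.band.name, "low_hz": c.band.low, "high_hz": c.band.high,
             "median_vehicle": c.median_a, "median_pcp": c.median_b,
             "U": c.U, "p": c.p_two_sided} for c in comps]
    pd.DataFrame(rows).to_csv(out / "band_comparison.csv", index=False)
    return rows


def _stage_units(records, cfg: RunConfig, out: Path) -> list[dict]:
    rows = []
    for r in records:
        for t in r["trains"]:
            rate = un.firing_rate(t)
            row = {"session_id": r["session_id"], "group": r["group"],
                   "unit_id": t.unit_id, "n_spikes": t.n_spikes,
                   "firing_rate_hz": rate, "initial_wave_ms": np.nan,
                   "second_phase_ms": np.nan, "putative_pyramidal": None}
            wf = r["waveforms"].get(t.unit_id)
            if wf is not None:
                try:
                    feats = un.waveform_features(wf)
                    row["initial_wave_ms"] = feats.initial_wave_duration
                    row["second_phase_ms"] = feats.second_phase_duration
                    row["putative_pyramidal"] = un.screen_putative_pyramidal(
                        rate, feats, cfg.max_rate, cfg.min_initial_ms)
                except ValueError:
                    pass
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "units.csv", index=False)
    return rows


def _session_pair_curves(r, cfg: RunConfig) -> list[sy.SynchronyCurve]:
    by_id = {t.unit_id: t for t in r["trains"]}
    ids = sorted(by_id)
    curves = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cc = sy.cross_correlogram(by_id[ids[i]], by_id[ids[j]],
                                      bin_width=cfg.bin_width,
                                      max_lag=cfg.max_lag,
                                      normalization=cfg.normalization)
            curves.append(sy.integrated_area(cc, cfg.windows,
                                             pair_id=f"{ids[i]}|{ids[j]}"))
    return curves


def _stage_xcorr(records, cfg: RunConfig, out: Path, seed: int) -> dict:
    group_curves: dict[str, list] = {}
    long_rows = []
    for r in records:
        for curve in _session_pair_curves(r, cfg):
            group_curves.setdefault(r["group"], []).append(curve)
            for w, a in zip(curve.window_half_lengths, curve.area):
                long_rows.append({"session_id": r["session_id"],
                                  "group": r["group"],
                                  "pair_id": curve.pair_id,
                                  "window_s": w, "area": a})
    pd.DataFrame(long_rows).to_csv(out / "synchrony_pairs.csv", index=False)
    result, grows = {}, []
    for gi, (group, curves) in enumerate(sorted(group_curves.items())):
        mean_curve, ci = sy.bootstrap_group_curves(
            curves, n_boot=cfg.n_boot, level=cfg.ci_level,
            seed=seed + 1000 + gi)
        result[group] = {"windows": mean_curve.window_half_lengths,
                         "mean_area": mean_curve.area, "ci_lower": ci.lower,
                         "ci_upper": ci.upper, "n_pairs": mean_curve.n_pairs}
        for k, w in enumerate(mean_curve.window_half_lengths):
            grows.append({"group": group, "window_s": w,
                          "mean_area": mean_curve.area[k],
                          "ci_lower": ci.lower[k], "ci_upper": ci.upper[k],
                          "n_pairs": mean_curve.n_pairs})
    pd.DataFrame(grows).to_csv(out / "synchrony_groups.csv", index=False)
    return result


def _stage_updown(records, cfg: RunConfig, out: Path) -> dict:
    rows, result = [], {}
    for r in records:
        segments = sy.segment_up_down(r["lfp"], r["trains"])
        by_id = {t.unit_id: t for t in r["trains"]}
        ids = sorted(by_id)
        for state in ("UP", "DOWN"):
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    curve = sy.state_restricted_curves(
                        by_id[ids[i]], by_id[ids[j]], segments, state,
                        bin_width=cfg.bin_width, max_lag=cfg.max_lag,
                        windows=cfg.windows,
                        normalization=cfg.normalization)
                    for w, a in zip(curve.window_half_lengths, curve.area):
                        rows.append({"session_id": r["session_id"],
                                     "group": r["group"], "state": state,
                                     "pair_id": curve.pair_id,
                                     "window_s": w, "area": a})
    df = pd.DataFrame(rows)
    df.to_csv(out / "synchrony_updown.csv", index=False)
    if len(df):
        g = (df.groupby(["group", "state", "window_s"])["area"]
               .mean().reset_index())
        for (group, state), sub in g.groupby(["group", "state"]):
            result.setdefault(group, {})[state] = {
                "windows": sub["window_s"].to_numpy(),
                "mean_area": sub["area"].to_numpy()}
    return result


def _stage_locking(records, cfg: RunConfig, out: Path) -> dict:
    centers = cfg.centers()
    by_group: dict[str, list] = {}
    rows = []
    for r in records:
        profiles = lk.session_locking_profiles(
            r["lfp"], r["trains"], centers=centers, width=cfg.band_width,
            min_spikes=cfg.min_spikes)
        for p in profiles:
            by_group.setdefault(r["group"], []).append(p)
            for k, c in enumerate(centers):
                rows.append({"session_id": r["session_id"],
                             "group": r["group"], "unit_id": p.unit_id,
                             "center_hz": c, "R": p.R[k],
                             "mean_angle": p.mean_angle[k],
                             "n_spikes": int(p.n_spikes[k])})
    pd.DataFrame(rows).to_csv(out / "locking_units.csv", index=False)
    result, prows = {}, []
    for group, profiles in sorted(by_group.items()):
        pop = lk.population_profile(profiles, group)
        result[group] = {"centers": pop.centers, "mean_R": pop.mean_R,
                         "sem_R": pop.sem_R, "n_units": pop.n_units}
        for k, c in enumerate(pop.centers):
            prows.append({"group": group, "center_hz": c,
                          "mean_R": pop.mean_R[k], "sem_R": pop.sem_R[k],
                          "n_valid": int(pop.n_valid[k])})
    pd.DataFrame(prows).to_csv(out / "locking_population.csv", index=False)
    return result


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all enabled stages and write artifacts to the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        log.info("stage=load input_dir=%s", config.input_dir)
        records = read_dataset(config.input_dir)
    elif config.synthetic is not None:
        syn = replace(config.synthetic, seed=config.seed)
        log.info("stage=simulate sessions=%d seed=%d",
                 syn.n_vehicle_sessions + syn.n_pcp_sessions, config.seed)
        dataset = gen_experiment(syn)
        if config.save_data:
            write_dataset(dataset, out / "data")
        records = _dataset_to_records(dataset)
    else:
        raise ValueError("RunConfig needs either synthetic or input_dir")

    report = RunReport(config=config.to_dict(), seed=config.seed)
    if config.run_spectral:
        log.info("stage=spectral sessions=%d", len(records))
        report.band_comparisons = _stage_spectral(records, config, out)
    if config.run_units:
        log.info("stage=units")
        report.unit_table = _stage_units(records, config, out)
    if config.run_xcorr:
        log.info("stage=xcorr")
        report.synchrony = _stage_xcorr(records, config, out, config.seed)
    if config.run_updown:
        log.info("stage=updown")
        report.updown_synchrony = _stage_updown(records, config, out)
    if config.run_locking:
        log.info("stage=locking")
        report.locking = _stage_locking(records, config, out)
    payload = report.payload()
    report.payload_hash = _payload_hash(payload)
    payload["payload_hash"] = report.payload_hash
    (out / "report.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True,
                   default=_json_default))
    log.info("run complete: %s hash=%s", out / "report.json",
             report.payload_hash[:12])
    return report
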