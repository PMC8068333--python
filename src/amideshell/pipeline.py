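"""End-to-end pipeline: windowed hydration statistics, Fourier and wavelet
frequencies, interaction records, zones and the energy-frequency
correlation, reported as one per-window table."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from amideshell import fragment_energy as fe
from amideshell import hbond, spectra, synthetic, wavelet
from amideshell.trajectory_io import Trajectory, load_topology, read_xyz

__all__ = ["PipelineError", "ConfigError", "validate_config", "run_pipeline", "Report"]

log = logging.getLogger("amideshell.pipeline")

_ALLOWED_KEYS = {
    "seed",
    "dt",
    "windows",
    "group",
    "peptide_bond",
    "input",
    "frequency_segments",
    "hydration_segments",
    "oscillator",
    "hydration",
    "criteria",
    "spectra",
    "wavelet",
    "records",
}

_DEFAULTS = {
    "seed": synthetic.DEFAULT_SEED,
    "dt": 0.5,
    "group": "C2=O2",
    "peptide_bond": None,
    "criteria": {"r_max": 2.5, "ang_max": 45.0},
    "spectra": {"depth": 4096, "pad_factor": 8, "window": "hann"},
    "wavelet": {"band": [1000.0, 2200.0], "scales": 512, "floor": 1500.0, "smooth": 25},
    "records": {"interval_fs": 50.0, "n_ranked": 4, "k": 3, "restarts": 50},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed (CLI exit code 1)."""


def validate_config(config: dict) -> dict:
    """Check keys and window layout; return config merged with defaults."""
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {}
    for k, v in _DEFAULTS.items():
        if isinstance(v, dict):
            merged = dict(v)
            merged.update(config.get(k) or {})
            cfg[k] = merged
        else:
            cfg[k] = config.get(k, v)
    for k in ("windows", "input", "frequency_segments", "hydration_segments",
              "oscillator", "hydration"):
        if k in config:
            cfg[k] = config[k]
    if "windows" not in cfg or not cfg["windows"]:
        raise ConfigError("config must define analysis windows")
    wins = sorted((float(a), float(b)) for a, b in cfg["windows"])
    for (a, b) in wins:
        if b <= a:
            raise ConfigError(f"window ({a}, {b}) is empty")
    for (_, e0), (s1, _) in zip(wins, wins[1:]):
        if s1 < e0 - 1e-9:
            raise ConfigError("windows overlap")
    cfg["windows"] = wins
    has_input = "input" in cfg and cfg["input"]
    has_synth = "hydration_segments" in cfg or "frequency_segments" in cfg
    if not has_input and not has_synth:
        raise ConfigError("config needs either 'input' files or synthetic schedules")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class Report:
    """Per-window results plus stage outputs."""

    window_rows: list[dict]
    full_row: dict
    correlation_w2: float | None
    zone_centers: list[float]
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = self.window_rows + [self.full_row]
        cols = list(rows[0].keys())
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write(
                    "\t".join(
                        f"{row[c]:.6g}" if isinstance(row[c], float) else str(row[c])
                        for c in cols
                    )
                    + "\n"
                )


def _build_trajectory(cfg: dict) -> Trajectory:
    if cfg.get("input"):
        inp = cfg["input"]
        top = load_topology(inp["topology"]) if "topology" in inp else None
        return read_xyz(inp["trajectory"], dt=cfg["dt"], topology=top)
    freq_sched = None
    if cfg.get("frequency_segments"):
        osc = cfg.get("oscillator") or {}
        freq_sched = synthetic.FrequencySchedule(
            segments=[tuple(s) for s in cfg["frequency_segments"]],
            amplitude=float(osc.get("amplitude", 0.03)),
            noise_sd=float(osc.get("noise_sd", 0.0)),
        )
    if cfg.get("hydration_segments"):
        hyd = cfg.get("hydration") or {}
        sched = synthetic.HydrationSchedule(
            segments=[tuple(s) for s in cfg["hydration_segments"]],
            **{k: float(v) for k, v in hyd.items()},
        )
        return synthetic.gen_hydration_trajectory(
            sched, dt=cfg["dt"], seed=cfg["seed"], freq_schedule=freq_sched
        )
    return synthetic.gen_oscillator_trajectory(freq_sched, dt=cfg["dt"], seed=cfg["seed"])


def _bond_length_series(traj: Trajectory, group: str) -> np.ndarray:
    idx = traj.topology.groups[group]
    c_idx = next(i for i in idx if traj.topology.elements[i] == "C")
    o_idx = next(i for i in idx if traj.topology.elements[i] == "O")
    return np.linalg.norm(traj.positions[:, o_idx] - traj.positions[:, c_idx], axis=1)


def _collect_records(
    traj: Trajectory, cfg: dict, backend: fe.EnergyBackend
) -> list[fe.InteractionRecord]:
    group = cfg["group"]
    rc = cfg["records"]
    every = max(1, int(round(rc["interval_fs"] / traj.dt)))
    pb = cfg.get("peptide_bond")
    if pb is None:
        gidx = traj.topology.groups[group]
        c_idx = next(i for i in gidx if traj.topology.elements[i] == "C")
        n_cands = [j for j in traj.topology.bonded_to(c_idx)
                   if traj.topology.elements[j] == "N"]
        pb = (c_idx, n_cands[0]) if n_cands else None
    records: list[fe.InteractionRecord] = []
    donors = hbond.group_donors(traj.topology, "N2-D2") \
        if "N2-D2" in traj.topology.groups else []
    for i in range(0, traj.n_frames, every):
        frame = traj.frame(i)
        if pb is not None:
            frag = fe.extract_capped_fragment(frame, traj.topology, tuple(pb), i)
        else:
            continue
        ranking = hbond.rank_waters(frame, group, n=rc["n_ranked"])
        for rank, rw in enumerate(ranking, start=1):
            wat = fe.water_geometry(frame, rw.oxygen, reference=frame.positions[
                traj.topology.groups[group][1]])
            e = fe.interaction_energy(frag, wat, backend)
            nd = np.inf
            for d, h in donors:
                nd = min(nd, float(np.min(np.linalg.norm(
                    wat.positions[1:] - frame.positions[h], axis=1))))
            records.append(
                fe.InteractionRecord(
                    frame=i, rank=rank, water_id=rw.oxygen, r=rw.r, theta=rw.theta,
                    e_int=e, nd_distance=nd if np.isfinite(nd) else -1.0,
                )
            )
    return records


def run_pipeline(config: dict) -> Report:
    """Run the full analysis described by ``config`` and return a Report.

    Deterministic given the config seed.  Stage failures raise
    :class:`PipelineError` naming the stage."""
    cfg = validate_config(config)
    chash = config_hash(cfg)
    from amideshell import __version__

    log.info("amideshell %s | config %s | seed %s", __version__, chash, cfg["seed"])

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ConfigError,):
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    traj = _stage("build_trajectory", _build_trajectory, cfg)
    group = cfg["group"]
    crit = hbond.HBondCriteria(cfg["criteria"]["r_max"], cfg["criteria"]["ang_max"])
    has_waters = "water" in traj.topology.groups

    series = _stage("hbond_series", hbond.hbond_count_series, traj, group, crit) \
        if has_waters else None

    bond = _stage("bond_series", _bond_length_series, traj, group)
    sp = cfg["spectra"]
    wv = cfg["wavelet"]
    band = (float(wv["band"][0]), float(wv["band"][1]))
    scales = wavelet.scales_for_band(band[0], band[1], int(wv["scales"]))

    def _wavelet_stage():
        inst = wavelet.ridge_frequencies(bond - bond.mean(), traj.dt, scales)
        return wavelet.filter_jumps(inst, floor=float(wv["floor"]),
                                    smooth_window=int(wv["smooth"]))

    inst = _stage("wavelet", _wavelet_stage)

    backend = fe.toy_energy_backend()
    records = _stage("records", _collect_records, traj, cfg, backend) if has_waters else []
    zones = None
    if len(records) >= cfg["records"]["k"]:
        try:
            zones = fe.kmeans_zones(records, k=cfg["records"]["k"], seed=cfg["seed"],
                                    restarts=cfg["records"]["restarts"])
        except ValueError:
            zones = None

    times = traj.times

    def _window_row(start: float, end: float, label: str) -> dict:
        idx = traj.window(start, end)
        row: dict = {"window": label, "start_fs": start, "end_fs": end}
        depth = min(int(sp["depth"]), len(idx))
        spec = spectra.power_spectrum(bond[idx], traj.dt, depth,
                                      int(sp["pad_factor"]), sp["window"])
        row["freq_cm"] = spectra.peak_position(spec, band)
        row["freq_resolution_cm"] = spec.resolution
        m = (times >= start - 1e-9) & (times < end - 1e-9) & inst.valid
        row["wavelet_mean_cm"] = float(inst.frequency[m].mean()) if m.any() else float("nan")
        if series is not None:
            mean, sd = series.window_stats(start, end)
            row["hbond_mean"] = mean
            row["hbond_sd"] = sd
        wrecs = [r for r in records if start - 1e-9 <= times[r.frame] < end - 1e-9]
        for rank in range(1, cfg["records"]["n_ranked"] + 1):
            sel = [r for r in wrecs if r.rank == rank]
            if sel:
                ee = np.array([r.e_int for r in sel])
                rr = np.array([r.r for r in sel])
                th = np.array([r.theta for r in sel])
                row[f"E_W{rank}_mean"] = float(ee.mean())
                row[f"E_W{rank}_sd"] = float(ee.std())
                row[f"r_W{rank}_mean"] = float(rr.mean())
                row[f"theta_W{rank}_mean"] = float(th.mean())
        if zones is not None and wrecs:
            sub_idx = [i for i, r in enumerate(records)
                       if start - 1e-9 <= times[r.frame] < end - 1e-9]
            names = zones.label_names()
            frames_w = sorted({records[i].frame for i in sub_idx})
            ns, nm = {}, {}
            for i in sub_idx:
                f = records[i].frame
                if names[i] in ("strong", "very_strong"):
                    ns[f] = ns.get(f, 0) + 1
                elif names[i] == "moderate":
                    nm[f] = nm.get(f, 0) + 1
            row["strong_occ_mean"] = float(np.mean([ns.get(f, 0) for f in frames_w]))
            row["moderate_occ_mean"] = float(np.mean([nm.get(f, 0) for f in frames_w]))
        return row

    rows = [
        _stage("window_table", _window_row, a, b, f"w{i + 1}")
        for i, (a, b) in enumerate(cfg["windows"])
    ]
    full = _stage("window_table", _window_row, float(times[0]),
                  float(times[-1] + traj.dt), "full")

    corr = None
    w2 = [r for r in records if r.rank == 2]
    if len(w2) >= 10:
        e2 = np.array([r.e_int for r in w2])
        f2 = inst.frequency[[r.frame for r in w2]]
        v2 = inst.valid[[r.frame for r in w2]]
        if v2.sum() >= 10 and e2[v2].std() > 0 and f2[v2].std() > 0:
            corr = float(np.corrcoef(e2[v2], f2[v2])[0, 1])

    keys = sorted({k for row in rows + [full] for k in row})
    for row in rows + [full]:
        for k in keys:
            row.setdefault(k, float("nan"))

    return Report(
        window_rows=rows,
        full_row=full,
        correlation_w2=corr,
        zone_centers=[] if zones is None else [float(c) for c in zones.centers],
        meta={"config_hash": chash, "seed": cfg["seed"], "n_frames": traj.n_frames},
    )
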