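"""Reproducible experiment runner: config schema, named experiments, output.

Each named experiment corresponds to one of the standard analyses of the
model (dose-response scans, calibrated single spikes, 0.5 Hz pulse trains
with the leaky-integrator fit, CaM-binding trains, the bistability check
and the CaMKII-free control).  ``run_experiment`` executes the pipeline
end to end and writes trajectories, metrics and fits together with full
provenance (effective config, config hash, rate-table version and
overrides, protocol JSON, seeds) so any output bundle can be reproduced
bit-identically from its own header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import species as sp
from .analysis import (delta_curve, ensemble_average, fit_leaky_integrator,
                       compute_metrics)
from .network import (dose_response_scan, equilibrate, generate_network,
                      initial_state, simulate_ode, w_cam_bound_k, w_total_p)
from .protocols import PulseProtocol, calibrate_pulse, make_pulse_train
from .rates import (ConfigurationError, VolumeContext, build_rule_set,
                    load_rate_table)
from . import ssa

logger = logging.getLogger("camkinet")

EXPERIMENTS = ("dose-response", "spike-sweep", "single-spike", "train-10",
               "train-30", "cam-binding-train", "bistability-check",
               "no-camkii-control")


@dataclasses.dataclass
class SimulationConfig:
    """Effective configuration of one experiment run.

    Concentrations in uM.  ``model`` selects the deterministic monomer
    network ("monomer_ode") or the stochastic holoenzyme simulator
    ("holoenzyme_ssa") where an experiment supports both.
    """

    model: str = "holoenzyme_ssa"
    camkii: float = 80.0
    cam: float = 30.0
    ng: float = 20.0
    pp1: float = 1.25
    volume_um3: float = 0.0156
    rate_overrides: Dict[str, float] = dataclasses.field(default_factory=dict)
    target_peak: float = 10.0
    baseline_ca: float = 0.1
    tau_r: float = 0.005
    tau_f: float = 0.015
    k_e: float = 1000.0
    frequency_hz: float = 0.5
    n_runs: int = 30
    base_seed: int = 42
    record_dt: float = 0.25
    burn_in: float = 3.0

    def __post_init__(self):
        if self.model not in ("monomer_ode", "holoenzyme_ssa"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        for f in ("camkii", "cam", "ng", "pp1"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if self.volume_um3 <= 0:
            raise ConfigurationError("volume must be positive")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")

    @property
    def volume(self) -> VolumeContext:
        return VolumeContext(self.volume_um3)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def parse_config(path) -> SimulationConfig:
    """Load a YAML config file, filling defaults and validating fields.

    An empty file yields the full-default configuration.  Unknown keys and
    schema violations raise a :class:`ConfigurationError` naming the
    offending field; rate overrides are logged as deviations from the
    tabulated constants.
    """
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    try:
        cfg = SimulationConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    for name in cfg.rate_overrides:
        logger.warning("rate override deviates from the tabulated value: %s",
                       name)
    logger.info("effective config: %s", json.dumps(cfg.to_dict(),
                                                   sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# shared pipeline pieces
# ---------------------------------------------------------------------------

def _monomer_network(cfg: SimulationConfig):
    rules = build_rule_set(include_monomer_dimerization=True)
    seeds = [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"), sp.PP1]
    return generate_network(rules, seeds, load_rate_table(cfg.rate_overrides))


def _totals(cfg: SimulationConfig, ng: Optional[float] = None) -> Dict:
    return {"CaM": cfg.cam, "Ng": cfg.ng if ng is None else ng,
            "K": cfg.camkii, "PP1": cfg.pp1}


def _calibrated_train(cfg: SimulationConfig, n_pulses: int, start: float,
                      network, steady):
    cal = calibrate_pulse(network, steady, target_peak=cfg.target_peak,
                          tau_r=cfg.tau_r, tau_f=cfg.tau_f, k_e=cfg.k_e)
    proto = make_pulse_train(n_pulses, cfg.frequency_hz,
                             amplitude=cal.amplitude, tau_r=cfg.tau_r,
                             tau_f=cfg.tau_f, k_e=cfg.k_e,
                             baseline=cfg.baseline_ca, start=start)
    return cal, proto


def _ssa_ensemble(cfg: SimulationConfig, proto: PulseProtocol, t_end: float):
    rates = load_rate_table(cfg.rate_overrides)
    return ssa.run_ensemble(
        rates, proto, n_runs=cfg.n_runs, base_seed=cfg.base_seed,
        cam_total=cfg.cam, ng_total=cfg.ng, camkii_total=cfg.camkii,
        pp1_total=cfg.pp1, t_end=t_end, record_dt=cfg.record_dt,
        burn_in=cfg.burn_in, volume=cfg.volume)


def _train_bundle(cfg: SimulationConfig, n_pulses: int, fit: bool):
    """Calibrate, run an SSA train ensemble, average and (optionally) fit."""
    start = 5.0
    net = _monomer_network(cfg)
    steady = equilibrate(net, _totals(cfg), target_free_ca=cfg.baseline_ca)
    cal, proto = _calibrated_train(cfg, n_pulses, start, net, steady)
    t_end = proto.onsets[-1] + (10.0 if n_pulses > 1 else 25.0)
    trs = _ssa_ensemble(cfg, proto, t_end)
    curves = [delta_curve(tr.t, tr.conc("n_p"), (0.0, start - cfg.record_dt),
                          start) for tr in trs]
    responders = [tr.meta["n_phospho_events"] > 0 for tr in trs]
    policy = "all" if n_pulses > 1 else "responders"
    summary = ensemble_average(curves, responders, policy)
    out = {
        "protocol": proto, "calibration": cal, "summary": summary,
        "trajectories": trs,
        "mean_metrics": compute_metrics(summary.mean),
    }
    if fit:
        out["fit"] = fit_leaky_integrator(
            summary.mean, window=(0.0, proto.onsets[-1] - start + 7.0))
    return out


# ---------------------------------------------------------------------------
# named experiments
# ---------------------------------------------------------------------------

def _exp_dose_response(cfg: SimulationConfig, camkii: Optional[float] = None):
    cam_grid = np.logspace(-1, 5, 25)
    net = _monomer_network(cfg)
    frames = []
    for with_ng in (False, True):
        frames.append(dose_response_scan(
            net, cam_grid, with_ng, total_ca=10.0,
            camkii=cfg.camkii if camkii is None else camkii,
            ng=cfg.ng if cfg.ng > 0 else 20.0, pp1=cfg.pp1))
    return {"dose_response": pd.concat(frames, ignore_index=True)}


def _exp_spike_sweep(cfg: SimulationConfig):
    targets = [1.0, 2.0, 5.0, 10.0, 20.0]
    net = _monomer_network(cfg)
    wp = net.weights(w_total_p)
    rows = []
    for ng in (0.0, 20.0):
        steady = equilibrate(net, _totals(cfg, ng=ng),
                             target_free_ca=cfg.baseline_ca)
        for target in targets:
            cal = calibrate_pulse(net, steady, target_peak=target,
                                  tau_r=cfg.tau_r, tau_f=cfg.tau_f,
                                  k_e=cfg.k_e)
            proto = cal.protocol(onsets=(1.0,), baseline=cfg.baseline_ca)
            t_grid = np.linspace(0.0, 30.0, 400)
            traj = simulate_ode(net, steady.y, proto, t_grid)
            p = traj.observable(wp)
            rows.append({"ng": ng, "target_peak": target,
                         "achieved_peak": cal.achieved_peak,
                         "delta_peak_p": float(np.max(p) - p[0])})
    return {"spike_sweep": pd.DataFrame(rows)}


def _exp_single_spike(cfg: SimulationConfig):
    if cfg.model == "holoenzyme_ssa":
        return _train_bundle(cfg, n_pulses=1, fit=False)
    net = _monomer_network(cfg)
    steady = equilibrate(net, _totals(cfg), target_free_ca=cfg.baseline_ca)
    cal, proto = _calibrated_train(cfg, 1, 5.0, net, steady)
    t_grid = np.concatenate([np.linspace(0, 6.0, 200),
                             np.linspace(6.1, 400.0, 800)])
    traj = simulate_ode(net, steady.y, proto, t_grid)
    p = traj.observable(net.weights(w_total_p))
    curve = delta_curve(traj.t, p, (0.0, 4.9), 5.0)
    return {"protocol": proto, "calibration": cal, "trajectory": traj,
            "metrics": compute_metrics(curve)}


def _exp_train(cfg: SimulationConfig, n_pulses: int):
    return _train_bundle(cfg, n_pulses=n_pulses, fit=(n_pulses >= 30))


def _exp_cam_binding_train(cfg: SimulationConfig):
    cfg = dataclasses.replace(cfg, cam=50.0)
    start = 5.0
    net = _monomer_network(cfg)
    steady = equilibrate(net, _totals(cfg), target_free_ca=cfg.baseline_ca)
    cal, proto = _calibrated_train(cfg, 30, start, net, steady)
    trs = _ssa_ensemble(cfg, proto, proto.onsets[-1] + 5.0)
    # per-pulse peaks of CaM-bound and CaM-bound-unphosphorylated subunits
    rows = []
    for tr in trs:
        for j, onset in enumerate(proto.onsets):
            m = (tr.t >= onset) & (tr.t < onset + 1.0 / cfg.frequency_hz)
            rows.append({"run_seed": tr.meta["seed"], "pulse": j,
                         "peak_cam_bound": float(tr.conc("n_cam_bound")[m].max()),
                         "peak_cam_bound_u": float(tr.conc("n_cam_bound_u")[m].max())})
    return {"protocol": proto, "calibration": cal, "trajectories": trs,
            "pulse_peaks": pd.DataFrame(rows)}


def _exp_bistability(cfg: SimulationConfig):
    """All-phosphorylated start at resting calcium must relax to baseline."""
    results = {}
    net = _monomer_network(cfg)
    steady = equilibrate(net, _totals(cfg), target_free_ca=cfg.baseline_ca)
    y0 = initial_state(net, {**_totals(cfg), "K": 0.0}, cfg.baseline_ca)
    y0[net.index[sp.k("P")]] = cfg.camkii  # every monomer phosphorylated
    proto = PulseProtocol(mode="clamp", clamp_value=cfg.baseline_ca)
    t_grid = np.linspace(0.0, 2000.0, 500)
    traj = simulate_ode(net, y0, proto, t_grid)
    p = traj.observable(net.weights(w_total_p))
    p_base = float(net.weights(w_total_p) @ steady.y)
    results["ode"] = {"p_initial": float(p[0]), "p_final": float(p[-1]),
                      "p_baseline": p_base,
                      "decayed": bool(p[-1] < p_base + 0.05 * cfg.camkii)}
    if cfg.model == "holoenzyme_ssa":
        rates = load_rate_table(cfg.rate_overrides)
        st = ssa.build_initial_state(
            rates, cfg.cam, cfg.ng, cfg.camkii, cfg.pp1, volume=cfg.volume,
            baseline_ca=cfg.baseline_ca, seed=cfg.base_seed,
            burn_in=cfg.burn_in, k_e=cfg.k_e)
        for u in range(st.n_sub):   # phosphorylate every subunit
            if not st.sub_p[u]:
                st.sub_p[u] = 1
                st.np_count += 1
                ci = st.sub_cam[u]
                if ci >= 0:
                    st._cam_move(ci, 18 + 3 * st.cam_a[ci] + st.cam_b[ci])
                    st.ncbu -= 1
                else:
                    st._lrem(st.slotU, st.sub_slot_pos, u)
                    st._ladd(st.slotP, st.sub_slot_pos, u)
                st._ladd(st.pfree, st.sub_pp1_pos, u)
        for u in range(st.n_sub):
            st._update_elig(u)
        base_proto = PulseProtocol(baseline=cfg.baseline_ca, onsets=(),
                                   k_e=cfg.k_e)
        tr = ssa.ssa_run(st, base_proto, t_end=400.0, record_dt=1.0,
                         seed=cfg.base_seed + 1)
        results["ssa"] = {
            "p_initial_uM": float(tr.conc("n_p")[0]),
            "p_final_uM": float(tr.conc("n_p")[-1]),
            "decayed": bool(tr.conc("n_p")[-1] < 0.05 * cfg.camkii)}
    return results


def run_experiment(name: str, cfg: SimulationConfig,
                   out_dir: Optional[str] = None) -> Dict:
    """Run a named experiment end to end; optionally write an output bundle."""
    if name not in EXPERIMENTS:
        raise ConfigurationError(
            f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    logger.info("running experiment %s (config %s)", name, cfg.digest())
    if name == "dose-response":
        out = _exp_dose_response(cfg)
    elif name == "no-camkii-control":
        out = _exp_dose_response(cfg, camkii=0.0)
    elif name == "spike-sweep":
        out = _exp_spike_sweep(cfg)
    elif name == "single-spike":
        out = _exp_single_spike(cfg)
    elif name == "train-10":
        out = _exp_train(cfg, 10)
    elif name == "train-30":
        out = _exp_train(cfg, 30)
    elif name == "cam-binding-train":
        out = _exp_cam_binding_train(cfg)
    else:
        out = _exp_bistability(cfg)
    if out_dir is not None:
        write_bundle(name, cfg, out, out_dir)
    return out


# ---------------------------------------------------------------------------
# output bundle
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_bundle(name: str, cfg: SimulationConfig, out: Dict, out_dir):
    """Write an experiment's outputs under ``out_dir/<name>-<confighash>``."""
    root = pathlib.Path(out_dir) / f"{name}-{cfg.digest()}"
    root.mkdir(parents=True, exist_ok=True)
    rates = load_rate_table(cfg.rate_overrides)
    prov = {"experiment": name, "config": cfg.to_dict(),
            "config_hash": cfg.digest(),
            "rate_overrides": rates.overrides}
    proto = out.get("protocol")
    if proto is not None:
        prov["protocol"] = proto.to_dict()
    (root / "provenance.json").write_text(json.dumps(prov, indent=2))

    scalars = {}
    for key, val in out.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(root / f"{key}.csv", index=False)
        elif key == "trajectories":
            frames = [tr.to_frame() for tr in val]
            pd.concat(frames, ignore_index=True).to_csv(
                root / "trajectories.csv", index=False)
            scalars["runs"] = [
                {"seed": tr.meta["seed"],
                 "peak_free_ca_uM": tr.meta["peak_free_ca_uM"],
                 "n_phospho_events": tr.meta["n_phospho_events"]}
                for tr in val]
        elif key == "trajectory":
            val.to_frame({"total_p": w_total_p,
                          "cam_bound": w_cam_bound_k}).to_csv(
                root / "trajectory.csv", index=False)
        elif key == "summary":
            mean = val.mean
            pd.DataFrame({"time": mean.t, "mean_delta_p": mean.x}).to_csv(
                root / "mean_delta_curve.csv", index=False)
            scalars["ensemble"] = {
                "n_runs": val.n_runs, "n_responders": val.n_responders,
                "responder_fraction": val.responder_fraction,
                "responder_ci": list(val.responder_ci),
                "policy": val.policy}
        elif key == "protocol":
            (root / "protocol.json").write_text(val.to_json())
        else:
            scalars[key] = _jsonable(val)
    (root / "results.json").write_text(json.dumps(_jsonable(scalars),
                                                  indent=2, default=str))
    logger.info("wrote %s", root)
    return root
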