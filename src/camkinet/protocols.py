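"""Synthetic calcium input protocols: clamps, single spikes and trains.

Free calcium in a spine sits near 100 nM at rest; synaptic stimulation
produces brief transients that peak around 10 uM and decay back to near
baseline within ~100 ms.  The generator reproduces that structure
phenomenologically: each pulse injects calcium with the alpha-like rate
envelope ``A * ((t - t0)/tau_r) * exp(-(t - t0)/tau_f)`` and free calcium
is removed by first-order efflux ``k_e * [Ca]``, with a constant baseline
influx ``k_e * baseline`` maintaining the resting level.  No explicit
buffer molecules are modeled; the CaM/Ng/CaMKII species themselves provide
the (leaky) buffering, so the amplitude ``A`` is calibrated per condition
against the deterministic model to hit the requested free-calcium peak.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .rates import ConfigurationError

__all__ = [
    "PulseProtocol", "CalibrationResult", "make_pulse_train",
    "pulse_shape_peak", "calibrate_pulse", "amplitude_sweep",
]


@dataclasses.dataclass(frozen=True)
class PulseProtocol:
    """A calcium input program.

    In ``pulse`` mode calcium is dynamic: the influx rate at time ``t`` is
    the baseline term plus the sum of the pulse envelopes of all onsets at
    or before ``t``; efflux is first order with rate ``k_e``.  In ``clamp``
    mode free calcium is held constant at ``clamp_value`` and the pulse
    fields are unused (onsets must be empty).

    Units: concentrations uM, times s, ``amplitude`` uM/s.
    """

    baseline: float = 0.1
    onsets: Tuple[float, ...] = ()
    amplitude: float = 0.0
    tau_r: float = 0.005
    tau_f: float = 0.015
    k_e: float = 1000.0
    mode: str = "pulse"
    clamp_value: float = 0.1

    def __post_init__(self):
        if self.mode not in ("pulse", "clamp"):
            raise ConfigurationError(f"unknown protocol mode {self.mode!r}")
        if self.tau_r <= 0 or self.tau_f <= 0:
            raise ConfigurationError("tau_r and tau_f must be positive")
        if self.mode == "clamp" and self.onsets:
            raise ConfigurationError("clamp protocols carry no pulses")
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ConfigurationError("pulse onsets must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def baseline_influx(self) -> float:
        """Constant influx (uM/s) balancing efflux at the resting level."""
        return self.k_e * self.baseline

    def pulse_envelope(self, t, onset: float):
        """Influx rate contribution (uM/s) of one pulse at time ``t``."""
        dt = np.asarray(t, dtype=float) - onset
        out = np.where(dt > 0,
                       self.amplitude * (dt / self.tau_r)
                       * np.exp(-np.minimum(dt, 700 * self.tau_f) / self.tau_f),
                       0.0)
        return out if out.shape else float(out)

    def total_influx(self, t) -> float:
        """Baseline plus all pulse envelopes (uM/s) at time ``t``."""
        tot = self.baseline_influx
        for o in self.onsets:
            tot = tot + self.pulse_envelope(t, o)
        return tot

    def injected_per_pulse(self) -> float:
        """Analytic integral of one pulse envelope: ``A * tau_f^2 / tau_r``."""
        return self.amplitude * self.tau_f ** 2 / self.tau_r

    # serialization ------------------------------------------------------
    def to_dict(self) -> Dict:
        return {"baseline": self.baseline, "onsets": list(self.onsets),
                "amplitude": self.amplitude, "tau_r": self.tau_r,
                "tau_f": self.tau_f, "k_e": self.k_e, "mode": self.mode,
                "clamp_value": self.clamp_value}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: Dict) -> "PulseProtocol":
        d = dict(d)
        d["onsets"] = tuple(d.get("onsets", ()))
        return cls(**d)


def pulse_shape_peak(amplitude: float, tau_r: float,
                     tau_f: float) -> Tuple[float, float]:
    """Analytic maximum of the influx envelope.

    ``d/dt [A (t/tau_r) e^(-t/tau_f)] = 0`` at ``t = tau_f``, where the
    rate is ``A (tau_f/tau_r) e^(-1)``.
    """
    if amplitude <= 0 or tau_r <= 0 or tau_f <= 0:
        raise ConfigurationError("pulse parameters must be positive")
    return tau_f, amplitude * (tau_f / tau_r) * math.exp(-1.0)


def make_pulse_train(n_pulses: int, frequency_hz: float,
                     amplitude: float = 0.0, tau_r: float = 0.005,
                     tau_f: float = 0.015, k_e: float = 1000.0,
                     baseline: float = 0.1,
                     start: float = 0.0) -> PulseProtocol:
    """Protocol with ``n_pulses`` onsets at ``start + k/frequency``.

    Overlapping pulse envelopes simply sum.  A single pulse gives the
    single-spike protocol; 10 or 30 pulses at 0.5 Hz give the standard
    train stimuli.
    """
    if n_pulses < 1:
        raise ConfigurationError("need at least one pulse")
    if frequency_hz <= 0:
        raise ConfigurationError("frequency must be positive")
    onsets = tuple(start + i / frequency_hz for i in range(n_pulses))
    return PulseProtocol(baseline=baseline, onsets=onsets,
                         amplitude=amplitude, tau_r=tau_r, tau_f=tau_f,
                         k_e=k_e, mode="pulse")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationResult:
    """Outcome of tuning the influx amplitude to a target free-Ca peak."""

    amplitude: float
    tau_r: float
    tau_f: float
    k_e: float
    achieved_peak: float           # deterministic peak free Ca, uM
    return_time: Optional[float]   # time to fall within 2x baseline, s
    decay_ok: bool
    target_peak: float

    def protocol(self, onsets: Sequence[float],
                 baseline: float = 0.1) -> PulseProtocol:
        return PulseProtocol(baseline=baseline, onsets=tuple(onsets),
                             amplitude=self.amplitude, tau_r=self.tau_r,
                             tau_f=self.tau_f, k_e=self.k_e, mode="pulse")


def _deterministic_peak(network, steady_y, amplitude, tau_r, tau_f, k_e,
                        baseline, horizon=0.6, n_eval=1200):
    from .network import simulate_ode
    proto = PulseProtocol(baseline=baseline, onsets=(0.0,),
                          amplitude=amplitude, tau_r=tau_r, tau_f=tau_f,
                          k_e=k_e, mode="pulse")
    t_grid = np.linspace(0.0, horizon, n_eval)
    traj = simulate_ode(network, steady_y, proto, t_grid)
    ca = traj.concentration(("Ca",))
    return traj.t, ca


def calibrate_pulse(network, steady, target_peak: float = 10.0,
                    decay_window: float = 0.1, tau_r: float = 0.005,
                    tau_f: float = 0.015, k_e: float = 1000.0,
                    tolerance: float = 0.02,
                    max_iter: int = 60) -> CalibrationResult:
    """Bisect the influx amplitude to hit a free-calcium peak.

    The calibration runs on the deterministic model *in the condition's
    full buffering context* (CaM, Ng, CaMKII as configured in ``steady``),
    since bound calcium shapes the free-calcium transient; the resulting
    amplitude is therefore per-condition.  The achieved peak must lie
    within ``tolerance`` (relative) of ``target_peak``; whether free
    calcium re-enters twice-baseline within ``decay_window`` is measured
    and reported alongside.
    """
    baseline = steady.free_ca
    if target_peak < baseline:
        raise ConfigurationError("target peak below baseline")
    if target_peak <= baseline * 1.001:
        return CalibrationResult(0.0, tau_r, tau_f, k_e, baseline, 0.0, True,
                                 target_peak)

    def peak_of(a):
        t, ca = _deterministic_peak(network, steady.y, a, tau_r, tau_f, k_e,
                                    baseline)
        return float(np.max(ca)), t, ca

    # bracket the target
    lo, hi = 0.0, max(2.0 * k_e * target_peak, 100.0)
    p_hi, _, _ = peak_of(hi)
    for _ in range(20):
        if p_hi >= target_peak:
            break
        hi *= 2.0
        p_hi, _, _ = peak_of(hi)
    else:
        raise RuntimeError(
            f"calibration failed: amplitude {hi:g} uM/s reaches only "
            f"{p_hi:.3g} uM (target {target_peak} uM)")

    best = (hi, p_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid, _, _ = peak_of(mid)
        if abs(p_mid - target_peak) < abs(best[1] - target_peak):
            best = (mid, p_mid)
        if abs(p_mid - target_peak) <= tolerance * target_peak:
            best = (mid, p_mid)
            break
        if p_mid < target_peak:
            lo = mid
        else:
            hi = mid

    amplitude, achieved = best
    if abs(achieved - target_peak) > tolerance * target_peak:
        raise RuntimeError(
            f"calibration did not converge: best amplitude {amplitude:g} "
            f"gives peak {achieved:.4g} uM (target {target_peak} uM)")

    _, t, ca = peak_of(amplitude)
    i_peak = int(np.argmax(ca))
    after = ca[i_peak:] <= 2.0 * baseline
    if np.any(after):
        return_time = float(t[i_peak + int(np.argmax(after))])
    else:
        return_time = None
    decay_ok = return_time is not None and return_time <= decay_window
    return CalibrationResult(amplitude, tau_r, tau_f, k_e, achieved,
                             return_time, decay_ok, target_peak)


def amplitude_sweep(network, steady, targets: Sequence[float],
                    **calib_kwargs) -> List[CalibrationResult]:
    """One calibrated single-pulse protocol per target free-Ca peak."""
    if any(t <= 0 for t in targets):
        raise ConfigurationError("target peaks must be positive")
    return [calibrate_pulse(network, steady, target_peak=t, **calib_kwargs)
            for t in targets]
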