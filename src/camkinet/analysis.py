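"""Response metrics, responder statistics and the leaky-integrator fit.

Turns phosphorylation time courses into the quantities used to compare
conditions: baseline-subtracted curves, area under the curve, peak height
and time, the post-peak lifetime (time to fall to 10% of the peak), the
fraction of stochastic runs that respond at all, the 10-pulse:1-pulse
ratios that expose sub-linear signal integration, and the fit of the
train response to the leaky-integrator form ``x(t) = k (1 - e^(-a t))``
(capacity ``k``, integration/leak rate ``a``).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = ["DeltaCurve", "ResponseMetrics", "LeakyFit", "EnsembleSummary",
           "delta_curve", "compute_metrics", "ensemble_average",
           "fit_leaky_integrator", "pulse_ratio", "wilson_interval"]


@dataclasses.dataclass
class DeltaCurve:
    """Baseline-subtracted observable, time re-referenced to stimulus onset."""

    t: np.ndarray          # seconds from first pulse onset
    x: np.ndarray          # observable minus baseline mean
    baseline: float        # subtracted baseline level


@dataclasses.dataclass
class ResponseMetrics:
    """Scalar response descriptors of one baseline-subtracted curve."""

    delta_auc: float               # uM*s, trapezoid over the record
    delta_peak: float              # uM
    t_peak: Optional[float]        # s from first onset
    lifetime: Optional[float]      # s from peak to 10% of peak
    lifetime_censored: bool        # 10% level not reached within the record
    responder: bool


@dataclasses.dataclass
class LeakyFit:
    """Saturating-exponential fit ``x = k (1 - e^(-a t))``."""

    k: float
    a: float
    r_squared: float
    covariance: np.ndarray
    k_stderr: float
    a_stderr: float


@dataclasses.dataclass
class EnsembleSummary:
    mean: DeltaCurve
    per_run: List[ResponseMetrics]
    n_runs: int
    n_responders: int
    responder_fraction: float
    responder_ci: Tuple[float, float]
    policy: str


def delta_curve(t: np.ndarray, x: np.ndarray,
                baseline_window: Tuple[float, float],
                onset: float) -> DeltaCurve:
    """Subtract the mean over ``baseline_window`` and re-reference time.

    The baseline window must precede the first pulse onset; the returned
    curve has time zero at ``onset``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    lo, hi = baseline_window
    if hi > onset + 1e-12:
        raise ValueError("baseline window must precede the stimulus onset")
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError("baseline window contains no samples")
    base = float(np.mean(x[mask]))
    return DeltaCurve(t=t - onset, x=x - base, baseline=base)


def compute_metrics(curve: DeltaCurve,
                    window: Optional[Tuple[float, float]] = None,
                    responder_threshold: float = 0.0) -> ResponseMetrics:
    """AUC, peak, peak time and lifetime of a baseline-subtracted curve.

    The lifetime is the time from the peak until the curve first falls to
    10% of the peak, located by linear interpolation between samples; if
    the 10% level is not reached within the record the lifetime is
    censored at the record end.
    """
    t, x = curve.t, curve.x
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, x = t[m], x[m]
    if len(t) < 2:
        raise ValueError("curve too short")
    auc = float(np.trapezoid(x, t))
    i_peak = int(np.argmax(x))
    peak = float(x[i_peak])
    if peak <= responder_threshold or peak <= 0:
        return ResponseMetrics(auc, max(peak, 0.0), None, None, False, False)
    level = 0.1 * peak
    lifetime = None
    censored = True
    below = np.nonzero(x[i_peak:] <= level)[0]
    if below.size:
        j = i_peak + below[0]
        if j == i_peak:
            t_cross = t[j]
        else:
            f = (x[j - 1] - level) / (x[j - 1] - x[j])
            t_cross = t[j - 1] + f * (t[j] - t[j - 1])
        lifetime = float(t_cross - t[i_peak])
        censored = False
    else:
        lifetime = float(t[-1] - t[i_peak])
    return ResponseMetrics(auc, peak, float(t[i_peak]), lifetime,
                           censored, True)


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    p = k / n
    den = 1 + z * z / n
    center = (p + z * z / (2 * n)) / den
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / den
    return (max(0.0, center - half), min(1.0, center + half))


def ensemble_average(curves: Sequence[DeltaCurve],
                     responders: Sequence[bool],
                     policy: str = "all") -> EnsembleSummary:
    """Mean curve and per-run metrics of a stochastic ensemble.

    ``policy`` selects which runs enter the mean curve: ``"all"`` (the
    convention for pulse-train analyses) or ``"responders"`` (the
    convention for single-spike analyses, where runs without any
    phosphorylation event are excluded).  The responder fraction and its
    Wilson 95% interval are always reported over all runs.
    """
    if not curves:
        raise ValueError("need at least one trajectory")
    if policy not in ("all", "responders"):
        raise ValueError(f"unknown responder policy {policy!r}")
    responders = list(responders)
    n = len(curves)
    n_resp = sum(bool(r) for r in responders)
    chosen = (curves if policy == "all"
              else [c for c, r in zip(curves, responders) if r])
    if not chosen:
        raise ValueError(
            f"responder-only averaging with zero responders ({n} runs)")
    t0 = chosen[0].t
    for c in chosen[1:]:
        if len(c.t) != len(t0) or not np.allclose(c.t, t0):
            raise ValueError("ensemble members must share a time grid")
    mean = DeltaCurve(t=t0.copy(),
                      x=np.mean([c.x for c in chosen], axis=0),
                      baseline=float(np.mean([c.baseline for c in chosen])))
    per_run = [compute_metrics(c) for c in curves]
    return EnsembleSummary(mean=mean, per_run=per_run, n_runs=n,
                           n_responders=n_resp,
                           responder_fraction=n_resp / n,
                           responder_ci=wilson_interval(n_resp, n),
                           policy=policy)


def fit_leaky_integrator(curve: DeltaCurve,
                         window: Optional[Tuple[float, float]] = None
                         ) -> LeakyFit:
    """Nonlinear least squares of ``x(t) = k (1 - e^(-a t))``.

    Initialized from the data: ``k0`` is the final value and ``a0`` the
    reciprocal of the time to reach half of it.  ``R^2`` is computed on
    the fitted grid with uniform weights.  A non-positive leak rate at the
    optimum is reported as a fit failure.
    """
    t, x = curve.t, curve.x
    m = t >= 0
    if window is not None:
        m &= (t >= window[0]) & (t <= window[1])
    t, x = t[m], x[m]
    if len(t) < 3:
        raise ValueError("too few samples to fit")

    k0 = float(x[-1]) if x[-1] > 0 else max(float(np.max(x)), 1e-6)
    above = np.nonzero(x >= 0.5 * k0)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else \
        max(t[-1] / 2, 1e-3)
    a0 = 1.0 / t_half

    def model(tv, k, a):
        return k * (1.0 - np.exp(-a * tv))

    popt, pcov = scipy.optimize.curve_fit(
        model, t, x, p0=(k0, a0), maxfev=20000)
    k, a = float(popt[0]), float(popt[1])
    if a <= 0 or k < 0:
        raise RuntimeError(
            f"leaky-integrator fit failed: k={k:.4g}, a={a:.4g}")
    resid = x - model(t, k, a)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((x - np.mean(x)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    err = np.sqrt(np.diag(pcov))
    return LeakyFit(k=k, a=a, r_squared=r2, covariance=pcov,
                    k_stderr=float(err[0]), a_stderr=float(err[1]))


def pulse_ratio(metrics_multi: ResponseMetrics,
                metrics_single: ResponseMetrics
                ) -> Dict[str, Optional[float]]:
    """AUC and peak ratios of a multi-pulse to a single-pulse response.

    A ratio below the pulse-count ratio (10 for the standard comparison)
    flags sub-linear integration.  Zero denominators give undefined
    ratios, reported as ``None``.
    """
    out: Dict[str, Optional[float]] = {}
    out["auc_ratio"] = (metrics_multi.delta_auc / metrics_single.delta_auc
                        if metrics_single.delta_auc > 0 else None)
    out["peak_ratio"] = (metrics_multi.delta_peak / metrics_single.delta_peak
                         if metrics_single.delta_peak > 0 else None)
    out["sublinear"] = (out["peak_ratio"] is not None
                        and out["peak_ratio"] < 10.0)
    return out
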