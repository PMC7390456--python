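"""Shared fixtures.

The expensive stochastic ensembles (single-spike responder statistics,
10-pulse and 30-pulse trains) are session-scoped and shared between the
property tests and the acceptance tests so each condition is simulated
once per session.
"""

import numpy as np
import pytest

from camkinet import (
    build_rule_set, calibrate_pulse, delta_curve, equilibrate,
    generate_network, load_rate_table, make_pulse_train, run_ensemble,
)
from camkinet import species as sp

PULSE_START = 5.0


@pytest.fixture(scope="session")
def rates():
    return load_rate_table()


@pytest.fixture(scope="session")
def monomer_rules():
    return build_rule_set(include_monomer_dimerization=True)


@pytest.fixture(scope="session")
def full_network(rates, monomer_rules):
    """Full monomer-model network over all five molecule kinds."""
    return generate_network(
        monomer_rules, [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"), sp.PP1], rates)


@pytest.fixture(scope="session")
def ca_cam_network(rates, monomer_rules):
    """Calcium-binding subnetwork: the nine CaM states only."""
    rules = [r for r in monomer_rules
             if r.name in ("ca_bind_cam", "ca_unbind_cam")]
    return generate_network(rules, [sp.CA, sp.cam(0, 0)], rates)


@pytest.fixture(scope="session")
def baseline_steady(full_network):
    """Deterministic 100 nM baselines keyed by (CaM, Ng) totals."""
    cache = {}

    def get(cam, ng, camkii=80.0, pp1=1.25):
        key = (cam, ng, camkii, pp1)
        if key not in cache:
            cache[key] = equilibrate(
                full_network,
                {"CaM": cam, "Ng": ng, "K": camkii, "PP1": pp1},
                target_free_ca=0.1)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def calibrations(full_network, baseline_steady):
    """Per-condition calibrated 10 uM pulse amplitudes."""
    cache = {}

    def get(cam, ng):
        if (cam, ng) not in cache:
            cache[(cam, ng)] = calibrate_pulse(
                full_network, baseline_steady(cam, ng), target_peak=10.0)
        return cache[(cam, ng)]

    return get


def _ensemble(rates, calibrations, cam, ng, n_pulses, n_runs, base_seed,
              t_tail, record_dt):
    cal = calibrations(cam, ng)
    proto = make_pulse_train(n_pulses, 0.5, amplitude=cal.amplitude,
                             k_e=cal.k_e, start=PULSE_START)
    return proto, run_ensemble(
        rates, proto, n_runs=n_runs, base_seed=base_seed, cam_total=cam,
        ng_total=ng, t_end=proto.onsets[-1] + t_tail, record_dt=record_dt,
        burn_in=3.0)


@pytest.fixture(scope="session")
def single_spike_ensembles(rates, calibrations):
    """30 single-spike runs per (CaM, Ng) condition for responder stats."""
    out = {}
    for i, (cam, ng) in enumerate([(30.0, 0.0), (30.0, 20.0),
                                   (50.0, 0.0), (50.0, 20.0)]):
        out[(cam, ng)] = _ensemble(rates, calibrations, cam, ng,
                                   n_pulses=1, n_runs=30,
                                   base_seed=1000 + i, t_tail=6.0,
                                   record_dt=0.05)
    return out


@pytest.fixture(scope="session")
def train10_ensembles(rates, calibrations):
    """10-pulse trains at physiological CaM."""
    out = {}
    for i, (cam, ng) in enumerate([(30.0, 0.0), (50.0, 0.0), (30.0, 20.0)]):
        out[(cam, ng)] = _ensemble(rates, calibrations, cam, ng, n_pulses=10,
                                   n_runs=10, base_seed=2000 + i, t_tail=6.0,
                                   record_dt=0.05)
    return out


@pytest.fixture(scope="session")
def train30_ensembles(rates, calibrations):
    """30-pulse trains at CaM 30 uM, with and without Ng (the fit input)."""
    out = {}
    # the Ng-condition signal is a few subunits, so it gets the larger
    # ensemble; runs there are also several-fold cheaper
    for i, (ng, n_runs) in enumerate([(0.0, 12), (20.0, 30)]):
        out[ng] = _ensemble(rates, calibrations, 30.0, ng, n_pulses=30,
                            n_runs=n_runs, base_seed=3000 + i, t_tail=10.0,
                            record_dt=0.25)
    return out


@pytest.fixture(scope="session")
def dose_scan(full_network):
    """Steady-state CaM dose response at 10 uM total calcium.

    The grid is dense around the first (multi-calcium-CaM-driven) peak
    near a few uM CaM and logarithmic out to the ultra-high regime where
    per-molecule calcium load vanishes.
    """
    from camkinet import dose_response_scan
    grid = np.concatenate([
        [0.1, 0.3, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.5, 8.0,
         10.0, 14.0, 20.0],
        np.logspace(1.5, 5.0, 11)])
    return {ng: dose_response_scan(full_network, grid, with_ng=ng)
            for ng in (False, True)}


def ensemble_curves(trs, record_dt):
    """Baseline-subtracted phospho-subunit curves (uM) for an ensemble."""
    return ([delta_curve(tr.t, tr.conc("n_p"),
                         (0.0, PULSE_START - record_dt), PULSE_START)
             for tr in trs],
            [tr.meta["n_phospho_events"] > 0 for tr in trs])
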