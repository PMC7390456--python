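"""Stochastic holoenzyme simulator: propensities, events and exactness."""

import random

import numpy as np
import pytest

from camkinet import (
    ConfigurationError, PulseProtocol, apply_event, build_initial_state,
    build_rule_set, compute_propensities, conc_to_count, equilibrate,
    generate_network, simulate_ode, ssa_run,
)
from camkinet.ssa import HoloState, InternalConsistencyError, _S
from camkinet import species as sp


@pytest.fixture
def tiny_state(rates):
    """One holoenzyme, a few CaM/Ng/PP1 agents, clamped calcium."""
    return HoloState(rates, n_holo=1, n_cam=6, n_ng=2, n_pp1=1,
                     clamp_ca_count=5)


def _place_cam(state, ci, u, a, b, phospho=False):
    state.cam_a[ci], state.cam_b[ci] = a, b
    state.cam_loc[ci] = u
    state.sub_cam[u] = ci
    if phospho:
        state.sub_p[u] = 1
        state.np_count += 1
        state._lrem(state.slotU, state.sub_slot_pos, u)
        state._ladd(state.pfree, state.sub_pp1_pos, u)
        state._cam_move(ci, 18 + _S(a, b))
    else:
        state._lrem(state.slotU, state.sub_slot_pos, u)
        state._cam_move(ci, 9 + _S(a, b))
        state.ncbu += 1
    state.ncb += 1
    for v in range(state.n_sub):
        state._update_elig(v)


class TestPropensities:
    def test_cam_unbinding_uses_state_indexed_rate(self, rates, tiny_state):
        # CaM(2C,0N) on an unphosphorylated subunit unbinds at koffCaM2C
        _place_cam(tiny_state, 0, 3, 2, 0)
        props = compute_propensities(tiny_state)
        s = _S(2, 0)
        assert props[f"cam_unbind_camkii_{s}"] == pytest.approx(6.35)

    def test_phosphorylated_subunit_releases_cam_slowly(self, rates,
                                                        tiny_state):
        # any CaM on a phosphorylated subunit unbinds at kp,offCaM = 0.07/s
        _place_cam(tiny_state, 0, 3, 2, 2, phospho=True)
        props = compute_propensities(tiny_state)
        assert props["cam_unbind_pcamkii"] == pytest.approx(0.07)
        assert all(props[f"cam_unbind_camkii_{s}"] == 0 for s in range(9))

    def test_calcium_free_substrate_cam_gives_zero_phospho_propensity(
            self, tiny_state):
        # kinase at position i is CaM-bound (active); its target at i+1
        # carries apo-CaM: no phosphorylation channel may open
        _place_cam(tiny_state, 0, 0, 0, 0)   # kinase, apo-CaM, active
        _place_cam(tiny_state, 1, 1, 0, 0)   # substrate, apo-CaM
        props = compute_propensities(tiny_state)
        assert all(props[f"phospho_{s}"] == 0 for s in range(1, 9))

    def test_calcium_loaded_substrate_opens_phospho_channel(self, rates,
                                                            tiny_state):
        _place_cam(tiny_state, 0, 0, 0, 0)   # active kinase at position 0
        _place_cam(tiny_state, 1, 1, 2, 2)   # 4-Ca substrate at position 1
        props = compute_propensities(tiny_state)
        assert props[f"phospho_{_S(2, 2)}"] == pytest.approx(rates.kpCaM4)

    def test_full_lobe_has_no_binding_channel(self, tiny_state):
        # all CaM at 2C2N: no further C- or N-lobe binding propensity
        for ci in range(tiny_state.n_cam):
            tiny_state.cam_a[ci] = tiny_state.cam_b[ci] = 2
            tiny_state._cam_move(ci, _S(2, 2))
        props = compute_propensities(tiny_state)
        for name in ("ca_bind_cam_C1", "ca_bind_cam_C2",
                     "ca_bind_cam_N1", "ca_bind_cam_N2"):
            assert props[name] == 0.0

    def test_no_agents_no_channels(self, rates):
        empty = HoloState(rates, 0, 0, 0, 0, clamp_ca_count=10)
        assert all(v == 0.0 for v in compute_propensities(empty).values())


class TestApplyEvent:
    def test_ng_binding_consumes_free_ng_and_cam(self, tiny_state):
        rng = random.Random(0)
        apply_event(tiny_state, "ng_bind", rng)
        assert tiny_state.n_ng_free == 1
        assert len(tiny_state.cam_groups[27]) == 1
        tiny_state.check_consistency()

    def test_pp1_catalysis_dephosphorylates_and_releases(self, tiny_state):
        rng = random.Random(0)
        _place_cam(tiny_state, 0, 3, 1, 0, phospho=True)
        apply_event(tiny_state, "pp1_bind", rng)
        assert tiny_state.n_pp1_free == 0
        apply_event(tiny_state, "pp1_catalysis", rng)
        assert tiny_state.np_count == 0
        assert tiny_state.n_pp1_free == 1
        assert tiny_state.sub_p[3] == 0
        tiny_state.check_consistency()

    def test_channel_without_participants_rejected(self, tiny_state):
        with pytest.raises(InternalConsistencyError):
            apply_event(tiny_state, "pp1_bind", random.Random(0))

    def test_phosphorylation_flips_exactly_one_substrate(self, tiny_state):
        rng = random.Random(0)
        _place_cam(tiny_state, 0, 0, 0, 0)
        _place_cam(tiny_state, 1, 1, 2, 1)
        apply_event(tiny_state, f"phospho_{_S(2, 1)}", rng)
        assert tiny_state.np_count == 1
        assert tiny_state.sub_p[1] == 1 and tiny_state.sub_p[0] == 0
        tiny_state.check_consistency()


class TestInitialState:
    def test_default_camkii_gives_63_complete_holoenzymes(self, rates):
        st = build_initial_state(rates, cam_total=30.0, ng_total=20.0,
                                 seed=0, burn_in=0.0)
        assert st.n_holo == 63
        assert st.n_sub == 756
        assert conc_to_count(80.0) == 752  # the rounded monomer count

    def test_agent_counts_match_concentrations(self, rates):
        st = build_initial_state(rates, cam_total=30.0, ng_total=20.0,
                                 seed=0, burn_in=0.0)
        assert st.n_cam == 282
        assert st.n_ng_total == 188
        st.check_consistency()

    def test_baseline_free_calcium_is_a_small_count(self, rates):
        counts = [build_initial_state(rates, 30.0, 0.0, seed=s,
                                      burn_in=0.5).n_ca
                  for s in range(8)]
        assert max(counts) <= 8
        assert 0 <= np.mean(counts) < 4  # ~0.94 expected at 100 nM

    def test_construction_is_seed_deterministic(self, rates):
        a = build_initial_state(rates, 30.0, 20.0, seed=5, burn_in=1.0)
        b = build_initial_state(rates, 30.0, 20.0, seed=5, burn_in=1.0)
        assert np.array_equal(a.cam_a, b.cam_a)
        assert np.array_equal(a.cam_loc, b.cam_loc)
        assert a.n_ca == b.n_ca


@pytest.fixture(scope="module")
def audited_run(rates):
    """A short audited spike run with the event log retained."""
    st = build_initial_state(rates, 30.0, 20.0, pp1_total=1.25,
                             seed=11, burn_in=1.0)
    proto = PulseProtocol(baseline=0.1, onsets=(0.5,), amplitude=9688.0)
    traj = ssa_run(st, proto, t_end=4.0, record_dt=0.05, seed=12,
                   record_events=True)
    return st, traj


class TestRunInvariants:
    def test_consistency_audit_after_randomized_run(self, audited_run):
        st, _ = audited_run
        st.check_consistency()

    def test_molecule_counts_conserved_through_every_event(self, audited_run):
        st, _ = audited_run
        # group lists partition all agents: totals are structural
        assert sum(len(g) for g in st.cam_groups) == st.n_cam
        assert st.n_ng_free + len(st.cam_groups[27]) == st.n_ng_total
        assert st.n_pp1_free + len(st.pbound) == st.n_pp1_total
        assert int(np.sum(st.sub_p)) == st.np_count

    def test_no_forbidden_event_ever_fires(self, audited_run):
        st, _ = audited_run
        log = st.event_log
        assert log, "expected events in the audit log"
        # replay-independent checks on logged participants
        for t, kind, ps in log:
            if kind == "ng_bind":
                (ci,) = ps
                assert st.cam_loc[ci] != -3  # participant exists
        # phosphorylation events: kinase and substrate share holo and ring
        phos = [ps for t, kind, ps in log if kind == "phospho"]
        for kin, sub in phos:
            assert kin // 12 == sub // 12          # same holoenzyme
            assert (kin % 12) // 6 == (sub % 12) // 6  # same ring
            assert (kin % 6 + 1) % 6 == sub % 6    # directed neighbor

    def test_reproducibility_identical_seeds(self, rates):
        from camkinet import run_ensemble, make_pulse_train
        proto = make_pulse_train(1, 0.5, amplitude=9688.0, start=1.0)
        a = run_ensemble(rates, proto, n_runs=2, base_seed=77,
                         cam_total=30.0, ng_total=20.0, t_end=3.0,
                         record_dt=0.1, burn_in=0.5)
        b = run_ensemble(rates, proto, n_runs=2, base_seed=77,
                         cam_total=30.0, ng_total=20.0, t_end=3.0,
                         record_dt=0.1, burn_in=0.5)
        for x, y in zip(a, b):
            assert np.array_equal(x["n_p"], y["n_p"])
            assert np.array_equal(x["n_free_ca"], y["n_free_ca"])
            assert x.meta["seed"] == y.meta["seed"]


class TestCamBoundTrainPeaks:
    def test_unphosphorylated_cam_bound_peaks_do_not_grow_over_a_train(
            self, train10_ensembles):
        """Across a pulse train the per-pulse peaks of CaM-bound
        *unphosphorylated* subunits stay level or shrink, while total
        CaM-bound peaks may creep up as phosphorylated subunits trap CaM."""
        proto, trs = train10_ensembles[(50.0, 0.0)]
        peaks_u = []
        for tr in trs:
            per_pulse = []
            for onset in proto.onsets:
                m = (tr.t >= onset) & (tr.t < onset + 2.0)
                per_pulse.append(tr.conc("n_cam_bound_u")[m].max())
            peaks_u.append(per_pulse)
        mean_u = np.mean(peaks_u, axis=0)
        early, late = mean_u[:3].mean(), mean_u[-3:].mean()
        assert late <= early * 1.10


class TestClampGuards:
    def test_clamped_state_rejects_pulse_protocol(self, rates):
        st = HoloState(rates, 0, 10, 0, 0, clamp_ca_count=5)
        with pytest.raises(ConfigurationError):
            ssa_run(st, PulseProtocol(onsets=(0.1,), amplitude=100.0),
                    t_end=1.0, seed=0)
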