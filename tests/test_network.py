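"""Rule closure, mass-action kinetics, equilibration and dose response."""

import numpy as np
import pytest

from camkinet import (
    PulseProtocol, dose_response_scan, equilibrate, generate_network,
    initial_state, mass_action_rhs, simulate_ode, w_free_cam, w_total_p,
)
from camkinet.network import NetworkGenerationError
from camkinet import species as sp


class TestGenerateNetwork:
    def test_calcium_binding_closure_gives_nine_cam_states(self, ca_cam_network):
        net = ca_cam_network
        cam_species = [s for s in net.species if s[0] == "CaM"]
        assert len(cam_species) == 9
        # 6 C-lobe + 6 N-lobe transitions, each reversible
        assert len(net.reactions) == 24

    def test_adding_ng_adds_one_species_one_reversible_reaction(
            self, rates, monomer_rules, ca_cam_network):
        rules = [r for r in monomer_rules
                 if r.name in ("ca_bind_cam", "ca_unbind_cam",
                               "ng_bind", "ng_unbind")]
        net = generate_network(rules, [sp.CA, sp.cam(0, 0), sp.NG], rates)
        assert net.n_species == ca_cam_network.n_species + 2  # Ng, CaM.Ng
        assert len(net.reactions) == len(ca_cam_network.reactions) + 2

    def test_closure_is_deterministic(self, rates, monomer_rules):
        seeds = [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"), sp.PP1]
        a = generate_network(monomer_rules, seeds, rates)
        b = generate_network(monomer_rules, seeds, rates)
        assert a.species == b.species
        assert a.reactions == b.reactions

    def test_every_phosphorylation_substrate_has_calcium(self, full_network):
        for rx in full_network.reactions:
            if not rx.rate_name.startswith("kpCaM"):
                continue
            (i,) = rx.reactants
            term = full_network.species[i]
            assert term[0] == "KK"
            # some U member with >= 1 Ca must exist to be the substrate
            assert any(m[0] == "U" and m[1] + m[2] >= 1 for m in term[1:3])

    def test_every_rate_name_resolves(self, full_network, rates):
        for rx in full_network.reactions:
            assert rx.rate_name in rates

    def test_export_formats(self, ca_cam_network):
        text = ca_cam_network.to_reaction_text()
        assert len(text.strip().splitlines()) == len(ca_cam_network.reactions)
        assert "kon1C" in text
        table = ca_cam_network.species_table()
        assert set(table.columns) >= {"label", "kind", "CaM", "Ca"}
        assert len(table) == ca_cam_network.n_species

    def test_species_cap_guard(self, rates, monomer_rules):
        with pytest.raises(NetworkGenerationError):
            generate_network(monomer_rules,
                             [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"), sp.PP1],
                             rates, max_species=20)


class TestConservation:
    def test_conserved_moieties_are_exact_left_null_vectors(self, full_network):
        S = full_network.stoichiometry().toarray().astype(int)
        C = full_network.conservation_matrix()
        for group in ("CaM", "K", "Ng", "PP1"):
            assert not np.any(C[group] @ S), group

    def test_calcium_conserved_by_reactions_alone(self, full_network):
        S = full_network.stoichiometry().toarray().astype(int)
        C = full_network.conservation_matrix()
        assert not np.any(C["Ca"] @ S)


class TestMassActionRhs:
    def test_ng_binding_flux_from_tabulated_rate(self, full_network):
        # [CaM]=[Ng]=1 uM, nothing else: d[CaM.Ng]/dt = konNg*1*1 = 5 uM/s
        y = np.zeros(full_network.n_species)
        y[full_network.index[sp.cam(0, 0)]] = 1.0
        y[full_network.index[sp.NG]] = 1.0
        dy = mass_action_rhs(full_network, y, clamp_ca=True)
        assert dy[full_network.index[sp.CAMNG]] == pytest.approx(5.0)

    def test_single_reversible_reaction_detailed_balance(self, full_network):
        # at [CaM][Ng]/[CaM.Ng] = Kd = koffNg/konNg the three derivatives vanish
        y = np.zeros(full_network.n_species)
        kd = 1.0 / 5.0
        y[full_network.index[sp.cam(0, 0)]] = 1.0
        y[full_network.index[sp.NG]] = kd
        y[full_network.index[sp.CAMNG]] = 1.0
        dy = mass_action_rhs(full_network, y, clamp_ca=True)
        for term in (sp.cam(0, 0), sp.NG, sp.CAMNG):
            assert dy[full_network.index[term]] == pytest.approx(0.0, abs=1e-12)

    def test_cam_moiety_has_zero_net_derivative(self, full_network, rates):
        rng = np.random.default_rng(0)
        y = rng.random(full_network.n_species)
        dy = mass_action_rhs(full_network, y, clamp_ca=True)
        w = full_network.conservation_matrix()["CaM"]
        assert float(w @ dy) == pytest.approx(0.0, abs=1e-9)

    def test_wrong_state_length_rejected(self, full_network):
        with pytest.raises(ValueError):
            mass_action_rhs(full_network, np.zeros(3))


class TestEquilibrate:
    def test_ng_sequestration_matches_quadratic_oracle(self, rates,
                                                       monomer_rules):
        # (30-b)(20-b) = Kd*b with Kd = 0.2 uM gives b = 19.62 uM
        net = generate_network(monomer_rules, [sp.CA, sp.cam(0, 0), sp.NG],
                               rates)
        ss = equilibrate(net, {"CaM": 30.0, "Ng": 20.0}, target_free_ca=1e-8)
        kd = rates.koffNg / rates.konNg
        b = np.roots([1.0, -(30 + 20 + kd), 600.0]).min()
        assert ss.concentration(sp.CAMNG) == pytest.approx(b, rel=1e-6)

    def test_without_ng_no_complex(self, rates, monomer_rules):
        net = generate_network(monomer_rules, [sp.CA, sp.cam(0, 0), sp.NG],
                               rates)
        ss = equilibrate(net, {"CaM": 30.0, "Ng": 0.0}, target_free_ca=0.1)
        assert ss.concentration(sp.CAMNG) == pytest.approx(0.0, abs=1e-10)

    def test_ca_cam_equilibrium_matches_sequential_binding_closed_form(
            self, ca_cam_network, rates):
        """Steady state equals the product of stepwise Kd occupancies."""
        ca = 1.0
        ss = equilibrate(ca_cam_network, {"CaM": 10.0}, target_free_ca=ca)
        kd_c = (rates.koff1C / rates.kon1C, rates.koff2C / rates.kon2C)
        kd_n = (rates.koff1N / rates.kon1N, rates.koff2N / rates.kon2N)

        def rel(a, b):  # occupancy relative to apo-CaM
            w = 1.0
            for i in range(a):
                w *= ca / kd_c[i]
            for i in range(b):
                w *= ca / kd_n[i]
            return w

        weights = {(a, b): rel(a, b) for a in range(3) for b in range(3)}
        z = sum(weights.values())
        for (a, b), w in weights.items():
            expected = 10.0 * w / z
            assert ss.concentration(sp.cam(a, b)) == pytest.approx(
                expected, rel=1e-8)

    def test_disabling_catalysis_cannot_lower_phosphorylation(
            self, rates, full_network):
        """Removing the only dephosphorylation flux: phosphorylation at any
        fixed horizon is at least that of the normal-catalysis network."""
        from camkinet import build_rule_set, generate_network, load_rate_table
        slow = load_rate_table({"kcat": 1e-9})  # catalysis effectively off
        net0 = generate_network(build_rule_set(True),
                                [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"),
                                 sp.PP1], slow)
        totals = {"CaM": 30.0, "Ng": 0.0, "K": 80.0, "PP1": 1.25}
        grid = np.linspace(0.0, 300.0, 30)
        proto = PulseProtocol(mode="clamp", clamp_value=0.1)
        p = {}
        for net in (full_network, net0):
            y0 = initial_state(net, totals, 0.1)
            traj = simulate_ode(net, y0, proto, grid)
            p[net is net0] = traj.observable(net.weights(w_total_p))
        assert np.all(p[True] >= p[False] - 1e-9)

    def test_negative_totals_rejected(self, full_network):
        with pytest.raises(Exception):
            equilibrate(full_network, {"CaM": -1.0}, target_free_ca=0.1)


class TestSimulateOde:
    def test_zero_amplitude_protocol_is_stationary(self, full_network,
                                                   baseline_steady):
        ss = baseline_steady(30.0, 20.0)
        proto = PulseProtocol(baseline=0.1, onsets=(), amplitude=0.0)
        traj = simulate_ode(full_network, ss.y, proto,
                            np.linspace(0.0, 20.0, 50))
        drift = np.abs(traj.Y - ss.y[None, :]).max()
        assert drift < 1e-6 * max(1.0, ss.y.max())

    def test_single_spike_lifetime_on_the_order_of_minutes(
            self, full_network, baseline_steady, calibrations):
        from camkinet.analysis import compute_metrics, delta_curve
        ss = baseline_steady(30.0, 0.0)
        cal = calibrations(30.0, 0.0)
        proto = cal.protocol(onsets=(5.0,))
        t_grid = np.concatenate([np.linspace(0, 8, 160),
                                 np.linspace(8.1, 500, 600)])
        traj = simulate_ode(full_network, ss.y, proto, t_grid)
        p = traj.observable(full_network.weights(w_total_p))
        m = compute_metrics(delta_curve(traj.t, p, (0.0, 4.9), 5.0))
        assert m.responder
        assert 30.0 < m.lifetime < 600.0  # minutes, not seconds or hours

    def test_ng_lowers_peak_monomer_response_at_every_amplitude(
            self, full_network, baseline_steady):
        from camkinet import calibrate_pulse
        peaks = {}
        for ng in (0.0, 20.0):
            ss = baseline_steady(30.0, ng)
            rows = []
            for target in (2.0, 10.0):
                cal = calibrate_pulse(full_network, ss, target_peak=target)
                proto = cal.protocol(onsets=(1.0,))
                traj = simulate_ode(full_network, ss.y, proto,
                                    np.linspace(0.0, 30.0, 300))
                p = traj.observable(full_network.weights(w_total_p))
                rows.append(float(np.max(p) - p[0]))
            peaks[ng] = rows
        for no_ng, with_ng in zip(peaks[0.0], peaks[20.0]):
            assert no_ng > with_ng

    def test_all_phosphorylated_state_relaxes_to_baseline(self, full_network,
                                                          baseline_steady):
        """No bistability at resting calcium."""
        ss = baseline_steady(30.0, 20.0)
        y0 = initial_state(full_network,
                           {"CaM": 30.0, "Ng": 20.0, "PP1": 1.25}, 0.1)
        y0[full_network.index[sp.k("P")]] = 80.0
        proto = PulseProtocol(mode="clamp", clamp_value=0.1)
        traj = simulate_ode(full_network, y0, proto,
                            np.linspace(0.0, 2500.0, 300))
        w = full_network.weights(w_total_p)
        p = traj.observable(w)
        p_base = float(w @ ss.y)
        assert p[0] == pytest.approx(80.0)
        assert abs(p[-1] - p_base) < 0.05


class TestDoseResponse:
    def test_multi_calcium_cam_curves_cross_with_ng(self, dose_scan):
        """Ng raises the 3Ca/4Ca CaM fraction at low CaM, lowers it at high."""
        for col in ("max_rel_cam3", "max_rel_cam4"):
            diff = (dose_scan[True][col] - dose_scan[False][col]).to_numpy()
            assert diff.max() > 0 and diff.min() < 0

    def test_phosphorylation_vanishes_at_ultra_high_cam(self, dose_scan):
        for ng in (False, True):
            curve = dose_scan[ng]["ss_total_p"].to_numpy()
            assert curve[-1] < 0.02 * curve.max()

    def test_two_local_maxima_first_peak_larger_with_ng(self, dose_scan):
        def local_maxima(c):
            return [i for i in range(1, len(c) - 1)
                    if c[i] > c[i - 1] and c[i] >= c[i + 1]]

        peaks = {}
        for ng in (False, True):
            c = dose_scan[ng]["ss_total_p"].to_numpy()
            idx = local_maxima(c)
            assert len(idx) >= 2
            peaks[ng] = c[idx[0]]
        assert peaks[True] > peaks[False]
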