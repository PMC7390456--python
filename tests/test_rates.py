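"""Rate table, count conversions, CaM state and rule-set construction."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from camkinet import (
    CaMState, ConfigurationError, DEFAULT_VOLUME, VolumeContext,
    bimolecular_to_propensity, build_rule_set, ca_binding_rate_name,
    conc_to_count, load_rate_table,
)
from camkinet.rates import RateTable, ca_unbinding_rate_name
from camkinet.species import CAM_STATE_KEY


class TestRateTable:
    @pytest.mark.parametrize("name,value", [
        ("konNg", 5.0), ("koffNg", 1.0),          # Ng binding to CaM
        ("kcat", 0.41), ("Km", 11.0),             # PP1 Michaelis-Menten
        ("kon1C", 4.0), ("koff1C", 40.24),
        ("kon2N", 150.0), ("koff2N", 990.0),
        ("konCaM0", 0.0038), ("konCaM4", 30.0),
        ("konK2C", 44.0), ("koffK2C", 2.42),
        ("konCaMKII", 50.0), ("koffCaMKII", 60.0),
        ("kpCaM1C", 0.032), ("kpCaM4", 0.96),
        ("kponCaM1C", 19.7), ("kpoffCaM", 0.07),
    ])
    def test_default_values(self, rates, name, value):
        assert rates[name] == value

    def test_derived_phosphatase_off_rate_reproduces_km(self, rates):
        km = (rates.koffPP1 + rates.kcat) / rates.konPP1
        assert km == pytest.approx(rates.Km, rel=1e-12)

    def test_every_on_rate_has_an_off_rate(self, rates):
        for name in rates:
            if name.startswith("kon"):
                assert "koff" + name[3:] in rates
            if name.startswith("kponCaM"):
                assert "kpoffCaM" in rates

    def test_no_phosphorylation_rate_for_calcium_free_cam(self, rates):
        assert "kpCaM0" not in rates
        for (a, b), key in CAM_STATE_KEY.items():
            if a + b > 0:
                assert f"kpCaM{key}" in rates

    def test_round_trip_is_exact(self, rates):
        again = RateTable.from_text(rates.to_text())
        assert set(again.entries) == set(rates.entries)
        for name in rates:
            assert again[name] == rates[name]

    def test_overrides_merge_and_are_flagged(self):
        rt = load_rate_table({"konNg": 2.5})
        assert rt.konNg == 2.5
        assert rt.overrides == {"konNg": 2.5}
        assert load_rate_table().konNg == 5.0

    @pytest.mark.parametrize("bad", [{"konNg": -1}, {"konNg": 0},
                                     {"nonexistent": 1.0}])
    def test_invalid_overrides_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            load_rate_table(bad)


class TestVolumeAndCounts:
    def test_80_uM_camkii_gives_752_monomers_63_holoenzymes(self):
        n = conc_to_count(80.0)
        assert n == 752
        assert round(n / 12) == 63

    @pytest.mark.parametrize("conc,count", [(0.0, 0), (20.0, 188)])
    def test_count_conversion(self, conc, count):
        assert conc_to_count(conc) == count

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            conc_to_count(-1.0)

    def test_per_pair_rate(self):
        # 50 / 9.394 and 4 / 9.394 molecules-per-uM at the default volume
        assert bimolecular_to_propensity(50.0) == pytest.approx(5.322, abs=2e-3)
        assert bimolecular_to_propensity(4.0) == pytest.approx(0.4258, abs=2e-4)

    def test_doubling_volume_halves_per_pair_rate(self):
        big = VolumeContext(2 * DEFAULT_VOLUME.volume_um3)
        assert bimolecular_to_propensity(50.0, big) == pytest.approx(
            bimolecular_to_propensity(50.0) / 2)

    @given(st.floats(min_value=0, max_value=1e4),
           st.floats(min_value=0, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_count_monotone_in_concentration(self, c1, c2):
        lo, hi = sorted([c1, c2])
        assert conc_to_count(lo) <= conc_to_count(hi)


class TestCaMState:
    def test_ng_exclusive_with_calcium_and_kinase(self):
        CaMState(nC=0, nN=0, ng_bound=True)
        with pytest.raises(ConfigurationError):
            CaMState(nC=1, nN=0, ng_bound=True)
        with pytest.raises(ConfigurationError):
            CaMState(ng_bound=True, partner=object())

    def test_lobe_counts_bounded(self):
        with pytest.raises(ConfigurationError):
            CaMState(nC=3, nN=0)

    def test_state_key_matches_rate_suffixes(self):
        assert CaMState(2, 1).state_key == "2C1N"
        assert CaMState(0, 0).state_key == "0"
        assert CaMState(2, 2).state_key == "4"


class TestRateSelection:
    """The Ca on/off rate depends only on (lobe, count, CaM context)."""

    @pytest.mark.parametrize("kinase_bound,prefix", [(False, "kon"),
                                                     (True, "konK")])
    def test_exhaustive_on_rate_names(self, rates, kinase_bound, prefix):
        for lobe in ("C", "N"):
            for count in (0, 1):
                name = ca_binding_rate_name(lobe, count, kinase_bound)
                assert name == f"{prefix}{count + 1}{lobe}"
                assert name in rates

    def test_exhaustive_off_rate_names(self, rates):
        for kb, prefix in ((False, "koff"), (True, "koffK")):
            for lobe in ("C", "N"):
                for count in (1, 2):
                    name = ca_unbinding_rate_name(lobe, count, kb)
                    assert name == f"{prefix}{count}{lobe}"
                    assert name in rates

    def test_full_lobe_has_no_on_rate(self):
        with pytest.raises(ConfigurationError):
            ca_binding_rate_name("C", 2, False)


class TestRuleSet:
    def test_monomer_variant_has_reversible_dimerization(self):
        rules = {r.name: r for r in build_rule_set(True)}
        assert "camkii_dimerize" in rules
        assert rules["camkii_dimerize"].rate_names == ("konCaMKII",)
        assert "camkii_undimerize" in rules

    def test_holoenzyme_variant_replaces_dimerization_with_neighbor_guard(self):
        rules = {r.name: r for r in build_rule_set(False)}
        assert "camkii_dimerize" not in rules
        phos = rules["autophosphorylation"]
        assert "neighbor" in phos.guard
        assert "active" in phos.guard

    @pytest.mark.parametrize("with_dimer", [True, False])
    def test_phosphorylation_requires_calcium_on_substrate_cam(self, with_dimer):
        rules = {r.name: r for r in build_rule_set(with_dimer)}
        names = rules["autophosphorylation"].rate_names
        assert "kpCaM0" not in names
        assert len(names) == 8

    def test_rules_change_only_named_fields(self):
        # applying the C-lobe Ca rule to a dimer leaves the partner intact
        from camkinet.species import dimer
        rules = {r.name: r for r in build_rule_set(True)}
        d = dimer(("U", 0, 2), ("P", 1, 1))
        for prods, rate, mult in rules["ca_bind_kcam"].apply(("Ca",), d):
            (out,) = prods
            members = sorted([out[1], out[2]])
            untouched = [m for m in members if m in (("U", 0, 2), ("P", 1, 1))]
            assert len(untouched) >= 1
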