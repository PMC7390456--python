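"""Kinetic constants, unit conversions and the reaction rule set.

This module is the single source of truth for every rate constant of the
model (shipped as a plain-text, diffable table in ``data/rate_table.tsv``),
for the conversion between concentrations and discrete molecule counts in
the fixed postsynaptic-density volume, and for the eight reaction-rule
families that both the deterministic monomer network and the network-free
holoenzyme simulator are built from.

Rate naming follows the field's conventions: ``kon1C`` is the on-rate of
the first Ca2+ ion onto the CaM C lobe, ``konCaM2C1N`` the on-rate of CaM
carrying 2 C-lobe and 1 N-lobe calcium ions onto an unphosphorylated
CaMKII, ``kpCaM...`` the (irreversible) autophosphorylation rate indexed by
the *substrate's* CaM state, ``kponCaM...``/``kpoffCaM`` CaM exchange on
phosphorylated CaMKII, and ``kcat``/``Km`` the Michaelis-Menten constants
of dephosphorylation by PP1.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .species import (
    CA,
    CAM_STATE_KEY,
    CAMNG,
    NG,
    PP1,
    Term,
    cam,
    dimer,
    k,
    kcam,
    pp1k,
)

AVOGADRO = 6.022e23

#: CaM states carrying at least one calcium ion (the only states whose
#: CaMKII partner can be phosphorylated).
PHOSPHO_COMPETENT = tuple(s for s in sorted(CAM_STATE_KEY) if sum(s) > 0)


class ConfigurationError(ValueError):
    """Raised for unknown rate names, non-positive rates or bad config."""


# ---------------------------------------------------------------------------
# volume context and count conversions
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VolumeContext:
    """The well-mixed simulation compartment.

    The default volume is the modeled postsynaptic density,
    ``V = 0.0156 um^3``, for which one micromolar corresponds to
    ``6.022e23 * 0.0156e-15 * 1e-6 ~= 9.39`` molecules.
    """

    volume_um3: float = 0.0156

    @property
    def molecules_per_uM(self) -> float:
        return AVOGADRO * self.volume_um3 * 1e-15 * 1e-6

    def __post_init__(self):
        if self.volume_um3 <= 0:
            raise ConfigurationError("volume must be positive")


DEFAULT_VOLUME = VolumeContext()


def conc_to_count(conc_uM: float, ctx: VolumeContext = DEFAULT_VOLUME) -> int:
    """Round-to-nearest molecule count for a concentration in uM.

    At the default volume, 80 uM of CaMKII monomers corresponds to 752
    molecules (63 complete holoenzymes when divided into dodecamers).
    """
    if conc_uM < 0:
        raise ConfigurationError("concentration must be non-negative")
    return int(round(conc_uM * ctx.molecules_per_uM))


def count_to_conc(count: float, ctx: VolumeContext = DEFAULT_VOLUME) -> float:
    """Concentration (uM) of a molecule count in the compartment."""
    return count / ctx.molecules_per_uM


def bimolecular_to_propensity(kon_per_uM_s: float,
                              ctx: VolumeContext = DEFAULT_VOLUME) -> float:
    """Stochastic per-molecule-pair rate (1/s) for a bimolecular on-rate.

    Dividing a mass-action on-rate (uM^-1 s^-1) by the number of molecules
    per uM gives the hazard of one specific reactant pair meeting in the
    compartment, the quantity the stochastic simulator uses.
    """
    if kon_per_uM_s <= 0:
        raise ConfigurationError("on-rate must be positive")
    return kon_per_uM_s / ctx.molecules_per_uM


# ---------------------------------------------------------------------------
# rate table
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RateEntry:
    name: str
    value: float
    unit: str
    group: str
    note: str = ""
    derived: bool = False
    overridden: bool = False


class RateTable:
    """All kinetic constants of the model, by name.

    Behaves as a read-only mapping from rate name to value; entry metadata
    (unit, group, provenance note, whether the value was overridden or is
    derived rather than tabulated) is available via :attr:`entries`.

    The only derived entry is ``koffPP1 = konPP1 * Km - kcat`` which makes
    the explicit two-step phosphatase scheme reproduce the printed
    Michaelis constant ``(koffPP1 + kcat) / konPP1 = Km``.
    """

    def __init__(self, entries: Dict[str, RateEntry]):
        self.entries: Dict[str, RateEntry] = dict(entries)
        if "koffPP1" not in self.entries:
            koff = self["konPP1"] * self["Km"] - self["kcat"]
            self.entries["koffPP1"] = RateEntry(
                "koffPP1", koff, "s-1", "pp1",
                "derived: konPP1*Km - kcat", derived=True)
        for e in self.entries.values():
            if e.value <= 0:
                raise ConfigurationError(
                    f"rate {e.name} must be positive, got {e.value}")

    # mapping-like access -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __getattr__(self, name: str) -> float:
        if name == "entries":
            raise AttributeError(name)
        try:
            return self.entries[name].value
        except KeyError:
            raise AttributeError(name) from None

    @property
    def overrides(self) -> Dict[str, float]:
        return {n: e.value for n, e in self.entries.items() if e.overridden}

    # serialization -------------------------------------------------------
    def to_text(self) -> str:
        lines = ["# camkinet rate table, version 1",
                 "# name\tvalue\tunit\tgroup\tnote"]
        for e in self.entries.values():
            if e.derived:
                continue
            note = e.note
            if e.overridden:
                note = (note + "; " if note else "") + "OVERRIDDEN"
            row = [e.name, repr(e.value), e.unit, e.group]
            if note:
                row.append(note)
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RateTable":
        entries: Dict[str, RateEntry] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ConfigurationError(f"malformed rate-table row: {line!r}")
            name, value, unit, group = parts[:4]
            note = parts[4] if len(parts) > 4 else ""
            overridden = "OVERRIDDEN" in note
            entries[name] = RateEntry(name, float(value), unit, group,
                                      note, overridden=overridden)
        return cls(entries)


def _default_table_text() -> str:
    ref = importlib.resources.files("camkinet").joinpath("data/rate_table.tsv")
    return ref.read_text(encoding="utf-8")


def load_rate_table(overrides: Optional[Dict[str, float]] = None) -> RateTable:
    """Load the default rate table, optionally overriding named entries.

    Overrides must name existing entries and be positive; overridden
    entries are flagged in the table metadata (and echoed by the runners)
    so that any deviation from the tabulated constants is visible in every
    output file.
    """
    table = RateTable.from_text(_default_table_text())
    if overrides:
        for name, value in overrides.items():
            if name not in table.entries:
                raise ConfigurationError(f"unknown rate name: {name}")
            if table.entries[name].derived:
                raise ConfigurationError(
                    f"{name} is derived and cannot be overridden directly")
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigurationError(
                    f"rate {name} must be a positive number, got {value!r}")
            old = table.entries[name]
            table.entries[name] = dataclasses.replace(
                old, value=float(value), overridden=True)
        # re-derive dependent entries
        return RateTable({n: e for n, e in table.entries.items()
                          if not e.derived})
    return table


# ---------------------------------------------------------------------------
# CaM state
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CaMState:
    """State of one calmodulin molecule.

    ``nC``/``nN`` count the calcium ions on the C and N lobes (two
    indistinguishable sites each).  Ng binding is mutually exclusive with
    carrying calcium and with being bound to a CaMKII subunit.
    """

    nC: int = 0
    nN: int = 0
    ng_bound: bool = False
    partner: Optional[object] = None  # a CaMKII subunit reference, or None

    def __post_init__(self):
        if not (0 <= self.nC <= 2 and 0 <= self.nN <= 2):
            raise ConfigurationError("lobe counts must be in 0..2")
        if self.ng_bound and (self.nC or self.nN or self.partner is not None):
            raise ConfigurationError(
                "Ng-bound CaM cannot carry Ca2+ or bind CaMKII")

    @property
    def n_ca(self) -> int:
        return self.nC + self.nN

    @property
    def state_key(self) -> str:
        return CAM_STATE_KEY[(self.nC, self.nN)]


def ca_binding_rate_name(lobe: str, current_count: int,
                         kinase_bound: bool) -> str:
    """Name of the on-rate for the next Ca2+ onto a CaM lobe.

    The rate is determined solely by the lobe, the current occupancy of
    that lobe, and whether the CaM is CaMKII-bound (``konK...``) or free
    (``kon...``); the phosphorylation state of a bound subunit does not
    enter.
    """
    if lobe not in ("C", "N"):
        raise ConfigurationError("lobe must be 'C' or 'N'")
    if not 0 <= current_count <= 1:
        raise ConfigurationError("lobe is full or count invalid")
    prefix = "konK" if kinase_bound else "kon"
    return f"{prefix}{current_count + 1}{lobe}"


def ca_unbinding_rate_name(lobe: str, current_count: int,
                           kinase_bound: bool) -> str:
    if not 1 <= current_count <= 2:
        raise ConfigurationError("lobe is empty or count invalid")
    prefix = "koffK" if kinase_bound else "koff"
    return f"{prefix}{current_count}{lobe}"


# ---------------------------------------------------------------------------
# reaction rules
# ---------------------------------------------------------------------------

Option = Tuple[Tuple[Term, ...], str, int]  # products, rate name, multiplicity


@dataclasses.dataclass(frozen=True)
class Rule:
    """One reaction-rule family.

    Rules follow "don't care, don't write" semantics: a rule names only the
    state it tests and changes, everything else on the matched species is a
    wildcard and is carried through untouched.  ``apply`` instantiates the
    rule on concrete species terms, returning ``(products, rate_name,
    multiplicity)`` options; the rate name is resolved against the
    :class:`RateTable` at network-compile time.  Rules that require agent
    context (holoenzyme neighbor phosphorylation) carry their guard as
    metadata and instantiate to nothing on well-mixed terms.
    """

    name: str
    table_row: int
    arity: int
    rate_names: Tuple[str, ...]
    guard: str = ""
    _fn: Optional[Callable] = None

    def apply(self, s1: Term, s2: Optional[Term] = None) -> List[Option]:
        if self._fn is None:
            return []
        if self.arity == 1:
            assert s2 is None
            return _merged(self._fn(s1))
        assert s2 is not None
        return _merged(self._fn(s1, s2))


def _merged(options: Iterable[Tuple[Tuple[Term, ...], str]]) -> List[Option]:
    """Collapse options with identical products and rate into a multiplicity."""
    out: Dict[Tuple, int] = {}
    for prods, rate in options:
        key = (tuple(sorted(prods)), rate)
        out[key] = out.get(key, 0) + 1
    return [(prods, rate, mult) for (prods, rate), mult in out.items()]


def _ca_transitions(a: int, b: int, kinase_bound: bool):
    """(new_a, new_b, rate_name, direction) for all Ca moves on one CaM."""
    moves = []
    if a < 2:
        moves.append((a + 1, b, ca_binding_rate_name("C", a, kinase_bound), +1))
    if b < 2:
        moves.append((a, b + 1, ca_binding_rate_name("N", b, kinase_bound), +1))
    if a > 0:
        moves.append((a - 1, b, ca_unbinding_rate_name("C", a, kinase_bound), -1))
    if b > 0:
        moves.append((a, b - 1, ca_unbinding_rate_name("N", b, kinase_bound), -1))
    return moves


# -- rule instantiation functions -------------------------------------------

def _ca_bind_cam(s1, s2):
    pair = {s1[0], s2[0]}
    if pair != {"Ca", "CaM"}:
        return []
    c = s1 if s1[0] == "CaM" else s2
    a, b = c[1], c[2]
    return [((cam(na, nb),), rate)
            for na, nb, rate, d in _ca_transitions(a, b, False) if d > 0]


def _ca_unbind_cam(s):
    if s[0] != "CaM":
        return []
    a, b = s[1], s[2]
    return [((cam(na, nb), CA), rate)
            for na, nb, rate, d in _ca_transitions(a, b, False) if d < 0]


def _ng_bind(s1, s2):
    if {s1, s2} != {NG, cam(0, 0)}:
        return []
    return [((CAMNG,), "konNg")]


def _ng_unbind(s):
    if s != CAMNG:
        return []
    return [((NG, cam(0, 0)), "koffNg")]


def _cam_bind_k(s1, s2):
    pair = {s1[0], s2[0]}
    if pair != {"K", "CaM"}:
        return []
    kin = s1 if s1[0] == "K" else s2
    c = s1 if s1[0] == "CaM" else s2
    key = CAM_STATE_KEY[(c[1], c[2])]
    if kin[1] == "U":
        return [((kcam("U", c[1], c[2]),), f"konCaM{key}")]
    return [((kcam("P", c[1], c[2]),), f"kponCaM{key}")]


def _cam_unbind_k_u(s):
    if s[0] != "KCaM" or s[1] != "U":
        return []
    key = CAM_STATE_KEY[(s[2], s[3])]
    return [((k("U"), cam(s[2], s[3])), f"koffCaM{key}")]


def _cam_unbind_k_p(s):
    if s[0] != "KCaM" or s[1] != "P":
        return []
    return [((k("P"), cam(s[2], s[3])), "kpoffCaM")]


def _ca_bind_kcam(s1, s2):
    pair = {s1[0], s2[0]}
    if "Ca" not in pair:
        return []
    other = s1 if s2[0] == "Ca" else s2
    opts = []
    if other[0] == "KCaM":
        p, a, b = other[1], other[2], other[3]
        for na, nb, rate, d in _ca_transitions(a, b, True):
            if d > 0:
                opts.append(((kcam(p, na, nb),), rate))
    elif other[0] == "KK":
        for i in (1, 2):
            p, a, b = other[i]
            mate = other[3 - i]
            for na, nb, rate, d in _ca_transitions(a, b, True):
                if d > 0:
                    opts.append(((dimer((p, na, nb), mate),), rate))
    return opts


def _ca_unbind_kcam(s):
    opts = []
    if s[0] == "KCaM":
        p, a, b = s[1], s[2], s[3]
        for na, nb, rate, d in _ca_transitions(a, b, True):
            if d < 0:
                opts.append(((kcam(p, na, nb), CA), rate))
    elif s[0] == "KK":
        for i in (1, 2):
            p, a, b = s[i]
            mate = s[3 - i]
            for na, nb, rate, d in _ca_transitions(a, b, True):
                if d < 0:
                    opts.append(((dimer((p, na, nb), mate), CA), rate))
    return opts


def _dimerize(s1, s2):
    if s1[0] != "KCaM" or s2[0] != "KCaM":
        return []
    m1 = (s1[1], s1[2], s1[3])
    m2 = (s2[1], s2[2], s2[3])
    return [((dimer(m1, m2),), "konCaMKII")]


def _undimerize(s):
    if s[0] != "KK":
        return []
    m1, m2 = s[1], s[2]
    return [((kcam(*m1), kcam(*m2)), "koffCaMKII")]


def _dimer_phospho(s):
    # substrate member must be unphosphorylated with >= 1 Ca on its CaM;
    # the partner (necessarily CaM-bound) is the kinase, any Ca load.
    if s[0] != "KK":
        return []
    opts = []
    for i in (1, 2):
        p, a, b = s[i]
        mate = s[3 - i]
        if p == "U" and a + b >= 1:
            key = CAM_STATE_KEY[(a, b)]
            opts.append(((dimer(("P", a, b), mate),), f"kpCaM{key}"))
    return opts


def _pp1_bind(s1, s2):
    # the phosphatase tests only the substrate's phosphorylation state; a
    # phosphorylated monomer engaged in a transient kinase-substrate pair
    # (lifetime 1/koffCaMKII ~ 17 ms) is captured with its partner released
    pair = {s1[0], s2[0]}
    if "PP1" not in pair:
        return []
    other = s1 if s2[0] == "PP1" else s2
    if other == k("P"):
        return [((pp1k(None),), "konPP1")]
    if other[0] == "KCaM" and other[1] == "P":
        return [((pp1k((other[2], other[3])),), "konPP1")]
    if other[0] == "KK":
        opts = []
        for i in (1, 2):
            p, a, b = other[i]
            mate = other[3 - i]
            if p == "P":
                opts.append(((pp1k((a, b)), kcam(*mate)), "konPP1"))
        return opts
    return []


def _pp1_unbind(s):
    if s[0] != "PP1K":
        return []
    c = s[1]
    sub = k("P") if c is None else kcam("P", c[0], c[1])
    return [((PP1, sub), "koffPP1")]


def _pp1_catalysis(s):
    if s[0] != "PP1K":
        return []
    c = s[1]
    sub = k("U") if c is None else kcam("U", c[0], c[1])
    return [((PP1, sub), "kcat")]


def build_rule_set(include_monomer_dimerization: bool = True) -> List[Rule]:
    """The eight reaction-rule families of the model.

    With ``include_monomer_dimerization`` (the monomer model, Model 1) two
    CaM-bound monomers reversibly dimerize at ``konCaMKII``/``koffCaMKII``
    and phosphorylation happens inside the dimer.  Without it (the
    holoenzyme model, Model 2) the subunits are permanently linked within
    the two hexameric rings, so the dimerization rule is absent and the
    phosphorylation rule instead requires the dedicated ring neighbor of
    the substrate to be in the active conformation; that rule carries its
    neighbor guard as metadata and is applied agent-wise by the stochastic
    simulator rather than instantiated on well-mixed species.

    In both variants a phosphorylation rate exists only for substrates
    whose CaM carries at least one calcium ion.
    """
    kp_names = tuple(f"kpCaM{CAM_STATE_KEY[s]}" for s in PHOSPHO_COMPETENT)
    kon_cam = tuple(f"konCaM{CAM_STATE_KEY[s]}" for s in sorted(CAM_STATE_KEY))
    koff_cam = tuple(f"koffCaM{CAM_STATE_KEY[s]}" for s in sorted(CAM_STATE_KEY))
    kpon_cam = tuple(f"kponCaM{CAM_STATE_KEY[s]}" for s in sorted(CAM_STATE_KEY))

    rules = [
        Rule("ca_bind_cam", 1, 2, ("kon1C", "kon2C", "kon1N", "kon2N"),
             _fn=_ca_bind_cam),
        Rule("ca_unbind_cam", 1, 1, ("koff1C", "koff2C", "koff1N", "koff2N"),
             _fn=_ca_unbind_cam),
        Rule("ng_bind", 2, 2, ("konNg",),
             guard="CaM must be calcium-free and unbound", _fn=_ng_bind),
        Rule("ng_unbind", 2, 1, ("koffNg",), _fn=_ng_unbind),
        Rule("cam_bind_camkii", 3, 2, kon_cam + kpon_cam, _fn=_cam_bind_k),
        Rule("cam_unbind_camkii", 3, 1, koff_cam, _fn=_cam_unbind_k_u),
        Rule("cam_unbind_pcamkii", 7, 1, ("kpoffCaM",), _fn=_cam_unbind_k_p),
        Rule("ca_bind_kcam", 4, 2, ("konK1C", "konK2C", "konK1N", "konK2N"),
             _fn=_ca_bind_kcam),
        Rule("ca_unbind_kcam", 4, 1,
             ("koffK1C", "koffK2C", "koffK1N", "koffK2N"), _fn=_ca_unbind_kcam),
        Rule("pp1_bind", 8, 2, ("konPP1",),
             guard="substrate CaMKII must be phosphorylated", _fn=_pp1_bind),
        Rule("pp1_unbind", 8, 1, ("koffPP1",), _fn=_pp1_unbind),
        Rule("pp1_catalysis", 8, 1, ("kcat",), _fn=_pp1_catalysis),
    ]
    if include_monomer_dimerization:
        rules += [
            Rule("camkii_dimerize", 5, 2, ("konCaMKII",),
                 guard="both partners CaM-bound", _fn=_dimerize),
            Rule("camkii_undimerize", 5, 1, ("koffCaMKII",), _fn=_undimerize),
            Rule("autophosphorylation", 6, 1, kp_names,
                 guard="substrate CaM must carry >= 1 Ca2+",
                 _fn=_dimer_phospho),
        ]
    else:
        rules.append(
            Rule("autophosphorylation", 6, 1, kp_names,
                 guard=("substrate CaM must carry >= 1 Ca2+; kinase is the "
                        "dedicated ring neighbor and must be active "
                        "(CaM-bound or phosphorylated)"),
                 _fn=None))
    return rules
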