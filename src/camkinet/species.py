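"""Canonical species terms for the Ca2+/CaM/Ng/CaMKII/PP1 reaction system.

Every chemical species handled by the deterministic network is represented
as a small immutable tuple ("term").  The first element names the molecule
kind; the remaining elements encode internal state:

``("Ca",)``
    a free calcium ion.
``("CaM", a, b)``
    free calmodulin with ``a`` Ca2+ ions on the C lobe and ``b`` on the
    N lobe (``0 <= a, b <= 2``; sites within a lobe are indistinguishable,
    so only the counts are tracked).
``("Ng",)`` and ``("CaMNg",)``
    free neurogranin and the Ng-bound (necessarily calcium-free) CaM complex.
``("K", p)``
    a free CaMKII monomer, ``p`` in ``{"U", "P"}`` for the T286
    phosphorylation flag.
``("KCaM", p, a, b)``
    a CaM-bound monomer together with its CaM lobe counts.
``("KK", m1, m2)``
    a transient dimer of two CaM-bound monomers, each member
    ``m = (p, a, b)``; members are kept sorted so the term is canonical.
``("PP1",)`` and ``("PP1K", c)``
    free phosphatase and the PP1 / phospho-CaMKII Michaelis complex;
    ``c`` is ``None`` for a CaM-free substrate or ``(a, b)`` for the CaM
    lobe counts of a CaM-bound substrate.
"""

from __future__ import annotations

from typing import Optional, Tuple

Term = Tuple  # species term; see module docstring

CA = ("Ca",)
NG = ("Ng",)
CAMNG = ("CaMNg",)
PP1 = ("PP1",)

#: CaM lobe-count pair -> rate-name suffix used throughout Table-style names
#: (e.g. konCaM2C1N for the state with 2 C-lobe and 1 N-lobe calcium ions).
CAM_STATE_KEY = {
    (0, 0): "0",
    (1, 0): "1C",
    (2, 0): "2C",
    (0, 1): "1N",
    (1, 1): "1C1N",
    (2, 1): "2C1N",
    (0, 2): "2N",
    (1, 2): "1C2N",
    (2, 2): "4",
}

#: all nine CaM lobe-occupancy states, in a fixed deterministic order
CAM_STATES = tuple(sorted(CAM_STATE_KEY))


def cam(a: int, b: int) -> Term:
    return ("CaM", a, b)


def k(p: str) -> Term:
    return ("K", p)


def kcam(p: str, a: int, b: int) -> Term:
    return ("KCaM", p, a, b)


def dimer(m1: Tuple[str, int, int], m2: Tuple[str, int, int]) -> Term:
    """Unordered dimer of two CaM-bound monomers, canonically sorted."""
    lo, hi = sorted((m1, m2))
    return ("KK", lo, hi)


def pp1k(camstate: Optional[Tuple[int, int]]) -> Term:
    return ("PP1K", camstate)


def composition(sp: Term) -> dict:
    """Molecule content of a species term.

    Returns integer counts for the conserved moieties ``CaM``, ``K``
    (CaMKII monomers/subunits), ``Ng``, ``PP1`` and for ``Ca`` (free plus
    CaM-bound calcium ions).  These vectors are exact left null vectors of
    the stoichiometric matrix for every reaction family except calcium
    influx/efflux, which only touch free Ca.
    """
    kind = sp[0]
    if kind == "Ca":
        return {"Ca": 1}
    if kind == "CaM":
        return {"CaM": 1, "Ca": sp[1] + sp[2]}
    if kind == "Ng":
        return {"Ng": 1}
    if kind == "CaMNg":
        return {"CaM": 1, "Ng": 1}
    if kind == "K":
        return {"K": 1}
    if kind == "KCaM":
        return {"K": 1, "CaM": 1, "Ca": sp[2] + sp[3]}
    if kind == "KK":
        (_, a1, b1), (_, a2, b2) = sp[1], sp[2]
        return {"K": 2, "CaM": 2, "Ca": a1 + b1 + a2 + b2}
    if kind == "PP1":
        return {"PP1": 1}
    if kind == "PP1K":
        c = sp[1]
        if c is None:
            return {"PP1": 1, "K": 1}
        return {"PP1": 1, "K": 1, "CaM": 1, "Ca": c[0] + c[1]}
    raise ValueError(f"unknown species term {sp!r}")


def label(sp: Term) -> str:
    """Human-readable species label, e.g. ``mCaMKII(P)·CaM(2C1N)``."""
    kind = sp[0]
    if kind == "Ca":
        return "Ca"
    if kind == "CaM":
        return f"CaM({sp[1]}C{sp[2]}N)"
    if kind == "Ng":
        return "Ng"
    if kind == "CaMNg":
        return "CaM·Ng"
    if kind == "K":
        return f"mCaMKII({sp[1]})"
    if kind == "KCaM":
        return f"mCaMKII({sp[1]})·CaM({sp[2]}C{sp[3]}N)"
    if kind == "KK":
        def half(m):
            return f"mCaMKII({m[0]})·CaM({m[1]}C{m[2]}N)"
        return half(sp[1]) + "··" + half(sp[2])
    if kind == "PP1":
        return "PP1"
    if kind == "PP1K":
        c = sp[1]
        if c is None:
            return "PP1·mCaMKII(P)"
        return f"PP1·mCaMKII(P)·CaM({c[0]}C{c[1]}N)"
    raise ValueError(f"unknown species term {sp!r}")
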