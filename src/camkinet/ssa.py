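"""Network-free stochastic simulation of CaMKII holoenzymes (Model 2).

Discrete agents — dodecameric CaMKII holoenzymes (two stacked hexameric
rings of subunits), CaM, Ng and PP1 molecules, and individual free calcium
ions — react in the fixed postsynaptic-density volume under the same rule
set as the deterministic monomer model, applied agent-wise.  The one
structural difference is autophosphorylation: subunits are permanently
linked, each subunit can phosphorylate only its dedicated ring neighbor
(position ``i`` targets ``(i+1) mod 6`` in the same ring; the rings do not
interact), the kinase must be in the active conformation (CaM-bound with
any calcium load, or phosphorylated — a subunit stays active after losing
CaM) and the substrate must be unphosphorylated with CaM carrying at least
one calcium ion; the rate is indexed by the substrate's CaM state.

The simulator is an exact Gillespie SSA over grouped event channels (one
channel per rule instantiation class; a member is drawn uniformly within
the selected class, which is equivalent to one channel per concrete event).
The time-inhomogeneous calcium-influx channel is simulated by thinning
against a piecewise analytic envelope bound.
"""

from __future__ import annotations

import math
import random
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import equilibrate, generate_network
from .protocols import PulseProtocol
from .rates import (
    ConfigurationError,
    DEFAULT_VOLUME,
    RateTable,
    VolumeContext,
    build_rule_set,
    conc_to_count,
)
from . import species as sp

__all__ = ["HoloState", "SSATrajectory", "build_initial_state", "ssa_run",
           "run_ensemble", "compute_propensities", "apply_event"]

_S = lambda a, b: 3 * a + b  # CaM lobe counts -> flat state index 0..8

#: state indices with at least one calcium ion
_PHOSPHO_OK = tuple(s for s in range(9) if s // 3 + s % 3 > 0)

# CaM agent group ids: 0-8 free by state, 9-17 bound to U subunit by state,
# 18-26 bound to P subunit by state, 27 Ng-bound.
_G_FREE, _G_BU, _G_BP, _G_NG = 0, 9, 18, 27


class InternalConsistencyError(AssertionError):
    pass


class SSATrajectory:
    """Recorded observables of one stochastic run (counts, not uM)."""

    def __init__(self, t: np.ndarray, data: Dict[str, np.ndarray],
                 meta: Dict):
        self.t = t
        self.data = data
        self.meta = meta

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    def conc(self, key: str) -> np.ndarray:
        """Observable converted from molecule counts to uM."""
        return self.data[key] / self.meta["molecules_per_uM"]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({"time": self.t, **self.data})
        df["run_seed"] = self.meta.get("seed")
        return df


class HoloState:
    """Mutable agent state plus the grouped event-channel bookkeeping.

    Per-agent arrays hold the raw state (CaM lobe counts and location,
    subunit phosphorylation / CaM / PP1 flags); redundant group lists (with
    back-pointer position arrays) index agents by event class so channel
    propensities are O(1) and participants are drawn uniformly.  The
    :meth:`check_consistency` audit rebuilds every group from the raw
    arrays and is used by the tests after randomized runs.
    """

    def __init__(self, rates: RateTable, n_holo: int, n_cam: int, n_ng: int,
                 n_pp1: int, volume: VolumeContext = DEFAULT_VOLUME,
                 clamp_ca_count: Optional[int] = None):
        self.rates = rates
        self.vol = volume
        omega = volume.molecules_per_uM
        self.omega = omega
        self.n_holo = n_holo
        self.n_sub = 12 * n_holo
        self.n_cam = n_cam
        self.n_ng_total = n_ng
        self.n_pp1_total = n_pp1
        self.clamped = clamp_ca_count is not None

        # --- per-pair / unimolecular constants -------------------------
        g = rates.__getitem__
        self.c_kon_free_C = (g("kon1C") / omega, g("kon2C") / omega)
        self.c_kon_free_N = (g("kon1N") / omega, g("kon2N") / omega)
        self.koff_free_C = (g("koff1C"), g("koff2C"))
        self.koff_free_N = (g("koff1N"), g("koff2N"))
        self.c_kon_bnd_C = (g("konK1C") / omega, g("konK2C") / omega)
        self.c_kon_bnd_N = (g("konK1N") / omega, g("konK2N") / omega)
        self.koff_bnd_C = (g("koffK1C"), g("koffK2C"))
        self.koff_bnd_N = (g("koffK1N"), g("koffK2N"))
        key = {s: sp.CAM_STATE_KEY[(s // 3, s % 3)] for s in range(9)}
        self.c_konCaM = [g(f"konCaM{key[s]}") / omega for s in range(9)]
        self.koffCaM = [g(f"koffCaM{key[s]}") for s in range(9)]
        self.c_kponCaM = [g(f"kponCaM{key[s]}") / omega for s in range(9)]
        self.kpoffCaM = g("kpoffCaM")
        self.kp = [g(f"kpCaM{key[s]}") if s in _PHOSPHO_OK else 0.0
                   for s in range(9)]
        self.c_konNg = g("konNg") / omega
        self.koffNg = g("koffNg")
        self.c_konPP1 = g("konPP1") / omega
        self.koffPP1 = g("koffPP1")
        self.kcat = g("kcat")

        # --- raw agent state -------------------------------------------
        self.cam_a = np.zeros(n_cam, dtype=np.int8)
        self.cam_b = np.zeros(n_cam, dtype=np.int8)
        self.cam_loc = np.full(n_cam, -1, dtype=np.int64)  # -1 free, -2 Ng
        self.sub_p = np.zeros(self.n_sub, dtype=np.int8)
        self.sub_cam = np.full(self.n_sub, -1, dtype=np.int64)
        self.sub_pp1 = np.zeros(self.n_sub, dtype=np.int8)
        self.n_ng_free = n_ng
        self.n_pp1_free = n_pp1
        self.n_ca = clamp_ca_count if self.clamped else 0
        self.t = 0.0

        # directed neighbor map: kinase (ring r, pos i) -> substrate
        # (r, (i+1) mod 6); equivalently substrate u's kinase is pred[u]
        l = np.arange(self.n_sub) % 12
        h = np.arange(self.n_sub) - l
        r, i = l // 6, l % 6
        self.pred = h + r * 6 + (i - 1) % 6
        self.succ = h + r * 6 + (i + 1) % 6

        # --- group lists ------------------------------------------------
        self.cam_groups: List[List[int]] = [[] for _ in range(28)]
        self.cam_gid = np.full(n_cam, _G_FREE, dtype=np.int64)
        self.cam_gpos = np.zeros(n_cam, dtype=np.int64)
        for ci in range(n_cam):
            self.cam_gpos[ci] = ci
            self.cam_groups[_G_FREE].append(ci)
        self._gs = [len(g) for g in self.cam_groups]  # group sizes
        self._stale = True  # propensity cache invalid

        self.slotU: List[int] = list(range(self.n_sub))
        self.slotP: List[int] = []
        self.sub_slot_pos = np.arange(self.n_sub, dtype=np.int64)
        self.elig: List[List[int]] = [[] for _ in range(9)]
        self.sub_elig_s = np.full(self.n_sub, -1, dtype=np.int64)
        self.sub_elig_pos = np.full(self.n_sub, -1, dtype=np.int64)
        self.pfree: List[int] = []
        self.pbound: List[int] = []
        self.sub_pp1_pos = np.full(self.n_sub, -1, dtype=np.int64)

        # --- counters and audit trail ----------------------------------
        self.np_count = 0           # phosphorylated subunits
        self.ncb = 0                # CaM-bound subunits
        self.ncbu = 0               # CaM-bound unphosphorylated subunits
        self.n_phospho_events = 0
        self.peak_ca = self.n_ca
        self.event_log: Optional[List[Tuple[float, str, Tuple]]] = None

    # -- small list helpers --------------------------------------------
    @staticmethod
    def _ladd(lst, pos, idx):
        pos[idx] = len(lst)
        lst.append(idx)

    @staticmethod
    def _lrem(lst, pos, idx):
        p = pos[idx]
        last = lst[-1]
        lst[p] = last
        pos[last] = p
        lst.pop()
        pos[idx] = -1

    def _cam_move(self, ci, gid_new):
        gid_old = self.cam_gid[ci]
        grp = self.cam_groups[gid_old]
        p = self.cam_gpos[ci]
        last = grp[-1]
        grp[p] = last
        self.cam_gpos[last] = p
        grp.pop()
        self.cam_gid[ci] = gid_new
        self.cam_gpos[ci] = len(self.cam_groups[gid_new])
        self.cam_groups[gid_new].append(ci)
        self._gs[gid_old] -= 1
        self._gs[gid_new] += 1

    # -- derived state --------------------------------------------------
    def _active(self, u) -> bool:
        return bool(self.sub_p[u]) or self.sub_cam[u] >= 0

    def _update_elig(self, u):
        ci = self.sub_cam[u]
        if ci >= 0:
            s = _S(self.cam_a[ci], self.cam_b[ci])
        else:
            s = 0
        want = (not self.sub_p[u]) and ci >= 0 and s > 0 \
            and self._active(self.pred[u])
        cur = self.sub_elig_s[u]
        if want and cur == s:
            return
        if cur >= 0:
            self._lrem(self.elig[cur], self.sub_elig_pos, u)
            self.sub_elig_s[u] = -1
        if want:
            self._ladd(self.elig[s], self.sub_elig_pos, u)
            self.sub_elig_s[u] = s

    def _touch(self, u):
        self._update_elig(u)
        self._update_elig(self.succ[u])

    # ------------------------------------------------------------------
    # channel propensities (fixed layout, see _CHANNEL_LABELS)
    # ------------------------------------------------------------------
    def propensity_vector(self) -> List[float]:
        gs = self._gs
        f0, f1, f2, f3, f4, f5, f6, f7, f8 = gs[0:9]
        u0, u1, u2, u3, u4, u5, u6, u7, u8 = gs[9:18]
        p0, p1, p2, p3, p4, p5, p6, p7, p8 = gs[18:27]
        b0 = u0 + p0; b1 = u1 + p1; b2 = u2 + p2
        b3 = u3 + p3; b4 = u4 + p4; b5 = u5 + p5
        b6 = u6 + p6; b7 = u7 + p7; b8 = u8 + p8
        nca = self.n_ca
        nsU = len(self.slotU)
        nsP = len(self.slotP)
        npb = len(self.pbound)
        kb = self.c_konCaM
        kpb = self.c_kponCaM
        ko = self.koffCaM
        kp = self.kp
        e = self.elig
        return [
            self.c_kon_free_C[0] * nca * (f0 + f1 + f2),
            self.c_kon_free_C[1] * nca * (f3 + f4 + f5),
            self.c_kon_free_N[0] * nca * (f0 + f3 + f6),
            self.c_kon_free_N[1] * nca * (f1 + f4 + f7),
            self.koff_free_C[0] * (f3 + f4 + f5),
            self.koff_free_C[1] * (f6 + f7 + f8),
            self.koff_free_N[0] * (f1 + f4 + f7),
            self.koff_free_N[1] * (f2 + f5 + f8),
            self.c_kon_bnd_C[0] * nca * (b0 + b1 + b2),
            self.c_kon_bnd_C[1] * nca * (b3 + b4 + b5),
            self.c_kon_bnd_N[0] * nca * (b0 + b3 + b6),
            self.c_kon_bnd_N[1] * nca * (b1 + b4 + b7),
            self.koff_bnd_C[0] * (b3 + b4 + b5),
            self.koff_bnd_C[1] * (b6 + b7 + b8),
            self.koff_bnd_N[0] * (b1 + b4 + b7),
            self.koff_bnd_N[1] * (b2 + b5 + b8),
            kb[0] * f0 * nsU, kb[1] * f1 * nsU, kb[2] * f2 * nsU,
            kb[3] * f3 * nsU, kb[4] * f4 * nsU, kb[5] * f5 * nsU,
            kb[6] * f6 * nsU, kb[7] * f7 * nsU, kb[8] * f8 * nsU,
            kpb[0] * f0 * nsP, kpb[1] * f1 * nsP, kpb[2] * f2 * nsP,
            kpb[3] * f3 * nsP, kpb[4] * f4 * nsP, kpb[5] * f5 * nsP,
            kpb[6] * f6 * nsP, kpb[7] * f7 * nsP, kpb[8] * f8 * nsP,
            ko[0] * u0, ko[1] * u1, ko[2] * u2, ko[3] * u3, ko[4] * u4,
            ko[5] * u5, ko[6] * u6, ko[7] * u7, ko[8] * u8,
            self.kpoffCaM * (p0 + p1 + p2 + p3 + p4 + p5 + p6 + p7 + p8),
            self.c_konNg * self.n_ng_free * f0,
            self.koffNg * gs[_G_NG],
            kp[1] * len(e[1]), kp[2] * len(e[2]), kp[3] * len(e[3]),
            kp[4] * len(e[4]), kp[5] * len(e[5]), kp[6] * len(e[6]),
            kp[7] * len(e[7]), kp[8] * len(e[8]),
            self.c_konPP1 * self.n_pp1_free * len(self.pfree),
            self.koffPP1 * npb,
            self.kcat * npb,
        ]

    # ------------------------------------------------------------------
    # event application
    # ------------------------------------------------------------------
    def _pick_weighted(self, rng, groups, weights):
        total = sum(weights)
        x = rng.random() * total
        for g, w in zip(groups, weights):
            if x < w:
                return g[rng.randrange(len(g))]
            x -= w
        return groups[-1][rng.randrange(len(groups[-1]))]

    def _log(self, label, *participants):
        if self.event_log is not None:
            self.event_log.append((self.t, label, participants))

    def apply_channel(self, ch: int, rng: random.Random):
        """Execute one event drawn from channel ``ch``."""
        self._stale = True
        gr = self.cam_groups
        if ch < 4:  # Ca binds free CaM
            states = {0: [0, 1, 2], 1: [3, 4, 5],
                      2: [0, 3, 6], 3: [1, 4, 7]}[ch]
            glists = [gr[s] for s in states]
            ci = self._pick_weighted(rng, [g for g in glists if g],
                                     [len(g) for g in glists if g])
            if not self.clamped:
                self.n_ca -= 1
            if ch < 2:
                self.cam_a[ci] += 1
            else:
                self.cam_b[ci] += 1
            self._cam_move(ci, _S(self.cam_a[ci], self.cam_b[ci]))
            self._log("ca_bind_cam", ci)
        elif ch < 8:  # Ca unbinds free CaM
            states = {4: [3, 4, 5], 5: [6, 7, 8],
                      6: [1, 4, 7], 7: [2, 5, 8]}[ch]
            glists = [gr[s] for s in states]
            ci = self._pick_weighted(rng, [g for g in glists if g],
                                     [len(g) for g in glists if g])
            if not self.clamped:
                self.n_ca += 1
                if self.n_ca > self.peak_ca:
                    self.peak_ca = self.n_ca
            if ch < 6:
                self.cam_a[ci] -= 1
            else:
                self.cam_b[ci] -= 1
            self._cam_move(ci, _S(self.cam_a[ci], self.cam_b[ci]))
            self._log("ca_unbind_cam", ci)
        elif ch < 12:  # Ca binds subunit-bound CaM
            states = {8: [0, 1, 2], 9: [3, 4, 5],
                      10: [0, 3, 6], 11: [1, 4, 7]}[ch]
            glists = []
            for s in states:
                glists += [gr[_G_BU + s], gr[_G_BP + s]]
            glists = [g for g in glists if g]
            ci = self._pick_weighted(rng, glists, [len(g) for g in glists])
            if not self.clamped:
                self.n_ca -= 1
            if ch < 10:
                self.cam_a[ci] += 1
            else:
                self.cam_b[ci] += 1
            u = self.cam_loc[ci]
            base = _G_BP if self.sub_p[u] else _G_BU
            self._cam_move(ci, base + _S(self.cam_a[ci], self.cam_b[ci]))
            self._touch(u)
            self._log("ca_bind_kcam", ci, u)
        elif ch < 16:  # Ca unbinds subunit-bound CaM
            states = {12: [3, 4, 5], 13: [6, 7, 8],
                      14: [1, 4, 7], 15: [2, 5, 8]}[ch]
            glists = []
            for s in states:
                glists += [gr[_G_BU + s], gr[_G_BP + s]]
            glists = [g for g in glists if g]
            ci = self._pick_weighted(rng, glists, [len(g) for g in glists])
            if not self.clamped:
                self.n_ca += 1
                if self.n_ca > self.peak_ca:
                    self.peak_ca = self.n_ca
            if ch < 14:
                self.cam_a[ci] -= 1
            else:
                self.cam_b[ci] -= 1
            u = self.cam_loc[ci]
            base = _G_BP if self.sub_p[u] else _G_BU
            self._cam_move(ci, base + _S(self.cam_a[ci], self.cam_b[ci]))
            self._touch(u)
            self._log("ca_unbind_kcam", ci, u)
        elif ch < 25:  # CaM binds U subunit
            s = ch - 16
            ci = gr[s][rng.randrange(len(gr[s]))]
            u = self.slotU[rng.randrange(len(self.slotU))]
            self._bind_cam(ci, u, s, phospho=False)
            self._log("cam_bind_camkii", ci, u)
        elif ch < 34:  # CaM binds P subunit
            s = ch - 25
            ci = gr[s][rng.randrange(len(gr[s]))]
            u = self.slotP[rng.randrange(len(self.slotP))]
            self._bind_cam(ci, u, s, phospho=True)
            self._log("cam_bind_pcamkii", ci, u)
        elif ch < 43:  # CaM unbinds from U subunit
            s = ch - 34
            ci = gr[_G_BU + s][rng.randrange(len(gr[_G_BU + s]))]
            self._unbind_cam(ci)
            self._log("cam_unbind_camkii", ci)
        elif ch == 43:  # CaM unbinds from P subunit (state-independent rate)
            glists = [gr[_G_BP + s] for s in range(9) if gr[_G_BP + s]]
            ci = self._pick_weighted(rng, glists, [len(g) for g in glists])
            self._unbind_cam(ci)
            self._log("cam_unbind_pcamkii", ci)
        elif ch == 44:  # Ng binds calcium-free free CaM
            ci = gr[0][rng.randrange(len(gr[0]))]
            self.cam_loc[ci] = -2
            self._cam_move(ci, _G_NG)
            self.n_ng_free -= 1
            self._log("ng_bind", ci)
        elif ch == 45:  # Ng unbinds
            ci = gr[_G_NG][rng.randrange(len(gr[_G_NG]))]
            self.cam_loc[ci] = -1
            self._cam_move(ci, 0)
            self.n_ng_free += 1
            self._log("ng_unbind", ci)
        elif ch < 54:  # neighbor phosphorylation, by substrate CaM state
            s = _PHOSPHO_OK[ch - 46]
            u = self.elig[s][rng.randrange(len(self.elig[s]))]
            ci = self.sub_cam[u]
            self.sub_p[u] = 1
            self._cam_move(ci, _G_BP + s)
            self.ncbu -= 1
            self.np_count += 1
            self.n_phospho_events += 1
            self._ladd(self.pfree, self.sub_pp1_pos, u)
            self._touch(u)
            self._log("phospho", int(self.pred[u]), u)
        elif ch == 54:  # PP1 binds a phosphorylated subunit
            u = self.pfree[rng.randrange(len(self.pfree))]
            self._lrem(self.pfree, self.sub_pp1_pos, u)
            self.sub_pp1[u] = 1
            self._ladd(self.pbound, self.sub_pp1_pos, u)
            self.n_pp1_free -= 1
            self._log("pp1_bind", u)
        elif ch == 55:  # PP1 unbinds without catalysis
            u = self.pbound[rng.randrange(len(self.pbound))]
            self._lrem(self.pbound, self.sub_pp1_pos, u)
            self.sub_pp1[u] = 0
            self._ladd(self.pfree, self.sub_pp1_pos, u)
            self.n_pp1_free += 1
            self._log("pp1_unbind", u)
        elif ch == 56:  # PP1 catalysis: dephosphorylate and release
            u = self.pbound[rng.randrange(len(self.pbound))]
            self._lrem(self.pbound, self.sub_pp1_pos, u)
            self.sub_pp1[u] = 0
            self.sub_p[u] = 0
            self.n_pp1_free += 1
            self.np_count -= 1
            ci = self.sub_cam[u]
            if ci >= 0:
                self._cam_move(ci, _G_BU + _S(self.cam_a[ci], self.cam_b[ci]))
                self.ncbu += 1
            else:
                self._lrem(self.slotP, self.sub_slot_pos, u)
                self._ladd(self.slotU, self.sub_slot_pos, u)
            self._touch(u)
            self._log("pp1_catalysis", u)
        else:
            raise InternalConsistencyError(f"unknown channel {ch}")

    def _bind_cam(self, ci, u, s, phospho):
        self.cam_loc[ci] = u
        self.sub_cam[u] = ci
        if phospho:
            self._lrem(self.slotP, self.sub_slot_pos, u)
            self._cam_move(ci, _G_BP + s)
        else:
            self._lrem(self.slotU, self.sub_slot_pos, u)
            self._cam_move(ci, _G_BU + s)
            self.ncbu += 1
        self.ncb += 1
        self._touch(u)

    def _unbind_cam(self, ci):
        u = self.cam_loc[ci]
        self.cam_loc[ci] = -1
        self.sub_cam[u] = -1
        if self.sub_p[u]:
            self._ladd(self.slotP, self.sub_slot_pos, u)
        else:
            self._ladd(self.slotU, self.sub_slot_pos, u)
            self.ncbu -= 1
        self.ncb -= 1
        self._cam_move(ci, _S(self.cam_a[ci], self.cam_b[ci]))
        self._touch(u)

    # ------------------------------------------------------------------
    def check_consistency(self):
        """Rebuild all group structures from raw arrays and compare."""
        if self._gs != [len(g) for g in self.cam_groups]:
            raise InternalConsistencyError("group size cache broken")
        n_ng_bound = 0
        for ci in range(self.n_cam):
            loc = self.cam_loc[ci]
            s = _S(self.cam_a[ci], self.cam_b[ci])
            if loc == -2:
                gid = _G_NG
                n_ng_bound += 1
                if s != 0:
                    raise InternalConsistencyError("Ng-bound CaM carries Ca")
            elif loc == -1:
                gid = s
            else:
                if self.sub_cam[loc] != ci:
                    raise InternalConsistencyError("cam/subunit link broken")
                gid = (_G_BP if self.sub_p[loc] else _G_BU) + s
            if self.cam_gid[ci] != gid:
                raise InternalConsistencyError(
                    f"cam {ci} group {self.cam_gid[ci]} != {gid}")
            grp = self.cam_groups[gid]
            if grp[self.cam_gpos[ci]] != ci:
                raise InternalConsistencyError("cam group position broken")
        if self.n_ng_free != self.n_ng_total - n_ng_bound:
            raise InternalConsistencyError("Ng count broken")
        np_c = ncb = ncbu = n_pp1_bound = 0
        for u in range(self.n_sub):
            ci = self.sub_cam[u]
            if self.sub_pp1[u] and not self.sub_p[u]:
                raise InternalConsistencyError("PP1 bound to U subunit")
            if self.sub_p[u]:
                np_c += 1
            if ci >= 0:
                ncb += 1
                if not self.sub_p[u]:
                    ncbu += 1
            else:
                slot = self.slotP if self.sub_p[u] else self.slotU
                if slot[self.sub_slot_pos[u]] != u:
                    raise InternalConsistencyError("slot list broken")
            if self.sub_pp1[u]:
                n_pp1_bound += 1
                if self.pbound[self.sub_pp1_pos[u]] != u:
                    raise InternalConsistencyError("pbound list broken")
            elif self.sub_p[u]:
                if self.pfree[self.sub_pp1_pos[u]] != u:
                    raise InternalConsistencyError("pfree list broken")
            # eligibility
            want = (not self.sub_p[u]) and ci >= 0 \
                and _S(self.cam_a[ci], self.cam_b[ci]) > 0 \
                and self._active(self.pred[u])
            cur = self.sub_elig_s[u]
            if want != (cur >= 0):
                raise InternalConsistencyError(f"eligibility broken at {u}")
            if cur >= 0 and self.elig[cur][self.sub_elig_pos[u]] != u:
                raise InternalConsistencyError("elig list broken")
        if (np_c, ncb, ncbu) != (self.np_count, self.ncb, self.ncbu):
            raise InternalConsistencyError("counters broken")
        if self.n_pp1_free != self.n_pp1_total - n_pp1_bound:
            raise InternalConsistencyError("PP1 count broken")


_CHANNEL_LABELS = (
    ["ca_bind_cam_C1", "ca_bind_cam_C2", "ca_bind_cam_N1", "ca_bind_cam_N2",
     "ca_unbind_cam_C1", "ca_unbind_cam_C2", "ca_unbind_cam_N1",
     "ca_unbind_cam_N2",
     "ca_bind_kcam_C1", "ca_bind_kcam_C2", "ca_bind_kcam_N1",
     "ca_bind_kcam_N2",
     "ca_unbind_kcam_C1", "ca_unbind_kcam_C2", "ca_unbind_kcam_N1",
     "ca_unbind_kcam_N2"]
    + [f"cam_bind_camkii_{s}" for s in range(9)]
    + [f"cam_bind_pcamkii_{s}" for s in range(9)]
    + [f"cam_unbind_camkii_{s}" for s in range(9)]
    + ["cam_unbind_pcamkii", "ng_bind", "ng_unbind"]
    + [f"phospho_{s}" for s in _PHOSPHO_OK]
    + ["pp1_bind", "pp1_unbind", "pp1_catalysis"]
)


def compute_propensities(state: HoloState) -> Dict[str, float]:
    """Named propensity of every constant-rate event channel (1/s).

    The calcium influx/efflux channels depend on the protocol and are
    reported by :func:`ssa_run`; everything else is here.
    """
    return dict(zip(_CHANNEL_LABELS, state.propensity_vector()))


def apply_event(state: HoloState, channel: str, rng: random.Random):
    """Apply one event drawn from the named channel (testing hook)."""
    idx = _CHANNEL_LABELS.index(channel)
    props = state.propensity_vector()
    if props[idx] <= 0:
        raise InternalConsistencyError(
            f"channel {channel} has no valid participants")
    state.apply_channel(idx, rng)


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------

def build_initial_state(rates: RateTable, cam_total: float, ng_total: float,
                        camkii_total: float = 80.0, pp1_total: float = 1.25,
                        volume: VolumeContext = DEFAULT_VOLUME,
                        baseline_ca: float = 0.1,
                        equilibrium=None, seed: int = 0,
                        burn_in: float = 5.0,
                        k_e: float = 1000.0) -> HoloState:
    """Agent state at the resting calcium baseline.

    Molecule counts are the rounded counts of the configured totals (80 uM
    CaMKII gives 752 monomers, instantiated as 63 complete holoenzymes /
    756 subunits so no partial ring exists).  CaM occupancies (free state,
    Ng-bound, subunit-bound) are sampled from the deterministic baseline
    equilibrium marginals and the state is then relaxed by a short SSA
    burn-in at baseline.  The construction is fully determined by ``seed``.
    """
    n_mono = conc_to_count(camkii_total, volume)
    n_holo = int(round(n_mono / 12.0))
    n_cam = conc_to_count(cam_total, volume)
    n_ng = conc_to_count(ng_total, volume)
    n_pp1 = conc_to_count(pp1_total, volume)

    if equilibrium is None:
        rules = build_rule_set(include_monomer_dimerization=False)
        seeds = [sp.CA, sp.cam(0, 0)]
        if n_ng:
            seeds.append(sp.NG)
        if n_holo:
            seeds.append(sp.k("U"))
        net = generate_network(rules, seeds, rates)
        totals = {"CaM": cam_total, "Ng": ng_total}
        if n_holo:
            totals["K"] = camkii_total
        equilibrium = equilibrate(net, totals, target_free_ca=baseline_ca)

    state = HoloState(rates, n_holo, n_cam, n_ng, n_pp1, volume)
    rng_np = np.random.default_rng(np.random.SeedSequence(seed))
    rng = random.Random(seed)

    # marginal occupancy of one CaM molecule at baseline
    net = equilibrium.network
    probs = []
    cells = []  # (state index s, context: "free" | "bound" | "ng")
    for (a, b) in sorted(sp.CAM_STATE_KEY):
        c = equilibrium.concentration(sp.cam(a, b)) if sp.cam(a, b) in net.index else 0.0
        probs.append(c)
        cells.append((_S(a, b), "free"))
        term = sp.kcam("U", a, b)
        c = equilibrium.concentration(term) if term in net.index else 0.0
        probs.append(c)
        cells.append((_S(a, b), "bound"))
    camng = equilibrium.concentration(sp.CAMNG) if sp.CAMNG in net.index else 0.0
    probs.append(camng)
    cells.append((0, "ng"))
    probs = np.array(probs)
    probs = probs / probs.sum() if probs.sum() > 0 else None
    if probs is not None and n_cam:
        counts = rng_np.multinomial(n_cam, probs)
    else:
        counts = np.zeros(len(cells), dtype=int)

    free_subunits = list(range(state.n_sub))
    rng.shuffle(free_subunits)
    ci = 0
    for (s, ctx), n in zip(cells, counts):
        for _ in range(int(n)):
            a, b = s // 3, s % 3
            state.cam_a[ci], state.cam_b[ci] = a, b
            if ctx == "free":
                state._cam_move(ci, s)
            elif ctx == "ng":
                state.cam_loc[ci] = -2
                state._cam_move(ci, _G_NG)
                state.n_ng_free -= 1
            else:
                if not free_subunits:
                    state._cam_move(ci, s)  # overflow: leave free
                else:
                    u = free_subunits.pop()
                    state.cam_loc[ci] = u
                    state.sub_cam[u] = ci
                    state._lrem(state.slotU, state.sub_slot_pos, u)
                    state._cam_move(ci, _G_BU + s)
                    state.ncb += 1
                    state.ncbu += 1
            ci += 1
    for u in range(state.n_sub):
        state._update_elig(u)
    state.n_ca = int(rng_np.poisson(baseline_ca * volume.molecules_per_uM))
    state.peak_ca = state.n_ca

    if burn_in > 0:
        proto = PulseProtocol(baseline=baseline_ca, onsets=(), k_e=k_e)
        ssa_run(state, proto, t_end=burn_in, record_dt=burn_in,
                seed=rng.randrange(2 ** 31))
        state.t = 0.0
        state.n_phospho_events = 0
        state.peak_ca = state.n_ca
    return state


# ---------------------------------------------------------------------------
# the SSA driver
# ---------------------------------------------------------------------------

def ssa_run(state: HoloState, protocol: PulseProtocol, t_end: float,
            record_dt: float = 0.1, seed: int = 0,
            record_events: bool = False) -> SSATrajectory:
    """Exact SSA run from ``state.t`` to ``t_end`` under a calcium protocol.

    Constant-rate channels are simulated exactly; the time-inhomogeneous
    influx channel is thinned against a piecewise bound that is refreshed
    at every step and at pulse onsets (the envelope of a pulse is bounded
    by its analytic peak before the peak time and by its current, strictly
    decreasing value after it).  Identical (state, protocol, seed) produce
    identical trajectories.
    """
    rng = random.Random(seed)
    omega = state.omega
    if state.clamped and protocol.mode != "clamp":
        raise ConfigurationError("clamped state requires a clamp protocol")
    if protocol.mode == "clamp" and not state.clamped:
        state.clamped = True
        state.n_ca = int(round(protocol.clamp_value * omega))
    pulse_mode = protocol.mode == "pulse"

    if record_events and state.event_log is None:
        state.event_log = []

    j0 = protocol.baseline_influx * omega if pulse_mode else 0.0
    amp = protocol.amplitude * omega
    tau_r, tau_f, k_e = protocol.tau_r, protocol.tau_f, protocol.k_e
    peak_env = amp * (tau_f / tau_r) * math.exp(-1.0) if amp > 0 else 0.0
    onsets = list(protocol.onsets)
    horizon = 40.0 * tau_f  # pulses older than this contribute ~A*4e-16

    def env_at(t):
        lam = 0.0
        for o in onsets:
            dt = t - o
            if 0.0 < dt < horizon:
                lam += amp * (dt / tau_r) * math.exp(-dt / tau_f)
        return lam

    def env_bound(t):
        b = 0.0
        for o in onsets:
            dt = t - o
            if dt < 0 or dt >= horizon:
                continue
            b += peak_env if dt < tau_f else \
                amp * (dt / tau_r) * math.exp(-dt / tau_f)
        return b

    n_rec = int(math.floor((t_end - state.t) / record_dt + 1e-9)) + 1
    rec_t = state.t + record_dt * np.arange(n_rec)
    rec = {k: np.zeros(n_rec, dtype=np.int64) for k in
           ("n_p", "n_cam_bound", "n_cam_bound_u", "n_free_ca", "n_camng")}
    i_rec = 0

    def record_until(t_now):
        nonlocal i_rec
        while i_rec < n_rec and rec_t[i_rec] <= t_now + 1e-12:
            rec["n_p"][i_rec] = state.np_count
            rec["n_cam_bound"][i_rec] = state.ncb
            rec["n_cam_bound_u"][i_rec] = state.ncbu
            rec["n_free_ca"][i_rec] = state.n_ca
            rec["n_camng"][i_rec] = len(state.cam_groups[_G_NG])
            i_rec += 1

    t = state.t
    record_until(t)
    next_onset_i = 0
    while next_onset_i < len(onsets) and onsets[next_onset_i] <= t:
        next_onset_i += 1

    props = state.propensity_vector()
    p_sum = sum(props)
    state._stale = False
    while t < t_end:
        if state._stale:
            props = state.propensity_vector()
            p_sum = sum(props)
            state._stale = False
        if pulse_mode:
            s_const = p_sum + k_e * state.n_ca
            bound = j0 + env_bound(t)
        else:
            s_const = p_sum
            bound = 0.0
        total = s_const + bound
        barrier = onsets[next_onset_i] if next_onset_i < len(onsets) else t_end
        barrier = min(barrier, t_end)
        if total <= 0.0:
            t = barrier
        else:
            dt = -math.log(1.0 - rng.random()) / total
            if t + dt >= barrier:
                t = barrier
            else:
                t += dt
                record_until(t)  # grid points before this event keep pre-event state
                x = rng.random() * total
                if x < bound:
                    # influx candidate: thin against the envelope bound
                    if x < (j0 + env_at(t)):
                        state.n_ca += 1
                        state._stale = True
                        if state.n_ca > state.peak_ca:
                            state.peak_ca = state.n_ca
                        state._log("ca_influx")
                elif x < bound + (k_e * state.n_ca if pulse_mode else 0.0):
                    state.n_ca -= 1
                    state._stale = True
                    state._log("ca_efflux")
                else:
                    x -= bound + (k_e * state.n_ca if pulse_mode else 0.0)
                    ch = 0
                    acc = props[0]
                    while acc < x and ch < len(props) - 1:
                        ch += 1
                        acc += props[ch]
                    state.t = t
                    state.apply_channel(ch, rng)
        record_until(t)
        while next_onset_i < len(onsets) and onsets[next_onset_i] <= t:
            next_onset_i += 1
        state.t = t

    record_until(t_end)
    meta = {
        "seed": seed,
        "molecules_per_uM": omega,
        "protocol": protocol.to_dict(),
        "peak_free_ca_uM": state.peak_ca / omega,
        "n_phospho_events": state.n_phospho_events,
        "n_holo": state.n_holo, "n_cam": state.n_cam,
        "n_ng": state.n_ng_total, "n_pp1": state.n_pp1_total,
    }
    return SSATrajectory(rec_t, rec, meta)


def run_ensemble(rates: RateTable, protocol: PulseProtocol, n_runs: int,
                 base_seed: int, cam_total: float, ng_total: float,
                 camkii_total: float = 80.0, pp1_total: float = 1.25,
                 t_end: Optional[float] = None, record_dt: float = 0.1,
                 burn_in: float = 5.0,
                 volume: VolumeContext = DEFAULT_VOLUME) -> List[SSATrajectory]:
    """Independent stochastic runs with seeds derived from ``base_seed``.

    The deterministic baseline equilibrium is computed once and shared;
    each run gets its own sampled initial state, burn-in and event
    sequence.  Per-run metadata (seed, peak free calcium, number of
    phosphorylation events) is retained for the responder statistics.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    if t_end is None:
        t_end = (protocol.onsets[-1] + 10.0) if protocol.onsets else 10.0
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) % (2 ** 31) for s in ss.generate_state(2 * n_runs)]

    rules = build_rule_set(include_monomer_dimerization=False)
    seeds_sp = [sp.CA, sp.cam(0, 0)]
    if ng_total > 0:
        seeds_sp.append(sp.NG)
    if camkii_total > 0:
        seeds_sp.append(sp.k("U"))
    net = generate_network(rules, seeds_sp, rates)
    totals = {"CaM": cam_total, "Ng": ng_total}
    if camkii_total > 0:
        totals["K"] = camkii_total
    eq = equilibrate(net, totals, target_free_ca=protocol.baseline)

    out = []
    for i in range(n_runs):
        st = build_initial_state(
            rates, cam_total, ng_total, camkii_total, pp1_total,
            volume=volume, baseline_ca=protocol.baseline, equilibrium=eq,
            seed=seeds[2 * i], burn_in=burn_in, k_e=protocol.k_e)
        out.append(ssa_run(st, protocol, t_end=t_end, record_dt=record_dt,
                           seed=seeds[2 * i + 1]))
    return out
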