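"""Whole-body model: blood pools, lungs, kidneys, rest-of-body, gut wall
with multi-dose oral absorption, portal vein, and the lobule liver.

All compartments except the liver and gut wall are flow-limited,
well-stirred tissues with a partition coefficient ``Kp`` and the
blood-to-plasma ratio ``R_BP`` mapping tissue concentration back to the
emergent venous blood.  Oral doses enter the gut wall by first-order
absorption; drug leaves the gut wall to the portal vein at the hybrid flow
``Q_g`` acting on the unbound concentration, and the liver inlet mixes
hepatic-artery and portal-vein blood by flow weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .kinetics import DrugSet, EnzymeSet, InteractionTable
from .liver import LiverGrid, LiverModel


@dataclass
class BodyParams:
    """Compartment volumes (L), flows (L/h) and per-drug distribution data."""

    V_AB: float
    V_VB: float
    V_Lungs: float
    V_K: float
    V_RB: float
    V_GW: float
    V_PV: float
    Q_T: float
    Q_Lungs: float
    Q_K: float
    Q_RB: float
    Q_Liver: float
    Q_ha: float
    Q_pv: float
    # per-drug arrays (nC,)
    Kp_Lungs: np.ndarray
    Kp_K: np.ndarray
    Kp_RB: np.ndarray
    R_BP: np.ndarray
    CL_int_R: np.ndarray
    Qg: np.ndarray

    def __post_init__(self):
        for name in ("Kp_Lungs", "Kp_K", "Kp_RB", "R_BP", "CL_int_R", "Qg"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        vols = (self.V_AB, self.V_VB, self.V_Lungs, self.V_K, self.V_RB,
                self.V_GW, self.V_PV)
        flows = (self.Q_T, self.Q_Lungs, self.Q_K, self.Q_RB, self.Q_Liver,
                 self.Q_ha, self.Q_pv)
        if any(v <= 0 for v in vols) or any(q <= 0 for q in flows):
            raise ValueError("all volumes and flows must be > 0")
        if abs(self.Q_T - (self.Q_Liver + self.Q_K + self.Q_RB)) > 1e-6 * self.Q_T:
            raise ValueError("flow closure violated: Q_T != Q_Liver + Q_K + Q_RB")
        if abs(self.Q_Liver - (self.Q_ha + self.Q_pv)) > 1e-6 * self.Q_Liver:
            raise ValueError("liver flow split violated: Q_Liver != Q_ha + Q_pv")


@dataclass
class Regimen:
    """Oral dosing schedule of one drug.

    ``doses`` is a list of ``(amount_umol, time_h)`` pairs; ``Fa`` is the
    fraction absorbed and ``ka`` the first-order absorption rate.
    """

    Fa: float
    ka: float
    doses: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.Fa <= 1.0:
            raise ValueError("Fa must be in (0, 1]")
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        times = [t for _, t in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")

    @property
    def dose_times(self) -> list:
        return [t for _, t in self.doses]

    def absorption_rate(self, t: float) -> float:
        """Total absorption input at time t, umol/h (sum over past doses)."""
        rate = 0.0
        for amount, ti in self.doses:
            if t >= ti:
                rate += self.Fa * amount * self.ka * np.exp(-self.ka * (t - ti))
        return rate

    def absorbed_by(self, t: float) -> float:
        """Cumulative amount absorbed up to time t, umol."""
        tot = 0.0
        for amount, ti in self.doses:
            if t >= ti:
                tot += self.Fa * amount * (1.0 - np.exp(-self.ka * (t - ti)))
        return tot


def liver_inflow(c_ab: np.ndarray, c_pv: np.ndarray,
                 q_ha: float, q_pv: float) -> np.ndarray:
    """Lobule-inlet concentration: flow-weighted artery/portal mixture."""
    return (q_ha * c_ab + q_pv * c_pv) / (q_ha + q_pv)


class PBPKSystem:
    """Assembled ODE system d y / d t = f(t, y) for an arbitrary drug set.

    State layout (flattened): liver blood Cb (nC x N), liver hepatocytes
    Ch (nC x N), liver enzymes Etot (nE x N), then per-drug scalars
    C_AB, C_VB, C_Lungs, C_K, C_RB, C_g, C_pv, then gut enzymes (nE).
    All concentrations start at zero and enzymes at 1 (basal).
    """

    def __init__(self, grid: LiverGrid, drugs: DrugSet, enzymes: EnzymeSet,
                 table_liver: InteractionTable, table_gut: InteractionTable,
                 body: BodyParams, regimens: list):
        if len(regimens) != drugs.n_drugs:
            raise ValueError("one regimen per drug required")
        self.grid = grid
        self.drugs = drugs
        self.enzymes = enzymes
        self.table_gut = table_gut
        self.body = body
        self.regimens = regimens
        self.liver = LiverModel(grid, drugs, enzymes, table_liver)

        nC, nE, N = drugs.n_drugs, enzymes.n_enzymes, grid.n_cells
        self.nC, self.nE, self.N = nC, nE, N
        self._i_cb = 0
        self._i_ch = nC * N
        self._i_et = 2 * nC * N
        self._i_cmp = 2 * nC * N + nE * N
        self._i_etg = self._i_cmp + 7 * nC
        self.size = self._i_etg + nE

    # ------------------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.size)
        y[self._i_et:self._i_cmp].reshape(self.nE, self.N)[:] = 1.0
        y[self._i_etg:] = 1.0
        return y

    def unpack(self, y: np.ndarray) -> dict:
        """Split a state vector (size,) or trajectory (size, T) into views."""
        nC, nE, N = self.nC, self.nE, self.N
        y = np.asarray(y)
        tail = y.shape[1:]

        def seg(a, b, *shape):
            return y[a:b].reshape(*shape, *tail)

        cmp_ = seg(self._i_cmp, self._i_etg, 7, nC)
        return {
            "Cb": seg(self._i_cb, self._i_ch, nC, N),
            "Ch": seg(self._i_ch, self._i_et, nC, N),
            "Etot": seg(self._i_et, self._i_cmp, nE, N),
            "C_AB": cmp_[0], "C_VB": cmp_[1], "C_Lungs": cmp_[2],
            "C_K": cmp_[3], "C_RB": cmp_[4], "C_g": cmp_[5], "C_pv": cmp_[6],
            "Etot_g": y[self._i_etg:],
        }

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        s = self.unpack(y)
        b = self.body
        dy = np.empty_like(y)

        c0 = np.maximum(liver_inflow(s["C_AB"], s["C_pv"], b.Q_ha, b.Q_pv), 0.0)
        d_cb, d_ch, d_et = self.liver.rhs(s["Cb"], s["Ch"], s["Etot"], c0)
        dy[self._i_cb:self._i_ch] = d_cb.ravel()
        dy[self._i_ch:self._i_et] = d_ch.ravel()
        dy[self._i_et:self._i_cmp] = d_et.ravel()

        c_liver = self.liver.outlet(s["Cb"])
        back_k = s["C_K"] * b.R_BP / b.Kp_K
        back_rb = s["C_RB"] * b.R_BP / b.Kp_RB
        back_lu = s["C_Lungs"] * b.R_BP / b.Kp_Lungs

        d_ab = b.Q_T * (back_lu - s["C_AB"]) / b.V_AB
        d_vb = (b.Q_Liver * c_liver + b.Q_K * back_k + b.Q_RB * back_rb
                - b.Q_T * s["C_VB"]) / b.V_VB
        d_k = (b.Q_K * (s["C_AB"] - back_k) - b.CL_int_R * s["C_K"]) / b.V_K
        d_lu = b.Q_Lungs * (s["C_VB"] - back_lu) / b.V_Lungs
        d_rb = b.Q_RB * (s["C_AB"] - back_rb) / b.V_RB

        # gut wall: absorption + metabolism + convection to the portal vein
        fuCg = self.drugs.fu_g * s["C_g"]
        met_g = kinetics.metabolism_rates(fuCg, s["Etot_g"], self.table_gut,
                                          self.enzymes.E0_gut)
        absorb = np.array([r.absorption_rate(t) for r in self.regimens])
        d_g = absorb / b.V_GW - met_g - b.Qg * fuCg / b.V_GW
        d_etg = kinetics.enzyme_rhs(s["Etot_g"], fuCg, self.table_gut,
                                    self.enzymes.kdeg_gut)
        d_pv = (b.Q_pv * (s["C_AB"] - s["C_pv"]) + b.Qg * fuCg) / b.V_PV

        cmp_out = np.stack([d_ab, d_vb, d_lu, d_k, d_rb, d_g, d_pv])
        dy[self._i_cmp:self._i_etg] = cmp_out.ravel()
        dy[self._i_etg:] = d_etg
        return dy

    # ------------------------------------------------------------------
    def total_amount(self, y: np.ndarray) -> np.ndarray:
        """Drug amount in the whole system per drug, umol (for mass audits)."""
        s = self.unpack(y)
        b = self.body
        g = self.grid
        amt = (s["Cb"] * g.blood_volumes[None, :]).sum(axis=1)
        amt += (s["Ch"] * g.hepatocyte_volumes[None, :]).sum(axis=1)
        amt += b.V_AB * s["C_AB"] + b.V_VB * s["C_VB"] + b.V_Lungs * s["C_Lungs"]
        amt += b.V_K * s["C_K"] + b.V_RB * s["C_RB"]
        amt += b.V_GW * s["C_g"] + b.V_PV * s["C_pv"]
        return amt

    # ------------------------------------------------------------------
    def jac_sparsity(self):
        """Boolean Jacobian structure for the stiff integrator."""
        from scipy.sparse import lil_matrix

        nC, nE, N = self.nC, self.nE, self.N
        sp = lil_matrix((self.size, self.size), dtype=bool)

        def cb(i, j):
            return self._i_cb + i * N + j

        def ch(i, j):
            return self._i_ch + i * N + j

        def et(e, j):
            return self._i_et + e * N + j

        def cmp_(k, i):
            return self._i_cmp + k * nC + i

        AB, VB, LU, K, RB, G, PV = range(7)
        for i in range(nC):
            for j in range(N):
                sp[cb(i, j), cb(i, j)] = True
                sp[cb(i, j), ch(i, j)] = True
                if j > 0:
                    sp[cb(i, j), cb(i, j - 1)] = True
                else:
                    sp[cb(i, 0), cmp_(AB, i)] = True
                    sp[cb(i, 0), cmp_(PV, i)] = True
                sp[ch(i, j), cb(i, j)] = True
                for k in range(nC):
                    sp[ch(i, j), ch(k, j)] = True
                for e in range(nE):
                    sp[ch(i, j), et(e, j)] = True
            for e in range(nE):
                for j in range(N):
                    for k in range(nC):
                        sp[et(e, j), ch(k, j)] = True
                    sp[et(e, j), et(e, j)] = True
            sp[cmp_(AB, i), cmp_(AB, i)] = True
            sp[cmp_(AB, i), cmp_(LU, i)] = True
            sp[cmp_(VB, i), cb(i, N - 1)] = True
            for k in (VB, K, RB):
                sp[cmp_(VB, i), cmp_(k, i)] = True
            sp[cmp_(K, i), cmp_(AB, i)] = True
            sp[cmp_(K, i), cmp_(K, i)] = True
            sp[cmp_(LU, i), cmp_(VB, i)] = True
            sp[cmp_(LU, i), cmp_(LU, i)] = True
            sp[cmp_(RB, i), cmp_(AB, i)] = True
            sp[cmp_(RB, i), cmp_(RB, i)] = True
            for k in range(nC):
                sp[cmp_(G, i), cmp_(G, k)] = True
            for e in range(nE):
                sp[cmp_(G, i), self._i_etg + e] = True
            sp[cmp_(PV, i), cmp_(AB, i)] = True
            sp[cmp_(PV, i), cmp_(PV, i)] = True
            sp[cmp_(PV, i), cmp_(G, i)] = True
        for e in range(nE):
            for k in range(nC):
                sp[self._i_etg + e, cmp_(G, k)] = True
            sp[self._i_etg + e, self._i_etg + e] = True
        return sp.tocsr()
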