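"""Drug-enzyme interaction kinetics shared by hepatocytes and gut wall.

For ``nC`` drugs and ``nE`` enzymes the model tracks, per tissue site, the
unbound intracellular drug concentrations and a normalized total enzyme
level per enzyme (1 = basal).  Under the rapid-equilibrium assumption the
free enzyme is the total divided by a competition factor and three coupled
processes act on the enzyme pool:

* competitive (reversible) inhibition, affinity ``Ki``;
* mechanism-based inactivation (MBI), affinity ``KI`` and rate ``kinact``;
* additive induction, maximal fold ``FImax`` and potency ``EC50``.

A drug that does not interact through a given route has the corresponding
affinity at infinity.  All affinities are therefore stored as reciprocals,
with 0 encoding "no interaction", which keeps every term finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DrugSet:
    """Per-drug transport and binding constants (vectors of length nC)."""

    names: list
    fu_b: np.ndarray          # fraction unbound in blood
    fu_h: np.ndarray          # fraction unbound in hepatocytes
    fu_g: np.ndarray          # fraction unbound in gut wall
    permeability: np.ndarray  # um/h
    uptake_rate: np.ndarray   # um/h, active uptake into hepatocytes
    efflux_rate: np.ndarray   # um/h, active efflux back to blood

    def __post_init__(self):
        for name in ("fu_b", "fu_h", "fu_g", "permeability",
                     "uptake_rate", "efflux_rate"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.fu_b <= 0) or np.any(self.fu_b > 1) \
                or np.any(self.fu_h <= 0) or np.any(self.fu_h > 1) \
                or np.any(self.fu_g <= 0) or np.any(self.fu_g > 1):
            raise ValueError("unbound fractions must lie in (0, 1]")
        if np.any(self.permeability < 0) or np.any(self.uptake_rate < 0) \
                or np.any(self.efflux_rate < 0):
            raise ValueError("transport rates must be >= 0")

    @property
    def n_drugs(self) -> int:
        return len(self.names)


@dataclass
class EnzymeSet:
    """Per-enzyme basal concentrations and turnover rates (length nE)."""

    names: list
    E0_liver: np.ndarray   # uM in hepatocyte water
    E0_gut: np.ndarray     # uM in gut-wall tissue
    kdeg_liver: np.ndarray  # 1/h
    kdeg_gut: np.ndarray    # 1/h

    def __post_init__(self):
        for name in ("E0_liver", "E0_gut", "kdeg_liver", "kdeg_gut"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be > 0")

    @property
    def n_enzymes(self) -> int:
        return len(self.names)


@dataclass
class InteractionTable:
    """nC x nE interaction constants plus the per-drug unspecified pathway.

    Affinities are reciprocals (1/uM); ``inv_X == 0`` means no interaction
    through route X.  ``kcat`` (1/h) is the catalytic turnover of the
    metabolising complex and ``kinact`` (1/h) the MBI inactivation rate.
    ``FImax`` is the maximal induction fold (1 = non-inducer) paired with
    ``inv_EC50``.  ``Vmax2``/``Km2`` describe a lumped Michaelis-Menten
    pathway not attributed to any modelled enzyme (per drug, Vmax2 in uM/h
    relative to the tissue volume, Km2 in uM of unbound drug).
    """

    kcat: np.ndarray
    inv_Km1: np.ndarray
    inv_Ki: np.ndarray
    inv_KI: np.ndarray
    kinact: np.ndarray
    FImax: np.ndarray
    inv_EC50: np.ndarray
    Vmax2: np.ndarray
    Km2: np.ndarray

    def __post_init__(self):
        mats = ("kcat", "inv_Km1", "inv_Ki", "inv_KI", "kinact",
                "FImax", "inv_EC50")
        for name in mats:
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        for name in ("Vmax2", "Km2"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        for name in mats + ("Vmax2", "Km2"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and >= 0 "
                                 "(infinite affinities are stored as zero reciprocals)")
        if np.any(self.FImax < 1):
            raise ValueError("FImax must be >= 1")

    @property
    def shape(self):
        return self.kcat.shape

    @property
    def binding_coef(self) -> np.ndarray:
        """(1/Km1 + 1/Ki + 1/KI), the competition weight per drug-enzyme pair."""
        return self.inv_Km1 + self.inv_Ki + self.inv_KI

    @property
    def elimination_coef(self) -> np.ndarray:
        """(kcat/Km1 + kinact/KI), first-order loss weight per pair, 1/(uM h)."""
        return self.kcat * self.inv_Km1 + self.kinact * self.inv_KI

    @classmethod
    def empty(cls, n_drugs: int, n_enzymes: int) -> "InteractionTable":
        z = np.zeros((n_drugs, n_enzymes))
        return cls(kcat=z.copy(), inv_Km1=z.copy(), inv_Ki=z.copy(),
                   inv_KI=z.copy(), kinact=z.copy(),
                   FImax=np.ones((n_drugs, n_enzymes)), inv_EC50=z.copy(),
                   Vmax2=np.zeros(n_drugs), Km2=np.ones(n_drugs))


def _as2d(a):
    a = np.asarray(a, dtype=float)
    return (a[:, None], True) if a.ndim == 1 else (a, False)


def competition_factor(fuC, tbl: InteractionTable) -> np.ndarray:
    """Denominator D_j = 1 + sum_i (1/Km1 + 1/Ki + 1/KI)_ij fuC_i, per enzyme.

    ``fuC`` is the unbound intracellular concentration, shape (nC,) or
    (nC, N) for N spatial nodes; the result has shape (nE,) or (nE, N).
    """
    fuC, squeeze = _as2d(fuC)
    d = 1.0 + tbl.binding_coef.T @ fuC
    return d[:, 0] if squeeze else d


def free_enzyme(Etot_norm, fuC, tbl: InteractionTable) -> np.ndarray:
    """Normalized free enzyme: E = Etot / D (rapid-equilibrium binding)."""
    fuC2, squeeze = _as2d(fuC)
    e = np.asarray(Etot_norm, float)
    if e.ndim == 1:
        e = e[:, None]
    out = e / (1.0 + tbl.binding_coef.T @ fuC2)
    return out[:, 0] if squeeze else out


def metabolism_rates(fuC, Etot_norm, tbl: InteractionTable, E0) -> np.ndarray:
    """Per-drug elimination rate, uM/h.

    rate_i = sum_j (kcat/Km1 + kinact/KI)_ij E0_j E_j fuC_i
             + Vmax2_i fuC_i / (Km2_i + fuC_i)

    where E_j is the normalized free enzyme.  The first term is the
    enzyme-mediated loss (metabolism plus the drug consumed by MBI), the
    second the unspecified Michaelis-Menten pathway.
    """
    fuC2, squeeze = _as2d(fuC)
    efree = free_enzyme(Etot_norm if np.ndim(Etot_norm) > 1 else np.asarray(Etot_norm, float),
                        fuC2, tbl)
    if efree.ndim == 1:
        efree = efree[:, None]
    e_conc = np.asarray(E0, float)[:, None] * efree
    rate = (tbl.elimination_coef @ e_conc) * fuC2
    rate = rate + tbl.Vmax2[:, None] * fuC2 / (tbl.Km2[:, None] + fuC2)
    return rate[:, 0] if squeeze else rate


def enzyme_rhs(Etot_norm, fuC, tbl: InteractionTable, kdeg) -> np.ndarray:
    """Turnover of the normalized total enzyme pool, 1/h.

    dEtot/dt = kdeg [1 + sum_i (FImax-1) fuC/(EC50+fuC)]
               - Etot [kdeg + (sum_i kinact_ij fuC_i / KI_ij) / D_j]

    Production is basal synthesis amplified additively by every inducer;
    loss is basal degradation plus MBI acting on the bound fraction
    (hence the division by the competition factor D).
    """
    fuC2, squeeze = _as2d(fuC)
    e = np.asarray(Etot_norm, float)
    if e.ndim == 1:
        e = e[:, None]
    kdeg = np.asarray(kdeg, float)[:, None]
    u = fuC2[:, None, :] * tbl.inv_EC50[:, :, None]          # (nC, nE, N)
    induction = ((tbl.FImax[:, :, None] - 1.0) * u / (1.0 + u)).sum(axis=0)
    mbi = (tbl.kinact * tbl.inv_KI).T @ fuC2                 # (nE, N)
    d = 1.0 + tbl.binding_coef.T @ fuC2
    out = kdeg * (1.0 + induction) - e * (kdeg + mbi / d)
    return out[:, 0] if squeeze else out


def complex_concentrations(fuC, Etot_norm, tbl: InteractionTable, E0):
    """Rapid-equilibrium complex concentrations (uM), shape (nC, nE) each.

    EC_X[i, j] = fuC_i * E0_j * Efree_j / K_X[i, j] for X in
    {metabolism, reversible inhibition, MBI}.  Together with the free
    enzyme they satisfy Etot = E + sum_i (EC_met + EC_inh + EC_mbi) / E0.
    """
    fuC = np.asarray(fuC, float)
    if fuC.ndim != 1:
        raise ValueError("complex_concentrations expects a single site (1-D fuC)")
    efree_conc = np.asarray(E0, float) * free_enzyme(np.asarray(Etot_norm, float), fuC, tbl)
    outer = fuC[:, None] * efree_conc[None, :]
    return (outer * tbl.inv_Km1, outer * tbl.inv_Ki, outer * tbl.inv_KI)
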