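"""Derivation of simulator constants from clinically reported quantities.

Clinical studies report whole-organ blood clearances; the simulator needs
per-complex rate constants on the lobule grid.  The chain is:

1. hepatic blood clearance ``CL_H`` -> apparent intrinsic clearance
   ``CL_int`` by inverting the parallel-tube relation (the natural limit of
   the lobule model);
2. ``CL_int`` -> metabolic intrinsic clearance ``CL_int*`` correcting for
   the finite blood-hepatocyte exchange (surface ``S_ex`` times
   permeability, with optional active uptake/efflux);
3. ``CL_int*`` split into the CYP-mediated turnover ``kcat`` (fraction
   ``fm_3A4``) and a lumped Michaelis-Menten pathway ``Vmax2`` for the
   remainder, with the gut-wall counterpart scaled by relative CYP
   abundances;
4. renal blood clearance -> intrinsic renal clearance by the well-stirred
   inversion for the kidney.

Units: concentrations uM, volumes L, flows/clearances L/h, permeabilities
um/h, surfaces dm^2 (1 dm^2 * um/h = 1e-5 L/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import LobuleParams, LobuleGeometry, build_lobule
from .kinetics import DrugSet, EnzymeSet, InteractionTable

#: 1 dm^2 * (um/h) in L/h
DM2_UM_TO_L = 1e-5


class ValidationError(ValueError):
    """A drug record violates a physical or model constraint."""


# ----------------------------------------------------------------------
# closed-form derivations
# ----------------------------------------------------------------------

def clint_from_clh(cl_h: float, fu_b: float, q_liver: float) -> float:
    """Apparent intrinsic clearance by parallel-tube inversion, L/h.

    CL_int = -(Q_liver / fu_b) ln(1 - CL_H / Q_liver)
    """
    if not 0.0 <= cl_h < q_liver:
        raise ValidationError(
            f"CL_H = {cl_h} must satisfy 0 <= CL_H < Q_liver = {q_liver} "
            "(hepatic extraction cannot reach 1)")
    return -(q_liver / fu_b) * math.log1p(-cl_h / q_liver)


def clint_star(cl_int: float, s_ex: float, p: float,
               rho_in: float = 0.0, rho_out: float = 0.0) -> float:
    """Metabolic intrinsic clearance corrected for membrane exchange, L/h.

    CL_int* = S_ex (P + rho_out) CL_int / (S_ex (P + rho_in) - CL_int)
    """
    sp_in = s_ex * (p + rho_in) * DM2_UM_TO_L
    sp_out = s_ex * (p + rho_out) * DM2_UM_TO_L
    denom = sp_in - cl_int
    if denom <= 0:
        raise ValidationError(
            "S_ex (P + rho_in) must exceed CL_int: apparent clearance is "
            "permeability-limited beyond model validity")
    return sp_out * cl_int / denom


def scale_metabolism(cl_int_star: float, fm_3a4: float, km1: float,
                     km2: float, e_amount: float, v_h: float,
                     a_cyp: float, a_cyp_gut: float, f_3a4: float,
                     f_3a4_gut: float, v_gw: float):
    """Split CL_int* into kcat (1/h), Vmax2 and Vmax2_gut (uM/h).

    kcat = fm_3A4 CL_int* Km1 / (E0 V_h) where E0 V_h is the total enzyme
    amount (umol); Vmax2 = (1 - fm_3A4) CL_int* Km2 / V_h; the gut-wall
    Vmax2 is scaled by the per-volume abundance of non-3A4 CYPs.
    """
    if e_amount <= 0 or v_h <= 0:
        raise ValidationError("enzyme amount and hepatocyte volume must be > 0")
    kcat = fm_3a4 * cl_int_star * km1 / e_amount
    vmax2 = (1.0 - fm_3a4) * cl_int_star * km2 / v_h
    gut_scale_num = (1.0 - f_3a4_gut) * a_cyp_gut / v_gw
    gut_scale_den = (1.0 - f_3a4) * a_cyp / v_h
    vmax2_gut = vmax2 * gut_scale_num / gut_scale_den
    return kcat, vmax2, vmax2_gut


def clint_renal(cl_r: float, q_k: float, r_bp: float, kp_k: float) -> float:
    """Intrinsic renal clearance by well-stirred inversion, L/h.

    CL_int,R = (R_BP / Kp_K) Q_K CL_R / (Q_K - CL_R)
    """
    if not 0.0 <= cl_r < q_k:
        raise ValidationError(
            f"CL_R = {cl_r} must satisfy 0 <= CL_R < Q_K = {q_k}")
    return (r_bp / kp_k) * q_k * cl_r / (q_k - cl_r)


def ec50_correction(ec50: float, fu_inc: float, s_ex: float, p: float,
                    rho_in: float, rho_out: float,
                    cl_int_star: float) -> float:
    """In-vivo induction potency from the in-vitro EC50, uM.

    EC50* = fu_inc * S_ex (P + rho_in) / (S_ex (P + rho_out) + CL_int*) * EC50

    corrects for incubation binding and for the cell/blood unbound
    concentration gradient set up by metabolism.  Infinite EC50
    (non-inducer) stays infinite.
    """
    if not ec50 > 0:
        raise ValidationError("EC50 must be > 0 (or infinite for non-inducers)")
    if math.isinf(ec50):
        return math.inf
    sp_in = s_ex * (p + rho_in) * DM2_UM_TO_L
    sp_out = s_ex * (p + rho_out) * DM2_UM_TO_L
    return fu_inc * sp_in / (sp_out + cl_int_star) * ec50


def blood_plasma_partition(kp_rbc: float, hematocrit: float = 0.45) -> float:
    """Blood-to-plasma ratio R_BP = h Kp_RBC + 1 - h."""
    if not 0.0 < hematocrit < 1.0:
        raise ValidationError("hematocrit must be in (0, 1)")
    return hematocrit * kp_rbc + 1.0 - hematocrit


def kp_rest_of_body(kps, volumes) -> float:
    """Volume-weighted average partition coefficient of pooled tissues."""
    kps = np.asarray(kps, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise ValidationError("tissue volumes must be > 0")
    return float(np.sum(volumes * kps) / np.sum(volumes))


def qg_hybrid(cl_perm: float, q_v: float, fu_b: float) -> float:
    """Hybrid gut-wall flow Q_g = CL_perm Q_v fu_b / (CL_perm + Q_v fu_b), L/h.

    Harmonic combination of permeation capacity and villous blood flow;
    bounded by both.
    """
    if cl_perm <= 0 or q_v <= 0:
        raise ValidationError("CL_perm and Q_v must be > 0")
    return cl_perm * q_v * fu_b / (cl_perm + q_v * fu_b)


# ----------------------------------------------------------------------
# physiology
# ----------------------------------------------------------------------

@dataclass
class Physiology:
    """Compartment volumes/flows of the reference 70-kg man plus enzyme pools."""

    V_AB: float
    V_VB: float
    V_Lungs: float
    V_K: float
    V_RB: float
    V_GW: float
    V_PV: float
    Q_T: float
    Q_K: float
    Q_RB: float
    Q_Liver: float
    portal_fraction: float
    hematocrit: float
    enzyme_names: list
    enzyme_amount_liver: np.ndarray   # umol
    enzyme_amount_gut: np.ndarray     # umol
    kdeg_liver: np.ndarray            # 1/h
    kdeg_gut: np.ndarray              # 1/h
    a_cyp_liver: float                # umol, all CYPs
    a_cyp_gut: float
    f_3a4_liver: float
    f_3a4_gut: float
    s_ex_ref: float                   # dm^2, reference exchange surface
    lobule: LobuleParams = field(default_factory=LobuleParams)

    def __post_init__(self):
        if abs(self.Q_T - (self.Q_Liver + self.Q_K + self.Q_RB)) > 1e-6 * self.Q_T:
            raise ValidationError("venous return must close: Q_T = Q_Liver + Q_K + Q_RB")

    @property
    def Q_Lungs(self) -> float:
        """Series pulmonary circulation carries the whole cardiac output."""
        return self.Q_T

    @property
    def Q_pv(self) -> float:
        return self.portal_fraction * self.Q_Liver

    @property
    def Q_ha(self) -> float:
        return self.Q_Liver - self.Q_pv


def _data_path() -> Path:
    return Path(resources.files("lobulepk") / "data")


def load_physiology(path: str | Path | None = None) -> Physiology:
    """Load the physiology config (defaults to the packaged reference man)."""
    if path is None:
        path = _data_path() / "physiology.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    body = cfg["body"]
    enz = cfg["enzymes"]
    pool = cfg["cyp_pool"]
    lob = cfg["lobule"]
    lobule = LobuleParams(
        lobule_radius=lob["R_Lobule_um"],
        min_sinusoid_radius=lob["R_sin_um"],
        lobule_thickness=lob["e_Lobule_um"],
        hepatocyte_radius=lob["R_H_um"],
        liver_volume=lob["V_Liver_L"],
        liver_blood_flow=body["Q_Liver_L_h"],
        cell_volume=lob["V_cell_uL_per_1e6"],
        liver_mass=lob["liver_mass_g"],
    )
    return Physiology(
        V_AB=body["V_AB_L"], V_VB=body["V_VB_L"], V_Lungs=body["V_Lungs_L"],
        V_K=body["V_K_L"], V_RB=body["V_RB_L"], V_GW=body["V_GW_L"],
        V_PV=body["V_PV_L"],
        Q_T=body["Q_T_L_h"], Q_K=body["Q_K_L_h"], Q_RB=body["Q_RB_L_h"],
        Q_Liver=body["Q_Liver_L_h"],
        portal_fraction=body["portal_fraction"],
        hematocrit=body["hematocrit"],
        enzyme_names=[e["name"] for e in enz],
        enzyme_amount_liver=np.array([e["amount_liver_umol"] for e in enz]),
        enzyme_amount_gut=np.array([e["amount_gut_umol"] for e in enz]),
        kdeg_liver=np.array([e["kdeg_liver_per_h"] for e in enz]),
        kdeg_gut=np.array([e["kdeg_gut_per_h"] for e in enz]),
        a_cyp_liver=pool["A_CYP_liver_umol"],
        a_cyp_gut=pool["A_CYP_gut_umol"],
        f_3a4_liver=pool["f_3A4_liver"],
        f_3a4_gut=pool["f_3A4_gut"],
        s_ex_ref=cfg["reference"]["S_ex_dm2"],
        lobule=lobule,
    )


# ----------------------------------------------------------------------
# drug records
# ----------------------------------------------------------------------

@dataclass
class DrugRecord:
    """Clinically reported constants for one drug (config-file mirror)."""

    name: str
    molar_mass: float          # g/mol (external annotation, not a model claim)
    CL_H: float                # hepatic blood clearance, L/h
    CL_R: float                # renal blood clearance, L/h
    fu_p: float
    fu_b: float
    R_BP: float
    fu_h: float
    fu_gw: float
    Kp: dict                   # RBC, RB, Kidney, Lungs, Liver, Gut
    Km: float                  # uM; Km1 of the CYP when fm_3A4>0, else Km2
    fm_3A4: float
    Fa: float
    ka: float                  # 1/h
    Qg: float                  # L/h
    P: float                   # um/h
    rho_in: float = 0.0
    rho_out: float = 0.0
    Ki: float = math.inf       # uM, reversible inhibition of the CYP
    kinact: float = 0.0        # 1/h
    KI: float = math.inf       # uM
    FImax: float = 1.0
    EC50: float = math.inf     # uM, in-vitro
    fu_inc: float = 1.0        # incubation unbound fraction (EC50 correction)
    reported: dict = field(default_factory=dict)
    notes: str = ""

    def validate(self, phys: Physiology) -> None:
        if not 0.0 <= self.fm_3A4 <= 1.0:
            raise ValidationError(f"{self.name}: fm_3A4 out of [0, 1]")
        if self.CL_H >= phys.Q_Liver:
            raise ValidationError(
                f"{self.name}: CL_H {self.CL_H} >= hepatic blood flow {phys.Q_Liver}")
        if self.CL_R >= phys.Q_K:
            raise ValidationError(
                f"{self.name}: CL_R {self.CL_R} >= renal blood flow {phys.Q_K}")
        for fname in ("fu_p", "fu_b", "fu_h", "fu_gw", "Fa"):
            v = getattr(self, fname)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{self.name}: {fname} = {v} not in (0, 1]")
        if self.ka <= 0 or self.Qg <= 0 or self.P <= 0:
            raise ValidationError(f"{self.name}: ka, Qg, P must be > 0")
        if self.FImax < 1:
            raise ValidationError(f"{self.name}: FImax must be >= 1")


@dataclass
class DerivedParams:
    """Simulator constants derived from one :class:`DrugRecord`."""

    CL_int: float
    CL_int_star: float
    kcat: float
    Vmax2: float
    Vmax2_gut: float
    Km2: float
    CL_int_R: float
    EC50_star: float


def _record_from_yaml(cfg: dict) -> DrugRecord:
    inter = cfg.get("interaction") or {}

    def num(d, key, default):
        v = d.get(key, default)
        return math.inf if v in ("inf", "+inf") else float(v)

    return DrugRecord(
        name=cfg["name"],
        molar_mass=float(cfg["molar_mass_g_mol"]),
        CL_H=float(cfg["CL_H_L_h"]), CL_R=float(cfg["CL_R_L_h"]),
        fu_p=float(cfg["fu_p"]), fu_b=float(cfg["fu_b"]),
        R_BP=float(cfg["R_BP"]), fu_h=float(cfg["fu_h"]),
        fu_gw=float(cfg["fu_gw"]),
        Kp={k: float(v) for k, v in cfg["Kp"].items()},
        Km=float(cfg["Km_uM"]), fm_3A4=float(cfg["fm_3A4"]),
        Fa=float(cfg["Fa"]), ka=float(cfg["ka_per_h"]),
        Qg=float(cfg["Qg_L_h"]), P=float(cfg["P_um_h"]),
        rho_in=float(cfg.get("rho_in_um_h", 0.0)),
        rho_out=float(cfg.get("rho_out_um_h", 0.0)),
        Ki=num(inter, "Ki_uM", math.inf),
        kinact=num(inter, "kinact_per_h", 0.0),
        KI=num(inter, "KI_uM", math.inf),
        FImax=num(inter, "FImax", 1.0),
        EC50=num(inter, "EC50_uM", math.inf),
        fu_inc=num(inter, "fu_inc", 1.0),
        reported=cfg.get("reported", {}) or {},
        notes=cfg.get("notes", "") or "",
    )


def _inv(x: float) -> float:
    return 0.0 if math.isinf(x) else 1.0 / x


class DrugLibrary:
    """Validated drug records plus the derivation chain and system assembly."""

    def __init__(self, records: dict, phys: Physiology,
                 geometry: LobuleGeometry):
        self.records = records
        self.physiology = phys
        self.geometry = geometry
        #: hepatocyte volume of the constructed liver, L
        self.v_h = geometry.hepatocyte_volume / 1e3
        self.derived: dict[str, DerivedParams] = {}
        for rec in records.values():
            rec.validate(phys)
            self.derived[rec.name] = self._derive(rec)

    def _derive(self, rec: DrugRecord) -> DerivedParams:
        phys = self.physiology
        cl_int = clint_from_clh(rec.CL_H, rec.fu_b, phys.Q_Liver)
        cl_star = clint_star(cl_int, phys.s_ex_ref, rec.P,
                             rec.rho_in, rec.rho_out) if cl_int > 0 else 0.0
        km1 = rec.Km if rec.fm_3A4 > 0 else math.inf
        km2 = rec.Km if rec.fm_3A4 < 1 else 1.0
        kcat, vmax2, vmax2_g = scale_metabolism(
            cl_star, rec.fm_3A4, rec.Km if rec.fm_3A4 > 0 else 0.0, km2,
            float(phys.enzyme_amount_liver[0]), self.v_h,
            phys.a_cyp_liver, phys.a_cyp_gut,
            phys.f_3a4_liver, phys.f_3a4_gut, phys.V_GW)
        cl_int_r = clint_renal(rec.CL_R, phys.Q_K, rec.R_BP, rec.Kp["Kidney"])
        ec50_star = ec50_correction(rec.EC50, rec.fu_inc, phys.s_ex_ref,
                                    rec.P, rec.rho_in, rec.rho_out, cl_star)
        return DerivedParams(CL_int=cl_int, CL_int_star=cl_star, kcat=kcat,
                             Vmax2=vmax2, Vmax2_gut=vmax2_g, Km2=km2,
                             CL_int_R=cl_int_r, EC50_star=ec50_star)

    # ------------------------------------------------------------------
    def audit(self) -> pd.DataFrame:
        """Derived-vs-reported parameter table for the whole library."""
        rows = []
        for name, rec in self.records.items():
            der = self.derived[name]
            rows.append({
                "drug": name,
                "CL_int": der.CL_int,
                "CL_int_reported": rec.reported.get("CL_int_L_h", np.nan),
                "CL_int_star": der.CL_int_star,
                "CL_int_star_reported": rec.reported.get("CL_int_star_L_h", np.nan),
                "EC50_star": der.EC50_star,
                "EC50_star_reported": rec.reported.get("EC50_star_uM", np.nan),
            })
        df = pd.DataFrame(rows).set_index("drug")
        for col in ("CL_int", "CL_int_star"):
            df[f"{col}_rel_err"] = (df[col] - df[f"{col}_reported"]).abs() \
                / df[f"{col}_reported"]
        return df

    # ------------------------------------------------------------------
    def drug_set(self, names: list) -> DrugSet:
        recs = [self.records[n] for n in names]
        return DrugSet(
            names=list(names),
            fu_b=np.array([r.fu_b for r in recs]),
            fu_h=np.array([r.fu_h for r in recs]),
            fu_g=np.array([r.fu_gw for r in recs]),
            permeability=np.array([r.P for r in recs]),
            uptake_rate=np.array([r.rho_in for r in recs]),
            efflux_rate=np.array([r.rho_out for r in recs]),
        )

    def enzyme_set(self) -> EnzymeSet:
        phys = self.physiology
        return EnzymeSet(
            names=list(phys.enzyme_names),
            E0_liver=phys.enzyme_amount_liver / self.v_h,
            E0_gut=phys.enzyme_amount_gut / phys.V_GW,
            kdeg_liver=phys.kdeg_liver,
            kdeg_gut=phys.kdeg_gut,
        )

    def interaction_tables(self, names: list):
        """Liver and gut-wall interaction tables for the listed drugs.

        Gut-wall constants equal the liver ones except for the basal
        enzyme pool (handled by :class:`EnzymeSet`) and the unspecified
        pathway ``Vmax2``, which scales with non-3A4 CYP abundance.  When
        ``fm_3A4 > 0`` the metabolic affinity ``Km1`` doubles as the
        competitive binding constant, so the separate ``Ki`` is dropped to
        avoid counting one binding site twice.
        """
        n = len(names)
        liver = InteractionTable.empty(n, len(self.physiology.enzyme_names))
        gut = InteractionTable.empty(n, len(self.physiology.enzyme_names))
        for i, name in enumerate(names):
            rec = self.records[name]
            der = self.derived[name]
            if rec.fm_3A4 > 0:
                inv_km1, kcat, inv_ki = 1.0 / rec.Km, der.kcat, 0.0
            else:
                inv_km1, kcat, inv_ki = 0.0, 0.0, _inv(rec.Ki)
            for tbl in (liver, gut):
                tbl.inv_Km1[i, 0] = inv_km1
                tbl.kcat[i, 0] = kcat
                tbl.inv_Ki[i, 0] = inv_ki
                tbl.inv_KI[i, 0] = _inv(rec.KI)
                tbl.kinact[i, 0] = rec.kinact
                tbl.FImax[i, 0] = rec.FImax
                tbl.inv_EC50[i, 0] = _inv(der.EC50_star)
            liver.Vmax2[i] = der.Vmax2
            liver.Km2[i] = der.Km2
            gut.Vmax2[i] = der.Vmax2_gut
            gut.Km2[i] = der.Km2
        return liver, gut

    def amount_from_mg(self, name: str, dose_mg: float) -> float:
        """Dose in umol from a dose in mg."""
        return dose_mg / self.records[name].molar_mass * 1e3


def load_drug_library(path: str | Path | None = None,
                      phys: Physiology | None = None,
                      geometry: LobuleGeometry | None = None) -> DrugLibrary:
    """Load and validate the packaged (or a user) drug library.

    Every record's invariants are checked and the full derivation chain is
    executed; :meth:`DrugLibrary.audit` reports derived vs printed values.
    """
    if phys is None:
        phys = load_physiology()
    if geometry is None:
        geometry = build_lobule(phys.lobule)
    if path is None:
        path = _data_path() / "drugs"
    path = Path(path)
    records = {}
    for f in sorted(path.glob("*.yaml")):
        with open(f) as fh:
            rec = _record_from_yaml(yaml.safe_load(fh))
        records[rec.name] = rec
    if not records:
        raise ValidationError(f"no drug records found under {path}")
    return DrugLibrary(records, phys, geometry)
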