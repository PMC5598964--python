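"""Scenario integration, PK metrics and DDI reporting.

A DDI study is simulated twice with an identical victim regimen — once
with the perpetrator, once with a placebo — and summarised by the ratios
of the victim's AUC and Cmax between the two arms.  Accuracy against
clinical observations is expressed as fold errors and their geometric
mean (GMFE).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .liver import build_grid
from .params import DrugLibrary
from .pbpk import BodyParams, PBPKSystem, Regimen


@dataclass
class SolverSettings:
    """Stiff-integrator configuration.

    The system is integrated with a variable-order BDF method; the run is
    restarted at every dose time so absorption onsets (Heaviside terms) do
    not destabilise stiff stepping.  ``output_dt`` is the dense-output
    spacing used for metrics and exports.
    """

    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = math.inf
    dose_restart: bool = True
    output_dt: float = 0.02
    method: str = "BDF"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.output_dt <= 0:
            raise ValueError("tolerances and output_dt must be > 0")


@dataclass
class Scenario:
    """One clinical DDI study: perpetrator regimen + victim regimen.

    Dose lists are ``(dose_mg, time_h)`` pairs, allowing regimens whose
    strength changes mid-treatment.
    """

    name: str
    victim: str
    victim_doses: list
    perpetrator: str | None = None
    perp_doses: list = field(default_factory=list)
    observed_auc_ratio: float | None = None
    observed_cmax_ratio: float | None = None

    @property
    def victim_times(self) -> list:
        return [t for _, t in self.victim_doses]

    @property
    def perp_times(self) -> list:
        return [t for _, t in self.perp_doses]

    @property
    def first_victim_time(self) -> float:
        return min(self.victim_times)


@dataclass
class SimulationResult:
    """Dense trajectories of a single simulation run."""

    times: np.ndarray
    states: np.ndarray              # (size, len(times))
    system: PBPKSystem
    drug_names: list
    solver_stats: dict = field(default_factory=dict)

    def _idx(self, drug: str) -> int:
        return self.drug_names.index(drug)

    def series(self, drug: str, compartment: str = "venous_plasma") -> np.ndarray:
        """Concentration time series, uM.

        ``venous_blood``/``venous_plasma`` are the clinical observables;
        plasma is blood divided by the blood-to-plasma ratio.
        """
        i = self._idx(drug)
        frames = self.system.unpack(self.states)
        if compartment == "venous_blood":
            return frames["C_VB"][i]
        if compartment == "venous_plasma":
            return frames["C_VB"][i] / self.system.body.R_BP[i]
        if compartment == "arterial_blood":
            return frames["C_AB"][i]
        if compartment == "liver_outlet":
            return frames["Cb"][i, -1]
        if compartment == "gut_wall":
            return frames["C_g"][i]
        raise KeyError(f"unknown compartment {compartment!r}")

    def liver_enzyme(self, enzyme_index: int = 0) -> np.ndarray:
        """Normalized enzyme level per node, shape (N, T)."""
        return self.system.unpack(self.states)["Etot"][enzyme_index]

    def gut_enzyme(self, enzyme_index: int = 0) -> np.ndarray:
        return self.system.unpack(self.states)["Etot_g"][enzyme_index]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export of the clinical observables."""
        rows = []
        for name in self.drug_names:
            for comp in ("venous_blood", "venous_plasma", "liver_outlet",
                         "gut_wall"):
                rows.append(pd.DataFrame({
                    "time_h": self.times, "drug": name, "series": comp,
                    "value_uM": self.series(name, comp)}))
        return pd.concat(rows, ignore_index=True)

    def liver_field_frame(self) -> pd.DataFrame:
        """Long-format per-node liver state (blood, hepatocyte, enzyme)."""
        frames = self.system.unpack(self.states)
        x = self.system.grid.x_centers
        rows = []
        for i, name in enumerate(self.drug_names):
            for label, arr in (("liver_blood", frames["Cb"][i]),
                               ("hepatocyte", frames["Ch"][i])):
                for j in range(arr.shape[0]):
                    rows.append(pd.DataFrame({
                        "time_h": self.times, "x_um": x[j], "species":
                        f"{label}:{name}", "value": arr[j]}))
        enz = frames["Etot"][0]
        for j in range(enz.shape[0]):
            rows.append(pd.DataFrame({
                "time_h": self.times, "x_um": x[j],
                "species": "enzyme:" + self.system.enzymes.names[0],
                "value": enz[j]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class PKMetrics:
    auc: float    # uM h
    cmax: float   # uM


@dataclass
class DDIResult:
    scenario: Scenario
    auc_ratio: float
    cmax_ratio: float
    victim_with: PKMetrics
    victim_without: PKMetrics


# ----------------------------------------------------------------------
# simulation driver
# ----------------------------------------------------------------------

def _integrate(system: PBPKSystem, t0: float, t_end: float,
               settings: SolverSettings) -> SimulationResult:
    """Integrate with restarts at dose times and a fixed output grid."""
    breaks = {t0, t_end}
    if settings.dose_restart:
        for reg in system.regimens:
            breaks.update(t for t in reg.dose_times if t0 < t < t_end)
    breaks = sorted(breaks)

    n_out = int(round((t_end - t0) / settings.output_dt))
    t_grid = t0 + settings.output_dt * np.arange(n_out + 1)
    t_grid[-1] = t_end

    y = system.initial_state()
    sparsity = system.jac_sparsity()
    out = np.empty((system.size, len(t_grid)))
    out[:, 0] = y
    filled = 1
    stats = {"nfev": 0, "njev": 0, "segments": 0, "wall_s": 0.0}
    tic = time.perf_counter()
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        mask = (t_grid > ta) & (t_grid <= tb)
        t_eval = t_grid[mask]
        n_grid = len(t_eval)
        if n_grid == 0 or not np.isclose(t_eval[-1], tb):
            t_eval = np.append(t_eval, tb)  # always land on the break point
        sol = solve_ivp(system.rhs, (ta, tb), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        max_step=settings.max_step,
                        t_eval=t_eval, jac_sparsity=sparsity)
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed on [{ta}, {tb}]: {sol.message}; "
                f"state snapshot max |y| = {np.abs(y).max():.3g}")
        y = sol.y[:, -1].copy()
        if n_grid:
            out[:, filled:filled + n_grid] = sol.y[:, :n_grid]
            filled += n_grid
        stats["nfev"] += sol.nfev
        stats["njev"] += getattr(sol, "njev", 0)
        stats["segments"] += 1
    stats["wall_s"] = time.perf_counter() - tic
    return SimulationResult(times=t_grid[:filled], states=out[:, :filled],
                            system=system,
                            drug_names=list(system.drugs.names),
                            solver_stats=stats)


def build_system(library: DrugLibrary, drug_names: list,
                 regimens: list, nodes_per_level: int = 10) -> PBPKSystem:
    """Assemble a :class:`PBPKSystem` for the listed drugs."""
    phys = library.physiology
    grid = build_grid(library.geometry, nodes_per_level)
    drugs = library.drug_set(drug_names)
    enzymes = library.enzyme_set()
    tbl_liver, tbl_gut = library.interaction_tables(drug_names)
    recs = [library.records[n] for n in drug_names]
    body = BodyParams(
        V_AB=phys.V_AB, V_VB=phys.V_VB, V_Lungs=phys.V_Lungs, V_K=phys.V_K,
        V_RB=phys.V_RB, V_GW=phys.V_GW, V_PV=phys.V_PV,
        Q_T=phys.Q_T, Q_Lungs=phys.Q_Lungs, Q_K=phys.Q_K, Q_RB=phys.Q_RB,
        Q_Liver=phys.Q_Liver, Q_ha=phys.Q_ha, Q_pv=phys.Q_pv,
        Kp_Lungs=np.array([r.Kp["Lungs"] for r in recs]),
        Kp_K=np.array([r.Kp["Kidney"] for r in recs]),
        Kp_RB=np.array([r.Kp["RB"] for r in recs]),
        R_BP=np.array([r.R_BP for r in recs]),
        CL_int_R=np.array([library.derived[n].CL_int_R for n in drug_names]),
        Qg=np.array([r.Qg for r in recs]),
    )
    return PBPKSystem(grid, drugs, enzymes, tbl_liver, tbl_gut, body, regimens)


def run_scenario(scenario: Scenario, library: DrugLibrary,
                 settings: SolverSettings | None = None,
                 with_perpetrator: bool = True,
                 horizon_h: float = 48.0,
                 nodes_per_level: int = 10) -> SimulationResult:
    """Simulate one arm of a scenario.

    The placebo arm contains only the victim and starts at its first dose
    (the state is identically zero before).  The treatment arm starts at
    the earliest dose of either drug.  Both arms end ``horizon_h`` after
    the last victim dose.
    """
    settings = settings or SolverSettings()
    t_end = max(scenario.victim_times) + horizon_h

    def regimen(name: str, dose_list) -> Regimen:
        rec = library.records[name]
        return Regimen(Fa=rec.Fa, ka=rec.ka,
                       doses=[(library.amount_from_mg(name, mg), float(t))
                              for mg, t in dose_list])

    if with_perpetrator and scenario.perpetrator is not None:
        names = [scenario.victim, scenario.perpetrator]
        regs = [regimen(scenario.victim, scenario.victim_doses),
                regimen(scenario.perpetrator, scenario.perp_doses)]
        t0 = min(min(scenario.victim_times), min(scenario.perp_times))
    else:
        names = [scenario.victim]
        regs = [regimen(scenario.victim, scenario.victim_doses)]
        t0 = scenario.first_victim_time
    system = build_system(library, names, regs, nodes_per_level)
    return _integrate(system, t0, t_end, settings)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def pk_metrics(result: SimulationResult, drug: str,
               start: float, end: float,
               compartment: str = "venous_plasma") -> PKMetrics:
    """Trapezoidal AUC and grid Cmax over the window [start, end]."""
    t = result.times
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError("metrics window outside the simulated span")
    c = result.series(drug, compartment)
    mask = (t >= start - 1e-12) & (t <= end + 1e-12)
    auc = float(np.trapezoid(c[mask], t[mask]))
    cmax = float(c[mask].max())
    return PKMetrics(auc=auc, cmax=cmax)


def ddi_ratios(scenario: Scenario, library: DrugLibrary,
               settings: SolverSettings | None = None,
               horizon_h: float = 48.0,
               nodes_per_level: int = 10) -> DDIResult:
    """AUC and Cmax ratios of the victim with vs without the perpetrator."""
    res_with = run_scenario(scenario, library, settings, True,
                            horizon_h, nodes_per_level)
    res_without = run_scenario(scenario, library, settings, False,
                               horizon_h, nodes_per_level)
    start = scenario.first_victim_time
    end = max(scenario.victim_times) + horizon_h
    m_with = pk_metrics(res_with, scenario.victim, start, end)
    m_without = pk_metrics(res_without, scenario.victim, start, end)
    return DDIResult(
        scenario=scenario,
        auc_ratio=m_with.auc / m_without.auc,
        cmax_ratio=m_with.cmax / m_without.cmax,
        victim_with=m_with, victim_without=m_without)


def fold_error(observed: float, predicted: float) -> float:
    """Fold error 10^|log10(obs/pred)| >= 1."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold error requires positive values")
    return 10.0 ** abs(math.log10(observed / predicted))


def gmfe(pairs) -> float:
    """Geometric mean fold error: 10^mean(|log10(obs/pred)|)."""
    logs = [abs(math.log10(o / p)) for o, p in pairs]
    if not logs:
        raise ValueError("gmfe requires at least one (obs, pred) pair")
    return 10.0 ** (sum(logs) / len(logs))


# ----------------------------------------------------------------------
# packaged scenarios
# ----------------------------------------------------------------------

def _scenario_dir() -> Path:
    return Path(resources.files("lobulepk") / "data" / "scenarios")


def load_scenario(name_or_path: str | Path) -> Scenario:
    path = Path(name_or_path)
    if not path.exists():
        path = _scenario_dir() / f"{name_or_path}.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    def doses(block) -> list:
        times = [float(t) for t in block["times_h"]]
        mgs = block.get("dose_mg_list")
        if mgs is None:
            mgs = [float(block["dose_mg"])] * len(times)
        if len(mgs) != len(times):
            raise ValueError("dose_mg_list length must match times_h")
        return list(zip([float(m) for m in mgs], times))

    perp = cfg.get("perpetrator")
    obs = cfg.get("observed", {}) or {}
    return Scenario(
        name=cfg["name"],
        victim=cfg["victim"]["drug"],
        victim_doses=doses(cfg["victim"]),
        perpetrator=perp["drug"] if perp else None,
        perp_doses=doses(perp) if perp else [],
        observed_auc_ratio=obs.get("auc_ratio"),
        observed_cmax_ratio=obs.get("cmax_ratio"),
    )


def list_scenarios(with_observations: bool = True) -> list:
    """Names of packaged scenarios (by default only the graded studies)."""
    names = sorted(p.stem for p in _scenario_dir().glob("*.yaml"))
    if with_observations:
        names = [n for n in names
                 if load_scenario(n).observed_auc_ratio is not None]
    return names


def run_all_studies(library: DrugLibrary,
                    settings: SolverSettings | None = None,
                    scenario_names: list | None = None,
                    nodes_per_level: int = 10) -> pd.DataFrame:
    """Run the shipped DDI studies and tabulate ratios, fold errors, GMFE."""
    names = scenario_names or list_scenarios()
    rows = []
    for name in names:
        sc = load_scenario(name)
        res = ddi_ratios(sc, library, settings, nodes_per_level=nodes_per_level)
        rows.append({
            "study": sc.name,
            "perpetrator": sc.perpetrator,
            "obs_AUC_ratio": sc.observed_auc_ratio,
            "pred_AUC_ratio": res.auc_ratio,
            "fold_error": fold_error(sc.observed_auc_ratio, res.auc_ratio)
            if sc.observed_auc_ratio else math.nan,
            "obs_Cmax_ratio": sc.observed_cmax_ratio,
            "pred_Cmax_ratio": res.cmax_ratio,
            "fold_error_Cmax": fold_error(sc.observed_cmax_ratio, res.cmax_ratio)
            if sc.observed_cmax_ratio else math.nan,
        })
    df = pd.DataFrame(rows)
    auc_pairs = [(r["obs_AUC_ratio"], r["pred_AUC_ratio"]) for _, r in df.iterrows()
                 if r["obs_AUC_ratio"]]
    cmax_pairs = [(r["obs_Cmax_ratio"], r["pred_Cmax_ratio"]) for _, r in df.iterrows()
                  if r["obs_Cmax_ratio"]]
    df.attrs["GMFE_AUC"] = gmfe(auc_pairs) if auc_pairs else math.nan
    df.attrs["GMFE_Cmax"] = gmfe(cmax_pairs) if cmax_pairs else math.nan
    return df
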