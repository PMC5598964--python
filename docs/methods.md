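# Methods

## Scope

`lobulepk` predicts pharmacokinetic drug–drug interactions (DDIs) mediated
by hepatic and intestinal drug-metabolising enzymes. Instead of treating
the liver as a well-stirred pool, it resolves the functional unit of the
organ — the lobule — as a one-dimensional hierarchy of converging
sinusoids, so that blood velocity, drug concentration and enzyme level all
vary along the periportal → perivenous axis. The lobule is embedded in a
seven-compartment whole-body model (arterial and venous blood, lungs,
kidneys, rest of body, gut wall + portal vein, liver) with multi-dose oral
absorption. Three interaction mechanisms act on the enzyme pool:
competitive (reversible) inhibition, mechanism-based inactivation (MBI)
and induction, for an arbitrary number of drugs and enzymes.

## Lobule geometry

The hexagonal lobule cross-section (circumradius R_lobule = 790.57 µm,
thickness e_L = 25 µm) is replaced by a disc of equal area; by six-fold
symmetry only one sector is constructed. Hepatocyte plates (width
e = 2 R_H = 16.98 µm) are placed iteratively outward from the central
vein, halving the sector angle (60°, 30°, 15°, …) at each generation and
enforcing a minimal sinusoid half-width R_sin = 3.65 µm between plates;
the loop stops when the next sinusoid output would fall outside the disc.
With the reference dimensions this generates **5 sinusoid levels** of
lengths 348.0, 185.4, 92.6, 46.0 and 22.5 µm (periphery → centre). The
outermost level is truncated by the disc edge and is the one construction
output sensitive to the exact placement formulas; it carries ~1%
uncertainty, the inner four are robust to <0.1 µm.

Within a level the sinusoid radius tapers linearly to R_sin at the
downstream end and jumps up at each pairwise merge; flow doubles at each
merge, so each level of a sector carries the same total flow. Elementary
volumes and contact surface per unit path length are

    dV_blood = 2 R(x) (e_L − 2 R_H) dx
    dV_hep   = 2 R_H (2 R(x) + e_L cos θ) dx
    dS       = 2 (2 R(x) + (e_L − 2 R_H) cos θ) dx

with θ the level's construction angle. These forms are the unique ones
consistent with the two published surface-to-volume exchange ratios, and
integrated over the whole liver (1.69 L, ~4.16×10⁷ lobules) they
reproduce the reference organ: blood volume 285 mL, hepatocyte volume
1401 mL, exchange surface 10 126 dm², 3.5×10¹¹ hepatocytes (195×10⁶
cells/g at 1800 g liver mass) — each within 1% of the published
reconstruction (283 mL / 1392 mL / 10 046 dm² / 348×10⁹ / 193×10⁶).
All per-level integrals are polynomials in x and are evaluated in closed
form.

Velocity is reported as per-sinusoid flow over the rectangular
cross-section R(x)(e_L − 2R_H); a circular-cross-section (πR²) variant is
kept as a sensitivity option but is not used by the transport model,
which works directly with cell volumes and fluxes.

## Liver transport and kinetics

The sinusoid path is discretized with a conservative finite-volume
scheme: 10 equal cells per level (50 cells total) by default, level
boundaries always cell faces. The advective flux Q·C_b is first-order
upwind — flow is unidirectional — and at a merge the two symmetric
upstream streams have equal concentration, so the junction condition is
concentration continuity. Cell volumes come from the closed-form
elementary integrals, so they sum exactly to the organ totals and the
scheme conserves mass to solver tolerance (verified to <0.01% over 100 h
in a closed system). First-order upwinding at 50 cells biases
steady-state extraction by ≲0.5%; doubling the resolution moves the oral
AUC of the probe substrate by <1% (tested).

Blood–hepatocyte exchange is passive permeation P plus optional active
uptake/efflux ρ_in/ρ_out (both zero for every shipped drug), acting on
unbound concentrations through each cell's contact surface. Hepatocytes
are node-local (no axial diffusion). Metabolism follows
rapid-equilibrium enzyme kinetics: free enzyme is the total pool divided
by a competition factor 1 + Σ_i (1/K_m,1 + 1/K_i + 1/K_I)_i fu_h·C_h,i,
and the per-drug loss is (k_cat/K_m,1 + k_inact/K_I)·E·fu_h·C_h plus a
lumped Michaelis–Menten pathway (V_max,2, K_m,2) for clearance not
attributed to the modelled enzyme. Affinities are stored as reciprocals
with 0 meaning "no interaction", which keeps every expression finite.

The normalized enzyme pool at every node follows

    dĒ_tot/dt = k_deg [1 + Σ_i (FI_max−1) u_i/(EC50+u_i)]
                − Ē_tot [k_deg + (Σ_i k_inact u_i/K_I) / D],   u_i = fu_h C_h,i

i.e. basal turnover, additive induction, and MBI acting on the bound
fraction. With no perpetrator the pool sits at 1; induction-only and
MBI-only steady states match their algebraic closed forms to 1e-6
(tested). Because each node sees its own drug microenvironment, zonation
of inactivation/induction emerges along the path.

## Whole-body model

All compartments except liver and gut wall are flow-limited well-stirred
tissues with partition coefficient Kp and blood-to-plasma ratio R_BP.
Oral doses enter the gut wall by first-order absorption (F_a, k_a,
Heaviside onsets); the gut wall metabolises drug with the same kinetics
as hepatocytes (its own basal enzyme level and turnover rate) and drains
into the portal vein at the hybrid flow Q_g acting on the unbound
concentration. The liver inlet mixes hepatic artery and portal vein by
flow weighting. Renal elimination is CL_int,R·C_K in the kidney
compartment. The pulmonary circulation is in series, so the lung flow
equals cardiac output.

## Parameter derivation

Clinical inputs per drug are blood clearances (CL_H, CL_R), binding
fractions, partition coefficients, absorption constants and interaction
constants. The derivation chain is:

1. CL_int = −(Q_liver/fu_b) ln(1 − CL_H/Q_liver)  (parallel-tube
   inversion — the high-permeability limit of this liver model, verified
   to 2%);
2. CL_int* = S_ex(P+ρ_out)·CL_int / (S_ex(P+ρ_in) − CL_int)
   (membrane-exchange correction; 1 dm²·µm/h = 1e-5 L/h);
3. k_cat = f_m·CL_int*·K_m,1 / (E0·V_h) and
   V_max,2 = (1−f_m)·CL_int*·K_m,2 / V_h, with the gut-wall V_max,2
   scaled by the per-volume abundance of non-CYP3A4 enzymes;
4. CL_int,R = (R_BP/Kp_K)·Q_K·CL_R/(Q_K − CL_R) (well-stirred kidney);
5. in-vitro induction EC50 mapped to the in-vivo unbound scale via
   EC50* = fu_inc·S_ex(P+ρ_in)/(S_ex(P+ρ_out)+CL_int*)·EC50.

The derivation uses the reference exchange surface 10 046 dm² stored in
the physiology config (the lobule reconstruction's own output; a freshly
built geometry reproduces it to 0.8%). Round trip: simulating
steady-state extraction with the derived constants recovers every library
drug's CL_H within 1.2% (tolerance 3% in tests).

When a perpetrator is itself a substrate (f_m > 0), its metabolic K_m,1
doubles as its competitive binding constant and the separate K_i is set
to infinity — the library's K_i equals K_m for every such drug, and
counting one binding site twice would overstate inhibition.

## Reference physiology

The 70-kg reference man: hepatic blood flow 87 L/h (the value under
which the parallel-tube inversion reproduces the library's reported
CL_int column to 0.5%), cardiac output 336 L/h, renal flow 66 L/h,
rest-of-body flow 183 L/h by closure; portal vein carries 75% of liver
flow. Volumes: arterial blood 1.7 L, venous blood 3.4 L, lungs 0.5 L,
kidneys 0.31 L, rest of body 62 L, portal vein 0.07 L. The gut wall is
the metabolically active mucosa, 0.30 L: with the hybrid-flow exit
Q_g·fu_g/V_GW this reproduces an early (~1.7 h) oral peak for the probe
substrate and a gut availability F_g ≈ 0.52, both consistent with
clinical midazolam data (F_g itself is independent of V_GW in the linear
regime; the volume controls transit time and local concentrations).
CYP3A4: 9.228 µmol in the liver, 0.070 µmol in the gut wall, turnover
0.0192 h⁻¹ and 0.0288 h⁻¹. CYP3A4 is taken as 30% of hepatic and 80% of
intestinal total CYP for scaling the non-3A4 gut pathway (this only
affects a pathway that is negligible for every shipped drug).

## Numerics

The assembled ODE system (50 liver cells × (blood + hepatocyte + enzyme)
+ 7 compartments per drug + gut enzyme; 265 states for a two-drug study)
is stiff — per-cell blood residence times are milliseconds while
simulations span weeks. It is integrated with variable-order BDF and a
finite-difference Jacobian exploiting the known sparsity structure
(advection chain, node-local kinetics). Default tolerances rtol 1e-6,
atol 1e-9 µM; the integrator restarts at every dose time so Heaviside
absorption onsets never fall inside a step. Dense output on a 0.02 h
grid feeds trapezoidal AUC and grid Cmax. A full two-arm DDI study runs
in ~1 s; AUC ratios move <2% under tenfold tolerance tightening and <1%
under doubled spatial resolution (tested). The pipeline is fully
deterministic.

## DDI studies and metrics

Ten clinical studies (perpetrator regimen + single midazolam probe dose)
ship as scenario files, including the irregular cimetidine schedule and
the two-strength fluoxetine regimen. Each study is simulated twice with
an identical victim regimen — with perpetrator and with placebo — and
summarised by AUC and Cmax ratios of venous plasma (blood divided by
R_BP; ratios are nearly invariant to the blood/plasma choice because
R_BP cancels). AUC integrates from the victim dose to 48 h after it,
identical in both arms. Accuracy versus clinical observations is the
fold error 10^|log10(obs/pred)| per study and its geometric mean (GMFE)
across studies. The placebo arm starts at the victim dose time (the
state is identically zero before it). For the rifampin study, which
reports two probe intakes, the shipped graded scenario uses the first;
the second ships as a companion scenario for inspection.

## Known limitations

* The supplementary reference-man table of the original reconstruction
  is not distributed with its text; volumes were fixed once from
  standard literature values (above). Most predictions are insensitive
  to this, but perpetrators whose own clearance collapses as they
  inactivate CYP3A4 (diltiazem: f_m = 1) amplify any exposure
  difference, and the diltiazem AUC ratio lands ~30% above the reference
  prediction.
* One enzyme (CYP3A4) is parameterized, although the data structures are
  n_drugs × n_enzymes throughout.
* No dispersion term, biliary excretion, enterohepatic recirculation,
  uncompetitive/non-competitive inhibition, metabolite cascades, oxygen
  or shear-stress zonation of enzyme expression; active hepatic
  uptake/efflux is modelled but zero for all shipped drugs.
* The outermost sinusoid level's length carries ~1% construction
  ambiguity (disc truncation), which propagates to <1% in organ totals.
* Simulations describe one average 70-kg man; there is no inter-subject
  variability.
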