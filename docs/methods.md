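# Methods

## Model structure

The circulation is a single closed loop in the electrical analogy:
pressures are voltages (mmHg), flows currents (mL/s), resistances
viscous losses (mmHg·s/mL), compliances vessel distension (mL/mmHg) and
inertances blood inertia (mmHg·s²/mL).

**Chambers.** The four cardiac chambers are time-varying elastances,
`p = E(t)(V − V₀)`. The activation waveform is a raised cosine: up over a
fraction `t_contract` of the cycle, down over `t_relax`, zero otherwise.
This is the standard smooth choice in lumped-parameter circulation
models; the model's behaviour depends on `E_max`, `E_min` and timing far
more than on the exact ramp shape. Atrial activation leads ventricular
activation by 0.1 cycle (a normal AV delay). Heart rate is fixed at
75 bpm (period 0.8 s).

**Valves.** Non-ideal diodes: conductance `1/R_open` for forward
gradients, `1/R_closed` for reverse ones, blended with a tanh of width
`valve_smoothing_eps = 10⁻³ mmHg` so the right-hand side is smooth at
`Δp = 0`. `R_closed` is set ~5·10⁴ × `R_open` rather than the 10³
diode floor because the atrioventricular valves face reverse gradients
(~90 mmHg in systole) roughly 50× their forward ones; the larger ratio
keeps the regurgitant leak below 1% of forward flow.

**Vessels.** Systemic arterial (R, L, C), systemic capillary (purely
resistive), systemic venous (R, C), a single lumped caval compartment
(R, L, C) representing SVC+IVC together, pulmonary arterial (C), a
per-vein pulmonary capillary bed, and four pulmonary-vein R–L branches.
Each vein drains an equal quarter of the capillary bed through two
parallel resistive paths: oxygenated (97% of the conductance) and
non-oxygenated/shunt (3%, a configurable fraction representing
physiological intrapulmonary shunt; it is haemodynamically passive and
carries no gas-transport meaning here). Normal veins terminate at a
common pulmonary venous pool (compliance C_VENPUL) that empties into the
left atrium through a small resistance.

**Anatomies.** `baseline` routes all four veins to the pool. The `RA`
variant reroutes the chosen anomalous veins to the right atrial chamber
node; the `VC` variant reroutes them to the caval node *upstream of the
caval resistance*. The caval compartment is present in every anatomy —
systemic venous return always traverses it — so the two variants differ
only in the anomalous vein terminals, and a variant with zero anomalous
veins is the baseline circuit exactly.

**Wood units.** `pvr_wood_units` sets the *precapillary*
(arteriolar + capillary) resistance of the whole lung:
`R_precap = WU × 0.06 mmHg·s/mL`, split equally across the four per-vein
paths (each path carries 4× the total). The postcapillary venous limb
(per-vein `r_vein = 0.18 mmHg·s/mL`, about 0.8 WU-equivalent in total)
is deliberately comparable to the precapillary resistance at baseline —
the low-resistance regime in which drainage-site effects are visible.

## State vector and equations

19 states: chamber volumes (V_LA, V_LV, V_RA, V_RV), node pressures
(systemic arterial, systemic venous, caval, pulmonary arterial, four
capillary nodes, venous pool) and inductive branch flows (systemic
arterial, caval, four veins). For capacitive nodes `C·dp/dt = ΣQ_in −
ΣQ_out`; for inductive branches `L·dQ/dt = Δp − R·Q`; for chambers
`dV/dt = Q_in − Q_out`; purely resistive branches (valves, capillary
paths, pool outlet, systemic venous outlet) contribute algebraic flows.
Total blood volume `ΣV + ΣC_k·p_k` is conserved identically by
construction; the tests verify drift < 0.1 mL/cycle through the solver.

## Integration and steady state

LSODA (stiff-capable, adaptive) integrates cycle by cycle with rel/abs
tolerances 10⁻⁷/10⁻⁹ and 400 output points per cycle. The output grid
doubles as the trapezoid quadrature grid for cycle means; 400 points are
needed because valve switchings put kinks in the waveforms — at 200
points the cycle-mean Qp/Qs carries ~0.01 quadrature noise, which is the
same order as the RA-vs-VC differences at high PVR. With the chosen
settings Qp/Qs is solver-independent to ~3 decimals (checked against 600
points and rel 10⁻⁸).

The periodic steady state is declared when the relative cycle-to-cycle
change of every cycle-mean state variable falls below
`steady_state_tol = 10⁻⁴` (with a 0.5-unit floor on the denominator so
near-zero means do not dominate). The criterion is cycle-mean based
because the reported quantity, Qp/Qs, is a ratio of cycle means. The
initial state is an arbitrary physiological guess (uniform 10 mmHg,
chambers at V₀ + 50 mL, stressed-volume offset on the systemic venous
node); correctness relies on convergence to the unique periodic
attractor, which the restart test verifies (re-running from a converged
state converges within 2 cycles). Non-convergence within `max_cycles`
returns a flagged result rather than raising.

## Calibration

The defaults are calibrated so the baseline (shunt-free) anatomy at 1 WU
hits clinical-normal anchors: cardiac output 5 ± 0.5 L/min, mean PA
16 ± 3 mmHg, mean RA 8 ± 3 mmHg, mean aortic 90 ± 10 mmHg.
`calibrate_baseline` polishes four scalar handles by bounded least
squares — stressed-volume offset, systemic resistance scale, ventricular
`E_max` scale, right-atrial elastance scale — and raises a calibration
report if the anchors cannot be reached within bounds. Calibration is
idempotent to < 1%.

Two calibration choices carry the physiology that shapes the Qp/Qs
predictions:

- **Stiff right-ventricular diastole** (`E_min,RV = 0.095 mmHg/mL`).
  Mean right atrial pressure is pinned to RV end-diastolic pressure
  through the open tricuspid valve, so the 8-mmHg RA anchor itself
  requires a stiff RV diastole. The same stiffness makes right-heart
  filling pressure climb as the shunt volume-loads the right heart,
  which back-pressures the anomalous veins: the shunt is self-limiting,
  and Qp/Qs stays below the perfect-recirculation ceiling `1/(1 − k/4)`
  by a margin that grows with the vein count.
- **Caval resistance** (`R_VC = 0.04 mmHg·s/mL`). The entire systemic
  venous return crosses it, so the caval node sits a few mmHg above the
  right atrium; veins draining there (VC variant) shunt correspondingly
  less than veins draining directly to the RA. This sets the RA-vs-VC
  Qp/Qs separation (~0.09/0.20/0.42 for 1–3 veins at 1 WU).

## Behaviour under the resistance sweeps

Raising the *precapillary* resistance uniformly attenuates the RA-vs-VC
difference several-fold by 8 WU: once arteriolar drops dominate each
path, the downstream routing matters little. Note that the absolute
Qp/Qs of each variant *rises* mildly (concavely) along this sweep. That
direction is forced by the topology: with the capillary bed balanced
across the four veins, the cycle-mean flow split is an exact linear
resistive divider, so any fixed downstream-pressure deficit washes out
as the common per-path resistance grows and the anomalous share
converges to k/4 from below. Right-heart congestion raises RA pressure
by only a few mmHg over the sweep and cannot outpace the tens of mmHg of
added arteriolar drop, in any contractility regime we examined.

Raising the *postcapillary* resistance of the anomalous limb alone
squeezes the shunt monotonically; in the occlusion limit Qp/Qs returns
to 1.

## Synthetic cohort

The generator emulates the *structure* of a 49-patient clinical cohort:
fixed stratum counts over (lung territory 1–3) × (clinical variant
SVC/RA/L), 36 right-sided / 13 left-sided, model groups 19 RA / 30 VC,
and the measurement-availability pattern 16 invasive-only / 20 both /
13 CMR-only. The published stratum table covers only the 36 catheterized
patients; the full-cohort completion used here is chosen to be
consistent with all published marginals and is fixed in
`SyntheticCohortConfig`. Lung territories are the standard six-region
functional scheme (three per lung); since the mapping from territories
to the model's four veins is not defined, the cohort arm never feeds
the simulator.

Per stratum, a latent shunt severity is drawn from a log-normal matched
to the target median and IQR (log-normal because Qp/Qs is a positive,
right-skewed ratio); the invasive estimate is the latent value, and the
CMR estimate multiplies it by log-normal measurement noise whose
variance is set from the latent log-spread to hit a target Spearman
correlation of 0.75 between modalities. Distances to the RA are drawn
uniform on [0, 2] cm for clinical-RA patients and 2 + log-normal cm for
SVC patients; PVR values are log-normal per stratum, clipped to the
≤ 3 WU inclusion criterion. Everything is driven by one seed; the same
seed reproduces the table byte-for-byte.

What the generator does *not* emulate: real covariance between Qp/Qs and
PVR or age, measurement censoring mechanisms, inter-observer CMR
variability, or any patient-level link to the simulator. Pipeline tests
passing on this cohort therefore demonstrate the statistics and
reporting machinery, not clinical reproduction; published medians,
p-values and correlations of the real cohort are not reproduction
targets. Significance is reported at 0.05 uncorrected for multiple
testing, and the reports say so.

## Statistics

Wilcoxon rank-sum (exact enumeration for combined n ≤ 12 without ties,
normal approximation with tie correction otherwise), Kruskal–Wallis with
tie correction (chi-square p on k−1 df, with a full-enumeration exact
option for total n ≤ 10), Pearson and Spearman correlations on complete
cases. Degenerate inputs (all values tied, zero variance, n < 3) are
reported as p = 1 or absent rather than raising.

## Known limitations

- Instantaneous haemodynamics only: no chronic vascular remodelling, no
  autonomic reflexes, no heart-rate response; resistance sweeps are
  acute thought experiments.
- Linear elastances and linear vessels; no pericardial constraint, no
  valve disease, no atrial septal defect, no scimitar anatomy.
- The caval compartment is a single lumped SVC+IVC element (a
  two-compartment split is a natural refinement; the config reserves the
  anatomy field for it).
- The six-values reproduction depends on a calibrated but unpublished
  parameter regime; the robust (parameter-independent) statements are
  the orderings — Qp/Qs convex in vein count, RA > VC at matched
  settings, attenuation of the difference with precapillary resistance,
  monotone decrease under anomalous-limb postcapillary scaling — which
  is what the property tests assert.
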