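# Methods

## The physical model

A planar phosphatidylcholine bilayer is reduced to a one-dimensional lumped
potential profile along the membrane normal: cis bulk (grounded), cis diffuse
layer, cis interfacial (dipolar) zone of width 1.0 nm, hydrophobic core of
thickness h = 3 nm, trans interfacial zone, trans diffuse layer, trans bulk at
the clamped holding potential V (negative).  Each leaflet carries two
independent boundary potentials:

* **dipole potential** — a rise of ψ_d across the interfacial zone, positive
  toward the membrane interior.  Only its *change* Δψ_d matters; an arbitrary
  250 mV baseline (middle of the 200–300 mV range reported for PC monolayers)
  is used when drawing absolute profiles.  Amphiphiles such as RH-421 raise a
  monolayer's ψ_d; phlorizin lowers it.
* **surface potential** — a Gouy–Chapman boundary potential ψ_s between the
  bulk bath and the leaflet surface, produced by net interfacial charge such
  as adsorbed dodecyl sulfate anions.

Because dielectric displacement and potential are continuous across the
uncharged interfacial/core boundary, a perturbation confined to one leaflet
changes the potential drop across the hydrophobic core.  The signed change of
that core drop relative to the unperturbed membrane at the same applied
potential is the **equivalent voltage shift**

    ΔU = (Δψ_d,cis − Δψ_d,trans) + (ψ_s,cis − ψ_s,trans),

with the convention that positive ΔU is activity-enhancing (it acts like a
more negative holding potential).  ΔU is additive over leaflet perturbations,
antisymmetric under swapping a perturbation between leaflets, and vanishes
for any symmetric perturbation — the electric-cancellation property the
symmetric-detergent scenario exercises.  A voltage-sensing peptide whose
helix dipole moment is p (75 D for the alamethicin-like model peptide)
experiences a molar insertion-energy change

    ΔG = N_A · p · ΔU / h,

which evaluates to 0.19, 0.14, 0.50 and 0.40 kJ/mol for ΔU = 3.7, 2.8, 10
and 8 mV at h = 3 nm.

## Surface charge: Grahame and Stern

For a symmetric z:z electrolyte the Grahame relation σ = √(8 c ε ε₀ k_B T) ·
sinh(z e ψ / 2 k_B T) links surface charge density and surface potential; the
package inverts it in closed form (asinh) and the tests cross-check that
inversion against bracketed root finding on the forward relation and against
the Debye–Hückel linearization ψ = σ/(ε ε₀ κ) below 5 mV.

Dodecyl sulfate adsorption is a Stern picture: Langmuir occupancy of
saturable sites with the Boltzmann-weighted surface concentration of the
monovalent anion, closed self-consistently through the Grahame relation
(damped fixed-point iteration, damping 0.5, tolerance 1e-10 mV).  The
literature gives no isotherm parameters for this system, so the binding
constant is set to the surfactant/PC association scale (K = 2000 L/mol) and
the saturation site density (1.385 e/nm²) is calibrated by root finding so
that 25 µM SDS in 0.1 M KCl yields ψ_s = −10 mV, the value the trans-side
activity shift implies.  One consequence is worth stating plainly: with this
anchor, ψ_s(c) is strictly concave (asinh compression, Boltzmann depletion
and site saturation all act in the same direction), so the near-linearity of
ψ_s — and hence of ln σ — in the dose holds in the *low-concentration
regime the titration actually uses* (5–25 µM, deviation ≈ 3.7 % of range,
model-output ln σ regression R² ≈ 0.993 at −40 mV).  Over a hypothetical
0–250 µM sweep the same calibrated curve deviates from a straight line by
≈ 10 % of range; a model that stayed linear that far out would have to
violate the 25 µM anchor.  Saturation of the pore population similarly bends
ln σ at stronger drivings, which is why the titration regression is reported
per voltage and is cleanest at the lowest one.

The measured cis/trans asymmetry of the SDS effect (8 vs 10 mV at the same
dose) is *not* modelled mechanistically — both leaflets share identical
adsorption parameters — so the cis-SDS scenario imposes the measured −8 mV
directly as a per-leaflet override.

## Ion flux and conductance direction

Transport through an open substate is treated with the constant-field
(Goldman–Hodgkin–Katz) flux generalised to the full piecewise-linear
profile: the current of a single ion species is proportional to
c_cis e^{zφ(0)} − c_trans e^{zφ(L)} and inversely proportional to
∫ e^{zφ(x)} dx across the span (φ = eψ/k_BT).  Per segment the integral is
evaluated in closed form, so a single linear ramp reduces exactly to the
textbook GHK equation and constant gauge shifts cancel identically.

The *direction* of a conductance change is computed through the equivalence
formalism: a perturbed membrane conducts as the unperturbed one would at
|V| + ΔU, so the sign is sign(|I(|V|+ΔU)| − |I(|V|)|) on the control
profile.  A literal single-cation flux over the perturbed profile is not
used for this purpose: lowering the *cis* interfacial barrier (cis SDS)
raises such a current even though the core driving force drops, i.e. it
gets the observed direction wrong; the equivalence route reproduces all
four observed directions (phlorizin and trans-SDS enhance, RH-421 and
cis-SDS reduce).  No attempt is made to reproduce absolute nS values from
first principles — pore geometry is unknown — so the simulator's substate
conductances are fixed inputs, not GHK outputs.

## The gating simulator

The pore is a continuous-time birth–death chain on levels 0..K (K = 3 by
default) with substate conductances g = (0.09, 0.37, 1.04) nS, the control
values from the I–V fits being emulated.  All voltage dependence sits on the
insertion step, k_ins = k0 · exp(D/V_e) with driving D = |V| + ΔU and
V_e = 5 mV, reflecting the accepted picture that the transmembrane field
drives the interfacial-to-inserted transition of the helix dipole;
inter-substate rates are voltage independent.  Defaults: closure 1000 s⁻¹,
step-up 500 s⁻¹, step-down 1000 s⁻¹, and k0 = 2.4576×10⁻³ s⁻¹ chosen once so
that the control occupancy of levels ≥ 2 at −60 mV is 17.6 % (inside the
10–20 % band typical of moderately active recordings) while level-3 visits
at −40 mV over 20 s still clear the ">20 readings" rule for I–V points.  At
low occupancy every open level scales as e^{D/V_e}, giving ln σ a slope
between 1/(2V_e) (variance-dominated) and 1/V_e in the driving potential —
the exponential activity premise.  Traces are simulated event-exactly
(embedded-chain draws), point-sampled at 20 kHz, and white Gaussian noise of
1 pA is added per sample from a separate seeded stream; no recording-filter
emulation is attempted.  An analytic stationary-law σ (used as the
simulator's oracle) is provided alongside.

A detergent on the cis-facing leaflet additionally multiplies k0 by a
phenomenological `curvature_attenuation` ∈ (0,1], standing in for the
positive spontaneous curvature it imposes; this factor does not cancel when
the detergent is symmetric, producing the observed partial (rather than
full) recovery.  The default is 1.0 (off); the reversibility scenario uses
0.78, which puts symmetric-dose activity near √0.78 ≈ 88 % of control, the
observed recovery level.  The dwell-time realism of alamethicin and
multi-pore superposition are out of scope.

## The ΔU estimator

Both conditions' activity curves sample the same underlying function of the
driving potential, so the estimator fits the common-slope model
y = a_c + b(|V| + ΔU·1[treated]) jointly (an exactly linear least-squares
problem via y = a + b|V| + c·1[treated], ΔU = c/b), with the sem from
first-order propagation of the OLS covariance (bootstrap over voltages
optional at ≥ 5 points).  Two corrections, both derived from the generator
model before any stochastic run, are applied by the pipeline:

1. **drive normalization** — level currents scale ohmically as g|V|, adding
   a ln|V| term that is *common to both conditions at the same voltages*;
   it cancels in the intercept difference but inflates the shared slope,
   biasing ΔU = 10 mV recovery to ≈ 7.3 mV.  Dividing σ by |V| before the
   log removes the term; recovery is then accurate to ≲ 0.2 mV even though
   pore-population saturation curves both activity functions.
2. **noise-floor subtraction** — the known 1 pA thermal noise adds in
   variance and flattens the low-voltage end asymmetrically between
   conditions; the estimator subtracts it (clamped at 5 % of the sample
   variance to keep the log defined).

Swapping control and treated flips the sign exactly.  The estimator rejects
non-overlapping voltage ranges and vanishing common slopes.

## Trace quantification

σ is the sample standard deviation of the whole trace (closed-level mean is
zero by construction, so no baseline subtraction is applied).  Amplitude
histograms use Freedman–Diaconis binning clamped to ≥ 50 bins and unit
integral.  Mixture decomposition is EM (scikit-learn, diagonal covariances)
with the order chosen by BIC up to k_max (the pipeline caps it at K+1);
components whose means differ by less than 3× their pooled sd are reported
as one convolved peak — the (0, 1) closed/first-substate case that thermal
noise creates.  Components are matched to conductance levels by nearest
expected mean current; collisions raise an error rather than guessing.
Idealization assigns samples to nearest component means; maximal constant
runs of ≥ 5 samples are dwells, each contributing its mean current as one
reading, and an I–V point is considered usable at > 20 readings.  I–V fits
are ordinary least squares on signed (V, I) readings with the conductance
reported as the positive slope magnitude.

## Problem sizes and determinism

The shipped designs use 6 voltages (−40…−65 mV, step 5), 20 s traces at
20 kHz and 10 repeats for the single-amphiphile scenarios (ΔU sem per repeat
≈ 0.5 mV, median over repeats well inside ±1 mV), 3 repeats for the
reversibility scenario and 2 for the titration; mixture fits thin traces to
≤ 30 k (pipeline) or 100 k (conductance analysis) samples before EM.  Every
stochastic quantity flows from a master seed through stable per-condition
hashes (SHA-256 of master seed and label), so reruns are byte-identical;
wall-clock time never enters any output.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis assumes — discrete
substates, exponential voltage dependence, Gaussian noise, amphiphile action
through ΔU — so passing tests demonstrate that the analysis chain recovers
the generator's parameters, not that the underlying membrane physics is
correct.  Real recordings add filter distortion, baseline drift, multi-pore
activity, flicker/shot noise and dwell-time structure none of which are
modelled; per-condition percentage changes of substate probability measured
on real recordings depend on those features and on raw data that is not
available, so the package asserts directions and orderings rather than
specific percentages.
The simulator also keeps substate conductances fixed across conditions (the
constant-field model supplies only the sign of conductance changes), and the
Stern calibration rests on a single anchor point.
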