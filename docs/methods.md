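# Methods

`reflectedflow` models the self-organization of the auxin distribution along
the central axis of a young plant root.  The core hypothesis is a
*reflected-flow* feedback: auxin at low concentrations promotes expression of
its own efflux carrier PIN1 (self-reinforcing acropetal transport toward the
root tip), while auxin above a threshold destroys PIN1 (shutting the pump
down).  Pumping piles auxin up against the closed root end, back-diffusion
("the reflected flow") pushes the neighbouring cells over the degradation
threshold, and the maximum steps proximally until pumping and reflection
balance — producing a stable auxin maximum a few cells away from the tip
without any pre-assigned tissue structure.

## The transport models

**1D minimal model.** A file of N non-dividing cells, cell 1 at the root
end.  Per cell i, auxin a_i and carrier PIN_i obey

    da_i/dt  = α·[i=N] − K_d a_i + D(a_{i−1}−a_i) + D(a_{i+1}−a_i)
               + K_0 PIN_{i+1} a_{i+1} − K_0 PIN_i a_i
    dPIN_i/dt = V_syn(a_i) − V_deg(a_i, PIN_i)

with one-sided boundary terms: influx α only at the basal cell N, no
diffusion past either end, and no active export from cell 1 (the physical
boundary).  Every internal flux enters a donor/acceptor pair
antisymmetrically, so Σ_i da_i/dt = α − K_d Σ_i a_i holds algebraically; at
stationarity the total auxin content is exactly α/K_d.

The regulatory terms are generalized Hill functions:

    V_syn(a)      = k_1 a^{2h_1} / ((q_1^{h_1}+a^{h_1})(q_2^{h_1}+a^{h_1}))
    V_deg(a, PIN) = k_2 PIN (1 + (a/q_3)^{h_2})

V_syn vanishes at a=0, activates near q_1, saturates near q_2 with supremum
k_1.  V_deg reduces to basal first-order decay k_2·PIN at a=0 and rises
steeply (exponent h_2) once a crosses the inhibition threshold q_3.  The
reflected-flow pattern requires q_3 to lie between the interior and the
boundary-plateau stationary auxin levels; that separation is asserted by the
test suite for both bundled parameter sets.

**2D minimal model.** An M×N grid (default 8×50) of the same cells, rows
3..M−2 "provascular" (full 1D dynamics per row, each with influx α at its
basal cell) and the two outermost row pairs "epidermal" (no PIN1, no influx;
auxin enters only by transverse diffusion from the provascular core, moves
by diffusion and degrades).  Transverse diffusion uses the same constant D
as longitudinal diffusion by default (configurable); outermost rows have
one-sided transverse exchange.  Epidermal PIN is structurally zero and is
excluded from the dynamic state vector, so the stability spectrum is not
polluted by frozen components.

**1D extended model.** A growing, dividing cell file.  Each cell carries a
size r and a two-phase cycle: a growth phase (elongation dr/dt = K_growth,
with dilution −(ṙ/r)c applied to every concentration c — elongation spreads
a fixed amount over an increasing volume) and a non-growing idle phase whose
completion is division.  Phase completions are random events with
state-dependent instantaneous hazards

    f_GP(r) = k_gp (r/r_min)^{h_gp} / (1 + (r/r_min)^{h_gp})       (growth)
    f_IP(y) = k_ip (y/q_lo)^{h_lo} / (1 + (y/q_lo)^{h_lo} + (y/q_hi)^{h_hi})

f_GP is negligible below the minimal division size r_min and plateaus at
k_gp above it; f_IP is bell-shaped in the Division Factor concentration y
(two exponents, h_hi > h_lo): deficiency and excess both suppress division.
Because the hazards depend on the evolving state, completion is sampled with
the accumulated-hazard construction: each cell draws a unit-exponential
threshold on phase entry, integrates its hazard along the trajectory
(trapezoid rule), and fires when the integral crosses the threshold.  The
event time is located inside the step by bisection to 1e-6 tu, the event is
applied atomically (division: two half-size daughters inheriting the
mother's concentrations unchanged, so amounts c·r are conserved; the file is
renumbered), and integration resumes.  An acceptance test verifies the
sampled completion times against the analytic survival curve
exp(−∫ hazard).

**Division Factor.** A hypothetical morphogen (standing in for the combined
cytokinin/ethylene control of division) coupling division rates to the auxin
pattern:

    dDivF_i/dt = β σ((a_i − a_{i+1})/T − 5)·[i<N] − k_deg DivF_i g(a_i)
                 + D_DivF (DivF_{i−1}−DivF_i) + D_DivF (DivF_{i+1}−DivF_i)
    g(a) = (1 + (a/q_4)^{h_3}) / (1 + (a/q_5)^{h_4})

Synthesis is a logistic sigmoid of the *tipward drop* of the auxin profile
on scale T (default 0.1 cu), midpoint at five scales, so it is active only
where the profile falls steeply toward the base — the proximal flank of the
auxin maximum — and is <1% of β in flat regions.  (A sigmoid of the rising
gradient cannot work here: in any stationary profile the only steep
gradients are the proximal drops, so a rising-gradient source would be
either negligible or spatially uniform, and no localized morphogen peak
could form.)  Degradation is a two-plateau response in auxin, low plateau
k_deg at low auxin and high plateau k_deg(q_5/q_4)^{h_3} in auxin-rich
cells, which confines the morphogen away from the columella; the weak basal
turnover sets the exponential length of its proximal tail.  The stationary
outcome is a DivF peak in the cell adjacent (proximal) to the auxin maximum
— the quiescent-centre position, where f_IP sits in the excess band and
division is suppressed — a moderate-DivF meristem over the tail, and a
DivF-depleted differentiation zone beyond it.

**Sloughing.** Root-cap turnover is modelled by a policy (the source
specifies the event but not its rule): the tipmost cell is removed when more
than `cap` (default 5) cells lie distal to the distal-most prominent auxin
maximum, at most once per `min_interval` (default 20 tu).  Two details
matter.  The anchor is the distal-most *local* maximum (5% prominence), not
the global argmax: a transient secondary maximum far up the file must not
teleport the anchor and erode the tip.  And the maximal removal rate
1/min_interval is kept below the meristem's division capacity (~0.1
cells/tu), otherwise a transient over-supply triggers an erosion spiral.

## Parameters

Concentration (cu) and time (tu) units are abstract; no SI conversion is
attempted.  Two presets ship with the package.  The anchored values are
α = 1 (the influx at which the stationary pattern is compared against
staining data), K_0 = 0.1 (the active-transport scale for inhibitor
sweeps), T = 0.1, and for the robust set q_3 = 3.26 with h_2 = 10
(pronounced inhibition; fibrous-root-like behaviour).  All other values
were calibrated once, coordinatewise, to place the models in the
reflected-flow regime, and are not tuned thereafter:

| parameter | basic | robust | role |
|---|---|---|---|
| K_d | 0.014 | 0.014 | auxin turnover; sets total content α/K_d |
| D | 1.0 | 1.0 | diffusion; strength of the reflected flow |
| k_1, q_1, q_2, h_1 | 1, 0.1, 1, 1 | same | PIN1 synthesis response |
| k_2 | 0.02 | 0.02 | basal PIN1 turnover |
| q_3, h_2 | 2.2, 8 | 3.26, 10 | PIN1 inhibition threshold/sharpness |
| β, k_deg, q_4, q_5, h_3, h_4, D_DivF | 1, 0.03, 1.3, 3, 4, 4, 0.3 | same | Division Factor |
| K_growth, r_min, r_0 | 0.002, 1.8, 1 | same | elongation and division size |
| k_gp, h_gp; k_ip, q_lo, q_hi, h_lo, h_hi | 0.05, 20; 0.02, 0.8, 1.3, 3, 8 | same | phase hazards |

With the basic set at N = 50 the package's own milestones are: detachment
onset (maximum leaves cell 1) at α ≈ 0.34, a stable maximum at cell 12 with
peak ≈ 5.6 cu at α = 1, loss of stability at α ≈ 1.23 with mid-file
oscillations above it, extra low-amplitude maxima for K_0 ≈ 0.08–0.06 and a
two-maxima (tip + base) pattern for K_0 ≤ 0.05, a single-cell bolus
tolerance ≈ 4.2 cu, and a detached provascular maximum (column 3) in 2D.
The growing root's default influx ramp is α(t) = 0.06 + 1.5e-4·t, matched
to the presets: ~1.5 cu per cell at the 3-cell start and crossing the N=50
detachment onset as the root reaches that size.  Under it the maximum
settles ~5 cells from the tip, is maintained while the root is below
~80–100 cells, and is lost (shifts to the root end, the profile flattens)
beyond that — the model's own statement that shoot-derived supply cannot
sustain the pattern in a long root.

## Numerics

* Minimal models: stiff implicit multistep integration (BDF via
  `scipy.integrate.solve_ivp`) with rtol 1e-8 / atol 1e-10 and analytically
  assembled Jacobians (the q_3-thresholded degradation with h_2 = 10 is
  sharp).  Stationary profiles: Newton (hybr) with a long-time-integration
  fallback; zero initial data skips the direct Newton attempt so the
  computed state is the one the Cauchy problem actually selects.  Residual
  tolerance 1e-10 in max norm.
* Extended model: fixed-step classical RK4 with dt = min(dt_max, 2.5/λ_max)
  where λ_max is the fastest local decay rate (RK4's real-axis stability
  limit with 10% margin); the step is halved whenever a concentration would
  go negative.  Integrator-internal rate evaluations clamp transient
  negative undershoots for fractional powers only; the public rate-law
  functions raise on negative input instead of clamping.
* Continuation: pseudo-arclength with secant predictor, Newton corrector on
  the tangent-orthogonality augmented system, adaptive step, fold recording
  at parameter-tangent sign changes, and an orientation guard (the realized
  secant must not reverse against the predictor) against branch jumping and
  retracing.  Stationary branches of this system snake heavily (hundreds of
  folds at N = 50), so solution counts at a given influx are reported
  together with the number of branch points traversed and the stopping
  reason.
* Perturbation tolerance relaxes the bolus by integration before polishing
  — a direct Newton solve would short-circuit the basin-of-attraction
  question.
* Coordinatewise descent: cyclic bounded golden-section line searches;
  convergence on relative per-cycle improvement; a finite-difference Hessian
  at the end point flags near-singular (non-identifiable) directions, in
  which case the fit is reported unconverged.

## What the synthetic data are, and are not

The bundled "digitized staining" reference profile
(`presets/dr5_profile_synthetic.csv`) is a synthetic densitometry emulation
generated from the basic-set model solution (affine response, constant
background, optical blur, 4% multiplicative noise); it is *not* measured
data.  Tests against it demonstrate that the affine profile-matching
pipeline recovers a known generating profile through realistic measurement
distortions — they say nothing about agreement with any real root.
Likewise the growing-root simulations emulate a cell file under an
exogenous, linearly ramped supply; real roots regulate auxin synthesis and
transport in ways deliberately out of scope here, so passing tests
demonstrate internal consistency of the mechanism, not quantitative
agreement with planta measurements.

## Known limitations

* The stationary-branch geometry, milestone values (onset, critical influx,
  tolerance) and the growing root's loss length depend on the calibrated
  preset values; other parameterizations satisfying the same shape
  contracts shift them.
* The growing root has no supply-to-size feedback: trajectories whose early
  divisions lag the ramp enter an over-supplied regime and can degenerate
  into an auxin-saturated stub (runs stop early, via `min_cells`, when that
  terminal state is reached).  This mirrors the model's requirement that
  growth and supply be coordinated, but it makes some random seeds
  uninformative for patterning statistics; patterning summaries are
  therefore evaluated at the latest "patterned" snapshot (detached maximum)
  rather than at the final instant.
* Sloughing is a documented stand-in policy; the mechanism's true rule is
  not specified by the biology the model encodes.
* No basipetal transport, no PIN polarization dynamics, no root-born auxin
  synthesis, and no 2D growing tissue (growth is combined with the 1D model
  only).
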