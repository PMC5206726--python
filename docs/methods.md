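# Methods

## Model

`mapkosc` simulates a closed mass-action reaction network for EGF-driven
MAPK/ERK signaling. The network couples four feedback loops around the
three-tier RAF → MEK → ERK kinase cascade:

* **Positive feedback (RAS ↔ SOS).** Activated receptors (EGFR_a) bind
  free, unphosphorylated SOS. The resulting complex is a GEF for RAS,
  and its catalytic rate depends on which nucleotide state of RAS
  occupies the allosteric REM site on SOS: `k2A` with RAS-GTP bound,
  `k2B = 0.1 k2A` with RAS-GDP bound, and zero with the site empty
  (`k2C = 0`). RAS-GTP therefore amplifies its own production.
* **GAP saturation.** RasGAP works as a two-step enzyme (binding at
  `b3`, conversion-and-release at `u3`). Because `RasGAP_tot` is well
  below `RAS_tot` and `u3/b3` is small, the GAP flux saturates at
  `u3 * RasGAP_tot`, which is what allows the positive feedback to
  produce two stable RAS states at a fixed level of receptor-SOS
  complexes.
* **ERK-to-SOS negative feedback (NF1).** Active ERK phosphorylates
  free SOS distributively on `n_sos_sites = 4` residues (sequential,
  one site per encounter, per-site rate `q1`; per-site removal `d1`).
  A single phosphorylated site abolishes receptor binding, and SOS in
  a receptor complex can be neither phosphorylated nor
  dephosphorylated. NF1 therefore drains the pool of complex-competent
  SOS while ERK is active, and the multi-step dephosphorylation chain
  delays its return.
* **ERK-to-RAF (NF2) and ERK-to-MEK (NF3).** Active ERK also converts
  RAF (both forms; switchable) and unphosphorylated MEK into inhibited
  phospho-states that recover at `d2`, `d3`. These loops sit downstream
  of the positive feedback and shape the pulse waveform rather than
  generate oscillations.

MEK and ERK are activated by two distributive (de)phosphorylation
steps; singly phosphorylated MEK is assumed inactive. Two ERK-activity
reporters with slow (EKAR3-like) and fast (ERKTR-like) phospho-cycling
kinetics read out ERK_pp without consuming it.

Units: concentrations are normalized so `ERK_tot = 1`; time is in
minutes; the EGF dose (pg/ml) enters only through the receptor
activation propensity `egf_gain * dose`.

## Dynamical skeleton

With the negative feedbacks off, scanning the total receptor-SOS
complex level (`clamp_complex_variant`) yields an S-shaped branch of
steady states with two saddle-node points SN1 < SN2: the system is
bistable over a window of complex abundance. The full model turns this
switch into a relaxation oscillator: EGF builds complexes past the
SN2-equivalent, ERK fires, NF1 drains free SOS until the complex level
falls below the SN1-equivalent, ERK shuts off, and the slow multi-site
dephosphorylation of SOS resets the cycle. Amplitude is set by the two
branches and is nearly independent of dose; the period is the sum of a
dose-dependent inhibition phase and a dose-dependent recovery phase,
which makes it non-monotone in dose (long near both boundaries).

## Default parameters and how they were chosen

There is no public numeric parameter table for this network, so the
package ships a calibrated reference set (`mapkosc.params.ParameterSet`
defaults). Structure was fixed first (`k2C = 0`, `k2B = 0.1 k2A`, four
SOS sites); the remaining values were selected by the staged procedure
in `mapkosc.calibrate` to reproduce target behaviors:

1. **Positive-feedback stage** — `k2A = 60`, `b3 = 1600`, `u3 = 1`,
   `RasGAP_tot/RAS_tot = 0.05`: the clamped-complex scan is bistable
   with SN2/SN1 ≈ 5 in complex units. Making RasGAP less saturable
   (larger `u3` at fixed `b3 * RasGAP_tot`) shrinks and then destroys
   the window, as does removing the GEF-rate asymmetry
   (`k2B = k2C = k2A`).
2. **Cascade-timing stage** — `k_raf_act = 2`, `k_mek_ph = k_erk_ph =
   4`, deactivation rates 0.5/min: after the RAS switch flips, ERK
   reaches half-activation within ~5–10 min.
3. **Negative-feedback stage** — `q1 = 0.465`, `d1 = 0.1` put the
   per-site drain against the binding protection of complexed SOS such
   that (i) a two-site chain can never drain the complex pool below the
   SN1-equivalent, so oscillations require at least three sites, and
   (ii) the four-site chain sustains a limit cycle over roughly two
   decades of dose with a period above one hour. The auxiliary
   feedbacks (`q2 = q3 = 0.05`, `d2 = d3 = 0.05`) close the top of the
   oscillatory range: at strong stimulation they weaken ERK activity
   enough that NF1 can no longer disengage the positive feedback, and
   the system locks into a persistent on state.
4. **Input-gain stage** — `k_egfr_deact = 0.5/min` sets the receptor
   activation/deactivation timescale (≈ 2 min), which controls how the
   critical dose rises as stimulation gets shorter; `egf_gain` is then
   rescaled (a one-step exact operation, since dose enters only as
   `egf_gain * dose`) so that the minimal sustained dose that fires a
   full ERK pulse is exactly 2.5 pg/ml. This anchor makes the
   critical-dose check a pipeline consistency test rather than an
   independent prediction; the other calibrated behaviors (range ratio,
   period, site-count threshold, pulse-duration thresholds) are not
   directly optimized by the anchor.

The sustained-dose/pulse-duration trade-off deserves a note: for short
pulses the receptor pool integrates the input, so the critical
condition is approximately `dose x duration ≈ const`, while for long
pulses the critical dose converges to the sustained threshold. The
crossover timescale is `1/k_egfr_deact` plus the commitment time of
the RAS switch; both were chosen so that at 3 pg/ml only stimulations
longer than ~14 min trigger a pulse while at 60 pg/ml ~25–30 s
suffice.

## Numerical choices

* ODE integration: LSODA with `rtol = 1e-8`, `atol = 1e-10`; the dose
  is piecewise constant and integration restarts at protocol
  breakpoints. Conservation of all protein totals is asserted on every
  checked trajectory at 1e-8 relative tolerance.
* Pulse threshold: active-ERK fraction 0.5 ("high ERK activity").
  Long-run classification uses 50 h of simulated time with a 10 h
  transient discard; a trajectory is oscillatory if ≥ 4 peaks give
  inter-peak intervals with CV < 5% and peak-to-trough amplitude
  > 0.1. Acceptance results are insensitive to the pulse threshold
  within 0.3–0.7.
* Steady states: multi-start damped root finding (`scipy.optimize.root`,
  hybr) on the conservation manifold; one redundant rate equation per
  conserved pool is replaced by its conservation residual. Stability
  comes from eigenvalues of the numerically differentiated Jacobian
  projected onto the manifold's null-space basis (removing the zero
  modes along conservation directions). Duplicate roots are merged at
  1e-6 (infinity norm). Fold points are refined by bisection on the
  steady-state count (0.1% of the scan span); regime boundaries by
  bisection on the oscillation classifier (5% in dose).
* Continuation is intentionally replaced by scan + bisection. Hopf
  points appear only as oscillatory/monostable boundary points; the
  sub/supercritical distinction and unstable-cycle branches are out of
  scope. Near period discontinuities the scanner just reports what the
  detector sees; no attempt is made to resolve the bifurcation fine
  structure there.

## Stochastic extension

The network is recast as a Markov jump process (copy numbers
`round(omega * concentration)`; default test scale `omega = 1e3`,
population figures use the hybrid mode). Extrinsic noise enters through
bursty EGFR surface expression: a telegraph process switches synthesis
on (rate `lam_interburst = 1/120 min^-1`) and off (`lam_burst = 1/30
min^-1`); while on, receptors are produced at `A_burst * alpha_cell`
with `alpha_cell` log-normal with mean exactly 1 (sigma 0.3); every
EGFR-containing species decays with half-life `tau_egfr = 360 min`,
with receptor-bound SOS and REM-site RAS released on decay so that all
non-receptor conservation laws hold exactly. These burst parameters are
package defaults chosen so receptor abundance fluctuates on a
multi-hour timescale; they are not published values. The full SSA is an
exact direct-method implementation (numba); the hybrid mode samples the
telegraph process exactly and integrates the network deterministically
between switches, which isolates the extrinsic-noise channel (the
receptor path is then identical across doses for a fixed burst path,
which is what makes dose panels comparable cell by cell).

## Spatial extension

Extracellular EGF from paracrine point sources obeys a 3-D
diffusion-degradation equation in unbounded space and is evaluated
analytically via the constant-source Green's-function solution
(complementary error functions; the growing-exponential term is
computed with `erfcx` for stability), with finite-duration releases as
time-shifted differences. Default field parameters: `D_EGF = 100
um^2/s`, `gamma_EGF = 0.01/s`, sources uniform in a shell between the
cell radius (10 um) and 50 um.

The cell itself is reduced from a sphere to a periodic 1-D angular
ring of `n_nodes = 64` nodes carrying both membrane species (receptors,
complexes, RAS, RasGAP; `D_mem = 0.1 um^2/s`) and cytosolic species
(SOS, RAF, MEK, ERK, reporters; `D_cyt = 10 x D_mem`). Reaction terms
are the full network RHS with the local EGF dose sampled at each
node's 3-D position on the equator; membrane-to-cytosol activation and
cytosol-to-membrane inhibition are local in angle, which is the 1-D
reduction of the Robin boundary coupling with geometric factors
absorbed into `k_raf_act` and `q1`. Integration is fixed-step RK4 with
a CFL-safe step. The reduction preserves the phenomena of interest —
bistable-front (heteroclinic) RAS waves and local-excitation /
global-inhibition pulses — at desk scale; it does not resolve
radial cytosolic gradients or a nucleus, and the grid abstraction
leaves room for a spherical-surface backend.

## What the synthetic data do and do not show

All inputs are generated by the package itself (protocols, burst
paths, source events); there is no external data. Passing tests
demonstrate internal consistency of the model family — the ODE, SSA,
and PDE layers agree in their common limits (large omega, frozen
receptor path, homogeneous field) and reproduce the calibrated
behaviors. They do not validate the parameter values against
measurements; real dose-response curves, receptor counts and reporter
kinetics would constrain the same parameters differently.

## Known limitations

* The upper oscillatory boundary is sensitive to the NF1/NF2/NF3
  balance (the underlying transition is nearly an infinite-period
  one), so the ~100-fold range figure should be read as "about two
  decades", not a sharp prediction.
* No receptor trafficking, no RAS membrane microdomains, no
  GAB1-PI3K loop, no phosphatase-saturation bistability in the
  MEK/ERK cycle; intrinsic (GAP-independent) RAS-GTP hydrolysis is
  omitted.
* Whether NF2 targets RAF, RAF_a or both is not settled; both are
  targeted by default (`nf2_targets_active`).
* SBML export covers the core mass-action network (dose as a constant
  parameter); it is a cross-validation aid, not a round-trip format.
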