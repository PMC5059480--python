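# Methods

This note records the models, numerical choices and limitations behind
`thiodyn`.  Units throughout: energies in eV, times in fs, wavelengths
in nm, spin–orbit couplings quoted in cm⁻¹ (8065.543937 cm⁻¹/eV,
1239.84198 eV·nm, ħ = 0.6582119569 eV·fs).

## Transient-absorption kinetics

The ΔA(λ, t) map is modelled bilinearly: shared concentration profiles
times per-wavelength amplitudes (decay-associated spectra, DAS).  The
profiles follow the two-step sequential scheme *A* →(τ₁) *B* →(τ₂) *C*
with *C* a non-decaying offset, each convolved with a Gaussian IRF of
fixed FWHM (default 200 fs, the value determined experimentally from a
solvent coherence signal and therefore not floated in the fit).  The
convolution has the exponentially-modified-Gaussian closed form; we
evaluate it in two algebraically identical branches (scaled
complementary error function `erfcx` for early delays, plain `erfc`
late) so that neither branch overflows anywhere on a −1…+20 ps axis.
The equal-lifetime degeneracy |k₁ − k₂| < 10⁻¹² fs⁻¹ switches to the
analytic t-weighted limit rather than subtracting nearly equal terms.

The global fit treats (τ₁, τ₂, t₀) as the only nonlinear parameters;
for every trial the DAS are the exact masked linear least-squares
solution (variable projection), so the optimiser never sees the
~600-dimensional joint space.  Bounded trust-region least squares with
three log-spaced starts guards against the shallow slow-lifetime
direction; ties resolve by residual, then smaller τ₁.  A test asserts
the variable-projection optimum coincides with the full joint fit to
10⁻⁶ relative.  Lifetimes whose optimum touches the bounds are flagged
non-identifiable instead of being reported silently.  Uncertainties
come either from the linearised covariance of a single fit or, as in
the replicate-experiment convention, as twice the standard deviation
over independent fits.

Chirp (probe group-velocity dispersion) is a polynomial t₀(λ) in nm;
correction resamples each wavelength's trace at t + t₀(λ) by linear
interpolation and masks points leaving the recorded window.  The
workflow order is fixed: chirp correction first, then a single global
t₀ in the fit.

## Excited-state absorption spectra

Stick spectra (transition energy, oscillator strength) are broadened
with Gaussians of constant **energy-domain** width (default 0.7 eV
FWHM) and sampled on the wavelength grid without a dE/dλ Jacobian: the
band is a function of energy re-plotted against wavelength, which keeps
a single stick's arg-max exactly at its nominal wavelength.  The
Jacobian alternative would shift band maxima red-ward by several nm;
the no-Jacobian convention is the one under which the quoted band
positions (363 nm, 441/546 nm, …) are self-consistent.  Decomposition
of a transient spectrum into component bands uses non-negative least
squares, because the components represent additive populations of
absorbers; weights are reported as percentages of their sum.

## The vibronic model

The electronic landscape is a linear vibronic coupling (LVC) model on
three dimensionless effective modes (frequencies 0.12, 0.10, 0.08 eV —
free calibration parameters of skeletal-stretch magnitude, not fitted
to any spectrum):

    H_aa(q) = E_a + Σ_i κ_ai q_i + Σ_i (ω_i/2) q_i²
    H_ab(q) = λ⁰_ab + Σ_i λ_abi q_i        (same multiplicity only)

with five spin-free states (S0, ¹n_Sπ*, ¹π_Sπ*, ³n_Sπ*, ³π_Sπ*).  Modes
1–2 are tuning modes (state-specific gradients κ); mode 3 is a pure
coupling mode carrying λ = 0.02 eV for the ¹ππ*/¹nπ* and ³nπ*/³ππ*
pairs.  Spin expansion gives 3 + 3·2 = 9 spin components.  Spin–orbit
coupling is coordinate-independent (Condon approximation) at the
reported trajectory-average magnitudes — 160 cm⁻¹ for the El-Sayed-
allowed pairs (¹nπ*–³ππ*, ¹ππ*–³nπ*), 50 cm⁻¹ for the same-character
pairs, 5 cm⁻¹ between S0 and the triplets — distributed over the
mₛ = ±1 sublevels by a unit-norm pattern; only the Frobenius norm of
each singlet–triplet block (which equals the configured magnitude by
construction) affects rate-level observables, so the sublevel pattern
is a convention, not a physical claim.

Minima are located by L-BFGS descent on the adiabatic spin-free surface
that carries each diabatic character (character followed by eigenvector
weight), started from the analytic diabatic minimum.  Crossing seams
(conical intersections within a multiplicity, singlet–triplet MECPs
across) minimise the mean energy under a squared-gap penalty whose
weight ramps ×10 per cycle until the gap closes below 10⁻⁴ eV; this is
robust on a 3-mode model where only 0.05 eV accuracy is required.  The
ground-state-recovery barrier is measured as the minimum-energy point
of the S0/¹nπ* seam relative to the ¹nπ* minimum and is only checked
against its 0.8 eV lower bound.

Calibration adjusts the four excited states' vertical energies and
tuning-mode gradients (12 parameters) by derivative-free least squares
until all ten packaged reference energies are met within 0.05 eV; the
shipped `2tc_model.yaml` resource is the result and the calibration is
a deterministic fixed point of its own output.  The model's coordinates
are abstract: no claim is made that they resemble real nuclear
displacements of 2-thiocytosine, only that the energetics of the
minima, crossings and barriers match the reference landscape.

## Surface hopping

Dynamics runs on the *diagonal* surfaces (eigenstates of the spin-free
Hamiltonian plus SOC).  Nuclear motion: velocity Verlet with effective
masses ħ²/ω_i, the gradient of the active diagonal state being the
diagonal element of the transformed diabatic gradient (u†∇H u — no
response terms, consistent with computing diagonal-state gradients from
spin-free gradients).  Electronic motion: local diabatization — the
eigenbasis overlap S = U†(t)U(t+Δt) (Löwdin-orthonormalised; exactly
unitary here because the diabatic basis is global) freezes a locally
diabatic basis over the step, the end-point Hamiltonian is transformed
into it, and the Schrödinger equation is integrated with 25 midpoint
exponentials (Δt_e = 0.02 fs for Δt_N = 0.5 fs).  The scheme conserves
the electronic norm to rounding (observed ≤ 10⁻¹³).

Hops use the propagator-resolved fewest-switches form: the probability
of leaving the active state is its fractional population loss over the
step, partitioned over targets by the interference terms
Re[c_k*(t+Δt) R_ka c_a(t)] of the full step propagator R.  This form is
invariant under basis reordering between steps; a naive partition that
matches state indices across the step by overlap argmax is not (two new
eigenvectors can claim the same old index near strong mixing, which
manufactures population flux and spurious hops into remote states), so
the propagator-resolved flux is the one implemented.  The active
surface's identity is followed through trivial crossings by the
overlap row argmax.  Accepted hops rescale the full velocity vector
uniformly to conserve total energy (coupling vectors are not available
in an overlap-based scheme); energetically frustrated hops are rejected
with momenta unchanged (no reflection).  The energy-based decoherence
correction damps every non-active amplitude with
τ_k = ħ/|E_k − E_active| · (1 + C/E_kin), C defaulting to the customary
0.1 hartree (2.7211 eV), then restores unit norm on the active state; a
vanishing gap means no damping.

Initial conditions sample the harmonic ground-state Wigner distribution
(variance ½ per mode in q and p, no thermal excitation).  Initial-state
selection accepts a geometry with probability proportional to summed
oscillator-strength surrogate weights of the singlet adiabats whose
vertical excitation falls in a configurable window, then picks among
them by weight; weights and window live in config because the exact
experimental weighting is not published.  Trajectory *i* draws its
hopping randoms from the dedicated stream seed + i, so single
trajectories coincide bit-for-bit with ensemble members and ensembles
are reproducible.

Energy bookkeeping: between changes of the active surface's identity,
total energy drift is pure integrator error and scales as Δt²
(measured: 2×10⁻² eV at 0.5 fs down to 8×10⁻⁵ eV at 0.01 fs on the
calibrated model).  At a *relabel* through a narrow avoided crossing
the active energy legitimately jumps by the local gap — the
trivial-crossing problem common to all hopping codes — so the
conservation metric resets there, and the conservation suite runs the
integrator in its converged regime (Δt_N = 0.01 fs over 100 fs) while
production ensembles use the standard 0.5/0.02 fs protocol.  A
trajectory whose drift exceeds 0.1 eV is flagged invalid; an ensemble
with > 20% invalid trajectories raises.

The Landau–Zener validation (1D linear diabats, slopes ±0.02 eV,
constant coupling 0.02 eV) scans five velocities with crossing-point
kinetic energies 0.2–0.6 eV — large against the 0.04 eV adiabatic
splitting, the regime in which the closed form's constant-velocity
assumption holds.  Observed agreement is ~1%; at crossing energies
comparable to the splitting (≤ 0.1 eV) surface hopping undershoots the
formula by 10–20% because the post-hop momentum rescaling is no longer
a small perturbation, a known regime limitation rather than an
implementation artifact (the electronic propagation alone reproduces
the closed form to < 1% along a frozen path there).

## Populations, lifetimes, kinetic surrogate

Ensemble populations count active states (trajectory fractions), not
coefficient populations.  Each active diagonal state is assigned to the
spin-free class with the largest eigenvector weight — classes are
S0/S1/S2/T1/T2 by energetic ordering *at each geometry*, triplet
sublevels pooled, ties (< 10⁻⁶) broken towards the lower index and
counted.  Lifetimes come from least-squares fits of
p(t) = A·exp(−max(t−t_d, 0)/τ) or its rise complement; the delayed
onset t_d is optional because the convention is not pinned down.
Confidence intervals bootstrap over trajectories (200 seeded
resamples).

The Markov surrogate of the relaxation scheme uses exact event-driven
simulation plus the master-equation solution via the generator's matrix
exponential.  Packaged rates (fs⁻¹): S2 depopulates at 1/160 (0.95/160
to S1, a minor 0.05/160 directly to T2), S1 at 1/250 split 2.5 : 1
between T2 (1/350) and T1 (1/875), and T2 → T1 at 1/480.  The S2 and
S1 totals are the published simulation-derived time constants; the
branching split and the minor direct channel are declared package
choices consistent with the reported faster T2 rise, and no ground-state
recovery channel is included.

## What the synthetic data does and does not emulate

The ΔA generator reproduces the structure the analysis assumes —
bilinear sequential kinetics, 200 fs IRF, polynomial chirp, iid
Gaussian noise (0.05 mOD default; the experimental noise level is
unpublished), a masked 600–632 nm pump-overtone window, and a
linear-then-logarithmic delay grid — with DAS shapes that are declared
sums of two Gaussians placed at the reported band positions, not
digitised figure data.  It does not emulate coherent artifacts, solvent
signals, anisotropy, or correlated noise, so passing recovery tests
demonstrates correctness of the estimator under the model's own
assumptions, not robustness to every systematic a real experiment
carries.  Likewise the vibronic model reproduces the reference
energetics but not ab initio surfaces; headline figures that depend on
those surfaces (e.g. the exact triplet yield at 1 ps) are treated as
qualitative properties — triplet majority over the excited singlets,
strict monotonicity of the yield in the SOC magnitude — never as
numerical reproduction targets.

## Problem sizes

Default study conditions: 196 × 141 ΔA maps (320–710 nm step 2 nm,
−1…+5 ps), five map replicates for lifetime statistics, 137 jump
trajectories over 1 ps, 10⁴ trajectories per Landau–Zener velocity,
50-trajectory conservation ensembles over 100 fs, and 100-trajectory
mechanism ensembles over 1 ps.
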