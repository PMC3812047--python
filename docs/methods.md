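# Methods

## Scope and units

`protoadapt` simulates two minimal "protocell" adaptation mechanisms built
from equilibrium physics, a non-equilibrium bacterial-chemotaxis reference
model, the thermodynamic accounting that separates the two regimes, a metrics
suite for step responses, and 2D gradient sensing on a disk.  Units are fixed
package-wide: lengths in um, times in s, concentrations in mM, energies in
k_B·T, entropy in k_B.  All models are deterministic; there is no RNG anywhere
in the core computations.

## Transmembrane diffusion (one-component model)

After an external step from c0 to c1, the interior concentration of a sphere
of radius R with a permeable membrane (Dirichlet surface condition) is

    u(rho, t) = c1 + (c0 - c1) * phi(rho, D t / R^2),

with rho = r/R and phi the classical eigenfunction series

    phi(rho, tau) = -(2/(pi rho)) * sum_{n>=1} ((-1)^n / n) sin(n pi rho) e^{-n^2 pi^2 tau}.

Numerical choices: the Fourier form is used for tau >= 0.02 (48 terms put the
truncation remainder far below 1e-12 mM); for tau < 0.02 the exact
method-of-images (erfc) representation is used instead, which converges
superexponentially at short times.  The two branches agree to ~1e-12 at the
switch point.  The 1/rho prefactor makes rho = 0 singular in this form; the
API rejects it and models only ever sample the receptor radius rho = (R-l)/R.
An independent Crank–Nicolson solver (on v = r·u, with Rannacher startup
steps to damp the boundary-discontinuity oscillations) cross-validates the
series to sup relative error < 1e-4 over a 10x10 (rho, t) lattice.

## Receptor free energy and activity

The one-component receptor has an extracellular site that binds ligand
preferentially in the *off* state and an intracellular site that binds
preferentially in the *on* state.  With receptor conformations in
quasi-equilibrium (binding is ns–us, diffusion is ms–s), the on/off free
energy difference is the difference of per-state binding polynomials,

    F = eps + ln[(1+c_out/K_off_out)/(1+c_out/K_on_out)]
            + ln[(1+c_in/K_off_in)/(1+c_in/K_on_in)],      A = 1/(1+e^F).

Under the symmetric simplification K_off_out = K_on_in and K_on_out = K_off_in
the two logs cancel identically at c_in = c_out, so the adapted activity is
exactly the baseline A(eps) whatever the stimulus: precise adaptation with
zero cellular energy expenditure.  Defaults: K_off_out = K_on_in = 0.01 mM,
K_on_out = K_off_in = 100 mM, eps = 0.  The wide K separation puts the
mid-range concentrations (0.1–5 mM) in the logarithmic-sensing regime where
F ≈ eps + ln(c_out/c_in), which is a function of the fold alone — the origin
of the approximate fold-change detection the tests verify (sup-norm < 1e-2
between the 0.1→0.5 and 0.2→1 mM responses).

Default geometry: R = 5 um (eukaryote-scale cell), receptor inner length
l = 0.5 um (rho = 0.9), with {0.5, 0.7, 0.9} swept in the fig3 scenario;
D_ligand = 100 um^2/s (small molecule in cytoplasm).  These constants are
package choices on the scale a cell biophysicist would pick for a
eukaryote-sized protocell; every one is config-overridable.

## Two-component model

The first component senses only c_out (K_on1 = 0.01, K_off1 = 100 mM,
bias eps1 = 2 k_B T) and does not adapt.  It releases alpha and betagamma
subunits whose source concentration is clamped at k_release * A1
(k_release = 0.1 mM).  Each subunit arrives at the second component through
the same normalized diffusion solution with its own diffusivity
(D_alpha = 200, D_betagamma = 20 um^2/s) over length scale L2 = 2.5 um at
sampling radius rho2 = 0.5.  The released-subunit boundary condition is
concentration-clamped (Dirichlet), matching the reuse of the spherical-step
solution; a flux-based source would change transient shapes but not the
cancellation structure.  General A1 histories are handled by Duhamel
superposition of step responses — exact for the linear diffusion equation and
identical to the single-step formula for step stimuli.

The second component's free energy mirrors alpha (activating, tight constant
K_tight = 10 mM) against betagamma (inhibiting, same constants mirrored), so
c_alpha = c_betagamma cancels exactly and A2 adapts precisely.  Subunit
levels (<= 0.1 mM) sit far below K_tight, so the response is linear in the
concentration difference; a consequence is that the A2 peak time is set only
by the arrival-profile difference of the two subunits, making the response
time strictly positive and independent of the background stimulus, at the
cost of small absolute sensitivity (both features the step-response tests
check).

## Thermodynamic accounting

For a reaction with one-way rates J+ and J-, the entropy production rate is
(J+ - J-) ln(J+/J-) in k_B per time — nonnegative and zero exactly at
detailed balance.  For transmembrane diffusion, Fick's first law gives
J+ = (D_m/d) c_out and J- = (D_m/d) c_in per unit area (D_m = 1 um^2/s,
d = 5 nm), hence for the whole cell

    sigma = 4 pi R^2 (D_m/d) nu (c_out - c_in) ln(c_out/c_in),

with nu = 6.022e5 molecules/(um^3 mM) converting concentration to number
density so that sigma is in k_B/s.  Concentrations are floored at 1e-12 mM
before the log so zero-concentration stimuli remain defined; equal
concentrations give exactly zero.  The rate is maximal immediately after a
step and decays monotonically to zero with equilibration; this dissipation is
paid by the changing environment, not by the cell — the module reports one
series and this note carries the attribution.

## Chemotaxis reference model

Activity is the linear MWC form with cluster size 6, eps(m) = 1 - m/2,
K_off = 0.02 mM, K_on = 0.5 mM (Tar/MeAsp scale).  The precise pathway is the
linear CheR/CheB methylation model extended with reverse reactions,

    dm/dt = (gamma_R - gamma'_R)(1-a) - (gamma_B - gamma'_B) a,

with gamma_R = 0.0069/s, gamma_B = 0.0138/s (set-point a* = 1/3) and reverse
rates one fifth of the forward ones, keeping the net CheR/CheB actions as
methylation and demethylation.  Its steady state pins a to a* for every c,
while the four one-way fluxes remain pairwise unbalanced — a futile cycle
dissipating N_rec * [Gamma_R(1-a*) + Gamma_B a*] * ln 5 ≈ 1.2e2 k_B/s for
N_rec = 1e4 receptors.

The equilibrium variant couples methylation to ligand binding instead of
activity.  Methylation proceeds through a ligand-free route (rates
alpha+ = 0.005, alpha- = 0.015 /s; binding constant K_free = 0.5 mM) and a
ligand-bound route (beta+ = 0.125, beta- = 0.015 /s; K_meth = 0.02 mM), with
binding pre-equilibrated:

    dm/dt = k+(c) (m_max - m) - k-(c) m,
    k+(c) = (alpha+ + beta+ c/K_free) / (1 + c/K_free),
    k-(c) = (alpha- + beta- c/K_meth) / (1 + c/K_meth).

The thermodynamic cycle-closure (equilibration) condition
beta+/beta- = (alpha+/alpha-)(K_free/K_meth) makes the steady state a true
four-state Boltzmann equilibrium: each route balances individually, so the
entropy production is exactly zero — yet because the methylated receptor
binds ligand more tightly (K_meth < K_free) the equilibrium methylation
shifts with c, so the adapted activity moves with the stimulus: imprecise
adaptation at zero dissipation.  m_max = 8 methylation sites; the optional
clamp of m to [0, m_max] is off by default (the linear model is unbounded)
and available to demonstrate precision loss from finite methylation range.

The convex mixture dm/dt = (1-x)·precise + x·equilibrium and the
per-reaction entropy sum (precise channel weighted by 1-x, equilibrium
routes by x) trace the dissipation–precision trade-off.  Steady states are
found by bracketed root solving (the mixed rate is strictly decreasing in m,
xtol 1e-14) and confirmed against long Radau integrations (rtol 1e-8,
agreement < 1e-8).  Imprecision is measured between adapted states before
and after a 0.1 → 0.2 mM step as |(a_ss - a_pre)/a_pre| / |Δc/c0|.  The sweep
magnitudes depend on the package's chosen rate constants; the asserted
content is the monotone trade-off and the zero/positive dissipation
distinction at the endpoints.

## Step-response metrics

Peak detection uses the extremum of |a(t) - a_pre| so drops and rises are
handled uniformly; ties resolve to the earliest sample.  Adaptation time is
the first post-peak time at which the displacement halves, with linear
interpolation between samples; response time is onset-to-peak; sensitivity
and imprecision are the relative-change ratios
|Δa/a_pre| / |Δc/c0| evaluated at the peak and at steady state respectively
(the Ma-et-al convention; each lives in one function so an alternative
normalization is a one-line change).  Degenerate inputs (flat response, no
recovery, zero baseline, unsteady tail) raise `MetricError` rather than
returning a number.

## Gradient sensing on a disk

The interior field solves the diffusion equation on a polar grid (center node
with the averaged-neighbor stencil; default 40 rings x 96 angles) with
implicit backward-Euler stepping (unconditionally stable; the factorization
is reused over the uniform grid).  The external field is linear in x: 0 mM at
the rear, 1 mM at the front, from a uniform 0.5 mM start; the fig8 scenario
uses D = 10 um^2/s so the interior relaxes over seconds.

Membrane coupling: Dirichlet by default, with a Robin mode
-D du/dn = kappa (u - c_ext), kappa = D_m/d, selectable and verified to
converge to Dirichlet as kappa grows.  Dirichlet is the default because any
finite Robin coupling sustains a steady membrane flux, which would leave a
permanent receptor-activity asymmetry; with the Dirichlet condition the
steady interior field is the harmonic extension of the boundary data — the
same linear-in-x profile as outside — and the receptors adapt exactly.

Each receptor compares the interior concentration at its intracellular site
(radius R - l along its ray) with the external field *evaluated at that same
point*.  The external gradient is defined across the whole cell length, so
this is the physically consistent comparison; it is also the only one under
which circumferential adaptation is exact at steady state (pairing the
boundary value at radius R with the interior value at R - l leaves a residual
proportional to l times the gradient).  The activity dipole is the
mesh-independent mean P = <(a_i - a*) x_i / R> over boundary receptors
(a* = adapted baseline activity); the polarization is the front-rear interior
concentration difference at the sampling radius normalized by the rear value.
P pulses at gradient onset and decays below 1e-3 of its peak, while the
polarization persists (≈ 2 rho/(1-rho) = 18 for rho = 0.9): the response
ceases, the internal gradient remains.

## Problem sizes and tolerances

Default grids: step responses at dt = 1e-3 s; the adaptation-time ladders use
dt = 2e-6 s because the fastest positive-step half-recovery is ~1 ms; the
two-component response-time comparison uses dt = 2e-4 s; the gradient run
takes 3000 implicit steps on ~3.8k nodes (a few seconds).  Series truncation
is bounded by 1e-12 mM; precise-adaptation checks use 1e-6 on activity;
solver cross-validation uses 1e-4 relative.  These sizes were chosen so each
scenario resolves its fastest feature by at least two orders of magnitude in
time while remaining desk-scale.

## Known limitations

* No receptor clustering, cooperativity, or multiple receptor species; the
  models' sensitivity is accordingly low by construction.
* No cell motility, shape change, or 3D gradient variant.
* No CheY/CheB phosphorylation dynamics in the chemotaxis entropy accounting.
* The synthetic scenarios exercise clean steps and perfect linear gradients;
  real stimuli are noisy and temporally structured, so passing tests
  demonstrate the mechanisms' mathematical structure, not quantitative
  agreement with any measured pathway.
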