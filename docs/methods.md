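# Methods

## Two-state exchange model

The dispersion model assumes a single global exchange process
A ⇄ B with forward rate k_AB, reverse rate k_BA, exchange rate
k_ex = k_AB + k_BA and excited-state population p_B = k_AB/k_ex < 0.5.
During the CPMG relaxation delay the transverse magnetisation
(one complex component per state) evolves under

    d/dt [M_A, M_B] = [[-R2,0 - k_AB,            k_BA],
                       [        k_AB, -R2,0 - k_BA + iΔω]] [M_A, M_B]

with ideal, instantaneous 180° pulses implemented as complex conjugation.
A CPMG element is τ–180–τ with τ = 1/(4ν_CPMG); the element count
n = 2 ν_CPMG T_relax must be integer (nominal frequencies within 1% of an
integer count are snapped to it, e.g. 66.7 Hz → 4 elements in 30 ms; others
are rejected with the closest valid frequency named).  Starting from
equilibrium populations, R2,eff = −(1/T_relax) ln(|M_A(T_relax)|/p_A).

Modelling assumptions: both states share one intrinsic rate R2,0 (per
residue and field); |Δω| per residue is temperature independent and stored
in ppm, converted per field via the ¹⁵N/¹H frequency ratio 0.1013 and 2π;
the sign of Δω is not identifiable in single-quantum CPMG and the
generators emit positive values only; longitudinal relaxation during the
constant-time delay cancels in the I/I₀ ratio and is ignored; pulse
imperfections are outside scope (the relaxation-compensated experiment
justifies the ideal-pulse treatment at this level).

The batched evaluator used by the global fit propagates all data points at
once: the 2×2 matrix exponential is evaluated in closed form through the
eigenstructure of each rate matrix, and the two-element propagator
P·conj(P)·conj(P)·P is raised to n/2 by binary exponentiation.  It is
tested to agree with the scalar propagator to machine precision.

## Closed-form oracle

`carver_richards_r2eff` solves the same echo-train problem analytically:
closed-form half-element propagator entries, eigenvalues and spectral
projectors of the two-element propagator, and the finite train length,
all in scalar complex arithmetic with no matrix exponentials or repeated
matrix products.  It matches the numerical propagator to better than 0.1%
over k_ex ∈ [100, 5000] s⁻¹, p_B ∈ [0.01, 0.15], Δω ∈ [0.5, 6] ppm at
500/700 MHz, giving a genuinely independent route to the same observable.
The widely quoted shorthand of this solution — the decay rate of the
dominant eigenvalue alone, available via `asymptotic=True` — neglects the
finite-train intensity prefactor.  It agrees in fast exchange but
overestimates R2,eff by up to ~10% at low CPMG frequencies in
slow-intermediate exchange (k_ex below |Δω|) with appreciable p_B, where
only a handful of echoes fit into the 30 ms delay; that regime is why the
full closed form is the default oracle.  The Luz–Meiboom fast-exchange
expression provides a third, independent limit check
(R_ex = p_A p_B Δω²/k_ex · [1 − (4ν/k_ex) tanh(k_ex/4ν)]).

## Experimental-side conventions

R2,eff errors follow σ/(T_relax · I_CPMG(500 Hz)) with a floor of 3% of
R2,eff; when no noise estimate is available the floor alone is used, and
the 500 Hz spectrum is replaced by the nearest measured frequency when
absent.  The exchange filter retains a residue when
ΔR2,eff = R2,eff(66.7 Hz) − R2,eff(1000 Hz) exceeds 5 s⁻¹ in *any*
field/temperature condition (the alternative "all conditions" rule would
discard residues whose exchange contribution collapses at high
temperature); residues tagged for peak overlap or low quality are excluded
regardless.

## Global fit

The target function is the error-weighted sum of squared R2,eff residuals
over every point.  Parameters are log-transformed (rates, Δω, R2,0) and
logit-transformed (p_B), keeping the physical values positive and p_B
inside (0, 1) without explicit bounds; p_B approaching 0.5 (state
relabelling degeneracy) raises an identifiability warning.  The default
joint mode shares Δω and R2,0 across temperatures and fits one
(p_B, k_AB) pair per temperature — for the reference design that is
2·n_T + n_R + n_R·n_B = 76 parameters against 2640 points.  A strict
per-temperature mode (every temperature fitted independently, Δω free per
temperature) is available for comparison.

Minimisation uses trust-region least squares with a sparse finite-difference
Jacobian (each residual depends on only four parameters), relative-χ²
tolerance 1e-8 and at most 10⁴ evaluations.  The automatic initialisation
takes R2,0 from the high-frequency plateau, Δω from the dispersion
amplitude through the fast-exchange relation at k_ex = 1000 s⁻¹ and
p_B = 0.05, and the default five multi-starts perturb the kinetics by
about a factor of two; on the reference design the fit lands at the global
optimum from the automatic start alone, and the multi-start guard is kept
for less regular data.  Uncertainties come either from the Gauss–Newton
covariance scaled by the reduced χ² (so exactly-fitting data yield zero
error) or from a seeded residual bootstrap.

## Thermodynamic analysis

ln Kₑ and ln(k_AB/T) − ln(κ k_B/h) are regressed linearly on 1/T
(unweighted by default, as Kₑ uncertainties are usually unavailable;
optional weights accepted), with R = 8.314 J K⁻¹ mol⁻¹ and
κ = 1.6×10⁻⁷ (configurable).  κ scales only the intercept: doubling it
shifts ΔS* by −R ln 2 and leaves ΔH* untouched.  At least three
temperatures are required.  Energies are carried in J/mol internally,
reported in kJ/mol; the reaction-coordinate diagram enforces
ΔG = ΔH − TΔS per level by construction.

## Backbone relaxation

Exponential decays are fitted with inverse-variance weights when per-point
intensity errors are known.  τ_c inversion uses the isotropic-rotor
spectral densities J(ω) = (2/5)τ_c/(1+(ωτ_c)²) with ¹⁵N CSA −160 ppm and
r_NH = 1.02 Å (both configurable), a 10% trimmed mean of the R₂/R₁ ratios
of rigid residues (Het-NOE ≥ 0.65), and Brent root finding over
0.5–50 ns.  The method for the reference τ_c (8.2 ns) was not part of the
source analysis' stated procedure, so this package's choice — standard
R₂/R₁ inversion — is validated only by forward-simulation round trips.
Exchange-broadened residues can be excluded from the estimate, as R_ex
inflates R₂.

## Shift analyses

Temperature coefficients are linear regressions of the ¹H shift (ppb) on
temperature; classification is strict (> −5 ppb/K counts as H-bonded,
exactly −5 does not).  The combined CSP uses
√(Δδ_H² + (0.14·Δδ_N)²) with the mean + 1 SD significance rule.  Binding
fits use the exact quadratic single-site isotherm (no weak-binding
approximation) for (K_D, Δω_max); titrations whose largest ligand
concentration does not exceed the fitted K_D are flagged poorly
determined, and residues whose peaks vanish during the titration carry a
`disappeared` flag and are excluded from fitting rather than imputed.
The titration-vs-dispersion |Δω| comparison flags residues disagreeing by
more than 0.5 ppm (configurable; the threshold marks clear outliers, not a
statistical test).

## Cavity volume

The two-probe difference method runs on a regular grid (default 0.5 Å,
required ≤ small_probe/2).  The large probe (3.0 Å) defines the molecular
envelope by rolling from the outside: probe positions are clash-free grid
points connected to the box boundary (6-neighbourhood), and everything the
probe cannot sweep is excluded volume.  The small probe (1.3 Å,
water-sized) defines the fine-grained excluded volume with no
connectivity requirement: any pocket the probe fits into counts as
solvent.  The difference of the two isolates enclosed cavities and
channels too narrow for the large probe; connected components are reported
individually and components touching the box boundary are discarded as
solvent.  This pairing — envelope with connectivity, fine volume without —
is what lets a fully enclosed void be recovered: with connectivity on both
probes an airtight cavity would be excluded volume for both and cancel in
the difference.  Van der Waals radii are the Bondi set (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å; unknown elements fall back to 1.70 Å with a
warning); hydrogens are kept when present, since NMR ensembles carry them.
On the analytic hollow-shell fixture the method recovers 4/3·π·r³ within
1% at the default grid; discretisation error under grid refinement and
rigid motion stays below 2–3%.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:
Bloch–McConnell dispersion intensities with Gaussian noise of 3% of the
reference intensity (the error-floor level; the source spectra's true
noise was not published), exponential decays with noise proportional to
the decaying intensity (σ = 0.02·I(t) at the default 2%), linear
shift-temperature series, exact quadratic binding curves, and Fibonacci-
lattice atomic shells (chosen over cubic packings because they stay
leak-free at coarser atom counts), which are verified solvent-tight to a
1.3 Å probe by flood fill before use.  The default kinetic truth is
anchored to the reference system: p_B(298 K) = 8.5% and
k_ex(298 K) = 812 s⁻¹ with ΔH_BA = −37 kJ/mol fix ΔS_BA; the activation
enthalpy is not published, so the default ΔH* = 40 kJ/mol was chosen to
give an identifiable Eyring slope (k_ex varies ~1.7× over 298–308 K), with
ΔS* then fixed by k_AB(298 K).  Per-residue |Δω| are uniform on
0.8–3.5 ppm and R2,0 uniform on 8–20 s⁻¹, typical amide ranges for a
~17 kDa protein.

What the generators do *not* emulate: spectral lineshapes, peak overlap,
exchange broadening to invisibility, temperature-dependent R2,0,
multi-state exchange, anisotropic rotational diffusion, or baseline/phase
artefacts.  Passing recovery tests therefore demonstrates the estimators
are correct and well-conditioned under the stated model, not that real
spectra meet the model's assumptions.

## Numerical choices and edge cases

Degenerate eigenvalues in the closed-form propagator fall back to series
limits (sinh(x)/x → 1) and a Jordan-block branch; non-positive CPMG
intensities are rejected as log-undefined with the offending frequency
named; groups missing the I₀ reference row are reported, never silently
dropped; underdetermined fits (points ≤ parameters) and non-decaying
exponential series are errors, not warnings.  Fit results on identical
inputs with identical seeds are byte-reproducible, and the pipeline report
echoes every effective configuration value.

## Problem sizes used in the checks

The recovery studies run the full reference design (22 residues × 2 fields
× 5 temperatures × 12 frequencies) over 20 Monte-Carlo replicates, the
oracle grid covers 2400 parameter/frequency combinations, relaxation
recoveries use 50 replicates per grid, and the cavity fixtures use a
~2700-atom shell and a 216-atom solid cluster — sizes at which every check
completes in seconds while matching the reference design exactly where one
is stated.
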