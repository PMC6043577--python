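# nmrdyn

Structural-dynamics analysis for proteins undergoing two-state
conformational exchange, built around the kind of dataset collected for
PR-10 food and pollen allergens (Bet v 1-like proteins such as Fag s 1):
¹⁵N CPMG relaxation-dispersion experiments at several magnetic fields and
temperatures, backbone ¹⁵N relaxation, amide-shift temperature series,
ligand-titration chemical shifts, and a solution structure with a large
internal cavity.

## What it computes

**Conformational exchange.** Constant-time CPMG peak intensities are
converted to effective transverse relaxation rates,
R₂,eff = −(1/T_relax) ln(I_CPMG/I₀), with errors floored at 3% of R₂,eff.
Residues whose dispersion amplitude ΔR₂,eff = R₂,eff(ν_low) − R₂,eff(ν_high)
exceeds 5 s⁻¹ are fitted globally with a two-state Bloch–McConnell model
(ground state A ⇄ sparsely populated state B) by minimising

χ²(ζ) = Σ [(R₂,eff^calc(ζ) − R₂,eff^exp)/ΔR₂,eff^exp]²

over all residues, fields and temperatures together, with one
(p_B, k_AB) pair per temperature, one |Δϖ| per residue (ppm, field
independent), and one R₂,₀ per residue and field shared by both states.
R₂,eff^calc comes from numerical propagation of the Bloch–McConnell
equations through the echo train; an independent closed-form solution of
the same problem (the Carver–Richards treatment, including the
finite-train intensity prefactor) serves as a cross-check oracle.

**Thermodynamics.** The fitted equilibrium constants Kₑ = p_B/p_A and
forward rates k_AB are analysed with the Van't Hoff relation
ln Kₑ = ΔS_BA/R − ΔH_BA/(RT) and the Eyring equation
ln(k_AB/T) − ln(κ k_B/h) = ΔS*/R − ΔH*/(RT) (transmission coefficient
κ = 1.6×10⁻⁷ by default), giving the reaction-coordinate diagram of the
ground, transition, and excited states.

**Fast dynamics.** R₁/R₂ from weighted single-exponential fits, the
heteronuclear NOE with the 0.65 flexibility cut, and the overall
rotational correlation time τ_c by inverting the isotropic-rotor R₂/R₁
ratio of rigid residues.

**Shift analyses.** Amide-proton temperature coefficients (H-bonded if the
slope is more positive than −5 ppb/K), combined ¹H/¹⁵N chemical-shift
perturbations (α = 0.14), and per-residue K_D from the quadratic single-site
binding isotherm fitted to ¹⁵N titration shifts.

**Cavity volume.** The internal cavity of the structure by the two-probe
rolling-probe difference on a grid (small probe 1.3 Å, large probe 3.0 Å,
0.5 Å spacing).

Every stage has a seeded synthetic-data generator with known ground truth,
so the entire pipeline is verified by parameter recovery without any
external data.

## Worked example

Simulate the reference design (22 residues, 500/700 MHz, five temperatures
298.0–308.0 K, twelve CPMG frequencies 66.7–1000 Hz, 3% intensity noise),
fit it, and extract the thermodynamics:

```python
from nmrdyn.synthetic import generate_two_state_system, generate_dispersion_intensities
from nmrdyn.dispersion import DispersionDataset, r2eff_from_intensities, select_exchange_residues
from nmrdyn.globalfit import fit_global, FitConfig
from nmrdyn.thermo import fit_thermo

truth = generate_two_state_system(n_residues=22, noise_fraction=0.03, seed=1)
table = generate_dispersion_intensities(truth, seed=1001)
dataset = DispersionDataset(r2eff_from_intensities(table, noise_sd=3.0))
selected, _ = select_exchange_residues(dataset, threshold=5.0)
result = fit_global(dataset.subset(selected), config=FitConfig(n_starts=1, seed=1))

print(f"residues in exchange: {len(selected)} / {dataset.n_r}")
print(f"reduced chi2 = {result.reduced_chi2:.2f}")
print(f"kex(298 K) = {result.params.kex_at(298.0):.0f} s^-1   "
      f"pB(298 K) = {100 * result.params.p_b_at(298.0):.1f} %")

kinetics = [(t, k, k * (1 - p) / p) for t, p, k in result.params.per_temperature]
thermo = fit_thermo(kinetics)
print(f"dH_BA = {thermo.dh_ba / 1e3:.1f} kJ/mol   "
      f"TdS_BA(298 K) = {298 * thermo.ds_ba / 1e3:.1f} kJ/mol   "
      f"dG_BA(298 K) = {thermo.dg_ba(298.0) / 1e3:.1f} kJ/mol")
```

Output:

```
residues in exchange: 22 / 22
reduced chi2 = 1.61
kex(298 K) = 848 s^-1   pB(298 K) = 8.8 %
dH_BA = -32.7 kJ/mol   TdS_BA(298 K) = -38.6 kJ/mol   dG_BA(298 K) = 5.8 kJ/mol
```

The generating truth here has k_ex(298 K) = 812 s⁻¹ and p_B = 8.5%: the fit
recovers the exchange kinetics within a few percent at 3% intensity noise,
and the Van't Hoff/Eyring analysis recovers an enthalpically favourable,
entropically penalised excited state roughly 6 kJ/mol above the ground
state.  The excited-state population corresponds directly to this gap:
ΔG_BA = −RT ln(p_B/p_A) = 5.89 kJ/mol for p_B = 8.5% at 298 K.

The same stages are available from the shell:

```sh
nmrdyn run --seed 1 --out results/        # everything, synthetic inputs
nmrdyn cavity --pdb structure.pdb --out results/
nmrdyn fit-dispersion --peak-table peaks.csv --out results/
```

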