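# titrakit

Quantitative NMR titration analysis for proteins with a slow-exchange
conformational equilibrium — built around the case of serine-65
phosphorylated ubiquitin (pUb), which populates a native-like conformer
(`nat`) and an alternate, β5-slipped conformer (`alt`) that exchange
slowly enough to give two resolved amide cross-peaks per residue.

The package is aimed at protein NMR practitioners who have assigned
¹H–¹⁵N peak lists from pH, temperature or ligand titrations and want the
downstream numbers: conformer populations and their thermodynamics,
per-residue pKa values, binding affinities from a global fit, relaxation
comparisons, and crystal-structure RMSD/contact tables.

## What it computes

**Chemical shift perturbations.** For each residue, the combined amide
CSP between two states is

    Δδ = sqrt(Δδ_H² + (Δδ_N / 5)²)

**Conformer populations.** With matched transverse relaxation in the two
signal sets, peak intensities measure populations directly:
`f_alt = I_alt / (I_nat + I_alt)`.

**van't Hoff thermodynamics.** Over a temperature series,
`ln(I_alt/I_nat) = −ΔH/(RT) + ΔS/R`; a linear regression on 1/T gives
ΔH, ΔS and ΔG(T) with uncertainties propagated through the full
(ΔH, ΔS) covariance.

**Acid–base pKa fits.** Against pH, both the conformer population and
each residue's normalized CSP follow
`offset + amplitude · 10^(pH−pKa) / (1 + 10^(pH−pKa))` — the
Henderson–Hasselbalch population of the deprotonated phosphate.

**Ligand binding.** Fast-exchange titration CSPs follow the exact
single-site isotherm

    Δδ = Δδ_max · {[P]t + [L]t + Kd − sqrt(([P]t+[L]t+Kd)² − 4[P]t[L]t)} / (2[P]t)

fit globally across residues with one shared Kd and per-residue Δδ_max;
interface residues that attenuate by >75% (intermediate exchange) are
detected and excluded automatically.

**Relaxation and oligomerization.** ¹⁵N R1/R2 rates of the two signal
groups are compared with 10%-trimmed means and seeded bootstrap CIs;
dimerization would scale R2 by ~1.6 and R1 by ~1/1.6, and the verdict
(`monomer-like` / `dimer-like` / `inconclusive`) tests exactly that.

**Structure comparison.** PDB models are superposed with the Kabsch
algorithm over pairwise-matched backbone selections (with or without the
flexible C-terminal tail residues 74–76), and polar-contact distances
(e.g. Q62 amide nitrogen to the nearest residue-65 side-chain oxygen)
are tabulated.

A seeded synthetic-data generator (`titrakit.synthetic`) produces peak
lists and rate tables with all of this structure plus realistic noise,
so every stage is testable without external data.

## Worked example

```python
import titrakit as tk

truth = tk.GroundTruth(seed=1)            # pUb-like study conditions

# temperature series -> conformer thermodynamics
series = tk.gen_temperature_series(truth)
vh = tk.vant_hoff_fit(tk.fraction_alt_series(series))
print(f"dH = {vh.delta_H/1e3:.1f} kJ/mol, dS = {vh.delta_S:.1f} J/(mol K), "
      f"dG(25C) = {vh.delta_G(298.15)/1e3:.2f} kJ/mol")

# pH series -> phosphate pKa from conformer populations
ph = tk.gen_ph_series(truth)
fit = tk.ph_population_fit(tk.fraction_alt_series(ph))
print(f"pKa = {fit.pKa:.2f} (per-residue spread {fit.pka_spread})")

# ligand titration -> global Kd
binding = tk.gen_binding_series(truth)
points, attenuated = tk.binding_points_from_series(binding)
kd = tk.global_kd_fit(points)
print(f"Kd = {kd.kd*1e6:.1f} uM, attenuated residues: {attenuated}")
```

prints (seed 1):

```
dH = 21.7 kJ/mol, dS = 61.4 J/(mol K), dG(25C) = 3.36 kJ/mol
pKa = 7.07 (per-residue spread (6.905981472429061, 7.33384395731653))
Kd = 4.8 uM, attenuated residues: [8, 44, 46, 48, 49, 68]
```

The generating truth was ΔH = 22.0 kJ/mol, ΔS = 62.5 J/(mol·K), a
population pKa of 7.08, Kd = 4.9 µM, and the six hydrophobic-patch
interface residues planted as attenuating — the fits recover them within
the noise.

The same analyses are available from the shell: `titrakit simulate`,
`titrakit vanthoff`, `titrakit pka`, `titrakit kdfit`, `titrakit relax`,
`titrakit csp`, `titrakit rmsd`.

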