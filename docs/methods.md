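# Models and methods

This note records the models titrakit implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## The physical picture

A protein carrying a titratable modification (here: a phosphate on
serine-65 of ubiquitin) exchanges between two conformers slowly on the
chemical-shift timescale, so each backbone amide shows two resolved
¹H–¹⁵N cross-peaks, `nat` and `alt`. Because the two signal sets relax
comparably, peak intensities are proportional to conformer populations.
Superimposed on the slow conformer exchange, protonation equilibria and
ligand binding are fast on the shift timescale, so those processes move
peaks rather than splitting them.

## Chemical shift perturbations

`Δδ = sqrt(Δδ_H² + (Δδ_N/5)²)`. The ¹⁵N weighting of 1/5 is the common
field convention for amides; it is exposed as `scale_N` because other
weightings (e.g. 1/6.5, gyromagnetic-ratio-based) are in use. CSPs
between conformers are computed only where both labels exist for a
residue; unmatched keys are returned explicitly, never dropped.

## Conformer populations and thermodynamics

`f_alt = I_alt/(I_nat + I_alt)` per residue, aggregated as mean ± sd
across residues. The temperature dependence of `ln(I_alt/I_nat)` is fit
by ordinary least squares on 1/T (slope −ΔH/R, intercept ΔS/R,
R = 8.314 J mol⁻¹ K⁻¹). ΔG(T) = ΔH − TΔS. The standard error of ΔG uses
the full regression covariance of (ΔH, ΔS): the two estimates from one
line are almost perfectly correlated, and ignoring the cross term
overestimates the ΔG error by roughly an order of magnitude. Intensity
ratios must be strictly positive; a nonpositive ratio is an error naming
the offending point rather than a silent drop.

## Acid–base (pKa) fits

Populations and normalized CSPs against pH are fit to

    value(pH) = offset + amplitude · θ(pH),
    θ = 10^(pH−pKa) / (1 + 10^(pH−pKa))

the Henderson–Hasselbalch population of the deprotonated species. The
saturating θ is the default because titration data plateau at both ends
of the pH range; the unbounded form `θ = 10^(pH−pKa)` is retained behind
`mode="literal"` for comparison with analyses that used it. In the
literal form only the product `amplitude·10^(−pKa)` is identifiable, so
the implementation holds the amplitude at its data-range estimate and
fits offset and pKa.

Fitting is trust-region nonlinear least squares (lmfit). Initialization:
pKa at the midpoint of the steepest data increment, offset at the data
minimum, amplitude at the data range; pKa bounded to the sampled pH
range ± 1. A flat curve (range below `min_amplitude`) is rejected with a
warning instead of returning a meaningless pKa; a fitted pKa outside the
sampled range triggers a warning. Normalized CSPs are measured against
the low-pH baseline point and divided by the value at the high-pH
reference, so the curve is exactly 0 at baseline and 1 at reference.

Both analysis paths the headline pKa could come from are provided: a fit
to the residue-averaged curve (the default headline number) and
individual per-residue fits, whose values and spread are reported
alongside.

## Peak tracking and residue selection

Trajectories across a titration are built point-to-point. For assigned
peak lists (the normal case) linking is by the (residue, site,
conformer) key, with the combined-shift metric used to *validate* each
link: a jump larger than `max_jump` breaks the trajectory. Pure
nearest-neighbour linking (`by_assignment=False`) is available for
effectively unassigned data; it refuses links beyond `max_jump` and
flags, rather than guesses, links whose two nearest candidates are
within 10% of each other's distance. Nearest-neighbour tracking cannot
distinguish crossing peaks — in a realistic spectrum with ~150 peaks and
per-step movements of ~0.1 ppm, mislinks are guaranteed — which is why
assignment-based linking is the default.

Residues are excluded from population/pKa analysis when (1) any of
their peaks lies within an elliptical overlap radius (default 0.03 ppm
¹H / 0.15 ppm ¹⁵N, typical linewidths) of another peak at any titration
point, (2) their trajectory is broken by signal loss or ambiguous
migration, or (3) where required, they lack an alternate-conformer
signal. The exclusion report states which rule removed each residue,
and the filter is idempotent.

## Single-site binding

The observed fast-exchange CSP follows the exact quadratic mass-balance
isotherm (see README). It is evaluated in the numerically stable root
form `[PL] = 2[P]t[L]t / (S + sqrt(S² − 4[P]t[L]t))` to avoid
catastrophic cancellation when binding is weak. The global fit shares
one Kd across all residues with a per-residue Δδ_max, minimizing the
summed squared residuals over every (residue, point) pair; standard
errors come from the Jacobian at the optimum. Kd is bounded positive and
initialized at the median protein concentration.

Residues in intermediate/slow exchange do not trace the fast-exchange
isotherm; they are detected by intensity attenuation (endpoint below
25% of the start, i.e. >75% attenuation, configurable) and excluded
from the CSP fit by default. Per-point protein and ligand totals live in
the condition metadata, so dilution across the titration is handled by
construction.

## Relaxation comparison and the oligomerization rule

R1 and R2 of the two signal groups are compared as ratios of
10%-trimmed means over paired residues, with 95% percentile bootstrap
CIs (2000 seeded resamples, bit-for-bit reproducible). Robust statistics
are used because the flexible C-terminal tail residues are outliers in
any ubiquitin relaxation profile. Residues flagged by the exchange
detector (R2 above median + z·1.4826·MAD, default z = 3) are excluded
from the group comparison by default: exchange contributions to R2
report chemistry, not rotational diffusion, and bias even trimmed means
by displacing trim slots.

Dimerization is expected to scale R2 by ~1.6 and R1 by ~1/1.6. The
verdict compares the bootstrap CIs against the unity and 1.6-fold
hypothesis points, each carrying a 5% relative equivalence band: a CI
"supports" a hypothesis when it overlaps the band and "excludes" it
otherwise, and a verdict requires supporting one hypothesis and
excluding the other on both rates. The band matters: a strict
"CI-contains-the-point" rule would misclassify ~5% of genuinely
monomeric datasets per CI by construction, while rate agreement within a
few percent is negligible next to the ~60% dimerization effect.

## Structure comparison

PDB/mmCIF parsing is via gemmi. Alternate locations resolve to the
highest-occupancy conformer (ties to altloc A); waters and heteroatoms
are kept in the model but excluded from protein selections. Backbone
selections default to N, CA, C, O (N-CA-C is available; the difference
is a few hundredths of an Å in the RMSDs). "Tail excluded" means
residues 1–73, dropping the flexible R74–G76. Superposition is the
closed-form Kabsch algorithm with the SVD determinant corrected so the
result is always a proper rotation, applied to selections matched
pairwise-complete by (residue number, atom name); the RMSD is evaluated
on the same matched set used for the superposition. Fewer than 50%
matched pairs is an error (mis-specified chains or numbering). Contact
tables report Euclidean donor–acceptor distances with a 3.5 Å
hydrogen-bond plausibility flag. B-factors and occupancy weighting are
ignored.

## The synthetic-data generator

The generator is the package's source of test data and encodes the
study conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| population pKa / offset / scale | 7.08 / 0.10 / 0.45 | acid–base conformer model: f_alt ~0.10 at low pH, ~0.55 at high |
| ΔH, ΔS | 22.0 kJ/mol, 62.5 J/(mol·K) | Boltzmann temperature model of the conformer ratio |
| pH grid | 4.6–7.6 in 7 steps | titration span |
| temperature grid | 291–306 K in 6 steps | temperature series |
| per-residue pKa | uniform 6.8–7.4 | fast-exchange shift titration |
| limiting CSP | uniform 0.05–0.7 ppm | per-residue titration amplitude |
| alt damping | 0.3 | alt peaks move 30% of the nat shift with pH |
| Kd / [P]t | 4.9 µM / 50 µM | single-site binding model |
| Δδ_max | uniform 0.05–0.40 ppm | per-residue binding amplitude |
| attenuating set | {8, 44, 46, 48, 49, 68} | hydrophobic-patch interface residues, intensity → <25% at saturation |
| R1, R2 baselines | 1.4, 11.5 s⁻¹ | monomeric ubiquitin-like rates at 600 MHz |
| exchange elevations | +6 s⁻¹ at {3, 63, 73} | planted µs–ms exchange in the alt conformer |
| noise | σ_H 0.003 ppm, σ_N 0.02 ppm, 5% intensity CV | SOFAST-HMQC-like repeatability |

Randomness is split into a *layout* stream (fixed `layout_seed`: peak
positions, per-residue parameters) and a *noise* stream keyed by the run
seed, so different seeds share an identical noise-free core and every
series is bit-for-bit reproducible. Peak positions are placed by
rejection sampling so that no two signals approach within about twice
the overlap radius at any default-grid pH point: the default spectra are
well resolved by construction, and overlapping, lost or alt-less
residues are *planted* through explicit knobs rather than arising by
accident — giving residue-selection tests exact ground truth.

Titration trajectories are linear (fixed direction per residue on the
(Δδ_H, Δδ_N/5) unit circle), matching the observed proportional
movement of ¹H and ¹⁵N resonances. Ligand binding depletes the alt
conformer in proportion to the bound fraction, modelling a
binding-competent nat conformer only.

What the generator does **not** emulate: lineshapes and exchange
broadening (attenuation is imposed on intensities, not derived from
exchange rates), peak overlap in the spectral sense (only co-location of
peak centres), temperature-dependent shift changes, scalar couplings,
and assignment errors. Passing tests therefore demonstrate correctness
of the *quantitative analysis chain* given assigned peak lists, not
robustness to spectral-processing artifacts.

## Problem sizes

The parameter-recovery checks use 100-seed Monte-Carlo ensembles: 27
residues × 7 pH points for the pKa design, 10 residues × 8 titration
points for each Kd design (Gaussian CSP noise σ = 0.005 ppm), the full
72-residue generator for the temperature and relaxation designs, and
20 random 5-point instances for the superposition oracle comparison.
These sizes mirror the emulated experiments while keeping the whole
suite fast on a single CPU.

## Known limitations

* Multi-site (two-pKa) titrations and cooperative or two-site binding
  models are out of scope; curved low-pH behaviour of residues near the
  modification site will bias a single-pKa fit.
* Rate *fitting* from raw relaxation decays is not included; the
  relaxation module consumes rate tables.
* The literal acid–base mode is retained for fidelity only; its
  parameters are degenerate (see above) and its pKa should not be
  interpreted.
* Attenuation classification uses the first and last titration points
  only; a residue that attenuates transiently mid-titration would be
  missed.
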