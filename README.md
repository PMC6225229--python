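# ramapop

Ramachandran basin population analysis of peptide conformational ensembles.

`ramapop` is for structural biophysicists who want to quantify how much
polyproline II (PII) — or any other local backbone geometry — an unfolded
peptide ensemble contains, and what that implies thermodynamically and for
small-angle scattering observables. It was built around two model systems:
the 11-residue XAO peptide X₂A₇O₂ (X = 2,4-diaminobutyric acid,
O = ornithine; acetyl/amide caps) and the 9-mer
Arg-Pro-Pro-Gly-Phe-Ser-Ala-Phe-Lys with free charged termini.

The package provides:

- **Peptide construction** from backbone torsions by NeRF-style
  internal-coordinate chain extension (each atom placed from a bond length,
  bond angle and torsion relative to three previously placed atoms), with
  all-trans side chains and standard backbone geometry.
- **Six-basin classification** of (Φ, Ψ) pairs — PII, β, αR, 3₁₀, C7eq on
  the Φ < 0 half-plane, αL on the right — with the PII/β boundary at
  Ψ = 135° by default and a sensitivity scan that moves it (e.g. to 115°).
- **Boltzmann inversion** of basin populations into relative free energies,
  F_b = −k_B T ln(N_b/N_ref), with the most populated basin as reference
  (k_B = 0.0019872 kcal mol⁻¹ K⁻¹, T = 300 K by default).
- **Geometric observables**: end-to-end distance (backbone N of residue 1
  to carbonyl C of the last residue) and weighted radius of gyration.
- **Vacuum Debye scattering** I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) with
  electron-count form factors (q = 2πs), ensemble averaging over 100
  randomly drawn frames, and **Guinier analysis**
  I(s) = I(0)·exp(−⅓(2πs·R_gyr)²) restricted to the 2πs·R_gyr < 1 regime.
- A **synthetic ensemble generator** that draws per-residue basin labels
  from a categorical distribution with prescribed weights and samples
  torsions inside each basin's box — a controllable stand-in for MD
  trajectories with known ground-truth populations.

## Worked example

Run the packaged demo — an 18,148-frame synthetic XAO ensemble (11 dihedral
pairs per frame → 199,628 data points) generated with the aqueous-solution
basin populations as weights, then analysed end to end:

```sh
ramapop run -o out        # uses the packaged demo config and seed
```

`out/populations.tsv` (basin, Φ-range, Ψ-range, relative population, free
energy in kcal/mol):

```
basin     phi_range          psi_range            relative_population  free_energy_kcal_mol
PII       -180 <= phi < 0    135 <= psi <= 180    0.533                0.00
beta      -180 <= phi < 0    50 <= psi < 135      0.202                0.58
alphaR    -180 <= phi < 0    -180 <= psi < -25    0.127                0.86
three10   -180 <= phi < 0    -25 <= psi < 0       0.061                1.29
C7eq      -180 <= phi < 0    0 <= psi < 50        0.035                1.62
alphaL    0 <= phi < 180     -180 <= psi <= 180   0.042                1.52
```

The recovered populations match the generator weights (0.534, 0.202, 0.126,
0.062, 0.035, 0.041) to within binomial sampling error, and the Boltzmann
inversion turns them into the expected sub-2 kcal/mol free-energy ladder:
a 0.202 β population against a 0.534 PII reference gives
−k_B·300·ln(0.202/0.534) = 0.58 kcal/mol. The sensitivity table at
Ψ-cutoff 115° shows PII growing to 0.581 at β's expense while their union
is conserved exactly.

The same run reports per-frame observables and the scattering analysis:

```
end_to_end_mean_A   20.52     # mean over 18,148 frames
rgyr_mean_A          8.60
first_half_mean_A    8.608    # split-half convergence of rgyr
second_half_mean_A   8.591
rgyr_A               8.6607   # Guinier fit of the 100-frame Debye profile
r_squared            0.99967
```

The Guinier-effective radius (8.66 Å) sits close to the ensemble-mean
geometric R_gyr (8.60 Å), as it should for a vacuum Debye profile fitted in
its validity window. For single ideal geometries the library gives the
classic reference values: XAO built entirely at the canonical PII torsions
(Φ = −75°, Ψ = +145°) has an end-to-end distance of 33.1 Å and
R_gyr = 11.3 Å; the fully extended chain (Φ = Ψ = 180°) has R_gyr = 13.3 Å.

As a library:

```python
from ramapop import (xao_spec, build_conformation, extract_phi_psi,
                     classify_pair, tally_populations, radius_of_gyration)

conf = build_conformation(xao_spec(), (-75.0, 145.0))   # canonical PII
pairs = extract_phi_psi(conf)                           # 11 (phi, psi) records
labels = [classify_pair(r.phi, r.psi) for r in pairs]   # all 'PII'
table = tally_populations(labels, temperature=300.0)
print(radius_of_gyration(conf))                         # 11.31 Å
```

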