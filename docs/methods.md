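# Methods

This note records the models, conventions and numerical choices behind
`ramapop`, and what its synthetic ensembles can and cannot say about real
peptide data.

## Peptide construction

Conformations are built by sequential internal-coordinate placement
(NeRF-style): each atom is positioned from a bond length, a bond angle and
a torsion relative to three already-placed atoms. Backbone geometry uses
canonical single-conformation values — N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å; angles N–Cα–C 111.0°, Cα–C–N 116.6°,
C–N–Cα 121.7°, N–C=O 122.9°; ω = 180° unless overridden. A built chain
therefore reproduces its requested (Φ, Ψ, ω) exactly (round-trip error
< 1e-6°, in practice ~1e-13°) and every bonded distance equals its template
value.

Side chains are placed as fixed all-trans rotamers with tetrahedral
(111°) angles: X (2,4-diaminobutyric acid) Cβ–Cγ–Nδ, O (ornithine)
Cβ–Cγ–Cδ–Nε, plus standard heavy-atom topologies for the 9-mer residues
(Arg guanidinium planar; Phe ring planar at χ₂ = 90°). Cβ chirality is
fixed by the improper torsion N–C–Cα–Cβ = −120°, measured on ideal
L-residue reference geometry. The proline ring is laid out from
ideal-residue torsions (χ₁ ≈ 24°) without closure refinement — the Cδ–N
closure is approximate by design. Hydrogens are never built; all analyses
are heavy-atom analyses.

Terminal chemistry: the XAO peptide carries acetyl (CH₃–CO–) and amide
(–NH₂) caps, so the flanking cap C and N make all 11 (Φ, Ψ) pairs
well-defined. The 9-mer has free charged termini (N₃H⁺ implicit on N,
carboxylate O/OXT on the C-terminus); strictly per-residue pairing then
yields 7 pairs (residues 2–8). An "adjacent" pairing mode that combines
Ψᵢ with Φᵢ₊₁ yields 8 pairs and is available because trajectory-analysis
bookkeeping conventions differ on this point; "strict" is the default.

The end-to-end distance is anchored at the backbone N of residue 1 and the
backbone carbonyl C of the last residue, caps excluded — with this choice
an ideal PII XAO chain spans ≈ 33 Å, matching the ~32 Å textbook estimate
for an 11-residue PII helix (3.1 Å rise per residue). The radius of
gyration defaults to mass weighting over heavy atoms with caps included;
electron-count and uniform weightings are available (the scattering module
uses electron weighting internally).

## Basin classification and thermodynamics

Torsions are canonicalised to (−180°, 180°], with Φ = +180° identified
with −180° and assigned to the left half-plane so the partition is total.
The six boxes are:

| basin | Φ | Ψ |
|---|---|---|
| PII | −180 ≤ Φ < 0 | 135 ≤ Ψ ≤ 180 |
| β | −180 ≤ Φ < 0 | 50 ≤ Ψ < 135 |
| αR | −180 ≤ Φ < 0 | −180 ≤ Ψ < −25 |
| 3₁₀ | −180 ≤ Φ < 0 | −25 ≤ Ψ < 0 |
| C7eq | −180 ≤ Φ < 0 | 0 ≤ Ψ < 50 |
| αL | 0 ≤ Φ ≤ 180 | any Ψ |

Totality and uniqueness are grid-verified at 1° resolution in the test
suite. Two quirks of the conventional basin table are worth noting: the
ideal 3₁₀ conformer (−60°, −30°) falls inside the αR box, and the ideal
C7eq conformer (−120°, 50°) sits on the β floor; classification follows
the boxes, not the ideal points. Each residue is classified discretely,
with no run-length or hydrogen-bond (DSSP-style) smoothing — a deliberate
non-goal.

Populations convert to free energies by Boltzmann inversion,
F_b = −k_B T ln(N_b/N_ref), k_B = 0.0019872 kcal mol⁻¹ K⁻¹, default
T = 300 K. The reference is the most populated basin (ties break by the
partition order above), so F_ref = 0 and all other values are ≥ 0. Empty
basins are reported as "n/a", not infinity. The inversion is scale
invariant: counts and fractions give identical results to 1e-12.

The Ψ-cutoff sensitivity scan moves only the PII/β boundary (default 135°,
e.g. to 115°); it conserves the PII ∪ β count exactly and cannot touch the
other four basins. Cutoffs at or below 50° would invert the β box and are
rejected. Split-half convergence compares first- and second-half summaries
(means for numeric series, per-basin fractions for label series); odd
lengths put the middle frame in the first half.

## Synthetic ensembles

The generator emulates the *statistics* a long MD trajectory feeds into
this analysis — per-frame, per-residue (Φ, Ψ) pairs with a prescribed
basin-population structure — not the trajectory itself. Per frame and per
residue, a basin label is drawn i.i.d. from a categorical distribution
with configurable weights; a (Φ, Ψ) pair is then drawn inside that basin's
box and the frame is built in Cartesian space. Defaults follow the study
conditions: 18,148 frames for XAO (11 pairs per frame → 199,628 data
points) and 2,000 frames for the 9-mer, with the aqueous-solution
populations (0.534, 0.202, 0.126, 0.062, 0.041, 0.035) as the demo
weights.

Within-basin sampling is uniform over the box by default: because two of
the ideal conformer points are not interior to their boxes (see above),
box-uniform is the only convention that is always well defined. A von
Mises jitter mode concentrates samples around the ideal conformer center
(box midpoint where the ideal point is exterior) with rejection until
inside the box, so emitted labels always re-classify correctly — an exact
invariant of the generator, verified per frame. Proline Φ is restricted to
[−110°, −50°] intersected with the basin box (crude ring-constraint
realism); no steric-clash filtering is applied, since it would distort the
prescribed weights. Frames are independent by default; a first-order
label-persistence knob exists but defaults off.

What passing tests therefore show: the analysis pipeline recovers known
ground-truth populations within binomial sampling error at the study's
data volume, and all bookkeeping (classification, inversion, cutoff moves,
convergence splits) is exact. What they do not show: anything about force
fields, solvent, kinetics, or whether real XAO ensembles have these
populations — synthetic frames have no autocorrelation, no steric
exclusion and no correlated neighbouring residues. MD-derived ensemble
averages (e.g. mean end-to-end distance or R_gyr of a real trajectory) are
consequently outside what this package can reproduce.

## Scattering and Guinier analysis

Scattering uses the exact Debye orientational average with q = 2πs and
electron counts as q-independent form factors, in vacuum: no hydration
layer, no excluded-volume term, and hydrogens neither built nor folded
into heavy atoms. This is a deliberately simple model — effective radii
from experimental SAXS or hydration-aware calculators (which add a dense
water shell) will differ systematically from it. The ensemble protocol
averages the profiles of 100 frames drawn uniformly at random (seeded)
and fits once.

The Guinier fit is a least-squares line through (s², ln I), giving
R_gyr = √(−3·slope)/(2π) and I(0) = exp(intercept). The fit window starts
at the full grid (default 0.001–0.05 Å⁻¹, 100 points) and is restricted
iteratively to 2πs·R_gyr < 1 until the included point set is stable (≤ 20
iterations); non-decaying profiles and windows with fewer than 3 points
raise errors rather than returning garbage. Exact Guinier-law profiles are
inverted to 1e-9 relative error; Debye profiles of compact structures
recover the electron-weighted geometric R_gyr to 2% when fitted within
2πs·R_gyr < 0.5.

## Pipeline and reproducibility

One YAML config drives synthesis → dihedral extraction → classification →
populations/free energies → Ψ-cutoff sensitivity → observables →
split-half convergence → Debye/Guinier. All randomness derives from the
config seed (the scattering subsample uses seed+1), so a rerun produces
byte-identical report tables; the log carries timestamps, config hash and
per-stage timings, including the pairs × frames bookkeeping line. Problem
sizes in the shipped demo (18,148 frames, 100 scattering structures,
100-point s-grid) run in a few seconds on one CPU; the test suite uses
smaller ensembles where the property under test does not need the full
data volume.

## Known limitations

- Single fixed backbone geometry: no bond/angle variance, so built
  ensembles underestimate real geometric diversity at fixed torsions.
- Proline ring closure is approximate; Phe/Arg side-chain torsions are
  fixed, not sampled.
- Free N-terminal Φ and C-terminal Ψ (uncapped chains) are accepted as
  input but the Φ of residue 1 has no Cartesian realisation; the terminal
  Ψ only orients the carboxylate.
- The vacuum Debye model intentionally omits hydration effects; its
  effective R_gyr should only be compared against other vacuum
  calculations.
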