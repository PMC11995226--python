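# Methods

`chamscope` analyzes conformational ensembles of large, flexible,
beyond-rule-of-5 molecules — degraders (PROTACs) being the motivating case —
to ask whether a molecule behaves as a *molecular chameleon*: compact and
polarity-shielding in an apolar, membrane-like environment while exposing
polarity in water, or *congruent*: populating the same property space in
both environments. This note records the models, defaults, and design
choices, and what the synthetic benchmark does and does not demonstrate.

## Descriptors

**Radius of gyration.** `R_gyr = sqrt(Σ wᵢ|rᵢ − r̄|²/Σ wᵢ)` with weights
`wᵢ` equal to atomic masses by default (`geometric` and `heavy_only`
variants available). Mass weighting over all atoms including hydrogens is
the molecular-dynamics community convention; whether published ensemble
analyses weight by mass is usually unstated, and the difference is small for
C/N/O-dominated molecules. Invariant under rigid motion by construction.

**Solvent-accessible surface area.** Shrake–Rupley test-point quadrature:
each atom's sphere is expanded by the probe radius (default 1.4 Å, a water
molecule) and covered with a deterministic golden-angle Fibonacci lattice
(default 960 points); a test point is accessible if outside every other
expanded sphere. Per-atom area = `4π(rᵢ+p)² × accessible fraction`. The
Fibonacci lattice was chosen over the classical icosahedral subdivision
because it is defined for any point count and trivially reproducible. Van
der Waals radii are Bondi (1964); elements outside the table raise rather
than defaulting. Quadrature error at 960 points is well under 0.5% for an
isolated atom and ~1% per atom in clusters (validated against the
closed-form two-sphere solution and a 10⁶-sample Monte Carlo
surface-rejection oracle in the test suite).

**Polar/nonpolar partition (SA 3D PSA / SA 3D NPSA).** An element-based
scheme marks N, O and hydrogens bonded to them as polar (sulfur optional,
off by default). SA 3D PSA is the summed area of polar atoms, SA 3D NPSA
the remainder; the two add to the total exactly. Published SA 3D PSA values
are tool-dependent — different programs use different radii and polar-atom
schemes and disagree systematically — so absolute areas from any one tool
should not be compared against another's; this package records its scheme
in every output sidecar for exactly that reason.

**Intramolecular hydrogen bonds.** Geometric criteria: donors are H bonded
to N/O; acceptors N/O; a bond is counted when H···A ≤ 2.5 Å and the
D–H···A angle ≥ 120°, excluding pairs fewer than 3 bonds apart. These are
standard geometric cutoffs; no energetic model is implied.

**Fold classes.** `folded` (R_gyr ≤ 7.0 Å), `semifolded`, `extended`
(R_gyr ≥ 9.5 Å), with boundary ties resolving to the more compact class.
The defaults suit degrader-sized molecules, whose folded ensembles center
near 5–7 Å, semifolded near 8 Å and extended near 11 Å; the bands scale
with molecular size and are fully configurable.

**ETR.** The ratio of experimental (chromatographic) to topological polar
surface area, EPSA/TPSA. Both are scalar inputs; the package does not
predict either.

## Ensemble analysis

Conformers are clustered by a deterministic leader algorithm on heavy-atom
Kabsch RMSD (default cutoff 1.0 Å): visited in ascending energy order, a
conformer joins the first cluster whose representative is within the
cutoff, else founds a new cluster. Representatives are therefore local
energy minima and pairwise separated by more than the cutoff. Leader
clustering was chosen over hierarchical/density methods because it is
order-deterministic, O(nk), and its invariants are directly testable.

Boltzmann weights use `pᵢ ∝ exp(−Eᵢ/RT)` with R = 1.987204×10⁻³ kcal/(mol·K)
and T = 300 K by default, computed with the min-energy shift for stability.
Cluster population is the summed weight of members; clusters above a 1%
population threshold (strict inequality) are reported, and the MEC is the
representative of the most-populated cluster (ties → lower representative
energy, then lower index).

**Property landscapes and congruence.** The landscape is a normalized 2D
histogram over (R_gyr, SA 3D PSA). For ensembles produced by Metropolis or
MD sampling, the sample *is* the Boltzmann ensemble, so the pipeline
weights landscape cells by sampling frequency (uniform per conformer);
re-weighting such samples by conformer energies would double-count the
Boltzmann factor. A `landscape_weighting: population` option exists for
enumerated conformer pools that are not themselves Boltzmann-distributed.

Two ensembles of the same molecule in different solvents are compared by
(a) the population-weighted centroid shift Δ of R_gyr and SA 3D PSA
(apolar minus polar) and (b) the histogram overlap Σ min(d_A, d_B) on a
common grid. The pair is *congruent* when |ΔR_gyr| ≤ 1.0 Å and overlap ≥
0.25 on a 12×12 grid. These thresholds are calibrated on the synthetic
generator (seeds 0–19) such that the PEG-linker mimic is judged congruent
and the alkyl-linker mimic is not; they are qualitative dials, not
universal constants. The grid is deliberately coarse: with a few hundred
conformers per ensemble, finer grids (e.g. 40×40) drive the overlap of even
identically distributed samples toward zero and the statistic loses
meaning.

## NAMFIS-style NOE deconvolution

Given a pool of n candidate conformers and m experimental interproton
distances, the fitted populations w minimize

    Σⱼ λⱼ (d_exp,ⱼ − (Σᵢ wᵢ d_ij^-6)^(-1/6))²,   w on the probability simplex,

with λⱼ = 1/toleranceⱼ² (uniform optionally). The r⁻⁶ power mean is the
rigid-molecule NOE limit; r⁻³ is available for motion-averaged regimes.
Equivalent-proton groups (e.g. methyls) are r⁻⁶-averaged within each
conformer when building the distance matrix.

Optimization: multi-start local search through a softmax reparameterization
with analytic gradients (L-BFGS-B), with deterministic starts — uniform, a
non-negative least-squares solution of the r⁻⁶-linearized problem, the two
best single-conformer vertices — plus seeded Dirichlet draws, followed by
an SLSQP polish directly on the simplex (softmax cannot reach exact zeros).
Populations below a 0.5% reporting floor are zeroed and the fit repeated on
the surviving support; the floored refit is kept only if it does not
degrade the objective, so the reported SSD is always the minimum over
starts. Identical seeds give identical results.

**Identifiability.** With m restraints and k nonzero true populations,
unique recovery requires roughly m ≥ 2k and a pool whose distance columns
are distinct. Two situations defeat it honestly: (i) underdetermined
instances where an alternative exact nonnegative solution exists — the fit
reaches SSD ≈ 0 but a different split; (ii) near-duplicate pool conformers
(e.g. consecutive, insufficiently thinned Metropolis samples), between which
population mass can shift freely. The package warns when all pool columns
are identical; users should decorrelate sampled pools (generous thinning)
before deconvolution. Stability is probed by a leave-one-restraint-out
jackknife reporting per-conformer population ranges.

## Synthetic degrader mimics

The generator builds a toy topology with the architecture that matters for
the chameleonicity question: two rigid ligand bodies (16 heavy atoms each,
two polar atoms at seed-dependent positions, tagged NOE protons) joined by
a flexible 12-atom linker — all-carbon ("alkyl") or with every third atom
an ether-like oxygen ("peg"). An alkyl/PEG pair with the same seed differs
only in the linker elements. Bodies are deterministic compact blobs grown
along a fixed quasi-random direction sequence; conformers are assembled
from linker dihedrals by natural-extension-reference-frame geometry
(bond 1.54 Å, angle 112°), with the second body placed by two extra
dihedrals and a spin angle.

The pseudo-energy is deliberately physics-light — no electrostatics, no
force field — because its only job is to produce ensembles with the
statistical structure the analysis assumes:

    E = E_clash + w_h·(nonpolar linker-contact burial) + w_p·(polar linker burial)

where burial scores count cross-region contacts (< 4.5 Å) involving linker
atoms, normalized per linker atom, and E_clash is a soft-sphere repulsion.
Only linker-involving contacts are scored: ligand–ligand attraction is
identical for both linker types and would mask the contrast. The water
profile (w_h = +2.5, w_p = +2.0 kcal/mol per contact unit) rewards burying
nonpolar linker surface (hydrophobic effect) and penalizes burying polar
atoms. The chloroform profile (w_h = −1.0, w_p = −1.5) *penalizes* burying
nonpolar surface — chloroform solvates aliphatic linkers favorably, which
is precisely what drives the extension of alkyl-linked chameleons in
apolar media — and mildly rewards polar burial (internal hydrogen bonding
is cheap in apolar solvents). Conformers are sampled by single-dihedral
Metropolis moves at 300 K (600 burn-in moves, every 15th move recorded);
all randomness flows through one seeded generator.

Under these defaults the alkyl mimic collapses in water and extends in
chloroform (ΔR_gyr ≈ +1.4–2.6 Å across seeds) while the PEG mimic stays
congruent (|ΔR_gyr| ≲ 1 Å, overlap 0.28–0.53). On the documented seed set
0–19 the alkyl mimic is classified non-congruent in 19/20 seeds (seed 9
collapses only weakly, ΔR_gyr = 0.85 Å) and the PEG mimic congruent in
20/20 — the ≥95% end-to-end bar, with the single failure documented rather
than tuned away.

Synthetic NOEs are generated from a chosen ground-truth mixture by exact
r⁻⁶ population averaging over all tagged proton pairs, discarding pairs
averaging beyond a 5 Å observability ceiling (the practical NOE detection
limit), optionally adding Gaussian noise; inter-ligand pairs are labeled
long-range. Folded-dominated mixtures produce observable long-range NOEs;
extended-only mixtures do not — the geometric signature NMR readers expect.

**What the mimics do not show.** They are not real PROTACs: no real
chemistry, no electrostatics or explicit solvent, body geometries are
abstract blobs, and absolute descriptor values (Å², Å) are not comparable
to published values for real molecules. Passing the end-to-end contrast
demonstrates that the *analysis chain* detects solvent-dependent collapse
vs congruence when it is present by construction — not that any particular
real molecule behaves this way.

## Problem sizes and numerical choices

Tests and the acceptance script use ensembles of 100–120 conformers per
solvent, 8–20 generator seeds, SASA at 960 lattice points, NAMFIS pools of
5–30 conformers with up to ~16 restraints, chosen to exercise every code
path at full fidelity while keeping the whole suite in the tens of
minutes on a single CPU. Convergence/tie-break details: optimizer objective
tolerance 1e-12 (softmax stage) and 1e-14 (SLSQP); cluster tie-breaks by
energy then index; fold-class boundary ties toward the compact class;
histogram bins right-open with the last bin closed; degenerate
single-point landscapes fall back to numpy's unit-width bin expansion.

## Known limitations

- The leader clustering depends on the energy ordering; pools without
  energies fall back to input order, which is deterministic but arbitrary.
- The congruence verdict is threshold-based and calibrated for the mimic
  scale; real molecules need molecule-appropriate thresholds.
- NAMFIS population uncertainties come only from the jackknife; no full
  posterior is attempted.
- The PDB writer emits a minimal dialect (HETATM + CONECT, single chain);
  occupancy/altloc/insertion codes are ignored on read with a warning.
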