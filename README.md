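# chamscope

Conformational-ensemble analysis for **molecular chameleons** — large,
flexible molecules (degraders/PROTACs and other beyond-rule-of-5 compounds)
whose membrane permeability depends on how their 3D shape and exposed
polarity change between water and the apolar interior of a membrane.

The package answers two questions practitioners ask of a conformer
ensemble:

1. **Is the molecule chameleonic or congruent?** Compute per-conformer
   size and polarity descriptors — radius of gyration
   `R_gyr = sqrt(Σ mᵢ|rᵢ − r̄|²/Σ mᵢ)`, Shrake–Rupley solvent-accessible
   surface area partitioned into polar (SA 3D PSA) and nonpolar
   (SA 3D NPSA) parts, intramolecular H-bond counts — then cluster the
   ensemble (leader algorithm on Kabsch RMSD), weight clusters by
   Boltzmann populations `pᵢ ∝ exp(−Eᵢ/RT)`, locate the minimum-energy
   conformation (MEC), and compare the (R_gyr, SA 3D PSA) property
   landscapes across solvents: a small population-weighted centroid shift
   plus high landscape overlap ⇒ *congruent*; a collapse in water with
   extension in the apolar solvent ⇒ *chameleonic/non-congruent*.

2. **Which conformers does the NMR data support?** Deconvolute NOE
   distance restraints into conformer populations (NAMFIS style): find
   weights w on the probability simplex minimizing
   `Σⱼ λⱼ (d_exp,ⱼ − (Σᵢ wᵢ d_ij⁻⁶)^(−1/6))²` with λⱼ = 1/tolⱼ², report
   per-restraint residuals, leave-one-out jackknife stability ranges, and
   fold-class (folded/semifolded/extended) population percentages.

A synthetic degrader-mimic generator — two rigid ligand bodies joined by an
alkyl or PEG-like linker, sampled by Metropolis over linker dihedrals under
a solvent-dependent pseudo-energy — provides ground-truth ensembles and NOE
datasets so the entire chain is testable without any external data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Analyze the chameleonicity of the two synthetic mimics (water vs
chloroform, 150 conformers each, seed 3):

```bash
$ chamscope chameleonicity --linker alkyl --seed 3 --out out_alkyl
Δr_gyr = +1.71 Å, overlap = 0.03 → non-congruent
report: out_alkyl/chameleonicity_report.json

$ chamscope chameleonicity --linker peg --seed 3 --out out_peg
Δr_gyr = +0.30 Å, overlap = 0.51 → congruent
report: out_peg/chameleonicity_report.json
```

The alkyl-linker mimic collapses in water (ensemble mean R_gyr 5.10 Å,
MEC R_gyr 4.84 Å, folded) and extends in chloroform (mean R_gyr 6.80 Å;
MEC SA 3D NPSA rises from 747 to 899 Å² as the aliphatic linker becomes
solvent-exposed): its positive Δr_gyr and near-zero landscape overlap mark
it non-congruent — the chameleonic signature associated with poor
permeability at the degrader scale. The PEG-linker mimic, identical except
that every third linker atom is an ether oxygen, keeps a similar ensemble
in both solvents (Δr_gyr = +0.30 Å, overlap = 0.51): congruent.

Fit populations to synthetic NOE data generated from a known 3-conformer
mixture and summarize fold classes:

```bash
$ chamscope namfis --seed 3 --out out_namfis
ssd = 1.891e-24
fold-class populations: {"folded": 100.0, "semifolded": 0.0, "extended": 0.0}
report: out_namfis/namfis_report.json
```

The near-zero weighted sum of squared deviations (ssd) says the fitted
mixture reproduces every restraint exactly (the data are noise-free here);
the report also contains the recovered populations, residuals and
jackknife ranges.

The same workflows run on your own data: multi-model PDB, multi-record SDF
or multi-frame XYZ conformer files plus a delimited NOE table
(`atom_i, atom_j, distance[, tolerance][, range_class]`):

```bash
chamscope chameleonicity --polar-ensemble water.sdf --apolar-ensemble chcl3.sdf
chamscope namfis --ensemble pool.sdf --noe-table noes.tsv
```

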