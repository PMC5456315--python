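# episurf

Comparative protein surface electrostatics in Python: a reusable pipeline
that computes grid electrostatic potentials for protein structures, compares
them over surface-skin regions, clusters the resulting distance matrices
into dendrograms ("epograms"), builds in-silico mutant panels, and predicts
ln(kcat/Km) for uncharacterized enzymes from electrostatic-potential
differences anchored on experimentally characterized references.

## Components

| module | what it does |
| --- | --- |
| `episurf.structure_io` | PDB/PQR parsing and writing, reduced charge model (one net charge per charged residue), per-element radii, composition summaries |
| `episurf.mutator` | point mutations by side-chain truncation to a CB stub; bundled mutant panels as TSV |
| `episurf.electrostatics` | finite-difference linearized Poisson-Boltzmann solver (7-point stencil, red-black SOR, Debye-Hueckel boundary), analytic Coulomb/Debye-Hueckel oracles, OpenDX grid I/O |
| `episurf.epsim` | skin-region masks, motif-anchored comparison spheres, Hodgkin/Carbo similarity indices, electrostatic distance matrices, mean potential differences (kcal/mol/e) |
| `episurf.epogram` | UPGMA epograms and neighbor-joining trees, Newick export, cophenetic distances, flat cuts |
| `episurf.kinetics` | ln(kcat/Km) transforms, antisymmetrized through-origin fits of potential differences vs ln differences, anchored predictions |
| `episurf.seq_structure_compare` | p-distance matrices from aligned FASTA, Kabsch superposition/RMSD, per-residue Q profiles, coarse Ramachandran classification |
| `episurf.synthetic_data` | ideal-helix scaffolds, charge-variant families, end-to-end qPIPSA-style benchmark with a known generating slope |

All potentials are stored in kT/e; conversion to kcal/mol/e (x 0.5922 at
298.15 K) happens once, in the comparison/kinetics layer.

## CLI

```sh
episurf structure info model.pdb
episurf structure charge model.pdb -o model.pqr
episurf mutate wt.pdb --set panel.tsv -o mutants/
episurf pb model.pqr --h 1.0 --pad 15 -o pot.dx
episurf epsim-matrix inputs.tsv --region anchored --motif CFT --radius 35 -o dist.csv
episurf epogram dist.csv --method upgma -o tree.nwk
episurf seqdiv aligned.fasta -o pdist.csv
episurf struct-compare ref.pdb mov.pdb
episurf struct-rama model.pdb
episurf kinetics-predict --refs refs.tsv --ep ep.tsv --slope -0.1046 -o pred.tsv
episurf fixtures --n 20 --slope -0.1046 --noise 0.05 --seed 1 -o bench/
```

`epsim-matrix` consumes a TSV of `label<TAB>structure.pqr<TAB>potential.dx`
rows; structures must be pre-superposed onto a common frame and all grids
must share one grid specification.

## Notes on the physics defaults

Solver defaults: eps_in 4, eps_out 78.4, 0.15 M 1:1 salt, 298.15 K,
h = 1.0 A, 15 A padding, Stern layer 2 A, tolerance 1e-6. The dielectric
boundary is the union of inflated atom spheres (no molecular-surface
construction), charges spread trilinearly, boundary potentials from
Debye-Hueckel monopoles. Skin defaults sigma 3 A, delta 4 A; anchored
comparisons use a 35 A sphere centred on a motif CA centroid. All defaults
are explicit, configurable, and recorded in output metadata.
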