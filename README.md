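# oligodestab

Trajectory analysis for the destabilization of β-sheet-rich amyloid
oligomers, with a ground-truth synthetic trajectory generator.

Amyloid oligomers of peptides such as amylin (hIAPP, the 37-residue islet
amyloid polypeptide of type-2 diabetes) stack U-bend β-strand–turn–β-strand
monomers into a parallel, in-register cross-β sheet.  Small molecules such
as green-tea polyphenols can break this order, and molecular-dynamics
studies quantify the effect through a standard panel of ensemble statistics.
This package implements that panel as a reusable library for multi-model PDB
trajectories:

- **Nematic order parameter** *P₂*: with uᵢ the unit vector joining the
  terminal Cα atoms of chain *i*, the ordering tensor
  Q = (1/N) Σᵢ (3/2 uᵢuᵢᵀ − ½ I) has largest eigenvalue
  P₂ = (1/N) Σᵢ [3/2 (uᵢ·d)² − ½], with the director **d** its principal
  eigenvector.  Ensembles with mean P₂ > 0.5 are classified ordered.
- **Secondary structure**: a hydrogen-bond-topology assignment (6-letter
  alphabet H/G/E/B/T/C) driven by the geometric H-bond criterion
  *d*(D···A) < 3.5 Å and ∠(D–H–A) > 150°; β content is the fraction of
  residues labelled E or B.
- **Free-energy landscape**: ΔG(V) = −k_B T ln [P(V)/P_max] over the 2-D
  histogram of (β content, radius of gyration), so the most populated bin
  sits at ΔG = 0 exactly; local minima are reported as basins.
- **Interactions**: geometric H-bond detection and per-residue-pair maps
  (normalized to a maximum of 1), ligand–residue contact probabilities and
  mean contact numbers at 3.5 Å, π-stacking geometry classification, and a
  pairwise Coulomb + 12-6 Lennard-Jones interaction energy with the
  10–12 Å switching function.
- **Clustering and sites**: k-medoids (PAM) on the pairwise Cα-RMSD matrix
  with occupancies and medoid representatives; binding-site discovery by
  contact persistence, ranked by mean interaction energy.
- **Synthetic generator**: an idealized single-layer U-bend cross-β
  oligomer (4.8 Å stacking, 3.4 Å rise, strands 1–17/28–37, turn 18–27)
  with tunable orientational disorder, β-ladder breakage, terminal fraying
  and rigid surface-anchored or free-floating ligand copies — every
  analysis can be validated against known ground truth.

## Worked example

```sh
python examples/02_disorder_scan.py
```

```
 sigma (deg)  mean P2  mean beta  state
           0    1.000      0.730  ordered
          15    0.947      0.219  ordered
          45    0.657      0.068  ordered
          90    0.457      0.045  disordered
```

Increasing the per-chain rotational disorder σ degrades both the nematic
order parameter (1.0 = all chains parallel) and the β content (0.73 = all
strand residues in intact inter-chain ladders); past σ ≈ 90° the ensemble
mean P₂ falls below the 0.5 cutoff and the system is called disordered.
The other examples build the ordered template (`01`), recover a bimodal
free-energy landscape (`03`), discover and rank ligand binding sites
(`04`), and run the full report pipeline on a PDB file (`05`).

A thin CLI wraps the same library:

```sh
oligodestab synth --chains 5 --frames 100 --orientation-sigma 10 \
    --ligand-site B:26 --ligand-copies 1 --seed 42 -o traj.pdb
oligodestab analyze order --traj traj.pdb --ligand-resname EGC -o p2.csv
oligodestab run --config run.cfg     # key=value config, full report bundle
```

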