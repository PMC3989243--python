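# Methods

This note records the models, conventions and design choices behind
`oligodestab`, in the order an analysis pipeline encounters them.  Units
are Å, ps, kcal/mol and elementary charges unless stated otherwise.

## Containers and formats

A `Topology` is an ordered atom list with cached column views; a `Frame` is
an `(n_atoms, 3)` coordinate array; a `Trajectory` is a list of frames with
strictly increasing times.  Multi-model PDB is the interchange dialect (one
MODEL per frame), parsed with Biopython; CONECT records are collected
separately so nonstandard hydrogens can still be parented.  Hydrogen
parentage is inferred from names (amide names → N, `H<rest>` → a heavy
atom of the same residue, `HA`→`CA` style prefixing) with CONECT as a
fallback; unparented hydrogens are excluded from the donor search with a
warning.  Structures without hydrogens are accepted, but hydrogen-bond
analyses refuse to run on them — hydrogen reconstruction is deliberately
out of scope, since a silently rebuilt geometry would fabricate the very
quantity being measured.

Selections use a small expression language (`chain A and calpha`,
`backbone and residue 26`, `ligand`, ranges as `residue 1-17`) returning
topology-ordered index arrays.  "Backbone" is N, CA, C, O plus amide
hydrogens; everything else protein-side is "sidechain".

## Synthetic oligomer generator

The generator emulates a single-layer, parallel, in-register cross-β
oligomer of U-bend chains: strand 1–17, turn 18–27, strand 28–37 (the
amylin numbering and sequence), chains stacked along the fibril axis.

Geometry defaults: 4.8 Å inter-chain stacking and 3.4 Å in-strand rise are
the canonical cross-β lattice constants.  The turn is a semicircular arc
whose width (strand separation, default 10 Å) is decoupled from the strand
rise: a turn arc at full rise would be so shallow that no Cα(i)–Cα(i+3)
reversal criterion could ever recognize it.  Strand residues place the
carbonyl oxygen on the amide rail of the next chain so that
N···O = 2.9 Å with a collinear D–H–A geometry — the β-ladder hydrogen
bonds hold by construction, giving (n_chains − 1) × 27 inter-chain bonds
for the default fold.  Turn residues point their carbonyls in-plane and
form no ladder.  The representation is backbone (N, H, CA, C, O) plus one
pseudo-sidechain CB per non-glycine residue; that is sufficient for every
analysis in the package (P₂ uses Cα termini, secondary structure and maps
use the backbone, contacts distinguish backbone from sidechain through the
CB) and keeps every geometric property exactly controllable.

Disorder is applied per frame, independently — the analyses in scope are
ensemble statistics, and temporal correlation is a non-goal:

- `orientation_sigma` (degrees): each chain is rotated about its centroid
  by an angle drawn from N(0, σ) about a random axis.  Degrades P₂ and,
  because registry is lost, β content and H-bond counts.
- `ladder_break_fraction`: the stated fraction of constructed ladder bonds
  is broken per frame by displacing the donor amide 2.5 Å laterally
  (placing N···O at 3.8 Å, safely past the 3.5 Å criterion without
  creating new bonds).  The surviving count is (1 − f) × ground truth by
  construction.
- `fray_terminal`: the last k C-terminal residues of the two edge chains
  are displaced off the lattice (outward plus Gaussian jitter), emulating
  terminal fraying; their strand labels disappear while interior chains
  stay intact.

All randomness flows from one `numpy` generator seeded by `DisorderSpec.seed`;
identical specs give bit-identical trajectories.  With all dials at zero
every frame equals the template.

Ligand copies are rigid.  The default template is a three-ring
polyphenol-like caricature (two hydroxylated rings plus an ester-linked
ring, four hydroxyl donors, five acceptor oxygens) — a synthetic stand-in,
not real ligand coordinates; real parameters may be supplied as a custom
`LigandTemplate`.  Anchored copies are placed tip-first along a local
surface normal (plane fit of the protein patch within 10 Å of the anchor,
signed away from the protein centroid), scanning the standoff for the gap
closest to the requested offset subject to ≥ 2.5 Å clearance from all
protein atoms and ≤ 3.5 Å contact with the anchor; the successful pose is
cached and reused frame to frame so a bound copy tracks its site
coherently.  Free copies are re-placed each frame at random positions
outside the protein envelope and therefore never build persistent
contacts.

Generator energetics: the default partial charges follow the amide-dipole
sign pattern but are deliberately small (|q| ≤ 0.05 e), and LJ radii are
compact (pair minima near 2.4 Å, well depths 0.03–0.5 kcal/mol).  The
choice is geometric: the placement rules force ligand contacts into the
2.5–3.5 Å window, so the radii must put that window on the attractive
branch of the 12-6 potential, and the charges must not let pose-dependent
Coulomb sums mask the contact-density signal the site-ranking analyses
measure.  These are synthetic-system defaults for validating machinery,
not a force field; energies computed with them are meaningful relative to
each other, not in absolute terms.

What the generator does *not* emulate: thermal vibration within chains,
temporally correlated dynamics, sidechain rotamers, solvent, a second
β-layer.  Tests passing on this substrate demonstrate that the analysis
machinery measures what it claims on known ground truth; they do not
demonstrate force-field-level realism on experimental trajectories.

## Order and fluctuation metrics

P₂ and the director come from the eigendecomposition of the ordering
tensor (see README for the formula); this estimator maximizes P₂ over all
unit directors, keeps it in [0, 1] for generic data, and is invariant
under global rotation and under flipping any chain vector.  Chain vectors
join the first- and last-residue Cα ("N to C terminus").  The
ordered/disordered call uses a strict mean-P₂ > 0.5 cutoff; the reported
spread is the plain standard deviation over frames (not over chains — the
choice is logged here since either reading is defensible).

Superposition is Kabsch SVD with reflection guard; RMSD is reported over
the fitted selection (default: all protein Cα, reference = first frame).
RMSF is computed about the time-mean position per Cα after fitting, then
arithmetically averaged across chains at equal residue index; trajectories
not flagged as superposed are refused rather than silently fitted.
Radius of gyration supports uniform or mass weighting; it is reported in
Å internally and converted to nm only on the free-energy-landscape axis.

## Secondary structure

The assignment is a Kabsch–Sander-style hydrogen-bond-topology scheme fed
by the geometric H-bond criterion, with STRIDE's output alphabet: α-helix
(H) from two consecutive i→i+4 backbone bonds, 3₁₀ (G) from i→i+3,
extended (E) for bridge residues whose neighbor also bridges to an
adjacent partner (a ladder), isolated bridge (B), turn (T) from single
helical turns or the Cα(i)–Cα(i+3) < 7 Å reversal fallback (which covers
the U-bend, where H-bond-only rules under-call turns), coil (C) otherwise;
priority H > G > E > B > T > C.  STRIDE itself mixes in empirical dihedral
propensity energies whose constants are unpublished; exact STRIDE parity
is a non-goal and the assignment is documented as STRIDE-like.  β content
counts {E, B} by default (a flag restricts to E); reported fractions
always sum to 1 over {coil, turn, β, helix}.

## Interactions

Hydrogen bonds: strict inequalities at both thresholds (D···A < 3.5 Å,
D–H–A > 150°), donor–acceptor distance (not H···A) as the distance
criterion, intra-residue pairs excluded, triples directional.  The
production detector uses a k-d tree over acceptors; an O(n²) brute-force
oracle lives in the test suite and the two are required to agree
triple-for-triple.  Maps accumulate backbone bonds per residue pair of a
chain pair over a frame window and normalize the largest cell to 1
(all-zero maps are flagged instead of divided).  Occupancies are per
donor-atom/acceptor-atom pair (any hydrogen), with residue-level
aggregation available by summing keys.

Contacts: any-atom distance < 3.5 Å between a residue and a ligand copy,
protein heavy atoms only by default (`include_protein_h` flips it), all
ligand atoms always.  Contact probability is the fraction of window
frames in contact; contact numbers count atom pairs within the cutoff.
Residues with probability > 0.1 are reported as important, backbone and
sidechain separately.

π-stacking uses community-standard geometric criteria (centroid distance
≤ 5.5 Å; interplanar angle < 30° parallel, > 60° perpendicular, otherwise
tilted) since the underlying literature names the interactions without
printing thresholds.

Energies: pairwise Coulomb (332.0636·qᵢqⱼ/r) and 12-6 LJ with
Lorentz–Berthelot combining on Rmin/2, both multiplied by the polynomial
switching function S(r) = (r_off² − r²)²(r_off² + 2r² − 3r_on²)/(r_off² −
r_on²)³ between r_on = 10 Å and r_off = 12 Å (1 below, 0 above, C¹ at
both ends — verified numerically).  No periodicity, no solvent term: a
group–group gas-phase energy of the kind trajectory-viewer plugins report.

## Landscape, basins, clustering

The FEL histograms two reaction-coordinate series over their data range
padded by 2% per side (default 40×40 bins; k_B = 0.0019872 kcal/mol/K,
T = 310 K).  ΔG = −kT ln(count/max); the most populated bin is exactly 0
and empty bins are +∞.  Zero-variance axes degenerate to a single bin
with a warning.  Basins are 8-neighborhood local minima filtered to a
minimum pairwise separation in bin space, deepest first with ties broken
toward lower x then lower y; the global minimum is always reported first.
Basin depth is ΔG at the minimum; barrier heights are out of scope.

Clustering is k-medoids on the pairwise Cα-RMSD matrix of frames
superposed onto the first frame, with deterministic PAM BUILD
initialization (ties to the lowest frame index) followed by alternating
assignment/update.  BUILD was chosen over random initialization after the
latter proved able to seed all medoids inside one metastable state and
collapse a cluster; with BUILD the result is deterministic independent of
the seed argument (kept for API stability).  Degenerate inputs (identical
frames) may leave a cluster empty; this is warned about, not hidden.  The
default frame stride for clustering is 2.

## Pipeline and site discovery

The report pipeline runs convergence (RMSD/β/H-bond series), order (P₂,
RMSF), secondary structure, the FEL with basins, backbone H-bond maps for
all adjacent chain pairs, clustering, and site discovery, writing
fixed-name CSV/JSON outputs; reruns with identical config and seed are
byte-identical.  The default analysis window discards the first half of
the trajectory (`equilibrated_from = 0.5`; an integer selects a start
frame instead, and a window beyond the trajectory aborts before any
stage runs).

Site discovery operationalizes "the ligand stays put": a copy is
site-forming if the set of residues it contacts keeps Jaccard overlap
≥ 0.5 with its own most-frequent contact set in at least half the window
frames; copies whose stable sets overlap ≥ 0.5 merge into one site.
Sites are ranked by mean interaction energy (most negative first) when
per-atom parameters exist, by total contact density otherwise.  This
persistence rule is an explicit operationalization — visual alignment of
cluster representatives, the usual manual procedure, is not reproducible
programmatically.

## Problem sizes

The validation suite and the acceptance script run the generator at 5
chains × 37 residues with trajectories of 20–200 frames and 5 seeds per
condition — large enough for the ensemble means being tested to
stabilize, small enough to iterate on quickly.  All quantities scale
linearly or quadratically in atoms and frames; nothing in the
implementation assumes these sizes.

## Known limitations

- The generator builds one β-layer only; stacked two-layer polymorphs are
  not emulated.
- Frame-independent disorder means time-series panels (RMSD vs. time)
  show noise about a level rather than drift; convergence machinery is
  exercised, convergence behavior itself is not emulated.
- The STRIDE-like assignment can differ from STRIDE/DSSP near chain
  termini and in mixed bridge topologies.
- Energies with generator defaults are relative, not calibrated (see
  above); supply real charges/LJ parameters for physical magnitudes.
- π-stacking on synthetic systems is limited to ligand rings: the
  pseudo-sidechain representation has no aromatic protein rings.
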