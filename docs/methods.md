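# Methods

This note documents the models and procedures implemented in `ensembledyn`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions that affect results.

## Data model and units

All analyses consume an `EnsembleFrameSet`: an ordered list of coordinate
frames (nm) over a fixed atom table with 1-based residue indices, a frame
spacing in ps, and a `superposed` flag.  PDB input (Å) is converted on
read; multi-model PDB and topology+trajectory pairs are read through
MDAnalysis.  Frames are equally weighted everywhere; no mass weighting is
applied (all Cα-based statistics treat residues identically).

Replica simulations are concatenated into a macro-trajectory by
`join_macrotrajectory`, dropping a per-replica equilibration prefix
(given in ps).  All persistence statistics are computed on the joined
macro-trajectory, not per replica; per-replica values can be obtained by
analysing the parts separately.

## Superposition

`superpose` iteratively least-squares fits every frame (Kabsch, on the Cα
selection by default) to the running mean structure until the mean shifts
by < 1e-6 nm.  This is the standard prerequisite of covariance analysis;
the iteration makes the reference self-consistent rather than tied to an
arbitrary frame.  A collinear selection is rejected: superposition onto a
(near-)linear structure leaves rotation about the axis unconstrained, and
the fit would scramble transverse fluctuations.  Rigid transforms are the
only operation applied, so intra-frame distances are preserved exactly.

The "average structure" of an ensemble is reported as the sampled frame
with the least main-chain rmsd (N/Cα/C/O when present, Cα-only otherwise,
with a logged downgrade) from the coordinate mean — a real conformation,
unlike the mean itself.

## Surrounding hydrophobicity

`Hp(i) = Σ_{j≠i} H(r_d − r_ij) h_j` with `r_d = 0.8 nm` by default, Cα–Cα
distances, and `H(0) = 1` (a pair exactly at the cutoff counts as inside).
The residue's own index is excluded — Hp measures the *environment* — with
an `include_self` flag for sensitivity checks.  Hp is computed per frame
and averaged; computing it once on the mean structure is available as an
option and differs only through cutoff-crossing fluctuations.

The hydrophobicity scale is an editable TSV; the packaged default is a
transfer-free-energy compilation (Jones 1975, kcal/mol, nonnegative).
Absolute Hp values depend on the scale — comparative statements between
systems analysed with the same scale do not — so every profile and report
records the scale's provenance label.

## Hydrogen bonds

A donor–acceptor pair is bonded in a frame when the D–A distance is
≤ 0.35 nm and the donor-vertex angle between D→H and D→A is ≤ 30°.  The
donor-vertex convention is the common MD-package reading of a 30° cutoff;
a hydrogen-vertex variant (deviation of D–H···A from linearity) sits
behind the `angle_vertex` flag.  Donor/acceptor chemistry is an editable
TSV following standard amino-acid chemistry (backbone N–H donor, backbone
O acceptor, canonical side-chain groups); intra-residue pairs are excluded.
Structures whose donors lack explicit hydrogens are rejected outright —
falling back to distance-only detection would silently change the
statistic.

The ensemble summary counts *atoms*, not events: the mean percentage of
donor+acceptor heavy atoms participating in ≥ 1 bond per frame (atoms
playing both roles counted once).  Event-based normalisation can be
derived from the per-pair persistence table the detector also returns.

## Essential dynamics

The 3N×3N covariance of Cα fluctuations is diagonalised
(`numpy.linalg.eigh`); eigenvalues are clipped at zero and sorted
descending, and each eigenvector's sign is fixed by making its
largest-magnitude component positive, so reports are reproducible.  The
essential subspace dimension k is the smallest reaching a cumulative
variance fraction of 0.70 (the conventional target; in well-sampled
protein ensembles this is typically ~10 eigenvectors); a fixed k can be
requested for cross-system comparability, since per-system k-by-variance
may select different dimensions.

Projected rmsf reconstructs each frame from its first-k projections and
takes the per-residue rmsf of the reconstruction — this yields per-residue
values and guarantees `rmsf_k ≤ rmsf_full` with equality at k = 3N.
Anisotropic U-tensors are the per-residue 3×3 covariances of the same
reconstructed fluctuations; their traces equal the squared subspace rmsf.
The ellipsoid scale for a probability level p is `sqrt(chi2.ppf(p, 3))`
(χ²₃ quantile convention), recorded with the default p = 0.1.

Sampling quality: cosine content compares the i-th principal projection
with an i-half-period cosine on a half-step time grid (values near 1 flag
diffusion-like, unconverged sampling); RMSIP is computed over the first 10
eigenvectors by default.  rmsf convergence uses sliding windows (lengths
1–20 ns, step 500 ps, count `floor((T−L)/step)+1`); windows longer than
the trajectory are skipped with a warning rather than failing the run.

`compute_subspace` refuses ensembles that are detectably unsuperposed:
when the `superposed` flag is absent, a Cα-centroid drift above 0.02 nm is
treated as rigid motion contaminating the covariance.  The threshold is
deliberately loose — genuine fluctuation ensembles move their centroid a
little — and catches gross omissions, not subtle ones.

## Cross-correlation networks

`C(i,j) = c(i,j)/√(c(i,i)c(j,j))` with `c(i,j)` the mean scalar product of
the two residues' Cα displacement vectors about the window mean.
Correlations are computed on non-overlapping windows (default 1 ns; 2–3 ns
for consistency checks), the trailing partial window dropped, and averaged
elementwise; per-window matrices are retained so window-to-average
consistency can be inspected.  Thresholding applies to the averaged
matrix.  Residues with zero variance in a window are masked (NaN) there
and logged.

Window refitting: each window's frames can be re-superposed onto the
window mean so slow inter-window drift does not inflate correlations.  The
default (`"auto"`) refits only ensembles not already superposed: on a
drift-free ensemble the refit has nothing to remove and would only perturb
the fluctuations (measurably so — it is a 6-degree-of-freedom projection
applied per window).

The network keeps edges with `|C| > 0.4` (strict) and `|i−j| > 12`
(strict; 12 is excluded).  The sequence cutoff removes within-helix and
contiguous-residue couplings.  On 1 ns windows essentially only positive
couplings pass 0.4, but the filter uses `|C|` as stated.  Pairs inside the
same annotated helix, or both inside barrel strands, can additionally be
excluded through `build_ss_exclusion_mask`; the element membership is
explicit caller configuration, because which elements constitute "the
barrel" is a per-protein annotation choice, not something the matrix can
decide.  Network diffs map edges through the residue correspondence; edges
touching gapped residues are reported in a separate unmappable set, never
silently dropped.

## Salt-bridge networks

Charged groups default to Asp(OD1/OD2)⁻, Glu(OE1/OE2)⁻, Lys(NZ)⁺,
Arg(NE/NH1/NH2)⁺; His is excluded by default (ambiguous protonation at
neutral pH) and termini are off unless enabled.  The table is editable and
recorded in every report.  A pair is in contact in a frame when the
minimum distance between oppositely signed atoms is < 0.4 nm (with 0.45
and 0.5 nm as sensitivity settings); persistence is the contact fraction
over the macro-trajectory.  Detection returns the full unfiltered
persistence spectrum; thresholding (default 24%, sensitivity 20%) is a
separate step.  Only geometry and persistence are analysed — salt-bridge
strength (electrostatic free energy, desolvation) is explicitly out of
scope, as is pKa prediction.

### Persistence-cutoff selection

Observed charge-pair persistence distributions are bimodal: a large
population below 10% ("noise") and a population above 30% ("signal"),
with a sparse gap between.  The cutoff is placed by two supervised
classifiers trained on those two classes over the 1-D persistence feature:
a hard-margin linear SVM (C = 1e6; on separable 1-D data its boundary is
the max-margin midpoint) and a k-nearest-neighbours vote with k = 4,
scanned on a fine grid to locate its decision flip.  k-NN ties (2–2 votes)
break toward noise — the conservative choice, admitting fewer bridges.  If
the two boundaries differ, the midpoint is used and the disagreement width
is logged and reported; mid-range points are labelled by both classifiers
with an agreement flag.  When either training class is empty the
procedure refuses and directs the caller to the fixed default cutoff
(0.24).

### Proximity clusters and conservation classes

Salt-bridging residues form an undirected graph: arcs join bridged pairs
and any two nodes strictly fewer than 5 residues apart in sequence
(|i−j| ≤ 4 — stated explicitly because the off-by-one changes clusters).
Clusters are the connected components (via networkx), ordered by smallest
member; they partition the bridging residues and are input-order
invariant.  Nodes are residues, not charged groups: a residue making two
bridges is one node.

Conservation classes across a cold reference, a warm reference and
mutants (bridges mapped into cold numbering through the correspondences):
group I = present in every system; group IV = present in the warm
reference and ≥ 1 mutant but not the cold wild type (mesophilic-like
bridges acquired by mutants); II/III = wild-type-specific bridges on
residues without a correspondent in the other wild type (gap-mediated);
everything else is reported unclassified rather than forced into a class.
The per-mutant count of group-IV bridges is the feature exposed to
`phenotype_correlation` (plain Pearson r against Tm and kcat/Km columns,
n reported, ≥ 3 systems required, zero-variance features flagged
undefined instead of crashing).

## PDSSP

Per-frame secondary-structure labels are consumed from external
DSSP-style output — the package never computes secondary structure.  Per
residue, the modal label and its frame fraction are reported; ties break
by a fixed priority order (H G I E B T S - C) and are flagged.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the analyses measure,
with none of the physics:

* `gen_gaussian_ensemble` samples i.i.d. frames about a fixed coarse
  helical bead chain from Σ = Σ_k λ_k v_k v_kᵀ + σ²I, returning the
  analytic covariance, residue correlation matrix and eigensystem.  The
  helix matters: a straight chain would make superposition degenerate.
  `rigid_free_pair_modes` builds in-phase residue-pair modes orthogonal to
  the 6 rigid-body directions, so planted correlations survive any
  superposition step exactly.  Defaults (λ ≈ 0.02–0.04 nm², σ² = 5e-4 nm²,
  0.38 nm bead spacing, 2 ps/frame) give fluctuation amplitudes of
  0.1–0.2 nm against a 0.02 nm noise floor — the regime where essential
  modes dominate rmsf, as in equilibrated protein ensembles.
* `gen_contact_series` plants per-pair Bernoulli contact series at
  persistences drawn from a truncated Beta mixture (modes near 0.05 and
  0.6, zero mass in (0.10, 0.30)), embedded as charged pseudo-residue
  pairs 6 nm apart (formed 0.30 nm, broken 0.80 nm, around the 0.4 nm
  detection cutoff).
* `gen_homolog_pair` builds two chains sharing planted modes on mapped
  positions, with insertion/deletion gaps in the correspondence.
* `gen_mutant_comparison` is the end-to-end fixture: 40 residues,
  3000 frames (6 ns at 2 ps/frame — six 1 ns correlation windows), one
  shared correlated pair (3–20) and salt bridge (5–30, p = 0.9), one
  extra mutant coupling (8–35) and gained bridge (12–33, p = 0.85 vs 0.03),
  one noise bridge (17–38, p = 0.05), and a backbone N–H···O pseudo-atom
  ladder so the H-bond stage has real work.

Because frames are i.i.d., passing tests demonstrate correctness of the
estimators, not robustness to the time correlation, anharmonicity,
conformational substates or force-field artifacts of real MD — sampling
errors on real data will be larger than the i.i.d. rates seen here, which
is precisely what the cosine-content and rmsf-convergence diagnostics are
for.  Same seed ⇒ bit-identical output throughout.

## Problem sizes in the validation suite

Brute-force oracle comparisons use 50-residue systems; covariance/
correlation recovery uses 5000 frames (elementwise tolerance 0.05) and
eigensystem recovery 10000 frames (5% on eigenvalues, RMSIP ≥ 0.98);
persistence estimation uses 2000-frame series checked at binomial-σ
bounds (3σ single-pair, 4σ family-wise across 30 pairs); cutoff selection
is repeated over 100 seeded mixtures; clustering over 100 random graphs.
These sizes put statistical fluctuations well inside the stated
tolerances at the 1/√n rate.

## Known limitations

* No PBC handling beyond what the input format already resolved, no
  solvent/ion analysis, no trajectory generation.
* DSSP, structural alignment (the correspondence table) and SASA are
  inputs, not computations.
* The Hp additivity assumption (summing independent per-residue transfer
  free energies) and scale transferability are inherited from the method
  itself; absolute values are scale-dependent.
* Conservation classification reports patterns outside groups I/IV and the
  gap-mediated class as "unclassified" instead of guessing.
* The comparison reference is the first configured system; reports
  otherwise sort deterministically by label.
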