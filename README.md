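# ensembledyn

Comparative analysis of protein conformational ensembles from molecular
dynamics.  The package is aimed at the classic question of protein
adaptation studies — *which structural-dynamical features distinguish two
homologous enzymes (or a wild type and its mutants), given equilibrated
conformational ensembles of each?* — as it arises, for instance, when
contrasting a cold-adapted enzyme with a warm-adapted homolog and with
mutants engineered to shift one toward the other.

It computes, per system and comparatively across systems linked by a
residue correspondence:

* **Surrounding hydrophobicity** — per residue *i*,
  `Hp(i) = Σ_{j≠i} H(r_d − r_ij) · h_j` (kcal/mol), where `r_ij` is the
  Cα–Cα distance, `H` the Heaviside step (`H(0)=1`), `r_d = 0.8 nm`, and
  `h_j` a transfer-free-energy hydrophobicity index; averaged over frames.
* **Hydrogen-bond persistence** — geometric detection (donor–acceptor
  distance ≤ 0.35 nm, donor-vertex angle ≤ 30°), normalised as the
  percentage of donor+acceptor atoms involved per frame.
* **Essential dynamics** — diagonalisation of the 3N×3N Cα fluctuation
  covariance; the essential subspace is the top-k eigenvectors reaching 70%
  of the variance; per-residue rmsf after projection onto that subspace;
  anisotropic U-tensors; cosine content and RMSIP sampling diagnostics;
  rmsf convergence over sliding windows (1–20 ns).
* **Cross-correlation networks** — `C(i,j) = c(i,j)/√(c(i,i)c(j,j))`
  averaged over non-overlapping 1 ns windows, keeping significant
  (`|C| > 0.4`) long-range (`|i−j| > 12`) couplings, with optional
  secondary-structure pair exclusions; networks diffed across systems.
* **Salt-bridge networks** — oppositely charged groups within 0.4 nm, kept
  when formed in ≥ 24% of the macro-trajectory; the persistence cutoff can
  instead be derived from the data's bimodal persistence distribution by a
  linear SVM and a k-NN (k = 4) classifier trained on the noise (< 10%) and
  signal (> 30%) populations; salt-bridging residues are clustered as
  connected components of a graph whose arcs are bridges or close sequence
  neighbours (|i−j| < 5); cross-system conservation classes and the Pearson
  correlation of acquired bridges with phenotype (Tm, kcat/Km) close the loop.

Because public trajectory data for such studies is rarely deposited, the
package ships a first-class synthetic-data module: bead-chain ensembles
sampled from planted low-rank Gaussian covariances (analytic correlation
matrix and eigensystem returned alongside), two-state salt-bridge contact
series with bimodal persistence, homolog pairs with indels, and a
wild-type/mutant fixture with one planted gained bridge and one planted
extra correlated pair.  Every analysis stage is validated against this
ground truth.

## Worked example

Run the packaged two-system comparison (synthetic wild type vs mutant,
seeded, generated at run time):

```bash
python -c "
from importlib import resources
print(resources.files('ensembledyn.data') / 'example_config.yaml')
"   # copy this config anywhere, then:
ensembledyn run --config example_config.yaml --out out/
```

`out/summary.tsv` ends with:

```
system    n_frames  n_residues  mean_hp  mean_rmsf_nm  subspace_k  hbond_fraction_pct  n_corr_edges  n_bridges_kept  n_clusters
wildtype  3000      40          3.43758  0.0341698     63          44.9326             1             1               1
mutant    3000      40          3.4367   0.0359002     51          45.0884             2             2               1
```

and `out/diff_wildtype_vs_mutant.tsv` lists the cross-system differences:

```
category          residue_a  residue_b
corr_shared       3          20
corr_only_mutant  8          35
bridge_shared     5          30
bridge_gained     12         33
```

Reading: both systems share the correlated pair 3–20 and the persistent
salt bridge 5–30; the mutant additionally shows the long-range coupling
8–35 and has gained the bridge 12–33 — exactly the two differences planted
in the generator, and nothing else.  The slightly higher mean rmsf of the
mutant reflects its extra collective mode.

The same analyses are available on real data (multi-model PDB, or
PDB/GRO + XTC/DCD pairs) through `ensembledyn hp|hbonds|ed|corr|saltbridges`
and the library API (`load_ensemble`, `superpose`, `compute_hp`,
`compute_subspace`, `windowed_correlation`, `detect_salt_bridges`, ...).

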