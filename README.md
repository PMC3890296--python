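# znfarray

Minisatellite-aware phylogenetic and functional-divergence analysis of
PRDM9-style C2H2 zinc-finger (ZnF) arrays.

The DNA-binding domain of PRDM9 — the protein that positions meiotic
recombination hotspots in mice and humans — is encoded by a coding
minisatellite: a tandem array of 84-bp repeat units, each unit one
28-residue C2H2 finger. The array mutates both by point substitution
(concentrated at the DNA-contact codons, helix positions −1, 3 and 6) and by
tandem duplication/contraction of whole units, which makes ordinary multiple
alignment and bootstrap phylogenetics inapplicable. This package implements
the analysis chain for such data, for molecular evolution researchers
working on hypervariable tandem repeats:

- **`arrays`** — decompose an allele into its 84-bp (or 9-bp-deleted 75-bp
  first-position) units, translate, classify (functional / first-position /
  terminal-stop via the C2H2 anchor `C-x2-C-x12-H-x3-H`), and count identity
  classes at the DNA, protein and contact-triplet levels.
- **`unitdist`** — evolutionary distances between repeat units: Jukes–Cantor
  within the first-position group (the 9-bp deletion counts as one mutation),
  Kimura 2-parameter with gamma rate heterogeneity
  (`d = (α/2)[(1−2P−Q)^(−1/α) −1] + (α/4)[(1−2Q)^(−1/α) −1]`, default
  α = 0.31286) within the main group; distances × coefficient, rounded
  half-up, give the integer mutation penalty matrix **M**.
- **`msalign`** — optimal alignment of two alleles as unit sequences under
  mutation (cost `M[u][v]`), tandem amplification (cost `A` + divergence of
  the copy from its nearer neighbor) and contraction (symmetric, cost `C`);
  exact dynamic programming, default `A = C = 1`, coefficient 1000.
- **`phylo`** — neighbor joining plus NNI hill climbing under balanced
  minimum evolution, OLS branch lengths; confidence via the whole-tree
  **VAF** (`1 − Σ(d−t)²/Σ(d−d̄)²` over pairs) and per-edge **Re**, the
  fraction of cross-split quartets whose strict four-point condition agrees
  with the split (bootstrap is deliberately absent — unit indels preclude a
  site-wise alignment).
- **`triplets`** — reduce each functional finger to its −1/3/6 contact
  triplet (His-anchored), search the longest words shared by a quorum of a
  group, and summarize positional amino-acid diversity.
- **`popgen`** — observed and expected heterozygosity and allele-size
  spectra from repeat-number genotype tables.
- **`motifs`** — scan a genome with per-allele predicted binding-site PWMs
  at an exact p-value-derived threshold, merge hits, compare alleles by the
  coverage overlap distance `D = 1 − intersection/union`, partition
  repeat-overlapping hit coverage among repeat families, and run a PCA over
  those compositions.
- **`synthetic`** — forward simulation of arrays along a Yule tree (tandem
  duplication, contraction, contact-accelerated point mutation, with an
  auditable event log), Hardy–Weinberg genotype cohorts, and synthetic
  genomes with planted repeat families and motif occurrences.

## Worked example

```python
from znfarray import synthetic, unitdist, msalign, phylo, triplets

sim = synthetic.simulate_arrays(synthetic.SimParams(n_leaves=6, seed=11))
units = [u for a in sim.alleles for u in a.units]
udm = unitdist.build_unit_distance_matrix(units)          # JC / K2P+gamma
pc = unitdist.scale_to_penalties(udm)                     # A=C=1, coeff 1000
ids = {s: u for s, u in zip(udm.seqs, udm.unit_ids)}
pairs = [(a.allele_id, [ids[u.dna] for u in a.units]) for a in sim.alleles]
adm = msalign.allele_distance_matrix(pairs, pc)           # M/A/C alignment
tree = phylo.build_tree(adm, method="me_nni")
print("units:", [a.n_units for a in sim.alleles])
print("VAF :", round(phylo.vaf(adm, tree), 3))
print("mean Re:", round(phylo.average_re(adm, tree, seed=0), 3))
print("tree:", tree.to_newick())
```

prints

```
units: [12, 12, 12, 13, 13, 13]
VAF : 0.999
mean Re: 1.0
tree: ((L1:480.167,(L2:3.36128e-13,L3:3.92972e-13)1.0000:274.833)1.0000:48.3889,(L4:84.75,L5:58.25)1.0000:355.833,L6:199.667);
```

Six simulated alleles of 12–13 units each; the alignment distance matrix is
in integer penalty units (a duplication costs 1, substitution divergence
hundreds), the inferred unrooted tree carries per-edge Re values as internal
labels, a VAF of 0.999 says the tree's patristic distances reproduce the
matrix almost exactly, and mean Re = 1.0 says every internal edge is
supported by all of its quartets. Reducing an allele to contact triplets and
searching group-wide common words works the same way:

```python
group = [triplets.reduce_to_triplets(a) for a in sim.alleles]
print(triplets.longest_common_words(group, quorum=1.0).length)  # -> 2 (aa)
```

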