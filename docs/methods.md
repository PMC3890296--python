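# Methods

## The data model

An allele of the ZnF-array locus is a tandem concatenation of 84-bp repeat
units in reading frame, each encoding one 28-residue C2H2 zinc finger. Two
departures from the 84-bp rule are modeled: the first unit of an array may
carry a 9-bp in-frame deletion (75 bp, 25 residues), and the last unit may
contain a stop codon. Classification is structural: a unit is *functional*
iff its translation matches the C2H2 anchor `C-x(2)-C-x(12)-H-x(3)-H` with
the fixed Mus spacing (a configurable tolerant mode allows `x(2,4)` between
the cysteines); a unit failing the anchor — they always occur at the first
array position and lack an essential zinc-coordinating cysteine — is
*first_position*; a stop codon is tolerated only in the last unit and makes
it *terminal_stop*. A stop anywhere else raises an error rather than
truncating silently, because internal stops indicate a broken reading frame,
not a shorter protein. Ambiguity codes are rejected by default and
propagated as `X` under a lenient flag. Identity classes ("alleles",
"protein variants", "triplet variants") are exact string identity at the
DNA, protein and contact-triplet levels respectively; the identity window is
the repeat array only, not PCR flanks.

## Unit distances

The distinct repeat units of a dataset split into two well-separated groups:
first-position units and everything else. Within the first-position group a
Jukes–Cantor distance is used, `d = -(3/4) ln(1 - (4/3)p)`, with the 9-bp
deletion counted as exactly one mutation over a fixed denominator of 84
sites; when a 75-nt and an 84-nt unit are compared, the deletion is placed
at the offset maximizing matches (leftmost on ties) so the comparison is
deterministic. Within the main group the distance is Kimura 2-parameter with
gamma-distributed rate heterogeneity across sites,

    d = (α/2) [(1 − 2P − Q)^(−1/α) − 1] + (α/4) [(1 − 2Q)^(−1/α) − 1],

with transition/transversion proportions P, Q (transitions are A↔G and
C↔T) and shape α = 0.31286 by default — a fitted constant treated as
configuration, since substitution-model selection is outside this package's
scope. As α → ∞ the expression reduces to plain K2P; for finite α it is
strictly larger (rate heterogeneity implies more hidden multiple hits).
Cross-group entries use K2P+gamma on the gap-free aligned portion and are
floored at the maximum within-group distance: the groups are far apart under
any model, and the floor makes the (immaterial) choice deterministic.
Saturated pairs (p ≥ 3/4, or non-positive power arguments) raise a
`SaturationError` naming the units rather than returning NaN.

An auxiliary `fit_alpha` estimates the gamma shape from per-column pairwise
difference counts (gamma-mixed Poisson = negative binomial, shape = α). It
is a coarse column-count method, adequate for sanity checks; the pipeline
itself always takes α as a constant.

## Allele alignment

Two alleles are aligned as sequences of unit identifiers under three events:
mutation of one unit into another (cost `M[u][v]`, the unit distance times a
coefficient, rounded half-up to an integer — half-up because rounding ties
move M by 1 and must be reproducible), tandem amplification of a unit (cost
`A` plus the mutation cost between the new copy and the nearer of its two
sequence-adjacent neighbors — the duplication source; boundary units use
their single neighbor, a lone unit costs `A` alone), and tandem contraction
(symmetric, cost `C`). Defaults `A = C = 1`, coefficient 1000, so one indel
event is worth 0.001 substitutions/site of unit divergence. The optimum is
found by exact dynamic programming over monotone matchings; because the
unmatched-unit cost depends only on the unit's static neighbors, the DP is a
standard three-move recursion and the integer score is exact. DP ties break
match > contract > amplify so scripts are deterministic (the score is
unaffected). A `flat` indel model (`A`/`C` only, no divergence term) is
available behind `PenaltyConfig.indel_model` because the published penalty
listing does not disambiguate the two; `neighbor_mutation` is the default
as it reflects duplication-then-divergence.

With `A = C` the all-against-all matrix is symmetric with zero diagonal,
but the **triangle inequality is not guaranteed** (neighbor-dependent indel
costs can undercut composite paths); the tree stage therefore never assumes
metricity.

## Tree inference and confidence

`build_tree` offers canonical neighbor joining (`nj`) and NJ followed by
nearest-neighbor-interchange hill climbing under balanced minimum evolution
(`me_nni`), where the criterion is Pauplin's tree length
`Σ_{i<j} 2^(1−p_ij) d_ij` with `p_ij` the topological path length; sweeps
accept the best improving swap until none remains. Branch lengths are then
refit by ordinary least squares against the input matrix and negative
estimates are clamped to zero. Tiny floating asymmetries in input matrices
(patristic sums accumulated in different orders) are removed by averaging
`(D + Dᵀ)/2` after validation.

Confidence is distance-based, not bootstrap-based — resampling alignment
columns is meaningless when alleles differ by whole-unit indels:

- **VAF** (variance accounted for): `1 − Σ(d_ij − t_ij)² / Σ(d_ij − d̄)²`
  over unordered pairs, `t` the patristic distances. 1.0 on additive input.
- **Re** per internal edge: the fraction of quartets `{a,a'} × {b,b'}`
  across the split satisfying the strict four-point condition
  `d(a,a') + d(b,b') < min(d(a,b)+d(a',b'), d(a,b')+d(a',b))`. Ties count
  against the edge. Quartets are enumerated exhaustively up to 100,000 per
  edge and uniformly sampled with a caller seed beyond that. Re is invariant
  to rescaling the matrix but *not* to additive shifts, which can flip
  strict inequalities. The reported "average Re" is the mean over internal
  edges with at least two leaves on each side.

## Contact triplets and word search

Each functional finger binds DNA through helix positions −1, 3 and 6. The
residues are located by anchoring on the first conserved histidine of the
C2H2 match (helix +7): indices `h−7`, `h−4`, `h−1` within the unit. The
anchor-based rule fails loudly on degenerate units instead of silently
extracting the wrong columns; an explicit `contact_offsets` override is
honored when set. First-position and terminal-stop units are excluded.

The longest-common-word search runs over the *concatenated residue strings*
(step 1 in residue space, not whole triplets), so shared runs crossing a
triplet boundary count and lengths are reported in amino acids. A word is
common when it occurs exactly (no substitutions) in at least
`ceil(quorum · n)` of the group's sequences; all maximal words are returned.
Existence of a common word is monotone decreasing in length, so the maximum
is found by binary search; tests check it against an all-substrings oracle.

Positional diversity profiles count amino-acid frequencies at each of the
28 codon positions over all functional units, flagging residues present in
every allele and residues below 10% of units; the per-group triplet
spectrum classifies variant frequencies as rare `[0, 2%)`, common
`[2%, 10%]` or frequent `(10%, 100%]` (left-closed boundaries, so a
1-in-10 singleton is "common").

## Heterozygosity

Observed heterozygosity H is the fraction of individuals whose two
repeat-number calls differ — estimator-free. Expected heterozygosity He is
Nei's `1 − Σ p_i²` over the 2N gene copies by default; the
`2N/(2N−1)`-corrected estimator is available, as published tables rarely
state which was used. A `field_only` filter restricts to field-caught
animals, mirroring the dual presentation of such tables.

## Motif scanning and overlap analytics

Per-allele PWMs (length 3× the number of functional fingers; an external
ZnF→motif predictor is explicitly a pre-step, not part of this package) are
scored as log-odds against a 0-order background (estimated from the scanned
genome, or uniform), discretized to a 0.001-bit grid with zero
probabilities floored at −30 bits/position. The score threshold for a
p-value (default 10⁻⁴, per strand per window) comes from the exact null
distribution of the integer score, computed by position-wise convolution;
the threshold is the smallest score whose tail probability is ≤ the
requested p-value, and the attained tail is reported (it matters for
calibration checks because the score distribution is discrete). Requests
below the distribution's resolution return the maximal score with a warning
flag. The scanner applies the same integer matrix to both strands (reverse
strand = reverse-complemented matrix), projects hits to forward coordinates,
and merges overlapping or touching windows into maximal half-open intervals.
Bases outside ACGT score the floor and so never seed hits.

The overlap distance between two alleles' hit sets is
`D = 1 − |intersection bp| / |union bp|` — the Jaccard distance on covered
base sets, hence a true metric on coverages; two empty hit sets give an
undefined marker which downstream matrix construction reports as an error
listing the offending alleles. NJ clustering on D (optionally on
`log(D + 1e-6)`, shifted non-negative) reuses the tree stage. Repeat-family
composition counts a (hit, element) overlap toward the element's family only
when the overlap spans at least the full motif length, and reports both the
repeat-overlapping fraction of hit coverage and per-family proportions of
that qualifying coverage. The PCA over compositions is covariance PCA
(columns centered, not scaled, matching the R `princomp` default behavior
emulated here; a `scale` flag gives correlation PCA).

## The synthetic generator

`simulate_arrays` evolves a root allele along a Yule tree (birth rate 1.0,
death rate 0) with, per branch: a Gillespie walk of unit duplications and
contractions at per-unit rates `lambda_dup = lambda_con = 0.1` per
branch-length unit (the first unit is never copied or deleted; counts are
reflected at `min_units = 7` and `max_units = 17`, the observed wild range),
then per-site Poisson substitutions at `mu_site = 0.04` per nucleotide per
branch-length unit, with the nine contact-codon nucleotides accelerated
`contact_multiplier = 10`-fold. Substitutions that would create a stop or
break the C2H2 scaffold are rejected, emulating purifying selection on the
structural residues; duplications insert an exact adjacent copy that
diverges only subsequently, matching the alignment model's assumption. The
default root is a 12-unit mouse-like array whose contact triplets cycle
through a small realistic vocabulary. Every event is logged so stochastic
claims (e.g. contact-codon enrichment of substitutions) are auditable, and
all randomness derives from one seed.

The time-scale calibration deserves a note: rates are per branch-length
unit, so only the products rate × branch length matter. `mu_site = 0.04`
makes one branch-length unit ≈ 4% per-site divergence at background sites —
enough substitution input for internal edges of typical Yule trees to carry
events, while keeping even the deepest leaf-to-leaf paths below the
saturation regime where the K2P+gamma correction becomes unstable.

What the generator does *not* emulate: recombination-mediated gene
conversion within arrays (concerted evolution beyond simple tandem
duplication), multi-unit duplication runs, selection on binding specificity,
and population-level processes (each leaf is one allele, not a population
sample). Passing tests therefore demonstrate correctness of the analysis
chain under the simple indel+substitution model, not robustness to the full
mutational complexity of real minisatellites.

`sample_genotypes` draws two repeat-number alleles i.i.d. per individual
(Hardy–Weinberg), and `synth_genome` produces i.i.d.-background genomes with
labeled repeat-family intervals (optionally with their own base
composition) and exact motif words planted at truth positions.

## Known limitations

- **Topology recovery on simulated arrays is bounded well below 1.** Two
  effects cap it. First, Yule trees conditioned on 8 tips regularly contain
  internal edges shorter than 1% of tree height; an edge on which no
  mutational event falls is unresolvable by any method, and raising the
  event density enough to mark such edges pushes deep paths on a ~1000-nt
  array into saturation, which degrades distance additivity faster than the
  extra events help. Second, the minisatellite process is intrinsically
  non-additive: contractions erase previously accumulated divergence and
  tandem duplications create homoplasy, so on some replicates the true
  topology scores *worse* under balanced minimum evolution than a rival —
  the inference is then optimal for the data it sees and still "wrong".
  At the default operating point the pipeline recovers the full 8-leaf
  topology in roughly six replicates out of ten (the acceptance script
  measures this as `topology_recovery_pct`), with VAF and mean Re of the
  inferred trees remaining high — the usual situation for real minisatellite
  phylogenies, where individual deep edges, not whole topologies, carry the
  interpretable signal.
- The alignment model charges single-unit events only; run amplifications
  are out of scope, so distances between alleles related by multi-unit
  duplications are overestimated.
- `fit_alpha` is a column-count approximation, not a tree-based ML fit.
- The PWM scan is gapless and 0-order-background only, and hit merging is
  per allele before any pairwise comparison; per-window raw hits are exposed
  for calibration but not kept in `HitSet`s.
- Quartet sampling beyond 100,000 quartets per edge introduces Monte-Carlo
  error in Re of order 1/√100,000 ≈ 0.3%.
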