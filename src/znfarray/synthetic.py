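"""Synthetic data with the statistical structure the pipeline assumes.

Three generators: (1) ZnF-array alleles evolved forward in time along a Yule
tree under tandem unit duplication, unit contraction and point mutation, with
mutation concentrated at the nine nucleotides of the DNA-contact codons
(helix positions -1, 3 and 6) and purifying selection holding the C2H2
scaffold residues fixed; (2) genotype cohorts drawn under Hardy-Weinberg
proportions from given repeat-number allele frequencies; (3) genomes of
i.i.d. background composition with labeled repeat-family intervals and exact
motif words planted at known truth positions.

Every stochastic claim is auditable: the array simulator emits an event log
alongside its outputs and everything is reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
from dendropy.simulate import treesim

from .arrays import (
    C2H2_PATTERN,
    UNIT_NT,
    ZnfAllele,
    allele_from_dna,
    translate_unit,
)
from .phylo import PhyloTree
from .popgen import GenotypeRecord
from .motifs import RepeatAnnotation

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

#: consensus-style functional unit; C2H2 anchor C-x2-C-x12-H-x3-H at 7..27
CONSENSUS_UNIT_AA = "TGEKPYECKECGKAFSRSDELTRHQRTH"
#: the same scaffold with the essential cysteines substituted (non-finger)
FIRST_UNIT_AA = "TGEKPYESKERGKAFSRSDELTRHQRTH"
#: aa indices of the -1/3/6 contact residues (His anchor at index 23)
CONTACT_AA_IDX = (16, 19, 22)
#: the nine contact nucleotides within an 84-nt unit
CONTACT_NT_IDX = tuple(i * 3 + k for i in CONTACT_AA_IDX for k in range(3))

#: contact-triplet vocabulary used to diversify the root array
_ROOT_TRIPLETS = ["QNK", "QDQ", "ANQ", "VVQ", "QHK", "ADK", "ESK", "QNQ"]


def _aa_to_dna(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def default_root_allele(n_units: int = 12, allele_id: str = "root") -> ZnfAllele:
    """A mouse-like root array: one non-finger first unit, then functional
    fingers whose contact triplets cycle through a small realistic vocabulary."""
    units = [_aa_to_dna(FIRST_UNIT_AA)]
    for i in range(1, n_units):
        aa = list(CONSENSUS_UNIT_AA)
        trip = _ROOT_TRIPLETS[(i - 1) % len(_ROOT_TRIPLETS)]
        for pos, res in zip(CONTACT_AA_IDX, trip):
            aa[pos] = res
        units.append(_aa_to_dna("".join(aa)))
    return allele_from_dna("".join(units), allele_id)


@dataclass
class SimParams:
    """Forward-simulation settings.

    Rates are per branch-length unit of the Yule tree: ``mu_site`` per
    nucleotide, ``lambda_dup``/``lambda_con`` per eligible unit. Contact
    sites mutate at ``mu_site * contact_multiplier``. Unit counts emulate
    observed wild arrays (7-17 units).
    """

    n_leaves: int = 8
    birth_rate: float = 1.0
    mu_site: float = 0.04
    contact_multiplier: float = 10.0
    lambda_dup: float = 0.1
    lambda_con: float = 0.1
    min_units: int = 7
    max_units: int = 17
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (2 <= self.min_units <= self.max_units):
            raise ValueError("need 2 <= min_units <= max_units")
        if self.contact_multiplier < 1:
            raise ValueError("contact_multiplier must be >= 1")
        for r in (self.mu_site, self.lambda_dup, self.lambda_con):
            if r < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class ArraySimResult:
    tree: PhyloTree  # true topology (branch lengths from the Yule tree)
    newick: str
    alleles: list[ZnfAllele]  # one per leaf
    events: list[dict] = field(default_factory=list)


def _dendropy_to_phylotree(tree: dendropy.Tree) -> PhyloTree:
    adj: dict = {}
    lengths: dict = {}
    counter = [0]
    ids: dict = {}

    def nid(node):
        if node.is_leaf():
            return node.taxon.label
        if node not in ids:
            ids[node] = counter[0]
            counter[0] += 1
        return ids[node]

    for node in tree.preorder_node_iter():
        n = nid(node)
        adj.setdefault(n, [])
        for child in node.child_nodes():
            c = nid(child)
            adj[n].append(c)
            adj.setdefault(c, []).append(n)
            lengths[frozenset((n, c))] = child.edge.length or 0.0
    for n in [k for k, v in adj.items() if isinstance(k, int) and len(v) == 2]:
        a, b = adj.pop(n)
        adj[a] = [x for x in adj[a] if x != n] + [b]
        adj[b] = [x for x in adj[b] if x != n] + [a]
        lengths[frozenset((a, b))] = (
            lengths.pop(frozenset((n, a))) + lengths.pop(frozenset((n, b)))
        )
    labels = sorted(k for k in adj if isinstance(k, str))
    return PhyloTree(labels=labels, adj=adj, lengths=lengths)


def _unit_ok(dna: str, index: int) -> bool:
    """Purifying-selection filter: scaffold intact, no stop codons."""
    aa = translate_unit(dna)
    if "*" in aa:
        return False
    has_anchor = C2H2_PATTERN.search(aa) is not None
    return not has_anchor if index == 0 else has_anchor


def _mutate_branch(
    units: list[str], t: float, params: SimParams, rng: random.Random,
    branch: str, events: list[dict],
) -> list[str]:
    units = list(units)
    # --- unit duplications / contractions: Gillespie along the branch ---
    clock = 0.0
    while True:
        eligible = len(units) - 1  # the first unit is never copied or deleted
        rate_dup = params.lambda_dup * eligible if len(units) < params.max_units else 0.0
        rate_con = params.lambda_con * eligible if len(units) > params.min_units else 0.0
        total = rate_dup + rate_con
        if total == 0.0:
            break
        clock += rng.expovariate(total)
        if clock >= t:
            break
        src = rng.randrange(1, len(units))
        if rng.random() < rate_dup / total:
            units.insert(src + 1, units[src])  # exact tandem copy
            events.append({"branch": branch, "type": "dup", "source": src})
        else:
            events.append({"branch": branch, "type": "con", "source": src})
            del units[src]
    # --- point mutations, contact codons accelerated ---
    for ui, dna in enumerate(units):
        site_list = list(dna)
        changed = False
        contacts = set(CONTACT_NT_IDX) if ui > 0 else set()
        for pos in range(len(dna)):
            rate = params.mu_site * (
                params.contact_multiplier if pos in contacts else 1.0
            )
            k = _poisson(rate * t, rng)
            for _ in range(k):
                old = site_list[pos]
                new = rng.choice([b for b in "ACGT" if b != old])
                site_list[pos] = new
                cand = "".join(site_list)
                if _unit_ok(cand, ui):
                    changed = True
                    events.append(
                        {
                            "branch": branch, "type": "sub", "unit": ui,
                            "site": pos, "from": old, "to": new,
                            "contact": pos in contacts,
                        }
                    )
                else:
                    site_list[pos] = old  # rejected by purifying selection
        if changed:
            units[ui] = "".join(site_list)
    return units


def _poisson(lam: float, rng: random.Random) -> int:
    if lam <= 0:
        return 0
    # inversion by sequential search; lam is small per site
    L = 2.718281828459045 ** (-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def simulate_arrays(
    params: SimParams, root_allele: ZnfAllele | None = None
) -> ArraySimResult:
    """Evolve a root ZnF array along a simulated Yule tree.

    Along each branch, unit duplications (an exact adjacent copy of a
    uniformly chosen unit) and contractions are drawn by a Gillespie walk at
    per-unit rates, respecting the min/max unit counts and never touching
    the first-position unit; point substitutions then accrue per site, with
    the contact codons accelerated and substitutions that would break the
    C2H2 scaffold or create a stop codon rejected. Leaf alleles, the true
    tree and the full event log are returned; everything derives from
    ``params.seed``.
    """
    rng = random.Random(params.seed)
    if root_allele is None:
        root_allele = default_root_allele()
    tree = treesim.birth_death_tree(
        birth_rate=params.birth_rate,
        death_rate=0.0,
        num_extant_tips=params.n_leaves,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i + 1}"

    events: list[dict] = []
    alleles: list[ZnfAllele] = []
    state = {tree.seed_node: [u.dna for u in root_allele.units]}
    n_internal = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_units = state[node.parent_node]
        if node.is_leaf():
            label = node.taxon.label
        else:
            n_internal += 1
            label = f"internal{n_internal}"
        units = _mutate_branch(
            parent_units, node.edge.length or 0.0, params, rng, label, events
        )
        state[node] = units
        if node.is_leaf():
            alleles.append(
                allele_from_dna(
                    "".join(units), node.taxon.label,
                    taxon="synthetic", locality="sim", source="synthetic",
                )
            )
    alleles.sort(key=lambda a: a.allele_id)
    return ArraySimResult(
        tree=_dendropy_to_phylotree(tree),
        newick=tree.as_string(schema="newick", suppress_rooting=True).strip(),
        alleles=alleles,
        events=events,
    )


# ---------------------------------------------------------------------------
# Genotype cohorts under Hardy-Weinberg proportions
# ---------------------------------------------------------------------------

def sample_genotypes(
    allele_freqs: Mapping[int, float],
    n_individuals: int,
    seed: int | None = None,
    taxon: str = "synthetic",
    locality: str = "sim",
    source: str = "field",
) -> list[GenotypeRecord]:
    """Draw two repeat-number alleles i.i.d. per individual."""
    total = sum(allele_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {total}, not 1")
    rng = random.Random(seed)
    sizes = sorted(allele_freqs)
    weights = [allele_freqs[s] for s in sizes]
    records = []
    for i in range(n_individuals):
        a1, a2 = rng.choices(sizes, weights=weights, k=2)
        records.append(
            GenotypeRecord(
                individual_id=f"ind{i + 1:05d}",
                taxon=taxon,
                locality=locality,
                source=source,
                allele_sizes=(a1, a2),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Synthetic genomes with planted repeats and motif occurrences
# ---------------------------------------------------------------------------

@dataclass
class PlantedRepeat:
    family: str
    subfamily: str
    start: int
    end: int
    composition: tuple[float, float, float, float] | None = None


@dataclass
class PlantedMotif:
    allele_id: str
    position: int
    word: str


def synth_genome(
    length: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    repeat_spec: Sequence[PlantedRepeat] = (),
    planted_motifs: Sequence[PlantedMotif] = (),
    seed: int | None = None,
    chrom: str = "chrS",
) -> tuple[dict[str, str], RepeatAnnotation, list[dict]]:
    """An i.i.d. background genome with labeled repeats and planted motifs.

    Repeat intervals get their own base sub-composition when given; exact
    motif words overwrite the sequence at the truth positions. Planted
    intervals must not overlap. Returns the genome, the BED-style repeat
    annotation and a truth table of the planted motif positions.
    """
    ivs = sorted(
        [(r.start, r.end) for r in repeat_spec]
        + [(m.position, m.position + len(m.word)) for m in planted_motifs]
    )
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError("planted intervals overlap")
    if ivs and (ivs[0][0] < 0 or ivs[-1][1] > length):
        raise ValueError("planted interval outside the genome")

    rng = random.Random(seed)
    seq = rng.choices("ACGT", weights=base_composition, k=length)
    for r in repeat_spec:
        comp = r.composition or tuple(base_composition)
        seq[r.start : r.end] = rng.choices("ACGT", weights=comp, k=r.end - r.start)
    truth = []
    for m in planted_motifs:
        seq[m.position : m.position + len(m.word)] = list(m.word.upper())
        truth.append(
            {
                "allele_id": m.allele_id, "chrom": chrom,
                "start": m.position, "end": m.position + len(m.word),
                "word": m.word.upper(),
            }
        )
    annotation = RepeatAnnotation(
        intervals=[(chrom, r.start, r.end, r.family, r.subfamily) for r in repeat_spec]
    )
    return {chrom: "".join(seq)}, annotation, truth


def write_repeat_bed(annotation: RepeatAnnotation, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, fam, sub in annotation.intervals:
            name = f"{fam}/{sub}" if sub else fam
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t+\n")


def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
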