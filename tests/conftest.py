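"""Shared builders: hand-made units/alleles and random additive trees."""

from __future__ import annotations

import random

import pytest

from znfarray import phylo
from znfarray.arrays import allele_from_dna
from znfarray.synthetic import (
    CONSENSUS_UNIT_AA,
    CONTACT_AA_IDX,
    FIRST_UNIT_AA,
    _aa_to_dna,
)


def make_unit_dna(triplet: str = "QNK", aa_edits: dict[int, str] | None = None) -> str:
    """84-nt functional unit with the given contact triplet and extra edits."""
    aa = list(CONSENSUS_UNIT_AA)
    for pos, res in zip(CONTACT_AA_IDX, triplet):
        aa[pos] = res
    for pos, res in (aa_edits or {}).items():
        aa[pos] = res
    return _aa_to_dna("".join(aa))


def make_allele(triplets, allele_id="a1", taxon="tax", first=True, stop=False):
    """Allele from contact triplets, with optional first/stop flanking units."""
    units = []
    if first:
        units.append(_aa_to_dna(FIRST_UNIT_AA))
    units += [make_unit_dna(t) for t in triplets]
    if stop:
        stop_aa = CONSENSUS_UNIT_AA[:-1]
        dna = _aa_to_dna(stop_aa) + "TAA"
        units.append(dna)
    return allele_from_dna("".join(units), allele_id, taxon=taxon, locality="loc")


@pytest.fixture
def unit_factory():
    return make_unit_dna


@pytest.fixture
def allele_factory():
    return make_allele


def random_additive_tree(n: int, seed: int) -> phylo.PhyloTree:
    """Random unrooted binary tree with branch lengths in [0.5, 3]."""
    rng = random.Random(seed)
    adj: dict = {0: []}
    labels = [f"t{i}" for i in range(n)]
    for leaf in labels[:3]:
        adj[0].append(leaf)
        adj[leaf] = [0]
    nxt = 1
    for leaf in labels[3:]:
        edges = sorted(
            {frozenset((u, v)) for u in adj for v in adj[u]},
            key=lambda e: sorted(map(str, e)),
        )
        u, v = tuple(rng.choice(edges))
        w = nxt
        nxt += 1
        adj[u] = [x if x != v else w for x in adj[u]]
        adj[v] = [x if x != u else w for x in adj[v]]
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    edges = sorted(
        {frozenset((u, v)) for u in adj for v in adj[u]},
        key=lambda e: sorted(map(str, e)),
    )
    lengths = {e: rng.uniform(0.5, 3.0) for e in edges}
    return phylo.PhyloTree(labels=labels, adj=adj, lengths=lengths)


@pytest.fixture
def additive_tree():
    return random_additive_tree
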