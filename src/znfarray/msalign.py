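"""Optimal alignment of two alleles as sequences of repeat units.

An allele is compared to another as an ordered sequence of unit identifiers
under three event types: changing one unit into another (mutation, cost
M[u][v] from the scaled unit-distance matrix), duplicating a unit in tandem
(amplification, cost A plus the divergence of the new copy from its better
sequence-adjacent neighbor), and deleting a unit in tandem (contraction,
cost C plus the symmetric neighbor term). With A = C the resulting score is
symmetric. Because the indel cost of a unit depends on its neighbors, the
score is not guaranteed to satisfy the triangle inequality; downstream tree
building must not assume metricity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .unitdist import PenaltyConfig

MATCH = "match"
AMPLIFY = "amplify"
CONTRACT = "contract"


@dataclass(frozen=True)
class AlignmentEvent:
    kind: str  # match | amplify | contract
    i: int | None  # position in x (None for amplify)
    j: int | None  # position in y (None for contract)
    source: int | None  # neighbor position the duplicated/contracted copy maps to
    cost: int


@dataclass
class AlleleAlignment:
    score: int
    script: list[AlignmentEvent]


@dataclass
class AlleleDistanceMatrix:
    allele_ids: list[str]
    D_align: np.ndarray  # symmetric non-negative integers


def _indel_costs(
    seq: Sequence[str], pc: PenaltyConfig, base: int
) -> tuple[list[int], list[int | None]]:
    """Static unmatched-unit cost per position of ``seq``.

    Cost = base penalty + divergence from the cheaper sequence-adjacent
    neighbor (tandem duplication source). Boundary units use their single
    neighbor; a lone unit uses itself (zero divergence).
    """
    costs: list[int] = []
    sources: list[int | None] = []
    n = len(seq)
    for j, u in enumerate(seq):
        if pc.indel_model == "flat":
            costs.append(base)
            sources.append(None)
            continue
        cand: list[tuple[int, int]] = []
        if j > 0:
            cand.append((pc.mut(seq[j - 1], u), j - 1))
        if j < n - 1:
            cand.append((pc.mut(seq[j + 1], u), j + 1))
        if not cand:
            cand = [(0, j)]
        c, s = min(cand)
        costs.append(base + c)
        sources.append(s)
    return costs, sources


def align_arrays(
    x: Sequence[str], y: Sequence[str], pc: PenaltyConfig
) -> AlleleAlignment:
    """Minimum-cost alignment of unit-id sequences x and y.

    Dynamic programming over (i, j) with three moves (match / contract a unit
    of x / amplify a unit of y); ties break toward match, then contract, then
    amplify for a deterministic script. The score is exact for this integer
    cost model.
    """
    if len(x) < 1 or len(y) < 1:
        raise ValueError("alleles must have at least one unit")
    for u in list(x) + list(y):
        if u not in pc:
            raise KeyError(f"unknown unit id {u!r} (not in penalty matrix)")

    nx, ny = len(x), len(y)
    del_cost, del_src = _indel_costs(x, pc, pc.C)  # unmatched unit of x
    ins_cost, ins_src = _indel_costs(y, pc, pc.A)  # unmatched unit of y

    INF = np.iinfo(np.int64).max // 4
    S = np.full((nx + 1, ny + 1), INF, dtype=np.int64)
    S[0, 0] = 0
    for i in range(1, nx + 1):
        S[i, 0] = S[i - 1, 0] + del_cost[i - 1]
    for j in range(1, ny + 1):
        S[0, j] = S[0, j - 1] + ins_cost[j - 1]
    for i in range(1, nx + 1):
        mrow = [pc.mut(x[i - 1], v) for v in y]
        for j in range(1, ny + 1):
            S[i, j] = min(
                S[i - 1, j - 1] + mrow[j - 1],
                S[i - 1, j] + del_cost[i - 1],
                S[i, j - 1] + ins_cost[j - 1],
            )

    # traceback, preferring match > contract > amplify on ties
    script: list[AlignmentEvent] = []
    i, j = nx, ny
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + pc.mut(x[i - 1], y[j - 1]):
            script.append(
                AlignmentEvent(MATCH, i - 1, j - 1, None, pc.mut(x[i - 1], y[j - 1]))
            )
            i, j = i - 1, j - 1
        elif i > 0 and S[i, j] == S[i - 1, j] + del_cost[i - 1]:
            script.append(
                AlignmentEvent(CONTRACT, i - 1, None, del_src[i - 1], del_cost[i - 1])
            )
            i -= 1
        else:
            script.append(
                AlignmentEvent(AMPLIFY, None, j - 1, ins_src[j - 1], ins_cost[j - 1])
            )
            j -= 1
    script.reverse()
    return AlleleAlignment(score=int(S[nx, ny]), script=script)


def allele_distance_matrix(
    alleles: Sequence, pc: PenaltyConfig, unit_key=None
) -> AlleleDistanceMatrix:
    """All-against-all alignment scores between alleles.

    ``alleles`` may be ZnfAllele objects (unit ids default to the unit DNA
    sequences, which must index the penalty matrix) or (allele_id, unit-id
    sequence) pairs. First-position and stop-codon units align like any
    other: they carry their own rows in M.
    """
    if len(alleles) < 3:
        raise ValueError("need at least 3 alleles for a distance matrix")
    ids: list[str] = []
    seqs: list[list[str]] = []
    for a in alleles:
        if isinstance(a, tuple):
            aid, seq = a
        else:
            aid = a.allele_id
            seq = [unit_key(u) if unit_key else u.dna for u in a.units]
        ids.append(aid)
        seqs.append(list(seq))
    n = len(ids)
    D = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = align_arrays(seqs[i], seqs[j], pc).score
    return AlleleDistanceMatrix(allele_ids=ids, D_align=D)


def write_phylip(dm: AlleleDistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.allele_ids)}\n")
        for name, row in zip(dm.allele_ids, dm.D_align):
            fh.write(name + "  " + " ".join(str(int(v)) for v in row) + "\n")


def write_tsv(dm: AlleleDistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["allele"] + dm.allele_ids) + "\n")
        for name, row in zip(dm.allele_ids, dm.D_align):
            fh.write("\t".join([name] + [str(int(v)) for v in row]) + "\n")
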