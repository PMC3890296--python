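"""Evolutionary distances between individual repeat units and penalty scaling.

The distinct repeat units of a ZnF-array dataset fall into two well separated
groups: the units found at the first array position (non-finger, one of them
carrying a 9-bp deletion) and all the others. Within the first-position group
a Jukes-Cantor distance fits; within the main group a Kimura two-parameter
distance with gamma-distributed rate heterogeneity across sites (shape
alpha = 0.31286 by default) fits best. The resulting unit-by-unit distance
matrix, multiplied by a fixed coefficient and rounded to integers, supplies
the mutation penalties M of the duplication/contraction alignment model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .arrays import FIRST_POSITION, SHORT_UNIT_NT, UNIT_NT, RepeatUnit

DEFAULT_ALPHA = 0.31286  # gamma shape for the K2P+gamma model
DEFAULT_COEFFICIENT = 1000.0
DEFAULT_A = 1
DEFAULT_C = 1

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Observed divergence too high for the distance formula to be finite."""


def _gap_alignment(short: str, full: str) -> list[tuple[str, str]]:
    """Best end-to-end alignment of a 75-nt unit against an 84-nt unit.

    The 9-bp deletion is placed as one contiguous gap at the offset that
    maximizes matches; ties resolve to the leftmost offset, deterministically.
    Returns the 75 aligned site pairs (gap columns dropped).
    """
    best_off, best_mm = 0, None
    for off in range(len(short) + 1):
        aligned = full[:off] + full[off + 9 :]
        mm = sum(a != b for a, b in zip(short, aligned))
        if best_mm is None or mm < best_mm:
            best_off, best_mm = off, mm
    aligned = full[:best_off] + full[best_off + 9 :]
    return list(zip(short, aligned))


def _site_pairs(u: str, v: str) -> tuple[list[tuple[str, str]], bool]:
    """Aligned site pairs for two units plus a flag for the one-sided deletion."""
    u, v = u.upper(), v.upper()
    if len(u) == len(v):
        return list(zip(u, v)), False
    short, full = (u, v) if len(u) < len(v) else (v, u)
    if len(short) != SHORT_UNIT_NT or len(full) != UNIT_NT:
        raise ValueError(f"cannot align unit lengths {len(u)} and {len(v)}")
    return _gap_alignment(short, full), True


def jc_distance(u: str, v: str) -> float:
    """Jukes-Cantor distance between two repeat units, in substitutions/site.

    The 9-bp deletion distinguishing the 75-nt first-position unit counts as
    a single mutation, over a fixed denominator of 84 sites.
    """
    pairs, one_deleted = _site_pairs(u, v)
    diffs = sum(a != b for a, b in pairs)
    if one_deleted:
        diffs += 1
        denom = UNIT_NT
    else:
        denom = len(pairs)
    p = diffs / denom
    if p >= 0.75:
        raise SaturationError(f"proportion of differences p={p:.3f} >= 3/4")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _transition_transversion(pairs: Sequence[tuple[str, str]]) -> tuple[float, float]:
    n = len(pairs)
    ts = sum((a, b) in _TRANSITIONS for a, b in pairs)
    tv = sum(a != b and (a, b) not in _TRANSITIONS for a, b in pairs)
    return ts / n, tv / n


def k2p_gamma_distance(u: str, v: str, alpha: float = DEFAULT_ALPHA) -> float:
    """Kimura two-parameter distance with gamma rate heterogeneity.

    d = (alpha/2) * [(1-2P-Q)^(-1/alpha) - 1] + (alpha/4) * [(1-2Q)^(-1/alpha) - 1]

    where P and Q are the observed transition and transversion proportions.
    When units of unequal length are compared (the first-position 75-nt unit
    against an 84-nt unit) the gap-free aligned portion is used.
    """
    pairs, _ = _site_pairs(u, v)
    P, Q = _transition_transversion(pairs)
    return k2p_gamma_from_pq(P, Q, alpha)


def k2p_gamma_from_pq(P: float, Q: float, alpha: float) -> float:
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(
            f"K2P arguments non-positive (1-2P-Q={a1:.3f}, 1-2Q={a2:.3f})"
        )
    return (alpha / 2.0) * (a1 ** (-1.0 / alpha) - 1.0) + (alpha / 4.0) * (
        a2 ** (-1.0 / alpha) - 1.0
    )


def k2p_distance(u: str, v: str) -> float:
    """Plain Kimura two-parameter distance (no rate heterogeneity)."""
    pairs, _ = _site_pairs(u, v)
    P, Q = _transition_transversion(pairs)
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError("K2P log arguments non-positive")
    return 0.5 * math.log(1.0 / a1) + 0.25 * math.log(1.0 / a2)


@dataclass
class UnitDistanceMatrix:
    """Pairwise distances between the distinct repeat units of a dataset."""

    unit_ids: list[str]
    seqs: list[str]
    group: list[str]  # per unit: first_position | other
    d: np.ndarray

    def id_of(self, seq: str) -> str:
        return self.unit_ids[self.seqs.index(seq)]


@dataclass
class PenaltyConfig:
    """Integer alignment costs: mutation matrix M plus indel penalties A, C."""

    unit_ids: list[str]
    M: np.ndarray  # integer, symmetric, zero diagonal
    A: int = DEFAULT_A
    C: int = DEFAULT_C
    coefficient: float = DEFAULT_COEFFICIENT
    indel_model: str = "neighbor_mutation"  # or "flat"

    def __post_init__(self) -> None:
        self._index = {u: i for i, u in enumerate(self.unit_ids)}

    def mut(self, u: str, v: str) -> int:
        try:
            return int(self.M[self._index[u], self._index[v]])
        except KeyError as exc:
            raise KeyError(f"unknown unit id {exc.args[0]!r}") from None

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._index


def build_unit_distance_matrix(
    units: Sequence[RepeatUnit], alpha: float = DEFAULT_ALPHA
) -> UnitDistanceMatrix:
    """Distance matrix over the distinct unit DNA sequences of a dataset.

    Within the first-position group the JC distance is used, within the main
    group K2P+gamma; cross-group entries use K2P+gamma on the gap-free
    aligned portion and are floored at the maximum within-group distance, so
    the two groups stay separated whatever the raw value.
    """
    seen: dict[str, str] = {}
    for u in units:
        grp = FIRST_POSITION if u.unit_class == FIRST_POSITION else "other"
        if u.dna in seen:
            if seen[u.dna] != grp:
                raise ValueError(
                    f"unit sequence occurs in both groups: {u.dna[:20]}..."
                )
        else:
            seen[u.dna] = grp
    seqs = sorted(seen)
    groups = [seen[s] for s in seqs]
    ids = [f"U{i:04d}" for i in range(len(seqs))]
    n = len(seqs)
    d = np.zeros((n, n))
    cross: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[i], groups[j]
            try:
                if gi == gj == FIRST_POSITION:
                    val = jc_distance(seqs[i], seqs[j])
                else:
                    val = k2p_gamma_distance(seqs[i], seqs[j], alpha)
            except SaturationError as exc:
                raise SaturationError(
                    f"saturated pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = val
            if gi != gj:
                cross.append((i, j))
    if cross:
        within_max = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if groups[i] == groups[j]:
                    within_max = max(within_max, d[i, j])
        for i, j in cross:
            if d[i, j] < within_max:
                d[i, j] = d[j, i] = within_max
    return UnitDistanceMatrix(unit_ids=ids, seqs=seqs, group=groups, d=d)


def scale_to_penalties(
    dm: UnitDistanceMatrix,
    coefficient: float = DEFAULT_COEFFICIENT,
    A: int = DEFAULT_A,
    C: int = DEFAULT_C,
    indel_model: str = "neighbor_mutation",
) -> PenaltyConfig:
    """Scale distances by ``coefficient`` and round half-up to integer penalties."""
    if coefficient <= 0:
        raise ValueError("coefficient must be positive")
    M = np.floor(coefficient * dm.d + 0.5).astype(int)
    np.fill_diagonal(M, 0)
    return PenaltyConfig(
        unit_ids=list(dm.unit_ids), M=M, A=A, C=C,
        coefficient=coefficient, indel_model=indel_model,
    )


def write_penalties_tsv(pc: PenaltyConfig, path) -> None:
    """TSV matrix with a 2-line header recording A, C and the coefficient."""
    with open(path, "w") as fh:
        fh.write(f"#A={pc.A}\tC={pc.C}\n")
        fh.write(f"#coefficient={pc.coefficient}\tindel_model={pc.indel_model}\n")
        fh.write("\t".join(["unit"] + pc.unit_ids) + "\n")
        for i, u in enumerate(pc.unit_ids):
            fh.write("\t".join([u] + [str(int(x)) for x in pc.M[i]]) + "\n")


def read_penalties_tsv(path) -> PenaltyConfig:
    with open(path) as fh:
        head1 = dict(kv.lstrip("#").split("=") for kv in fh.readline().split())
        head2 = dict(kv.lstrip("#").split("=") for kv in fh.readline().split())
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
    M = np.array(rows, dtype=int)
    return PenaltyConfig(
        unit_ids=ids, M=M, A=int(head1["A"]), C=int(head1["C"]),
        coefficient=float(head2["coefficient"]),
        indel_model=head2.get("indel_model", "neighbor_mutation"),
    )


def fit_alpha(
    units: Sequence[RepeatUnit], bounds: tuple[float, float] = (0.01, 10.0)
) -> float:
    """Maximum-likelihood gamma shape for rate heterogeneity across unit sites.

    Per-site substitution heterogeneity is estimated from the distribution of
    pairwise difference counts per alignment column across all equal-length
    distinct units: a gamma-distributed site rate makes the column counts
    negative-binomial, whose shape parameter is the gamma shape alpha. This is
    an auxiliary re-fit; the pipeline default alpha is a configuration
    constant.
    """
    seqs = sorted({u.dna for u in units if len(u.dna) == UNIT_NT})
    if len(seqs) < 3:
        raise ValueError("need >= 3 distinct equal-length units to fit alpha")
    arr = np.array([list(s) for s in seqs])
    n_pairs = len(seqs) * (len(seqs) - 1) // 2
    counts = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        col = arr[:, j]
        _, c = np.unique(col, return_counts=True)
        same = (c * (c - 1) // 2).sum()
        counts[j] = n_pairs - same
    mean = counts.mean()
    if mean == 0:
        raise ValueError("no variation among units; alpha is unidentifiable")

    def nll(log_a: float) -> float:
        a = math.exp(log_a)
        p = a / (a + mean)
        from scipy.stats import nbinom

        return -nbinom.logpmf(counts, a, p).sum()

    res = minimize_scalar(
        nll, bounds=(math.log(bounds[0]), math.log(bounds[1])), method="bounded"
    )
    return float(math.exp(res.x))
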