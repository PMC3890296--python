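"""Genome scanning with predicted binding-site matrices and overlap analytics.

Each allele's predicted DNA recognition motif (a position weight matrix of
length 3x the number of functional fingers, produced by an external
ZnF-to-motif predictor) is scanned gaplessly along both strands of a genome
at a p-value-derived log-odds threshold. Hits are merged into maximal
intervals; pairs of alleles are compared by the coverage overlap distance
D = 1 - intersection/union (in bp), clustered by neighbor joining, and the
partition of repeat-overlapping hit coverage among repeat families feeds a
principal component analysis over alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .msalign import AlleleDistanceMatrix
from . import phylo

BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
DEFAULT_GRANULARITY = 0.001  # bits per integer score unit
DEFAULT_FLOOR_BITS = -30.0  # per-position log-odds floor for zero probabilities
DEFAULT_PVALUE = 1e-4
LOG_EPS = 1e-6  # pseudocount distance before log-transforming D


class GenomeMismatchError(ValueError):
    pass


class UndefinedDistanceError(ValueError):
    pass


class ZeroVarianceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Per-allele position weight matrix over ACGT (rows sum to 1)."""

    allele_id: str
    matrix: np.ndarray  # L x 4 base probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        L = len(self.matrix)
        if L < 6:
            raise ValueError(f"PWM length {L} < 6 (need >= 2 fingers)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return len(self.matrix)


def read_pwm(path, allele_id: str | None = None) -> Pwm:
    """Read a PWM from a tab-separated matrix, or a MEME-like motif block.

    The minimal format is one line per position with 4 probabilities
    (optional ``#`` comments and an optional ``>name`` header); a block
    starting with ``letter-probability matrix`` (MEME dialect) is also
    accepted.
    """
    name = allele_id
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                name = name or line[1:].split()[0]
                continue
            if line.lower().startswith(("meme", "alphabet", "strands",
                                        "background", "motif",
                                        "letter-probability")):
                if line.lower().startswith("motif") and name is None:
                    parts = line.split()
                    if len(parts) > 1:
                        name = parts[1]
                continue
            rows.append([float(x) for x in line.split()])
    return Pwm(allele_id=name or "pwm", matrix=np.array(rows))


def write_pwm(pwm: Pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.allele_id}\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def estimate_background(genome: Mapping[str, str]) -> np.ndarray:
    """0-order base composition of the scanned genome."""
    counts = np.zeros(4)
    for seq in genome.values():
        s = seq.upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Score threshold from the exact null score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreThreshold:
    """Integer-discretized log-odds threshold and its attained p-value."""

    threshold: int  # in granularity units
    attained_p: float
    unattainable: bool
    granularity: float
    background: np.ndarray
    lo_int: np.ndarray  # L x 4 integer log-odds, shared by the scanner
    floor_bits: float = DEFAULT_FLOOR_BITS

    @property
    def threshold_bits(self) -> float:
        return self.threshold * self.granularity


def _logodds_int(
    pwm: Pwm,
    background: np.ndarray,
    granularity: float = DEFAULT_GRANULARITY,
    floor_bits: float = DEFAULT_FLOOR_BITS,
) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        bits = np.log2(pwm.matrix / bg)
    bits = np.maximum(bits, floor_bits)
    return np.round(bits / granularity).astype(np.int64)


def score_threshold(
    pwm: Pwm,
    background: np.ndarray | Sequence[float],
    pvalue: float = DEFAULT_PVALUE,
    granularity: float = DEFAULT_GRANULARITY,
    floor_bits: float = DEFAULT_FLOOR_BITS,
) -> ScoreThreshold:
    """Smallest integer score t with P(score >= t) <= pvalue under background.

    The null distribution of the integer-discretized log-odds score is
    computed exactly by position-wise convolution under the 0-order
    background. When the requested p-value lies below the resolution of the
    null distribution the maximal score is returned with a warning flag.
    """
    if not 0 < pvalue < 1:
        if pvalue == 1.0:
            lo = _logodds_int(pwm, background, granularity, floor_bits)
            return ScoreThreshold(int(lo.min(axis=1).sum()), 1.0, False,
                                  granularity, np.asarray(background, float),
                                  lo, floor_bits)
        raise ValueError("pvalue must lie in (0, 1]")
    bg = np.asarray(background, dtype=float)
    lo = _logodds_int(pwm, bg, granularity, floor_bits)
    cur = np.array([1.0])
    cur_lo = 0
    for k in range(len(lo)):
        deltas = lo[k]
        new_lo = cur_lo + int(deltas.min())
        new_hi = cur_lo + len(cur) - 1 + int(deltas.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(deltas[b]) - new_lo
            new[off : off + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]  # tail[i] = P(score >= cur_lo + i)
    ok = np.nonzero(tail <= pvalue)[0]
    if len(ok) == 0:
        return ScoreThreshold(
            threshold=cur_lo + len(cur) - 1,
            attained_p=float(tail[-1]),
            unattainable=True,
            granularity=granularity, background=bg, lo_int=lo,
            floor_bits=floor_bits,
        )
    i = int(ok[0])
    return ScoreThreshold(
        threshold=cur_lo + i,
        attained_p=float(tail[i]),
        unattainable=False,
        granularity=granularity, background=bg, lo_int=lo,
        floor_bits=floor_bits,
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass
class HitSet:
    """Merged genomic intervals where an allele's PWM scan passes threshold."""

    allele_id: str
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    genome_id: str = ""

    def coverage(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, lo: np.ndarray, floor_int: int) -> np.ndarray:
    L = len(lo)
    n = len(enc) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    lo5 = np.column_stack([lo, np.full(L, floor_int, dtype=np.int64)])
    scores = np.zeros(n, dtype=np.int64)
    for k in range(L):
        scores += lo5[k, enc[k : k + n]]
    return scores


def scan_windows(
    seq: str, thr: ScoreThreshold
) -> list[tuple[int, str, int]]:
    """Raw (unmerged) windows passing threshold on either strand.

    Returns (start, strand, score) triples in forward-strand coordinates;
    each window covers [start, start + L). Reverse-strand windows are scored
    by scanning with the reverse-complemented matrix.
    """
    enc = _encode(seq)
    floor_int = int(np.round(thr.floor_bits / thr.granularity))
    lo = thr.lo_int
    rc = np.array([[lo[len(lo) - 1 - k, _COMP[b]] for b in range(4)]
                   for k in range(len(lo))], dtype=np.int64)
    out = []
    for strand, mat in (("+", lo), ("-", rc)):
        scores = _window_scores(enc, mat, floor_int)
        for p in np.nonzero(scores >= thr.threshold)[0]:
            out.append((int(p), strand, int(scores[p])))
    out.sort()
    return out


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge overlapping or touching half-open intervals, per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def scan_genome(
    pwm: Pwm,
    genome: Mapping[str, str],
    thr: ScoreThreshold,
    genome_id: str = "",
) -> HitSet:
    """Gapless both-strand scan of a genome; hits merged into maximal intervals.

    Contigs shorter than the motif contribute no hits. Both strands are
    projected to forward coordinates before merging (coverage is strandless).
    """
    L = len(pwm)
    intervals = []
    for chrom in sorted(genome):
        for start, _strand, _score in scan_windows(genome[chrom], thr):
            intervals.append((chrom, start, start + L))
    return HitSet(
        allele_id=pwm.allele_id,
        intervals=merge_intervals(intervals),
        genome_id=genome_id,
    )


# ---------------------------------------------------------------------------
# Overlap distance and clustering
# ---------------------------------------------------------------------------

def _intersection_bp(
    a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]
) -> int:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in b:
        by_chrom.setdefault(chrom, []).append((s, e))
    total = 0
    for chrom, s, e in a:
        for s2, e2 in by_chrom.get(chrom, ()):
            total += max(0, min(e, e2) - max(s, s2))
    return total


def overlap_distance(h1: HitSet, h2: HitSet) -> float | None:
    """D = 1 - intersection/union of the two hit coverages, in bp.

    Returns None (undefined) when both hit sets are empty; raises on a
    genome identifier mismatch.
    """
    if h1.genome_id != h2.genome_id:
        raise GenomeMismatchError(
            f"hit sets from different genomes: {h1.genome_id!r} vs {h2.genome_id!r}"
        )
    c1, c2 = h1.coverage(), h2.coverage()
    if c1 == 0 and c2 == 0:
        return None
    inter = _intersection_bp(h1.intervals, h2.intervals)
    union = c1 + c2 - inter
    return 1.0 - inter / union


def hit_distance_tree(
    hitsets: Sequence[HitSet],
    log_transform: bool = False,
    eps: float = LOG_EPS,
) -> tuple[phylo.PhyloTree, AlleleDistanceMatrix]:
    """Neighbor-joining clustering of alleles from the D matrix.

    With ``log_transform`` the matrix entries become log(D + eps) shifted to
    be non-negative (the pseudocount guards log of zero distances).
    """
    ids = [h.allele_id for h in hitsets]
    n = len(ids)
    D = np.zeros((n, n))
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            d = overlap_distance(hitsets[i], hitsets[j])
            if d is None:
                bad.append((ids[i], ids[j]))
            else:
                D[i, j] = D[j, i] = d
    if bad:
        raise UndefinedDistanceError(
            f"overlap distance undefined (both hit sets empty) for pairs: {bad}"
        )
    if log_transform:
        off = ~np.eye(n, dtype=bool)
        logs = np.log(D[off] + eps)
        D[off] = logs - logs.min()
    dm = AlleleDistanceMatrix(allele_ids=ids, D_align=D)
    return phylo.build_tree(dm, method="nj"), dm


# ---------------------------------------------------------------------------
# Repeat-family composition
# ---------------------------------------------------------------------------

@dataclass
class RepeatAnnotation:
    """Labeled repeat-element intervals (family/subfamily) on a genome."""

    intervals: list[tuple[str, int, int, str, str]]  # chrom, start, end, family, sub


def read_repeat_bed(path) -> RepeatAnnotation:
    """BED6 with the name field carrying ``family/subfamily``."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            fam, _, sub = f[3].partition("/")
            if not fam:
                raise ValueError(f"empty family label in BED line: {line!r}")
            out.append((f[0], int(f[1]), int(f[2]), fam, sub))
    return RepeatAnnotation(intervals=out)


def read_repeatmasker_out(path) -> RepeatAnnotation:
    """RepeatMasker .out table (1-based inclusive coordinates)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].isdigit():
                continue
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            fam, _, sub = parts[10].partition("/")
            out.append((chrom, begin - 1, end, fam, sub))
    return RepeatAnnotation(intervals=out)


def repeat_family_coverage(
    hitset: HitSet, annotation: RepeatAnnotation, motif_length: int
) -> tuple[float, dict[str, float]]:
    """Partition of a hit set's repeat-overlapping coverage among families.

    A (hit, element) overlap counts toward the element's family only when it
    spans at least ``motif_length`` bp (the full predicted motif). Returns
    the fraction of total hit coverage in qualifying repeat overlaps and the
    per-family proportions of that qualifying coverage.
    """
    fam_bp: dict[str, int] = {}
    for chrom, s, e in hitset.intervals:
        for c2, s2, e2, fam, _sub in annotation.intervals:
            if c2 != chrom:
                continue
            ov = min(e, e2) - max(s, s2)
            if ov >= motif_length:
                fam_bp[fam] = fam_bp.get(fam, 0) + ov
    total_cov = hitset.coverage()
    qual = sum(fam_bp.values())
    fraction = qual / total_cov if total_cov else 0.0
    proportions = {f: bp / qual for f, bp in sorted(fam_bp.items())} if qual else {}
    return fraction, proportions


def build_composition_table(
    hitsets: Sequence[HitSet], annotation: RepeatAnnotation, motif_lengths: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.Series]:
    """Allele-by-family proportion table plus per-allele repeat fractions."""
    rows, fracs = {}, {}
    for h in hitsets:
        frac, props = repeat_family_coverage(h, annotation, motif_lengths[h.allele_id])
        rows[h.allele_id] = props
        fracs[h.allele_id] = frac
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    table = table[sorted(table.columns)]
    return table, pd.Series(fracs).sort_index()


@dataclass
class PcaResult:
    scores: pd.DataFrame  # alleles x components
    loadings: pd.DataFrame  # families x components
    variance_fractions: np.ndarray


def pca_composition(table: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Covariance PCA of the composition table (columns centered, not scaled).

    Alleles are observations, repeat families variables; with ``scale`` the
    columns are standardized first (correlation PCA).
    """
    if len(table) < 3 or table.shape[1] < 2:
        raise ValueError("need >= 3 alleles and >= 2 families")
    X = table.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ZeroVarianceError("composition table has zero variance")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=table.columns,
                              columns=comp_names),
        variance_fractions=pca.explained_variance_ratio_,
    )
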