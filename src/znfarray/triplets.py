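"""Contact-residue triplets, common-word search and positional diversity.

Each functional C2H2 finger contacts DNA through the helix residues at
positions -1, 3 and 6 (helix numbering; the first conserved histidine sits at
helix position +7). Reducing every functional unit of an allele to that
triplet captures nearly all of the array's amino-acid variability. Groups of
alleles are then compared by the longest words (contiguous residue runs over
the concatenated triplet strings) shared by at least a quorum of the group,
and by per-position diversity profiles across the 28 codons of the unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import islice
from typing import Mapping, Sequence

import pandas as pd

from .arrays import C2H2_PATTERN, FUNCTIONAL, ZnfAllele

#: helix positions -1, 3, 6 relative to the first conserved His at +7:
#: with the His at unit index h, the contacts sit at h-7, h-4 and h-1.
CONTACT_HIS_OFFSETS = (-7, -4, -1)
UNIT_AA = 28


class TripletExtractionError(ValueError):
    """A unit classified functional does not match the C2H2 anchor."""


@dataclass
class TripletSeq:
    allele_id: str
    triplets: list[str]  # one 3-residue string per functional unit

    def __str__(self) -> str:  # Fig-style dash-separated serialization
        return "-".join(self.triplets)

    @property
    def residues(self) -> str:
        return "".join(self.triplets)


@dataclass
class WordResult:
    length: int  # in amino acids over the concatenated triplet string
    words: set[str]
    quorum_used: float


def contact_positions(aa: str) -> tuple[int, int, int]:
    """0-based indices of the -1/3/6 contact residues within a unit."""
    m = C2H2_PATTERN.search(aa)
    if m is None:
        raise TripletExtractionError(
            f"functional unit does not match the C2H2 anchor: {aa}"
        )
    h = m.start() + 16  # first conserved His of C-x2-C-x12-H-x3-H
    return tuple(h + off for off in CONTACT_HIS_OFFSETS)


def reduce_to_triplets(
    allele: ZnfAllele, contact_offsets: Sequence[int] | None = None
) -> TripletSeq:
    """Contact triplet sequence of an allele's functional units.

    First-position and stop-codon units are excluded. Offsets are anchored on
    the first conserved histidine of each unit unless an explicit 0-based
    ``contact_offsets`` override is given.
    """
    triplets = []
    for unit in allele.units:
        if unit.unit_class != FUNCTIONAL:
            continue
        if contact_offsets is not None:
            pos = tuple(contact_offsets)
        else:
            pos = contact_positions(unit.aa)
        triplets.append("".join(unit.aa[p] for p in pos))
    return TripletSeq(allele_id=allele.allele_id, triplets=triplets)


def _substrings(s: str, length: int) -> set[str]:
    return {s[i : i + length] for i in range(len(s) - length + 1)}


def longest_common_words(
    group: Sequence[TripletSeq], quorum: float = 1.0
) -> WordResult:
    """Longest exact words shared by at least a quorum of a group.

    Words are contiguous residue runs over the concatenated triplet strings
    (lengths are reported in amino acids). No substitutions are allowed; a
    word counts as common when it occurs in at least ceil(quorum * n)
    sequences. All maximal words are returned.
    """
    if not group:
        raise ValueError("group is empty")
    if not 0 < quorum <= 1:
        raise ValueError("quorum must be in (0, 1]")
    import math

    seqs = [t.residues for t in group]
    need = math.ceil(quorum * len(seqs))

    def words_at(length: int) -> set[str]:
        counts: Counter[str] = Counter()
        for s in seqs:
            counts.update(_substrings(s, length))
        return {w for w, c in counts.items() if c >= need}

    lo, hi = 0, max((len(s) for s in seqs), default=0)
    # common-word existence is monotone in length: binary search the maximum
    best = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if mid == 0 or words_at(mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return WordResult(
        length=best,
        words=words_at(best) if best > 0 else set(),
        quorum_used=quorum,
    )


@dataclass
class PositionalDiversity:
    """Per-codon amino-acid frequencies over all functional units."""

    frequencies: pd.DataFrame  # index 0..27, columns amino acids, rows sum to 1
    in_every_allele: dict[int, set[str]]
    rare: dict[int, set[str]]  # < 10% of units at the position

    @property
    def n_variable_positions(self) -> int:
        return int((self.frequencies.gt(0).sum(axis=1) >= 2).sum())


def positional_diversity(alleles: Sequence[ZnfAllele]) -> PositionalDiversity:
    """Amino-acid diversity profile along the 28-residue functional unit."""
    units = [u for a in alleles for u in a.units if u.unit_class == FUNCTIONAL]
    if not units:
        raise ValueError("no functional units among the alleles")
    counts = [Counter() for _ in range(UNIT_AA)]
    for u in units:
        for i, aa in enumerate(islice(u.aa, UNIT_AA)):
            counts[i][aa] += 1
    all_aas = sorted({aa for c in counts for aa in c})
    freq = pd.DataFrame(0.0, index=range(UNIT_AA), columns=all_aas)
    for i, c in enumerate(counts):
        total = sum(c.values())
        for aa, k in c.items():
            freq.loc[i, aa] = k / total
    in_every: dict[int, set[str]] = {}
    rare: dict[int, set[str]] = {}
    for i in range(UNIT_AA):
        per_allele = []
        for a in alleles:
            fus = [u for u in a.units if u.unit_class == FUNCTIONAL]
            per_allele.append({u.aa[i] for u in fus if len(u.aa) > i})
        present_everywhere = set.intersection(*(s for s in per_allele if s)) \
            if any(per_allele) else set()
        in_every[i] = present_everywhere
        rare[i] = {aa for aa in all_aas if 0 < freq.loc[i, aa] < 0.10}
    return PositionalDiversity(frequencies=freq, in_every_allele=in_every, rare=rare)


def znf_variant_spectrum(
    alleles: Sequence[ZnfAllele],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Frequency table of distinct contact triplets per allele group.

    ``groups`` maps a group name to allele_ids; by default alleles group by
    taxon. Within each group every functional unit contributes one triplet;
    frequencies classify as rare [0, 2%), common [2%, 10%] or frequent
    (10%, 100%].
    """
    if groups is None:
        groups = {}
        for a in alleles:
            groups.setdefault(a.taxon, []).append(a.allele_id)
    by_id = {a.allele_id: a for a in alleles}
    rows = []
    for gname in sorted(groups):
        counter: Counter[str] = Counter()
        for aid in groups[gname]:
            counter.update(reduce_to_triplets(by_id[aid]).triplets)
        total = sum(counter.values())
        for trip in sorted(counter):
            f = counter[trip] / total
            if f < 0.02:
                cat = "rare"
            elif f <= 0.10:
                cat = "common"
            else:
                cat = "frequent"
            rows.append(
                {
                    "group": gname,
                    "triplet": trip,
                    "count": counter[trip],
                    "frequency": f,
                    "category": cat,
                }
            )
    return pd.DataFrame(rows)
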