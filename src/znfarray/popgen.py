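"""Repeat-number allele statistics from genotype tables.

PCR genotyping of a ZnF-array minisatellite yields, per individual, a pair
of repeat-number calls (possibly equal). This module computes observed
heterozygosity (fraction of individuals whose two calls differ), expected
heterozygosity under panmixia from the 2N gene copies (Nei's 1 - sum p_i^2,
optionally with the 2N/(2N-1) small-sample correction), and per-taxon
allele-size spectra.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

GENOTYPE_COLUMNS = ["individual", "taxon", "locality", "source", "allele1", "allele2"]


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeRecord:
    individual_id: str
    taxon: str
    locality: str
    source: str  # field | colony
    allele_sizes: tuple[int, int]  # unordered pair of repeat counts

    def __post_init__(self) -> None:
        if min(self.allele_sizes) < 2:
            raise ValueError("repeat counts must be >= 2")

    @property
    def is_heterozygous(self) -> bool:
        return self.allele_sizes[0] != self.allele_sizes[1]


def read_genotypes_csv(path) -> list[GenotypeRecord]:
    df = pd.read_csv(path)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype CSV missing columns {sorted(missing)}")
    return [
        GenotypeRecord(
            individual_id=str(r.individual),
            taxon=str(r.taxon),
            locality=str(r.locality),
            source=str(r.source),
            allele_sizes=(int(r.allele1), int(r.allele2)),
        )
        for r in df.itertuples()
    ]


def write_genotypes_csv(records: Sequence[GenotypeRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "individual": r.individual_id,
                "taxon": r.taxon,
                "locality": r.locality,
                "source": r.source,
                "allele1": r.allele_sizes[0],
                "allele2": r.allele_sizes[1],
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def field_only(records: Sequence[GenotypeRecord]) -> list[GenotypeRecord]:
    """Restrict to mice sampled in the field (colony animals excluded)."""
    return [r for r in records if r.source == "field"]


def observed_heterozygosity(records: Sequence[GenotypeRecord]) -> float:
    """Fraction of individuals whose two repeat-number calls differ."""
    if not records:
        raise UndefinedStatisticError("no genotype records")
    return sum(r.is_heterozygous for r in records) / len(records)


def allele_frequencies(records: Sequence[GenotypeRecord]) -> dict[int, float]:
    counts: Counter[int] = Counter()
    for r in records:
        counts.update(r.allele_sizes)
    total = sum(counts.values())
    return {size: c / total for size, c in sorted(counts.items())}


def expected_heterozygosity(
    records: Sequence[GenotypeRecord], estimator: str = "nei"
) -> float:
    """Expected heterozygosity from allele frequencies of the 2N gene copies.

    ``nei``: 1 - sum p_i^2. ``unbiased``: the same with the 2N/(2N-1)
    small-sample correction.
    """
    if not records:
        raise UndefinedStatisticError("no genotype records")
    freqs = allele_frequencies(records)
    he = 1.0 - sum(p * p for p in freqs.values())
    if estimator == "nei":
        return he
    if estimator == "unbiased":
        two_n = 2 * len(records)
        return he * two_n / (two_n - 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def size_spectrum(records: Sequence[GenotypeRecord]) -> pd.DataFrame:
    """Per-taxon distinct allele sizes (NA), min, max and size histogram.

    Empty groups do not occur (a taxon appears only if it has records).
    The histogram column maps repeat number to the count of gene copies.
    """
    rows = []
    for taxon in sorted({r.taxon for r in records}):
        sizes: Counter[int] = Counter()
        group = [r for r in records if r.taxon == taxon]
        for r in group:
            sizes.update(r.allele_sizes)
        rows.append(
            {
                "taxon": taxon,
                "n_individuals": len(group),
                "n_allele_sizes": len(sizes),
                "min_repeats": min(sizes),
                "max_repeats": max(sizes),
                "histogram": dict(sorted(sizes.items())),
            }
        )
    return pd.DataFrame(rows)
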