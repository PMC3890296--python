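"""Decomposition, translation and classification of zinc-finger array alleles.

A PRDM9-style zinc-finger (ZnF) array is a coding minisatellite: a tandem
concatenation of 84-bp repeat units, each encoding one 28-residue C2H2 finger.
The first unit of an array may instead be 75 bp long (a 9-bp in-frame deletion)
and, like all first-position units, lacks an essential zinc-coordinating
cysteine; the last unit may carry an in-frame stop codon. This module turns a
raw allele DNA sequence into an ordered list of classified repeat units, and
provides identity-class bookkeeping (DNA / protein / contact-triplet level)
and per-taxon summaries.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNIT_NT = 84
SHORT_UNIT_NT = UNIT_NT - 9  # first-position unit carrying the 9-bp deletion

#: C2H2 anchor with the fixed Mus spacing: C-x(2)-C-x(12)-H-x(3)-H.
C2H2_PATTERN = re.compile(r"C.{2}C.{12}H.{3}H")
#: Tolerant variant allowing 2-4 residues between the two cysteines.
C2H2_PATTERN_TOLERANT = re.compile(r"C.{2,4}C.{12}H.{3}H")

FIRST_POSITION = "first_position"
FUNCTIONAL = "functional"
TERMINAL_STOP = "terminal_stop"


class MalformedArrayError(ValueError):
    """Array length is not 84*k or 84*k - 9 (k >= 2)."""


class InconsistentArrayError(ValueError):
    """Unit classification contradicts array structure (e.g. internal stop)."""


class AmbiguousSequenceError(ValueError):
    """DNA contains ambiguity codes and strict mode is in force."""


@dataclass(frozen=True)
class RepeatUnit:
    """One 84-bp (or 75-bp) repeat unit of a ZnF array."""

    dna: str
    aa: str
    unit_class: str
    index: int

    def __post_init__(self) -> None:
        if len(self.dna) not in (SHORT_UNIT_NT, UNIT_NT):
            raise ValueError(f"unit length {len(self.dna)} not in {{75, 84}}")
        if len(self.aa) * 3 != len(self.dna):
            raise ValueError("translation length does not match DNA length")


@dataclass
class ZnfAllele:
    """An ordered ZnF array with its sampling metadata."""

    allele_id: str
    taxon: str
    locality: str
    source: str  # wild | lab | synthetic
    units: list[RepeatUnit] = field(default_factory=list)

    @property
    def dna(self) -> str:
        return "".join(u.dna for u in self.units)

    @property
    def protein(self) -> str:
        return "".join(u.aa for u in self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def functional_units(self) -> list[RepeatUnit]:
        return [u for u in self.units if u.unit_class == FUNCTIONAL]

    def validate(self) -> None:
        if len(self.units) < 2:
            raise InconsistentArrayError(
                f"{self.allele_id}: an array needs >= 2 units"
            )
        for u in self.units:
            if u.unit_class == FIRST_POSITION and u.index != 0:
                raise InconsistentArrayError(
                    f"{self.allele_id}: first_position unit at index {u.index}"
                )
            if u.unit_class == TERMINAL_STOP and u.index != len(self.units) - 1:
                raise InconsistentArrayError(
                    f"{self.allele_id}: stop-codon unit at internal index {u.index}"
                )


@dataclass(frozen=True)
class TaxonSummary:
    taxon: str
    n_sequences: int
    n_dna_alleles: int
    n_protein_variants: int
    n_triplet_variants: int


def translate_unit(dna: str, lenient: bool = False) -> str:
    """Translate one repeat unit under the standard genetic code.

    Ambiguity codes are rejected in strict mode; under ``lenient`` they
    propagate as ``X`` in the protein.
    """
    dna = dna.upper()
    if not set(dna) <= set("ACGT"):
        if not lenient:
            bad = sorted(set(dna) - set("ACGT"))
            raise AmbiguousSequenceError(
                f"ambiguity codes {bad} in unit (use lenient=True to accept)"
            )
        aa = []
        for i in range(0, len(dna), 3):
            codon = dna[i : i + 3]
            aa.append("X" if set(codon) - set("ACGT") else str(Seq(codon).translate()))
        return "".join(aa)
    return str(Seq(dna).translate())


def classify_unit(
    aa: str,
    is_first: bool,
    is_last: bool,
    dna_len: int = UNIT_NT,
    tolerant: bool = False,
) -> str:
    """Classify a translated unit as functional / first_position / terminal_stop.

    A functional verdict requires the full C2H2 anchor (both conserved
    cysteines and both conserved histidines); a unit failing the anchor, or
    any 75-nt unit, is a first-position (non-finger) unit. A stop codon is
    only tolerated in the last unit of the array.
    """
    if "*" in aa:
        if not is_last:
            raise InconsistentArrayError("stop codon in a non-terminal unit")
        return TERMINAL_STOP
    pattern = C2H2_PATTERN_TOLERANT if tolerant else C2H2_PATTERN
    if dna_len == SHORT_UNIT_NT or not pattern.search(aa):
        return FIRST_POSITION
    return FUNCTIONAL


def decompose_array(
    dna: str, lenient: bool = False, tolerant: bool = False
) -> list[RepeatUnit]:
    """Cut an allele DNA sequence into classified repeat units.

    The sequence must be in reading frame and of length 84*k, or 84*k - 9
    when the first unit carries the 9-bp deletion (then the first unit is
    75 nt and all others 84 nt).
    """
    n = len(dna)
    if n % UNIT_NT == 0:
        k = n // UNIT_NT
        first_len = UNIT_NT
    elif n % UNIT_NT == SHORT_UNIT_NT:
        k = n // UNIT_NT + 1
        first_len = SHORT_UNIT_NT
    else:
        raise MalformedArrayError(
            f"array length {n} leaves residue {n % UNIT_NT} modulo {UNIT_NT}; "
            f"expected 0 or {SHORT_UNIT_NT}"
        )
    if k < 2:
        raise MalformedArrayError(f"array of length {n} has fewer than 2 units")

    units: list[RepeatUnit] = []
    pos = 0
    for i in range(k):
        length = first_len if i == 0 else UNIT_NT
        chunk = dna[pos : pos + length].upper()
        pos += length
        aa = translate_unit(chunk, lenient=lenient)
        cls = classify_unit(
            aa, is_first=(i == 0), is_last=(i == k - 1),
            dna_len=length, tolerant=tolerant,
        )
        units.append(RepeatUnit(dna=chunk, aa=aa, unit_class=cls, index=i))
    return units


def allele_from_dna(
    dna: str,
    allele_id: str,
    taxon: str = "",
    locality: str = "",
    source: str = "synthetic",
    lenient: bool = False,
    tolerant: bool = False,
) -> ZnfAllele:
    allele = ZnfAllele(
        allele_id=allele_id,
        taxon=taxon,
        locality=locality,
        source=source,
        units=decompose_array(dna, lenient=lenient, tolerant=tolerant),
    )
    allele.validate()
    return allele


# ---------------------------------------------------------------------------
# FASTA I/O — headers carry metadata as pipe-delimited fields
# `allele_id|taxon|locality|source`; extra fields are tolerated.
# ---------------------------------------------------------------------------

def read_alleles_fasta(path, lenient: bool = False, tolerant: bool = False) -> list[ZnfAllele]:
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        allele_id = fields[0].split()[0]
        taxon = fields[1] if len(fields) > 1 else ""
        locality = fields[2] if len(fields) > 2 else ""
        source = fields[3] if len(fields) > 3 else "wild"
        alleles.append(
            allele_from_dna(
                str(rec.seq), allele_id, taxon, locality, source,
                lenient=lenient, tolerant=tolerant,
            )
        )
    return alleles


def write_alleles_fasta(alleles: Iterable[ZnfAllele], path) -> None:
    records = [
        SeqRecord(
            Seq(a.dna),
            id=f"{a.allele_id}|{a.taxon}|{a.locality}|{a.source}",
            description="",
        )
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Identity classes and summaries
# ---------------------------------------------------------------------------

def _identity_key(allele: ZnfAllele, level: str) -> str:
    if level == "dna":
        return allele.dna
    if level == "protein":
        return allele.protein
    if level == "triplet":
        from .triplets import reduce_to_triplets

        return "-".join(reduce_to_triplets(allele).triplets)
    raise ValueError(f"unknown identity level {level!r}")


def dedupe_alleles(
    alleles: Sequence[ZnfAllele], level: str = "dna"
) -> list[list[ZnfAllele]]:
    """Partition alleles into exact-identity classes at the requested level.

    Classes come back in deterministic order, lexicographic by the identity
    string of the class representative.
    """
    classes: "OrderedDict[str, list[ZnfAllele]]" = OrderedDict()
    for a in alleles:
        classes.setdefault(_identity_key(a, level), []).append(a)
    return [classes[k] for k in sorted(classes)]


def summarize_by_taxon(alleles: Sequence[ZnfAllele]) -> list[TaxonSummary]:
    """Per-taxon distinct counts at the DNA, protein and triplet levels.

    An allele shared by two taxa counts once in each, so per-taxon totals may
    exceed the global distinct counts.
    """
    out = []
    taxa = sorted({a.taxon for a in alleles})
    for taxon in taxa:
        group = [a for a in alleles if a.taxon == taxon]
        out.append(
            TaxonSummary(
                taxon=taxon,
                n_sequences=len(group),
                n_dna_alleles=len(dedupe_alleles(group, "dna")),
                n_protein_variants=len(dedupe_alleles(group, "protein")),
                n_triplet_variants=len(dedupe_alleles(group, "triplet")),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[TaxonSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "n_sequences": s.n_sequences,
                "n_dna_alleles": s.n_dna_alleles,
                "n_protein_variants": s.n_protein_variants,
                "n_triplet_variants": s.n_triplet_variants,
            }
            for s in summaries
        ]
    )
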