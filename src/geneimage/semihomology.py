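"""Semihomologous comparison of aligned amino-acid positions.

Two aligned residues are *homologous* (``R``) when identical, *semihomologous*
when their codon sets are separated by exactly one point mutation — typed
``#`` if a distance-1 codon pair differs by a transition (purine-purine or
pyrimidine-pyrimidine) and ``$`` if by a transversion — and *other* (``-``)
when at least two point mutations separate every codon pair, or when either
side is a pad or has no codons.

Codon sets come from an NCBI translation table (universal code 1 by default;
vertebrate-mitochondrial code 2 is natural for cytochrome b / COI). The
choice of table and of the tie-break, when both a transition-type and a
transversion-type distance-1 codon pair exist, can change the ``#``/``$``
split but never the ``R`` count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CodonTable",
    "PositionClassCounts",
    "is_transition",
    "min_point_mutations",
    "classify_pair",
    "pair_class_table",
    "count_positions",
    "UNCODABLE",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")
RNA_BASES = frozenset("ACGU")

TIE_POLICIES = ("transition", "transversion")

#: sentinel returned by min_point_mutations when a residue has no codons
UNCODABLE = -1

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True, eq=False)
class CodonTable:
    """Codon sets of a genetic code, keyed by amino-acid letter (RNA codons)."""

    table_id: int
    codons_of: dict[str, frozenset[str]]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "CodonTable":
        """Build from Biopython's copy of the NCBI translation tables."""
        return _ncbi_table(table_id)

    @property
    def sense_codons(self) -> frozenset[str]:
        out: set[str] = set()
        for cods in self.codons_of.values():
            out |= cods
        return frozenset(out)

    def translate(self, codon: str) -> str:
        for aa, cods in self.codons_of.items():
            if codon in cods:
                return aa
        raise KeyError(f"codon {codon} is a stop or unknown in table {self.table_id}")


@dataclass(frozen=True)
class PositionClassCounts:
    """Tallies of R / # / $ / - positions for one aligned sequence pair."""

    r: int
    ts: int
    tv: int
    other: int

    @property
    def total(self) -> int:
        return self.r + self.ts + self.tv + self.other

    def as_bracket(self) -> str:
        """Render as the conventional ``[R/#/$/-]`` bracket string."""
        return f"[{self.r}/{self.ts}/{self.tv}/{self.other}]"


@lru_cache(maxsize=None)
def _ncbi_table(table_id: int) -> CodonTable:
    bio = _BioCodonTable.unambiguous_rna_by_id[table_id]
    by_aa: dict[str, set[str]] = {}
    for codon, aa in bio.forward_table.items():
        by_aa.setdefault(aa, set()).add(codon)
    return CodonTable(
        table_id=table_id,
        codons_of={aa: frozenset(cods) for aa, cods in by_aa.items()},
        stop_codons=frozenset(bio.stop_codons),
    )


def is_transition(base1: str, base2: str) -> bool:
    """True for purine-purine or pyrimidine-pyrimidine interchanges.

    False means transversion. Identical or non-RNA bases are rejected.
    """
    b1, b2 = base1.upper(), base2.upper()
    if b1 not in RNA_BASES or b2 not in RNA_BASES:
        raise ValueError(f"not RNA bases: {base1!r}, {base2!r}")
    if b1 == b2:
        raise ValueError("bases must differ")
    return {b1, b2} <= PURINES or {b1, b2} <= PYRIMIDINES


def _hamming(c1: str, c2: str) -> int:
    return sum(a != b for a, b in zip(c1, c2))


def min_point_mutations(aa1: str, aa2: str, table: CodonTable | None = None) -> int:
    """Minimum Hamming distance over all codon pairs of two residues.

    Returns 0 iff the residues are equal; ``UNCODABLE`` when either residue
    has no codons in the table (pads, ambiguity codes).
    """
    table = table or CodonTable.from_ncbi(1)
    a1, a2 = aa1.upper(), aa2.upper()
    cods1 = table.codons_of.get(a1)
    cods2 = table.codons_of.get(a2)
    if not cods1 or not cods2:
        return UNCODABLE
    if a1 == a2:
        return 0
    return min(_hamming(c1, c2) for c1 in cods1 for c2 in cods2)


def _distance1_mutation_types(
    cods1: frozenset[str], cods2: frozenset[str]
) -> tuple[bool, bool]:
    """(has transition-type, has transversion-type) distance-1 codon pair."""
    has_ts = has_tv = False
    for c1 in cods1:
        for c2 in cods2:
            diff = [(a, b) for a, b in zip(c1, c2) if a != b]
            if len(diff) != 1:
                continue
            if is_transition(*diff[0]):
                has_ts = True
            else:
                has_tv = True
    return has_ts, has_tv


def classify_pair(
    aa1: str,
    aa2: str,
    table: CodonTable | None = None,
    tie_policy: str = "transition",
) -> str:
    """Classify one aligned residue pair as ``R``, ``#``, ``$`` or ``-``.

    ``tie_policy`` decides the label when both a transition-type and a
    transversion-type one-point mutation connect the codon sets; the default
    prefers ``#`` since transitions dominate in molecular evolution.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    table = table or CodonTable.from_ncbi(1)
    a1, a2 = aa1.upper(), aa2.upper()
    cods1 = table.codons_of.get(a1)
    cods2 = table.codons_of.get(a2)
    if not cods1 or not cods2:
        return "-"
    if a1 == a2:
        return "R"
    if min(_hamming(c1, c2) for c1 in cods1 for c2 in cods2) != 1:
        return "-"
    has_ts, has_tv = _distance1_mutation_types(cods1, cods2)
    if has_ts and has_tv:
        return "#" if tie_policy == "transition" else "$"
    return "#" if has_ts else "$"


_PAIR_TABLE_CACHE: dict[tuple[int, str], dict[tuple[str, str], str]] = {}


def pair_class_table(
    table: CodonTable | None = None, tie_policy: str = "transition"
) -> dict[tuple[str, str], str]:
    """Full classification matrix over the standard residue pairs."""
    table = table or CodonTable.from_ncbi(1)
    key = (id(table), tie_policy)
    cached = _PAIR_TABLE_CACHE.get(key)
    if cached is None:
        aas = sorted(table.codons_of)
        cached = {
            (a1, a2): classify_pair(a1, a2, table, tie_policy)
            for a1 in aas
            for a2 in aas
        }
        _PAIR_TABLE_CACHE[key] = cached
    return cached


def count_positions(
    seq_a: str,
    seq_b: str,
    table: CodonTable | None = None,
    tie_policy: str = "transition",
) -> PositionClassCounts:
    """Tally R / # / $ / - over two equal-length fitted residue strings."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)} "
            "(fit both to the reference lengths first)"
        )
    table = table or CodonTable.from_ncbi(1)
    lookup = pair_class_table(table, tie_policy)
    tally = {"R": 0, "#": 0, "$": 0, "-": 0}
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        cls = lookup.get((a, b))
        if cls is None:
            cls = classify_pair(a, b, table, tie_policy)
        tally[cls] += 1
    return PositionClassCounts(r=tally["R"], ts=tally["#"], tv=tally["$"], other=tally["-"])


def classify_track(
    seq_a: str,
    seq_b: str,
    table: CodonTable | None = None,
    tie_policy: str = "transition",
) -> list[str]:
    """Per-position class labels for an aligned pair (same order as input)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequence lengths differ")
    table = table or CodonTable.from_ncbi(1)
    lookup = pair_class_table(table, tie_policy)
    return [
        lookup.get((a, b)) or classify_pair(a, b, table, tie_policy)
        for a, b in zip(seq_a.upper(), seq_b.upper())
    ]
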