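"""Genetic code tables and codon indexing.

The likelihood engine works on the 61 sense codons of the standard
nuclear code, indexed in fixed lexicographic order (AAA, AAC, ...,
TTT minus stops).  All other modules address codons through the
:class:`GeneticCode` instance rather than raw strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

ALL_CODONS = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Parameters
    ----------
    table:
        Mapping of all 64 codons to one-letter amino acids, stop codons
        excluded from the mapping.
    stop_codons:
        The stop triplets of this code.
    """

    table: dict[str, str]
    stop_codons: frozenset[str]
    name: str = "standard"
    sense_codons: tuple[str, ...] = field(init=False)
    codon_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.table) | set(self.stop_codons) != set(ALL_CODONS):
            raise ValueError("code must cover all 64 codons")
        sense = tuple(c for c in ALL_CODONS if c not in self.stop_codons)
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "codon_index", {c: i for i, c in enumerate(sense)})

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def translate(self, codon: str) -> str:
        """One-letter amino acid of a sense codon ('*' for stops)."""
        if codon in self.stop_codons:
            return "*"
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def synonymous_family(self, amino_acid: str) -> tuple[str, ...]:
        """All sense codons encoding the given amino acid."""
        return tuple(c for c in self.sense_codons if self.table[c] == amino_acid)

    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.table.values())))


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    bio = CodonTable.unambiguous_dna_by_id[1]
    table = {c: aa for c, aa in bio.forward_table.items() if len(c) == 3}
    return GeneticCode(table=table, stop_codons=frozenset(bio.stop_codons))
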