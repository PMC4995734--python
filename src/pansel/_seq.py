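"""Genetic-code tables and small sequence helpers shared across modules.

The universal (standard) code is used throughout; the 61 sense codons are
indexed in alphabetical order, which fixes the state order of every codon
rate matrix in :mod:`pansel.selection`.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: the 61 sense codons of the universal code, alphabetically ordered
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
           if a + b + c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA: dict[str, str] = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

#: purine/pyrimidine pairs — substitutions within a set are transitions
_PURINES = {"A", "G"}


def is_transition(x: str, y: str) -> bool:
    """True if the single-nucleotide change x->y is a transition (A<->G, C<->T)."""
    return (x in _PURINES) == (y in _PURINES) and x != y


def translate_cds(cds: str, *, allow_terminal_stop: bool = True) -> str:
    """Translate a CDS under the standard code.

    Raises ``ValueError`` on length not divisible by 3 or an internal stop.
    A terminal stop codon is stripped when ``allow_terminal_stop``.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if allow_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for pos, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon position {pos + 1}")
        aa.append(str(Seq(codon).translate()))
    return "".join(aa)


def validate_protein(seq: str, *, allow_x: bool = True) -> None:
    """Raise ``ValueError`` naming the first illegal residue, if any."""
    legal = set(AMINO_ACIDS) | ({"X"} if allow_x else set())
    for i, ch in enumerate(seq.upper()):
        if ch not in legal:
            raise ValueError(f"illegal amino-acid symbol {ch!r} at position {i + 1}")
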