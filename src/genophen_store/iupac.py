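"""IUPAC nucleotide ambiguity codes.

The single-letter codes encode every non-empty subset of {A, C, G, T}
(15 codes; the four bases themselves are their own codes and N covers all
four).  The table is derived from Biopython's published ambiguity map so
the package never maintains its own copy of the standard.
"""
from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import FlankingError

_BASES = frozenset("ACGT")

#: frozenset of bases -> single-character IUPAC code (15 entries).
IUPAC_BY_BASES: dict[frozenset, str] = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if code != "X" and set(bases) <= _BASES
}

#: inverse map, code -> frozenset of bases.
BASES_BY_IUPAC: dict[str, frozenset] = {v: k for k, v in IUPAC_BY_BASES.items()}


def iupac_code(alleles) -> str:
    """Return the IUPAC ambiguity character for a set of nucleotides.

    Parameters
    ----------
    alleles : iterable of str
        Non-empty collection of single bases drawn from {A, C, G, T}
        (case-insensitive).

    Raises
    ------
    FlankingError
        If the set is empty or contains anything outside {A, C, G, T}.
    """
    bases = frozenset(str(a).upper() for a in alleles)
    if not bases:
        raise FlankingError("IUPAC code undefined for an empty allele set")
    if not bases <= _BASES:
        bad = sorted(bases - _BASES)
        raise FlankingError(f"non-ACGT allele(s) {bad} have no IUPAC nucleotide code")
    return IUPAC_BY_BASES[bases]
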