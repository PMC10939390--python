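"""Reference table of the 20 standard amino acids plus the undefined residue.

Every residue symbol stored in the database is one of the 21 three-letter
abbreviations below.  Non-standard or chemically modified residues are mapped
to ``UND`` (one-letter symbol ``U``) at ingest time, so downstream relations
are total over this table.

Polarity classes partition the 20 standard residues into the four classes a
structural pattern's AnyAmino node can filter on; ``UND`` carries the class
``unknown``, which matches only the wildcard polarity ``any``.
"""

from __future__ import annotations

from dataclasses import dataclass

NON_POLAR = "non-polar"
POLAR_UNCHARGED = "polar uncharged"
POSITIVE = "positively charged"
NEGATIVE = "negatively charged"
UNKNOWN = "unknown"

#: Legal values of an AnyAmino node's ``polarity`` property.
POLARITY_VALUES = ("any", NON_POLAR, POLAR_UNCHARGED, POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class StandardAminoEntry:
    """One row of the ``standard_amino`` reference table."""

    symbol: str  # one-letter code
    abbreviation: str  # three-letter code
    name: str
    polarity: str


STANDARD_AMINO_ACIDS: tuple[StandardAminoEntry, ...] = (
    StandardAminoEntry("A", "ALA", "Alanine", NON_POLAR),
    StandardAminoEntry("R", "ARG", "Arginine", POSITIVE),
    StandardAminoEntry("N", "ASN", "Asparagine", POLAR_UNCHARGED),
    StandardAminoEntry("D", "ASP", "Aspartic acid", NEGATIVE),
    StandardAminoEntry("C", "CYS", "Cysteine", POLAR_UNCHARGED),
    StandardAminoEntry("Q", "GLN", "Glutamine", POLAR_UNCHARGED),
    StandardAminoEntry("E", "GLU", "Glutamic acid", NEGATIVE),
    StandardAminoEntry("G", "GLY", "Glycine", NON_POLAR),
    StandardAminoEntry("H", "HIS", "Histidine", POSITIVE),
    StandardAminoEntry("I", "ILE", "Isoleucine", NON_POLAR),
    StandardAminoEntry("L", "LEU", "Leucine", NON_POLAR),
    StandardAminoEntry("K", "LYS", "Lysine", POSITIVE),
    StandardAminoEntry("M", "MET", "Methionine", NON_POLAR),
    StandardAminoEntry("F", "PHE", "Phenylalanine", NON_POLAR),
    StandardAminoEntry("P", "PRO", "Proline", NON_POLAR),
    StandardAminoEntry("S", "SER", "Serine", POLAR_UNCHARGED),
    StandardAminoEntry("T", "THR", "Threonine", POLAR_UNCHARGED),
    StandardAminoEntry("W", "TRP", "Tryptophan", NON_POLAR),
    StandardAminoEntry("Y", "TYR", "Tyrosine", POLAR_UNCHARGED),
    StandardAminoEntry("V", "VAL", "Valine", NON_POLAR),
    StandardAminoEntry("U", "UND", "Undefined", UNKNOWN),
)

#: Three-letter codes of the 20 standard residues (UND excluded).
STANDARD_CODES = frozenset(e.abbreviation for e in STANDARD_AMINO_ACIDS[:-1])

#: All 21 legal residue symbols.
KNOWN_CODES = frozenset(e.abbreviation for e in STANDARD_AMINO_ACIDS)

_POLARITY = {e.abbreviation: e.polarity for e in STANDARD_AMINO_ACIDS}


def polarity_of(symbol: str) -> str:
    """Polarity class of a three-letter residue code.

    Total over the 21-entry table; ``UND`` yields ``"unknown"``, which is
    compatible only with an ``any`` polarity filter.  Raises ``KeyError``
    for codes outside the table.
    """
    try:
        return _POLARITY[symbol]
    except KeyError:
        raise KeyError(f"unknown amino-acid code {symbol!r}") from None
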