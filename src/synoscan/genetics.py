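"""Standard genetic code helpers shared across the package.

All codons are handled as upper-case DNA triplets (T, not U); transcription
to RNA happens only at the folding-engine boundary.  The standard (NCBI
table 1) code is taken from Biopython; stop codons translate to ``"*"``.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stops included as "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of codons (includes "*" -> stop codons)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

VALID_BASES = frozenset("ACGT")


def validate_codon(codon: str) -> str:
    """Return the upper-case codon or raise ``ValueError``."""
    c = str(codon).upper().replace("U", "T")
    if len(c) != 3 or not VALID_BASES.issuperset(c):
        raise ValueError(f"invalid codon {codon!r}")
    return c


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[validate_codon(codon)]


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """True when both codons encode the same amino acid (or both are stops)."""
    return translate_codon(codon_a) == translate_codon(codon_b)


def synonymous_codons(codon: str) -> list[str]:
    """All codons encoding the same amino acid, the input codon included."""
    return list(AA_TO_CODONS[translate_codon(codon)])


def split_codons(sequence: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons."""
    seq = str(sequence).upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(sequence: str) -> str:
    return str(Seq(str(sequence).upper().replace("U", "T")).translate())


def reverse_complement(sequence: str) -> str:
    return str(Seq(str(sequence).upper()).reverse_complement())


def gc_count(codon: str) -> int:
    c = validate_codon(codon)
    return c.count("G") + c.count("C")
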