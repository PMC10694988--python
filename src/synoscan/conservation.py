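"""Codon- and residue-level evolutionary conservation from alignments.

Inputs are user-supplied multiple alignments (FASTA or Clustal) of homologs
against the wild-type gene: an in-frame nucleotide alignment for codon
conservation and a protein alignment for residue conservation, optionally
with a per-hit identity/coverage metadata table used to filter homologs
before tallying (keep hits with identity <= 95% and coverage in [90, 100],
boundaries inclusive).

At each codon position the homolog codons synonymous with the WT amino
acid are tallied; the WT codon is classed "most" conserved when its count
is the strict maximum among observed synonymous codons, "least" when the
strict minimum, and "intermediate" otherwise (ties included).  Codons with
gaps or encoding a different amino acid are excluded from the synonymous
ranking and reported separately.  Residue conservation is the percent of
non-gap homolog residues matching the WT residue at each column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import AlignIO

from . import genetics

CLASSES = ("most", "intermediate", "least")


@dataclass(frozen=True)
class HomologHit:
    """One homolog with its alignment-search metadata."""

    id: str
    percent_identity: float
    query_coverage: float
    aligned_sequence: str = ""


@dataclass
class ConservationResult:
    """Per-position codon tallies, WT codon classes and residue conservation."""

    codon_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    nonsyn_counts: dict[int, int] = field(default_factory=dict)
    wt_codons: dict[int, str] = field(default_factory=dict)
    wt_codon_class: dict[int, str] = field(default_factory=dict)
    residue_conservation: dict[int, float] = field(default_factory=dict)

    def codon_fractions(self, position: int) -> dict[str, float]:
        counts = self.codon_counts.get(position, {})
        total = sum(counts.values())
        return {c: n / total for c, n in counts.items()} if total else {}


def filter_homologs(
    hits: Iterable[HomologHit],
    max_identity: float = 95.0,
    min_coverage: float = 90.0,
    max_coverage: float = 100.0,
) -> list[HomologHit]:
    """Keep hits with identity <= max_identity and coverage within bounds."""
    return [
        h
        for h in hits
        if h.percent_identity <= max_identity
        and min_coverage <= h.query_coverage <= max_coverage
    ]


def read_hit_metadata(path) -> list[HomologHit]:
    """Load a hit-metadata TSV (id, percent_identity, query_coverage)."""
    df = pd.read_csv(path, sep="\t")
    return [
        HomologHit(str(r["id"]), float(r["percent_identity"]), float(r["query_coverage"]))
        for _, r in df.iterrows()
    ]


def read_alignment(path, fmt: str = "fasta"):
    """Read a multiple alignment (fasta or clustal) via Biopython."""
    return AlignIO.read(path, fmt)


def _rows(alignment, wt_row: str):
    wt = None
    homologs = []
    for record in alignment:
        if record.id == wt_row:
            wt = str(record.seq).upper()
        else:
            homologs.append((record.id, str(record.seq).upper()))
    if wt is None:
        raise ValueError(f"WT row {wt_row!r} not found in alignment")
    return wt, homologs


def codon_conservation(
    alignment,
    wt_row: str,
    keep_ids: Iterable[str] | None = None,
) -> ConservationResult:
    """Tally synonymous codon preference at every WT codon position.

    The WT row must be ungapped with length divisible by 3; homolog rows
    share the alignment width.  ``keep_ids`` optionally restricts the
    homologs (e.g. to the identity/coverage-filtered set).
    """
    wt, homologs = _rows(alignment, wt_row)
    if "-" in wt:
        raise ValueError("WT row must be ungapped")
    if len(wt) % 3:
        raise ValueError(f"WT row length {len(wt)} violates frame")
    if keep_ids is not None:
        keep = set(keep_ids)
        homologs = [(hid, seq) for hid, seq in homologs if hid in keep]
    result = ConservationResult()
    n_pos = len(wt) // 3
    for pos in range(1, n_pos + 1):
        lo = 3 * (pos - 1)
        wt_codon = wt[lo : lo + 3]
        wt_aa = genetics.translate_codon(wt_codon)
        counts: dict[str, int] = {}
        nonsyn = 0
        for _, seq in homologs:
            codon = seq[lo : lo + 3]
            if "-" in codon or not set(codon) <= genetics.VALID_BASES:
                nonsyn += 1
                continue
            if genetics.translate_codon(codon) != wt_aa:
                nonsyn += 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
        result.codon_counts[pos] = counts
        result.nonsyn_counts[pos] = nonsyn
        result.wt_codons[pos] = wt_codon
        if counts:
            wt_n = counts.get(wt_codon, 0)
            others = [n for c, n in counts.items() if c != wt_codon]
            if wt_n > 0 and (not others or wt_n > max(others)):
                cls = "most"  # strict maximum
            elif others and wt_n < min(others):
                cls = "least"  # strict minimum (ties go to intermediate)
            else:
                cls = "intermediate"
            result.wt_codon_class[pos] = cls
    return result


def residue_conservation(
    alignment,
    wt_row: str,
    keep_ids: Iterable[str] | None = None,
) -> dict[int, float]:
    """Percent of non-gap homolog residues matching WT at each position.

    All-gap columns are undefined and omitted from the result.
    """
    wt, homologs = _rows(alignment, wt_row)
    if "-" in wt:
        raise ValueError("WT row must be ungapped")
    if keep_ids is not None:
        keep = set(keep_ids)
        homologs = [(hid, seq) for hid, seq in homologs if hid in keep]
    out: dict[int, float] = {}
    for pos in range(1, len(wt) + 1):
        wt_res = wt[pos - 1]
        observed = [seq[pos - 1] for _, seq in homologs if seq[pos - 1] != "-"]
        if not observed:
            continue
        out[pos] = 100.0 * sum(r == wt_res for r in observed) / len(observed)
    return out


def conserved_codon_summary(result: ConservationResult) -> dict[str, float]:
    """Fraction of classified positions in each conservation class."""
    classes = list(result.wt_codon_class.values())
    if not classes:
        raise ValueError("no classified positions in conservation result")
    n = len(classes)
    return {cls: classes.count(cls) / n for cls in CLASSES}


def conservation_table(result: ConservationResult) -> pd.DataFrame:
    """Flat per-position table (codon, class, synonymous/other tallies)."""
    rows = []
    for pos in sorted(result.wt_codons):
        counts = result.codon_counts.get(pos, {})
        rows.append(
            {
                "position": pos,
                "wt_codon": result.wt_codons[pos],
                "wt_codon_class": result.wt_codon_class.get(pos, ""),
                "wt_codon_count": counts.get(result.wt_codons[pos], 0),
                "synonymous_total": sum(counts.values()),
                "non_synonymous_or_gap": result.nonsyn_counts.get(pos, 0),
                "codon_tally": ";".join(
                    f"{c}:{n}" for c, n in sorted(counts.items())
                ),
            }
        )
    return pd.DataFrame(rows)
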