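"""Reading, validating and normalising per-mutant read-count tables.

A deep-sequencing scan of single synonymous codon substitutions yields, for
every variant, a read count in each of six conditions: three strains
(a CcdB-resistant strain, a CcdB-sensitive strain, and a RelE reporter
strain) by two biological replicates.  This module parses those tables,
verifies the synonymy contract of every row against the standard genetic
code, applies the resistant-strain minimum-depth filter, and converts counts
to within-condition fraction representations

    F(x_i) = x_i / (sum_i x_i + x_WT)

where the sum runs over the variants retained by the depth filter, so the
fractions form a proper composition of the analysed set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import genetics

STRAINS = ("resistant", "sensitive", "relE")
REPLICATES = (1, 2)

#: default TSV column per (strain, replicate)
DEFAULT_SCHEMA: dict[tuple[str, int], str] = {
    ("resistant", 1): "res_rep1",
    ("resistant", 2): "res_rep2",
    ("sensitive", 1): "sen_rep1",
    ("sensitive", 2): "sen_rep2",
    ("relE", 1): "relE_rep1",
    ("relE", 2): "relE_rep2",
}


class CountTableError(ValueError):
    """Malformed or internally inconsistent count-table input."""


@dataclass(frozen=True, order=True)
class MutantVariant:
    """A single synonymous codon substitution.

    position is the 1-based codon index within the gene; wt_codon and
    mut_codon are DNA triplets encoding the same amino acid.
    """

    position: int
    wt_codon: str
    mut_codon: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_codon", genetics.validate_codon(self.wt_codon))
        object.__setattr__(self, "mut_codon", genetics.validate_codon(self.mut_codon))
        if self.position < 1:
            raise CountTableError(f"position must be >= 1, got {self.position}")
        if not genetics.is_synonymous(self.wt_codon, self.mut_codon):
            raise CountTableError(
                f"non-synonymous codon pair at position {self.position}: "
                f"{self.wt_codon} ({genetics.translate_codon(self.wt_codon)}) vs "
                f"{self.mut_codon} ({genetics.translate_codon(self.mut_codon)})"
            )

    @property
    def amino_acid(self) -> str:
        return genetics.translate_codon(self.wt_codon)

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``K4_AAA`` for an AAA Lys codon at position 4."""
        return f"{self.amino_acid}{self.position}_{self.mut_codon}"

    @property
    def is_identity(self) -> bool:
        return self.wt_codon == self.mut_codon

    @property
    def is_stop(self) -> bool:
        return self.amino_acid == "*"


@dataclass
class CountTable:
    """Read counts for one (strain, replicate) condition."""

    counts: dict[MutantVariant, int]
    wt_count: int
    strain: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for v, c in self.counts.items():
            if c < 0:
                raise CountTableError(f"negative count for {v.label}")
        if self.wt_count < 0:
            raise CountTableError("negative reference count")

    @property
    def variants(self) -> set[MutantVariant]:
        return set(self.counts)

    def get(self, variant: MutantVariant) -> int:
        return self.counts.get(variant, 0)


@dataclass
class FractionTable:
    """Fraction representation of each variant within one condition."""

    fractions: dict[MutantVariant, float]
    wt_fraction: float
    strain: str = ""
    replicate: int = 0

    def get(self, variant: MutantVariant) -> float:
        return self.fractions.get(variant, 0.0)

    def total(self) -> float:
        return sum(self.fractions.values()) + self.wt_fraction


def read_count_table(
    path,
    schema: Mapping[tuple[str, int], str] | None = None,
) -> dict[tuple[str, int], CountTable]:
    """Parse a six-condition count TSV into one CountTable per condition.

    The file must carry a header with columns position, wt_codon, mut_codon,
    is_wt and one count column per condition (default names in
    DEFAULT_SCHEMA).  Exactly one row must be flagged is_wt=1; its codon pair
    must be the identity.  Stop-codon rows (e.g. the terminator at the last
    position) are accepted but flagged with a warning, matching the
    convention that residue-level analyses exclude them downstream.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, sep="\t", dtype={"wt_codon": str, "mut_codon": str})

    required = ["position", "wt_codon", "mut_codon", "is_wt", *schema.values()]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountTableError(f"missing required column(s): {', '.join(missing)}")

    wt_rows = df[df["is_wt"] == 1]
    if len(wt_rows) != 1:
        raise CountTableError(f"expected exactly one is_wt=1 row, found {len(wt_rows)}")
    wt_row = wt_rows.iloc[0]
    if str(wt_row["wt_codon"]).upper() != str(wt_row["mut_codon"]).upper():
        raise CountTableError("reference row must have wt_codon == mut_codon")

    variants: list[MutantVariant] = []
    seen: set[MutantVariant] = set()
    for idx, row in df[df["is_wt"] != 1].iterrows():
        try:
            v = MutantVariant(int(row["position"]), row["wt_codon"], row["mut_codon"])
        except CountTableError as exc:
            raise CountTableError(f"row {idx}: {exc}") from exc
        if v.is_identity:
            raise CountTableError(f"row {idx}: identity codon pair without is_wt flag")
        if v in seen:
            raise CountTableError(f"row {idx}: duplicate variant {v.label}")
        if v.is_stop:
            warnings.warn(f"stop-codon variant {v.label} accepted but flagged")
        seen.add(v)
        variants.append(v)

    tables: dict[tuple[str, int], CountTable] = {}
    for cond, col in schema.items():
        if (df[col] < 0).any():
            raise CountTableError(f"negative count in column {col}")
        if not (df[col] == df[col].astype(int)).all():
            raise CountTableError(f"non-integer count in column {col}")
        counts = {
            v: int(c)
            for v, c in zip(variants, df.loc[df["is_wt"] != 1, col].astype(int))
        }
        tables[cond] = CountTable(
            counts=counts,
            wt_count=int(wt_row[col]),
            strain=cond[0],
            replicate=cond[1],
        )
    return tables


def write_count_table(
    path,
    tables: Mapping[tuple[str, int], CountTable],
    wt_variant: MutantVariant,
    schema: Mapping[tuple[str, int], str] | None = None,
) -> None:
    """Write condition CountTables back to the TSV schema (inverse of read)."""
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    any_table = next(iter(tables.values()))
    variants = sorted(any_table.variants)
    rows = []
    for v in variants:
        row = {
            "position": v.position,
            "wt_codon": v.wt_codon,
            "mut_codon": v.mut_codon,
            "is_wt": 0,
        }
        for cond, col in schema.items():
            row[col] = tables[cond].get(v)
        rows.append(row)
    wt = {
        "position": wt_variant.position,
        "wt_codon": wt_variant.wt_codon,
        "mut_codon": wt_variant.wt_codon,
        "is_wt": 1,
    }
    for cond, col in schema.items():
        wt[col] = tables[cond].wt_count
    rows.append(wt)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def normalize_fractions(
    counts: CountTable,
    retained: Iterable[MutantVariant] | None = None,
) -> FractionTable:
    """Fraction representation over the retained variant set plus reference.

    The denominator is the total reads of all retained variants plus the
    reference count within the condition, so the resulting fractions sum to
    one.  ``retained=None`` keeps every variant.
    """
    if retained is None:
        kept = sorted(counts.variants)
    else:
        kept = sorted(set(retained))
    total = sum(counts.get(v) for v in kept) + counts.wt_count
    if total <= 0:
        raise CountTableError(
            f"zero total reads in condition {counts.strain} rep {counts.replicate}"
        )
    return FractionTable(
        fractions={v: counts.get(v) / total for v in kept},
        wt_fraction=counts.wt_count / total,
        strain=counts.strain,
        replicate=counts.replicate,
    )


def filter_by_resistant_depth(
    counts_rep1: CountTable,
    counts_rep2: CountTable,
    min_reads: int = 20,
) -> set[MutantVariant]:
    """Variants with at least ``min_reads`` in BOTH resistant replicates.

    The boundary is inclusive: a variant with exactly ``min_reads`` reads in
    each replicate is retained.  The reference variant is tracked separately
    from the variant map and is always carried through; a warning is emitted
    when its own depth falls below the cutoff because every downstream score
    is a ratio to it.
    """
    universe = counts_rep1.variants | counts_rep2.variants
    kept = {
        v
        for v in universe
        if counts_rep1.get(v) >= min_reads and counts_rep2.get(v) >= min_reads
    }
    if counts_rep1.wt_count < min_reads or counts_rep2.wt_count < min_reads:
        warnings.warn(
            "reference variant below the resistant-depth cutoff; it is retained "
            "but downstream scoring may be unreliable"
        )
    return kept
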