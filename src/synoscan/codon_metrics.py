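"""Codon-level covariates: usage, adaptation indices, wobble, hydropathy.

Per-variant covariates compare the mutant codon with the wild-type codon it
replaces:

* delta GC — difference in G+C count between the two codons;
* RCU — ratio of genome-wide usage frequencies, mutant over WT;
* RtrnaA — ratio of the percent of the cellular tRNA pool decoding each
  codon (codons read by several tRNAs sum their decoders);
* RCU degree of variation — log2 fold-distance of RCU from the
  least-deviating variant at the same position.

Per-gene indices follow the standard definitions: CAI is the geometric mean
of relative-adaptiveness weights (w = usage / max usage among synonyms) and
tAI the geometric mean of tRNA-availability weights computed from tRNA gene
copy numbers under wobble-pairing rules with selective-constraint
penalties.  Default parameter tables for E. coli K-12 ship with the package
and every operation accepts an explicit table instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import genetics
from .io_counts import MutantVariant

_DATA = resources.files("synoscan") / "data"

#: anticodon34:codon3 wobble pairings recognised beyond Watson-Crick, per
#: codon third base: (anticodon first base standing in for the decoder,
#: pairing label used in the penalty table)
_WOBBLE_RULES: dict[str, tuple[str, str]] = {
    "T": ("G", "G:U"),  # G34 reads U3
    "C": ("A", "I:C"),  # A34 (read as inosine) reads C3
    "A": ("A", "I:A"),  # inosine reads A3 weakly
    "G": ("T", "U:G"),  # U34 reads G3
}


def load_table(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_usage_frequencies(path=None) -> dict[str, float]:
    """codon -> usage per 1000 codons (packaged E. coli K-12 table by default)."""
    df = pd.read_csv(path, sep="\t") if path else load_table("ecoli_codon_usage.tsv")
    return dict(zip(df["codon"], df["usage_per_1000"].astype(float)))


def load_hydropathy(path=None) -> dict[str, float]:
    """amino acid -> Kyte-Doolittle hydropathy value."""
    df = pd.read_csv(path, sep="\t") if path else load_table("kyte_doolittle.tsv")
    return dict(zip(df["amino_acid"], df["kd_value"].astype(float)))


def load_tgcn(path=None) -> pd.DataFrame:
    """tRNA gene copy numbers by anticodon, with optional decoding overrides."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False) if path else None
    if df is None:
        with (_DATA / "ecoli_trna_gcn.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    return df


def load_wobble_penalties(path=None) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t") if path else load_table("wobble_penalties.tsv")
    return dict(zip(df["pairing"], df["s"].astype(float)))


@dataclass
class CodonParameterSet:
    """Bundle of codon-level parameter tables used across the pipeline."""

    usage_freq: dict[str, float] = field(default_factory=load_usage_frequencies)
    trna_fraction: dict[str, float] = field(default_factory=lambda: default_trna_fractions())
    cai_weights: dict[str, float] = field(default_factory=dict)
    tai_weights: dict[str, float] = field(default_factory=dict)
    hydropathy: dict[str, float] = field(default_factory=load_hydropathy)

    def __post_init__(self) -> None:
        if not self.cai_weights:
            self.cai_weights = cai_weights_from_usage(self.usage_freq)
        if not self.tai_weights:
            self.tai_weights = tai_weights(load_tgcn(), load_wobble_penalties())


def delta_gc(mut_codon: str, wt_codon: str) -> int:
    """G+C count of the mutant codon minus that of the WT codon."""
    return genetics.gc_count(mut_codon) - genetics.gc_count(wt_codon)


def _require_synonymous(mut_codon: str, wt_codon: str) -> tuple[str, str]:
    m = genetics.validate_codon(mut_codon)
    w = genetics.validate_codon(wt_codon)
    if not genetics.is_synonymous(m, w):
        raise ValueError(
            f"{m} ({genetics.translate_codon(m)}) and {w} "
            f"({genetics.translate_codon(w)}) are not synonymous"
        )
    return m, w


def rcu(mut_codon: str, wt_codon: str, usage_freq: Mapping[str, float]) -> float:
    """Relative codon usage: usage(mut) / usage(wt) for a synonymous pair."""
    m, w = _require_synonymous(mut_codon, wt_codon)
    if usage_freq.get(w, 0.0) <= 0:
        raise ValueError(f"WT codon {w} has zero or missing usage frequency")
    if m not in usage_freq:
        raise ValueError(f"mutant codon {m} missing from usage table")
    return usage_freq[m] / usage_freq[w]


def rcu_dv(
    rcu_values_at_position: Mapping[MutantVariant, float]
) -> dict[MutantVariant, float]:
    """log2 fold-distance of each RCU from the position's least-deviating one."""
    defined = {v: r for v, r in rcu_values_at_position.items() if r > 0}
    out = {v: float("nan") for v in set(rcu_values_at_position) - set(defined)}
    if defined:
        z = {v: (r if r > 1 else 1.0 / r) for v, r in defined.items()}
        z_min = min(z.values())
        out.update({v: math.log2(zi / z_min) for v, zi in z.items()})
    return out


def cai_weights_from_usage(usage_freq: Mapping[str, float]) -> dict[str, float]:
    """Relative adaptiveness w = usage / max usage among synonymous codons."""
    weights: dict[str, float] = {}
    for aa, codons in genetics.AA_TO_CODONS.items():
        if aa == "*":
            continue
        peak = max(usage_freq.get(c, 0.0) for c in codons)
        if peak <= 0:
            raise ValueError(f"no usage data for amino acid {aa}")
        for c in codons:
            weights[c] = usage_freq.get(c, 0.0) / peak
    return weights


def cai(gene_codons: Sequence[str] | str, cai_weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of weights over all codons."""
    codons = (
        genetics.split_codons(gene_codons)
        if isinstance(gene_codons, str)
        else [genetics.validate_codon(c) for c in gene_codons]
    )
    if not codons:
        raise ValueError("empty gene")
    log_sum = 0.0
    for c in codons:
        if genetics.translate_codon(c) == "*":
            raise ValueError(f"stop codon {c} inside gene")
        w = cai_weights.get(c, 0.0)
        if w <= 0:
            raise ValueError(f"non-positive CAI weight for codon {c}")
        log_sum += math.log(w)
    return math.exp(log_sum / len(codons))


def cai_ratio(
    gene_a: Sequence[str] | str,
    gene_b: Sequence[str] | str,
    cai_weights: Mapping[str, float],
) -> float:
    """CAI(a) / CAI(b); > 1 when gene a is the better-adapted of the two."""
    return cai(gene_a, cai_weights) / cai(gene_b, cai_weights)


def default_trna_fractions(
    tgcn: pd.DataFrame | None = None,
    penalties: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """codon -> percent of the tRNA gene pool whose tRNAs decode it.

    A proxy for measured tRNA abundance: gene copy number tracks cellular
    tRNA level in fast-growing E. coli.  Each codon sums the copies of every
    anticodon that can read it (Watson-Crick or wobble, restricted to tRNAs
    of the codon's amino acid), expressed as percent of all tRNA genes.
    """
    tgcn = load_tgcn() if tgcn is None else tgcn
    total = float(tgcn["gene_copy_number"].sum())
    fractions: dict[str, float] = {}
    for codon in genetics.SENSE_CODONS:
        copies = sum(n for n, _s in _decoders(codon, tgcn))
        fractions[codon] = 100.0 * copies / total
    return fractions


def rtrnaa(
    mut_codon: str, wt_codon: str, trna_fraction: Mapping[str, float]
) -> float:
    """Relative tRNA abundance: summed decoder fraction, mutant over WT."""
    m, w = _require_synonymous(mut_codon, wt_codon)
    for c in (m, w):
        if c not in trna_fraction:
            raise ValueError(f"codon {c} missing from tRNA fraction table")
        if trna_fraction[c] <= 0:
            raise ValueError(f"codon {c} has non-positive tRNA fraction")
    return trna_fraction[m] / trna_fraction[w]


def _decoders(codon: str, tgcn: pd.DataFrame) -> list[tuple[float, float]]:
    """(gene copies, selective constraint s) for each tRNA reading the codon.

    Watson-Crick pairing carries s = 0; wobble pairings carry the penalty of
    their pairing class.  Decoding is restricted to tRNAs charged with the
    codon's amino acid, and explicit ``decodes_override`` rows (e.g. the
    lysidine-modified isoleucine tRNA reading ATA) pair as cognate.
    """
    aa = genetics.translate_codon(codon)
    base_ac = tgcn["anticodon"].astype(str).str.slice(0, 3).str.upper()
    out: list[tuple[float, float]] = []
    overridden = tgcn["decodes_override"].astype(str).str.upper() == codon
    for _, row in tgcn[overridden].iterrows():
        if row["gene_copy_number"] > 0:
            out.append((float(row["gene_copy_number"]), 0.0))
    plain = tgcn[~overridden & (tgcn["decodes_override"].astype(str) == "")]
    plain_ac = base_ac[plain.index]
    wc = genetics.reverse_complement(codon)
    match = plain[(plain_ac == wc) & (plain["amino_acid"] == aa)]
    for _, row in match.iterrows():
        if row["gene_copy_number"] > 0:
            out.append((float(row["gene_copy_number"]), 0.0))
    first, _pairing = _WOBBLE_RULES[codon[2]]
    wobble_ac = first + wc[1:]
    if wobble_ac != wc:
        match = plain[(plain_ac == wobble_ac) & (plain["amino_acid"] == aa)]
        for _, row in match.iterrows():
            if row["gene_copy_number"] > 0:
                out.append((float(row["gene_copy_number"]), _pairing))  # type: ignore[arg-type]
    return out


def tai_weights(
    tgcn: pd.DataFrame | None = None,
    wobble_penalties: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Normalised tAI weight per sense codon.

    Raw weight = sum over recognising tRNAs of (1 - s) * gene copies;
    weights are divided by the maximum, and zero-weight codons are replaced
    by the geometric mean of the nonzero weights so the gene-level geometric
    mean stays defined.
    """
    tgcn = load_tgcn() if tgcn is None else tgcn
    if tgcn.empty or tgcn["gene_copy_number"].sum() <= 0:
        raise ValueError("empty tRNA gene copy number table")
    penalties = load_wobble_penalties() if wobble_penalties is None else dict(wobble_penalties)
    raw: dict[str, float] = {}
    for codon in genetics.SENSE_CODONS:
        w = 0.0
        for copies, s in _decoders(codon, tgcn):
            s_val = s if isinstance(s, float) else penalties[s]
            w += (1.0 - s_val) * copies
        raw[codon] = w
    peak = max(raw.values())
    weights = {c: w / peak for c, w in raw.items()}
    nonzero = [w for w in weights.values() if w > 0]
    gm = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
    return {c: (w if w > 0 else gm) for c, w in weights.items()}


def tai(
    gene_codons: Sequence[str] | str,
    tgcn: pd.DataFrame | None = None,
    wobble_penalties: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> float:
    """tRNA adaptation index: geometric mean of per-codon tAI weights."""
    if weights is None:
        weights = tai_weights(tgcn, wobble_penalties)
    codons = (
        genetics.split_codons(gene_codons)
        if isinstance(gene_codons, str)
        else [genetics.validate_codon(c) for c in gene_codons]
    )
    if not codons:
        raise ValueError("empty gene")
    return math.exp(sum(math.log(weights[c]) for c in codons) / len(codons))


def wobble_base(codon: str) -> str:
    """Third (wobble) base of a codon."""
    return genetics.validate_codon(codon)[2]


def wobble_composition(
    variants: Iterable[MutantVariant | str],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions of wobble-position bases over a variant set."""
    counts = {b: 0 for b in "ACGT"}
    for v in variants:
        codon = v if isinstance(v, str) else v.mut_codon
        counts[wobble_base(codon)] += 1
    total = sum(counts.values())
    fractions = {b: (c / total if total else 0.0) for b, c in counts.items()}
    return counts, fractions


def hydropathy_profile(
    protein_sequence: str,
    hydropathy_table: Mapping[str, float] | None = None,
    window: int = 1,
) -> list[float]:
    """Per-residue Kyte-Doolittle values, optionally smoothed.

    Smoothing uses a centred moving average with truncated windows at the
    edges; window must be a positive odd integer.
    """
    table = load_hydropathy() if hydropathy_table is None else hydropathy_table
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = []
    for aa in str(protein_sequence).upper():
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r}")
        values.append(table[aa])
    if window == 1:
        return values
    half = window // 2
    smoothed = []
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        smoothed.append(float(np.mean(values[lo:hi])))
    return smoothed


def covariates_for_variants(
    variants: Iterable[MutantVariant],
    params: CodonParameterSet | None = None,
) -> pd.DataFrame:
    """Per-variant covariate table (delta GC, RCU, RCU DoV, RtrnaA, CAI, tAI)."""
    params = CodonParameterSet() if params is None else params
    all_variants = sorted(variants)
    variants = [v for v in all_variants if not v.is_stop]
    if len(variants) != len(all_variants):
        import warnings

        warnings.warn("stop-codon variants excluded from codon covariates")
    rows = []
    for v in variants:
        rows.append(
            {
                "label": v.label,
                "position": v.position,
                "wt_codon": v.wt_codon,
                "mut_codon": v.mut_codon,
                "delta_gc": delta_gc(v.mut_codon, v.wt_codon),
                "rcu": rcu(v.mut_codon, v.wt_codon, params.usage_freq),
                "rtrnaa": rtrnaa(v.mut_codon, v.wt_codon, params.trna_fraction),
                "cai_mut": params.cai_weights[v.mut_codon],
                "cai_wt": params.cai_weights[v.wt_codon],
                "tai_mut": params.tai_weights[v.mut_codon],
                "tai_wt": params.tai_weights[v.wt_codon],
                "wobble_base": wobble_base(v.mut_codon),
            }
        )
    df = pd.DataFrame(rows).set_index("label")
    by_pos: dict[int, dict[MutantVariant, float]] = {}
    for v, r in zip(variants, df["rcu"]):
        by_pos.setdefault(v.position, {})[v] = float(r)
    dv: dict[str, float] = {}
    for pos_values in by_pos.values():
        for v, d in rcu_dv(pos_values).items():
            dv[v.label] = d
    df["rcu_dv"] = pd.Series(dv)
    return df
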