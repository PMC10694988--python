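"""Enrichment scores, degree-of-variation statistics and phenotype classes.

For each variant i the deepseq ratio in a selective condition is the ratio
of its fraction representation there to its fraction in the resistant
(neutral) strain, and the enrichment score normalises that ratio to the
reference variant:

    ratio_i = F(sel_i) / F(res_i)        ES_i = ratio_i / ratio_WT

so ES = 1 means wild-type-like behaviour.  ES^CcdB (sensitive strain)
tracks free toxin: ES < 1 means the variant kills the sensitive strain more
efficiently than WT (hyperactive).  ES^RelE (RelE reporter strain) tracks
the amount of CcdA-CcdB complex repressing the operon promoter: ES > 1
means more repression.

The degree of variation converts a score into a log2 fold-distance from the
least-deviating variant at the same codon position:

    x_i = ES_i if ES_i > 1 else 1/ES_i       DoV_ij = log2(x_ij / x_min_j)

Phenotypes combine an activity class from ES^CcdB (hyperactive < 0.7,
inactive > 1.8, strict inequalities) with a regulation class from ES^RelE
(repressing > 1, derepressing < 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_counts import (
    REPLICATES,
    CountTable,
    FractionTable,
    MutantVariant,
    filter_by_resistant_depth,
    normalize_fractions,
)

PHENOTYPES = ("H+D", "H+R", "I+D", "I+R", "neutral")


class ScoringError(RuntimeError):
    """Raised when scores cannot be computed (e.g. reference dropout)."""


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs on the linear ES scale."""

    hyperactive_max: float = 0.7
    inactive_min: float = 1.8
    rele_neutral: float = 1.0

    def __post_init__(self) -> None:
        if not self.hyperactive_max < self.inactive_min:
            raise ValueError("hyperactive_max must be < inactive_min")


def deepseq_ratio(
    f_selective: FractionTable, f_resistant: FractionTable
) -> tuple[dict[MutantVariant, float], float]:
    """Per-variant selective/resistant fraction ratios plus the WT ratio.

    A retained variant must have a positive resistant fraction (the depth
    filter guarantees it); zero selective fraction yields ratio 0, flagged
    downstream as depletion.
    """
    if f_resistant.wt_fraction <= 0:
        raise ScoringError("reference variant has zero resistant fraction")
    ratios: dict[MutantVariant, float] = {}
    for v, f_sel in f_selective.fractions.items():
        f_res = f_resistant.get(v)
        if f_res <= 0:
            raise ScoringError(
                f"retained variant {v.label} has zero resistant fraction; "
                "the depth filter should have removed it"
            )
        ratios[v] = f_sel / f_res
    wt_ratio = f_selective.wt_fraction / f_resistant.wt_fraction
    return ratios, wt_ratio


def enrichment_score(ratio_variant: float, ratio_wt: float) -> float:
    """Normalise a deepseq ratio to the reference ratio."""
    if ratio_wt <= 0:
        raise ScoringError("reference variant dropped out of the selective strain")
    return ratio_variant / ratio_wt


def combine_replicates(values: Sequence[float], how: str = "mean") -> float:
    """Average per-replicate scores (arithmetic by default, geometric option)."""
    if how == "mean":
        return float(np.mean(values))
    if how == "geometric":
        if any(v <= 0 for v in values):
            return 0.0
        return float(np.exp(np.mean(np.log(values))))
    raise ValueError(f"unknown replicate combination {how!r}")


def fold_distance(es: float) -> float:
    """Distance of a score from 1 on the fold scale: ES if >1 else 1/ES."""
    if es <= 0:
        raise ValueError("fold distance undefined for non-positive score")
    return es if es > 1 else 1.0 / es


def degree_of_variation(
    scores_at_position: Mapping[MutantVariant, float]
) -> dict[MutantVariant, float]:
    """Per-variant log2 fold-distance from the position's least-deviating variant.

    Variants with ES = 0 (selective-strain dropout) are excluded with a
    warning and reported as NaN.
    """
    defined = {v: es for v, es in scores_at_position.items() if es > 0}
    dropped = set(scores_at_position) - set(defined)
    if dropped:
        warnings.warn(
            "degree of variation undefined for depleted variant(s): "
            + ", ".join(sorted(v.label for v in dropped))
        )
    out: dict[MutantVariant, float] = {v: float("nan") for v in dropped}
    if defined:
        x = {v: fold_distance(es) for v, es in defined.items()}
        x_min = min(x.values())
        for v, xi in x.items():
            out[v] = math.log2(xi / x_min)
    return out


def classify(
    es_ccdb: float, es_rele: float, thresholds: Thresholds = Thresholds()
) -> tuple[str, str, str]:
    """(activity_class, regulation_class, phenotype) for one variant.

    All inequalities are strict: a score exactly at a cutoff is not called.
    """
    if es_ccdb < thresholds.hyperactive_max:
        activity = "hyperactive"
    elif es_ccdb > thresholds.inactive_min:
        activity = "inactive"
    else:
        activity = "intermediate"
    if es_rele > thresholds.rele_neutral:
        regulation = "repressing"
    elif es_rele < thresholds.rele_neutral:
        regulation = "derepressing"
    else:
        regulation = "neutral"
    if activity == "intermediate" or regulation == "neutral":
        phenotype = "neutral"
    else:
        phenotype = f"{activity[0].upper()}+{regulation[0].upper()}"
    return activity, regulation, phenotype


def kmeans_thresholds(
    es_values: Iterable[float],
    k: int = 3,
    seed: int = 0,
    n_init: int = 100,
) -> Thresholds:
    """Advisory thresholds from k-means clustering of log2-scores.

    Clusters log2(ES) into k groups and returns the midpoints between
    adjacent cluster extremes, mapped back to the linear scale, as candidate
    hyperactive/inactive cutoffs.  Classification itself defaults to the
    fixed constants; this is a data-driven sanity check only.
    """
    from sklearn.cluster import KMeans

    values = np.asarray([v for v in es_values if v > 0], dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2 to define boundaries")
    if len(np.unique(values)) < k:
        raise ValueError(f"need at least {k} distinct positive values")
    log_v = np.log2(values).reshape(-1, 1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(log_v)
    order = np.argsort(km.cluster_centers_.ravel())
    boundaries = []
    for lo, hi in zip(order[:-1], order[1:]):
        upper_of_lo = log_v[km.labels_ == lo].max()
        lower_of_hi = log_v[km.labels_ == hi].min()
        boundaries.append((2.0 ** upper_of_lo + 2.0 ** lower_of_hi) / 2.0)
    return Thresholds(
        hyperactive_max=float(boundaries[0]), inactive_min=float(boundaries[-1])
    )


def _replicate_es(
    tables: Mapping[tuple[str, int], CountTable],
    retained: set[MutantVariant],
    strain: str,
    rep: int,
    pseudocount: float = 0.0,
) -> dict[MutantVariant, float]:
    res = tables[("resistant", rep)]
    sel = tables[(strain, rep)]
    if pseudocount:
        res = CountTable(
            {v: c + pseudocount for v, c in res.counts.items()},
            res.wt_count + pseudocount,
            res.strain,
            res.replicate,
        )
        sel = CountTable(
            {v: c + pseudocount for v, c in sel.counts.items()},
            sel.wt_count + pseudocount,
            sel.strain,
            sel.replicate,
        )
    f_res = normalize_fractions(res, retained)
    f_sel = normalize_fractions(sel, retained)
    ratios, wt_ratio = deepseq_ratio(f_sel, f_res)
    return {v: enrichment_score(r, wt_ratio) for v, r in ratios.items()}


def _with_reference(
    tables: Mapping[tuple[str, int], CountTable],
    reference_label: str,
) -> Mapping[tuple[str, int], CountTable]:
    """Re-anchor the tables on a mutant variant chosen as the new reference.

    Used for the double-library analysis where a parent hyperactive mutation
    (e.g. K4_AAA) is the background 'wild type': that variant's counts
    become the reference counts and it leaves the variant set.
    """
    any_table = next(iter(tables.values()))
    matches = [v for v in any_table.variants if v.label == reference_label]
    if not matches:
        raise ScoringError(f"reference variant {reference_label!r} not in tables")
    ref = matches[0]
    out = {}
    for cond, t in tables.items():
        counts = {v: c for v, c in t.counts.items() if v != ref}
        out[cond] = CountTable(counts, t.get(ref), t.strain, t.replicate)
    return out


def score_library(
    tables: Mapping[tuple[str, int], CountTable],
    min_reads: int = 20,
    thresholds: Thresholds = Thresholds(),
    combine: str = "mean",
    reference_label: str | None = None,
    dv_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Full scoring pass: filter, normalise, score, average, classify.

    Returns one row per retained variant, indexed by label, with
    per-replicate and averaged ES^CcdB / ES^RelE, a depleted flag (zero
    reads in a selective strain), degree-of-variation columns, and the
    activity/regulation/phenotype classes.  ``dv_pseudocount`` optionally
    adds a pseudocount to every count when computing the scores underlying
    the log-based DoV statistics; the reported ES columns are never
    pseudocounted.
    """
    if reference_label is not None:
        tables = _with_reference(tables, reference_label)
    retained = filter_by_resistant_depth(
        tables[("resistant", 1)], tables[("resistant", 2)], min_reads
    )
    es: dict[str, dict[MutantVariant, float]] = {}
    for strain, key in (("sensitive", "ccdb"), ("relE", "rele")):
        per_rep = [
            _replicate_es(tables, retained, strain, rep) for rep in REPLICATES
        ]
        es[key] = {
            v: combine_replicates([per_rep[0][v], per_rep[1][v]], combine)
            for v in retained
        }
        es[f"{key}_rep"] = per_rep  # type: ignore[assignment]

    if dv_pseudocount:
        dv_es = {}
        for strain, key in (("sensitive", "ccdb"), ("relE", "rele")):
            per_rep = [
                _replicate_es(tables, retained, strain, rep, dv_pseudocount)
                for rep in REPLICATES
            ]
            dv_es[key] = {
                v: combine_replicates([per_rep[0][v], per_rep[1][v]], combine)
                for v in retained
            }
    else:
        dv_es = {"ccdb": es["ccdb"], "rele": es["rele"]}

    dv: dict[str, dict[MutantVariant, float]] = {"ccdb": {}, "rele": {}}
    for key in ("ccdb", "rele"):
        by_pos: dict[int, dict[MutantVariant, float]] = {}
        for v, s in dv_es[key].items():
            by_pos.setdefault(v.position, {})[v] = s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pos_scores in by_pos.values():
                dv[key].update(degree_of_variation(pos_scores))

    rows = []
    for v in sorted(retained):
        e_c, e_r = es["ccdb"][v], es["rele"][v]
        activity, regulation, phenotype = classify(e_c, e_r, thresholds)
        rows.append(
            {
                "label": v.label,
                "position": v.position,
                "wt_codon": v.wt_codon,
                "mut_codon": v.mut_codon,
                "amino_acid": v.amino_acid,
                "es_ccdb_rep1": es["ccdb_rep"][0][v],
                "es_ccdb_rep2": es["ccdb_rep"][1][v],
                "es_rele_rep1": es["rele_rep"][0][v],
                "es_rele_rep2": es["rele_rep"][1][v],
                "es_ccdb": e_c,
                "es_rele": e_r,
                "depleted": e_c == 0 or e_r == 0,
                "es_ccdb_dv": dv["ccdb"][v],
                "es_rele_dv": dv["rele"][v],
                "activity_class": activity,
                "regulation_class": regulation,
                "phenotype": phenotype,
            }
        )
    return pd.DataFrame(rows).set_index("label")
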