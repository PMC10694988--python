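"""Region-stratified summaries, correlation matrices and pipeline orchestration.

The gene is partitioned into an N-terminal (codons 1-13), middle (14-86)
and C-terminal (87-101) region — the initiation, elongation and
termination neighbourhoods of a 101-codon toxin.  Summaries include
position-averaged scores, moving averages over mutants ordered by position
(window of 5), Pearson correlation matrices between scores and covariates
with a p <= 0.05 significance mask, per-residue coefficients of variation,
and per-amino-acid phenotype counts.

``run_pipeline`` chains simulation (or count-table input), filtering,
scoring, classification, covariates and summaries into a TSV report bundle
plus a run-metadata log; with a fixed seed the bundle is byte-identical
across runs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import Thresholds, score_library
from .io_counts import MutantVariant, read_count_table, write_count_table
from . import codon_metrics, simulate

REGIONS = ("N-terminal", "middle", "C-terminal")


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous, non-overlapping split of codon positions into regions."""

    n_terminal_end: int = 13
    middle_end: int = 86
    length: int = 101

    def __post_init__(self) -> None:
        if not 1 <= self.n_terminal_end < self.middle_end < self.length:
            raise ValueError("region bounds must satisfy 1 <= n < m < length")

    def region_of(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        if position <= self.n_terminal_end:
            return "N-terminal"
        if position <= self.middle_end:
            return "middle"
        return "C-terminal"


def region_of(position: int, partition: RegionPartition = RegionPartition()) -> str:
    return partition.region_of(position)


def position_average(scores: pd.DataFrame, column: str = "es_ccdb") -> pd.Series:
    """Arithmetic mean of a score over the variants at each position."""
    return scores.groupby("position")[column].mean()


def moving_average(values: Sequence[float], window: int = 5) -> list[float]:
    """Centred moving average with truncated edge windows; length-preserving."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = pd.Series(list(values), dtype=float)
    if arr.empty:
        raise ValueError("empty input")
    return arr.rolling(window, center=True, min_periods=1).mean().tolist()


def correlation_matrix(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values and a mask.

    Observations are pairwise-complete; cells with fewer than 3 complete
    pairs or zero variance are reported as NaN.  ``mask`` is True where the
    correlation is significant (p <= alpha); ``bh_correct`` optionally
    applies a Benjamini-Hochberg adjustment to the off-diagonal p-values
    (off by default, matching the unadjusted convention).
    """
    cols = list(variables) if variables is not None else list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3 or pair[cols[i]].nunique() < 2 or pair[cols[j]].nunique() < 2:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(pair[cols[i]], pair[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(k, 1)
        flat = p.values[iu]
        ok = ~np.isnan(flat)
        if ok.any():
            adj = flat.copy()
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
            p_adj = p.values.copy()
            p_adj[iu] = adj
            p_adj[(iu[1], iu[0])] = adj
            p = pd.DataFrame(p_adj, index=cols, columns=cols)
    mask = p <= alpha
    return {"r": r, "p": p, "mask": mask}


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation over mean; NaN with fewer than 2 values."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(arr.std(ddof=1) / mean)


def cv_by_position(scores: pd.DataFrame, column: str = "es_ccdb") -> pd.Series:
    return scores.groupby("position")[column].apply(
        lambda s: coefficient_of_variation(s.values)
    )


def aa_phenotype_counts(
    scores: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Hyperactive and inactive variant counts per amino acid (20 rows)."""
    amino_acids = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
    out = pd.DataFrame(0, index=amino_acids, columns=["hyperactive", "inactive"])
    for _, row in scores.iterrows():
        aa = row["amino_acid"]
        if aa not in out.index:
            continue
        if row["es_ccdb"] < thresholds.hyperactive_max:
            out.loc[aa, "hyperactive"] += 1
        elif row["es_ccdb"] > thresholds.inactive_min:
            out.loc[aa, "inactive"] += 1
    return out


def region_summary(
    scores: pd.DataFrame, partition: RegionPartition
) -> pd.DataFrame:
    """Variant counts and mean scores per gene region."""
    df = scores.copy()
    df["region"] = [partition.region_of(p) for p in df["position"]]
    grouped = df.groupby("region")
    summary = grouped.agg(
        n_variants=("es_ccdb", "size"),
        mean_es_ccdb=("es_ccdb", "mean"),
        mean_es_rele=("es_rele", "mean"),
    )
    return summary.reindex([r for r in REGIONS if r in summary.index])


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_codons": 101, "depth": 1_000_000, "model": "direct-rho"},
    "counts_path": None,
    "min_reads": 20,
    "thresholds": {"hyperactive_max": 0.7, "inactive_min": 1.8},
    "replicate_combine": "mean",
    "reference_label": None,
    "partition": {"n_terminal_end": 13, "middle_end": 86},
}


def run_pipeline(config: Mapping, out_dir) -> dict[str, Path]:
    """Execute filter -> normalise -> score -> classify -> covariates -> summaries.

    ``config`` follows DEFAULT_CONFIG: either ``counts_path`` points at a
    count TSV, or the ``simulate`` block generates one (written alongside
    the outputs together with a ground-truth table).  Returns the mapping
    of artifact names to written paths.
    """
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    seed = int(cfg["seed"])

    try:
        if cfg.get("counts_path"):
            tables = read_count_table(cfg["counts_path"], cfg.get("schema"))
            truth = None
        else:
            sim_cfg = simulate.SimConfig(
                depth=int(cfg["simulate"].get("depth", 1_000_000)),
                seed=seed,
                model=cfg["simulate"].get("model", "direct-rho"),
            )
            gene = simulate.random_gene(int(cfg["simulate"].get("n_codons", 101)), seed)
            variants = simulate.enumerate_synonymous_library(gene)
            truth = simulate.make_truth(variants, sim_cfg)
            tables = simulate.sample_counts(truth, sim_cfg)
            wt_variant = MutantVariant(1, gene[0], gene[0])
            counts_path = out / "counts.tsv"
            write_count_table(counts_path, tables, wt_variant)
            written["counts"] = counts_path
            truth_path = out / "truth.tsv"
            pd.DataFrame(
                {
                    "label": [v.label for v in truth.variants],
                    "rho_sen": truth.rho_sen,
                    "rho_rele": truth.rho_rele,
                }
            ).to_csv(truth_path, sep="\t", index=False)
            written["truth"] = truth_path
    except Exception as exc:
        raise RuntimeError(f"[input stage] {exc}") from exc

    try:
        thresholds = Thresholds(**cfg["thresholds"])
        scores = score_library(
            tables,
            min_reads=int(cfg["min_reads"]),
            thresholds=thresholds,
            combine=cfg["replicate_combine"],
            reference_label=cfg.get("reference_label"),
        )
    except Exception as exc:
        raise RuntimeError(f"[scoring stage] {exc}") from exc

    try:
        variants = [
            MutantVariant(int(r["position"]), r["wt_codon"], r["mut_codon"])
            for _, r in scores.iterrows()
        ]
        covariates = codon_metrics.covariates_for_variants(variants)
    except Exception as exc:
        raise RuntimeError(f"[covariate stage] {exc}") from exc

    try:
        merged = scores.join(covariates[["delta_gc", "rcu", "rcu_dv", "rtrnaa"]])
        corr = correlation_matrix(
            merged,
            ["es_ccdb", "es_rele", "es_ccdb_dv", "es_rele_dv", "delta_gc", "rcu", "rcu_dv", "rtrnaa"],
        )
        max_pos = int(scores["position"].max())
        partition = RegionPartition(
            length=max(max_pos, cfg["partition"]["middle_end"] + 1),
            **cfg["partition"],
        )
        regions = region_summary(scores, partition)
    except Exception as exc:
        raise RuntimeError(f"[summary stage] {exc}") from exc

    float_fmt = "%.10g"
    scores_path = out / "scores.tsv"
    scores.to_csv(scores_path, sep="\t", float_format=float_fmt)
    written["scores"] = scores_path
    cov_path = out / "covariates.tsv"
    covariates.to_csv(cov_path, sep="\t", float_format=float_fmt)
    written["covariates"] = cov_path
    for name in ("r", "p"):
        path = out / f"correlation_{name}.tsv"
        corr[name].to_csv(path, sep="\t", float_format=float_fmt)
        written[f"correlation_{name}"] = path
    regions_path = out / "regions.tsv"
    regions.to_csv(regions_path, sep="\t", float_format=float_fmt)
    written["regions"] = regions_path

    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write("synoscan run metadata\n")
        fh.write(f"python: {sys.version.split()[0]}\n")
        fh.write(f"seed: {seed}\n")
        fh.write(f"min_reads: {cfg['min_reads']}\n")
        fh.write(f"thresholds: {cfg['thresholds']}\n")
        fh.write(f"replicate_combine: {cfg['replicate_combine']}\n")
        fh.write(f"n_scored_variants: {len(scores)}\n")
    written["log"] = log_path
    return written
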