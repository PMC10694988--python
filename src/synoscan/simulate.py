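"""Synthetic synonymous-variant libraries with known ground truth.

The generator emulates the study design end to end: every position of a
~100-codon toxin gene mutated to each synonymous codon, the resulting
library observed as multinomial read counts in three strains (resistant =
neutral, sensitive = survival decreasing with free toxin, RelE reporter =
survival increasing with repression by the toxin-antitoxin complex), in two
replicates anchored by a wild-type reference.

Ground truth is carried as per-variant true ratios rho_sen and rho_relE
(expected fraction enrichment relative to the resistant strain, WT = 1).
Two truth models are offered:

* direct-rho — rho values specified or drawn directly; the cleanest setting
  for estimator-recovery tests.
* mechanistic — rho derived from a translational-efficiency factor epsilon
  and a folded-fraction phi through a minimal toxin-antitoxin balance:
  total active toxin t = epsilon * phi, complex = min(t, alpha) for an
  antitoxin capacity alpha, free toxin = t - complex, and promoter
  derepression = (alpha - complex) + gamma * free.  The gamma term models
  conditional cooperativity: excess free toxin converts the repressing
  complex into a non-repressing form, the hallmark behaviour that lets an
  over-translated toxin derepress its own operon.  Survival maps through
  exponential selection:

      rho_sen  = exp(-k_f * (free - free_WT))
      rho_relE = exp(-k_r * (derepression - derepression_WT))

  With gamma = 0 the model reduces to the pure capacity model, which can
  only reach the I+D and H+R corners; gamma > 0 also opens H+D and I+R.

The generator does not model PCR bias, sequencing error or barcode
misassignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import genetics
from .io_counts import STRAINS, CountTable, MutantVariant


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated experiment."""

    depth: int = 1_000_000
    replicates: int = 2
    seed: int = 0
    model: str = "direct-rho"
    # mechanistic constants: selection strengths, antitoxin capacity,
    # conditional-cooperativity factor
    k_f: float = 4.0
    k_r: float = 4.0
    alpha: float = 0.7
    gamma: float = 1.0
    # Dirichlet concentration for library composition; None = uniform
    dirichlet_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.model not in ("direct-rho", "mechanistic"):
            raise ValueError(f"unknown truth model {self.model!r}")


@dataclass
class SimTruth:
    """Per-variant ground truth: true ratios and library composition."""

    variants: list[MutantVariant]
    rho_sen: np.ndarray
    rho_rele: np.ndarray
    composition: np.ndarray  # simplex over variants + WT (WT last)
    epsilon: np.ndarray | None = None
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.variants)
        if len(self.rho_sen) != n or len(self.rho_rele) != n:
            raise ValueError("rho arrays must match the variant list")
        if len(self.composition) != n + 1:
            raise ValueError("composition must cover variants plus WT")
        if not np.isclose(self.composition.sum(), 1.0):
            raise ValueError("composition must sum to 1")
        if (self.composition < 0).any():
            raise ValueError("composition must be non-negative")


def random_gene(n_codons: int, seed: int, start_codon: str = "ATG") -> list[str]:
    """A random sense-codon gene (Met start, no internal stops)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    pool = [c for c in genetics.SENSE_CODONS]
    body = rng.choice(pool, size=n_codons - 1, replace=True)
    return [start_codon, *body.tolist()]


def enumerate_synonymous_library(gene: Sequence[str] | str) -> list[MutantVariant]:
    """Every single synonymous codon substitution of the gene.

    For each position, all codons of the WT amino acid other than the WT
    codon, in deterministic (position, then codon lexicographic) order.
    Synonymy guarantees no stop codon can arise at a sense position.
    """
    codons = (
        genetics.split_codons(gene) if isinstance(gene, str) else
        [genetics.validate_codon(c) for c in gene]
    )
    variants: list[MutantVariant] = []
    for pos, wt in enumerate(codons, start=1):
        if genetics.translate_codon(wt) == "*" and pos < len(codons):
            raise ValueError(f"internal stop codon at position {pos}")
        for syn in sorted(genetics.synonymous_codons(wt)):
            if syn != wt:
                variants.append(MutantVariant(pos, wt, syn))
    return variants


def truth_from_mechanism(
    epsilon: float,
    phi: float,
    config: SimConfig,
) -> tuple[float, float]:
    """(rho_sen, rho_relE) for one variant from its mechanistic parameters."""
    if epsilon <= 0 or phi <= 0:
        raise ValueError("epsilon and phi must be positive")
    if not 0 < phi <= 1:
        raise ValueError("folded fraction phi must lie in (0, 1]")

    def state(total: float) -> tuple[float, float]:
        complexed = min(total, config.alpha)
        free = total - complexed
        derepression = (config.alpha - complexed) + config.gamma * free
        return free, derepression

    free_wt, derep_wt = state(1.0)
    free, derep = state(epsilon * phi)
    rho_sen = float(np.exp(-config.k_f * (free - free_wt)))
    rho_rele = float(np.exp(-config.k_r * (derep - derep_wt)))
    return rho_sen, rho_rele


def make_truth(
    variants: Sequence[MutantVariant],
    config: SimConfig,
    rho_sen: Sequence[float] | None = None,
    rho_rele: Sequence[float] | None = None,
    epsilon: Sequence[float] | None = None,
    phi: Sequence[float] | None = None,
    rho_sigma: float = 0.5,
) -> SimTruth:
    """Assemble ground truth under the configured model.

    direct-rho: use the supplied rho arrays, or draw both from a lognormal
    with log-sd ``rho_sigma`` (median 1).  mechanistic: map per-variant
    (epsilon, phi) — default neutral (1, 1) — through the balance model.
    """
    n = len(variants)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    eps_arr = phi_arr = None
    if config.model == "direct-rho":
        if rho_sen is None:
            rho_sen = np.exp(rng.normal(0.0, rho_sigma, size=n))
        if rho_rele is None:
            rho_rele = np.exp(rng.normal(0.0, rho_sigma, size=n))
        rs, rr = np.asarray(rho_sen, float), np.asarray(rho_rele, float)
    else:
        eps_arr = np.ones(n) if epsilon is None else np.asarray(epsilon, float)
        phi_arr = np.ones(n) if phi is None else np.asarray(phi, float)
        pairs = [
            truth_from_mechanism(e, p, config) for e, p in zip(eps_arr, phi_arr)
        ]
        rs = np.array([p[0] for p in pairs])
        rr = np.array([p[1] for p in pairs])
    if config.dirichlet_concentration is None:
        comp = np.full(n + 1, 1.0 / (n + 1))
    else:
        comp = rng.dirichlet(np.full(n + 1, config.dirichlet_concentration))
    return SimTruth(
        variants=list(variants),
        rho_sen=rs,
        rho_rele=rr,
        composition=comp,
        epsilon=eps_arr,
        phi=phi_arr,
    )


#: Mechanistic parameter signatures realising each phenotype class, chosen
#: so the implied true ES values sit well clear of the 0.7 / 1.8 / 1.0
#: classification cutoffs (outside a +/-40% guard band).  alpha below the
#: WT toxin level (0.7) opens the derepressing classes; alpha above it
#: (1.5, antitoxin excess) opens the repressing hyperactive corner.
CLASS_SIGNATURES: dict[str, dict[str, float]] = {
    "H+D": {"alpha": 0.7, "epsilon": 1.8, "phi": 1.0},
    "I+D": {"alpha": 0.7, "epsilon": 1.0, "phi": 0.2},
    "I+R": {"alpha": 0.7, "epsilon": 0.75, "phi": 1.0},
    "H+R": {"alpha": 1.5, "epsilon": 1.9, "phi": 1.0},
}


_STRAIN_INDEX = {s: i for i, s in enumerate(STRAINS)}


def sample_counts(
    truth: SimTruth, config: SimConfig
) -> dict[tuple[str, int], CountTable]:
    """Multinomial read counts for 3 strains x ``config.replicates`` replicates.

    Expected fractions are the library composition p in the resistant
    strain, p_i * rho_sen_i (renormalised) in the sensitive strain, and
    p_i * rho_relE_i in the RelE reporter; WT carries rho = 1 exactly.
    Each condition/replicate draws one multinomial of size ``depth`` from a
    substream derived from the master seed by fixed (strain, replicate)
    offsets, so adding a condition never perturbs existing draws.
    """
    p = truth.composition
    if p.sum() <= 0 or (p <= 0).all():
        raise ValueError("degenerate library composition")
    weights = {
        "resistant": np.ones(len(p)),
        "sensitive": np.append(truth.rho_sen, 1.0),
        "relE": np.append(truth.rho_rele, 1.0),
    }
    tables: dict[tuple[str, int], CountTable] = {}
    for strain in STRAINS:
        expected = p * weights[strain]
        expected = expected / expected.sum()
        for rep in range(1, config.replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    config.seed, spawn_key=(1 + _STRAIN_INDEX[strain], rep)
                )
            )
            draw = rng.multinomial(config.depth, expected)
            tables[(strain, rep)] = CountTable(
                counts={v: int(c) for v, c in zip(truth.variants, draw[:-1])},
                wt_count=int(draw[-1]),
                strain=strain,
                replicate=rep,
            )
    return tables
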