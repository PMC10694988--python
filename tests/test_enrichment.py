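import math

import numpy as np
import pytest

from synoscan.enrichment import (
    ScoringError,
    Thresholds,
    classify,
    combine_replicates,
    deepseq_ratio,
    degree_of_variation,
    enrichment_score,
    fold_distance,
    kmeans_thresholds,
    score_library,
)
from synoscan.io_counts import CountTable, FractionTable, MutantVariant

from conftest import make_tables

V = MutantVariant(2, "AAA", "AAG")


def frac(fractions, wt):
    return FractionTable(fractions=fractions, wt_fraction=wt)


class TestDeepseqRatio:
    def test_direct_substitution(self):
        ratios, wt = deepseq_ratio(frac({V: 0.25}, 0.75), frac({V: 0.5}, 0.5))
        assert ratios[V] == 0.5
        assert wt == 1.5

    def test_zero_selective_fraction_gives_zero_ratio(self):
        ratios, _ = deepseq_ratio(frac({V: 0.0}, 1.0), frac({V: 0.5}, 0.5))
        assert ratios[V] == 0.0

    def test_equal_fractions_give_unity(self):
        ratios, _ = deepseq_ratio(frac({V: 0.3}, 0.7), frac({V: 0.3}, 0.7))
        assert ratios[V] == 1.0

    def test_zero_resistant_fraction_is_internal_inconsistency(self):
        with pytest.raises(ScoringError, match="depth filter"):
            deepseq_ratio(frac({V: 0.5}, 0.5), frac({V: 0.0}, 1.0))


class TestEnrichmentScore:
    def test_reference_scores_exactly_one(self):
        assert enrichment_score(1.5, 1.5) == 1.0

    def test_worked_example_from_counts(self):
        # resistant: mut 100 / WT 100; sensitive: mut 50 / WT 150
        f_res = frac({V: 0.5}, 0.5)
        f_sen = frac({V: 0.25}, 0.75)
        ratios, wt_ratio = deepseq_ratio(f_sen, f_res)
        assert enrichment_score(ratios[V], wt_ratio) == pytest.approx(1 / 3)

    def test_wt_dropout_raises(self):
        with pytest.raises(ScoringError, match="reference"):
            enrichment_score(0.5, 0.0)

    def test_depth_rescaling_leaves_es_unchanged(self):
        # multiplying all counts in one condition by any constant cancels
        f_res = frac({V: 0.5}, 0.5)
        for scale in (1, 7, 100):
            counts = CountTable({V: 50 * scale}, wt_count=150 * scale)
            total = 200 * scale
            f_sen = frac({V: counts.get(V) / total}, counts.wt_count / total)
            ratios, wt_ratio = deepseq_ratio(f_sen, f_res)
            assert enrichment_score(ratios[V], wt_ratio) == pytest.approx(1 / 3)

    def test_geometric_combination_option(self):
        assert combine_replicates([0.25, 1.0], "geometric") == pytest.approx(0.5)
        assert combine_replicates([0.25, 1.0], "mean") == pytest.approx(0.625)


class TestClassify:
    @pytest.mark.parametrize(
        "es_ccdb,es_rele,expected",
        [
            (0.42, 0.35, ("hyperactive", "derepressing", "H+D")),
            (2.0, 1.5, ("inactive", "repressing", "I+R")),
            (1.0, 1.0, ("intermediate", "neutral", "neutral")),
            (0.7, 0.5, ("intermediate", "derepressing", "neutral")),  # boundary strict
            (1.8, 1.5, ("intermediate", "repressing", "neutral")),
            (0.2, 1.2, ("hyperactive", "repressing", "H+R")),
            (2.5, 0.8, ("inactive", "derepressing", "I+D")),
        ],
    )
    def test_threshold_semantics(self, es_ccdb, es_rele, expected):
        assert classify(es_ccdb, es_rele) == expected

    def test_monotone_in_es_ccdb(self):
        # decreasing es_ccdb can never move a variant towards inactive
        order = {"hyperactive": 0, "intermediate": 1, "inactive": 2}
        grid = np.linspace(0.01, 3.0, 120)
        ranks = [order[classify(e, 1.5)[0]] for e in grid]
        assert ranks == sorted(ranks)


class TestDegreeOfVariation:
    def test_fold_distance_reflects_below_one(self):
        assert fold_distance(0.25) == 4.0
        assert fold_distance(4.0) == 4.0

    def test_worked_example(self, toy_variants):
        dv = degree_of_variation(dict(zip(toy_variants, [0.5, 2.0, 4.0])))
        assert [dv[v] for v in toy_variants] == [0.0, 0.0, 1.0]

    def test_singleton_position_is_zero(self):
        assert degree_of_variation({V: 3.0}) == {V: 0.0}

    def test_depleted_variant_excluded_with_warning(self, toy_variants):
        with pytest.warns(UserWarning, match="depleted"):
            dv = degree_of_variation(dict(zip(toy_variants, [0.0, 2.0, 4.0])))
        assert math.isnan(dv[toy_variants[0]])
        assert dv[toy_variants[2]] == 1.0

    def test_minimum_is_always_zero(self):
        rng = np.random.default_rng(7)
        variants = [MutantVariant(5, "CGT", c) for c in ["CGA", "CGC", "CGG", "AGA", "AGG"]]
        for _ in range(20):
            es = rng.lognormal(0, 1, size=5)
            dv = degree_of_variation(dict(zip(variants, es)))
            assert min(dv.values()) == 0.0
            assert all(d >= 0 for d in dv.values())


class TestKmeansThresholds:
    def test_recovers_cluster_boundaries(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [
                rng.lognormal(np.log(0.3), 0.1, 60),
                rng.lognormal(0.0, 0.1, 200),
                rng.lognormal(np.log(3.0), 0.1, 40),
            ]
        )
        th = kmeans_thresholds(values, k=3, seed=0)
        assert th.hyperactive_max < 1 < th.inactive_min

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_thresholds([1.0, 1.0, 1.0], k=3, seed=0)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            kmeans_thresholds([0.5, 1.0, 2.0], k=1, seed=0)


class TestScoreLibrary:
    def _tables(self):
        variants = [
            MutantVariant(2, "AAA", "AAG"),
            MutantVariant(4, "AAG", "AAA"),
            MutantVariant(5, "CTG", "CTA"),
        ]
        counts = {
            ("resistant", 1): [100, 100, 100],
            ("resistant", 2): [100, 100, 100],
            ("sensitive", 1): [50, 100, 200],
            ("sensitive", 2): [50, 100, 200],
            ("relE", 1): [100, 100, 100],
            ("relE", 2): [100, 100, 100],
        }
        wt = {c: 100 for c in counts}
        return make_tables(counts, wt, variants), variants

    def test_scores_are_ratios_to_wt(self):
        tables, variants = self._tables()
        scores = score_library(tables)
        # all conditions share the WT count, so ES reduces to sen/res counts
        assert scores.loc[variants[0].label, "es_ccdb"] == pytest.approx(0.5)
        assert scores.loc[variants[2].label, "es_ccdb"] == pytest.approx(2.0)
        assert (scores["es_rele"] == 1.0).all()

    def test_reference_relabelling_rescales_scores(self):
        # re-anchoring on a mutant divides every score by that mutant's score
        tables, variants = self._tables()
        base = score_library(tables, min_reads=10)
        re = score_library(tables, min_reads=10, reference_label=variants[1].label)
        assert variants[1].label not in re.index
        anchor = base.loc[variants[1].label, "es_ccdb"]
        for v in (variants[0], variants[2]):
            assert re.loc[v.label, "es_ccdb"] == pytest.approx(
                base.loc[v.label, "es_ccdb"] / anchor
            )

    def test_unknown_reference_label_raises(self):
        tables, _ = self._tables()
        with pytest.raises(ScoringError, match="not in tables"):
            score_library(tables, reference_label="K99_AAA")
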