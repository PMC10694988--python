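import itertools
import math

import numpy as np
import pandas as pd
import pytest

from synoscan import codon_metrics as cm
from synoscan import genetics
from synoscan.io_counts import MutantVariant


@pytest.fixture(scope="module")
def params():
    return cm.CodonParameterSet()


class TestDeltaGC:
    @pytest.mark.parametrize(
        "mut,wt,expected", [("AAA", "AAG", -1), ("GTC", "GTG", 0), ("AAA", "AAA", 0)]
    )
    def test_examples(self, mut, wt, expected):
        assert cm.delta_gc(mut, wt) == expected

    def test_bounded_by_three_over_all_synonymous_pairs(self):
        for aa, codons in genetics.AA_TO_CODONS.items():
            for a, b in itertools.permutations(codons, 2):
                assert abs(cm.delta_gc(a, b)) <= 3

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            cm.delta_gc("AXA", "AAA")


class TestRCU:
    def test_identity_is_one(self, params):
        assert cm.rcu("CTG", "CTG", params.usage_freq) == 1.0

    def test_direct_ratio_on_toy_table(self):
        assert cm.rcu("GGA", "GGC", {"GGA": 10.0, "GGC": 20.0}) == 0.5

    def test_non_synonymous_pair_rejected(self, params):
        with pytest.raises(ValueError, match="not synonymous"):
            cm.rcu("AAA", "GGG", params.usage_freq)

    def test_zero_wt_usage_rejected(self):
        with pytest.raises(ValueError, match="zero or missing"):
            cm.rcu("GGA", "GGC", {"GGA": 10.0, "GGC": 0.0})

    def test_reciprocal_under_swap(self, params):
        r = cm.rcu("CTA", "CTG", params.usage_freq)
        assert cm.rcu("CTG", "CTA", params.usage_freq) == pytest.approx(1 / r)

    def test_dv_mirrors_score_dv(self):
        variants = [MutantVariant(3, "GGG", c) for c in ("GGA", "GGC", "GGT")]
        dv = cm.rcu_dv(dict(zip(variants, [0.5, 2.0, 4.0])))
        assert [dv[v] for v in variants] == [0.0, 0.0, 1.0]
        assert cm.rcu_dv({variants[0]: 3.0}) == {variants[0]: 0.0}


class TestCAI:
    def test_all_optimal_codons_score_one(self, params):
        optimal = [
            max(codons, key=lambda c: params.cai_weights[c])
            for aa, codons in genetics.AA_TO_CODONS.items()
            if aa != "*"
        ]
        assert cm.cai(optimal, params.cai_weights) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        weights = {"AAA": 1.0, "AAG": 0.25}
        assert cm.cai(["AAA", "AAG"], weights) == pytest.approx(0.5)

    def test_matches_log_domain_oracle_on_random_genes(self, params):
        rng = np.random.default_rng(11)
        sense = list(genetics.SENSE_CODONS)
        for _ in range(10):
            gene = rng.choice(sense, size=50).tolist()
            # independent oracle: product of weights, n-th root, in log domain
            log_cai = sum(math.log(params.cai_weights[c]) for c in gene) / 50
            assert cm.cai(gene, params.cai_weights) == pytest.approx(
                math.exp(log_cai), abs=1e-12
            )

    def test_stop_codon_inside_gene_rejected(self, params):
        with pytest.raises(ValueError, match="stop"):
            cm.cai(["ATG", "TAA"], params.cai_weights)

    def test_ratio_symmetry(self, params):
        a, b = ["CTG", "AAA"], ["CTA", "AAG"]
        r = cm.cai_ratio(a, b, params.cai_weights)
        assert cm.cai_ratio(b, a, params.cai_weights) == pytest.approx(1 / r)
        assert cm.cai_ratio(a, a, params.cai_weights) == pytest.approx(1.0)

    def test_bounds(self, params):
        rng = np.random.default_rng(5)
        gene = rng.choice(list(genetics.SENSE_CODONS), size=30).tolist()
        assert 0 < cm.cai(gene, params.cai_weights) <= 1


class TestRtrnaA:
    def test_identity_is_one(self, params):
        assert cm.rtrnaa("GCG", "GCG", params.trna_fraction) == 1.0

    def test_summed_decoder_rule(self):
        # mutant decoded by two tRNAs at 1% and 2%, WT by one at 1.5%
        table = {"CTA": 3.0, "CTG": 1.5}  # CTA row already summed upstream
        assert cm.rtrnaa("CTA", "CTG", table) == 2.0

    def test_missing_codon_named_in_error(self, params):
        with pytest.raises(ValueError, match="GGA"):
            cm.rtrnaa("GGA", "GGC", {"GGC": 1.0})

    def test_reciprocal_under_swap(self, params):
        r = cm.rtrnaa("AAA", "AAG", params.trna_fraction)
        assert cm.rtrnaa("AAG", "AAA", params.trna_fraction) == pytest.approx(1 / r)


class TestTAI:
    def _toy_tables(self):
        # four-codon world: Lys (AAA/AAG) and Phe (TTT/TTC)
        tgcn = pd.DataFrame(
            {
                "anticodon": ["TTT", "CTT", "GAA"],
                "amino_acid": ["K", "K", "F"],
                "gene_copy_number": [4, 1, 2],
                "decodes_override": ["", "", ""],
            }
        )
        penalties = {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}
        return tgcn, penalties

    def test_weights_match_hand_computation(self):
        tgcn, penalties = self._toy_tables()
        w = cm.tai_weights(tgcn, penalties)
        # raw weights per the wobble rules:
        # AAA: WC anticodon TTT (4 copies)                  -> 4
        # AAG: WC CTT (1 copy) + U:G wobble TTT (4 copies)  -> 1 + 0.32*4 = 2.28
        # TTT: WC AAA (0) + G:U wobble GAA (2 copies)       -> 0.59*2 = 1.18
        # TTC: WC GAA (2 copies)                            -> 2
        assert w["AAA"] == pytest.approx(1.0)
        assert w["AAG"] == pytest.approx(2.28 / 4)
        assert w["TTT"] == pytest.approx(1.18 / 4)
        assert w["TTC"] == pytest.approx(2 / 4)

    def test_max_weight_codon_normalises_to_one(self, params):
        assert max(params.tai_weights.values()) == pytest.approx(1.0)
        assert all(0 < v <= 1 for v in params.tai_weights.values())

    def test_single_codon_gene_is_its_own_weight(self, params):
        w = params.tai_weights["GCG"]
        assert cm.tai(["GCG"], weights=params.tai_weights) == pytest.approx(w)

    def test_gene_score_is_geometric_mean(self):
        tgcn, penalties = self._toy_tables()
        w = cm.tai_weights(tgcn, penalties)
        gene = ["AAA", "AAG", "TTC"]
        expected = (w["AAA"] * w["AAG"] * w["TTC"]) ** (1 / 3)
        assert cm.tai(gene, tgcn, penalties) == pytest.approx(expected)

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(
            {"anticodon": [], "amino_acid": [], "gene_copy_number": [], "decodes_override": []}
        )
        with pytest.raises(ValueError, match="empty"):
            cm.tai_weights(empty, {})


class TestWobble:
    def test_third_base_extraction(self):
        assert cm.wobble_base("AAA") == "A"

    def test_composition_counts_and_fractions(self):
        counts, fractions = cm.wobble_composition(["AAA", "AAT", "AAG", "AAG"])
        assert counts == {"A": 1, "T": 1, "G": 2, "C": 0}
        assert fractions["G"] == 0.5

    def test_empty_set_is_all_zero(self):
        counts, fractions = cm.wobble_composition([])
        assert set(counts.values()) == {0}
        assert set(fractions.values()) == {0.0}


class TestHydropathy:
    def test_poly_alanine_unsmoothed(self, params):
        assert cm.hydropathy_profile("AAAA", params.hydropathy) == [1.8] * 4

    def test_full_window_equals_sequence_mean(self, params):
        seq = "MKLVI"
        prof = cm.hydropathy_profile(seq, params.hydropathy, window=5)
        mean = np.mean([params.hydropathy[a] for a in seq])
        assert prof[2] == pytest.approx(mean)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_bad_window_rejected(self, params, window):
        with pytest.raises(ValueError, match="odd"):
            cm.hydropathy_profile("AAA", params.hydropathy, window=window)

    def test_unknown_residue_rejected(self, params):
        with pytest.raises(ValueError, match="unknown residue"):
            cm.hydropathy_profile("AXZ", params.hydropathy)


class TestCovariateTable:
    def test_identity_invariants_and_columns(self, params):
        variants = [MutantVariant(4, "AAG", "AAA"), MutantVariant(4, "AAG", "AAG")]
        df = cm.covariates_for_variants(variants, params)
        ident = df.loc["K4_AAG"]
        assert ident["rcu"] == 1.0 and ident["delta_gc"] == 0
        assert set(df["wobble_base"]) <= set("ACGT")
        assert not df["rcu_dv"].isna().any()
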