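import pytest

from synoscan.io_counts import CountTable, MutantVariant
from synoscan.rna import ViennaEngine


@pytest.fixture(scope="session")
def engine():
    return ViennaEngine()


@pytest.fixture()
def toy_variants():
    return [
        MutantVariant(2, "AAA", "AAG"),
        MutantVariant(3, "CTG", "CTA"),
        MutantVariant(3, "CTG", "TTA"),
    ]


def make_tables(counts_by_cond, wt_by_cond, variants):
    """Build a full six-condition table dict from per-condition count lists."""
    tables = {}
    for cond, counts in counts_by_cond.items():
        tables[cond] = CountTable(
            counts=dict(zip(variants, counts)),
            wt_count=wt_by_cond[cond],
            strain=cond[0],
            replicate=cond[1],
        )
    return tables


@pytest.fixture()
def toy_count_tsv(tmp_path):
    """A well-formed three-row count table: two variants plus the WT anchor."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "position\twt_codon\tmut_codon\tres_rep1\tres_rep2\tsen_rep1\tsen_rep2\trelE_rep1\trelE_rep2\tis_wt\n"
        "2\tAAA\tAAG\t100\t110\t50\t55\t80\t88\t0\n"
        "3\tCTG\tCTA\t200\t190\t210\t200\t150\t140\t0\n"
        "1\tATG\tATG\t500\t480\t520\t510\t450\t430\t1\n"
    )
    return path
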