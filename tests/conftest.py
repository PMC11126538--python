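import numpy as np
import pytest

from pqtlmr import fixtures
from pqtlmr.sumstats import SummaryRecord, SummaryTable


@pytest.fixture
def toy_exposure():
    return fixtures.toy_exposure()


@pytest.fixture
def toy_outcome():
    return fixtures.toy_outcome()


@pytest.fixture
def toy_ld():
    return fixtures.toy_ld()


@pytest.fixture
def toy_locus():
    return fixtures.toy_locus()


def make_record(variant_id="rs1", chrom="1", pos=100, effect_allele="A",
                other_allele="G", eaf=0.3, beta=0.1, se=0.05, pval=0.0455,
                n=10_000, n_cases=None, n_controls=None) -> SummaryRecord:
    return SummaryRecord(variant_id, chrom, pos, effect_allele, other_allele,
                         eaf, beta, se, pval, n, n_cases, n_controls)


def make_table(records, trait_id="trait", trait_type="quantitative") -> SummaryTable:
    return SummaryTable.from_records(trait_id, trait_type, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240429)
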