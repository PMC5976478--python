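import pytest

from lumdriver import CohortVariants, SimulationParams, VariantRecord, simulate_cohort


def make_variant(**overrides) -> VariantRecord:
    base = dict(
        sample_id="S01",
        gene="GENE1",
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        flank5="A",
        flank3="G",
        consequence="missense",
    )
    base.update(overrides)
    return VariantRecord(**base)


@pytest.fixture
def tiny_cohort() -> CohortVariants:
    records = [
        make_variant(sample_id="S01", pos=100),
        make_variant(sample_id="S01", pos=200, ref="G", alt="A", flank5="C", flank3="G",
                     consequence="synonymous"),
        make_variant(sample_id="S02", pos=300, gene="GENE2", consequence="nonsense"),
    ]
    return CohortVariants(records=records, territory_mbp=62.0)


@pytest.fixture(scope="session")
def default_cohort() -> CohortVariants:
    """The emulated 8-sample cohort under the default study conditions."""
    return simulate_cohort(SimulationParams(seed=11))
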