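import pytest

from methmorph import PromoterSpec, generate_promoter


@pytest.fixture(scope="session")
def promoter():
    """Default 2 kb promoter carrying three CpG islands."""
    return generate_promoter(PromoterSpec(seed=0))


@pytest.fixture(scope="session")
def amplicon(promoter):
    """Short amplicon over the first island, the unit the reads cover."""
    a, b = promoter.islands[0]
    start = max(0, a - 20)
    end = min(len(promoter), min(b, a + 220) + 20)
    return promoter.subregion(start, end, name="amplicon")
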