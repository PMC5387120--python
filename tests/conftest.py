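import pytest

import hmoxmeta as hm


@pytest.fixture(scope="session")
def studies():
    """The seven published case-control studies packaged with the library."""
    return hm.load_fixture()


@pytest.fixture(scope="session")
def allele_effects_l(studies):
    """Woolf effects for the L vs S+M contrast (five studies report alleles)."""
    return hm.study_effects(studies, hm.Comparison.ALLELE_L)


@pytest.fixture(scope="session")
def genotype_effects(studies):
    """Woolf effects for the type I vs type II contrast (all seven studies)."""
    return hm.study_effects(studies, hm.Comparison.GENOTYPE)


@pytest.fixture(scope="session")
def by_id(studies):
    """Select fixture studies by id, preserving the requested order."""
    index = {s.study_id: s for s in studies}

    def _select(*ids):
        return [index[i] for i in ids]

    return _select
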