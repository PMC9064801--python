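import pytest

import viroconverge as vc


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    params = vc.SyntheticParams(seed=1)
    meta, viral, catalog, bacteria, tree, truth = vc.generate_cohort(params)
    return {
        "params": params,
        "meta": meta,
        "viral": viral,
        "catalog": catalog,
        "bacteria": bacteria,
        "tree": tree,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_abundance(default_cohort):
    c = default_cohort
    return vc.rpk_normalize(c["viral"], c["catalog"], c["meta"].samples)


@pytest.fixture(scope="session")
def default_anchored(default_cohort):
    return vc.anchor(default_cohort["meta"])
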