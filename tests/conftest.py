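import numpy as np
import pytest

import phylosite as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient deep-validation cohort, shared across read-only tests."""
    return ps.simulate_cohort(ps.deep_validation_config(seed=11, n_patients=4))


def make_call(**kw):
    """A VariantCall with passing-quality defaults, overridable per test."""
    base = dict(
        patient_id="P01",
        sample_id="P01a",
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        t_depth=100,
        t_alt=20,
        n_depth=50,
        n_alt=0,
        consequence="nonsynonymous",
        gene="G0001",
        maf_esp6500=0.0,
        maf_1000g=0.0,
        is_cancer_gene=False,
    )
    base.update(kw)
    return ps.VariantCall(**base)
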