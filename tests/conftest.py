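import numpy as np
import pytest

from mosaicevo import CohortConfig, simulate_cohort
from mosaicevo.filters import VariantCall


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 3-mouse cohort with the recurrent arm events."""
    cfg = CohortConfig(n_mice=3, samples_per_mouse=2, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_variant(
    chrom="chr1",
    pos=1000,
    ref="C",
    alt="T",
    variant_class="SNV",
    tumor_depth=50,
    tumor_alt=10,
    normal_depth=40,
    normal_alt=0,
    **kw,
):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=variant_class,
        tumor_depth=tumor_depth, tumor_alt=tumor_alt,
        normal_depth=normal_depth, normal_alt=normal_alt, **kw,
    )
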