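import numpy as np
import pytest

import cenchrom as cc


@pytest.fixture(scope="session")
def minimal_model():
    """Small single-chromosome genome with planted chromatin, shared read-only."""
    cfg = cc.minimal_preset(seed=1)
    model = cc.generate_genome(cfg)
    cc.plant_nucleosomes(model)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20151112)


def make_fragments(mids, chrom="chr1", length=147, **kw):
    mids = np.asarray(mids, dtype=np.int64)
    starts = mids - length // 2
    return cc.FragmentSet.from_arrays(np.full(len(mids), chrom, dtype=object), starts, starts + length, **kw)
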