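import numpy as np
import pytest

import pepferm as pf


@pytest.fixture(scope="session")
def media():
    return {name: pf.builtin_medium(name) for name in ("NA100", "NAP200", "P200", "P200-SO4")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)


def make_series(times, abundance, **kw):
    defaults = dict(analyte_id="a", kind="peptide", length=2)
    defaults.update(kw)
    return pf.AbundanceSeries(times=np.asarray(times, float),
                              abundance=np.asarray(abundance, float), **defaults)
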