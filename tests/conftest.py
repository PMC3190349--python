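import numpy as np
import pytest

from oamq import synthetic as syn


@pytest.fixture
def band_phantom():
    """A 60x9 px straight cartilage band at 0.3 mm pixels, one slice."""
    spec = syn.PhantomSpec(
        shape="band", thickness_px=9, length_px=60, pixel_spacing_mm=0.3,
        n_slices=1,
    )
    return syn.make_phantom(spec)


@pytest.fixture
def gapped_band_phantom():
    """Two collinear 30-px bands separated by a 10-px full-thickness gap."""
    spec = syn.PhantomSpec(
        shape="band", thickness_px=8, length_px=70, gaps=((30, 10),),
        pixel_spacing_mm=0.5, n_slices=1,
    )
    return syn.make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
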