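import numpy as np
import pytest

from plateletquant import ImagePlane, PlateletSegConfig, SynthConfig
from plateletquant import generate_field, segment_platelets


def make_plane(arr, pixel_size_nm=40.0):
    return ImagePlane(pixels=np.asarray(arr, dtype=float),
                      pixel_size_nm=pixel_size_nm)


@pytest.fixture(scope="session")
def field5():
    """One synthetic field with 5 isolated platelets and 4 debris blobs,
    segmented once and shared across tests."""
    cfg = SynthConfig(field_px=(512, 512), n_platelets=5, n_debris=4, seed=3)
    tubulin, cd63, truth = generate_field(cfg)
    platelets = segment_platelets(tubulin, cd63, PlateletSegConfig())
    return {"cfg": cfg, "tubulin": tubulin, "cd63": cd63, "truth": truth,
            "platelets": platelets}
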