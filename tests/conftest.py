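import numpy as np
import pytest

from vasoreact import spectral, synth


@pytest.fixture(scope="session")
def toy_extinction() -> spectral.ExtinctionSet:
    """Well-conditioned O(1) extinction matrix for unit-scale phantoms."""
    return spectral.ExtinctionSet(eps_hbo2_l1=1.0, eps_hbr_l1=2.0,
                                  eps_hbo2_l2=3.0, eps_hbr_l2=1.0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless DWI phantom with the built-in hemoglobin table."""
    spec = synth.default_dwi_phantom_spec(shape=(24, 24),
                                          frame_interval_s=10.0, seed=0)
    ext = spectral.default_extinction()
    return synth.gen_dwi_stack(spec, ext), spec, ext


def straight_tube_image(shape: tuple[int, int], width: int,
                        row: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Bright horizontal bar of given width and its truth mask."""
    img = np.zeros(shape)
    r0 = (shape[0] // 2 if row is None else row) - width // 2
    truth = np.zeros(shape, dtype=bool)
    truth[r0:r0 + width, :] = True
    img[truth] = 1.0
    return img, truth
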