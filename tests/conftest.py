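import numpy as np
import pytest

from lungseg import PhantomSpec, make_phantom


def brute_median(img: np.ndarray, window: int) -> np.ndarray:
    """Independent median oracle: pad by edge replication, sort each
    window, take the middle element."""
    r = window // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = np.sort(padded[i : i + window, j : j + window].ravel())
            out[i, j] = win[win.size // 2]
    return out


def brute_average(img: np.ndarray, window: int) -> np.ndarray:
    """Independent mean oracle: explicit window sums over a replicated pad."""
    r = window // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = padded[i : i + window, j : j + window].mean()
    return out


@pytest.fixture
def clean_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture
def speckled_phantom():
    return make_phantom(PhantomSpec(speckle_var=0.05, seed=7))


@pytest.fixture
def two_level_image():
    """Noiseless two-intensity image (0.2 / 0.8) with the bright disc as truth."""
    img = np.full((32, 32), 0.2)
    rr, cc = np.mgrid[0:32, 0:32]
    disc = (rr - 16) ** 2 + (cc - 16) ** 2 <= 36
    img[disc] = 0.8
    return img, disc.astype(np.uint8)
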