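import numpy as np
import pytest

from moldseed import CalibrationPair, HyperCube, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube():
    """2x2x3 cube with distinct values per voxel."""
    data = np.arange(12, dtype=np.float64).reshape(2, 2, 3)
    return HyperCube(data=data, wavelengths_nm=np.array([500.0, 600.0, 700.0]),
                     meta={"plate": "demo"})


@pytest.fixture
def fast_synth():
    """Small, quick synthetic configuration shared across tests."""
    return SyntheticConfig(
        n_bands=50, seeds_per_class=6, lines=150, samples=150,
        ellipse_axes=(7, 5), noise_sd=0.02,
    )


class StubRng:
    """Deterministic stand-in for np.random.Generator in oracle tests.

    Each method pops from a preloaded queue so a test controls every draw.
    """

    def __init__(self, uniforms=(), normals=(), signs=(), choices=()):
        self._uniforms = list(uniforms)
        self._normals = list(normals)
        self._signs = list(signs)
        self._choices = list(choices)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is not None:
            n = int(np.prod(size))
            vals = [self._pop(self._uniforms) for _ in range(n)]
            return low + np.array(vals).reshape(size) * (high - low)
        return low + self._pop(self._uniforms) * (high - low)

    def standard_normal(self, size=None):
        if size is None:
            return self._pop(self._normals)
        return np.array([self._pop(self._normals) for _ in range(int(np.prod(size)))]).reshape(size)

    def integers(self, low, high, size=None):
        # only used for +/-1 sign rows: values in {0, 1}
        vals = [self._pop(self._signs) for _ in range(int(np.prod(size)))]
        return np.array(vals, dtype=int).reshape(size)

    def choice(self, n, size=None, replace=True, p=None):
        return np.array([self._pop(self._choices) for _ in range(int(size))], dtype=int)

    @staticmethod
    def _pop(queue):
        if not queue:
            raise AssertionError("StubRng queue exhausted")
        return queue.pop(0)


@pytest.fixture
def stub_rng_cls():
    return StubRng
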