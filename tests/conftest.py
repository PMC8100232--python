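import numpy as np
import pytest

from dtialps import AcquisitionScheme, PhantomConfig, TensorField


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    """Study-protocol scheme: one b=0 plus 20 directions at b=1000."""
    return AcquisitionScheme.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noiseless_config() -> PhantomConfig:
    """Small phantom for mechanics tests (noise-free, fast to fit)."""
    return PhantomConfig(grid_shape=(20, 20, 6), snr=0.0, seed=0)


def uniform_field(diag, grid=(4, 4, 3), voxel_size=(2.0, 2.0, 2.0)) -> TensorField:
    """Spatially uniform diagonal tensor field helper."""
    t = np.zeros((*grid, 3, 3))
    for i in range(3):
        t[..., i, i] = diag[i]
    return TensorField(tensors=t, s0=np.full(grid, 100.0), voxel_size=voxel_size)


def random_spd_tensor(rng: np.random.Generator, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite tensor with diffusivity-like scale."""
    A = rng.standard_normal((3, 3))
    D = A @ A.T + 0.3 * np.eye(3)
    return D * scale / np.trace(D)
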