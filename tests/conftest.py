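import numpy as np
import pytest

from tfanet import ExpressionMatrix, generate_tfa_dataset


@pytest.fixture(scope="session")
def small_truth():
    """Small ground-truth dataset shared by model-fitting tests."""
    return generate_tfa_dataset(L=3, K=8, N=15, M=120, support_density=0.3,
                                noise_sd_P=0.1, noise_sd_E=0.1, seed=11)


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(5)
    return ExpressionMatrix(
        [f"G{i}" for i in range(4)],
        [f"S{j}" for j in range(6)],
        rng.normal(size=(4, 6)),
    )


def bivariate_normal(rho: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return z[:, 0], z[:, 1]
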