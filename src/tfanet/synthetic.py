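"""Synthetic data with the exact structure the inference method assumes.

The generator realizes the two-layer linear-Gaussian hierarchy (activities as
sparse linear combinations of regulator mRNA, targets as sparse linear
combinations of activities) and, separately, modulator-gated pairs where the
TF–target dependency switches on only when the modulator is highly expressed.
Every stage of the pipeline can therefore be tested against known ground
truth without any external data. The generator makes no attempt to mimic
microarray noise, batch structure, or real-compendium covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix
from .tfa_model import DraftNetwork


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset.

    ``E = A_true·P_true + ε_E`` and ``P_true = B_true·Q + ε_P`` hold by
    construction (exactly when the noise sds are zero). ``gated_triplets``
    lists every (modulator, tf, target) implied by the nonzero supports.
    """

    A_true: np.ndarray
    B_true: np.ndarray
    P_true: np.ndarray
    Q: np.ndarray
    E: np.ndarray
    gated_triplets: list
    noise_sd_P: float
    noise_sd_E: float
    seed: int

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.B_true.shape[0])]

    @property
    def regulator_ids(self) -> list[str]:
        L, K = self.B_true.shape
        return self.tf_ids + [f"MOD{i:03d}" for i in range(K - L)]

    @property
    def target_ids(self) -> list[str]:
        return [f"TG{i:03d}" for i in range(self.A_true.shape[0])]

    def draft(self) -> DraftNetwork:
        """The true-support draft network (self-edges forced into B)."""
        b = self.B_true != 0
        L = b.shape[0]
        b[np.arange(L), np.arange(L)] = True
        return DraftNetwork(self.tf_ids, self.regulator_ids, self.target_ids,
                            self.A_true != 0, b)

    def expression(self) -> ExpressionMatrix:
        """All regulators and targets stacked into one expression matrix."""
        genes = self.regulator_ids + self.target_ids
        values = np.vstack([self.Q, self.E])
        samples = [f"S{j:04d}" for j in range(self.Q.shape[1])]
        return ExpressionMatrix(genes, samples, values)


def _sparse_weights(rng: np.random.Generator, shape: tuple[int, int],
                    density: float, force_diag: bool) -> np.ndarray:
    """Random sparse weights, magnitudes uniform in [0.5, 1.5], random sign.

    Magnitudes are bounded away from zero so "nonzero support" is
    unambiguous in recovery tests.
    """
    mask = rng.random(shape) < density
    if force_diag:
        d = min(shape)
        mask[np.arange(d), np.arange(d)] = True
    mag = rng.uniform(0.5, 1.5, size=shape)
    sign = rng.choice([-1.0, 1.0], size=shape)
    return np.where(mask, sign * mag, 0.0)


def generate_tfa_dataset(
    L: int = 5,
    K: int = 20,
    N: int = 60,
    M: int = 400,
    support_density: float = 0.2,
    noise_sd_P: float = 0.1,
    noise_sd_E: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Simulate the two-layer latent-activity model.

    Q rows are i.i.d. standard normal; B_true has forced TF self-edges plus
    off-support entries at ``support_density``; A_true is Bernoulli at the
    same density. Deterministic given ``seed``.
    """
    if K < L:
        raise ValueError("need K >= L (TFs are the first L regulators)")
    if not (0 < support_density <= 1):
        raise ValueError("support_density must lie in (0, 1]")
    if min(L, K, N, M) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    Q = rng.standard_normal((K, M))
    B = _sparse_weights(rng, (L, K), support_density, force_diag=True)
    A = _sparse_weights(rng, (N, L), support_density, force_diag=False)
    P = B @ Q + noise_sd_P * rng.standard_normal((L, M))
    E = A @ P + noise_sd_E * rng.standard_normal((N, M))

    tf_ids = [f"TF{i:03d}" for i in range(L)]
    mod_ids = [f"MOD{i:03d}" for i in range(K - L)]
    tg_ids = [f"TG{i:03d}" for i in range(N)]
    reg_ids = tf_ids + mod_ids
    triplets = [
        (reg_ids[k], tf_ids[l], tg_ids[n])
        for l in range(L)
        for k in np.flatnonzero(B[l]) if k != l
        for n in np.flatnonzero(A[:, l])
    ]
    return SyntheticTruth(A, B, P, Q, E, triplets, noise_sd_P, noise_sd_E, seed)


def generate_modulated_triplet(
    M_samples: int = 500,
    gate_strength: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one modulator-gated pair: (m, x, y).

    m and x are i.i.d. standard normal; y = gate·x·1[m > median(m)] + noise.
    ``gate_strength=0`` yields a null triplet with no dependency anywhere.
    """
    if M_samples < 40:
        raise ValueError("need at least 40 samples")
    rng = np.random.default_rng(seed)
    m = rng.standard_normal(M_samples)
    x = rng.standard_normal(M_samples)
    gate = (m > np.median(m)).astype(float)
    y = gate_strength * x * gate + noise_sd * rng.standard_normal(M_samples)
    return m, x, y


def generate_null_matrix(G: int, M: int, seed: int = 0) -> ExpressionMatrix:
    """A G×M matrix of i.i.d. standard normals (type-I-error calibration)."""
    if G < 2 or M < 2:
        raise ValueError("need G, M >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(G)]
    samples = [f"S{j:04d}" for j in range(M)]
    return ExpressionMatrix(genes, samples, rng.standard_normal((G, M)))
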