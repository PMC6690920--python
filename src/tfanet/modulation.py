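"""Step 2: modulator detection by conditional mutual information.

A modulator is a gene whose expression level changes the strength of a
TF → target regulation. Following the MINDy-style approximation, the CMI of a
TF (x) and a target (y) given a modulator (m) is the difference between the
kernel MI computed on the samples where the modulator is most highly
expressed (top fraction) and where it is most lowly expressed (bottom
fraction):

    CMI(x, y | m) = MI(x, y | m high) − MI(x, y | m low)

Significance is assessed by permuting the modulator: each permutation induces
a random low/high sample split, the CMI is recomputed, and the observed value
is compared to that empirical null with the add-one p-value formula. A
cofactor is called a modulator of a TF when its CMI is significant for at
least half of that TF's Step-1 targets.

The permutation splits are drawn on the modulator's rank ordering, so
p-values are deterministic under a fixed seed and exactly invariant to any
sample permutation applied jointly to x, y and m (tie-free m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix
from .mi_inference import _DENSITY_FLOOR

logger = logging.getLogger(__name__)

#: chunk size cap (floats) for the batched subset-MI kernel tensors
_BATCH_BUDGET = 8_000_000


@dataclass(frozen=True)
class ModulationTriplet:
    """A modulator → TF → target triplet with its low/high MI and p-value."""

    modulator: str
    tf: str
    target: str
    mi_low: float
    mi_high: float
    p_value: float

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")

    @property
    def cmi(self) -> float:
        """CMI score: MI on the high-modulator split minus the low split."""
        return self.mi_high - self.mi_low


def split_by_modulator(m_expr: np.ndarray, fraction: float = 0.35):
    """Indices of the bottom- and top-``fraction`` samples by modulator level.

    Returns ``(low_idx, high_idx)``: the floor(fraction·M) smallest and
    largest values; ties are broken by sample order (stable sort), and both
    index arrays are returned in ascending sample order.
    """
    m_expr = np.asarray(m_expr, dtype=float)
    M = m_expr.size
    if M < 20:
        raise ValueError(f"need at least 20 samples, got {M}")
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    if np.ptp(m_expr) == 0:
        raise ValueError("constant modulator: low/high split is meaningless")
    c = int(np.floor(fraction * M))
    order = np.argsort(m_expr, kind="stable")
    return np.sort(order[:c]), np.sort(order[M - c:])


def _batch_subset_mi(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Kernel MI of (x, y) restricted to each row of subset indices ``idx``.

    ``idx`` is an (R, c) integer array; returns R clamped MI values (nats).
    Vectorised over subsets in memory-bounded chunks; bandwidths follow
    Silverman's rule on each subset.
    """
    idx = np.atleast_2d(idx)
    R, c = idx.shape
    if c < 10:
        raise ValueError(f"subset size {c} too small for kernel MI")
    chunk = max(1, _BATCH_BUDGET // (c * c))
    out = np.empty(R)
    for start in range(0, R, chunk):
        sub = idx[start:start + chunk]
        X = x[sub]  # (r, c)
        Y = y[sub]
        hx = 1.06 * X.std(axis=1) * c ** (-0.2)
        hy = 1.06 * Y.std(axis=1) * c ** (-0.2)
        if np.any(hx == 0) or np.any(hy == 0):
            raise ValueError("constant subset: kernel MI undefined")
        dX = X[:, :, None] - X[:, None, :]
        Kx = np.exp(-(dX * dX) / (2.0 * (hx * hx)[:, None, None]))
        dY = Y[:, :, None] - Y[:, None, :]
        Ky = np.exp(-(dY * dY) / (2.0 * (hy * hy)[:, None, None]))
        joint = np.einsum("rij,rij->ri", Kx, Ky)
        mx = Kx.sum(axis=2)
        my = Ky.sum(axis=2)
        ratio = c * joint / np.maximum(mx * my, _DENSITY_FLOOR)
        out[start:start + chunk] = np.log(np.maximum(ratio, _DENSITY_FLOOR)).mean(axis=1)
    return np.maximum(out, 0.0)


def _batch_subset_mi_multi(x: np.ndarray, Ys: list, idx: np.ndarray) -> np.ndarray:
    """Subset MI of (x, y) for several y vectors over shared subsets.

    Returns a (len(Ys), R) array. The x-kernel is computed once per chunk
    and reused across targets, which is what makes sharing one set of
    permuted splits across a cofactor's targets cheap.
    """
    idx = np.atleast_2d(idx)
    R, c = idx.shape
    chunk = max(1, _BATCH_BUDGET // (c * c))
    out = np.empty((len(Ys), R))
    for start in range(0, R, chunk):
        sub = idx[start:start + chunk]
        X = x[sub]
        hx = 1.06 * X.std(axis=1) * c ** (-0.2)
        if np.any(hx == 0):
            raise ValueError("constant subset: kernel MI undefined")
        dX = X[:, :, None] - X[:, None, :]
        Kx = np.exp(-(dX * dX) / (2.0 * (hx * hx)[:, None, None]))
        mx = Kx.sum(axis=2)
        for t, y in enumerate(Ys):
            Y = y[sub]
            hy = 1.06 * Y.std(axis=1) * c ** (-0.2)
            if np.any(hy == 0):
                raise ValueError("constant subset: kernel MI undefined")
            dY = Y[:, :, None] - Y[:, None, :]
            Ky = np.exp(-(dY * dY) / (2.0 * (hy * hy)[:, None, None]))
            joint = np.einsum("rij,rij->ri", Kx, Ky)
            my = Ky.sum(axis=2)
            ratio = c * joint / np.maximum(mx * my, _DENSITY_FLOOR)
            out[t, start:start + chunk] = np.log(
                np.maximum(ratio, _DENSITY_FLOOR)).mean(axis=1)
    return np.maximum(out, 0.0)


def conditional_mi(x, y, m, fraction: float = 0.35) -> tuple[float, float, float]:
    """CMI of a (TF, target) pair given a modulator.

    Returns ``(mi_low, mi_high, cmi)`` where ``cmi = mi_high − mi_low``
    (may be negative: a loss of dependency at high modulator levels).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (x.shape == y.shape == m.shape):
        raise ValueError("x, y, m must have equal lengths")
    low, high = split_by_modulator(m, fraction)
    mi_low, mi_high = _batch_subset_mi(x, y, np.vstack([low, high]))
    return float(mi_low), float(mi_high), float(mi_high - mi_low)


def _permuted_splits(m: np.ndarray, c: int, n_perm: int, rng: np.random.Generator):
    """Random disjoint low/high sample splits for the permutation null.

    Permuting the modulator and re-splitting is equivalent to drawing the
    low/high groups at random; drawing them on m's rank ordering makes the
    result invariant to joint sample reordering.
    """
    M = m.size
    base = np.argsort(m, kind="stable")
    low = np.empty((n_perm, c), dtype=np.intp)
    high = np.empty((n_perm, c), dtype=np.intp)
    for r in range(n_perm):
        sel = base[rng.permutation(M)]
        low[r] = sel[:c]
        high[r] = sel[M - c:]
    return low, high


def permutation_pvalue(
    x, y, m,
    n_perm: int = 1000,
    seed: int | None = None,
    fraction: float = 0.35,
) -> float:
    """One-sided permutation p-value for an observed CMI gain.

    The modulator is permuted ``n_perm`` times, the CMI recomputed on each
    permuted split, and p = (1 + #{permuted cmi ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    _, _, observed = conditional_mi(x, y, m, fraction)
    rng = np.random.default_rng(seed)
    c = int(np.floor(fraction * m.size))
    low, high = _permuted_splits(m, c, n_perm, rng)
    cmi_perm = _batch_subset_mi(x, y, high) - _batch_subset_mi(x, y, low)
    return float((1 + np.sum(cmi_perm >= observed)) / (1 + n_perm))


def call_modulators(
    expr: ExpressionMatrix,
    tf: str,
    targets: list[str],
    cofactors: list[str],
    p_cutoff: float = 0.001,
    majority: float = 0.5,
    n_perm: int = 1000,
    seed: int | None = None,
    fraction: float = 0.35,
) -> list[ModulationTriplet]:
    """Call modulators of one TF among its candidate cofactors.

    For each cofactor, a per-target permutation p-value is computed against
    the cofactor-permutation null; one set of permuted splits is shared
    across that cofactor's targets (the permutation acts on the modulator
    alone, so it induces the same split for every target). The cofactor is a
    modulator iff the fraction of targets with p < ``p_cutoff`` is at least
    ``majority``; returned triplets cover the called modulators' significant
    targets only.
    """
    if not targets:
        logger.warning("call_modulators: TF %s has no Step-1 targets", tf)
        return []
    x = expr.row(tf)
    ys = [expr.row(tg) for tg in targets]
    rng = np.random.default_rng(seed)
    results: list[ModulationTriplet] = []
    for cof in cofactors:
        m = expr.row(cof)
        low, high = split_by_modulator(m, fraction)
        c = low.size
        perm_low, perm_high = _permuted_splits(m, c, n_perm, rng)
        obs = _batch_subset_mi_multi(x, ys, np.vstack([low, high]))
        cmi_perm = (_batch_subset_mi_multi(x, ys, perm_high)
                    - _batch_subset_mi_multi(x, ys, perm_low))
        sig: list[ModulationTriplet] = []
        for t, tg in enumerate(targets):
            obs_low, obs_high = obs[t]
            observed = obs_high - obs_low
            p = float((1 + np.sum(cmi_perm[t] >= observed)) / (1 + n_perm))
            if p < p_cutoff:
                sig.append(ModulationTriplet(cof, tf, tg, float(obs_low),
                                             float(obs_high), p))
        if len(sig) / len(targets) >= majority:
            results.extend(sig)
            logger.info("call_modulators: %s called for TF %s (%d/%d targets)",
                        cof, tf, len(sig), len(targets))
    return results
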