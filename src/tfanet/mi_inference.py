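"""Step 1: pairwise TF–target screening by kernel mutual information.

Mutual information between a TF and a candidate target is estimated with a
product-Gaussian-kernel density estimator evaluated at the observed points
(resubstitution average of ``log f(x,y)/(f1(x) f2(y))``), per-variable
bandwidths from Silverman's rule. Significance comes from a location-scale
Student-t null fitted to the pooled MI of all screened pairs: each pair gets
the upper-tail probability of its MI under that fit, and pairs below the
p-value cutoff form the draft regulatory layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix, GeneRoleSets

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
# densities are floored before taking logs
_DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class RegulatoryPair:
    """A screened TF → target edge with its MI score and null p-value."""

    tf: str
    target: str
    mi: float
    p_value: float

    def __post_init__(self):
        if self.mi < 0:
            raise ValueError("mi must be nonnegative (clamp before constructing)")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class MiNullFit:
    """Location-scale Student-t fitted to pooled pair MI values."""

    loc: float
    scale: float
    df: float
    n_pairs_fit: int
    method: str = "mle"

    def __post_init__(self):
        if self.scale <= 0 or self.df <= 0:
            raise ValueError("scale and df must be positive")

    def upper_tail(self, mi) -> np.ndarray:
        """P(T > (mi − μ)/s) under the fitted null."""
        return stats.t.sf(np.asarray(mi, dtype=float), self.df,
                          loc=self.loc, scale=self.scale)


def estimate_bandwidth(x: np.ndarray) -> float:
    """Silverman rule-of-thumb Gaussian bandwidth h = 1.06 · sd(x) · n^(−1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("constant vector: bandwidth undefined")
    return 1.06 * sd * n ** (-0.2)


def _kernel_matrix(x: np.ndarray, h: float) -> np.ndarray:
    """Unnormalised Gaussian kernel matrix exp(−(xi−xj)²/2h²)."""
    d = x[:, None] - x[None, :]
    return np.exp(-(d * d) / (2.0 * h * h))


def _mi_from_kernels(Kx: np.ndarray, Ky: np.ndarray) -> float:
    """Resubstitution MI from two precomputed kernel matrices (nats, unclamped).

    Normalisation constants of the Gaussian kernels cancel in the ratio
    f(x,y) / (f1(x) f2(y)), leaving n·Σⱼ KxKy / (Σⱼ Kx · Σⱼ Ky) per point.
    """
    n = Kx.shape[0]
    joint = np.einsum("ij,ij->i", Kx, Ky)
    mx = Kx.sum(axis=1)
    my = Ky.sum(axis=1)
    ratio = n * joint / np.maximum(mx * my, _DENSITY_FLOOR)
    return float(np.mean(np.log(np.maximum(ratio, _DENSITY_FLOOR))))


def kernel_mi(x: np.ndarray, y: np.ndarray, units: str = "nats") -> float:
    """Gaussian-kernel mutual information estimate between two samples.

    Parameters
    ----------
    x, y
        Equal-length vectors of at least 20 paired observations, neither
        constant.
    units
        ``"nats"`` (natural log, default) or ``"bits"``.

    Returns
    -------
    Nonnegative MI estimate; small negative estimates are clamped to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 20:
        raise ValueError(f"need at least 20 observations, got {x.size}")
    Kx = _kernel_matrix(x, estimate_bandwidth(x))
    Ky = _kernel_matrix(y, estimate_bandwidth(y))
    mi = max(_mi_from_kernels(Kx, Ky), 0.0)
    if units == "bits":
        mi /= LN2
    elif units != "nats":
        raise ValueError(f"unknown units {units!r}")
    return mi


def fit_mi_null(mis: np.ndarray) -> MiNullFit:
    """Fit a location-scale Student-t to pooled MI values by MLE.

    Falls back to method-of-moments with ν fixed at 5 if the MLE does not
    produce a usable fit (logged).
    """
    mis = np.asarray(mis, dtype=float)
    try:
        df, loc, scale = stats.t.fit(mis)
        if not (np.isfinite([df, loc, scale]).all() and df > 0 and scale > 0):
            raise RuntimeError("degenerate t fit")
        return MiNullFit(float(loc), float(scale), float(df), mis.size, "mle")
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("t MLE failed (%s); falling back to moments, df=5", exc)
        df = 5.0
        loc = float(np.mean(mis))
        # var of t(ν, loc, s) is s²·ν/(ν−2)
        scale = float(np.sqrt(np.var(mis) * (df - 2) / df))
        return MiNullFit(loc, max(scale, 1e-12), df, mis.size, "moments")


def _gene_kernel_cache(expr: ExpressionMatrix, genes: list[str],
                       max_bytes: int = 2_000_000_000) -> dict | None:
    """Precompute per-gene kernel matrices when they fit in memory."""
    n = expr.n_samples
    if len(genes) * n * n * 8 > max_bytes:
        return None
    cache = {}
    for g in genes:
        row = expr.row(g)
        cache[g] = _kernel_matrix(row, estimate_bandwidth(row))
    return cache


def screen_pairs(
    expr: ExpressionMatrix,
    roles: GeneRoleSets,
    p_cutoff: float = 1e-4,
    units: str = "nats",
) -> tuple[list[RegulatoryPair], MiNullFit]:
    """Screen every TF × candidate-target pair by MI against a fitted t null.

    MI is computed for all pairs (TF–self pairs excluded), a Student-t is
    fitted to the pooled MI values, and each pair is assigned the upper-tail
    probability of its MI. Pairs with p < ``p_cutoff`` are returned sorted by
    p ascending (ties by descending MI), together with the null fit.
    """
    tfs = [t for t in roles.tf_ids if t in expr]
    targets = roles.targets_for(expr)
    if len(tfs) < 2 or len(targets) < 2:
        raise ValueError("need at least 2 TFs and 2 candidate targets in matrix")

    pair_list = [(tf, tg) for tf in tfs for tg in targets if tf != tg]
    if len(pair_list) < 50:
        raise ValueError(
            f"only {len(pair_list)} TF–target pairs; need >= 50 for a stable null fit"
        )

    cache = _gene_kernel_cache(expr, sorted({g for p in pair_list for g in p}))
    mis = np.empty(len(pair_list))
    for i, (tf, tg) in enumerate(pair_list):
        if cache is not None:
            mi = max(_mi_from_kernels(cache[tf], cache[tg]), 0.0)
        else:
            mi = kernel_mi(expr.row(tf), expr.row(tg))
        mis[i] = mi
    if units == "bits":
        mis /= LN2

    null = fit_mi_null(mis)
    pvals = np.clip(null.upper_tail(mis), np.finfo(float).tiny, 1.0)

    selected = [
        RegulatoryPair(tf, tg, float(mis[i]), float(pvals[i]))
        for i, (tf, tg) in enumerate(pair_list)
        if pvals[i] < p_cutoff
    ]
    selected.sort(key=lambda p: (p.p_value, -p.mi))
    logger.info("screen_pairs: %d/%d pairs significant at p<%g",
                len(selected), len(pair_list), p_cutoff)
    return selected, null
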