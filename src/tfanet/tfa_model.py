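"""Step 3: latent transcription-factor-activity model fitted by hard-EM.

The model is a two-layer linear-Gaussian hierarchy over M samples:

    P = B·Q + noise,   p_l | pa ~ N(Σ_k β_lk q_k, σ²_{P_l})     (L TFs)
    E = A·P + noise,   e_n | pa ~ N(Σ_l α_nl p_l, σ²_{E_n})     (N targets)

where Q (K×M) stacks the observed mRNA of the L TFs (first L rows, each TF's
own mRNA always a parent of its activity) and of the candidate modulators,
P (L×M) is the hidden TF activity, and E (N×M) the target expression. The
support of A (regulation) and B (modulation) is fixed to the draft network
from Steps 1–2.

Fitting is hard-assignment EM on the penalized negative log-likelihood
(the Q-marginal terms carry no information about Θ once rows are z-scored
and are dropped):

* E-step: P solves the L×L linear system C·P = D column-wise, with
  C = AᵀW_E A + diag(1/σ²_P) and D = diag(1/σ²_P)·B·Q + AᵀW_E·E —
  the exact maximizer of the complete-data likelihood in P.
* M-step: rows of A and B solve independent support-restricted lasso
  problems by ADMM (pseudo-inverse / plain least squares when λ=0). Each
  row's L1 penalty is scaled by 2σ² of that row so the row solve is the
  exact minimizer of its penalized negative-log-likelihood term; with equal
  variances this reduces to the plain ‖E−AP‖² + ‖P−BQ‖² + λ(‖A‖₁+‖B‖₁)
  objective.
* Variance step: σ² are the mean squared residuals (floored at 1e−8, which
  also keeps C positive definite).

Each step exactly (or monotonically — see the ADMM safeguard) minimizes its
block of the penalized objective, so the recorded objective trace is
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
#: coefficients below this magnitude count as zero after ADMM thresholding
ZERO_TOL = 1e-10
#: default L1 penalty: retains roughly half of a decoy-augmented draft
#: support on the standard synthetic preset (L=5, K=20, N=60, M=400,
#: noise sd 0.1), zeroing most spurious edges while keeping true ones
DEFAULT_LAMBDA = 300.0

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class DraftNetwork:
    """Candidate structure from Steps 1–2: fixed support of A and B.

    ``regulators`` lists the K rows of Q, TFs first (k = 1..L are the TFs'
    own mRNA; each TF's self-edge in B is always allowed). ``a_support`` is
    an N×L boolean mask (target regulated by TF), ``b_support`` an L×K mask
    (TF activity influenced by regulator).
    """

    tfs: list[str]
    regulators: list[str]
    targets: list[str]
    a_support: np.ndarray
    b_support: np.ndarray

    def __post_init__(self):
        L, K, N = len(self.tfs), len(self.regulators), len(self.targets)
        self.a_support = np.asarray(self.a_support, dtype=bool)
        self.b_support = np.asarray(self.b_support, dtype=bool)
        if self.regulators[:L] != self.tfs:
            raise ValueError("regulators must start with the TFs, in order")
        if self.a_support.shape != (N, L):
            raise ValueError(f"a_support must be {(N, L)}, got {self.a_support.shape}")
        if self.b_support.shape != (L, K):
            raise ValueError(f"b_support must be {(L, K)}, got {self.b_support.shape}")
        diag = self.b_support[np.arange(L), np.arange(L)]
        if not diag.all():
            missing = [self.tfs[i] for i in np.flatnonzero(~diag)]
            raise ValueError(f"TF self-edges missing from B support: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(L, K, N)."""
        return len(self.tfs), len(self.regulators), len(self.targets)

    @classmethod
    def from_step_results(cls, pairs, triplets=()) -> "DraftNetwork":
        """Build the draft support from Step-1 pairs and Step-2 triplets."""
        tfs = sorted({p.tf for p in pairs})
        targets = sorted({p.target for p in pairs})
        modulators = sorted({t.modulator for t in triplets} - set(tfs))
        regulators = tfs + modulators
        tf_i = {t: i for i, t in enumerate(tfs)}
        reg_i = {r: i for i, r in enumerate(regulators)}
        tg_i = {g: i for i, g in enumerate(targets)}

        a = np.zeros((len(targets), len(tfs)), dtype=bool)
        for p in pairs:
            a[tg_i[p.target], tf_i[p.tf]] = True
        b = np.zeros((len(tfs), len(regulators)), dtype=bool)
        b[np.arange(len(tfs)), np.arange(len(tfs))] = True
        for t in triplets:
            if t.tf not in tf_i:
                raise ValueError(f"triplet TF {t.tf!r} absent from Step-1 pairs")
            b[tf_i[t.tf], reg_i[t.modulator]] = True
        return cls(tfs, regulators, targets, a, b)

    def build_matrices(self, expr) -> tuple[np.ndarray, np.ndarray]:
        """Extract row-aligned Q (K×M) and E (N×M) from an expression matrix."""
        missing = [g for g in self.regulators + self.targets if g not in expr]
        if missing:
            raise ValueError(f"draft references genes absent from matrix: {missing}")
        return expr.subset(self.regulators), expr.subset(self.targets)


@dataclass
class TFAModel:
    """Fitted model state: strengths A/B, activities P, variances, trace."""

    draft: DraftNetwork
    A: np.ndarray
    B: np.ndarray
    P: np.ndarray
    sigma2_P: np.ndarray
    sigma2_E: np.ndarray
    lam: float
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Z-score each row (population sd); constant rows become all-zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _restricted_lstsq_rows(Y: np.ndarray, X: np.ndarray,
                           support: np.ndarray) -> np.ndarray:
    """Per-row least squares of Y (R×M) on rows of X (F×M), masked by support.

    Row r solves min_w ‖Y_r − w·X[S_r]‖² over its support columns; entries
    outside the support stay exactly zero.
    """
    R, F = support.shape
    W = np.zeros((R, F))
    for r in range(R):
        S = np.flatnonzero(support[r])
        if S.size == 0:
            continue
        sol, *_ = np.linalg.lstsq(X[S].T, Y[r], rcond=None)
        W[r, S] = sol
    return W


def init_model(draft: DraftNetwork, Q: np.ndarray, E: np.ndarray,
               lam: float = DEFAULT_LAMBDA, seed: int | None = None) -> TFAModel:
    """Deterministic initialization: activity = TF mRNA, B = self-identity.

    A⁽⁰⁾ is the per-target support-restricted least squares of E on P⁽⁰⁾;
    target variances come from the initial residuals (floored) and activity
    variances start at 1 (the scale of z-scored rows). ``seed`` is accepted
    for interface symmetry; the initialization itself draws no randomness.
    """
    L, K, N = draft.shape
    Q = np.asarray(Q, dtype=float)
    E = np.asarray(E, dtype=float)
    if Q.shape[0] != K or E.shape[0] != N or Q.shape[1] != E.shape[1]:
        raise ValueError(
            f"Q {Q.shape} / E {E.shape} do not match draft (L={L}, K={K}, N={N})"
        )
    P0 = Q[:L].copy()
    B0 = np.zeros((L, K))
    B0[np.arange(L), np.arange(L)] = 1.0
    A0 = _restricted_lstsq_rows(E, P0, draft.a_support)
    _, s2E = update_variances(P0, Q, E, A0, B0)
    # the self-edge construction makes the P-layer residual exactly zero at
    # init; starting σ²_P at the floor would pin P to the TF mRNA, so start
    # at the unit scale of z-scored rows instead
    s2P = np.ones(L)
    return TFAModel(draft, A0, B0, P0, s2P, s2E, float(lam))


def e_step(model: TFAModel, Q: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Hidden activities maximizing the complete-data likelihood.

    Solves C·P = D with C = AᵀW_E A + diag(1/σ²_P) (sample-independent,
    positive definite thanks to the variance floor) and
    D = diag(1/σ²_P)·B·Q + AᵀW_E·E, all M columns at once.
    """
    A, B = model.A, model.B
    wE = 1.0 / model.sigma2_E
    wP = 1.0 / model.sigma2_P
    C = (A * wE[:, None]).T @ A + np.diag(wP)
    D = wP[:, None] * (B @ Q) + (A * wE[:, None]).T @ E
    cho = linalg.cho_factor(C, lower=True)
    return linalg.cho_solve(cho, D)


def m_step_dense(P: np.ndarray, Q: np.ndarray, E: np.ndarray,
                 draft: DraftNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-inverse M-step: A = E·P⁺ and B = P·Q⁺ on the draft support.

    Requires P and Q to have full row rank; otherwise raises, directing the
    caller to the sparse (L1/ADMM) path.
    """
    for name, X in (("P", P), ("Q", Q)):
        if np.linalg.matrix_rank(X) < X.shape[0]:
            raise np.linalg.LinAlgError(
                f"{name} is row-rank deficient; use m_step_sparse (L1/ADMM) instead"
            )
    A = _restricted_lstsq_rows(E, P, draft.a_support)
    B = _restricted_lstsq_rows(P, Q, draft.b_support)
    return A, B


def lasso_lambda_max(Phi: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which argmin ‖y − Φw‖² + λ‖w‖₁ is exactly zero."""
    return float(2.0 * np.max(np.abs(Phi.T @ y))) if Phi.size else 0.0


def _soft(v: np.ndarray, k: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - k, 0.0)


def admm_lasso(
    Phi: np.ndarray,
    y: np.ndarray,
    lam: float,
    rho: float = 1.0,
    abs_tol: float = 1e-6,
    rel_tol: float = 1e-4,
    max_iter: int = 500,
    over_relax: float = 1.5,
) -> np.ndarray:
    """Solve min_w ‖y − Φw‖² + λ‖w‖₁ by ADMM with over-relaxation.

    Returns the sparse iterate z (exact zeros from soft-thresholding),
    polished by an exact solve on its active set when the sign pattern is
    KKT-consistent. A warning is logged when the residual criteria are not
    met within ``max_iter``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    M, F = Phi.shape
    if lam == 0.0:
        sol, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        return sol
    GtG = 2.0 * Phi.T @ Phi
    cho = linalg.cho_factor(GtG + rho * np.eye(F), lower=True)
    Pty2 = 2.0 * Phi.T @ y
    z = np.zeros(F)
    u = np.zeros(F)
    converged = False
    for _ in range(max_iter):
        w = linalg.cho_solve(cho, Pty2 + rho * (z - u))
        w_hat = over_relax * w + (1.0 - over_relax) * z
        z_old = z
        z = _soft(w_hat + u, lam / rho)
        u = u + w_hat - z
        r_norm = np.linalg.norm(w - z)
        s_norm = np.linalg.norm(rho * (z - z_old))
        eps_pri = np.sqrt(F) * abs_tol + rel_tol * max(
            np.linalg.norm(w), np.linalg.norm(z))
        eps_dual = np.sqrt(F) * abs_tol + rel_tol * np.linalg.norm(rho * u)
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break
        # residual balancing (Boyd et al. §3.4.1) keeps the two residuals
        # comparable; without it rho=1 crawls when 2ΦᵀΦ is large
        if r_norm > 10.0 * s_norm:
            rho *= 2.0
            u /= 2.0
            cho = linalg.cho_factor(GtG + rho * np.eye(F), lower=True)
        elif s_norm > 10.0 * r_norm:
            rho /= 2.0
            u *= 2.0
            cho = linalg.cho_factor(GtG + rho * np.eye(F), lower=True)
    if not converged:
        logger.warning("admm_lasso: residual criteria not met in %d iterations",
                       max_iter)
    return _polish_active_set(Phi, y, lam, z)


def _polish_active_set(Phi: np.ndarray, y: np.ndarray, lam: float,
                       z: np.ndarray) -> np.ndarray:
    """Exact lasso solution on z's active set if the KKT signs check out."""
    S = np.flatnonzero(z)
    if S.size == 0:
        return z
    signs = np.sign(z[S])
    PhiS = Phi[:, S]
    try:
        wS = np.linalg.solve(2.0 * PhiS.T @ PhiS,
                             2.0 * PhiS.T @ y - lam * signs)
    except np.linalg.LinAlgError:
        return z
    if np.any(np.sign(wS) != signs):
        return z
    resid = y - PhiS @ wS
    inactive = np.setdiff1d(np.arange(Phi.shape[1]), S)
    if inactive.size and np.max(np.abs(2.0 * Phi[:, inactive].T @ resid)) > lam * (1 + 1e-6):
        return z
    out = np.zeros_like(z)
    out[S] = wS
    return out


def _row_objective(y: np.ndarray, Phi: np.ndarray, w: np.ndarray,
                   sigma2: float, lam: float) -> float:
    r = y - Phi @ w
    return float(r @ r / (2.0 * sigma2) + lam * np.abs(w).sum())


def _sparse_rows(
    Y: np.ndarray, X: np.ndarray, support: np.ndarray, lam: float,
    sigma2: np.ndarray, prev: np.ndarray | None, admm_params: dict,
) -> np.ndarray:
    """Row-wise penalized solves with a monotonicity safeguard.

    Each row minimizes ‖y − Φw‖²/(2σ²) + λ‖w‖₁, solved as a standard lasso
    with penalty 2σ²λ. If the ADMM answer would score worse than the
    previous iterate's row (finite-tolerance effect), the previous row is
    kept so block-coordinate descent stays monotone.
    """
    R, F = support.shape
    W = np.zeros((R, F))
    for r in range(R):
        S = np.flatnonzero(support[r])
        if S.size == 0:
            continue
        Phi = X[S].T
        w = admm_lasso(Phi, Y[r], 2.0 * sigma2[r] * lam, **admm_params)
        if prev is not None:
            w_prev = prev[r, S]
            if (_row_objective(Y[r], Phi, w, sigma2[r], lam)
                    > _row_objective(Y[r], Phi, w_prev, sigma2[r], lam)):
                w = w_prev
        W[r, S] = w
    return W


def m_step_sparse(
    P: np.ndarray, Q: np.ndarray, E: np.ndarray, draft: DraftNetwork,
    lam: float,
    sigma2_P: np.ndarray | None = None,
    sigma2_E: np.ndarray | None = None,
    prev_A: np.ndarray | None = None,
    prev_B: np.ndarray | None = None,
    admm_params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-regularized M-step: separable per-row lasso for A and B by ADMM.

    The joint objective splits into independent rows of A (targets on
    activities) and of B (activities on regulators); each row's penalty is
    scaled by its 2σ² (uniform σ²=0.5, i.e. raw ‖·‖² + λ‖·‖₁, when no
    variances are supplied). λ=0 reduces to the support-restricted least
    squares of the dense step.
    """
    L, K, N = draft.shape
    if sigma2_P is None:
        sigma2_P = np.full(L, 0.5)
    if sigma2_E is None:
        sigma2_E = np.full(N, 0.5)
    params = admm_params or {}
    A = _sparse_rows(E, P, draft.a_support, lam, np.asarray(sigma2_E),
                     prev_A, params)
    B = _sparse_rows(P, Q, draft.b_support, lam, np.asarray(sigma2_P),
                     prev_B, params)
    return A, B


def update_variances(P, Q, E, A, B, floor: float = VARIANCE_FLOOR):
    """Per-node mean squared residuals (the exact variance M-step), floored."""
    M = P.shape[1]
    rP = P - B @ Q
    rE = E - A @ P
    s2P = np.maximum(np.einsum("lm,lm->l", rP, rP) / M, floor)
    s2E = np.maximum(np.einsum("nm,nm->n", rE, rE) / M, floor)
    return s2P, s2E


def penalized_objective(A, B, P, Q, E, sigma2_P, sigma2_E, lam: float) -> float:
    """Penalized negative log-likelihood (Q-marginal terms omitted).

    0.5·M·Σ log(2πσ²) + Σ ‖residual‖²/(2σ²) over both layers, plus
    λ·(‖A‖₁ + ‖B‖₁).
    """
    M = P.shape[1]
    rP = P - B @ Q
    rE = E - A @ P
    nll = 0.5 * M * (np.log(sigma2_P).sum() + np.log(sigma2_E).sum())
    nll += 0.5 * M * (len(sigma2_P) + len(sigma2_E)) * _LOG2PI
    nll += float((rP * rP / (2.0 * sigma2_P[:, None])).sum())
    nll += float((rE * rE / (2.0 * sigma2_E[:, None])).sum())
    return nll + lam * (np.abs(A).sum() + np.abs(B).sum())


def fit(
    draft: DraftNetwork,
    Q: np.ndarray,
    E: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    standardize: bool = True,
    admm_params: dict | None = None,
) -> TFAModel:
    """Fit the latent-activity model by hard-assignment EM.

    Alternates the closed-form E-step for P with the sparse M-step for
    (A, B) and the variance update until the relative change of the
    penalized objective drops below ``tol`` or ``max_iter`` is reached.
    Deterministic given the inputs (``seed`` reserved for interface
    symmetry; no step draws randomness).

    Variance updates are deferred during a warm-up stage in which σ² stays
    at its initial value and the fit is pure alternating least squares:
    updating per-node variances from the very first residuals lets a
    latent-layer variance collapse to the floor before the strengths are
    learned, pinning the activities to B·Q and freezing the fit (a
    degenerate hard-EM attractor). The warm-up lasts half the iteration
    budget; each warm-up step is still exact coordinate descent at the
    frozen variances, so the recorded objective trace remains
    non-increasing throughout.
    """
    Q = np.asarray(Q, dtype=float)
    E = np.asarray(E, dtype=float)
    if standardize:
        Q = standardize_rows(Q)
        E = standardize_rows(E)
    model = init_model(draft, Q, E, lam, seed)
    obj = penalized_objective(model.A, model.B, model.P, Q, E,
                              model.sigma2_P, model.sigma2_E, lam)
    model.objective_trace.append(obj)
    warmup = max_iter // 2
    for it in range(1, max_iter + 1):
        update_sigma = it > warmup
        model.P = e_step(model, Q, E)
        model.A, model.B = m_step_sparse(
            model.P, Q, E, draft, lam, model.sigma2_P, model.sigma2_E,
            prev_A=model.A, prev_B=model.B, admm_params=admm_params)
        if update_sigma:
            model.sigma2_P, model.sigma2_E = update_variances(
                model.P, Q, E, model.A, model.B)
        new_obj = penalized_objective(model.A, model.B, model.P, Q, E,
                                      model.sigma2_P, model.sigma2_E, lam)
        model.objective_trace.append(new_obj)
        model.n_iter = it
        if update_sigma and abs(new_obj - obj) <= tol * max(1.0, abs(obj)):
            model.converged = True
            obj = new_obj
            break
        obj = new_obj
    if not model.converged:
        logger.info("fit: reached max_iter=%d without convergence", max_iter)
    return model


def select_active_triplets(model: TFAModel, triplets) -> list:
    """Triplets whose modulation (β) and regulation (α) both survived the fit.

    A draft triplet (modulator, tf, target) is retained iff |β_{tf,mod}| and
    |α_{target,tf}| both exceed the zero tolerance.
    """
    draft = model.draft
    tf_i = {t: i for i, t in enumerate(draft.tfs)}
    reg_i = {r: i for i, r in enumerate(draft.regulators)}
    tg_i = {g: i for i, g in enumerate(draft.targets)}
    kept = []
    for t in triplets:
        l, k, n = tf_i[t.tf], reg_i[t.modulator], tg_i[t.target]
        if abs(model.B[l, k]) > ZERO_TOL and abs(model.A[n, l]) > ZERO_TOL:
            kept.append(t)
    return kept
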