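"""EM-REML estimation of the three variance components, per transcript.

The full model (m2) carries a biological and a blending random term plus a
residual; the reduced model (m1) omits the blending term.  Estimation
iterates Henderson's mixed model equations

    [ X'X        X'Z1              X'Z2            ] [beta]   [X'y ]
    [ Z1'X   Z1'Z1 + G1^-1 l1      Z1'Z2           ] [u1  ] = [Z1'y]
    [ Z2'X       Z2'Z1         Z2'Z2 + G2^-1 l2    ] [u2  ]   [Z2'y]

with ``l_j = sigma_e^2 / sigma_j^2`` and applies the classical EM updates

    sigma_j^2 <- (u_j' G_j^-1 u_j + sigma_e^2 tr(G_j^-1 C^jj)) / q_j
    sigma_e^2 <- y'(y - X beta - sum_j Z_j u_j) / (n - p)

where ``C^jj`` is the corresponding diagonal block of the inverse MME
coefficient matrix.  Convergence is declared when the relative change of
the estimate vector ``B = (sigma_1^2[, sigma_2^2], sigma_e^2)`` satisfies
``||B_prev - B|| / ||B|| < epsilon`` (default 1e-8).  The EM iteration
cannot cross zero, so variances are floored at a small multiple of the
sample variance of y; estimates stuck at the floor are reported as 0.

The restricted log-likelihood is defined (up to the fixed constant
``-(n - p)/2 * log(2*pi)``) as

    l(theta) = -1/2 [ log|V| + log|X'V^-1 X| + y'P y ] + const

so that values are directly comparable between the nested models m1/m2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .design import ModelMatrices, VarianceComponents, assemble_covariance

__all__ = [
    "FitConfig",
    "REMLFit",
    "MMESolution",
    "solve_mme",
    "reml_loglik",
    "em_reml_fit",
]

LOG2PI = float(np.log(2.0 * np.pi))

# boundary handling: a variance component below TRIGGER_FRAC * ||B|| whose
# REML score at zero is non-positive is frozen at the floor (plain EM only
# approaches a boundary polynomially); frozen components are re-checked at
# convergence and released at most MAX_RELEASES times.
TRIGGER_FRAC = 0.01
MAX_RELEASES = 2


@dataclass
class FitConfig:
    """Tuning knobs of the EM-REML iteration.

    ``boundary_floor`` (absolute) defaults to ``1e-10 * var(y)`` when None.
    ``init`` optionally fixes the starting values (sigma1^2, sigma2^2,
    sigma_e^2); by default sigma_e^2 starts at the OLS residual variance
    and both random components at half of it.
    """

    epsilon: float = 1e-8
    max_iter: int = 1000
    init: tuple[float, float, float] | None = None
    boundary_floor: float | None = None
    track_loglik: bool = False
    accelerate: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class REMLFit:
    """Result of one per-transcript EM-REML fit."""

    vc: VarianceComponents
    loglik: float
    beta_hat: np.ndarray
    u1_hat: np.ndarray
    u2_hat: np.ndarray | None
    iterations: int
    converged: bool
    criterion: float
    at_floor: tuple[bool, ...]
    loglik_trace: np.ndarray | None = None

    @property
    def includes_blending(self) -> bool:
        return self.vc.blending is not None


@dataclass
class MMESolution:
    beta: np.ndarray
    u1: np.ndarray
    u2: np.ndarray | None
    c_inv: np.ndarray  # inverse of the full MME coefficient matrix
    blocks: tuple[slice, slice, slice | None]


def _check_dims(mats: ModelMatrices, y: np.ndarray) -> None:
    y = np.asarray(y)
    if y.ndim != 1 or y.shape[0] != mats.n:
        raise ValueError(f"y must be a length-{mats.n} vector, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")


def solve_mme(
    mats: ModelMatrices,
    y: np.ndarray,
    vc: VarianceComponents,
    include_blending: bool | None = None,
) -> MMESolution:
    """Solve the mixed model equations at fixed variance components.

    Returns the fixed-effect estimates (BLUE), random-effect predictions
    (BLUP) and the full inverse coefficient matrix whose diagonal blocks
    feed the EM trace terms and the Kenward-Roger adjustment.  Raises a
    ``LinAlgError``-derived :class:`ValueError` naming aliased columns when
    the system is singular.
    """
    _check_dims(mats, y)
    if include_blending is None:
        include_blending = vc.blending is not None
    if vc.biological <= 0 or vc.residual <= 0:
        raise ValueError("sigma1^2 and sigma_e^2 must be > 0 to form the MME")
    if include_blending and (vc.blending is None or vc.blending <= 0):
        raise ValueError("blending variance must be > 0 when the u2 block is included")

    X, Z1, G1 = mats.X, mats.Z1, mats.G1
    parts = [X, Z1]
    if include_blending and mats.Z2.shape[1] > 0:
        parts.append(mats.Z2)
    W = np.hstack(parts)
    C = W.T @ W
    p, q1 = X.shape[1], Z1.shape[1]
    s_beta, s_u1 = slice(0, p), slice(p, p + q1)
    lam1 = vc.residual / vc.biological
    G1_inv = np.linalg.inv(G1)
    C[s_u1, s_u1] += lam1 * G1_inv
    s_u2: slice | None = None
    if include_blending and mats.Z2.shape[1] > 0:
        q2 = mats.Z2.shape[1]
        s_u2 = slice(p + q1, p + q1 + q2)
        lam2 = vc.residual / vc.blending
        C[s_u2, s_u2] += lam2 * np.linalg.inv(mats.G2)
    rhs = W.T @ y
    try:
        cf = scipy.linalg.cho_factor(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular MME coefficient matrix: {exc}") from exc
    except scipy.linalg.LinAlgError as exc:
        # identify aliased columns of [X Z1 Z2] via pivoted QR
        _, _, piv = scipy.linalg.qr(W, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(W)
        raise ValueError(
            "singular MME coefficient matrix; aliased effect columns (0-based "
            f"indices into [X Z1 Z2]): {sorted(piv[rank:].tolist())}"
        ) from exc
    sol = scipy.linalg.cho_solve(cf, rhs)
    c_inv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0]))
    return MMESolution(
        beta=sol[s_beta],
        u1=sol[s_u1],
        u2=None if s_u2 is None else sol[s_u2],
        c_inv=c_inv,
        blocks=(s_beta, s_u1, s_u2),
    )


def reml_loglik(
    mats: ModelMatrices,
    y: np.ndarray,
    vc: VarianceComponents,
    include_blending: bool | None = None,
) -> float:
    """Restricted log-likelihood at the given variance components.

    Evaluated densely through the observation covariance; the additive
    constant is fixed at ``-(n - p)/2 * log(2*pi)`` so that m1 and m2
    values are directly comparable.  ``sigma2^2 = 0`` (or excluding the
    blending term) is allowed as long as ``sigma_e^2 > 0``.
    """
    _check_dims(mats, y)
    if include_blending is None:
        include_blending = vc.blending is not None
    eff = VarianceComponents(
        biological=vc.biological,
        residual=vc.residual,
        blending=vc.blending if include_blending else None,
    )
    V = assemble_covariance(mats, eff)
    X = mats.X
    n, p = X.shape
    try:
        cf = scipy.linalg.cho_factor(V)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("observation covariance is not positive definite") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = scipy.linalg.cho_solve(cf, X)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ValueError("X'V^-1X is not positive definite (rank-deficient X?)")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return float(-0.5 * (logdet_v + logdet_x + yPy) - 0.5 * (n - p) * LOG2PI)


def _component_matrix(mats: ModelMatrices, which: int) -> np.ndarray:
    if which == 1:
        return mats.Z1 @ mats.G1 @ mats.Z1.T
    return mats.Z2 @ mats.G2 @ mats.Z2.T


def _score_at_zero(
    mats: ModelMatrices,
    y: np.ndarray,
    which: int,
    s1: float,
    s2: float | None,
    se: float,
) -> float:
    """REML score d l/d sigma_which^2 evaluated at sigma_which^2 = 0.

    The other components are held at the supplied values.  A non-positive
    score means the restricted likelihood is maximized on the boundary in
    that direction, which is how the EM iteration decides that a collapsing
    component is a true zero (plain EM only reaches zero asymptotically).
    """
    vc = VarianceComponents(
        biological=0.0 if which == 1 else s1,
        residual=se,
        blending=(0.0 if which == 2 else s2) if s2 is not None else None,
    )
    V = assemble_covariance(mats, vc)
    X = mats.X
    cf = scipy.linalg.cho_factor(V)
    Vi_X = scipy.linalg.cho_solve(cf, X)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    Py = Vi_y - Vi_X @ np.linalg.solve(XtViX, X.T @ Vi_y)
    Vj = _component_matrix(mats, which)
    VjPy = Vj @ Py
    quad = float(Py @ VjPy)
    # tr(P Vj) = tr(V^-1 Vj) - tr((X'V^-1X)^-1 (X'V^-1 Vj V^-1 X))
    tr_vinv_vj = float(np.trace(scipy.linalg.cho_solve(cf, Vj)))
    A = Vi_X.T @ Vj @ Vi_X
    tr_corr = float(np.trace(np.linalg.solve(XtViX, A)))
    return 0.5 * (quad - (tr_vinv_vj - tr_corr))


def _initial_values(mats: ModelMatrices, y: np.ndarray) -> tuple[float, float, float]:
    X = mats.X
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(n - p, 1)
    return s2 / 2.0, s2 / 2.0, s2


def em_reml_fit(
    mats: ModelMatrices,
    y: np.ndarray,
    cfg: FitConfig | None = None,
    include_blending: bool = True,
) -> REMLFit:
    """Fit one transcript by EM-REML (reference implementation).

    Model m2 (``include_blending=True``) estimates (sigma1^2, sigma2^2,
    sigma_e^2); m1 drops the blending term.  Non-convergence at
    ``max_iter`` is reported through ``converged=False``, never raised.
    """
    cfg = cfg or FitConfig()
    _check_dims(mats, y)
    y = np.asarray(y, dtype=float)
    n, p = mats.X.shape
    q1 = mats.Z1.shape[1]
    q2 = mats.Z2.shape[1]
    use_blend = include_blending and q2 > 0
    var_y = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if var_y <= 0:
        raise ValueError("degenerate input: y is constant")
    if n <= p:
        raise ValueError("not enough residual degrees of freedom")
    floor = cfg.boundary_floor if cfg.boundary_floor is not None else 1e-10 * var_y

    if cfg.init is not None:
        s1, s2b, se = cfg.init
    else:
        s1, s2b, se = _initial_values(mats, y)
    s1, s2b, se = max(s1, floor), max(s2b, floor), max(se, floor)

    G1_inv = np.linalg.inv(mats.G1)
    G2_inv = np.linalg.inv(mats.G2) if use_blend else None
    dim = 3 if use_blend else 2
    i_se = dim - 1  # theta layout: (sigma1^2[, sigma2^2], sigma_e^2)

    last_sol: list[MMESolution | None] = [None]

    def unpack(theta: np.ndarray) -> VarianceComponents:
        return VarianceComponents(
            biological=theta[0], residual=theta[i_se],
            blending=theta[1] if use_blend else None)

    def ll(theta: np.ndarray) -> float:
        return reml_loglik(mats, y, unpack(theta), include_blending=use_blend)

    def em(theta: np.ndarray, frozen: np.ndarray) -> np.ndarray:
        sol = solve_mme(mats, y, unpack(theta), include_blending=use_blend)
        last_sol[0] = sol
        _, s_u1, s_u2 = sol.blocks
        new = theta.copy()
        if not frozen[0]:
            c11 = sol.c_inv[s_u1, s_u1]
            new[0] = (sol.u1 @ G1_inv @ sol.u1
                      + theta[i_se] * np.trace(G1_inv @ c11)) / q1
        if use_blend and not frozen[1]:
            c22 = sol.c_inv[s_u2, s_u2]
            new[1] = (sol.u2 @ G2_inv @ sol.u2
                      + theta[i_se] * np.trace(G2_inv @ c22)) / q2
        fitted = mats.X @ sol.beta + mats.Z1 @ sol.u1
        if use_blend:
            fitted = fitted + mats.Z2 @ sol.u2
        new[i_se] = float(y @ (y - fitted)) / (n - p)
        return np.maximum(new, floor)

    def score0(which: int, theta: np.ndarray) -> float:
        return _score_at_zero(
            mats, y, which, theta[0],
            theta[1] if use_blend else None, theta[i_se])

    def advance(theta: np.ndarray, frozen: np.ndarray):
        """One EM iterate plus boundary detection; returns (new, crit, event)."""
        if cfg.track_loglik:
            trace.append(ll(theta))
        new = em(theta, frozen)
        crit = float(np.linalg.norm(theta - new) / np.linalg.norm(new))
        scale = float(np.linalg.norm(new))
        event = False
        for j in (0, 1) if use_blend else (0,):
            which = j + 1
            if (not frozen[j] and floor < new[j] < TRIGGER_FRAC * scale
                    and score0(which, _zeroed(new, j)) <= 0):
                new[j] = floor
                frozen[j] = True
                event = True
        return new, crit, event

    def _zeroed(theta: np.ndarray, j: int) -> np.ndarray:
        out = theta.copy()
        out[j] = 0.0
        return out

    def maybe_release(theta: np.ndarray, frozen: np.ndarray) -> bool:
        released = False
        scale = float(np.linalg.norm(theta))
        for j in (0, 1) if use_blend else (0,):
            if frozen[j] and score0(j + 1, _zeroed(theta, j)) > 0:
                frozen[j] = False
                theta[j] = TRIGGER_FRAC * scale
                released = True
        return released

    trace: list[float] = []
    theta = np.array([s1, s2b, se] if use_blend else [s1, se])
    frozen = np.zeros(dim, dtype=bool)
    crit = np.inf
    converged = False
    releases = 0
    it = 0

    def finish(theta: np.ndarray, frozen: np.ndarray) -> bool:
        """Convergence bookkeeping at a met criterion; True when done."""
        nonlocal releases, converged
        if releases < MAX_RELEASES and maybe_release(theta, frozen):
            releases += 1
            return False
        converged = True
        return True

    while it < cfg.max_iter and not converged:
        th0 = theta.copy()
        th1, c1, ev1 = advance(th0.copy(), frozen)
        it += 1
        crit = c1
        if c1 < cfg.epsilon:
            theta = th1
            if finish(theta, frozen):
                break
            continue
        if it >= cfg.max_iter or not cfg.accelerate:
            theta = th1
            continue
        th2, c2, ev2 = advance(th1.copy(), frozen)
        it += 1
        crit = c2
        if c2 < cfg.epsilon:
            theta = th2
            if finish(theta, frozen):
                break
            continue
        theta = th2
        if ev1 or ev2 or it >= cfg.max_iter:
            continue
        # SQUAREM-type extrapolation through the last two EM steps,
        # accepted only if the restricted likelihood does not decrease
        r = th1 - th0
        v = th2 - 2.0 * th1 + th0
        nv = float(np.linalg.norm(v))
        if nv <= 0:
            continue
        alpha = -float(np.linalg.norm(r)) / nv
        if alpha > -1.0:
            continue
        thc = np.maximum(th0 - 2.0 * alpha * r + alpha**2 * v, floor)
        thc[frozen] = th0[frozen]
        frozen_before = frozen.copy()
        th3, c3, ev3 = advance(thc, frozen)
        it += 1
        if ll(th3) >= ll(th2) - 1e-10:
            theta = th3
            crit = c3
            if c3 < cfg.epsilon and not ev3:
                if finish(theta, frozen):
                    break
        else:
            frozen[:] = frozen_before

    s1, se = float(theta[0]), float(theta[i_se])
    s2b = float(theta[1]) if use_blend else s2b
    at_floor = (s1 <= floor, *([s2b <= floor] if use_blend else []), se <= floor)
    vc_final = VarianceComponents(biological=s1, residual=se,
                                  blending=s2b if use_blend else None)
    ll_final = reml_loglik(mats, y, vc_final, include_blending=use_blend)
    if cfg.track_loglik:
        trace.append(ll_final)
    sol = last_sol[0]
    # boundary estimates of the random components are reported as zero
    vc_out = VarianceComponents(
        biological=0.0 if at_floor[0] else s1,
        residual=se,
        blending=(0.0 if at_floor[1] else s2b) if use_blend else None,
    )
    return REMLFit(
        vc=vc_out,
        loglik=ll_final,
        beta_hat=sol.beta,
        u1_hat=sol.u1,
        u2_hat=sol.u2,
        iterations=it,
        converged=converged,
        criterion=crit,
        at_floor=at_floor,
        loglik_trace=np.array(trace) if cfg.track_loglik else None,
    )
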