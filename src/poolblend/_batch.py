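"""Vectorized EM-REML across many transcripts sharing one design.

All transcripts of an experiment share the design matrices; only the
response vector changes.  Fitting therefore works in the space of residual
contrasts: with ``K`` an orthonormal basis of the null space of ``X'``,
REML for ``y`` is maximum likelihood for ``w = K'y`` with covariance

    K'V K = sigma1^2 A1 + sigma2^2 A2 + sigma_e^2 I,
    A1 = K'Z1 G1 Z1'K,   A2 = K'Z2 G2 Z2'K = U U'.

``A1`` is eigendecomposed once (``A1 = Q Lam Q'``); in the rotated basis
the m1 covariance is diagonal and the m2 covariance is diagonal plus a
rank-q2 term handled through the Woodbury identity, so one EM sweep over
all active transcripts costs O(m * n * q2^2) vectorized numpy work.

The iteration is step-for-step the one performed by
:func:`poolblend.reml.em_reml_fit`: the mixed-model-equation EM updates in
their P-form

    sigma_j^2 <- sigma_j^2 + sigma_j^4 / q_j * (y'P Vj P y - tr(P Vj))
    sigma_e^2 <- sigma_e^2 * y'P y / (n - p)

with ``P = K (K'VK)^-1 K'``, the same boundary detection (a component
below ``TRIGGER_FRAC * ||B||`` with a non-positive REML score at zero is
frozen at the floor and re-checked at convergence) and the same guarded
SQUAREM-type extrapolation.  Equality of the two routes is covered by the
test suite, and results are independent of how transcripts are batched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .design import ModelMatrices
from .reml import LOG2PI, MAX_RELEASES, TRIGGER_FRAC, FitConfig

__all__ = ["BatchFit", "ReducedDesign", "reduce_design", "fit_transcripts"]


@dataclass
class BatchFit:
    """Per-transcript EM-REML results for one model over a transcript matrix.

    Variance estimates that ended on the boundary floor are reported as 0
    with the corresponding ``*_at_floor`` flag set; log-likelihoods are
    evaluated at the floored (numerically tiny) values, which is also how
    the reference per-transcript path behaves.
    """

    sigma1: np.ndarray
    sigma2: np.ndarray | None
    sigma_e: np.ndarray
    loglik: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    sigma1_at_floor: np.ndarray
    sigma2_at_floor: np.ndarray | None
    ok: np.ndarray  # transcripts with a usable fit

    @property
    def includes_blending(self) -> bool:
        return self.sigma2 is not None


@dataclass
class ReducedDesign:
    """Design quantities precomputed once and shared by every transcript."""

    K: np.ndarray
    lam: np.ndarray           # eigenvalues of A1 in the rotated basis
    Q: np.ndarray
    U: np.ndarray             # rotated, scaled blending incidence (nk x q2)
    u_outer: np.ndarray       # per-contrast outer products (nk, q2, q2)
    row_sq: np.ndarray        # diag(U U'), length nk
    utu: np.ndarray           # U'U, (q2, q2)
    q1: int
    q2: int
    n: int
    p: int
    logdet_xtx: float

    @property
    def nk(self) -> int:
        return self.K.shape[1]


def reduce_design(mats: ModelMatrices) -> ReducedDesign:
    X = mats.X
    n, p = X.shape
    K = scipy.linalg.null_space(X.T)
    if K.shape[1] != n - p:
        raise ValueError("X is rank deficient; cannot form residual contrasts")
    A1 = K.T @ mats.Z1 @ mats.G1 @ mats.Z1.T @ K
    lam, Q = np.linalg.eigh((A1 + A1.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    q2 = mats.Z2.shape[1]
    if q2 > 0:
        L2 = np.linalg.cholesky(mats.G2)
        U = Q.T @ (K.T @ (mats.Z2 @ L2))
    else:
        U = np.zeros((n - p, 0))
    u_outer = U[:, :, None] * U[:, None, :]
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise ValueError("X'X is not positive definite")
    return ReducedDesign(K=K, lam=lam, Q=Q, U=U, u_outer=u_outer,
                         row_sq=np.sum(U**2, axis=1), utu=U.T @ U,
                         q1=mats.Z1.shape[1], q2=q2, n=n, p=p,
                         logdet_xtx=float(logdet_xtx))


def _score2_at_zero(red: ReducedDesign, w, s1, se):
    """Score of sigma2^2 at 0, holding (sigma1^2, sigma_e^2); vectorized."""
    minv = 1.0 / (se[:, None] + s1[:, None] * red.lam[None, :])
    t = (w * minv) @ red.U
    quad = np.einsum("ij,ij->i", t, t)
    tr = minv @ red.row_sq
    return 0.5 * (quad - tr)


def _score1_at_zero(red: ReducedDesign, w, s2, se, use_blend: bool):
    """Score of sigma1^2 at 0, holding (sigma2^2, sigma_e^2); vectorized."""
    lam = red.lam
    if not use_blend:
        quad = np.einsum("j,ij,ij->i", lam, w, w) / se**2
        return 0.5 * (quad - lam.sum() / se)
    q2 = red.q2
    S = (np.eye(q2)[None, :, :] / s2[:, None, None]
         + red.utu[None, :, :] / se[:, None, None])
    Sinv = np.linalg.inv(S)
    r = w / se[:, None]
    t = r @ red.U
    svec = np.einsum("aij,aj->ai", Sinv, t)
    v0w = r - (svec @ red.U.T) / se[:, None]
    quad = np.einsum("j,ij,ij->i", lam, v0w, v0w)
    diag_corr = np.einsum("aij,kij->ak", Sinv, red.u_outer, optimize=True)
    tr = lam.sum() / se - (diag_corr @ lam) / se**2
    return 0.5 * (quad - tr)


def _loglik_vec(red: ReducedDesign, w, s1, s2, se, use_blend: bool):
    """Restricted log-likelihood (canonical normalization); vectorized."""
    lam = red.lam
    Minv = 1.0 / (se[:, None] + s1[:, None] * lam[None, :])
    logdet = -np.sum(np.log(Minv), axis=1)
    r = w * Minv
    if use_blend:
        q2 = red.q2
        H = np.einsum("ak,kij->aij", Minv, red.u_outer, optimize=True)
        S = H + np.eye(q2)[None, :, :] / s2[:, None, None]
        _, logdet_s = np.linalg.slogdet(S)
        logdet = logdet + logdet_s + q2 * np.log(s2)
        t = r @ red.U
        svec = np.einsum("aij,aj->ai", np.linalg.inv(S), t)
        Vw = r - Minv * (svec @ red.U.T)
    else:
        Vw = r
    ypy = np.einsum("ij,ij->i", w, Vw)
    return (-0.5 * (logdet + ypy)
            - 0.5 * red.logdet_xtx - 0.5 * red.nk * LOG2PI)


class _BatchState:
    """Mutable per-transcript state of the batched EM iteration."""

    def __init__(self, red: ReducedDesign, W: np.ndarray, cfg: FitConfig,
                 use_blend: bool, floor: np.ndarray, s1, s2, se):
        m = W.shape[0]
        self.red, self.W, self.cfg = red, W, cfg
        self.use_blend = use_blend
        self.floor = floor
        self.s1, self.s2, self.se = s1, s2, se
        self.frozen1 = np.zeros(m, dtype=bool)
        self.frozen2 = np.zeros(m, dtype=bool)
        self.releases = np.zeros(m, dtype=int)
        self.iterations = np.zeros(m, dtype=int)
        self.converged = np.zeros(m, dtype=bool)
        self.active = np.zeros(m, dtype=bool)

    def theta(self, idx) -> np.ndarray:
        cols = [self.s1[idx]]
        if self.use_blend:
            cols.append(self.s2[idx])
        cols.append(self.se[idx])
        return np.stack(cols, axis=1)

    def set_theta(self, idx, th: np.ndarray) -> None:
        self.s1[idx] = th[:, 0]
        if self.use_blend:
            self.s2[idx] = th[:, 1]
        self.se[idx] = th[:, -1]

    def loglik(self, idx) -> np.ndarray:
        return _loglik_vec(self.red, self.W[idx], self.s1[idx],
                           self.s2[idx] if self.use_blend else None,
                           self.se[idx], self.use_blend)

    # -- one EM iterate plus boundary detection ------------------------
    def advance(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        red, use_blend = self.red, self.use_blend
        lam, U, u_outer, q2 = red.lam, red.U, red.u_outer, red.q2
        w = self.W[idx]
        a_s1, a_se = self.s1[idx], self.se[idx]
        a_f1, a_f2 = self.frozen1[idx], self.frozen2[idx]
        floor = self.floor[idx]
        Minv = 1.0 / (a_se[:, None] + a_s1[:, None] * lam[None, :])
        r = w * Minv
        if use_blend:
            a_s2 = self.s2[idx]
            H = np.einsum("ak,kij->aij", Minv, u_outer, optimize=True)
            S = H + np.eye(q2)[None, :, :] / a_s2[:, None, None]
            Sinv = np.linalg.inv(S)
            t = r @ U
            svec = np.einsum("aij,aj->ai", Sinv, t)
            Vw = r - Minv * (svec @ U.T)
            diag_vinv = Minv - Minv**2 * np.einsum(
                "aij,kij->ak", Sinv, u_outer, optimize=True)
            c = Vw @ U
            ypv2py = np.einsum("ai,ai->a", c, c)
            trv2 = np.einsum("aii->a", H) - np.einsum(
                "aij,ajk,aki->a", H, Sinv, H, optimize=True)
        else:
            Vw = r
            diag_vinv = Minv
        ypy = np.einsum("ij,ij->i", w, Vw)
        ypv1py = np.einsum("j,ij,ij->i", lam, Vw, Vw)
        trv1 = diag_vinv @ lam

        n_s1 = np.where(
            a_f1, a_s1,
            np.maximum(a_s1 + a_s1**2 / red.q1 * (ypv1py - trv1), floor))
        n_se = np.maximum(a_se * ypy / red.nk, floor)
        if use_blend:
            n_s2 = np.where(
                a_f2, a_s2,
                np.maximum(a_s2 + a_s2**2 / q2 * (ypv2py - trv2), floor))
            b_old = np.stack([a_s1, a_s2, a_se], axis=1)
            b_new = np.stack([n_s1, n_s2, n_se], axis=1)
        else:
            b_old = np.stack([a_s1, a_se], axis=1)
            b_new = np.stack([n_s1, n_se], axis=1)
        crit = np.sqrt(np.sum((b_old - b_new) ** 2, axis=1)
                       / np.sum(b_new**2, axis=1))
        scale = np.sqrt(np.sum(b_new**2, axis=1))

        self.s1[idx], self.se[idx] = n_s1, n_se
        if use_blend:
            self.s2[idx] = n_s2
        self.iterations[idx] += 1

        event = np.zeros(idx.size, dtype=bool)
        cand1 = ~a_f1 & (n_s1 > floor) & (n_s1 < TRIGGER_FRAC * scale)
        if np.any(cand1):
            sub = np.flatnonzero(cand1)
            gi = idx[sub]
            sc = _score1_at_zero(red, self.W[gi],
                                 self.s2[gi] if use_blend else None,
                                 self.se[gi], use_blend)
            hit = sc <= 0
            self.s1[gi[hit]] = self.floor[gi[hit]]
            self.frozen1[gi[hit]] = True
            event[sub[hit]] = True
        if use_blend:
            cand2 = ~a_f2 & (n_s2 > floor) & (n_s2 < TRIGGER_FRAC * scale)
            if np.any(cand2):
                sub = np.flatnonzero(cand2)
                gi = idx[sub]
                sc = _score2_at_zero(red, self.W[gi], self.s1[gi], self.se[gi])
                hit = sc <= 0
                self.s2[gi[hit]] = self.floor[gi[hit]]
                self.frozen2[gi[hit]] = True
                event[sub[hit]] = True
        return crit, event

    # -- convergence bookkeeping at a met criterion --------------------
    def finish(self, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        released = np.zeros(idx.size, dtype=bool)
        can = self.releases[idx] < MAX_RELEASES
        scale = np.sqrt(self.s1[idx] ** 2 + self.se[idx] ** 2
                        + (self.s2[idx] ** 2 if self.use_blend else 0.0))
        f1 = self.frozen1[idx] & can
        if np.any(f1):
            sub = np.flatnonzero(f1)
            gi = idx[sub]
            sc = _score1_at_zero(self.red, self.W[gi],
                                 self.s2[gi] if self.use_blend else None,
                                 self.se[gi], self.use_blend)
            rel = sc > 0
            self.frozen1[gi[rel]] = False
            self.s1[gi[rel]] = TRIGGER_FRAC * scale[sub[rel]]
            released[sub[rel]] = True
        if self.use_blend:
            f2 = self.frozen2[idx] & can
            if np.any(f2):
                sub = np.flatnonzero(f2)
                gi = idx[sub]
                sc = _score2_at_zero(self.red, self.W[gi], self.s1[gi],
                                     self.se[gi])
                rel = sc > 0
                self.frozen2[gi[rel]] = False
                self.s2[gi[rel]] = TRIGGER_FRAC * scale[sub[rel]]
                released[sub[rel]] = True
        self.releases[idx[released]] += 1
        done = idx[~released]
        self.converged[done] = True
        self.active[done] = False


def fit_transcripts(
    mats: ModelMatrices,
    Y: np.ndarray,
    cfg: FitConfig | None = None,
    include_blending: bool = True,
    red: ReducedDesign | None = None,
) -> BatchFit:
    """Fit every row of ``Y`` (transcripts x observations) by EM-REML.

    Equivalent to calling :func:`poolblend.reml.em_reml_fit` row by row,
    but batched.  Constant rows are flagged ``ok=False`` and carry NaN
    results instead of raising.
    """
    cfg = cfg or FitConfig()
    red = red or reduce_design(mats)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != red.n:
        raise ValueError(f"Y must have {red.n} columns, got {Y.shape[1]}")
    m = Y.shape[0]
    use_blend = include_blending and red.q2 > 0

    var_y = Y.var(axis=1, ddof=1)
    ok = np.isfinite(Y).all(axis=1) & (var_y > 0)
    floor = np.where(ok, 1e-10 * var_y, np.nan)
    if cfg.boundary_floor is not None:
        floor = np.where(ok, cfg.boundary_floor, np.nan)

    W = (Y @ red.K) @ red.Q  # (m, nk)
    se = np.einsum("ij,ij->i", W, W) / red.nk
    if cfg.init is not None:
        s1 = np.full(m, cfg.init[0])
        s2 = np.full(m, cfg.init[1])
        se = np.full(m, cfg.init[2])
    else:
        s1 = se / 2.0
        s2 = se / 2.0
    s1 = np.maximum(s1, floor)
    s2 = np.maximum(s2, floor)
    se = np.maximum(se, floor)

    st = _BatchState(red, W, cfg, use_blend, floor, s1, s2, se)
    st.active = ok.copy()
    dim = 3 if use_blend else 2
    TH0 = np.zeros((m, dim))
    TH1 = np.zeros((m, dim))

    while True:
        over = st.active & (st.iterations >= cfg.max_iter)
        st.active[over] = False
        idx = np.flatnonzero(st.active)
        if idx.size == 0:
            break
        TH0[idx] = st.theta(idx)
        c1, ev1 = st.advance(idx)
        met = c1 < cfg.epsilon
        st.finish(idx[met])
        cohort = idx[~met]
        if not cfg.accelerate:
            continue
        ev_cycle = np.zeros(m, dtype=bool)
        ev_cycle[idx] = ev1
        cohort = cohort[st.iterations[cohort] < cfg.max_iter]
        if cohort.size == 0:
            continue
        TH1[cohort] = st.theta(cohort)
        c2, ev2 = st.advance(cohort)
        ev_cycle[cohort] |= ev2
        met2 = c2 < cfg.epsilon
        st.finish(cohort[met2])
        cohort2 = cohort[~met2]
        cohort2 = cohort2[~ev_cycle[cohort2]
                          & (st.iterations[cohort2] < cfg.max_iter)]
        if cohort2.size == 0:
            continue
        th0, th1, th2 = TH0[cohort2], TH1[cohort2], st.theta(cohort2)
        r = th1 - th0
        v = th2 - 2.0 * th1 + th0
        nv = np.sqrt(np.sum(v**2, axis=1))
        nr = np.sqrt(np.sum(r**2, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = -nr / nv
        extr = (nv > 0) & (alpha <= -1.0)
        ext = cohort2[extr]
        if ext.size == 0:
            continue
        th0e, th2e = th0[extr], th2[extr]
        re_, ve, al = r[extr], v[extr], alpha[extr][:, None]
        ll2 = st.loglik(ext)
        thc = np.maximum(th0e - 2.0 * al * re_ + al**2 * ve,
                         st.floor[ext][:, None])
        fz = np.stack([st.frozen1[ext]]
                      + ([st.frozen2[ext]] if use_blend else [])
                      + [np.zeros(ext.size, dtype=bool)], axis=1)
        thc[fz] = th0e[fz]
        f1_before = st.frozen1[ext].copy()
        f2_before = st.frozen2[ext].copy()
        st.set_theta(ext, thc)
        c3, ev3 = st.advance(ext)
        ll3 = st.loglik(ext)
        reject = ll3 < ll2 - 1e-10
        if np.any(reject):
            rej = ext[reject]
            st.set_theta(rej, th2e[reject])
            st.frozen1[rej] = f1_before[reject]
            st.frozen2[rej] = f2_before[reject]
        met3 = ~reject & (c3 < cfg.epsilon) & ~ev3
        st.finish(ext[met3])

    # final log-likelihood at the estimates (floored values, like the
    # reference path), in the canonical normalization
    loglik = np.full(m, np.nan)
    idx = np.flatnonzero(ok)
    if idx.size:
        loglik[idx] = st.loglik(idx)

    s1, s2, se = st.s1, st.s2, st.se
    s1_floor = ok & (s1 <= floor)
    s2_floor = (ok & (s2 <= floor)) if use_blend else None
    out_s1 = np.where(s1_floor, 0.0, s1)
    out_se = np.where(ok, se, np.nan)
    out_s1 = np.where(ok, out_s1, np.nan)
    out_s2 = None
    if use_blend:
        out_s2 = np.where(s2_floor, 0.0, s2)
        out_s2 = np.where(ok, out_s2, np.nan)
    return BatchFit(
        sigma1=out_s1,
        sigma2=out_s2,
        sigma_e=out_se,
        loglik=loglik,
        iterations=st.iterations,
        converged=st.converged & ok,
        sigma1_at_floor=s1_floor,
        sigma2_at_floor=s2_floor,
        ok=ok,
    )
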