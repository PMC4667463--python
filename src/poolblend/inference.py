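"""Per-transcript hypothesis tests for the pooled-sample mixed model.

Two tests are provided:

* the residual likelihood ratio test (RLRT) of ``H0: sigma2^2 = 0``.  The
  null parameter sits on the boundary of the parameter space, so the
  statistic ``T = 2 (l_m2 - l_m1)`` is referred to a half-half mixture of
  a point mass at zero and a chi-square with one degree of freedom:
  ``p = 1`` when ``T = 0`` and ``p = 0.5 P(chi2_1 >= T)`` otherwise;

* a Wald-type F-test of the treatment contrast with the Kenward-Roger
  small-sample adjustment: the covariance of the fixed-effect estimates is
  inflated for the uncertainty of the variance components and the
  denominator degrees of freedom are matched to the first two moments of
  the adjusted statistic.  The covariance of the variance-component
  estimates entering the adjustment is the inverse expected information at
  the REML estimate.  Components estimated as zero (boundary) are treated
  as known zeros and dropped from the adjustment; components whose
  covariance contribution is structurally proportional to another (e.g. a
  biological term indistinguishable from the residual when every sample is
  a single individual measured once) are merged, which makes the
  classical-ANOVA limit exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .design import ModelMatrices
from .reml import REMLFit

__all__ = ["RLRTResult", "FTestResult", "rlrt", "rlrt_pvalues",
           "ftest_treatment", "kr_ftest"]

# treat T below this as the boundary point mass (finite convergence
# tolerance can leave a vanishing positive difference)
T_TOL = 1e-8


@dataclass
class RLRTResult:
    """Residual likelihood ratio test of a zero blending variance."""

    statistic: float
    p_value: float


@dataclass
class FTestResult:
    """Treatment F-test with Kenward-Roger adjusted denominator df."""

    statistic: float
    df_num: float
    df_den: float
    p_value: float
    model: str
    fallback: bool = False  # True when the KR moment match was infeasible


def _rlrt_from_values(t_raw: float, boundary: bool = False) -> tuple[float, float]:
    t = max(0.0, float(t_raw))
    if boundary or t <= T_TOL:
        return 0.0, 1.0
    return t, float(0.5 * stats.chi2.sf(t, df=1))


def rlrt(fit_m1: REMLFit, fit_m2: REMLFit) -> RLRTResult:
    """RLRT of ``H0: sigma2^2 = 0`` from the two nested REML fits.

    Both fits must share the fixed-effect structure, otherwise their
    restricted likelihoods are not comparable.  A blending variance
    estimated on the boundary gives ``T = 0`` and ``p = 1`` exactly.
    """
    if fit_m1.includes_blending:
        raise ValueError("fit_m1 must be the reduced model without blending")
    if not fit_m2.includes_blending:
        raise ValueError("fit_m2 must include the blending component")
    if fit_m1.beta_hat.shape != fit_m2.beta_hat.shape:
        raise ValueError("fits have different fixed-effect structures; "
                         "restricted likelihoods are not comparable")
    boundary = fit_m2.vc.blending == 0.0
    t, p = _rlrt_from_values(2.0 * (fit_m2.loglik - fit_m1.loglik), boundary)
    return RLRTResult(statistic=t, p_value=p)


def rlrt_pvalues(loglik_m1: np.ndarray, loglik_m2: np.ndarray,
                 boundary: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized RLRT over aligned per-transcript log-likelihood arrays."""
    t = np.maximum(0.0, 2.0 * (np.asarray(loglik_m2) - np.asarray(loglik_m1)))
    zero = t <= T_TOL
    if boundary is not None:
        zero |= np.asarray(boundary, dtype=bool)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, 0.5 * stats.chi2.sf(t, df=1))
    return t, p


# ---------------------------------------------------------------------------
# Kenward-Roger adjusted F-test
# ---------------------------------------------------------------------------

def _component_basis(mats: ModelMatrices, theta: list[float],
                     include: list[bool]) -> tuple[list[np.ndarray], list[float]]:
    """Active covariance components [(Vi, sigma_i^2)] with aliased ones merged.

    The component list is (biological, blending, residual); entries with
    ``include=False`` (boundary zeros or model m1) are dropped.  A
    component whose matrix is numerically proportional to an earlier one
    is folded into it.
    """
    n = mats.n
    cand: list[tuple[np.ndarray, float]] = []
    mats_all = [mats.Z1 @ mats.G1 @ mats.Z1.T,
                mats.Z2 @ mats.G2 @ mats.Z2.T if mats.Z2.shape[1] else None,
                np.eye(n)]
    for Vi, th, inc in zip(mats_all, theta, include):
        if not inc or Vi is None:
            continue
        merged = False
        for k, (Vk, thk) in enumerate(cand):
            c = float(np.sum(Vi * Vk) / np.sum(Vk * Vk))
            if c > 0 and np.linalg.norm(Vi - c * Vk) <= 1e-10 * np.linalg.norm(Vi):
                cand[k] = (Vk, thk + th / c)
                merged = True
                break
        if not merged:
            cand.append((Vi, th))
    return [c[0] for c in cand], [c[1] for c in cand]


def kr_ftest(
    mats: ModelMatrices,
    y: np.ndarray,
    theta: tuple[float, float | None, float],
    L: np.ndarray | None = None,
    model: str = "m2",
) -> FTestResult:
    """Kenward-Roger adjusted Wald F-test of an estimable contrast ``L beta``.

    ``theta = (sigma1^2, sigma2^2 or None, sigma_e^2)`` are the REML
    estimates (zeros allowed; zero components drop out of the adjustment).
    ``L`` defaults to the design's treatment contrast.  Falls back to the
    residual degrees of freedom ``n - p`` when the KR moment match is
    numerically infeasible (flagged, never raised).
    """
    X = mats.X
    n, p = X.shape
    if L is None:
        L = mats.treatment_contrast
    L = np.atleast_2d(np.asarray(L, dtype=float))
    ell = L.shape[0]
    if L.shape[1] != p:
        raise ValueError(f"contrast has {L.shape[1]} columns, expected {p}")
    if np.linalg.matrix_rank(L) < ell:
        raise ValueError("contrast rows are linearly dependent")

    s1, s2, se = theta
    include = [s1 > 0, s2 is not None and s2 > 0, True]
    Vlist, th = _component_basis(mats, [s1, s2 or 0.0, se], include)
    V = sum(t * Vi for t, Vi in zip(th, Vlist))
    cf = scipy.linalg.cho_factor(V)
    ViX = scipy.linalg.cho_solve(cf, X)
    Viy = scipy.linalg.cho_solve(cf, y) if y is not None else None
    phi_inv = X.T @ ViX
    Phi = np.linalg.inv(phi_inv)
    beta = Phi @ (X.T @ Viy)

    # contrast not estimable -> L beta not defined (X full rank here, so
    # any L is estimable; the check above guards rank of L itself)
    r = len(Vlist)
    PViX = [scipy.linalg.cho_solve(cf, Vi @ ViX) for Vi in Vlist]
    # big-P projections of each component: P Vi with P = Vi^-1 - ViX Phi ViX'
    # expected information I_ij = 1/2 tr(P Vi P Vj)
    VinvVi = [scipy.linalg.cho_solve(cf, Vi) for Vi in Vlist]
    PVi = [VinvVi[i] - ViX @ (Phi @ (ViX.T @ Vlist[i])) for i in range(r)]
    info = np.empty((r, r))
    for i in range(r):
        for j in range(i, r):
            info[i, j] = info[j, i] = 0.5 * np.sum(PVi[i] * PVi[j].T)
    try:
        Wc = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        Wc = np.linalg.pinv(info)

    Ai = [ViX.T @ Vlist[i] for i in range(r)]          # X'V^-1 Vi  (p x n)
    Pi = [-Ai[i] @ ViX for i in range(r)]              # p x p
    Qij = [[Ai[i] @ scipy.linalg.cho_solve(cf, Ai[j].T) for j in range(r)]
           for i in range(r)]

    # adjusted covariance of beta-hat
    M = np.zeros((p, p))
    for i in range(r):
        for j in range(r):
            M += Wc[i, j] * (Qij[i][j] - Pi[i] @ Phi @ Pi[j])
    Phi_a = Phi + 2.0 * Phi @ M @ Phi

    Lb = L @ beta
    LPhiAL = L @ Phi_a @ L.T
    try:
        f_star = float(Lb @ np.linalg.solve(LPhiAL, Lb)) / ell
    except np.linalg.LinAlgError:
        return FTestResult(np.nan, ell, np.nan, np.nan, model, fallback=True)

    Theta = L.T @ np.linalg.solve(L @ Phi @ L.T, L)
    TP = [Theta @ Phi @ Pi[i] @ Phi for i in range(r)]
    tr1 = np.array([np.trace(t) for t in TP])
    A1 = float(tr1 @ Wc @ tr1)
    A2 = 0.0
    for i in range(r):
        for j in range(r):
            A2 += Wc[i, j] * np.sum(TP[i] * TP[j].T)

    df_res = n - p
    fallback = False
    with np.errstate(divide="ignore", invalid="ignore"):
        B = (A1 + 6.0 * A2) / (2.0 * ell)
        g = ((ell + 1.0) * A1 - (ell + 4.0) * A2) / ((ell + 2.0) * A2) \
            if A2 > 0 else 0.0
        den = 3.0 * ell + 2.0 * (1.0 - g)
        c1, c2, c3 = g / den, (ell - g) / den, (ell + 2.0 - g) / den
        e_star = 1.0 / (1.0 - A2 / ell)
        v_star = (2.0 / ell) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2
                                                 * (1.0 - c3 * B))
        rho = v_star / (2.0 * e_star**2)
        df_den = 4.0 + (ell + 2.0) / (ell * rho - 1.0)
        lam = df_den / (e_star * (df_den - 2.0))
    if (not np.isfinite(df_den)) or df_den <= 2.0 or not np.isfinite(lam) \
            or lam <= 0:
        df_den, lam, fallback = float(df_res), 1.0, True
    df_den = min(float(df_den), float(df_res))
    f_val = lam * f_star
    p_val = float(stats.f.sf(f_val, ell, df_den))
    return FTestResult(statistic=float(f_val), df_num=float(ell),
                       df_den=float(df_den), p_value=p_val, model=model,
                       fallback=fallback)


def _kr_chunk(X: np.ndarray, Vcomps: list[np.ndarray], th: np.ndarray,
              Yc: np.ndarray, L: np.ndarray, df_res: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized KR over a chunk of transcripts sharing one component set.

    ``th`` is (a, r) with the active variance components, ``Yc`` the
    matching rows of the expression matrix.  Same algebra as
    :func:`kr_ftest`.
    """
    a, r = th.shape
    n, p = X.shape
    ell = L.shape[0]
    V = np.einsum("ar,rij->aij", th, np.stack(Vcomps))
    Vinv = np.linalg.inv(V)
    ViX = Vinv @ X                                       # (a, n, p)
    phi_inv = np.einsum("ji,ajk->aik", X, ViX)
    Phi = np.linalg.inv(phi_inv)
    Viy = np.einsum("aij,aj->ai", Vinv, Yc)
    beta = np.einsum("aij,aj->ai", Phi, np.einsum("ji,aj->ai", X, Viy))

    VinvVi = [Vinv @ Vi for Vi in Vcomps]
    Ai = [np.einsum("ji,ajk->aik", X, vv) for vv in VinvVi]  # X'V^-1 Vi (a,p,n)
    PVi = [VinvVi[i] - ViX @ (Phi @ Ai[i]) for i in range(r)]
    info = np.empty((a, r, r))
    for i in range(r):
        for j in range(i, r):
            tr = 0.5 * np.einsum("aij,aji->a", PVi[i], PVi[j])
            info[:, i, j] = info[:, j, i] = tr
    Wc = np.linalg.inv(info)

    AiV = [Ai[i] @ Vinv for i in range(r)]
    Pi = [-Ai[i] @ ViX for i in range(r)]
    M = np.zeros((a, p, p))
    for i in range(r):
        for j in range(r):
            Qij = AiV[i] @ np.transpose(Ai[j], (0, 2, 1))
            M += Wc[:, i, j, None, None] * (Qij - Pi[i] @ Phi @ Pi[j])
    Phi_a = Phi + 2.0 * Phi @ M @ Phi

    Lb = np.einsum("ij,aj->ai", L, beta)
    LPhiAL = L @ Phi_a @ L.T
    f_star = np.einsum("ai,aij,aj->a", Lb, np.linalg.inv(LPhiAL), Lb) / ell

    LPhiL = L @ Phi @ L.T
    Theta = np.einsum("ji,ajk,kl->ail", L, np.linalg.inv(LPhiL), L)
    TP = [Theta @ Phi @ Pi[i] @ Phi for i in range(r)]
    tr1 = np.stack([np.einsum("aii->a", t) for t in TP], axis=1)  # (a, r)
    A1 = np.einsum("ai,aij,aj->a", tr1, Wc, tr1)
    A2 = np.zeros(a)
    for i in range(r):
        for j in range(r):
            A2 += Wc[:, i, j] * np.einsum("aij,aji->a", TP[i], TP[j])

    with np.errstate(divide="ignore", invalid="ignore"):
        B = (A1 + 6.0 * A2) / (2.0 * ell)
        g = np.where(A2 > 0,
                     ((ell + 1.0) * A1 - (ell + 4.0) * A2)
                     / ((ell + 2.0) * np.where(A2 > 0, A2, 1.0)), 0.0)
        den = 3.0 * ell + 2.0 * (1.0 - g)
        c1, c2, c3 = g / den, (ell - g) / den, (ell + 2.0 - g) / den
        e_star = 1.0 / (1.0 - A2 / ell)
        v_star = (2.0 / ell) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2
                                                 * (1.0 - c3 * B))
        rho = v_star / (2.0 * e_star**2)
        df_den = 4.0 + (ell + 2.0) / (ell * rho - 1.0)
        lam = df_den / (e_star * (df_den - 2.0))
    bad = (~np.isfinite(df_den)) | (df_den <= 2.0) | (~np.isfinite(lam)) \
        | (lam <= 0)
    df_den = np.where(bad, float(df_res), np.minimum(df_den, float(df_res)))
    lam = np.where(bad, 1.0, lam)
    f_val = lam * f_star
    p_val = stats.f.sf(f_val, ell, df_den)
    return f_val, df_den, p_val, bad


def kr_ftest_batch(
    mats: ModelMatrices,
    Y: np.ndarray,
    sigma1: np.ndarray,
    sigma2: np.ndarray | None,
    sigma_e: np.ndarray,
    L: np.ndarray | None = None,
    model: str = "m2",
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized KR treatment F-tests over a transcript matrix.

    Transcripts are grouped by which variance components are active
    (boundary zeros drop out of the adjustment, as in :func:`kr_ftest`)
    and processed in chunks.  Returns ``(F, df_den, p, fallback)`` arrays
    aligned with the rows of ``Y``; rows with non-finite estimates carry
    NaN.
    """
    X = mats.X
    n, p = X.shape
    if L is None:
        L = mats.treatment_contrast
    L = np.atleast_2d(np.asarray(L, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = Y.shape[0]
    s1 = np.asarray(sigma1, dtype=float)
    s2 = None if sigma2 is None else np.asarray(sigma2, dtype=float)
    se = np.asarray(sigma_e, dtype=float)

    V1 = mats.Z1 @ mats.G1 @ mats.Z1.T
    V2 = mats.Z2 @ mats.G2 @ mats.Z2.T if mats.Z2.shape[1] else None
    eye = np.eye(n)

    F = np.full(m, np.nan)
    DF = np.full(m, np.nan)
    P = np.full(m, np.nan)
    FB = np.zeros(m, dtype=bool)

    ok = np.isfinite(s1) & np.isfinite(se) & (se > 0)
    if s2 is not None:
        ok &= np.isfinite(s2)
    inc1 = ok & (s1 > 0)
    inc2 = ok & (s2 > 0) if (s2 is not None and V2 is not None) \
        else np.zeros(m, dtype=bool)

    for pat1 in (False, True):
        for pat2 in (False, True):
            sel = np.flatnonzero(ok & (inc1 == pat1) & (inc2 == pat2))
            if sel.size == 0:
                continue
            comps = []
            cols = []
            if pat1:
                comps.append(V1)
                cols.append(s1[sel])
            if pat2:
                comps.append(V2)
                cols.append(s2[sel])
            comps.append(eye)
            cols.append(se[sel])
            th = np.stack(cols, axis=1)
            for lo in range(0, sel.size, chunk):
                gi = sel[lo:lo + chunk]
                f, d, pv, bad = _kr_chunk(X, comps, th[lo:lo + chunk],
                                          Y[gi], L, n - p)
                F[gi], DF[gi], P[gi], FB[gi] = f, d, pv, bad
    return F, DF, P, FB


def ftest_treatment(
    fit: REMLFit,
    mats: ModelMatrices,
    y: np.ndarray,
    contrast: np.ndarray | None = None,
) -> FTestResult:
    """KR-adjusted treatment F-test for a fitted transcript.

    A contrast of a treatment with itself (an all-zero row) gives
    ``F = 0, p = 1``.
    """
    if contrast is not None:
        Lr = np.atleast_2d(np.asarray(contrast, dtype=float))
        if np.allclose(Lr, 0.0):
            return FTestResult(0.0, float(Lr.shape[0]), float(mats.n - mats.X.shape[1]),
                               1.0, "m2" if fit.includes_blending else "m1")
    theta = (fit.vc.biological, fit.vc.blending, fit.vc.residual)
    return kr_ftest(mats, y, theta, L=contrast,
                    model="m2" if fit.includes_blending else "m1")
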