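"""Unified SEM (lag-1 structural VAR) estimation for a single individual.

The model for a p-variate ROI series is

    y_t = A y_t + Phi y_{t-1} + zeta_t,    zeta_t ~ N(0, Psi), Psi diagonal,

with A the contemporaneous directed paths (zero diagonal) and Phi the
lag-1 paths (diagonal = autoregressive effects).  Estimation is maximum
likelihood on the lag-embedded observations [y_{t-1}, y_t], treating the
lagged block as saturated/exogenous, which makes the discrepancy

    F = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^{-1}) - 2p

equal to the conditional Gaussian deviance of y_t given y_{t-1}.  The
residual variances are profiled out analytically and the free (A, Phi)
elements are optimized by L-BFGS with closed-form gradients.

Modification indices are score tests: the approximate chi-square drop
from freeing one currently fixed element, computed from the gradient and
the Schur complement of the Hessian of the profiled discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "USEMSpec",
    "USEMFit",
    "FitIndexSet",
    "embed_lag",
    "fit_usem",
    "modification_indices",
    "fit_indices",
]


class ConvergenceError(RuntimeError):
    """Raised when the ML search fails to converge."""

    def __init__(self, message: str, best_F: float | None = None):
        super().__init__(message)
        self.best_F = best_F


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class USEMSpec:
    """Pattern of free contemporaneous (A) and lagged (Phi) paths."""

    p: int
    free_A: np.ndarray
    free_Phi: np.ndarray

    def __post_init__(self) -> None:
        self.free_A = np.asarray(self.free_A, dtype=bool)
        self.free_Phi = np.asarray(self.free_Phi, dtype=bool)
        if self.free_A.shape != (self.p, self.p) or self.free_Phi.shape != (self.p, self.p):
            raise ValueError("free_A and free_Phi must be p×p boolean masks")
        if np.any(np.diag(self.free_A)):
            raise ValueError("diagonal of free_A must be fixed (no self-loops at lag 0)")

    @classmethod
    def ar_only(cls, p: int) -> "USEMSpec":
        """Null/baseline spec: autoregressive paths only."""
        return cls(p=p, free_A=np.zeros((p, p), bool), free_Phi=np.eye(p, dtype=bool))

    @classmethod
    def saturated(cls, p: int) -> "USEMSpec":
        """A just-identified spec: lower-triangular A plus full Phi."""
        return cls(p=p, free_A=np.tril(np.ones((p, p), bool), -1),
                   free_Phi=np.ones((p, p), bool))

    @property
    def n_free(self) -> int:
        return int(self.free_A.sum() + self.free_Phi.sum())

    def copy(self) -> "USEMSpec":
        return USEMSpec(self.p, self.free_A.copy(), self.free_Phi.copy())

    def candidates(self) -> list[tuple[str, int, int]]:
        """All currently-fixed, testable elements (off-diagonal A, any Phi)."""
        out = []
        p = self.p
        for i in range(p):
            for j in range(p):
                if i != j and not self.free_A[i, j]:
                    out.append(("A", i, j))
        for i in range(p):
            for j in range(p):
                if not self.free_Phi[i, j]:
                    out.append(("Phi", i, j))
        return out


# ---------------------------------------------------------------------------
# lag embedding
# ---------------------------------------------------------------------------


def embed_lag(ts: np.ndarray) -> tuple[np.ndarray, int]:
    """Build the 2p-column lag-embedded observations [y_{t-1}, y_t].

    Rows containing NaN are missing-frame placeholders; any pair that
    spans a missing frame is dropped.  Returns ``(pairs, n_used)``.
    Raises ValueError when fewer than 10*p usable pairs remain.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need a T×p series with T >= 2")
    p = ts.shape[1]
    ok = ~np.isnan(ts).any(axis=1)
    keep = ok[:-1] & ok[1:]
    pairs = np.hstack([ts[:-1][keep], ts[1:][keep]])
    n_used = pairs.shape[0]
    if n_used < 10 * p:
        raise ValueError(
            f"only {n_used} usable lag-embedded pairs for p={p} ROIs; "
            f"at least {10 * p} are required for stable estimation"
        )
    return pairs, n_used


def _standardize(ts: np.ndarray) -> np.ndarray:
    """Z-score each column over its observed entries (NaN preserved)."""
    ts = np.asarray(ts, dtype=float)
    mu = np.nanmean(ts, axis=0)
    sd = np.nanstd(ts, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (ts - mu) / sd


# ---------------------------------------------------------------------------
# moments and discrepancy
# ---------------------------------------------------------------------------


class _Moments:
    """Second moments of the lag-embedded sample, split into blocks."""

    def __init__(self, pairs: np.ndarray, p: int):
        self.p = p
        self.n = pairs.shape[0]
        S = np.cov(pairs, rowvar=False, ddof=1)
        self.S = S
        self.S_xx = S[:p, :p]          # lagged block
        self.S_yx = S[p:, :p]          # cross block  cov(y_t, y_{t-1})
        self.S_yy = S[p:, p:]
        # saturated conditional residual covariance
        self.S_res = self.S_yy - self.S_yx @ np.linalg.solve(self.S_xx, self.S_yx.T)
        sign, self.logdet_Sres = np.linalg.slogdet(self.S_res)
        if sign <= 0:
            raise ValueError("singular lag-embedded covariance; data degenerate")


def _residual_moment(A, Phi, m: _Moments):
    C = np.eye(m.p) - A
    CS_yy = C @ m.S_yy
    PhiS_xy = Phi @ m.S_yx.T
    Se = (CS_yy @ C.T - C @ m.S_yx @ Phi.T - PhiS_xy @ C.T + Phi @ m.S_xx @ Phi.T)
    return C, Se


def _profile_F_and_grad(A, Phi, m: _Moments):
    """Profiled discrepancy (Psi concentrated out) and its full gradients."""
    C, Se = _residual_moment(A, Phi, m)
    d = np.diag(Se).copy()
    sign, logdetC = np.linalg.slogdet(C)
    if sign == 0 or np.any(d <= 0):
        # barrier pushing back toward the feasible region
        pen = float(np.sum(A**2) + np.sum(Phi**2))
        return 1e8 * (1.0 + pen), 2e8 * A, 2e8 * Phi
    F = float(np.sum(np.log(d)) - 2.0 * logdetC - m.logdet_Sres)
    Dinv = 1.0 / d
    # d sum(log Se_ii)/dC = 2 D^{-1} (C S_yy - Phi S_yx'), dC/dA = -1
    T1 = (C @ m.S_yy - Phi @ m.S_yx.T) * Dinv[:, None]
    Cinv_T = np.linalg.inv(C).T
    gA = -2.0 * T1 + 2.0 * Cinv_T
    gPhi = 2.0 * ((Phi @ m.S_xx - C @ m.S_yx) * Dinv[:, None])
    return F, gA, gPhi


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class FitIndexSet:
    rmsea: float
    srmr: float
    cfi: float
    nnfi: float
    defined: bool = True

    def excellent(self, rules_needed: int = 2) -> bool:
        """GIMME-convention rule: at least `rules_needed` of the four hold."""
        if not self.defined:
            return False
        hits = sum([
            self.rmsea <= 0.05,
            self.srmr <= 0.05,
            self.cfi >= 0.95,
            self.nnfi >= 0.95,
        ])
        return hits >= rules_needed


@dataclass
class USEMFit:
    """ML estimates of a uSEM for one individual."""

    spec: USEMSpec
    A_hat: np.ndarray
    Phi_hat: np.ndarray
    psi_hat: np.ndarray
    se_A: np.ndarray
    se_Phi: np.ndarray
    chi2: float
    df: int
    loglik: float
    n_used: int
    F: float
    converged: bool
    moments: _Moments = field(repr=False, default=None)

    def z_value(self, kind: str, i: int, j: int) -> float:
        if kind == "A":
            return self.A_hat[i, j] / self.se_A[i, j]
        return self.Phi_hat[i, j] / self.se_Phi[i, j]

    def p_value(self, kind: str, i: int, j: int) -> float:
        return 2.0 * stats.norm.sf(abs(self.z_value(kind, i, j)))


def _pack(A, Phi, spec):
    return np.concatenate([A[spec.free_A], Phi[spec.free_Phi]])


def _unpack(theta, spec):
    A = np.zeros((spec.p, spec.p))
    Phi = np.zeros((spec.p, spec.p))
    nA = int(spec.free_A.sum())
    A[spec.free_A] = theta[:nA]
    Phi[spec.free_Phi] = theta[nA:]
    return A, Phi


def _grad_vector(gA, gPhi, spec):
    return np.concatenate([gA[spec.free_A], gPhi[spec.free_Phi]])


def _free_hessian(theta, spec, m, eps: float = 1e-5) -> np.ndarray:
    """Finite-difference Hessian of the profiled F over the free parameters."""
    k = theta.size
    A0, Phi0 = _unpack(theta, spec)
    _, gA0, gPhi0 = _profile_F_and_grad(A0, Phi0, m)
    g0 = _grad_vector(gA0, gPhi0, spec)
    H = np.empty((k, k))
    for a in range(k):
        th = theta.copy()
        th[a] += eps
        A1, Phi1 = _unpack(th, spec)
        _, gA1, gPhi1 = _profile_F_and_grad(A1, Phi1, m)
        H[:, a] = (_grad_vector(gA1, gPhi1, spec) - g0) / eps
    return 0.5 * (H + H.T)


def fit_usem(
    ts: np.ndarray,
    spec: USEMSpec,
    start: np.ndarray | None = None,
    standardize: bool = False,
    max_iter: int = 500,
    compute_se: bool = True,
) -> USEMFit:
    """Fit the uSEM to one individual's series by maximum likelihood.

    The series is mean-centered implicitly (moments are covariances).
    Betas are invariant to an individual's global signal scale; optional
    per-ROI z-scoring (``standardize=True``) additionally equates ROI
    variances but rescales every beta by sample-sd ratios.
    """
    if standardize:
        ts = _standardize(ts)
    pairs, n_used = embed_lag(ts)
    m = _Moments(pairs, spec.p)
    return _fit_from_moments(m, spec, start=start, max_iter=max_iter,
                             compute_se=compute_se)


def _fit_from_moments(m, spec, start=None, max_iter=500, compute_se=True) -> USEMFit:
    p = spec.p
    if spec.n_free + p > p * p + p * (p + 1) // 2:
        raise ValueError(
            f"over-parameterized spec: {spec.n_free} free paths exceed the "
            f"{p * p + p * (p + 1) // 2 - p} identifiable by the lag-embedded "
            "covariance (df would be negative)"
        )
    theta0 = np.zeros(spec.n_free) if start is None else np.asarray(start, float)

    def fun(theta):
        A, Phi = _unpack(theta, spec)
        F, gA, gPhi = _profile_F_and_grad(A, Phi, m)
        return F, _grad_vector(gA, gPhi, spec)

    if spec.n_free:
        res = optimize.minimize(
            fun, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        converged = bool(res.success) or res.status == 0
        if not converged and not np.isfinite(res.fun):
            raise ConvergenceError(
                f"uSEM optimization failed: {res.message}", best_F=float(res.fun)
            )
    else:
        theta = theta0
        converged = True

    A_hat, Phi_hat = _unpack(theta, spec)
    C, Se = _residual_moment(A_hat, Phi_hat, m)
    if abs(np.linalg.det(C)) < 1e-12:
        raise ConvergenceError("terminal estimate has singular (I - A)")
    F, _, _ = _profile_F_and_grad(A_hat, Phi_hat, m)
    psi_hat = np.diag(Se).copy()
    n = m.n
    chi2 = max((n - 1) * F, 0.0)
    df = p * p + p * (p + 1) // 2 - (spec.n_free + p)
    loglik = -0.5 * n * (
        p * np.log(2 * np.pi) + float(np.sum(np.log(psi_hat)))
        - 2.0 * np.linalg.slogdet(C)[1] + p
    )

    se_A = np.full((p, p), np.nan)
    se_Phi = np.full((p, p), np.nan)
    if compute_se and spec.n_free:
        H = _free_hessian(theta, spec, m)
        try:
            cov = np.linalg.inv(H) * 2.0 / (n - 1)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(spec.n_free, np.nan)
        nA = int(spec.free_A.sum())
        se_A[spec.free_A] = se[:nA]
        se_Phi[spec.free_Phi] = se[nA:]

    return USEMFit(
        spec=spec, A_hat=A_hat, Phi_hat=Phi_hat, psi_hat=psi_hat,
        se_A=se_A, se_Phi=se_Phi, chi2=float(chi2), df=int(df),
        loglik=float(loglik), n_used=n, F=float(F), converged=converged,
        moments=m,
    )


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------


def modification_indices(
    fit: USEMFit,
    spec: USEMSpec | None = None,
) -> dict[tuple[str, int, int], tuple[float, float]]:
    """Score-test modification index and expected parameter change.

    For each currently fixed off-diagonal A element and fixed Phi element,
    approximates the chi-square drop from freeing that single element.
    """
    if spec is None:
        spec = fit.spec
    m = fit.moments
    cands = spec.candidates()
    if not cands:
        return {}
    _, gA, gPhi = _profile_F_and_grad(fit.A_hat, fit.Phi_hat, m)

    free_idx = [("A", i, j) for i, j in zip(*np.where(spec.free_A))]
    free_idx += [("Phi", i, j) for i, j in zip(*np.where(spec.free_Phi))]
    labels = free_idx + cands
    nf, nc = len(free_idx), len(cands)

    def full_grad_vec(A, Phi):
        _, gA_, gPhi_ = _profile_F_and_grad(A, Phi, m)
        return np.array([
            (gA_ if k == "A" else gPhi_)[i, j] for k, i, j in labels
        ])

    g0 = full_grad_vec(fit.A_hat, fit.Phi_hat)
    eps = 1e-5
    H = np.empty((nf + nc, nf + nc))
    for a, (k, i, j) in enumerate(labels):
        A1 = fit.A_hat.copy()
        Phi1 = fit.Phi_hat.copy()
        (A1 if k == "A" else Phi1)[i, j] += eps
        H[:, a] = (full_grad_vec(A1, Phi1) - g0) / eps
    H = 0.5 * (H + H.T)

    n = fit.n_used
    out = {}
    if nf:
        Hff = H[:nf, :nf]
        try:
            Hff_inv_Hfc = np.linalg.solve(Hff, H[:nf, nf:])
        except np.linalg.LinAlgError:
            Hff_inv_Hfc = np.linalg.lstsq(Hff, H[:nf, nf:], rcond=None)[0]
    for c, cand in enumerate(cands):
        jj = nf + c
        h = H[jj, jj]
        if nf:
            h = h - H[jj, :nf] @ Hff_inv_Hfc[:, c]
        h = max(h, 1e-10)
        g = g0[jj]
        mi = (n - 1) * g * g / (2.0 * h)
        epc = -g / h
        out[cand] = (float(max(mi, 0.0)), float(epc))
    return out


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def _srmr(fit: USEMFit) -> float:
    """RMS standardized residual over the modeled (yy and yx) blocks."""
    m = fit.moments
    p = fit.spec.p
    C = np.eye(p) - fit.A_hat
    B = np.linalg.inv(C)
    Psi = np.diag(fit.psi_hat)
    Sigma_yy = B @ (fit.Phi_hat @ m.S_xx @ fit.Phi_hat.T + Psi) @ B.T
    Sigma_yx = B @ fit.Phi_hat @ m.S_xx
    sd_y = np.sqrt(np.diag(m.S_yy))
    sd_x = np.sqrt(np.diag(m.S_xx))
    res_yy = (m.S_yy - Sigma_yy) / np.outer(sd_y, sd_y)
    res_yx = (m.S_yx - Sigma_yx) / np.outer(sd_y, sd_x)
    iu = np.triu_indices(p)
    vals = np.concatenate([res_yy[iu], res_yx.ravel()])
    return float(np.sqrt(np.mean(vals**2)))


def fit_indices(fit: USEMFit, null_fit: USEMFit) -> FitIndexSet:
    """Standard SEM fit indices relative to an AR-only null model."""
    srmr = _srmr(fit)
    if fit.df <= 0:
        warnings.warn("saturated model: rmsea/cfi/nnfi undefined (df = 0)")
        return FitIndexSet(rmsea=np.nan, srmr=srmr, cfi=np.nan, nnfi=np.nan,
                           defined=False)
    n = fit.n_used
    rmsea = float(np.sqrt(max(fit.chi2 - fit.df, 0.0) / (fit.df * (n - 1))))
    denom = max(null_fit.chi2 - null_fit.df, fit.chi2 - fit.df, 0.0)
    cfi = 1.0 - (max(fit.chi2 - fit.df, 0.0) / denom if denom > 0 else 0.0)
    null_ratio = null_fit.chi2 / null_fit.df if null_fit.df > 0 else np.nan
    if np.isfinite(null_ratio) and null_ratio != 1.0:
        nnfi = (null_ratio - fit.chi2 / fit.df) / (null_ratio - 1.0)
    else:
        nnfi = np.nan
    return FitIndexSet(rmsea=rmsea, srmr=srmr, cfi=float(cfi), nnfi=float(nnfi))
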