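"""Linear mixed models with random intercepts, fit by profiled (RE)ML.

The model is ``y = X beta + sum_g Z_g b_g + e`` with independent random
intercepts ``b_g ~ N(0, sigma_g^2 I)`` per grouping factor and residual
``e ~ N(0, sigma^2 I)``.  The covariance ``V = sigma^2 (I + sum_g lambda_g
Z_g Z_g^T)`` is handled through the Woodbury identity, so cost scales with
the (small) number of groups rather than n.  Scale and fixed effects are
profiled out; the optimizer works on ``gamma_g = sqrt(lambda_g) >= 0`` so
variance components can sit exactly on the zero boundary (flagged, not an
error).

Satterthwaite denominator degrees of freedom use the variance-parameter
covariance from a numerical Hessian of the REML deviance in the
``(sigma_1^2, ..., sigma_G^2, sigma^2)`` parametrization, with multi-df
terms combined by the eigen-decomposition (Fai-Cornelius) approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

BOUNDARY_TOL = 1e-6  # lambda below this counts as a zero variance component


def _group_matrix(codes: np.ndarray) -> np.ndarray:
    """Dense indicator matrix (n x n_levels) from integer codes."""
    codes = np.asarray(codes)
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z


@dataclass
class LmmFit:
    """Fitted random-intercepts model (REML unless noted)."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray  # Phi-hat
    vc: dict  # group name -> sigma_g^2
    sigma2: float
    loglik: float  # restricted (or full) log-likelihood
    reml: bool
    fitted: np.ndarray
    residuals: np.ndarray
    boundary: dict = field(default_factory=dict)  # group name -> at zero?
    n: int = 0
    p: int = 0
    model: "RandomInterceptLMM | None" = None

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


class RandomInterceptLMM:
    """REML/ML estimator for a random-intercepts linear mixed model."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: dict[str, np.ndarray],
        reml: bool = True,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effects design is rank deficient")
        self.group_names = list(groups)
        self.Z = [_group_matrix(groups[g]) for g in self.group_names]
        self.reml = reml

    # -- profiled criterion -------------------------------------------------

    def _profiled(self, lam: np.ndarray) -> tuple[float, dict]:
        """-2 log (RE)ML with sigma^2 and beta profiled out, at ratios lam."""
        X, y, n, p = self.X, self.y, self.n, self.p
        blocks = [np.sqrt(l) * Z for l, Z in zip(lam, self.Z) if l > 0]
        if blocks:
            Zs = np.hstack(blocks)
            q = Zs.shape[1]
            A = np.eye(q) + Zs.T @ Zs
            cA = np.linalg.cholesky(A)
            logdetA = 2.0 * np.log(np.diag(cA)).sum()

            def wsolve(M):  # W^{-1} M  via Woodbury
                return M - Zs @ np.linalg.solve(A, Zs.T @ M)

        else:
            logdetA = 0.0

            def wsolve(M):
                return M

        WiX = wsolve(X)
        Wiy = wsolve(y)
        XtWiX = X.T @ WiX
        XtWiy = X.T @ Wiy
        beta = np.linalg.solve(XtWiX, XtWiy)
        rtWir = float(y @ Wiy - beta @ XtWiy)
        rtWir = max(rtWir, 1e-300)
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        dof = n - p if self.reml else n
        sigma2 = rtWir / dof
        dev = dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdetA
        if self.reml:
            dev += logdetXtWiX
        aux = {
            "beta": beta,
            "sigma2": sigma2,
            "XtWiX": XtWiX,
            "rtWir": rtWir,
            "logdetA": logdetA,
            "logdetXtWiX": logdetXtWiX,
        }
        return dev, aux

    def deviance_theta(self, theta: np.ndarray) -> float:
        """-2 log (RE)ML at explicit variance parameters
        ``theta = (sigma_1^2, ..., sigma_G^2, sigma^2)`` (beta profiled)."""
        *vcs, sigma2 = theta
        if sigma2 <= 0:
            return np.inf
        lam = np.asarray(vcs) / sigma2
        X, y, n, p = self.X, self.y, self.n, self.p
        dev_prof, aux = self._profiled(lam)
        # rebuild the unprofiled criterion at this fixed sigma2
        dof = n - p if self.reml else n
        dev = (
            dof * np.log(2 * np.pi * sigma2)
            + aux["logdetA"]
            + aux["rtWir"] / sigma2
        )
        if self.reml:
            dev += aux["logdetXtWiX"]
        return float(dev)

    def cov_beta_theta(self, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance Phi(theta) at explicit variance params."""
        *vcs, sigma2 = theta
        lam = np.asarray(vcs) / sigma2
        _, aux = self._profiled(lam)
        return sigma2 * np.linalg.inv(aux["XtWiX"])

    # -- fitting ------------------------------------------------------------

    def fit(self, starts: tuple[float, ...] = (1.0, 0.01)) -> LmmFit:
        G = len(self.Z)
        if G == 0:
            return self._ols_fit()

        def objective(lam):
            dev, _ = self._profiled(lam)
            return dev

        best = None
        for s in starts:
            res = optimize.minimize(
                objective,
                x0=np.full(G, s),
                method="L-BFGS-B",
                bounds=[(0.0, 1e6)] * G,
                options={"ftol": 1e-13, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        lam = np.asarray(best.x, dtype=float)
        # accept the boundary only if it is genuinely at least as good
        lam_zeroed = np.where(lam < BOUNDARY_TOL, 0.0, lam)
        if objective(lam_zeroed) <= best.fun + 1e-10:
            lam = lam_zeroed
        dev, aux = self._profiled(lam)
        sigma2 = aux["sigma2"]
        cov_beta = sigma2 * np.linalg.inv(aux["XtWiX"])
        beta = aux["beta"]
        fitted = self.X @ beta
        return LmmFit(
            beta=beta,
            se=np.sqrt(np.diag(cov_beta)),
            cov_beta=cov_beta,
            vc={g: float(l * sigma2) for g, l in zip(self.group_names, lam)},
            sigma2=float(sigma2),
            loglik=-dev / 2.0,
            reml=self.reml,
            fitted=fitted,
            residuals=self.y - fitted,
            boundary={g: bool(l == 0.0) for g, l in zip(self.group_names, lam)},
            n=self.n,
            p=self.p,
            model=self,
        )

    def _ols_fit(self) -> LmmFit:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        r = self.y - self.X @ beta
        dof = self.n - self.p if self.reml else self.n
        sigma2 = float(r @ r) / dof
        cov_beta = sigma2 * np.linalg.inv(self.X.T @ self.X)
        dev = dof * (np.log(2 * np.pi * sigma2) + 1.0)
        if self.reml:
            dev += np.linalg.slogdet(self.X.T @ self.X)[1]
        return LmmFit(
            beta=beta,
            se=np.sqrt(np.diag(cov_beta)),
            cov_beta=cov_beta,
            vc={},
            sigma2=sigma2,
            loglik=-dev / 2.0,
            reml=self.reml,
            fitted=self.X @ beta,
            residuals=r,
            n=self.n,
            p=self.p,
            model=self,
        )


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------


def _theta_of(fit: LmmFit) -> tuple[np.ndarray, list[int]]:
    """Variance parameters of a fit, excluding boundary (zero) components.

    Returns theta and the indices of the retained group components.
    """
    keep = [i for i, g in enumerate(fit.model.group_names) if not fit.boundary.get(g, False)]
    theta = np.array(
        [fit.vc[fit.model.group_names[i]] for i in keep] + [fit.sigma2]
    )
    return theta, keep


def _embed(theta: np.ndarray, keep: list[int], fit: LmmFit) -> np.ndarray:
    """Re-insert zero variance components dropped at the boundary."""
    full = np.zeros(len(fit.model.group_names) + 1)
    for j, i in enumerate(keep):
        full[i] = theta[j]
    full[-1] = theta[-1]
    return full


def vcov_varpar(fit: LmmFit) -> tuple[np.ndarray, list[int]]:
    """Asymptotic covariance of the (non-boundary) variance parameters,
    ``2 H^{-1}`` with H the numerical Hessian of the REML deviance."""
    theta, keep = _theta_of(fit)
    m = fit.model

    def dev(th):
        return m.deviance_theta(_embed(th, keep, fit))

    k = len(theta)
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))
    H = np.zeros((k, k))
    f0 = dev(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (dev(theta + ei) - 2 * f0 + dev(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    dev(theta + ei + ej)
                    - dev(theta + ei - ej)
                    - dev(theta - ei + ej)
                    + dev(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        A = 2.0 * np.linalg.pinv(H)
    return A, keep


def _grad_v(fit: LmmFit, c: np.ndarray, keep: list[int]) -> np.ndarray:
    """Numerical gradient of v(theta) = c' Phi(theta) c."""
    theta, _ = _theta_of(fit)
    m = fit.model
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))
    g = np.zeros(len(theta))
    for i in range(len(theta)):
        e = np.zeros(len(theta))
        e[i] = h[i]
        vp = c @ m.cov_beta_theta(_embed(theta + e, keep, fit)) @ c
        vm = c @ m.cov_beta_theta(_embed(theta - e, keep, fit)) @ c
        g[i] = (vp - vm) / (2 * h[i])
    return g


def satterthwaite_df(fit: LmmFit, c: np.ndarray, A: np.ndarray | None = None, keep: list[int] | None = None) -> float:
    """Satterthwaite denominator df for a single contrast ``c``."""
    if A is None or keep is None:
        A, keep = vcov_varpar(fit)
    v = float(c @ fit.cov_beta @ c)
    g = _grad_v(fit, c, keep)
    denom = float(g @ A @ g)
    if denom <= 0:
        return float(fit.n - fit.p)
    return 2.0 * v**2 / denom


def f_test(fit: LmmFit, C: np.ndarray, A: np.ndarray | None = None, keep: list[int] | None = None) -> dict:
    """F test of H0: C beta = 0 with Satterthwaite denominator df.

    Multi-row C uses the eigen-decomposition of C Phi C' to split the
    hypothesis into independent 1-df contrasts whose Satterthwaite dfs are
    pooled by the Fai-Cornelius formula.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    q = C.shape[0]
    if A is None or keep is None:
        A, keep = vcov_varpar(fit)
    M = C @ fit.cov_beta @ C.T
    Cb = C @ fit.beta
    Fstat = float(Cb @ np.linalg.solve(M, Cb)) / q
    if q == 1:
        ddf = satterthwaite_df(fit, C[0], A, keep)
    else:
        w, Q = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            if w[i] <= 1e-12 * w.max():
                continue
            a = C.T @ Q[:, i]
            nus.append(satterthwaite_df(fit, a, A, keep))
        nus = [nu for nu in nus if nu > 2.0]
        if not nus:
            ddf = float(fit.n - fit.p)
        else:
            E = sum(nu / (nu - 2.0) for nu in nus)
            ddf = 2.0 * E / (E - len(nus)) if E > len(nus) else float(fit.n - fit.p)
    p = float(stats.f.sf(Fstat, q, ddf)) if np.isfinite(Fstat) else np.nan
    return {"F": Fstat, "ndf": q, "ddf": float(ddf), "p": p}


def lrt_random(fit_full: LmmFit, fit_reduced: LmmFit) -> dict:
    """Boundary-aware likelihood-ratio test of nested random structures.

    Both fits must share the fixed-effects design and the (RE)ML convention;
    the reduced model's grouping factors must be a subset of the full
    model's.  The statistic ``2 (l_full - l_reduced)`` is referred to the
    ``0.5 chi2_0 + 0.5 chi2_1`` mixture appropriate for one variance
    component tested on its boundary.
    """
    mf, mr = fit_full.model, fit_reduced.model
    if mf.reml != mr.reml:
        raise ValueError("mixed REML/ML comparison")
    if not set(mr.group_names) <= set(mf.group_names):
        raise ValueError("reduced random structure is not nested in the full one")
    if mf.X.shape != mr.X.shape or not np.allclose(mf.X, mr.X):
        raise ValueError("fixed effects differ between models")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return {"statistic": stat, "p": p, "df_mixture": "0.5*chi2_0 + 0.5*chi2_1"}
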