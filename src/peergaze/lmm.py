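"""Maximum-likelihood linear mixed model with crossed random intercepts.

The model for trial-level ratings is

    y = X beta + Z_s b_s + Z_c b_c + e,
    b_s ~ N(0, sigma_s^2 I),  b_c ~ N(0, sigma_c^2 I),  e ~ N(0, sigma_e^2 I),

with subjects and scenes (stimuli) as crossed grouping factors.  Fitting is
by maximum likelihood (not REML) so that AIC values are comparable across
fixed-effect structures.

The deviance is profiled: with variance ratios lambda = sigma^2 / sigma_e^2,

    V* = I + lambda_s Z_s Z_s' + lambda_c Z_c Z_c',

beta and sigma_e^2 have closed forms given lambda, and all quadratic forms
reduce via the Woodbury identity to dense algebra on the q = S + C
random-effect cross-products.  The remaining 2-D optimisation over
(log lambda_s, log lambda_c) uses Nelder-Mead.  Because the cross-products
are shared across fixed-effect subsets, an all-subsets candidate scan fits
in seconds; every fit is cross-checkable against a generic mixed-model
routine on small problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = ["LMMFit", "CrossedLMMWorkspace", "fit_crossed_lmm"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LMMFit:
    """One fitted candidate model."""

    beta: np.ndarray            # fixed-effect estimates (intercept first)
    se: np.ndarray              # standard errors of beta
    loglik: float
    k: int                      # parameter count: p fixed + 2 vc + residual
    aic: float
    sigma_subject: float
    sigma_scene: float
    sigma_resid: float
    converged: bool
    n: int

    @property
    def p(self) -> int:
        return len(self.beta)


class CrossedLMMWorkspace:
    """Shared cross-products for all-subsets fitting on one dataset.

    Parameters
    ----------
    y : response vector (n,)
    X : global fixed-effect design matrix (n, p), intercept in column 0
    subject, scene : integer codes (n,) in [0, S) and [0, C)
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 subject: np.ndarray, scene: np.ndarray) -> None:
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        subject = np.asarray(subject)
        scene = np.asarray(scene)
        n = len(y)
        if X.shape[0] != n or len(subject) != n or len(scene) != n:
            raise ValueError("y, X, subject, scene must share length")
        subj_codes, subj_idx = np.unique(subject, return_inverse=True)
        scene_codes, scene_idx = np.unique(scene, return_inverse=True)
        S, C = len(subj_codes), len(scene_codes)
        if S < 2 or C < 2:
            raise ValueError("need >= 2 subjects and >= 2 scenes")
        self.n, self.S, self.C = n, S, C
        q = S + C
        # Z'Z in block form
        ZtZ = np.zeros((q, q))
        ZtZ[:S, :S] = np.diag(np.bincount(subj_idx, minlength=S).astype(float))
        ZtZ[S:, S:] = np.diag(np.bincount(scene_idx, minlength=C).astype(float))
        N = np.zeros((S, C))
        np.add.at(N, (subj_idx, scene_idx), 1.0)
        ZtZ[:S, S:] = N
        ZtZ[S:, :S] = N.T
        self.ZtZ = ZtZ
        # Z'X and Z'y
        p = X.shape[1]
        ZtX = np.zeros((q, p))
        for j in range(p):
            ZtX[:S, j] = np.bincount(subj_idx, weights=X[:, j], minlength=S)
            ZtX[S:, j] = np.bincount(scene_idx, weights=X[:, j], minlength=C)
        Zty = np.concatenate([
            np.bincount(subj_idx, weights=y, minlength=S),
            np.bincount(scene_idx, weights=y, minlength=C)])
        self.ZtX, self.Zty = ZtX, Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        #: (log lambda_s, log lambda_c) at the most recent optimum
        self.last_opt: tuple[float, float] | None = None
        self._eye = np.eye(q)

    # -- profiled deviance -------------------------------------------------
    def _profile(self, log_lam: np.ndarray, cols: np.ndarray):
        lam_s, lam_c = np.exp(np.clip(log_lam, -40.0, 40.0))
        d = np.concatenate([np.full(self.S, math.sqrt(lam_s)),
                            np.full(self.C, math.sqrt(lam_c))])
        M = self._eye + (d[:, None] * self.ZtZ) * d[None, :]
        L = cholesky(M, lower=True, check_finite=False)
        A = solve_triangular(L, d[:, None] * self.ZtX[:, cols], lower=True,
                             check_finite=False)
        b = solve_triangular(L, d * self.Zty, lower=True, check_finite=False)
        XtVX = self.XtX[np.ix_(cols, cols)] - A.T @ A
        XtVy = self.Xty[cols] - A.T @ b
        ytVy = self.yty - b @ b
        cf = cho_factor(XtVX, lower=True)
        beta = cho_solve(cf, XtVy)
        rss = ytVy - XtVy @ beta
        rss = max(rss, 1e-12)
        sigma2 = rss / self.n
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        n2ll = self.n * (_LOG_2PI + math.log(sigma2)) + logdet + self.n
        return n2ll, beta, sigma2, cf, (lam_s, lam_c)

    def fit(self, cols: np.ndarray,
            start: tuple[float, float] | None = None) -> LMMFit:
        """ML fit of the candidate using the global design columns ``cols``.

        ``start`` optionally warm-starts the (log lambda_s, log lambda_c)
        search, e.g. from the global model's optimum during candidate scans.
        """
        cols = np.asarray(cols, dtype=int)

        def objective(x: np.ndarray) -> float:
            try:
                return self._profile(x, cols)[0]
            except np.linalg.LinAlgError:
                return np.inf

        starts: list[tuple[float, float]] = []
        if start is not None:
            starts.append(tuple(start))
        starts += [(math.log(0.1), math.log(0.1)), (math.log(1.0), math.log(0.05))]
        best = None
        for x0 in starts:
            res = minimize(objective, x0=np.asarray(x0), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 5e-8, "maxiter": 600})
            if best is None or res.fun < best.fun:
                best = res
            if best.success and best.fun < np.inf:
                break
        converged = bool(best.success and np.isfinite(best.fun))
        n2ll, beta, sigma2, cf, (lam_s, lam_c) = self._profile(best.x, cols)
        self.last_opt = (float(best.x[0]), float(best.x[1]))
        p = len(cols)
        cov = sigma2 * cho_solve(cf, np.eye(p))
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        k = p + 3
        loglik = -0.5 * n2ll
        return LMMFit(beta=beta, se=se, loglik=loglik, k=k,
                      aic=n2ll + 2 * k,
                      sigma_subject=math.sqrt(lam_s * sigma2),
                      sigma_scene=math.sqrt(lam_c * sigma2),
                      sigma_resid=math.sqrt(sigma2),
                      converged=converged, n=self.n)


def fit_crossed_lmm(y: np.ndarray, X: np.ndarray, subject: np.ndarray,
                    scene: np.ndarray) -> LMMFit:
    """Fit one crossed random-intercepts model by ML."""
    ws = CrossedLMMWorkspace(y, X, subject, scene)
    return ws.fit(np.arange(X.shape[1]))
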