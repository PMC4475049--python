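"""Restricted maximum likelihood for Gaussian random-intercept models.

Supports the model y = X beta + sum_k Z_k b_k + e with b_k ~ N(0, s2_k I)
for one or more (nested) categorical grouping factors and e ~ N(0, s2 I).
The first factor must be the coarsest: every level of a later factor has to
lie inside a single level of the first, so the marginal covariance V is
block-diagonal by the first factor and all quantities are accumulated
block by block.  A closed-form path handles the single-factor case
(V_g = s2 I + theta J) without forming any matrix.

Beyond point estimation this module provides the two quantities the
comparative analyses need that standard fitting libraries do not expose
together: Satterthwaite denominator degrees of freedom for fixed-effect
t-tests (from the gradient of Var(beta_j) and the observed information of
the REML criterion) and REML log-likelihoods that are directly comparable
across random-effect structures, including the no-random-effect model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .exceptions import ConvergenceError

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLFit:
    """Converged REML solution."""

    beta: np.ndarray
    cov_beta: np.ndarray
    variances: np.ndarray  # one per random factor, order as supplied
    sigma2: float  # residual variance
    loglik: float  # restricted log-likelihood
    converged: bool


class RandomInterceptModel:
    """REML machinery for one response, fixed design and nested grouping factors."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        factors: list[np.ndarray] | None = None,
        factor_names: list[str] | None = None,
    ):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y and X are not conformable")
        factors = factors or []
        self.factor_names = factor_names or [f"g{k}" for k in range(len(factors))]
        codes = [np.unique(np.asarray(f), return_inverse=True) for f in factors]
        self.levels = [c[0] for c in codes]
        raw_codes = [c[1] for c in codes]

        if factors:
            order = np.argsort(raw_codes[0], kind="stable")
        else:
            order = np.arange(y.shape[0])
        self.order = order
        self.y = y[order]
        self.X = X[order]
        self.codes = [c[order] for c in raw_codes]
        self.n, self.p = self.X.shape

        if factors:
            # block boundaries by the coarsest factor
            first = self.codes[0]
            self.block_starts = np.flatnonzero(np.r_[True, np.diff(first) != 0])
            self.block_ends = np.r_[self.block_starts[1:], self.n]
            for k, c in enumerate(self.codes[1:], start=1):
                # nested structure check: each level inside one coarse block
                owner = {}
                for blk, (s, e) in enumerate(zip(self.block_starts, self.block_ends)):
                    for lev in np.unique(c[s:e]):
                        if owner.setdefault(lev, blk) != blk:
                            raise ValueError(
                                f"factor {self.factor_names[k]!r} is not nested "
                                f"within {self.factor_names[0]!r}"
                            )

    @property
    def k(self) -> int:
        return len(self.codes)

    # ------------------------------------------------------------------ #
    # restricted log-likelihood and GLS pieces

    def _gls_pieces(self, params: np.ndarray):
        """Return (logdetV, XtViX, XtViy, ytViy) for params = [*variances, sigma2]."""
        sigma2 = params[-1]
        thetas = params[:-1]
        if self.k == 0:
            XtX = self.X.T @ self.X
            return (
                self.n * np.log(sigma2),
                XtX / sigma2,
                self.X.T @ self.y / sigma2,
                self.y @ self.y / sigma2,
            )
        if self.k == 1:
            return self._one_factor_pieces(thetas[0], sigma2)
        return self._block_pieces(thetas, sigma2)

    def _one_factor_pieces(self, theta: float, sigma2: float):
        codes = self.codes[0]
        G = self.levels[0].size
        m = np.bincount(codes, minlength=G).astype(float)
        Sx = np.zeros((G, self.p))
        for j in range(self.p):
            Sx[:, j] = np.bincount(codes, weights=self.X[:, j], minlength=G)
        Sy = np.bincount(codes, weights=self.y, minlength=G)
        c = theta / (sigma2 + m * theta)  # Sherman–Morrison coefficient per group
        logdetV = (self.n - G) * np.log(sigma2) + np.sum(np.log(sigma2 + m * theta))
        XtViX = (self.X.T @ self.X - Sx.T @ (c[:, None] * Sx)) / sigma2
        XtViy = (self.X.T @ self.y - Sx.T @ (c * Sy)) / sigma2
        ytViy = (self.y @ self.y - Sy @ (c * Sy)) / sigma2
        return logdetV, XtViX, XtViy, ytViy

    def _block_pieces(self, thetas: np.ndarray, sigma2: float):
        logdetV = 0.0
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        for s, e in zip(self.block_starts, self.block_ends):
            nb = e - s
            V = sigma2 * np.eye(nb)
            for th, codes in zip(thetas, self.codes):
                cb = codes[s:e]
                V += th * (cb[:, None] == cb[None, :])
            cho = linalg.cho_factor(V, lower=True)
            logdetV += 2.0 * np.sum(np.log(np.diag(cho[0])))
            Xb, yb = self.X[s:e], self.y[s:e]
            ViX = linalg.cho_solve(cho, Xb)
            Viy = linalg.cho_solve(cho, yb)
            XtViX += Xb.T @ ViX
            XtViy += Xb.T @ Viy
            ytViy += yb @ Viy
        return logdetV, XtViX, XtViy, ytViy

    def loglik(self, params: np.ndarray) -> float:
        """Restricted log-likelihood at params = [*variances, sigma2]."""
        params = np.asarray(params, dtype=float)
        if params[-1] <= 0 or np.any(params[:-1] < 0):
            return -np.inf
        try:
            logdetV, XtViX, XtViy, ytViy = self._gls_pieces(params)
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            # numerically non-PD for extreme variance ratios proposed by the
            # optimizer; treat as infinitely unlikely
            return -np.inf
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - beta @ XtViy
        return -0.5 * (logdetV + logdetXVX + quad + (self.n - self.p) * _LOG2PI)

    def beta_cov(self, params: np.ndarray):
        """GLS fixed effects and their covariance at the given params."""
        _, XtViX, XtViy, _ = self._gls_pieces(np.asarray(params, dtype=float))
        cov = np.linalg.inv(XtViX)
        return cov @ XtViy, cov

    # ------------------------------------------------------------------ #
    # fitting

    def fit(self, start: np.ndarray | None = None) -> REMLFit:
        """Maximize the restricted likelihood over the variance parameters."""
        resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        vtot = float(resid @ resid / max(self.n - self.p, 1))
        vtot = max(vtot, 1e-12)

        if self.k == 0:
            sigma2 = vtot
            params = np.array([sigma2])
            beta, cov = self.beta_cov(params)
            return REMLFit(beta, cov, np.array([]), sigma2, self.loglik(params), True)

        floor = 1e-10 * vtot
        starts = [start] if start is not None else []
        k = self.k
        starts += [
            np.r_[np.full(k, vtot / (2 * k)), vtot / 2],
            np.r_[np.full(k, floor), vtot],
            np.r_[np.full(k, vtot), vtot / 4],
        ]
        best = None
        for s0 in starts:
            s0 = np.maximum(np.asarray(s0, dtype=float), floor)
            res = optimize.minimize(
                lambda p: -self.loglik(p),
                s0,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * k + [(floor, None)],
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed to produce a finite value")
        params = np.asarray(best.x, dtype=float)
        # snap boundary variances to exactly zero
        params[:-1][params[:-1] < 10 * floor] = 0.0
        beta, cov = self.beta_cov(np.r_[params[:-1], params[-1]])
        return REMLFit(
            beta=beta,
            cov_beta=cov,
            variances=params[:-1].copy(),
            sigma2=float(params[-1]),
            loglik=float(self.loglik(params)),
            converged=bool(best.success),
        )

    # ------------------------------------------------------------------ #
    # Satterthwaite degrees of freedom

    def satterthwaite_df(self, fit: REMLFit, coef_index: int) -> float:
        """Denominator df for the t-test of beta[coef_index].

        df = 2 f^2 / (g' A g) with f = Var(beta_j), g its gradient in the
        variance parameters and A the inverse observed information of the
        restricted likelihood.  Variance components estimated on the zero
        boundary are held fixed (excluded from the parameter vector).
        """
        full = np.r_[fit.variances, fit.sigma2]
        scale = max(fit.sigma2, 1e-12)
        active = [i for i, v in enumerate(full[:-1]) if v > 1e-8 * scale]
        active.append(len(full) - 1)  # residual variance always active
        if len(active) == 1 and self.k == 0:
            return float(self.n - self.p)

        def expand(phi):
            p = full.copy()
            p[active] = phi
            return p

        def var_j(phi):
            _, cov = self.beta_cov(expand(phi))
            return cov[coef_index, coef_index]

        phi0 = full[active]
        h = np.maximum(np.abs(phi0), scale) * 1e-5
        m = phi0.size

        grad = np.empty(m)
        for i in range(m):
            e = np.zeros(m)
            e[i] = h[i]
            grad[i] = (var_j(phi0 + e) - var_j(phi0 - e)) / (2 * h[i])

        def nll(phi):
            return -self.loglik(expand(np.maximum(phi, 0.0)))

        H = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                if i == j:
                    H[i, i] = (nll(phi0 + ei) - 2 * nll(phi0) + nll(phi0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(phi0 + ei + ej)
                        - nll(phi0 + ei - ej)
                        - nll(phi0 - ei + ej)
                        + nll(phi0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(H)
        denom = float(grad @ A @ grad)
        f = var_j(phi0)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * f * f / denom
        return float(np.clip(df, 1.0, self.n - self.p))

    # ------------------------------------------------------------------ #
    # predictions

    def blups(self, fit: REMLFit) -> list[dict]:
        """Predicted random intercepts per factor, as {level: blup} dicts."""
        params = np.r_[fit.variances, fit.sigma2]
        resid = self.y - self.X @ fit.beta
        # V^{-1} residual, blockwise
        vir = np.empty(self.n)
        if self.k == 0:
            vir[:] = resid / fit.sigma2
        elif self.k == 1:
            codes = self.codes[0]
            G = self.levels[0].size
            m = np.bincount(codes, minlength=G).astype(float)
            theta = fit.variances[0]
            c = theta / (fit.sigma2 + m * theta)
            Sr = np.bincount(codes, weights=resid, minlength=G)
            vir = (resid - c[codes] * Sr[codes]) / fit.sigma2
        else:
            for s, e in zip(self.block_starts, self.block_ends):
                nb = e - s
                V = fit.sigma2 * np.eye(nb)
                for th, codes in zip(fit.variances, self.codes):
                    cb = codes[s:e]
                    V += th * (cb[:, None] == cb[None, :])
                vir[s:e] = linalg.solve(V, resid[s:e], assume_a="pos")
        out = []
        for kk in range(self.k):
            codes, levels = self.codes[kk], self.levels[kk]
            sums = np.bincount(codes, weights=vir, minlength=levels.size)
            out.append(dict(zip(levels, fit.variances[kk] * sums)))
        return out

    def fitted(self, fit: REMLFit, conditional: bool = True) -> np.ndarray:
        """Fitted values in the original row order."""
        vals = self.X @ fit.beta
        if conditional and self.k:
            for kk, b in enumerate(self.blups(fit)):
                lev_b = np.array([b[lev] for lev in self.levels[kk]])
                vals = vals + lev_b[self.codes[kk]]
        out = np.empty(self.n)
        out[self.order] = vals
        return out
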