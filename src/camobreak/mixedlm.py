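"""Profiled-likelihood solver for linear mixed models with crossed random
intercepts.

The analysis model is y = X b + Z u + e with u a stack of independent
random intercepts (one block per grouping factor, e.g. session and
photograph) and homoscedastic residuals.  For this structure the entire
likelihood can be evaluated from fixed-size cross-products (X'X, Z'X, Z'Z,
Z'y, X'y, y'y): writing the covariance as V = sigma^2 (I + Z L Z') with
L = diag of per-factor variance ratios, the Woodbury identity reduces every
GLS quantity to solves against M = I_q + L^{1/2} Z'Z L^{1/2}, a dense q x q
matrix (q = total number of random-effect levels).  Profiling b and sigma^2
leaves only the variance ratios to optimize numerically, so a fit costs
O(q^3) per likelihood evaluation, independent of the number of rows -- the
property the stepwise model selection relies on, since candidate fits reuse
one set of cross-products and merely slice columns.

Both ML and REML criteria are implemented; REML is used for comparisons of
random structures, ML for fixed-effect comparisons.  Zero variance ratios
(degenerate random effects) are admissible boundary fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomInterceptLMM", "LMMResult"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LMMResult:
    """Converged (or boundary) fit of a random-intercepts mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float          # residual variance (ML or REML estimate)
    vc_sd: dict[str, float]  # random-intercept SDs, same scale as response
    llf: float
    reml: bool
    n: int
    p: int
    n_levels: int          # total random-effect levels across factors
    k_params: int          # p + number of variance components + 1 (residual)
    converged: bool
    lam: np.ndarray        # fitted variance ratios (warm-start for neighbours)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.n)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


class RandomInterceptLMM:
    """Cross-product store for one response/design/grouping configuration.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) full fixed-effect design; candidate fits may use any column
        subset
    factors : mapping factor name -> (n,) integer codes in [0, n_levels)
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, factors: dict[str, np.ndarray]):
        y = np.asarray(y, dtype=np.float64).ravel()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        self.n = y.shape[0]
        self.p_full = X.shape[1]
        self.factor_names = list(factors)
        self.codes: dict[str, np.ndarray] = {}
        self.n_lvl: dict[str, int] = {}
        for name, c in factors.items():
            c = np.asarray(c)
            if c.shape[0] != self.n:
                raise ValueError(f"factor {name!r} length mismatch")
            if c.min() < 0:
                raise ValueError(f"factor {name!r} has unassigned (negative) codes")
            self.codes[name] = c.astype(np.intp)
            self.n_lvl[name] = int(c.max()) + 1
            if self.n_lvl[name] < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels")

        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

        self.ZtX: dict[str, np.ndarray] = {}
        self.Zty: dict[str, np.ndarray] = {}
        for name in self.factor_names:
            c, q = self.codes[name], self.n_lvl[name]
            m = np.zeros((q, X.shape[1]))
            np.add.at(m, c, X)
            self.ZtX[name] = m
            v = np.zeros(q)
            np.add.at(v, c, y)
            self.Zty[name] = v

        self.ZtZ: dict[tuple[str, str], np.ndarray] = {}
        for i, a in enumerate(self.factor_names):
            ca, qa = self.codes[a], self.n_lvl[a]
            self.ZtZ[(a, a)] = np.diag(np.bincount(ca, minlength=qa).astype(float))
            for b in self.factor_names[i + 1 :]:
                cb, qb = self.codes[b], self.n_lvl[b]
                ct = np.zeros((qa, qb))
                np.add.at(ct, (ca, cb), 1.0)
                self.ZtZ[(a, b)] = ct

    # -- assembly helpers ---------------------------------------------------

    def _stack(self, names: list[str], cols: np.ndarray):
        q_sizes = [self.n_lvl[f] for f in names]
        q = sum(q_sizes)
        ZtX = np.vstack([self.ZtX[f][:, cols] for f in names]) if names else np.zeros((0, len(cols)))
        Zty = np.concatenate([self.Zty[f] for f in names]) if names else np.zeros(0)
        ZtZ = np.zeros((q, q))
        off = dict(zip(names, np.cumsum([0] + q_sizes[:-1])))
        for i, a in enumerate(names):
            oa, qa = off[a], self.n_lvl[a]
            ZtZ[oa : oa + qa, oa : oa + qa] = self.ZtZ[(a, a)]
            for b in names[i + 1 :]:
                ob, qb = off[b], self.n_lvl[b]
                blk = self.ZtZ[(a, b)]
                ZtZ[oa : oa + qa, ob : ob + qb] = blk
                ZtZ[ob : ob + qb, oa : oa + qa] = blk.T
        return q_sizes, ZtX, Zty, ZtZ

    # -- likelihood ---------------------------------------------------------

    def _profile(self, lam, q_sizes, ZtX, Zty, ZtZ, XtX, Xty, reml):
        """Profiled -2 log-likelihood at the given variance ratios."""
        n, p = self.n, XtX.shape[0]
        lam_vec = np.repeat(np.maximum(lam, 0.0), q_sizes)
        sq = np.sqrt(lam_vec)
        q = len(lam_vec)
        if q:
            M = sq[:, None] * ZtZ * sq[None, :]
            M[np.diag_indices_from(M)] += 1.0
            cf = cho_factor(M, lower=True)
            logdetW = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            A = sq[:, None] * ZtX
            ay = sq * Zty
            UA = cho_solve(cf, A)
            uy = cho_solve(cf, ay)
            XtWiX = XtX - A.T @ UA
            XtWiy = Xty - A.T @ uy
            ytWiy = self.yty - ay @ uy
        else:
            logdetW = 0.0
            XtWiX, XtWiy, ytWiy = XtX, Xty, self.yty

        XtWiX = (XtWiX + XtWiX.T) / 2.0
        try:
            cfx = cho_factor(XtWiX, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("rank-deficient fixed-effect design") from exc
        beta = cho_solve(cfx, XtWiy)
        logdetXtWiX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        r2 = max(float(ytWiy - beta @ XtWiy), 1e-12)

        if reml:
            sigma2 = r2 / (n - p)
            neg2ll = (
                (n - p) * (_LOG2PI + np.log(sigma2))
                + logdetW
                + logdetXtWiX
                + (n - p)
            )
        else:
            sigma2 = r2 / n
            neg2ll = n * (_LOG2PI + np.log(sigma2)) + logdetW + n
        return float(neg2ll), beta, XtWiX, sigma2

    # -- public fit ---------------------------------------------------------

    def fit(
        self,
        cols: np.ndarray | list[int] | None = None,
        factor_subset: list[str] | None = None,
        reml: bool = False,
        start_lam: np.ndarray | None = None,
    ) -> LMMResult:
        """Fit by numerical optimization of the profiled criterion.

        ``cols`` selects fixed-effect design columns from the full design;
        ``factor_subset`` selects the random-intercept factors.  The
        variance ratios are optimized on a log scale via Nelder-Mead
        (robust for the 1-3 parameters that occur here), with the boundary
        lambda -> 0 reachable to numerical precision; a ratio below 1e-8 is
        reported as a zero-variance (degenerate) random effect.
        """
        cols = np.arange(self.p_full) if cols is None else np.asarray(cols, dtype=np.intp)
        names = self.factor_names if factor_subset is None else list(factor_subset)
        for f in names:
            if f not in self.n_lvl:
                raise KeyError(f"unknown factor {f!r}")
        p = len(cols)
        XtX = self.XtX[np.ix_(cols, cols)]
        Xty = self.Xty[cols]
        q_sizes, ZtX, Zty, ZtZ = self._stack(names, cols)

        args = (q_sizes, ZtX, Zty, ZtZ, XtX, Xty, reml)
        converged = True
        if names:
            x0 = np.log(np.full(len(names), 0.1) if start_lam is None else np.maximum(start_lam, 1e-6))

            def objective(theta):
                return self._profile(np.exp(theta), *args)[0]

            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 2000},
            )
            converged = bool(res.success)
            lam = np.exp(res.x)
            lam[lam < 1e-8] = 0.0
        else:
            lam = np.zeros(0)

        neg2ll, beta, XtWiX, sigma2 = self._profile(lam, *args)
        cov_beta = sigma2 * np.linalg.inv(XtWiX)
        vc_sd = {f: float(np.sqrt(l * sigma2)) for f, l in zip(names, lam)}
        return LMMResult(
            beta=beta,
            cov_beta=cov_beta,
            sigma2=sigma2,
            vc_sd=vc_sd,
            llf=-neg2ll / 2.0,
            reml=reml,
            n=self.n,
            p=p,
            n_levels=sum(self.n_lvl[f] for f in names),
            k_params=p + len(names) + 1,
            converged=converged,
            lam=lam,
        )
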