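"""Mixed-model trajectory analysis (MMTA) for windowed shift data.

Within-person trajectories are modeled at level 1 and officers at level 2
with the linear mixed model

    Y_it = b0 + u_0i + b1 * time + u_1i * time + b2 * Intx_it
           + b3 * (Intx * time)_it + e_it ,

where ``time`` is coded 0 at the start of each shift, ``Intx`` marks an
intervention (or any contrasted) phase, ``u_0i``/``u_1i`` are normally
distributed per-officer deviations with covariance G, and ``e_it`` is
level-1 error that may be independent, first-order autoregressive (AR(1)),
or banded Toeplitz within an officer's series.

Estimation is by maximum likelihood (for model comparison) or restricted
maximum likelihood (for reported estimates; ML underestimates variance
components in small samples).  Fixed-effect inference uses a
Satterthwaite-style small-sample degrees-of-freedom approximation — the
spirit of the Kenward–Roger correction, controlling type-1 error with few
officers — and every fit records which method produced its df.

The likelihood is evaluated per officer: the residual correlation is
whitened away (closed form for AR(1), banded Cholesky for Toeplitz), after
which the random-effect contribution is handled by the Woodbury identity,
so cost is linear in the number of windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky_banded, solve_banded

logger = logging.getLogger(__name__)

__all__ = [
    "MmtaSpec",
    "MmtaFit",
    "fit_mmta",
    "compare_models",
    "phase_contrast",
    "simulate_trajectories",
    "recovery_study",
    "ConvergenceError",
]

ERROR_STRUCTURES = ("independent", "ar1", "toeplitz")


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed to converge."""


@dataclass
class MmtaSpec:
    """Model specification.

    ``fixed_effects`` are column names of the data (an intercept is always
    included); a term ``"a:b"`` is the product of columns a and b.
    ``random_effects`` is a subset of {"intercept", <time column>}.
    """

    outcome: str
    fixed_effects: tuple[str, ...] = ("time", "intervention", "intervention:time")
    random_effects: tuple[str, ...] = ("intercept", "time")
    error_structure: str = "independent"
    toeplitz_bands: int = 1
    estimation: str = "reml"
    df_method: str = "auto"
    group_col: str = "officer_id"

    def __post_init__(self) -> None:
        if self.error_structure not in ERROR_STRUCTURES:
            raise ValueError(f"error_structure must be one of {ERROR_STRUCTURES}")
        if self.estimation not in ("ml", "reml"):
            raise ValueError("estimation must be 'ml' or 'reml'")
        if self.df_method not in ("auto", "kenward-roger", "satterthwaite",
                                  "residual"):
            raise ValueError(
                "df_method must be 'auto', 'kenward-roger', 'satterthwaite' "
                "or 'residual'"
            )


@dataclass
class MmtaFit:
    """Fitted model: estimates, covariance parameters, fit statistics."""

    spec: MmtaSpec
    fe_names: list[str]
    beta: pd.Series
    se: pd.Series
    tstat: pd.Series
    df: pd.Series
    pvalues: pd.Series
    cov_beta: pd.DataFrame
    G: pd.DataFrame              # random-effect covariance (may be empty)
    sigma2: float                # level-1 error variance
    error_params: dict           # rho for ar1, band correlations for toeplitz
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    n_params: int
    converged: bool
    df_method_used: str
    blups: pd.DataFrame | None = None
    n_dropped: int = 0
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df)
        return pd.DataFrame(
            {"lower": self.beta - q * self.se, "upper": self.beta + q * self.se},
            index=self.beta.index,
        )

    def summary(self) -> str:
        lines = [
            f"MMTA fit ({self.spec.estimation.upper()}, "
            f"errors={self.spec.error_structure}, df={self.df_method_used})",
            f"  n_obs={self.n_obs}  n_officers={self.n_groups}  "
            f"dropped={self.n_dropped}  converged={self.converged}",
            f"  loglik={self.loglik:.3f}  AIC={self.aic:.3f}  BIC={self.bic:.3f}",
            "  Fixed effects:",
        ]
        for name in self.fe_names:
            lines.append(
                f"    {name:>20s}  {self.beta[name]: .5f}  "
                f"se={self.se[name]:.5f}  t={self.tstat[name]: .3f}  "
                f"df={self.df[name]:.1f}  p={self.pvalues[name]:.4g}"
            )
        if len(self.G):
            lines.append("  Random-effect covariance G:")
            lines.append("    " + self.G.round(6).to_string().replace("\n", "\n    "))
        lines.append(f"  sigma2={self.sigma2:.6f}  {self.error_params}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimation": self.spec.estimation,
            "error_structure": self.spec.error_structure,
            "df_method": self.df_method_used,
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "tstat": self.tstat.to_dict(),
            "df": self.df.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "G": self.G.to_dict() if len(self.G) else {},
            "sigma2": self.sigma2,
            "error_params": self.error_params,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = term.split(":")
        col = np.ones(len(data))
        for p in parts:
            col = col * data[p].to_numpy(dtype=float)
        return col
    return data[term].to_numpy(dtype=float)


def _build_design(
    data: pd.DataFrame, spec: MmtaSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list]:
    used_cols = {spec.outcome, spec.group_col}
    for term in spec.fixed_effects:
        used_cols.update(term.split(":"))
    for term in spec.random_effects:
        if term != "intercept":
            used_cols.add(term)
    y = data[spec.outcome]
    keep = data[sorted(used_cols)].notna().all(axis=1)
    clean = data.loc[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing values", n_dropped)

    fe_names = ["intercept"] + list(spec.fixed_effects)
    X = np.column_stack(
        [np.ones(len(clean))]
        + [_term_column(clean, t) for t in spec.fixed_effects]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    re_cols = []
    for term in spec.random_effects:
        if term == "intercept":
            re_cols.append(np.ones(len(clean)))
        else:
            re_cols.append(clean[term].to_numpy(dtype=float))
    Z = np.column_stack(re_cols) if re_cols else np.empty((len(clean), 0))
    y = clean[spec.outcome].to_numpy(dtype=float)
    groups = clean[spec.group_col].to_numpy()
    return y, X, Z, groups, fe_names, [n_dropped]


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class _Engine:
    """Profiled (RE)ML for a 2-level mixed model with structured errors."""

    def __init__(self, y, X, Z, groups, spec: MmtaSpec):
        self.spec = spec
        self.p = X.shape[1]
        self.q = Z.shape[1]
        order = np.argsort(groups, kind="stable")
        y, X, Z, groups = y[order], X[order], Z[order], groups[order]
        self.group_ids, starts = np.unique(groups, return_index=True)
        starts = np.sort(starts)
        bounds = list(starts) + [len(y)]
        self.blocks = [
            (y[a:b], X[a:b], Z[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        self.n = len(y)
        self.n_groups = len(self.blocks)
        struct = spec.error_structure
        if struct == "ar1":
            self.n_corr = 1
        elif struct == "toeplitz":
            self.n_corr = spec.toeplitz_bands
        else:
            self.n_corr = 0
        self.n_theta = self.q * (self.q + 1) // 2 + 1 + self.n_corr

    # -- parameter packing ------------------------------------------------

    def unpack(self, theta: np.ndarray):
        q = self.q
        k = q * (q + 1) // 2
        L = np.zeros((q, q))
        idx = 0
        for j in range(q):
            for i in range(j, q):
                if i == j:
                    L[i, j] = np.exp(theta[idx])
                else:
                    L[i, j] = theta[idx]
                idx += 1
        sigma2 = float(np.exp(theta[k]))
        corr = np.tanh(theta[k + 1 : k + 1 + self.n_corr])
        return L, sigma2, corr

    def start_theta(self) -> np.ndarray:
        yall = np.concatenate([b[0] for b in self.blocks])
        Xall = np.vstack([b[1] for b in self.blocks])
        beta, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
        resid = yall - Xall @ beta
        s2 = max(resid.var(), 1e-8)
        theta = np.zeros(self.n_theta)
        idx = 0
        for j in range(self.q):
            for i in range(j, self.q):
                if i == j:
                    theta[idx] = 0.5 * np.log(0.1 * s2 + 1e-10)
                idx += 1
        theta[self.q * (self.q + 1) // 2] = np.log(s2)
        return theta

    # -- whitening for the residual correlation ---------------------------

    def _whiten(self, y, X, Z, corr):
        """Transform so residual errors are iid; return logdet of R."""
        struct = self.spec.error_structure
        n = len(y)
        if struct == "independent" or n == 0 or self.n_corr == 0:
            return y, X, Z, 0.0
        if struct == "ar1":
            rho = corr[0]
            c = np.sqrt(1.0 - rho**2)
            W = np.column_stack([y, X, Z]) if Z.size else np.column_stack([y, X])
            Wt = W.copy()
            Wt[1:] = (W[1:] - rho * W[:-1]) / c
            logdet = (n - 1) * np.log(1.0 - rho**2)
            yw, Xw = Wt[:, 0], Wt[:, 1 : 1 + self.p]
            Zw = Wt[:, 1 + self.p :] if Z.size else Z
            return yw, Xw, Zw, logdet
        # banded Toeplitz correlation: 1 on the diagonal, corr[j] at lag j+1
        b = self.n_corr
        ab = np.zeros((b + 1, n))
        ab[0] = 1.0
        for j in range(1, b + 1):
            ab[j, : n - j] = corr[j - 1]
        # lower-banded storage for cholesky_banded
        try:
            cb = cholesky_banded(ab, lower=True)
        except np.linalg.LinAlgError as exc:
            raise _NotPD from exc
        logdet = 2.0 * np.sum(np.log(cb[0]))
        W = np.column_stack([y, X, Z]) if Z.size else np.column_stack([y, X])
        # solve L W' = W with L lower-banded
        Wt = solve_banded((b, 0), _banded_to_lower(cb, b), W)
        yw, Xw = Wt[:, 0], Wt[:, 1 : 1 + self.p]
        Zw = Wt[:, 1 + self.p :] if Z.size else Z
        return yw, Xw, Zw, logdet

    # -- profiled likelihood ----------------------------------------------

    def _accumulate(self, theta):
        L, sigma2, corr = self.unpack(theta)
        p, q = self.p, self.q
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        for y, X, Z in self.blocks:
            yw, Xw, Zw, ld_r = self._whiten(y, X, Z, corr)
            n = len(yw)
            logdet += ld_r
            if q:
                U = Zw @ L
                M = sigma2 * np.eye(q) + U.T @ U
                cf = cho_factor(M)
                Uy = U.T @ yw
                UX = U.T @ Xw
                XtVX += (Xw.T @ Xw - UX.T @ cho_solve(cf, UX)) / sigma2
                XtVy += (Xw.T @ yw - UX.T @ cho_solve(cf, Uy)) / sigma2
                ytVy += (yw @ yw - Uy @ cho_solve(cf, Uy)) / sigma2
                logdet += (n - q) * np.log(sigma2) + 2.0 * np.sum(
                    np.log(np.diag(cf[0]))
                )
            else:
                XtVX += Xw.T @ Xw / sigma2
                XtVy += Xw.T @ yw / sigma2
                ytVy += yw @ yw / sigma2
                logdet += n * np.log(sigma2)
        return XtVX, XtVy, ytVy, logdet

    def loglik(self, theta, reml: bool) -> float:
        try:
            XtVX, XtVy, ytVy, logdet = self._accumulate(theta)
            cf = cho_factor(XtVX)
        except (np.linalg.LinAlgError, _NotPD):
            return -np.inf
        beta = cho_solve(cf, XtVy)
        rss = ytVy - beta @ XtVy  # r' V^-1 r at the GLS solution
        ll = -0.5 * (logdet + rss + self.n * np.log(2 * np.pi))
        if reml:
            ll -= 0.5 * (
                2.0 * np.sum(np.log(np.diag(cf[0]))) - self.p * np.log(2 * np.pi)
            )
        return float(ll)

    _PENALTY = 1e10  # finite stand-in for an infeasible parameter point

    def fit(self) -> tuple[np.ndarray, bool]:
        reml = self.spec.estimation == "reml"

        def fun(th: np.ndarray) -> float:
            v = -self.loglik(th, reml)
            return v if np.isfinite(v) else self._PENALTY

        th0 = self.start_theta()
        bounds = []
        k = self.q * (self.q + 1) // 2
        for i in range(self.n_theta):
            if i <= k:
                bounds.append((-15.0, 12.0))  # log-scale variance parameters
            else:
                bounds.append((-3.0, 3.0))    # atanh correlations
        best_x, best_f = th0, fun(th0)
        res = optimize.minimize(fun, th0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
        # simplex polish: recovers when the quasi-Newton step stalled on the
        # feasibility penalty and refines correlation parameters
        res2 = optimize.minimize(
            fun, best_x, method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-7, "fatol": 1e-9},
        )
        if np.isfinite(res2.fun) and res2.fun < best_f:
            best_x, best_f = res2.x, res2.fun
        if best_f >= self._PENALTY:
            raise ConvergenceError("likelihood optimization failed")
        return np.asarray(best_x), True

    # -- post-fit quantities ----------------------------------------------

    def gls(self, theta):
        XtVX, XtVy, ytVy, _ = self._accumulate(theta)
        C = np.linalg.inv(XtVX)
        beta = C @ XtVy
        return beta, C

    def cov_diag(self, theta) -> np.ndarray:
        XtVX, *_ = self._accumulate(theta)
        return np.diag(np.linalg.inv(XtVX)).copy()

    def blups(self, theta, beta) -> np.ndarray:
        """Best linear unbiased predictors of each officer's random effects."""
        L, sigma2, corr = self.unpack(theta)
        G = L @ L.T
        out = np.zeros((self.n_groups, self.q))
        for gi, (y, X, Z) in enumerate(self.blocks):
            yw, Xw, Zw, _ = self._whiten(y, X, Z, corr)
            r = yw - Xw @ beta
            U = Zw @ L
            M = sigma2 * np.eye(self.q) + U.T @ U
            # G Z' V^-1 r via Woodbury on the whitened block
            Zr = Zw.T @ r
            UU = U.T @ Zw
            Vinv_r_part = (Zr - UU.T @ np.linalg.solve(M, U.T @ r)) / sigma2
            out[gi] = G @ Vinv_r_part
        return out

    def kenward_roger(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """Small-sample adjusted covariance of the fixed effects and
        Satterthwaite-type df computed from it.

        Implements the Kenward–Roger inflation for covariance structures
        linear in the variance parameters — here vech(G) and the error
        variance with independent level-1 errors — in which the second
        derivative of V vanishes.  Uses the expected REML information for
        the variance-parameter covariance.  Returns ``(cov_beta, df)``.
        """
        if self.spec.error_structure != "independent":
            raise ValueError("adjusted covariance requires independent errors")
        L, sigma2, _ = self.unpack(theta)
        p, q = self.p, self.q
        pairs = [(a, b) for a in range(q) for b in range(a, q)]
        m = len(pairs) + 1  # vech(G) then sigma2
        P = [np.zeros((p, p)) for _ in range(m)]
        Q = [[np.zeros((p, p)) for _ in range(m)] for _ in range(m)]
        S = np.zeros((m, m))
        XtViX = np.zeros((p, p))
        basis = []
        for a, b in pairs:
            E = np.zeros((q, q))
            E[a, b] = E[b, a] = 1.0
            basis.append(E)
        for y, X, Z in self.blocks:
            n = len(y)
            U = Z @ L
            N = U.T @ U
            M = sigma2 * np.eye(q) + N
            cf = cho_factor(M)

            def vinv(A):
                return (A - U @ cho_solve(cf, U.T @ A)) / sigma2

            ViX = vinv(X)
            XtViX += X.T @ ViX
            if q:
                ViZ = vinv(Z)
                ZtViX = Z.T @ ViX          # q x p
                ZtViZ = Z.T @ ViZ          # q x q
                Zt2X = ViZ.T @ ViX         # Z' V^-2 X
                Zt2Z = ViZ.T @ ViZ         # Z' V^-2 Z
            Xt2X = ViX.T @ ViX
            Xt3X = ViX.T @ vinv(ViX)
            MN = cho_solve(cf, N) if q else np.zeros((0, 0))
            tr_mn = np.trace(MN)
            tr_vi2 = (n - 2 * tr_mn + np.trace(MN @ MN)) / sigma2**2
            for i, Ei in enumerate(basis):
                P[i] += ZtViX.T @ Ei @ ZtViX
                S[i, m - 1] += np.trace(Ei @ Zt2Z)
                Q[i][m - 1] += ZtViX.T @ Ei @ Zt2X
                for j, Ej in enumerate(basis):
                    S[i, j] += np.trace(Ei @ ZtViZ @ Ej @ ZtViZ)
                    Q[i][j] += ZtViX.T @ Ei @ ZtViZ @ Ej @ ZtViX
            P[m - 1] += Xt2X
            S[m - 1, m - 1] += tr_vi2
            Q[m - 1][m - 1] += Xt3X
            for i, Ei in enumerate(basis):
                Q[m - 1][i] += Zt2X.T @ Ei @ ZtViX
        S[m - 1, : m - 1] = S[: m - 1, m - 1]
        Phi = np.linalg.inv(XtViX)
        info = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                info[i, j] = 0.5 * (
                    S[i, j]
                    - 2.0 * np.trace(Phi @ Q[i][j])
                    + np.trace(Phi @ P[i] @ Phi @ P[j])
                )
        W = np.linalg.pinv(info)
        mid = np.zeros((p, p))
        for i in range(m):
            for j in range(m):
                mid += W[i, j] * (Q[i][j] - P[i] @ Phi @ P[j])
        cov = Phi + 2.0 * Phi @ mid @ Phi
        cov = 0.5 * (cov + cov.T)
        # guard: the adjustment must not shrink variances
        d = np.diag(cov) - np.diag(Phi)
        if np.any(d < 0):
            cov = cov + np.diag(np.where(d < 0, -d, 0.0))
        # Satterthwaite-type df from the gradient of the unadjusted variance
        df = np.empty(p)
        resid_df = float(max(self.n - p, 1))
        for jj in range(p):
            g = np.array([(Phi @ P[i] @ Phi)[jj, jj] for i in range(m)])
            var_c = float(g @ W @ g)
            df[jj] = (
                2.0 * Phi[jj, jj] ** 2 / var_c if var_c > 0 else resid_df
            )
        return cov, np.clip(df, 1.0, resid_df)

    def satterthwaite_df(self, theta, reml: bool) -> np.ndarray:
        """df_j = 2 C_jj^2 / Var(C_jj), Var via the delta method with the
        inverse observed information of the (RE)ML likelihood."""
        eps = 1e-4
        nt = self.n_theta
        # gradient of each C_jj wrt theta
        grads = np.zeros((self.p, nt))
        base_C = self.cov_diag(theta)
        for t in range(nt):
            d = np.zeros(nt)
            d[t] = eps
            grads[:, t] = (self.cov_diag(theta + d) - self.cov_diag(theta - d)) / (2 * eps)
        # observed information of -loglik
        H = np.zeros((nt, nt))
        for a in range(nt):
            for b in range(a, nt):
                da = np.zeros(nt); da[a] = eps
                db = np.zeros(nt); db[b] = eps
                fpp = -self.loglik(theta + da + db, reml)
                fpm = -self.loglik(theta + da - db, reml)
                fmp = -self.loglik(theta - da + db, reml)
                fmm = -self.loglik(theta - da - db, reml)
                H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
        try:
            A = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return np.full(self.p, float(self.n - self.p))
        df = np.empty(self.p)
        resid_df = float(max(self.n - self.p, 1))
        for j in range(self.p):
            var_c = float(grads[j] @ A @ grads[j])
            if var_c <= 0 or not np.isfinite(var_c) or base_C[j] <= 0:
                df[j] = resid_df
            else:
                df[j] = 2.0 * base_C[j] ** 2 / var_c
        return np.clip(df, 1.0, resid_df)


class _NotPD(Exception):
    pass


def _banded_to_lower(cb: np.ndarray, b: int) -> np.ndarray:
    """cholesky_banded lower output is already the (b+1, n) lower-banded form
    solve_banded((b, 0), ...) expects."""
    return cb


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------


def fit_mmta(
    data: pd.DataFrame | Sequence[pd.DataFrame],
    spec: MmtaSpec,
) -> MmtaFit:
    """Fit the trajectory model to fused window data.

    ``data`` is one long DataFrame (or a list of per-officer tables to be
    concatenated) containing the outcome, predictors, and the officer-id
    grouping column.  Rows with missing values in any used column are
    dropped listwise with a logged count.  Random effects need at least two
    officers.  Non-convergence raises :class:`ConvergenceError`.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.concat(list(data), ignore_index=True)
    y, X, Z, groups, fe_names, (n_dropped,) = _build_design(data, spec)
    n_groups = len(np.unique(groups))
    if spec.random_effects and n_groups < 2:
        raise ValueError("random effects require at least 2 officers")
    eng = _Engine(y, X, Z, groups, spec)
    theta, converged = eng.fit()
    reml = spec.estimation == "reml"
    beta, C = eng.gls(theta)
    method = spec.df_method
    if method == "auto":
        if spec.error_structure == "independent":
            method = "kenward-roger" if eng.q else "residual"
        else:
            method = "satterthwaite"
    if method == "kenward-roger" and spec.error_structure != "independent":
        logger.info(
            "Kenward-Roger adjustment needs independent errors; "
            "using Satterthwaite df"
        )
        method = "satterthwaite"
    if method == "kenward-roger":
        C, df = eng.kenward_roger(theta)
        df_used = "kenward-roger"
    elif method == "satterthwaite":
        df = eng.satterthwaite_df(theta, reml)
        df_used = "satterthwaite"
    else:
        df = np.full(len(beta), float(max(eng.n - eng.p, 1)))
        df_used = "residual"
    se = np.sqrt(np.diag(C))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    L, sigma2, corr = eng.unpack(theta)
    G = L @ L.T
    re_names = list(spec.random_effects)
    ll = eng.loglik(theta, reml)
    k = eng.p + eng.n_theta
    n_eff = eng.n - (eng.p if reml else 0)
    aic = -2 * ll + 2 * k
    bic = -2 * ll + k * np.log(n_eff)
    error_params: dict = {}
    if spec.error_structure == "ar1":
        error_params["rho"] = float(corr[0])
    elif spec.error_structure == "toeplitz":
        error_params["band_corr"] = [float(c) for c in corr]
    blup_arr = eng.blups(theta, beta) if eng.q else None
    blups = (
        pd.DataFrame(blup_arr, index=eng.group_ids, columns=re_names)
        if blup_arr is not None
        else None
    )
    idx = pd.Index(fe_names)
    return MmtaFit(
        spec=spec,
        fe_names=fe_names,
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tstat=pd.Series(tstat, index=idx),
        df=pd.Series(df, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov_beta=pd.DataFrame(C, index=idx, columns=idx),
        G=pd.DataFrame(G, index=re_names, columns=re_names),
        sigma2=sigma2,
        error_params=error_params,
        loglik=float(ll),
        aic=float(aic),
        bic=float(bic),
        n_obs=eng.n,
        n_groups=eng.n_groups,
        n_params=k,
        converged=converged,
        df_method_used=df_used,
        blups=blups,
        n_dropped=n_dropped,
        theta=theta,
    )


def compare_models(fits: Sequence[MmtaFit], names: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank candidate models by information criteria.

    All fits must use ML estimation on the same data (REML likelihoods are
    not comparable across mean structures).  Pairs with nested parameter
    counts additionally get a likelihood-ratio test.
    """
    fits = list(fits)
    if any(f.spec.estimation != "ml" for f in fits):
        raise ValueError("model comparison requires ML fits (REML rejected)")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError("model comparison requires fits on the same data")
    names = list(names) if names is not None else [
        f"model_{i}" for i in range(len(fits))
    ]
    rows = []
    for name, f in zip(names, fits):
        rows.append(
            {"model": name, "k": f.n_params, "loglik": f.loglik,
             "aic": f.aic, "bic": f.bic}
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["aic"].rank(method="min").astype(int)
    out = out.sort_values(["rank", "model"]).reset_index(drop=True)
    # likelihood-ratio statistics for nested-by-parameter-count pairs
    lrt = []
    for i, fi in enumerate(fits):
        for j, fj in enumerate(fits):
            if fi.n_params < fj.n_params:
                stat = 2.0 * (fj.loglik - fi.loglik)
                ddf = fj.n_params - fi.n_params
                lrt.append(
                    {"reduced": names[i], "full": names[j],
                     "lr_stat": max(stat, 0.0), "df": ddf,
                     "p": float(stats.chi2.sf(max(stat, 0.0), ddf))}
                )
    out.attrs["lrt"] = pd.DataFrame(lrt)
    return out


def phase_contrast(
    data: pd.DataFrame,
    labels: Sequence,
    outcome: str = "avg_eda_level",
    group_col: str = "officer_id",
    reference: str | None = None,
    error_structure: str = "independent",
) -> dict:
    """Descriptive per-class statistics and a model-based class contrast.

    ``labels`` classifies each window (None/NaN = excluded).  The contrast
    comes from a mixed model with the class as a fixed effect and a random
    intercept per officer (plain generalized least squares when only one
    officer is present).  Coefficients are differences from ``reference``
    (default: first class in sorted order).
    """
    labels = pd.Series(list(labels), index=data.index, dtype=object)
    keep = labels.notna() & data[outcome].notna()
    d = data.loc[keep].copy()
    labs = labels.loc[keep].astype(str)
    classes = sorted(labs.unique())
    if len(classes) < 2:
        raise ValueError("phase contrast needs at least 2 classes")
    counts = labs.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 windows")
    if reference is None:
        reference = classes[0]
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} not present")
    others = [c for c in classes if c != reference]

    class_stats = (
        d.assign(_cls=labs.values)
        .groupby("_cls")[outcome]
        .agg(n="count", mean="mean", sd="std")
    )

    if group_col not in d.columns:
        d[group_col] = "officer-1"
    for c in others:
        d[f"class_{c}"] = (labs == c).astype(float).values
    multi_officer = d[group_col].nunique() >= 2
    spec = MmtaSpec(
        outcome=outcome,
        fixed_effects=tuple(f"class_{c}" for c in others),
        random_effects=("intercept",) if multi_officer else (),
        error_structure=error_structure,
        estimation="reml",
        group_col=group_col,
    )
    fit = fit_mmta(d, spec)
    contrasts = {
        c: {
            "estimate": float(fit.beta[f"class_{c}"]),
            "se": float(fit.se[f"class_{c}"]),
            "t": float(fit.tstat[f"class_{c}"]),
            "df": float(fit.df[f"class_{c}"]),
            "p": float(fit.pvalues[f"class_{c}"]),
        }
        for c in others
    }
    return {
        "class_stats": class_stats,
        "reference": reference,
        "contrasts": contrasts,
        "fit": fit,
    }


# ---------------------------------------------------------------------------
# Simulation harness
# ---------------------------------------------------------------------------


def simulate_trajectories(
    n_officers: int,
    n_windows: int,
    beta: Sequence[float] = (0.3, 0.0, 0.6, 0.0),
    sigma: float = 0.3,
    var_u0: float = 0.01,
    var_u1: float = 0.0,
    rho: float = 0.0,
    window_s: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate windowed outcomes directly from the trajectory model.

    ``beta`` = (intercept, time, intervention, intervention×time); time is
    hours from shift start, and the intervention phase is the second half of
    each shift.  Errors are iid or AR(1) with lag-1 correlation ``rho``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b0, b1, b2, b3 = beta
    rows = []
    for i in range(n_officers):
        t = np.arange(n_windows) * window_s / 3600.0
        intx = (np.arange(n_windows) >= n_windows // 2).astype(float)
        u0 = rng.normal(0.0, np.sqrt(var_u0)) if var_u0 > 0 else 0.0
        u1 = rng.normal(0.0, np.sqrt(var_u1)) if var_u1 > 0 else 0.0
        e = rng.normal(0.0, sigma, size=n_windows)
        if rho:
            for k in range(1, n_windows):
                e[k] = rho * e[k - 1] + np.sqrt(1 - rho**2) * e[k]
        y = (b0 + u0) + (b1 + u1) * t + b2 * intx + b3 * intx * t + e
        rows.append(
            pd.DataFrame(
                {"officer_id": f"officer-{i + 1}", "time": t,
                 "intervention": intx, "y": y}
            )
        )
    return pd.concat(rows, ignore_index=True)


def recovery_study(
    n_replicates: int = 100,
    n_officers: int = 3,
    n_windows: int = 2160,
    beta: Sequence[float] = (0.3, 0.0, 0.6, 0.0),
    sigma: float = 0.3,
    var_u0: float = 0.01,
    var_u1: float = 0.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo fixed-effect recovery: per-coefficient CI coverage and bias.

    Returns a DataFrame indexed by coefficient with columns ``truth``,
    ``mean_est``, ``bias``, ``rel_bias`` (NaN where truth is 0) and
    ``coverage`` of the (1−alpha) Satterthwaite confidence intervals.
    """
    rng = np.random.default_rng(seed)
    spec = MmtaSpec(
        outcome="y",
        fixed_effects=("time", "intervention", "intervention:time"),
        random_effects=("intercept",) if var_u1 == 0 else ("intercept", "time"),
        estimation="reml",
    )
    truth = np.asarray(beta, dtype=float)
    est = np.zeros((n_replicates, 4))
    covered = np.zeros((n_replicates, 4), dtype=bool)
    for r in range(n_replicates):
        data = simulate_trajectories(
            n_officers, n_windows, beta, sigma, var_u0, var_u1, seed=rng
        )
        fit = fit_mmta(data, spec)
        est[r] = fit.beta.to_numpy()
        ci = fit.conf_int(alpha)
        covered[r] = (ci["lower"].to_numpy() <= truth) & (
            truth <= ci["upper"].to_numpy()
        )
    mean_est = est.mean(axis=0)
    bias = mean_est - truth
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(truth != 0, bias / truth, np.nan)
    return pd.DataFrame(
        {
            "truth": truth,
            "mean_est": mean_est,
            "bias": bias,
            "rel_bias": rel,
            "coverage": covered.mean(axis=0),
        },
        index=["intercept", "time", "intervention", "intervention:time"],
    )
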