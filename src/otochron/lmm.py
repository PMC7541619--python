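"""Gaussian linear mixed models with crossed random intercepts and slopes.

This is the numerical core of the package: a REML/ML fitter for models of the
form

    y = X beta + sum_g Z_g b_g + eps,      b_g ~ N(0, I_{L_g} (x) Sigma_g),
    eps ~ N(0, sigma^2 I),

with several *crossed* grouping factors g (fish, year, cohort), each carrying
a random intercept and/or random slopes with an optional intercept-slope
correlation.  Estimation profiles out beta and sigma^2 and minimises the
profiled (restricted) deviance over the relative covariance factors
Lambda_g = chol(Sigma_g / sigma^2), exactly as in the standard mixed-model
normal-equation formulation:

    -2 log L_ML   = log|M| + n (1 + log(2 pi r^2 / n))
    -2 log L_REML = log|M| + log|S| + (n-p)(1 + log(2 pi r^2 / (n-p)))

where M = Lambda' Z'Z Lambda + I, S = X'X - C' M^-1 C with C = Lambda' Z'X,
and r^2 is the penalised residual sum of squares.  The largest grouping
factor's block of M is block-diagonal (one small block per level), so it is
eliminated analytically by a Schur complement; only the remaining factors
(typically a few hundred columns) require a dense factorisation.  This keeps
one objective evaluation at a few milliseconds even with thousands of fish.

A dense brute-force likelihood (`loglik_oracle`) provides an independent
check of the objective on small problems.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .containers import GrowthTable
from .errors import (
    ComparisonError,
    ParameterError,
    SpecificationError,
)

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "FitResult",
    "fit",
    "loglik_oracle",
    "aicc",
    "icc",
    "r2_components",
    "r2_nakagawa",
    "blup_extract",
    "compare",
    "standardized_refit",
    "vif",
]

_SINGULAR_TOL = 1e-4


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomTerm:
    """One random-effect block: a grouping factor with an intercept and/or
    slopes.  ``correlated=False`` makes the block's covariance diagonal.

    Several terms may name the same grouping factor; they are merged into one
    per-level block-diagonal covariance (e.g. a correlated (intercept, age)
    pair plus an independent temperature slope, all on fish).
    """

    group: str
    intercept: bool = True
    slopes: tuple[str, ...] = ()
    correlated: bool = True

    def __post_init__(self):
        object.__setattr__(self, "slopes", tuple(self.slopes))
        if not self.intercept and not self.slopes:
            raise SpecificationError(f"random term for {self.group!r} is empty")

    @property
    def effects(self) -> tuple[str, ...]:
        return (("1",) if self.intercept else ()) + self.slopes

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "intercept": self.intercept,
            "slopes": list(self.slopes),
            "correlated": self.correlated,
        }


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description: response, fixed terms (main effects and
    ``a:b`` interactions), random terms, and the estimation criterion."""

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    method: str = "REML"

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if self.method not in ("ML", "REML"):
            raise SpecificationError(f"method must be ML or REML, got {self.method!r}")

    def with_method(self, method: str) -> "ModelSpec":
        return replace(self, method=method)

    def with_fixed(self, fixed: Sequence[str]) -> "ModelSpec":
        return replace(self, fixed=tuple(fixed))

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fixed": list(self.fixed),
            "random": [r.to_dict() for r in self.random],
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            response=d["response"],
            fixed=tuple(d.get("fixed", ())),
            random=tuple(RandomTerm(**r) for r in d.get("random", ())),
            method=d.get("method", "REML"),
        )


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


def _column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "1":
        return np.ones(len(df))
    if name not in df.columns:
        raise SpecificationError(f"column {name!r} not in frame")
    col = df[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(pd.unique(col.dropna()))
    if len(levels) != 2:
        raise SpecificationError(
            f"categorical column {name!r} must have exactly two levels, "
            f"found {len(levels)}"
        )
    return (col == levels[1]).to_numpy(dtype=float)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    out = np.ones(len(df))
    for part in term.split(":"):
        out = out * _column(df, part.strip())
    return out


def build_fixed_design(df: pd.DataFrame, terms: Sequence[str]):
    """Intercept plus one column per term (``a:b`` terms are products)."""
    names = ["(Intercept)"] + list(terms)
    X = np.column_stack([np.ones(len(df))] + [_term_column(df, t) for t in terms])
    return X, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns by pivoted QR
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[r:]]
        raise SpecificationError(f"fixed design is rank deficient; collinear terms: {bad}")


class _Group:
    """All random effects sharing one grouping factor, as block structure."""

    def __init__(self, name: str, codes: np.ndarray, levels: np.ndarray,
                 blocks: list[tuple[tuple[str, ...], bool]], cols: list[np.ndarray]):
        self.name = name
        self.codes = codes
        self.levels = levels
        self.blocks = blocks          # [(effect names, correlated)]
        self.cols = cols              # column arrays, concatenated over blocks
        self.effects = tuple(e for b, _ in blocks for e in b)
        self.d = len(self.effects)
        self.L = len(levels)

    @property
    def n_theta(self) -> int:
        return sum(len(b) * (len(b) + 1) // 2 if corr else len(b)
                   for b, corr in self.blocks)

    def theta_template(self):
        """Per-theta (row, col) position in the d x d lambda block and a
        diagonal mask (diagonal entries are bounded below by zero)."""
        rows, cols, diag = [], [], []
        off = 0
        for b, corr in self.blocks:
            s = len(b)
            if corr:
                r, c = np.tril_indices(s)
                rows += list(off + r)
                cols += list(off + c)
                diag += [ri == ci for ri, ci in zip(r, c)]
            else:
                rows += list(off + np.arange(s))
                cols += list(off + np.arange(s))
                diag += [True] * s
            off += s
        return np.array(rows), np.array(cols), np.array(diag, dtype=bool)


def _build_groups(df: pd.DataFrame, terms: Sequence[RandomTerm]) -> list[_Group]:
    by_group: dict[str, list[RandomTerm]] = {}
    for t in terms:
        by_group.setdefault(t.group, []).append(t)
    groups = []
    for gname, ts in by_group.items():
        if gname not in df.columns:
            raise SpecificationError(f"grouping column {gname!r} not in frame")
        codes, levels = pd.factorize(df[gname], sort=True)
        blocks, cols = [], []
        seen: set[str] = set()
        for t in ts:
            effs = t.effects
            dup = seen & set(effs)
            if dup:
                raise SpecificationError(
                    f"effect(s) {sorted(dup)} listed twice for group {gname!r}")
            seen |= set(effs)
            blocks.append((effs, t.correlated))
            cols += [_column(df, e) for e in effs]
        groups.append(_Group(gname, codes.astype(np.int64), np.asarray(levels), blocks, cols))
    # eliminate the largest factor analytically: put it first
    groups.sort(key=lambda g: g.L * g.d, reverse=True)
    return groups


# --------------------------------------------------------------------------
# profiled deviance workspace
# --------------------------------------------------------------------------


def _group_Z(g: _Group, n: int) -> sp.csc_matrix:
    rows = np.tile(np.arange(n), g.d)
    cols = np.concatenate([g.codes * g.d + j for j in range(g.d)])
    data = np.concatenate(g.cols)
    return sp.csc_matrix((data, (rows, cols)), shape=(n, g.L * g.d))


@dataclass
class _Solution:
    """Everything computed at one theta (used for SEs, BLUPs, refits)."""

    theta: np.ndarray
    deviance: float
    reml: bool
    beta: np.ndarray
    r2: float
    sigma2: float
    uF: np.ndarray | None
    uR: np.ndarray | None
    lam_blocks: list[np.ndarray]
    Dinv: np.ndarray | None          # (L_F, d_F, d_F)
    DinvB: sp.spmatrix | None
    schur_inv: np.ndarray | None     # (qR, qR)
    cov_beta_unscaled: np.ndarray | None  # S^-1
    logdetM: float


class _CrossedLMM:
    """Precomputed sufficient statistics + fast profiled deviance."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: list[_Group]):
        self.y = y
        self.n = len(y)
        self.groups = groups
        self.gF = groups[0]
        self.rest = groups[1:]
        n = self.n
        self.ZF = _group_Z(self.gF, n)
        self.qF = self.ZF.shape[1]
        self.dF, self.LF = self.gF.d, self.gF.L
        AFF = (self.ZF.T @ self.ZF).tocoo()
        self.AFF = np.zeros((self.LF, self.dF, self.dF))
        self.AFF[AFF.row // self.dF, AFF.row % self.dF, AFF.col % self.dF] = AFF.data
        if self.rest:
            self.ZR = sp.hstack([_group_Z(g, n) for g in self.rest]).tocsc()
            self.qR = self.ZR.shape[1]
            self.AFR = (self.ZF.T @ self.ZR).tocsr()
            self.ARR = (self.ZR.T @ self.ZR).tocsr()
            rows_R, cols_R = [], []
            off = 0
            for g in self.rest:
                r, c = np.meshgrid(np.arange(g.d), np.arange(g.d), indexing="ij")
                for _ in range(g.L):
                    rows_R.append(off + r.ravel())
                    cols_R.append(off + c.ravel())
                    off += g.d
            self._rows_R = np.concatenate(rows_R)
            self._cols_R = np.concatenate(cols_R)
        else:
            self.ZR = None
            self.qR = 0
        self._bd_rows = np.repeat(np.arange(self.qF), self.dF)
        self._bd_cols = (
            np.arange(self.LF)[:, None, None] * self.dF
            + np.arange(self.dF)[None, None, :]
        ).repeat(self.dF, axis=1).reshape(-1)
        self.n_theta_per_group = [g.n_theta for g in groups]
        self._templates = [g.theta_template() for g in groups]
        self.n_theta = sum(self.n_theta_per_group)
        self.set_X(X)

    # -- fixed part can be swapped cheaply (window scans) --
    def set_X(self, X: np.ndarray) -> None:
        self.X = X
        self.p = X.shape[1]
        yX = np.column_stack([self.y, X])
        self.XtX = X.T @ X
        self.Xty = X.T @ self.y
        self.GF = self.ZF.T @ yX
        if self.rest:
            self.GR = self.ZR.T @ yX

    def lam_blocks(self, theta: np.ndarray) -> list[np.ndarray]:
        out = []
        i = 0
        for g, m, (rows, cols, _) in zip(self.groups, self.n_theta_per_group,
                                         self._templates):
            lam = np.zeros((g.d, g.d))
            lam[rows, cols] = theta[i:i + m]
            i += m
            out.append(lam)
        return out

    def theta_bounds(self) -> list[tuple]:
        bounds = []
        for _, _, diag in self._templates:
            bounds += [(0.0, None) if d else (None, None) for d in diag]
        return bounds

    def theta_start(self) -> np.ndarray:
        th = np.zeros(self.n_theta)
        i = 0
        for _, _, diag in self._templates:
            th[i:i + len(diag)][diag] = 1.0
            i += len(diag)
        return th

    def _bdiagF(self, mats: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix(
            (np.ascontiguousarray(mats).reshape(-1), (self._bd_rows, self._bd_cols)),
            shape=(self.qF, self.qF))

    def _lamR(self, lams: list[np.ndarray]) -> sp.csr_matrix:
        data = np.concatenate(
            [np.broadcast_to(lam, (g.L, g.d, g.d)).reshape(-1)
             for g, lam in zip(self.rest, lams)])
        return sp.csr_matrix((data, (self._rows_R, self._cols_R)),
                             shape=(self.qR, self.qR))

    def solve(self, theta: np.ndarray, reml: bool, full: bool = False,
              return_beta: bool = False):
        """Profiled deviance at theta; with ``full`` also everything needed
        for standard errors and BLUPs."""
        n, p = self.n, self.p
        lams = self.lam_blocks(theta)
        lamF = lams[0]
        D = lamF.T[None] @ self.AFF @ lamF[None] + np.eye(self.dF)[None]
        cD = np.linalg.cholesky(D)  # PD by construction
        logdetD = 2.0 * np.log(np.diagonal(cD, axis1=1, axis2=2)).sum()
        Dinv = np.linalg.inv(D)
        Dinv_sp = self._bdiagF(Dinv)
        LamF = self._bdiagF(np.broadcast_to(lamF, (self.LF, self.dF, self.dF)))
        c1 = LamF.T @ self.GF
        if self.rest:
            LamR = self._lamR(lams[1:])
            B = (LamF.T @ self.AFR) @ LamR
            E = (LamR.T @ self.ARR @ LamR).toarray() + np.eye(self.qR)
            DinvB = Dinv_sp @ B
            schur = E - (B.T @ DinvB).toarray()
            cS = cho_factor(schur, lower=True)
            logdetS = 2.0 * np.log(np.diag(cS[0])).sum()
            c2 = LamR.T @ self.GR
            x2 = cho_solve(cS, c2 - DinvB.T @ c1)
            x1 = Dinv_sp @ (c1 - B @ x2)
            CtMC = c1.T @ x1 + c2.T @ x2
        else:
            LamR = B = DinvB = None
            cS = None
            logdetS = 0.0
            x2 = None
            x1 = Dinv_sp @ c1
            CtMC = c1.T @ x1
        logdetM = logdetD + logdetS
        S_b = self.XtX - CtMC[1:, 1:]
        rhs_b = self.Xty - CtMC[1:, 0]
        cSb = cho_factor(S_b, lower=True)
        beta = cho_solve(cSb, rhs_b)
        uF = x1[:, 0] - x1[:, 1:] @ beta
        fitted = self.X @ beta + self.ZF @ (LamF @ uF)
        pen = uF @ uF
        uR = None
        if self.rest:
            uR = x2[:, 0] - x2[:, 1:] @ beta
            fitted = fitted + self.ZR @ (LamR @ uR)
            pen += uR @ uR
        resid = self.y - fitted
        r2 = float(resid @ resid + pen)
        r2 = max(r2, 1e-300)
        if reml:
            logdetSb = 2.0 * np.log(np.diag(cSb[0])).sum()
            dev = logdetM + logdetSb + (n - p) * (1 + np.log(2 * np.pi * r2 / (n - p)))
            sigma2 = r2 / (n - p)
        else:
            dev = logdetM + n * (1 + np.log(2 * np.pi * r2 / n))
            sigma2 = r2 / n
        if not full:
            return (dev, beta) if return_beta else dev
        schur_inv = None
        if self.rest:
            schur_inv = cho_solve(cS, np.eye(self.qR))
        cov_beta = cho_solve(cSb, np.eye(p))
        return _Solution(
            theta=np.asarray(theta, dtype=float).copy(), deviance=dev, reml=reml,
            beta=beta, r2=r2, sigma2=sigma2, uF=uF, uR=uR, lam_blocks=lams,
            Dinv=Dinv, DinvB=DinvB, schur_inv=schur_inv,
            cov_beta_unscaled=cov_beta, logdetM=logdetM)

    def deviance(self, theta: np.ndarray, reml: bool) -> float:
        try:
            return self.solve(theta, reml)
        except np.linalg.LinAlgError:
            return 1e12


def _optimize(work: _CrossedLMM, reml: bool, theta0: np.ndarray | None,
              max_restarts: int = 2, seed: int = 0,
              ftol: float = 1e-11, gtol: float = 1e-6, maxiter: int = 500):
    """Bounded quasi-Newton minimisation of the profiled deviance.

    Cold starts run from two standard points (relative factors at 0.3 and at
    1.0) and keep the better optimum -- the profiled deviance can have a
    shallow ridge near correlation boundaries that traps a single start.
    Warm starts (``theta0``) run once from the supplied point.  Jittered,
    seeded restarts are used only if no run converged."""
    bounds = work.theta_bounds()
    fun = lambda th: work.deviance(th, reml)
    opts = dict(ftol=ftol, gtol=gtol, maxiter=maxiter)
    if theta0 is None:
        starts = [work.theta_start() * 0.3, work.theta_start()]
    else:
        starts = [np.asarray(theta0, dtype=float)]
    best = None
    for s in starts:
        res = minimize(fun, s, method="L-BFGS-B", bounds=bounds, options=opts)
        if best is None or res.fun < best.fun:
            best = res
    rng = np.random.default_rng(seed)
    tries = 0
    base = starts[0]
    while (not best.success or not np.isfinite(best.fun)) and tries < max_restarts:
        jitter = base * rng.uniform(0.5, 1.5, size=base.shape) + rng.normal(0, 0.1, base.shape)
        jitter = np.array([max(j, 1e-3) if b[0] == 0.0 else j
                           for j, b in zip(jitter, bounds)])
        res = minimize(fun, jitter, method="L-BFGS-B", bounds=bounds, options=opts)
        if res.fun < best.fun or (res.success and not best.success):
            best = res
        tries += 1
    return best


# --------------------------------------------------------------------------
# fit result
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, variance components, criteria, and handles for BLUPs."""

    spec: ModelSpec
    method: str
    beta: pd.Series
    se: pd.Series
    ci: pd.DataFrame
    sigma2: float
    varcomps: dict
    theta: np.ndarray | None
    loglik: float
    n_obs: int
    n_fixed: int
    n_params: int
    aicc: float
    converged: bool
    singular: bool
    centering: dict = field(default_factory=dict)
    fixed_theta: bool = False
    _work: "_CrossedLMM | None" = field(default=None, repr=False)
    _sol: "_Solution | None" = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def params(self) -> dict:
        """Parameters in the form `loglik_oracle` consumes."""
        return {
            "sigma2": self.sigma2,
            "Sigma": {g: v["cov"] for g, v in self.varcomps.items()},
            "beta": self.beta.to_numpy(),
        }

    def blups(self, group: str, effect: str = "1") -> pd.DataFrame:
        return blup_extract(self, group, effect)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "method": self.method,
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "ci": {k: [float(self.ci.loc[k, "lower"]), float(self.ci.loc[k, "upper"])]
                   for k in self.ci.index},
            "sigma2": float(self.sigma2),
            "varcomps": {
                g: {
                    "effects": list(v["effects"]),
                    "tau": [float(x) for x in v["tau"]],
                    "corr": np.asarray(v["corr"]).tolist(),
                }
                for g, v in self.varcomps.items()
            },
            "loglik": float(self.loglik),
            "aicc": float(self.aicc),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
            "centering": {k: float(v) for k, v in self.centering.items()},
        }


def _frame_df(frame) -> tuple[pd.DataFrame, dict]:
    if isinstance(frame, GrowthTable):
        return frame.data, dict(frame.centering)
    return frame, {}


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike criterion
    ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    k, n = n_params, n_obs
    if n <= k + 1:
        raise ParameterError(f"AICc undefined for n_obs={n} <= n_params+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit(spec: ModelSpec, frame, *, theta0: np.ndarray | None = None,
        fix_theta: np.ndarray | None = None, restart_seed: int = 0,
        max_restarts: int = 2) -> FitResult:
    """Fit a crossed random-effects LMM.

    ``theta0`` warm-starts the optimizer; ``fix_theta`` skips optimisation and
    profiles only beta and sigma^2 at the given relative covariance factors
    (used by the climate window scan for fast screening).
    """
    df, centering = _frame_df(frame)
    if len(df) == 0:
        raise SpecificationError("empty frame")
    X, names = build_fixed_design(df, spec.fixed)
    _check_rank(X, names)
    y = df[spec.response].to_numpy(dtype=float)
    reml = spec.method == "REML"
    n, p = len(y), X.shape[1]

    if not spec.random:
        return _fit_ols(spec, X, names, y, reml, centering)

    groups = _build_groups(df, spec.random)
    work = _CrossedLMM(y, X, groups)
    if fix_theta is not None:
        sol = work.solve(np.asarray(fix_theta, float), reml, full=True)
        converged = True
        fixed_theta = True
    else:
        res = _optimize(work, reml, theta0, max_restarts=max_restarts,
                        seed=restart_seed)
        sol = work.solve(res.x, reml, full=True)
        converged = bool(res.success and np.isfinite(res.fun))
        fixed_theta = False

    sigma2 = sol.sigma2
    varcomps = {}
    singular = False
    for g, lam in zip(groups, sol.lam_blocks):
        cov = sigma2 * lam @ lam.T
        tau = np.diag(cov).copy()
        sd = np.sqrt(np.maximum(tau, 1e-300))
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        if np.any(np.sqrt(np.maximum(tau, 0.0) / sigma2) < _SINGULAR_TOL):
            singular = True
        varcomps[g.name] = {"effects": g.effects, "cov": cov, "tau": tau, "corr": corr}

    beta = pd.Series(sol.beta, index=names)
    cov_beta = sigma2 * sol.cov_beta_unscaled
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    z = 1.959963984540054
    ci = pd.DataFrame({"lower": beta - z * se, "upper": beta + z * se})
    loglik = -0.5 * sol.deviance
    k = p + work.n_theta + 1
    return FitResult(
        spec=spec, method=spec.method, beta=beta, se=se, ci=ci, sigma2=sigma2,
        varcomps=varcomps, theta=sol.theta, loglik=loglik, n_obs=n, n_fixed=p,
        n_params=k, aicc=aicc(loglik, k, n), converged=converged,
        singular=singular, centering=centering, fixed_theta=fixed_theta,
        _work=work, _sol=sol, _X=X)


def _fit_ols(spec, X, names, y, reml, centering) -> FitResult:
    n, p = X.shape
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    dfree = n - p if reml else n
    sigma2 = rss / dfree
    if reml:
        sign, logdetXtX = np.linalg.slogdet(X.T @ X)
        dev = logdetXtX + (n - p) * (1 + np.log(2 * np.pi * rss / (n - p)))
    else:
        dev = n * (1 + np.log(2 * np.pi * rss / n))
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    beta = pd.Series(beta_hat, index=names)
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    z = 1.959963984540054
    ci = pd.DataFrame({"lower": beta - z * se, "upper": beta + z * se})
    loglik = -0.5 * dev
    k = p + 1
    return FitResult(
        spec=spec, method=spec.method, beta=beta, se=se, ci=ci, sigma2=sigma2,
        varcomps={}, theta=None, loglik=loglik, n_obs=n, n_fixed=p, n_params=k,
        aicc=aicc(loglik, k, n), converged=True, singular=False,
        centering=centering, _X=X)


# --------------------------------------------------------------------------
# dense brute-force likelihood oracle
# --------------------------------------------------------------------------


def loglik_oracle(spec: ModelSpec, frame, params: Mapping, *,
                  max_n: int = 4000) -> float:
    """Exact Gaussian (restricted) log-likelihood by dense linear algebra.

    ``params`` carries ``sigma2``, ``Sigma`` (mapping group name to its d x d
    response-scale covariance) and, for ML, optionally ``beta`` (otherwise the
    GLS solution at the implied V is profiled in).  Entirely independent of
    the sparse fitting path; only feasible for small n.
    """
    df, _ = _frame_df(frame)
    n = len(df)
    if n > max_n:
        raise ParameterError(f"oracle limited to n <= {max_n}, got {n}")
    X, names = build_fixed_design(df, spec.fixed)
    y = df[spec.response].to_numpy(dtype=float)
    p = X.shape[1]
    sigma2 = float(params["sigma2"])
    if sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    V = sigma2 * np.eye(n)
    sig = params.get("Sigma", {})
    if spec.random:
        groups = _build_groups(df, spec.random)
        for g in groups:
            if g.name not in sig:
                raise ParameterError(f"missing covariance for group {g.name!r}")
            S = np.atleast_2d(np.asarray(sig[g.name], dtype=float))
            if S.shape != (g.d, g.d):
                raise ParameterError(
                    f"covariance for {g.name!r} has shape {S.shape}, expected {(g.d, g.d)}")
            Z = _group_Z(g, n).toarray()
            V += Z @ np.kron(np.eye(g.L), S) @ Z.T
    try:
        cV = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as e:
        raise ParameterError("marginal covariance V is not positive definite") from e
    logdetV = 2.0 * np.log(np.diag(cV[0])).sum()
    Vi_y = cho_solve(cV, y)
    if p > 0:
        Vi_X = cho_solve(cV, X)
        XtViX = X.T @ Vi_X
    if spec.method == "REML":
        if p == 0:
            raise ParameterError("REML oracle needs at least one fixed effect")
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = r @ cho_solve(cV, r)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetXtViX + quad)
    beta = params.get("beta")
    if beta is None:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y) if p else np.zeros(0)
    else:
        beta = np.asarray(beta, dtype=float)
    r = y - (X @ beta if p else 0.0)
    quad = r @ cho_solve(cV, r)
    return -0.5 * (n * np.log(2 * np.pi) + logdetV + quad)


# --------------------------------------------------------------------------
# summaries derived from fits
# --------------------------------------------------------------------------


def icc(fit_result: FitResult, group: str) -> float:
    """Intraclass correlation of a random-intercept factor in an
    intercept-only model: tau00_g / (sum_g' tau00_g' + sigma^2)."""
    if group not in fit_result.varcomps:
        raise SpecificationError(f"group {group!r} not in fit")
    tot = fit_result.sigma2
    num = None
    for g, v in fit_result.varcomps.items():
        if "1" not in v["effects"]:
            if g == group:
                raise SpecificationError(f"group {group!r} has no random intercept")
            continue
        t00 = float(v["tau"][v["effects"].index("1")])
        tot += t00
        if g == group:
            num = t00
    if num is None:
        raise SpecificationError(f"group {group!r} has no random intercept")
    return num / tot


def r2_components(var_fixed: float, var_random: float,
                  sigma2: float) -> tuple[float, float]:
    """(marginal, conditional) R^2 from variance components."""
    denom = var_fixed + var_random + sigma2
    return var_fixed / denom, (var_fixed + var_random) / denom


def r2_nakagawa(fit_result: FitResult) -> tuple[float, float]:
    """Marginal and conditional R^2: fixed-effect variance share and
    fixed-plus-random share of total (including residual) variance.

    For slope-carrying factors the random-effect variance is the
    observation-averaged quadratic form z' Sigma z.
    """
    if not fit_result.converged:
        raise SpecificationError("R^2 requires a converged fit")
    X = fit_result._X
    var_fixed = float(np.var(X @ fit_result.beta.to_numpy()))
    var_random = 0.0
    if fit_result._work is not None:
        for g, v in zip(fit_result._work.groups, fit_result.varcomps.values()):
            cols = np.column_stack(g.cols)
            var_random += float(np.mean(np.einsum("ij,jk,ik->i", cols, v["cov"], cols)))
    return r2_components(var_fixed, var_random, fit_result.sigma2)


def blup_extract(fit_result: FitResult, group: str, effect: str = "1") -> pd.DataFrame:
    """Conditional modes of the random effects (shrunk towards zero) with
    conditional standard errors, per level of ``group``."""
    if fit_result._work is None or fit_result._sol is None:
        raise SpecificationError("fit has no random-effect solution")
    work, sol = fit_result._work, fit_result._sol
    gi = next((i for i, g in enumerate(work.groups) if g.name == group), None)
    if gi is None:
        raise SpecificationError(f"group {group!r} not in fit")
    g = work.groups[gi]
    if effect not in g.effects:
        raise SpecificationError(f"effect {effect!r} not in group {group!r}")
    ei = g.effects.index(effect)
    sigma2 = fit_result.sigma2
    lam = sol.lam_blocks[gi]
    if gi == 0:
        u = sol.uF.reshape(g.L, g.d)
        b = u @ lam.T
        # Var(u|y) diag blocks: Dinv_i + T_i Schur^-1 T_i'
        V = sol.Dinv.copy()
        if work.rest:
            T = np.asarray(sol.DinvB.todense()).reshape(g.L, g.d, work.qR)
            V = V + T @ sol.schur_inv @ np.transpose(T, (0, 2, 1))
        var_b = sigma2 * np.einsum("ab,ibc,dc->iad", lam, V, lam)
        se = np.sqrt(np.maximum(np.diagonal(var_b, axis1=1, axis2=2), 0.0))
        return pd.DataFrame({"level": g.levels, "blup": b[:, ei], "se": se[:, ei]})
    # rest factors live inside the Schur block
    off = 0
    for gg in work.rest:
        if gg.name == group:
            break
        off += gg.L * gg.d
    u = sol.uR[off:off + g.L * g.d].reshape(g.L, g.d)
    b = u @ lam.T
    Sinv = sol.schur_inv
    blocks = np.stack([
        Sinv[off + lv * g.d: off + (lv + 1) * g.d,
             off + lv * g.d: off + (lv + 1) * g.d]
        for lv in range(g.L)])
    var_b = sigma2 * np.einsum("ab,ibc,dc->iad", lam, blocks, lam)
    se = np.sqrt(np.maximum(np.diagonal(var_b, axis1=1, axis2=2), 0.0))
    return pd.DataFrame({"level": g.levels, "blup": b[:, ei], "se": se[:, ei]})


def compare(fits: Sequence[FitResult], names: Sequence[str] | None = None) -> pd.DataFrame:
    """AICc ranking with the parsimony tie rule: among models within 2 AICc
    units of the best, the one with fewest parameters ranks first."""
    if len(fits) < 2:
        raise ComparisonError("need at least two fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ComparisonError("fits are on different observation sets")
    methods = {f.method for f in fits}
    if len(methods) != 1:
        raise ComparisonError("cannot mix ML and REML fits in one comparison")
    if methods == {"REML"}:
        fixed_sets = {tuple(f.spec.fixed) for f in fits}
        if len(fixed_sets) != 1:
            raise ComparisonError(
                "REML fits with different fixed structures are not comparable")
    names = list(names) if names is not None else [f"model_{i}" for i in range(len(fits))]
    tbl = pd.DataFrame({
        "name": names,
        "aicc": [f.aicc for f in fits],
        "k": [f.n_params for f in fits],
        "loglik": [f.loglik for f in fits],
        "converged": [f.converged for f in fits],
    })
    best = tbl["aicc"].min()
    tbl["delta_aicc"] = tbl["aicc"] - best
    near = tbl["delta_aicc"] <= 2.0
    order = pd.concat([
        tbl[near].sort_values(["k", "aicc"], kind="mergesort"),
        tbl[~near].sort_values("aicc", kind="mergesort"),
    ])
    order["rank"] = np.arange(1, len(order) + 1)
    return order.reset_index(drop=True)


def standardized_refit(spec: ModelSpec, frame) -> FitResult:
    """Refit with z-scored response and continuous predictors so coefficient
    magnitudes are comparable across predictors."""
    df, centering = _frame_df(frame)
    df = df.copy()
    cols = {spec.response}
    for t in spec.fixed:
        cols.update(p.strip() for p in t.split(":"))
    for rt in spec.random:
        cols.update(rt.slopes)
    cols.discard("1")
    for c in cols:
        if c not in df.columns or not pd.api.types.is_numeric_dtype(df[c]):
            continue
        sd = df[c].std(ddof=0)
        if sd > 0:
            df[c] = (df[c] - df[c].mean()) / sd
    out = fit(spec, df)
    out.centering = centering
    return out


def vif(frame, fixed_terms: Sequence[str]) -> pd.Series:
    """Variance inflation factors 1/(1-R^2_j) from auxiliary regressions of
    each term on all the others (plus an intercept)."""
    df, _ = _frame_df(frame)
    terms = [t for t in fixed_terms if t != "1"]
    if len(terms) < 2:
        raise ParameterError("VIF needs at least two terms")
    cols = np.column_stack([_term_column(df, t) for t in terms])
    out = {}
    n = len(df)
    ones = np.ones((n, 1))
    for j, t in enumerate(terms):
        yj = cols[:, j]
        Xj = np.hstack([ones, np.delete(cols, j, axis=1)])
        bj, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        rss = float(np.sum((yj - Xj @ bj) ** 2))
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
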