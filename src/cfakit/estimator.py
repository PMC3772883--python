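"""Maximum-likelihood covariance-structure estimation.

The observed correlation matrix S is analysed as a covariance matrix (the
convention of classical SEM software when given matrix input) by minimizing
the Wishart ML discrepancy

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free parameters of Sigma(theta) = Lambda Phi Lambda' + Theta,
subject to lower bounds on the variance parameters (uniquenesses and
second-order disturbances), with chi^2 = (N - 1) * F_min.  Optimization is
bound-constrained quasi-Newton (L-BFGS-B) with analytic gradients; no
randomness is used, so a fit is a deterministic function of
(spec, sample, start).

The public surface is the scikit-learn style
:class:`ConfirmatoryFactorAnalysis` estimator plus thin functional wrappers
(:func:`fit_model`, :func:`ml_discrepancy`, :func:`implied_matrix`,
:func:`information_matrix`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, eigh
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .corr_data import CorrelationSample
from .model_spec import FactorModelSpec, model_df

__all__ = [
    "FitResult",
    "ConfirmatoryFactorAnalysis",
    "ConvergenceError",
    "fit_model",
    "ml_discrepancy",
    "implied_matrix",
    "information_matrix",
    "sign_normalize",
    "embed_start",
]

_BIG = 1e10
_ACTIVE_TOL = 1e-8
_PHI_CORR_BOUND = 0.995


class ConvergenceError(RuntimeError):
    """Optimization failed to reach the gradient tolerance.

    Carries the best point found in ``result``.
    """

    def __init__(self, message: str, result: "FitResult"):
        super().__init__(message)
        self.result = result


def _principal_axis(S: np.ndarray, m: int, iters: int = 50) -> np.ndarray:
    """Iterated principal-axis loadings: SMC communality start, then repeated
    truncated eigendecomposition of the reduced matrix."""
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(S))
    L = None
    for _ in range(iters):
        reduced = S - np.diag(1.0 - h2)
        w, V = eigh(reduced)
        idx = np.argsort(w)[::-1][:m]
        L = V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
        h2 = np.clip((L**2).sum(axis=1), 0.0, 0.999)
    return L


class ParamLayout:
    """Maps a spec's free parameters onto a flat vector.

    Order: free loadings (row-major over the pattern), structure block
    (oblique correlations in lower-triangle order, or Gamma then Psi for
    second-order), then the p uniquenesses.
    """

    def __init__(self, spec: FactorModelSpec):
        self.spec = spec
        pat = spec.pattern
        self.p, self.m = pat.p, pat.m
        self.free_rows, self.free_cols = np.nonzero(pat.free)
        self.nl = len(self.free_rows)
        kind = spec.structure.kind
        self.kind = kind
        if kind == "oblique":
            idx = np.tril_indices(self.m, -1)
            self.phi_rows, self.phi_cols = idx
            ns = len(self.phi_rows)
        elif kind == "second_order":
            ns = 2 * self.m
        else:
            ns = 0
        self.ns = ns
        self.n_params = self.nl + ns + self.p
        self.struct_sl = slice(self.nl, self.nl + ns)
        self.theta_sl = slice(self.nl + ns, self.n_params)

        names = [
            f"lambda[{pat.row_labels[i]},{pat.col_labels[k]}]"
            for i, k in zip(self.free_rows, self.free_cols)
        ]
        if kind == "oblique":
            names += [
                f"phi[{pat.col_labels[i]},{pat.col_labels[j]}]"
                for i, j in zip(self.phi_rows, self.phi_cols)
            ]
        elif kind == "second_order":
            names += [f"gamma[{f}]" for f in pat.col_labels]
            names += [f"psi[{f}]" for f in pat.col_labels]
        names += [f"theta[{s}]" for s in pat.row_labels]
        self.names: tuple[str, ...] = tuple(names)

        lower = np.full(self.n_params, -np.inf)
        upper = np.full(self.n_params, np.inf)
        if kind == "oblique":
            lower[self.struct_sl] = -_PHI_CORR_BOUND
            upper[self.struct_sl] = _PHI_CORR_BOUND
        elif kind == "second_order":
            lower[self.nl + self.m : self.nl + 2 * self.m] = 0.0  # Psi >= 0
        lower[self.theta_sl] = spec.uniqueness_lower
        self.lower, self.upper = lower, upper

    # -- parameter vector <-> matrices -------------------------------------

    def loadings(self, theta: np.ndarray) -> np.ndarray:
        Lam = self.spec.pattern.fixed.copy()
        Lam[self.free_rows, self.free_cols] = theta[: self.nl]
        return Lam

    def phi(self, theta: np.ndarray) -> np.ndarray:
        m = self.m
        if self.kind == "oblique":
            Phi = np.eye(m)
            Phi[self.phi_rows, self.phi_cols] = theta[self.struct_sl]
            Phi[self.phi_cols, self.phi_rows] = theta[self.struct_sl]
            return Phi
        if self.kind == "second_order":
            gamma = theta[self.nl : self.nl + m]
            psi = theta[self.nl + m : self.nl + 2 * m]
            return np.outer(gamma, gamma) + np.diag(psi)
        if self.kind == "fixed":
            return self.spec.structure.fixed_phi
        return np.eye(m)

    def uniquenesses(self, theta: np.ndarray) -> np.ndarray:
        return theta[self.theta_sl]

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        Lam = self.loadings(theta)
        Sigma = Lam @ self.phi(theta) @ Lam.T
        Sigma[np.diag_indices(self.p)] += self.uniquenesses(theta)
        return Sigma

    # -- starting values ----------------------------------------------------

    def default_start(self, S: np.ndarray | None = None) -> np.ndarray:
        """Deterministic default starts.

        Free loadings 0.5, oblique correlations 0.2, second-order loadings
        0.5, disturbances 0.3, uniquenesses 0.5.  When two factor columns
        have identical free-masks (fully crossed orthogonal patterns) a
        uniform start is a symmetry point the optimizer cannot leave, and
        flat rotation directions invite local minima; the loading block then
        starts from an iterated principal-axis factorization of S, with
        uniquenesses completing its communalities.
        """
        x0 = np.empty(self.n_params)
        x0[: self.nl] = 0.5
        x0[self.theta_sl] = np.maximum(0.5, self.spec.uniqueness_lower + 0.1)
        if self.m > 1 and S is not None:
            masks = [tuple(self.spec.pattern.free[:, k]) for k in range(self.m)]
            if len(set(masks)) < self.m:
                L0 = _principal_axis(S, self.m)
                L0 *= np.where(L0.sum(axis=0) < 0, -1.0, 1.0)
                x0[: self.nl] = L0[self.free_rows, self.free_cols]
                x0[self.theta_sl] = np.maximum(
                    np.clip(1.0 - (L0**2).sum(axis=1), 0.05, None),
                    self.spec.uniqueness_lower + 0.01,
                )
        if self.kind == "oblique":
            x0[self.struct_sl] = 0.2
        elif self.kind == "second_order":
            x0[self.nl : self.nl + self.m] = 0.5
            x0[self.nl + self.m : self.nl + 2 * self.m] = 0.3
        return x0

    # -- objective ----------------------------------------------------------

    def value_and_grad(
        self, theta: np.ndarray, S: np.ndarray, logdet_S: float
    ) -> tuple[float, np.ndarray]:
        p, m = self.p, self.m
        Lam = self.loadings(theta)
        Phi = self.phi(theta)
        Sigma = Lam @ Phi @ Lam.T
        Sigma[np.diag_indices(p)] += theta[self.theta_sl]
        try:
            c = cho_factor(Sigma, lower=True)
        except LinAlgError:
            return _BIG, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        Sigma_inv = cho_solve(c, np.eye(p))
        A = Sigma_inv @ S
        F = logdet + np.trace(A) - logdet_S - p
        if not np.isfinite(F):
            return _BIG, np.zeros_like(theta)
        W = Sigma_inv - A @ Sigma_inv  # dF = tr(W dSigma), symmetric
        g = np.empty_like(theta)
        GL = 2.0 * W @ Lam @ Phi
        g[: self.nl] = GL[self.free_rows, self.free_cols]
        if self.kind == "oblique":
            G = Lam.T @ W @ Lam
            g[self.struct_sl] = 2.0 * G[self.phi_rows, self.phi_cols]
        elif self.kind == "second_order":
            G = Lam.T @ W @ Lam
            gamma = theta[self.nl : self.nl + m]
            g[self.nl : self.nl + m] = 2.0 * (G @ gamma)
            g[self.nl + m : self.nl + 2 * m] = np.diag(G)
        g[self.theta_sl] = np.diag(W)
        return float(F), g

    def projected_gradient(self, theta: np.ndarray, g: np.ndarray) -> np.ndarray:
        gp = g.copy()
        at_lower = (theta <= self.lower + _ACTIVE_TOL) & (gp > 0)
        at_upper = (theta >= self.upper - _ACTIVE_TOL) & (gp < 0)
        gp[at_lower | at_upper] = 0.0
        return gp

    def active_bounds(self, theta: np.ndarray) -> tuple[str, ...]:
        at = (np.isfinite(self.lower) & (theta <= self.lower + _ACTIVE_TOL)) | (
            np.isfinite(self.upper) & (theta >= self.upper - _ACTIVE_TOL)
        )
        return tuple(n for n, a in zip(self.names, at) if a)


@dataclass
class FitResult:
    """Outcome of one ML fit."""

    spec: FactorModelSpec
    theta_hat: np.ndarray
    Sigma_hat: np.ndarray
    F_min: float
    chi2: float
    df: int
    n_obs: int
    converged: bool
    grad_norm: float
    active_bounds: tuple[str, ...]
    n_iter: int
    sample: CorrelationSample | None = None
    _layout: ParamLayout | None = field(default=None, repr=False)
    _info: np.ndarray | None = field(default=None, repr=False)

    @property
    def layout(self) -> ParamLayout:
        if self._layout is None:
            self._layout = ParamLayout(self.spec)
        return self._layout

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.layout.names

    @property
    def loadings(self) -> np.ndarray:
        return self.layout.loadings(self.theta_hat)

    @property
    def phi(self) -> np.ndarray:
        return self.layout.phi(self.theta_hat)

    @property
    def uniquenesses(self) -> np.ndarray:
        return self.layout.uniquenesses(self.theta_hat)

    def to_dict(self) -> dict:
        from .model_spec import spec_to_dict

        return {
            "spec": spec_to_dict(self.spec),
            "theta_hat": [float(v) for v in self.theta_hat],
            "param_names": list(self.param_names),
            "F_min": float(self.F_min),
            "chi2": float(self.chi2),
            "df": int(self.df),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "active_bounds": list(self.active_bounds),
            "n_iter": int(self.n_iter),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        from .model_spec import spec_from_dict

        spec = spec_from_dict(d["spec"])
        layout = ParamLayout(spec)
        theta = np.asarray(d["theta_hat"], dtype=float)
        return cls(
            spec=spec,
            theta_hat=theta,
            Sigma_hat=layout.sigma(theta),
            F_min=float(d["F_min"]),
            chi2=float(d["chi2"]),
            df=int(d["df"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            grad_norm=float(d["grad_norm"]),
            active_bounds=tuple(d.get("active_bounds", ())),
            n_iter=int(d.get("n_iter", 0)),
            _layout=layout,
        )


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape != (p, p):
        raise ValueError("S and Sigma must be square matrices of the same order")
    c = cho_factor(Sigma, lower=True)
    sign_S, logdet_S = np.linalg.slogdet(S)
    if sign_S <= 0:
        raise LinAlgError("S is not positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return float(logdet + np.trace(cho_solve(c, S)) - logdet_S - p)


def implied_matrix(spec: FactorModelSpec, theta: Sequence[float]) -> np.ndarray:
    """Sigma(theta) = Lambda Phi Lambda' + Theta for a flat parameter vector."""
    layout = ParamLayout(spec)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (layout.n_params,):
        raise ValueError(
            f"theta has length {theta.size}, spec needs {layout.n_params}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter values")
    return layout.sigma(theta)


class ConfirmatoryFactorAnalysis(BaseEstimator):
    """ML confirmatory factor analysis of a correlation matrix.

    Parameters
    ----------
    spec : FactorModelSpec or str
        The model.  A string names an entry of the built-in catalog.
    start : array-like, optional
        Starting parameter vector; defaults to the deterministic package
        starts (see :meth:`ParamLayout.default_start`).
    gtol : float
        Convergence tolerance on the infinity norm of the projected
        gradient of the discrepancy.
    max_iter : int
        Iteration cap per optimizer round.

    Attributes (after :meth:`fit`)
    ------------------------------
    result_ : FitResult
    theta_, loadings_, phi_, uniquenesses_, sigma_ : parameter estimates
    fmin_, chi2_, df_, n_obs_, converged_, grad_norm_, active_bounds_, n_iter_
    """

    def __init__(self, spec=None, *, start=None, gtol=1e-7, max_iter=2000):
        self.spec = spec
        self.start = start
        self.gtol = gtol
        self.max_iter = max_iter

    def _resolve_spec(self) -> FactorModelSpec:
        if isinstance(self.spec, FactorModelSpec):
            return self.spec
        if isinstance(self.spec, str):
            from .model_spec import build_catalog

            catalog = build_catalog()
            try:
                return catalog[self.spec]
            except KeyError:
                raise ValueError(
                    f"unknown catalog model {self.spec!r}; "
                    f"choices: {sorted(catalog)}"
                ) from None
        raise ValueError("spec must be a FactorModelSpec or a catalog name")

    @staticmethod
    def _as_sample(X, n_obs, label="") -> CorrelationSample:
        if isinstance(X, CorrelationSample):
            return X
        X = np.asarray(X, dtype=float)
        if n_obs is None:
            raise ValueError("n_obs is required when X is a bare matrix")
        names = tuple(f"v{i + 1}" for i in range(X.shape[0]))
        return CorrelationSample(names=names, R=X, n_obs=n_obs, label=label)

    def fit(self, X, y=None, *, n_obs: int | None = None):
        """Fit the model to a correlation sample (or bare matrix + n_obs)."""
        spec = self._resolve_spec()
        sample = self._as_sample(X, n_obs)
        if sample.p != spec.p:
            raise ValueError(f"sample has p={sample.p}, spec needs p={spec.p}")
        df = model_df(spec)  # raises on over-parameterization
        layout = ParamLayout(spec)
        S = sample.R
        _, logdet_S = np.linalg.slogdet(S)
        if self.start is not None:
            x0 = np.asarray(self.start, dtype=float)
            if x0.shape != (layout.n_params,):
                raise ValueError(
                    f"start has length {x0.size}, spec needs {layout.n_params}"
                )
        else:
            x0 = layout.default_start(S)
        x0 = np.clip(x0, layout.lower, layout.upper)
        bounds = list(zip(layout.lower, layout.upper))
        fun = lambda x: layout.value_and_grad(x, S, logdet_S)

        x, n_iter = x0, 0
        F = np.inf
        for _round in range(4):
            res = minimize(
                fun, x, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter,
                         "ftol": 1e-14, "gtol": 1e-9},
            )
            x, F = res.x, res.fun
            n_iter += res.nit
            _, g = fun(x)
            gnorm = float(np.max(np.abs(layout.projected_gradient(x, g))))
            if gnorm <= self.gtol:
                break
        converged = gnorm <= max(self.gtol, 1e-5)

        Sigma_hat = layout.sigma(x)
        F_min = max(float(F), 0.0)
        result = FitResult(
            spec=spec,
            theta_hat=x,
            Sigma_hat=Sigma_hat,
            F_min=F_min,
            chi2=(sample.n_obs - 1) * F_min,
            df=df,
            n_obs=sample.n_obs,
            converged=converged,
            grad_norm=gnorm,
            active_bounds=layout.active_bounds(x),
            n_iter=n_iter,
            sample=sample,
            _layout=layout,
        )
        if not converged:
            raise ConvergenceError(
                f"{spec.name}: projected gradient norm {gnorm:.3g} above tolerance "
                f"after {n_iter} iterations",
                result,
            )
        self.result_ = result
        self.theta_ = x
        self.loadings_ = result.loadings
        self.phi_ = result.phi
        self.uniquenesses_ = result.uniquenesses
        self.sigma_ = Sigma_hat
        self.fmin_ = F_min
        self.chi2_ = result.chi2
        self.df_ = df
        self.n_obs_ = sample.n_obs
        self.converged_ = converged
        self.grad_norm_ = gnorm
        self.active_bounds_ = result.active_bounds
        self.n_iter_ = n_iter
        return self

    def score(self, X, y=None, *, n_obs: int | None = None) -> float:
        """Negative ML discrepancy of the fitted Sigma against a new matrix."""
        S = X.R if isinstance(X, CorrelationSample) else np.asarray(X, dtype=float)
        return -ml_discrepancy(S, self.sigma_)


def fit_model(
    spec: FactorModelSpec | str,
    sample: CorrelationSample,
    start: Sequence[float] | None = None,
    *,
    gtol: float = 1e-7,
    max_iter: int = 2000,
) -> FitResult:
    """Functional wrapper around :class:`ConfirmatoryFactorAnalysis`."""
    est = ConfirmatoryFactorAnalysis(spec, start=start, gtol=gtol, max_iter=max_iter)
    est.fit(sample)
    return est.result_


def _sigma_derivs(layout: ParamLayout, theta: np.ndarray) -> list[np.ndarray]:
    """Per-parameter derivative matrices dSigma/dtheta_j."""
    p, m = layout.p, layout.m
    Lam = layout.loadings(theta)
    Phi = layout.phi(theta)
    A = Lam @ Phi  # column k = d(Lambda Phi Lambda')/dlambda_{.k} contraction
    derivs: list[np.ndarray] = []
    for i, k in zip(layout.free_rows, layout.free_cols):
        D = np.zeros((p, p))
        D[i, :] += A[:, k]
        D[:, i] += A[:, k]
        derivs.append(D)
    if layout.kind == "oblique":
        for i, j in zip(layout.phi_rows, layout.phi_cols):
            D = np.outer(Lam[:, i], Lam[:, j])
            derivs.append(D + D.T)
    elif layout.kind == "second_order":
        gamma = theta[layout.nl : layout.nl + m]
        Lg = Lam @ gamma
        for k in range(m):
            D = np.outer(Lam[:, k], Lg)
            derivs.append(D + D.T)
        for k in range(m):
            derivs.append(np.outer(Lam[:, k], Lam[:, k]))
    for i in range(p):
        D = np.zeros((p, p))
        D[i, i] = 1.0
        derivs.append(D)
    return derivs


def expected_information_F(layout: ParamLayout, theta: np.ndarray) -> np.ndarray:
    """Expected (Fisher-form) Hessian of F: tr(Sigma^-1 Di Sigma^-1 Dj)."""
    Sigma = layout.sigma(theta)
    Si = np.linalg.inv(Sigma)
    derivs = _sigma_derivs(layout, theta)
    B = [Si @ D @ Si for D in derivs]
    n = layout.n_params
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            H[i, j] = H[j, i] = np.sum(B[i] * derivs[j])
    return H


def information_matrix(
    fit: FitResult, S: np.ndarray | None = None, method: str = "expected"
) -> np.ndarray:
    """Information over the free parameters at the solution.

    ``method="expected"`` (default) is the analytic Fisher form evaluated at
    the implied matrix, the convention of classical SEM software;
    ``method="observed"`` is the Hessian of (N - 1)/2 times the discrepancy
    by central differences of the analytic gradient.  The two coincide when
    the model reproduces S exactly.  An indefinite numerical Hessian gets an
    eigenvalue floor, with a warning.
    """
    if fit._info is not None and method == "expected":
        return fit._info
    layout = fit.layout
    if method == "expected":
        H = expected_information_F(layout, fit.theta_hat)
        H *= (fit.n_obs - 1) / 2.0
        fit._info = H
        return H
    if S is None:
        if fit.sample is None:
            raise ValueError("fit carries no sample; pass S explicitly")
        S = fit.sample.R
    H = _hessian(layout, fit.theta_hat, S)
    H *= (fit.n_obs - 1) / 2.0
    w = np.linalg.eigvalsh(H)
    if w[0] < -1e-6 * max(abs(w[-1]), 1.0):
        warnings.warn(
            f"indefinite numerical Hessian (min eigenvalue {w[0]:.3g}); "
            "eigenvalue floor applied",
            RuntimeWarning,
        )
        wv, V = np.linalg.eigh(H)
        floor = 1e-10 * max(abs(w[-1]), 1.0)
        H = (V * np.maximum(wv, floor)) @ V.T
    return H


def _hessian(layout: ParamLayout, theta: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of F from the analytic gradient."""
    _, logdet_S = np.linalg.slogdet(S)
    n = layout.n_params
    H = np.empty((n, n))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(n):
        tp = theta.copy()
        tp[j] += h[j]
        tm = theta.copy()
        tm[j] -= h[j]
        _, gp = layout.value_and_grad(tp, S, logdet_S)
        _, gm = layout.value_and_grad(tm, S, logdet_S)
        H[:, j] = (gp - gm) / (2.0 * h[j])
    return (H + H.T) / 2.0


def sign_normalize(fit: FitResult) -> FitResult:
    """Report-time sign convention: largest-|loading| per factor positive.

    Factor signs are indeterminate; this returns an equivalent fit with each
    factor column flipped so its largest-magnitude loading is positive.  Phi
    (or Gamma) is adjusted so the implied matrix is unchanged.  Raw estimates
    are never flipped in place.
    """
    layout = fit.layout
    m = layout.m
    if m == 0:
        return fit
    Lam = fit.loadings
    signs = np.ones(m)
    for k in range(m):
        col = Lam[:, k]
        if np.any(col != 0.0):
            signs[k] = np.sign(col[np.argmax(np.abs(col))]) or 1.0
    theta = fit.theta_hat.copy()
    theta[: layout.nl] *= signs[layout.free_cols]
    if layout.kind == "oblique":
        theta[layout.struct_sl] *= signs[layout.phi_rows] * signs[layout.phi_cols]
    elif layout.kind == "second_order":
        gamma = theta[layout.nl : layout.nl + m] * signs
        # the second-order factor's own sign: dominant gamma positive
        if np.sign(gamma[np.argmax(np.abs(gamma))]) < 0:
            gamma = -gamma
        theta[layout.nl : layout.nl + m] = gamma
    out = FitResult(
        spec=fit.spec,
        theta_hat=theta,
        Sigma_hat=fit.Sigma_hat,
        F_min=fit.F_min,
        chi2=fit.chi2,
        df=fit.df,
        n_obs=fit.n_obs,
        converged=fit.converged,
        grad_norm=fit.grad_norm,
        active_bounds=fit.active_bounds,
        n_iter=fit.n_iter,
        sample=fit.sample,
        _layout=layout,
    )
    return out


def embed_start(fit: FitResult, new_spec: FactorModelSpec) -> np.ndarray:
    """Starting vector for ``new_spec`` seeded from a previous fit.

    Parameters shared by name keep their estimates; parameters new to
    ``new_spec`` start at 0 (loadings) or the package defaults.
    """
    new_layout = ParamLayout(new_spec)
    x0 = new_layout.default_start()
    x0[: new_layout.nl] = 0.0
    old = dict(zip(fit.param_names, fit.theta_hat))
    for j, name in enumerate(new_layout.names):
        if name in old:
            x0[j] = old[name]
    return np.clip(x0, new_layout.lower, new_layout.upper)
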