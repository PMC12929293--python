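"""Normal-theory maximum-likelihood estimation of covariance-structure models.

Models are evaluated in the RAM parameterization: a directed-coefficient
matrix ``A`` (regressions and loadings), a symmetric matrix ``S`` of
variances/covariances of exogenous terms and disturbances, and a selection
matrix ``F`` onto the observed variables.  The implied covariance matrix is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and the ML discrepancy minimized is

    F_ML = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p

with the chi-square statistic ``(n - 1) * F_ML`` at the minimum (Wishart
convention; switchable to ``n`` via ``chisq_multiplier``).

Free variances are optimized on the log scale so the search stays in the
admissible region; the quasi-Newton search uses analytic gradients and a
small number of jittered restarts when the first attempt fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .model_syntax import (
    COVARIANCE,
    MEASUREMENT,
    REGRESSION,
    ModelSpec,
    model_df,
)

_PENALTY = 1e10
_GTOL = 1e-6
_MAX_RESTARTS = 5


@dataclass
class RAMMatrices:
    """RAM matrices with a map from free-parameter index to matrix slots."""

    variables: tuple[str, ...]
    observed: tuple[str, ...]
    A: np.ndarray
    S: np.ndarray
    F: np.ndarray
    # one entry per free parameter: ("A"|"S", row, col)
    param_map: list[tuple[str, int, int]]
    param_names: list[tuple[str, str, str]]
    is_variance: list[bool]

    @property
    def n_free(self) -> int:
        return len(self.param_map)

    def update(self, theta: np.ndarray) -> None:
        """Write free-parameter values into A and S (symmetric slots together)."""
        for value, (mat, i, j) in zip(theta, self.param_map):
            if mat == "A":
                self.A[i, j] = value
            else:
                self.S[i, j] = value
                self.S[j, i] = value

    def implied_covariance(self, theta: Optional[np.ndarray] = None) -> np.ndarray:
        if theta is not None:
            self.update(np.asarray(theta, dtype=float))
        k = len(self.variables)
        B = np.linalg.solve(np.eye(k) - self.A, np.eye(k))
        sigma_full = B @ self.S @ B.T
        return self.F @ sigma_full @ self.F.T


def build_ram(spec: ModelSpec) -> RAMMatrices:
    """Construct RAM matrices from a normalized model spec."""
    variables = spec.variables
    idx = {v: i for i, v in enumerate(variables)}
    k = len(variables)
    A = np.zeros((k, k))
    S = np.zeros((k, k))
    F = np.zeros((spec.p, k))
    for r, v in enumerate(spec.observed):
        F[r, idx[v]] = 1.0

    param_map: list[tuple[str, int, int]] = []
    param_names: list[tuple[str, str, str]] = []
    is_variance: list[bool] = []
    for par in spec.parameters:
        if par.op == REGRESSION:
            slot = ("A", idx[par.lhs], idx[par.rhs])
        elif par.op == MEASUREMENT:
            slot = ("A", idx[par.rhs], idx[par.lhs])
        else:
            slot = ("S", idx[par.lhs], idx[par.rhs])
        if par.free:
            param_map.append(slot)
            param_names.append(par.key)
            is_variance.append(par.is_variance)
        else:
            mat, i, j = slot
            if mat == "A":
                A[i, j] = par.fixed_value
            else:
                S[i, j] = par.fixed_value
                S[j, i] = par.fixed_value
    return RAMMatrices(
        variables=variables,
        observed=spec.observed,
        A=A,
        S=S,
        F=F,
        param_map=param_map,
        param_names=param_names,
        is_variance=is_variance,
    )


@dataclass
class FitResult:
    """ML solution of a covariance-structure model."""

    theta_hat: np.ndarray
    f_min: float
    chisq: float
    df: int
    n: int
    p_value: float
    converged: bool
    n_starts_used: int
    implied_cov: np.ndarray
    param_names: list[tuple[str, str, str]]
    identified: bool = True
    spec: Optional[ModelSpec] = None

    @property
    def ok(self) -> bool:
        return self.converged and self.identified

    def estimates(self) -> dict[tuple[str, str, str], float]:
        return dict(zip(self.param_names, self.theta_hat))


def chi_square_p_value(chisq: float, df: int) -> float:
    """Upper-tail p of the central chi-square; NaN for df = 0 (saturated)."""
    if df == 0:
        return math.nan
    if chisq < 0 or df < 0:
        raise ValueError("chisq and df must be nonnegative")
    return float(stats.chi2.sf(chisq, df))


def _f_ml(sigma: np.ndarray, sample_cov: np.ndarray, logdet_s: float) -> float:
    p = sample_cov.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return math.inf
    try:
        sol = np.linalg.solve(sigma, sample_cov)
    except np.linalg.LinAlgError:
        return math.inf
    return logdet + float(np.trace(sol)) - logdet_s - p


class _Objective:
    """F_ML and its gradient on the transformed (log-variance) scale."""

    def __init__(self, ram: RAMMatrices, sample_cov: np.ndarray):
        self.ram = ram
        self.sample_cov = sample_cov
        sign, self.logdet_s = np.linalg.slogdet(sample_cov)
        if sign <= 0:
            raise ValueError("sample covariance matrix is not positive definite")
        self.is_var = np.asarray(ram.is_variance, dtype=bool)

    def to_internal(self, theta: np.ndarray) -> np.ndarray:
        z = np.array(theta, dtype=float)
        z[self.is_var] = np.log(np.maximum(z[self.is_var], 1e-10))
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        theta = np.array(z, dtype=float)
        theta[self.is_var] = np.exp(theta[self.is_var])
        return theta

    def value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        theta = self.to_natural(z)
        ram = self.ram
        ram.update(theta)
        k = len(ram.variables)
        try:
            B = np.linalg.solve(np.eye(k) - ram.A, np.eye(k))
        except np.linalg.LinAlgError:
            return _PENALTY * (1 + float(z @ z)), 2 * _PENALTY * z
        G = ram.F @ B                     # p x k
        sigma = G @ ram.S @ G.T
        f = _f_ml(sigma, self.sample_cov, self.logdet_s)
        if not math.isfinite(f):
            # inadmissible point: smooth penalty pushing back toward origin
            return _PENALTY * (1 + float(z @ z)), 2 * _PENALTY * z
        sigma_inv = np.linalg.inv(sigma)
        W = sigma_inv @ (sigma - self.sample_cov) @ sigma_inv  # d f / d sigma
        H = B @ ram.S @ G.T               # k x p
        HWG = H @ W @ G                   # k x k
        GWG = G.T @ W @ G                 # k x k
        grad = np.empty(len(theta))
        for t, (mat, i, j) in enumerate(ram.param_map):
            if mat == "A":
                grad[t] = 2.0 * HWG[j, i]
            elif i == j:
                grad[t] = GWG[i, i]
            else:
                grad[t] = 2.0 * GWG[i, j]
        # chain rule through the log transform of variances
        grad[self.is_var] *= theta[self.is_var]
        return f, grad


def _start_values(ram: RAMMatrices, sample_cov: np.ndarray) -> np.ndarray:
    """Heuristic starts: sample variances on the diagonal slots, loadings at
    ~0.7 on the marker scale, regressions and covariances at 0."""
    obs_idx = {v: i for i, v in enumerate(ram.observed)}
    var_idx = {v: i for i, v in enumerate(ram.variables)}
    theta = np.zeros(ram.n_free)
    for t, ((mat, i, j), name) in enumerate(zip(ram.param_map, ram.param_names)):
        lhs, op, rhs = name
        if op == COVARIANCE and lhs == rhs:
            if lhs in obs_idx:
                theta[t] = 0.5 * sample_cov[obs_idx[lhs], obs_idx[lhs]] + 0.05
            else:
                # latent variance: half the variance of its marker-scale range
                theta[t] = 0.05 + 0.5 * float(np.mean(np.diag(sample_cov)))
        elif op == MEASUREMENT:
            theta[t] = 0.7
    return theta


def fit_ml(
    spec: ModelSpec,
    sample_cov: np.ndarray,
    n: int,
    *,
    seed: int = 1234,
    max_restarts: int = _MAX_RESTARTS,
    chisq_multiplier: str = "n-1",
) -> FitResult:
    """Fit a model by normal-theory ML to a sample covariance matrix.

    Parameters
    ----------
    spec:
        Normalized model spec.
    sample_cov:
        Positive-definite sample covariance matrix, ordered as
        ``spec.observed``.
    n:
        Sample size (must exceed the number of observed variables).
    seed:
        Seed of the jitter used for restart start values.
    chisq_multiplier:
        ``"n-1"`` (Wishart, default) or ``"n"``.
    """
    sample_cov = np.asarray(sample_cov, dtype=float)
    p = spec.p
    if sample_cov.shape != (p, p):
        raise ValueError(f"sample covariance must be {p}x{p}")
    if not np.allclose(sample_cov, sample_cov.T, rtol=1e-8, atol=1e-10):
        raise ValueError("sample covariance matrix is not symmetric")
    if n <= p:
        raise ValueError("sample size must exceed the number of variables")
    dof = model_df(spec)
    if dof.df < 0:
        raise ValueError(f"model has negative df ({dof.df}): unidentifiable by counting")

    ram = build_ram(spec)
    obj = _Objective(ram, sample_cov)
    rng = np.random.default_rng(seed)

    best = None
    n_starts = 0
    theta0 = _start_values(ram, sample_cov)
    if ram.n_free == 0:
        theta_hat = np.zeros(0)
        f_min = _f_ml(ram.implied_covariance(theta_hat), sample_cov, obj.logdet_s)
        best = (f_min, theta_hat, True)
        n_starts = 1
    for attempt in range(max_restarts + 1):
        if ram.n_free == 0:
            break
        start = theta0.copy()
        if attempt > 0:
            start = start + rng.normal(scale=0.1 * (1 + np.abs(start)))
            start[obj.is_var] = np.abs(start[obj.is_var]) + 1e-3
        z0 = obj.to_internal(start)
        res = optimize.minimize(
            obj.value_and_grad,
            z0,
            jac=True,
            method="BFGS",
            options={"gtol": _GTOL, "maxiter": 2000},
        )
        n_starts = attempt + 1
        f_val, grad = obj.value_and_grad(res.x)
        converged = bool(math.isfinite(f_val) and np.max(np.abs(grad)) <= 1e-4)
        theta_hat = obj.to_natural(res.x)
        if best is None or f_val < best[0] - 1e-12:
            best = (f_val, theta_hat, converged)
        if converged and np.max(np.abs(grad)) <= _GTOL * 10:
            best = (f_val, theta_hat, True)
            break

    f_min, theta_hat, converged = best
    f_min = max(f_min, 0.0)
    implied = ram.implied_covariance(theta_hat)
    mult = (n - 1) if chisq_multiplier == "n-1" else n
    chisq = max(mult * f_min, 0.0)
    identified = _identified_at(obj, theta_hat) if ram.n_free else True
    return FitResult(
        theta_hat=theta_hat,
        f_min=f_min,
        chisq=chisq,
        df=dof.df,
        n=n,
        p_value=chi_square_p_value(chisq, dof.df),
        converged=converged,
        n_starts_used=n_starts,
        implied_cov=implied,
        param_names=list(ram.param_names),
        identified=identified,
        spec=spec,
    )


def _identified_at(obj: _Objective, theta_hat: np.ndarray) -> bool:
    """Empirical identification: the information matrix (Hessian of F_ML on
    the internal scale) must not be numerically rank deficient."""
    z = obj.to_internal(theta_hat)
    k = len(z)
    if k == 0:
        return True
    hess = np.empty((k, k))
    h = 1e-5
    for j in range(k):
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        _, gp = obj.value_and_grad(zp)
        _, gm = obj.value_and_grad(zm)
        hess[:, j] = (gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    eig = np.linalg.eigvalsh(hess)
    largest = max(abs(eig[0]), abs(eig[-1]), 1e-300)
    return bool(eig[0] >= -1e-6 * largest and eig[0] >= 1e-8 * largest)


def fit_baseline(sample_cov: np.ndarray, n: int, *, chisq_multiplier: str = "n-1") -> FitResult:
    """Closed-form fit of the independence (baseline) model.

    With all covariances fixed to zero the ML variance estimates equal the
    sample variances, so F_ML reduces to ``-ln|R|`` with ``R`` the sample
    correlation matrix.
    """
    sample_cov = np.asarray(sample_cov, dtype=float)
    p = sample_cov.shape[0]
    variances = np.diag(sample_cov)
    if np.any(variances <= 0):
        raise ValueError("sample variances must be positive")
    sign, logdet_s = np.linalg.slogdet(sample_cov)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    f_min = float(np.sum(np.log(variances)) - logdet_s)
    f_min = max(f_min, 0.0)
    mult = (n - 1) if chisq_multiplier == "n-1" else n
    chisq = mult * f_min
    df = p * (p - 1) // 2
    return FitResult(
        theta_hat=variances.copy(),
        f_min=f_min,
        chisq=chisq,
        df=df,
        n=n,
        p_value=chi_square_p_value(chisq, df),
        converged=True,
        n_starts_used=0,
        implied_cov=np.diag(variances),
        param_names=[(f"v{i}", COVARIANCE, f"v{i}") for i in range(p)],
        identified=True,
        spec=None,
    )
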