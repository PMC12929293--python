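"""Independent brute-force SEM oracle used only by the tests.

Deliberately implemented with different algorithms than the package:

* the implied covariance is built from the *total-effect* matrix obtained
  by summing powers of the coefficient matrix (path tracing over an
  acyclic graph), not by inverting (I - A);
* the ML discrepancy is minimized by derivative-free Nelder-Mead over the
  raw parameters, not by the package's analytic-gradient quasi-Newton
  search on a log-variance scale.

It is slow and only suitable for tiny models; that is the point.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from sembpp.model_syntax import COVARIANCE, MEASUREMENT, REGRESSION, ModelSpec


def oracle_implied_cov(spec: ModelSpec, values: dict[tuple[str, str, str], float]) -> np.ndarray:
    """Implied covariance via total effects: T = I + A + A^2 + ... (A is
    nilpotent for acyclic models), Sigma_full = T S T', then select the
    observed block."""
    variables = list(spec.variables)
    k = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    A = np.zeros((k, k))
    S = np.zeros((k, k))
    for par in spec.parameters:
        val = values[par.key] if par.free else par.fixed_value
        if par.op == REGRESSION:
            A[idx[par.lhs], idx[par.rhs]] = val
        elif par.op == MEASUREMENT:
            A[idx[par.rhs], idx[par.lhs]] = val
        else:
            S[idx[par.lhs], idx[par.rhs]] = val
            S[idx[par.rhs], idx[par.lhs]] = val
    total = np.eye(k)
    power = np.eye(k)
    for _ in range(k):
        power = power @ A
        if not power.any():
            break
        total = total + power
    else:
        raise ValueError("structural part is cyclic; oracle requires acyclic models")
    sigma_full = total @ S @ total.T
    obs = [idx[v] for v in spec.observed]
    return sigma_full[np.ix_(obs, obs)]


def _f_ml(sigma: np.ndarray, sample_cov: np.ndarray) -> float:
    p = sample_cov.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(sample_cov)
    return logdet + float(np.trace(np.linalg.solve(sigma, sample_cov))) - logdet_s - p


def oracle_fit_ml(spec: ModelSpec, sample_cov: np.ndarray, n: int,
                  n_starts: int = 8, seed: int = 0):
    """Derivative-free ML fit; returns (chisq, estimates dict, f_min)."""
    free = [par.key for par in spec.free_parameters()]
    is_var = [lhs == rhs and op == COVARIANCE for (lhs, op, rhs) in free]
    sample_cov = np.asarray(sample_cov, dtype=float)
    rng = np.random.default_rng(seed)

    def objective(x):
        values = {}
        for key, var_flag, xi in zip(free, is_var, x):
            values[key] = abs(xi) + 1e-8 if var_flag else xi
        try:
            sigma = oracle_implied_cov(spec, values)
        except ValueError:
            return np.inf
        return _f_ml(sigma, sample_cov)

    mean_var = float(np.mean(np.diag(sample_cov)))
    base = np.array([mean_var if v else 0.1 for v in is_var])
    best_f, best_x = np.inf, None
    for start in range(n_starts):
        x0 = base if start == 0 else base + rng.normal(scale=0.3, size=len(base))
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    estimates = {}
    for key, var_flag, xi in zip(free, is_var, best_x):
        estimates[key] = abs(xi) + 1e-8 if var_flag else xi
    return (n - 1) * max(best_f, 0.0), estimates, max(best_f, 0.0)


def brute_force_additions(spec: ModelSpec, exclude_xy_cov: bool = True,
                          exclude_error_cov: bool | None = None) -> set[tuple[str, str, str]]:
    """Exhaustive enumeration over every absent parameter, applying the
    exclusion rules directly via descendant sets computed by DFS."""
    variables = list(spec.variables)
    indicators = set(spec.indicators)
    structural = [v for v in variables if v not in indicators]
    if exclude_error_cov is None:
        exclude_error_cov = bool(spec.latent)

    children: dict[str, set[str]] = {v: set() for v in variables}
    for src, dst in spec.structural_edges():
        children[src].add(dst)

    def descendants(v: str) -> set[str]:
        seen, stack = set(), [v]
        while stack:
            u = stack.pop()
            for w in children[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    existing_free = {p.key for p in spec.parameters if p.free}
    # a parameter fixed to zero counts as absent (freeing it is an addition)
    blocked = {p.key for p in spec.parameters if p.free or p.fixed_value != 0.0}
    out: set[tuple[str, str, str]] = set()

    for target in structural:
        for source in structural:
            if source == target:
                continue
            key = (target, REGRESSION, source)
            if key in blocked:
                continue
            if (source, REGRESSION, target) in existing_free:
                continue
            if source in descendants(target) or source == target:
                continue
            pair = tuple(sorted((target, source)))
            cov_key = None
            for par in spec.parameters:
                if par.op == COVARIANCE and tuple(sorted((par.lhs, par.rhs))) == pair and par.free:
                    cov_key = par.key
            if cov_key is not None:
                continue
            out.add(key)

    for lat in spec.latent:
        for ind in indicators:
            key = (lat, MEASUREMENT, ind)
            if key in blocked:
                continue
            if lat in descendants(ind):
                continue
            out.add(key)

    order = spec.variable_order
    for i, u in enumerate(variables):
        for v in variables[i + 1:]:
            a, b = (u, v) if order[u] <= order[v] else (v, u)
            if (a, COVARIANCE, b) in blocked:
                continue
            if (u in indicators) != (v in indicators):
                continue
            if u in indicators and v in indicators and exclude_error_cov:
                continue
            ordered_pair = v in descendants(u) or u in descendants(v)
            if ordered_pair and exclude_xy_cov:
                continue
            out.add((a, COVARIANCE, b))
    return out


def brute_force_drops(spec: ModelSpec) -> set[tuple[str, str, str]]:
    return {p.key for p in spec.parameters
            if p.free and not (p.op == COVARIANCE and p.lhs == p.rhs)}
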