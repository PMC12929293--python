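"""Synthetic-data generation from known covariance-structure models.

Every test stage can run without external data: a generator configuration
couples a model spec with true parameter values and yields either the exact
model-implied covariance matrix or a multivariate-normal sample drawn from
it.  Shipped analog models emulate the two structures used throughout the
workflow's illustrations: a serial-parallel mediation path model
(x -> m11 -> m12 -> y and x -> m2 -> y) and a three-factor CFA with 13
indicators (spatial/verbal/speed-like abilities).

True standardized path magnitudes are drawn from {0.1 (weak), 0.3, 0.5},
spanning the weak-path regime where parsimony pressure can beat a true but
small effect at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import build_ram
from .model_syntax import COVARIANCE, MEASUREMENT, REGRESSION, ModelSpec, parse_model

ParamKey = tuple[str, str, str]


@dataclass
class GeneratorConfig:
    """A data-generating model: spec, true free-parameter values, n, seed."""

    spec: ModelSpec
    theta: dict[ParamKey, float]
    n: int = 200
    seed: int = 1234
    noise: str = "exact"  # "exact" | "sampled"

    def __post_init__(self):
        if self.noise not in ("exact", "sampled"):
            raise ValueError("noise must be 'exact' or 'sampled'")
        free = {par.key for par in self.spec.free_parameters()}
        given = set(self.theta)
        if free != given:
            missing = free - given
            extra = given - free
            raise ValueError(
                f"theta does not match free parameters (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )

    def theta_vector(self) -> np.ndarray:
        ram = build_ram(self.spec)
        return np.array([self.theta[key] for key in ram.param_names])


def exact_covariance(config: GeneratorConfig) -> np.ndarray:
    """Model-implied covariance matrix at the true parameters."""
    ram = build_ram(config.spec)
    sigma = ram.implied_covariance(config.theta_vector())
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] <= 0:
        raise ValueError(f"implied covariance not positive definite (min eig {eig[0]:.3g})")
    return sigma


def sample_data(config: GeneratorConfig) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal rows with the implied covariance."""
    if config.noise != "sampled":
        raise ValueError("sample_data requires noise='sampled'")
    p = config.spec.p
    if config.n <= p:
        raise ValueError("sample size must exceed the number of observed variables")
    sigma = exact_covariance(config)
    rng = np.random.default_rng(config.seed)
    x = rng.multivariate_normal(np.zeros(p), sigma, size=config.n, method="cholesky")
    return pd.DataFrame(x, columns=list(config.spec.observed))


def sample_covariance(data: pd.DataFrame) -> np.ndarray:
    """Unbiased (n-1 divisor) sample covariance in column order."""
    return np.cov(data.to_numpy(), rowvar=False, ddof=1)


SERIAL_PARALLEL_SYNTAX = """\
m11 ~ x
m12 ~ m11
m2 ~ x
y ~ m12 + m2
"""

# true standardized coefficients of the serial-parallel analog; disturbance
# variances chosen so every variable has unit variance
_SP_THETA = {
    ("m11", REGRESSION, "x"): 0.5,
    ("m12", REGRESSION, "m11"): 0.5,
    ("m2", REGRESSION, "x"): 0.5,
    ("y", REGRESSION, "m12"): 0.3,
    ("y", REGRESSION, "m2"): 0.3,
    ("x", COVARIANCE, "x"): 1.0,
    ("m11", COVARIANCE, "m11"): 0.75,
    ("m12", COVARIANCE, "m12"): 0.75,
    ("m2", COVARIANCE, "m2"): 0.75,
    ("y", COVARIANCE, "y"): 0.7975,
}

SERIAL_PARALLEL_WEAK_SYNTAX = SERIAL_PARALLEL_SYNTAX + "m12 ~ x\n"

CFA_THREE_FACTOR_SYNTAX = """\
spatial =~ t1 + t2 + t3 + t4 + t5
verbal  =~ t6 + t7 + t8 + t9
speed   =~ t10 + t11 + t12 + t13
"""


def _cfa_theta(spec: ModelSpec, loading: float = 0.8, error: float = 0.5,
               factor_cov: float = 0.4) -> dict[ParamKey, float]:
    theta: dict[ParamKey, float] = {}
    for par in spec.free_parameters():
        if par.op == MEASUREMENT:
            theta[par.key] = loading
        elif par.is_variance and par.lhs in spec.latent:
            theta[par.key] = 1.0
        elif par.is_variance:
            theta[par.key] = error
        else:  # factor covariance
            theta[par.key] = factor_cov
    return theta


def paper_analog_models() -> list[tuple[str, GeneratorConfig]]:
    """Shipped analog models with documented true parameters.

    * ``serial_parallel`` — the mediation model itself as data generator.
    * ``serial_parallel_weak_extra`` — same structure plus a weak (0.1)
      x -> m12 path, so the 1-df-away candidate that adds this path is the
      quasi-true model when the plain structure is hypothesized.
    * ``cfa_three_factor`` — simple-structure CFA, 13 indicators.
    * ``cfa_cross_loading`` — the CFA plus one true cross-loading
      (spatial on t13, 0.3).
    """
    sp_spec = parse_model(SERIAL_PARALLEL_SYNTAX)
    sp = GeneratorConfig(sp_spec, dict(_SP_THETA), n=200, noise="exact")

    spw_spec = parse_model(SERIAL_PARALLEL_WEAK_SYNTAX)
    spw_theta = dict(_SP_THETA)
    spw_theta[("m12", REGRESSION, "x")] = 0.1
    # keep var(m12) at 1 given the extra path: 0.25 + 0.01 + 2*.5*.1*cov(m11,x)
    spw_theta[("m12", COVARIANCE, "m12")] = 1.0 - (0.25 + 0.01 + 2 * 0.5 * 0.1 * 0.5)
    spw = GeneratorConfig(spw_spec, spw_theta, n=200, noise="exact")

    cfa_spec = parse_model(CFA_THREE_FACTOR_SYNTAX)
    cfa = GeneratorConfig(cfa_spec, _cfa_theta(cfa_spec), n=145, noise="exact")

    cfa_x_spec = parse_model(CFA_THREE_FACTOR_SYNTAX + "spatial =~ t13\n")
    cfa_x_theta = _cfa_theta(cfa_x_spec)
    cfa_x_theta[("spatial", MEASUREMENT, "t13")] = 0.3
    cfa_x = GeneratorConfig(cfa_x_spec, cfa_x_theta, n=145, noise="exact")

    return [
        ("serial_parallel", sp),
        ("serial_parallel_weak_extra", spw),
        ("cfa_three_factor", cfa),
        ("cfa_cross_loading", cfa_x),
    ]


def analog(name: str, n: int | None = None, seed: int | None = None,
           noise: str | None = None) -> GeneratorConfig:
    """Look up a shipped analog by name, optionally overriding n/seed/noise."""
    for nm, config in paper_analog_models():
        if nm == name:
            return GeneratorConfig(
                spec=config.spec,
                theta=config.theta,
                n=n if n is not None else config.n,
                seed=seed if seed is not None else config.seed,
                noise=noise if noise is not None else config.noise,
            )
    known = ", ".join(nm for nm, _ in paper_analog_models())
    raise KeyError(f"unknown analog {name!r}; known: {known}")
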