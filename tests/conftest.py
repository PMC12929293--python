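import numpy as np
import pytest

import sembpp as s
from sembpp import fixtures as fx

# chi-square / df rows of the four-model hypothetical scenario used as a
# golden test throughout: p = 6 observed variables, N = 180, baseline
# model chisq 400 on 15 df
TABLE1_ROWS = {"A": (21.0, 10), "B": (17.0, 9), "C": (15.8, 8), "D": (14.5, 7)}
TABLE1_N = 180
TABLE1_P = 6
TABLE1_BASELINE = (400.0, 15)


@pytest.fixture(scope="session")
def table1_bics():
    return {
        name: s.bic_from_chisq(chisq, df, TABLE1_N, TABLE1_P)
        for name, (chisq, df) in TABLE1_ROWS.items()
    }


CHAIN_SYNTAX = "m ~ x\ny ~ m"
CHAIN_THETA = {
    ("m", "~", "x"): 0.5,
    ("y", "~", "m"): 0.7,
    ("x", "~~", "x"): 1.0,
    ("m", "~~", "m"): 1.0,
    ("y", "~~", "y"): 1.0,
}


@pytest.fixture(scope="session")
def chain_spec():
    return s.parse_model(CHAIN_SYNTAX)


@pytest.fixture(scope="session")
def chain_sigma(chain_spec):
    """Exact implied covariance of the x -> m -> y chain (0.5, 0.7)."""
    return fx.exact_covariance(fx.GeneratorConfig(chain_spec, dict(CHAIN_THETA)))


@pytest.fixture(scope="session")
def fork_spec():
    """Two outcomes regressed on one predictor: y ~ x; m ~ x."""
    return s.parse_model("y ~ x\nm ~ x")


@pytest.fixture(scope="session")
def fork_sample_cov(fork_spec):
    theta = {
        ("y", "~", "x"): 0.4,
        ("m", "~", "x"): 0.5,
        ("x", "~~", "x"): 1.0,
        ("y", "~~", "y"): 0.84,
        ("m", "~~", "m"): 0.75,
    }
    config = fx.GeneratorConfig(fork_spec, theta, n=500, seed=7, noise="sampled")
    return fx.sample_covariance(fx.sample_data(config)), 500


@pytest.fixture(scope="session")
def serial_parallel():
    return fx.analog("serial_parallel")


def random_small_model(rng: np.random.Generator):
    """A random identified path model on 3-5 observed variables together
    with admissible true parameter values; used for oracle cross-checks."""
    n_vars = int(rng.integers(3, 6))
    names = [f"v{i}" for i in range(n_vars)]
    lines = []
    edges = []
    # random DAG respecting the index order, each non-source gets >=1 parent
    for j in range(1, n_vars):
        parents = [i for i in range(j) if rng.random() < 0.6]
        if not parents:
            parents = [int(rng.integers(0, j))]
        for i in parents:
            edges.append((i, j))
        lines.append(f"{names[j]} ~ " + " + ".join(names[i] for i in parents))
    spec = s.parse_model("\n".join(lines))
    theta = {}
    for par in spec.free_parameters():
        if par.op == "~~" and par.lhs == par.rhs:
            theta[par.key] = float(rng.uniform(0.5, 1.5))
        elif par.op == "~~":
            theta[par.key] = float(rng.uniform(-0.2, 0.2))
        else:
            theta[par.key] = float(rng.uniform(-0.6, 0.6))
    return spec, theta
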