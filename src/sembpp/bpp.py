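"""BIC-based Bayesian posterior model probabilities (BPP).

For candidate models M_1 ... M_m with BIC scores BIC_i and prior
probabilities Prior(M_i), the posterior probability of M_i is

    Posterior(M_i) = exp(-(BIC_i - BIC_ref)/2) Prior(M_i) / D,
    D = sum_i exp(-(BIC_i - BIC_ref)/2) Prior(M_i),

with an arbitrary reference model (the choice cancels in the
normalization).  Computation is overflow-safe via a log-sum-exp shift:
BIC differences well above 1400 occur in practice.

Prior helpers implement the "modestly favored" schemes: a single
hypothesized model gets prior p1 = 1/(0.80 m + 0.20) so that every other
model's prior is 0.80 p1; with k1 favored models among k, each favored
model gets p1 = 1/(0.80 k + 0.20 k1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

_PRIOR_SUM_TOL = 1e-8


@dataclass
class PriorSpec:
    """A prior distribution over named candidate models."""

    priors: dict[str, float] = field(default_factory=dict)
    unbiased: bool = False
    p1: Optional[float] = None
    p2: Optional[float] = None
    k: Optional[int] = None
    k1: Optional[int] = None

    def validate(self) -> None:
        for name, pr in self.priors.items():
            if pr < 0 or pr > 1:
                raise ValueError(f"prior of {name!r} outside [0, 1]: {pr}")
        total = sum(self.priors.values())
        if self.priors and abs(total - 1.0) > _PRIOR_SUM_TOL:
            raise ValueError(f"priors sum to {total!r}, not 1")

    def materialize(self, names: Sequence[str], favored: Sequence[str] = ()) -> "PriorSpec":
        """Bind a scheme built by the prior helpers to concrete model names."""
        names = list(names)
        if self.unbiased or self.p1 is None:
            return unbiased_priors(names)
        favored = list(favored)
        if self.k is not None and self.k != len(names):
            raise ValueError(f"prior scheme built for {self.k} models, got {len(names)}")
        if self.k1 is not None and self.k1 != max(len(favored), 1):
            raise ValueError(f"prior scheme favors {self.k1} models, got {len(favored)}")
        if not favored:
            favored = [names[0]]
        unknown = set(favored) - set(names)
        if unknown:
            raise ValueError(f"favored models not in set: {sorted(unknown)}")
        priors = {nm: (self.p1 if nm in favored else self.p2) for nm in names}
        out = PriorSpec(priors=priors, unbiased=False, p1=self.p1, p2=self.p2,
                        k=len(names), k1=len(favored))
        out.validate()
        return out


def unbiased_priors(names: Sequence[str]) -> PriorSpec:
    """Equal prior 1/m over all m models."""
    m = len(names)
    if m == 0:
        raise ValueError("empty model set")
    return PriorSpec(priors={nm: 1.0 / m for nm in names}, unbiased=True,
                     p1=1.0 / m, p2=1.0 / m, k=m, k1=m)


def prior_single_target(m: int) -> PriorSpec:
    """Prior scheme favoring one hypothesized model among m: its prior is
    p1 = 1/(0.80 m + 0.20); every other model gets 0.80 p1 (so the target is
    1.25 times as plausible a priori as each alternative)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p1 = 1.0 / (0.80 * m + 0.20)
    return PriorSpec(priors={}, unbiased=False, p1=p1, p2=0.80 * p1, k=m, k1=1)


def prior_multiple_targets(k: int, k1: int) -> PriorSpec:
    """Prior scheme favoring k1 models among k: each favored model gets
    p1 = 1/(0.80 k + 0.20 k1); every other model gets 0.80 p1."""
    if not 1 <= k1 <= k:
        raise ValueError("need 1 <= k1 <= k")
    p1 = 1.0 / (0.80 * k + 0.20 * k1)
    return PriorSpec(priors={}, unbiased=False, p1=p1, p2=0.80 * p1, k=k, k1=k1)


def complete_priors(partial: Mapping[str, float], names: Sequence[str]) -> PriorSpec:
    """Complete a partial prior assignment: named models keep their priors,
    the remaining mass is split equally over the unnamed models."""
    names = list(names)
    unknown = set(partial) - set(names)
    if unknown:
        raise ValueError(f"priors given for unknown models: {sorted(unknown)}")
    assigned = sum(partial.values())
    if assigned < 0 or assigned > 1 + _PRIOR_SUM_TOL:
        raise ValueError("partial priors must lie in [0, 1] and sum to at most 1")
    rest = [nm for nm in names if nm not in partial]
    if rest:
        share = (1.0 - assigned) / len(rest)
        priors = {nm: partial.get(nm, share) for nm in names}
    else:
        priors = {nm: partial[nm] for nm in names}
    out = PriorSpec(priors=priors)
    out.validate()
    return out


@dataclass
class BPPResult:
    """Posterior model probabilities with the normalizer that produced them."""

    bpp: dict[str, float]
    normalizer: float
    reference_model: str
    bics: dict[str, float]
    priors: PriorSpec

    def sorted_names(self) -> list[str]:
        return sorted(self.bpp, key=lambda nm: (-self.bpp[nm], nm))


def compute_bpp(
    bics: Mapping[str, float],
    priors: PriorSpec | Mapping[str, float] | None = None,
    reference_model: Optional[str] = None,
) -> BPPResult:
    """Posterior probabilities from BICs and priors.

    ``priors=None`` uses unbiased (equal) priors.  Priors must cover exactly
    the models in ``bics`` and sum to 1; no silent renormalization.
    """
    names = list(bics)
    if not names:
        raise ValueError("at least one model required")
    if priors is None:
        prior_spec = unbiased_priors(names)
    elif isinstance(priors, PriorSpec):
        prior_spec = priors if priors.priors else priors.materialize(names)
    else:
        prior_spec = PriorSpec(priors=dict(priors))
    prior_spec.validate()
    if set(prior_spec.priors) != set(names):
        raise ValueError("priors must cover exactly the models with BICs")

    if reference_model is None:
        reference_model = names[0]
    elif reference_model not in bics:
        raise ValueError(f"reference model {reference_model!r} not in set")

    b = np.array([bics[nm] for nm in names], dtype=float)
    pr = np.array([prior_spec.priors[nm] for nm in names], dtype=float)
    b_ref = bics[reference_model]
    with np.errstate(divide="ignore"):
        log_num = -0.5 * (b - b_ref) + np.log(pr)
    log_d = logsumexp(log_num)
    post = np.exp(log_num - log_d)
    post = post / post.sum()  # guard rounding
    with np.errstate(over="ignore"):
        normalizer = float(np.exp(log_d))  # may overflow to inf; only D's
        # role in the posteriors (already normalized) matters
    return BPPResult(
        bpp={nm: float(v) for nm, v in zip(names, post)},
        normalizer=normalizer,
        reference_model=reference_model,
        bics=dict(bics),
        priors=prior_spec,
    )


@dataclass(frozen=True)
class SensitivityResult:
    target_model: str
    bpp_target: float
    min_prior: float
    achievable: bool


def min_prior_for_target(
    bics: Mapping[str, float], target: str, bpp_target: float
) -> SensitivityResult:
    """Minimum prior on ``target`` needed for its posterior to reach
    ``bpp_target``, with the remaining prior mass split equally over the
    other models.

    With BIC weight w_t for the target and mean weight W of the others,
    the posterior equals b at prior  pi = b W / (w_t (1 - b) + b W).
    """
    if target not in bics:
        raise ValueError(f"target {target!r} not in BIC table")
    if not 0.0 < bpp_target < 1.0:
        raise ValueError("bpp_target must lie strictly between 0 and 1")
    if len(bics) < 2:
        raise ValueError("need at least two models")
    names = list(bics)
    b = np.array([bics[nm] for nm in names], dtype=float)
    shift = b.min()
    w = np.exp(-0.5 * (b - shift))
    t = names.index(target)
    w_t = w[t]
    w_bar = float(np.mean(np.delete(w, t)))
    pi = bpp_target * w_bar / (w_t * (1.0 - bpp_target) + bpp_target * w_bar)
    achievable = bool(pi < 1.0)
    return SensitivityResult(
        target_model=target,
        bpp_target=bpp_target,
        min_prior=float(min(pi, 1.0)),
        achievable=achievable,
    )


def bpp_at_target_prior(bics: Mapping[str, float], target: str, pi: float) -> float:
    """Posterior of ``target`` when it has prior ``pi`` and the other models
    share ``1 - pi`` equally.  Inverse of :func:`min_prior_for_target`."""
    names = list(bics)
    m = len(names)
    priors = {nm: (pi if nm == target else (1.0 - pi) / (m - 1)) for nm in names}
    return compute_bpp(bics, priors).bpp[target]


def combine_model_sets(sets):
    """Combine several fitted model sets into one posterior over the union.

    Thin wrapper over :func:`sembpp.neighborhood.combine_model_sets`.
    """
    from .neighborhood import combine_model_sets as _combine

    return _combine(sets)
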