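"""Parsing and serialization of the compact SEM model-syntax dialect.

The dialect is a subset of the formula language common in SEM software:

* ``f =~ x1 + x2 + x3`` — measurement: latent ``f`` measured by indicators.
* ``y ~ x1 + x2``       — regression: ``y`` regressed on predictors.
* ``x1 ~~ x2``          — (co)variance between two variables, or a variance
  when both sides are the same variable.
* A numeric premultiplier fixes a coefficient: ``f =~ 1*x1`` fixes the
  loading of ``x1`` to 1.  A non-numeric premultiplier is kept as a label.
* ``#`` starts a comment; blank lines are ignored.

Parsing *normalizes* a model: free variances are materialized for every
variable, covariances among exogenous variables are freed by default, and
each latent variable is identified by the marker method (first indicator
loading fixed to 1 unless the user fixed a loading themselves).

The parameter count ``q`` and the model degrees of freedom
``df = p(p+1)/2 - q`` (``p`` observed variables) are derived from the
normalized parameter table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

MEASUREMENT = "=~"
REGRESSION = "~"
COVARIANCE = "~~"
_OPS = (MEASUREMENT, COVARIANCE, REGRESSION)  # order matters: "~~" before "~"

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


class ModelSyntaxError(ValueError):
    """Raised on malformed model syntax; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ParameterEntry:
    """One row of the parameter table of a covariance-structure model."""

    lhs: str
    op: str
    rhs: str
    free: bool = True
    fixed_value: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        if not self.free and self.fixed_value is None:
            raise ValueError("fixed parameter requires fixed_value")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lhs, self.op, self.rhs)

    @property
    def is_variance(self) -> bool:
        return self.op == COVARIANCE and self.lhs == self.rhs


@dataclass(frozen=True)
class DegreesOfFreedom:
    df: int
    q: int
    moments: int


def _norm_pair(lhs: str, rhs: str, order: dict[str, int]) -> tuple[str, str]:
    """Order a covariance pair by the model's variable ordering."""
    if order.get(lhs, 10**9) <= order.get(rhs, 10**9):
        return lhs, rhs
    return rhs, lhs


@dataclass(frozen=True)
class ModelSpec:
    """Normalized parameter table of a covariance-structure model.

    ``observed`` and ``latent`` keep the order of first appearance in the
    syntax; covariance pairs are normalized against that ordering so that
    each pair occurs at most once.
    """

    observed: tuple[str, ...]
    latent: tuple[str, ...]
    parameters: tuple[ParameterEntry, ...]

    def __post_init__(self):
        names = set(self.observed) | set(self.latent)
        if set(self.observed) & set(self.latent):
            raise ModelSyntaxError(
                "variable used as both observed and latent: "
                + ", ".join(sorted(set(self.observed) & set(self.latent)))
            )
        seen: set[tuple[str, str, str]] = set()
        order = self.variable_order
        for par in self.parameters:
            if par.lhs not in names or par.rhs not in names:
                raise ModelSyntaxError(f"unknown variable in {par.lhs} {par.op} {par.rhs}")
            if par.op == COVARIANCE and order[par.lhs] > order[par.rhs]:
                raise ModelSyntaxError(f"covariance {par.lhs} ~~ {par.rhs} not order-normalized")
            if par.key in seen:
                raise ModelSyntaxError(f"duplicate parameter {par.lhs} {par.op} {par.rhs}")
            seen.add(par.key)

    # -- basic views ---------------------------------------------------

    @property
    def variables(self) -> tuple[str, ...]:
        return self.observed + self.latent

    @property
    def variable_order(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    @property
    def p(self) -> int:
        return len(self.observed)

    @property
    def q(self) -> int:
        return sum(1 for par in self.parameters if par.free)

    def free_parameters(self) -> tuple[ParameterEntry, ...]:
        return tuple(par for par in self.parameters if par.free)

    def get(self, lhs: str, op: str, rhs: str) -> Optional[ParameterEntry]:
        if op == COVARIANCE:
            lhs, rhs = _norm_pair(lhs, rhs, self.variable_order)
        for par in self.parameters:
            if par.key == (lhs, op, rhs):
                return par
        return None

    def indicators_of(self, lat: str) -> tuple[str, ...]:
        return tuple(p.rhs for p in self.parameters if p.op == MEASUREMENT and p.lhs == lat)

    @property
    def indicators(self) -> tuple[str, ...]:
        """Observed variables that load on at least one latent."""
        out: list[str] = []
        for par in self.parameters:
            if par.op == MEASUREMENT and par.rhs not in out:
                out.append(par.rhs)
        return tuple(out)

    def structural_edges(self) -> list[tuple[str, str]]:
        """Directed edges (source, target): regressions and loadings."""
        edges = []
        for par in self.parameters:
            if par.op == REGRESSION:
                edges.append((par.rhs, par.lhs))
            elif par.op == MEASUREMENT:
                edges.append((par.lhs, par.rhs))
        return edges

    # -- equality (structure, not bookkeeping order) -------------------

    def _canonical(self):
        pars = set()
        for par in self.parameters:
            lhs, rhs = par.lhs, par.rhs
            if par.op == COVARIANCE:
                lhs, rhs = min(lhs, rhs), max(lhs, rhs)
            pars.add((lhs, par.op, rhs, par.free, par.fixed_value))
        return (frozenset(self.observed), frozenset(self.latent), frozenset(pars))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelSpec):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())


def model_df(spec: ModelSpec) -> DegreesOfFreedom:
    """Counting-rule degrees of freedom: unique moments minus free parameters."""
    p = spec.p
    moments = p * (p + 1) // 2
    q = spec.q
    return DegreesOfFreedom(df=moments - q, q=q, moments=moments)


# ---------------------------------------------------------------------------
# parsing


def _parse_term(term: str, lineno: int) -> tuple[str, Optional[float], Optional[str]]:
    """Parse one right-hand-side term: ``var``, ``1*var`` or ``lab*var``."""
    term = term.strip()
    if "*" in term:
        pre, _, var = term.partition("*")
        pre, var = pre.strip(), var.strip()
        if not _NAME_RE.match(var):
            raise ModelSyntaxError(f"bad variable name {var!r}", lineno)
        try:
            return var, float(pre), None
        except ValueError:
            if not _NAME_RE.match(pre):
                raise ModelSyntaxError(f"bad premultiplier {pre!r}", lineno)
            return var, None, pre
    if not _NAME_RE.match(term):
        raise ModelSyntaxError(f"bad variable name {term!r}", lineno)
    return term, None, None


def _split_line(line: str, lineno: int) -> tuple[str, str, str]:
    for op in _OPS:
        if op in line:
            lhs, _, rhs = line.partition(op)
            lhs, rhs = lhs.strip(), rhs.strip()
            if not lhs or not rhs:
                raise ModelSyntaxError("missing left- or right-hand side", lineno)
            return lhs, op, rhs
    raise ModelSyntaxError(f"no operator found in {line!r}", lineno)


def parse_model(syntax: str) -> ModelSpec:
    """Parse model syntax into a normalized :class:`ModelSpec`.

    Normalization materializes implicit parameters: a free variance for
    every variable (an error/disturbance variance for endogenous ones),
    free covariances among all exogenous variables, and marker-method
    identification of each latent (first loading fixed to 1 unless the
    user fixed one explicitly).
    """
    if not syntax or not syntax.strip():
        raise ModelSyntaxError("empty model syntax")

    explicit: list[tuple[int, str, str, str, Optional[float], Optional[str]]] = []
    appearance: list[str] = []

    def _see(v: str) -> None:
        if v not in appearance:
            appearance.append(v)

    for lineno, raw in enumerate(syntax.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lhs, op, rhs = _split_line(line, lineno)
        if not _NAME_RE.match(lhs):
            raise ModelSyntaxError(f"bad variable name {lhs!r}", lineno)
        _see(lhs)
        for term in rhs.split("+"):
            var, fixed, label = _parse_term(term, lineno)
            _see(var)
            explicit.append((lineno, lhs, op, var, fixed, label))

    latent = tuple(dict.fromkeys(e[1] for e in explicit if e[2] == MEASUREMENT))
    observed = tuple(v for v in appearance if v not in latent)
    for _, lhs, op, rhs, _, _ in explicit:
        if op == MEASUREMENT and rhs in latent:
            raise ModelSyntaxError(
                f"variable {rhs!r} used as both latent and indicator (higher-order "
                "factors are outside this dialect)"
            )

    order = {v: i for i, v in enumerate(observed + latent)}

    entries: dict[tuple[str, str, str], ParameterEntry] = {}
    for lineno, lhs, op, rhs, fixed, label in explicit:
        if op == COVARIANCE:
            lhs, rhs = _norm_pair(lhs, rhs, order)
        key = (lhs, op, rhs)
        if key in entries:
            raise ModelSyntaxError(f"duplicate parameter {lhs} {op} {rhs}", lineno)
        entries[key] = ParameterEntry(
            lhs, op, rhs, free=fixed is None, fixed_value=fixed, label=label
        )

    # marker method: fix the first loading of each latent to 1 unless the
    # user already fixed one for that latent
    for lat in latent:
        loadings = [k for k in entries if k[1] == MEASUREMENT and k[0] == lat]
        if not any(not entries[k].free for k in loadings):
            first = loadings[0]
            entries[first] = replace(entries[first], free=False, fixed_value=1.0)

    endogenous = {e.lhs for e in entries.values() if e.op == REGRESSION}
    endogenous |= {e.rhs for e in entries.values() if e.op == MEASUREMENT}
    exogenous = [v for v in observed + latent if v not in endogenous]

    # free variance (or disturbance variance) for every variable
    for v in observed + latent:
        key = (v, COVARIANCE, v)
        if key not in entries:
            entries[key] = ParameterEntry(v, COVARIANCE, v, free=True)

    # free covariances among exogenous variables
    for i, u in enumerate(exogenous):
        for v in exogenous[i + 1:]:
            a, b = _norm_pair(u, v, order)
            key = (a, COVARIANCE, b)
            if key not in entries:
                entries[key] = ParameterEntry(a, COVARIANCE, b, free=True)

    ordered = sorted(
        entries.values(),
        key=lambda e: (_OPS.index(e.op), order[e.lhs], order[e.rhs]),
    )
    return ModelSpec(observed=observed, latent=latent, parameters=tuple(ordered))


def spec_to_string(spec: ModelSpec) -> str:
    """Serialize a spec so that ``parse_model(spec_to_string(s)) == s``.

    Every parameter is written explicitly (one formula per line), so the
    parser's default materialization is a no-op on the output.  Variance
    lines come first, in the spec's variable order, which preserves the
    variable ordering on re-parse.
    """
    lines: list[str] = []
    for v in spec.variables:
        par = spec.get(v, COVARIANCE, v)
        if par is not None:
            lines.append(_format_entry(par))
    for par in spec.parameters:
        if not par.is_variance:
            lines.append(_format_entry(par))
    return "\n".join(lines) + "\n"


def _format_entry(par: ParameterEntry) -> str:
    rhs = par.rhs
    if not par.free:
        rhs = f"{_format_number(par.fixed_value)}*{rhs}"
    elif par.label:
        rhs = f"{par.label}*{rhs}"
    return f"{par.lhs} {par.op} {rhs}"


def _format_number(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(x)


# ---------------------------------------------------------------------------
# spec surgery used by the neighborhood search


def with_parameter_added(spec: ModelSpec, par: ParameterEntry) -> ModelSpec:
    """Return a spec with ``par`` added free (replacing a fixed slot if any)."""
    lhs, rhs = par.lhs, par.rhs
    if par.op == COVARIANCE:
        lhs, rhs = _norm_pair(lhs, rhs, spec.variable_order)
        par = replace(par, lhs=lhs, rhs=rhs)
    existing = spec.get(lhs, par.op, rhs)
    pars = list(spec.parameters)
    if existing is not None:
        if existing.free:
            raise ValueError(f"parameter {lhs} {par.op} {rhs} already free")
        pars[pars.index(existing)] = replace(existing, free=True, fixed_value=None)
    else:
        pars.append(par)
    return ModelSpec(spec.observed, spec.latent, tuple(pars))


def with_parameter_dropped(spec: ModelSpec, lhs: str, op: str, rhs: str) -> ModelSpec:
    """Return a spec with a free parameter fixed to zero (dropped)."""
    existing = spec.get(lhs, op, rhs)
    if existing is None or not existing.free:
        raise ValueError(f"parameter {lhs} {op} {rhs} not free in spec")
    if existing.is_variance:
        raise ValueError("variances cannot be dropped")
    pars = list(spec.parameters)
    pars[pars.index(existing)] = replace(existing, free=False, fixed_value=0.0)
    return ModelSpec(spec.observed, spec.latent, tuple(pars))
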