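"""Enumeration and fitting of neighboring models: the model-set engine.

A *neighboring model* differs from the hypothesized model by freeing
(adding) or fixing to zero (dropping) free parameters.  The default
1-df-away set contains every model reachable by a single change; wider
radii compose several changes.  Enumeration applies the exclusion rules of
the workflow:

* added directed paths must keep the structural part acyclic (no feedback
  loops);
* a covariance involving the error term of a variable and a variable that
  causally precedes it (an ancestor in the directed structural graph), or
  that variable's error term, is excluded unless ``exclude_xy_cov=False``;
* for latent-variable models, cross-loadings are always candidates while
  indicator error covariances are excluded unless
  ``exclude_error_cov=False`` (their number grows quadratically and they
  are rarely interpretable outside longitudinal designs).

Fitted candidates that are empirically equivalent (same df, same
chi-square, same implied covariance matrix up to tolerance) are collapsed
to a single representative; equivalence is empirical equality on the data,
not a graph-theoretic rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import bpp as _bpp
from .estimation import FitResult, fit_baseline, fit_ml
from .fit_measures import FitIndices, compute_indices
from .model_syntax import (
    COVARIANCE,
    MEASUREMENT,
    REGRESSION,
    ModelSpec,
    ParameterEntry,
    model_df,
    with_parameter_added,
    with_parameter_dropped,
)

ORIGINAL = "original"


@dataclass(frozen=True)
class ModelModification:
    """A single add/drop change relative to the original model."""

    kind: str  # "add" | "drop"
    parameter: ParameterEntry
    df_delta: int  # +1 for add (one more free parameter), -1 for drop

    def __post_init__(self):
        if self.kind not in ("add", "drop"):
            raise ValueError(f"unknown modification kind {self.kind!r}")

    def label(self) -> str:
        par = self.parameter
        if par.op == REGRESSION:
            body = f"{par.lhs} {par.rhs}"
        elif par.op == MEASUREMENT:
            body = f"{par.lhs}=~{par.rhs}"
        else:
            body = f"{par.lhs}~~{par.rhs}"
        return f"{self.kind}: {body}"


@dataclass
class NeighborhoodOptions:
    """Options of the neighborhood search.

    ``exclude_error_cov=None`` resolves to True when the model has latent
    variables (the conventional default) and is irrelevant otherwise.
    """

    df_change_add: int = 1
    df_change_drop: int = 1
    exclude_xy_cov: bool = True
    exclude_error_cov: Optional[bool] = None
    restart_budget: int = 5
    max_models: int = 500
    equivalence_tol: float = 1e-6

    def __post_init__(self):
        if self.df_change_add < 0 or self.df_change_drop < 0:
            raise ValueError("df radii must be nonnegative")

    def resolved_exclude_error_cov(self, spec: ModelSpec) -> bool:
        if self.exclude_error_cov is None:
            return bool(spec.latent)
        return self.exclude_error_cov


@dataclass
class CandidateModel:
    """One member of a model set: a modified spec with its fit and indices."""

    name: str
    spec: ModelSpec
    modifications: tuple[ModelModification, ...]
    fit: Optional[FitResult]
    indices: Optional[FitIndices]
    equivalence_class: int = -1
    flagged: bool = False
    flag_reason: str = ""

    @property
    def df_diff(self) -> int:
        """Paper sign convention: +1 means one free parameter added."""
        return sum(m.df_delta for m in self.modifications)

    def free_key_set(self) -> frozenset[tuple[str, str, str]]:
        keys = set()
        for par in self.spec.parameters:
            if par.free and not par.is_variance:
                lhs, rhs = par.lhs, par.rhs
                if par.op == COVARIANCE:
                    lhs, rhs = min(lhs, rhs), max(lhs, rhs)
                keys.add((lhs, par.op, rhs))
            elif par.free:
                keys.add((par.lhs, par.op, par.rhs))
        return frozenset(keys)


def name_modification(mods: Sequence[ModelModification], order: Mapping[str, int] | None = None) -> str:
    """Deterministic label: single changes as ``add: m12 x`` / ``drop: y m2``,
    several changes joined by ``"; "``; the empty list is ``original``."""
    if not mods:
        return ORIGINAL

    def sort_key(m: ModelModification):
        par = m.parameter
        o = order or {}
        return (
            0 if m.kind == "add" else 1,
            ("~", "=~", "~~").index(par.op) if par.op in ("~", "=~", "~~") else 3,
            o.get(par.lhs, 10**9),
            o.get(par.rhs, 10**9),
            par.lhs,
            par.rhs,
        )

    return "; ".join(m.label() for m in sorted(mods, key=sort_key))


# ---------------------------------------------------------------------------
# enumeration


def _structural_graph(spec: ModelSpec) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(spec.variables)
    g.add_edges_from(spec.structural_edges())
    return g


def _precedes(g: nx.DiGraph, u: str, v: str) -> bool:
    """True when u is an ancestor of v in the directed structural graph."""
    return nx.has_path(g, u, v) and u != v


def enumerate_additions(spec: ModelSpec, options: Optional[NeighborhoodOptions] = None) -> list[ModelModification]:
    """All single-parameter additions allowed by the exclusion rules."""
    options = options or NeighborhoodOptions()
    g = _structural_graph(spec)
    indicators = set(spec.indicators)
    structural = [v for v in spec.variables if v not in indicators]
    excl_err = options.resolved_exclude_error_cov(spec)
    mods: list[ModelModification] = []

    def addable(lhs: str, op: str, rhs: str) -> bool:
        existing = spec.get(lhs, op, rhs)
        if existing is None:
            return True
        return (not existing.free) and existing.fixed_value == 0.0

    # directed paths among structural variables; reject feedback loops
    for target in structural:
        for source in structural:
            if source == target or not addable(target, REGRESSION, source):
                continue
            if spec.get(source, REGRESSION, target) is not None and spec.get(source, REGRESSION, target).free:
                # reverse path present: adding would create a 2-cycle
                continue
            if nx.has_path(g, target, source):
                continue  # feedback loop
            cov = spec.get(target, COVARIANCE, source)
            if cov is not None and cov.free:
                # a free covariance already links the pair; a path on top is
                # redundant (not identified)
                continue
            mods.append(ModelModification("add", ParameterEntry(target, REGRESSION, source), +1))

    # cross-loadings: latent -> indicator of some other latent
    for lat in spec.latent:
        for ind in indicators:
            if not addable(lat, MEASUREMENT, ind):
                continue
            if nx.has_path(g, ind, lat):
                continue
            mods.append(ModelModification("add", ParameterEntry(lat, MEASUREMENT, ind), +1))

    # covariances between error terms / exogenous variables
    variables = spec.variables
    for i, u in enumerate(variables):
        for v in variables[i + 1:]:
            if not addable(u, COVARIANCE, v):
                continue
            u_ind, v_ind = u in indicators, v in indicators
            if u_ind != v_ind:
                continue  # indicator-with-structural covariances not searched
            if u_ind and v_ind:
                if excl_err:
                    continue
            ordered = _precedes(g, u, v) or _precedes(g, v, u)
            if ordered and options.exclude_xy_cov:
                continue
            mods.append(ModelModification("add", ParameterEntry(u, COVARIANCE, v), +1))

    return mods


def enumerate_drops(spec: ModelSpec, options: Optional[NeighborhoodOptions] = None) -> list[ModelModification]:
    """All single-parameter drops: free paths, free non-marker loadings and
    free covariances.  Variances and marker loadings are never dropped."""
    mods: list[ModelModification] = []
    for par in spec.parameters:
        if not par.free or par.is_variance:
            continue
        mods.append(ModelModification("drop", par, -1))
    return mods


def apply_modifications(spec: ModelSpec, mods: Sequence[ModelModification]) -> ModelSpec:
    out = spec
    for mod in mods:
        par = mod.parameter
        if mod.kind == "drop":
            out = with_parameter_dropped(out, par.lhs, par.op, par.rhs)
        else:
            out = with_parameter_added(out, replace(par, free=True, fixed_value=None))
    return out


def _candidate_subsets(
    adds: Sequence[ModelModification],
    drops: Sequence[ModelModification],
    options: NeighborhoodOptions,
) -> list[tuple[ModelModification, ...]]:
    """Compose single modifications into candidate change sets.

    Up to ``df_change_add`` additions and ``df_change_drop`` drops may be
    combined, with the total number of changes capped by the larger radius,
    so radius (1, 1) yields exactly the single-change neighbors while
    radius (2, 2) also yields paired and mixed changes.
    """
    total_cap = max(options.df_change_add, options.df_change_drop)
    out: list[tuple[ModelModification, ...]] = []
    for na in range(options.df_change_add + 1):
        for nd in range(options.df_change_drop + 1):
            if na + nd == 0 or na + nd > total_cap:
                continue
            for add_combo in combinations(adds, na):
                for drop_combo in combinations(drops, nd):
                    out.append(tuple(add_combo) + tuple(drop_combo))
    return out


# ---------------------------------------------------------------------------
# equivalence


def detect_equivalent(candidates: Sequence[CandidateModel], tol: float = 1e-6) -> dict[str, int]:
    """Partition fitted candidates into empirical-equivalence classes.

    Two candidates are equivalent iff they have the same df, chi-squares
    within ``tol`` and implied covariance matrices within ``tol`` elementwise.
    Assigns ``equivalence_class`` ids and returns name -> class id.
    """
    classes: list[list[CandidateModel]] = []
    for cand in candidates:
        placed = False
        if cand.fit is not None and not cand.flagged:
            for cls in classes:
                rep = cls[0]
                if rep.fit is None or rep.flagged:
                    continue
                if rep.fit.df != cand.fit.df:
                    continue
                if abs(rep.fit.chisq - cand.fit.chisq) > tol:
                    continue
                if rep.fit.implied_cov.shape != cand.fit.implied_cov.shape:
                    continue
                if np.max(np.abs(rep.fit.implied_cov - cand.fit.implied_cov)) > tol:
                    continue
                cls.append(cand)
                placed = True
                break
        if not placed:
            classes.append([cand])
    mapping: dict[str, int] = {}
    for cid, cls in enumerate(classes):
        for cand in cls:
            cand.equivalence_class = cid
            mapping[cand.name] = cid
    return mapping


def _class_representative(cls: list[CandidateModel]) -> CandidateModel:
    for cand in cls:
        if cand.name == ORIGINAL:
            return cand
    return min(cls, key=lambda c: c.name)


# ---------------------------------------------------------------------------
# the model set


@dataclass
class ModelSet:
    """A candidate collection with priors, BICs and posterior probabilities."""

    candidates: list[CandidateModel]
    sample_cov: np.ndarray
    n: int
    options: NeighborhoodOptions
    baseline: FitResult
    merged: dict[str, list[str]] = field(default_factory=dict)
    priors: Optional[_bpp.PriorSpec] = None
    bpp_result: Optional[_bpp.BPPResult] = None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.candidates]

    @property
    def original(self) -> CandidateModel:
        for cand in self.candidates:
            if cand.name == ORIGINAL:
                return cand
        raise KeyError("no original model in set")

    def __getitem__(self, name: str) -> CandidateModel:
        for cand in self.candidates:
            if cand.name == name:
                return cand
        raise KeyError(name)

    def usable(self) -> list[CandidateModel]:
        return [c for c in self.candidates if not c.flagged]

    def bics(self) -> dict[str, float]:
        return {c.name: c.indices.bic for c in self.usable()}

    def set_priors(
        self,
        priors: _bpp.PriorSpec | Mapping[str, float] | None = None,
        favored: Sequence[str] = (),
    ) -> _bpp.BPPResult:
        """(Re)compute posteriors.  ``None`` uses unbiased priors over the
        usable candidates; flagged candidates always receive prior 0."""
        usable_names = [c.name for c in self.usable()]
        if priors is None:
            prior_spec = _bpp.unbiased_priors(usable_names)
        elif isinstance(priors, _bpp.PriorSpec) and not priors.priors:
            prior_spec = priors.materialize(usable_names, favored=favored or (ORIGINAL,) if ORIGINAL in usable_names else favored)
        elif isinstance(priors, _bpp.PriorSpec):
            prior_spec = priors
        else:
            prior_spec = _bpp.complete_priors(dict(priors), usable_names)
        result = _bpp.compute_bpp(self.bics(), prior_spec)
        full_priors = dict(prior_spec.priors)
        full_bpp = dict(result.bpp)
        for cand in self.candidates:
            if cand.flagged:
                full_priors[cand.name] = 0.0
                full_bpp[cand.name] = 0.0
        self.priors = _bpp.PriorSpec(priors=full_priors, unbiased=prior_spec.unbiased,
                                     p1=prior_spec.p1, p2=prior_spec.p2,
                                     k=prior_spec.k, k1=prior_spec.k1)
        self.bpp_result = _bpp.BPPResult(
            bpp=full_bpp,
            normalizer=result.normalizer,
            reference_model=result.reference_model,
            bics=result.bics,
            priors=self.priors,
        )
        return self.bpp_result

    def min_prior_for_target(self, bpp_target: float, target: str = ORIGINAL) -> _bpp.SensitivityResult:
        return _bpp.min_prior_for_target(self.bics(), target, bpp_target)

    def table(self) -> pd.DataFrame:
        """Results table sorted by BPP in descending order."""
        if self.bpp_result is None:
            self.set_priors(None)
        rows = []
        for cand in self.candidates:
            fit = cand.fit
            idx = cand.indices
            rows.append({
                "model": cand.name,
                "sep": "|",
                "df_diff": cand.df_diff,
                "df": fit.df if fit is not None else np.nan,
                "chisq": fit.chisq if fit is not None else np.nan,
                "p": fit.p_value if fit is not None else np.nan,
                "Prior": self.priors.priors.get(cand.name, 0.0),
                "BIC": idx.bic if idx is not None else np.nan,
                "BPP": self.bpp_result.bpp.get(cand.name, 0.0),
                "CFI": idx.cfi if idx is not None else np.nan,
                "RMSEA": idx.rmsea if idx is not None else np.nan,
                "SRMR": idx.srmr if idx is not None else np.nan,
            })
        frame = pd.DataFrame(rows)
        return frame.sort_values(["BPP", "model"], ascending=[False, True], kind="mergesort").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)

    def data_fingerprint(self) -> tuple:
        return (self.n, self.sample_cov.shape, float(np.sum(self.sample_cov)), float(np.sum(self.sample_cov ** 2)))


def _fit_candidate(
    spec: ModelSpec,
    sample_cov: np.ndarray,
    n: int,
    options: NeighborhoodOptions,
    seed: int,
) -> tuple[Optional[FitResult], bool, str]:
    dof = model_df(spec)
    if dof.df < 0:
        return None, True, f"negative df ({dof.df}): not identifiable by counting"
    fit = fit_ml(spec, sample_cov, n, seed=seed, max_restarts=options.restart_budget)
    if not fit.converged:
        return fit, True, "nonconvergent after all restarts"
    if not fit.identified:
        return fit, True, "information matrix rank deficient at solution"
    return fit, False, ""


def generate_model_set(
    original: ModelSpec | FitResult,
    sample_cov: np.ndarray,
    n: int,
    options: Optional[NeighborhoodOptions] = None,
    *,
    seed: int = 1234,
) -> ModelSet:
    """Enumerate, fit and deduplicate all models within the df radius of the
    original model; compute fit indices and unbiased-prior BPPs.

    ``original`` may be a spec (fitted here) or an existing
    :class:`~sembpp.estimation.FitResult` carrying its spec.
    """
    options = options or NeighborhoodOptions()
    sample_cov = np.asarray(sample_cov, dtype=float)

    if isinstance(original, FitResult):
        if original.spec is None:
            raise ValueError("FitResult must carry its spec")
        spec = original.spec
        orig_fit = original
    else:
        spec = original
        orig_fit = fit_ml(spec, sample_cov, n, seed=seed, max_restarts=options.restart_budget)
    if not orig_fit.converged:
        raise RuntimeError("the original model did not converge; cannot build a model set")

    adds = enumerate_additions(spec, options)
    drops = enumerate_drops(spec, options)
    subsets = _candidate_subsets(adds, drops, options)
    if len(subsets) + 1 > options.max_models:
        raise RuntimeError(
            f"{len(subsets) + 1} candidate models exceed the cap of "
            f"{options.max_models}; the number of models increases exponentially "
            "with the df radius — raise max_models explicitly if intended"
        )

    baseline = fit_baseline(sample_cov, n)
    order = spec.variable_order

    candidates: list[CandidateModel] = []
    orig_indices = compute_indices(
        orig_fit.chisq, orig_fit.df, n, spec.p, baseline.chisq, baseline.df,
        sample_cov, orig_fit.implied_cov,
    )
    candidates.append(CandidateModel(ORIGINAL, spec, (), orig_fit, orig_indices))

    seen_specs = {spec}
    for mods in subsets:
        try:
            cand_spec = apply_modifications(spec, mods)
        except ValueError:
            continue
        # composed additions may jointly create a cycle even when each is
        # individually acyclic
        if sum(1 for m in mods if m.kind == "add") >= 2:
            if not nx.is_directed_acyclic_graph(_structural_graph(cand_spec)):
                continue
        if cand_spec in seen_specs:
            continue
        seen_specs.add(cand_spec)
        name = name_modification(mods, order)
        fit, flagged, reason = _fit_candidate(cand_spec, sample_cov, n, options, seed)
        indices = None
        if fit is not None:
            indices = compute_indices(
                fit.chisq, fit.df, n, spec.p, baseline.chisq, baseline.df,
                sample_cov, fit.implied_cov,
            )
        if flagged:
            warnings.warn(f"candidate {name!r} excluded from BPP: {reason}", stacklevel=2)
        candidates.append(CandidateModel(name, cand_spec, tuple(mods), fit, indices,
                                         flagged=flagged, flag_reason=reason))

    detect_equivalent(candidates, options.equivalence_tol)
    by_class: dict[int, list[CandidateModel]] = {}
    for cand in candidates:
        by_class.setdefault(cand.equivalence_class, []).append(cand)
    retained: list[CandidateModel] = []
    merged: dict[str, list[str]] = {}
    for cid in sorted(by_class):
        cls = by_class[cid]
        rep = _class_representative(cls)
        retained.append(rep)
        if len(cls) > 1:
            merged[rep.name] = sorted(c.name for c in cls if c is not rep)
    retained.sort(key=lambda c: (c.name != ORIGINAL, c.name))

    model_set = ModelSet(
        candidates=retained,
        sample_cov=sample_cov,
        n=n,
        options=options,
        baseline=baseline,
        merged=merged,
    )
    model_set.set_priors(None)
    return model_set


def combine_model_sets(sets: Sequence[ModelSet]) -> ModelSet:
    """Union of several model sets fitted on identical data: duplicates and
    equivalents merged, unbiased priors over the union, BPPs recomputed."""
    if not sets:
        raise ValueError("no model sets to combine")
    first = sets[0]
    for other in sets[1:]:
        if other.n != first.n or other.sample_cov.shape != first.sample_cov.shape or \
                not np.allclose(other.sample_cov, first.sample_cov, atol=1e-12):
            raise ValueError("model sets were not fitted on identical data")

    union: list[CandidateModel] = []
    used_names: set[str] = set()
    for i, ms in enumerate(sets):
        for cand in ms.candidates:
            name = cand.name
            if len(sets) > 1 and name == ORIGINAL:
                name = f"{ORIGINAL}_{i + 1}"
            if name in used_names:
                name = f"{name} [{i + 1}]"
            if name != cand.name:
                cand = replace_name(cand, name)
            union.append(cand)
            used_names.add(name)

    detect_equivalent(union, first.options.equivalence_tol)
    by_class: dict[int, list[CandidateModel]] = {}
    for cand in union:
        by_class.setdefault(cand.equivalence_class, []).append(cand)
    retained: list[CandidateModel] = []
    merged: dict[str, list[str]] = {}
    for cid in sorted(by_class):
        cls = by_class[cid]
        rep = min(cls, key=lambda c: c.name)
        retained.append(rep)
        if len(cls) > 1:
            merged[rep.name] = sorted(c.name for c in cls if c is not rep)
    retained.sort(key=lambda c: c.name)

    combined = ModelSet(
        candidates=retained,
        sample_cov=first.sample_cov,
        n=first.n,
        options=first.options,
        baseline=first.baseline,
        merged=merged,
    )
    combined.set_priors(None)
    return combined


def replace_name(cand: CandidateModel, name: str) -> CandidateModel:
    return CandidateModel(
        name=name,
        spec=cand.spec,
        modifications=cand.modifications,
        fit=cand.fit,
        indices=cand.indices,
        equivalence_class=cand.equivalence_class,
        flagged=cand.flagged,
        flag_reason=cand.flag_reason,
    )
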