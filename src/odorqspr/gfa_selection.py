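"""Genetic function approximation (GFA) variable selection.

A genetic algorithm evolves a population of small regression equations
whose basis terms are either a descriptor itself or a truncated spline
<knot - descriptor> with the knot placed at an observed training value.
Each candidate equation is least-squares fitted and scored by Friedman's
lack-of-fit (LOF), which penalizes the residual sum of squares by model
size and the smoothness parameter d:

    LOF = LSE / [1 - (c + d*p)/M]^2

with c basis terms, p fitted parameters (coefficients plus knots), and M
training samples.  Evolution is steady-state: two parents picked by
size-2 tournaments on LOF produce a crossover child, which is mutated
with probability p_mut and replaces the worst individual.  The union of
descriptors over the best equations is the reduced pool passed on to
best-subset selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptor_prep import SplineTerm, spline_value

__all__ = [
    "TermSpec",
    "ModelGenome",
    "GFAConfig",
    "lof_score",
    "initialize_population",
    "crossover",
    "mutate",
    "evolve",
    "descriptor_pool",
]


class GFAError(ValueError):
    pass


@dataclass(frozen=True)
class TermSpec:
    """One basis term: a bare descriptor or a spline <knot - descriptor>."""

    descriptor: str
    kind: str  # "linear" | "spline"
    knot: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "spline"):
            raise GFAError(f"unknown term kind {self.kind!r}")
        if self.kind == "spline":
            if self.knot is None or not np.isfinite(self.knot):
                raise GFAError(f"spline term on {self.descriptor!r} needs a finite knot")
        elif self.knot is not None:
            raise GFAError(f"linear term on {self.descriptor!r} must not carry a knot")

    @property
    def label(self) -> str:
        if self.kind == "linear":
            return self.descriptor
        return SplineTerm(self.descriptor, self.knot).label

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        col = X[self.descriptor].to_numpy(dtype=float)
        if self.kind == "linear":
            return col
        return spline_value(SplineTerm(self.descriptor, self.knot), col)


@dataclass
class ModelGenome:
    """A candidate GFA equation with fitted coefficients and LOF score."""

    terms: list[TermSpec]
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    lse: float = np.inf
    lof: float = np.inf

    @property
    def descriptors(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            if t.descriptor not in seen:
                seen.append(t.descriptor)
        return seen

    @property
    def n_knots(self) -> int:
        return sum(1 for t in self.terms if t.kind == "spline")

    def design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))] + [t.evaluate(X) for t in self.terms]
        return np.column_stack(cols)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.design(X) @ self.coefficients

    def report_terms(self) -> str:
        return " + ".join(t.label for t in self.terms)


@dataclass
class GFAConfig:
    """GFA run parameters.

    Defaults follow the study conditions: mutation probability 0.5,
    smoothness d = 1.0, initial equation length 4, no cap on final
    length, 5000 iterations.  ``term_kind`` selects mixed linear+spline
    populations (default) or a single-kind run.
    """

    population_size: int = 100
    iterations: int = 5000
    p_mut: float = 0.5
    d: float = 1.0
    initial_length: int = 4
    max_length: Optional[int] = None
    term_kind: str = "mixed"  # "mixed" | "linear" | "spline"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_mut <= 1.0):
            raise GFAError("p_mut must lie in [0, 1]")
        if self.iterations < 0:
            raise GFAError("iterations must be non-negative")
        if self.term_kind not in ("mixed", "linear", "spline"):
            raise GFAError(f"unknown term_kind {self.term_kind!r}")


def lof_score(lse: float, c: int, p: int, M: int, d: float) -> float:
    """Friedman's lack-of-fit; +inf when the model is overparameterized."""
    if lse < 0:
        raise GFAError("lse must be non-negative")
    denom = 1.0 - (c + d * p) / M
    if denom <= 0:
        return float("inf")
    return lse / denom**2


def _fit(genome: ModelGenome, X: pd.DataFrame, y: np.ndarray, d: float) -> ModelGenome:
    A = genome.design(X)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    lse = float(resid @ resid)
    c = len(genome.terms)
    p = len(coef) + genome.n_knots  # intercept + slopes + knot positions
    genome.coefficients = coef
    genome.lse = lse
    genome.lof = lof_score(lse, c, p, len(y), d)
    return genome


def _random_term(descriptor: str, X: pd.DataFrame, rng: np.random.Generator,
                 term_kind: str) -> TermSpec:
    if term_kind == "mixed":
        kind = "spline" if rng.random() < 0.5 else "linear"
    else:
        kind = term_kind
    if kind == "linear":
        return TermSpec(descriptor, "linear")
    knot = float(rng.choice(X[descriptor].to_numpy(dtype=float)))
    return TermSpec(descriptor, "spline", knot)


def initialize_population(X: pd.DataFrame, y: np.ndarray, cfg: GFAConfig,
                          rng: np.random.Generator | None = None) -> list[ModelGenome]:
    """Random initial population, each genome fitted and LOF-scored."""
    if X.shape[1] < cfg.initial_length:
        raise GFAError(
            f"descriptor pool has {X.shape[1]} columns, fewer than initial length {cfg.initial_length}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cols = list(X.columns)
    pop = []
    for _ in range(cfg.population_size):
        chosen = rng.choice(len(cols), size=cfg.initial_length, replace=False)
        terms = [_random_term(cols[j], X, rng, cfg.term_kind) for j in chosen]
        pop.append(_fit(ModelGenome(terms=terms), X, y, cfg.d))
    return pop


def _dedup(terms: Sequence[TermSpec]) -> list[TermSpec]:
    out: list[TermSpec] = []
    for t in terms:
        if t not in out:
            out.append(t)
    return out


def crossover(a: ModelGenome, b: ModelGenome, rng: np.random.Generator,
              X: pd.DataFrame, y: np.ndarray, d: float,
              max_length: Optional[int] = None, max_retries: int = 10) -> ModelGenome:
    """Single-point splice: prefix of one parent plus suffix of the other.

    Duplicate terms are dropped; an empty child triggers a bounded retry,
    after which the fitter parent is copied.
    """
    if not a.terms or not b.terms:
        raise GFAError("crossover requires non-empty parents")
    for _ in range(max_retries):
        i = int(rng.integers(0, len(a.terms) + 1))
        j = int(rng.integers(0, len(b.terms) + 1))
        terms = _dedup(list(a.terms[:i]) + list(b.terms[j:]))
        if max_length is not None:
            terms = terms[:max_length]
        if terms:
            return _fit(ModelGenome(terms=terms), X, y, d)
    fitter = a if a.lof <= b.lof else b
    return _fit(ModelGenome(terms=list(fitter.terms)), X, y, d)


def mutate(g: ModelGenome, X: pd.DataFrame, y: np.ndarray, p_mut: float,
           rng: np.random.Generator, d: float, term_kind: str = "mixed",
           max_length: Optional[int] = None) -> ModelGenome:
    """With probability p_mut apply one structural mutation and refit.

    The mutation menu: add a term, delete a term (length > 1 only),
    replace a term's descriptor, resample a spline knot (spline terms
    present only), toggle a term between linear and spline.
    """
    if rng.random() >= p_mut:
        return g
    cols = list(X.columns)
    menu = ["add", "replace", "toggle"]
    if len(g.terms) > 1:
        menu.append("delete")
    if any(t.kind == "spline" for t in g.terms):
        menu.append("reknot")
    if max_length is not None and len(g.terms) >= max_length:
        menu.remove("add")
    for _ in range(20):
        op = menu[int(rng.integers(0, len(menu)))]
        terms = list(g.terms)
        if op == "add":
            desc = cols[int(rng.integers(0, len(cols)))]
            terms.append(_random_term(desc, X, rng, term_kind))
        elif op == "delete":
            terms.pop(int(rng.integers(0, len(terms))))
        elif op == "replace":
            i = int(rng.integers(0, len(terms)))
            desc = cols[int(rng.integers(0, len(cols)))]
            t = terms[i]
            knot = (float(rng.choice(X[desc].to_numpy(dtype=float)))
                    if t.kind == "spline" else None)
            terms[i] = TermSpec(desc, t.kind, knot)
        elif op == "reknot":
            idx = [i for i, t in enumerate(terms) if t.kind == "spline"]
            i = idx[int(rng.integers(0, len(idx)))]
            t = terms[i]
            knot = float(rng.choice(X[t.descriptor].to_numpy(dtype=float)))
            terms[i] = TermSpec(t.descriptor, "spline", knot)
        else:  # toggle
            if term_kind != "mixed":
                continue
            i = int(rng.integers(0, len(terms)))
            t = terms[i]
            if t.kind == "linear":
                knot = float(rng.choice(X[t.descriptor].to_numpy(dtype=float)))
                terms[i] = TermSpec(t.descriptor, "spline", knot)
            else:
                terms[i] = TermSpec(t.descriptor, "linear")
        terms = _dedup(terms)
        if terms and terms != list(g.terms):
            return _fit(ModelGenome(terms=terms), X, y, d)
    return g


def evolve(Xtrain: pd.DataFrame, ytrain: np.ndarray, cfg: GFAConfig) -> list[ModelGenome]:
    """Run the steady-state GFA loop; returns the population sorted by LOF."""
    y = np.asarray(ytrain, dtype=float)
    if np.std(y) == 0:
        raise GFAError("response has zero variance")
    rng = np.random.default_rng(cfg.seed)
    pop = initialize_population(Xtrain, y, cfg, rng)
    best = min(p.lof for p in pop)
    for _ in range(cfg.iterations):
        parents = []
        for _ in range(2):
            i, j = rng.integers(0, len(pop), size=2)
            parents.append(pop[i] if pop[i].lof <= pop[j].lof else pop[j])
        child = crossover(parents[0], parents[1], rng, Xtrain, y, cfg.d, cfg.max_length)
        child = mutate(child, Xtrain, y, cfg.p_mut, rng, cfg.d, cfg.term_kind, cfg.max_length)
        worst = max(range(len(pop)), key=lambda i: pop[i].lof)
        pop[worst] = child
        assert min(p.lof for p in pop) <= best + 1e-9
        best = min(best, min(p.lof for p in pop))
    return sorted(pop, key=lambda g: g.lof)


def descriptor_pool(top_models: Sequence[ModelGenome], m: int = 5) -> list[str]:
    """Union of descriptor names over the m best models, rank-ordered."""
    if not top_models:
        raise GFAError("no models supplied")
    if m > len(top_models):
        raise GFAError(f"requested top {m} of only {len(top_models)} models")
    pool: list[str] = []
    for g in list(top_models)[:m]:
        for name in g.descriptors:
            if name not in pool:
                pool.append(name)
    return pool


def term_pool(top_models: Sequence[ModelGenome], m: int = 5) -> list[TermSpec]:
    """Union of distinct terms (with knots) over the m best models.

    Spline terms keep their fitted knots so they can enter best-subset
    selection as fixed transformed columns.
    """
    if not top_models:
        raise GFAError("no models supplied")
    terms: list[TermSpec] = []
    for g in list(top_models)[:m]:
        for t in g.terms:
            if all(t.descriptor != u.descriptor or t.kind != u.kind for u in terms):
                terms.append(t)
    return terms


def model_report(models: Sequence[ModelGenome]) -> pd.DataFrame:
    rows = []
    for rank, g in enumerate(models, start=1):
        rows.append(
            {
                "rank": rank,
                "lof": g.lof,
                "lse": g.lse,
                "terms": g.report_terms(),
                "coefficients": ";".join(f"{c:.6g}" for c in g.coefficients),
            }
        )
    return pd.DataFrame(rows)
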