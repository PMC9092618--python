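"""Synthetic study generator.

Emulates the statistical structure the pipeline assumes so that every
stage can be exercised without external data: a descriptor matrix with
intercorrelated Gaussian blocks plus pathological columns (constant,
near-constant, missing values), and a response built from an intercept,
linear terms and truncated-spline terms <knot - x> with Gaussian noise.
The planted truth is returned alongside the data for recovery scoring.

Defaults mirror the modeled study: 85 compounds, a six-block descriptor
pool, a response mixing linear and spline effects whose signal SD is a
few times the noise SD, and a log(OT)-like intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


from .descriptor_prep import DescriptorMatrix
from .gfa_selection import TermSpec
from .composite_wine import WineComposition

__all__ = ["SyntheticSpec", "make_study", "make_wines"]


class SyntheticError(ValueError):
    pass


#: default planted effect sizes: two linear + two spline terms
_DEFAULT_BETAS = (("linear", 1.2), ("linear", -1.0), ("spline", 1.5), ("spline", -1.2))


def _auto_terms(names: list[str], n_blocks: int) -> list[tuple[TermSpec, float]]:
    """Place the default effects on descriptors in distinct correlation
    blocks (block = column index mod n_blocks) so the planted truth stays
    identifiable despite within-block collinearity."""
    chosen: list[int] = []
    used_blocks: set[int] = set()
    for j in range(len(names)):
        if len(chosen) == len(_DEFAULT_BETAS):
            break
        if (j % n_blocks) not in used_blocks or len(used_blocks) >= n_blocks:
            chosen.append(j)
            used_blocks.add(j % n_blocks)
    if len(chosen) < len(_DEFAULT_BETAS):
        chosen = list(range(min(len(names), len(_DEFAULT_BETAS))))
    return [
        (TermSpec(names[j], kind, 0.0 if kind == "spline" else None), beta)
        for j, (kind, beta) in zip(chosen, _DEFAULT_BETAS)
    ]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic QSPR study.

    ``n_blocks`` informative-descriptor blocks share a latent factor
    giving within-block correlation ``rho``; pathological columns are
    appended after the informative ones.  ``true_terms`` are
    (term, coefficient) pairs; spline knots equal to 0.0 are re-placed
    at the sample quantile ``knot_quantile`` so the truncation is active
    for roughly half the compounds.
    """

    n_compounds: int = 85
    n_descriptors: int = 60
    n_blocks: int = 6
    rho: float = 0.7
    n_constant: int = 2
    n_near_constant: int = 2
    n_missing: int = 2
    true_terms: Optional[list[tuple[TermSpec, float]]] = None
    intercept: float = 3.0
    noise_sd: float = 0.5
    knot_quantile: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_constant, self.n_near_constant, self.n_missing) < 0:
            raise SyntheticError("pathological column counts must be non-negative")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be non-negative")
        if self.n_blocks < 1 or self.n_descriptors < self.n_blocks:
            raise SyntheticError("need at least one descriptor per block")


@dataclass
class PlantedTruth:
    terms: list[tuple[TermSpec, float]]
    intercept: float
    noise_sd: float
    signal: np.ndarray
    descriptors: list[str]


def make_study(spec: SyntheticSpec) -> tuple[pd.DataFrame, DescriptorMatrix, PlantedTruth]:
    """Generate (compound table, descriptor matrix, planted truth).

    The compound table has columns id, name, log_ot.  Informative
    columns are named d00..dNN; pathological columns carry const/near/
    miss prefixes and may not be referenced by ``true_terms``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    names = [f"d{j:02d}" for j in range(p)]

    # correlated blocks: x_j = sqrt(rho) z_block + sqrt(1-rho) eps
    block_of = np.arange(p) % spec.n_blocks
    Z = rng.standard_normal((n, spec.n_blocks))
    X = np.sqrt(spec.rho) * Z[:, block_of] + np.sqrt(1.0 - spec.rho) * rng.standard_normal((n, p))
    df = pd.DataFrame(X, columns=names, index=[f"c{i:03d}" for i in range(n)])

    # resolve default placement and placeholder knots
    base_terms = spec.true_terms if spec.true_terms is not None else _auto_terms(names, spec.n_blocks)
    terms: list[tuple[TermSpec, float]] = []
    for term, beta in base_terms:
        if term.descriptor not in names:
            raise SyntheticError(f"true term references unknown column {term.descriptor!r}")
        if term.kind == "spline" and term.knot == 0.0:
            knot = float(df[term.descriptor].quantile(spec.knot_quantile))
            term = TermSpec(term.descriptor, "spline", knot)
        terms.append((term, beta))

    signal = spec.intercept + sum(beta * t.evaluate(df) for t, beta in terms)
    y = signal + rng.normal(0.0, spec.noise_sd, size=n)

    # pathological columns (never part of the signal)
    patho = {}
    for j in range(spec.n_constant):
        patho[f"const{j:02d}"] = np.full(n, float(j))
    for j in range(spec.n_near_constant):
        patho[f"near{j:02d}"] = 1.0 + 1e-5 * rng.standard_normal(n)
    for j in range(spec.n_missing):
        col = rng.standard_normal(n)
        holes = rng.choice(n, size=max(1, n // 20), replace=False)
        col[holes] = np.nan
        patho[f"miss{j:02d}"] = col
    for name, col in patho.items():
        df[name] = col

    compounds = pd.DataFrame(
        {
            "id": df.index,
            "name": [f"synthetic odorant {i}" for i in range(n)],
            "log_ot": y,
        }
    ).set_index("id", drop=False)
    truth = PlantedTruth(
        terms=terms,
        intercept=spec.intercept,
        noise_sd=spec.noise_sd,
        signal=np.asarray(signal, dtype=float),
        descriptors=sorted({t.descriptor for t, _ in terms}),
    )
    return compounds, DescriptorMatrix(data=df), truth


def make_wines(compound_ids: Sequence[str], n_wines: int = 4,
               components_per_wine: int | Sequence[int] = (42, 42, 45, 45),
               seed: int = 0) -> list[WineComposition]:
    """Random wine compositions: subsets of compounds without replacement.

    ``components_per_wine`` may be one size for all wines or one per
    wine; wines may overlap in composition (as real wines do).
    """
    ids = [str(i) for i in compound_ids]
    if isinstance(components_per_wine, int):
        sizes = [components_per_wine] * n_wines
    else:
        sizes = list(components_per_wine)[:n_wines]
        if len(sizes) < n_wines:
            sizes += [sizes[-1]] * (n_wines - len(sizes))
    if max(sizes) > len(ids):
        raise SyntheticError(
            f"components_per_wine {max(sizes)} exceeds available compounds {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    wines = []
    for w, size in enumerate(sizes):
        members = rng.choice(len(ids), size=size, replace=False)
        wines.append(WineComposition(f"wine{w + 1}", [ids[i] for i in sorted(members)]))
    return wines


def overlap_matrix(wines: Sequence[WineComposition]) -> pd.DataFrame:
    """Pairwise component-overlap counts between wines."""
    ids = [w.wine_id for w in wines]
    sets = [set(w.components) for w in wines]
    mat = [[len(a & b) for b in sets] for a in sets]
    return pd.DataFrame(mat, index=ids, columns=ids)
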