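"""Model specifications and design matrices for the three model families.

Each family writes the mean of a genotype *G* (with m active genes) as the
intercept (the all-mutant phenotype) plus a weighted sum of the terms T that
are subsets of its active genes.  The weight depends only on the family, the
term order k = |T| and the genotype order m:

- additive:  1                       (classical ANOVA with interaction)
- nr:        1 if k == 1 else 1/C(m,k)   (network reconstitution)
- averaging: 1/C(m,k)

The averaging weight is equivalently defined by the recursion
``w(m, m) = 1``, ``w(k, m) = ((m - k) / m) * w(k, m - 1)``, which encodes
"each coefficient is the deviation from the average of the genotypes with one
gene fewer"; :func:`averaging_weight_recursive` implements it exactly (as a
rational) and is kept as an independent cross-check of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .genotypes import GeneUniverse, Genotype, Term, enumerate_genotypes, enumerate_terms

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ModelMatrix",
    "model_weight",
    "averaging_weight_recursive",
    "build_model_matrix",
]

FAMILIES = ("additive", "nr", "averaging")

#: term-label separator per family (":" additive/NR, ";" averaging)
SEPARATORS = {"additive": ":", "nr": ":", "averaging": ";"}


def model_weight(family: str, k: int, m: int) -> float:
    """Design weight of an order-k term in an order-m genotype (1 <= k <= m)."""
    return float(model_weight_exact(family, k, m))


def model_weight_exact(family: str, k: int, m: int) -> Fraction:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if k < 1:
        raise ValueError(f"term order must be >= 1, got {k}")
    if k > m:
        raise ValueError(f"term order {k} exceeds genotype order {m}")
    if family == "additive":
        return Fraction(1)
    if family == "nr" and k == 1:
        return Fraction(1)
    return Fraction(1, comb(m, k))


@lru_cache(maxsize=None)
def averaging_weight_recursive(k: int, m: int) -> Fraction:
    """Averaging weight by its defining recursion, exact rationals.

    w(m, m) = 1; w(k, m) = ((m - k) / m) * w(k, m - 1).
    """
    if not 1 <= k <= m:
        raise ValueError(f"need 1 <= k <= m, got k={k}, m={m}")
    if k == m:
        return Fraction(1)
    return Fraction(m - k, m) * averaging_weight_recursive(k, m - 1)


@dataclass(frozen=True)
class ModelSpec:
    """A model family over a gene universe, truncated at `max_order`.

    The full model (max_order = n) has one term per nonempty gene subset and
    its 2^n x 2^n design matrix over the genotype lattice is invertible.
    """

    family: str
    universe: GeneUniverse
    max_order: int = 0  # 0 -> full model (resolved in __post_init__)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.max_order == 0:
            object.__setattr__(self, "max_order", self.universe.n)
        if not 1 <= self.max_order <= self.universe.n:
            raise ValueError(
                f"max_order must be in [1, {self.universe.n}], got {self.max_order}"
            )

    @property
    def n(self) -> int:
        return self.universe.n

    @property
    def is_full(self) -> bool:
        return self.max_order == self.universe.n

    @property
    def terms(self) -> list[Term]:
        return enumerate_terms(self.universe, self.max_order)

    @property
    def separator(self) -> str:
        return SEPARATORS[self.family]

    def term_labels(self) -> list[str]:
        sep = self.separator
        return [t.label(sep) for t in self.terms]

    def reduce(self, new_max_order: int) -> "ModelSpec":
        """Truncate the term list at a lower order (model reduction)."""
        if not 1 <= new_max_order <= self.max_order:
            raise ValueError(
                f"new_max_order must be in [1, {self.max_order}], got {new_max_order}"
            )
        return ModelSpec(self.family, self.universe, new_max_order)


@dataclass
class ModelMatrix:
    """Dense design matrix over the genotype lattice.

    Rows are the 2^n genotypes in canonical order, columns are the intercept
    followed by the model terms in canonical order.  For a full model the
    matrix is lower-triangular with unit diagonal (hence invertible) because
    a term can only appear in genotypes that contain it.
    """

    spec: ModelSpec
    genotypes: list[Genotype]
    terms: list[Term]
    values: np.ndarray  # shape (2^n, 1 + n_terms)

    @property
    def column_labels(self) -> list[str]:
        sep = self.spec.separator
        return ["intercept"] + [t.label(sep) for t in self.terms]

    @property
    def row_labels(self) -> list[str]:
        return [str(g) for g in self.genotypes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.column_labels)

    def design_rows(self, genotypes: list[Genotype]) -> np.ndarray:
        """Observation-expanded design: one row per entry of `genotypes`."""
        lookup = {g.mask: i for i, g in enumerate(self.genotypes)}
        idx = np.array([lookup[g.mask] for g in genotypes])
        return self.values[idx]


def build_model_matrix(spec: ModelSpec) -> ModelMatrix:
    """Build the dense design matrix of `spec` over all 2^n genotypes.

    entry(G, T) = model_weight(family, |T|, |active(G)|) if T is a subset of
    G's active genes, else 0; the intercept column is all ones.  Weights are
    computed as exact rationals and converted to float once, so large binomial
    denominators do not accumulate drift.
    """
    genotypes = enumerate_genotypes(spec.universe)
    terms = spec.terms
    n_rows, n_terms = len(genotypes), len(terms)
    mat = np.zeros((n_rows, 1 + n_terms))
    mat[:, 0] = 1.0
    # float weights indexed by (k, m); exact rational underneath
    wt = {}
    for m in range(1, spec.n + 1):
        for k in range(1, min(m, spec.max_order) + 1):
            wt[(k, m)] = float(model_weight_exact(spec.family, k, m))
    for i, g in enumerate(genotypes):
        m = g.order
        if m == 0:
            continue
        for j, t in enumerate(terms):
            if t.mask & ~g.mask:
                continue  # term not contained in the active set
            mat[i, 1 + j] = wt[(t.order, m)]
    return ModelMatrix(spec=spec, genotypes=genotypes, terms=terms, values=mat)
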