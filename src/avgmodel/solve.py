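"""Exact, noise-free conversion between genotype means and model coefficients.

With one mean phenotype per genotype and a full model (max_order = n) the
design matrix over the 2^n-genotype lattice is square, lower-triangular in
canonical order, and unit-diagonal, so coefficients are obtained by a forward
triangular solve -- no least squares, no conditioning worries.  The intercept
of the solved model is always the phenotype of the most disrupted (all-mutant)
genotype; that reference is what makes wild-type allele effects mechanistically
interpretable.  Mutant-allele effects (the conventional coding against the
wild type) are obtained by relabelling every genotype by its complement
(:func:`recode_to_mutant`) and solving the same model.

Two independent closed forms are provided as oracles against the triangular
solve: Moebius inversion over the subset lattice for the additive family, and
the deviation-from-the-average-of-one-gene-fewer definition for the averaging
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .design import ModelSpec, build_model_matrix
from .genotypes import GeneUniverse, Genotype, Term, enumerate_genotypes, parse_genotype

__all__ = [
    "MeanTable",
    "CoefficientVector",
    "solve_means",
    "predict_means",
    "averaging_coef_direct",
    "mobius_additive_oracle",
    "recode_to_mutant",
]


@dataclass
class MeanTable:
    """One phenotype mean per genotype, complete over a universe.

    Stored as a vector in canonical genotype order; indexable by
    :class:`Genotype` or genotype string.
    """

    universe: GeneUniverse
    values: np.ndarray  # canonical genotype order, length 2^n

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2**self.universe.n,):
            raise ValueError(
                f"means must have one value per genotype "
                f"(expected {2**self.universe.n}, got {self.values.shape})"
            )

    @classmethod
    def from_dict(cls, universe: GeneUniverse, means: Mapping) -> "MeanTable":
        """Build from a mapping keyed by Genotype or genotype string."""
        by_mask: dict[int, float] = {}
        for key, val in means.items():
            g = key if isinstance(key, Genotype) else parse_genotype(str(key), universe)
            by_mask[g.mask] = float(val)
        genotypes = enumerate_genotypes(universe)
        missing = [str(g) for g in genotypes if g.mask not in by_mask]
        if missing:
            raise ValueError(f"incomplete mean table; missing genotypes: {missing}")
        return cls(universe, np.array([by_mask[g.mask] for g in genotypes]))

    @property
    def genotypes(self) -> list[Genotype]:
        return enumerate_genotypes(self.universe)

    @property
    def _index(self) -> dict[int, int]:
        idx = getattr(self, "_index_cache", None)
        if idx is None:
            idx = {g.mask: i for i, g in enumerate(self.genotypes)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def __getitem__(self, key) -> float:
        g = key if isinstance(key, Genotype) else parse_genotype(str(key), self.universe)
        return float(self.values[self._index[g.mask]])

    def value_of_mask(self, mask: int) -> float:
        try:
            return float(self.values[self._index[mask]])
        except KeyError:
            raise KeyError(f"no genotype with mask {mask} in the mean table") from None

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=[str(g) for g in self.genotypes], name="mean")


@dataclass
class CoefficientVector:
    """Intercept plus one value per model term, in the spec's canonical order."""

    spec: ModelSpec
    intercept: float
    values: np.ndarray  # one per term, canonical order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_terms = len(self.spec.terms)
        if self.values.shape != (n_terms,):
            raise ValueError(f"expected {n_terms} term values, got {self.values.shape}")

    @classmethod
    def from_dict(
        cls, spec: ModelSpec, coefficients: Mapping, intercept: float = 0.0
    ) -> "CoefficientVector":
        """Build from {Term or label: value}; unlisted terms are zero."""
        by_mask: dict[int, float] = {}
        for key, val in coefficients.items():
            if isinstance(key, Term):
                t = key
            else:
                genes = [c for c in str(key) if c not in ":;"]
                t = Term.from_genes(spec.universe, genes)
            by_mask[t.mask] = float(val)
        vals = np.array([by_mask.get(t.mask, 0.0) for t in spec.terms])
        return cls(spec, float(intercept), vals)

    def __getitem__(self, key) -> float:
        if isinstance(key, Term):
            mask = key.mask
        else:
            genes = [c for c in str(key) if c not in ":;"]
            mask = Term.from_genes(self.spec.universe, genes).mask
        for t, v in zip(self.spec.terms, self.values):
            if t.mask == mask:
                return float(v)
        raise KeyError(key)

    @property
    def full(self) -> np.ndarray:
        """Intercept-prepended coefficient array matching the design columns."""
        return np.concatenate([[self.intercept], self.values])

    def to_series(self) -> pd.Series:
        labels = ["intercept"] + self.spec.term_labels()
        return pd.Series(self.full, index=labels, name="estimate")


def solve_means(spec: ModelSpec, means: MeanTable) -> CoefficientVector:
    """Solve the full model exactly from one mean per genotype.

    Requires ``spec.max_order == n`` (square system).  The canonical-order
    design matrix is lower-triangular with unit diagonal, so the solution is a
    forward substitution; the intercept equals the all-mutant genotype's mean.
    """
    if not spec.is_full:
        raise ValueError(
            "exact solving requires the full model (max_order = n); "
            "fit reduced models by least squares via MultiGeneModel"
        )
    if means.universe.genes != spec.universe.genes:
        raise ValueError("mean table universe does not match the model spec")
    mm = build_model_matrix(spec)
    coef = solve_triangular(mm.values, means.values, lower=True, unit_diagonal=True)
    return CoefficientVector(spec, float(coef[0]), coef[1:])


def predict_means(spec: ModelSpec, coefficients: CoefficientVector) -> MeanTable:
    """Genotype means implied by a coefficient vector (inverse of solve_means)."""
    if coefficients.spec.family != spec.family or coefficients.spec.universe.genes != spec.universe.genes:
        raise ValueError("coefficient vector does not match the model spec")
    if len(coefficients.values) != len(spec.terms):
        raise ValueError("coefficient vector term list does not match the spec")
    mm = build_model_matrix(spec)
    return MeanTable(spec.universe, mm.values @ coefficients.full)


def _subset_masks(mask: int) -> Iterable[int]:
    """All submasks of `mask` (including 0 and mask itself)."""
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


def averaging_coef_direct(subset, means: MeanTable) -> float:
    """Averaging coefficient straight from its definition.

    For a gene set S (in the otherwise-mutant background):
    coef(S) = G(S) - (1/|S|) * sum over the |S| subsets T of S with one gene
    fewer of G(T).  For |S| = 1 this is G({g}) - G(empty): the 1-gene effect
    against the most disrupted state.
    """
    t = subset if isinstance(subset, Term) else Term.from_genes(means.universe, list(subset))
    g_s = means.value_of_mask(t.mask)
    if t.order == 0:
        raise ValueError("subset must be nonempty")
    drops = [t.mask & ~(1 << i) for i in range(means.universe.n) if t.mask >> i & 1]
    return g_s - sum(means.value_of_mask(d) for d in drops) / t.order


def mobius_additive_oracle(subset, means: MeanTable) -> float:
    """Additive coefficient by Moebius inversion over the subset lattice.

    coef(S) = sum over T subset of S of (-1)^(|S|-|T|) G(T).  Independent of
    the triangular solve; used as an oracle for the additive family.
    """
    t = subset if isinstance(subset, Term) else Term.from_genes(means.universe, list(subset))
    s_order = t.order
    total = 0.0
    for sub in _subset_masks(t.mask):
        sign = -1.0 if (s_order - sub.bit_count()) % 2 else 1.0
        total += sign * means.value_of_mask(sub)
    return total


def recode_to_mutant(means: MeanTable) -> MeanTable:
    """Relabel each genotype by its complement (active *mutant* set).

    The reference genotype then becomes the all-wild-type one, so solving the
    additive model on the recoded table yields the conventional mutant-allele
    effects (a, b, c, ...).  The operation is an involution.
    """
    genotypes = means.genotypes
    by_mask = {g.mask: means.values[i] for i, g in enumerate(genotypes)}
    flipped = np.array([by_mask[g.complement().mask] for g in genotypes])
    return MeanTable(means.universe, flipped)
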