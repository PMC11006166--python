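"""Genotype and term algebra over the subset lattice of an n-gene universe.

A genotype of an n-gene system is identified with the subset of genes carrying
the active (wild-type) allele; all other genes carry the null mutant allele.
Genotypes and model terms are therefore subsets of an ordered gene universe,
and both are kept in a canonical order -- by subset size, then lexicographic
position within the universe -- so that design matrices built from them are
lower-triangular and all outputs are reproducible.

Two text dialects are understood, matching common usage in combinatorial
genetics:

- *full*: one character per gene in universe order, case encoding the allele
  state, e.g. ``"ABc"`` for active A and B, mutant C;
- *omission*: only the active genes listed, e.g. ``"AB"``; the all-mutant
  genotype is written ``"-"`` (or the empty string).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

__all__ = [
    "GeneUniverse",
    "Genotype",
    "Term",
    "parse_genotype",
    "enumerate_genotypes",
]

MAX_GENES = 16  # dense 2^n enumeration must stay in memory


class GenotypeParseError(ValueError):
    """Raised when a genotype string cannot be interpreted over a universe."""


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of single-letter gene labels, e.g. ``A,B,C`` or ``J,E,P,S``."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not 1 <= len(genes) <= MAX_GENES:
            raise ValueError(f"universe must have 1..{MAX_GENES} genes, got {len(genes)}")
        for g in genes:
            if len(g) != 1 or g not in string.ascii_uppercase:
                raise ValueError(f"gene labels must be single uppercase letters, got {g!r}")
        if len({g.upper() for g in genes}) != len(genes):
            raise ValueError(f"gene labels must be unique: {genes}")

    @classmethod
    def from_string(cls, text: str | int) -> "GeneUniverse":
        """Build from a label string like ``"JEPS"``, or from an integer n
        (first n letters of the alphabet, handy for simulations)."""
        if isinstance(text, int) or (isinstance(text, str) and text.isdigit()):
            n = int(text)
            return cls(tuple(string.ascii_uppercase[:n]))
        return cls(tuple(text.upper()))

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self.genes.index(gene.upper())
        except ValueError:
            raise KeyError(f"gene {gene!r} not in universe {''.join(self.genes)}") from None

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        return "".join(self.genes)

    def drop(self, gene: str) -> "GeneUniverse":
        """Universe with one gene removed (used when bundling a gene away)."""
        i = self.index(gene)
        return GeneUniverse(self.genes[:i] + self.genes[i + 1 :])

    def subset_mask(self, genes: Sequence[str]) -> int:
        mask = 0
        for g in genes:
            bit = 1 << self.index(g)
            if mask & bit:
                raise GenotypeParseError(f"gene {g!r} duplicated")
            mask |= bit
        return mask


def _mask_genes(universe: GeneUniverse, mask: int) -> tuple[str, ...]:
    return tuple(g for i, g in enumerate(universe.genes) if mask >> i & 1)


@dataclass(frozen=True, order=False)
class Genotype:
    """A genotype: the subset of a universe carrying the wild-type allele."""

    universe: GeneUniverse
    mask: int  # bit i set <=> universe.genes[i] is active

    def __post_init__(self) -> None:
        if not 0 <= self.mask < (1 << self.universe.n):
            raise ValueError("active set is not a subset of the universe")

    @classmethod
    def from_genes(cls, universe: GeneUniverse, genes: Sequence[str]) -> "Genotype":
        return cls(universe, universe.subset_mask(genes))

    @property
    def active(self) -> tuple[str, ...]:
        """Active (wild-type) genes in universe order."""
        return _mask_genes(self.universe, self.mask)

    @property
    def order(self) -> int:
        return self.mask.bit_count()

    def complement(self) -> "Genotype":
        """Genotype whose active set is the set of *mutant* genes of this one."""
        return Genotype(self.universe, self.mask ^ ((1 << self.universe.n) - 1))

    def drop_gene(self, gene: str) -> "Genotype":
        """Relabel over the universe without `gene` (allele state discarded)."""
        i = self.universe.index(gene)
        low = self.mask & ((1 << i) - 1)
        high = (self.mask >> (i + 1)) << i
        return Genotype(self.universe.drop(gene), low | high)

    def format(self, dialect: str = "omission") -> str:
        if dialect == "omission":
            return "".join(self.active) or "-"
        if dialect == "full":
            return "".join(
                g if self.mask >> i & 1 else g.lower() for i, g in enumerate(self.universe.genes)
            )
        raise ValueError(f"unknown dialect {dialect!r}")

    def __str__(self) -> str:
        return self.format()

    def __repr__(self) -> str:
        return f"Genotype({self.format()!r} over {self.universe})"

    def sort_key(self) -> tuple[int, tuple[int, ...]]:
        return (self.order, tuple(i for i in range(self.universe.n) if self.mask >> i & 1))


@dataclass(frozen=True)
class Term:
    """A model term: a nonempty gene subset (the intercept is not a Term)."""

    universe: GeneUniverse
    mask: int

    def __post_init__(self) -> None:
        if self.mask == 0:
            raise ValueError("a term must involve at least one gene; the intercept is held separately")
        if self.mask >= 1 << self.universe.n:
            raise ValueError("term subset is not a subset of the universe")

    @classmethod
    def from_genes(cls, universe: GeneUniverse, genes: Sequence[str]) -> "Term":
        return cls(universe, universe.subset_mask(genes))

    @property
    def genes(self) -> tuple[str, ...]:
        return _mask_genes(self.universe, self.mask)

    @property
    def order(self) -> int:
        return self.mask.bit_count()

    def label(self, sep: str = ";") -> str:
        """Field notation: ':' joins additive/NR interactions, ';' averaging."""
        return sep.join(self.genes)

    def __str__(self) -> str:
        return self.label()

    def __repr__(self) -> str:
        return f"Term({self.label()!r})"

    def sort_key(self) -> tuple[int, tuple[int, ...]]:
        return (self.order, tuple(i for i in range(self.universe.n) if self.mask >> i & 1))


def parse_genotype(text: str, universe: GeneUniverse, dialect: str | None = None) -> Genotype:
    """Parse a genotype string over `universe`.

    Dialect is auto-detected per token unless forced: *full* iff the string has
    one character per gene and the characters match the universe order
    case-insensitively; otherwise *omission* (only active genes listed, ``"-"``
    or ``""`` for the all-mutant genotype).

    Parameters
    ----------
    text : str
        The genotype token, e.g. ``"ABc"``, ``"AB"``, ``"-"``.
    universe : GeneUniverse
    dialect : {"full", "omission", None}
        Force a dialect instead of auto-detecting.
    """
    token = text.strip()
    if dialect not in (None, "full", "omission"):
        raise ValueError(f"unknown dialect {dialect!r}")

    def _is_full(tok: str) -> bool:
        return len(tok) == universe.n and all(
            c.upper() == g for c, g in zip(tok, universe.genes)
        )

    use = dialect
    if use is None:
        if token in ("-", ""):
            use = "omission"
        elif _is_full(token):
            use = "full"
        else:
            # a full-length permutation of the universe is a malformed full
            # string, not an omission genotype; force omission to accept it
            if len(token) == universe.n and sorted(c.upper() for c in token) == sorted(
                universe.genes
            ):
                raise GenotypeParseError(
                    f"genotype {token!r} has one character per gene of {universe} but not in "
                    "universe order; full-dialect strings must follow it "
                    "(pass dialect='omission' to parse as an active-gene list)"
                )
            use = "omission"

    if use == "full":
        if len(token) != universe.n:
            raise GenotypeParseError(
                f"full-dialect genotype {token!r} must have one character per gene of {universe}"
            )
        mask = 0
        for i, (c, g) in enumerate(zip(token, universe.genes)):
            if c.upper() != g:
                raise GenotypeParseError(
                    f"genotype {token!r}: position {i} is {c!r}, expected allele of gene {g!r}"
                    " (full-dialect strings must follow universe order)"
                )
            if c.isupper():
                mask |= 1 << i
        return Genotype(universe, mask)

    # omission dialect
    if token in ("-", ""):
        return Genotype(universe, 0)
    mask = 0
    for c in token:
        if c.upper() not in universe:
            raise GenotypeParseError(f"genotype {token!r}: unknown gene {c!r} for universe {universe}")
        bit = 1 << universe.index(c)
        if mask & bit:
            raise GenotypeParseError(f"genotype {token!r}: gene {c.upper()!r} duplicated")
        mask |= bit
    return Genotype(universe, mask)


def enumerate_genotypes(universe: GeneUniverse) -> list[Genotype]:
    """All 2^n genotypes in canonical order (by active-set size, then
    lexicographic); first is the all-mutant genotype, last the all-wild-type."""
    out: list[Genotype] = []
    idx = range(universe.n)
    for k in range(universe.n + 1):
        for combo in combinations(idx, k):
            mask = 0
            for i in combo:
                mask |= 1 << i
            out.append(Genotype(universe, mask))
    return out


def enumerate_terms(universe: GeneUniverse, max_order: int) -> list[Term]:
    """All nonempty subsets with size <= max_order, canonical order."""
    out: list[Term] = []
    idx = range(universe.n)
    for k in range(1, max_order + 1):
        for combo in combinations(idx, k):
            mask = 0
            for i in combo:
                mask |= 1 << i
            out.append(Term(universe, mask))
    return out
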