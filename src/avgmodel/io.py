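"""Reading and writing the package's delimited text formats.

The domain has no binary standard for genotype-phenotype tables, so all
inputs and outputs are plain delimited text (TSV by default, CSV accepted by
extension or explicit separator).  Genotype strings in inputs may use either
dialect; outputs always use the omission dialect and keep a deterministic
term order (by interaction order, then lexicographic) with the field's
separator convention -- ":" joins additive/NR interaction labels, ";" joins
averaging ones.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .genotypes import GeneUniverse, GenotypeParseError, parse_genotype
from .simulate import SimulationSummary

__all__ = [
    "read_phenotype_table",
    "write_coefficient_table",
    "read_coefficient_table",
    "write_summary",
    "write_matrix",
]

logger = logging.getLogger("avgmodel")


def _sep_for(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_phenotype_table(
    path,
    genes,
    dialect: str | None = None,
    sep: str | None = None,
    genotype_col: str = "genotype",
    value_col: str = "value",
) -> pd.DataFrame:
    """Read and validate a long-format phenotype table.

    Requires `genotype` and `value` columns; genotype strings are parsed over
    the universe (reporting the offending row on failure) and rewritten in
    canonical omission dialect; values must be numeric.  Per-genotype
    observation counts are logged.
    """
    universe = genes if isinstance(genes, GeneUniverse) else GeneUniverse.from_string(genes)
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.empty:
        raise ValueError(f"{path}: empty table")
    for col in (genotype_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing (have {list(df.columns)})")
    canonical = []
    for i, tok in enumerate(df[genotype_col]):
        try:
            canonical.append(str(parse_genotype(str(tok), universe, dialect)))
        except GenotypeParseError as e:
            raise GenotypeParseError(f"{path}: row {i + 2}: {e}") from None
    df[genotype_col] = canonical
    try:
        df[value_col] = pd.to_numeric(df[value_col], errors="raise")
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: non-numeric phenotype value: {e}") from None
    counts = df[genotype_col].value_counts()
    logger.info(
        "read %d observations of %d genotypes from %s (min %d, max %d per genotype)",
        len(df), counts.size, path, counts.min(), counts.max(),
    )
    return df


def write_coefficient_table(table: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a coefficient table (from MultiGeneResults.to_frame or a solved
    CoefficientVector rendered as a frame) as delimited text."""
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_coefficient_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path, sep))


def write_summary(summary: SimulationSummary, path, sep: str | None = None) -> None:
    """Write a simulation summary (family, term, order, quartiles, IQR)."""
    path = Path(path)
    summary.to_frame().to_csv(path, sep=_sep_for(path, sep), index=False)


def write_matrix(frame: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a design matrix with genotype row labels and term column labels."""
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path, sep), index=True, index_label="genotype")
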