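"""Monte-Carlo studies and a synthetic replicated-data generator.

Two simulation tools live here:

- :func:`run_uniform_study` -- the model-stability study: draw one mean per
  genotype from a uniform distribution, solve each model family exactly, and
  summarize the per-term coefficient distributions across many repeats.  With
  a limited phenotype range the additive family's high-order interactions blow
  up (at n=7 the 7-gene interaction's IQR is ~7.5x the 1-gene effects') while
  the averaging family's stay homogeneous across orders.
- :func:`generate_replicated_data` -- synthetic long-format phenotype tables
  with known true coefficients, Gaussian residual noise, nested random
  intercepts (e.g. replicate/flat/pot) and optional two-level treatment
  structure, for exercising and validating the statistical fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import FAMILIES, ModelSpec, build_model_matrix
from .genotypes import GeneUniverse, enumerate_genotypes
from .solve import CoefficientVector, predict_means

__all__ = [
    "StudyConfig",
    "SimulationSummary",
    "run_uniform_study",
    "iqr_ratio",
    "SyntheticDataConfig",
    "generate_replicated_data",
]


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the uniform-random stability study.

    Defaults are the study's standard conditions: a 7-gene system, 10,000
    repeats, genotype means drawn from Uniform(1, 10).
    """

    n_genes: int = 7
    n_reps: int = 10_000
    low: float = 1.0
    high: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.low < self.high:
            raise ValueError("need low < high")


@dataclass
class SimulationSummary:
    """Per-family, per-term quartile summaries across Monte-Carlo repeats.

    Each family maps to a DataFrame with columns
    term, order, q25, q50, q75, iqr, whisker_low, whisker_high
    (whiskers use the plotting convention of 1.5*IQR beyond the quartiles,
    clipped to the observed range; acceptance statistics use quartiles only).
    The model intercept is excluded from the summary.
    """

    study: StudyConfig
    frames: dict[str, pd.DataFrame]
    samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def frame(self, family: str) -> pd.DataFrame:
        try:
            return self.frames[family]
        except KeyError:
            raise KeyError(f"family {family!r} not in summary ({sorted(self.frames)})") from None

    def order_mean_iqr(self, family: str, order: int) -> float:
        """Mean IQR across all terms of a given interaction order."""
        df = self.frame(family)
        sel = df[df["order"] == order]
        if sel.empty:
            raise KeyError(f"no terms of order {order} for family {family!r}")
        return float(sel["iqr"].mean())

    def to_frame(self) -> pd.DataFrame:
        out = []
        for fam, df in self.frames.items():
            d = df.copy()
            d.insert(0, "family", fam)
            out.append(d)
        return pd.concat(out, ignore_index=True)


def run_uniform_study(
    study: StudyConfig, families: Sequence[str] = FAMILIES, keep_samples: bool = False
) -> SimulationSummary:
    """Run the uniform-random model-stability study.

    Per repeat, one mean per genotype is drawn independently from
    Uniform(low, high) in canonical genotype order; each requested family's
    full model is solved exactly on the *same* draws (so 1-gene effect samples
    are identical across families, their formulas coinciding), and coefficient
    samples are accumulated.  Bit-reproducible for a fixed seed and rep count.
    """
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
    universe = GeneUniverse.from_string(study.n_genes)
    n_genotypes = 2**universe.n
    rng = np.random.default_rng(study.seed)
    means = rng.uniform(study.low, study.high, size=(study.n_reps, n_genotypes))

    frames: dict[str, pd.DataFrame] = {}
    samples: dict[str, np.ndarray] = {}
    for fam in families:
        spec = ModelSpec(fam, universe)
        mm = build_model_matrix(spec)
        # coefficient samples for all repeats at once: M c = y  =>  c = y M^-T
        inv = np.linalg.inv(mm.values)
        coefs = means @ inv.T  # (reps, 1 + n_terms)
        term_coefs = coefs[:, 1:]  # intercept excluded from summaries
        q25, q50, q75 = np.percentile(term_coefs, [25, 50, 75], axis=0)
        iqr = q75 - q25
        lo = np.maximum(term_coefs.min(axis=0), q25 - 1.5 * iqr)
        hi = np.minimum(term_coefs.max(axis=0), q75 + 1.5 * iqr)
        frames[fam] = pd.DataFrame(
            {
                "term": [t.label(spec.separator) for t in spec.terms],
                "order": [t.order for t in spec.terms],
                "q25": q25,
                "q50": q50,
                "q75": q75,
                "iqr": iqr,
                "whisker_low": lo,
                "whisker_high": hi,
            }
        )
        if keep_samples:
            samples[fam] = term_coefs
    return SimulationSummary(study=study, frames=frames, samples=samples)


def iqr_ratio(
    summary: SimulationSummary,
    family: str,
    numerator_order: int,
    denominator_order: int | None = None,
    vs_range: bool = False,
) -> float:
    """Ratio of coefficient IQRs between interaction orders.

    Numerator: mean IQR across the family's terms of `numerator_order` (a
    single term when that order is n).  Denominator: mean IQR across terms of
    `denominator_order`, or the phenotype range high - low if ``vs_range``.
    """
    num = summary.order_mean_iqr(family, numerator_order)
    if vs_range:
        if denominator_order is not None:
            raise ValueError("give either denominator_order or vs_range, not both")
        return num / (summary.study.high - summary.study.low)
    if denominator_order is None:
        raise ValueError("denominator_order required unless vs_range=True")
    return num / summary.order_mean_iqr(family, denominator_order)


@dataclass
class SyntheticDataConfig:
    """Generator settings for synthetic replicated phenotype tables.

    The generated layout mimics a replicated combinatorial-knockout
    experiment: each top-level replicate contains every genotype; within a
    replicate, genotypes are laid out in flats of `flat_size` pots, one
    genotype per pot, with `obs_per_pot` measurements per pot.  Random
    intercepts are drawn per level of `random_sds` (an ordered mapping,
    outermost first, e.g. {"replicate": .., "flat": .., "pot": ..}); with a
    single observation per pot the innermost level is confounded with the
    residual, which is the realistic situation the mixed model must cope with.

    `treatment_effects`, if given, is a second coefficient vector whose
    predicted means are the genotype-specific (treated - control) shifts; both
    treatment levels are then observed in every pot.
    """

    spec: ModelSpec
    coefficients: CoefficientVector
    residual_sd: float = 0.5
    n_replicates: int = 3
    random_sds: Mapping[str, float] = field(default_factory=dict)
    flat_size: int = 8
    obs_per_pot: int = 1
    treatment_effects: CoefficientVector | None = None
    treatment_levels: tuple[str, str] = ("control", "treated")
    dropout: float = 0.0  # per-observation drop probability (unbalanced data)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or any(sd < 0 for sd in self.random_sds.values()):
            raise ValueError("standard deviations must be >= 0")
        if self.n_replicates < 1 or self.obs_per_pot < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def generate_replicated_data(cfg: SyntheticDataConfig) -> pd.DataFrame:
    """Generate a long-format phenotype table from known coefficients.

    Returns a DataFrame with columns ``genotype`` (omission dialect),
    ``value``, one column per random-effect level in `cfg.random_sds`, and
    ``treatment`` if treatment effects are configured.  Observation =
    predicted genotype mean (+ treatment shift if treated) + nested random
    intercepts + Gaussian residual.  Reproducible under `cfg.seed`; with all
    noise at zero the observations equal the predicted means exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec
    means = predict_means(ModelSpec(spec.family, spec.universe), cfg.coefficients)
    shift = None
    if cfg.treatment_effects is not None:
        shift = predict_means(ModelSpec(spec.family, spec.universe), cfg.treatment_effects)
    genotypes = enumerate_genotypes(spec.universe)
    levels = list(cfg.random_sds)
    if len(levels) > 3:
        raise ValueError("at most three nesting levels (replicate/flat/pot) are supported")

    rows: list[dict] = []
    for rep in range(1, cfg.n_replicates + 1):
        rep_label = f"R{rep}"
        rep_off = rng.normal(0.0, cfg.random_sds[levels[0]]) if len(levels) >= 1 else 0.0
        n_flats = (len(genotypes) + cfg.flat_size - 1) // cfg.flat_size
        flat_offs = (
            rng.normal(0.0, cfg.random_sds[levels[1]], size=n_flats) if len(levels) >= 2 else None
        )
        for gi, g in enumerate(genotypes):
            flat = gi // cfg.flat_size
            pot_off = rng.normal(0.0, cfg.random_sds[levels[2]]) if len(levels) >= 3 else 0.0
            base = means.values[gi] + rep_off + pot_off
            if flat_offs is not None:
                base += flat_offs[flat]
            labels = {}
            if len(levels) >= 1:
                labels[levels[0]] = rep_label
            if len(levels) >= 2:
                labels[levels[1]] = f"{rep_label}.F{flat + 1}"
            if len(levels) >= 3:
                labels[levels[2]] = f"{rep_label}.P{gi + 1}"
            for _ in range(cfg.obs_per_pot):
                if shift is None:
                    rows.append(
                        {"genotype": str(g), "value": base + rng.normal(0.0, cfg.residual_sd)}
                        | labels
                    )
                else:
                    for li, level_name in enumerate(cfg.treatment_levels):
                        delta = shift.values[gi] if li == 1 else 0.0
                        rows.append(
                            {
                                "genotype": str(g),
                                "value": base + delta + rng.normal(0.0, cfg.residual_sd),
                                "treatment": level_name,
                            }
                            | labels
                        )
    df = pd.DataFrame(rows)
    if cfg.dropout > 0:
        keep = rng.uniform(size=len(df)) >= cfg.dropout
        # never drop a genotype (or genotype x treatment cell) entirely
        group_cols = ["genotype"] + (["treatment"] if shift is not None else [])
        for _, idx in df.groupby(group_cols).groups.items():
            if not keep[df.index.get_indexer(idx)].any():
                keep[df.index.get_indexer(idx)[0]] = True
        df = df[keep].reset_index(drop=True)
    return df
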