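"""Statistical fitting of the model families to replicated phenotype data.

The central objects follow the familiar model/results pattern:

>>> m = MultiGeneModel(df, genes="JEPS", family="averaging",
...                    random="replicate/flat/pot")
>>> res = m.fit()
>>> res.summary()

:class:`MultiGeneModel` binds a long-format phenotype table to a model
specification (family, universe, maximum interaction order) and optional
nested random-effect and treatment structure.  ``fit()`` performs ordinary
least squares on the observation-expanded design matrix, or REML-fitted
nested random intercepts when a random hierarchy is declared, and returns a
:class:`MultiGeneResults` carrying estimates, standard errors, t-based 95%
confidence intervals and Holm-corrected p-values over the non-intercept
terms.

The full models of the three families are reparameterizations of the same
genotype cell-means model, so their fitted values and residuals on the same
data are identical; the families differ only in how those fitted values are
decomposed into effects and interactions.

Gene-inclusion screening (:func:`screen_genes`) and bundling of an
insignificant gene (:func:`bundle_gene`) implement the pre-modelling step:
for each gene, all 2^(n-1) background contrasts "adding the gene" are
t-tested against zero and Benjamini-Hochberg corrected; a gene with no
significant contrast is dropped, and the data are collapsed over its allele
states before the model of interest is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, build_model_matrix
from .genotypes import GeneUniverse, Genotype, enumerate_genotypes, parse_genotype
from .multitest import bh_adjust, holm_adjust
from .solve import CoefficientVector

__all__ = [
    "MultiGeneModel",
    "MultiGeneResults",
    "screen_genes",
    "GeneScreenResult",
    "bundle_gene",
]


class FitError(RuntimeError):
    """Raised when a model cannot be estimated from the supplied data."""


def _parse_random(random) -> list[str]:
    if random is None:
        return []
    if isinstance(random, str):
        return [c for c in random.split("/") if c]
    return list(random)


def _prepare_table(
    data: pd.DataFrame,
    universe: GeneUniverse,
    genotype_col: str,
    value_col: str,
    dialect: str | None,
) -> tuple[list[Genotype], np.ndarray]:
    if genotype_col not in data.columns or value_col not in data.columns:
        raise ValueError(
            f"data must have {genotype_col!r} and {value_col!r} columns; got {list(data.columns)}"
        )
    genotypes = [parse_genotype(str(t), universe, dialect) for t in data[genotype_col]]
    values = pd.to_numeric(data[value_col], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValueError(f"non-finite phenotype value at row {bad}")
    return genotypes, values


def _fit_gls(
    y: np.ndarray,
    exog: np.ndarray,
    data: pd.DataFrame | None,
    random_cols: list[str],
    reml: bool = True,
):
    """Fit y on exog, OLS or (if random_cols) nested-random-intercept REML.

    Returns (params, cov_params, df_resid, info-dict).  df for the mixed fit
    is the N - p approximation documented in the methods note.
    """
    n, p = exog.shape
    if np.linalg.matrix_rank(exog) < p:
        raise FitError(
            "design matrix is rank deficient -- some genotypes required by the "
            "requested interaction order are missing from the data"
        )
    if not random_cols:
        import statsmodels.api as sm

        res = sm.OLS(y, exog).fit()
        return (
            np.asarray(res.params),
            np.asarray(res.cov_params()) if n > p else np.full((p, p), np.nan),
            n - p,
            {"method": "ols", "converged": True, "scale": float(res.scale) if n > p else np.nan},
        )

    from statsmodels.regression.mixed_linear_model import MixedLM

    df = pd.DataFrame(exog, columns=[f"x{j}" for j in range(p)])
    df["_y"] = y
    for c in random_cols:
        df[c] = np.asarray(data[c]).astype(str)
    top = random_cols[0]
    if df[top].nunique() < 2:
        raise FitError(f"mixed fitting needs >= 2 groups at the top level {top!r}")
    # nested levels enter as variance components; labels must be unique across
    # parents, so qualify each child label by its full ancestry
    vc = {}
    for depth, c in enumerate(random_cols[1:], start=1):
        qual = df[random_cols[: depth + 1]].agg("/".join, axis=1)
        df[f"_vc_{c}"] = qual
        vc[c] = f"0 + C(_vc_{c})"
    formula = "_y ~ 0 + " + " + ".join(f"x{j}" for j in range(p))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM.from_formula(
            formula, groups=top, re_formula="1", vc_formula=vc or None, data=df
        )
        res = model.fit(reml=reml)
    converged = bool(getattr(res, "converged", True))
    messages = [str(w.message) for w in caught]
    cov = np.asarray(res.cov_params())[:p, :p]
    if not (np.all(np.isfinite(res.fe_params)) and np.all(np.isfinite(cov))):
        raise FitError(
            "mixed model estimation failed (non-finite estimates); diagnostics: "
            + "; ".join(messages)
        )
    if not converged:
        # typically a variance component on the boundary (zero variance);
        # estimates are still valid -- report, do not abort
        warnings.warn(
            "mixed-model optimizer reported non-convergence (often a variance "
            "component at zero); estimates returned. Diagnostics: "
            + "; ".join(m for m in messages if "boundary" in m or "converge" in m),
            stacklevel=2,
        )
    info = {
        "method": "mixed",
        "converged": converged,
        "warnings": messages,
        "scale": float(res.scale),
        "vc_estimates": {k: float(v) for k, v in zip(res.model.exog_vc.names, res.vcomp)}
        if len(getattr(res, "vcomp", [])) > 0
        else {},
        "group_var": float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else np.nan,
    }
    return np.asarray(res.fe_params), cov, n - p, info


class MultiGeneModel:
    """A model family bound to long-format combinatorial phenotype data.

    Parameters
    ----------
    data : DataFrame
        One row per observation with a genotype string column and a numeric
        phenotype column, plus optional treatment and nesting columns.
    genes : str, int or GeneUniverse
        The gene universe, e.g. ``"JEPS"``.
    family : {"additive", "nr", "averaging"}
    max_order : int, optional
        Highest interaction order kept in the model; defaults to n (full).
    random : str or sequence, optional
        Nested random-intercept hierarchy, outermost first, as column names,
        e.g. ``"replicate/flat/pot"``.
    treatment : str, optional
        Name of a two-level treatment column.  When given, the modeled
        quantity per genotype is the within-genotype treatment contrast
        (treated - control); genotype main effects are retained as nuisance
        cell means.
    control : str, optional
        Label of the control level (defaults to the alphabetically first).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        genes,
        family: str = "averaging",
        max_order: int | None = None,
        random=None,
        treatment: str | None = None,
        control: str | None = None,
        genotype_col: str = "genotype",
        value_col: str = "value",
        dialect: str | None = None,
    ):
        self.universe = genes if isinstance(genes, GeneUniverse) else GeneUniverse.from_string(genes)
        self.spec = ModelSpec(family, self.universe, max_order or self.universe.n)
        self.data = data.reset_index(drop=True)
        self.random_cols = _parse_random(random)
        for c in self.random_cols:
            if c not in self.data.columns:
                raise ValueError(f"random-effect column {c!r} not in data")
        self.genotype_col, self.value_col, self.dialect = genotype_col, value_col, dialect
        self.genotypes, self.endog = _prepare_table(
            self.data, self.universe, genotype_col, value_col, dialect
        )

        observed = {g.mask for g in self.genotypes}
        missing = [str(g) for g in enumerate_genotypes(self.universe) if g.mask not in observed]
        if missing and self.spec.is_full:
            raise FitError(f"full model needs every genotype observed; missing: {missing}")
        if missing:
            warnings.warn(
                f"{len(missing)} genotype(s) unobserved; reduced model fitted on the "
                f"available lattice: {missing}",
                stacklevel=2,
            )

        self.treatment_col = treatment
        self.control = control
        self._build_design()

    # ------------------------------------------------------------------ design
    def _build_design(self) -> None:
        mm = build_model_matrix(self.spec)
        x_model = mm.design_rows(self.genotypes)  # (N, 1 + n_terms)
        self._model_matrix = mm
        cell_index = {g.mask: i for i, g in enumerate(mm.genotypes)}
        cells = np.array([cell_index[g.mask] for g in self.genotypes])
        self._cells = cells

        if self.treatment_col is None:
            self.exog = x_model
            self._coef_slice = slice(0, x_model.shape[1])
            self.treated = None
            return

        col = self.data[self.treatment_col].astype(str)
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ValueError(f"treatment column must have exactly two levels, got {levels}")
        control = self.control if self.control is not None else levels[0]
        if control not in levels:
            raise ValueError(f"control level {control!r} not among {levels}")
        treated_level = next(l for l in levels if l != control)
        self.control, self.treated_level = control, treated_level
        treated = (col == treated_level).to_numpy()
        for gi in np.unique(cells):
            got = set(col[cells == gi])
            if len(got) < 2:
                g = str(self._model_matrix.genotypes[gi])
                raise ValueError(f"genotype {g} observed under only one treatment level")
        # cell-means nuisance for genotype main effects + model design applied
        # to the treatment indicator: the model decomposes the per-genotype
        # (treated - control) contrast
        present = np.unique(cells)
        dummies = (cells[:, None] == present[None, :]).astype(float)
        self.exog = np.hstack([dummies, x_model * treated[:, None]])
        self._coef_slice = slice(dummies.shape[1], dummies.shape[1] + x_model.shape[1])
        self.treated = treated

    # -------------------------------------------------------------------- fit
    def fit(
        self,
        method: str = "auto",
        reml: bool = True,
        allow_fixed_fallback: bool = False,
    ) -> "MultiGeneResults":
        """Estimate the model.

        method "auto" uses the nested mixed model when a random hierarchy was
        declared and ordinary least squares otherwise; "ols" ignores the
        hierarchy; "mixed" requires one.  A variance component estimated on
        the boundary (zero variance) is reported as a warning, with estimates
        returned; estimation *failure* raises FitError unless
        ``allow_fixed_fallback`` requests an explicit fall-back to OLS.
        """
        if method not in ("auto", "ols", "mixed"):
            raise ValueError(f"unknown method {method!r}")
        if method == "auto":
            method = "mixed" if self.random_cols else "ols"
        if method == "mixed" and not self.random_cols:
            raise FitError("mixed fitting requires a random-effect hierarchy")
        random_cols = self.random_cols if method == "mixed" else []
        try:
            params, cov, df_resid, info = _fit_gls(
                self.endog, self.exog, self.data, random_cols, reml=reml
            )
        except FitError:
            if not (allow_fixed_fallback and method == "mixed"):
                raise
            params, cov, df_resid, info = _fit_gls(self.endog, self.exog, self.data, [], reml=reml)
            info["fallback"] = "ols"
        return MultiGeneResults(self, params, cov, df_resid, info)

    def reduce(self, new_max_order: int) -> "MultiGeneModel":
        """Same data and structure with interactions truncated at a lower order."""
        return MultiGeneModel(
            self.data,
            self.universe,
            self.spec.family,
            new_max_order,
            random=self.random_cols or None,
            treatment=self.treatment_col,
            control=self.control,
            genotype_col=self.genotype_col,
            value_col=self.value_col,
            dialect=self.dialect,
        )

    @property
    def param_names(self) -> list[str]:
        return ["intercept"] + self.spec.term_labels()

    @property
    def nobs(self) -> int:
        return len(self.endog)


@dataclass
class MultiGeneResults:
    """Fitted coefficients of a :class:`MultiGeneModel` with inference fields.

    ``params`` holds the intercept and model terms in canonical order (for
    treatment models these describe the per-genotype treatment contrast; the
    genotype nuisance means are in ``nuisance``).  Confidence intervals are
    t-based at the residual degrees of freedom N - p; Holm correction spans
    all non-intercept terms of this one fit.
    """

    model: MultiGeneModel
    _params_all: np.ndarray
    _cov_all: np.ndarray
    df_resid: int
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sl = self.model._coef_slice
        self._coef = np.asarray(self._params_all)[sl]
        self._coef_cov = np.asarray(self._cov_all)[sl, sl]

    # ------------------------------------------------------------- accessors
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._coef, index=self.model.param_names, name="estimate")

    @property
    def nuisance(self) -> pd.Series | None:
        """Genotype cell means retained as nuisance in treatment models."""
        sl = self.model._coef_slice
        if sl.start == 0:
            return None
        labels = [str(self.model._model_matrix.genotypes[i]) for i in np.unique(self.model._cells)]
        return pd.Series(np.asarray(self._params_all)[: sl.start], index=labels)

    @property
    def inference_available(self) -> bool:
        return self.df_resid > 0 and np.all(np.isfinite(np.diag(self._coef_cov)))

    @property
    def bse(self) -> pd.Series:
        if not self.inference_available:
            return pd.Series(np.nan, index=self.model.param_names, name="se")
        return pd.Series(
            np.sqrt(np.diag(self._coef_cov)), index=self.model.param_names, name="se"
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        if not self.inference_available:
            return pd.Series(np.nan, index=self.model.param_names, name="p")
        t = self.tvalues
        return pd.Series(
            2 * stats.t.sf(np.abs(t), self.df_resid), index=t.index, name="p"
        )

    @property
    def pvalues_holm(self) -> pd.Series:
        """Holm-adjusted p-values; family = all non-intercept terms of this fit."""
        p = self.pvalues
        out = p.copy()
        out.name = "p_holm"
        if self.inference_available and len(p) > 1:
            out.iloc[1:] = holm_adjust(p.iloc[1:].to_numpy())
        return out

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if not self.inference_available:
            ci = np.full((len(self._coef), 2), np.nan)
        else:
            tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
            se = self.bse.to_numpy()
            ci = np.column_stack([self._coef - tcrit * se, self._coef + tcrit * se])
        return pd.DataFrame(ci, index=self.model.param_names, columns=["ci_low", "ci_high"])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ np.asarray(self._params_all)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    # --------------------------------------------------------------- exports
    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: term, order, estimate, se, df, ci, p, p_holm."""
        orders = [0] + [t.order for t in self.model.spec.terms]
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.model.param_names,
                "order": orders,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "df": self.df_resid,
                "ci_low": ci["ci_low"].to_numpy(),
                "ci_high": ci["ci_high"].to_numpy(),
                "p": self.pvalues.to_numpy(),
                "p_holm": self.pvalues_holm.to_numpy(),
            }
        )

    def to_coefficient_vector(self) -> CoefficientVector:
        return CoefficientVector(self.model.spec, float(self._coef[0]), self._coef[1:])

    def summary(self) -> str:
        spec = self.model.spec
        head = [
            f"{spec.family} model over genes {spec.universe} (max order {spec.max_order})",
            f"observations: {self.model.nobs}   method: {self.info.get('method', '?')}"
            f"   residual df: {self.df_resid}",
        ]
        if self.model.treatment_col is not None:
            head.append(
                f"response: within-genotype treatment contrast "
                f"({self.model.treated_level} - {self.model.control})"
            )
        if self.info.get("method") == "mixed":
            vcs = {"group": self.info.get("group_var"), **self.info.get("vc_estimates", {})}
            head.append("variance components: " + ", ".join(f"{k}={v:.4g}" for k, v in vcs.items()))
        if not self.inference_available:
            head.append("NOTE: zero residual df -- estimates only, no inference fields")
        table = self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .4f}")
        return "\n".join(head) + "\n" + table

    def plot(self, ax=None, alpha: float = 0.05):
        """Coefficient/CI plot: terms on y, estimate +- CI on x, order bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(self._coef) + 1.5))
        frame = self.to_frame().iloc[1:]  # drop the intercept
        y = np.arange(len(frame))[::-1]
        for order in sorted(frame["order"].unique()):
            if order % 2 == 0:
                rows = frame["order"] == order
                ax.axhspan(y[rows.to_numpy()].min() - 0.5, y[rows.to_numpy()].max() + 0.5,
                           color="0.92", zorder=0)
        ax.errorbar(
            frame["estimate"],
            y,
            xerr=[frame["estimate"] - frame["ci_low"], frame["ci_high"] - frame["estimate"]],
            fmt="o",
            color="C0",
            ecolor="0.4",
            capsize=2,
        )
        ax.axvline(0.0, color="0.6", lw=0.8)
        ax.set_yticks(y, frame["term"])
        ax.set_xlabel("estimate (95% CI)")
        ax.set_title(f"{self.model.spec.family} model coefficients")
        return ax


# ---------------------------------------------------------------- screening


@dataclass
class GeneScreenResult:
    """Outcome of the gene-inclusion screen.

    ``contrasts`` has one row per (gene, background) with the estimated
    effect of adding the gene to that background, its t-test and the per-gene
    BH-adjusted p-value; ``decisions`` maps gene -> "keep"/"drop" (drop iff
    no BH-corrected p < alpha among the gene's 2^(n-1) contrasts).
    """

    universe: GeneUniverse
    alpha: float
    contrasts: pd.DataFrame
    decisions: dict[str, str]

    @property
    def dropped(self) -> list[str]:
        return [g for g, d in self.decisions.items() if d == "drop"]

    @property
    def kept(self) -> list[str]:
        return [g for g, d in self.decisions.items() if d == "keep"]

    def summary(self) -> str:
        lines = [
            f"gene screen over {self.universe} at alpha={self.alpha}: "
            + ", ".join(f"{g}:{d}" for g, d in self.decisions.items())
        ]
        lines.append(self.contrasts.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def screen_genes(
    data: pd.DataFrame,
    genes,
    alpha: float = 0.05,
    random=None,
    treatment: str | None = None,
    control: str | None = None,
    genotype_col: str = "genotype",
    value_col: str = "value",
    dialect: str | None = None,
) -> GeneScreenResult:
    """Screen each gene for significant involvement in the phenotype.

    A cell-means model (one mean per genotype, with nested random intercepts
    if ``random`` is given, and per-genotype treatment contrasts if
    ``treatment`` is given) is fitted once.  For every gene g and every
    background B not containing g, the difference mean(B + g) - mean(B) is
    t-tested using the coefficient covariance and the residual df; the 2^(n-1)
    p-values of each gene are Benjamini-Hochberg adjusted, and the gene is
    dropped iff none falls below `alpha`.
    """
    universe = genes if isinstance(genes, GeneUniverse) else GeneUniverse.from_string(genes)
    df = data.reset_index(drop=True)
    genotypes, y = _prepare_table(df, universe, genotype_col, value_col, dialect)
    all_genotypes = enumerate_genotypes(universe)
    observed = {g.mask for g in genotypes}
    missing = [str(g) for g in all_genotypes if g.mask not in observed]
    if missing:
        raise FitError(f"gene screening needs the complete lattice; missing: {missing}")

    cell_of = {g.mask: i for i, g in enumerate(all_genotypes)}
    cells = np.array([cell_of[g.mask] for g in genotypes])
    dummies = (cells[:, None] == np.arange(len(all_genotypes))[None, :]).astype(float)
    if treatment is not None:
        col = df[treatment].astype(str)
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ValueError(f"treatment column must have exactly two levels, got {levels}")
        ctrl = control if control is not None else levels[0]
        treated = (col != ctrl).to_numpy().astype(float)
        exog = np.hstack([dummies, dummies * treated[:, None]])
        block = slice(len(all_genotypes), 2 * len(all_genotypes))
    else:
        exog = dummies
        block = slice(0, len(all_genotypes))

    params, cov, df_resid, _ = _fit_gls(y, exog, df, _parse_random(random))
    beta = params[block]
    vmat = cov[block, block]
    if df_resid <= 0:
        raise FitError("no residual degrees of freedom for screening t-tests")

    rows = []
    decisions: dict[str, str] = {}
    for gene in universe.genes:
        bit = 1 << universe.index(gene)
        prows = []
        for bg in all_genotypes:
            if bg.mask & bit:
                continue
            i_with = cell_of[bg.mask | bit]
            i_without = cell_of[bg.mask]
            est = beta[i_with] - beta[i_without]
            var = vmat[i_with, i_with] + vmat[i_without, i_without] - 2 * vmat[i_with, i_without]
            se = float(np.sqrt(max(var, 0.0)))
            if se > 0:
                t = est / se
                p = float(2 * stats.t.sf(abs(t), df_resid))
            else:  # exact fit: a zero contrast carries no evidence, a nonzero one is certain
                t = np.nan
                p = 1.0 if abs(est) < 1e-12 else 0.0
            prows.append(
                {
                    "gene": gene,
                    "background": str(bg),
                    "added": str(Genotype(universe, bg.mask | bit)),
                    "estimate": float(est),
                    "se": se,
                    "t": float(t),
                    "df": df_resid,
                    "p": p,
                }
            )
        padj = bh_adjust([r["p"] for r in prows])
        for r, q in zip(prows, padj):
            r["p_bh"] = float(q)
        decisions[gene] = "keep" if (padj < alpha).any() else "drop"
        rows.extend(prows)
    return GeneScreenResult(universe, alpha, pd.DataFrame(rows), decisions)


def bundle_gene(
    data: pd.DataFrame,
    gene: str,
    genes,
    genotype_col: str = "genotype",
    dialect: str | None = None,
) -> pd.DataFrame:
    """Collapse the data over a gene's allele states (irreversible).

    Every genotype is relabeled over the universe without `gene` -- e.g.
    bundling J in a JEPS table sends both *JEPS* and *EPS* observations to the
    *EPS* genotype of the 3-gene universe.  All observations are retained;
    only the labels change.  The allele state of the removed gene is
    discarded, so the operation cannot be undone.
    """
    universe = genes if isinstance(genes, GeneUniverse) else GeneUniverse.from_string(genes)
    if gene.upper() not in universe:
        raise KeyError(f"gene {gene!r} not in universe {universe}")
    out = data.copy()
    out[genotype_col] = [
        str(parse_genotype(str(t), universe, dialect).drop_gene(gene)) for t in out[genotype_col]
    ]
    return out
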