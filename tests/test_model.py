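"""Statistical fitting, screening, bundling, reduction, multiple testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avgmodel as am
from avgmodel.model import FitError


def make_dataset(universe, family="averaging", seed=0, **cfg_kw):
    spec = am.ModelSpec(family, universe)
    rng = np.random.default_rng(seed)
    coef = am.CoefficientVector(spec, 4.0, rng.normal(0.0, 1.0, len(spec.terms)))
    defaults = dict(spec=spec, coefficients=coef, residual_sd=0.4, n_replicates=3, seed=seed)
    defaults.update(cfg_kw)
    cfg = am.SyntheticDataConfig(**defaults)
    return coef, am.generate_replicated_data(cfg)


class TestFixedEffects:
    def test_noiseless_fit_equals_exact_solution(self, abc, fig1_means):
        df = pd.DataFrame(
            {"genotype": fig1_means.to_series().index, "value": fig1_means.values}
        )
        df = pd.concat([df, df], ignore_index=True)  # replication, zero noise
        for family in am.FAMILIES:
            res = am.MultiGeneModel(df, abc, family).fit()
            exact = am.solve_means(am.ModelSpec(family, abc), fig1_means)
            np.testing.assert_allclose(res.params.to_numpy(), exact.full, atol=1e-10)

    def test_fitted_values_identical_across_families(self, jeps, synthetic_jeps):
        """The three full models are reparameterizations of the genotype
        cell-means model: same fitted values and residuals."""
        _, _, df = synthetic_jeps
        fits = {f: am.MultiGeneModel(df, jeps, f).fit() for f in am.FAMILIES}
        cell_means = df.groupby("genotype")["value"].mean()
        for f, res in fits.items():
            assert np.abs(res.fittedvalues - fits["additive"].fittedvalues).max() < 1e-8
            fitted_by_geno = pd.Series(res.fittedvalues, index=df["genotype"]).groupby(level=0).mean()
            np.testing.assert_allclose(fitted_by_geno, cell_means[fitted_by_geno.index], atol=1e-8)

    def test_missing_genotype_fatal_for_full_model(self, abc):
        _, df = make_dataset(abc)
        with pytest.raises(FitError, match="missing"):
            am.MultiGeneModel(df[df["genotype"] != "AB"], abc, "averaging")

    def test_reduced_model_tolerates_missing_genotype(self, abc):
        _, df = make_dataset(abc)
        with pytest.warns(UserWarning, match="unobserved"):
            m = am.MultiGeneModel(df[df["genotype"] != "ABC"], abc, "averaging", max_order=1)
        res = m.fit()
        assert res.params.shape == (4,)

    def test_zero_residual_df_returns_estimates_only(self, abc, fig1_means):
        df = pd.DataFrame(
            {"genotype": fig1_means.to_series().index, "value": fig1_means.values}
        )
        res = am.MultiGeneModel(df, abc, "averaging").fit()
        assert not res.inference_available
        np.testing.assert_allclose(
            res.params.to_numpy(),
            am.solve_means(am.ModelSpec("averaging", abc), fig1_means).full,
            atol=1e-10,
        )
        assert res.bse.isna().all() and res.pvalues.isna().all()

    def test_ci_coverage_small_monte_carlo(self, abc):
        """95% CIs cover the true coefficients at roughly nominal rate."""
        hits = total = 0
        for seed in range(120):
            true, df = make_dataset(abc, seed=seed, residual_sd=0.5, n_replicates=3)
            res = am.MultiGeneModel(df, abc, "averaging").fit()
            ci = res.conf_int()
            cover = (ci["ci_low"].to_numpy() <= true.full) & (true.full <= ci["ci_high"].to_numpy())
            hits += cover.sum()
            total += cover.size
        assert 0.90 <= hits / total <= 0.98


class TestMixedEffects:
    def test_zero_variance_groups_match_ols(self, abc):
        true, df = make_dataset(
            abc, seed=3, residual_sd=0.3, n_replicates=4,
            random_sds={"replicate": 0.0, "flat": 0.0},
        )
        m = am.MultiGeneModel(df, abc, "averaging", random="replicate/flat")
        mixed = m.fit(method="mixed")
        ols = m.fit(method="ols")
        np.testing.assert_allclose(
            mixed.params.to_numpy(), ols.params.to_numpy(), atol=1e-6
        )

    def test_variance_component_recovery(self):
        """REML variance components track the generator's sds (2-level
        hierarchy, moderate Monte-Carlo)."""
        u = am.GeneUniverse.from_string("AB")
        group_vars, resid_vars = [], []
        for seed in range(60):
            _, df = make_dataset(
                u, seed=seed, residual_sd=0.5, n_replicates=6,
                random_sds={"replicate": 0.6},
            )
            res = am.MultiGeneModel(df, u, "averaging", random="replicate").fit()
            group_vars.append(res.info["group_var"])
            resid_vars.append(res.info["scale"])
        for est, truth in ((group_vars, 0.36), (resid_vars, 0.25)):
            mc_se = np.std(est) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * mc_se + 0.02

    def test_unbalanced_estimates_unbiased(self, abc):
        """With unequal replicate counts the mixed fit differs from plain
        genotype-mean solving but remains unbiased across simulations."""
        errs = []
        for seed in range(40):
            true, df = make_dataset(
                abc, seed=seed, residual_sd=0.4, n_replicates=4,
                random_sds={"replicate": 0.3}, dropout=0.25,
            )
            res = am.MultiGeneModel(df, abc, "averaging", random="replicate").fit()
            errs.append(res.params.to_numpy() - true.full)
        bias = np.mean(errs, axis=0)
        mc_se = np.std(errs, axis=0) / np.sqrt(len(errs))
        assert np.all(np.abs(bias) < 3 * mc_se + 1e-6)

    def test_mixed_requires_hierarchy(self, abc):
        _, df = make_dataset(abc)
        with pytest.raises(FitError):
            am.MultiGeneModel(df, abc, "averaging").fit(method="mixed")


class TestReduction:
    def test_reduce_identity(self, abc):
        _, df = make_dataset(abc, seed=5)
        m = am.MultiGeneModel(df, abc, "averaging")
        full = m.fit()
        same = m.reduce(3).fit()
        np.testing.assert_allclose(full.params.to_numpy(), same.params.to_numpy(), atol=1e-10)

    def test_low_order_mechanism_fits_reduced_model_perfectly(self, jeps):
        """Noiseless order-2 additive data: the order-2 additive model has
        zero residuals."""
        spec = am.ModelSpec("additive", jeps)
        rng = np.random.default_rng(8)
        vals = np.array([rng.normal() if t.order <= 2 else 0.0 for t in spec.terms])
        means = am.predict_means(spec, am.CoefficientVector(spec, 1.0, vals))
        df = pd.DataFrame({"genotype": means.to_series().index, "value": means.values})
        res = am.MultiGeneModel(df, jeps, "additive", max_order=2).fit()
        assert np.abs(res.resid).max() < 1e-9

    def test_reduction_shifts_additive_more_than_averaging(self):
        """Dropping the top-order interaction perturbs 1-gene estimates far
        more in the additive family than in the averaging family."""
        u = am.GeneUniverse.from_string(4)
        rng = np.random.default_rng(17)
        shifts = {"additive": [], "averaging": []}
        for _ in range(50):
            means = am.MeanTable(u, rng.uniform(1, 10, 16))
            df = pd.DataFrame({"genotype": means.to_series().index, "value": means.values})
            for fam in shifts:
                full = am.solve_means(am.ModelSpec(fam, u), means).to_series()
                red = am.MultiGeneModel(df, u, fam, max_order=3).fit().params
                one_gene = list(u.genes)
                shifts[fam].append(np.abs(full[one_gene] - red[one_gene]).mean())
        assert np.mean(shifts["additive"]) > np.mean(shifts["averaging"])


class TestScreening:
    def test_contrast_structure_three_genes(self, abc):
        _, df = make_dataset(abc, seed=2)
        scr = am.screen_genes(df, abc)
        c_rows = scr.contrasts[scr.contrasts["gene"] == "C"]
        assert len(c_rows) == 4  # 2^(n-1) backgrounds
        pairs = {(r.background, r.added) for r in c_rows.itertuples()}
        assert pairs == {("-", "C"), ("A", "AC"), ("B", "BC"), ("AB", "ABC")}

    def test_null_gene_dropped_active_genes_kept(self):
        """A gene whose addition never moves a genotype mean (all its additive
        terms zero) is dropped; genes with large 1-gene effects are kept."""
        u = am.GeneUniverse.from_string("ABCD")
        spec = am.ModelSpec("additive", u)
        vals = {g: 2.0 for g in "ABC"}  # strong single-gene effects, D entirely null
        coef = am.CoefficientVector.from_dict(spec, vals, intercept=4.0)
        dropped_d = kept_abc = 0
        n_sim = 60
        for seed in range(n_sim):
            cfg = am.SyntheticDataConfig(
                spec=spec, coefficients=coef, residual_sd=0.4, n_replicates=3, seed=seed
            )
            scr = am.screen_genes(am.generate_replicated_data(cfg), u)
            dropped_d += scr.decisions["D"] == "drop"
            kept_abc += all(scr.decisions[g] == "keep" for g in "ABC")
        assert dropped_d >= 0.9 * n_sim
        assert kept_abc == n_sim

    def test_screening_needs_complete_lattice(self, abc):
        _, df = make_dataset(abc)
        with pytest.raises(FitError, match="missing"):
            am.screen_genes(df[df["genotype"] != "AC"], abc)


class TestBundling:
    def test_bundle_collapses_labels_keeps_rows(self, jeps):
        _, df = make_dataset(jeps, seed=4)
        out = am.bundle_gene(df, "J", jeps)
        assert len(out) == len(df)
        assert out["genotype"].nunique() == 8
        assert not out["genotype"].str.contains("J").any()

    def test_bundle_then_screen_reduced_universe(self, jeps):
        _, df = make_dataset(jeps, seed=4)
        out = am.bundle_gene(df, "J", jeps)
        scr = am.screen_genes(out, "EPS")
        assert set(scr.decisions) == {"E", "P", "S"}

    def test_bundle_unknown_gene(self, jeps):
        _, df = make_dataset(jeps)
        with pytest.raises(KeyError):
            am.bundle_gene(df, "Q", jeps)


class TestTreatment:
    def test_equal_levels_give_zero_contrasts(self, abc):
        _, df = make_dataset(abc, seed=6, residual_sd=0.0)
        both = pd.concat(
            [df.assign(treatment="control"), df.assign(treatment="treated")],
            ignore_index=True,
        )
        res = am.MultiGeneModel(both, abc, "averaging", treatment="treatment").fit()
        np.testing.assert_allclose(res.params.to_numpy(), 0.0, atol=1e-10)
        scr = am.screen_genes(both, abc, treatment="treatment")
        # identical values under both levels: nothing significant
        assert scr.dropped == ["A", "B", "C"]

    def test_recovers_treatment_coefficients(self, abc):
        """Averaging fit on within-genotype contrasts recovers the generating
        treatment coefficients without bias."""
        spec = am.ModelSpec("averaging", abc)
        rng = np.random.default_rng(30)
        teff = am.CoefficientVector(spec, 1.5, rng.normal(0, 0.8, len(spec.terms)))
        errs = []
        for seed in range(40):
            base = am.CoefficientVector(spec, 4.0, rng.normal(0, 1, len(spec.terms)))
            cfg = am.SyntheticDataConfig(
                spec=spec, coefficients=base, treatment_effects=teff,
                residual_sd=0.3, n_replicates=3, seed=1000 + seed,
            )
            df = am.generate_replicated_data(cfg)
            res = am.MultiGeneModel(
                df, abc, "averaging", treatment="treatment", control="control"
            ).fit()
            errs.append(res.params.to_numpy() - teff.full)
        bias = np.mean(errs, axis=0)
        mc_se = np.std(errs, axis=0) / np.sqrt(len(errs))
        assert np.all(np.abs(bias) < 3 * mc_se + 1e-6)

    def test_missing_level_rejected(self, abc):
        _, df = make_dataset(abc, seed=6)
        both = pd.concat(
            [df.assign(treatment="control"), df.assign(treatment="treated")],
            ignore_index=True,
        )
        broken = both[~((both["genotype"] == "AB") & (both["treatment"] == "treated"))]
        with pytest.raises(ValueError, match="one treatment level"):
            am.MultiGeneModel(broken, abc, "averaging", treatment="treatment")


class TestMultipleTesting:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(am.holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])
        np.testing.assert_allclose(am.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert am.holm_adjust([0.2]) == pytest.approx([0.2])
        assert am.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            am.holm_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            am.bh_adjust([-0.1])

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.floats(0.0, 0.5),
    )
    def test_monotone_in_pvalues(self, p, bump):
        """Uniformly inflating p-values never shrinks adjusted values, and
        adjusted values are capped at 1 and >= raw."""
        p = np.asarray(p)
        bigger = np.clip(p + bump, 0, 1)
        for adjust in (am.holm_adjust, am.bh_adjust):
            a, b = adjust(p), adjust(bigger)
            assert np.all(b >= a - 1e-12)
            assert np.all(a >= p - 1e-12) and np.all(a <= 1.0)

    def test_results_holm_family_is_non_intercept_terms(self, abc):
        _, df = make_dataset(abc, seed=9)
        res = am.MultiGeneModel(df, abc, "averaging").fit()
        p, ph = res.pvalues, res.pvalues_holm
        assert ph["intercept"] == p["intercept"]
        np.testing.assert_allclose(
            ph.iloc[1:].to_numpy(), am.holm_adjust(p.iloc[1:].to_numpy())
        )

    def test_screen_type_one_error_rate(self):
        """With a truly null gene the keep decision fires at a rate consistent
        with BH at 0.05."""
        u = am.GeneUniverse.from_string("ABC")
        spec = am.ModelSpec("additive", u)
        vals = {"A": 2.0, "B": 2.0}
        coef = am.CoefficientVector.from_dict(spec, vals, intercept=4.0)
        kept_null = 0
        n_sim = 150
        for seed in range(n_sim):
            cfg = am.SyntheticDataConfig(
                spec=spec, coefficients=coef, residual_sd=0.4, n_replicates=3, seed=seed
            )
            scr = am.screen_genes(am.generate_replicated_data(cfg), u)
            kept_null += scr.decisions["C"] == "keep"
        rate = kept_null / n_sim
        # binomial 3-sigma band around 0.05
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)


def test_coefficient_plot_renders(abc):
    import matplotlib

    matplotlib.use("Agg")
    _, df = make_dataset(abc, seed=12)
    ax = am.MultiGeneModel(df, abc, "averaging").fit().plot()
    assert len(ax.lines) + len(ax.collections) > 0
    labels = [t.get_text() for t in ax.get_yticklabels()]
    assert "A;B;C" in labels and "intercept" not in labels


def test_summary_and_frame_shapes(synthetic_jeps, jeps):
    _, _, df = synthetic_jeps
    res = am.MultiGeneModel(df, jeps, "averaging", random="replicate/flat/pot").fit()
    frame = res.to_frame()
    assert list(frame.columns) == [
        "term", "order", "estimate", "se", "df", "ci_low", "ci_high", "p", "p_holm"
    ]
    assert (frame["ci_low"] <= frame["estimate"]).all()
    assert (frame["estimate"] <= frame["ci_high"]).all()
    assert (frame["p_holm"] >= frame["p"] - 1e-12).all()
    text = res.summary()
    assert "averaging model" in text and "J;E;P;S" in text
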