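"""Curvilinear scaling regressions: design, REML, Gibbs sampler, variants."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lactscale import allometry, pattern_features, phylo
from lactscale.synthetic_data import SimulationConfig, simulate_dataset

FAST_MCMC = dict(n_iter=8000, burn_in=2000, thin=5)


def exact_table(n_species=6, reps=2, b0=-0.2, b1=0.7, b2=0.05, bd=0.02, seed=0):
    """Characteristics that follow the scaling law exactly (no noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_species + 1):  # labels match simulate_tree tips
        mass = 10.0 ** rng.uniform(-2, 2.5)
        for j in range(reps):
            d = rng.uniform(8, 20)
            x = np.log10(mass)
            y = 10 ** (b0 + b1 * x + b2 * x * x + bd * d)
            rows.append(
                {
                    "pattern_id": f"s{i}r{j}",
                    "species": f"sp_{i:03d}",
                    "breed": f"sp_{i:03d}_b1",
                    "peak_rate": y,
                    "mass_peak_kg": mass,
                    "mass_onset_kg": mass,
                    "diet_me_mj_per_kg_dm": d,
                }
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_unit_mass_maps_to_zero_log(self):
        tab = exact_table()
        tab.loc[0, "mass_peak_kg"] = 1.0
        data = allometry.build_design(tab, "peak_rate")
        row = data.df[data.df["pattern_id"] == "s1r0"].iloc[0]
        assert row["x"] == 0.0 and row["x2"] == 0.0

    def test_nonpositive_characteristic_dropped_and_logged(self):
        tab = exact_table()
        tab.loc[0, "peak_rate"] = 0.0
        with pytest.warns(UserWarning, match="dropped"):
            data = allometry.build_design(tab, "peak_rate")
        assert data.dropped == ["s1r0"]
        assert data.n_obs == len(tab) - 1

    def test_row_count_preserved_when_all_valid(self):
        tab = exact_table()
        data = allometry.build_design(tab, "peak_rate")
        assert data.n_obs == len(tab)

    def test_onset_mass_variant_changes_design(self):
        tab = exact_table()
        tab["mass_onset_kg"] = tab["mass_peak_kg"] * 1.2
        a = allometry.build_design(tab, "peak_rate", mass_column="mass_peak_kg")
        b = allometry.build_design(tab, "peak_rate", mass_column="mass_onset_kg")
        assert not np.allclose(a.df["x"], b.df["x"])


class TestLocalExponent:
    def test_peak_rate_exponents_small_and_large_mothers(self):
        assert round(allometry.local_exponent(0.67, 0.050, 0.05), 2) == 0.60
        assert round(allometry.local_exponent(0.67, 0.050, 500), 2) == 0.80

    def test_zero_curvature_constant_exponent(self):
        for mass in (0.01, 1.0, 600.0):
            assert allometry.local_exponent(0.7, 0.0, mass) == 0.7

    def test_cumulative_elevation_exponent(self):
        assert round(allometry.local_exponent(0.73, 0.092, 500), 2) == 0.98

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            allometry.local_exponent(0.7, 0.05, 0.0)


class TestReml:
    def test_exact_data_recovers_fixed_effects(self):
        tab = exact_table()
        data = allometry.build_design(tab, "peak_rate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.fit_lmm(data)
        assert fit.coef["b1"] == pytest.approx(0.7, abs=1e-6)
        assert fit.coef["b2"] == pytest.approx(0.05, abs=1e-6)
        assert fit.coef["diet_coef"] == pytest.approx(0.02, abs=1e-6)

    def test_row_permutation_invariance(self, small_dataset):
        patterns, _, _, _ = small_dataset
        tab = pattern_features.characteristics_table(patterns)
        data1 = allometry.build_design(tab, "peak_rate")
        data2 = allometry.build_design(
            tab.sample(frac=1.0, random_state=5), "peak_rate"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, f2 = allometry.fit_lmm(data1), allometry.fit_lmm(data2)
        for nm in f1.coef:
            assert f1.coef[nm] == pytest.approx(f2.coef[nm], abs=1e-6)


class TestMarginalR2:
    def test_flat_predictions_give_zero(self):
        X = np.ones((10, 1))
        assert allometry.marginal_r2([2.0], X, [0.5], 0.5) == 0.0

    def test_no_random_or_residual_variance_gives_one(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        assert allometry.marginal_r2([0.0, 1.0], X, [0.0], 0.0) == 1.0


class TestGibbsSampler:
    def test_pinned_variances_match_gls_closed_form(self, small_dataset):
        """Degenerate variance priors: posterior mean of beta equals GLS."""
        patterns, tree, _, _ = small_dataset
        tab = pattern_features.characteristics_table(patterns)
        data = allometry.build_design(tab, "peak_rate")
        fv = {"phylo": 0.005, "breed": 0.001, "resid": 0.002}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.fit_phylo_mcmc(
                data, tree, seed=3, fixed_variances=fv, n_iter=20000,
                burn_in=2000, thin=10,
            )
        # independent GLS oracle with the implied covariance
        pruned, report = phylo.prune_and_match(
            tree, list(dict.fromkeys(data.df["species"]))
        )
        V = phylo.vcv_matrix(pruned)
        sp = data.df["species"].to_numpy()
        idx = {lab: i for i, lab in enumerate(V.index)}
        Za = np.zeros((len(sp), len(V)))
        Za[np.arange(len(sp)), [idx[report.matched[s]] for s in sp]] = 1.0
        br = (data.df["species"] + ":" + data.df["breed"]).to_numpy()
        lev = sorted(set(br))
        bidx = {b: i for i, b in enumerate(lev)}
        Zb = np.zeros((len(br), len(lev)))
        Zb[np.arange(len(br)), [bidx[b] for b in br]] = 1.0
        Sigma = (
            fv["phylo"] * Za @ V.values @ Za.T
            + fv["breed"] * Zb @ Zb.T
            + fv["resid"] * np.eye(len(sp))
        )
        X, _ = data.design_matrix()
        y = data.df["y"].to_numpy()
        Si = np.linalg.inv(Sigma)
        beta_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        for i, nm in enumerate(["intercept", "b1", "b2", "diet_coef"]):
            mc_sd = float(fit.draws[nm].std())
            assert abs(fit.coef[nm] - beta_gls[i]) < 0.2 * mc_sd

    def test_reproducible_under_seed(self, small_dataset):
        patterns, tree, _, _ = small_dataset
        tab = pattern_features.characteristics_table(patterns)
        data = allometry.build_design(tab, "peak_rate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = allometry.fit_phylo_mcmc(data, tree, seed=11, **FAST_MCMC)
            f2 = allometry.fit_phylo_mcmc(data, tree, seed=11, **FAST_MCMC)
        assert f1.coef == f2.coef and f1.lambda_ == f2.lambda_

    def test_lambda_in_unit_interval_and_r2_sane(self, small_dataset):
        patterns, tree, _, _ = small_dataset
        tab = pattern_features.characteristics_table(patterns)
        data = allometry.build_design(tab, "peak_rate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.fit_phylo_mcmc(data, tree, seed=2, **FAST_MCMC)
        assert 0.0 <= fit.lambda_ <= 1.0
        assert 0.0 <= fit.marginal_r2 <= 1.0
        assert fit.marginal_r2 > 0.9  # rate characteristics are strongly mass-driven


class TestVariants:
    def test_species_average_collapse_idempotent(self):
        tab = exact_table(n_species=6, reps=1)
        data = allometry.build_design(tab, "peak_rate")
        collapsed = allometry.collapse_to_species_means(data)
        merged = collapsed.df.merge(data.df, on="species", suffixes=("_c", ""))
        np.testing.assert_allclose(merged["y_c"], merged["y"])
        np.testing.assert_allclose(merged["x_c"], merged["x"])
        assert collapsed.n_species == data.n_species

    def test_species_average_attenuates_within_species_diet_effect(self):
        # diet varies only within one heavily replicated species; averaging
        # per species removes that information
        rng = np.random.default_rng(8)
        rows = []
        for i in range(1, 9):
            mass = 10.0 ** rng.uniform(-1, 2)
            reps = 12 if i == 1 else 1
            for j in range(reps):
                d = rng.uniform(8, 20) if i == 1 else 14.0
                x = np.log10(mass)
                y = 10 ** (0.0 + 0.7 * x + 0.04 * d + 0.01 * rng.standard_normal())
                rows.append(
                    {"pattern_id": f"s{i}r{j}", "species": f"sp_{i:03d}",
                     "breed": f"sp_{i:03d}_b1", "peak_rate": y,
                     "mass_peak_kg": mass, "mass_onset_kg": mass,
                     "diet_me_mj_per_kg_dm": d}
                )
        tab = pd.DataFrame(rows)
        from lactscale.synthetic_data import simulate_tree

        tree = simulate_tree(8, seed=1)
        data = allometry.build_design(tab, "peak_rate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = allometry.fit_phylo_mcmc(data, tree, seed=5, **FAST_MCMC)
            avg = allometry.species_average_analysis(data, tree, seed=5, **FAST_MCMC)
        assert abs(avg.coef["diet_coef"] - 0.04) > abs(full.coef["diet_coef"] - 0.04)
        assert full.coef["diet_coef"] == pytest.approx(0.04, abs=0.01)

    def test_ratio_of_identical_series_is_zero(self):
        tab = exact_table()
        tab["initial_rate"] = tab["peak_rate"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.ratio_scaling(tab, "peak_rate", "initial_rate")
        assert fit.extras["fold_change"] == pytest.approx(1.0, abs=1e-9)
        assert fit.coef["b1"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_fold_change_recovered(self):
        tab = exact_table()
        tab["initial_rate"] = tab["peak_rate"] / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.ratio_scaling(tab, "peak_rate", "initial_rate")
        assert fit.extras["fold_change"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coef["b1"] == pytest.approx(0.0, abs=1e-6)
        assert fit.coef["b2"] == pytest.approx(0.0, abs=1e-6)

    def test_parallel_laws_give_mass_free_ratio(self, small_dataset):
        """The generator builds initial rates as peak/fold, so the ratio's
        mass terms should vanish."""
        patterns, tree, _, _ = small_dataset
        tab = pattern_features.characteristics_table(patterns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = allometry.ratio_scaling(
                tab, "peak_rate", "initial_rate", tree=tree, seed=9, **FAST_MCMC
            )
        assert abs(fit.coef["b1"]) < 0.05
        assert abs(fit.coef["b2"]) < 0.03
        assert 1.4 < fit.extras["fold_change"] < 2.2
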