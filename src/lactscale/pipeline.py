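"""End-to-end analysis pipeline.

Stages, in the order the method runs:

1. extract the six raw characteristics from every intake pattern;
2. fit the generalized Von Bertalanffy curve to each cumulative-elevation
   series, derive the model-based characteristics and the shape
   statistic, and exclude non-converged and abnormal fits (Tukey-fence
   screening on the model-vs-raw time-to-peak relative difference);
3. run the curvilinear scaling regressions for the raw characteristics
   and the model-derived ones, with and without phylogeny;
4. optional variants: species-averaged analysis, mass-at-onset design,
   shape-as-covariate regression, and the peak/initial ratio analysis;
5. write a Table-style TSV report, a per-pattern fits TSV, the excluded
   pattern log, and a machine-readable JSON of all estimates.

Every stage is a pure function of its inputs and the configuration; a
fixed seed makes the whole run (including every MCMC stream) bitwise
reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, pattern_features, phylo, vb_growth
from .synthetic_data import read_dataset

__all__ = [
    "PipelineConfig",
    "RAW_CHARACTERISTICS",
    "MODEL_CHARACTERISTICS",
    "fit_all_patterns",
    "run_scaling",
    "shape_covariate_run",
    "run_pipeline",
    "table_report",
]

logger = logging.getLogger("lactscale")

RAW_CHARACTERISTICS = [
    "average_rate",
    "initial_rate",
    "peak_rate",
    "amplitude",
    "time_to_peak",
    "cumulative_elevation_to_peak",
]
MODEL_CHARACTERISTICS = [
    "vb_time_to_peak",
    "vb_amplitude",
    "vb_cumulative_to_peak",
]


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    dataset_csv: str
    newick: str
    out_dir: str
    robust_peak: bool = False
    run_raw: bool = True
    run_model: bool = True
    run_phylo: bool = True
    run_nonphylo: bool = True
    apply_exclusions: bool = True
    variant_species_average: bool = False
    variant_onset_mass: bool = False
    variant_shape_covariate: bool = False
    variant_ratio: bool = False
    mcmc_iterations: int = 60_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _seed_for(base_seed: int, tag: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    h = np.uint64(14695981039346656037)
    for b in f"{base_seed}:{tag}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % np.uint64(2**31 - 1))


def fit_all_patterns(
    patterns, characteristics: pd.DataFrame, apply_exclusions: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Fit the growth curve to every pattern and screen the fits.

    Returns the per-pattern fits table (parameters, derived
    characteristics, shape, goodness of fit, flags) and the list of
    excluded pattern ids (non-converged or abnormal). Time to peak is
    measured from the initial-rate measurement for both the model and the
    raw value so the two are comparable.
    """
    chars = characteristics.set_index("pattern_id")
    rows = []
    for p in patterns:
        if p.pattern_id not in chars.index:
            continue
        raw = chars.loc[p.pattern_id]
        try:
            t, cum = pattern_features.cumulative_series(p)
        except pattern_features.InvalidPatternError as exc:
            logger.info("pattern %s not fitted: %s", p.pattern_id, exc)
            continue
        t_first = p.analysable()[0][0]
        raw_tpeak_shifted = float(raw["time_to_peak"]) - t_first
        try:
            fit = vb_growth.fit_vb(
                t, cum, pattern_id=p.pattern_id,
                t_peak_guess=raw_tpeak_shifted if raw_tpeak_shifted > 0 else None,
            )
        except vb_growth.FitError as exc:
            logger.info("pattern %s: %s", p.pattern_id, exc)
            fit = vb_growth.VBFit(p.pattern_id, np.nan, np.nan, np.nan,
                                  converged=False, nrmse_cumulative=np.nan,
                                  message=str(exc))
        row = {
            "pattern_id": p.pattern_id,
            "species": p.species,
            "breed": p.breed,
            "diet_me_mj_per_kg_dm": p.diet_me_density,
            "mass_peak_kg": p.mass_peak_kg,
            "mass_onset_kg": p.mass_onset_kg,
            "A": fit.A,
            "k": fit.k,
            "c": fit.c,
            "converged": fit.converged,
            "nrmse_cumulative": fit.nrmse_cumulative,
            "raw_time_to_peak_shifted": raw_tpeak_shifted,
        }
        if fit.converged and fit.derived:
            row["vb_time_to_peak"] = fit.derived["time_to_peak"]
            row["vb_amplitude"] = fit.derived["amplitude"]
            row["vb_cumulative_to_peak"] = fit.derived["cumulative_to_peak"]
            row["shape"] = fit.derived["shape"]
            t_obs, y_obs = p.analysable()
            rate_obs = y_obs - y_obs[0]
            rate_fit = vb_growth.vb_rate(fit.A, fit.k, fit.c, t_obs - t_first)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["nrmse_rate"] = vb_growth.normalized_rmse(rate_obs, rate_fit)
        rows.append(row)
    fits = pd.DataFrame(rows)
    excluded: list[str] = []
    if not fits.empty:
        conv = fits["converged"].to_numpy(bool)
        for pid in fits.loc[~conv, "pattern_id"]:
            excluded.append(str(pid))
            logger.info("excluded %s: optimizer did not converge", pid)
        ok = fits.loc[conv & (fits.get("vb_time_to_peak").notna())]
        flags, r = vb_growth.detect_abnormal_fits(
            ok["vb_time_to_peak"].to_numpy(float),
            ok["raw_time_to_peak_shifted"].to_numpy(float),
        )
        fits["abnormal"] = False
        fits.loc[ok.index, "abnormal"] = flags
        fits.loc[ok.index, "tpeak_rel_diff"] = r
        for pid in ok.loc[flags, "pattern_id"]:
            excluded.append(str(pid))
            logger.info("excluded %s: abnormal fit (time-to-peak outlier)", pid)
    if not apply_exclusions:
        excluded = []
    return fits, excluded


def run_scaling(
    table: pd.DataFrame,
    characteristic: str,
    tree,
    cfg: PipelineConfig,
    mass_column: str = "mass_peak_kg",
    extra_covariates: list[str] | None = None,
) -> dict[str, allometry.ScalingFit]:
    """Fit one characteristic's scaling model, phylo and/or non-phylo."""
    data = allometry.build_design(
        table, characteristic, mass_column=mass_column,
        extra_covariates=extra_covariates,
    )
    fits: dict[str, allometry.ScalingFit] = {}
    if cfg.run_nonphylo:
        fits["no_phylo"] = allometry.fit_lmm(data)
    if cfg.run_phylo:
        fits["phylo"] = allometry.fit_phylo_mcmc(
            data,
            tree,
            n_iter=cfg.mcmc_iterations,
            burn_in=cfg.mcmc_burn_in,
            thin=cfg.mcmc_thin,
            seed=_seed_for(cfg.seed, f"{characteristic}:{mass_column}"),
        )
    return fits


def shape_covariate_run(
    model_table: pd.DataFrame, tree, cfg: PipelineConfig
) -> allometry.ScalingFit:
    """Cumulative-elevation regression with the shape statistic as covariate.

    If the shape is (numerically) constant across patterns it is collinear
    with the intercept; the covariate is then dropped with a log entry and
    the plain regression returned.
    """
    shape = model_table["shape"].to_numpy(float)
    extra = ["shape"]
    if np.nanstd(shape) < 1e-12:
        logger.info("shape covariate constant across patterns; dropped")
        extra = []
    data = allometry.build_design(
        model_table, "vb_cumulative_to_peak", extra_covariates=extra
    )
    return allometry.fit_phylo_mcmc(
        data,
        tree,
        n_iter=cfg.mcmc_iterations,
        burn_in=cfg.mcmc_burn_in,
        thin=cfg.mcmc_thin,
        seed=_seed_for(cfg.seed, "shape_covariate"),
    )


def _fit_to_dict(fit: allometry.ScalingFit) -> dict:
    return {
        "characteristic": fit.characteristic,
        "method": fit.method,
        "coef": fit.coef,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "p": fit.p,
        "variance_components": fit.variance_components,
        "marginal_r2": fit.marginal_r2,
        "lambda": fit.lambda_,
        "n_obs": fit.n_obs,
        "n_species": fit.n_species,
        "extras": fit.extras,
    }


def table_report(fits: dict[str, dict[str, allometry.ScalingFit]]) -> pd.DataFrame:
    """Table-style report: one row per characteristic x phylogeny setting."""
    rows = []
    for characteristic, by_route in fits.items():
        for route, fit in by_route.items():
            row = {
                "characteristic": characteristic,
                "phylogeny_controlled": "Yes" if route == "phylo" else "No",
                "lambda": fit.lambda_ if fit.lambda_ is not None else "",
                "marginal_r2": fit.marginal_r2,
                "n_obs": fit.n_obs,
                "n_species": fit.n_species,
            }
            for nm in fit.coef:
                lo, hi = fit.ci[nm]
                row[nm] = fit.coef[nm]
                row[f"{nm}_ci"] = f"[{lo:.3f}, {hi:.3f}]"
                row[f"{nm}_signif"] = allometry.significance_stars(fit.p[nm])
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the report dictionary that is also written as JSON. Outputs in
    ``out_dir``: ``characteristics.tsv``, ``vb_fits.tsv``,
    ``excluded_patterns.txt``, ``scaling_report.tsv``, ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = phylo.read_newick(config.newick)
    patterns = read_dataset(config.dataset_csv, tree=tree)
    logger.info("loaded %d patterns", len(patterns))

    chars = pattern_features.characteristics_table(
        patterns, robust_peak=config.robust_peak
    )
    if chars.empty:
        raise RuntimeError("feature extraction produced no analysable patterns")
    chars.to_csv(out / "characteristics.tsv", sep="\t", index=False)

    report: dict = {"seed": config.seed, "n_patterns": len(patterns)}
    scaling: dict[str, dict[str, allometry.ScalingFit]] = {}

    fits_tab = pd.DataFrame()
    excluded: list[str] = []
    if config.run_model or config.variant_shape_covariate:
        fits_tab, excluded = fit_all_patterns(
            patterns, chars, apply_exclusions=config.apply_exclusions
        )
        fits_tab.to_csv(out / "vb_fits.tsv", sep="\t", index=False)
        (out / "excluded_patterns.txt").write_text(
            "".join(f"{pid}\n" for pid in excluded)
        )
        report["excluded_patterns"] = excluded
        ok = fits_tab[
            fits_tab["converged"] & ~fits_tab["pattern_id"].isin(excluded)
        ].dropna(subset=["vb_time_to_peak"])
        report["n_model_fitted"] = int(len(ok))
        report["mean_shape"] = float(ok["shape"].mean()) if len(ok) else None
        report["mean_nrmse_cumulative"] = (
            float(ok["nrmse_cumulative"].mean()) if len(ok) else None
        )
        report["mean_nrmse_rate"] = (
            float(ok["nrmse_rate"].mean()) if "nrmse_rate" in ok and len(ok) else None
        )

    if config.run_raw:
        for ch in RAW_CHARACTERISTICS:
            scaling[ch] = run_scaling(chars, ch, tree, config)

    if config.run_model and not fits_tab.empty:
        model_tab = fits_tab[
            fits_tab["converged"] & ~fits_tab["pattern_id"].isin(excluded)
        ].dropna(subset=["vb_time_to_peak"])
        for ch in MODEL_CHARACTERISTICS:
            scaling[ch] = run_scaling(model_tab, ch, tree, config)

        if config.variant_shape_covariate:
            fit = shape_covariate_run(model_tab, tree, config)
            scaling["vb_cumulative_to_peak + shape"] = {"phylo": fit}
            # shape-vs-mass scaling: tests mass independence of the curvature
            scaling["shape"] = run_scaling(model_tab, "shape", tree, config)

    if config.variant_species_average:
        for ch in ("peak_rate", "average_rate"):
            data = allometry.build_design(chars, ch)
            fit = allometry.species_average_analysis(
                data,
                tree,
                n_iter=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin,
                seed=_seed_for(config.seed, f"s3:{ch}"),
            )
            scaling[f"{ch} (species means)"] = {"phylo": fit}

    if config.variant_onset_mass:
        for ch in RAW_CHARACTERISTICS:
            scaling[f"{ch} (onset mass)"] = run_scaling(
                chars, ch, tree, config, mass_column="mass_onset_kg"
            )

    if config.variant_ratio:
        fit = allometry.ratio_scaling(
            chars,
            "peak_rate",
            "initial_rate",
            tree=tree,
            n_iter=config.mcmc_iterations,
            burn_in=config.mcmc_burn_in,
            thin=config.mcmc_thin,
            seed=_seed_for(config.seed, "ratio"),
        )
        scaling["peak_rate / initial_rate"] = {"phylo": fit}

    report["scaling"] = {
        ch: {route: _fit_to_dict(f) for route, f in by.items()}
        for ch, by in scaling.items()
    }
    table_report(scaling).to_csv(out / "scaling_report.tsv", sep="\t", index=False)
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, allow_nan=True)
    )
    return report
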