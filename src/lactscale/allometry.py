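"""Curvilinear allometric regression of intake characteristics on body mass.

Each characteristic ``y`` (a rate in MJ/day, a duration in days, or a
cumulative energy in MJ) is modelled on the log10 scale as

    log10(y) = intercept + b1*x + b2*x^2 + diet_coef*d + u_species + u_breed + e

with ``x = log10(maternal body mass, kg)`` and ``d`` the diet
metabolizable-energy density (MJ/kg DM, untransformed). On the raw scale
this is the scaling law ``y = a * mass^(b1 + b2*log10(mass))`` whose
normalization constant depends on the diet; the *local* scaling exponent
at mass ``M`` is ``b = b1 + b2*log10(M)``, so ``b2 != 0`` means
curvilinear log-log scaling.

Two fitting routes are provided behind the same result type:

* :func:`fit_lmm` — restricted maximum likelihood via
  :class:`statsmodels` MixedLM, with species and breed-within-species
  random intercepts (no phylogeny); Wald intervals and p-values.
* :func:`fit_phylo_mcmc` — a Gibbs-sampled Bayesian animal model in
  which the species effects are correlated according to the
  Brownian-motion tree covariance ``V``: ``u_species ~ N(0, s2_phylo*V)``
  mapped to the repeated measures through an incidence matrix, plus
  ``u_breed ~ N(0, s2_breed*I)`` and ``e ~ N(0, s2_resid*I)``. Priors are
  flat on the fixed effects and weakly informative inverse-gamma
  (shape 0.001, scale 0.001) on each variance; the conditional updates
  are the standard mixed-model-equations normal draw for (beta, u) and
  inverse-gamma draws for the variances. Phylogenetic signal is reported
  as lambda = s2_phylo / (s2_phylo + s2_breed + s2_resid), the posterior
  mean of the per-draw ratio.

Goodness of fit is the marginal r^2 of Nakagawa & Schielzeth:
``var(X beta) / (var(X beta) + sum(variance components) + s2_resid)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import phylo as _phylo

__all__ = [
    "ScalingData",
    "ScalingFit",
    "VariancePriors",
    "build_design",
    "fit_lmm",
    "fit_phylo_mcmc",
    "marginal_r2",
    "local_exponent",
    "species_average_analysis",
    "ratio_scaling",
    "significance_stars",
]

#: design-column -> reported coefficient name
_COEF_NAMES = {"const": "intercept", "x": "b1", "x2": "b2", "d": "diet_coef"}


def local_exponent(b1: float, b2: float, mass_kg: float) -> float:
    """Local scaling exponent ``b1 + b2 * log10(mass_kg)`` at a body mass."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return b1 + b2 * np.log10(mass_kg)


def significance_stars(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class ScalingData:
    """Design table for one characteristic's scaling regression."""

    characteristic: str
    df: pd.DataFrame  # columns: pattern_id, y, x, x2, d, species, breed, extras...
    extra_covariates: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_species(self) -> int:
        return self.df["species"].nunique()

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        cols = ["const", "x", "x2", "d"] + list(self.extra_covariates)
        X = np.column_stack(
            [np.ones(len(self.df))]
            + [self.df[c].to_numpy(float) for c in cols[1:]]
        )
        return X, cols


@dataclass
class ScalingFit:
    """Estimated scaling relationship for one characteristic.

    ``coef``, ``ci``, ``p`` are keyed by coefficient name (``intercept``,
    ``b1``, ``b2``, ``diet_coef``, plus any extra covariates). For the
    MCMC route the point estimates are posterior means, the intervals 95 %
    equal-tailed credible intervals and the p-values pMCMC; for REML they
    are point estimates with Wald intervals/p-values. ``lambda_`` is the
    posterior-mean phylogenetic signal (MCMC only).
    """

    characteristic: str
    method: str  # "reml" or "mcmc"
    coef: dict[str, float]
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    variance_components: dict[str, float]
    marginal_r2: float
    lambda_: float | None = None
    n_obs: int = 0
    n_species: int = 0
    draws: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    def local_exponent(self, mass_kg: float) -> float:
        return local_exponent(self.coef["b1"], self.coef["b2"], mass_kg)


def build_design(
    table: pd.DataFrame,
    characteristic: str,
    mass_column: str = "mass_peak_kg",
    extra_covariates: list[str] | None = None,
) -> ScalingData:
    """Build the regression design for one characteristic.

    ``table`` has one row per pattern with the characteristic columns and
    covariates (as produced by the feature-extraction or model-fitting
    stages). The body-mass column is selectable: mass at the time of peak
    intake by default, mass at lactation onset for the sensitivity
    variant. Rows with a non-positive characteristic (log undefined) are
    dropped and recorded.
    """
    extra_covariates = list(extra_covariates or [])
    needed = [characteristic, mass_column, "diet_me_mj_per_kg_dm", "species"]
    for col in needed + extra_covariates:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r} in characteristics table")
    ok = (table[characteristic] > 0) & (table[mass_column] > 0)
    ok &= np.isfinite(table[characteristic]) & np.isfinite(table[mass_column])
    dropped = (
        table.loc[~ok, "pattern_id"].astype(str).tolist()
        if "pattern_id" in table.columns
        else []
    )
    if dropped:
        warnings.warn(
            f"{characteristic}: dropped rows with non-positive values: {dropped}"
        )
    sub = table.loc[ok]
    if sub.empty:
        raise ValueError(f"no usable rows for characteristic {characteristic!r}")
    x = np.log10(sub[mass_column].to_numpy(float))
    df = pd.DataFrame(
        {
            "pattern_id": (
                sub["pattern_id"].astype(str)
                if "pattern_id" in sub.columns
                else np.arange(len(sub)).astype(str)
            ),
            "y": np.log10(sub[characteristic].to_numpy(float)),
            "x": x,
            "x2": x * x,
            "d": sub["diet_me_mj_per_kg_dm"].to_numpy(float),
            "species": sub["species"].astype(str).to_numpy(),
            "breed": (
                sub["breed"].astype(str).to_numpy()
                if "breed" in sub.columns
                else sub["species"].astype(str).to_numpy()
            ),
        }
    )
    for c in extra_covariates:
        df[c] = sub[c].to_numpy(float)
    df = df.reset_index(drop=True)
    return ScalingData(characteristic, df, extra_covariates, dropped)


# ---------------------------------------------------------------------------
# REML route (no phylogeny): statsmodels MixedLM
# ---------------------------------------------------------------------------


def fit_lmm(data: ScalingData) -> ScalingFit:
    """REML linear mixed model with species and breed-in-species intercepts.

    Singular variance components are reported as (near-)zero with a
    warning rather than failing.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if data.n_species < 2:
        raise ValueError("need at least 2 species")
    df = data.df.copy()
    df["species_breed"] = df["species"] + ":" + df["breed"]
    fixed = "y ~ x + x2 + d" + "".join(f" + {c}" for c in data.extra_covariates)
    # breed appears as a variance component nested within the species groups
    multi_breed = df.groupby("species")["species_breed"].nunique().max() > 1
    vc = {"breed": "0 + C(species_breed)"} if multi_breed else None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(fixed, df, groups=df["species"], re_formula="1",
                            vc_formula=vc)
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True)
    singular = any("singular" in str(w.message).lower() or
                   "converge" in str(w.message).lower() for w in caught)
    if singular:
        warnings.warn(
            f"{data.characteristic}: variance structure near-singular; "
            "some components may be estimated at zero"
        )

    names = ["Intercept", "x", "x2", "d"] + list(data.extra_covariates)
    coef, ci, p = {}, {}, {}
    conf = res.conf_int()
    for nm in names:
        out = _COEF_NAMES.get("const" if nm == "Intercept" else nm,
                              "intercept" if nm == "Intercept" else nm)
        coef[out] = float(res.fe_params[nm])
        ci[out] = (float(conf.loc[nm, 0]), float(conf.loc[nm, 1]))
        p[out] = float(res.pvalues[nm])

    s2_species = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    s2_breed = float(res.vcomp[0]) if vc is not None and len(res.vcomp) else 0.0
    s2_resid = float(res.scale)
    vcs = {"species": s2_species, "breed": s2_breed, "resid": s2_resid}

    X, cols = data.design_matrix()
    beta = np.array([coef[_COEF_NAMES.get(c, c)] for c in cols])
    r2 = marginal_r2(beta, X, [s2_species, s2_breed], s2_resid)

    return ScalingFit(
        characteristic=data.characteristic,
        method="reml",
        coef=coef,
        ci=ci,
        p=p,
        variance_components=vcs,
        marginal_r2=r2,
        lambda_=None,
        n_obs=data.n_obs,
        n_species=data.n_species,
        diagnostics={"converged": bool(res.converged), "singular": singular},
    )


def marginal_r2(
    beta: np.ndarray, X: np.ndarray, variance_components, s2_resid: float
) -> float:
    """Nakagawa-Schielzeth marginal r^2: fixed-effect variance share."""
    var_fixed = float(np.var(X @ np.asarray(beta, float)))
    denom = var_fixed + float(np.sum(variance_components)) + float(s2_resid)
    return var_fixed / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Bayesian animal model: Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class VariancePriors:
    """Inverse-gamma priors for the variance components.

    Each variance gets an inverse-gamma(shape, scale) prior; the defaults
    (0.001, 0.001) are weakly informative. Fixed effects have improper
    flat priors.
    """

    shape: float = 0.001
    scale: float = 0.001


def _incidence(levels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    uniq = sorted(set(levels))
    index = {u: i for i, u in enumerate(uniq)}
    Z = np.zeros((len(levels), len(uniq)))
    Z[np.arange(len(levels)), [index[v] for v in levels]] = 1.0
    return Z, uniq


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of one scalar chain (split into two halves)."""
    n = draws.size // 2
    if n < 4:
        return np.nan
    chains = np.stack([draws[:n], draws[n : 2 * n]])
    mean_c = chains.mean(axis=1)
    var_c = chains.var(axis=1, ddof=1)
    W = var_c.mean()
    B = n * mean_c.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _pmcmc(draws: np.ndarray) -> float:
    """MCMC p-value: 2 * min(Pr(draw > 0), Pr(draw < 0)), floored at 2/n."""
    n = draws.size
    p = 2.0 * min(np.mean(draws > 0), np.mean(draws < 0))
    return float(max(p, 2.0 / n))


def fit_phylo_mcmc(
    data: ScalingData,
    tree,
    priors: VariancePriors | None = None,
    n_iter: int = 60_000,
    burn_in: int = 10_000,
    thin: int = 25,
    seed: int = 0,
    fixed_variances: dict[str, float] | None = None,
    include_breed: bool = True,
) -> ScalingFit:
    """Phylogenetically informed Bayesian mixed regression (animal model).

    Species effects are drawn with covariance ``s2_phylo * V`` where ``V``
    is the Brownian covariance of the (pruned, unit-height) tree, so
    multiple patterns per species share one phylogenetically structured
    effect without any weighting. See the module docstring for the full
    model and the sampler's conditional updates.

    ``fixed_variances`` pins chosen components (keys ``"phylo"``,
    ``"breed"``, ``"resid"``) at given values instead of sampling them —
    the degenerate-prior limit, useful for validating the fixed-effect
    update against generalized least squares.

    Chain lengths default to a desk-scale 60,000 iterations with 10,000
    burn-in and thinning of 25 (2,000 retained draws); split-R-hat above
    1.1 on any fixed effect is reported as a warning in ``diagnostics``.
    """
    priors = priors or VariancePriors()
    fixed_variances = dict(fixed_variances or {})
    rng = np.random.default_rng(seed)

    species = data.df["species"].to_numpy()
    pruned, report = _phylo.prune_and_match(tree, list(dict.fromkeys(species)))
    keep = np.array([sp in report.matched for sp in species])
    df = data.df.loc[keep].reset_index(drop=True)
    if report.unmatched_species:
        warnings.warn(
            f"{data.characteristic}: {len(report.unmatched_species)} species "
            "dropped from the phylogenetic fit (not on tree)"
        )
    sub = ScalingData(data.characteristic, df, data.extra_covariates)
    if sub.n_species < 2:
        raise ValueError("need at least 2 tree-matched species")

    V = _phylo.vcv_matrix(pruned, scale_to_unit=True)
    eigmin = float(np.linalg.eigvalsh(V.values).min())
    if eigmin < -1e-10:
        raise ValueError(f"tree covariance is not positive semidefinite ({eigmin})")

    y = df["y"].to_numpy(float)
    X, cols = sub.design_matrix()
    n, p = X.shape

    tip_of = {sp: tip for sp, tip in report.matched.items()}
    sp_levels = list(V.index)  # tip-label order of the covariance
    sp_index = {lab: i for i, lab in enumerate(sp_levels)}
    Za = np.zeros((n, len(sp_levels)))
    Za[np.arange(n), [sp_index[tip_of[sp]] for sp in df["species"]]] = 1.0
    qa = Za.shape[1]

    if include_breed:
        Zb, _ = _incidence((df["species"] + ":" + df["breed"]).to_numpy())
    else:
        Zb = np.zeros((n, 0))
    qb = Zb.shape[1]

    Vj = V.values + 1e-10 * np.eye(qa)
    Vinv = cho_solve(cho_factor(Vj, lower=True), np.eye(qa))

    W = np.hstack([X, Za, Zb])
    WtW = W.T @ W
    Wty = W.T @ y
    dim = p + qa + qb

    # start variances from the OLS residual variance
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_tot = max(float(np.var(y - X @ beta_ols)), 1e-8)
    s_phylo = fixed_variances.get("phylo", s2_tot / 3)
    s_breed = fixed_variances.get("breed", s2_tot / 3) if qb else 0.0
    s_resid = fixed_variances.get("resid", s2_tot / 3)

    a0, b0 = priors.shape, priors.scale
    ia, ib = slice(p, p + qa), slice(p + qa, dim)
    n_keep = (n_iter - burn_in) // thin
    out_beta = np.empty((n_keep, p))
    out_var = np.empty((n_keep, 3))
    kept = 0

    fe_idx = np.arange(p)
    for it in range(n_iter):
        M = WtW / s_resid
        M[ia, ia] += Vinv / s_phylo
        if qb:
            idx = np.arange(p + qa, dim)
            M[idx, idx] += 1.0 / s_breed
        # tiny ridge on the flat-prior fixed-effect block so near-collinear
        # designs (e.g. a nearly constant covariate) stay factorizable
        M[fe_idx, fe_idx] += 1e-10 * np.max(np.diagonal(M))
        cf = cho_factor(M, lower=True)
        mean = cho_solve(cf, Wty / s_resid)
        z = rng.standard_normal(dim)
        theta = mean + solve_triangular(cf[0], z, lower=True, trans="T")

        ua = theta[ia]
        resid = y - W @ theta
        if "phylo" not in fixed_variances:
            ss = float(ua @ (Vinv @ ua))
            s_phylo = 1.0 / rng.gamma(a0 + qa / 2, 1.0 / (b0 + ss / 2))
        if qb and "breed" not in fixed_variances:
            ub = theta[ib]
            s_breed = 1.0 / rng.gamma(a0 + qb / 2, 1.0 / (b0 + float(ub @ ub) / 2))
        if "resid" not in fixed_variances:
            s_resid = 1.0 / rng.gamma(a0 + n / 2, 1.0 / (b0 + float(resid @ resid) / 2))

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            out_beta[kept] = theta[:p]
            out_var[kept] = (s_phylo, s_breed, s_resid)
            kept += 1

    out_beta = out_beta[:kept]
    out_var = out_var[:kept]
    coef_names = [_COEF_NAMES.get(c, c) for c in cols]
    draws = pd.DataFrame(out_beta, columns=coef_names)
    draws[["s2_phylo", "s2_breed", "s2_resid"]] = out_var
    lam_draws = out_var[:, 0] / out_var.sum(axis=1)
    draws["lambda"] = lam_draws

    coef = {nm: float(draws[nm].mean()) for nm in coef_names}
    ci = {
        nm: tuple(np.percentile(draws[nm], [2.5, 97.5]).astype(float))
        for nm in coef_names
    }
    pvals = {nm: _pmcmc(draws[nm].to_numpy()) for nm in coef_names}
    vcs = {
        "phylo": float(out_var[:, 0].mean()),
        "breed": float(out_var[:, 1].mean()),
        "resid": float(out_var[:, 2].mean()),
    }
    r2_draws = [
        marginal_r2(out_beta[i], X, out_var[i, :2], out_var[i, 2])
        for i in range(kept)
    ]
    rhat = {nm: _split_rhat(draws[nm].to_numpy()) for nm in coef_names}
    warn_list = [
        f"split-R-hat {v:.3f} > 1.1 for {nm}" for nm, v in rhat.items() if v > 1.1
    ]
    for w in warn_list:
        warnings.warn(f"{data.characteristic}: {w}")

    return ScalingFit(
        characteristic=data.characteristic,
        method="mcmc",
        coef=coef,
        ci=ci,
        p=pvals,
        variance_components=vcs,
        marginal_r2=float(np.mean(r2_draws)),
        lambda_=float(np.mean(lam_draws)),
        n_obs=n,
        n_species=sub.n_species,
        draws=draws,
        diagnostics={
            "rhat": rhat,
            "warnings": warn_list,
            "n_retained": kept,
            "unmatched_species": report.unmatched_species,
        },
    )


# ---------------------------------------------------------------------------
# Variant analyses
# ---------------------------------------------------------------------------


def collapse_to_species_means(data: ScalingData) -> ScalingData:
    """Average y, x, x^2 and diet per species (one row per species)."""
    agg = {"y": "mean", "x": "mean", "x2": "mean", "d": "mean"}
    for c in data.extra_covariates:
        agg[c] = "mean"
    df = data.df.groupby("species", as_index=False).agg(agg)
    df["breed"] = df["species"]
    df["pattern_id"] = df["species"]
    return ScalingData(data.characteristic, df, list(data.extra_covariates))


def species_average_analysis(data: ScalingData, tree, **mcmc_kwargs) -> ScalingFit:
    """Species-averaged variant: one point per species, no breed effect.

    Collapses each species to its mean log-characteristic and mean
    covariates, then runs the same sampler with an identity species
    incidence — a Bayesian phylogenetic GLS.
    """
    if data.n_species < 3:
        raise ValueError("need at least 3 species for a species-level analysis")
    collapsed = collapse_to_species_means(data)
    fit = fit_phylo_mcmc(collapsed, tree, include_breed=False, **mcmc_kwargs)
    fit.characteristic = f"{data.characteristic} (species means)"
    return fit


def ratio_scaling(
    table: pd.DataFrame,
    numerator: str,
    denominator: str,
    tree=None,
    mass_column: str = "mass_peak_kg",
    **mcmc_kwargs,
) -> ScalingFit:
    """Scaling of the ratio of two characteristics (e.g. peak / initial rate).

    Fits the same model to ``y = log10(numerator / denominator)``; rows
    with a non-positive denominator are dropped. The back-transformed
    fixed-effect prediction at the covariate means is reported as
    ``extras["fold_change"]``.
    """
    tab = table.copy()
    ok = (tab[numerator] > 0) & (tab[denominator] > 0)
    tab = tab.loc[ok].copy()
    name = f"{numerator}_over_{denominator}"
    tab[name] = tab[numerator] / tab[denominator]
    data = build_design(tab, name, mass_column=mass_column)
    if tree is not None:
        fit = fit_phylo_mcmc(data, tree, **mcmc_kwargs)
    else:
        fit = fit_lmm(data)
    X, cols = data.design_matrix()
    beta = np.array([fit.coef[_COEF_NAMES.get(c, c)] for c in cols])
    fit.extras["fold_change"] = float(10.0 ** (X.mean(axis=0) @ beta))
    return fit
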