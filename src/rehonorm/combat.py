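"""Parametric empirical-Bayes ComBat harmonization of multi-site features.

Removes additive (location) and multiplicative (scale) site effects per
site x region while preserving the covariate-explained structure (age,
sex, and optionally diagnosis).  Location effects get a normal prior and
scale effects an inverse-gamma prior, both estimated across regions within
each site, with posterior (shrunken) estimates obtained by the standard
iterative conditional scheme.

Model for feature r of subject i at site s:

    y_isr = alpha_r + x_i beta_r + gamma_sr + delta_sr * eps_isr

Harmonization standardizes each feature, subtracts the shrunken site
location gamma*_sr, divides by the shrunken site scale delta*_sr, and
restores the grand mean plus covariate fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HarmonizationModel:
    sites: list  # site labels, fixed order
    region_names: list[str]
    beta_hat: np.ndarray       # (n_sites + n_cov) x R full design coefficients
    grand_mean: np.ndarray     # R
    var_pooled: np.ndarray     # R
    gamma_star: np.ndarray     # n_sites x R (EB-shrunken location)
    delta_star: np.ndarray     # n_sites x R (EB-shrunken scale, > 0)
    gamma_bar: np.ndarray      # n_sites (normal prior mean)
    t2: np.ndarray             # n_sites (normal prior variance)
    a_prior: np.ndarray        # n_sites (inverse-gamma shape)
    b_prior: np.ndarray        # n_sites (inverse-gamma rate)
    n_covariates: int = 0
    covariate_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "sites": [str(s) for s in self.sites],
            "region_names": self.region_names,
            "covariate_names": self.covariate_names,
            "n_covariates": self.n_covariates,
        }
        for name in (
            "beta_hat",
            "grand_mean",
            "var_pooled",
            "gamma_star",
            "delta_star",
            "gamma_bar",
            "t2",
            "a_prior",
            "b_prior",
        ):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            name: np.asarray(payload[name])
            for name in (
                "beta_hat",
                "grand_mean",
                "var_pooled",
                "gamma_star",
                "delta_star",
                "gamma_bar",
                "t2",
                "a_prior",
                "b_prior",
            )
        }
        return cls(
            sites=payload["sites"],
            region_names=payload["region_names"],
            covariate_names=payload["covariate_names"],
            n_covariates=payload["n_covariates"],
            **arrays,
        )


def _design(site_codes: np.ndarray, n_sites: int, covariates: np.ndarray | None):
    onehot = np.eye(n_sites)[site_codes]
    if covariates is None or covariates.shape[1] == 0:
        return onehot
    return np.hstack([onehot, covariates])


def _as_covariate_array(covariates) -> tuple[np.ndarray | None, list[str]]:
    if covariates is None:
        return None, []
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.copy()
        for col in cov.columns:
            if cov[col].dtype == object or str(cov[col].dtype) == "category":
                cov[col] = pd.factorize(cov[col])[0]
        return cov.to_numpy(dtype=float), [str(c) for c in cov.columns]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, tol=1e-4, max_iter=100):
    """Iterative conditional posterior for one site's gamma*, delta*.

    s_data: n_site x R standardized data; updates run until the maximum
    relative change of both estimates drops below ``tol`` (the convergence
    criterion of the reference implementations, kept so results agree with
    them to machine precision).
    """
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def fit_combat(
    features: pd.DataFrame,
    site,
    covariates=None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the parametric EB ComBat model.

    Parameters
    ----------
    features : subjects x regions DataFrame.
    site : per-subject site labels.
    covariates : design whose effects are preserved (e.g. age, sex); a
        DataFrame (categoricals factorized) or array, or None.
    """
    x = features.to_numpy(dtype=float)
    n, n_regions = x.shape
    site = np.asarray(site)
    if len(site) != n:
        raise ValueError("site labels must match number of subjects")
    sites, site_codes = np.unique(site, return_inverse=True)
    n_sites = len(sites)
    if n_sites < 2:
        raise ValueError(
            "ComBat needs >= 2 sites; for single-site data skip harmonization"
        )
    counts = np.bincount(site_codes)
    if counts.min() < 2:
        raise ValueError("every site needs >= 2 subjects")

    cov, cov_names = _as_covariate_array(covariates)
    design = _design(site_codes, n_sites, cov)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear covariates)")

    # data is transposed to regions x subjects internally (genes x samples)
    dat = x.T
    beta_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # p x R
    grand_mean = (counts / n) @ beta_hat[:n_sites]
    resid = dat - (design @ beta_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance in at least one region")

    stand_mean = grand_mean[:, None] @ np.ones((1, n))
    if cov is not None:
        stand_mean += (cov @ beta_hat[n_sites:]).T
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]  # R x n

    gamma_hat = np.vstack(
        [s_data[:, site_codes == s].mean(axis=1) for s in range(n_sites)]
    )
    delta_hat = np.vstack(
        [s_data[:, site_codes == s].var(axis=1, ddof=1) for s in range(n_sites)]
    )
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for s in range(n_sites):
        gamma_star[s], delta_star[s] = _it_sol(
            s_data[:, site_codes == s].T,
            gamma_hat[s],
            delta_hat[s],
            gamma_bar[s],
            t2[s],
            a_prior[s],
            b_prior[s],
            tol=tol,
            max_iter=max_iter,
        )

    return HarmonizationModel(
        sites=list(sites),
        region_names=[str(c) for c in features.columns],
        beta_hat=beta_hat,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_covariates=0 if cov is None else cov.shape[1],
        covariate_names=cov_names,
    )


def apply_combat(
    model: HarmonizationModel,
    features: pd.DataFrame,
    site,
    covariates=None,
) -> pd.DataFrame:
    """Remove site effects:  y* = (y_std - gamma*) / delta* , rescaled back."""
    x = features.to_numpy(dtype=float)
    n = x.shape[0]
    site = np.asarray(site)
    # string-keyed so a JSON round trip of the model keeps sites matchable
    site_lut = {str(s): i for i, s in enumerate(model.sites)}
    try:
        site_codes = np.array([site_lut[str(s)] for s in site])
    except KeyError as exc:
        raise ValueError(f"site {exc.args[0]!r} was not seen during fitting") from exc

    cov, _ = _as_covariate_array(covariates)
    if (0 if cov is None else cov.shape[1]) != model.n_covariates:
        raise ValueError("covariate count differs from the fitted model")

    n_sites = len(model.sites)
    dat = x.T
    stand_mean = model.grand_mean[:, None] @ np.ones((1, n))
    if cov is not None:
        stand_mean += (cov @ model.beta_hat[n_sites:]).T
    s_data = (dat - stand_mean) / np.sqrt(model.var_pooled)[:, None]
    adj = (s_data - model.gamma_star[site_codes].T) / np.sqrt(
        model.delta_star[site_codes].T
    )
    out = adj * np.sqrt(model.var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out.T, index=features.index, columns=features.columns)


def harmonize(
    features: pd.DataFrame, site, covariates=None, **kwargs
) -> tuple[pd.DataFrame, HarmonizationModel]:
    """Fit and apply in one call (the usual entry point)."""
    model = fit_combat(features, site, covariates, **kwargs)
    return apply_combat(model, features, site, covariates), model
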