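"""Per-region Gaussian-process normative models of ReHo on age and sex.

Each of the 246 regions gets an independent GP regression of regional ReHo
on [age, sex] fitted to healthy controls.  The kernel is a sum of a
squared-exponential (anisotropic over standardized age and the 0/1 sex
code), a linear (dot-product) term, and white noise; hyperparameters are
chosen by maximizing the log marginal likelihood with restarts.  The model
yields, at any covariate point, a predictive mean mu, a function variance
sigma_f^2, and the noise variance sigma_n^2; an individual's deviation is

    Z = (y - mu) / sqrt(sigma_f^2 + sigma_n^2)

with |Z| > 2.6 (two-sided p < 0.005 under normality) flagged extreme.
Model accuracy is assessed by k-fold cross-validation with standardized
mean squared error (SMSE; 1 = no better than the mean) and mean
standardized log loss (MSLL; 0 = trivial Gaussian, negative = better).
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field

from sklearn.exceptions import ConvergenceWarning

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

EXTREME_Z = 2.6


@dataclass
class GPRRegionModel:
    """Fitted per-region GP with covariate/target standardization folded in."""

    gpr: GaussianProcessRegressor
    age_mean: float
    age_sd: float
    y_mean: float
    y_sd: float
    noise_variance: float  # on the original target scale
    log_marginal_likelihood: float
    age_support: tuple[float, float]
    region: str = ""

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = X.copy()
        Xs[:, 0] = (Xs[:, 0] - self.age_mean) / self.age_sd
        return Xs

    def predict(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Posterior mean, function variance sigma_f^2 (noise excluded),
        and a boolean extrapolation flag per row (age outside training
        support)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu_s, sd_s = self.gpr.predict(self._transform(X), return_std=True)
        noise_std_scale = self.noise_variance / self.y_sd**2
        var_f_s = np.clip(sd_s**2 - noise_std_scale, 0.0, None)
        mu = self.y_mean + self.y_sd * mu_s
        var_f = self.y_sd**2 * var_f_s
        lo, hi = self.age_support
        extrap = (X[:, 0] < lo) | (X[:, 0] > hi)
        return mu, var_f, extrap


def _make_kernel() -> object:
    return (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e4))
        + DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-3, 1e3))
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e2))
    )


def fit_gpr_region(
    X,
    y,
    seed: int = 0,
    n_restarts: int = 2,
    region: str = "",
) -> GPRRegionModel:
    """Fit one region's GP normative model of y on [age, sex].

    Age is standardized internally; the target is standardized and mapped
    back on prediction.  Hyperparameters maximize the log marginal
    likelihood over ``n_restarts + 1`` seeded starts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be n x 2 ([age, sex])")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(y) < 20:
        raise ValueError("need at least 20 training subjects")
    age_sd = float(X[:, 0].std())
    if age_sd <= 0:
        raise ValueError("age has zero variance")
    age_mean = float(X[:, 0].mean())
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd <= 0:
        y_sd = 1.0  # constant target: keep scale trivial, noise soaks it up

    Xs = X.copy()
    Xs[:, 0] = (Xs[:, 0] - age_mean) / age_sd
    ys = (y - y_mean) / y_sd

    gpr = GaussianProcessRegressor(
        kernel=_make_kernel(),
        n_restarts_optimizer=n_restarts,
        normalize_y=False,
        random_state=np.random.RandomState(seed % (2**31)),
    )
    try:
        with warnings.catch_warnings():
            # hyperparameters pinned at a bound are acceptable optima here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(Xs, ys)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        raise RuntimeError(f"GPR fit failed for region {region!r}: {exc}") from exc

    noise_std_scale = float(gpr.kernel_.k2.noise_level)
    return GPRRegionModel(
        gpr=gpr,
        age_mean=age_mean,
        age_sd=age_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        noise_variance=noise_std_scale * y_sd**2,
        log_marginal_likelihood=float(gpr.log_marginal_likelihood_value_),
        age_support=(float(X[:, 0].min()), float(X[:, 0].max())),
        region=region,
    )


def predict_normative(model: GPRRegionModel, X):
    """Posterior mean and function variance (noise excluded) at X."""
    mu, var_f, extrap = model.predict(X)
    return mu, var_f, extrap


def z_deviation(y_true, mu, var_f, var_n) -> np.ndarray:
    """Z = (y - mu) / sqrt(sigma_f^2 + sigma_n^2), elementwise."""
    y_true = np.asarray(y_true, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var_f = np.asarray(var_f, dtype=float)
    var_n = np.asarray(var_n, dtype=float)
    if np.any(var_f < 0):
        raise ValueError("sigma_f^2 must be nonnegative")
    total = var_f + var_n
    if np.any(total <= 0):
        raise ValueError("total predictive variance must be positive")
    return (y_true - mu) / np.sqrt(total)


def normative_range(model: GPRRegionModel, age_grid, sex, z_level: float = EXTREME_Z):
    """Normative band mu +/- z * sqrt(sigma_f^2 + sigma_n^2) over an age grid."""
    age_grid = np.asarray(age_grid, dtype=float)
    X = np.column_stack([age_grid, np.full_like(age_grid, float(sex))])
    mu, var_f, _ = model.predict(X)
    half = z_level * np.sqrt(var_f + model.noise_variance)
    return mu - half, mu + half


@dataclass
class NormativeModelSet:
    """One GP model per region plus optional cross-validation metrics."""

    models: dict[str, GPRRegionModel]
    population: str = "HC"
    cv_metrics: pd.DataFrame | None = None

    @property
    def regions(self) -> list[str]:
        return list(self.models)

    def deviations(self, features: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
        """Z-deviation map (subjects x regions) for arbitrary subjects."""
        X = covariate_matrix(covariates)
        z = {}
        for name, model in self.models.items():
            mu, var_f, _ = model.predict(X)
            z[name] = z_deviation(
                features[name].to_numpy(), mu, var_f, model.noise_variance
            )
        return pd.DataFrame(z, index=features.index)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "NormativeModelSet":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError("file does not contain a NormativeModelSet")
        return obj


def covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """[age, sex(0/1 with F=1)] design from a cohort-style frame."""
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"]
    if sex.dtype == object:
        sex = (sex == "F").astype(float)
    return np.column_stack([age, sex.to_numpy(dtype=float)])


def fit_normative_set(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 1,
    population: str = "HC",
) -> NormativeModelSet:
    """Fit independent GP models for every region column."""
    X = covariate_matrix(covariates)
    models = {}
    for j, name in enumerate(features.columns):
        models[name] = fit_gpr_region(
            X, features[name].to_numpy(), seed=seed + j, n_restarts=n_restarts,
            region=str(name),
        )
    return NormativeModelSet(models=models, population=population)


def crossval_metrics(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    k_folds: int = 10,
    seed: int = 0,
    n_restarts: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-fold CV of the per-region normative models.

    Returns ``(metrics, z_map)``: per-region SMSE/MSLL (fold-averaged) and
    the held-out Z-deviation map for the training population itself.

    SMSE per fold = mean squared test error / test-target variance.
    MSLL per fold = mean Gaussian negative log predictive density minus the
    same loss for the trivial model (training-fold mean and variance).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = len(features)
    if n // k_folds < 2:
        raise ValueError("folds would contain fewer than 2 subjects")
    X = covariate_matrix(covariates)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(kf.split(X))

    smse = np.zeros((k_folds, features.shape[1]))
    msll = np.zeros((k_folds, features.shape[1]))
    z_map = pd.DataFrame(
        np.nan, index=features.index, columns=features.columns, dtype=float
    )
    for j, name in enumerate(features.columns):
        y = features[name].to_numpy(dtype=float)
        for f, (tr, te) in enumerate(folds):
            model = fit_gpr_region(
                X[tr], y[tr], seed=seed + 1000 * f + j, n_restarts=n_restarts,
                region=str(name),
            )
            mu, var_f, _ = model.predict(X[te])
            total = var_f + model.noise_variance
            err2 = (y[te] - mu) ** 2
            smse[f, j] = err2.mean() / y[te].var(ddof=1)
            loss = 0.5 * np.log(2 * np.pi * total) + err2 / (2 * total)
            triv_var = y[tr].var(ddof=1)
            triv = 0.5 * np.log(2 * np.pi * triv_var) + (y[te] - y[tr].mean()) ** 2 / (
                2 * triv_var
            )
            msll[f, j] = (loss - triv).mean()
            z_map.iloc[te, j] = (y[te] - mu) / np.sqrt(total)

    metrics = pd.DataFrame(
        {"smse": smse.mean(axis=0), "msll": msll.mean(axis=0)},
        index=features.columns,
    )
    return metrics, z_map


def cluster_trajectories(
    model_set: NormativeModelSet,
    sex: float,
    age_grid,
    seed: int = 0,
) -> pd.Series:
    """Group regional age trajectories into increasing/decreasing patterns.

    Each region's predicted mean curve over the grid is standardized and
    the curves are 2-means clustered; the cluster whose mean end-minus-
    start difference is positive is labeled "increasing".
    """
    age_grid = np.asarray(age_grid, dtype=float)
    X = np.column_stack([age_grid, np.full_like(age_grid, float(sex))])
    curves = []
    for name, model in model_set.models.items():
        mu, _, _ = model.predict(X)
        curves.append(mu)
    curves = np.asarray(curves)
    sd = curves.std(axis=1, keepdims=True)
    if np.all(sd < 1e-12) or np.allclose(curves, curves[0]):
        raise ValueError("all trajectories are identical; nothing to cluster")
    std_curves = (curves - curves.mean(axis=1, keepdims=True)) / np.where(
        sd < 1e-12, 1.0, sd
    )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed % (2**31)).fit(std_curves)
    diffs = np.array(
        [
            (std_curves[km.labels_ == c, -1] - std_curves[km.labels_ == c, 0]).mean()
            for c in (0, 1)
        ]
    )
    inc_cluster = int(np.argmax(diffs))
    labels = np.where(km.labels_ == inc_cluster, "increasing", "decreasing")
    return pd.Series(labels, index=model_set.regions, name="trajectory_pattern")
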