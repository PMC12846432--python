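"""Binomial and Poisson GLMs with cluster-robust (sandwich) variance.

Hut-trial proportions (mortality, blood feeding) are modelled by
logistic regression on hut-night binomial counts, adjusting for
treatment arm, hut and bait as categorical fixed effects; nightly
totals can be modelled by Poisson regression with a log link.  The
fit is by iteratively reweighted least squares (IRLS) with
step-halving, and the variance is the cluster-robust sandwich

    V = A^{-1} B A^{-1} * G/(G-1),   A = X'WX,
    B = sum_g s_g s_g',  s_g = sum_{i in g} x_i (y_i - mu_i),

with one cluster g per hut-night (G clusters in all).  Treatment
contrasts are returned on the odds-ratio scale with delta-method CIs
from the robust covariance.

Hut and bait enter as fixed effects rather than random effects: with a
Latin-square rotation the design is balanced over both, the fixed-effect
fit is exactly reproducible, and hut-night clustering absorbs the
residual nightly correlation.  Records enter as binomial counts per
hut-night (successes/trials), which has the same likelihood as
per-mosquito rows on a smaller design matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import COUNT_COLUMNS, TrialDataset

__all__ = [
    "GlmSpec",
    "GlmFit",
    "OrEstimate",
    "SeparationWarning",
    "fit_glm",
    "odds_ratio_contrast",
]

_OUTCOME_FAMILY = {"died": "binomial", "fed": "binomial", "caught": "poisson"}


class SeparationWarning(UserWarning):
    """A factor level has all-success or all-failure outcomes; the
    corresponding coefficient tends to +/- infinity."""


@dataclass(frozen=True)
class GlmSpec:
    """Model specification.

    outcome: 'died' or 'fed' (binomial, logit link, trials = caught)
             or 'caught' (Poisson, log link).
    covariates: categorical fixed effects, reference-cell coded.
    reference: optional explicit reference level per covariate; by
             default the lexicographically first level.
    """

    outcome: str = "died"
    covariates: tuple[str, ...] = ("arm", "hut", "bait")
    reference: dict = field(default_factory=dict)

    @property
    def family(self) -> str:
        try:
            return _OUTCOME_FAMILY[self.outcome]
        except KeyError:
            raise ValueError(f"unknown outcome {self.outcome!r}") from None


@dataclass
class GlmFit:
    """Fitted GLM with model-based and cluster-robust covariances."""

    spec: GlmSpec
    params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame
    n_obs: int
    n_clusters: int
    deviance: float
    converged: bool
    n_iter: int
    reference_levels: dict
    separation: list[str] = field(default_factory=list)
    deviance_path: list[float] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "family": self.spec.family,
            "params": self.params.to_dict(),
            "cov_model": self.cov_model.to_dict(),
            "cov_robust": self.cov_robust.to_dict(),
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "reference_levels": self.reference_levels,
            "separation": self.separation,
        }


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio (or rate ratio) for one treatment contrast."""

    oratio: float
    ci_low: float
    ci_high: float
    p: float
    z: float
    se_log: float

    def __post_init__(self) -> None:
        if self.oratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.oratio <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")


# ---------------------------------------------------------------------------
# design construction


def _aggregate(spec: GlmSpec, ds: TrialDataset) -> pd.DataFrame:
    frame = ds.frame
    cube = frame[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64).reshape(-1, 3, 2, 2)
    out = frame[["night", "hut", "bait", "arm"]].copy()
    out["trials"] = cube.sum(axis=(1, 2, 3))
    if spec.outcome == "died":
        out["y"] = cube[:, :, :, 1].sum(axis=(1, 2))
    elif spec.outcome == "fed":
        out["y"] = cube[:, :, 1, :].sum(axis=(1, 2))
    elif spec.outcome == "caught":
        out["y"] = out["trials"]
    else:
        raise ValueError(f"unknown outcome {spec.outcome!r}")
    out["cluster"] = out["hut"].astype(str) + "|" + out["night"].astype(str)
    if spec.family == "binomial":
        # hut-nights with no catches carry no binomial information
        out = out[out["trials"] > 0].reset_index(drop=True)
    return out

def build_design(spec: GlmSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """Reference-cell coded design matrix with an intercept."""
    columns = ["Intercept"]
    blocks = [np.ones((len(data), 1))]
    references: dict = {}
    for cov in spec.covariates:
        levels = sorted(data[cov].astype(str).unique().tolist())
        ref = str(spec.reference.get(cov, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from covariate {cov!r}")
        references[cov] = ref
        for lev in levels:
            if lev == ref:
                continue
            columns.append(f"{cov}[{lev}]")
            blocks.append((data[cov].astype(str) == lev).to_numpy(float)[:, None])
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after reference-cell coding")
    return X, columns, references


def _detect_separation(spec: GlmSpec, data: pd.DataFrame) -> list[str]:
    flags = []
    if spec.family != "binomial":
        return flags
    for cov in spec.covariates:
        grouped = data.groupby(data[cov].astype(str))[["y", "trials"]].sum()
        for level, row in grouped.iterrows():
            if row["trials"] > 0 and row["y"] in (0, row["trials"]):
                kind = "all-failure" if row["y"] == 0 else "all-success"
                flags.append(f"{cov}[{level}]: {kind} cell (coefficient tends to infinity)")
    return flags


# ---------------------------------------------------------------------------
# IRLS

_EPS = 1e-10


def _mu_weights(family: str, eta: np.ndarray, trials: np.ndarray):
    if family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, _EPS, 1 - _EPS)
        mu = trials * p
        w = trials * p * (1 - p)
    else:  # poisson, log link
        mu = np.exp(np.clip(eta, -500, 30))
        w = mu
    return mu, np.maximum(w, _EPS)


def _deviance(family: str, y: np.ndarray, mu: np.ndarray, trials: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "binomial":
            mu = np.clip(mu, _EPS, trials - _EPS)
            term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            term2 = np.where(
                trials - y > 0, (trials - y) * np.log((trials - y) / (trials - mu)), 0.0
            )
            return float(2.0 * np.sum(term1 + term2))
        mu = np.maximum(mu, _EPS)
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))


def fit_glm(
    spec: GlmSpec,
    ds: TrialDataset,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 20,
) -> GlmFit:
    """Fit the GLM by IRLS with step-halving and a sandwich variance.

    Convergence is declared when the relative deviance change falls
    below ``tol``; a deviance increase triggers step-halving so the
    deviance path is non-increasing.  Separation (an all-0 or all-1
    factor cell) is detected up front and reported as a warning and in
    ``GlmFit.separation``; the coefficient is still reported at the
    point IRLS stops.
    """
    data = _aggregate(spec, ds)
    if data.empty:
        raise ValueError("no usable records for this outcome")
    if data["cluster"].nunique() < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")

    X, columns, references = build_design(spec, data)
    y = data["y"].to_numpy(float)
    trials = data["trials"].to_numpy(float)
    family = spec.family

    separation = _detect_separation(spec, data)
    for msg in separation:
        warnings.warn(msg, SeparationWarning, stacklevel=2)

    # start from the empirical proportions / counts
    if family == "binomial":
        p0 = (y + 0.5) / (trials + 1.0)
        eta = np.log(p0 / (1 - p0))
    else:
        eta = np.log(np.maximum(y, 0.5))
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]

    mu, w = _mu_weights(family, X @ beta, trials)
    dev = _deviance(family, y, mu, trials)
    path = [dev]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu, w = _mu_weights(family, eta, trials)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)

        # step-halving: never let the deviance increase
        step = beta_new - beta
        for _ in range(max_halvings):
            mu_new, _ = _mu_weights(family, X @ (beta + step), trials)
            dev_new = _deviance(family, y, mu_new, trials)
            if dev_new <= dev + 1e-12:
                break
            step /= 2.0
        beta = beta + step
        mu, _ = _mu_weights(family, X @ beta, trials)
        dev_new = _deviance(family, y, mu, trials)
        path.append(dev_new)
        if abs(dev - dev_new) < tol * (abs(dev_new) + tol):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations", UserWarning, stacklevel=2
        )

    mu, w = _mu_weights(family, X @ beta, trials)
    A = (X.T * w) @ X
    A_inv = np.linalg.inv(A)

    scores = X * (y - mu)[:, None]
    score_sums = (
        pd.DataFrame(scores).groupby(data["cluster"].to_numpy()).sum().to_numpy()
    )
    G = score_sums.shape[0]
    B = score_sums.T @ score_sums
    cov_robust = A_inv @ B @ A_inv * (G / (G - 1))
    cov_robust = (cov_robust + cov_robust.T) / 2.0

    return GlmFit(
        spec=spec,
        params=pd.Series(beta, index=columns),
        cov_model=pd.DataFrame(A_inv, index=columns, columns=columns),
        cov_robust=pd.DataFrame(cov_robust, index=columns, columns=columns),
        n_obs=len(data),
        n_clusters=G,
        deviance=dev,
        converged=converged,
        n_iter=n_iter,
        reference_levels=references,
        separation=separation,
        deviance_path=path,
    )


def odds_ratio_contrast(
    fit: GlmFit, candidate: str, reference: str, factor: str = "arm", level: float = 0.95
) -> OrEstimate:
    """Odds ratio candidate vs reference from a fitted model.

    OR = exp(beta_candidate - beta_reference); the CI and two-sided p
    come from the cluster-robust covariance via the delta method on the
    log scale.  The factor's reference-cell level has an implicit zero
    coefficient with zero variance.
    """
    names = list(fit.params.index)
    ref_level = fit.reference_levels.get(factor)
    contrast = np.zeros(len(names))

    def add(levelname: str, sign: float) -> None:
        if levelname == ref_level:
            return
        col = f"{factor}[{levelname}]"
        if col not in names:
            raise KeyError(f"level {levelname!r} of {factor!r} not in fitted model")
        contrast[names.index(col)] += sign

    add(candidate, +1.0)
    add(reference, -1.0)

    log_or = float(contrast @ fit.params.to_numpy())
    var = float(contrast @ fit.cov_robust.to_numpy() @ contrast)
    se = math.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.5 + level / 2)
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = log_or / se
        p = 2.0 * stats.norm.sf(abs(z))
    return OrEstimate(
        oratio=math.exp(log_or),
        ci_low=math.exp(log_or - zq * se),
        ci_high=math.exp(log_or + zq * se),
        p=p,
        z=z,
        se_log=se,
    )
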