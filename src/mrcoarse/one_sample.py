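"""One-sample estimators for individual-level data.

Two routes are provided:

* ``fit_naive`` — the conventional approach with the coarsened measurement
  D used directly as the exposure (Wald ratio / 2SLS).  Its probability
  limit is the analytically biased quantity computed in :mod:`mrcoarse.bias`.
* ``fit_latent`` — the latent-variable estimator: (1) fit a GLM of D on the
  instruments and auxiliary variants, (2) standardise the estimated
  genetic-share linear predictor to mean 0 / SD 1, (3) use it as the
  exposure in a 2SLS regression instrumented by the SNPs, giving an effect
  per SD of the genetic share (beta_G), and (4) rescale by a user-supplied
  sensitivity parameter theta^2 (genetic variance share of the latent
  exposure) to obtain the effect per SD of the latent exposure,
  beta_L = beta_G / sqrt(theta^2).

Because the exposure in step 3 is itself an estimate, analytic IV standard
errors are invalid; confidence intervals come from a nonparametric
bootstrap that re-runs the whole pipeline on each resample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import glm
from .data import (
    DegenerateDataError,
    EstimationError,
    IndividualDataset,
    ValidationError,
)

__all__ = [
    "BootSpec",
    "BootstrapResult",
    "FirstStageResult",
    "LatentFitResult",
    "NaiveFitResult",
    "NoInstrumentsError",
    "bootstrap_ci",
    "fit_first_stage",
    "fit_latent",
    "fit_naive",
    "prune_instruments",
    "standardise",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class NoInstrumentsError(EstimationError):
    """No instruments survive pruning."""


@dataclass
class BootSpec:
    """Bootstrap configuration: B resamples, RNG seed, CI level."""

    B: int = 1000
    seed: int | None = None
    level: float = 0.95


@dataclass
class BootstrapResult:
    ci: tuple
    estimates: np.ndarray
    n_failed: int
    B: int


@dataclass
class NaiveFitResult:
    """Wald/2SLS fit with D as the exposure."""

    beta_D_hat: float
    se: float
    ci: tuple


@dataclass
class FirstStageResult:
    """Estimated GLM linear-predictor parameters and genetic share."""

    fit: glm.GlmFit
    g_tilde: np.ndarray  # mu~ + alpha~'Z + gamma~'X per individual (no covariates)
    link: str
    instruments: np.ndarray  # column indices into data.Z


@dataclass
class LatentFitResult:
    """Output of the four-step latent-variable estimator."""

    beta_G_hat: float
    beta_L_by_theta: dict  # theta^2 -> (beta_L, ci_low, ci_high)
    link: str
    g_tilde_mean: float
    g_tilde_sd: float
    n: int
    J: int
    K: int
    beta_G_ci: tuple = (np.nan, np.nan)
    theta2_model_implied: float = np.nan
    first_stage: FirstStageResult | None = None
    boot: BootstrapResult | None = None


def standardise(g_tilde) -> np.ndarray:
    """Centre and scale to sample mean 0 / SD 1 (ddof=1).

    An affine map only, so any positive affine transform of the input gives
    an identical output — this is what removes the unknown sigma_v scale of
    the first-stage coefficients.
    """
    g = np.asarray(g_tilde, dtype=float)
    sd = g.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("cannot standardise a constant linear predictor")
    return (g - g.mean()) / sd


def _tsls(y: np.ndarray, exog: np.ndarray, instr: np.ndarray):
    """Two-stage least squares with classical homoskedastic IV covariance."""
    n, k = exog.shape
    ztz = instr.T @ instr
    try:
        fitted = instr @ np.linalg.solve(ztz, instr.T @ exog)
        xtpx = fitted.T @ exog
        coef = np.linalg.solve(xtpx, fitted.T @ y)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"rank-deficient IV system: {exc}") from exc
    resid = y - exog @ coef
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(xtpx)
    return coef, cov


def _design(data: IndividualDataset, instruments: np.ndarray, link: str):
    """First-stage design matrix and the slice that defines the genetic share."""
    cols = [data.Z[:, instruments]]
    if data.X is not None:
        cols.append(data.X)
    genetic = np.hstack(cols)
    binary = link in glm.BINARY_LINKS
    parts = ([np.ones((len(data), 1))] if binary else []) + [genetic]
    if data.covariates is not None:
        parts.append(data.covariates)
    design = np.hstack(parts)
    n_genetic = genetic.shape[1] + (1 if binary else 0)
    return design, n_genetic


def _resolve_instruments(data: IndividualDataset, instruments) -> np.ndarray:
    if instruments is None:
        return np.arange(data.n_instruments)
    idx = np.asarray(instruments, dtype=int)
    if idx.size == 0:
        raise ValidationError("at least one instrument is required")
    if idx.min() < 0 or idx.max() >= data.n_instruments:
        raise ValidationError("instrument index out of range")
    return idx


def fit_first_stage(
    data: IndividualDataset,
    link: str = "probit",
    instruments=None,
    start: np.ndarray | None = None,
) -> FirstStageResult:
    """Step 1: GLM of D on instruments Z and auxiliary variants X.

    Covariates (if present in the dataset) enter the model additively but
    are excluded from the returned genetic share ``g_tilde``.  For ordered
    links the cutpoints are likewise excluded; location and scale of
    ``g_tilde`` are irrelevant after standardisation.
    """
    idx = _resolve_instruments(data, instruments)
    design, n_genetic = _design(data, idx, link)
    if link in glm.BINARY_LINKS:
        if data.n_categories > 2:
            raise ValidationError(
                "binary link requested but D has more than 2 categories"
            )
        fit = glm.fit_binary(data.D, design, link=link, start=start)
    elif link in glm.ORDERED_LINKS:
        fit = glm.fit_ordered(data.D, design, link=link, start=start)
    else:
        raise ValidationError(f"unknown link {link!r}")
    g_tilde = design[:, :n_genetic] @ fit.coef[:n_genetic]
    return FirstStageResult(fit=fit, g_tilde=g_tilde, link=link, instruments=idx)


def fit_naive(data: IndividualDataset, instruments=None) -> NaiveFitResult:
    """Wald/2SLS estimate using the coarsened D directly as the exposure.

    A single instrument reduces to the Wald ratio cov(Z,Y)/cov(Z,D);
    covariates, when present, enter both stages additively.
    """
    idx = _resolve_instruments(data, instruments)
    n = len(data)
    const = np.ones((n, 1))
    cov_part = [] if data.covariates is None else [data.covariates]
    exog = np.hstack([const, np.asarray(data.D, dtype=float)[:, None]] + cov_part)
    instr = np.hstack([const, data.Z[:, idx]] + cov_part)
    if np.allclose((data.Z[:, idx] * (data.D - data.D.mean())[:, None]).mean(0), 0):
        raise DegenerateDataError("zero first-stage covariance between Z and D")
    coef, cov = _tsls(data.Y, exog, instr)
    est, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    return NaiveFitResult(beta_D_hat=est, se=se, ci=(est - _Z95 * se, est + _Z95 * se))


def _latent_point(
    data: IndividualDataset,
    link: str,
    instruments: np.ndarray,
    start: np.ndarray | None = None,
):
    """Steps 1-3; returns (beta_G, first_stage, standardised predictor)."""
    fs = fit_first_stage(data, link=link, instruments=instruments, start=start)
    g_std = standardise(fs.g_tilde)
    n = len(data)
    const = np.ones((n, 1))
    cov_part = [] if data.covariates is None else [data.covariates]
    exog = np.hstack([const, g_std[:, None]] + cov_part)
    instr = np.hstack([const, data.Z[:, instruments]] + cov_part)
    coef, _ = _tsls(data.Y, exog, instr)
    return float(coef[1]), fs, g_std


def fit_latent(
    data: IndividualDataset,
    link: str = "probit",
    theta2_grid=(1.0,),
    instruments=None,
    boot: BootSpec | None = None,
) -> LatentFitResult:
    """Four-step latent-variable estimator with optional bootstrap CIs.

    ``theta2_grid`` is the sensitivity grid of genetic-variance shares in
    (0, 1]; for each value, ``beta_L = beta_G / sqrt(theta2)`` exactly.
    Bootstrap CIs re-run the entire pipeline (GLM, standardisation, 2SLS)
    on each resample of individuals; resamples with a degenerate D are
    skipped and counted.
    """
    theta2_grid = [float(t) for t in np.atleast_1d(theta2_grid)]
    if any(t <= 0 or t > 1 for t in theta2_grid):
        raise ValidationError("every theta^2 must lie in (0, 1]")
    idx = _resolve_instruments(data, instruments)

    beta_G, fs, g_std = _latent_point(data, link, idx)
    var_g_tilde = float(fs.g_tilde.var(ddof=1))
    theta2_implied = var_g_tilde / (1.0 + var_g_tilde)
    for t in theta2_grid:
        if not (0.2 * theta2_implied <= t <= 5.0 * theta2_implied):
            warnings.warn(
                f"theta2={t:g} differs substantially from the first-stage-"
                f"implied value {theta2_implied:.4g}; the rescaled estimate "
                "is only as credible as this sensitivity choice",
                UserWarning,
            )
            break

    boot_res = None
    ci_G = (np.nan, np.nan)
    if boot is not None:
        warm = getattr(fs.fit, "full_params", fs.fit.coef)

        def _one(ds: IndividualDataset) -> float:
            return _latent_point(ds, link, idx, start=warm)[0]

        boot_res = bootstrap_ci(_one, data, B=boot.B, seed=boot.seed, level=boot.level)
        ci_G = boot_res.ci

    by_theta = {}
    for t in theta2_grid:
        theta = float(np.sqrt(t))
        by_theta[t] = (beta_G / theta, ci_G[0] / theta, ci_G[1] / theta)

    return LatentFitResult(
        beta_G_hat=beta_G,
        beta_L_by_theta=by_theta,
        link=link,
        g_tilde_mean=float(g_std.mean()),
        g_tilde_sd=float(g_std.std(ddof=1)),
        n=len(data),
        J=int(idx.size),
        K=data.n_auxiliary,
        beta_G_ci=ci_G,
        theta2_model_implied=theta2_implied,
        first_stage=fs,
        boot=boot_res,
    )


def _take(data, idx: np.ndarray):
    if hasattr(data, "take") and not isinstance(data, np.ndarray):
        return data.take(idx)
    if hasattr(data, "iloc"):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def bootstrap_ci(fit, data, B: int = 1000, seed=None, level: float = 0.95) -> BootstrapResult:
    """Nonparametric bootstrap percentile CI for an arbitrary estimator.

    ``fit`` maps a resampled data object to a scalar (or vector) estimate.
    Resamples on which ``fit`` raises an :class:`EstimationError` (e.g. a
    single-class D) are skipped and counted in ``n_failed``.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(data)
    estimates, n_failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(fit(_take(data, idx)))
        except EstimationError:
            n_failed += 1
    if not estimates:
        raise DegenerateDataError("every bootstrap resample failed")
    if n_failed:
        warnings.warn(
            f"{n_failed}/{B} bootstrap resamples failed and were skipped",
            RuntimeWarning,
        )
    arr = np.asarray(estimates, dtype=float)
    tail = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(arr, tail, axis=0)
    hi = np.percentile(arr, 100.0 - tail, axis=0)
    if arr.ndim == 1:
        ci = (float(lo), float(hi))
    else:
        ci = (lo, hi)
    return BootstrapResult(ci=ci, estimates=arr, n_failed=n_failed, B=B)


def prune_instruments(
    data: IndividualDataset,
    exposure=None,
    t_threshold: float = 4.0,
    link: str = "probit",
) -> np.ndarray:
    """Select instruments by conditional first-stage strength.

    Fits one joint first-stage model of the exposure on all candidate
    instruments (plus auxiliary variants and covariates) and keeps the SNPs
    with |t| (OLS, continuous exposure) or |z| (GLM, coarsened exposure)
    above ``t_threshold`` conditional on the others.

    ``exposure=None`` uses the coarsened D with the configured link; a
    continuous vector switches to a linear first stage.
    """
    J = data.n_instruments
    if J < 1:
        raise ValidationError("at least one candidate instrument is required")
    if exposure is None:
        if data.n_categories > 2 and link in glm.BINARY_LINKS:
            link = f"ordered-{link}"
        fs = fit_first_stage(data, link=link)
        offset = 1 if link in glm.BINARY_LINKS else 0
        tstats = fs.fit.zstats[offset : offset + J]
    else:
        y = np.asarray(exposure, dtype=float)
        if y.shape[0] != len(data):
            raise ValidationError("exposure vector length differs from data")
        parts = [np.ones((len(data), 1)), data.Z]
        if data.X is not None:
            parts.append(data.X)
        if data.covariates is not None:
            parts.append(data.covariates)
        Xd = np.hstack(parts)
        coef, res, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ coef
        sigma2 = float(resid @ resid) / (len(data) - Xd.shape[1])
        cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
        tstats = (coef / np.sqrt(np.diag(cov)))[1 : 1 + J]
    selected = np.flatnonzero(np.abs(tstats) > t_threshold)
    if selected.size == 0:
        raise NoInstrumentsError(
            f"no instruments survive pruning at |t| > {t_threshold:g}"
        )
    return selected
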