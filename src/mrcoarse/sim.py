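"""Liability-threshold simulator.

Generates individual-level data and two-sample GWAS-style summary
statistics from the structural model

    L = mu + alpha'Z + gamma'X - V,      D = coarsen(L),      Y = beta*L + delta*D + eps,

with genotypes Binomial(ploidy, p) under HWE, V drawn from a configurable
continuous family scaled to SD sigma_v, an optional random individual
threshold R, and confounding between V and the outcome disturbance.

Randomness is consumed in a fixed order (genotypes, V, R, eps) so a fixed
seed yields bit-identical output.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import expit, ndtr
from scipy.stats import norm

from . import glm
from .data import (
    IndividualDataset,
    ModelParams,
    SeparationError,
    SnpSummary,
    SummaryPair,
    ValidationError,
)

__all__ = [
    "coarsen",
    "simulate_individual",
    "simulate_two_sample",
    "standard_family_cdf",
    "standard_family_pdf",
]

_LOGISTIC_SCALE = math.sqrt(3.0) / math.pi  # unit-SD logistic scale


def standard_family_cdf(v_family):
    """CDF of the standardised (mean-0, SD-1) environmental share V/sigma_v."""
    if v_family == "normal":
        return ndtr
    if v_family == "logistic":
        return lambda x: expit(np.asarray(x, dtype=float) / _LOGISTIC_SCALE)
    m, s = v_family.mean(), v_family.std()
    if not (np.isfinite(m) and np.isfinite(s) and s > 0):
        raise ValidationError("user-supplied v_family needs finite mean and SD > 0")
    return lambda x: v_family.cdf(m + np.asarray(x, dtype=float) * s)


def standard_family_pdf(v_family):
    """Density of the standardised environmental share."""
    if v_family == "normal":
        return norm.pdf
    if v_family == "logistic":
        def _pdf(x):
            z = np.asarray(x, dtype=float) / _LOGISTIC_SCALE
            p = expit(z)
            return p * (1.0 - p) / _LOGISTIC_SCALE
        return _pdf
    m, s = v_family.mean(), v_family.std()
    return lambda x: v_family.pdf(m + np.asarray(x, dtype=float) * s) * s


def _draw_v(rng: np.random.Generator, v_family, sigma_v: float, n: int) -> np.ndarray:
    if v_family == "normal":
        return sigma_v * rng.standard_normal(n)
    if v_family == "logistic":
        return rng.logistic(0.0, sigma_v * _LOGISTIC_SCALE, n)
    draws = np.asarray(v_family.rvs(size=n, random_state=rng), dtype=float)
    return (draws - v_family.mean()) / v_family.std() * sigma_v


def _draw_r(rng: np.random.Generator, r_dist, n: int) -> np.ndarray:
    if isinstance(r_dist, (int, float)):
        return float(r_dist) * rng.standard_normal(n)
    return np.asarray(r_dist.rvs(size=n, random_state=rng), dtype=float)


def coarsen(L, thresholds=(), R=None) -> np.ndarray:
    """Map the latent exposure onto its coarsened measurement.

    Binary (no thresholds): ``D = 1`` iff ``L >= 0`` (or ``L >= R`` when a
    random threshold is supplied).  Ordered: ``D = 0`` iff ``L <= 0``,
    ``D = k`` iff ``d_{k-1} < L <= d_k``, and ``D = K`` iff ``L > d_{K-1}``;
    a random threshold shifts all cutpoints by R.
    """
    L = np.asarray(L, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (thresholds[0] <= 0 or np.any(np.diff(thresholds) <= 0)):
        raise ValidationError("thresholds must satisfy 0 < d1 < d2 < ...")
    if R is not None:
        R = np.asarray(R, dtype=float)
        if R.shape != L.shape:
            raise ValidationError("R must have the same length as L")
        L = L - R
    if thresholds.size == 0:
        return (L >= 0.0).astype(np.int64)
    edges = np.concatenate([[0.0], thresholds])
    return (L[:, None] > edges[None, :]).sum(axis=1).astype(np.int64)


def simulate_individual(params: ModelParams, n: int, seed=None) -> IndividualDataset:
    """Draw an individual-level dataset of size ``n`` from the model.

    The returned dataset carries the latent ground truth (L, G, V) for
    validation; estimators must not touch it.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    J, K = params.n_instruments, params.n_auxiliary
    geno = rng.binomial(params.ploidy, params.snp_freqs, size=(n, J + K)).astype(float)
    Z, X = geno[:, :J], geno[:, J:]
    V = _draw_v(rng, params.v_family, params.sigma_v, n)
    R = _draw_r(rng, params.r_dist, n) if params.r_dist is not None else None
    G = params.mu + Z @ params.alpha + (X @ params.gamma if K else 0.0)
    L = G - V
    D = coarsen(L, params.thresholds, R)
    eps = params.confounding * (V / params.sigma_v) + params.sigma_eps * rng.standard_normal(n)
    Y = params.beta * L + params.delta * D + eps
    return IndividualDataset(
        Z=Z,
        D=D,
        Y=Y,
        X=X if K else None,
        latent={"L": L, "G": G, "V": V},
    )


def _marginal_exposure_scans(
    data: IndividualDataset, link: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP marginal regressions of D on each instrument.

    Binary D uses the requested binary link; ordered D uses the matching
    ordered link.  Returns (alpha_hat, se, ok_mask).
    """
    J = data.n_instruments
    est = np.full(J, np.nan)
    se = np.full(J, np.nan)
    ok = np.zeros(J, dtype=bool)
    ordered = data.n_categories > 2
    use_link = link if not ordered else f"ordered-{link}"
    for j in range(J):
        zj = data.Z[:, j]
        try:
            if ordered:
                fit = glm.fit_ordered(data.D, zj[:, None], link=use_link)
                est[j], se[j] = fit.coef[0], fit.se[0]
            else:
                Xd = np.column_stack([np.ones(len(data)), zj])
                fit = glm.fit_binary(data.D, Xd, link=link)
                est[j], se[j] = fit.coef[1], fit.se[1]
            ok[j] = True
        except SeparationError:
            warnings.warn(
                f"separation in marginal regression for SNP {j}; dropping it",
                RuntimeWarning,
            )
    return est, se, ok


def _marginal_outcome_scans(
    data: IndividualDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-SNP OLS of Y on each instrument (with intercept)."""
    Z, Y = data.Z, data.Y
    n = len(data)
    zc = Z - Z.mean(axis=0)
    yc = Y - Y.mean()
    ssz = np.einsum("ij,ij->j", zc, zc)
    b = (zc.T @ yc) / ssz
    # residual variance per SNP without forming n x J residual matrix twice
    ssy = float(yc @ yc)
    rss = ssy - b**2 * ssz
    sigma2 = rss / (n - 2)
    return b, np.sqrt(sigma2 / ssz)


def simulate_two_sample(
    params: ModelParams,
    n_exposure: int,
    n_outcome: int,
    seeds=(0, 1),
    link: str = "probit",
    outcome_snps=None,
) -> SummaryPair:
    """Assemble two-sample summary statistics from two independent samples.

    The exposure sample yields per-SNP marginal coarsened-exposure
    regressions of D on each instrument (``alpha_hat`` on the linear-
    predictor scale of ``link``); the outcome sample yields per-SNP linear
    regressions of Y on each instrument.  ``outcome_snps`` optionally
    restricts the instrument subset taken from the outcome GWAS (indices
    into the instrument columns); default: all instruments.
    """
    seed_exp, seed_out = seeds
    data_exp = simulate_individual(params, n_exposure, seed_exp)
    data_out = simulate_individual(params, n_outcome, seed_out)
    J = params.n_instruments
    a_hat, a_se, ok = _marginal_exposure_scans(data_exp, link)
    g_hat, g_se = _marginal_outcome_scans(data_out)
    eaf_exp = data_exp.Z.mean(axis=0) / params.ploidy
    eaf_out = data_out.Z.mean(axis=0) / params.ploidy

    subset = np.arange(J) if outcome_snps is None else np.asarray(outcome_snps)
    exposure, outcome = [], []
    for j in range(J):
        if not ok[j]:
            continue
        sid = f"snp_{j + 1}"
        exposure.append(
            SnpSummary(
                snp_id=sid,
                effect_allele="A",
                other_allele="G",
                eaf=float(eaf_exp[j]),
                alpha_hat=float(a_hat[j]),
                alpha_se=float(a_se[j]),
                n=n_exposure,
            )
        )
        if j in subset:
            outcome.append(
                SnpSummary(
                    snp_id=sid,
                    effect_allele="A",
                    other_allele="G",
                    eaf=float(eaf_out[j]),
                    alpha_hat=float(a_hat[j]),
                    alpha_se=float(a_se[j]),
                    gamma_hat=float(g_hat[j]),
                    gamma_se=float(g_se[j]),
                    n=n_outcome,
                )
            )
    return SummaryPair(exposure=exposure, outcome=outcome)
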