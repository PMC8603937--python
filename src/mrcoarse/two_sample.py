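"""Two-sample summary-statistics estimator.

Given per-SNP instrument-exposure associations ``alpha_hat`` (on the
first-stage linear-predictor scale, e.g. log-odds) over a SNP set J, and
instrument-outcome associations ``gamma_hat`` over a subset J0, the
genetic-share effect is estimated as the product of two terms:

    beta_G = [ sum_J alpha_j^2 sigma_Zj^2 ]^{1/2}
             * [ sum_J0 w_j (gamma_j / alpha_j) / sum_J0 w_j ],
      w_j = alpha_j^2 / gamma_se_j^2

i.e. an estimate of the genetic-share SD (on the linear-predictor scale)
times the standard inverse-variance weighted average of per-SNP Wald
ratios.  ``sigma_Zj^2 = 2 p (1 - p)`` under HWE from reported allele
frequencies.  Rescaling by a sensitivity parameter theta^2 gives the
effect per SD of the latent exposure, beta_L = beta_G / sqrt(theta^2).

Mutual independence of the instruments is assumed throughout.  Standard
errors use the delta method over the two (independent) samples, optionally
treating the scale term as fixed, with a parametric bootstrap available as
a cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SummaryPair, ValidationError

__all__ = [
    "TwoSampleResult",
    "snp_variance_from_af",
    "ivw_latent",
    "two_sample_se",
    "parametric_bootstrap_se",
    "reanalysis_grid",
]

_Z95 = 1.959963984540054


@dataclass
class TwoSampleResult:
    """Decomposed two-sample estimate: beta_G = scale_term * ivw_term."""

    scale_term: float  # [sum alpha^2 sigma_Z^2]^{1/2} over the exposure set
    ivw_term: float  # IVW average of Wald ratios over the outcome subset
    beta_G_hat: float
    se_beta_G: float
    beta_L_by_theta: dict  # theta^2 -> (beta_L, ci_low, ci_high)
    n_exposure_snps: int
    n_outcome_snps: int


def snp_variance_from_af(eaf: float) -> float:
    """Genotype dosage variance 2p(1-p) under HWE for a biallelic SNP."""
    eaf = float(eaf)
    if not (0.0 < eaf < 1.0):
        raise ValidationError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf)


def _sorted(records):
    # canonical SNP order makes every output invariant to input row order
    return sorted(records, key=lambda s: s.snp_id)


def _terms(pair: SummaryPair):
    exposure = _sorted(pair.exposure)
    outcome = _sorted(pair.outcome)
    if not exposure or not outcome:
        raise ValidationError("exposure and outcome SNP sets must be nonempty")
    a_all = np.array([s.alpha_hat for s in exposure])
    a_se_all = np.array([s.alpha_se for s in exposure])
    v_all = np.array([snp_variance_from_af(s.eaf) for s in exposure])
    a = np.array([s.alpha_hat for s in outcome])
    if np.any(a == 0.0):
        bad = [s.snp_id for s in outcome if s.alpha_hat == 0.0]
        raise ValidationError(f"alpha_hat is zero for outcome SNP(s) {bad}; "
                              "Wald ratios are undefined")
    g = np.array([s.gamma_hat for s in outcome])
    g_se = np.array([s.gamma_se for s in outcome])
    out_ids = [s.snp_id for s in outcome]
    exp_index = {s.snp_id: i for i, s in enumerate(exposure)}
    out_pos = np.array([exp_index[i] for i in out_ids])
    return a_all, a_se_all, v_all, a, g, g_se, out_pos


def ivw_latent(pair: SummaryPair, theta2_grid=(1.0,), se_scale_noise: bool = True) -> TwoSampleResult:
    """Two-sample estimate of beta_G with theta^2-rescaled beta_L values.

    The scale term is computed over the full exposure set and the IVW term
    over the outcome subset; when the two coincide the estimate uses a
    subset-based genetic-share SD (warn upstream if that subset is small).
    Wald 95% CIs for beta_L use the delta-method SE of beta_G.
    """
    theta2_grid = [float(t) for t in np.atleast_1d(theta2_grid)]
    if any(t <= 0 or t > 1 for t in theta2_grid):
        raise ValidationError("every theta^2 must lie in (0, 1]")
    a_all, _, v_all, a, g, g_se, _ = _terms(pair)
    scale = float(np.sqrt(np.sum(a_all**2 * v_all)))
    w = a**2 / g_se**2
    ivw = float(np.sum(w * (g / a)) / np.sum(w))
    beta_G = scale * ivw
    se = two_sample_se(pair, include_scale_noise=se_scale_noise)
    by_theta = {}
    for t in theta2_grid:
        theta = float(np.sqrt(t))
        bl, sl = beta_G / theta, se / theta
        by_theta[t] = (bl, bl - _Z95 * sl, bl + _Z95 * sl)
    return TwoSampleResult(
        scale_term=scale,
        ivw_term=ivw,
        beta_G_hat=beta_G,
        se_beta_G=se,
        beta_L_by_theta=by_theta,
        n_exposure_snps=len(pair.exposure),
        n_outcome_snps=len(pair.outcome),
    )


def two_sample_se(pair: SummaryPair, include_scale_noise: bool = True) -> float:
    """Delta-method SE of beta_G over the two independent samples.

    Always propagates the outcome-association noise through the IVW term
    (yielding ``scale_term / sqrt(sum w)`` when alpha noise is ignored);
    with ``include_scale_noise`` the first-order contribution of the
    exposure-sample alpha_hat noise to both factors is added.
    """
    a_all, a_se_all, v_all, a, g, g_se, out_pos = _terms(pair)
    S = float(np.sqrt(np.sum(a_all**2 * v_all)))
    Dn = float(np.sum(a**2 / g_se**2))
    N = float(np.sum(a * g / g_se**2))
    W = N / Dn
    var = S**2 / Dn  # gamma noise through the IVW term
    if include_scale_noise:
        dS = a_all * v_all / S  # d scale / d alpha_j over the exposure set
        grad = W * dS
        # d ivw / d alpha_j for SNPs also in the outcome subset
        d_ivw = (g - 2.0 * a * W) / (g_se**2 * Dn)
        grad[out_pos] += S * d_ivw
        var += float(np.sum(grad**2 * a_se_all**2))
    return float(np.sqrt(var))


def parametric_bootstrap_se(pair: SummaryPair, n_draws: int = 10_000, seed=None) -> float:
    """Parametric-bootstrap cross-check of :func:`two_sample_se`.

    Resamples (alpha_hat, gamma_hat) from their reported normal sampling
    distributions (independent across SNPs and across the two samples) and
    returns the SD of the recomputed beta_G.
    """
    rng = np.random.default_rng(seed)
    a_all, a_se_all, v_all, a, g, g_se, out_pos = _terms(pair)
    a_star = a_all[None, :] + rng.standard_normal((n_draws, a_all.size)) * a_se_all
    g_star = g[None, :] + rng.standard_normal((n_draws, g.size)) * g_se
    a_sub = a_star[:, out_pos]
    scale = np.sqrt(np.sum(a_star**2 * v_all[None, :], axis=1))
    w = a_sub**2 / g_se[None, :] ** 2
    ivw = np.sum(w * (g_star / a_sub), axis=1) / np.sum(w, axis=1)
    return float(np.std(scale * ivw, ddof=1))


def reanalysis_grid(
    pair: SummaryPair,
    theta2_list,
    exponentiate: bool = False,
    se_scale_noise: bool = True,
) -> pd.DataFrame:
    """Per-theta^2 table of beta_L with Wald 95% CIs.

    With ``exponentiate`` the estimate and CI are reported as odds ratios
    (appropriate when the outcome associations are on the log-odds scale).
    """
    theta2_list = [float(t) for t in np.atleast_1d(theta2_list)]
    if not theta2_list:
        raise ValidationError("theta2 list must be nonempty")
    res = ivw_latent(pair, theta2_grid=theta2_list, se_scale_noise=se_scale_noise)
    rows = []
    for t in theta2_list:
        est, lo, hi = res.beta_L_by_theta[t]
        if exponentiate:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        rows.append(
            {
                "theta2": t,
                "estimate": float(est),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "scale": "odds_ratio" if exponentiate else "linear",
            }
        )
    return pd.DataFrame(rows)
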