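"""Closed-form probability limit of the naive Wald estimator.

With a binary instrument and genetic share ``G = mu + alpha*Z``, the naive
estimand (coarsened D used as the exposure) is

    beta_D = beta * alpha / (F_V(mu + alpha) - F_V(mu)),

where ``F_V(v) = F(v / sigma_v)`` is the CDF of the environmental share.
By the mean value theorem the denominator equals ``alpha * f_V(mu*)`` for
some ``mu* in [mu, mu + alpha]``, so the naive estimate is the true latent
effect divided by a density value — a multiplicative distortion that can
inflate or deflate but never flips sign.  ``mu*`` itself is not
point-identified; we return the exact ratio plus its bracketing interval.

The closed form is exact for a binary instrument only; for 0/1/2 dosages
use the simulator as the oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError
from .sim import standard_family_cdf

__all__ = ["NaiveLimit", "naive_limit", "inflation_curve"]


@dataclass
class NaiveLimit:
    """Probability limit of the naive Wald estimator at one (mu, alpha)."""

    beta_D: float
    inflation: float  # 1 / f_V(mu*), multiplicative bias factor
    mu_star_bracket: tuple  # interval guaranteed to contain mu*
    prevalence: float  # P(D = 1 | Z = 0) = F_V(mu)


def naive_limit(
    beta: float,
    mu: float,
    alpha: float,
    v_family="normal",
    sigma_v: float = 1.0,
) -> NaiveLimit:
    """Exact naive Wald estimand for a binary instrument.

    Raises if the instrument is irrelevant for D, i.e.
    ``F_V(mu + alpha) = F_V(mu)``.
    """
    if alpha == 0:
        raise ValidationError("alpha must be nonzero (instrument relevance)")
    if sigma_v <= 0:
        raise ValidationError("sigma_v must be > 0")
    F = standard_family_cdf(v_family)
    f_hi = float(F((mu + alpha) / sigma_v))
    f_lo = float(F(mu / sigma_v))
    denom = f_hi - f_lo
    if denom == 0.0 or not np.isfinite(denom):
        raise ValidationError(
            "F_V(mu + alpha) equals F_V(mu): the instrument does not move D "
            "and the naive estimand is undefined"
        )
    inflation = alpha / denom
    lo, hi = (mu, mu + alpha) if alpha > 0 else (mu + alpha, mu)
    return NaiveLimit(
        beta_D=beta * inflation,
        inflation=inflation,
        mu_star_bracket=(lo, hi),
        prevalence=f_lo,
    )


def inflation_curve(
    beta: float,
    alpha: float,
    mu_grid,
    v_family="normal",
    sigma_v: float = 1.0,
) -> list:
    """Evaluate :func:`naive_limit` over a grid of intercepts mu.

    For light-tailed families the inflation factor grows as the prevalence
    of D approaches 0 or 1 (the density in the denominator shrinks in the
    tails), reproducing the rarer-disease / larger-bias pattern.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if not np.all(np.isfinite(mu_grid)):
        raise ValidationError("mu_grid must be finite")
    return [naive_limit(beta, float(m), alpha, v_family, sigma_v) for m in mu_grid]
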