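"""Binary and ordered-response GLM fitting.

Binary probit/logit models are fit with a hand-rolled Fisher-scoring IRLS
loop: the latent-variable bootstrap re-fits the first stage thousands of
times, and warm-started IRLS is an order of magnitude faster than going
through a generic optimiser.  Correctness is pinned against statsmodels in
the test suite.  Ordered models delegate to
``statsmodels.miscmodels.ordinal_model.OrderedModel``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr
from scipy.stats import norm

from .data import DegenerateDataError, SeparationError, ValidationError

__all__ = ["GlmFit", "fit_binary", "fit_ordered", "BINARY_LINKS", "ORDERED_LINKS"]

BINARY_LINKS = ("probit", "logit")
ORDERED_LINKS = ("ordered-probit", "ordered-logit")

_PCLIP = 1e-10


@dataclass
class GlmFit:
    """First-stage fit: coefficients on the linear-predictor scale.

    ``coef``/``cov``/``zstats`` cover the exogenous regressors only (ordered
    models exclude the cutpoints).  ``linpred`` is X @ coef.
    """

    coef: np.ndarray
    cov: np.ndarray
    linpred: np.ndarray
    link: str
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zstats(self) -> np.ndarray:
        return self.coef / self.se


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValidationError("binary links require D coded 0/1")
    if vals.size < 2:
        raise DegenerateDataError("D takes a single value; cannot fit a GLM")
    return y


def fit_binary(
    y,
    X,
    link: str = "probit",
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """Fit a binary GLM by Fisher scoring.

    Parameters
    ----------
    y : 0/1 response.
    X : design matrix including any intercept column.
    link : "probit" or "logit".
    start : optional warm-start coefficients (bootstrap refits).
    """
    if link not in BINARY_LINKS:
        raise ValidationError(f"unknown binary link {link!r}")
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()

    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if link == "probit":
            p = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
            d = norm.pdf(eta)  # dp/deta
        else:
            p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
            d = p * (1.0 - p)
        w = d * d / (p * (1.0 - p))
        # working response: z = eta + (y - p)/d, guarded where d underflows
        d_safe = np.maximum(d, 1e-300)
        z = eta + (y - p) / d_safe
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        try:
            beta_new = np.linalg.solve(xtwx, Xw.T @ z)
        except np.linalg.LinAlgError as exc:  # rank deficiency
            raise SeparationError(f"singular information matrix: {exc}") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if not np.all(np.isfinite(beta)):
            raise SeparationError("divergent coefficients (perfect separation?)")
        if step < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    eta = X @ beta
    if np.max(np.abs(beta)) > 1e4 or (not converged and np.max(np.abs(eta)) > 30):
        raise SeparationError("apparent perfect separation in binary GLM")
    if not converged:
        warnings.warn("binary GLM did not reach tolerance", RuntimeWarning)
    if link == "probit":
        p = np.clip(ndtr(eta), _PCLIP, 1 - _PCLIP)
        d = norm.pdf(eta)
    else:
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        d = p * (1.0 - p)
    w = d * d / (p * (1.0 - p))
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return GlmFit(coef=beta, cov=cov, linpred=eta, link=link, converged=converged, n_iter=it)


def fit_ordered(
    y,
    X,
    link: str = "ordered-probit",
    start: np.ndarray | None = None,
) -> GlmFit:
    """Fit an ordered-response model; returns exogenous coefficients only.

    The linear predictor excludes the estimated cutpoints, matching the
    latent-variable pipeline's definition of the genetic share (location and
    scale are irrelevant downstream because the predictor is standardised).
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if link not in ORDERED_LINKS:
        raise ValidationError(f"unknown ordered link {link!r}")
    y = np.asarray(y)
    cats = np.unique(y)
    if cats.size < 3:
        raise DegenerateDataError(
            "ordered links require >= 3 observed categories; "
            f"found {cats.size} (use a binary link instead)"
        )
    if not np.array_equal(cats, np.arange(cats.size)):
        raise ValidationError("ordered D must be coded 0..K with every category present")
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    distr = "probit" if link == "ordered-probit" else "logit"
    model = OrderedModel(y, X, distr=distr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="lbfgs", maxiter=500, disp=0, start_params=start)
        except Exception as exc:  # pragma: no cover - rare optimiser failure
            raise SeparationError(f"ordered model failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise SeparationError("non-finite ordered-model parameters")
    coef = np.asarray(res.params[:k])
    cov = np.asarray(res.cov_params())[:k, :k]
    fit = GlmFit(
        coef=coef,
        cov=cov,
        linpred=X @ coef,
        link=link,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
    )
    fit.full_params = np.asarray(res.params)  # warm starts for the bootstrap
    return fit
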