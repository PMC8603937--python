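"""Shared data containers: structural-model parameters, individual-level
datasets, and GWAS summary-statistic records.

The structural model is a liability-threshold model.  A latent continuous
exposure ``L = mu + alpha'Z + gamma'X - V`` is observed only through a
coarsened (binary or ordered-categorical) measurement ``D``, and the outcome
follows ``Y = beta*L + delta*D + eps``.
"""
from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "EstimationError",
    "DegenerateDataError",
    "SeparationError",
    "ModelParams",
    "IndividualDataset",
    "SnpSummary",
    "SummaryPair",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented invariant."""


class EstimationError(RuntimeError):
    """Base class for recoverable estimation failures."""


class DegenerateDataError(EstimationError):
    """Data cannot support the requested fit (e.g. single-class D)."""


class SeparationError(EstimationError):
    """Perfect separation in a binary/ordered regression."""


def _vec(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-d vector")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    return arr


def _is_frozen_dist(obj) -> bool:
    return hasattr(obj, "cdf") and hasattr(obj, "rvs")


@dataclass
class ModelParams:
    """All structural parameters of the data-generating process.

    Parameters
    ----------
    alpha
        Instrument effects on the latent exposure, one per instrument SNP
        (length J).
    mu
        Intercept of the genetic share, on the latent-exposure scale.
    gamma
        Effects of auxiliary (possibly pleiotropic) variants X (length K,
        may be empty).
    beta
        Structural effect of the latent exposure L on the outcome Y.
    delta
        Direct effect of the coarsened measurement D on Y (default 0).
    sigma_v
        Standard deviation of the environmental share V (> 0).
    v_family
        Distribution family of ``V / sigma_v`` (unit SD): ``"normal"``,
        ``"logistic"``, or a frozen ``scipy.stats`` distribution which is
        standardised internally to mean 0 / SD 1.
    snp_freqs
        Effect-allele frequencies for the J instrument SNPs followed by the
        K auxiliary SNPs; genotypes are drawn Binomial(ploidy, p) under HWE.
    thresholds
        Strictly increasing positive cutpoints ``0 < d1 < ... < d_{K-1}``
        for an ordered coarsening; empty for binary D.
    r_dist
        Optional random individual-specific threshold R: either a float
        (SD of a mean-zero normal) or a frozen scipy distribution.  R is
        drawn independently of Z and X.  ``None`` means a fixed threshold,
        so D is a deterministic function of L.
    confounding
        Loading of standardised V in the outcome disturbance:
        ``eps = confounding * (V / sigma_v) + sigma_eps * N(0, 1)``.
    sigma_eps
        SD of the independent component of the outcome disturbance (> 0).
    ploidy
        2 for 0/1/2 dosages (default), 1 for a binary instrument.
    """

    alpha: np.ndarray
    mu: float = 0.0
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta: float = 0.0
    delta: float = 0.0
    sigma_v: float = 1.0
    v_family: object = "normal"
    snp_freqs: np.ndarray | None = None
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_dist: object = None
    confounding: float = 0.0
    sigma_eps: float = 1.0
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.alpha = _vec(self.alpha, "alpha")
        self.gamma = _vec(self.gamma, "gamma") if np.size(self.gamma) else np.empty(0)
        self.thresholds = (
            _vec(self.thresholds, "thresholds")
            if np.size(self.thresholds)
            else np.empty(0)
        )
        for name in ("mu", "beta", "delta", "sigma_v", "confounding", "sigma_eps"):
            val = getattr(self, name)
            if not (isinstance(val, numbers.Real) and np.isfinite(val)):
                raise ValidationError(f"{name} must be a finite real number")
            setattr(self, name, float(val))
        if self.sigma_v <= 0:
            raise ValidationError("sigma_v must be > 0")
        if self.sigma_eps <= 0:
            raise ValidationError("sigma_eps must be > 0")
        if self.snp_freqs is None:
            self.snp_freqs = np.full(self.n_snps, 0.5)
        self.snp_freqs = _vec(self.snp_freqs, "snp_freqs")
        if self.snp_freqs.size != self.n_snps:
            raise ValidationError(
                f"snp_freqs must have length J+K={self.n_snps}, "
                f"got {self.snp_freqs.size}"
            )
        if np.any(self.snp_freqs <= 0) or np.any(self.snp_freqs >= 1):
            raise ValidationError("allele frequencies must lie in (0, 1)")
        if self.thresholds.size:
            if self.thresholds[0] <= 0 or np.any(np.diff(self.thresholds) <= 0):
                raise ValidationError(
                    "thresholds must satisfy 0 < d1 < d2 < ... (strictly increasing)"
                )
        if isinstance(self.v_family, str):
            if self.v_family not in ("normal", "logistic"):
                raise ValidationError(
                    f"unknown v_family {self.v_family!r}; use 'normal', "
                    "'logistic' or a frozen scipy.stats distribution"
                )
        elif not _is_frozen_dist(self.v_family):
            raise ValidationError("v_family must be a name or a frozen distribution")
        if self.r_dist is not None and not (
            isinstance(self.r_dist, numbers.Real) or _is_frozen_dist(self.r_dist)
        ):
            raise ValidationError("r_dist must be None, a float SD, or a frozen dist")
        if self.ploidy not in (1, 2):
            raise ValidationError("ploidy must be 1 or 2")

    @property
    def n_instruments(self) -> int:
        return self.alpha.size

    @property
    def n_auxiliary(self) -> int:
        return self.gamma.size

    @property
    def n_snps(self) -> int:
        return self.alpha.size + self.gamma.size

    @property
    def n_categories(self) -> int:
        """Number of categories of D (2 for binary)."""
        return self.thresholds.size + 2

    def mean_g(self) -> float:
        """Population mean of the genetic share G under HWE.

        Useful for centring: ``mu = -(mean_g() - mu)`` puts the latent
        exposure at mean zero so a zero threshold gives ~50% prevalence.
        """
        p = self.snp_freqs
        coefs = np.concatenate([self.alpha, self.gamma])
        return float(self.mu + np.sum(coefs * self.ploidy * p))

    def var_g(self) -> float:
        """Population variance of the genetic share G under HWE."""
        p = self.snp_freqs
        var_snp = self.ploidy * p * (1.0 - p)
        coefs = np.concatenate([self.alpha, self.gamma])
        return float(np.sum(coefs**2 * var_snp))

    def var_l(self) -> float:
        """Population variance of the latent exposure L."""
        return self.var_g() + self.sigma_v**2

    def theta2(self) -> float:
        """True genetic variance share of the latent exposure, var(G)/var(L)."""
        return self.var_g() / self.var_l()

    def beta_latent(self) -> float:
        """True effect of a one-SD increase in L on Y, sd(L) * beta."""
        return float(np.sqrt(self.var_l()) * self.beta)


@dataclass
class IndividualDataset:
    """Individual-level columns for one-sample analysis.

    ``latent`` holds simulation-only ground truth (keys ``"L"``, ``"G"``,
    ``"V"``) and must never be consulted by estimators.
    """

    Z: np.ndarray
    D: np.ndarray
    Y: np.ndarray
    X: np.ndarray | None = None
    covariates: np.ndarray | None = None
    latent: dict | None = None

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] == 1 and np.asarray(self.D).size != 1:
            self.Z = self.Z.T
        self.D = np.asarray(self.D)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.Z.shape[0]
        if self.X is not None and np.size(self.X):
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != n:
                raise ValidationError("X row count differs from Z")
        else:
            self.X = None
        if self.covariates is not None and np.size(self.covariates):
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValidationError("covariates row count differs from Z")
        else:
            self.covariates = None
        if self.D.shape[0] != n or self.Y.shape[0] != n:
            raise ValidationError("Z, D, Y must have the same number of rows")
        if not np.all(np.isfinite(self.Y)):
            raise ValidationError("Y must be finite")

    def __len__(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def n_instruments(self) -> int:
        return self.Z.shape[1]

    @property
    def n_auxiliary(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    @property
    def n_categories(self) -> int:
        return int(np.max(self.D)) + 1

    def take(self, idx: np.ndarray) -> "IndividualDataset":
        """Row-subset (used by the bootstrap); latent columns follow along."""
        idx = np.asarray(idx)
        return IndividualDataset(
            Z=self.Z[idx],
            D=self.D[idx],
            Y=self.Y[idx],
            X=None if self.X is None else self.X[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            latent=None
            if self.latent is None
            else {k: v[idx] for k, v in self.latent.items()},
        )


@dataclass
class SnpSummary:
    """Per-SNP two-sample summary statistics.

    ``alpha_hat`` is the instrument-exposure association on the linear-
    predictor scale of the first-stage GLM (e.g. log-odds for a logit link).
    ``gamma_hat`` is the instrument-outcome association; the gamma fields
    are present only for SNPs selected as instruments in the outcome GWAS.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    alpha_hat: float
    alpha_se: float
    gamma_hat: float | None = None
    gamma_se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(
                f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}"
            )
        if not np.isfinite(self.alpha_hat):
            raise ValidationError(f"{self.snp_id}: alpha_hat must be finite")
        if not (self.alpha_se > 0 and np.isfinite(self.alpha_se)):
            raise ValidationError(f"{self.snp_id}: alpha_se must be > 0")
        if (self.gamma_hat is None) != (self.gamma_se is None):
            raise ValidationError(
                f"{self.snp_id}: gamma_hat and gamma_se must be supplied together"
            )
        if self.gamma_se is not None and not (
            self.gamma_se > 0 and np.isfinite(self.gamma_se)
        ):
            raise ValidationError(f"{self.snp_id}: gamma_se must be > 0")

    @property
    def has_outcome(self) -> bool:
        return self.gamma_hat is not None


@dataclass
class SummaryPair:
    """Harmonised exposure / outcome summary statistics.

    ``exposure`` covers the full exposure-GWAS SNP set; ``outcome`` is the
    subset selected as instruments from the outcome GWAS, with both alpha
    and gamma fields populated and alleles already harmonised to the
    exposure coding.
    """

    exposure: list
    outcome: list

    def __post_init__(self) -> None:
        exp_ids = {s.snp_id for s in self.exposure}
        if len(exp_ids) != len(self.exposure):
            raise ValidationError("duplicate snp_id in exposure set")
        out_ids = {s.snp_id for s in self.outcome}
        if len(out_ids) != len(self.outcome):
            raise ValidationError("duplicate snp_id in outcome set")
        if not out_ids <= exp_ids:
            raise ValidationError("outcome SNP set must be a subset of exposure set")
        for s in self.outcome:
            if not s.has_outcome:
                raise ValidationError(f"{s.snp_id}: outcome record lacks gamma fields")
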