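"""Readers/writers for tabular inputs and results, plus provenance records.

Canonical on-disk formats are plain delimited text with a header row:

* individual-level table: ``id, Z_1..Z_J, X_1..X_K, D, Y, C_1..`` (TSV)
* GWAS summary statistics: ``snp, effect_allele, other_allele, eaf, beta,
  se[, n]`` (TSV); foreign dialects are handled with a column map.

Loaders validate rather than coerce: missing required columns, non-numeric
genotypes, out-of-range allele frequencies and non-positive standard
errors are hard errors.  Rows with missing values in used columns are
dropped with a logged count; a non-contiguous category coding of D is
remapped to 0..K with a warning.
"""
from __future__ import annotations

import json
import logging
import warnings
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .data import IndividualDataset, SnpSummary, SummaryPair, ValidationError

__all__ = [
    "SchemaError",
    "read_individual_table",
    "write_individual_table",
    "read_summary_stats",
    "write_summary_stats",
    "harmonise",
    "write_results",
    "emit_provenance",
]

logger = logging.getLogger("mrcoarse")

SUMMARY_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SchemaError(ValidationError):
    """Input table does not match the documented schema."""


def _package_version() -> str:
    try:
        return version("mrcoarse")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = pd.to_numeric(df[c], errors="coerce")
        bad = out[c].isna() & df[c].notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric entries in column {c!r} "
                f"(e.g. {df.loc[bad, c].iloc[0]!r})"
            )
    return out


def read_individual_table(
    path,
    instruments,
    auxiliary=(),
    exposure_col: str = "D",
    outcome_col: str = "Y",
    covariates=(),
    sep: str = "\t",
) -> IndividualDataset:
    """Load an individual-level dataset from a delimited text table.

    ``instruments``/``auxiliary``/``covariates`` are column-name lists.
    The coarsened exposure must be integer-coded; categories that are not
    contiguous from 0 are remapped (order-preserving) with a warning.
    """
    instruments = list(instruments)
    auxiliary = list(auxiliary)
    covariates = list(covariates)
    if not instruments:
        raise SchemaError("at least one instrument column is required")
    df = pd.read_csv(path, sep=sep)
    used = instruments + auxiliary + [exposure_col, outcome_col] + covariates
    _require(df, used, path)
    if df[outcome_col].isna().all():
        raise SchemaError(f"{path}: outcome column {outcome_col!r} is entirely missing")
    df = _numeric(df[used], used, path)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d row(s) with missing values", n0 - len(df))
    if len(df) == 0:
        raise SchemaError(f"{path}: no complete rows remain after dropping missing")

    d_raw = df[exposure_col].to_numpy()
    if not np.allclose(d_raw, np.round(d_raw)):
        raise SchemaError(f"{path}: exposure column {exposure_col!r} must be integer-coded")
    d_int = np.round(d_raw).astype(np.int64)
    cats = np.unique(d_int)
    expected = np.arange(cats.size)
    if not np.array_equal(cats, expected):
        warnings.warn(
            f"exposure categories {cats.tolist()} remapped to {expected.tolist()}",
            UserWarning,
        )
        d_int = np.searchsorted(cats, d_int)

    return IndividualDataset(
        Z=df[instruments].to_numpy(dtype=float),
        D=d_int,
        Y=df[outcome_col].to_numpy(dtype=float),
        X=df[auxiliary].to_numpy(dtype=float) if auxiliary else None,
        covariates=df[covariates].to_numpy(dtype=float) if covariates else None,
    )


def write_individual_table(data: IndividualDataset, path, sep: str = "\t") -> None:
    """Write a dataset to the canonical delimited layout (no latent columns)."""
    cols = {"id": np.arange(1, len(data) + 1)}
    for j in range(data.n_instruments):
        cols[f"Z_{j + 1}"] = data.Z[:, j]
    for k in range(data.n_auxiliary):
        cols[f"X_{k + 1}"] = data.X[:, k]
    cols["D"] = data.D
    cols["Y"] = data.Y
    if data.covariates is not None:
        for c in range(data.covariates.shape[1]):
            cols[f"C_{c + 1}"] = data.covariates[:, c]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_summary_stats(path, col_map=None, sep: str = "\t") -> list:
    """Load GWAS summary statistics into :class:`SnpSummary` records.

    ``col_map`` maps foreign column names onto the canonical ones, e.g.
    ``{"FRQ": "eaf"}``.  The per-SNP association lands in ``alpha_hat`` /
    ``alpha_se`` regardless of whether the file describes the exposure or
    the outcome GWAS; :func:`harmonise` sorts out the roles.
    """
    df = pd.read_csv(path, sep=sep)
    if col_map:
        df = df.rename(columns=dict(col_map))
    _require(df, SUMMARY_COLUMNS, path)
    df = _numeric(df, ["eaf", "beta", "se"], path)
    dupes = df["snp"][df["snp"].duplicated()].unique()
    if dupes.size:
        raise SchemaError(f"{path}: duplicated snp id(s) {dupes.tolist()}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnpSummary(
                snp_id=str(row.snp),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                alpha_hat=float(row.beta),
                alpha_se=float(row.se),
                n=int(row.n) if "n" in df.columns and pd.notna(row.n) else None,
            )
        )
    return records


def write_summary_stats(records, path, sep: str = "\t") -> None:
    """Write SnpSummary records in the canonical GWAS-summary layout.

    Floats are written at full repr precision so a write/read round trip is
    bit-identical.
    """
    rows = []
    for s in records:
        rows.append(
            {
                "snp": s.snp_id,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "eaf": s.eaf,
                "beta": s.alpha_hat,
                "se": s.alpha_se,
                "n": s.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _is_palindromic(s: SnpSummary) -> bool:
    return _COMPLEMENT.get(s.effect_allele) == s.other_allele


def harmonise(
    exposure_records,
    outcome_records,
    palindromic_eaf_window=(0.42, 0.58),
) -> tuple[SummaryPair, dict]:
    """Match and allele-harmonise exposure and outcome summary statistics.

    Outcome records are matched to exposure records by snp id; a record
    whose coded allele is the exposure's other allele has its association
    sign flipped.  Palindromic SNPs (A/T or C/G) whose exposure EAF falls
    inside ``palindromic_eaf_window`` are ambiguous and dropped; so are
    SNPs whose allele pairs cannot be reconciled.  Returns the harmonised
    pair plus a report of dropped/flipped SNPs.  Palindromic filtering is
    standard two-sample hygiene beyond the core estimator.
    """
    report = {"flipped": [], "dropped_palindromic": [], "dropped_mismatch": []}
    lo, hi = palindromic_eaf_window
    exp_by_id = {}
    exposure_clean = []
    for s in exposure_records:
        if _is_palindromic(s) and lo <= s.eaf <= hi:
            report["dropped_palindromic"].append(s.snp_id)
            continue
        exp_by_id[s.snp_id] = s
        exposure_clean.append(s)

    outcome = []
    for o in outcome_records:
        e = exp_by_id.get(o.snp_id)
        if e is None:
            continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            gamma, gamma_se = o.alpha_hat, o.alpha_se
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            gamma, gamma_se = -o.alpha_hat, o.alpha_se
            report["flipped"].append(o.snp_id)
        else:
            oc = (_COMPLEMENT.get(o.effect_allele), _COMPLEMENT.get(o.other_allele))
            if oc == (e.effect_allele, e.other_allele):
                gamma, gamma_se = o.alpha_hat, o.alpha_se
            elif oc == (e.other_allele, e.effect_allele):
                gamma, gamma_se = -o.alpha_hat, o.alpha_se
                report["flipped"].append(o.snp_id)
            else:
                report["dropped_mismatch"].append(o.snp_id)
                continue
        outcome.append(
            SnpSummary(
                snp_id=e.snp_id,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                eaf=e.eaf,
                alpha_hat=e.alpha_hat,
                alpha_se=e.alpha_se,
                gamma_hat=gamma,
                gamma_se=gamma_se,
                n=o.n,
            )
        )
    return SummaryPair(exposure=exposure_clean, outcome=outcome), report


def write_results(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a results table with deterministic column order and precision."""
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def emit_provenance(config: dict, path) -> None:
    """Write a machine-readable provenance record next to the results."""
    record = {"version": _package_version(), **config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
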