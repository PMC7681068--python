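"""Per-analyte age-association statistics.

Each analyte's log10 intensity is regressed on age (optionally plus sex) by
ordinary least squares, vectorized across analytes through a shared design
matrix.  The age slope's two-sided t-test p-value is corrected for multiple
testing (Benjamini-Hochberg by default, Storey's pi0-adjusted variant on
request) and each analyte is classified as increasing, decreasing or flat.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ProteomicCohort

logger = logging.getLogger("plasmaclock")

__all__ = [
    "fit_age_regression",
    "adjust_fdr",
    "age_associations",
    "summarize_directions",
]


def fit_age_regression(
    cohort: ProteomicCohort, covariates: Sequence[str] | None = None
) -> pd.DataFrame:
    """OLS of log10 intensity on age, one fit per analyte.

    Returns a DataFrame indexed by analyte_id with columns age_coefficient
    (per-year change in log10 intensity), std_error, p_value and constant
    (True for zero-variance analytes, which get slope 0 and p 1 instead of
    an exception).  q-values are left to :func:`adjust_fdr`.
    """
    n = cohort.n_subjects
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    ages = cohort.ages.to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("ages are all equal; the age slope is unidentifiable")

    cols = [np.ones(n), ages]
    names = ["intercept", "age"]
    for cov in covariates or ():
        if cov not in cohort.subject_meta.columns:
            raise KeyError(f"covariate {cov!r} not in subject metadata")
        cols.append(cohort.subject_meta[cov].to_numpy(dtype=float))
        names.append(cov)
    D = np.column_stack(cols)
    k = D.shape[1]
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than model terms ({k})")

    Y = np.log10(cohort.intensities.to_numpy(dtype=float))
    xtx_inv = np.linalg.inv(D.T @ D)
    B = xtx_inv @ (D.T @ Y)  # k x p
    resid = Y - D @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])

    slope = B[1].copy()
    constant = Y.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), 1.0, p)
    slope[constant] = 0.0
    p[constant] = 1.0
    se[constant] = np.nan
    if constant.any():
        logger.warning("%d constant analytes flagged (slope 0, p 1)", int(constant.sum()))

    return pd.DataFrame(
        {
            "age_coefficient": slope,
            "std_error": se,
            "p_value": np.clip(p, 0.0, 1.0),
            "constant": constant,
        },
        index=cohort.intensities.columns.copy(),
    )


def adjust_fdr(p_values: Iterable[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values.

    ``"bh"`` is the Benjamini-Hochberg step-up; ``"storey"`` rescales BH by
    the pi0 estimate min(1, 2 * mean(p > 0.5)).
    """
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def age_associations(
    cohort: ProteomicCohort,
    covariates: Sequence[str] | None = None,
    q_threshold: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Full association table: slopes, p, q and direction calls.

    ``direction`` is "increasing"/"decreasing" for analytes significant at
    ``q_threshold`` and "none" otherwise.
    """
    df = fit_age_regression(cohort, covariates=covariates)
    df["q_value"] = adjust_fdr(df["p_value"].to_numpy(), method=fdr_method)
    sig = df["q_value"] < q_threshold
    df["direction"] = np.where(
        sig & (df["age_coefficient"] > 0),
        "increasing",
        np.where(sig & (df["age_coefficient"] < 0), "decreasing", "none"),
    )
    return df


def summarize_directions(
    associations: pd.DataFrame, q_threshold: float = 0.05
) -> dict[str, float]:
    """Counts and percentages of significant increasing/decreasing analytes."""
    if "q_value" not in associations:
        raise ValueError("associations must carry q_value; run age_associations first")
    sig = associations["q_value"] < q_threshold
    inc = int((sig & (associations["age_coefficient"] > 0)).sum())
    dec = int((sig & (associations["age_coefficient"] < 0)).sum())
    n_sig = inc + dec
    total = len(associations)
    return {
        "n_analytes": total,
        "n_significant": n_sig,
        "n_increasing": inc,
        "n_decreasing": dec,
        "n_nonsignificant": total - n_sig,
        "pct_increasing": 100.0 * inc / n_sig if n_sig else float("nan"),
        "pct_decreasing": 100.0 * dec / n_sig if n_sig else float("nan"),
    }
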