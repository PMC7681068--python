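"""Penalized-regression aging clocks.

Protocol: log10-transform and z-scale intensities (standardization fitted
on the training split only, by default), split subjects 2/3-1/3, fit ridge
(mixing 0) or LASSO (mixing 1) over a 100-value descending lambda path with
tenfold cross-validation, select the path value minimizing mean CV squared
error (the "lambda.min" rule, ties to the larger penalty), and report
Pearson r plus the *median* absolute error in years on each split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._solvers import ConvergenceError, enet_path, make_lambda_path
from .simulate import ProteomicCohort

logger = logging.getLogger("plasmaclock")

__all__ = [
    "StandardizationParams",
    "TrainTestSplit",
    "ClockModel",
    "ClockEvaluation",
    "ClockTrainingResult",
    "log_standardize",
    "split_train_test",
    "fit_penalized_clock",
    "predict_age",
    "evaluate_predictions",
    "build_clock",
]


@dataclass
class StandardizationParams:
    """Per-analyte mean and sd of log10 intensity on a reference set."""

    means: pd.Series
    sds: pd.Series

    def validate(self) -> None:
        if not self.means.index.equals(self.sds.index):
            raise ValueError("mean and sd series index mismatch")
        if (self.sds <= 0).any():
            raise ValueError("standardization sds must be > 0")

    @property
    def analytes(self) -> pd.Index:
        return self.means.index


def log_standardize(
    cohort: ProteomicCohort, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """z-scaled log10 intensities.

    Without ``params`` the column means/sds (ddof=1) are computed from this
    cohort; zero-variance analytes are dropped with a warning.  With
    ``params`` (e.g. training-set statistics applied to a test cohort) every
    analyte in ``params`` must be present in the cohort.
    """
    logx = cohort.log10()
    if params is None:
        sds = logx.std(axis=0, ddof=1)
        keep = sds > 0
        if not keep.all():
            dropped = sds.index[~keep].tolist()
            warnings.warn(f"dropped {len(dropped)} zero-variance analytes", stacklevel=2)
            logger.warning("dropped %d zero-variance analytes", len(dropped))
        logx = logx.loc[:, keep]
        params = StandardizationParams(means=logx.mean(axis=0), sds=sds[keep])
    else:
        params.validate()
        missing = params.analytes.difference(logx.columns)
        if len(missing):
            raise KeyError(
                f"cohort lacks analytes required by standardization params: {missing[:5].tolist()}"
            )
        logx = logx.loc[:, params.analytes]
    z = (logx - params.means) / params.sds
    return z, params


@dataclass(frozen=True)
class TrainTestSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int


def split_train_test(
    cohort: ProteomicCohort, fraction: float = 2.0 / 3.0, seed: int = 0
) -> TrainTestSplit:
    """Uniform random partition with |train| = round(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = cohort.n_subjects
    if n < 3:
        raise ValueError(f"need >= 3 subjects to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(cohort.intensities.index))
    n_train = int(round(fraction * n))
    return TrainTestSplit(
        train_ids=tuple(order[:n_train]),
        test_ids=tuple(order[n_train:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass
class ClockModel:
    """A fitted penalized linear age predictor.

    ``weights`` live on the standardized scale; prediction is
    intercept + sum_j w_j * (log10(x_j) - mean_j) / sd_j using the stored
    standardization parameters.
    """

    alpha: float
    lam: float
    lambda_path: np.ndarray
    intercept: float
    weights: pd.Series
    standardization: StandardizationParams | None = None
    n_train: int = 0
    seed: int | None = None
    split_fraction: float | None = None
    cv_mse: np.ndarray | None = None

    @property
    def feature_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def active_set_size(self) -> int:
        return int((self.weights != 0).sum())


@dataclass(frozen=True)
class ClockEvaluation:
    """Pearson r and median absolute error (years) of predicted vs actual age."""

    r: float
    mae: float
    n: int
    label: str = ""


def fit_penalized_clock(
    Z: pd.DataFrame | np.ndarray,
    ages: Sequence[float],
    alpha: float,
    n_lambda: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    lambda_min_ratio: float | None = None,
    standardization: StandardizationParams | None = None,
    solver: str = "auto",
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
) -> ClockModel:
    """Cross-validated elastic-net fit on a standardized matrix.

    The lambda path (``n_lambda`` log-spaced values descending from
    lambda_max) is computed on the full input; CV folds come from a seeded
    permutation; the selected penalty minimizes the mean of per-fold MSEs,
    ties resolved toward the larger lambda; the final model is refitted on
    all rows at that penalty via warm starts along the path.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if isinstance(Z, pd.DataFrame):
        feature_ids = Z.columns.copy()
        Zv = Z.to_numpy(dtype=float)
    else:
        Zv = np.asarray(Z, dtype=float)
        feature_ids = pd.Index([f"X{j}" for j in range(Zv.shape[1])])
    y = np.asarray(ages, dtype=float)
    n = Zv.shape[0]
    if y.shape != (n,):
        raise ValueError("ages length must match matrix rows")
    if n < n_folds:
        raise ValueError(f"need >= n_folds={n_folds} subjects, got {n}")
    if not (np.isfinite(Zv).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")

    if solver == "auto":
        solver = "svd" if alpha == 0.0 else "cd"
    lambdas = make_lambda_path(
        Zv - Zv.mean(axis=0), y - y.mean(), alpha, n_lambda, lambda_min_ratio
    )

    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % n_folds

    # per-fold SVD caches make re-evaluating extra lambdas nearly free for ridge
    svd_cache: list[tuple] = []

    def cv_curve(lams: np.ndarray) -> np.ndarray:
        fold_mse = np.empty((n_folds, len(lams)))
        for k in range(n_folds):
            test = fold_of == k
            if solver == "svd":
                if len(svd_cache) <= k:
                    Ztr = Zv[~test]
                    ytr = y[~test]
                    cm = Ztr.mean(axis=0)
                    U, d, Vt = np.linalg.svd(Ztr - cm, full_matrices=False)
                    uty = U.T @ (ytr - ytr.mean())
                    svd_cache.append(
                        (d, uty, (Zv[test] - cm) @ Vt.T, float(ytr.mean()), Ztr.shape[0])
                    )
                d, uty, Av, ym, ntr = svd_cache[k]
                scale = d[:, None] / (d[:, None] ** 2 + ntr * lams[None, :])
                preds = ym + Av @ (scale * uty[:, None])
            else:
                b0s, coefs = enet_path(
                    Zv[~test], y[~test], alpha, lams,
                    solver=solver, tol=tol, max_sweeps=max_sweeps,
                )
                preds = b0s[None, :] + Zv[test] @ coefs
            fold_mse[k] = ((preds - y[test, None]) ** 2).mean(axis=0)
        return fold_mse.mean(axis=0)

    # "lambda.min" rule; if the minimum sits on the small end of the path the
    # path is extended downward (same log spacing) until the minimum is
    # interior or the extension budget is spent.  SVD extensions are nearly
    # free so they come a full decade at a time; coordinate descent extends
    # in small chunks to avoid descending into the saturated-lasso regime.
    chunk = n_lambda if solver == "svd" else max(10, n_lambda // 4)
    max_added = 4 * n_lambda
    cv_mse = cv_curve(lambdas)
    n_base = len(lambdas)
    while len(lambdas) - n_base < max_added:
        best = int(np.argmin(cv_mse))  # first minimum = larger lambda on ties
        if best < len(lambdas) - 1:
            break
        step = lambdas[-1] / lambdas[-2]
        ext = lambdas[-1] * step ** np.arange(1, chunk + 1)
        if solver == "svd":
            cv_mse = np.concatenate([cv_mse, cv_curve(ext)])
        else:
            # coordinate descent needs the warm-start prefix: redo the path
            cv_mse = cv_curve(np.concatenate([lambdas, ext]))
        lambdas = np.concatenate([lambdas, ext])
        logger.info("CV minimum at path boundary; extended path to lambda=%.4g", lambdas[-1])
    best = int(np.argmin(cv_mse))

    b0s, coefs = enet_path(
        Zv, y, alpha, lambdas, solver=solver, tol=tol, max_sweeps=max_sweeps
    )
    model = ClockModel(
        alpha=alpha,
        lam=float(lambdas[best]),
        lambda_path=lambdas,
        intercept=float(b0s[best]),
        weights=pd.Series(coefs[:, best], index=feature_ids),
        standardization=standardization,
        n_train=n,
        seed=seed,
        cv_mse=cv_mse,
    )
    logger.info(
        "fitted clock alpha=%g: lambda=%.5g (index %d/%d), active set %d/%d, n=%d",
        alpha, model.lam, best, len(lambdas), model.active_set_size, len(feature_ids), n,
    )
    return model


def predict_age(model: ClockModel, cohort: ProteomicCohort) -> pd.Series:
    """Predicted ages (years) for every subject; needs all model features."""
    if model.standardization is None:
        raise ValueError("model carries no standardization parameters")
    missing = model.feature_ids.difference(cohort.intensities.columns)
    if len(missing):
        raise KeyError(
            f"cohort lacks {len(missing)} model features (e.g. {missing[:3].tolist()}); "
            "use predict_with_subset for partial panels"
        )
    z, _ = log_standardize(
        apply_columns(cohort, model.feature_ids), params=model.standardization
    )
    preds = model.intercept + z.to_numpy() @ model.weights.to_numpy()
    return pd.Series(preds, index=cohort.intensities.index, name="predicted_age")


def apply_columns(cohort: ProteomicCohort, columns: pd.Index) -> ProteomicCohort:
    """Column-restricted view used internally before standardization."""
    return ProteomicCohort(
        cohort.intensities.loc[:, columns],
        cohort.subject_meta,
        cohort.analyte_meta.loc[columns],
    )


def evaluate_predictions(
    predicted: Sequence[float], chronological: Sequence[float], label: str = ""
) -> ClockEvaluation:
    """Pearson r and median absolute error of predicted vs chronological age."""
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if pred.shape != chron.shape:
        raise ValueError("predicted and chronological lengths differ")
    if pred.size < 2:
        raise ValueError("need >= 2 subjects to evaluate")
    if np.ptp(chron) == 0:
        raise ValueError("chronological ages are constant; correlation undefined")
    if np.ptp(pred) == 0:
        # a degenerate clock (e.g. all weights zero) carries no age signal
        r = 0.0
    else:
        r = float(stats.pearsonr(pred, chron).statistic)
    mae = float(np.median(np.abs(pred - chron)))
    return ClockEvaluation(r=r, mae=mae, n=pred.size, label=label)


@dataclass
class ClockTrainingResult:
    model: ClockModel
    split: TrainTestSplit
    train_eval: ClockEvaluation
    test_eval: ClockEvaluation


def build_clock(
    cohort: ProteomicCohort,
    features: Sequence[str] | None = None,
    alpha: float = 0.0,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    n_lambda: int = 100,
    n_folds: int = 10,
    split: TrainTestSplit | None = None,
    global_scaling: bool = False,
    **fit_kwargs,
) -> ClockTrainingResult:
    """End-to-end protocol: split, standardize on train, CV-fit, evaluate.

    ``global_scaling=True`` computes the z-scaling on the whole cohort
    instead of the training split (whole-cohort fidelity option).
    """
    work = cohort if features is None else apply_columns(cohort, pd.Index(features))
    if split is None:
        split = split_train_test(cohort, fraction=fraction, seed=seed)
    train = ProteomicCohort(
        work.intensities.loc[list(split.train_ids)],
        work.subject_meta.loc[list(split.train_ids)],
        work.analyte_meta,
    )
    ref = work if global_scaling else train
    _, params = log_standardize(ref)
    z_train, _ = log_standardize(train, params=params)
    model = fit_penalized_clock(
        z_train, train.ages.to_numpy(), alpha,
        n_lambda=n_lambda, n_folds=n_folds, seed=seed,
        standardization=params, **fit_kwargs,
    )
    model.split_fraction = split.fraction
    pred_train = model.intercept + z_train.to_numpy() @ model.weights.to_numpy()
    train_eval = evaluate_predictions(pred_train, train.ages.to_numpy(), label="train")
    test = ProteomicCohort(
        work.intensities.loc[list(split.test_ids)],
        work.subject_meta.loc[list(split.test_ids)],
        work.analyte_meta,
    )
    pred_test = predict_age(model, test)
    test_eval = evaluate_predictions(
        pred_test.to_numpy(), test.ages.to_numpy(), label="test"
    )
    return ClockTrainingResult(model=model, split=split, train_eval=train_eval, test_eval=test_eval)
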