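"""Epigenetic clock models over targeted DNAm measurements.

The substrate is a samples x CpG matrix of beta values (methylated
fraction, internally always on the [0,1] scale) with chronological ages
in weeks. Three model families are covered:

* per-CpG linear DNAm-vs-age trajectories (also the basis of CpG
  selection and of the single-read model),
* a multivariable linear clock over a small set of chosen CpGs (one top
  CpG per amplicon by default, the classic 3-CpG design),
* a lasso clock over all CpGs with the penalty chosen by k-fold
  cross-validation on a glmnet-style lambda grid.

Evaluation reports the squared Pearson correlation of predicted versus
chronological age (the headline R^2), the identity-line R^2
(1 - SSres/SStot), and median/mean absolute error in weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

__all__ = [
    "MethylationMatrix",
    "CpGTrajectory",
    "ClockModel",
    "EvaluationReport",
    "fit_cpg_trajectory",
    "select_top_cpgs",
    "train_multivariable",
    "train_lasso",
    "predict_age",
    "evaluate",
    "cpg_age_correlation_profile",
    "fit_acceleration_curve",
    "glmnet_lambda_grid",
    "lasso_objective",
]


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta matrix with age (weeks) and strain metadata.

    ``betas`` is indexed by sample id with columns '<amplicon>:<index>';
    values are fractions in [0,1] or NaN. ``ages`` shares the index.
    """

    betas: pd.DataFrame
    ages: pd.Series
    strain: pd.Series | None = None

    def __post_init__(self) -> None:
        self.ages = self.ages.reindex(self.betas.index)
        if self.ages.isna().any():
            missing = list(self.ages.index[self.ages.isna()])
            raise ValueError(f"samples without age: {missing}")
        if (self.ages < 0).any():
            raise ValueError("ages must be non-negative")
        vals = self.betas.to_numpy(dtype=float)
        bad = (vals < -1e-9) | (vals > 1 + 1e-9)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("beta values must be in [0, 1] or missing")
        if self.strain is not None:
            self.strain = self.strain.reindex(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.betas.columns)

    def amplicons(self) -> dict[str, list[str]]:
        """CpG columns grouped by amplicon, preserving column order."""
        groups: dict[str, list[str]] = {}
        for c in self.betas.columns:
            amp = c.rsplit(":", 1)[0]
            groups.setdefault(amp, []).append(c)
        return groups


@dataclass(frozen=True)
class CpGTrajectory:
    """OLS line of beta (fraction) on age (weeks) for one CpG."""

    cpg_id: str
    slope: float  # beta-fraction per week
    intercept: float  # beta-fraction at age 0
    pearson_r: float  # NaN when beta variance is zero
    n_samples: int

    @property
    def r_squared(self) -> float:
        return self.pearson_r**2

    @property
    def defined(self) -> bool:
        return not np.isnan(self.pearson_r)

    def predict_beta(self, age: float | np.ndarray) -> np.ndarray:
        return np.clip(self.intercept + self.slope * np.asarray(age, dtype=float), 0.0, 1.0)


def fit_cpg_trajectory(
    betas: Sequence[float], ages: Sequence[float], cpg_id: str = ""
) -> CpGTrajectory:
    """Least-squares DNAm-vs-age line for one CpG.

    Rows with missing beta are dropped; fewer than 3 usable samples is
    an error, constant beta gives slope 0 with Pearson r undefined.
    """
    b = np.asarray(betas, dtype=float)
    a = np.asarray(ages, dtype=float)
    keep = ~np.isnan(b) & ~np.isnan(a)
    b, a = b[keep], a[keep]
    if b.size < 3:
        raise ValueError(f"{cpg_id or 'CpG'}: need >=3 samples with non-missing beta, got {b.size}")
    if np.ptp(a) == 0:
        raise ValueError(f"{cpg_id or 'CpG'}: ages are all equal")
    if np.ptp(b) == 0:
        return CpGTrajectory(cpg_id, 0.0, float(b[0]), np.nan, int(b.size))
    fit = stats.linregress(a, b)
    return CpGTrajectory(cpg_id, float(fit.slope), float(fit.intercept), float(fit.rvalue), int(b.size))


def trajectories_for(
    matrix: MethylationMatrix, cpg_ids: Sequence[str] | None = None
) -> dict[str, CpGTrajectory]:
    """Fit trajectories for a set of columns (default: all)."""
    ages = matrix.ages.to_numpy(dtype=float)
    out = {}
    for c in cpg_ids if cpg_ids is not None else matrix.cpg_ids:
        out[c] = fit_cpg_trajectory(matrix.betas[c].to_numpy(dtype=float), ages, cpg_id=c)
    return out


def select_top_cpgs(matrix: MethylationMatrix, per_amplicon: int = 1) -> list[str]:
    """Per amplicon, the CpGs most correlated (|Pearson r|) with age.

    Ties break toward the lower CpG index so selection is deterministic.
    The default of one per amplicon reproduces the classic three-CpG
    clock design. Amplicons whose every CpG has undefined correlation
    are excluded with a warning.
    """
    if per_amplicon < 1:
        raise ValueError("per_amplicon must be >= 1")
    chosen: list[str] = []
    for amp, cols in matrix.amplicons().items():
        trajs = trajectories_for(matrix, cols)
        scored = [
            (-(abs(t.pearson_r)), idx, c)
            for idx, (c, t) in enumerate(trajs.items())
            if t.defined
        ]
        if not scored:
            warnings.warn(f"{amp}: all CpG age-correlations undefined; amplicon excluded", stacklevel=2)
            continue
        scored.sort()
        chosen.extend(c for _, _, c in scored[:per_amplicon])
    return chosen


@dataclass
class ClockModel:
    """Linear age predictor: age_weeks = intercept + sum coef * beta."""

    kind: str  # 'multivariable-linear' | 'lasso'
    terms: list[tuple[str, float]]  # (cpg_id, weeks per beta-fraction)
    intercept: float  # weeks
    meta: dict = field(default_factory=dict)

    @property
    def cpg_ids(self) -> list[str]:
        return [c for c, _ in self.terms]


def _design(matrix: MethylationMatrix, cpg_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete-case design matrix for the selected columns; rows with
    any missing beta are dropped (and logged), never imputed."""
    missing_cols = [c for c in cpg_ids if c not in matrix.betas.columns]
    if missing_cols:
        raise KeyError(f"CpG columns not in matrix: {missing_cols}")
    sub = matrix.betas[list(cpg_ids)]
    keep = ~sub.isna().any(axis=1)
    dropped = list(sub.index[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples with missing betas: {dropped}", stacklevel=3)
    X = sub.loc[keep].to_numpy(dtype=float)
    y = matrix.ages.loc[keep].to_numpy(dtype=float)
    return X, y, list(sub.index[keep])


def train_multivariable(matrix: MethylationMatrix, cpg_ids: Sequence[str]) -> ClockModel:
    """OLS regression of age on the selected beta columns."""
    X, y, used = _design(matrix, cpg_ids)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than CpGs ({p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (cpg_ids[i], cpg_ids[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(cpg_ids)}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return ClockModel(
        kind="multivariable-linear",
        terms=[(c, float(b)) for c, b in zip(cpg_ids, coef[1:])],
        intercept=float(coef[0]),
        meta={"n": n, "samples": used},
    )


def glmnet_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all-zero solution) down
    by ``ratio``, for the objective (1/2n)||y-Xb||^2 + lambda*||b||_1 on
    centred/standardised data."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xc.T @ yc)) / n
    if lam_max == 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def lasso_objective(X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, lam: float) -> float:
    """(1/2n)*RSS + lam*||coef||_1 — the objective train_lasso minimises
    (on its standardised internal scale)."""
    resid = y - intercept - X @ coef
    return float(0.5 * np.mean(resid**2) + lam * np.sum(np.abs(coef)))


def _lasso_fit_std(Xs: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Solve the standardised lasso (no intercept) at one penalty."""
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return coef
    est = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-8)
    est.fit(Xs, yc)
    return est.coef_


def _lasso_path_std(Xs: np.ndarray, yc: np.ndarray, lams_desc: np.ndarray) -> np.ndarray:
    """Coefficients along a descending penalty path, warm-started."""
    out = np.empty((lams_desc.size, Xs.shape[1]))
    est = Lasso(alpha=1.0, fit_intercept=False, max_iter=100_000, tol=1e-8, warm_start=True)
    for k, lam in enumerate(lams_desc):
        if lam == 0.0:
            out[k], *_ = np.linalg.lstsq(Xs, yc, rcond=None)
            continue
        est.alpha = lam
        est.fit(Xs, yc)
        out[k] = est.coef_
    return out


def train_lasso(
    matrix: MethylationMatrix,
    cpg_ids: Sequence[str] | None = None,
    lambda_grid: Sequence[float] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> ClockModel:
    """Lasso age clock with the penalty chosen by cross-validation.

    Predictors are standardised internally; coefficients are reported on
    the original beta-fraction scale. Fold assignment is a deterministic
    shuffle under ``seed``; lambda is the grid minimiser of mean CV MSE
    (ties toward the larger, sparser penalty).
    """
    cols = list(cpg_ids) if cpg_ids is not None else matrix.cpg_ids
    X, y, used = _design(matrix, cols)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"{n} samples < {n_folds} folds; reduce n_folds")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    ybar = y.mean()
    yc = y - ybar

    grid = np.asarray(lambda_grid if lambda_grid is not None else glmnet_lambda_grid(Xs, yc), dtype=float)
    order = np.argsort(-grid)  # evaluate large->small so ties keep the sparser fit
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    lams_desc = grid[order]
    fold_mse = np.zeros((n_folds, grid.size))
    for fi, f in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        path = _lasso_path_std(Xs[mask], yc[mask], lams_desc)
        preds = Xs[f] @ path.T  # (|fold|, n_lambda)
        fold_mse[fi] = np.mean((yc[f][:, None] - preds) ** 2, axis=0)
    cv_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(cv_mse))
    lam_best = float(grid[order][best])

    coef_s = _lasso_fit_std(Xs, yc, lam_best)
    coef = coef_s / sd
    intercept = float(ybar - coef @ mu)
    terms = [(c, float(b)) for c, b in zip(cols, coef) if b != 0.0]
    return ClockModel(
        kind="lasso",
        terms=terms,
        intercept=intercept,
        meta={
            "n": n,
            "folds": n_folds,
            "seed": seed,
            "lambda": lam_best,
            "cv_mse": float(cv_mse[best]),
            "samples": used,
        },
    )


def predict_age(model: ClockModel, betas: Mapping[str, float] | pd.Series) -> float:
    """Apply a clock to one sample's betas (fractions, keyed by CpG id).

    Predictions are not clamped; a negative age is reported as-is.
    """
    total = model.intercept
    missing = []
    for cpg, coef in model.terms:
        v = betas.get(cpg) if isinstance(betas, Mapping) else (betas[cpg] if cpg in betas else None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing.append(cpg)
            continue
        total += coef * float(v)
    if missing:
        raise ValueError(f"missing required CpGs: {missing}")
    return float(total)


def predict_matrix(model: ClockModel, matrix: MethylationMatrix) -> pd.Series:
    """Vectorised predict_age over the rows of a matrix."""
    return pd.Series(
        [predict_age(model, matrix.betas.loc[s]) for s in matrix.sample_ids],
        index=matrix.betas.index,
        name="predicted_age_weeks",
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy summary of predicted vs chronological age (weeks)."""

    r_squared: float  # squared Pearson correlation (headline)
    r_squared_identity: float  # 1 - SSres/SStot on the identity line
    median_abs_error: float
    mean_abs_error: float
    pairs: tuple[tuple[float, float], ...]  # (predicted, chronological)


def evaluate(predicted: Sequence[float], chronological: Sequence[float]) -> EvaluationReport:
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape or p.size < 2:
        raise ValueError("predicted and chronological must be equal-length, n >= 2")
    err = np.abs(p - c)
    if np.ptp(p) == 0 or np.ptp(c) == 0:
        r2 = np.nan
    else:
        r2 = float(stats.pearsonr(p, c).statistic ** 2)
    sstot = float(np.sum((c - c.mean()) ** 2))
    r2_id = 1.0 - float(np.sum((p - c) ** 2)) / sstot if sstot > 0 else np.nan
    return EvaluationReport(
        r_squared=r2,
        r_squared_identity=r2_id,
        median_abs_error=float(np.median(err)),
        mean_abs_error=float(np.mean(err)),
        pairs=tuple(zip(p.tolist(), c.tolist())),
    )


def cpg_age_correlation_profile(matrix: MethylationMatrix, amplicon: str) -> list[tuple[int, float]]:
    """Pearson r of DNAm with age per CpG, in positional order along the
    amplicon — the bell-shaped profile when plotted against position."""
    cols = matrix.amplicons().get(amplicon)
    if not cols:
        raise KeyError(f"amplicon {amplicon!r} not in matrix")
    trajs = trajectories_for(matrix, cols)
    return [(i, trajs[c].pearson_r) for i, c in enumerate(cols)]


@dataclass(frozen=True)
class AccelerationFit:
    form: str  # 'linear' | 'logarithmic'
    a: float
    b: float
    r_squared: float

    def predict(self, age: np.ndarray) -> np.ndarray:
        x = np.asarray(age, dtype=float)
        return self.a * (np.log(x) if self.form == "logarithmic" else x) + self.b


def fit_acceleration_curve(
    predicted: Sequence[float], chronological: Sequence[float], form: str = "linear"
) -> AccelerationFit:
    """Fit predicted = a*x + b with x = chronological age or its log.

    The logarithmic form captures strain acceleration that is steep in
    young animals and flattens with age (as in short-lived strains).
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if form == "logarithmic":
        if np.any(c <= 0):
            raise ValueError("logarithmic form requires strictly positive chronological ages")
        x = np.log(c)
    elif form == "linear":
        x = c
    else:
        raise ValueError(f"unknown form {form!r}")
    if np.ptp(x) == 0:
        raise ValueError("chronological ages are all equal")
    if np.ptp(p) == 0:
        return AccelerationFit(form, 0.0, float(p[0]), 0.0)
    fit = stats.linregress(x, p)
    return AccelerationFit(form, float(fit.slope), float(fit.intercept), float(fit.rvalue**2))
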