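"""Continuous self-controlled case series (CSCCS) drug-effect estimation.

Each lab test is modelled as a linear fixed-effects panel

    y_ij = alpha_i + beta' x_ij + eps_ij,

where ``alpha_i`` is patient i's baseline for the lab (a nuisance) and
``beta`` holds one effect per drug.  Profiling out the per-patient
intercepts reduces the problem to ordinary regression on within-patient
*centered* data: subtract each patient's mean response and mean exposure,
then solve

    argmin_beta  1/2 ||y_c - X_c beta||^2 + lambda ||beta||_1.

The L1 penalty encodes the assumption that each lab is moved by only a
small fraction of the drugs.  Significant coefficients (post-selection
refit t-tests, p < alpha) are called +1 / -1 by coefficient sign; all other
drugs get 0, yielding the ternary clinical drug effect vector per drug.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from labcmap.connect import SignVector
from labcmap.datasets import LongitudinalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "CSCCSFit",
    "DrugEffectVectors",
    "build_design",
    "center_within_patient",
    "fit_cscc",
    "select_lambda",
    "coef_pvalues",
    "call_drug_directions",
    "build_drug_effect_vectors",
]


class Design(NamedTuple):
    """Stacked regression arrays for one lab test."""

    y: np.ndarray            # (n,) responses
    X: np.ndarray            # (n, M) binary exposures
    patient_index: np.ndarray  # (n,) integer patient codes, contiguous blocks
    patients: list[str]      # code -> patient id
    drugs: list[str]         # column -> drug id


def build_design(
    dataset: LongitudinalDataset,
    lab_id: str,
    drugs: Sequence[str] | None = None,
) -> Design:
    """Assemble the stacked (y, X) arrays for one lab.

    Rows are ordered by (patient, measurement index); ``patient_index``
    maps each row to its patient, standing in for the block-diagonal
    intercept design.  Rows with a missing value for this lab are dropped.
    """
    if lab_id not in dataset.labs:
        raise KeyError(f"lab {lab_id!r} not in catalog")
    use_drugs = list(drugs) if drugs is not None else list(dataset.drugs)
    sub = dataset.table[dataset.table["lab_id"] == lab_id]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"lab {lab_id!r} has no measurements (empty design)")
    sub = sub.sort_values(["patient_id", "meas_index"], kind="mergesort")
    codes, patients = pd.factorize(sub["patient_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    sub = sub.iloc[order]
    codes = codes[order]
    y = sub["value"].to_numpy(dtype=float)
    X = sub[use_drugs].to_numpy(dtype=float)
    return Design(y=y, X=X, patient_index=codes, patients=list(patients), drugs=use_drugs)


def center_within_patient(
    y: np.ndarray, X: np.ndarray, patient_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove each patient's mean response and mean exposures.

    This is the algebraic elimination of the per-patient intercepts: after
    centering, every patient's block of y_c and of each X_c column sums to
    zero, and regressing y_c on X_c recovers the same beta as the full
    fixed-effects least-squares fit.  A patient with a single measurement
    centers to an all-zero row and contributes nothing to the fit.
    """
    patient_index = np.asarray(patient_index)
    n_groups = patient_index.max() + 1 if len(patient_index) else 0
    counts = np.bincount(patient_index, minlength=n_groups).astype(float)

    y_means = np.bincount(patient_index, weights=y, minlength=n_groups) / counts
    y_c = y - y_means[patient_index]

    X = np.asarray(X, dtype=float)
    X_means = np.empty((n_groups, X.shape[1]))
    for m in range(X.shape[1]):
        X_means[:, m] = (
            np.bincount(patient_index, weights=X[:, m], minlength=n_groups) / counts
        )
    X_c = X - X_means[patient_index]
    return y_c, X_c


def fit_cscc(y_c: np.ndarray, X_c: np.ndarray, lam: float) -> np.ndarray:
    """Solve the centered lasso problem for one lab.

    Minimizes 1/2 ||y_c - X_c b||^2 + lam ||b||_1.  At lam = 0 the
    minimum-norm least-squares solution is returned (exact under rank
    deficiency, no coordinate-descent tolerance).
    """
    y_c = np.asarray(y_c, dtype=float)
    X_c = np.asarray(X_c, dtype=float)
    if not (np.isfinite(y_c).all() and np.isfinite(X_c).all()):
        raise ValueError("non-finite values in centered design")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X_c, y_c, rcond=None)
        return beta
    n = len(y_c)
    # sklearn's objective is 1/(2n)||.||^2 + alpha||.||_1, so alpha = lam/n
    model = Lasso(alpha=lam / n, fit_intercept=False, max_iter=100_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_c, y_c)
    return model.coef_.astype(float)


def default_lambda_grid(y_c: np.ndarray, X_c: np.ndarray, size: int = 16) -> np.ndarray:
    """Log-spaced grid from lambda_max (null solution) down three decades."""
    lam_max = float(np.abs(X_c.T @ y_c).max())
    if lam_max == 0:
        return np.array([0.0])
    return lam_max * np.logspace(0, -3, size)


def select_lambda(
    y_c: np.ndarray,
    X_c: np.ndarray,
    patient_index: np.ndarray,
    grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
    one_se: bool = True,
) -> float:
    """Pick lambda by patient-grouped k-fold cross-validation.

    Patients (not rows) are shuffled with ``seed`` and split into ``folds``
    groups, respecting the self-controlled structure: a patient's
    measurements never straddle train and test.  By default the
    one-standard-error rule is applied: the largest (sparsest) grid value
    whose cross-validated squared error is within one standard error of the
    minimum is returned, which keeps the null model at null data.  With
    ``one_se=False`` the plain CV minimizer is returned; ties go to the
    larger lambda either way.
    """
    if grid is None:
        grid = default_lambda_grid(y_c, X_c)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    unique_patients = np.unique(patient_index)
    if len(unique_patients) < folds:
        raise ValueError(
            f"{len(unique_patients)} patients is fewer than {folds} folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique_patients)
    fold_of_patient = {p: i % folds for i, p in enumerate(shuffled)}
    fold_of_row = np.array([fold_of_patient[p] for p in patient_index])

    # larger lambda first so ties resolve to the sparser model
    order = np.argsort(-grid, kind="stable")
    fold_err = np.zeros((grid.size, folds))
    for k in range(folds):
        test = fold_of_row == k
        train = ~test
        for gi in order:
            beta = fit_cscc(y_c[train], X_c[train], grid[gi])
            resid = y_c[test] - X_c[test] @ beta
            fold_err[gi, k] = float(resid @ resid)
    cv_err = fold_err.sum(axis=1)
    best = order[int(np.argmin(cv_err[order]))]
    if not one_se:
        return float(grid[best])
    se = float(fold_err[best].std(ddof=1) * np.sqrt(folds))
    within = cv_err[order] <= cv_err[best] + se
    return float(grid[order[int(np.argmax(within))]])


def coef_pvalues(
    beta: np.ndarray,
    y_c: np.ndarray,
    X_c: np.ndarray,
    patient_index: np.ndarray,
) -> np.ndarray:
    """Post-selection p-values for the lasso coefficients.

    Unpenalized least squares is refit on the selected support over the
    centered data; classical two-sided t-tests use residual degrees of
    freedom n - N - s, where N patient intercepts were absorbed by the
    centering and s is the support size.  Drugs outside the support get
    p = 1.  If the support exhausts the residual degrees of freedom every
    p-value is 1 and a warning is logged.
    """
    beta = np.asarray(beta, dtype=float)
    support = np.flatnonzero(beta != 0)
    p = np.ones(beta.shape[0])
    if support.size == 0:
        return p
    n = len(y_c)
    n_patients = len(np.unique(patient_index))
    df = n - n_patients - support.size
    if df <= 0:
        logger.warning(
            "support size %d exhausts residual degrees of freedom (n=%d, patients=%d)",
            support.size, n, n_patients,
        )
        return p
    Xs = X_c[:, support]
    coef, *_ = np.linalg.lstsq(Xs, y_c, rcond=None)
    resid = y_c - Xs @ coef
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf)
    p[support] = 2.0 * stats.t.sf(np.abs(t), df)
    return p


@dataclass
class CSCCSFit:
    """Fitted CSCCS model for one lab test."""

    lab_id: str
    drugs: list[str]
    beta: np.ndarray
    pvalues: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if not (len(self.beta) == len(self.pvalues) == len(self.drugs)):
            raise ValueError("beta, pvalues and drugs must have equal length")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)


def call_drug_directions(fit: CSCCSFit, alpha: float = 0.05) -> np.ndarray:
    """Ternary direction per drug: +1 / -1 when significant, else 0."""
    sig = fit.pvalues < alpha
    return np.where(sig, np.sign(fit.beta), 0.0)


@dataclass
class DrugEffectVectors:
    """Ternary drug x lab sign matrix plus per-coefficient statistics."""

    signs: pd.DataFrame   # drugs x labs, values in {+1,-1,0}
    stats: pd.DataFrame   # columns lab_id, drug_id, beta, pvalue, lambda

    def sign_vector(self, drug: str) -> SignVector:
        return SignVector(entity_id=drug, entries=self.signs.loc[drug])

    def as_sign_vectors(self) -> list[SignVector]:
        return [self.sign_vector(d) for d in self.signs.index]

    def to_csv(self, signs_path: str | Path, stats_path: str | Path | None = None) -> None:
        out = self.signs.astype(int)
        out.index.name = "drug_id"
        out.to_csv(signs_path)
        if stats_path is not None:
            self.stats.to_csv(stats_path, index=False)


def build_drug_effect_vectors(
    dataset: LongitudinalDataset,
    alpha: float = 0.05,
    lambda_strategy: str | float = "cv",
    min_patients: int = 1000,
    folds: int = 5,
    seed: int = 0,
    grid: Sequence[float] | None = None,
) -> DrugEffectVectors:
    """Fit the CSCCS model per lab and assemble ternary drug effect vectors.

    ``lambda_strategy`` is either ``"cv"`` (patient-grouped cross-validation)
    or a fixed numeric lambda.  Drugs prescribed to fewer than
    ``min_patients`` distinct patients are excluded before fitting (their
    entries stay 0).  Labs whose fit fails are skipped with a logged
    warning, leaving their column at 0.
    """
    if dataset.table.empty:
        raise ValueError("dataset is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    eligible = [d for d in dataset.drugs if dataset.patients_exposed(d) >= min_patients]
    excluded = set(dataset.drugs) - set(eligible)
    if excluded:
        logger.info("excluding %d drugs below %d-patient threshold", len(excluded), min_patients)

    signs = pd.DataFrame(
        0.0, index=pd.Index(dataset.drugs, name="drug_id"),
        columns=pd.Index(dataset.labs, name="lab_id"),
    )
    stat_rows = []
    for lab in dataset.labs:
        if not eligible:
            break
        try:
            design = build_design(dataset, lab, drugs=eligible)
            y_c, X_c = center_within_patient(design.y, design.X, design.patient_index)
            if lambda_strategy == "cv":
                lam = select_lambda(
                    y_c, X_c, design.patient_index, grid=grid, folds=folds, seed=seed
                )
            else:
                lam = float(lambda_strategy)
            beta = fit_cscc(y_c, X_c, lam)
            pvals = coef_pvalues(beta, y_c, X_c, design.patient_index)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping lab %s: %s", lab, exc)
            continue
        fit = CSCCSFit(lab_id=lab, drugs=eligible, beta=beta, pvalues=pvals, lam=lam)
        directions = call_drug_directions(fit, alpha=alpha)
        signs.loc[eligible, lab] = directions
        for d, b, p in zip(eligible, beta, pvals):
            stat_rows.append(
                {"lab_id": lab, "drug_id": d, "beta": b, "pvalue": p, "lambda": lam}
            )
    stats_df = pd.DataFrame(
        stat_rows, columns=["lab_id", "drug_id", "beta", "pvalue", "lambda"]
    )
    return DrugEffectVectors(signs=signs, stats=stats_df)
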