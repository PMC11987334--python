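"""Patch-level lasso regression of mRSS on QIFs and the Fibrosis Score.

The model is trained on pooled patches — every patch of a biopsy carries
that biopsy's mRSS as its label — minimizing

    (1/2) * mean squared error + lambda * sum |beta_j|

over standardized features, with an unpenalized intercept (which at the
strong-penalty limit equals the mean mRSS of the training population).
Per-biopsy prediction averages the 100 patch predictions into a single
scalar, the Fibrosis Score.  The penalty is selected from a fixed
logarithmic grid by patient-grouped cross-validation so that no
patient's biopsies ever straddle a train/test split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression

from fibroscore.errors import InvalidArgumentError, JoinError, ShapeError

#: coordinate-descent convergence tolerance and sweep cap for the lasso
LASSO_TOL = 1e-7
LASSO_MAX_ITER = 10_000

#: above this many patients, grouped k-fold replaces leave-one-patient-out
LOPO_MAX_PATIENTS = 10
GROUPED_KFOLD_K = 10


@dataclass
class LambdaGrid:
    """Logarithmically spaced penalty grid."""

    values: np.ndarray
    log10_min: float
    log10_max: float

    @property
    def n(self) -> int:
        return len(self.values)


def make_lambda_grid(n: int = 16, log10_min: float = -5, log10_max: float = 3) -> LambdaGrid:
    """Default: 16 values from 1e-5 (weak penalty) to 1e3 (strong penalty)."""
    if n < 2:
        raise InvalidArgumentError(f"grid needs n >= 2, got {n}")
    if not log10_min < log10_max:
        raise InvalidArgumentError("log10_min must be < log10_max")
    return LambdaGrid(
        values=np.logspace(log10_min, log10_max, n),
        log10_min=float(log10_min),
        log10_max=float(log10_max),
    )


def _as_matrix_list(qifs) -> list[np.ndarray]:
    out = []
    for q in qifs:
        m = q.values if hasattr(q, "values") and not isinstance(q, np.ndarray) else q
        out.append(np.asarray(m, dtype=np.float64))
    return out


def _pool(mats: list[np.ndarray], labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack patches; replicate each biopsy's label; record biopsy index."""
    labels = np.asarray(labels, dtype=np.float64)
    if len(mats) != len(labels):
        raise JoinError(f"{len(mats)} QIF matrices but {len(labels)} labels")
    if np.any(np.isnan(labels)):
        raise JoinError("missing (NaN) labels")
    X = np.vstack(mats)
    y = np.concatenate([np.full(m.shape[0], lab) for m, lab in zip(mats, labels)])
    idx = np.concatenate([np.full(m.shape[0], i) for i, m in enumerate(mats)])
    return X, y, idx


class FibrosisScoreRegressor(RegressorMixin, BaseEstimator):
    """Lasso on pooled patches with patch-mean biopsy scores.

    Parameters
    ----------
    lam : float or "auto"
        Penalty weight on sum |beta|.  ``"auto"`` selects from
        ``lambda_grid`` by patient-grouped cross-validation (requires
        ``groups`` at fit time), then refits on all biopsies.
    lambda_grid : LambdaGrid or None
        Penalty grid for auto selection (default 16 values, 1e-5..1e3).
    random_state : int
        Seed for grouped-fold assignment when there are more patients
        than the leave-one-patient-out cutover.

    Attributes
    ----------
    coef_ : (D,) lasso coefficients on the standardized scale
    intercept_ : float
    lambda_ : float — penalty actually used
    feature_means_, feature_sds_ : training standardization
    cv_table_ : DataFrame of per-(lambda, fold) held-out errors (auto mode)
    """

    def __init__(self, lam="auto", lambda_grid: LambdaGrid | None = None, random_state: int = 0):
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.random_state = random_state

    # ---- internals -------------------------------------------------
    def _standardize_fit(self, X: np.ndarray):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        const = sd < 1e-12
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature(s) dropped (coefficient fixed at 0)"
            )
        sd_safe = np.where(const, 1.0, sd)
        return mu, sd_safe, const

    def _fit_at(self, X: np.ndarray, y: np.ndarray, lam: float):
        mu, sd, const = self._standardize_fit(X)
        Z = (X - mu) / sd
        Z[:, const] = 0.0
        if len(np.unique(y)) < 2:
            coef = np.zeros(X.shape[1])
            return coef, float(y.mean()), mu, sd, const
        if lam == 0.0:
            reg = LinearRegression().fit(Z, y)
        else:
            with warnings.catch_warnings():
                # near-zero penalties stop on the sweep cap, not the duality
                # gap; predictions are converged for our purposes
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                reg = Lasso(alpha=lam, tol=LASSO_TOL, max_iter=LASSO_MAX_ITER).fit(Z, y)
        coef = np.asarray(reg.coef_, dtype=np.float64)
        coef[const] = 0.0
        return coef, float(reg.intercept_), mu, sd, const

    # ---- API -------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Fit on a list of per-biopsy patch matrices.

        X : sequence of (n_patches_i, D) arrays or QIFMatrix objects
        y : per-biopsy mRSS labels, same length as X
        groups : per-biopsy patient ids (required when ``lam="auto"``)
        """
        mats = _as_matrix_list(X)
        D = mats[0].shape[1]
        if any(m.shape[1] != D for m in mats):
            raise ShapeError("QIF matrices disagree on feature dimension")
        labels = np.asarray(y, dtype=np.float64)

        if self.lam == "auto":
            if groups is None:
                raise InvalidArgumentError("lam='auto' requires per-biopsy patient groups")
            grid = self.lambda_grid or make_lambda_grid()
            lam_star, cv_table = select_lambda_grouped_cv(
                mats, labels, groups, grid, seed=self.random_state
            )
            self.cv_table_ = cv_table
        else:
            lam_star = float(self.lam)
            self.cv_table_ = None
        Xp, yp, _ = _pool(mats, labels)
        coef, intercept, mu, sd, const = self._fit_at(Xp, yp, lam_star)
        self.coef_ = coef
        self.intercept_ = intercept
        self.lambda_ = lam_star
        self.feature_means_ = mu
        self.feature_sds_ = sd
        self.constant_features_ = const
        self.n_features_in_ = D
        return self

    def predict_patches(self, M) -> np.ndarray:
        """Per-patch linear predictions for one biopsy's matrix."""
        M = np.asarray(M.values if hasattr(M, "values") and not isinstance(M, np.ndarray) else M)
        if M.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"matrix has D={M.shape[1]} but model expects {self.n_features_in_}"
            )
        Z = (M - self.feature_means_) / self.feature_sds_
        Z[:, self.constant_features_] = 0.0
        return Z @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Fibrosis Score (patch-mean prediction) per biopsy."""
        return np.array([float(self.predict_patches(m).mean()) for m in _as_matrix_list(X)])


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)
# ---------------------------------------------------------------------------


@dataclass
class FibrosisModel:
    """Serializable fitted model."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "lambda": self.lam,
                "feature_means": self.feature_means.tolist(),
                "feature_sds": self.feature_sds.tolist(),
                "training_meta": self.training_meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FibrosisModel":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"]),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            feature_means=np.asarray(d["feature_means"]),
            feature_sds=np.asarray(d["feature_sds"]),
            training_meta=d.get("training_meta", {}),
        )


@dataclass
class FibrosisScore:
    biopsy_id: str
    score: float
    n_patches: int
    patch_predictions: np.ndarray


def fit_lasso_patchwise(qifs, labels, lam: float) -> FibrosisModel:
    """Fit the patch-pooled lasso at a fixed penalty."""
    est = FibrosisScoreRegressor(lam=float(lam)).fit(qifs, labels)
    return _model_from_estimator(est)


def _model_from_estimator(est: FibrosisScoreRegressor, meta: dict | None = None) -> FibrosisModel:
    return FibrosisModel(
        coefficients=est.coef_,
        intercept=est.intercept_,
        lam=est.lambda_,
        feature_means=est.feature_means_,
        feature_sds=est.feature_sds_,
        training_meta=meta or {},
    )


def _grouped_folds(groups: np.ndarray, seed: int) -> list[np.ndarray]:
    """Biopsy-index folds: LOPO, or k grouped folds for large cohorts."""
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise InvalidArgumentError("grouped CV needs >= 2 patients")
    rng = np.random.default_rng(seed)
    if len(uniq) <= LOPO_MAX_PATIENTS:
        chunks = [[g] for g in uniq]
    else:
        perm = rng.permutation(len(uniq))
        chunks = [list(uniq[perm[i::GROUPED_KFOLD_K]]) for i in range(GROUPED_KFOLD_K)]
        chunks = [c for c in chunks if c]
    return [np.flatnonzero(np.isin(groups, c)) for c in chunks]


def select_lambda_grouped_cv(
    qifs, labels, groups, grid: LambdaGrid | None = None, seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Pick lambda minimizing held-out biopsy-level squared error.

    Folds hold out whole patients (leave-one-patient-out up to 10
    patients, 10 grouped folds beyond).  Ties in CV error go to the
    larger (more parsimonious) lambda.  Returns (lambda*, cv_table).
    """
    mats = _as_matrix_list(qifs)
    labels = np.asarray(labels, dtype=np.float64)
    groups = np.asarray(groups)
    if len(groups) != len(mats):
        raise JoinError("groups must map each biopsy to exactly one patient")
    grid = grid or make_lambda_grid()
    folds = _grouped_folds(groups, seed)

    records = []
    sq_err = np.zeros((grid.n, len(mats)))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(mats)), test_idx)
        # no-leakage invariant: must be unreachable
        assert not set(groups[train_idx]) & set(groups[test_idx]), (
            "patient present in both train and test of one fold"
        )
        Xtr, ytr, _ = _pool([mats[i] for i in train_idx], labels[train_idx])
        helper = FibrosisScoreRegressor(lam=0.0)
        for li, lam in enumerate(grid.values):
            coef, intercept, mu, sd, const = helper._fit_at(Xtr, ytr, float(lam))
            errs = []
            for bi in test_idx:
                Z = (mats[bi] - mu) / sd
                Z[:, const] = 0.0
                score = float((Z @ coef + intercept).mean())
                e = (score - labels[bi]) ** 2
                sq_err[li, bi] = e
                errs.append(e)
            records.append(
                {
                    "lambda": float(lam),
                    "fold": fi,
                    "test_patients": ",".join(map(str, pd.unique(groups[test_idx]))),
                    "mse": float(np.mean(errs)),
                }
            )
    mean_err = sq_err.mean(axis=1)
    best = mean_err.min()
    lam_star = float(grid.values[np.flatnonzero(mean_err <= best + 1e-12)].max())
    return lam_star, pd.DataFrame(records)


def predict_fibrosis_score(model: FibrosisModel, qif) -> FibrosisScore:
    """Score one biopsy: mean of the per-patch linear predictions (unclipped)."""
    M = np.asarray(qif.values if hasattr(qif, "values") and not isinstance(qif, np.ndarray) else qif)
    if M.shape[1] != len(model.coefficients):
        raise ShapeError(
            f"QIF dimension {M.shape[1]} != model dimension {len(model.coefficients)}"
        )
    Z = (M - model.feature_means) / model.feature_sds
    preds = Z @ model.coefficients + model.intercept
    return FibrosisScore(
        biopsy_id=getattr(qif, "biopsy_id", "biopsy"),
        score=float(preds.mean()),
        n_patches=M.shape[0],
        patch_predictions=preds,
    )


def evaluate_scores(scores, labels):
    """Spearman correlation between biopsy scores and mRSS labels."""
    from fibroscore.stats import spearman_corr

    vals = [s.score if hasattr(s, "score") else float(s) for s in scores]
    return spearman_corr(vals, labels)
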