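"""Proportional-odds (cumulative logit) regression by Newton-Raphson.

Model: P(Y <= k | x) = logistic(theta_k - beta * x) with strictly
increasing cutpoints theta_1 < ... < theta_{K-1}.  The sign convention
makes OR = exp(beta) > 1 mean that larger x favors higher categories
(per unit of x, the odds of exceeding any cutpoint are multiplied by
exp(beta)).  With K = 2 the model reduces exactly to binary logistic
regression.

Inference is Wald throughout: SE from the observed information at the
MLE, 95% CI = exp(beta +/- 1.96 SE), two-sided p from the z statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from fibroscore import schema
from fibroscore.errors import InvalidArgumentError, JoinError, SeparationError

GRAD_TOL = 1e-8
MAX_ITER = 200
SEPARATION_BOUND = 30.0  # |beta| or |theta| beyond this flags separation


@dataclass
class ORResult:
    beta: float
    or_: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    thresholds: np.ndarray
    converged: bool
    n: int


class ProportionalOdds:
    """Single-predictor cumulative-logit MLE.

    ``fit(x, y)`` estimates (theta, beta); fitted attributes carry a
    trailing underscore.  ``result()`` packages the Wald inference.
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if x.shape != y.shape or x.ndim != 1:
            raise InvalidArgumentError("x and y must be paired 1-d vectors")
        cats = np.unique(y)
        K = len(cats)
        if K < 2:
            raise InvalidArgumentError(f"need >= 2 observed categories, got {K}")
        n = len(y)
        if n <= K:
            raise InvalidArgumentError(f"n={n} too small for {K - 1} thresholds + slope")
        yk = np.searchsorted(cats, y)  # 0..K-1

        # init: empirical cumulative logits, beta = 0
        cum = np.cumsum(np.bincount(yk, minlength=K))[:-1] / n
        cum = np.clip(cum, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        psi = np.concatenate([np.log(cum / (1.0 - cum)), [0.0]])

        ll = self._loglik(psi, x, yk, K)
        converged = False
        for _ in range(MAX_ITER):
            grad, H = self._grad_hess(psi, x, yk, K)
            if np.max(np.abs(grad)) < GRAD_TOL:
                converged = True
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                raise SeparationError(
                    "singular information matrix: data are separated or a "
                    "category is empty; consider pooling categories"
                ) from None
            # Newton with step halving to keep the likelihood ascending
            # and the thresholds ordered
            t = 1.0
            for _ in range(40):
                cand = psi - t * step
                if np.all(np.diff(cand[:-1]) > 0):
                    cand_ll = self._loglik(cand, x, yk, K)
                    if np.isfinite(cand_ll) and cand_ll >= ll - 1e-10:
                        break
                t *= 0.5
            else:
                break
            psi, ll = cand, cand_ll
            if abs(psi[-1]) > SEPARATION_BOUND or np.max(np.abs(psi[:-1])) > SEPARATION_BOUND:
                raise SeparationError(
                    f"estimate diverging (|beta| or |theta| > {SEPARATION_BOUND}): "
                    "complete or quasi-separation; the odds ratio is not "
                    "identifiable from these data"
                )

        grad, H = self._grad_hess(psi, x, yk, K)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
        cov = np.linalg.inv(-H)
        self.thresholds_ = psi[:-1].copy()
        self.coef_ = float(psi[-1])
        self.se_ = float(np.sqrt(max(cov[-1, -1], 0.0)))
        self.cov_params_ = cov
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.n_ = n
        self.categories_ = cats
        return self

    @staticmethod
    def _probs(psi, x, yk, K):
        theta = psi[:-1]
        beta = psi[-1]
        eta_hi = np.where(yk <= K - 2, theta[np.minimum(yk, K - 2)] - beta * x, np.inf)
        eta_lo = np.where(yk >= 1, theta[np.maximum(yk - 1, 0)] - beta * x, -np.inf)
        F_hi = expit(eta_hi)
        F_lo = expit(eta_lo)
        L = np.maximum(F_hi - F_lo, 1e-300)
        return F_hi, F_lo, L

    @classmethod
    def _loglik(cls, psi, x, yk, K):
        _, _, L = cls._probs(psi, x, yk, K)
        return float(np.sum(np.log(L)))

    @classmethod
    def _grad_hess(cls, psi, x, yk, K):
        n = len(x)
        P = K  # K-1 thresholds + beta
        F_hi, F_lo, L = cls._probs(psi, x, yk, K)
        f_hi = np.where(np.isfinite(F_hi * (1 - F_hi)), F_hi * (1 - F_hi), 0.0)
        f_lo = F_lo * (1 - F_lo)
        fp_hi = f_hi * (1 - 2 * F_hi)
        fp_lo = f_lo * (1 - 2 * F_lo)

        hi_ok = yk <= K - 2
        lo_ok = yk >= 1
        U = np.zeros((n, P))
        idx = np.arange(n)
        U[idx[hi_ok], yk[hi_ok]] += f_hi[hi_ok] / L[hi_ok]
        U[idx[lo_ok], yk[lo_ok] - 1] -= f_lo[lo_ok] / L[lo_ok]
        U[:, -1] = -x * (f_hi - f_lo) / L
        grad = U.sum(axis=0)

        A = np.zeros((P, P))
        w_hi = np.where(hi_ok, fp_hi / L, 0.0)
        w_lo = np.where(lo_ok, fp_lo / L, 0.0)
        np.add.at(A, (yk[hi_ok], yk[hi_ok]), w_hi[hi_ok])
        np.add.at(A, (yk[lo_ok] - 1, yk[lo_ok] - 1), -w_lo[lo_ok])
        cross_hi = np.bincount(yk[hi_ok], weights=(w_hi * -x)[hi_ok], minlength=K - 1)
        cross_lo = np.bincount(yk[lo_ok] - 1, weights=(w_lo * -x)[lo_ok], minlength=K - 1)
        A[:-1, -1] += cross_hi - cross_lo
        A[-1, :-1] += cross_hi - cross_lo
        A[-1, -1] += np.sum(w_hi * x * x) - np.sum(w_lo * x * x)
        H = A - U.T @ U
        return grad, H

    def result(self) -> ORResult:
        beta, se = self.coef_, self.se_
        z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
        return ORResult(
            beta=beta,
            or_=float(np.exp(beta)),
            se=se,
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            p=float(2 * norm.sf(abs(z))),
            thresholds=self.thresholds_,
            converged=self.converged_,
            n=self.n_,
        )


def fit_proportional_odds(y, x) -> ORResult:
    """Fit the cumulative-logit model; returns OR with Wald CI and p."""
    return ProportionalOdds().fit(x, y).result()


def _consensus_scores(sheets: pd.DataFrame) -> pd.DataFrame:
    """Per-biopsy consensus across raters/sessions.

    Binary -> majority vote; 0-5 ordinal -> rounded mean; continuous ->
    mean rounded to the nearest integer on the reported scale (the
    integer binning under which count/percent/µm parameters enter the
    ordinal fits).
    """
    grouped = sheets.groupby("biopsy_id")[list(schema.PARAMETER_NAMES)].mean()
    out = pd.DataFrame(index=grouped.index)
    for p in schema.PARAMETER_NAMES:
        kind = schema.PARAMETERS[p]
        if kind == schema.BINARY:
            out[p] = (grouped[p] >= 0.5).astype(int)
        else:
            out[p] = np.round(grouped[p]).astype(int)
    return out


def odds_ratio_table(sheets: pd.DataFrame, predictor) -> pd.DataFrame:
    """One proportional-odds fit per histological parameter.

    ``predictor`` maps biopsy_id -> per-biopsy score (mRSS or Fibrosis
    Score): a pandas Series, dict, or DataFrame with columns
    (biopsy_id, value).  Binary parameters reduce to logistic fits.  No
    multiplicity correction is applied.  Parameters whose fit fails a
    precondition are reported with NA and the reason.
    """
    if isinstance(predictor, pd.DataFrame):
        cols = [c for c in predictor.columns if c != "biopsy_id"]
        predictor = predictor.set_index("biopsy_id")[cols[0]]
    elif isinstance(predictor, dict):
        predictor = pd.Series(predictor)
    consensus = _consensus_scores(sheets)
    missing = sorted(set(consensus.index) - set(predictor.index))
    if missing:
        raise JoinError(f"biopsies without predictor value: {missing}")
    x = predictor.loc[consensus.index].to_numpy(dtype=float)
    rows = []
    for p in schema.PARAMETER_NAMES:
        y = consensus[p].to_numpy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = fit_proportional_odds(y, x)
            rows.append(
                {"parameter": p, "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high,
                 "p": r.p, "n": r.n, "note": "" if r.converged else "not converged"}
            )
        except (InvalidArgumentError, SeparationError) as e:
            rows.append(
                {"parameter": p, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "p": np.nan, "n": len(y), "note": str(e)}
            )
    return pd.DataFrame(rows)
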