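"""Simulate ordinal outcomes under the proportional-odds model.

The cumulative-logit (proportional-odds) model posits
``P(Y <= k | x) = logistic(theta_k - beta * x)`` with strictly increasing
cutpoints theta.  Data generated here are the recovery benchmark for the
package's ordinal regression estimator: refitting must return the planted
``exp(beta)`` odds ratio within simulation error.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from fibroscore.errors import InvalidArgumentError


def simulate_proportional_odds_data(
    beta: float,
    n: int,
    thresholds,
    x_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) from a proportional-odds model.

    Parameters
    ----------
    beta : float
        Log odds ratio per unit of x; positive beta shifts mass toward
        higher categories for larger x.
    n : int
        Number of observations.
    thresholds : strictly increasing sequence, length K-1
        Cutpoints theta_1 < ... < theta_{K-1} for K ordinal categories
        labeled 0..K-1.
    x_sd : float > 0
        The predictor is x ~ Normal(0, x_sd).
    seed : int

    Returns
    -------
    (x, y) : float array, int array
        y[i] in {0, ..., K-1} sampled from the cumulative logits
        ``P(Y <= k | x) = logistic(theta_k - beta x)``.
    """
    theta = np.asarray(thresholds, dtype=float)
    if theta.ndim != 1 or len(theta) < 1:
        raise InvalidArgumentError("thresholds must be a 1-d sequence of length >= 1")
    if np.any(np.diff(theta) <= 0):
        raise InvalidArgumentError(f"thresholds must be strictly increasing, got {theta}")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if x_sd <= 0:
        raise InvalidArgumentError("x_sd must be > 0")

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, x_sd, size=n)
    # cumulative probabilities P(Y <= k), k = 0..K-2, shape (n, K-1)
    cum = expit(theta[None, :] - beta * x[:, None])
    u = rng.random(n)
    y = (u[:, None] > cum).sum(axis=1)
    return x, y.astype(np.int64)
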