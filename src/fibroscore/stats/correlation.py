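"""Spearman rank correlation with a t-approximation or exact-permutation p."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

from fibroscore.errors import InvalidArgumentError


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    method: str = "t-approximation"


def spearman_corr(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rho (average ranks on ties) with two-sided p.

    The default p-value uses the t-approximation with n-2 degrees of
    freedom; ``exact=True`` (only for n <= 8) enumerates all n!
    permutations of one variable and reports the proportion with
    |rho| at least as extreme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 3:
        raise InvalidArgumentError(f"need n >= 3 pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise InvalidArgumentError("zero rank variance: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if not exact:
        return CorrelationResult(rho=rho, p=float(p), n=n)
    if n > 8:
        raise InvalidArgumentError("exact permutation p only supported for n <= 8")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return CorrelationResult(rho=rho, p=count / total, n=n, method="exact permutation")
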