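"""Cohen's kappa and the six agreement bands.

kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed agreement
fraction and p_e the chance agreement implied by the two raters'
marginal frequencies.  Bands follow the conventional cutpoints:
<= 0 no agreement, 0.01-0.20 none to slight, 0.21-0.40 fair,
0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect
(the open gap (0, 0.01) is assigned to "none to slight").

For the 16-parameter agreement table, continuous measurements are
discretized into quintile bins before kappa; binary and 0-5 ordinal
parameters are compared unweighted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibroscore import schema
from fibroscore.errors import DegenerateAgreementError, InvalidArgumentError, ShapeError


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    band: str
    n: int


def cohens_kappa(r1, r2) -> KappaResult:
    """Unweighted kappa from the raters' cross-tabulation."""
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"paired 1-d ratings required, got {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise InvalidArgumentError("need at least 2 paired ratings")
    universe = np.unique(np.concatenate([np.unique(a), np.unique(b)]))
    ai = np.searchsorted(universe, a)
    bi = np.searchsorted(universe, b)
    k = len(universe)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if p_e >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "both raters constant: expected agreement is 1, kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa), p_observed=p_o, p_expected=p_e,
        band=agreement_band(kappa), n=n,
    )


def agreement_band(kappa: float) -> str:
    if kappa > 1.0:
        raise InvalidArgumentError(f"kappa cannot exceed 1, got {kappa}")
    if kappa <= 0.0:
        return "no agreement"
    if kappa <= 0.20:
        return "none to slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def kappa_table(sheets: pd.DataFrame, session: int = 1) -> pd.DataFrame:
    """Inter-rater kappa per parameter from a two-rater score sheet table.

    ``sheets`` has one row per (biopsy, rater, session) with the 16
    schema columns.  Continuous parameters are quintile-binned jointly
    across both raters before kappa.  Parameters whose kappa is
    undefined (both raters constant) are reported as NA with a reason.
    """
    sub = sheets[sheets["session"] == session]
    raters = sorted(sub["rater_id"].unique())
    if len(raters) != 2:
        raise InvalidArgumentError(f"expected exactly 2 raters, found {raters}")
    a = sub[sub["rater_id"] == raters[0]].set_index("biopsy_id").sort_index()
    b = sub[sub["rater_id"] == raters[1]].set_index("biopsy_id").sort_index()
    common = a.index.intersection(b.index)
    rows = []
    for p in schema.PARAMETER_NAMES:
        va = a.loc[common, p].to_numpy()
        vb = b.loc[common, p].to_numpy()
        if schema.PARAMETERS[p] == schema.CONTINUOUS:
            pooled = np.concatenate([va, vb])
            edges = np.quantile(pooled, [0.2, 0.4, 0.6, 0.8])
            va = np.searchsorted(edges, va, side="right")
            vb = np.searchsorted(edges, vb, side="right")
        try:
            res = cohens_kappa(va, vb)
            rows.append(
                {"parameter": p, "kappa": res.kappa, "band": res.band, "n": res.n,
                 "note": ""}
            )
        except DegenerateAgreementError:
            rows.append(
                {"parameter": p, "kappa": np.nan, "band": "NA", "n": len(common),
                 "note": "degenerate: both raters constant"}
            )
    return pd.DataFrame(rows)
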