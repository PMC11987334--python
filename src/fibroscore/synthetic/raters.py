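"""Simulated dermatopathologist score sheets.

True parameter values derive from each biopsy's planted truth through
fixed monotone links (thresholds on severity, vessel count, collagen
fraction); two rater profiles then corrupt them with controllable noise —
independent flips on present/absent calls, ±1 jitter on 0-5 intensities,
multiplicative noise on continuous measurements — plus extra drift on the
second scoring session, emulating re-assessment after a washout period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibroscore import schema
from fibroscore.errors import InvalidArgumentError, SchemaError

TRUTH_FIELDS = (
    "severity",
    "collagen_fraction",
    "fat_vacuole_density",
    "vessel_ectasia_count",
    "infiltrate_density",
)

# fixed monotone truth -> label links (documented so tests are reproducible)
_BINARY_SEVERITY_THRESHOLDS = {
    "epidermal_papilla_loss": 0.30,
    "eccrine_entrapment": 0.45,
    "eccrine_coil_loss": 0.70,
    "hair_follicle_loss": 0.55,
    "calcification": 0.85,
    "sc_fat_loss_widened_septa": 0.50,
    "thickened_intima": 0.60,
}
TELANGIECTASIA_VESSEL_THRESHOLD = 8  # ectatic profiles per section


def true_scores_from_truth(truth: dict) -> dict:
    """Map one biopsy's planted parameters to its 16 true scores."""
    missing = [f for f in TRUTH_FIELDS if f not in truth]
    if missing:
        raise SchemaError(f"truth record missing field(s): {missing}")
    sev = float(truth["severity"])
    cf = float(truth["collagen_fraction"])
    infil = float(truth["infiltrate_density"])

    def lvl(x):
        return int(np.clip(np.round(x), 0, 5))

    scores = {
        p: int(sev > t) for p, t in _BINARY_SEVERITY_THRESHOLDS.items()
    }
    scores["telangiectasia"] = int(
        truth["vessel_ectasia_count"] >= TELANGIECTASIA_VESSEL_THRESHOLD
    )
    scores["mean_epidermal_thickness_um"] = 60.0 - 25.0 * sev
    cd3 = 0.3 * infil
    scores["perivascular_cd3_density"] = cd3
    scores["perivascular_cd8_density"] = cd3 * (0.35 + 0.25 * sev)
    scores["pct_cd8_among_cd3"] = 100.0 * (0.35 + 0.25 * sev)
    scores["hyalinized_collagen"] = lvl(5.0 * (cf - 0.2) / 0.5)
    scores["cd34"] = lvl(5.0 * (1.0 - sev))  # CD34 staining is lost with disease
    scores["trichrome"] = lvl(5.0 * cf)
    scores["asma"] = lvl(4.0 * sev)
    return {p: scores[p] for p in schema.PARAMETER_NAMES}


@dataclass
class RaterProfile:
    """Noise model for one dermatopathologist.

    Parameters
    ----------
    rater_id : str
    flip_prob : float in [0, 0.5)
        Probability of flipping a present/absent call.
    ordinal_noise : (p_minus, p_zero, p_plus)
        Jitter distribution on 0-5 intensity scores (clipped to 0-5).
    continuous_cv : float >= 0
        Coefficient of variation of multiplicative noise on continuous
        measurements (µm, counts, percent).
    session_drift : float >= 0
        Extra noise on the second session: additional flip/jitter
        probability and additional CV.
    """

    rater_id: str
    flip_prob: float = 0.05
    ordinal_noise: tuple[float, float, float] = (0.15, 0.70, 0.15)
    continuous_cv: float = 0.10
    session_drift: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.flip_prob < 0.5:
            raise InvalidArgumentError(
                f"flip_prob must be in [0, 0.5), got {self.flip_prob}"
            )
        p = np.asarray(self.ordinal_noise, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(
                "ordinal_noise must be three nonnegative probabilities summing to 1"
            )
        if self.continuous_cv < 0 or self.session_drift < 0:
            raise InvalidArgumentError("continuous_cv and session_drift must be >= 0")


def _noisy_binary(rng, value, p):
    return int(value) ^ int(rng.random() < p)


def _noisy_ordinal(rng, value, probs, drift):
    step = int(rng.choice([-1, 0, 1], p=probs))
    if drift > 0 and rng.random() < drift:
        step += int(rng.choice([-1, 1]))
    return int(np.clip(value + step, 0, 5))


def simulate_rater_scores(
    truth,
    profiles: tuple[RaterProfile, RaterProfile],
    sessions: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one score-sheet row per (biopsy, rater, session).

    Parameters
    ----------
    truth : DataFrame or list of dict
        One record per biopsy with a ``biopsy_id`` and the planted truth
        fields (severity, collagen_fraction, fat_vacuole_density,
        vessel_ectasia_count, infiltrate_density).
    profiles : two RaterProfile
    sessions : int >= 1
        Scoring sessions per rater (2 emulates re-scoring after washout).
    seed : int

    Returns
    -------
    DataFrame with columns biopsy_id, rater_id, session and the 16
    schema parameters.
    """
    if len(profiles) != 2:
        raise InvalidArgumentError(f"exactly 2 rater profiles required, got {len(profiles)}")
    if sessions < 1:
        raise InvalidArgumentError("sessions must be >= 1")
    if isinstance(truth, pd.DataFrame):
        records = truth.to_dict("records")
    else:
        records = list(truth)
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        bid = rec.get("biopsy_id", "B?")
        true_scores = true_scores_from_truth(rec)
        for prof in profiles:
            for s in range(1, sessions + 1):
                drift = prof.session_drift if s > 1 else 0.0
                row = {"biopsy_id": bid, "rater_id": prof.rater_id, "session": s}
                for p in schema.PARAMETER_NAMES:
                    kind = schema.PARAMETERS[p]
                    v = true_scores[p]
                    if kind == schema.BINARY:
                        row[p] = _noisy_binary(rng, v, min(prof.flip_prob + drift, 0.499))
                    elif kind == schema.ORDINAL:
                        row[p] = _noisy_ordinal(rng, v, prof.ordinal_noise, drift)
                    else:
                        cv = prof.continuous_cv + drift
                        x = v * (1.0 + rng.normal(0.0, cv)) if cv > 0 else float(v)
                        if p == "pct_cd8_among_cd3":
                            x = float(np.clip(x, 0.0, 100.0))
                        else:
                            x = max(x, 0.0)
                        row[p] = x
                rows.append(row)
    return pd.DataFrame(rows)
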