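"""The 16-parameter dermal histopathology score schema.

Two dermatopathologists score each biopsy for 16 published systemic-
sclerosis skin parameters: eight present/absent calls, four continuous
measurements, and four 0-5 staining intensities read against a standard
image set (0 = normal staining, 5 = maximum staining).
"""

from __future__ import annotations

BINARY = "binary"
ORDINAL = "ordinal"
CONTINUOUS = "continuous"

#: parameter name -> measurement kind, in the conventional reporting order
PARAMETERS: dict[str, str] = {
    "epidermal_papilla_loss": BINARY,
    "eccrine_entrapment": BINARY,
    "eccrine_coil_loss": BINARY,
    "telangiectasia": BINARY,
    "hair_follicle_loss": BINARY,
    "calcification": BINARY,
    "sc_fat_loss_widened_septa": BINARY,
    "thickened_intima": BINARY,
    "mean_epidermal_thickness_um": CONTINUOUS,
    "perivascular_cd3_density": CONTINUOUS,
    "perivascular_cd8_density": CONTINUOUS,
    "pct_cd8_among_cd3": CONTINUOUS,
    "hyalinized_collagen": ORDINAL,
    "cd34": ORDINAL,
    "trichrome": ORDINAL,
    "asma": ORDINAL,
}

PARAMETER_NAMES = tuple(PARAMETERS)
ORDINAL_LEVELS = (0, 1, 2, 3, 4, 5)

#: non-parameter columns of a score sheet
SHEET_KEYS = ("biopsy_id", "rater_id", "session")


def parameter_kind(name: str) -> str:
    try:
        return PARAMETERS[name]
    except KeyError:
        raise KeyError(f"unknown histological parameter: {name!r}") from None


def binary_parameters() -> list[str]:
    return [p for p, k in PARAMETERS.items() if k == BINARY]


def ordinal_parameters() -> list[str]:
    return [p for p, k in PARAMETERS.items() if k == ORDINAL]


def continuous_parameters() -> list[str]:
    return [p for p, k in PARAMETERS.items() if k == CONTINUOUS]
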