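"""Fixed Masson-trichrome stain model shared by the renderer and the
texture feature extractor.

Optical density follows the Beer–Lambert convention OD = -log10(I/I0).
The three unit absorption vectors below are fixed package constants
(aniline blue for collagen, a Biebrich-scarlet-like red counterstain for
cytoplasm/muscle, hematoxylin for nuclei); recalibration against real
scanner output is deliberately out of scope.  The synthetic renderer
colors pixels with the exact transmitted-light anchors implied by these
vectors, so stain separation of a rendered slide recovers the planted
concentrations up to uint8 rounding.
"""

from __future__ import annotations

import numpy as np

# rows: stain OD unit vectors in (R, G, B)
STAIN_NAMES = ("collagen", "counterstain", "hematoxylin")
_RAW = np.array(
    [
        [0.74, 0.61, 0.28],  # aniline blue: absorbs red/green, transmits blue
        [0.25, 0.80, 0.54],  # red counterstain: absorbs green/blue
        [0.59, 0.70, 0.40],  # hematoxylin: blue-purple nuclear stain
    ]
)
STAIN_MATRIX = _RAW / np.linalg.norm(_RAW, axis=1, keepdims=True)
STAIN_MATRIX_INV = np.linalg.inv(STAIN_MATRIX)

#: OD above which a pixel's collagen concentration counts toward the
#: collagen area fraction feature.
COLLAGEN_OD_THRESHOLD = 0.25

#: luminance (0-1) above which a pixel counts as a bright object (fat
#: vacuole lumen / vessel lumen / background white).
BRIGHT_THRESHOLD = 0.85

_EPS = 1e-6


_LN10 = float(np.log(10.0))


def concentrations_to_rgb(conc: np.ndarray) -> np.ndarray:
    """Map stain concentrations (..., 3) to uint8 RGB via Beer-Lambert."""
    od = conc @ STAIN_MATRIX.astype(conc.dtype, copy=False)
    np.multiply(od, -_LN10, out=od)
    np.exp(od, out=od)
    np.multiply(od, 255.0, out=od)
    np.add(od, 0.5, out=od)  # round half up before the uint8 cast
    np.clip(od, 0.0, 255.0, out=od)
    return od.astype(np.uint8)


def rgb_to_concentrations(rgb: np.ndarray) -> np.ndarray:
    """Unmix uint8 RGB (..., 3) into per-stain concentrations (..., 3)."""
    od = -np.log10(np.maximum(rgb.astype(np.float64), 1.0) / 255.0 + _EPS)
    return od @ STAIN_MATRIX_INV


def stain_anchor_rgb(stain: str, strength: float = 1.0) -> np.ndarray:
    """Pure-stain uint8 color at the given concentration."""
    conc = np.zeros(3)
    conc[STAIN_NAMES.index(stain)] = strength
    return concentrations_to_rgb(conc)
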