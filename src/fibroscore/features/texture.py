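"""The texture32 backend: 32 deterministic stain/texture descriptors.

Feature order (fixed; indices 0-based):

* 0-14   — per stain channel after optical-density separation with the
           fixed trichrome vectors (collagen, counterstain, hematoxylin):
           mean, sd, q10, q50, q90 of the concentration plane.
* 15     — collagen-channel area fraction above the fixed OD threshold.
* 16-21  — per RGB channel: gradient-magnitude mean and sd.
* 22-29  — GLCM contrast, homogeneity, energy, correlation at directed
           offsets (0,1) and (1,0) on a 16-level gray quantization
           (co-occurrence matrices normalized, not symmetrized; the four
           statistics are transpose-invariant so offset sign is
           immaterial).
* 30-31  — bright-object (lumen/fat/background-white) pixel fraction and
           connected-component count per 10^4 pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import label as cc_label
from sklearn.base import BaseEstimator, TransformerMixin

from fibroscore._stains import (
    BRIGHT_THRESHOLD,
    COLLAGEN_OD_THRESHOLD,
    rgb_to_concentrations,
)
from fibroscore.errors import GeometryError, NumericError

GLCM_LEVELS = 16
FEATURE_NAMES = (
    [f"{s}_{stat}" for s in ("collagen", "counterstain", "hematoxylin")
     for stat in ("mean", "sd", "q10", "q50", "q90")]
    + ["collagen_area_fraction"]
    + [f"grad_{ch}_{stat}" for ch in "rgb" for stat in ("mean", "sd")]
    + [f"glcm_{prop}_{off}" for prop in ("contrast", "homogeneity", "energy", "correlation")
       for off in ("01", "10")]
    + ["bright_fraction", "bright_components_per_1e4px"]
)
D_TEXTURE32 = 32


def quantize_gray(patch: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """16-level gray quantization used for the co-occurrence block."""
    g = rgb2gray(patch)  # float in [0, 1]
    return np.minimum((g * levels).astype(np.uint8), levels - 1)


def texture32_features(patch: np.ndarray) -> np.ndarray:
    """Compute the 32-vector for one square RGB patch."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3 or patch.shape[0] != patch.shape[1]:
        raise GeometryError(f"expected square RGB patch, got shape {patch.shape}")

    feats: list[float] = []
    conc = rgb_to_concentrations(patch)
    for k in range(3):
        plane = conc[..., k].ravel()
        feats += [
            float(plane.mean()),
            float(plane.std()),
            *(float(q) for q in np.quantile(plane, (0.10, 0.50, 0.90))),
        ]
    feats.append(float((conc[..., 0] > COLLAGEN_OD_THRESHOLD).mean()))

    fpatch = patch.astype(np.float64)
    for ch in range(3):
        gy, gx = np.gradient(fpatch[..., ch])
        mag = np.hypot(gx, gy)
        feats += [float(mag.mean()), float(mag.std())]

    q = quantize_gray(patch)
    # angle 0 -> offset (0,+1); angle pi/2 -> offset (-1,0), transpose of (1,0)
    glcm = graycomatrix(
        q, distances=[1], angles=[0.0, np.pi / 2], levels=GLCM_LEVELS,
        symmetric=False, normed=True,
    )
    for prop in ("contrast", "homogeneity", "energy", "correlation"):
        vals = graycoprops(glcm, prop)[0]
        feats += [float(vals[0]), float(vals[1])]

    gray = rgb2gray(patch)
    bright = gray > BRIGHT_THRESHOLD
    feats.append(float(bright.mean()))
    n_cc = int(cc_label(bright, connectivity=2).max())
    feats.append(float(n_cc / bright.size * 1e4))

    out = np.asarray(feats, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(out))]
        raise NumericError(f"non-finite texture features: {bad}")
    return out


class Texture32Backend:
    """Stateless deterministic backend; same bytes in, same vector out."""

    name = "texture32"
    D = D_TEXTURE32

    def extract(self, patch: np.ndarray) -> np.ndarray:
        return texture32_features(patch)

    @property
    def params(self) -> dict:
        return {"levels": GLCM_LEVELS}


class Texture32Features(TransformerMixin, BaseEstimator):
    """sklearn transformer over a stack/list of RGB patches."""

    def fit(self, X, y=None):
        self.n_features_out_ = D_TEXTURE32
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([texture32_features(p) for p in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
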