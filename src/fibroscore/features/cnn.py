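"""The cnn4096 backend: AlexNet fully-connected activations in numpy.

The classic AlexNet stack (five convolutions, three max-pools, two
4096-unit fully-connected layers) is implemented as im2col matrix
multiplications.  When a pretrained ONNX weights file is supplied the
backend runs it through onnxruntime; otherwise the same architecture is
built with seeded He-initialized random weights — shape-true and
download-free, which suffices for every pipeline/shape contract (the
statistical layer uses texture32).

Patch preprocessing: bilinear resize to 227x227, scale to [0, 1],
per-channel normalization with the standard ImageNet constants
(mean 0.485/0.456/0.406, sd 0.229/0.224/0.225).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from fibroscore.errors import FibroscoreError, InvalidArgumentError

INPUT_SIZE = 227
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_SD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

# (out_channels, kernel, stride, pad, pool_after)
_CONV_SPEC = [
    (96, 11, 4, 0, True),
    (256, 5, 1, 2, True),
    (384, 3, 1, 1, False),
    (384, 3, 1, 1, False),
    (256, 3, 1, 1, True),
]
_FC_IN = 256 * 6 * 6
D_CNN4096 = 4096


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int):
    """x: (C, H, W); w: (O, C, k, k). Returns (O, H', W')."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    k = w.shape[-1]
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    c, ho, wo = win.shape[:3]
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.T.reshape(w.shape[0], ho, wo)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2):
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(-1, -2))


class CNN4096Backend:
    """AlexNet feature extractor yielding a 4096-vector per patch.

    Parameters
    ----------
    layer : 'fc6' or 'fc7'
        Which 4096-unit fully-connected activation to report (post-ReLU).
    init_seed : int
        Seed for He-initialized weights in the download-free mode.
    weights : path or None
        Optional pretrained ONNX model; requires onnxruntime.
    """

    name = "cnn4096"
    D = D_CNN4096

    def __init__(self, layer: str = "fc7", init_seed: int = 0, weights=None):
        if layer not in ("fc6", "fc7"):
            raise InvalidArgumentError(f"layer must be 'fc6' or 'fc7', got {layer!r}")
        self.layer = layer
        self.init_seed = init_seed
        self.weights_path = weights
        self._session = None
        if weights is not None:
            self._load_onnx(weights)
        else:
            self._init_random(init_seed)

    def _load_onnx(self, path):
        try:
            import onnxruntime  # noqa: F401
        except ImportError as e:
            raise FibroscoreError(
                "pretrained weights require onnxruntime, which is not "
                "installed; omit `weights` to use the seeded-random mode"
            ) from e
        try:
            self._session = onnxruntime.InferenceSession(str(path))
        except Exception as e:  # corrupt/unreadable model
            raise FibroscoreError(f"failed to load ONNX weights from {path}: {e}") from e

    def _init_random(self, seed: int):
        rng = np.random.default_rng(seed)
        self._conv = []
        c_in = 3
        for c_out, k, stride, pad, pool in _CONV_SPEC:
            fan_in = c_in * k * k
            w = rng.standard_normal((c_out, c_in, k, k), dtype=np.float32)
            w *= np.sqrt(2.0 / fan_in)
            b = np.zeros(c_out, dtype=np.float32)
            self._conv.append((w, b, stride, pad, pool))
            c_in = c_out
        self._fc6 = (
            rng.standard_normal((_FC_IN, D_CNN4096), dtype=np.float32)
            * np.sqrt(2.0 / _FC_IN),
            np.zeros(D_CNN4096, dtype=np.float32),
        )
        self._fc7 = (
            rng.standard_normal((D_CNN4096, D_CNN4096), dtype=np.float32)
            * np.sqrt(2.0 / D_CNN4096),
            np.zeros(D_CNN4096, dtype=np.float32),
        )

    @property
    def params(self) -> dict:
        return {
            "layer": self.layer,
            "init_seed": self.init_seed,
            "weights": str(self.weights_path) if self.weights_path else None,
        }

    def preprocess(self, patch: np.ndarray) -> np.ndarray:
        x = resize(
            patch.astype(np.float32) / 255.0,
            (INPUT_SIZE, INPUT_SIZE),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        ).astype(np.float32)
        x = (x - IMAGENET_MEAN) / IMAGENET_SD
        return x.transpose(2, 0, 1)  # (3, H, W)

    def extract(self, patch: np.ndarray) -> np.ndarray:
        x = self.preprocess(patch)
        if self._session is not None:
            out = self._session.run(None, {self._session.get_inputs()[0].name: x[None]})
            return np.asarray(out[0]).ravel()[: self.D]
        for w, b, stride, pad, pool in self._conv:
            x = _conv2d(x, w, b, stride, pad)
            np.maximum(x, 0.0, out=x)
            if pool:
                x = _maxpool(x)
        v = x.ravel()
        w6, b6 = self._fc6
        v = np.maximum(v @ w6 + b6, 0.0)
        if self.layer == "fc6":
            return v.astype(np.float64)
        w7, b7 = self._fc7
        return np.maximum(v @ w7 + b7, 0.0).astype(np.float64)


class CNN4096Features(TransformerMixin, BaseEstimator):
    """sklearn transformer wrapper over :class:`CNN4096Backend`."""

    def __init__(self, layer: str = "fc7", init_seed: int = 0, weights=None):
        self.layer = layer
        self.init_seed = init_seed
        self.weights = weights

    def fit(self, X, y=None):
        self.backend_ = CNN4096Backend(
            layer=self.layer, init_seed=self.init_seed, weights=self.weights
        )
        self.n_features_out_ = D_CNN4096
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "backend_"):
            self.fit(X)
        return np.stack([self.backend_.extract(p) for p in X])
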