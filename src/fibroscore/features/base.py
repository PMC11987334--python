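"""Backend factory."""

from __future__ import annotations

from fibroscore.errors import InvalidArgumentError


def make_backend(name: str, **params):
    """Construct a feature backend by name.

    ``texture32`` takes no mandatory parameters; ``cnn4096`` accepts
    ``layer`` ('fc6'|'fc7'), ``init_seed`` and optional ``weights`` (path
    to a pretrained ONNX file).
    """
    if name == "texture32":
        from fibroscore.features.texture import Texture32Backend

        return Texture32Backend(**params)
    if name == "cnn4096":
        from fibroscore.features.cnn import CNN4096Backend

        return CNN4096Backend(**params)
    raise InvalidArgumentError(
        f"unknown feature backend {name!r}; available: texture32, cnn4096"
    )
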