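"""Patch set -> QIF matrix extraction and Zarr persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import zarr

from fibroscore.errors import NumericError
from fibroscore.patches import PatchSet, get_patch_pixels
from fibroscore.slide_io import SlideRef


@dataclass
class QIFMatrix:
    """Per-biopsy patches x features matrix with provenance."""

    biopsy_id: str
    values: np.ndarray  # (n_patches, D)
    backend_name: str
    patch_coords: list  # of (row0, col0, side_px)

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


def extract_qif(slide: SlideRef, patchset: PatchSet, backend) -> QIFMatrix:
    """Run the backend over every patch; fails loudly on non-finite output."""
    rows = []
    for i, patch in enumerate(patchset.patches):
        vec = backend.extract(get_patch_pixels(slide, patch))
        if not np.all(np.isfinite(vec)):
            raise NumericError(
                f"backend {backend.name} produced non-finite features for "
                f"patch {i} at {patch} of biopsy {patchset.biopsy_id}"
            )
        rows.append(vec)
    return QIFMatrix(
        biopsy_id=patchset.biopsy_id,
        values=np.stack(rows),
        backend_name=backend.name,
        patch_coords=list(patchset.patches),
    )


def save_qif(path, qif: QIFMatrix) -> None:
    """Persist as a Zarr array with a JSON header in the attrs."""
    arr = zarr.open(
        str(path), mode="w", shape=qif.values.shape,
        chunks=(min(qif.n_patches, 100), qif.D), dtype="f8",
    )
    arr[:] = qif.values
    arr.attrs["header"] = json.dumps(
        {
            "biopsy_id": qif.biopsy_id,
            "backend": qif.backend_name,
            "D": qif.D,
            "patch_coords": [list(p) for p in qif.patch_coords],
        }
    )


def load_qif(path) -> QIFMatrix:
    arr = zarr.open(str(path), mode="r")
    hdr = json.loads(arr.attrs["header"])
    return QIFMatrix(
        biopsy_id=hdr["biopsy_id"],
        values=np.asarray(arr),
        backend_name=hdr["backend"],
        patch_coords=[tuple(p) for p in hdr["patch_coords"]],
    )
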