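"""Random dermal patch sampling.

Each biopsy contributes ``n`` square patches of fixed physical area
(default 0.16 mm², i.e. 400 µm side) drawn uniformly at random — with
replacement, overlap allowed — from positions whose full footprint lies
inside the dermis label.  Epidermis and subcutis are excluded strictly:
a patch touching any non-dermis pixel is rejected.

Coordinates are 0-based (row, col) with half-open footprints
``[r0, r0+side) x [c0, c0+side)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibroscore.errors import (
    InvalidArgumentError,
    NoDermisError,
    SamplingExhaustedError,
)
from fibroscore.slide_io import DermisMask, SlideRef

DERMIS_LABEL = 2
#: rejected-candidate budget per requested patch
DRAW_CAP_PER_PATCH = 1000


@dataclass
class PatchSet:
    biopsy_id: str
    patches: list  # of (row0, col0, side_px)
    seed: int
    area_mm2: float
    side_px: int

    @property
    def n(self) -> int:
        return len(self.patches)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "biopsy_id": self.biopsy_id,
                    "row0": r,
                    "col0": c,
                    "side_px": s,
                    "seed": self.seed,
                }
                for r, c, s in self.patches
            ]
        )


def patch_side_px(area_mm2: float, mpp: float) -> int:
    """Side length in pixels of a square patch of the given area."""
    return int(round(1000.0 * np.sqrt(area_mm2) / mpp))


def _valid_positions(labels: np.ndarray, side: int) -> np.ndarray:
    """Boolean map over top-left corners whose footprint is all-dermis."""
    h, w = labels.shape
    if side > h or side > w:
        return np.zeros((0, 0), dtype=bool)
    dermis = (labels == DERMIS_LABEL).astype(np.int32)
    # integral image: window sum == side^2 iff every covered pixel is dermis
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(dermis, axis=0), axis=1, out=ii[1:, 1:])
    s = side
    win = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    return win == s * s


def sample_patches(
    slide: SlideRef,
    mask: DermisMask,
    n: int = 100,
    area_mm2: float = 0.16,
    seed: int = 0,
    biopsy_id: str = "biopsy",
) -> PatchSet:
    """Draw ``n`` dermis-only patches uniformly at random.

    Candidate top-left corners are drawn uniformly over the raster and
    accepted iff the full square footprint carries the dermis label;
    acceptance by rejection sampling keeps the accepted distribution
    uniform over valid positions.  Raises :class:`NoDermisError` when no
    valid position exists at all, and :class:`SamplingExhaustedError`
    when the draw cap (1000 candidates per requested patch) is hit on a
    fragmented dermis.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if area_mm2 <= 0:
        raise InvalidArgumentError(f"area_mm2 must be > 0, got {area_mm2}")
    side = patch_side_px(area_mm2, slide.mpp)
    labels = mask.labels
    valid = _valid_positions(labels, side)
    if valid.size == 0 or not valid.any():
        raise NoDermisError(
            f"no position admits a {side}x{side} px dermis-only patch "
            f"({area_mm2} mm^2 at {slide.mpp} µm/px)"
        )
    hmax, wmax = valid.shape
    rng = np.random.default_rng(seed)
    cap = DRAW_CAP_PER_PATCH * n
    placed: list[tuple[int, int, int]] = []
    drawn = 0
    while len(placed) < n and drawn < cap:
        batch = min(4 * n, cap - drawn)
        r0 = rng.integers(0, hmax, size=batch)
        c0 = rng.integers(0, wmax, size=batch)
        drawn += batch
        ok = valid[r0, c0]
        for r, c in zip(r0[ok], c0[ok]):
            placed.append((int(r), int(c), side))
            if len(placed) == n:
                break
    if len(placed) < n:
        raise SamplingExhaustedError(placed=len(placed), requested=n, cap=cap)
    return PatchSet(
        biopsy_id=biopsy_id, patches=placed, seed=seed, area_mm2=area_mm2, side_px=side
    )


def get_patch_pixels(slide: SlideRef, patch: tuple[int, int, int]) -> np.ndarray:
    """Extract one patch's (side, side, 3) pixel block."""
    r0, c0, s = patch
    h, w = slide.shape
    if r0 < 0 or c0 < 0 or r0 + s > h or c0 + s > w:
        from fibroscore.errors import GeometryError

        raise GeometryError(f"patch {patch} exceeds slide bounds {slide.shape}")
    return slide.pixels[r0 : r0 + s, c0 : c0 + s]


def patchset_from_frame(df: pd.DataFrame) -> PatchSet:
    """Rebuild a PatchSet from its CSV table."""
    if df.empty:
        raise InvalidArgumentError("empty patch table")
    side = int(df["side_px"].iloc[0])
    return PatchSet(
        biopsy_id=str(df["biopsy_id"].iloc[0]),
        patches=[(int(r), int(c), side) for r, c in zip(df["row0"], df["col0"])],
        seed=int(df["seed"].iloc[0]),
        area_mm2=float("nan"),  # not recoverable from the CSV (needs mpp)
        side_px=side,
    )
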