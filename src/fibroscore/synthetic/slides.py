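"""Stylized trichrome-like biopsy slide renderer with planted ground truth.

The rendering is deliberately schematic — a three-compartment band
geometry (epidermis strip / dermis band / subcutis band under a white
background margin), oriented band-pass fiber texture in the dermis,
sparse dark nuclei, ring-shaped vessel profiles, and white fat vacuoles
in the subcutis.  Photorealism is a non-goal: what matters for testing
the pipeline is that the blue-collagen pixel fraction in the dermis is a
monotone function of the planted severity and that every planted
parameter is reported as truth.

Colors come from the fixed Beer-Lambert stain model in
:mod:`fibroscore._stains`, so optical-density stain separation of a
rendered patch recovers the planted concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from fibroscore._stains import concentrations_to_rgb
from fibroscore.errors import GeometryError, InvalidArgumentError

# compartment labels, fixed package-wide
LABEL_BACKGROUND = 0
LABEL_EPIDERMIS = 1
LABEL_DERMIS = 2
LABEL_SUBCUTIS = 3

#: dermal collagen area fraction = COLLAGEN_BASE + COLLAGEN_GAIN * severity (+ seed jitter)
COLLAGEN_BASE = 0.2
COLLAGEN_GAIN = 0.5
COLLAGEN_JITTER_SD = 0.02


@dataclass
class SyntheticSlide:
    """RGB section raster + compartment mask + planted truth."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, labels 0-3
    mpp: float  # microns per pixel
    truth: dict  # severity, collagen_fraction, fat_vacuole_density,
    #              vessel_ectasia_count, infiltrate_density
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _stamp_disks(conc, centers, radii, values, bounds):
    """Write disk-shaped concentration triples into conc (in place)."""
    h, w = conc.shape[:2]
    r0b, r1b = bounds
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(int(cy - r), r0b), min(int(cy + r) + 1, r1b)
        x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        conc[y0:y1, x0:x1][inside] = values


def _stamp_rings(conc, centers, radii, thickness, values, bounds):
    h, w = conc.shape[:2]
    r0b, r1b = bounds
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(int(cy - r), r0b), min(int(cy + r) + 1, r1b)
        x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring = (d2 <= r * r) & (d2 >= (r - thickness) ** 2)
        lumen = d2 < (r - thickness) ** 2
        conc[y0:y1, x0:x1][ring] = values
        conc[y0:y1, x0:x1][lumen] = (0.0, 0.02, 0.0)  # near-white lumen


def render_biopsy_slide(
    severity: float,
    mpp: float = 2.0,
    height_px: int = 2048,
    width_px: int = 3072,
    seed: int = 0,
) -> SyntheticSlide:
    """Render a synthetic trichrome-stained skin section.

    Parameters
    ----------
    severity : float in [0, 1]
        Planted disease severity.  Drives the dermal collagen fraction
        (``0.2 + 0.5 * severity`` plus a small seed-only jitter), the
        dermal inflammatory-nucleus density, the number of ectatic vessel
        profiles, and (inversely) the subcutaneous fat vacuole density.
    mpp : float
        Microns per pixel; default 2.0 so a 0.16 mm^2 patch is 200 px.
    height_px, width_px : int
        Raster dimensions; must accommodate the three tissue compartments.
    seed : int
        Fixed seed gives byte-identical output.

    Returns
    -------
    SyntheticSlide
        With ``truth`` holding the planted parameters, including the
        realized ``collagen_fraction`` (monotone nondecreasing in
        severity at fixed seed by construction: the fiber field is
        thresholded at the quantile that yields the target fraction).
    """
    if not 0.0 <= severity <= 1.0:
        raise InvalidArgumentError(f"severity must be in [0, 1], got {severity}")
    if mpp <= 0:
        raise InvalidArgumentError(f"mpp must be > 0, got {mpp}")
    if height_px < 64 or width_px < 64:
        raise GeometryError(
            f"{height_px}x{width_px} raster too small for background + "
            "epidermis + dermis + subcutis bands (need >= 64x64)"
        )

    rng = np.random.default_rng(seed)
    h, w = height_px, width_px
    # jitter drawn before any severity-dependent use so the realized
    # collagen fraction is monotone in severity at a fixed seed
    jitter = rng.normal(0.0, COLLAGEN_JITTER_SD)

    bg_h = max(4, h // 32)
    epi_um = 60.0 - 25.0 * severity  # epidermis thins with disease
    epi_h = max(2, int(round(epi_um / mpp)))
    derm_h = int(round(0.68 * (h - bg_h - epi_h)))
    derm0, derm1 = bg_h + epi_h, bg_h + epi_h + derm_h
    if h - derm1 < 4 or derm_h < 16:
        raise GeometryError("raster too small: subcutis or dermis band would vanish")

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[bg_h:derm0] = LABEL_EPIDERMIS
    mask[derm0:derm1] = LABEL_DERMIS
    mask[derm1:] = LABEL_SUBCUTIS

    # concentration planes: (collagen, counterstain, hematoxylin)
    conc = np.zeros((h, w, 3), dtype=np.float32)

    # epidermis: dense hematoxylin/red band
    conc[bg_h:derm0] = (0.05, 0.45, 0.55)

    # dermis: oriented fiber field, thresholded at the quantile giving the
    # target collagen fraction
    target = float(np.clip(COLLAGEN_BASE + COLLAGEN_GAIN * severity + jitter, 0.02, 0.95))
    field = rng.standard_normal((derm_h, w)).astype(np.float32)
    field = gaussian_filter(field, sigma=(1.5, 10.0), mode="reflect")
    thresh = np.quantile(field, 1.0 - target)
    fibers = field >= thresh
    f01 = (field - field.min()) / max(float(np.ptp(field)), 1e-9)
    dermis = np.empty((derm_h, w, 3), dtype=np.float32)
    dermis[..., 0] = np.where(fibers, 0.65 + 0.5 * f01, 0.04)
    dermis[..., 1] = np.where(fibers, 0.08, 0.45 + 0.25 * (1.0 - f01))
    dermis[..., 2] = 0.02
    conc[derm0:derm1] = dermis
    collagen_fraction = float(fibers.mean())

    area_mm2 = h * w * (mpp / 1000.0) ** 2
    dermis_mm2 = derm_h * w * (mpp / 1000.0) ** 2

    # sparse dark nuclei (inflammatory infiltrate grows with severity)
    infiltrate_density = 60.0 + 140.0 * severity  # nuclei per mm^2 dermis
    n_nuclei = int(infiltrate_density * dermis_mm2)
    if n_nuclei > 0:
        cy = rng.uniform(derm0, derm1, n_nuclei)
        cx = rng.uniform(0, w, n_nuclei)
        rad = rng.uniform(1.5, 3.0, n_nuclei)
        _stamp_disks(conc, np.column_stack([cy, cx]), rad, (0.05, 0.1, 1.1), (derm0, derm1))

    # ring-shaped (ectatic) vessel profiles
    vessel_count = int(rng.poisson(2.0 + 10.0 * severity))
    if vessel_count > 0:
        cy = rng.uniform(derm0 + 20, derm1 - 20, vessel_count)
        cx = rng.uniform(20, w - 20, vessel_count)
        rad = rng.uniform(8, 16, vessel_count)
        _stamp_rings(
            conc, np.column_stack([cy, cx]), rad, 3.0, (0.05, 0.75, 0.35), (derm0, derm1)
        )

    # subcutis: pale red ground with white fat vacuoles; fat retreats with
    # severity (subcutaneous fat loss)
    sub_mm2 = (h - derm1) * w * (mpp / 1000.0) ** 2
    conc[derm1:] = (0.03, 0.30, 0.05)
    fat_density = 28.0 * (1.0 - 0.6 * severity)  # vacuoles per mm^2 subcutis
    n_fat = int(fat_density * sub_mm2)
    if n_fat > 0:
        cy = rng.uniform(derm1, h, n_fat)
        cx = rng.uniform(0, w, n_fat)
        rad = rng.uniform(6, 13, n_fat)
        _stamp_disks(conc, np.column_stack([cy, cx]), rad, (0.0, 0.01, 0.0), (derm1, h))

    image = concentrations_to_rgb(conc)
    image[:bg_h] = 255  # background margin stays white

    truth = {
        "severity": float(severity),
        "collagen_fraction": collagen_fraction,
        "fat_vacuole_density": float(fat_density),
        "vessel_ectasia_count": int(vessel_count),
        "infiltrate_density": float(infiltrate_density),
    }
    return SyntheticSlide(image=image, mask=mask, mpp=float(mpp), truth=truth, seed=seed)
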