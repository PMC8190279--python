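"""Whole-body integrated fluorescence quantification from images.

The imaging readout behind the PK analysis is simple by design: a
whole-body contour is drawn around the embryo, and the reported RFU is
the raw sum of pixel intensities inside it (no background subtraction by
default).  When different camera exposure times are used to avoid
saturation, signals are rescaled to a reference exposure assuming a
linear detector response.

Conventions are stated explicitly because acquisition software leaves
them implicit: images are 0-based row-major grids; a pixel (row, col)
covers the half-open square [col, col+1) × [row, row+1) and its center
sits at (col + 0.5, row + 0.5); a pixel belongs to a polygon when its
center does.  16-bit grayscale is assumed for file I/O, with saturation
flagged at the dtype maximum.

A synthetic renderer draws an ellipse-plus-tail "embryo" whose
within-contour intensity sum equals ``fluor × amount`` before noise, so
the amount→fluorescence mapping is testable from pixels upward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MaskedImage",
    "BodyContour",
    "rasterize_body_contour",
    "integrated_intensity",
    "exposure_correction",
    "render_synthetic_embryo",
    "read_image",
    "write_image",
    "contour_to_csv",
    "contour_from_csv",
]


@dataclass(frozen=True)
class BodyContour:
    """Closed polygon of (x, y) = (col, row) pixel coordinates."""

    vertices: np.ndarray    # (n, 2) float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)

    def shoelace_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass(frozen=True)
class MaskedImage:
    """An intensity grid with its analysis mask and acquisition exposure."""

    pixels: np.ndarray      # 2-D, nonnegative
    mask: np.ndarray        # 2-D bool, same shape
    exposure_ms: float = 100.0
    channel: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        mk = np.asarray(self.mask, dtype=bool)
        if px.ndim != 2 or px.shape != mk.shape:
            raise ValueError("pixels and mask must be 2-D arrays of the same shape")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be nonnegative")
        if not self.exposure_ms > 0:
            raise ValueError("exposure time must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mask", mk)

    @property
    def saturated(self) -> bool:
        """True when any pixel sits at the dtype maximum (integer images)."""
        if not np.issubdtype(self.pixels.dtype, np.integer):
            return False
        return bool((self.pixels == np.iinfo(self.pixels.dtype).max).any())


def rasterize_body_contour(contour: BodyContour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Pixel centers are sampled at (col + 0.5, row + 0.5) and classified
    with the even-odd (crossing-number) rule, implemented directly so the
    sampling convention is under our control rather than a plotting
    library's.  Simple (non-self-intersecting) polygons are expected.
    """
    rows, cols = shape
    v = contour.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    cx = np.arange(cols) + 0.5
    cy = np.arange(rows) + 0.5
    inside = np.zeros((rows, cols), dtype=bool)
    for r, py in enumerate(cy):
        # edges whose half-open y-span [min, max) straddles the scanline
        straddles = (y1 <= py) != (y2 <= py)
        if not straddles.any():
            continue
        xs = x1[straddles] + (py - y1[straddles]) / (y2[straddles] - y1[straddles]) * (
            x2[straddles] - x1[straddles]
        )
        crossings = (cx[:, None] < xs[None, :]).sum(axis=1)
        inside[r] = (crossings % 2) == 1
    return inside


def integrated_intensity(image: MaskedImage, subtract_background: float = 0.0) -> float:
    """Sum of pixel intensities inside the mask — the whole-body RFU.

    The default is the raw sum.  ``subtract_background`` removes a known
    mean background per masked pixel (floored at zero); intended for
    synthetic fixtures with a known Poisson background, not for real
    acquisitions.
    """
    if not image.mask.any():
        warnings.warn("empty mask: integrated intensity is 0", UserWarning, stacklevel=2)
        return 0.0
    total = float(image.pixels[image.mask].sum(dtype=np.float64))
    if subtract_background:
        total -= subtract_background * float(image.mask.sum())
    return max(total, 0.0)


def exposure_correction(rfu: float, exposure_ms: float, reference_exposure_ms: float) -> float:
    """Rescale an RFU to a reference exposure time (linear detector response)."""
    if exposure_ms <= 0 or reference_exposure_ms <= 0:
        raise ValueError("exposure times must be positive")
    return rfu * reference_exposure_ms / exposure_ms


def render_synthetic_embryo(
    amount: float,
    fluor: float,
    shape: tuple[int, int] = (128, 256),
    background: float = 0.0,
    seed: int = 0,
    exposure_ms: float = 100.0,
    channel: str = "synthetic",
) -> tuple[MaskedImage, BodyContour]:
    """Draw a synthetic embryo image with a known ground truth.

    An ellipse body with a triangular tail is placed in the frame; the
    total intensity inside the contour equals ``fluor × amount`` exactly
    (spread uniformly over the interior pixels) before Poisson background
    of the given mean is added everywhere.  With ``background = 0`` the
    rendering is noiseless.  Returns the image (with the ground-truth
    mask) and the contour itself.
    """
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError("image must be at least 64×64")
    if amount < 0 or fluor <= 0:
        raise ValueError("amount must be nonnegative and fluor positive")

    # ellipse head/body on the left, tail tapering to the right
    cy, cx = rows / 2.0, cols * 0.3
    ry, rx = rows * 0.22, cols * 0.18
    theta = np.linspace(np.pi / 2, 3 * np.pi / 2, 24, endpoint=True)
    left = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
    tail_tip = (cols * 0.85, cy)
    verts = np.vstack([
        [cx, cy - ry],
        left[::-1],
        [cx, cy + ry],
        [cols * 0.55, cy + ry * 0.35],
        tail_tip,
        [cols * 0.55, cy - ry * 0.35],
    ])
    contour = BodyContour(vertices=verts)
    mask = rasterize_body_contour(contour, shape)
    n_inside = int(mask.sum())

    pixels = np.zeros(shape, dtype=float)
    pixels[mask] = fluor * amount / n_inside
    if background > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x1A6E)))
        pixels = pixels + rng.poisson(background, size=shape)
    image = MaskedImage(pixels=pixels, mask=mask, exposure_ms=exposure_ms, channel=channel)
    return image, contour


# ---------------------------------------------------------------------------
# file I/O (16-bit grayscale TIFF/PNG; contours as CSV vertex lists)


def write_image(path: "str | Path", image: MaskedImage) -> None:
    p = Path(path)
    px = image.pixels
    if not np.issubdtype(px.dtype, np.integer):
        if px.max(initial=0) > 65535:
            raise ValueError("intensities exceed the 16-bit range")
        px = np.round(px).astype(np.uint16)
    if p.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(p, px)
    else:
        import imageio.v3 as iio

        iio.imwrite(p, px)


def read_image(path: "str | Path", mask: np.ndarray | None = None,
               exposure_ms: float = 100.0, channel: str = "") -> MaskedImage:
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        px = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        px = iio.imread(p)
    if mask is None:
        mask = np.ones(px.shape, dtype=bool)
    img = MaskedImage(pixels=px, mask=mask, exposure_ms=exposure_ms, channel=channel)
    if img.saturated:
        warnings.warn(f"{p.name}: saturated pixels at dtype maximum; "
                      "consider a shorter exposure with correction",
                      UserWarning, stacklevel=2)
    return img


def contour_to_csv(path: "str | Path", contour: BodyContour) -> None:
    np.savetxt(path, contour.vertices, delimiter=",", header="x,y", comments="")


def contour_from_csv(path: "str | Path") -> BodyContour:
    return BodyContour(vertices=np.loadtxt(path, delimiter=",", skiprows=1))
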