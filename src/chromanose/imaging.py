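"""ΔRGB feature extraction from before/after sensor-array scans.

The readout of a colorimetric sensor array is a pair of 8-bit RGB scans of
the same dye plate, taken before and after exposure to the sample headspace.
Each dye spot is summarized by the arithmetic mean color over a fixed disc
of pixels at its center, and the feature for spot *i* and channel *c* is the
absolute difference of that mean between the two scans:

    ΔR = |R_a − R_b|,  ΔG = |G_a − G_b|,  ΔB = |B_a − B_b|

Concatenated channel-major over all N spots this yields the 3N-dimensional
color-change profile (N = 12 spots → 36 features by default).

Disc membership convention: a pixel belongs to a spot's disc iff its integer
(row, col) coordinate lies at Euclidean distance ≤ radius_px from the spot
center. Coordinates are 0-based with row increasing downward. Under this
convention a radius-12 disc contains exactly ``disc_pixel_count(12)`` pixels
(a documented constant, the same for every spot and image); other inclusive
conventions give slightly different counts, so the radius is configurable
and no particular pixel total is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import Dataset, feature_columns
from .errors import DomainError, LayoutError

__all__ = [
    "SensorArrayImage",
    "SpotGrid",
    "ColorDifferenceProfile",
    "disc_pixel_count",
    "locate_spots",
    "spot_mean_color",
    "difference_profile",
    "read_image",
    "write_image",
    "read_profile_table",
    "write_profile_table",
]


@dataclass
class SensorArrayImage:
    """An 8-bit RGB raster of a scanned dye array."""

    pixels: np.ndarray  # H × W × 3, uint8
    phase: str = "before"  # "before" | "after"
    dpi: int = 400

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DomainError(f"expected H×W×3 RGB raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise DomainError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.phase not in ("before", "after"):
            raise DomainError(f"phase must be 'before' or 'after', got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SpotGrid:
    """Known positions of the dye spots on the plate (layout-driven, not detected)."""

    rows: int = 4
    cols: int = 3
    centers: list[tuple[int, int]] = field(default_factory=list)  # (row, col) px
    radius_px: int = 12

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.radius_px < 0:
            raise LayoutError("rows, cols must be ≥ 1 and radius_px ≥ 0")
        if len(self.centers) != self.rows * self.cols:
            raise LayoutError(
                f"{self.rows}×{self.cols} grid needs {self.rows * self.cols} centers,"
                f" got {len(self.centers)}"
            )
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                if np.hypot(*(c[i] - c[j])) <= 2 * self.radius_px:
                    raise LayoutError(
                        f"spot discs {i} and {j} overlap at radius {self.radius_px}"
                    )

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    def check_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        r = self.radius_px
        for k, (cr, cc) in enumerate(self.centers):
            if cr - r < 0 or cc - r < 0 or cr + r >= h or cc + r >= w:
                raise DomainError(
                    f"spot {k} disc (center ({cr},{cc}), radius {r}) exceeds "
                    f"image bounds {h}×{w}"
                )


@dataclass
class ColorDifferenceProfile:
    """3N-vector of per-spot |Δchannel| values, channel-major."""

    values: np.ndarray
    n_spots: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 3 * self.n_spots:
            raise DomainError(
                f"profile for {self.n_spots} spots must have length "
                f"{3 * self.n_spots}, got {self.values.size}"
            )
        if (self.values < 0).any() or (self.values > 255).any():
            raise DomainError("profile entries must lie in [0, 255]")


def _disc_offsets(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius_px)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dr * dr + dc * dc <= r * r
    return dr[mask], dc[mask]


def disc_pixel_count(radius_px: int) -> int:
    """Number of integer pixels at Euclidean distance ≤ radius_px of a center.

    Identical for every spot and image (the mask is translation invariant).
    """
    return int(_disc_offsets(radius_px)[0].size)


def locate_spots(
    rows: int = 4,
    cols: int = 3,
    *,
    margin: int = 24,
    spacing: int = 48,
    radius_px: int = 12,
) -> SpotGrid:
    """Lay the spot centers on a regular lattice, row-major.

    Center of spot (i, j) is at pixel (margin + i*spacing, margin + j*spacing).
    Deterministic; raises :class:`LayoutError` if discs would overlap.
    """
    if spacing <= 2 * radius_px:
        raise LayoutError(
            f"spacing {spacing} px cannot separate discs of radius {radius_px} px"
        )
    centers = [
        (margin + i * spacing, margin + j * spacing)
        for i in range(rows)
        for j in range(cols)
    ]
    return SpotGrid(rows=rows, cols=cols, centers=centers, radius_px=radius_px)


def spot_mean_color(
    image: SensorArrayImage | np.ndarray,
    center: tuple[int, int],
    radius_px: int,
) -> np.ndarray:
    """Per-channel mean color over the disc of pixels around ``center``.

    Raises :class:`DomainError` if the disc is not fully inside the image.
    """
    px = image.pixels if isinstance(image, SensorArrayImage) else np.asarray(image)
    h, w = px.shape[:2]
    cr, cc = center
    r = int(radius_px)
    if cr - r < 0 or cc - r < 0 or cr + r >= h or cc + r >= w:
        raise DomainError(
            f"disc at ({cr},{cc}) radius {r} partially outside {h}×{w} image"
        )
    dr, dc = _disc_offsets(r)
    return px[cr + dr, cc + dc, :].astype(float).mean(axis=0)


def difference_profile(
    before: SensorArrayImage | np.ndarray,
    after: SensorArrayImage | np.ndarray,
    grid: SpotGrid,
) -> ColorDifferenceProfile:
    """Absolute per-spot, per-channel mean-color difference of an image pair.

    Symmetric in its two image arguments (the difference is taken in absolute
    value), and invariant under adding a common constant to both images.
    """
    px_b = before.pixels if isinstance(before, SensorArrayImage) else np.asarray(before)
    px_a = after.pixels if isinstance(after, SensorArrayImage) else np.asarray(after)
    if px_b.shape != px_a.shape:
        raise DomainError(
            f"image size mismatch: before {px_b.shape} vs after {px_a.shape}"
        )
    grid.check_inside(px_b.shape[:2])
    n = grid.n_spots
    means_b = np.vstack(
        [spot_mean_color(px_b, c, grid.radius_px) for c in grid.centers]
    )
    means_a = np.vstack(
        [spot_mean_color(px_a, c, grid.radius_px) for c in grid.centers]
    )
    delta = np.abs(means_a - means_b)  # n × 3
    return ColorDifferenceProfile(values=delta.T.ravel(), n_spots=n)


def read_image(path: str | Path, phase: str = "before", dpi: int = 400) -> SensorArrayImage:
    """Load a PNG/TIFF scan as an 8-bit RGB sensor-array image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return SensorArrayImage(pixels=arr, phase=phase, dpi=dpi)


def write_image(image: SensorArrayImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_profile_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as the documented CSV feature table."""
    dataset.to_frame().to_csv(path, index=False)


def read_profile_table(path: str | Path) -> Dataset:
    """Read a CSV feature table; lossless inverse of :func:`write_profile_table`.

    The header must be ``sample_id,level,category`` followed by the full
    channel-major feature block (see :func:`chromanose.data.feature_columns`);
    any missing or extra feature column raises :class:`FormatError` with a
    column report.
    """
    df = pd.read_csv(path)
    return Dataset.from_frame(df)


# re-exported for convenience: the default 12-spot feature header
FEATURE_COLUMNS: list[str] = feature_columns(12)
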