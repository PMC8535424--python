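"""Pixel gain/loss between averaged and single images.

The averaged image A and the first-acquired single image S live in the same
registered frame, so change is a pixel-by-pixel subtraction: the positive
part of A - S localises pixel *gain* (signal present only after averaging),
the positive part of S - A pixel *loss*.  Each map is binarized at the
vessel/background grey-level limit of its slab (about 40 for the
superficial plexus; 60 for the deep complex, whose background is brighter),
overlaid in red for inspection, and scored on a 3x3 grid of 172x172-pixel
boxes: a box is flagged when it holds at least ``min_pixels`` suprathreshold
pixels, and the number of flagged boxes is the image's gain (or loss) score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .averaging import AveragedImage
from .io_manifest import EnFaceImage

#: grey-level limit between vessels and background, per slab
SLAB_THRESHOLDS = {"SVP": 40, "DVC": 60, "FULL": 40}

#: minimum suprathreshold pixels for a box to be flagged present
DEFAULT_MIN_PIXELS = 50


def _pixels(image) -> np.ndarray:
    if isinstance(image, (EnFaceImage, AveragedImage)):
        return image.pixels
    return np.asarray(image)


@dataclass(frozen=True)
class BoxGrid:
    """Regular grid of square grading boxes; the default tiles 516x516."""

    box_side: int = 172
    n_rows: int = 3
    n_cols: int = 3
    origin: tuple[int, int] = (0, 0)

    @property
    def n_boxes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[int, int]:
        return (
            self.origin[0] + self.n_rows * self.box_side,
            self.origin[1] + self.n_cols * self.box_side,
        )

    def check_fits(self, shape: tuple[int, int]) -> None:
        ey, ex = self.extent
        if ey > shape[0] or ex > shape[1]:
            raise ValueError(f"grid extent {ey}x{ex} overflows image {shape[0]}x{shape[1]}")

    def boxes(self) -> Iterator[tuple[int, slice, slice]]:
        """Yield (box index, row slice, col slice) in row-major order."""
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                r0 = self.origin[0] + i * self.box_side
                c0 = self.origin[1] + j * self.box_side
                yield (
                    i * self.n_cols + j,
                    slice(r0, r0 + self.box_side),
                    slice(c0, c0 + self.box_side),
                )

    @classmethod
    def for_image(cls, shape: tuple[int, int], n_rows: int = 3, n_cols: int = 3) -> "BoxGrid":
        """Grid of n_rows x n_cols boxes tiling the top-left of ``shape``."""
        side = min(shape[0] // n_rows, shape[1] // n_cols)
        return cls(box_side=side, n_rows=n_rows, n_cols=n_cols)


@dataclass
class BoxScores:
    """Per-box suprathreshold pixel counts and presence flags for one mask."""

    counts: np.ndarray  # (n_boxes,) int
    flags: np.ndarray  # (n_boxes,) bool
    min_pixels: int

    @property
    def score(self) -> int:
        """Number of flagged boxes (the image's gain or loss score)."""
        return int(self.flags.sum())

    @property
    def mean_pixels_per_box(self) -> float:
        return float(self.counts.mean())


@dataclass
class DifferenceMap:
    """Paired positive-part difference maps with their binary masks."""

    gain_map: np.ndarray
    loss_map: np.ndarray
    threshold: int
    gain_mask: np.ndarray
    loss_mask: np.ndarray
    slab: str = "SVP"


def subtract_positive(a, b) -> np.ndarray:
    """Per-pixel positive part max(a - b, 0) of two co-dimensional images."""
    pa = _pixels(a).astype(np.int16)
    pb = _pixels(b).astype(np.int16)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch {pa.shape} vs {pb.shape}")
    return np.maximum(pa - pb, 0).astype(np.uint8)


def binarize(diff_map: np.ndarray, threshold: int | None = None, slab: str = "SVP") -> np.ndarray:
    """Foreground = map >= threshold; default threshold is the slab's limit."""
    if threshold is None:
        threshold = SLAB_THRESHOLDS[slab]
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(diff_map) >= threshold


def make_overlay(base, mask: np.ndarray) -> np.ndarray:
    """Grey base replicated to RGB with mask pixels painted pure red."""
    px = _pixels(base)
    mask = np.asarray(mask, dtype=bool)
    if px.shape != mask.shape:
        raise ValueError("base and mask must be co-dimensional")
    rgb = np.repeat(px[:, :, None], 3, axis=2).astype(np.uint8)
    rgb[mask] = (255, 0, 0)
    return rgb


def _box_counts(mask: np.ndarray, grid: BoxGrid) -> np.ndarray:
    counts = np.zeros(grid.n_boxes, dtype=np.int64)
    for idx, rs, cs in grid.boxes():
        counts[idx] = int(mask[rs, cs].sum())
    return counts


def score_boxes(
    gain_mask: np.ndarray,
    loss_mask: np.ndarray,
    grid: BoxGrid,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    validity_mask: np.ndarray | None = None,
) -> tuple[BoxScores, BoxScores]:
    """Count suprathreshold pixels per box and flag boxes >= ``min_pixels``.

    The pixel floor is an automated surrogate for expert presence/absence
    grading: isolated noise pixels do not flip a box.  Counts can be
    restricted to a validity mask so border fill is never scored.
    """
    grid.check_fits(gain_mask.shape)
    if validity_mask is not None:
        gain_mask = gain_mask & validity_mask
        loss_mask = loss_mask & validity_mask
    out = []
    for mask in (gain_mask, loss_mask):
        counts = _box_counts(np.asarray(mask, dtype=bool), grid)
        out.append(BoxScores(counts=counts, flags=counts >= min_pixels, min_pixels=min_pixels))
    return out[0], out[1]


def surrogate_grade_gain(
    gain_mask: np.ndarray,
    gt_vessel_mask: np.ndarray,
    grid: BoxGrid,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> np.ndarray:
    """Automated stand-in for expert grading of gain in vessel detection.

    Restricting the gain mask to true vessel support separates genuine
    capillary gain (e.g. an intermittently perfused segment restored by
    averaging) from background-noise gain.  Requires synthetic ground truth.
    """
    if gt_vessel_mask is None:
        raise ValueError("ground-truth vessel mask required for surrogate grading")
    grid.check_fits(gain_mask.shape)
    counts = _box_counts(np.asarray(gain_mask, dtype=bool) & np.asarray(gt_vessel_mask, dtype=bool), grid)
    return counts >= min_pixels


def surrogate_grade_loss(
    loss_mask: np.ndarray,
    averaged,
    gt_persistent_vessel_mask: np.ndarray,
    grid: BoxGrid,
    detection_threshold: int | None = None,
    slab: str = "SVP",
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> np.ndarray:
    """Automated grading of *loss of vessel detection* after averaging.

    A pixel only counts when it lies on consistently perfused vessel
    support, shows suprathreshold loss, *and* has dropped below the
    vessel-detection grey level in the averaged image — i.e. a vessel that
    was detectable in the single image is no longer detectable at all.
    Mere brightness attenuation of a still-visible vessel is not a loss of
    detection, mirroring how expert graders judge detectability.
    """
    if gt_persistent_vessel_mask is None:
        raise ValueError("ground-truth vessel mask required for surrogate grading")
    if detection_threshold is None:
        detection_threshold = SLAB_THRESHOLDS[slab]
    grid.check_fits(loss_mask.shape)
    avg_px = _pixels(averaged)
    undetected = avg_px < detection_threshold
    mask = (
        np.asarray(loss_mask, dtype=bool)
        & np.asarray(gt_persistent_vessel_mask, dtype=bool)
        & undetected
    )
    return _box_counts(mask, grid) >= min_pixels


@dataclass
class DiffResult:
    """Everything the gain/loss comparison produces for one image pair."""

    difference: DifferenceMap
    gain_scores: BoxScores
    loss_scores: BoxScores
    gain_overlay: np.ndarray
    loss_overlay: np.ndarray

    @property
    def mean_gain_pixels_per_box(self) -> float:
        return self.gain_scores.mean_pixels_per_box

    @property
    def mean_loss_pixels_per_box(self) -> float:
        return self.loss_scores.mean_pixels_per_box


def diff_pipeline(
    averaged: AveragedImage,
    first_single: EnFaceImage,
    slab: str | None = None,
    grid: BoxGrid | None = None,
    threshold: int | None = None,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    restrict_to_validity: bool = True,
) -> DiffResult:
    """A-S / S-A maps, binarization, box scoring and red overlays.

    The first-acquired single image is the registration reference, so the
    pair is already in a common frame and no further alignment is needed.
    """
    slab = slab or getattr(first_single, "slab", "SVP")
    a_px, s_px = _pixels(averaged), _pixels(first_single)
    if a_px.shape != s_px.shape:
        raise ValueError("averaged and single images must be co-dimensional")
    if grid is None:
        if a_px.shape[0] < 516 or a_px.shape[1] < 516:
            raise ValueError(
                "image smaller than the 516x516 default grid; supply a custom BoxGrid"
            )
        grid = BoxGrid()
    gain_map = subtract_positive(a_px, s_px)
    loss_map = subtract_positive(s_px, a_px)
    thr = SLAB_THRESHOLDS[slab] if threshold is None else threshold
    gain_mask = binarize(gain_map, thr, slab)
    loss_mask = binarize(loss_map, thr, slab)
    validity = averaged.validity_mask if (
        restrict_to_validity and isinstance(averaged, AveragedImage)
    ) else None
    diff = DifferenceMap(
        gain_map=gain_map, loss_map=loss_map, threshold=thr,
        gain_mask=gain_mask, loss_mask=loss_mask, slab=slab,
    )
    gain_scores, loss_scores = score_boxes(gain_mask, loss_mask, grid, min_pixels, validity)
    return DiffResult(
        difference=diff,
        gain_scores=gain_scores,
        loss_scores=loss_scores,
        gain_overlay=make_overlay(a_px, gain_mask),
        loss_overlay=make_overlay(s_px, loss_mask),
    )


def box_montage(single, averaged, grid: BoxGrid, pad: int = 4) -> np.ndarray:
    """Side-by-side single/averaged crops per box, for manual grading."""
    s_px, a_px = _pixels(single), _pixels(averaged)
    grid.check_fits(s_px.shape)
    side = grid.box_side
    h = grid.n_boxes * (side + pad) - pad
    w = 2 * side + pad
    out = np.full((h, w), 255, dtype=np.uint8)
    for idx, rs, cs in grid.boxes():
        r0 = idx * (side + pad)
        out[r0 : r0 + side, :side] = s_px[rs, cs]
        out[r0 : r0 + side, side + pad :] = a_px[rs, cs]
    return out
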