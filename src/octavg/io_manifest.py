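"""Image I/O, study manifests and configuration.

En-face OCT angiography exports are plain 8-bit rasters (the device writes
JPEG; we read PNG/TIFF/JPEG and always write PNG to avoid recompression
loss).  A study is described by a :class:`StudyManifest` giving the factorial
design (participants x eyes x acquisitions x scan areas x slabs); the counts
that the design implies (number of acquisitions, ICC cells, averaged images,
grading boxes) are pure arithmetic on that manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .exceptions import ImageFormatError

SLABS = ("SVP", "DVC", "FULL")
SCAN_AREAS = ("A3x3", "A6x6")
GROUPS = ("healthy", "oedema")

#: number of grading boxes per 3x3-mm image (3 x 3 grid of 172-px squares)
BOXES_PER_IMAGE = 9

# ITU-R 601 luma weights, the convention scikit-image uses for rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class EnFaceImage:
    """One 8-bit en-face angiogram with its acquisition metadata.

    ``quality_index`` is a scalar in [0, 100] standing in for the device's
    Signal Strength Index (SSI); ``None`` when unknown.
    """

    pixels: np.ndarray
    slab: str = "SVP"
    scan_area: str = "A3x3"
    eye_id: str = ""
    acquisition_index: int = 1
    quality_index: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ImageFormatError(f"expected a non-empty 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        self.pixels = px
        if self.slab not in SLABS:
            raise ValueError(f"unknown slab {self.slab!r}")
        if self.scan_area not in SCAN_AREAS:
            raise ValueError(f"unknown scan area {self.scan_area!r}")
        if self.acquisition_index < 1:
            raise ValueError("acquisition_index must be >= 1")
        if self.quality_index is not None and not (0 <= self.quality_index <= 100):
            raise ValueError("quality_index must lie in [0, 100]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return replace(self, pixels=pixels)


def load_image(path: str | Path, **metadata) -> EnFaceImage:
    """Read a PNG/TIFF/JPEG raster into an :class:`EnFaceImage`.

    RGB(A) input is converted to luminance; rasters deeper than 8 bits are
    linearly rescaled so their maximum maps to 255.  Metadata keyword
    arguments (slab, scan_area, eye_id, ...) are attached unchanged.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # backends raise format-specific error types
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageFormatError(f"zero-sized raster in {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ImageFormatError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ImageFormatError(f"unsupported raster rank {arr.ndim} in {path}")
    arr = arr.astype(np.float64)
    peak = arr.max()
    if peak > 255:
        arr = arr * (255.0 / peak)
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return EnFaceImage(pixels=arr, **metadata)


def save_image(image: EnFaceImage | np.ndarray, path: str | Path) -> Path:
    """Write an image as PNG (or TIFF); 8-bit output, lossless round trip."""
    path = Path(path)
    px = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, px)
    return path


@dataclass(frozen=True)
class CropRegion:
    """A square logo region to remove, anchored to one image corner.

    The crop policy removes the full horizontal band of rows at the
    corner's vertical extreme (a square removal would leave a
    non-rectangular raster).  ``side_px=0`` is a no-op.
    """

    corner: str = "bottom_left"
    side_px: int = 0

    _CORNERS = ("bottom_left", "bottom_right", "top_left", "top_right")

    def __post_init__(self) -> None:
        if self.corner not in self._CORNERS:
            raise ValueError(f"unknown corner {self.corner!r}")
        if self.side_px < 0:
            raise ValueError("side_px must be >= 0")


def crop_logo(image: EnFaceImage, region: CropRegion) -> EnFaceImage:
    """Remove the logo band; surviving pixel intensities are untouched."""
    if region.side_px >= min(image.height, image.width):
        raise ValueError(
            f"crop side {region.side_px} does not fit inside {image.height}x{image.width}"
        )
    if region.side_px == 0:
        return image.with_pixels(image.pixels.copy())
    if region.corner.startswith("bottom"):
        px = image.pixels[: image.height - region.side_px, :]
    else:
        px = image.pixels[region.side_px :, :]
    return image.with_pixels(px.copy())


@dataclass(frozen=True)
class StudyManifest:
    """Factorial design of a repeatability study.

    The reference design images both eyes of every participant five times in
    each scan area, and projects every acquisition into each slab.
    """

    n_participants: int = 10
    eyes_per_participant: int = 2
    n_acquisitions: int = 5
    scan_areas: tuple[str, ...] = ("A3x3", "A6x6")
    slabs: tuple[str, ...] = ("SVP", "DVC")
    group_per_participant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_participants", "eyes_per_participant", "n_acquisitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.scan_areas or not self.slabs:
            raise ValueError("scan_areas and slabs must be non-empty")
        groups = self.group_per_participant or ("healthy",) * self.n_participants
        if len(groups) != self.n_participants:
            raise ValueError("group_per_participant length must equal n_participants")
        if any(g not in GROUPS for g in groups):
            raise ValueError("groups must be 'healthy' or 'oedema'")
        object.__setattr__(self, "group_per_participant", tuple(groups))

    @property
    def n_eyes(self) -> int:
        return self.n_participants * self.eyes_per_participant


def enumerate_counts(manifest: StudyManifest) -> dict[str, int]:
    """Counts implied by the study design (pure arithmetic).

    ``grading_boxes`` counts the nine 172x172 grading boxes of every
    averaged 3x3-mm image (box grading is only performed on the 3x3-mm
    scans).
    """
    m = manifest
    eyes = m.n_eyes
    acquisitions = eyes * m.n_acquisitions * len(m.scan_areas)
    icc_cells = eyes * len(m.scan_areas) * len(m.slabs)
    single_images = acquisitions * len(m.slabs)
    averaged_images = eyes * len(m.scan_areas) * len(m.slabs)
    grading_boxes = (
        eyes * len(m.slabs) * BOXES_PER_IMAGE if "A3x3" in m.scan_areas else 0
    )
    return {
        "acquisitions": acquisitions,
        "icc_cells": icc_cells,
        "single_images": single_images,
        "averaged_images": averaged_images,
        "grading_boxes": grading_boxes,
    }


def oedema_thickness_threshold(normal_mean_um: float, normal_sd_um: float) -> float:
    """Central-subfield thickness cut-off defining oedema: mean + 2 SD (μm)."""
    if normal_mean_um < 0 or normal_sd_um < 0:
        raise ValueError("thickness mean and SD must be non-negative")
    return normal_mean_um + 2.0 * normal_sd_um


# ---------------------------------------------------------------------------
# manifest tables

MANIFEST_COLUMNS = ["participant", "eye", "area", "slab", "acquisition", "file_path", "group"]


def manifest_rows(manifest: StudyManifest, path_fn=None) -> pd.DataFrame:
    """Expand a :class:`StudyManifest` into one row per single image."""
    rows = []
    for p in range(manifest.n_participants):
        group = manifest.group_per_participant[p]
        for e in range(manifest.eyes_per_participant):
            for area in manifest.scan_areas:
                for slab in manifest.slabs:
                    for k in range(1, manifest.n_acquisitions + 1):
                        fp = path_fn(p, e, area, slab, k) if path_fn else ""
                        rows.append((f"P{p:02d}", f"P{p:02d}E{e}", area, slab, k, str(fp), group))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"acquisition": int})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# configuration and logging

def load_config(path: str | Path | None) -> dict:
    """Load a nested key-value config file (YAML syntax); ``None`` -> {}."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping at top level")
    return cfg


def merge_config(base: Mapping, overrides: Mapping) -> dict:
    """Deep merge: values in ``overrides`` win over ``base`` (CLI over file)."""
    out = dict(base)
    for key, val in overrides.items():
        if val is None:
            continue
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = val
    return out


def get_logger(level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger("octavg")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


def checksum(arr: np.ndarray) -> str:
    """Short content hash used to log pipeline stage outputs."""
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:10]


def log_stage(logger: logging.Logger, stage: str, **fields) -> None:
    """One line per pipeline stage: inputs, parameters, seed, output checksum."""
    kv = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, kv)
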