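"""Average-intensity Z-projection of a registered stack."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_manifest import checksum
from .registration import RegisteredStack


@dataclass
class AveragedImage:
    """Per-pixel arithmetic mean of the registered acquisitions (8-bit).

    ``validity_mask`` is inherited from the registered stack: pixels with
    real data from every frame.
    """

    pixels: np.ndarray
    n_frames: int
    source_ids: tuple[str, ...]
    validity_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def average_stack(stack: RegisteredStack, exclude_invalid: bool = False) -> AveragedImage:
    """Mean projection over frames, accumulated in float, rounded once.

    By default every frame contributes at every pixel (invalid out-of-frame
    pixels were filled with 0 during resampling), matching a plain
    average-intensity projection; ``exclude_invalid=True`` instead averages
    only frames with real data at each pixel.
    """
    frames = [im.pixels for im in stack.images]
    if len(frames) < 2:
        raise ValueError("need at least two frames to average")
    acc = np.zeros(frames[0].shape, dtype=np.float64)
    if exclude_invalid:
        count = np.zeros(frames[0].shape, dtype=np.float64)
        for arr, mask in zip(frames, stack.frame_masks):
            acc += np.where(mask, arr, 0).astype(np.float64)
            count += mask
        mean = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    else:
        for arr in frames:
            acc += arr
        mean = acc / len(frames)
    pixels = np.clip(_round_half_away(mean), 0, 255).astype(np.uint8)
    ids = tuple(f"{im.eye_id}:{im.acquisition_index}:{checksum(im.pixels)}" for im in stack.images)
    return AveragedImage(
        pixels=pixels,
        n_frames=len(frames),
        source_ids=ids,
        validity_mask=stack.validity_mask.copy(),
    )
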