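"""Synthetic en-face angiograms with known ground truth.

Real OCTA exports are unavailable for testing pipelines end to end, so this
module emulates the features that matter to registration, averaging and
gain/loss analysis: a bright branching arteriolar tree plus a capillary
mesh on a dark background, per-acquisition speckle-like Gaussian noise,
rigid jitter between acquisitions (eye motion), a smooth elastic warp
(ocular curvature / scan distortion), bright full-width motion-stripe
artifacts, intermittent capillary perfusion (a capillary segment may carry
no flow signal in a given acquisition), dark cystoid regions for oedema
eyes, and a scalar quality index standing in for the device's Signal
Strength Index.

Everything is a pure function of (spec, seed): acquisition ``k`` draws from
a fixed per-acquisition substream, so any single frame is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import scipy.ndimage as ndi

from .io_manifest import EnFaceImage
from .registration import SimilarityTransform, sample_at

# fixed substream tags so acquisition k is reproducible in isolation
_STREAM_NETWORK = 11
_STREAM_CYSTS = 13
_STREAM_NOISE = 200
_STREAM_JITTER = 300
_STREAM_ELASTIC = 400
_STREAM_DROPOUT = 500
_STREAM_STRIPES = 600
_STREAM_SIGNAL = 700
_STREAM_COHORT = 777


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic eye (one acquisition stack).

    Intensities are on the 8-bit scale; geometric parameters in pixels and
    degrees.  ``dropout_rate`` is the per-acquisition probability that a
    capillary segment carries no flow signal.
    """

    image_side: int = 516
    slab_style: str = "SVP"
    group: str = "healthy"
    n_trunks: int = 6
    branching_depth: int = 4
    capillary_density: float = 0.15
    capillary_width: int = 2
    vessel_intensity_mean: float = 180.0
    background_mean: float = 20.0
    noise_sd: float = 15.0
    edge_sigma: float = 0.7
    motion_stripe_rate: float = 0.5
    jitter_translation_sd: float = 4.0
    jitter_rotation_sd: float = 2.0
    jitter_scale_sd: float = 0.01
    signal_jitter_sd: float = 0.05
    blur_jitter_sd: float = 0.3
    elastic_amp: float = 4.0
    elastic_scale: float = 64.0
    dropout_rate: float = 0.15
    n_cysts: int = 0
    n_acquisitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 8:
            raise ValueError("image_side too small")
        if self.slab_style not in ("SVP", "DVC"):
            raise ValueError(f"unknown slab style {self.slab_style!r}")
        if self.group not in ("healthy", "oedema"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.capillary_density <= 0.6:
            raise ValueError(
                "capillary_density must lie in [0, 0.6]; denser meshes defeat "
                "vessel/background separation"
            )
        for name in (
            "noise_sd", "motion_stripe_rate", "jitter_translation_sd",
            "jitter_rotation_sd", "jitter_scale_sd", "signal_jitter_sd",
            "blur_jitter_sd", "elastic_amp",
            "elastic_scale", "edge_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not self.vessel_intensity_mean > self.background_mean:
            raise ValueError("vessel intensity must exceed background")
        if self.n_acquisitions < 1 or self.n_trunks < 0 or self.n_cysts < 0:
            raise ValueError("counts must be non-negative (acquisitions >= 1)")


def healthy_spec(slab_style: str = "SVP", **overrides) -> SyntheticSpec:
    """Healthy-eye preset; SVP has trunks + coarse mesh and low noise, DVC a
    denser, finer mesh with stronger background noise and no large trunks."""
    base = dict(
        slab_style=slab_style, group="healthy", n_cysts=0,
        signal_jitter_sd=0.03, blur_jitter_sd=0.15,
    )
    if slab_style == "DVC":
        base.update(n_trunks=0, capillary_density=0.22, capillary_width=1, noise_sd=18.0)
    else:
        base.update(n_trunks=6, capillary_density=0.12, noise_sd=10.0)
    base.update(overrides)
    return SyntheticSpec(**base)


def oedema_spec(slab_style: str = "SVP", **overrides) -> SyntheticSpec:
    """Macular-oedema preset: cystoid dark regions, poorer fixation (larger
    jitter, more motion stripes, less stable signal) and more intermittent
    perfusion."""
    defaults = dict(
        group="oedema",
        n_cysts=4,
        vessel_intensity_mean=150.0,  # intraretinal fluid attenuates signal
        jitter_translation_sd=8.0,
        jitter_rotation_sd=3.0,
        motion_stripe_rate=1.5,
        signal_jitter_sd=0.12,
        blur_jitter_sd=0.6,
        dropout_rate=0.25,
    )
    defaults.update(overrides)
    return healthy_spec(slab_style=slab_style, **defaults)


@dataclass
class GroundTruth:
    """True geometry and perfusion state behind one acquisition stack."""

    vessel_mask: np.ndarray
    trunk_mask: np.ndarray
    capillary_segments: list
    per_acquisition_transforms: list
    per_acquisition_fields: list  # (d_row, d_col) arrays per acquisition
    per_acquisition_dropout_masks: list
    cyst_mask: np.ndarray
    cyst_factor: np.ndarray
    per_acquisition_stripe_rows: list
    per_acquisition_signal: list = field(default_factory=list)
    per_acquisition_blur: list = field(default_factory=list)

    @property
    def persistent_vessel_mask(self) -> np.ndarray:
        """Vessel support perfused in every acquisition."""
        out = self.vessel_mask.copy()
        for m in self.per_acquisition_dropout_masks:
            out &= ~m
        return out


# ---------------------------------------------------------------------------
# vessel geometry

def _disk_offsets(width: int) -> tuple[np.ndarray, np.ndarray]:
    r = max((width - 1) / 2.0, 0.0)
    n = int(np.ceil(r))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    keep = dy**2 + dx**2 <= max(r, 0.5) ** 2
    return dy[keep], dx[keep]


def _stamp(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray, width: int):
    """Draw a polyline of given width; returns the stamped pixel indices."""
    side = canvas.shape[0]
    dy, dx = _disk_offsets(width)
    rr = (rows[:, None] + dy[None, :]).ravel()
    cc = (cols[:, None] + dx[None, :]).ravel()
    keep = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < canvas.shape[1])
    rr, cc = rr[keep], cc[keep]
    canvas[rr, cc] = True
    return rr, cc


def _walk(start, heading, n_steps, step, wobble, rng, side):
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    h = heading
    for i in range(n_steps):
        h += rng.normal(0.0, wobble)
        pts[i + 1] = pts[i] + step * np.array([np.sin(h), np.cos(h)])
    pts = np.clip(np.rint(pts), 0, side - 1).astype(int)
    return pts[:, 0], pts[:, 1], h


def _draw_branch(canvas, start, heading, length, width, depth, rng):
    side = canvas.shape[0]
    n_steps = max(int(length / 1.2), 2)
    rows, cols, end_heading = _walk(start, heading, n_steps, 1.2, 0.08, rng, side)
    _stamp(canvas, rows, cols, max(int(round(width)), 1))
    if depth > 0 and length > 8:
        end = np.array([rows[-1], cols[-1]], dtype=float)
        for sign in (-1.0, 1.0):
            child_heading = end_heading + sign * np.radians(rng.uniform(18, 50))
            _draw_branch(
                canvas, end, child_heading, length * 0.72, max(width * 0.72, 1.0),
                depth - 1, rng,
            )


def _vessel_network(spec: SyntheticSpec, rng: np.random.Generator):
    side = spec.image_side
    trunk = np.zeros((side, side), dtype=bool)
    for _ in range(spec.n_trunks):
        edge = rng.integers(4)
        pos = rng.uniform(0.1, 0.9) * side
        start = {
            0: (0.0, pos), 1: (side - 1.0, pos), 2: (pos, 0.0), 3: (pos, side - 1.0)
        }[int(edge)]
        centre = np.array([side / 2.0, side / 2.0]) + rng.normal(0, side * 0.08, 2)
        d = centre - np.array(start)
        heading = np.arctan2(d[0], d[1]) + rng.normal(0, 0.2)
        _draw_branch(
            trunk, np.array(start), heading, side * 0.45, 4.0, spec.branching_depth, rng
        )

    capillary = np.zeros((side, side), dtype=bool)
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    # capillary segment length is fixed in retinal mm, so it scales with the raster
    frac = 0.048 if spec.slab_style == "DVC" else 0.078
    stroke_len = max(6, int(round(side * frac)))
    max_strokes = 60_000
    while capillary.mean() < spec.capillary_density and len(segments) < max_strokes:
        start = rng.uniform(0, side - 1, 2)
        heading = rng.uniform(0, 2 * np.pi)
        rows, cols, _ = _walk(start, heading, stroke_len, 1.4, 0.3, rng, side)
        rr, cc = _stamp(capillary, rows, cols, spec.capillary_width)
        segments.append((rr, cc))
    return trunk | capillary, trunk, segments


def generate_vessel_network(spec: SyntheticSpec) -> np.ndarray:
    """Binary vessel support: branching trunk trees plus a capillary mesh
    whose pixel fraction approximates ``capillary_density``."""
    rng = np.random.default_rng([spec.seed, _STREAM_NETWORK])
    mask, _, _ = _vessel_network(spec, rng)
    return mask


def _cyst_maps(spec: SyntheticSpec, rng: np.random.Generator):
    side = spec.image_side
    factor = np.ones((side, side))
    if spec.group != "oedema" or spec.n_cysts == 0:
        return np.zeros((side, side), dtype=bool), factor
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    for _ in range(spec.n_cysts):
        cy, cx = rng.uniform(0.2, 0.8, 2) * side
        ry = rng.uniform(side / 14, side / 7)
        rx = rng.uniform(side / 14, side / 7)
        th = rng.uniform(0, np.pi)
        f = rng.uniform(0.2, 0.5)
        dy, dx = yy - cy, xx - cx
        u = np.cos(th) * dx - np.sin(th) * dy
        v = np.sin(th) * dx + np.cos(th) * dy
        inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        factor = np.where(inside, np.minimum(factor, f), factor)
    factor = ndi.gaussian_filter(factor, side / 60.0)
    return factor < 0.95, factor


def _elastic_field(spec: SyntheticSpec, rng: np.random.Generator):
    side = spec.image_side
    dr = np.zeros((side, side))
    dc = np.zeros((side, side))
    if spec.elastic_amp == 0:
        return dr, dc
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    n_bumps = 6
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0, side, 2)
        sigma = spec.elastic_scale * rng.uniform(0.75, 1.25)
        amp = rng.normal(0.0, spec.elastic_amp * 0.6, 2)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        dr += amp[0] * bump
        dc += amp[1] * bump
    return dr, dc


# ---------------------------------------------------------------------------
# rendering

def render_acquisition(gt: GroundTruth, spec: SyntheticSpec, k: int) -> EnFaceImage:
    """Render acquisition ``k`` (1-based) from the ground truth.

    Pipeline: drop non-perfused segments -> two-level vessel/background
    rendering with soft (sub-pixel) vessel edges -> cyst darkening ->
    additive Gaussian noise -> rigid jitter + elastic warp -> motion
    stripes -> clamp to 8 bits.  Stripes are drawn after the warp because
    they are scan-line artifacts of the acquired frame.
    """
    if not 1 <= k <= len(gt.per_acquisition_transforms):
        raise ValueError(f"acquisition index {k} out of range")
    side = spec.image_side
    rng = np.random.default_rng([spec.seed, _STREAM_NOISE + k])
    eff = gt.vessel_mask & ~gt.per_acquisition_dropout_masks[k - 1]
    if spec.edge_sigma > 0:
        soft = np.clip(ndi.gaussian_filter(eff.astype(float), spec.edge_sigma) * 2.0, 0, 1)
        # keep true vessel pixels at full intensity; soften only the shoulders
        soft[eff] = 1.0
    else:
        soft = eff.astype(float)
    gain = gt.per_acquisition_signal[k - 1] if gt.per_acquisition_signal else 1.0
    canvas = spec.background_mean + gain * (
        spec.vessel_intensity_mean - spec.background_mean
    ) * soft
    canvas = canvas * gt.cyst_factor
    blur = gt.per_acquisition_blur[k - 1] if gt.per_acquisition_blur else 0.0
    if blur > 0.05:
        # acquisition-to-acquisition focus/motion blur of the flow signal;
        # faint capillaries sink toward the background while noise persists
        canvas = ndi.gaussian_filter(canvas, blur)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)

    t = gt.per_acquisition_transforms[k - 1]
    dr, dc = gt.per_acquisition_fields[k - 1]
    if not (t.is_identity and np.all(dr == 0) and np.all(dc == 0)):
        rows, cols = np.mgrid[0:side, 0:side].astype(float)
        src_r, src_c = t.map_coords(rows, cols, canvas.shape)
        src_r = src_r + dr
        src_c = src_c + dc
        warped, valid = sample_at(canvas, src_r, src_c)
        if not valid.all():
            fill = spec.background_mean + rng.normal(0.0, spec.noise_sd, canvas.shape)
            warped = np.where(valid, warped, fill)
        canvas = warped

    for row in gt.per_acquisition_stripe_rows[k - 1]:
        canvas[row, :] = rng.uniform(120, 255, side)

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = EnFaceImage(
        pixels=pixels,
        slab=spec.slab_style,
        scan_area="A3x3",
        eye_id=f"syn{spec.seed}",
        acquisition_index=k,
    )
    image.quality_index = ssi_surrogate(image)
    return image


def generate_stack(spec: SyntheticSpec):
    """Full synthetic acquisition stack plus its ground truth.

    Acquisition 1 carries identity geometry (it is the registration
    reference); later acquisitions draw independent jitter, elastic warps,
    perfusion dropout and stripe artifacts.
    """
    side = spec.image_side
    net_rng = np.random.default_rng([spec.seed, _STREAM_NETWORK])
    vessel_mask, trunk_mask, segments = _vessel_network(spec, net_rng)
    cyst_mask, cyst_factor = _cyst_maps(
        spec, np.random.default_rng([spec.seed, _STREAM_CYSTS])
    )

    transforms, fields, dropouts, stripes, signal, blur = [], [], [], [], [], []
    zero = np.zeros((side, side))
    for k in range(1, spec.n_acquisitions + 1):
        if k == 1:
            transforms.append(SimilarityTransform.identity())
            fields.append((zero, zero))
        else:
            jr = np.random.default_rng([spec.seed, _STREAM_JITTER + k])
            transforms.append(
                SimilarityTransform(
                    tx=jr.normal(0, spec.jitter_translation_sd),
                    ty=jr.normal(0, spec.jitter_translation_sd),
                    theta=jr.normal(0, spec.jitter_rotation_sd),
                    s=float(np.clip(1.0 + jr.normal(0, spec.jitter_scale_sd), 0.85, 1.15)),
                )
            )
            er = np.random.default_rng([spec.seed, _STREAM_ELASTIC + k])
            fields.append(_elastic_field(spec, er))
        dr = np.random.default_rng([spec.seed, _STREAM_DROPOUT + k])
        dropped = np.zeros((side, side), dtype=bool)
        if spec.dropout_rate > 0 and segments:
            pick = dr.random(len(segments)) < spec.dropout_rate
            for (rr, cc), take in zip(segments, pick):
                if take:
                    dropped[rr, cc] = True
            dropped &= ~trunk_mask  # large vessels are always perfused
        dropouts.append(dropped)
        sr = np.random.default_rng([spec.seed, _STREAM_STRIPES + k])
        n_stripes = sr.poisson(spec.motion_stripe_rate)
        stripes.append(sorted(sr.integers(0, side, n_stripes).tolist()))
        gr = np.random.default_rng([spec.seed, _STREAM_SIGNAL + k])
        signal.append(float(np.clip(1.0 + gr.normal(0, spec.signal_jitter_sd), 0.5, 1.5)))
        blur.append(float(abs(gr.normal(0, spec.blur_jitter_sd))))

    gt = GroundTruth(
        vessel_mask=vessel_mask,
        trunk_mask=trunk_mask,
        capillary_segments=segments,
        per_acquisition_transforms=transforms,
        per_acquisition_fields=fields,
        per_acquisition_dropout_masks=dropouts,
        cyst_mask=cyst_mask,
        cyst_factor=cyst_factor,
        per_acquisition_stripe_rows=stripes,
        per_acquisition_signal=signal,
        per_acquisition_blur=blur,
    )
    stack = [render_acquisition(gt, spec, k) for k in range(1, spec.n_acquisitions + 1)]
    return stack, gt


def cohort_specs(
    n_eyes: int,
    preset=healthy_spec,
    slab_style: str = "SVP",
    seed: int = 0,
    density_sd: float = 0.04,
    **overrides,
) -> list[SyntheticSpec]:
    """Specs for a cohort of eyes sharing study conditions.

    Eyes differ in their true capillary density (normal spread
    ``density_sd`` around the preset value, as real eyes differ in vessel
    density) and in their private seeds; everything else follows the preset.
    """
    rng = np.random.default_rng([seed, _STREAM_COHORT])
    specs = []
    for e in range(n_eyes):
        base = preset(slab_style=slab_style, seed=seed + 37 * e + 1, **overrides)
        dens = float(np.clip(rng.normal(base.capillary_density, density_sd), 0.04, 0.5))
        specs.append(replace(base, capillary_density=dens))
    return specs


# ---------------------------------------------------------------------------
# quality index

def ssi_surrogate(image: EnFaceImage | np.ndarray) -> float:
    """Scalar acquisition-quality score in [0, 100].

    A monotone transform of global contrast-to-noise: the spread between
    the bright-signal (95th) and dark-background (25th) intensity
    percentiles relative to full scale, discounted by a robust noise
    estimate (scaled MAD of the high-pass residual over background
    pixels, which vessel texture does not inflate).  The 95th rather than a
    more extreme percentile keeps bright motion-stripe rows from inflating
    the score.  Constant images score 0.
    """
    px = (image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)).astype(
        np.float64
    )
    if px.size == 0:
        raise ValueError("empty image")
    if px.max() == px.min():
        return 0.0
    p25, p95 = np.percentile(px, [25, 95])
    contrast = (p95 - p25) / 255.0
    resid = px - ndi.gaussian_filter(px, 1.0)
    background = px <= np.median(px)
    sigma = 1.4826 * float(np.median(np.abs(resid[background]))) * 1.2
    score = 100.0 * contrast / (1.0 + sigma / 40.0)
    return float(np.clip(score, 0.0, 100.0))


# ---------------------------------------------------------------------------
# ground-truth based evaluation helpers

def registration_residual(gt: GroundTruth, reg_stack, frame: int) -> float:
    """Mean geometric alignment error (px) of a registered frame.

    Composes the estimated output->acquisition mapping with the true
    acquisition->canonical mapping; for perfect registration the
    composition is the identity.  Averaged over the stack validity mask.
    """
    shape = reg_stack.shape
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    sy, sx = reg_stack.source_coords(frame)
    t = gt.per_acquisition_transforms[frame - 1]
    er, ec = t.map_coords(sy, sx, shape)
    dr, dc = gt.per_acquisition_fields[frame - 1]
    if np.any(dr != 0) or np.any(dc != 0):
        er = er + ndi.map_coordinates(dr, [sy, sx], order=1, mode="nearest")
        ec = ec + ndi.map_coordinates(dc, [sy, sx], order=1, mode="nearest")
    err = np.hypot(er - rows, ec - cols)
    return float(err[reg_stack.validity_mask].mean())
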