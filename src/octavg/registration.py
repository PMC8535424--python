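"""Intensity-based alignment of an acquisition stack to its first frame.

Two stages, mirroring the classic en-face OCTA averaging chain:

1. *Linear* — a similarity transform (translation + rotation + uniform
   scale, no shear) per frame, estimated by minimising the mean squared
   intensity difference to the reference over a 3-level Gaussian pyramid,
   initialised by phase correlation at the coarsest level.
2. *Elastic* — a B-spline free-form deformation refining the residual
   smooth warp (ocular curvature, scan distortion).  A dense displacement
   estimate from iterative Lucas-Kanade optical flow is projected onto a
   coarse control grid by confidence-weighted averaging with a
   bending-energy penalty (weight ``lam``), so the field stays smooth and
   shrinks to zero as ``lam`` grows.

Both stages are deterministic: fixed initialisation, fixed iteration caps,
no random numbers.  The reference frame is returned bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import minimize
from skimage.feature import structure_tensor
from skimage.registration import optical_flow_ilk, phase_cross_correlation
from skimage.transform import rescale

from .exceptions import RegistrationError
from .io_manifest import EnFaceImage


@dataclass
class SimilarityTransform:
    """Maps an output pixel (row, col) to source coordinates.

    ``src = s * R(theta) @ (p - c) + c + t`` with the centre ``c`` at the
    image midpoint; ``theta`` in degrees, translation in pixels.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.tx, self.ty, self.theta, self.s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("transform parameters must be finite")
        if self.s <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return self.tx == self.ty == self.theta == 0.0 and self.s == 1.0

    def map_coords(
        self, rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Source (row, col) coordinates for output pixel grid positions."""
        h, w = shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        th = math.radians(self.theta)
        cos_t, sin_t = math.cos(th), math.sin(th)
        dy = np.asarray(rows, dtype=np.float64) - cy
        dx = np.asarray(cols, dtype=np.float64) - cx
        src_c = self.s * (cos_t * dx - sin_t * dy) + cx + self.tx
        src_r = self.s * (sin_t * dx + cos_t * dy) + cy + self.ty
        return src_r, src_c

    def inverse(self) -> "SimilarityTransform":
        th = math.radians(self.theta)
        inv_s = 1.0 / self.s
        cos_t, sin_t = math.cos(-th), math.sin(-th)
        # t_inv = -(1/s) R(-theta) t
        tx = -inv_s * (cos_t * self.tx - sin_t * self.ty)
        ty = -inv_s * (sin_t * self.tx + cos_t * self.ty)
        return SimilarityTransform(tx=tx, ty=ty, theta=-self.theta, s=inv_s)


@dataclass
class DeformationField:
    """Smooth displacement field on a cubic B-spline control grid.

    ``coef`` has shape (2, n_rows, n_cols): per-node (d_row, d_col)
    displacements in pixels; the dense field interpolates the nodes with a
    bicubic spline surface.
    """

    spacing: float
    node_rows: np.ndarray
    node_cols: np.ndarray
    coef: np.ndarray

    _dense_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def zero(cls, shape: tuple[int, int], spacing: float = 32.0) -> "DeformationField":
        nr, nc = _control_nodes(shape, spacing)
        return cls(spacing, nr, nc, np.zeros((2, nr.size, nc.size)))

    @property
    def max_displacement(self) -> float:
        return float(np.abs(self.coef).max(initial=0.0))

    def dense(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (d_row, d_col) displacement arrays for ``shape``."""
        key = shape
        if key not in self._dense_cache:
            if np.all(self.coef == 0):
                dr = np.zeros(shape)
                dc = np.zeros(shape)
            else:
                rows = np.arange(shape[0], dtype=np.float64)
                cols = np.arange(shape[1], dtype=np.float64)
                ky = min(3, self.node_rows.size - 1)
                kx = min(3, self.node_cols.size - 1)
                dr = RectBivariateSpline(
                    self.node_rows, self.node_cols, self.coef[0], kx=kx, ky=ky
                )(rows, cols)
                dc = RectBivariateSpline(
                    self.node_rows, self.node_cols, self.coef[1], kx=kx, ky=ky
                )(rows, cols)
            self._dense_cache[key] = (dr, dc)
        return self._dense_cache[key]


@dataclass
class RegisteredStack:
    """Acquisitions resampled into the reference frame.

    ``validity_mask`` marks pixels with real data from *all* frames;
    ``images[reference_index - 1]`` is the untouched reference.
    """

    images: list[EnFaceImage]
    transforms: list[SimilarityTransform]
    fields: list[DeformationField]
    frame_masks: list[np.ndarray]
    validity_mask: np.ndarray
    reference_index: int = 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].pixels.shape

    @classmethod
    def from_arrays(cls, arrays: Sequence, reference_index: int = 1) -> "RegisteredStack":
        """Wrap already-aligned frames (identity geometry, full validity)."""
        images = [
            a if isinstance(a, EnFaceImage) else EnFaceImage(pixels=np.asarray(a))
            for a in arrays
        ]
        shape = images[0].pixels.shape
        n = len(images)
        return cls(
            images=images,
            transforms=[SimilarityTransform.identity() for _ in range(n)],
            fields=[DeformationField.zero(shape) for _ in range(n)],
            frame_masks=[np.ones(shape, dtype=bool) for _ in range(n)],
            validity_mask=np.ones(shape, dtype=bool),
            reference_index=reference_index,
        )

    def source_coords(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Composed mapping output pixel -> original frame coordinates.

        Elastic displacement is applied in the reference frame, then the
        similarity transform: ``src = T(p + D(p))``.  ``frame`` is 1-based.
        """
        shape = self.shape
        rows, cols = np.meshgrid(
            np.arange(shape[0], dtype=np.float64),
            np.arange(shape[1], dtype=np.float64),
            indexing="ij",
        )
        dr, dc = self.fields[frame - 1].dense(shape)
        return self.transforms[frame - 1].map_coords(rows + dr, cols + dc, shape)


# ---------------------------------------------------------------------------
# resampling

def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)


def sample_at(arr: np.ndarray, src_r: np.ndarray, src_c: np.ndarray):
    """Bilinear sampling at fractional coordinates; out-of-bounds -> 0/invalid."""
    h, w = arr.shape
    valid = (src_r >= 0) & (src_r <= h - 1) & (src_c >= 0) & (src_c <= w - 1)
    out = ndi.map_coordinates(
        arr.astype(np.float64), [src_r, src_c], order=1, mode="constant", cval=0.0
    )
    out[~valid] = 0.0
    return out, valid


def resample(
    image,
    transform: SimilarityTransform | None = None,
    fld: DeformationField | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp an image by ``field`` then ``transform`` (``src = T(p + D(p))``).

    Returns the resampled 8-bit array and the validity mask (pixels whose
    source location lies inside the original raster).  Identity transform
    with zero field is a bit-exact copy.
    """
    arr = _as_array(image)
    shape = arr.shape
    transform = transform or SimilarityTransform.identity()
    if transform.is_identity and (fld is None or np.all(fld.coef == 0)):
        return arr.copy(), np.ones(shape, dtype=bool)
    rows, cols = np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        indexing="ij",
    )
    if fld is not None:
        dr, dc = fld.dense(shape)
        rows = rows + dr
        cols = cols + dc
    src_r, src_c = transform.map_coords(rows, cols, shape)
    out, valid = sample_at(arr, src_r, src_c)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), valid


def mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared intensity difference, optionally over a validity mask."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if mask is not None:
        if not mask.any():
            return float("inf")
        a, b = a[mask], b[mask]
    return float(np.mean((a - b) ** 2))


# ---------------------------------------------------------------------------
# linear (similarity) stage

_DEFAULT_BOUNDS = {"max_scale_dev": 0.2, "max_rotation_deg": 20.0, "max_shift_frac": 0.45}


def _pyramid(arr: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [arr.astype(np.float64)]
    for _ in range(levels - 1):
        pyr.append(rescale(pyr[-1], 0.5, anti_aliasing=True, preserve_range=True))
    return pyr[::-1]  # coarse -> fine


def _level_grid(shape, max_samples=66_000):
    stride = 1
    while (shape[0] // stride) * (shape[1] // stride) > max_samples:
        stride += 1
    rows = np.arange(0, shape[0], stride, dtype=np.float64)
    cols = np.arange(0, shape[1], stride, dtype=np.float64)
    return np.meshgrid(rows, cols, indexing="ij")


def _pair_mse(params, ref, mov, rr, cc, ref_samples):
    tx, ty, theta, s100 = params
    t = SimilarityTransform(tx=tx, ty=ty, theta=theta, s=1.0 + s100 / 100.0)
    src_r, src_c = t.map_coords(rr, cc, mov.shape)
    warped, valid = sample_at(mov, src_r, src_c)
    frac = valid.mean()
    if frac < 0.2:
        return 1e8 * (1.2 - frac)
    diff = (warped - ref_samples)[valid]
    return float(np.mean(diff**2))


def _float_resample(arr: np.ndarray, transform: SimilarityTransform):
    rows, cols = np.meshgrid(
        np.arange(arr.shape[0], dtype=np.float64),
        np.arange(arr.shape[1], dtype=np.float64),
        indexing="ij",
    )
    src_r, src_c = transform.map_coords(rows, cols, arr.shape)
    return sample_at(arr, src_r, src_c)


def register_pair_linear(
    ref: np.ndarray, mov: np.ndarray, levels: int = 3, bounds: dict | None = None
) -> SimilarityTransform:
    """Estimate the similarity transform aligning ``mov`` to ``ref``."""
    b = {**_DEFAULT_BOUNDS, **(bounds or {})}
    pyr_ref = _pyramid(ref, levels)
    pyr_mov = _pyramid(mov, levels)
    # rotation sweep at the coarsest level: beyond ~3 degrees the texture
    # decorrelates and a translation-only start strands the optimiser
    rr0, cc0 = _level_grid(pyr_ref[0].shape)
    ref_samples0 = ndi.map_coordinates(pyr_ref[0], [rr0, cc0], order=1)
    best_params, best_cost = None, np.inf
    for theta0 in np.arange(-9.0, 9.1, 1.5):
        rot, _ = _float_resample(pyr_mov[0], SimilarityTransform(theta=theta0))
        shift, _, _ = phase_cross_correlation(
            pyr_ref[0], rot, upsample_factor=4, normalization=None
        )
        # transform samples mov at p + t: compose minus-shift with the rotation
        th = math.radians(theta0)
        sx, sy = -shift[1], -shift[0]
        tx = math.cos(th) * sx - math.sin(th) * sy
        ty = math.sin(th) * sx + math.cos(th) * sy
        cand = np.array([tx, ty, theta0, 0.0])
        cost = _pair_mse(cand, pyr_ref[0], pyr_mov[0], rr0, cc0, ref_samples0)
        if cost < best_cost:
            best_params, best_cost = cand, cost
    params = best_params
    for lvl, (ref_l, mov_l) in enumerate(zip(pyr_ref, pyr_mov)):
        if lvl > 0:
            params[:2] *= ref_l.shape[0] / pyr_ref[lvl - 1].shape[0]
        rr, cc = _level_grid(ref_l.shape)
        ref_samples = ndi.map_coordinates(ref_l, [rr, cc], order=1)
        res = minimize(
            _pair_mse,
            params,
            args=(ref_l, mov_l, rr, cc, ref_samples),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 60},
        )
        params = res.x
    t = SimilarityTransform(
        tx=params[0], ty=params[1], theta=params[2], s=1.0 + params[3] / 100.0
    )
    h, w = ref.shape
    if (
        abs(t.s - 1.0) > b["max_scale_dev"]
        or abs(t.theta) > b["max_rotation_deg"]
        or abs(t.tx) > b["max_shift_frac"] * w
        or abs(t.ty) > b["max_shift_frac"] * h
    ):
        raise RegistrationError(
            f"linear registration left sanity bounds: {t}", frame_index=None
        )
    return t


def register_linear(
    stack: Sequence, reference_index: int = 1, levels: int = 3, bounds: dict | None = None
):
    """Align every frame to the reference (1-based index) by similarity.

    Returns (transforms, resampled arrays, validity masks).  A frame whose
    optimisation does not improve on the identity keeps the identity, so the
    registered MSE never exceeds the unregistered one.
    """
    arrays = [_as_array(im) for im in stack]
    if len(arrays) < 2:
        raise ValueError("need at least two frames to register")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("stack frames must share dimensions")
    ref = arrays[reference_index - 1].astype(np.float64)
    transforms, images, masks = [], [], []
    for i, arr in enumerate(arrays):
        if i == reference_index - 1:
            transforms.append(SimilarityTransform.identity())
            images.append(arr.copy())
            masks.append(np.ones(arr.shape, dtype=bool))
            continue
        try:
            t = register_pair_linear(ref, arr.astype(np.float64), levels, bounds)
        except RegistrationError as exc:
            raise RegistrationError(str(exc), frame_index=i + 1) from exc
        warped, valid = resample(arr, t)
        if mse(warped, ref, valid) > mse(arr, ref):
            t = SimilarityTransform.identity()
            warped, valid = arr.copy(), np.ones(arr.shape, dtype=bool)
        transforms.append(t)
        images.append(warped)
        masks.append(valid)
    return transforms, images, masks


# ---------------------------------------------------------------------------
# elastic (B-spline) stage

def _control_nodes(shape: tuple[int, int], spacing: float):
    n_r = max(int(round((shape[0] - 1) / spacing)) + 1, 2)
    n_c = max(int(round((shape[1] - 1) / spacing)) + 1, 2)
    return np.linspace(0, shape[0] - 1, n_r), np.linspace(0, shape[1] - 1, n_c)


def _bending_penalty(n_r: int, n_c: int) -> sp.csr_matrix:
    """PSD quadratic form penalising second differences of the control grid."""
    def second_diff(n):
        if n < 3:
            return sp.csr_matrix((0, n))
        return sp.diags(
            [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
            [0, 1, 2],
            shape=(n - 2, n),
        ).tocsr()

    def first_diff(n):
        return sp.diags([-np.ones(n - 1), np.ones(n - 1)], [0, 1], shape=(n - 1, n)).tocsr()

    dr, dc = second_diff(n_r), second_diff(n_c)
    gr, gc = first_diff(n_r), first_diff(n_c)
    ir, ic = sp.identity(n_r), sp.identity(n_c)
    bend = sp.kron(dr.T @ dr, ic) + sp.kron(ir, dc.T @ dc)
    # mild gradient term: unsupported border nodes extrapolate as constants,
    # not linear ramps that overshoot the displacement bound
    grad = sp.kron(gr.T @ gr, ic) + sp.kron(ir, gc.T @ gc)
    return (bend + 0.1 * grad).tocsr()


def fit_deformation(
    flow: np.ndarray,
    weights: np.ndarray,
    shape: tuple[int, int],
    spacing: float = 32.0,
    lam: float = 0.1,
) -> DeformationField:
    """Project a dense displacement estimate onto a penalised control grid.

    Node values are confidence-weighted local averages of the flow; the
    bending penalty ``lam`` (plus a small ridge so the field vanishes as
    ``lam`` -> infinity) propagates displacement into low-confidence areas
    and keeps the surface smooth.
    """
    node_rows, node_cols = _control_nodes(shape, spacing)
    size = int(spacing) | 1
    nr = np.clip(np.rint(node_rows).astype(int), 0, shape[0] - 1)
    nc = np.clip(np.rint(node_cols).astype(int), 0, shape[1] - 1)
    # ridge keeps nodes without data support (margins, invalid wedges) near
    # zero rather than extrapolating, and makes the field vanish as lam grows
    penalty = _bending_penalty(node_rows.size, node_cols.size) + 0.3 * sp.identity(
        node_rows.size * node_cols.size
    )

    def solve_once(w):
        w_smooth = ndi.uniform_filter(w, size=size)
        w_nodes = w_smooth[np.ix_(nr, nc)].ravel()
        w_nodes = w_nodes / (w_nodes.mean() + 1e-12)
        solve = spla.factorized((sp.diags(w_nodes) + lam * penalty).tocsc())
        coef = np.zeros((2, node_rows.size, node_cols.size))
        for d in range(2):
            num = ndi.uniform_filter(flow[d] * w, size=size)
            avg = num / (w_smooth + 1e-12)
            c0 = avg[np.ix_(nr, nc)].ravel()
            coef[d] = solve(w_nodes * c0).reshape(node_rows.size, node_cols.size)
        return DeformationField(spacing, node_rows, node_cols, coef)

    fld = solve_once(weights)
    # one reweighting pass: flow in low-texture pockets can be wildly wrong;
    # discard estimates far from the fitted smooth surface and refit
    dr, dc = fld.dense(shape)
    resid = np.hypot(flow[0] - dr, flow[1] - dc)
    on = weights > 0
    if on.any():
        scale = 1.4826 * np.median(resid[on])
        keep = resid < max(3.0 * scale, 1.0)
        fld = solve_once(weights * keep)
    return fld


def register_pair_elastic(
    ref: np.ndarray,
    mov: np.ndarray,
    spacing: float = 32.0,
    lam: float = 0.1,
    max_displacement: float = 15.0,
    mask: np.ndarray | None = None,
) -> DeformationField:
    """Estimate the smooth residual deformation of an already-aligned frame."""
    radius = 8
    ref_f = ref.astype(np.float32)
    mov_f = mov.astype(np.float32)
    flow = np.asarray(optical_flow_ilk(ref_f, mov_f, radius=radius), dtype=np.float64)
    # border fill and stripe artifacts produce wild flow; keep the fit sane
    # (clip above the bound so genuinely oversized warps still raise)
    flow = np.clip(flow, -1.5 * max_displacement, 1.5 * max_displacement)
    # confidence = smaller structure-tensor eigenvalue: high only where the
    # local texture constrains BOTH flow components (along a straight vessel
    # edge the tangential component is unconstrained — aperture problem)
    arr, arc, acc = structure_tensor(ref.astype(np.float64), sigma=2.5, order="rc")
    half_tr = (arr + acc) / 2.0
    det = arr * acc - arc**2
    weights = half_tr - np.sqrt(np.maximum(half_tr**2 - det, 0.0))
    support = np.ones(ref.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    # flow is unreliable where its window straddles the raster edge or the
    # invalid border fill; erode that influence away
    margin = 2 * radius
    support = support.copy()
    support[:margin, :] = support[-margin:, :] = False
    support[:, :margin] = support[:, -margin:] = False
    eroded = ndi.uniform_filter(support.astype(np.float64), size=2 * radius + 1) > 0.999
    weights = weights * eroded
    # motion-stripe artifacts: a scan line present in only one frame differs
    # grossly across its whole width; such rows carry no correspondence
    diff = np.abs(ref.astype(np.float64) - mov.astype(np.float64))
    row_med = np.median(diff, axis=1)
    scale = np.median(row_med)
    bad = row_med > max(3.0 * scale, scale + 25.0)
    if bad.any():
        bad = ndi.binary_dilation(bad, iterations=radius)
        weights[bad, :] = 0.0
    fld = fit_deformation(np.asarray(flow, dtype=np.float64), weights, ref.shape, spacing, lam)
    if fld.max_displacement > max_displacement:
        raise RegistrationError(
            f"elastic displacement {fld.max_displacement:.1f} px exceeds bound "
            f"{max_displacement} px"
        )
    return fld


def register_elastic(
    images: Sequence[np.ndarray],
    reference_index: int = 1,
    grid_spacing: float = 32.0,
    lam: float = 0.1,
    max_displacement: float = 15.0,
    masks: Sequence[np.ndarray] | None = None,
):
    """Elastic refinement of a linearly aligned stack.

    Per frame the residual MSE to the reference never increases: if the
    fitted field does not help, the zero field is kept.  Returns (fields,
    resampled arrays, validity masks).
    """
    arrays = [_as_array(im) for im in images]
    ref = arrays[reference_index - 1].astype(np.float64)
    fields, out_images, out_masks = [], [], []
    for i, arr in enumerate(arrays):
        if i == reference_index - 1:
            fields.append(DeformationField.zero(arr.shape, grid_spacing))
            out_images.append(arr.copy())
            out_masks.append(np.ones(arr.shape, dtype=bool))
            continue
        mask_i = None if masks is None else masks[i]
        try:
            fld = register_pair_elastic(
                ref, arr, grid_spacing, lam, max_displacement, mask_i
            )
        except RegistrationError as exc:
            raise RegistrationError(str(exc), frame_index=i + 1) from exc
        warped, valid = resample(arr, None, fld)
        before = mse(arr, ref, mask_i)
        after = mse(warped, ref, valid if mask_i is None else valid & mask_i)
        if after > before:
            fld = DeformationField.zero(arr.shape, grid_spacing)
            warped, valid = arr.copy(), np.ones(arr.shape, dtype=bool)
        fields.append(fld)
        out_images.append(warped)
        out_masks.append(valid)
    return fields, out_images, out_masks


# ---------------------------------------------------------------------------
# full chain

def register_stack(
    stack: Sequence[EnFaceImage],
    reference_index: int = 1,
    grid_spacing: float = 32.0,
    lam: float = 0.1,
    elastic: bool = True,
    bounds: dict | None = None,
) -> RegisteredStack:
    """Linear then elastic alignment; final images resampled once from the
    originals through the composed mapping ``T(p + D(p))``."""
    arrays = [_as_array(im) for im in stack]
    transforms, lin_images, lin_masks = register_linear(
        stack, reference_index, bounds=bounds
    )
    if elastic:
        fields, _, _ = register_elastic(
            lin_images, reference_index, grid_spacing, lam, masks=lin_masks
        )
    else:
        fields = [DeformationField.zero(arrays[0].shape, grid_spacing) for _ in arrays]

    images, frame_masks = [], []
    for i, arr in enumerate(arrays):
        if i == reference_index - 1:
            images.append(arr.copy())
            frame_masks.append(np.ones(arr.shape, dtype=bool))
            continue
        warped, valid = resample(arr, transforms[i], fields[i])
        images.append(warped)
        frame_masks.append(valid)
    validity = np.logical_and.reduce(frame_masks)
    out = []
    for im, arr in zip(stack, images):
        if isinstance(im, EnFaceImage):
            out.append(im.with_pixels(arr))
        else:
            out.append(EnFaceImage(pixels=arr))
    return RegisteredStack(
        images=out,
        transforms=transforms,
        fields=fields,
        frame_masks=frame_masks,
        validity_mask=validity,
        reference_index=reference_index,
    )
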