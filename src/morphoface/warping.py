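"""Thin-plate-spline interpolation and image registration to the mean shape.

The thin-plate spline (TPS) with kernel U(r) = r^2 log r^2 is the unique
interpolant between two landmark sets minimizing the integrated squared
second derivatives ("bending energy").  Images are registered to the sample
mean shape by *backward* mapping: a TPS is fitted from the mean-shape frame to
the specimen's image landmarks, evaluated at every output pixel center, and
the source image is sampled bilinearly.  The registered images, all holding
the mean shape, form the texture data block of the analysis.

Landmark coordinates follow the TPS-file convention (y increasing upward);
the single flip to image row indices (row = H - 1 - y) happens inside the
sampling routines and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """TPS radial kernel U(r) = r^2 log r^2, with U(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz] ** 2)
    return out


@dataclass
class TpsTransform:
    """A fitted 2D thin-plate-spline mapping source landmarks to targets."""

    source: np.ndarray  # (k, 2)
    affine: np.ndarray  # (3, 2): row 0 constant, rows 1-2 linear
    weights: np.ndarray  # (k, 2) nonaffine coefficients
    regularization: float = 0.0

    @property
    def bending_energy(self) -> float:
        """w^T K w summed over the two coordinates (proportional to the TPS
        integral of squared second derivatives)."""
        r = np.sqrt(((self.source[:, None, :] - self.source[None, :, :]) ** 2).sum(axis=2))
        K = tps_kernel(r)
        return float(
            self.weights[:, 0] @ K @ self.weights[:, 0]
            + self.weights[:, 1] @ K @ self.weights[:, 1]
        )


def fit_tps(source: np.ndarray, target: np.ndarray, regularization: float = 0.0) -> TpsTransform:
    """Fit the TPS interpolating ``source`` onto ``target``.

    With ``regularization`` 0 the transform maps each source landmark exactly
    onto its target.  Coincident source points or a collinear source
    configuration make the bordered system singular and raise.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 2 or S.shape[0] < 3:
        raise ValueError("source and target must be matching (k>=3, 2) arrays")
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    k = S.shape[0]
    r2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
    if np.any(r2[~np.eye(k, dtype=bool)] == 0.0):
        raise ValueError("coincident source landmarks: singular TPS system")
    K = tps_kernel(np.sqrt(r2)) + regularization * np.eye(k)
    P = np.column_stack([np.ones(k), S])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = T
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular TPS system (collinear source landmarks?)") from e
    return TpsTransform(source=S, affine=sol[k:], weights=sol[:k], regularization=regularization)


def apply_tps(t: TpsTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at an (m, 2) set of points."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.sqrt(((P[:, None, :] - t.source[None, :, :]) ** 2).sum(axis=2))
    U = tps_kernel(r)
    out = np.column_stack([np.ones(P.shape[0]), P]) @ t.affine + U @ t.weights
    return out


def fit_similarity(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares similarity (rotation+scale matrix A, translation t)
    mapping source points onto target points, without reflection."""
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    sc = S - S.mean(axis=0)
    tc = T - T.mean(axis=0)
    # parametrize x' = a x - b y, y' = b x + a y
    denom = (sc**2).sum()
    a = (sc * tc).sum() / denom
    b = (sc[:, 0] * tc[:, 1] - sc[:, 1] * tc[:, 0]).sum() / denom
    A = np.array([[a, b], [-b, a]])  # row-vector convention: p @ A
    t = T.mean(axis=0) - S.mean(axis=0) @ A
    return A, t


@dataclass
class MeanFrame:
    """The mean shape placed at a fixed position inside an H x W raster frame.

    ``landmarks`` are the placed mean-shape landmarks in frame coordinates
    (x = column, y increasing upward); ``scale``/``offset`` record the
    placement so that other shapes (reconstructions) can be placed in the
    identical way.  Eight border pseudo-landmarks (frame corners and edge
    midpoints) stabilize the TPS extrapolation outside the landmark hull.
    """

    height: int
    width: int
    landmarks: np.ndarray
    scale: float
    offset: np.ndarray
    border_points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w, h = self.width - 1.0, self.height - 1.0
        self.border_points = np.array(
            [
                [0.0, 0.0], [w / 2, 0.0], [w, 0.0],
                [0.0, h / 2], [w, h / 2],
                [0.0, h], [w / 2, h], [w, h],
            ]
        )

    def place(self, shape: np.ndarray) -> np.ndarray:
        """Place a shape (same units as the mean shape used at construction)
        into this frame with the frame's own scale and offset."""
        return np.asarray(shape, dtype=float) * self.scale + self.offset


def build_mean_frame(mean_shape: np.ndarray, height: int = 256, width: int = 256,
                     margin: float = 0.10) -> MeanFrame:
    """Scale and center the mean shape into an H x W frame with a relative margin."""
    m = np.asarray(mean_shape, dtype=float)
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError("degenerate mean shape")
    usable = np.array([(width - 1) * (1 - 2 * margin), (height - 1) * (1 - 2 * margin)])
    scale = float(np.min(usable / extent))
    center_shape = (lo + hi) / 2
    center_frame = np.array([(width - 1) / 2.0, (height - 1) / 2.0])
    offset = center_frame - center_shape * scale
    return MeanFrame(height=height, width=width, landmarks=m * scale + offset,
                     scale=scale, offset=offset)


@dataclass
class RegisteredTexture:
    """An RGB image resampled onto the mean-shape frame.

    The flattened view (pixel-major, R,G,B within each pixel) is one row of
    the texture data matrix; the vectorization order is identical for every
    specimen registered to the same frame.
    """

    frame: MeanFrame
    channels: np.ndarray  # (H, W, 3) in [0, 1]
    mask: np.ndarray | None = None  # (H, W) True where source sample in bounds

    @property
    def vector(self) -> np.ndarray:
        return self.channels.reshape(-1)

    @classmethod
    def from_vector(cls, vec: np.ndarray, frame: MeanFrame) -> "RegisteredTexture":
        ch = np.asarray(vec, dtype=float).reshape(frame.height, frame.width, 3)
        return cls(frame=frame, channels=ch)


def _sample_bilinear(image: np.ndarray, xy_tps: np.ndarray, out_shape: tuple[int, int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sample an (H, W, 3) image at TPS-convention coordinates (x, y-up).

    Returns the sampled (h, w, 3) block and an in-bounds mask.  Out-of-bounds
    samples take the boundary-clamped value (``mode='nearest'``).
    """
    H, W = image.shape[:2]
    cols = xy_tps[:, 0]
    rows = (H - 1) - xy_tps[:, 1]  # the one documented y flip
    inb = (cols >= 0) & (cols <= W - 1) & (rows >= 0) & (rows <= H - 1)
    out = np.empty((xy_tps.shape[0], 3))
    coords = np.vstack([rows, cols])
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(image[:, :, c], coords, order=1, mode="nearest")
    h, w = out_shape
    return out.reshape(h, w, 3), inb.reshape(h, w)


def _frame_pixel_centers(frame: MeanFrame) -> np.ndarray:
    """(H*W, 2) TPS-convention coordinates of the frame's pixel centers,
    in row-major pixel order (matching the texture vectorization)."""
    cols, rows = np.meshgrid(np.arange(frame.width), np.arange(frame.height))
    x = cols.ravel().astype(float)
    y = (frame.height - 1) - rows.ravel().astype(float)
    return np.column_stack([x, y])


def register_image(image: np.ndarray, landmarks: np.ndarray, mean_frame: MeanFrame,
                   regularization: float = 0.0) -> RegisteredTexture:
    """Warp a specimen photograph onto the mean-shape frame.

    Fits a TPS from the frame landmarks to the specimen's image landmarks
    (both augmented with border pseudo-landmarks; the image-side border points
    come from the least-squares similarity fit of frame to image landmarks),
    evaluates it at every frame pixel center, and samples the photograph
    bilinearly.  Pixels whose source sample fell outside the photograph are
    boundary-clamped and flagged in the mask.
    """
    img = np.asarray(image, dtype=float)
    lm = np.asarray(landmarks, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    if lm.shape != mean_frame.landmarks.shape:
        raise ValueError("landmark count does not match the mean frame")
    A, t = fit_similarity(mean_frame.landmarks, lm)
    border_img = mean_frame.border_points @ A + t
    src = np.vstack([mean_frame.landmarks, mean_frame.border_points])
    dst = np.vstack([lm, border_img])
    transform = fit_tps(src, dst, regularization=regularization)
    mapped = apply_tps(transform, _frame_pixel_centers(mean_frame))
    channels, mask = _sample_bilinear(img, mapped, (mean_frame.height, mean_frame.width))
    return RegisteredTexture(frame=mean_frame, channels=np.clip(channels, 0.0, 1.0), mask=mask)


def mean_texture(textures: list[RegisteredTexture]) -> RegisteredTexture:
    """Per-pixel, per-channel arithmetic mean of registered textures."""
    if not textures:
        raise ValueError("empty texture list")
    frame = textures[0].frame
    for tex in textures:
        if tex.channels.shape != textures[0].channels.shape:
            raise ValueError("texture grid mismatch")
    stack = np.stack([tex.channels for tex in textures])
    mask = None
    if all(tex.mask is not None for tex in textures):
        mask = np.logical_and.reduce([tex.mask for tex in textures])
    return RegisteredTexture(frame=frame, channels=stack.mean(axis=0), mask=mask)


def render_shape(texture: RegisteredTexture, mean_frame: MeanFrame,
                 target_shape: np.ndarray) -> np.ndarray:
    """Deform a mean-frame texture into a target shape (forward visualization).

    The target shape (same landmark count and units as the mean shape) is
    placed into the frame with the frame's own placement; a TPS is fitted
    from the placed target back to the mean-frame landmarks (backward
    mapping) and the texture sampled bilinearly.  Returns an (H, W, 3) image.
    """
    tgt = np.asarray(target_shape, dtype=float)
    if tgt.shape != mean_frame.landmarks.shape:
        raise ValueError("target shape has wrong landmark count")
    placed = mean_frame.place(tgt)
    src = np.vstack([placed, mean_frame.border_points])
    dst = np.vstack([mean_frame.landmarks, mean_frame.border_points])
    transform = fit_tps(src, dst)
    mapped = apply_tps(transform, _frame_pixel_centers(mean_frame))
    out, _ = _sample_bilinear(texture.channels, mapped, (mean_frame.height, mean_frame.width))
    return np.clip(out, 0.0, 1.0)
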