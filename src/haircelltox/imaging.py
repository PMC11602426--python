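"""Pre-segmentation image corrections.

Rigid alignment (frame-to-frame for time lapses, slice-to-slice for
z-stacks), rolling-ball background subtraction, percentile intensity
normalization and maximum projection.  Alignment is estimated on a single
named channel and the identical transform is applied to every channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .io import VoxelStack

__all__ = [
    "RigidTransform2D",
    "estimate_rigid",
    "register_rigid",
    "rolling_ball_subtract",
    "normalize_intensity",
    "max_project",
    "transforms_to_frame",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotation about the image centre, then shift.

    The forward map in (y, x) pixel coordinates relative to the image
    centre ``c`` is ``p -> R(theta) (p - c) + c + s`` with ``s = shift_px``.
    """

    rotation_deg: float = 0.0
    shift_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx)

    @property
    def _matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def then(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Composite transform equivalent to applying ``self`` first, then ``other``."""
        rot = self.rotation_deg + other.rotation_deg
        s = other._matrix @ np.asarray(self.shift_px) + np.asarray(other.shift_px)
        return RigidTransform2D(rot, (float(s[0]), float(s[1])))

    def invert(self) -> "RigidTransform2D":
        s = -self._matrix.T @ np.asarray(self.shift_px)
        return RigidTransform2D(-self.rotation_deg, (float(s[0]), float(s[1])))

    @property
    def magnitude_px(self) -> float:
        return float(np.hypot(*self.shift_px))

    def apply(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Resample a 2-D image under the forward map (bilinear by default)."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("RigidTransform2D.apply expects a 2-D image")
        if abs(self.rotation_deg) < 1e-12:
            return ndi.shift(image, self.shift_px, order=order, cval=cval)
        centre = (np.array(image.shape) - 1) / 2.0
        rinv = self._matrix.T
        offset = centre - rinv @ (centre + np.asarray(self.shift_px))
        return ndi.affine_transform(image, rinv, offset=offset, order=order, cval=cval)

    def valid_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Pixels that map from inside the source field (True = valid)."""
        return self.apply(np.ones(shape), order=1) > 0.5


def estimate_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    refine_rotation: bool = True,
    upsample_factor: int = 50,
    max_rotation_deg: float = 10.0,
) -> RigidTransform2D:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Translation by sub-pixel phase correlation; rotation (when enabled)
    by a deterministic coarse-to-fine angle search (0.5 deg grid within
    ``max_rotation_deg``, refined to 0.05 deg), with the shift
    re-estimated by phase correlation at each candidate angle and the
    best candidate chosen by masked mean-squared intensity difference.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)

    def shift_and_cost(angle: float) -> tuple[RigidTransform2D, float]:
        rotated = RigidTransform2D(angle, (0.0, 0.0)).apply(moving) if angle else moving
        shift, _, _ = phase_cross_correlation(
            reference, rotated, upsample_factor=upsample_factor, normalization=None
        )
        tr = RigidTransform2D(angle, (float(shift[0]), float(shift[1])))
        warped = tr.apply(moving)
        valid = tr.valid_mask(moving.shape)
        if valid.sum() < 0.25 * valid.size:
            return tr, np.inf
        return tr, float(np.mean((warped[valid] - reference[valid]) ** 2))

    best_tr, best_cost = shift_and_cost(0.0)
    if not refine_rotation:
        return best_tr
    coarse = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 0.5)
    for angle in coarse:
        tr, cost = shift_and_cost(float(angle))
        if cost < best_cost:
            best_tr, best_cost = tr, cost
    for angle in best_tr.rotation_deg + np.arange(-0.45, 0.46, 0.05):
        tr, cost = shift_and_cost(float(angle))
        if cost < best_cost:
            best_tr, best_cost = tr, cost
    return best_tr


def register_rigid(
    stack: VoxelStack,
    channel: str,
    refine_rotation: bool = True,
    max_shift_warn_frac: float = 0.5,
) -> tuple[VoxelStack, list[RigidTransform2D]]:
    """Align a stack rigidly with "previous" as reference.

    Time-lapse stacks (>=2 frames) are aligned frame-to-frame on the
    maximum z-projection of the named channel; single-frame z-stacks are
    aligned slice-to-slice.  Per-plane transforms are estimated against the
    previous raw plane and composed cumulatively, then the composed
    transforms are applied identically to every channel.

    A cumulative shift beyond ``max_shift_warn_frac`` of the field half-size
    triggers a warning and flags the plane (transform still applied).

    Returns
    -------
    (aligned_stack, transforms)
        One transform per frame (or per z-slice); ``transforms[0]`` is the
        identity.
    """
    data = stack.data
    time_mode = stack.n_frames >= 2
    if time_mode:
        ref_chan = stack.channel(channel)  # (t, z, y, x)
        planes = ref_chan.max(axis=1) if ref_chan.shape[1] > 1 else ref_chan[:, 0]
    else:
        planes = stack.channel(channel)  # (z, y, x)
        if planes.shape[0] < 2:
            raise ValueError("need >=2 frames or >=2 z-slices to register")

    n_planes = planes.shape[0]
    field = min(planes.shape[-2:])
    transforms: list[RigidTransform2D] = [RigidTransform2D()]
    for i in range(1, n_planes):
        step = estimate_rigid(planes[i - 1], planes[i], refine_rotation=refine_rotation)
        cum = step.then(transforms[i - 1])
        if cum.magnitude_px > max_shift_warn_frac * field / 2:
            warnings.warn(
                f"plane {i}: estimated displacement {cum.magnitude_px:.1f} px exceeds "
                f"half the field; flagging",
                stacklevel=2,
            )
        transforms.append(cum)

    aligned = np.array(data, dtype=float, copy=True)
    if time_mode:
        for t in range(1, stack.n_frames):
            tr = transforms[t]
            for c in range(stack.n_channels):
                for z in range(data.shape[2]):
                    aligned[t, c, z] = tr.apply(data[t, c, z])
    else:
        for z in range(1, data.shape[2]):
            tr = transforms[z]
            for c in range(stack.n_channels):
                aligned[0, c, z] = tr.apply(data[0, c, z])
    return stack.with_data(aligned), transforms


def transforms_to_frame(transforms: list[RigidTransform2D]) -> pd.DataFrame:
    """Serialize a transform list as a table (frame, rotation_deg, dy, dx)."""
    return pd.DataFrame(
        {
            "frame": np.arange(len(transforms)),
            "rotation_deg": [t.rotation_deg for t in transforms],
            "dy": [t.shift_px[0] for t in transforms],
            "dx": [t.shift_px[1] for t in transforms],
        }
    )


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 10) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is estimated by grey-scale morphological opening with a
    flat disk footprint of the given radius (applied slice-wise on 3-D
    input) and subtracted.  The operation is anti-extensive: the output is
    everywhere <= the input and a flat image maps to zero exactly.
    """
    image = np.asarray(image, dtype=float)
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if 2 * radius_px + 1 > min(image.shape[-2:]) or radius_px >= min(image.shape[-2:]):
        raise ValueError("rolling-ball radius must be smaller than the image plane")
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    footprint = (yy**2 + xx**2) <= radius_px**2

    def _open2d(plane: np.ndarray) -> np.ndarray:
        # edge-replicate padding so the opening is exact up to the border
        # (monotone backgrounds stay fully removable at the image edge)
        padded = np.pad(plane, radius_px, mode="edge")
        opened = ndi.grey_opening(padded, footprint=footprint)
        return opened[radius_px:-radius_px, radius_px:-radius_px]

    if image.ndim == 2:
        return image - _open2d(image)
    if image.ndim == 3:
        out = np.empty_like(image)
        for z in range(image.shape[0]):
            out[z] = image[z] - _open2d(image[z])
        return out
    raise ValueError("expected a 2-D image or a 3-D (z, y, x) stack")


def normalize_intensity(
    data: np.ndarray, clip: tuple[float, float] = (0.0, 100.0)
) -> np.ndarray:
    """Scale intensities to [0, 1] after percentile clipping.

    ``clip`` gives the (low, high) percentiles mapped to 0 and 1; values
    outside saturate.  The map is monotone on the unclipped range and
    idempotent on already-[0, 1] data with ``clip=(0, 100)``.
    """
    data = np.asarray(data, dtype=float)
    lo_p, hi_p = clip
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
    lo = np.percentile(data, lo_p)
    hi = np.percentile(data, hi_p)
    if hi <= lo:
        raise ValueError("cannot normalize a (near-)constant image")
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def max_project(data: VoxelStack | np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection.

    For a :class:`VoxelStack` the projection collapses z and returns an
    array of shape ``(t, c, y, x)``; for a bare array it is ``max`` over
    ``axis``.
    """
    if isinstance(data, VoxelStack):
        return data.data.max(axis=2)
    return np.asarray(data).max(axis=axis)
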