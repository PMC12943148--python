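"""Volume assembly, trilinear resampling, and ray-cast rendering.

Beamformed slices acquired at uniform z steps are stacked into a voxel
volume; voxel (i, j, k) sits at the world position

    X_ijk = IPP_k + i * dr * r + j * dc * c,      IPP_k = IPP_0 + k * dz * z_hat

with r, c the orthonormal row/column direction vectors and dr, dc the
in-plane pixel spacings. Values between voxels are estimated by trilinear
interpolation (the weights form a partition of unity, so affine fields are
reproduced exactly), which also drives resampling to isotropic voxels and
sampling along rendering rays. Rendering is discrete front-to-back alpha
compositing of opacity-weighted voxel values:

    I = sum_t T_t * alpha(v_t) * v_t,   T_t = prod_{s<t} (1 - alpha(v_s)),

the discretization of emission-absorption ray casting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SliceGeometry",
    "Volume",
    "TransferFunction",
    "stack_slices",
    "voxel_position",
    "trilinear_sample",
    "resample_isotropic",
    "ray_cast",
    "project",
]

_PLANE_AXIS = {"axial": 0, "sagittal": 1, "coronal": 2}


@dataclass(frozen=True)
class SliceGeometry:
    """Placement of a stack of 2D slices in 3D space (lengths in mm)."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # IPP of slice 0
    row_dir: tuple[float, float, float] = (0.0, 1.0, 0.0)
    col_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    row_spacing: float = 1.0
    col_spacing: float = 1.0
    slice_step: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.row_dir, dtype=float)
        c = np.asarray(self.col_dir, dtype=float)
        if abs(np.linalg.norm(r) - 1) > 1e-9 or abs(np.linalg.norm(c) - 1) > 1e-9:
            raise ValueError("row_dir and col_dir must be unit vectors")
        if abs(float(r @ c)) > 1e-9:
            raise ValueError("row_dir and col_dir must be orthogonal")
        if min(self.row_spacing, self.col_spacing, self.slice_step) <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class Volume:
    """Voxel array V(i, j, k) with spacing and origin (axis order row, col, slice)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def voxel_position(geometry: SliceGeometry, i, j, k) -> np.ndarray:
    """World position of voxel (i, j, k); slices stack along +z."""
    ipp0 = np.asarray(geometry.origin, dtype=float)
    r = np.asarray(geometry.row_dir, dtype=float)
    c = np.asarray(geometry.col_dir, dtype=float)
    zhat = np.array([0.0, 0.0, 1.0])
    i, j, k = np.asarray(i, float), np.asarray(j, float), np.asarray(k, float)
    return (
        ipp0
        + np.multiply.outer(i * geometry.row_spacing, r)
        + np.multiply.outer(j * geometry.col_spacing, c)
        + np.multiply.outer(k * geometry.slice_step, zhat)
    )


def stack_slices(images, geometry: SliceGeometry) -> Volume:
    """Stack same-shape 2D slices into a Volume along the slice axis."""
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) < 1:
        raise ValueError("need at least one slice")
    shape = images[0].shape
    for idx, im in enumerate(images):
        if im.shape != shape:
            raise ValueError(f"slice {idx} has shape {im.shape}, expected {shape}")
    data = np.stack(images, axis=-1)
    return Volume(
        data,
        spacing=(geometry.row_spacing, geometry.col_spacing, geometry.slice_step),
        origin=tuple(np.asarray(geometry.origin, dtype=float)),
    )


def trilinear_sample(volume: Volume, point) -> np.ndarray | float:
    """Trilinearly interpolated value(s) at continuous index coordinates.

    ``point`` is (x, y, z) in voxel-index units (or an (..., 3) array); every
    coordinate must lie within [0, dim - 1] — no extrapolation.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    dims = np.array(volume.shape)
    if np.any(pts < -1e-12) or np.any(pts > dims - 1 + 1e-12):
        raise ValueError("sample point outside the volume (no extrapolation)")
    pts = np.clip(pts, 0.0, dims - 1)
    base = np.maximum(np.minimum(np.floor(pts).astype(int), dims - 2), 0)
    frac = pts - base
    v = volume.data
    out = np.zeros(pts.shape[:-1])
    for a in (0, 1):
        wa = frac[..., 0] if a else 1.0 - frac[..., 0]
        ia = np.minimum(base[..., 0] + a, dims[0] - 1)  # size-1 axes fold back
        for b in (0, 1):
            wb = frac[..., 1] if b else 1.0 - frac[..., 1]
            ib = np.minimum(base[..., 1] + b, dims[1] - 1)
            for c in (0, 1):
                wc = frac[..., 2] if c else 1.0 - frac[..., 2]
                ic = np.minimum(base[..., 2] + c, dims[2] - 1)
                out += wa * wb * wc * v[ia, ib, ic]
    return float(out[0]) if scalar else out


def resample_isotropic(volume: Volume, target_voxel: float) -> Volume:
    """Resample onto an isotropic lattice of ``target_voxel`` mm via trilinear interpolation."""
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    dims = np.array(volume.shape)
    spacing = np.asarray(volume.spacing, dtype=float)
    extent = (dims - 1) * spacing
    new_dims = np.floor(extent / target_voxel + 1e-9).astype(int) + 1
    axes = [np.arange(nd) * target_voxel / sp for nd, sp in zip(new_dims, spacing)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1)
    data = trilinear_sample(volume, pts)
    return Volume(data, spacing=(target_voxel,) * 3, origin=volume.origin)


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise-linear opacity over normalized intensity; identity value map."""

    opacity_points: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 1.0))

    def __post_init__(self) -> None:
        pts = np.asarray(self.opacity_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
            raise ValueError("opacity_points must be a sequence of (value, alpha) pairs")
        if np.any(np.diff(pts[:, 0]) < 0):
            raise ValueError("opacity breakpoints must be sorted by value")
        if np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > 1):
            raise ValueError("opacities must lie in [0, 1]")

    @classmethod
    def constant(cls, alpha: float) -> "TransferFunction":
        return cls(((0.0, alpha), (1.0, alpha)))

    def opacity(self, v: np.ndarray) -> np.ndarray:
        pts = np.asarray(self.opacity_points, dtype=float)
        return np.interp(v, pts[:, 0], pts[:, 1])


def ray_cast(
    volume: Volume,
    tf: TransferFunction | None = None,
    view: str = "+z",
    step: float | None = None,
) -> np.ndarray:
    """Front-to-back alpha compositing along an axis-aligned view direction.

    ``view`` is one of +x/-x/+y/-y/+z/-z (bare axis letters mean +). ``step``
    is the sampling interval along the ray in mm (default: half the smallest
    voxel spacing). Volume intensities are normalized to [0, 1] by the global
    maximum before the transfer-function lookup; the value term is the
    normalized intensity itself.
    """
    if tf is None:
        tf = TransferFunction()
    view = view if view[0] in "+-" else "+" + view
    sign, axis_name = view[0], view[1]
    if axis_name not in "xyz" or sign not in "+-":
        raise ValueError(f"invalid view {view!r}")
    axis = {"y": 0, "x": 1, "z": 2}[axis_name]  # rows ~ y, cols ~ x, slices ~ z
    if step is None:
        step = min(volume.spacing) / 2.0
    if step <= 0:
        raise ValueError("step must be positive")

    peak = volume.data.max()
    norm = volume.data / peak if peak > 0 else volume.data
    nvol = Volume(norm, volume.spacing, volume.origin)

    dim = volume.shape[axis]
    sp = volume.spacing[axis]
    n_steps = int(np.floor((dim - 1) * sp / step + 1e-9)) + 1
    coords = np.arange(n_steps) * step / sp
    if sign == "-":
        coords = (dim - 1) - coords

    other = [a for a in range(3) if a != axis]
    grids = np.meshgrid(
        np.arange(volume.shape[other[0]]), np.arange(volume.shape[other[1]]), indexing="ij"
    )
    out = np.zeros(grids[0].shape)
    transmittance = np.ones(grids[0].shape)
    pt = np.zeros(grids[0].shape + (3,))
    pt[..., other[0]] = grids[0]
    pt[..., other[1]] = grids[1]
    for t in coords:
        pt[..., axis] = t
        v = trilinear_sample(nvol, pt)
        a = tf.opacity(v)
        out += transmittance * a * v
        transmittance *= 1.0 - a
    return out


def project(volume: Volume, plane: str, mode: str = "max") -> np.ndarray:
    """Axis-aligned projection: max or mean along the axis the plane discards.

    Slices stack along z, so ``coronal`` collapses the slice axis (cylinder
    cross-sections), ``sagittal`` the column axis, and ``axial`` the row axis.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    axis = _PLANE_AXIS[plane]
    if mode == "max":
        return volume.data.max(axis=axis)
    if mode == "mean":
        return volume.data.mean(axis=axis)
    raise ValueError(f"mode must be 'max' or 'mean', got {mode!r}")
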