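"""Synthetic vertebral microCT phantom generator.

Real zero-strain studies image a vertebral body twice on a microCT
scanner; those scans are not generally redistributable, so this module
builds seeded stand-ins with known ground truth:

* an elliptic-cylinder vertebral *body* filled with a trabecular network
  (Gaussian-smoothed white noise thresholded at the quantile that yields
  a requested bone volume fraction),
* an optional cortical *shell* (a dense boundary layer of the body),
* *lytic* lesions (spherical regions where trabecular bone is resorbed
  to marrow grey) and *blastic* lesions (spherical regions of dense,
  almost texture-free bone),
* marrow background, small near-air bubbles, and additive Gaussian
  scanner noise.

A repeat scan with jig repositioning is emulated by rigidly resampling
the noiseless phantom and adding fresh independent noise; purely virtual
affine deformations are available for validating the strain pipeline
against an analytic displacement field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, GreyVolume, DEFAULT_VOXEL_SIZE_UM


@dataclass
class LesionSpec:
    """A spherical lesion: ``kind`` is ``"lytic"`` or ``"blastic"``."""

    kind: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.kind not in ("lytic", "blastic"):
            raise ValueError(f"lesion kind must be 'lytic' or 'blastic', got {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic vertebral phantom.

    Greyscale defaults put air at 0, marrow at 60 and bone at 160 on an
    arbitrary 8-bit-like scale; ``noise_sd`` defaults to 8, i.e. a
    bone–marrow contrast-to-noise ratio of ~12, a realistic figure for
    in vivo-grade microCT at 39 μm.  ``mean_struct_thickness`` of 5
    voxels corresponds to ~195 μm trabeculae at the default voxel size,
    in the range reported for human vertebral bodies.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    target_bvtv: float = 0.15
    mean_struct_thickness: float = 5.0
    shell_thickness: int = 3
    grey_bone: float = 160.0
    grey_marrow: float = 60.0
    grey_air: float = 0.0
    noise_sd: float = 8.0
    n_bubbles: int = 0
    lesions: list[LesionSpec] = dataclass_field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3 or any(s < 32 for s in self.shape):
            raise ValueError(f"shape must be 3 ints, each >= 32; got {self.shape}")
        if not 0.0 < self.target_bvtv < 1.0:
            raise ValueError(f"target_bvtv must be in (0, 1), got {self.target_bvtv}")
        if not self.grey_air < self.grey_marrow < self.grey_bone:
            raise ValueError("require grey_air < grey_marrow < grey_bone")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mean_struct_thickness <= 0:
            raise ValueError("mean_struct_thickness must be positive")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows exactly about a phantom."""

    bone_mask: BinaryMask
    body_mask: BinaryMask
    nocort_mask: BinaryMask
    lesion_masks: list[BinaryMask] = dataclass_field(default_factory=list)
    motion: dict | None = None
    true_displacement: "object | None" = None  # callable (N,3)->(N,3), voxels

    def __post_init__(self) -> None:
        shape = self.body_mask.shape
        for m in (self.bone_mask, self.nocort_mask, *self.lesion_masks):
            if m.shape != shape:
                raise ValueError("all ground-truth masks must share one shape")
        if np.any(self.bone_mask.data & ~self.body_mask.data):
            raise ValueError("bone_mask must be contained in body_mask")
        if np.any(self.nocort_mask.data & ~self.body_mask.data):
            raise ValueError("nocort_mask must be contained in body_mask")


def _elliptic_cylinder(shape: tuple[int, int, int]) -> np.ndarray:
    """Vertebral-body surrogate: an elliptic cylinder along z.

    Distinct in-plane semi-axes keep the inertia tensor non-degenerate so
    principal-axis rigid alignment is well posed.
    """
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :, None] - (ny - 1) / 2.0
    a, b = 0.42 * nx, 0.34 * ny
    body2d = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    body = np.broadcast_to(body2d, (nx, ny, nz)).copy()
    # leave two empty end slices so small rigid motions stay in-field
    body[:, :, :2] = False
    body[:, :, nz - 2:] = False
    return body


def _ball_mask(shape, center, radius) -> np.ndarray:
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None] - center[0]
    y = np.arange(ny)[None, :, None] - center[1]
    z = np.arange(nz)[None, None, :] - center[2]
    return x * x + y * y + z * z <= radius * radius


def generate_phantom(spec: PhantomSpec) -> tuple[GreyVolume, GroundTruth]:
    """Build a phantom and its exact ground truth, reproducibly from the seed.

    The trabecular network is white noise smoothed with a Gaussian of
    sigma = ``mean_struct_thickness / 2`` voxels and thresholded at the
    quantile giving the requested bone fraction inside the trabecular VOI
    (body minus shell).  An explicit error is raised if the realized
    fraction misses the target by more than 0.02 absolute.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    body = _elliptic_cylinder(shape)
    if spec.shell_thickness > 0:
        interior = ndimage.binary_erosion(body, iterations=spec.shell_thickness)
    else:
        interior = body
    nocort = interior
    shell = body & ~interior

    # trabecular texture: smoothed white noise, quantile-thresholded
    sigma = spec.mean_struct_thickness / 2.0
    noise_field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    inside = noise_field[nocort]
    thr = np.quantile(inside, 1.0 - spec.target_bvtv)
    trab = (noise_field >= thr) & nocort
    realized = trab.sum() / nocort.sum()
    if abs(realized - spec.target_bvtv) > 0.02:
        raise ValueError(
            f"could not realize target BV/TV {spec.target_bvtv:.3f}: achieved "
            f"{realized:.3f} (structure thickness {spec.mean_struct_thickness} voxels)"
        )

    bone = trab | shell
    lesion_masks: list[BinaryMask] = []
    blastic_regions = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        sphere = _ball_mask(shape, les.center, les.radius)
        if not np.any(sphere & nocort):
            raise ValueError(f"lesion at {les.center} does not intersect the body interior")
        if les.kind == "lytic":
            bone &= ~(sphere & nocort)
        else:  # blastic: dense, near-uniform bone
            region = sphere & nocort
            bone |= region
            blastic_regions |= region
        lesion_masks.append(BinaryMask(sphere & nocort, role=les.kind))

    grey = np.full(shape, spec.grey_air, dtype=np.float64)
    grey[body] = spec.grey_marrow
    grey[bone] = spec.grey_bone
    # blastic tissue: almost texture-free; internal texture well below noise
    if np.any(blastic_regions):
        grey[blastic_regions] = spec.grey_bone + 0.1 * spec.noise_sd * rng.standard_normal(
            int(blastic_regions.sum())
        )

    # air bubbles: small ellipsoids in the marrow space
    marrow_space = nocort & ~bone
    if spec.n_bubbles > 0:
        coords = np.argwhere(ndimage.binary_erosion(marrow_space, iterations=3))
        if len(coords) == 0:
            raise ValueError("no marrow space available for air bubbles")
        picks = coords[rng.choice(len(coords), size=spec.n_bubbles, replace=False)]
        for c in picks:
            radii = rng.uniform(1.5, 3.0, size=3)
            nx, ny, nz = shape
            dx = (np.arange(nx)[:, None, None] - c[0]) / radii[0]
            dy = (np.arange(ny)[None, :, None] - c[1]) / radii[1]
            dz = (np.arange(nz)[None, None, :] - c[2]) / radii[2]
            bubble = (dx * dx + dy * dy + dz * dz <= 1.0) & marrow_space
            grey[bubble] = spec.grey_air + np.abs(
                rng.normal(0.0, 2.0, size=int(bubble.sum()))
            )

    if spec.noise_sd > 0:
        grey += rng.normal(0.0, spec.noise_sd, size=shape)

    truth = GroundTruth(
        bone_mask=BinaryMask(bone, role="bone"),
        body_mask=BinaryMask(body, role="body"),
        nocort_mask=BinaryMask(nocort, role="nocort"),
        lesion_masks=lesion_masks,
    )
    return GreyVolume(grey, spec.voxel_size), truth


def _rotation_matrix(rotation_deg: tuple[float, float, float]) -> np.ndarray:
    """Intrinsic rotations about x, then y, then z (degrees)."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def simulate_repeat_scan(
    vol: GreyVolume,
    truth: GroundTruth,
    rigid: dict | None = None,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> GreyVolume:
    """Emulate the second scan of a zero-strain repeat-scan pair.

    ``rigid`` is ``{"translation": (tx, ty, tz) voxels, "rotation":
    (rx, ry, rz) degrees}`` applied about the volume centre (the jig
    repositioning); fresh zero-mean Gaussian noise of ``noise_sd`` is
    added on top.  The applied transform is recorded in ``truth.motion``.
    Raises if the transform pushes the body mask out of the lattice.
    """
    rigid = rigid or {}
    translation = np.asarray(rigid.get("translation", (0.0, 0.0, 0.0)), dtype=float)
    rotation = tuple(rigid.get("rotation", (0.0, 0.0, 0.0)))
    R = _rotation_matrix(rotation)
    center = (np.asarray(vol.shape) - 1) / 2.0

    identity = np.allclose(translation, 0.0) and np.allclose(R, np.eye(3))
    if identity:
        out = vol.data.astype(np.float64, copy=True)
    else:
        body_pts = np.argwhere(truth.body_mask.data).astype(float)
        moved = (R @ (body_pts - center).T).T + center + translation
        if moved.min() < -0.5 or np.any(moved.max(axis=0) > np.asarray(vol.shape) - 0.5):
            raise ValueError("rigid transform moves the vertebral body outside the lattice")
        # output(y) = input(R^-1 (y - c - t) + c); cubic spline resampling
        Rinv = R.T
        offset = center - Rinv @ (center + translation)
        out = ndimage.affine_transform(
            vol.data.astype(np.float64), Rinv, offset=offset, order=3,
            mode="constant", cval=float(vol.data[~truth.body_mask.data].mean())
            if np.any(~truth.body_mask.data) else 0.0,
        )

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    truth.motion = {
        "type": "rigid",
        "translation_voxels": translation.tolist(),
        "rotation_deg": list(rotation),
        "center_voxels": center.tolist(),
    }
    return GreyVolume(out, vol.voxel_size)


def strain_to_matrix(strain_ue) -> np.ndarray:
    """Six small-strain components (εxx, εyy, εzz, γxy, γyz, γxz in με)
    to a displacement-gradient matrix, engineering shear split
    symmetrically (A_xy = A_yx = γ_xy / 2)."""
    exx, eyy, ezz, gxy, gyz, gxz = (np.asarray(strain_ue, dtype=float) * 1e-6)
    return np.array(
        [
            [exx, gxy / 2.0, gxz / 2.0],
            [gxy / 2.0, eyy, gyz / 2.0],
            [gxz / 2.0, gyz / 2.0, ezz],
        ]
    )


def apply_affine_warp(
    vol: GreyVolume,
    strain_ue,
    translation=(0.0, 0.0, 0.0),
    fill: float | None = None,
):
    """Warp a volume under the affine field u(x) = E·x + t.

    ``strain_ue`` are the six small-strain components in microstrain
    (|each| ≤ 50,000 με); ``translation`` is in voxels.  Returns the
    warped volume and the exact displacement function (voxel coords in,
    voxel displacements out) for scoring recovered fields.
    """
    strain_ue = np.asarray(strain_ue, dtype=float)
    if np.any(np.abs(strain_ue) > 50_000):
        raise ValueError("affine strain components limited to |ε| ≤ 50,000 με")
    E = strain_to_matrix(strain_ue)
    t = np.asarray(translation, dtype=float)
    M = np.eye(3) + E  # map x -> M x + t

    def true_displacement(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ E.T + t

    if np.allclose(E, 0.0) and np.allclose(t, 0.0):
        return vol.copy(), true_displacement

    Minv = np.linalg.inv(M)
    offset = -Minv @ t
    cval = float(np.median(vol.data)) if fill is None else float(fill)
    warped = ndimage.affine_transform(
        vol.data.astype(np.float64), Minv, offset=offset, order=3,
        mode="constant", cval=cval,
    )
    return GreyVolume(warped, vol.voxel_size), true_displacement
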