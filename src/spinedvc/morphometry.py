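"""Trabecular morphometry: BV/TV, St.Th., St.Sp., St.N.

Local thickness follows the sphere-fitting definition: the thickness at
a voxel is the diameter of the largest sphere that fits entirely inside
the structure and contains that voxel.  It is computed with the standard
distance-transform construction (Euclidean distance map → inscribed-
sphere radii → sphere painting in descending radius order), which is
equivalent to brute-force sphere fitting.  Structure separation is the
same quantity on the background inside the VOI, and structure number
uses the model-free 3D convention St.N = (BV/TV) / St.Th.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask


@dataclass
class MorphometryResult:
    """One analysis row: bone fraction and structure metrics with spreads."""

    bvtv: float            # %
    st_th_mean: float      # μm
    st_th_sd: float        # μm
    st_sp_mean: float      # μm
    st_sp_sd: float        # μm
    st_n: float            # 1/mm
    voi_voxels: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.bvtv <= 100.0:
            raise ValueError("BV/TV must be a percentage in [0, 100]")


def compute_bvtv(bone: BinaryMask, voi: BinaryMask) -> float:
    """Bone volume fraction: 100 × |bone ∩ voi| / |voi| (percent)."""
    nv = voi.count()
    if nv == 0:
        raise ValueError("VOI is empty")
    return 100.0 * int((bone.data & voi.data).sum()) / nv


def local_thickness(
    structure: BinaryMask,
    voxel_size: float = 1.0,
    bin_width: float = 0.25,
) -> np.ndarray:
    """Per-voxel local thickness map (μm), zero on background.

    Each foreground voxel q carries an inscribed sphere of radius
    ``EDT(q) - 0.5`` (the sphere reaching the structure boundary, so an
    isolated voxel has diameter 1).  Radii are binned at ``bin_width``
    voxels and painted from the largest down: every voxel takes the
    diameter of the largest sphere covering it.
    """
    fg = structure.data
    if not np.any(fg):
        raise ValueError("structure is empty")
    edt = ndimage.distance_transform_edt(fg)
    radii = np.where(fg, edt - 0.5, 0.0)
    q = np.floor(radii / bin_width + 1e-9) * bin_width  # quantize down

    out = np.zeros(fg.shape)
    for r in np.unique(q[fg])[::-1]:
        centers = (q == r) & fg
        if not centers.any():
            continue
        if r <= 0:
            cover = centers
        else:
            d = ndimage.distance_transform_edt(~centers)
            cover = (d <= r + 1e-9) & fg
        np.maximum(out, np.where(cover, 2.0 * r, 0.0), out=out)
    return out * voxel_size


def _map_stats(thickness_map: np.ndarray, region: np.ndarray) -> tuple[float, float]:
    vals = thickness_map[region]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def compute_structure_thickness(
    bone: BinaryMask, voi: BinaryMask, voxel_size: float
) -> tuple[float, float]:
    """Voxel-weighted mean ± sample SD of bone local thickness in the VOI (μm)."""
    region = bone.data & voi.data
    if not np.any(region):
        raise ValueError("no bone inside VOI")
    tmap = local_thickness(BinaryMask(region), voxel_size)
    return _map_stats(tmap, region)


def compute_structure_separation(
    bone: BinaryMask, voi: BinaryMask, voxel_size: float
) -> tuple[float, float]:
    """Local thickness of the background (voi minus bone), mean ± SD in μm.

    Spheres are bounded by the VOI as well as by bone, so separations are
    truncated at the VOI boundary.
    """
    background = voi.data & ~bone.data
    if not np.any(background):
        raise ValueError("background inside VOI is empty")
    tmap = local_thickness(BinaryMask(background), voxel_size)
    return _map_stats(tmap, background)


def compute_structure_number(bvtv_percent: float, st_th_mean_um: float) -> float:
    """St.N = (BV/TV) / St.Th in 1/mm (model-free 3D convention)."""
    if st_th_mean_um <= 0:
        raise ValueError("structure thickness must be positive")
    return (bvtv_percent / 100.0) / (st_th_mean_um / 1000.0)


def analyze(bone: BinaryMask, voi: BinaryMask, voxel_size: float) -> MorphometryResult:
    """Full morphometry of one VOI."""
    bvtv = compute_bvtv(bone, voi)
    th_mean, th_sd = compute_structure_thickness(bone, voi, voxel_size)
    sp_mean, sp_sd = compute_structure_separation(bone, voi, voxel_size)
    return MorphometryResult(
        bvtv=bvtv,
        st_th_mean=th_mean,
        st_th_sd=th_sd,
        st_sp_mean=sp_mean,
        st_sp_sd=sp_sd,
        st_n=compute_structure_number(bvtv, th_mean),
        voi_voxels=voi.count(),
    )
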