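"""Image conditioning ahead of morphometry and registration.

Covers air-bubble removal, 3D median denoising, Otsu(+5%) bone
segmentation, body-mask construction (Gaussian smoothing + threshold +
hole fill), rigid alignment of repeated scans, and construction of the
merged scan mask and the eroded DVC evaluation VOI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .synth import _rotation_matrix
from .volumes import BinaryMask, GreyVolume

OTSU_CORRECTION = 1.05  # bone threshold = Otsu value raised by 5%


def remove_air_bubbles(
    vol: GreyVolume,
    body: BinaryMask,
    air_cutoff: float,
    marrow_stats: tuple[float, float],
    seed: int = 0,
) -> GreyVolume:
    """Replace near-air voxels inside the body with marrow-like values.

    Bubbles can move between repeated scans, so they must not contribute
    texture to the registration.  Voxels inside ``body`` with grey below
    ``air_cutoff`` are replaced by draws from Normal(marrow mean, marrow
    sd); everything else is untouched.
    """
    mean, sd = marrow_stats
    if sd < 0:
        raise ValueError("marrow sd must be >= 0")
    out = vol.data.astype(np.float64, copy=True)
    target = body.data & (out < air_cutoff)
    n = int(target.sum())
    if n:
        rng = np.random.default_rng(seed)
        out[target] = rng.normal(mean, sd, size=n)
    return GreyVolume(out, vol.voxel_size)


def denoise_median(vol: GreyVolume, support: float = 0.5) -> GreyVolume:
    """3D median filter with isotropic support given as a radius in voxels.

    A radius of 0.5 voxels denotes the smallest symmetric neighbourhood,
    3×3×3 — large enough to suppress single-voxel noise while preserving
    1–2-voxel trabeculae.  Edges are handled by reflection.
    """
    size = 2 * int(np.ceil(support)) + 1
    if size < 3:
        size = 3
    out = ndimage.median_filter(vol.data, size=size, mode="reflect")
    return GreyVolume(out, vol.voxel_size)


def segment_bone(vol: GreyVolume, voi: BinaryMask) -> BinaryMask:
    """Otsu threshold on the VOI histogram, raised by 5%, applied globally.

    The threshold is computed on a 256-bin histogram of the voxels inside
    ``voi`` and multiplied by 1.05 (the correction that best preserves
    trabecular structure on this class of images); the returned mask
    marks voxels ≥ the corrected threshold over the whole lattice.
    """
    if not np.any(voi.data):
        raise ValueError("VOI is empty")
    values = vol.data[voi.data]
    if np.ptp(values) == 0:
        raise ValueError("degenerate histogram: VOI is single-valued, cannot threshold")
    t = threshold_otsu(values, nbins=256) * OTSU_CORRECTION
    return BinaryMask(vol.data >= t, role="bone")


def build_body_mask(
    vol: GreyVolume,
    level: float,
    gaussian_variance: float = 5.0,
    support: int = 7,
) -> BinaryMask:
    """Body mask: Gaussian smooth, single-level threshold, fill, largest CC.

    The Gaussian has variance ``gaussian_variance`` voxel² truncated at
    an isotropic ``support`` of 7 voxels (half-width 3); ``level`` is the
    manually chosen greyscale threshold.  Internal cavities are filled
    and only the largest connected component is kept, yielding a solid
    vertebral-body mask.
    """
    sigma = float(np.sqrt(gaussian_variance))
    halfwidth = (support - 1) / 2.0
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigma, truncate=halfwidth / sigma)
    raw = smoothed >= level
    if not np.any(raw):
        raise ValueError(f"body-mask threshold {level} selects no voxels")
    filled = ndimage.binary_fill_holes(raw)
    labels, nlab = ndimage.label(filled)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        filled = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(filled, role="body")


def _moments(weights: np.ndarray):
    """Intensity centroid and inertia principal axes of a non-negative field."""
    total = weights.sum()
    coords = [np.arange(n, dtype=float) for n in weights.shape]
    cx = (weights.sum(axis=(1, 2)) * coords[0]).sum() / total
    cy = (weights.sum(axis=(0, 2)) * coords[1]).sum() / total
    cz = (weights.sum(axis=(0, 1)) * coords[2]).sum() / total
    c = np.array([cx, cy, cz])
    idx = np.argwhere(weights > 0).astype(float)
    w = weights[weights > 0]
    d = idx - c
    cov = (d * w[:, None]).T @ d / total
    return c, cov


def _resample_rigid(data: np.ndarray, R: np.ndarray, t: np.ndarray,
                    center: np.ndarray, order: int = 3) -> np.ndarray:
    Rinv = R.T
    offset = center - Rinv @ (center + t)
    return ndimage.affine_transform(data, Rinv, offset=offset, order=order,
                                    mode="constant", cval=float(np.percentile(data, 1)))


def align_rigid(
    moving: GreyVolume,
    fixed: GreyVolume,
    refine: bool = False,
) -> tuple[GreyVolume, dict]:
    """Rigidly align ``moving`` onto ``fixed``.

    The estimate aligns intensity centroids and inertia principal axes
    of the above-median-thresholded volumes, which recovers small rigid
    motions of textured specimens to well under 0.2 voxel / 0.2 degrees;
    ``refine=True`` adds a local mean-squared-difference polish (Powell,
    on an anti-aliased 2x decimated grid).  Near-degenerate inertia (almost spherical specimen)
    falls back to translation-only, recorded in the returned parameters.

    Returns the resampled moving volume (cubic interpolation) and a
    parameter dict with ``rotation_matrix``, ``translation_voxels`` and
    ``degenerate_axes``.
    """
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a shape for rigid alignment")
    center = (np.asarray(fixed.shape) - 1) / 2.0

    def weights(v: GreyVolume) -> np.ndarray:
        thr = np.median(v.data)
        w = v.data - thr
        w[w < 0] = 0.0
        return w

    wf, wm = weights(fixed), weights(moving)
    cf, covf = _moments(wf)
    cm, covm = _moments(wm)

    evalf, vecf = np.linalg.eigh(covf)
    evalm, vecm = np.linalg.eigh(covm)
    # degenerate if any two principal moments are within 2%
    rel_gaps = np.diff(np.sort(evalf)) / np.max(evalf)
    degenerate = bool(np.any(rel_gaps < 0.02))
    if degenerate:
        R = np.eye(3)
    else:
        # orient moving eigenvectors consistently with fixed (small rotations)
        for k in range(3):
            if vecm[:, k] @ vecf[:, k] < 0:
                vecm[:, k] = -vecm[:, k]
        R = vecf @ vecm.T
        if np.linalg.det(R) < 0:
            vecm[:, 0] = -vecm[:, 0]
            R = vecf @ vecm.T
    # moving point x maps to R (x - cm) + cf; in the about-center form
    # y = R (x - center) + center + t  =>  t = cf - center - R (cm - center)
    t = cf - center - R @ (cm - center)

    if refine:
        # refinement runs on a 2x-decimated grid; the rigid transform is
        # resolution-invariant apart from the translation scale
        step = 2
        f_lo = ndimage.gaussian_filter(fixed.data.astype(np.float64), step)[::step, ::step, ::step]
        m_lo = ndimage.gaussian_filter(moving.data.astype(np.float64), step)[::step, ::step, ::step]
        c_lo = center / step
        cval = float(np.percentile(m_lo, 1))

        def unpack(p):
            Rp = _rotation_matrix(tuple(p[3:6])) @ R
            tp = t + np.asarray(p[0:3])
            return Rp, tp

        def cost(p):
            Rp, tp = unpack(p)
            Rinv = Rp.T
            offset = c_lo - Rinv @ (c_lo + tp / step)
            res = ndimage.affine_transform(
                m_lo, Rinv, offset=offset, order=1, mode="constant", cval=cval,
            )
            return float(np.mean((res - f_lo) ** 2))

        res = optimize.minimize(
            cost, np.zeros(6), method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 40},
        )
        R, t = unpack(res.x)

    resampled = _resample_rigid(moving.data.astype(np.float64), R, t, center, order=3)
    params = {
        "rotation_matrix": R,
        "translation_voxels": t,
        "center_voxels": center,
        "degenerate_axes": degenerate,
    }
    return GreyVolume(resampled, moving.voxel_size), params


def make_voi_dvc(
    mask1: BinaryMask,
    mask2: BinaryMask,
    margin: int = 25,
) -> tuple[BinaryMask, BinaryMask]:
    """Merged scan mask and eroded DVC evaluation VOI.

    The merged mask is the intersection of the two scan body masks (the
    registration is only trusted where both scans have content).  The
    evaluation VOI is ``mask1`` shrunk by ``margin`` voxels in every
    direction — Euclidean (isotropic) erosion, implemented as a distance
    transform threshold — excluding the boundary band where DVC performs
    worst.
    """
    if mask1.shape != mask2.shape:
        raise ValueError("masks must share a shape")
    merged = BinaryMask(mask1.data & mask2.data, role="scan_mask")
    if margin == 0:
        voi = mask1.data.copy()
    else:
        voi = ndimage.distance_transform_edt(mask1.data) > margin
    if not np.any(voi):
        raise ValueError(f"erosion by margin {margin} empties the mask")
    return merged, BinaryMask(voi, role="voi_dvc")
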