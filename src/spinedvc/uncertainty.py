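"""Zero-strain uncertainty metrics and study statistics.

In a zero-strain repeat-scan pair any displacement variation and any
non-zero strain is measurement error.  This module computes:

* per-axis random displacement error (SD over retained nodes),
* per-component systematic (mean) and random (SD) strain error,
* MAER / SDER — the mean and standard deviation, across nodes, of each
  node's average absolute value of the six strain components:

      m_k  = (1/6) Σ_c |ε_c,k|
      MAER = (1/N) Σ_k m_k
      SDER = sqrt( (1/N) Σ_k (m_k − MAER)² )

  (population 1/N normalization throughout, so the two formulas share a
  convention; the difference from 1/(N−1) is < 4% for N ≥ 14),
* the 27-subROI partition of a vertebral body (3 longitudinal levels ×
  9 in-plane sectors) with the 1%-of-body-volume exclusion rule,
* rank-based group comparisons (Mann–Whitney, Kruskal–Wallis) and
  ordinary least-squares correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import analyze as morph_analyze
from .registration import DisplacementField
from .strain import HexMesh, StrainField, STRAIN_COMPONENTS
from .volumes import BinaryMask

SECTOR_NAMES = ("PL", "P", "PR", "L", "C", "R", "AL", "A", "AR")  # y-band major, x minor
LEVEL_NAMES = ("bottom", "middle", "top")


@dataclass
class ErrorReport:
    """Zero-strain error metrics for one specimen at one nodal spacing."""

    disp_random_um: np.ndarray       # (3,) SD of nodal displacement, μm
    strain_systematic_ue: np.ndarray  # (6,) mean of signed strain, με
    strain_random_ue: np.ndarray     # (6,) SD of signed strain, με
    maer_ue: float
    sder_ue: float
    n_nodes: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class SubROILabeling:
    """Per-voxel level/sector labels partitioning the VOI.

    ``level`` and ``sector`` are -1 outside the VOI; ``counts`` is a
    (3, 9) voxel-count table and ``excluded`` flags subROIs whose VOI
    volume is below 1% of the whole vertebral body.
    """

    level: np.ndarray
    sector: np.ndarray
    counts: np.ndarray
    excluded: np.ndarray
    z_edges: np.ndarray
    xy_edges: list  # per level: (x_edges, y_edges)


def _sd(values: np.ndarray, axis=0) -> np.ndarray:
    return np.asarray(values).std(axis=axis, ddof=0)  # population 1/N


def displacement_errors(field: DisplacementField, mesh: HexMesh) -> np.ndarray:
    """Per-axis random displacement error over retained mesh nodes, μm."""
    if mesh.n_nodes < 2:
        raise ValueError("need at least 2 retained nodes")
    u = field.u_flat()[mesh.grid_node_index] * field.voxel_size
    return _sd(u, axis=0)


def strain_component_errors(strain: StrainField) -> tuple[np.ndarray, np.ndarray]:
    """(systematic mean, random SD) per strain component, με."""
    if strain.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return strain.eps.mean(axis=0), _sd(strain.eps, axis=0)


def maer_sder(strain: StrainField) -> tuple[float, float]:
    """Accuracy (MAER) and precision (SDER) of the strain field, με."""
    if strain.n_nodes < 2:
        raise ValueError("SDER needs at least 2 nodes")
    m = np.abs(strain.eps).mean(axis=1)
    maer = float(m.mean())
    sder = float(np.sqrt(np.mean((m - maer) ** 2)))
    return maer, sder


def error_report(field: DisplacementField, mesh: HexMesh, strain: StrainField) -> ErrorReport:
    systematic, random_ = strain_component_errors(strain)
    maer, sder = maer_sder(strain)
    return ErrorReport(
        disp_random_um=displacement_errors(field, mesh),
        strain_systematic_ue=systematic,
        strain_random_ue=random_,
        maer_ue=maer,
        sder_ue=sder,
        n_nodes=strain.n_nodes,
    )


def _split_edges(lo: int, hi: int, n: int) -> np.ndarray:
    """n+1 edges splitting the inclusive index range [lo, hi] into n
    near-equal parts (upper-exclusive on voxel index + 1)."""
    return np.linspace(lo, hi + 1, n + 1)


def partition_subrois(
    voi: BinaryMask,
    body: BinaryMask,
    exclusion_fraction: float = 0.01,
) -> SubROILabeling:
    """3 longitudinal levels × 9 in-plane sectors over the VOI.

    The z extent of the VOI bounding box is split into three equal
    levels (bottom/middle/top = caudal → cranial); within each level the
    x and y extents of that level's VOI bounding box are split 3 × 3
    into sectors named by the anatomical convention y+ = anterior,
    x+ = right (AL, A, AR, L, C, R, PL, P, PR).  Boundary voxels go to
    the lower-index band.  SubROIs with fewer VOI voxels than
    ``exclusion_fraction`` of the whole body mask are flagged excluded.
    """
    if not np.any(voi.data):
        raise ValueError("VOI is empty")
    idx = np.argwhere(voi.data)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    if np.any(hi - lo + 1 < 3):
        raise ValueError("VOI bounding box thinner than 3 voxels in some axis")

    level = np.full(voi.shape, -1, dtype=np.int8)
    sector = np.full(voi.shape, -1, dtype=np.int8)
    z_edges = _split_edges(lo[2], hi[2], 3)
    zs = idx[:, 2]
    lev_of = np.clip(np.searchsorted(z_edges, zs, side="right") - 1, 0, 2)

    xy_edges = []
    for L in range(3):
        sel = lev_of == L
        pts = idx[sel]
        if len(pts) == 0:
            xy_edges.append((None, None))
            continue
        x_edges = _split_edges(pts[:, 0].min(), pts[:, 0].max(), 3)
        y_edges = _split_edges(pts[:, 1].min(), pts[:, 1].max(), 3)
        xb = np.clip(np.searchsorted(x_edges, pts[:, 0], side="right") - 1, 0, 2)
        yb = np.clip(np.searchsorted(y_edges, pts[:, 1], side="right") - 1, 0, 2)
        sec = yb * 3 + xb
        level[pts[:, 0], pts[:, 1], pts[:, 2]] = L
        sector[pts[:, 0], pts[:, 1], pts[:, 2]] = sec
        xy_edges.append((x_edges, y_edges))

    counts = np.zeros((3, 9), dtype=np.int64)
    inside = level >= 0
    np.add.at(counts, (level[inside], sector[inside]), 1)
    threshold = exclusion_fraction * body.count()
    excluded = counts < threshold
    return SubROILabeling(
        level=level, sector=sector, counts=counts, excluded=excluded,
        z_edges=z_edges, xy_edges=xy_edges,
    )


def subroi_table(
    strain: StrainField,
    labeling: SubROILabeling,
    bone: BinaryMask,
    voi: BinaryMask,
    voxel_size: float,
    min_nodes: int = 2,
) -> pd.DataFrame:
    """Per-subROI morphometry and strain uncertainty.

    Strain metrics use the mesh nodes whose voxel coordinates fall in
    the subROI; rows with fewer than ``min_nodes`` nodes keep their
    morphometry but have NaN strain metrics and ``enough_nodes=False``.
    Excluded subROIs (volume rule) are omitted.
    """
    node_idx = np.round(strain.nodes).astype(int)
    shape = np.asarray(labeling.level.shape)
    in_lat = np.all((node_idx >= 0) & (node_idx < shape), axis=1)
    node_lev = np.full(len(node_idx), -1, dtype=int)
    node_sec = np.full(len(node_idx), -1, dtype=int)
    ok = node_idx[in_lat]
    node_lev[in_lat] = labeling.level[ok[:, 0], ok[:, 1], ok[:, 2]]
    node_sec[in_lat] = labeling.sector[ok[:, 0], ok[:, 1], ok[:, 2]]

    rows = []
    for L in range(3):
        for S in range(9):
            if labeling.excluded[L, S]:
                continue
            region = (labeling.level == L) & (labeling.sector == S)
            row: dict = {
                "level": LEVEL_NAMES[L],
                "sector": SECTOR_NAMES[S],
                "voi_voxels": int(region.sum()),
            }
            try:
                # morphometry on the subROI bounding box only (the
                # distance transforms are local to the VOI anyway)
                idx = np.argwhere(region)
                lo = np.maximum(idx.min(axis=0) - 1, 0)
                hi = idx.max(axis=0) + 2
                box = tuple(slice(a, b) for a, b in zip(lo, hi))
                m = morph_analyze(BinaryMask(bone.data[box]),
                                  BinaryMask(region[box]), voxel_size)
                row.update(
                    bvtv_percent=m.bvtv, st_th_um=m.st_th_mean,
                    st_sp_um=m.st_sp_mean, st_n_per_mm=m.st_n,
                )
            except ValueError:
                row.update(bvtv_percent=np.nan, st_th_um=np.nan,
                           st_sp_um=np.nan, st_n_per_mm=np.nan)
            sel = (node_lev == L) & (node_sec == S)
            n = int(sel.sum())
            row["n_nodes"] = n
            row["enough_nodes"] = n >= min_nodes
            if n >= min_nodes:
                sub = StrainField(nodes=strain.nodes[sel], eps=strain.eps[sel])
                syst, rand_ = strain_component_errors(sub)
                maer, sder = maer_sder(sub)
                for c, name in enumerate(STRAIN_COMPONENTS):
                    row[f"systematic_{name}_ue"] = syst[c]
                    row[f"random_{name}_ue"] = rand_[c]
                row["maer_ue"] = maer
                row["sder_ue"] = sder
            else:
                for name in STRAIN_COMPONENTS:
                    row[f"systematic_{name}_ue"] = np.nan
                    row[f"random_{name}_ue"] = np.nan
                row["maer_ue"] = np.nan
                row["sder_ue"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(samples_by_group: dict) -> dict:
    """Two-sided rank tests at α = 0.05.

    Two groups → Mann–Whitney U (exact when sample sizes permit);
    three or more → Kruskal–Wallis.  Returns ``{"test", "p_value",
    "statistic"}``.
    """
    groups = [np.asarray(v, dtype=float) for v in samples_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 samples")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return {"test": "mann-whitney", "p_value": float(res.pvalue),
                "statistic": float(res.statistic)}
    res = stats.kruskal(*groups)
    return {"test": "kruskal-wallis", "p_value": float(res.pvalue),
            "statistic": float(res.statistic)}


def fit_linear(x, y) -> RegressionResult:
    """Ordinary least squares with R² and the two-sided slope-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )
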