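"""Zero-strain study orchestration and artifact I/O.

Runs the full uncertainty study over a list of specimens (synthetic
phantoms or user-supplied repeat-scan pairs): bubble removal, rigid
alignment, mask construction, elastic registration over a sweep of
nodal spacings, strain differentiation, error metrics, morphometry,
subROI analysis, and group statistics.  Everything is deterministic
given the master seed: per-specimen seeds are derived by a stable hash
of the specimen id, so adding a specimen never changes the others.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import morphometry, preprocess, uncertainty
from .registration import DisplacementField, RegistrationSettings, register_elastic
from .strain import StrainField, compute_nodal_strains, extract_mesh
from .synth import GroundTruth, PhantomSpec, generate_phantom, simulate_repeat_scan
from .volumes import BinaryMask, GreyVolume, read_volume, write_volume

volume_io_read = read_volume
volume_io_write = write_volume


@dataclass
class StudyConfig:
    """One zero-strain study.

    ``specimens`` maps specimen ids to :class:`PhantomSpec` objects (or
    dicts of their fields).  ``ns_sweep`` lists the nodal spacings in
    voxels; ``voi_margin`` is the erosion half-width building the DVC
    evaluation VOI; ``repositioning`` is the between-scan rigid motion
    (translation voxels, rotation degrees) and ``scan_noise_sd`` the
    per-scan additive noise.  ``subroi_ns`` selects the spacing for the
    local subROI analysis.
    """

    specimens: dict
    ns_sweep: tuple = (25, 50, 75, 100)
    subroi_ns: int = 50
    voi_margin: int = 25
    registration: dict = dataclass_field(default_factory=dict)
    repositioning: dict = dataclass_field(
        default_factory=lambda: {"translation": (1.5, -1.0, 0.5), "rotation": (0.0, 0.0, 1.0)}
    )
    scan_noise_sd: float = 8.0
    body_mask_level: float | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.specimens:
            raise ValueError("specimen list must be nonempty")
        if any(ns < 2 for ns in self.ns_sweep):
            raise ValueError("all NS values must be >= 2")


def child_seed(master_seed: int, specimen_id: str) -> int:
    """Stable per-specimen seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{specimen_id}".encode()) & 0x7FFFFFFF


@dataclass
class SpecimenResult:
    specimen_id: str
    error_reports: dict            # ns -> uncertainty.ErrorReport
    morphometry: morphometry.MorphometryResult | None
    subroi: pd.DataFrame | None
    failed: dict                   # stage -> message


@dataclass
class StudyReport:
    config: StudyConfig
    specimens: dict                # id -> SpecimenResult
    group_stats: dict
    regressions: dict

    def error_table(self) -> pd.DataFrame:
        rows = []
        for sid, res in self.specimens.items():
            for ns, rep in res.error_reports.items():
                rows.append({
                    "specimen": sid, "ns_voxels": ns,
                    "disp_sd_x_um": rep.disp_random_um[0],
                    "disp_sd_y_um": rep.disp_random_um[1],
                    "disp_sd_z_um": rep.disp_random_um[2],
                    "maer_ue": rep.maer_ue, "sder_ue": rep.sder_ue,
                    "n_nodes": rep.n_nodes,
                })
        return pd.DataFrame(rows)


def _as_phantom_spec(obj, seed: int) -> PhantomSpec:
    if isinstance(obj, PhantomSpec):
        obj.seed = seed
        return obj
    if isinstance(obj, dict):
        d = dict(obj)
        d.setdefault("seed", seed)
        return PhantomSpec(**d)
    raise TypeError(f"unsupported specimen spec: {type(obj)}")


def process_zero_strain_pair(
    scan1: GreyVolume,
    scan2: GreyVolume,
    truth: GroundTruth,
    ns_values,
    voi_margin: int,
    registration_kwargs: dict | None = None,
    align: bool = True,
):
    """Register a prepared repeat-scan pair at each nodal spacing.

    Returns ``(reports, fields, strains, voi_dvc)`` where reports maps
    ns → :class:`~spinedvc.uncertainty.ErrorReport`.
    """
    registration_kwargs = registration_kwargs or {}
    if align:
        scan2, _ = preprocess.align_rigid(scan2, scan1)
    mask1 = truth.body_mask
    merged, voi_dvc = preprocess.make_voi_dvc(mask1, mask1, margin=voi_margin)
    reports: dict = {}
    fields: dict = {}
    strains: dict = {}
    for ns in ns_values:
        settings = RegistrationSettings(ns=ns, **registration_kwargs)
        field = register_elastic(scan1, scan2, merged, settings)
        mesh = extract_mesh(field.grid, voi_dvc)
        strain = compute_nodal_strains(mesh, field)
        reports[ns] = uncertainty.error_report(field, mesh, strain)
        fields[ns] = field
        strains[ns] = (mesh, strain)
    return reports, fields, strains, voi_dvc


def run_zero_strain_study(config: StudyConfig) -> StudyReport:
    """Run the full study; failures are recorded per specimen, not fatal."""
    results: dict = {}
    for sid, spec_obj in config.specimens.items():
        sid = str(sid)
        seed = child_seed(config.master_seed, sid)
        failed: dict = {}
        reports: dict = {}
        morph = None
        subroi_df = None
        try:
            spec = _as_phantom_spec(spec_obj, seed)
            base_spec = PhantomSpec(**{**spec.__dict__, "noise_sd": 0.0,
                                       "lesions": spec.lesions, "seed": seed})
            base, truth = generate_phantom(base_spec)
            scan1 = simulate_repeat_scan(base, truth, rigid=None,
                                         noise_sd=config.scan_noise_sd, seed=seed + 1)
            scan2 = simulate_repeat_scan(base, truth, rigid=config.repositioning,
                                         noise_sd=config.scan_noise_sd, seed=seed + 2)
            marrow = (spec.grey_marrow, config.scan_noise_sd)
            cutoff = 0.5 * (spec.grey_air + spec.grey_marrow)
            scan1 = preprocess.remove_air_bubbles(scan1, truth.body_mask, cutoff, marrow, seed + 3)
            scan2 = preprocess.remove_air_bubbles(scan2, truth.body_mask, cutoff, marrow, seed + 4)
        except Exception as exc:  # noqa: BLE001 — study keeps going
            results[sid] = SpecimenResult(sid, {}, None, None, {"synthesis": str(exc)})
            continue

        try:
            reports, fields, strains, voi_dvc = process_zero_strain_pair(
                scan1, scan2, truth,
                ns_values=config.ns_sweep,
                voi_margin=config.voi_margin,
                registration_kwargs=config.registration,
            )
        except Exception as exc:  # noqa: BLE001
            failed["registration"] = str(exc)

        bone = None
        try:
            bone = preprocess.segment_bone(
                preprocess.denoise_median(scan1), truth.nocort_mask
            )
            morph = morphometry.analyze(bone, truth.nocort_mask, scan1.voxel_size)
        except Exception as exc:  # noqa: BLE001
            failed["morphometry"] = str(exc)

        try:
            if reports and bone is not None and config.subroi_ns in reports:
                mesh, strain = strains[config.subroi_ns]
                labeling = uncertainty.partition_subrois(voi_dvc, truth.body_mask)
                subroi_df = uncertainty.subroi_table(
                    strain, labeling, bone, voi_dvc, scan1.voxel_size
                )
        except Exception as exc:  # noqa: BLE001
            failed["subroi"] = str(exc)

        results[sid] = SpecimenResult(sid, reports, morph, subroi_df, failed)

    group_stats: dict = {}
    regressions: dict = {}
    sder_by_ns: dict = {ns: [] for ns in config.ns_sweep}
    for res in results.values():
        for ns, rep in res.error_reports.items():
            sder_by_ns[ns].append(rep.sder_ue)
    ns_list, sder_med = [], []
    for ns in config.ns_sweep:
        if sder_by_ns[ns]:
            ns_list.append(ns)
            sder_med.append(float(np.median(sder_by_ns[ns])))
    group_stats["sder_median_by_ns"] = dict(zip(ns_list, sder_med))
    if len(ns_list) >= 3:
        try:
            regressions["sder_vs_ns"] = uncertainty.fit_linear(ns_list, sder_med)
        except ValueError:
            pass
    # SDER vs morphometry across specimens, at the subROI analysis spacing
    xs, ys = {"bvtv": [], "st_th": [], "st_sp": []}, []
    for res in results.values():
        if res.morphometry and config.subroi_ns in res.error_reports:
            xs["bvtv"].append(res.morphometry.bvtv)
            xs["st_th"].append(res.morphometry.st_th_mean)
            xs["st_sp"].append(res.morphometry.st_sp_mean)
            ys.append(res.error_reports[config.subroi_ns].sder_ue)
    for name, x in xs.items():
        if len(ys) >= 3 and np.ptp(x) > 0:
            regressions[f"sder_vs_{name}"] = uncertainty.fit_linear(x, ys)

    return StudyReport(config=config, specimens=results,
                       group_stats=group_stats, regressions=regressions)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _vtk_data_array(name: str, data: np.ndarray, n_components: int) -> str:
    flat = " ".join(f"{v:.9g}" for v in np.asarray(data).ravel())
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{n_components}" format="ascii">{flat}</DataArray>'
    )


def write_vts(field: DisplacementField, path: str | os.PathLike) -> None:
    """Displacement field as VTK XML structured grid (points in voxels,
    displacements in μm)."""
    nn = field.grid.n_nodes_axis
    pts = field.grid.node_coordinates()
    u = field.u_flat() * field.voxel_size
    extent = f"0 {nn[0] - 1} 0 {nn[1] - 1} 0 {nn[2] - 1}"
    # VTK structured grids are x-fastest; our node arrays are z-fastest
    order = np.arange(np.prod(nn)).reshape(nn).transpose(2, 1, 0).ravel()
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="StructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        f'<StructuredGrid WholeExtent="{extent}">\n<Piece Extent="{extent}">\n'
        "<Points>" + _vtk_data_array("points", pts[order], 3) + "</Points>\n"
        "<PointData>" + _vtk_data_array("displacement_um", u[order], 3) + "</PointData>\n"
        "</Piece>\n</StructuredGrid>\n</VTKFile>\n"
    )
    with open(path, "w") as fh:
        fh.write(xml)


def write_vtu(strain: StrainField, elements: np.ndarray, path: str | os.PathLike) -> None:
    """Strain field as VTK XML unstructured grid of hexahedra (με)."""
    n_pts, n_cells = len(strain.nodes), len(elements)
    # VTK hexahedron corner order from our (dx,dy,dz) binary order
    vtk_order = [0, 4, 6, 2, 1, 5, 7, 3]
    conn = elements[:, vtk_order]
    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n'
        "<Points>" + _vtk_data_array("points", strain.nodes, 3) + "</Points>\n"
        "<PointData>" + _vtk_data_array("strain_ue", strain.eps, 6) + "</PointData>\n"
        "<Cells>"
        + _vtk_data_array("connectivity", conn.astype(float), 1)
        + _vtk_data_array("offsets", (np.arange(1, n_cells + 1) * 8).astype(float), 1)
        + _vtk_data_array("types", np.full(n_cells, 12.0), 1)
        + "</Cells>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n"
    )
    with open(path, "w") as fh:
        fh.write(xml)


def export_fields(
    field: DisplacementField,
    strain: StrainField,
    elements: np.ndarray,
    outdir: str | os.PathLike,
) -> dict:
    """Write VTK + unit-annotated CSV artifacts; returns the file map."""
    outdir = os.fspath(outdir)
    if strain.n_nodes == 0:
        raise ValueError("strain field is empty")
    if not os.path.isdir(outdir):
        raise ValueError(f"output directory does not exist: {outdir}")
    paths = {
        "displacement_vts": os.path.join(outdir, "displacement.vts"),
        "strain_vtu": os.path.join(outdir, "strain.vtu"),
        "displacement_csv": os.path.join(outdir, "displacement.csv"),
        "strain_csv": os.path.join(outdir, "strain.csv"),
    }
    write_vts(field, paths["displacement_vts"])
    write_vtu(strain, elements, paths["strain_vtu"])

    pts = field.grid.node_coordinates()
    u = field.u_flat() * field.voxel_size
    pd.DataFrame({
        "node": np.arange(len(pts)),
        "x_voxels": pts[:, 0], "y_voxels": pts[:, 1], "z_voxels": pts[:, 2],
        "ux_um": u[:, 0], "uy_um": u[:, 1], "uz_um": u[:, 2],
    }).to_csv(paths["displacement_csv"], index=False, float_format="%.9g")

    cols = {"node": np.arange(strain.n_nodes),
            "x_voxels": strain.nodes[:, 0], "y_voxels": strain.nodes[:, 1],
            "z_voxels": strain.nodes[:, 2]}
    from .strain import STRAIN_COMPONENTS

    for c, name in enumerate(STRAIN_COMPONENTS):
        cols[f"{name}_ue"] = strain.eps[:, c]
    pd.DataFrame(cols).to_csv(paths["strain_csv"], index=False, float_format="%.9g")
    return paths


def save_report_json(report: StudyReport, path: str | os.PathLike) -> None:
    """Provenance + headline numbers as JSON."""
    payload = {
        "master_seed": report.config.master_seed,
        "ns_sweep": list(report.config.ns_sweep),
        "group_stats": {
            k: ({str(a): b for a, b in v.items()} if isinstance(v, dict) else v)
            for k, v in report.group_stats.items()
        },
        "regressions": {
            k: vars(v) for k, v in report.regressions.items()
        },
        "failures": {
            sid: res.failed for sid, res in report.specimens.items() if res.failed
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
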