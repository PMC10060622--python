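"""Error metrics (MAER/SDER and friends), subROI partitioning and the
study statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinedvc import (
    DisplacementField,
    StrainField,
    build_grid,
    compare_groups,
    compute_nodal_strains,
    displacement_errors,
    extract_mesh,
    fit_linear,
    maer_sder,
    partition_subrois,
    strain_component_errors,
    subroi_table,
)
from spinedvc.tables import reference_morphometry
from spinedvc.volumes import BinaryMask


def strain_of(eps):
    eps = np.asarray(eps, dtype=float)
    return StrainField(nodes=np.zeros((len(eps), 3)), eps=eps)


class TestDisplacementErrors:
    def _mesh_field(self, u_fn):
        grid = build_grid((64, 64, 64), 16)
        mesh = extract_mesh(grid, BinaryMask(np.ones((64, 64, 64), bool)))
        coords = grid.node_coordinates()
        u = np.asarray(u_fn(coords)).reshape(*grid.n_nodes_axis, 3)
        return DisplacementField(grid=grid, u=u, voxel_size=1.0), mesh

    def test_constant_field_has_zero_random_error(self):
        f, mesh = self._mesh_field(lambda c: np.tile([0.3, -0.2, 0.9], (len(c), 1)))
        assert np.allclose(displacement_errors(f, mesh), 0.0)

    def test_two_point_population_sd(self):
        # ux = {0, 2} um over two nodes -> SD 1 um with 1/N normalization
        vals = np.array([0.0, 2.0])
        assert vals.std(ddof=0) == 1.0  # the convention the module uses
        f, mesh = self._mesh_field(
            lambda c: np.stack([(c[:, 0] > 32) * 2.0, 0 * c[:, 0], 0 * c[:, 0]], axis=1))
        sd = displacement_errors(f, mesh)
        n = mesh.n_nodes
        n_hi = int((f.grid.node_coordinates()[:, 0] > 32).sum())
        p = n_hi / n
        assert sd[0] == pytest.approx(2.0 * np.sqrt(p * (1 - p)))
        assert sd[1] == sd[2] == 0.0


class TestStrainErrors:
    def test_all_zero(self):
        syst, rand_ = strain_component_errors(strain_of(np.zeros((4, 6))))
        assert np.all(syst == 0) and np.all(rand_ == 0)

    def test_two_node_hand_case(self):
        eps = np.zeros((2, 6))
        eps[0, 2], eps[1, 2] = 100.0, -100.0
        syst, rand_ = strain_component_errors(strain_of(eps))
        assert syst[2] == 0.0
        assert rand_[2] == 100.0

    def test_constant_field(self):
        eps = np.tile([10.0, -5, 3, 0, 7, -2], (5, 1))
        syst, rand_ = strain_component_errors(strain_of(eps))
        assert np.allclose(syst, eps[0])
        assert np.allclose(rand_, 0.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            strain_component_errors(strain_of(np.zeros((1, 6))))


class TestMaerSder:
    def test_zero_field(self):
        assert maer_sder(strain_of(np.zeros((3, 6)))) == (0.0, 0.0)

    def test_two_node_worked_example(self):
        maer, sder = maer_sder(strain_of([[6.0] * 6, [0.0] * 6]))
        assert maer == pytest.approx(3.0)
        assert sder == pytest.approx(3.0)

    def test_constant_offset_shifts_maer_only(self):
        eps = np.abs(np.random.default_rng(3).normal(0, 50, (10, 6)))
        m0, s0 = maer_sder(strain_of(eps))
        m1, s1 = maer_sder(strain_of(eps + 25.0))
        assert m1 == pytest.approx(m0 + 25.0)
        assert s1 == pytest.approx(s0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.floats(-1e4, 1e4), min_size=6, max_size=6),
                    min_size=2, max_size=12))
    def test_invariant_to_node_order_and_component_relabeling(self, rows):
        eps = np.asarray(rows)
        base = maer_sder(strain_of(eps))
        perm_nodes = maer_sder(strain_of(eps[::-1]))
        perm_comps = maer_sder(strain_of(eps[:, [2, 0, 1, 5, 3, 4]]))
        assert base == pytest.approx(perm_nodes)
        assert base == pytest.approx(perm_comps)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.floats(-1e4, 1e4), min_size=6, max_size=6),
                    min_size=2, max_size=12))
    def test_sder_bounded_by_m_range(self, rows):
        eps = np.asarray(rows)
        m = np.abs(eps).mean(axis=1)
        _, sder = maer_sder(strain_of(eps))
        assert sder <= (m.max() - m.min()) + 1e-9

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            maer_sder(strain_of(np.zeros((1, 6))))


class TestSubrois:
    def _cube(self, n=60, pad=6):
        voi = np.zeros((n, n, n), bool)
        voi[pad:n - pad, pad:n - pad, pad:n - pad] = True
        body = np.zeros_like(voi)
        body[pad - 3:n - pad + 3, pad - 3:n - pad + 3, pad - 3:n - pad + 3] = True
        return BinaryMask(voi), BinaryMask(body)

    def test_uniform_cube_gives_27_equal_kept_subrois(self):
        voi, body = self._cube()
        lab = partition_subrois(voi, body)
        assert lab.counts.size == 27
        assert not lab.excluded.any()
        assert lab.counts.min() == lab.counts.max()

    def test_counts_partition_the_voi(self):
        voi, body = self._cube()
        lab = partition_subrois(voi, body)
        assert lab.counts.sum() == voi.count()

    def test_study_bookkeeping_648_subrois_for_24_vertebrae(self):
        voi, body = self._cube()
        per_vertebra = partition_subrois(voi, body).counts.size
        assert per_vertebra == 27
        assert 24 * per_vertebra == 648

    def test_small_protrusion_subroi_excluded_by_one_percent_rule(self):
        # a cube with a thin tongue sticking out in +x: the tongue owns
        # the rightmost x band of its level and is below 1% of the body
        voi = np.zeros((60, 60, 60), bool)
        voi[6:36, 6:36, 6:42] = True
        voi[36:58, 20:24, 20:24] = True  # tongue
        body = np.zeros_like(voi)
        body[3:39, 3:39, 3:45] = True
        body[36:59, 19:25, 19:25] = True
        lab = partition_subrois(BinaryMask(voi), BinaryMask(body))
        assert lab.excluded.any()
        assert lab.counts.sum() == int(voi.sum())

    def test_thin_voi_rejected(self):
        voi = BinaryMask(np.zeros((20, 20, 20), bool))
        voi.data[5:8, 5:8, 10] = True
        with pytest.raises(ValueError):
            partition_subrois(voi, voi)

    def test_table_rows_match_kept_subrois_and_lesion_contrast(self, small_phantom):
        _, vol, truth = small_phantom
        voi, body = truth.nocort_mask, truth.body_mask
        lab = partition_subrois(voi, body)
        grid = build_grid(vol.shape, 16)
        mesh = extract_mesh(grid, voi)
        coords = grid.node_coordinates()
        field = DisplacementField(
            grid=grid, u=np.zeros((*grid.n_nodes_axis, 3)), voxel_size=39.0)
        strain = compute_nodal_strains(mesh, field)
        df = subroi_table(strain, lab, truth.bone_mask, voi, 39.0)
        assert len(df) == int((~lab.excluded).sum())
        assert set(df.columns) >= {"bvtv_percent", "sder_ue", "n_nodes"}


def test_homogeneous_phantom_has_homogeneous_subroi_sder():
    """On a lesion-free phantom the between-subROI SDER spread stays
    loose-bounded: coefficient of variation under 50% (median over
    seeds)."""
    from spinedvc import RegistrationSettings, register_elastic, simulate_repeat_scan
    from spinedvc import PhantomSpec, generate_phantom, make_voi_dvc

    cvs = []
    for seed in range(1, 6):
        spec = PhantomSpec(shape=(96, 96, 96), target_bvtv=0.2, noise_sd=0.0, seed=seed)
        vol, truth = generate_phantom(spec)
        s1 = simulate_repeat_scan(vol, truth, None, noise_sd=6.0, seed=seed * 7 + 1)
        s2 = simulate_repeat_scan(vol, truth, None, noise_sd=6.0, seed=seed * 7 + 2)
        field = register_elastic(s1, s2, truth.body_mask, RegistrationSettings(ns=8))
        _, voi = make_voi_dvc(truth.body_mask, truth.body_mask, margin=12)
        mesh = extract_mesh(field.grid, voi)
        strain = compute_nodal_strains(mesh, field)
        lab = partition_subrois(voi, truth.body_mask)
        df = subroi_table(strain, lab, truth.bone_mask, voi, 39.0)
        vals = df.loc[df.enough_nodes, "sder_ue"].to_numpy()
        if len(vals) >= 3:
            cvs.append(vals.std() / vals.mean())
    assert np.median(cvs) < 0.5


class TestGroupComparisons:
    def test_reference_bvtv_differs_significantly(self):
        df = reference_morphometry()
        res = compare_groups({
            g: sub["bvtv_percent"].tolist() for g, sub in df.groupby("group")})
        assert res["test"] == "mann-whitney"
        assert res["p_value"] < 0.01

    def test_reference_stsp_not_significant(self):
        df = reference_morphometry()
        res = compare_groups({
            g: sub["st_sp_um"].tolist() for g, sub in df.groupby("group")})
        assert 0.05 < res["p_value"] < 0.15

    def test_identical_groups_p_one(self):
        res = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res["p_value"] == pytest.approx(1.0)

    def test_three_groups_use_kruskal_wallis(self, rng):
        res = compare_groups({
            "a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
            "c": rng.normal(3, 1, 10)})
        assert res["test"] == "kruskal-wallis"
        assert res["p_value"] < 0.01

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1], "b": [1, 2]})


class TestLinearFit:
    def test_exact_line(self):
        r = fit_linear([0, 1, 2, 3, 4], [1, 3, 5, 7, 9])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_three_point_hand_least_squares(self):
        # x={1,2,3}, y={1,2,4}: slope 3/2, intercept -2/3, R^2 = 27/28
        r = fit_linear([1, 2, 3], [1, 2, 4])
        assert r.slope == pytest.approx(1.5)
        assert r.intercept == pytest.approx(-2.0 / 3.0)
        assert r.r_squared == pytest.approx(27.0 / 28.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_linear([2, 2, 2], [1, 2, 3])
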