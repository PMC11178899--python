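"""The morphological-gradient method: falloff, deformation, field assembly."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import morphgrad as mg
from morphgrad.gradients import ScorerContractError, ScoringFunction

from .conftest import icosphere, random_convex_mesh


def max_z_scorer() -> ScoringFunction:
    """Score = (max z)/2: linear in apex height, in [0,1] for unit spheres."""
    return ScoringFunction(lambda m: float(m.positions[:, 2].max()) / 2.0, name="max_z")


def constant_scorer(value: float = 0.5) -> ScoringFunction:
    return ScoringFunction(lambda m: value, name="constant")


# -- sigma ---------------------------------------------------------------


@pytest.mark.parametrize("R", [0.1, 1.0, 10.0, 100.0])
def test_sigma_is_one_at_zero(R):
    assert mg.sigma(0.0, R) == 1.0


@pytest.mark.parametrize("r,R", [(1.0, 1.0), (2.0, 1.0), (20.0, 10.0), (10.0, 10.0)])
def test_sigma_vanishes_at_and_beyond_range(r, R):
    assert mg.sigma(r, R) == 0.0


def test_sigma_linear_inside_range():
    assert mg.sigma(2.5, 10.0) == pytest.approx(0.75)
    assert mg.sigma(5.0, 10.0) == pytest.approx(0.5)


def test_sigma_rejects_negative_distance():
    with pytest.raises(ValueError):
        mg.sigma(-0.1, 1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(r1=st.floats(0, 100), r2=st.floats(0, 100), R=st.floats(0.01, 100))
def test_sigma_monotone_nonincreasing_and_bounded(r1, r2, R):
    lo, hi = sorted((r1, r2))
    s_lo, s_hi = mg.sigma(lo, R), mg.sigma(hi, R)
    assert 0.0 <= s_hi <= s_lo <= 1.0


# -- deform --------------------------------------------------------------


def test_zero_delta_is_identity(sphere2):
    spec = mg.DeformationSpec(delta=0.0, range_R=5.0)
    out = mg.deform(sphere2, 0, spec)
    np.testing.assert_array_equal(out.positions, sphere2.positions)


def test_tight_falloff_moves_only_the_center(sphere2):
    min_edge = sphere2.edge_graph.data.min()
    spec = mg.DeformationSpec(delta=0.1, range_R=min_edge * 0.9)
    out = mg.deform(sphere2, 7, spec)
    moved = np.flatnonzero(np.linalg.norm(out.positions - sphere2.positions, axis=1) > 0)
    assert moved.tolist() == [7]
    # the center moves outward along its (nearly radial) normal
    assert np.linalg.norm(out.positions[7]) == pytest.approx(1.1, abs=5e-3)


def test_global_falloff_inflates_whole_sphere(sphere2):
    # R = 10 covers the whole unit sphere (max pairwise distance 2), so
    # sigma >= 0.8 everywhere and every vertex moves out by 0.08..0.1
    spec = mg.DeformationSpec(delta=0.1, range_R=10.0)
    out = mg.deform(sphere2, 0, spec)
    radii = np.linalg.norm(out.positions, axis=1)
    # brute-force per-vertex oracle
    d = np.linalg.norm(sphere2.positions - sphere2.positions[0], axis=1)
    expected = np.linalg.norm(
        sphere2.positions + 0.1 * ((10.0 - d) / 10.0)[:, None] * sphere2.vertex_normals,
        axis=1)
    np.testing.assert_allclose(radii, expected, atol=1e-12)
    assert radii.min() > 1.07  # normals deviate slightly from radial
    assert radii.max() <= 1.1 + 1e-12


def test_deform_never_moves_beyond_delta_or_range():
    mesh = random_convex_mesh(4)
    spec = mg.DeformationSpec(delta=1.5, range_R=6.0)
    out = mg.deform(mesh, 3, spec)
    step = np.linalg.norm(out.positions - mesh.positions, axis=1)
    assert step.max() <= 1.5 + 1e-12
    d = np.linalg.norm(mesh.positions - mesh.positions[3], axis=1)
    assert np.all(step[d >= 6.0] == 0.0)


def test_deform_leaves_input_untouched(sphere2):
    before = sphere2.positions.copy()
    mg.deform(sphere2, 0, mg.DeformationSpec(delta=1.0, range_R=2.0))
    np.testing.assert_array_equal(sphere2.positions, before)


def test_geodesic_mode_does_not_cross_gaps():
    """Two parallel sheets close in space: a Euclidean-falloff bump drags
    the far sheet, a geodesic one cannot."""
    n = 4
    xy = np.array([[i, j] for j in range(n) for i in range(n)], dtype=float)
    sheet_faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            v = j * n + i
            sheet_faces.append([v, v + 1, v + n])
            sheet_faces.append([v + 1, v + n + 1, v + n])
    top = np.column_stack([xy, np.full(len(xy), 0.5)])
    bottom = np.column_stack([xy, np.zeros(len(xy))])
    pos = np.vstack([top, bottom])
    faces = np.vstack([sheet_faces, np.asarray(sheet_faces) + len(xy)])
    mesh = mg.TriMesh(pos, faces)
    center = 5  # interior vertex of the top sheet
    spec_e = mg.DeformationSpec(delta=0.2, range_R=2.0, distance_mode="euclidean")
    spec_g = mg.DeformationSpec(delta=0.2, range_R=2.0, distance_mode="geodesic")
    moved_e = np.linalg.norm(mg.deform(mesh, center, spec_e).positions - pos, axis=1)
    moved_g = np.linalg.norm(mg.deform(mesh, center, spec_g).positions - pos, axis=1)
    lower = np.arange(len(xy), 2 * len(xy))
    assert moved_e[lower].max() > 0  # Euclidean falloff leaks across the gap
    assert np.all(moved_g[lower] == 0.0)  # geodesic falloff does not


# -- pointwise gradient --------------------------------------------------


def test_constant_scorer_gives_zero_gradient(sphere2):
    scorer = constant_scorer()
    spec = mg.DeformationSpec(delta=0.1, range_R=1.0)
    for c in (0, 10, 41):
        assert mg.morphological_gradient_at(sphere2, scorer, c, spec) == 0.0


def test_zero_delta_gives_zero_gradient(sphere2):
    scorer = max_z_scorer()
    spec = mg.DeformationSpec(delta=0.0, range_R=1.0)
    assert mg.morphological_gradient_at(sphere2, scorer, 0, spec) == 0.0


def test_apex_bump_raises_max_z_by_delta(sphere2):
    apex = int(np.argmax(sphere2.positions[:, 2]))
    min_edge = sphere2.edge_graph.data.min()
    spec = mg.DeformationSpec(delta=0.05, range_R=min_edge * 0.9)
    got = mg.morphological_gradient_at(sphere2, max_z_scorer(), apex, spec)
    # apex normal is +z, so max z rises by exactly delta; scorer scales by 1/2
    assert got == pytest.approx(0.05 / 2.0, abs=1e-9)


def test_gradient_linear_in_delta_for_linear_scorer(sphere2):
    apex = int(np.argmax(sphere2.positions[:, 2]))
    min_edge = sphere2.edge_graph.data.min()
    g1 = mg.morphological_gradient_at(
        sphere2, max_z_scorer(), apex,
        mg.DeformationSpec(delta=0.02, range_R=min_edge * 0.9))
    g2 = mg.morphological_gradient_at(
        sphere2, max_z_scorer(), apex,
        mg.DeformationSpec(delta=0.04, range_R=min_edge * 0.9))
    assert g2 == pytest.approx(2.0 * g1, rel=1e-9)


def test_wrong_baseline_is_callers_problem_but_contract_checked(sphere2):
    bad = ScoringFunction(lambda m: 1.5, name="broken")
    with pytest.raises(ScorerContractError):
        mg.morphological_gradient_at(sphere2, bad, 0, mg.DeformationSpec())


# -- field assembly ------------------------------------------------------


def test_constant_scorer_field_is_identically_zero(sphere2):
    field = mg.gradient_field(sphere2, constant_scorer(), mg.DeformationSpec(), rho=0.5)
    np.testing.assert_array_equal(field.values, np.zeros(sphere2.n_vertices))


def test_tiny_rho_equals_dense_evaluation(sphere2):
    min_edge = sphere2.edge_graph.data.min()
    spec = mg.DeformationSpec(delta=0.05, range_R=0.5)
    scorer = max_z_scorer()
    field = mg.gradient_field(sphere2, scorer, spec, rho=min_edge * 0.5)
    assert len(field.cover) == sphere2.n_vertices
    baseline = scorer(sphere2)
    dense = np.array([
        mg.morphological_gradient_at(sphere2, scorer, v, spec, baseline=baseline)
        for v in range(sphere2.n_vertices)])
    np.testing.assert_allclose(field.values, dense, atol=1e-12)


def test_scorer_call_budget_is_cover_plus_one(sphere2):
    scorer = max_z_scorer()
    field = mg.gradient_field(sphere2, scorer,
                              mg.DeformationSpec(delta=0.05, range_R=0.5), rho=0.6)
    assert scorer.calls == len(field.cover) + 1


def test_sparse_field_sign_agrees_with_dense():
    """Interpolated field sign matches dense per-vertex evaluation at >= 90%
    of vertices for a smooth analytic scorer."""
    mesh = icosphere(2)  # 162 vertices

    def smooth(m):
        return float(0.5 + 0.25 * np.tanh(m.positions[:, 2].mean() * 5.0))

    scorer = ScoringFunction(smooth, name="smooth_z")
    spec = mg.DeformationSpec(delta=0.05, range_R=0.5)
    field = mg.gradient_field(mesh, scorer, spec, rho=0.45)
    assert len(field.cover) < mesh.n_vertices  # genuinely sparse
    baseline = scorer(mesh)
    dense = np.array([
        mg.morphological_gradient_at(mesh, scorer, v, spec, baseline=baseline)
        for v in range(mesh.n_vertices)])
    agree = np.mean(np.sign(field.values) == np.sign(dense))
    assert agree >= 0.9


def test_field_respects_region_mask(sphere2):
    mask = sphere2.positions[:, 2] > 0.2
    scorer = max_z_scorer()
    field = mg.gradient_field(sphere2, scorer, mg.DeformationSpec(delta=0.05, range_R=0.5),
                              rho=0.5, region_mask=mask)
    assert np.all(field.values[~mask] == 0.0)
    assert np.all(np.isin(field.cover.cover_indices, np.flatnonzero(mask)))


def test_max_z_field_peaks_at_pole(sphere2):
    spec = mg.DeformationSpec(delta=0.05, range_R=0.3)
    field = mg.gradient_field(sphere2, max_z_scorer(), spec, rho=0.4)
    z = sphere2.positions[:, 2]
    top = field.values[z > 0.9].mean()
    equator_and_below = np.abs(field.values[z < 0.3]).mean()
    assert top > 0
    assert top > 5 * equator_and_below


# -- symmetrized field ---------------------------------------------------


def test_symmetrized_equals_plain_for_symmetric_setup(sphere2):
    scorer_a = max_z_scorer()
    scorer_b = max_z_scorer()
    spec = mg.DeformationSpec(delta=0.05, range_R=0.5)
    plain = mg.gradient_field(sphere2, scorer_a, spec, rho=0.5)
    sym = mg.symmetrized_field(sphere2, scorer_b, spec, rho=0.5, mirror_axis="x")
    # icosphere is exactly mirror-symmetric and max-z ignores x entirely
    np.testing.assert_allclose(sym.values, plain.values, atol=1e-9)


def test_symmetrized_field_is_mirror_symmetric(sphere2):
    def x_spread(m):
        c = m.positions[:, 0] - m.positions[:, 0].mean()
        return float(np.clip(0.5 + np.abs(c).mean(), 0, 1))

    scorer = ScoringFunction(x_spread, name="x_spread")
    spec = mg.DeformationSpec(delta=0.05, range_R=0.5)
    sym = mg.symmetrized_field(sphere2, scorer, spec, rho=0.4, mirror_axis="x")
    # pair each vertex with its mirror twin; field values must match
    mirrored = sphere2.positions * np.array([-1.0, 1.0, 1.0])
    from scipy.spatial import cKDTree

    d, twin = cKDTree(sphere2.positions).query(mirrored)
    assert d.max() < 1e-9  # icosphere is exactly symmetric
    np.testing.assert_allclose(sym.values, sym.values[twin], atol=5e-3)


def test_symmetrized_constant_scorer_is_zero(sphere2):
    sym = mg.symmetrized_field(sphere2, constant_scorer(), mg.DeformationSpec(), rho=0.5)
    np.testing.assert_array_equal(sym.values, 0.0)


# -- registry ------------------------------------------------------------


def test_scorer_registry_roundtrip():
    assert "constant" in mg.available_scorers()
    assert "analytic" in mg.available_scorers()
    with pytest.raises(KeyError, match="available"):
        mg.get_scorer("no_such_scorer")
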