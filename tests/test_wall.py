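"""Airway-wall constraint: ray marching, vertex projection, simplex build."""

import numpy as np
import pytest

from ebusreg import (AirwaySurface, CTVolume, FanSpec, InvalidInputError,
                     NoWallFoundError, Pose, WallConfig, first_wall_point,
                     initial_simplex, project_vertex, wall_adjust_pose)
from ebusreg.wall import _project_pose


def _tube_volume(inner_radius=8.0, shape=(60, 60, 40), spacing=1.0,
                 center=(30.0, 30.0)):
    """Air tube along z in tissue (wall = everything outside the lumen)."""
    xs = (np.arange(shape[0]) * spacing)[:, None, None]
    ys = (np.arange(shape[1]) * spacing)[None, :, None]
    rad2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    lumen = np.broadcast_to(rad2 <= inner_radius ** 2, shape)
    hu = np.where(lumen, -1000.0, 100.0).astype(np.float32)
    return CTVolume(hu=hu, spacing=(spacing,) * 3), lumen


def test_origin_in_wall_voxel_returns_it():
    """Zero-length march: an origin already above threshold returns its
    own voxel centre."""
    ct, _ = _tube_volume()
    origin = np.array([50.2, 30.1, 20.0])  # in tissue
    out = first_wall_point(ct, origin, np.array([1.0, 0.0, 0.0]))
    np.testing.assert_allclose(out, np.rint(origin), atol=1e-12)


def test_radial_ray_hits_tube_at_inner_radius():
    """From the axis of an 8 mm tube a radial ray reaches the wall at
    8 mm +/- one voxel diagonal."""
    ct, _ = _tube_volume(inner_radius=8.0)
    origin = np.array([30.0, 30.0, 20.0])
    for d in ([1.0, 0, 0], [0, 1.0, 0], [-1, 0, 0],
              [np.sqrt(0.5), np.sqrt(0.5), 0]):
        hit = first_wall_point(ct, origin, np.asarray(d, float))
        dist = np.linalg.norm(hit - origin)
        assert abs(dist - 8.0) <= np.sqrt(3.0)


def test_homogeneous_air_raises_no_wall():
    ct = CTVolume(hu=np.full((30, 30, 30), -1000.0, np.float32),
                  spacing=(1.0,) * 3)
    with pytest.raises(NoWallFoundError):
        first_wall_point(ct, np.array([15.0, 15.0, 15.0]),
                         np.array([0.0, 0.0, 1.0]))


def test_first_wall_point_input_validation():
    ct, _ = _tube_volume()
    with pytest.raises(InvalidInputError):
        first_wall_point(ct, np.array([30.0, 30.0, 20.0]),
                         np.array([2.0, 0.0, 0.0]))  # not unit
    with pytest.raises(InvalidInputError):
        first_wall_point(ct, np.array([500.0, 30.0, 20.0]),
                         np.array([1.0, 0.0, 0.0]))  # outside


def _surface_from_lumen(ct, lumen, centerline):
    from ebusreg import surface_from_mask
    return surface_from_mask(np.asarray(lumen), ct, centerline)


def test_project_vertex_idempotent_on_surface():
    ct, lumen = _tube_volume()
    cl = np.column_stack([np.full(40, 30.0), np.full(40, 30.0),
                          np.arange(40.0)])
    surface = _surface_from_lumen(ct, lumen, cl)
    ps = surface.surface_points[100]
    pi = np.array([38.0, 30.0, 20.0])
    out = project_vertex(ps, pi, surface, ct)
    np.testing.assert_allclose(out, ps)
    # and projecting the output again changes nothing
    np.testing.assert_allclose(project_vertex(out, pi, surface, ct), out)


def test_near_wall_candidate_accepted_unchanged():
    """A candidate above threshold within 1 mm of the surface is kept."""
    ct, lumen = _tube_volume()
    cl = np.column_stack([np.full(40, 30.0), np.full(40, 30.0),
                          np.arange(40.0)])
    surface = _surface_from_lumen(ct, lumen, cl)
    ps = surface.surface_points[200]
    outward = ps - np.array([30.0, 30.0, ps[2]])
    outward[2] = 0
    outward /= np.linalg.norm(outward)
    pv = ps + 0.5 * outward  # 0.5 mm outside, in tissue
    pi = ps
    out = project_vertex(pv, pi, surface, ct)
    np.testing.assert_allclose(out, pv)


def test_wrong_branch_resolved_via_centerline():
    """With two parallel tubes, a candidate whose nearest surface point is
    on the far tube lands back on the reference tube."""
    shape, spacing = (100, 40, 40), 1.0
    xs = (np.arange(shape[0]) * spacing)[:, None, None]
    ys = (np.arange(shape[1]) * spacing)[None, :, None]
    lumen_a = (xs - 25.0) ** 2 + (ys - 20.0) ** 2 <= 6.0 ** 2
    lumen_b = (xs - 75.0) ** 2 + (ys - 20.0) ** 2 <= 6.0 ** 2
    lumen = np.broadcast_to(lumen_a | lumen_b, shape)
    hu = np.where(lumen, -1000.0, 100.0).astype(np.float32)
    ct = CTVolume(hu=hu, spacing=(spacing,) * 3)
    cl = np.vstack([
        np.column_stack([np.full(40, 25.0), np.full(40, 20.0),
                         np.arange(40.0)]),
        np.column_stack([np.full(40, 75.0), np.full(40, 20.0),
                         np.arange(40.0)])])
    branches = np.repeat([0, 1], 40)
    from ebusreg import surface_from_mask
    surface = surface_from_mask(np.asarray(lumen), ct, cl, branches)
    pi = np.array([31.0, 20.0, 20.0])   # wall of tube A (+x side)
    pv = np.array([55.0, 20.0, 20.0])   # between tubes, nearer tube B wall
    ps = surface.nearest_surface_point(pv)
    assert ps[0] > 50.0                 # confirms naive NN picks tube B
    assert (pv - pi) @ (pv - ps) <= 0   # dot-product test fires
    out = project_vertex(pv, pi, surface, ct)
    # oracle: exhaustive nearest-surface search restricted to tube A
    tube_a_pts = surface.surface_points[surface.surface_points[:, 0] < 50.0]
    d_a = np.linalg.norm(tube_a_pts - out, axis=1).min()
    assert d_a <= np.sqrt(3.0)          # result lies on tube A's wall
    assert out[0] < 50.0


def test_nearest_neighbor_matches_brute_force(small_phantom, rng):
    surface = small_phantom.surface
    pts = surface.surface_points
    for _ in range(20):
        q = rng.uniform(pts.min(axis=0), pts.max(axis=0))
        nn = surface.nearest_surface_point(q)
        brute = pts[np.argmin(np.linalg.norm(pts - q, axis=1))]
        assert np.linalg.norm(nn - q) == pytest.approx(
            np.linalg.norm(brute - q))


def test_initial_simplex_zero_increments_warns_and_degenerates(small_phantom):
    pg = small_phantom.gt_poses[0]
    with pytest.warns(UserWarning, match="degenerate"):
        vertices = initial_simplex(pg, (0.0,) * 6, small_phantom.surface,
                                   small_phantom.ct)
    assert len(vertices) == 7
    assert all(v == vertices[0] for v in vertices)


def test_initial_simplex_positions_on_wall(small_phantom):
    """All seven vertices satisfy the wall condition (probe origin HU above
    threshold) and perturbed vertices keep their perturbed angles."""
    from ebusreg import pose_to_frame
    pg = small_phantom.gt_poses[0]
    vertices = initial_simplex(pg, surface=small_phantom.surface,
                               ct=small_phantom.ct)
    cfg = WallConfig()
    fan = FanSpec()
    for v in vertices:
        s_us = pose_to_frame(v, fan).s_us
        assert small_phantom.ct.hu_at_voxel(s_us) > cfg.hu_threshold
    assert vertices[1].a == pytest.approx(pg.a + 25.0)
    assert vertices[3].c == pytest.approx(pg.c + 25.0)


def test_flat_wall_translation_projects_along_wall():
    """On a flat wall, a 2.5 mm in-plane perturbation lands ~2.5 mm away
    along the wall."""
    shape, spacing = (40, 40, 40), 1.0
    hu = np.full(shape, -1000.0, dtype=np.float32)
    hu[:, :, 20:] = 100.0  # wall half-space z >= 20
    ct = CTVolume(hu=hu, spacing=(spacing,) * 3)
    wall_idx = np.argwhere(hu > -600)[:, 2] == 20
    pts = np.argwhere(hu > -600)[wall_idx].astype(float)
    cl = np.column_stack([np.arange(40.0), np.full(40, 20.0),
                          np.full(40, 10.0)])
    surface = AirwaySurface(surface_points=pts, centerline_points=cl)
    # pitch -90 deg turns the probe axis to +z (pointing at the wall)
    pose = Pose(b=-90.0, tx=26.0, ty=20.0, tz=14.0)
    base = wall_adjust_pose(pose, ct, FanSpec())
    from ebusreg import pose_to_frame
    s0 = pose_to_frame(base, FanSpec()).s_us
    assert s0[2] == pytest.approx(20.0)
    shifted = Pose(b=-90.0, tx=base.tx, ty=base.ty + 2.5, tz=base.tz)
    proj = _project_pose(shifted, s0, surface, ct, FanSpec(), WallConfig())
    s1 = pose_to_frame(proj, FanSpec()).s_us
    assert s1[2] == pytest.approx(20.0, abs=1.0)       # still on the wall
    assert np.linalg.norm(s1 - s0) == pytest.approx(2.5, abs=1.0)


def test_surface_csv_round_trip(tmp_path, small_phantom):
    surface = small_phantom.surface
    sp = tmp_path / "surface.csv"
    cp = tmp_path / "centerline.csv"
    surface.to_csv(sp, cp)
    back = AirwaySurface.from_csv(sp, cp)
    np.testing.assert_allclose(back.surface_points, surface.surface_points,
                               atol=1e-5)
    np.testing.assert_allclose(back.centerline_points,
                               surface.centerline_points, atol=1e-5)
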