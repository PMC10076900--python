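"""The five thickness methods against analytic and brute-force oracles."""
import numpy as np
import pytest

from conftest import trivial_labeling

from cartithick._geometry import fit_sphere, uv_sphere_directions, uv_sphere_vertex_count
from cartithick.errors import MethodFailureError
from cartithick.phantoms import make_slab_phantom
from cartithick.surfaces import SurfacePair, build_mesh, extract_surfaces_femur, extract_surfaces_tibia
from cartithick.thickness import (
    RaySphereConfig,
    fit_slice_polynomial,
    place_ray_spheres,
    sphere_ray_bundle,
    thickness_centerline_2d,
    thickness_mesh_normals,
    thickness_nearest_neighbors,
    thickness_ray_tracing,
    thickness_surface_normals_2d,
)
from cartithick.thickness.planar import SliceSkipped
from cartithick.volume_io import TIBIAL_CARTILAGE, VoxelPointSet, extract_structure_points

SPACING = (0.36, 0.7, 0.36)


def parallel_plane_pair(t_voxels=5, n=8, m=8):
    d = np.array([(i, j, t_voxels) for i in range(n) for j in range(m)])
    p = np.array([(i, j, 0) for i in range(n) for j in range(m)])
    return SurfacePair(
        distal=VoxelPointSet(d, SPACING), proximal=VoxelPointSet(p, SPACING), structure="tibia"
    )


# ---------------------------------------------------------------- 3D-MN


def test_mesh_normals_parallel_planes_exact():
    pair = parallel_plane_pair(t_voxels=5)
    lab = trivial_labeling(pair.distal, "tibia", "cLT")
    dmesh = build_mesh(pair.distal, "xy")
    pmesh = build_mesh(pair.proximal, "xy")
    tmap = thickness_mesh_normals(dmesh, pmesh, lab, "tibia")
    np.testing.assert_allclose(tmap.values, 5 * SPACING[2], atol=1e-9)
    assert len(tmap) == len(pair.distal)


def test_mesh_normals_shell_recovers_thickness(shell_points, shell_labeling):
    pair = extract_surfaces_femur(shell_points, np.zeros(len(shell_points), bool))
    tmap = thickness_mesh_normals(
        build_mesh(pair.distal, "xy"), build_mesh(pair.proximal, "xy"), shell_labeling, "femur"
    )
    assert abs(tmap.values.mean() - 2.0) < 0.36


def test_mesh_normals_failure_on_disjoint_meshes():
    pair = parallel_plane_pair()
    far = VoxelPointSet(pair.proximal.indices + np.array([500, 500, 0]), SPACING)
    lab = trivial_labeling(pair.distal, "tibia", "cLT")
    with pytest.raises(MethodFailureError):
        thickness_mesh_normals(
            build_mesh(pair.distal, "xy"), build_mesh(far, "xy"), lab, "tibia"
        )


# ---------------------------------------------------------------- 3D-NN


def test_nearest_neighbors_identical_sets_zero():
    d = np.array([(i, j, 0) for i in range(5) for j in range(5)])
    pair = SurfacePair(
        distal=VoxelPointSet(d, SPACING), proximal=VoxelPointSet(d.copy(), SPACING),
        structure="tibia",
    )
    lab = trivial_labeling(pair.distal, "tibia", "cLT")
    tmap = thickness_nearest_neighbors(pair, lab)
    np.testing.assert_allclose(tmap.values, 0.0)


def test_nearest_neighbors_parallel_planes():
    pair = parallel_plane_pair(t_voxels=4)
    lab = trivial_labeling(pair.distal, "tibia", "cLT")
    tmap = thickness_nearest_neighbors(pair, lab)
    np.testing.assert_allclose(tmap.values, 4 * SPACING[2], atol=1e-12)


def test_nearest_neighbors_matches_brute_force_all_pairs():
    rng = np.random.default_rng(5)
    d = np.unique(rng.integers(0, 40, size=(500, 3)), axis=0)
    p = np.unique(rng.integers(0, 40, size=(500, 3)), axis=0)
    pair = SurfacePair(
        distal=VoxelPointSet(d, SPACING), proximal=VoxelPointSet(p, SPACING), structure="tibia"
    )
    lab = trivial_labeling(pair.distal, "tibia", "cLT")
    tmap = thickness_nearest_neighbors(pair, lab)
    dd = np.linalg.norm(
        (d * SPACING)[:, None, :] - (p * SPACING)[None, :, :], axis=2
    ).min(axis=1)
    np.testing.assert_allclose(np.sort(tmap.values), np.sort(dd), atol=1e-12)


# ---------------------------------------------------------------- 3D-RT


def test_uv_sphere_vertex_counts():
    assert uv_sphere_vertex_count(60, 60) == 3482
    assert uv_sphere_vertex_count(3, 3) == 5
    assert len(uv_sphere_directions(3, 3)) == 5


def test_uv_sphere_directions_unit_and_symmetric():
    dirs = uv_sphere_directions(60, 60)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(dirs.mean(axis=0), 0.0, atol=1e-12)


def test_sphere_fit_recovers_shell_center(shell_points, shell_phantom):
    pair = extract_surfaces_femur(shell_points, np.zeros(len(shell_points), bool))
    center, radius = fit_sphere(pair.distal.coords)
    true_c = shell_phantom.params["center"]
    assert np.linalg.norm(center - true_c) < max(SPACING)
    assert abs(radius - 22.0) < 0.5  # outer surface voxel centers sit near R + t


def test_place_ray_spheres_returns_eight_centers(knee_points, knee_labeling, knee_surfaces):
    tibia, femur = knee_points
    _, fem_surf = knee_surfaces
    cfg = place_ray_spheres(tibia, femur, knee_labeling, fem_surf)
    assert set(cfg.centers) == {"LT", "MT", "aLF", "aMF", "cLF", "cMF", "pLF", "pMF"}
    assert cfg.rays_per_sphere == 3482
    # tibial centers directly below (bone-ward of) plate centroids
    for name in ("LT", "MT"):
        mask = knee_labeling.select([f"{p}{name[0]}T" for p in "ceiap"])
        cen = knee_labeling.coords[mask].mean(axis=0)
        np.testing.assert_allclose(cfg.centers[name][:2], cen[:2], atol=1e-9)
        assert cfg.centers[name][2] == pytest.approx(cen[2] + 10.0)


def test_ray_bundle_origin_on_sphere_surface():
    cfg = RaySphereConfig(centers={"LT": np.array([1.0, 2.0, 3.0])}, radius=2.0)
    origins, dirs = sphere_ray_bundle(cfg)["LT"]
    assert len(origins) == 3482
    np.testing.assert_allclose(
        np.linalg.norm(origins - [1.0, 2.0, 3.0], axis=1), 2.0, atol=1e-12
    )


def _slab_rt(slab_points, slab_labeling, offset, max_steps=250):
    center = slab_points.coords.mean(axis=0) + np.array([offset, 0.0, 25.0])
    cfg = RaySphereConfig(centers={"LT": center}, step_mm=0.18, max_steps=max_steps)
    return thickness_ray_tracing(slab_points, slab_labeling, cfg, "tibia")


def test_ray_tracing_perpendicular_slab(slab_points, slab_labeling):
    tmap = _slab_rt(slab_points, slab_labeling, offset=0.0)
    assert abs(tmap.values.mean() - 2.0) < 0.36
    assert abs(np.median(tmap.values) - 2.0) < 0.36
    assert len(tmap) < 3482  # fewer samples than rays


@pytest.mark.parametrize("tilt", [0.0, 30.0])
def test_ray_tracing_oblique_chord_closed_form(tilt):
    """A single vertical ray through a slab tilted by theta reports t/cos(theta).

    A (3, 3) tessellation yields the two pole rays plus three horizontal
    ones, so exactly one ray (the -z pole) pierces the slab; its chord must
    match the closed-form oblique crossing within one voxel + one step.
    """
    ph = make_slab_phantom(thickness=2.0, extent=(20.0, 20.0), tilt_deg=tilt)
    pts = extract_structure_points(ph.volume, TIBIAL_CARTILAGE)
    lab = trivial_labeling(pts, "tibia", "cLT")
    center = pts.coords.mean(axis=0) + np.array([0.0, 0.0, 15.0])
    cfg = RaySphereConfig(centers={"LT": center}, n_polar=3, n_azimuthal=3,
                          step_mm=0.18, max_steps=200)
    tmap = thickness_ray_tracing(pts, lab, cfg, "tibia")
    assert len(tmap) == 1
    expect = 2.0 / np.cos(np.deg2rad(tilt))
    assert abs(tmap.values[0] - expect) < SPACING[2] + 0.18 + 0.1


def test_ray_tracing_no_entry_rays_counted(slab_points, slab_labeling):
    tmap = _slab_rt(slab_points, slab_labeling, offset=0.0)
    assert tmap.counts["no_entry"] + len(tmap) + tmap.counts["no_exit"] == 3482


# ---------------------------------------------------------------- 2D fits


def test_fit_recovers_exact_cubic():
    x = np.linspace(0.0, 10.0, 30)
    coeffs = np.array([0.01, -0.2, 1.5, 3.0])
    z = np.polyval(coeffs, x)
    fit = fit_slice_polynomial(x, z, "centerline")
    np.testing.assert_allclose(fit.coeffs, coeffs, rtol=1e-8, atol=1e-10)
    with pytest.raises(ValueError):
        fit(11.5)  # outside the fit domain


def test_fit_requires_five_distinct_x():
    with pytest.raises(SliceSkipped):
        fit_slice_polynomial(np.array([0, 1, 2, 3.0]), np.zeros(4), "distal")


def test_fit_horizontal_band_centerline_is_mid_height():
    x = np.repeat(np.arange(20.0), 5)
    z = np.tile(np.arange(5.0), 20)
    fit = fit_slice_polynomial(x, z, "centerline")
    np.testing.assert_allclose(fit(np.arange(20.0)), 2.0, atol=1e-8)


def test_fit_noisy_cubic_residual_bounded():
    rng = np.random.default_rng(11)
    x = np.linspace(0, 20, 100)
    z = np.polyval([0.005, -0.1, 0.8, 1.0], x) + rng.normal(0, 0.1, 100)
    fit = fit_slice_polynomial(x, z, "centerline")
    rms = np.sqrt(np.mean((fit(x) - z) ** 2))
    assert rms < 0.1 * 1.2


# ---------------------------------------------------------------- 2D-CN


def test_centerline_2d_horizontal_band(slab_points, slab_labeling):
    tmap = thickness_centerline_2d(slab_points, slab_labeling, "tibia")
    # outline-accurate endpoints: occupied span +- one pixel
    span = (np.ptp(slab_points.indices[:, 2]) + 1) * SPACING[2]
    assert abs(tmap.values.mean() - span) < SPACING[2]
    assert len(tmap) == len(np.unique(slab_points.indices[:, [0, 1]], axis=0))


def test_centerline_2d_tilted_band_reports_normal_thickness():
    ph = make_slab_phantom(thickness=2.0, extent=(20.0, 20.0), tilt_deg=30.0)
    pts = extract_structure_points(ph.volume, TIBIAL_CARTILAGE)
    lab = trivial_labeling(pts, "tibia", "cLT")
    tmap = thickness_centerline_2d(pts, lab, "tibia")
    # normal distance ~ t, not t / cos(30) = 2.31
    assert abs(tmap.values.mean() - 2.0) < 0.36


def test_centerline_2d_annulus_radial_thickness():
    """Curved band (quarter annulus) of radial thickness t reports ~ t."""
    sp = (0.36, 0.7, 0.36)
    R, t = 15.0, 2.0
    rows = []
    for i in range(80):
        for k in range(80):
            x, z = i * sp[0], k * sp[2]
            r = np.hypot(x, z)
            if R <= r <= R + t and x <= r * np.sin(np.deg2rad(60)):
                rows.append((i, 0, k))
    pts = VoxelPointSet(np.array(rows), sp)
    lab = trivial_labeling(pts, "tibia", "cLT")
    tmap = thickness_centerline_2d(pts, lab, "tibia")
    assert abs(np.median(tmap.values) - t) < 0.36


# ---------------------------------------------------------------- 2D-SN


def test_surface_normals_2d_parallel_lines(slab_points, slab_labeling):
    tmap = thickness_surface_normals_2d(slab_points, slab_labeling, "tibia")
    span = np.ptp(slab_points.indices[:, 2]) * SPACING[2]
    np.testing.assert_allclose(tmap.values, span, atol=1e-6)


def test_surface_normals_2d_tilted_proximal_point_line_distance():
    """Flat distal, tilted proximal: sample = perpendicular point-line distance."""
    sp = (0.36, 0.7, 0.36)
    rows = []
    n = 40
    for i in range(n):
        k_top = 20
        k_bot = int(round(3 + 0.25 * i))  # proximal line z = (3 + 0.25 i) * sz
        for k in range(k_bot, k_top + 1):
            rows.append((i, 0, k))
    pts = VoxelPointSet(np.array(rows), sp)
    lab = trivial_labeling(pts, "tibia", "cLT")
    tmap = thickness_surface_normals_2d(pts, lab, "tibia")
    # oracle: distance from (x, 20*sz) to the continuous proximal line
    slope = 0.25 * sp[2] / sp[0]

    def point_line(x):
        z0 = 20 * sp[2]
        zl = 3 * sp[2] + slope * x
        return (z0 - zl) / np.sqrt(1 + slope**2)

    xs = tmap.origins[:, 0]
    expect = point_line(xs)
    inner = (xs > 3) & (xs < (n - 1) * sp[0] - 3)  # away from staircase edges
    assert np.median(np.abs(tmap.values[inner] - expect[inner])) < 0.2


def test_methods_report_nonnegative_and_capped(slab_points, slab_labeling):
    for fn in (thickness_centerline_2d, thickness_surface_normals_2d):
        tmap = fn(slab_points, slab_labeling, "tibia")
        assert tmap.values.min() >= 0
        assert tmap.values.max() <= 15.0
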