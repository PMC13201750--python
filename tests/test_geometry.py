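import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sntarget.atlas import LabelAtlas
from sntarget.geometry import (
    NativeFrame,
    PlaneSpec,
    angle_to_plane,
    bejjani_origin,
    depth_along_trajectory,
    extend_virtual,
    extract_features,
    find_max_rn_plane,
    line_plane_intersection,
    trajectory_norm,
)
from sntarget.models import Lead, get_lead_model
from sntarget.synthetic import AnatomyParams, make_atlas, make_frame, make_lead

MODEL = get_lead_model("Medtronic 3389")


def make_test_lead(contacts, hemisphere="right", virtual=None):
    return Lead("t", hemisphere, MODEL, np.asarray(contacts, dtype=float), virtual)


# ----------------------------------------------------------------- angles


@pytest.mark.parametrize(
    "direction, normal, expected",
    [
        ((0, 0, 1), (0, 0, 1), 90.0),  # line along the normal
        ((1, 0, 0), (0, 0, 1), 0.0),  # line in the plane
        ((1, 0, 1), (0, 0, 1), 45.0),  # symmetric oblique
    ],
)
def test_angle_to_plane_reference_cases(direction, normal, expected):
    plane = PlaneSpec((0, 0, 0), normal)
    assert angle_to_plane(np.array(direction, float), plane) == pytest.approx(expected)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_angle_to_plane_complements_normal_angle(seed):
    """Line-to-plane and line-to-normal angles always sum to 90 degrees."""
    rng = np.random.default_rng(seed)
    l = rng.normal(size=3)
    n = rng.normal(size=3)
    if np.linalg.norm(l) < 1e-6 or np.linalg.norm(n) < 1e-6:
        return
    n /= np.linalg.norm(n)
    plane = PlaneSpec(rng.normal(size=3), n)
    to_plane = angle_to_plane(l, plane)
    cosang = abs(l @ n) / np.linalg.norm(l)
    to_normal = np.degrees(np.arccos(min(1.0, cosang)))
    assert to_plane + to_normal == pytest.approx(90.0, abs=1e-9)
    assert 0.0 <= to_plane <= 90.0
    # symmetric under flipping either vector
    assert angle_to_plane(-l, plane) == pytest.approx(to_plane, abs=1e-9)
    assert angle_to_plane(l, PlaneSpec(plane.point, -n)) == pytest.approx(to_plane, abs=1e-9)


def test_angle_to_plane_rejects_zero_direction():
    with pytest.raises(ValueError, match="non-zero"):
        angle_to_plane(np.zeros(3), PlaneSpec((0, 0, 0), (0, 0, 1)))


# ------------------------------------------------------------ trajectory norm


def test_trajectory_norm_reference_cases():
    lead = make_test_lead([[0, 0, 0], [0, 0, 5], [0, 0, 10]])
    assert np.allclose(trajectory_norm(lead), [0, 0, 1])
    lead = make_test_lead([[0, 0, 0], [3, 0, 4], [6, 0, 8], [9, 0, 12]])
    assert np.allclose(trajectory_norm(lead), [0.6, 0, 0.8])


def test_trajectory_norm_matches_svd_line_fit():
    """Direction from the end contacts equals the least-squares line direction."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if d[2] < 0:
            d = -d
        ts = np.sort(rng.uniform(0, 10, size=4))
        contacts = rng.normal(size=3) + ts[:, None] * d
        if d[2] < 1e-3:  # ventral ordering ill-defined for near-axial lines
            continue
        got = trajectory_norm(make_test_lead(contacts))
        centered = contacts - contacts.mean(axis=0)
        svd_dir = np.linalg.svd(centered)[2][0]
        if svd_dir @ d < 0:
            svd_dir = -svd_dir
        assert np.allclose(got, svd_dir, atol=1e-9)


def test_trajectory_norm_translation_invariant():
    contacts = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 7.0]])
    shift = np.array([10.0, -4.0, 2.5])
    a = trajectory_norm(make_test_lead(contacts))
    b = trajectory_norm(make_test_lead(contacts + shift))
    assert np.allclose(a, b)


def test_trajectory_norm_rejects_coincident_endpoints():
    # end contacts coincide but the set is not a single point
    contacts = np.array([[0, 0, 0], [0.04, 0, 0], [0, 0, 0]], dtype=float)
    with pytest.raises(ValueError, match="coincide"):
        trajectory_norm(make_test_lead(contacts))


# ------------------------------------------------------------ virtual extension


def test_extend_virtual_axis_aligned_example():
    lead = make_test_lead([[0, 0, 10], [0, 0, 16]])
    out = extend_virtual(lead, (2.0,))
    assert np.allclose(out.contacts[0], [0, 0, 8])
    assert out.virtual_flags[0] and not out.virtual_flags[1:].any()


def test_extend_virtual_default_three_contacts():
    lead = make_test_lead([[0, 0, 0], [1.5, 1.0, 4.0]])
    out = extend_virtual(lead)
    virt = out.contacts[out.virtual_flags]
    assert len(virt) == 3
    gaps = np.linalg.norm(np.diff(virt, axis=0), axis=1)
    assert np.allclose(gaps, 2.0, atol=1e-9)
    # distances from the ventralmost implanted contact equal the extensions
    dists = np.linalg.norm(virt - lead.contacts[0], axis=1)
    assert np.allclose(sorted(dists), [2.0, 4.0, 6.0], atol=1e-9)
    # collinearity preserved to high precision
    direction = trajectory_norm(out)
    centered = out.contacts - out.contacts.mean(axis=0)
    perp = centered - np.outer(centered @ direction, direction)
    assert np.linalg.norm(perp, axis=1).max() < 1e-9


def test_extend_virtual_validates_extensions():
    lead = make_test_lead([[0, 0, 0], [0, 0, 4]])
    with pytest.raises(ValueError, match="strictly increasing"):
        extend_virtual(lead, (4.0, 2.0))
    with pytest.raises(ValueError, match="positive"):
        extend_virtual(lead, (-1.0,))


# ------------------------------------------------------------------- depth


def test_depth_along_trajectory_cases():
    plane = PlaneSpec((0, 0, 0), (0, 0, 1))
    vertical = make_test_lead([[0, 0, -10], [0, 0, 5]])
    assert depth_along_trajectory(np.array([0, 0, -4.0]), vertical, plane) == pytest.approx(4.0)
    assert depth_along_trajectory(np.array([0, 0, 0.0]), vertical, plane) == pytest.approx(0.0)
    # 60 degrees to the plane: 2 mm of z-drop is 2/sin(60) of arc
    d = np.array([np.cos(np.radians(60)), 0, np.sin(np.radians(60))])
    oblique = make_test_lead([(-10 * d).tolist(), (5 * d).tolist()])
    contact = -2.0 / np.sin(np.radians(60)) * d
    assert depth_along_trajectory(contact, oblique, plane) == pytest.approx(
        2.0 / np.sin(np.radians(60))
    )


def test_depth_at_least_z_drop():
    """Arc-length depth dominates the plain z-offset, equal only when vertical."""
    rng = np.random.default_rng(3)
    plane = PlaneSpec((0, 0, 0), (0, 0, 1))
    for _ in range(100):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if abs(d[2]) < 0.1:
            continue
        if d[2] < 0:
            d = -d
        lead = make_test_lead([(-8 * d).tolist(), (8 * d).tolist()])
        t = rng.uniform(-5, 5)
        contact = t * d
        depth = depth_along_trajectory(contact, lead, plane)
        assert abs(depth) >= abs(contact[2]) - 1e-12


def test_depth_errors_when_parallel():
    plane = PlaneSpec((0, 0, 0), (0, 0, 1))
    flat = make_test_lead([[0, 0, 0], [5, 0, 0]])
    with pytest.raises(ValueError, match="parallel"):
        depth_along_trajectory(np.array([1.0, 0, 0]), flat, plane)


# ------------------------------------------------------------- atlas planes


def test_max_rn_plane_at_rn_equator(atlas, frame):
    plane = find_max_rn_plane(atlas, frame, "right")
    assert plane.point[2] == pytest.approx(-3.0, abs=atlas.voxel_size[2])
    assert np.allclose(plane.normal, [0, 0, 1])


def test_max_rn_plane_tie_breaks_ventral():
    """Two equally large slices resolve to the more ventral one."""
    labels = np.zeros((9, 9, 9), dtype=np.int16)
    labels[2:6, 2:6, 3] = 5  # RN_R, 16 voxels
    labels[2:6, 2:6, 6] = 5  # same count, more dorsal
    affine = np.eye(4)
    affine[:3, 3] = (1.0, -4.0, -4.0)  # keep the block in the right hemisphere
    atlas = LabelAtlas(labels, affine, {"RN_R": 5})
    frame = NativeFrame((0, 10, 0), (0, -10, 0), (0, 0, 50))
    plane = find_max_rn_plane(atlas, frame, "right")
    assert plane.point[2] == pytest.approx(-1.0)  # k=3 -> z=-4+3


def test_max_rn_plane_requires_rn(frame):
    empty = LabelAtlas(np.zeros((4, 4, 4), dtype=np.int16), np.eye(4), {"RN_R": 5})
    with pytest.raises(ValueError, match="red-nucleus"):
        find_max_rn_plane(empty, frame, "right")


def test_bejjani_origin_construction(atlas, frame, anatomy):
    """Origin sits at the anterior RN tangent and the medial STN face."""
    origin = bejjani_origin(atlas, frame, "right")
    rn_anterior = anatomy.rn_spec.center[1] + anatomy.rn_spec.semi_axes[1]
    vs = anatomy.voxel_size_mm
    assert origin[1] == pytest.approx(rn_anterior, abs=2 * vs)
    # brute-force voxel scan in the max-RN slice as the oracle
    plane = find_max_rn_plane(atlas, frame, "right")
    k = int(round((plane.point[2] - atlas.affine[2, 3]) / atlas.affine[2, 2]))
    rn_pts = atlas.voxel_centers(atlas.mask("RN", "right"))
    rn_slice = rn_pts[np.isclose(rn_pts[:, 2], plane.point[2])]
    y0 = rn_slice[:, 1].max()
    stn_pts = atlas.voxel_centers(atlas.mask("STN", "right"))
    stn_slice = stn_pts[np.isclose(stn_pts[:, 2], plane.point[2])]
    band = stn_slice[np.abs(stn_slice[:, 1] - y0) <= 0.5]
    assert origin[0] == pytest.approx(band[:, 0].min())
    assert origin[1] == pytest.approx(y0)


def test_bejjani_origin_mirror_symmetry(atlas, frame):
    right = bejjani_origin(atlas, frame, "right")
    left = bejjani_origin(atlas, frame, "left")
    assert left[0] == pytest.approx(-right[0])
    assert left[1:] == pytest.approx(right[1:])


# ---------------------------------------------------------------- features


def test_extract_features_round_trips_requested_values(atlas, frame):
    origin = bejjani_origin(atlas, frame, "right")
    target = origin + np.array([1.5, 0.0, 0.0])
    lead = make_lead(MODEL, target, 22.0, 55.0, 4.0, frame)
    f = extract_features(lead, atlas, frame)
    assert f.x_mm == pytest.approx(1.5, abs=1e-6)
    assert f.y_mm == pytest.approx(0.0, abs=1e-6)
    assert f.ms_angle == pytest.approx(22.0, abs=1e-6)
    assert f.acpc_angle == pytest.approx(55.0, abs=1e-6)


def test_extract_features_crossing_at_origin_is_zero(atlas, frame):
    origin = bejjani_origin(atlas, frame, "right")
    lead = make_lead(MODEL, origin, 20.0, 50.0, 3.0, frame)
    f = extract_features(lead, atlas, frame)
    assert f.x_mm == pytest.approx(0.0, abs=1e-9)
    assert f.y_mm == pytest.approx(0.0, abs=1e-9)


def test_left_hemisphere_mirror_gives_identical_features(atlas, frame):
    origin_r = bejjani_origin(atlas, frame, "right")
    target_r = origin_r + np.array([1.2, -0.5, 0.0])
    lead_r = make_lead(MODEL, target_r, 23.0, 52.0, 4.0, frame)
    mirrored = lead_r.contacts * np.array([-1.0, 1.0, 1.0])
    lead_l = Lead("t", "left", MODEL, mirrored)
    fr = extract_features(lead_r, atlas, frame)
    fl = extract_features(lead_l, atlas, frame)
    assert fl.as_array() == pytest.approx(fr.as_array(), abs=1e-9)


def test_features_invariant_under_rigid_translation(atlas, frame, anatomy):
    shift = np.array([3.0, -7.0, 11.0])
    affine = atlas.affine.copy()
    affine[:3, 3] += shift
    moved_atlas = LabelAtlas(atlas.labels, affine, dict(atlas.label_table))
    moved_frame = NativeFrame(
        np.asarray(anatomy.ac) + shift,
        np.asarray(anatomy.pc) + shift,
        np.asarray(anatomy.midline_vertex) + shift,
    )
    origin = bejjani_origin(atlas, frame, "right")
    lead = make_lead(MODEL, origin + np.array([1.0, 0.5, 0.0]), 21.0, 49.0, 4.0, frame)
    moved_lead = Lead(lead.lead_id, lead.hemisphere, lead.model, lead.contacts + shift)
    f0 = extract_features(lead, atlas, frame)
    f1 = extract_features(moved_lead, moved_atlas, moved_frame)
    assert f1.as_array() == pytest.approx(f0.as_array(), abs=1e-9)


def test_line_plane_intersection_parallel_errors():
    plane = PlaneSpec((0, 0, 0), (0, 0, 1))
    with pytest.raises(ValueError, match="parallel"):
        line_plane_intersection(np.array([0.0, 0, 1]), np.array([1.0, 0, 0]), plane)
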