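import numpy as np
import pytest

from fosmap.atlas import atlas_section
from fosmap.evaluation import rigid_errors
from fosmap.registration import (
    Deformation,
    RigidParams,
    SliceImage,
    SliceRegistration,
    estimate_ap,
    fit_rigid,
    identity_registration,
    inverse_transform_points,
    refine_elastic,
    register_slice,
    similarity,
    transform_point,
    transform_points,
)


def _plane_extent(atlas):
    return (atlas.shape[1] * atlas.spacing_um[1], atlas.shape[2] * atlas.spacing_um[2])


# ---------------------------------------------------------------------------
# transforms

def test_identity_registration_is_voxel_center_embedding(small_atlas):
    atlas = small_atlas
    reg = identity_registration(atlas, ap_um=1250.0)
    H, W = atlas.shape[1], atlas.shape[2]
    # pixel grid at atlas resolution: pixel (x, y) is voxel (dv=y, ml=x)
    coords, region = transform_point(reg, atlas, (7, 11), atlas.spacing_um[1], (H, W))
    ap_i = int(1250.0 / atlas.spacing_um[0])
    assert region == atlas.annotation[ap_i, 11, 7]
    assert coords[1] == pytest.approx((11 + 0.5) * atlas.spacing_um[1])
    assert coords[2] == pytest.approx((7 + 0.5) * atlas.spacing_um[2])


def test_zero_deformation_matches_rigid_only(small_atlas):
    atlas = small_atlas
    rigid = RigidParams(ap_um=1000.0, rotation_deg=7.0, scale=1.1, tx_um=40.0, ty_um=-30.0)
    extent = _plane_extent(atlas)
    reg0 = SliceRegistration(rigid=rigid,
                             deformation=Deformation((2, 2), extent), atlas_name=atlas.name)
    reg1 = SliceRegistration(rigid=rigid,
                             deformation=Deformation((4, 4), extent), atlas_name=atlas.name)
    pts = np.random.default_rng(0).uniform(0, 39, size=(50, 2))
    c0, r0 = transform_points(reg0, atlas, pts, 50.0, (80, 80))
    c1, r1 = transform_points(reg1, atlas, pts, 50.0, (80, 80))
    assert np.array_equal(c0, c1)
    assert np.array_equal(r0, r1)


def test_transform_point_bounds_check(small_atlas):
    reg = identity_registration(small_atlas, 500.0)
    with pytest.raises(ValueError):
        transform_point(reg, small_atlas, (1000, 2), 100.0, (40, 40))


def test_roundtrip_with_elastic(small_atlas):
    atlas = small_atlas
    rng = np.random.default_rng(1)
    extent = _plane_extent(atlas)
    reg = SliceRegistration(
        rigid=RigidParams(ap_um=2000.0, rotation_deg=-9.0, scale=0.93,
                          tx_um=120.0, ty_um=-60.0, hflip=True),
        deformation=Deformation((3, 3), extent,
                                displacements_um=rng.uniform(-100, 100, (3, 3, 2)),
                                cap_um=300.0),
        atlas_name=atlas.name,
    )
    px, shape = 50.0, (80, 80)
    grid = np.stack(np.meshgrid(np.linspace(5, 74, 20), np.linspace(5, 74, 20)),
                    axis=-1).reshape(-1, 2)
    coords, _ = transform_points(reg, atlas, grid, px, shape)
    back = inverse_transform_points(reg, atlas, coords, px, shape)
    assert np.abs(back - grid).max() < 0.5


def test_registration_json_roundtrip(tmp_path, small_atlas):
    extent = _plane_extent(small_atlas)
    reg = SliceRegistration(
        rigid=RigidParams(ap_um=1234.5, rotation_deg=3.25, scale=1.01,
                          tx_um=-17.5, ty_um=8.25, hflip=True),
        deformation=Deformation((3, 4), extent,
                                displacements_um=np.arange(24).reshape(3, 4, 2) * 1.5),
        atlas_name="atlas-x",
        provenance={"method": "manual", "score": 0.5},
    )
    path = tmp_path / "reg.json"
    reg.save(path)
    loaded = SliceRegistration.load(path)
    assert loaded.rigid == reg.rigid
    assert loaded.atlas_name == reg.atlas_name
    assert loaded.provenance == reg.provenance
    assert np.array_equal(loaded.deformation.displacements_um,
                          reg.deformation.displacements_um)


def test_deformation_validation():
    with pytest.raises(ValueError):
        Deformation((1, 1), (100.0, 100.0))
    with pytest.raises(ValueError):
        Deformation((2, 2), (100.0, 100.0),
                    displacements_um=np.full((2, 2, 2), 1000.0), cap_um=10.0)


def test_rigid_params_validation():
    with pytest.raises(ValueError):
        RigidParams(ap_um=0, scale=-1.0)
    with pytest.raises(ValueError):
        RigidParams(ap_um=0, rotation_deg=270.0)


# ---------------------------------------------------------------------------
# similarity

def test_similarity_self_is_maximal_over_sections(atlas):
    ap_i = 30
    section = atlas.annotation[ap_i]
    self_score = similarity(section.astype(float), section)
    others = [similarity(section.astype(float), atlas.annotation[i])
              for i in range(0, atlas.shape[0], 4) if i != ap_i]
    assert self_score > max(others)


def test_similarity_degenerate_inputs_score_zero(atlas):
    section = atlas.annotation[30]
    assert similarity(np.zeros_like(section, dtype=float), section) == 0.0
    assert similarity(section.astype(float), np.zeros_like(section)) == 0.0


def test_similarity_affine_intensity_invariance(atlas):
    rng = np.random.default_rng(0)
    section = atlas.annotation[28]
    image = section.astype(float) + rng.normal(0, 0.05, section.shape)
    a = similarity(image, section)
    b = similarity(image * 2.0 + 10.0, section)
    assert a == pytest.approx(b, abs=1e-9)


def test_similarity_disjoint_foreground_low(atlas):
    section = atlas.annotation[30]
    shifted = np.zeros_like(section, dtype=float)
    shifted[:4, :4] = 1.0  # tiny blob in the background corner
    full = similarity(section.astype(float), section)
    assert similarity(shifted, section) < 0.5 * full


# ---------------------------------------------------------------------------
# estimation

def test_estimate_ap_rejects_empty_foreground(atlas):
    img = SliceImage(channels={"cFos": np.zeros((48, 48))}, pixel_size_um=100.0)
    with pytest.raises(ValueError, match="empty foreground"):
        estimate_ap(img, atlas)


def test_estimate_ap_rejects_substep(atlas, rendered_slice):
    with pytest.raises(ValueError):
        estimate_ap(rendered_slice.image, atlas, step_um=10.0)


def test_estimate_ap_recovers_position_and_flip(atlas, rendered_slice):
    ap, hflip, score = estimate_ap(rendered_slice.image, atlas, channel="tissue")
    assert abs(ap - 3050.0) <= 2 * atlas.spacing_um[0]
    # mirrored slice: same AP (the atlas is mirror-symmetric, so either flip
    # state is an equally valid explanation of the mirrored image)
    mirrored = SliceImage(
        channels={k: np.fliplr(v) for k, v in rendered_slice.image.channels.items()},
        pixel_size_um=rendered_slice.image.pixel_size_um,
    )
    ap_m, _, _ = estimate_ap(mirrored, atlas, channel="tissue")
    assert abs(ap_m - 3050.0) <= 2 * atlas.spacing_um[0]


def test_self_registration_recovers_identity(atlas):
    ap_i = 30
    section = atlas.annotation[ap_i].astype(float)
    img = SliceImage(channels={"tissue": section}, pixel_size_um=atlas.spacing_um[1])
    rigid = fit_rigid(img, atlas, (ap_i + 0.5) * atlas.spacing_um[0], hflip=False,
                      channel="tissue")
    assert abs(rigid.rotation_deg) <= 1.0
    assert abs(rigid.scale - 1.0) <= 0.02
    assert abs(rigid.tx_um) <= 2 * atlas.spacing_um[2]
    assert abs(rigid.ty_um) <= 2 * atlas.spacing_um[1]


def test_full_registration_recovers_known_warp(atlas, rendered_slice):
    reg = register_slice(rendered_slice.image, atlas)
    err = rigid_errors(reg.rigid, rendered_slice.true_registration.rigid)
    assert err is not None
    assert err["ap_um"] <= 2 * atlas.spacing_um[0]
    assert err["rotation_deg"] <= 1.0
    assert err["scale_pct"] <= 2.0
    assert err["tx_um"] <= 100.0 and err["ty_um"] <= 100.0


def test_registration_is_deterministic(atlas, rendered_slice):
    r1 = register_slice(rendered_slice.image, atlas)
    r2 = register_slice(rendered_slice.image, atlas)
    assert r1.to_dict() == r2.to_dict()


# ---------------------------------------------------------------------------
# elastic refinement

def test_refine_elastic_disabled_returns_identity(atlas, rendered_slice):
    rigid = rendered_slice.true_registration.rigid
    d = refine_elastic(rendered_slice.image, atlas, rigid, enabled=False)
    assert d.is_identity


def test_refine_elastic_rejects_degenerate_grid(atlas, rendered_slice):
    with pytest.raises(ValueError):
        refine_elastic(rendered_slice.image, atlas,
                       rendered_slice.true_registration.rigid, grid_shape=(1, 1))


def test_refine_elastic_on_aligned_slice_stays_small(atlas):
    ap_i = 30
    section = atlas.annotation[ap_i].astype(float)
    img = SliceImage(channels={"tissue": section}, pixel_size_um=atlas.spacing_um[1])
    rigid = RigidParams(ap_um=(ap_i + 0.5) * atlas.spacing_um[0])
    d = refine_elastic(img, atlas, rigid, grid_shape=(3, 3), cap_um=200.0,
                       n_sweeps=1, channel="tissue", enabled=True)
    # no residual to explain: displacements stay below one plane pixel
    assert np.linalg.norm(d.displacements_um, axis=-1).max() < atlas.spacing_um[1]


def test_refine_elastic_recovers_single_bump(atlas):
    # warp a section by a known one-bump TPS field, then refine with the
    # same grid and check the bump is (partly) explained
    from fosmap.synthetic import ExperimentConfig, generate_slice
    from fosmap.registration import transform_points as tp

    amp = 250.0
    extent = _plane_extent(atlas)
    disp = np.zeros((3, 3, 2))
    disp[1, 1] = (amp, 0.0)
    config = ExperimentConfig(pixel_size_um=50.0, seed=9)
    rng = np.random.default_rng(9)
    rates = {rid: 0.0 for rid in atlas.hierarchy.leaf_ids()}
    rec = generate_slice(atlas, 3050.0, {"cFos": rates}, config, rng)
    true_rigid = rec.true_registration.rigid
    # re-render the slice with the elastic bump added to the true transform
    truth = SliceRegistration(
        rigid=true_rigid,
        deformation=Deformation((3, 3), extent, displacements_um=disp, cap_um=400.0),
        atlas_name=atlas.name,
    )
    H, W = rec.image.shape
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    _, region = tp(truth, atlas, pts, 50.0, (H, W))
    base = np.array([0.0] + [0.25 + 0.5 * ((rid * 0.381966) % 1.0)
                             for rid in range(1, region.max() + 1)])
    img = base[region.reshape(H, W)] + rng.normal(0, 0.02, (H, W))
    warped = SliceImage(channels={"tissue": img}, pixel_size_um=50.0)

    fitted = refine_elastic(warped, atlas, true_rigid, grid_shape=(3, 3),
                            cap_um=400.0, channel="tissue", enabled=True)
    residual = np.linalg.norm(fitted.displacements_um - disp, axis=-1).mean()
    assert residual < 0.25 * amp
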