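import numpy as np
import pytest
from scipy.stats import spearmanr

from ctradiomics.errors import EmptyVOIError
from ctradiomics.features import (
    ExtractionConfig,
    extract_features,
    feature_registry,
    first_order_features,
    shape_features,
)
from ctradiomics.grids import ImageVolume, MaskVolume
from ctradiomics.phantom import PhantomParams, generate_phantom
from ctradiomics.preprocess import (
    DiscretizationSpec,
    discretize,
    resample_isotropic,
)
from ctradiomics.texture import glcm_features

from conftest import full_mask_like, make_mask, make_volume


# ---------------------------------------------------------------------------
# resampling


def test_resample_identity_on_isotropic_input(small_phantom):
    img, mask = small_phantom
    out_img, out_mask = resample_isotropic(img, mask, 1.0)
    np.testing.assert_allclose(out_img.voxels, img.voxels, atol=1e-9)
    assert np.array_equal(out_mask.voxels, mask.voxels)


def test_resample_conserves_mask_volume():
    params = PhantomParams(
        shape=(40, 40, 40), spacing=(0.5, 0.5, 0.5), semi_axes_mm=(7, 6, 5)
    )
    img, mask = generate_phantom(params, seed=2)
    vol_before = mask.n_foreground * 0.5**3
    _, mask_iso = resample_isotropic(img, mask, 1.0)
    vol_after = mask_iso.n_foreground * 1.0
    assert abs(vol_after - vol_before) / vol_before < 0.05


def test_resample_constant_image_stays_constant():
    img = make_volume(np.full((10, 10, 10), 7.0), spacing=(0.5, 0.5, 0.5))
    mask = full_mask_like(img.voxels, spacing=(0.5, 0.5, 0.5))
    out_img, _ = resample_isotropic(img, mask, 1.0)
    np.testing.assert_allclose(out_img.voxels, 7.0, atol=1e-9)


# ---------------------------------------------------------------------------
# discretization


def test_discretize_exact_bins_bijective():
    vals = np.arange(32, dtype=float).reshape(1, 4, 8)
    img = make_volume(vals)
    mask = full_mask_like(vals)
    levels, flag = discretize(img, mask, DiscretizationSpec(32))
    assert not flag
    assert sorted(levels.ravel()) == list(range(1, 33))


def test_discretize_constant_voi_flagged():
    img = make_volume(np.full((2, 2, 2), 5.0))
    levels, flag = discretize(img, full_mask_like(img.voxels), DiscretizationSpec(32))
    assert flag and set(levels.ravel()) == {1}


def test_discretize_range_contract():
    rng = np.random.default_rng(0)
    img = make_volume(rng.normal(size=(5, 5, 5)))
    mask = make_mask(rng.random((5, 5, 5)) < 0.6)
    levels, _ = discretize(img, mask, DiscretizationSpec(16))
    inside = levels[mask.voxels > 0]
    assert inside.min() >= 1 and inside.max() <= 16
    assert np.all(levels[mask.voxels == 0] == 0)


# ---------------------------------------------------------------------------
# first-order


def test_first_order_constant_voi():
    img = make_volume(np.full((3, 3, 3), 4.2))
    f = first_order_features(img, full_mask_like(img.voxels))
    for key in ("minimum", "maximum", "mean"):
        assert f[key] == pytest.approx(4.2)
    assert f["variance"] == pytest.approx(0.0, abs=1e-12)
    assert f["entropy"] == 0.0
    assert f["uniformity"] == pytest.approx(1.0)


def test_first_order_hand_computed_values():
    img = make_volume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
    f = first_order_features(img, full_mask_like(img.voxels))
    assert f["mean"] == pytest.approx(2.5)
    assert f["variance"] == pytest.approx(1.25)  # population convention
    assert f["median"] == pytest.approx(2.5)
    assert f["range"] == pytest.approx(3.0)
    assert f["energy"] == pytest.approx(1 + 4 + 9 + 16)
    assert f["root_mean_square"] == pytest.approx(np.sqrt(30 / 4))


def test_first_order_skewness_zero_for_symmetric_sample():
    img = make_volume(np.array([-3.0, 0.0, 3.0]).reshape(1, 1, 3))
    f = first_order_features(img, full_mask_like(img.voxels))
    assert f["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_first_order_requires_voi():
    img = make_volume(np.zeros((2, 2, 2)))
    mask = MaskVolume(np.zeros((2, 2, 2)), (1, 1, 1), require_nonempty=False)
    with pytest.raises(EmptyVOIError):
        first_order_features(img, mask)


# ---------------------------------------------------------------------------
# shape


def test_digital_ball_sphericity_near_one():
    r = 20
    n = 2 * r + 5
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    c = (n - 1) / 2
    ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2).astype(np.uint8)
    f = shape_features(make_mask(ball))
    assert 0.95 <= f["sphericity"] <= 1.0
    # analytic sphere values as sanity bounds
    assert abs(f["volume"] - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3) < 0.05
    assert abs(f["maximum_3d_diameter"] - 2 * r) / (2 * r) < 0.05


def test_sphericity_never_exceeds_one():
    rng = np.random.default_rng(3)
    for _ in range(5):
        arr = (rng.random((9, 9, 9)) < 0.4).astype(np.uint8)
        arr[4, 4, 4] = 1
        f = shape_features(make_mask(arr))
        assert f["sphericity"] <= 1.0 + 1e-12


def test_cube_volume_is_exact_voxel_count():
    arr = np.zeros((14, 14, 14), dtype=np.uint8)
    arr[2:12, 2:12, 2:12] = 1
    f = shape_features(make_mask(arr))
    assert f["volume"] == pytest.approx(1000.0)


def test_single_voxel_degenerate_axes():
    arr = np.zeros((5, 5, 5), dtype=np.uint8)
    arr[2, 2, 2] = 1
    f = shape_features(make_mask(arr))
    assert f["minor_axis_length"] == 0.0 and f["least_axis_length"] == 0.0
    assert f["elongation"] == 0.0 and f["flatness"] == 0.0
    assert f["sphericity"] <= 1.0


def test_shape_is_intensity_invariant(small_phantom):
    img, mask = small_phantom
    other = ImageVolume(voxels=img.voxels * 3.0 + 100.0, spacing=img.spacing)
    cfg = ExtractionConfig(wavelet=False)
    a = extract_features(img, mask, cfg)
    b = extract_features(other, mask, cfg)
    shape_cols = [c for c in a.index if "_shape_" in c]
    np.testing.assert_allclose(a[shape_cols], b[shape_cols], rtol=1e-12)


# ---------------------------------------------------------------------------
# full extraction


def test_registry_is_481_with_four_families():
    reg = feature_registry()
    assert len(reg) == 481
    assert set(reg["family"]) == {"shape", "first-order", "GLCM", "GLRLM"}
    assert reg["column"].is_unique


def test_extraction_is_deterministic(small_phantom):
    img, mask = small_phantom
    a = extract_features(img, mask)
    b = extract_features(img, mask)
    assert len(a) == 481
    assert np.array_equal(a.to_numpy(), b.to_numpy())


def test_first_order_shuffle_invariance_and_texture_sensitivity(small_phantom):
    """Moment statistics only see the intensity multiset; GLCM contrast sees
    the spatial arrangement and grows when a smooth texture is shuffled."""
    img, mask = small_phantom
    rng = np.random.default_rng(5)
    shuffled = img.voxels.copy()
    inside = mask.voxels > 0
    vals = shuffled[inside]
    shuffled[inside] = rng.permutation(vals)
    img2 = ImageVolume(voxels=shuffled, spacing=img.spacing)

    f1 = first_order_features(img, mask)
    f2 = first_order_features(img2, mask)
    for key in ("minimum", "maximum", "mean", "median", "variance", "energy"):
        assert f1[key] == pytest.approx(f2[key], rel=1e-12)

    spec = DiscretizationSpec(32)
    lev1, _ = discretize(img, mask, spec)
    lev2, _ = discretize(img2, mask, spec)
    c1 = glcm_features(lev1, 32)["contrast"]
    c2 = glcm_features(lev2, 32)["contrast"]
    assert c2 > c1  # spatial correlation destroyed


def test_cluster_shade_tracks_skewness_control():
    """Extracted GLCM cluster shade responds monotonically (in expectation)
    to the generator's skewness parameter gamma."""
    gammas = np.linspace(-0.8, 0.8, 5)
    spec = DiscretizationSpec(32)
    mean_shade = []
    for g in gammas:
        shades = []
        for seed in range(10):
            params = PhantomParams(
                shape=(22, 22, 22),
                semi_axes_mm=(7.5, 6, 5),
                sigma2=150.0,
                gamma=float(g),
            )
            img, mask = generate_phantom(params, seed=seed)
            levels, _ = discretize(img, mask, spec)
            shades.append(glcm_features(levels, 32)["cluster_shade"])
        mean_shade.append(np.mean(shades))
    rho, _ = spearmanr(gammas, mean_shade)
    assert rho > 0.8
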