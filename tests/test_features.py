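"""Feature extraction: first-order oracles, shape analytics, brute-force
GLCM/GLRLM enumeration oracles, gabor invariance, and the Z-transform."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_cube_mask, make_sphere_mask
from radgen.features import (FEATURE_NAMES, DegenerateFeatureWarning,
                             RadiomicsConfig, ZTransform, cluster_features,
                             compute_shape, compute_volume, extract_radiomics,
                             first_order_features, gabor_feature,
                             glcm_matrix_slice, glcm_props, glrlm_matrix_slice,
                             glrlm_props, quantize)

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
OFFSETS = (1, 2, 3, 4)


def test_feature_names_contract():
    assert len(FEATURE_NAMES) == 53
    assert FEATURE_NAMES[-2:] == ("vol", "normsurfvolratio")
    per_channel = [n for n in FEATURE_NAMES if n.startswith("ADC_")]
    assert len(per_channel) == 17


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def test_first_order_oracle():
    rng = np.random.default_rng(3)
    v = rng.gamma(2.0, 50.0, size=400)
    f = first_order_features(v)
    assert f["meanint"] == pytest.approx(v.mean(), abs=1e-12)
    assert f["stdint"] == pytest.approx(v.std(), abs=1e-12)
    k = int(np.ceil(0.15 * v.size))
    assert f["mean15perc"] == pytest.approx(np.sort(v)[:k].mean(), abs=1e-12)
    assert f["skewness"] == pytest.approx(sps.skew(v), abs=1e-12)
    assert f["kurtosis"] == pytest.approx(sps.kurtosis(v), abs=1e-12)
    hist, _ = np.histogram(v, bins=64, range=(v.min(), v.max()))
    p = hist[hist > 0] / v.size
    assert f["entropy"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)


def test_first_order_constant_degenerate():
    with pytest.warns(DegenerateFeatureWarning):
        f = first_order_features(np.full(50, 7.0))
    assert f["stdint"] == 0.0 and f["entropy"] == 0.0
    assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
    assert f["mean15perc"] == 7.0


def test_mean15perc_is_lowest_fraction():
    v = np.arange(100, dtype=float)  # lowest 15 values: 0..14
    f = first_order_features(v)
    assert f["mean15perc"] == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_sphere_normsurfvolratio(sphere_mask):
    shape = compute_shape(sphere_mask)
    assert shape.normsurfvolratio == pytest.approx(1.0 / 3.0, rel=0.02)


def test_cube_normsurfvolratio():
    shape = compute_shape(make_cube_mask(17))
    s = 17.0
    vol, area = s ** 3, 6 * s ** 2
    r = (3 * vol / (4 * np.pi)) ** (1 / 3)
    expected = vol / (area * r)  # ~= 0.2686 for a cube
    assert expected == pytest.approx(0.2686, abs=5e-4)
    assert shape.normsurfvolratio == pytest.approx(expected, rel=0.05)


def test_volume_in_ml():
    vox = np.zeros((12, 12, 12), dtype=np.uint8)
    vox[2:10, 2:10, 2:10] = 1  # 512 voxels
    from radgen.image import TumorMask
    mask = TumorMask(vox, (2.0, 2.0, 2.5))  # 10 mm^3 per voxel
    assert compute_volume(mask) == pytest.approx(512 * 10 / 1000.0)


def test_sphere_beats_cube_normsurfvolratio(sphere_mask):
    assert (compute_shape(sphere_mask).normsurfvolratio
            > compute_shape(make_cube_mask(17)).normsurfvolratio)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_bounds_and_mask():
    rng = np.random.default_rng(0)
    chan = rng.normal(0, 1, (6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.4
    q = quantize(chan, mask, 32)
    assert q[~mask].max() == -1
    assert q[mask].min() >= 0 and q[mask].max() <= 31
    # min and max in-mask intensities land in the extreme bins
    vals = chan[mask]
    assert q[mask][np.argmin(vals)] == 0
    assert q[mask][np.argmax(vals)] == 31


# ---------------------------------------------------------------------------
# GLCM / GLRLM brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm(q, levels):
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for dr, dc in DIRECTIONS:
        for d in OFFSETS:
            for i in range(h):
                for j in range(w):
                    i2, j2 = i + dr * d, j + dc * d
                    if 0 <= i2 < h and 0 <= j2 < w and q[i, j] >= 0 and q[i2, j2] >= 0:
                        counts[q[i, j], q[i2, j2]] += 1
                        counts[q[i2, j2], q[i, j]] += 1
    total = counts.sum()
    return counts / total if total else None


def brute_glrlm(q, levels):
    """Enumerate maximal runs along all four directions by walking each
    start pixel; average counts over directions."""
    h, w = q.shape
    counts = np.zeros((levels, max(h, w)))
    for dr, dc in DIRECTIONS:
        for i in range(h):
            for j in range(w):
                ip, jp = i - dr, j - dc
                prev_same = (0 <= ip < h and 0 <= jp < w and q[ip, jp] == q[i, j])
                if q[i, j] < 0 or prev_same:
                    continue  # out of mask, or not the start of a maximal run
                length = 0
                ci, cj = i, j
                while 0 <= ci < h and 0 <= cj < w and q[ci, cj] == q[i, j]:
                    length += 1
                    ci, cj = ci + dr, cj + dc
                counts[q[i, j], length - 1] += 1
    counts /= len(DIRECTIONS)
    total = counts.sum()
    return counts / total if total else None


@pytest.mark.parametrize("seed", range(12))
def test_glcm_matrix_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    q = rng.integers(0, 8, (8, 8))
    q[rng.random((8, 8)) < 0.3] = -1  # irregular mask
    P = glcm_matrix_slice(q, 8, DIRECTIONS, OFFSETS)
    B = brute_glcm(q, 8)
    if B is None:
        assert P is None
    else:
        np.testing.assert_allclose(P, B, atol=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_glrlm_matrix_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    q = rng.integers(0, 4, (8, 8))
    q[rng.random((8, 8)) < 0.3] = -1
    P = glrlm_matrix_slice(q, 4, DIRECTIONS)
    B = brute_glrlm(q, 4)
    if B is None:
        assert P is None
    else:
        np.testing.assert_allclose(P, B, atol=1e-12)


def test_glcm_props_hand_example():
    # 2x2 GLCM, hand-computed properties
    P = np.array([[0.5, 0.25], [0.25, 0.0]])
    f = glcm_props(P)
    assert f["glcm_contrast"] == pytest.approx(0.5, abs=1e-12)
    assert f["glcm_homogeneity"] == pytest.approx(0.5 + 0.25, abs=1e-12)
    assert f["glcm_energy"] == pytest.approx(0.25 + 2 * 0.0625, abs=1e-12)
    # marginals: p_i = (0.75, 0.25), mu = 0.25, var = 0.1875
    mu, var = 0.25, 0.1875
    i, j = np.meshgrid([0, 1], [0, 1], indexing="ij")
    corr = (P * (i - mu) * (j - mu)).sum() / var
    assert f["glcm_correlation"] == pytest.approx(corr, abs=1e-12)


def test_glrlm_props_hand_example():
    # single run of length 2 at level 0, and one run of length 1 at level 1
    P = np.zeros((2, 3))
    P[0, 1] = 0.5
    P[1, 0] = 0.5
    f = glrlm_props(P)
    assert f["glrlm_SRE"] == pytest.approx(0.5 / 4 + 0.5, abs=1e-12)
    assert f["glrlm_LRE"] == pytest.approx(0.5 * 4 + 0.5, abs=1e-12)
    assert f["glrlm_LGRE"] == pytest.approx(0.5 / 1 + 0.5 / 4, abs=1e-12)
    assert f["glrlm_HGRE"] == pytest.approx(0.5 * 1 + 0.5 * 4, abs=1e-12)


def test_glcm_checkerboard_contrast():
    # perfect checkerboard of 2 levels: every neighbor pair at offset 1
    # differs, so the offset-1-only GLCM has zero diagonal
    q = np.indices((8, 8)).sum(axis=0) % 2
    P = glcm_matrix_slice(q, 2, DIRECTIONS[:1], (1,))
    assert P[0, 0] == 0 and P[1, 1] == 0
    assert glcm_props(P)["glcm_contrast"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cluster + gabor features
# ---------------------------------------------------------------------------

def test_cluster_features_two_blobs():
    mask = np.zeros((12, 12, 3), dtype=bool)
    mask[1:5, 1:5, 1] = True
    mask[7:11, 7:11, 1] = True
    chan = np.zeros(mask.shape)
    chan[1:5, 1:5, 1] = 10.0   # high blob (16 voxels)
    chan[7:11, 7:11, 1] = 1.0  # low blob (16 voxels)
    f = cluster_features(chan, mask)
    assert f["clustindex"] == 2.0
    assert f["clustersize"] == pytest.approx(16.0)


def test_cluster_features_constant_warns():
    mask = np.zeros((6, 6, 3), dtype=bool)
    mask[1:4, 1:4, 1] = True
    with pytest.warns(DegenerateFeatureWarning):
        f = cluster_features(np.ones(mask.shape), mask)
    assert f == {"clustersize": 9.0, "clustindex": 1.0}


def test_gabor_scale_invariance():
    rng = np.random.default_rng(5)
    chan = rng.normal(100, 15, (16, 16, 4))
    mask = np.zeros(chan.shape, dtype=bool)
    mask[3:13, 3:13, 1:3] = True
    g1 = gabor_feature(chan, mask)
    g2 = gabor_feature(chan * 10.0, mask)
    assert g1 == pytest.approx(g2, rel=1e-6)
    assert g1 > 0


# ---------------------------------------------------------------------------
# full vector + Z-transform
# ---------------------------------------------------------------------------

def test_extract_radiomics_complete_and_finite(small_case):
    feats = extract_radiomics(small_case)
    assert tuple(feats) == FEATURE_NAMES
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["vol"] > 0
    assert 0 < feats["normsurfvolratio"] <= 1.0 / 3.0 + 0.01


def test_ztransform_per_stratum():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
    X.iloc[10:] += 50.0  # strong batch offset in the 3T stratum
    fs = np.array(["1.5T"] * 10 + ["3T"] * 10)
    zt = ZTransform().fit(X, fs)
    Z = zt.transform(X, fs)
    for stratum in ("1.5T", "3T"):
        sub = Z.loc[fs == stratum]
        np.testing.assert_allclose(sub.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sub.std(axis=0, ddof=1), 1.0, atol=1e-12)
    # the batch offset is gone after per-stratum normalization
    assert abs(Z.loc[fs == "3T"].mean().mean()) < 1e-10


def test_ztransform_applies_training_params_to_validation():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(10, 2, (12, 2)), columns=["a", "b"])
    fs = np.array(["1.5T"] * 12)
    zt = ZTransform().fit(X, fs)
    Xv = X + 5.0
    Zv = zt.transform(Xv, fs)
    # validation z-scores are shifted by 5/sd(train), not re-centred to 0
    expected_shift = 5.0 / X.std(axis=0, ddof=1)
    np.testing.assert_allclose(Zv.mean(axis=0) - zt.transform(X, fs).mean(axis=0),
                               expected_shift, rtol=1e-10)


def test_ztransform_unknown_stratum_and_columns():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 2)), columns=["a", "b"])
    zt = ZTransform().fit(X, ["1.5T"] * 6)
    with pytest.raises(ValueError):
        zt.transform(X, ["3T"] * 6)
    with pytest.raises(ValueError):
        zt.transform(X[["b", "a"]], ["1.5T"] * 6)


def test_ztransform_zero_sd_feature_warns():
    X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    with pytest.warns(DegenerateFeatureWarning):
        zt = ZTransform().fit(X, ["1.5T"] * 3)
    Z = zt.transform(X, ["1.5T"] * 3)
    assert (Z["a"] == 0).all()
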