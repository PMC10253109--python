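"""Granulation: tiling arithmetic, feature extraction, aggregation, saliency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import granulonet as gn
from granulonet.granulation import granule_saliency


@pytest.mark.parametrize("hw,g,expected", [
    ((224, 224), 32, (7, 7)),   # 49 granules, the canonical grid
    ((32, 32), 32, (1, 1)),     # single granule equals the whole image
    ((70, 70), 32, (2, 2)),     # trailing pixels 64..69 dropped
])
def test_granule_counts(rng, hw, g, expected):
    img = gn.ImageSample(pixels=rng.random((*hw, 1)).astype(np.float32),
                         label=0, sample_id="x")
    grid = gn.granulate(img, g)
    assert (grid.grid_rows, grid.grid_cols) == expected
    assert len(grid) == expected[0] * expected[1]


def test_row_major_order_and_exact_tiles(rng):
    img = gn.ImageSample(pixels=rng.random((64, 96, 1)).astype(np.float32),
                         label=0, sample_id="x")
    grid = gn.granulate(img, 32)
    assert grid.origin_coords == [(0, 0), (0, 32), (0, 64), (32, 0), (32, 32), (32, 64)]
    for tile, (i, j) in zip(grid.granules, grid.origin_coords):
        assert np.array_equal(tile, img.pixels[i:i + 32, j:j + 32])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(h=st.integers(16, 90), w=st.integers(16, 90), g=st.integers(4, 16))
def test_granule_count_formula_and_reassembly(h, w, g):
    rng = np.random.default_rng(h * 1000 + w * 10 + g)
    img = gn.ImageSample(pixels=rng.random((h, w, 1)).astype(np.float32),
                         label=0, sample_id="p")
    if g > min(h, w):
        with pytest.raises(ValueError):
            gn.granulate(img, g)
        return
    grid = gn.granulate(img, g)
    assert len(grid) == (h // g) * (w // g)
    recon = gn.reassemble(grid)
    assert np.array_equal(recon, img.pixels[:grid.grid_rows * g, :grid.grid_cols * g])


def test_granulate_validates_size(gray_image):
    with pytest.raises(ValueError):
        gn.granulate(gray_image, 3)
    with pytest.raises(ValueError):
        gn.granulate(gray_image, 128)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def test_constant_image_gives_identical_rows():
    img = gn.ImageSample(pixels=np.full((64, 64, 1), 0.4, np.float32),
                         label=0, sample_id="c")
    gf = gn.extract_granule_features(gn.granulate(img, 32), gn.TileStatsBackbone())
    assert np.allclose(gf.per_granule, gf.per_granule[0])


def test_feature_locality(rng):
    base = rng.random((64, 64, 1)).astype(np.float32)
    other = base.copy()
    other[:32, :32] = rng.random((32, 32, 1))  # change granule 0 only
    bb = gn.TileStatsBackbone()
    f1 = gn.extract_granule_features(gn.granulate(
        gn.ImageSample(pixels=base, label=0, sample_id="a"), 32), bb)
    f2 = gn.extract_granule_features(gn.granulate(
        gn.ImageSample(pixels=other, label=0, sample_id="b"), 32), bb)
    diff = np.abs(f1.per_granule - f2.per_granule).sum(axis=1)
    assert diff[0] > 0
    assert np.allclose(diff[1:], 0)


def test_tile_stats_on_two_tone_fixture():
    """Hand-built 64x64 two-tone image -> known per-tile channel means."""
    px = np.zeros((64, 64, 1), np.float32)
    px[:32, 32:] = 0.5   # tile (0,1)
    px[32:, :32] = 1.0   # tile (1,0)
    px[32:, 32:] = 0.25  # tile (1,1)
    img = gn.ImageSample(pixels=px, label=0, sample_id="t")
    gf = gn.extract_granule_features(gn.granulate(img, 32), gn.TileStatsBackbone())
    assert gf.per_granule.shape == (4, 3)
    assert np.allclose(gf.per_granule[:, 0], [0.0, 0.5, 1.0, 0.25], atol=1e-6)
    assert np.allclose(gf.per_granule[:, 1], 0.0, atol=1e-6)  # flat tiles


def test_random_conv_backbone_deterministic(rng):
    tile = rng.random((32, 32, 1)).astype(np.float32)
    a = gn.RandomConvBackbone(seed=5)(tile)
    b = gn.RandomConvBackbone(seed=5)(tile)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, gn.RandomConvBackbone(seed=6)(tile))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def test_aggregation_against_bruteforce_oracle(rng):
    per = rng.random((49, 7)).astype(np.float32)
    gf = gn.GranuleFeatures(per_granule=per, aggregated=None,
                            aggregation_mode=None, backbone_id="x")
    mean = gn.aggregate_features(gf, "mean").aggregated
    # independent summation oracle
    oracle = np.zeros(7)
    for row in per.astype(np.float64):
        oracle += row
    oracle /= 49
    assert np.allclose(mean, oracle, atol=1e-12)
    mx = gn.aggregate_features(gf, "max").aggregated
    assert np.array_equal(mx, per.max(axis=0))

    single = gn.GranuleFeatures(per_granule=per[:1], aggregated=None,
                                aggregation_mode=None, backbone_id="x")
    assert np.array_equal(gn.aggregate_features(single, "mean").aggregated, per[0])

    tiny = gn.GranuleFeatures(per_granule=np.array([[0.0, 2.0], [2.0, 0.0]]),
                              aggregated=None, aggregation_mode=None, backbone_id="x")
    assert np.allclose(gn.aggregate_features(tiny, "mean").aggregated, [1, 1])


def test_aggregation_permutation_invariant(rng):
    per = rng.random((12, 4))
    perm = rng.permutation(12)
    for mode in ("mean", "max"):
        a = gn.aggregate_features(gn.GranuleFeatures(per, None, None, "x"), mode)
        b = gn.aggregate_features(gn.GranuleFeatures(per[perm], None, None, "x"), mode)
        assert np.allclose(a.aggregated, b.aggregated)


def test_aggregation_rejects_empty_and_bad_mode(rng):
    gf = gn.GranuleFeatures(per_granule=np.empty((0, 3)), aggregated=None,
                            aggregation_mode=None, backbone_id="x")
    with pytest.raises(ValueError):
        gn.aggregate_features(gf, "mean")
    ok = gn.GranuleFeatures(per_granule=rng.random((2, 3)), aggregated=None,
                            aggregation_mode=None, backbone_id="x")
    with pytest.raises(ValueError):
        gn.aggregate_features(ok, "median")


# ---------------------------------------------------------------------------
# Highlighting
# ---------------------------------------------------------------------------

def test_uniform_saliency_is_identity():
    img = gn.ImageSample(pixels=np.full((64, 64, 1), 0.6, np.float32),
                         label=0, sample_id="u")
    gf = gn.extract_granule_features(gn.granulate(img, 32), gn.TileStatsBackbone())
    out = gn.highlight_image(img, gf, g=32)
    assert np.array_equal(out.pixels, img.pixels)


def test_min_max_scaling_on_two_granule_fixture():
    """Maximal-norm granule keeps scale 1; minimal-norm granule gets 0.2."""
    per = np.array([[3.0, 4.0], [0.3, 0.4]])  # norms 5 and 0.5
    sal = granule_saliency(gn.GranuleFeatures(per, None, None, "x"))
    assert sal[0] == pytest.approx(1.0)
    assert sal[1] == pytest.approx(0.2)

    px = np.full((64, 32, 1), 0.5, np.float32)
    img = gn.ImageSample(pixels=px, label=0, sample_id="two")
    gf = gn.GranuleFeatures(per, None, None, "x")
    out = gn.highlight_image(img, gf, g=32)
    assert out.pixels.shape == img.pixels.shape
    assert np.allclose(out.pixels[:32], 0.5 * 1.0, atol=1e-6)
    assert np.allclose(out.pixels[32:], 0.5 * 0.2, atol=1e-6)


def test_highlight_monotone_in_saliency(rng):
    """Raising one granule's feature norm never darkens that granule."""
    px = rng.random((64, 64, 1)).astype(np.float32)
    img = gn.ImageSample(pixels=px, label=0, sample_id="m")
    per = np.abs(rng.random((4, 3))) + 0.1
    lo = gn.highlight_image(img, gn.GranuleFeatures(per, None, None, "x"), g=32)
    per_hi = per.copy()
    per_hi[2] *= 5
    hi = gn.highlight_image(img, gn.GranuleFeatures(per_hi, None, None, "x"), g=32)
    assert np.all(hi.pixels[32:, :32] >= lo.pixels[32:, :32] - 1e-7)
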