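"""Mask pipeline: Otsu vs exhaustive-scan oracle, set-operation oracles,
blob selection, hole filling and the end-to-end chain."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skimage.filters import threshold_otsu as skimage_otsu

from dermopipe import synth
from dermopipe.preprocess import preprocess
from dermopipe.quality import dsc
from dermopipe.segment import (
    apply_mask,
    dilate_mask,
    fill_holes,
    largest_blob,
    otsu_threshold,
    segment,
    subtract_masks,
    to_grayscale,
)


def brute_otsu(img: np.ndarray) -> int:
    """Exhaustive scan of all 256 thresholds maximizing w0*w1*(mu0-mu1)^2."""
    flat = img.ravel().astype(float)
    best_t, best_s = 0, -1.0
    for t in range(256):
        lo, hi = flat[flat <= t], flat[flat > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        s = (len(lo) / len(flat)) * (len(hi) / len(flat)) * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_t, best_s = t, s
    return best_t


def test_otsu_two_level_mixture_separates_exactly():
    rng = np.random.default_rng(0)
    img = rng.choice([50, 200], size=(32, 32), p=[0.3, 0.7]).astype(np.uint8)
    res = otsu_threshold(img)
    assert 50 <= res.threshold < 200
    assert np.array_equal(res.mask == 255, img == 200)


def test_otsu_half_half_binary():
    img = np.zeros((16, 16), dtype=np.uint8)
    img[:, 8:] = 255
    res = otsu_threshold(img)
    assert (res.mask == 255).sum() == img.size // 2


def test_otsu_constant_image_rejected():
    with pytest.raises(ValueError):
        otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(arrays(np.uint8, (12, 12), elements=st.integers(0, 255)))
def test_otsu_equals_exhaustive_scan_oracle(img):
    if len(np.unique(img)) < 2:
        return
    assert otsu_threshold(img).threshold == brute_otsu(img)


def test_otsu_agrees_with_skimage_reference():
    rng = np.random.default_rng(3)
    for _ in range(10):
        img = np.clip(
            np.concatenate([rng.normal(80, 10, 300), rng.normal(180, 12, 400)]), 0, 255
        ).astype(np.uint8).reshape(1, -1)
        ours = otsu_threshold(img).threshold
        ref = skimage_otsu(img)
        assert abs(ours - ref) <= 1  # conventions differ by at most one level


def _disc(side, center, radius):
    rr, cc = np.mgrid[0:side, 0:side]
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2).astype(np.uint8) * 255


def brute_dilate(mask: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Set-union dilation: stamp the kernel at every foreground pixel."""
    out = np.zeros_like(mask)
    rh, rw = kh // 2, kw // 2
    h, w = mask.shape
    for i, j in zip(*np.nonzero(mask)):
        out[max(0, i - rh) : min(h, i + rh + 1), max(0, j - rw) : min(w, j + rw + 1)] = 255
    return out


def test_dilate_single_pixel_stamps_kernel():
    mask = np.zeros((11, 11), dtype=np.uint8)
    mask[5, 5] = 255
    out = dilate_mask(mask, (5, 5))
    expect = np.zeros_like(mask)
    expect[3:8, 3:8] = 255
    assert np.array_equal(out, expect)


def test_dilate_all_black_and_disc_oracle():
    assert np.array_equal(dilate_mask(np.zeros((9, 9), dtype=np.uint8)), np.zeros((9, 9)))
    disc = _disc(40, (20, 20), 10)
    out = dilate_mask(disc, (5, 5))
    assert np.array_equal(out, brute_dilate(disc, 5, 5))
    assert (out == 255).sum() > (disc == 255).sum()
    assert np.all(out[disc == 255] == 255)  # extensivity


def test_dilate_rejects_nonbinary():
    with pytest.raises(ValueError):
        dilate_mask(np.full((4, 4), 7, dtype=np.uint8))


def test_subtract_equal_masks_is_black():
    disc = _disc(20, (10, 10), 6)
    assert not subtract_masks(disc, disc).any()


def test_subtract_truth_table_and_ring_oracle():
    m1 = np.zeros((4, 4), dtype=np.uint8)
    m2 = np.zeros((4, 4), dtype=np.uint8)
    m2[0, 0] = 255  # mask2 white, mask1 black -> white
    out = subtract_masks(m2, m1)
    assert out[0, 0] == 255 and out.sum() == 255
    disc = _disc(40, (20, 20), 10)
    dilated = dilate_mask(disc, (5, 5))
    ring = subtract_masks(dilated, disc)
    assert np.array_equal(ring == 255, (dilated == 255) & ~(disc == 255))


def test_subtract_contract_violation_warns_and_zeroes():
    m1 = np.zeros((3, 3), dtype=np.uint8)
    m1[1, 1] = 255
    m2 = np.zeros((3, 3), dtype=np.uint8)
    with pytest.warns(UserWarning):
        out = subtract_masks(m2, m1)
    assert not out.any()


def test_largest_blob_picks_bigger_disc_and_identity():
    mask = np.zeros((40, 60), dtype=np.uint8)
    mask[5:10, 5:10] = 255  # 25 px
    mask[20:27, 30:37] = 255  # 49 px
    out = largest_blob(mask)
    assert out[22, 32] == 255 and out[6, 6] == 0
    single = _disc(30, (15, 15), 8)
    assert np.array_equal(largest_blob(single), single)


def test_largest_blob_ranks_rings_by_enclosed_area():
    # a thin large ring must beat a small solid square (filled-area ranking)
    mask = np.zeros((60, 60), dtype=np.uint8)
    big = _disc(60, (30, 30), 20) ^ _disc(60, (30, 30), 18)
    mask[big > 0] = 255
    mask[2:8, 2:8] = 255
    out = largest_blob(mask)
    assert out[30, 10] == 255 and out[4, 4] == 0


def test_largest_blob_empty_rejected():
    with pytest.raises(ValueError):
        largest_blob(np.zeros((5, 5), dtype=np.uint8))


def brute_fill(mask: np.ndarray) -> np.ndarray:
    """Border-seeded flood fill of the background; unreached black becomes white."""
    from collections import deque

    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    queue = deque()
    for i in range(h):
        for j in (0, w - 1):
            if mask[i, j] == 0 and not reach[i, j]:
                reach[i, j] = True
                queue.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if mask[i, j] == 0 and not reach[i, j]:
                reach[i, j] = True
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] == 0 and not reach[ni, nj]:
                reach[ni, nj] = True
                queue.append((ni, nj))
    return np.where(reach, 0, 255).astype(np.uint8)


def test_fill_holes_annulus_and_pinhole_match_flood_fill_oracle():
    ring = (_disc(30, (15, 15), 10) ^ _disc(30, (15, 15), 7)).astype(np.uint8)
    ring[ring > 0] = 255
    assert np.array_equal(fill_holes(ring), brute_fill(ring))
    solid = _disc(30, (15, 15), 9)
    assert np.array_equal(fill_holes(solid), solid)
    pin = solid.copy()
    pin[15, 15] = 0
    assert np.array_equal(fill_holes(pin), solid)


def test_apply_mask_identities():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 256, (10, 10, 3)).astype(np.uint8)
    full = np.full((10, 10), 255, dtype=np.uint8)
    assert np.array_equal(apply_mask(img, full), img)
    assert not apply_mask(img, np.zeros((10, 10), dtype=np.uint8)).any()
    with pytest.raises(ValueError):
        apply_mask(img, np.zeros((5, 5), dtype=np.uint8))


def test_segment_clean_lesion_high_dice():
    sample = synth.generate_sample(
        synth.LesionParams(n_hairs=0, n_bubbles=0, border_jitter=0.1, seed=4)
    )
    res = segment(preprocess(sample.image))
    assert res.final_mask is not None
    assert dsc(res.final_mask, sample.truth_mask) >= 0.90
    # invariants: mask2 superset of mask1; final mask solid and connected
    assert np.all(res.mask2[res.mask1 == 255] == 255)
    assert np.array_equal(fill_holes(res.final_mask), res.final_mask)


def test_segment_removes_corner_shadows():
    sample = synth.generate_sample(
        synth.LesionParams(n_hairs=0, n_bubbles=0, border_jitter=0.0, seed=6)
    )
    img = sample.image.copy()
    for corner in ((slice(0, 18), slice(0, 18)), (slice(-18, None), slice(-18, None))):
        img[corner] = (30, 25, 20)
    res = segment(preprocess(img))
    assert res.final_mask is not None
    assert res.final_mask[4, 4] == 0 and res.final_mask[-4, -4] == 0
    assert dsc(res.final_mask, sample.truth_mask) >= 0.85


def test_segment_all_skin_degenerate_path():
    flat = np.full((64, 64, 3), 180, dtype=np.uint8)
    res = segment(flat)
    assert res.final_mask is None and res.diagnostic is not None


def test_grayscale_weights():
    img = np.zeros((1, 3, 3), dtype=np.uint8)
    img[0, 0] = (255, 0, 0)
    img[0, 1] = (0, 255, 0)
    img[0, 2] = (0, 0, 255)
    g = to_grayscale(img)
    assert tuple(g[0]) == (round(0.299 * 255), round(0.587 * 255), round(0.114 * 255))


def test_segmentation_median_dice_over_fixture_set(lesion_fixtures):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples, _ = lesion_fixtures
        dices = []
        for s in samples:
            res = segment(preprocess(s.image))
            assert res.final_mask is not None
            dices.append(dsc(res.final_mask, s.truth_mask))
    assert np.median(dices) >= 0.90
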