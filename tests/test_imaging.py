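import numpy as np
import pandas as pd
import pytest

from ploidyscale.imaging import (
    clutch_normalize,
    fill_holes,
    huang_threshold,
    ratio_mask_measure,
    zproject,
)
from ploidyscale.simulate.images import default_brain_rois, simulate_ratio_images

SHAPE = (128, 96)
ROIS = default_brain_rois(SHAPE)


def brute_force_huang(image, n_bins=256):
    """Independent loop-based minimizer of the fuzzy-entropy objective."""
    img = np.asarray(image, dtype=float)
    gmin, gmax = img.min(), img.max()
    hist, edges = np.histogram(img, bins=n_bins, range=(gmin, gmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = gmax - gmin
    best_s, best_t = np.inf, None
    for t in range(n_bins - 1):
        w0 = hist[:t + 1].sum()
        w1 = hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * centers[:t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * centers[t + 1:]).sum() / w1
        s = 0.0
        for g in range(n_bins):
            mu = mu0 if g <= t else mu1
            m = 1.0 / (1.0 + abs(centers[g] - mu) / c)
            m = min(max(m, 1e-12), 1 - 1e-12)
            s += hist[g] * -(m * np.log(m) + (1 - m) * np.log(1 - m))
        # first minimum wins, with the same plateau-robust tolerance
        if best_t is None or s < best_s - 1e-9 * max(abs(best_s), 1.0):
            best_s, best_t = s, t
    return float(edges[best_t + 1])


# ------------------------------------------------------------------- zproject

def test_zproject_single_slice_identity():
    img = np.arange(12.0).reshape(3, 4)
    np.testing.assert_array_equal(zproject(img[None]), img)


def test_zproject_sum_and_mean():
    img = np.arange(12.0).reshape(3, 4)
    stack = np.stack([img, img])
    np.testing.assert_array_equal(zproject(stack, "sum"), 2 * img)
    np.testing.assert_array_equal(zproject(stack, "mean"), img)


def test_zproject_matches_loop_oracle():
    rng = np.random.default_rng(0)
    stack = rng.uniform(0, 100, (7, 5, 6))
    expected = np.zeros((5, 6))
    for z in range(7):
        for i in range(5):
            for j in range(6):
                expected[i, j] += stack[z, i, j]
    np.testing.assert_allclose(zproject(stack), expected, rtol=1e-12)


def test_zproject_empty_stack_rejected():
    with pytest.raises(ValueError):
        zproject(np.empty((0, 4, 4)))


# ---------------------------------------------------------------------- huang

def test_huang_binary_image_separates_classes():
    img = np.zeros((32, 32))
    img[8:24, 8:24] = 255.0
    thr = huang_threshold(img)
    assert 0 < thr <= 255
    assert np.array_equal(img >= thr, img == 255.0)


def test_huang_bimodal_threshold_between_modes():
    rng = np.random.default_rng(1)
    img = np.concatenate([
        rng.normal(50, 5, 3000), rng.normal(200, 10, 3000)
    ]).reshape(60, 100)
    thr = huang_threshold(img)
    # must fall in the valley separating the modes (above the 50 +- 5
    # background tail, below the 200 +- 10 foreground tail)
    assert 50 + 3 * 5 < thr < 200 - 3 * 10


def test_huang_constant_image_rejected():
    with pytest.raises(ValueError, match="constant"):
        huang_threshold(np.full((8, 8), 7.0))


def test_huang_equals_bruteforce_on_random_images():
    rng = np.random.default_rng(2)
    for i in range(100):
        kind = i % 3
        if kind == 0:
            img = rng.uniform(0, 255, (24, 24))
        elif kind == 1:
            img = np.concatenate([
                rng.normal(60, 10, 288), rng.normal(180, 20, 288)
            ]).reshape(24, 24)
        else:
            img = rng.exponential(40, (24, 24))
        assert huang_threshold(img) == pytest.approx(brute_force_huang(img), abs=1e-9)


def test_huang_shift_invariance():
    rng = np.random.default_rng(3)
    img = np.concatenate([
        rng.normal(60, 10, 512), rng.normal(180, 20, 512)
    ]).reshape(32, 32)
    thr = huang_threshold(img)
    assert huang_threshold(img + 37.0) == pytest.approx(thr + 37.0, abs=1e-9)


def test_mask_monotone_in_threshold():
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 255, (16, 16))
    thr = huang_threshold(img)
    assert np.all((img >= thr + 10).sum() <= (img >= thr).sum())


def test_fill_holes_closes_interior():
    mask = np.ones((10, 10), dtype=bool)
    mask[4:6, 4:6] = False    # interior hole
    mask[0, :] = False        # border notch stays open
    filled = fill_holes(mask)
    assert filled[4, 4] and filled[5, 5]
    assert not filled[0, 0]


# --------------------------------------------------------------- ratio + ROIs

def test_unit_fold_noise_free_ratio_is_one():
    perk, erk, _ = simulate_ratio_images(SHAPE, ROIS, noise_sd=0.0)
    rmap, means = ratio_mask_measure(perk, erk, ROIS, epsilon=0.0)
    assert np.allclose(rmap.ratio[rmap.mask], 1.0)
    assert np.allclose(means["mean_ratio"], 1.0)


def test_roi_fold_recovered_exactly_without_noise():
    perk, erk, _ = simulate_ratio_images(
        SHAPE, ROIS, perk_fold_by_roi={"midbrain": 2.0}, noise_sd=0.0
    )
    _, means = ratio_mask_measure(perk, erk, ROIS, epsilon=0.0)
    by_region = means.set_index("region")["mean_ratio"]
    assert by_region["midbrain"] == pytest.approx(2.0)
    assert by_region["hindbrain"] == pytest.approx(1.0)


def test_zero_erk_roi_reported_missing():
    erk = np.zeros(SHAPE)
    erk[:40] = 1000.0  # only the top band is tissue
    perk = erk.copy()
    _, means = ratio_mask_measure(perk, erk, {"hindbrain": ROIS["hindbrain"]})
    assert bool(means.iloc[0]["missing"])
    assert np.isnan(means.iloc[0]["mean_ratio"])


def test_noisy_fold_recovery_within_clt_bound():
    for seed in range(1, 6):
        perk, erk, truth = simulate_ratio_images(
            SHAPE, ROIS, base_erk=1000.0,
            perk_fold_by_roi={"diencephalon": 1.5}, noise_sd=30.0, seed=seed,
        )
        _, means = ratio_mask_measure(perk, erk, ROIS)
        row = means.set_index("region").loc["diencephalon"]
        n = row["n_pixels"]
        se = (30.0 / 1000.0) * np.sqrt(1 + 1.5**2) / np.sqrt(n)
        assert abs(row["mean_ratio"] - 1.5) < 4 * se


def test_roi_outside_image_rejected():
    perk, erk, _ = simulate_ratio_images(SHAPE, ROIS, noise_sd=0.0)
    with pytest.raises(ValueError, match="outside"):
        ratio_mask_measure(perk, erk, {"bad": [(0, 0), (0, 500), (500, 500)]})


def test_ratio_invariant_to_common_channel_scaling():
    perk, erk, _ = simulate_ratio_images(
        SHAPE, ROIS, perk_fold_by_roi={"midbrain": 1.4}, noise_sd=0.0
    )
    _, m1 = ratio_mask_measure(perk, erk, ROIS, epsilon=0.0)
    _, m2 = ratio_mask_measure(perk * 7.5, erk * 7.5, ROIS, epsilon=0.0)
    np.testing.assert_allclose(m1["mean_ratio"], m2["mean_ratio"], rtol=1e-12)


# --------------------------------------------------------- clutch normalizing

def _ratio_maps_and_measurements(folds_by_image, clutch_of):
    maps, rows = {}, []
    for image_id, fold in folds_by_image.items():
        perk, erk, _ = simulate_ratio_images(
            SHAPE, ROIS, perk_fold_by_roi={"midbrain": fold}, noise_sd=0.0
        )
        rmap, means = ratio_mask_measure(perk, erk, ROIS, epsilon=0.0)
        maps[image_id] = rmap.ratio
        for _, r in means.iterrows():
            rows.append(dict(image_id=image_id, region=r["region"],
                             mean_ratio=r["mean_ratio"]))
    return maps, pd.DataFrame(rows)


def test_clutch_normalization_divides_by_reference_max():
    maps, meas = _ratio_maps_and_measurements(
        {"d1": 2.0, "t1": 3.0}, {"d1": "A", "t1": "A"}
    )
    out = clutch_normalize(meas, maps, {"d1": "A", "t1": "A"},
                           {"d1": True, "t1": False})
    # reference (d1) ratio image has max 2.0 -> all values halved
    assert np.allclose(out["normalizer"], 2.0)
    got = out[(out.image_id == "t1") & (out.region == "midbrain")]
    assert got["normalized_ratio"].iloc[0] == pytest.approx(1.5)


def test_clutches_normalized_independently():
    maps, meas = _ratio_maps_and_measurements(
        {"a_ref": 2.0, "b_ref": 4.0},
        {"a_ref": "A", "b_ref": "B"},
    )
    out = clutch_normalize(meas, maps, {"a_ref": "A", "b_ref": "B"},
                           {"a_ref": True, "b_ref": True})
    norm = out.groupby("image_id")["normalizer"].first()
    assert norm["a_ref"] == pytest.approx(2.0)
    assert norm["b_ref"] == pytest.approx(4.0)


def test_missing_reference_clutch_rejected():
    maps, meas = _ratio_maps_and_measurements({"x": 2.0}, {"x": "A"})
    with pytest.raises(ValueError, match="reference"):
        clutch_normalize(meas, maps, {"x": "A"}, {"x": False})
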