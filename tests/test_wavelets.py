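"""À trous decomposition and spot/large-object detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import convolve2d

from stromascreen import (
    DetectionParams,
    atrous_decompose,
    detect_spots,
    detection_scores,
    render_well,
    segment_large_objects,
)
from stromascreen.wavelets import B3_KERNEL


def atrous_oracle(image, n_scales):
    """Brute-force decomposition: explicit dilated 2-D kernels, explicit
    reflective padding, direct convolution.  Independent of the
    separable correlate1d implementation path."""
    smooth = [np.asarray(image, float)]
    planes = []
    for s in range(1, n_scales + 1):
        step = 2 ** (s - 1)
        k1 = np.zeros(4 * step + 1)
        k1[::step] = B3_KERNEL
        kernel = np.outer(k1, k1)
        padded = np.pad(smooth[-1], 2 * step, mode="reflect")
        nxt = convolve2d(padded, kernel, mode="valid")
        planes.append(smooth[-1] - nxt)
        smooth.append(nxt)
    return smooth, planes


def test_constant_image_has_zero_wavelet_planes():
    dec = atrous_decompose(np.full((64, 64), 7.0), n_scales=3)
    for w in dec.planes:
        assert np.allclose(w, 0.0, atol=1e-12)
    assert np.allclose(dec.smooth[-1], 7.0)


def test_reconstruction_identity_on_random_images(rng):
    for shape in [(40, 40), (64, 48), (33, 57)]:
        img = rng.uniform(0, 1000, size=shape)
        dec = atrous_decompose(img, n_scales=3)
        err = np.abs(img - dec.reconstruct()).max()
        assert err < 1e-6 * np.abs(img).max()


def test_unit_impulse_first_plane_centre_value():
    img = np.zeros((65, 65))
    img[32, 32] = 1.0
    dec = atrous_decompose(img, n_scales=2)
    # centre of W_1 is 1 minus the squared central B3 tap (3/8 * 3/8)
    assert dec.planes[0][32, 32] == pytest.approx(1.0 - (3 / 8) ** 2, abs=1e-12)
    # full planes equal the brute-force dilated-kernel oracle
    _, oracle_planes = atrous_oracle(img, 2)
    for w, wo in zip(dec.planes, oracle_planes):
        assert np.allclose(w, wo, atol=1e-10)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(20, 64), st.integers(20, 64))
def test_matches_brute_force_oracle_on_small_images(seed, h, w):
    img = np.random.default_rng(seed).uniform(0, 4096, size=(h, w))
    dec = atrous_decompose(img, n_scales=2)
    oracle_smooth, oracle_planes = atrous_oracle(img, 2)
    for a, ao in zip(dec.smooth, oracle_smooth):
        assert np.allclose(a, ao, atol=1e-8)
    for p, po in zip(dec.planes, oracle_planes):
        assert np.allclose(p, po, atol=1e-8)


def test_rejects_bad_input():
    with pytest.raises(ValueError):
        atrous_decompose(np.zeros(64), n_scales=2)
    with pytest.raises(ValueError):
        atrous_decompose(np.zeros((64, 64)), n_scales=0)
    with pytest.raises(ValueError):
        atrous_decompose(np.zeros((10, 10)), n_scales=3)  # kernel support 17


# ---------------------------------------------------------------------------
# detection


def _spot_image(positions, radius=3.0, amplitude=1000.0, shape=(128, 128)):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in positions:
        img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * radius**2))
    return img


def test_blank_image_yields_no_spots(det_params):
    assert detect_spots(np.zeros((64, 64)), det_params) == []
    assert segment_large_objects(np.zeros((64, 64)), det_params) == []


def test_translation_equivariance(det_params):
    positions = [(40, 40), (60, 90), (90, 55)]
    img = _spot_image(positions)
    shift = (7, 5)
    shifted = np.roll(img, shift, axis=(0, 1))
    cents = sorted(s.centroid for s in detect_spots(img, det_params))
    cents_shifted = sorted(s.centroid for s in detect_spots(shifted, det_params))
    assert len(cents) == len(cents_shifted) == len(positions)
    for (r0, c0), (r1, c1) in zip(cents, cents_shifted):
        assert abs(r1 - r0 - shift[0]) <= 0.5
        assert abs(c1 - c0 - shift[1]) <= 0.5


def test_intensity_rescaling_leaves_spot_set_unchanged(det_params, rng):
    img = _spot_image([(30, 30), (80, 100), (100, 40)]) + rng.normal(
        500, 20, size=(128, 128)
    )
    base = detect_spots(img, det_params)
    for c in (0.25, 3.7):
        scaled = detect_spots(c * img, det_params)
        assert len(scaled) == len(base)
        for a, b in zip(base, scaled):
            assert np.array_equal(a.coords, b.coords)


def test_spots_match_simulated_ground_truth(single_field_config, det_params):
    config = single_field_config(n_all_viable=50, n_all_dead=0, n_msc=0)
    image_set, truth = render_well(config, "SNR", seed=21)
    spots = detect_spots(image_set.fields[0], det_params)
    m = det_params.border_margin_px
    h, w = config.field_size_px
    inner = truth[
        truth["imaged"]
        & truth["row"].between(m, h - 1 - m)
        & truth["col"].between(m, w - 1 - m)
    ]
    pred = np.array([s.centroid for s in spots])
    scores = detection_scores(pred, inner[["row", "col"]].to_numpy(), tolerance=2.0)
    assert scores["n_matched"] >= 0.96 * scores["n_truth"]
    assert scores["f1"] >= 0.95


def test_large_object_path_finds_msc_nuclei(det_params):
    # sparse stromal nuclei at the default well geometry
    from stromascreen import SimulationConfig

    config = SimulationConfig(n_all_viable=0, n_all_dead=0, n_msc=10)
    image_set, truth = render_well(config, "MSC", seed=8)
    n_matched = n_truth = 0
    for idx, img in enumerate(image_set.fields):
        large = segment_large_objects(img, det_params)
        assert all(c.area_px > det_params.max_spot_area_px for c in large)
        imaged = truth[truth["imaged"] & (truth["field_index"] == idx)]
        pred = np.array([c.centroid for c in large]) if large else np.empty((0, 2))
        scores = detection_scores(pred, imaged[["row", "col"]].to_numpy(), tolerance=8.0)
        n_matched += scores["n_matched"]
        n_truth += scores["n_truth"]
    assert n_truth >= 5  # most of the 10 fall inside the imaged grid
    assert n_matched >= 0.9 * n_truth


def test_spot_and_large_masks_are_disjoint(single_field_config, det_params):
    config = single_field_config(n_all_viable=20, n_all_dead=0, n_msc=1, well_radius_px=100.0, field_size_px=(200, 200))
    image_set, _ = render_well(config, "MIX", seed=13)
    img = image_set.fields[0]
    spots = detect_spots(img, det_params)
    large = segment_large_objects(img, det_params, spots=spots)
    assert len(large) >= 1
    assert len(spots) >= 15
    seen = set()
    for cand in spots + large:
        for r, c in cand.coords:
            assert (r, c) not in seen
            seen.add((r, c))


def test_false_positive_rate_on_pure_noise(single_field_config, det_params):
    config = single_field_config(n_all_viable=0, n_all_dead=0, n_msc=0)
    n_spots = []
    for seed in range(3):
        image_set, _ = render_well(config, f"NOISE{seed}", seed=seed)
        n_spots.append(len(detect_spots(image_set.fields[0], det_params)))
    # multiscale product at k=3 suppresses noise almost completely
    assert np.mean(n_spots) <= 5.0


def test_invalid_detection_params_raise():
    with pytest.raises(ValueError):
        DetectionParams(detection_scales=(4,))  # outside 1..n_scales
    with pytest.raises(ValueError):
        DetectionParams(k=0.0)
    with pytest.raises(ValueError):
        DetectionParams(min_spot_area_px=300, max_spot_area_px=250)
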