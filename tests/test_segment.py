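"""ROI, fiducials, thresholding, depot segmentation, boundary surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depotmri import segment as sg
from depotmri.phantom import generate_stage
from depotmri.volio import VoxelVolume
from tests.conftest import crop_to_roi, dice, small_spec


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def brute_force_otsu(values):
    """Independent exhaustive Otsu oracle (plain python loop)."""
    v = np.round(np.asarray(values, float)).astype(int)
    best_t, best_score = None, -1.0
    for t in range(v.min(), v.max()):
        lo, hi = v[v <= t], v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_score, best_t = score, t
    return best_t + 0.5


def test_otsu_on_two_gaussian_mixture_lands_between_modes():
    rng = np.random.default_rng(42)
    values = np.concatenate([rng.normal(100, 10, 20000), rng.normal(200, 10, 20000)])
    thr = sg.select_threshold(values, method="otsu")
    assert 130 <= thr <= 170
    assert thr == brute_force_otsu(values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=255), min_size=20, max_size=400))
def test_otsu_equals_exhaustive_search_on_integer_histograms(vals):
    vals = np.asarray(vals, dtype=float)
    if np.ptp(vals) < 1:
        return
    assert sg.otsu_threshold(vals) == brute_force_otsu(vals)


def test_valley_threshold_and_error_modes():
    rng = np.random.default_rng(0)
    values = np.concatenate([rng.normal(100, 8, 20000), rng.normal(200, 8, 5000)])
    thr = sg.valley_threshold(values)
    assert 120 <= thr <= 180
    with pytest.raises(ValueError, match="no depot"):
        sg.valley_threshold(np.full(1000, 80.0))
    assert sg.select_threshold(values, method="fixed", fixed_value=150.0) == 150.0


# ---------------------------------------------------------------------------
# fiducials and ROI
# ---------------------------------------------------------------------------

def test_detect_fiducials_recovers_all_capsules(small_series):
    spec, series, truth = small_series
    fids = sg.detect_fiducials(series.volumes["naive"])
    caps_true = truth.stages["naive"].capsule_centers_mm
    assert len(fids) == len(caps_true)
    got = fids.centroids
    want = caps_true[np.lexsort((np.round(caps_true[:, 0], 1), np.round(caps_true[:, 2], 1)))]
    # one-voxel accuracy per axis
    tol = np.array(series.volumes["naive"].spacing_mm)
    assert np.all(np.abs(got - want) < tol)


def test_detect_fiducials_errors_without_capsules():
    arr = np.full((30, 30, 8), 60.0)
    arr[:, 20:, :] = 100.0
    with pytest.raises(ValueError):
        sg.detect_fiducials(VoxelVolume(arr, (0.6, 0.6, 4.0)))


def test_mirrored_capsules_give_symmetric_centroids():
    spec = small_spec(fiducial_positions=((-18.0, 0.0), (18.0, 0.0)), noise_sigma=0.0,
                      void_radius_mm=0.0)
    vol, _ = generate_stage(spec, "insertion")  # identity frame
    fids = sg.detect_fiducials(vol)
    assert len(fids) == 2
    xs = sorted(c.oil_centroid_mm[0] for c in fids.capsules)
    assert xs[0] == pytest.approx(-xs[1], abs=0.3)


def test_extract_roi_clamps_and_validates(small_series):
    _, series, _ = small_series
    vol = series.volumes["naive"]
    fids = sg.detect_fiducials(vol)
    with pytest.warns(UserWarning, match="clipped"):
        roi = sg.extract_roi(vol, fids, 500.0)
    assert roi.shape == vol.shape  # clamp to full volume
    roi2 = sg.extract_roi(vol, fids, 15.0)
    cents = fids.centroids
    cx = roi2.origin_mm[0] + (roi2.shape[0] - 1) / 2 * roi2.spacing_mm[0]
    assert cx == pytest.approx(cents[:, 0].mean(), abs=vol.spacing_mm[0])
    bad = sg.FiducialSet([sg.Capsule(np.array([999.0, 0.0, 0.0]), 0.0, 4.0)])
    with pytest.raises(ValueError, match="outside"):
        sg.extract_roi(vol, bad, 15.0)


# ---------------------------------------------------------------------------
# depot segmentation
# ---------------------------------------------------------------------------

def test_segmented_depot_overlaps_truth(analyzed_small):
    spec, series, truth, analysis = analyzed_small
    for stage in ("v1", "v3"):
        res = analysis.results[stage]
        tm = crop_to_roi(truth.stages[stage].depot_mask, series.volumes[stage], res.roi)
        assert dice(res.seg.mask, tm) >= 0.90


def test_naive_stage_yields_empty_mask(analyzed_small):
    spec, series, truth, analysis = analyzed_small
    roi = analysis.results["v3"].roi
    thr = analysis.results["v3"].threshold
    naive_roi = sg.extract_roi(series.volumes["naive"],
                               analysis.results["naive"].fiducials, 40.0)
    seg = sg.segment_depot(naive_roi, thr, analysis.results["naive"].cannula_xz,
                           id_sc=analysis.results["naive"].id_sc_raw)
    assert not seg.mask.any()


def test_component_selection_prefers_cannula_touching_blob():
    arr = np.full((60, 60, 10), 100.0)
    arr[25:35, 25:35, 3:7] = 200.0   # at the cannula axis
    arr[45:57, 45:57, 3:8] = 200.0   # larger, far away
    roi = VoxelVolume(arr, (0.6, 0.6, 4.0), (-18.0, 0.0, -20.0))
    seg = sg.segment_depot(roi, 150.0, cannula_axis_xz=(0.0, 0.0), cylinder_radius_mm=6.0)
    picked = np.argwhere(seg.mask)
    assert picked[:, 0].max() < 40  # only the near-axis component survives


def test_segmentation_mesh_volume_consistent_with_mask(analyzed_small):
    *_, analysis = analyzed_small
    seg = analysis.results["v3"].seg
    mask_vol = seg.mask.sum() * seg.voxel_volume_mm3
    assert seg.mesh.volume == pytest.approx(mask_vol, rel=0.05)
    assert seg.mesh.is_watertight


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

def test_flat_layer_phantom_gives_flat_boundaries():
    spec = small_spec(sc_modulation_frac=0.0, skin_curvature_mm=0.0, noise_sigma=2.0)
    vol, truth = generate_stage(spec, "insertion")
    id_sc, sc_im = sg.extract_boundaries(vol, invalid_disk=(0.0, 0.0, 4.5))
    sep = sc_im.height_field - id_sc.height_field
    assert sep[id_sc.valid_mask].std() < 0.2
    assert sep[id_sc.valid_mask].mean() == pytest.approx(10.0, abs=0.5 * spec.slice_pitch_mm)
    assert np.all(id_sc.height_field < sc_im.height_field)


def test_undulating_muscle_profile_is_tracked():
    spec = small_spec(muscle_undulation_mm=1.5, noise_sigma=3.0)
    vol, truth = generate_stage(spec, "naive")
    id_sc, sc_im = sg.extract_boundaries(vol)
    ok = sc_im.valid_mask
    err = sc_im.height_field - truth.sc_im_height_mm
    rmse = np.sqrt((err[ok] ** 2).mean())
    assert rmse < spec.slice_pitch_mm  # well under one slice pitch
    meas = sc_im.height_field[ok] - sc_im.height_field[ok].mean()
    true = truth.sc_im_height_mm[ok] - truth.sc_im_height_mm[ok].mean()
    assert np.corrcoef(meas, true)[0, 1] > 0.9


def test_columns_through_depot_remain_valid(analyzed_small):
    spec, series, truth, analysis = analyzed_small
    res = analysis.results["v3"]
    xs, zs = res.id_sc_raw.x_mm, res.id_sc_raw.z_mm
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    rr = np.sqrt(X ** 2 + Z ** 2)
    under_depot = (rr > 6.0) & (rr < 10.0)  # inside depot footprint, outside void
    assert res.id_sc_raw.valid_mask[under_depot].mean() > 0.95


def test_depot_mask_never_extends_above_skin(analyzed_small):
    *_, analysis = analyzed_small
    res = analysis.results["v3"]
    ys = res.roi.axis_coords(1)
    above = ys[None, :, None] < (res.id_sc_raw.height_field[:, None, :] - 0.5)
    assert not (res.seg.mask & above).any()
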