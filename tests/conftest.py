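"""Shared fixtures: a small, fast phantom series plus its full analysis.

The small series keeps the study's voxel geometry (0.6 mm in-plane,
4 mm slice pitch) but shrinks the field of view and injected volumes so
a full generate + analyse cycle stays in the seconds range.
"""

import logging
import warnings

import numpy as np
import pytest

from depotmri.phantom import PhantomSpec, generate_series
from depotmri.pipeline import RunConfig, analyze_series

logging.getLogger("depotmri").setLevel(logging.WARNING)


def small_spec(**overrides) -> PhantomSpec:
    kw = dict(
        site_label="thigh",
        fov_lateral_mm=72.0,
        depth_extent_mm=48.0,
        stack_extent_mm=64.0,
        sc_baseline_thickness_mm=10.0,
        depot_volumes_mL=(1.0, 3.0),
        stage_expansion_pct=(10.0, 25.0),
        seed=3,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_series():
    spec = small_spec()
    series, truth = generate_series(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def analyzed_small(small_series):
    spec, series, truth = small_series
    cfg = RunConfig(site=spec.site_label, roi_half_extent_mm=40.0,
                    write_heatmaps=False, write_volumes=False, write_meshes=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis = analyze_series(series, cfg)
    return spec, series, truth, analysis


def crop_to_roi(full_mask: np.ndarray, full_volume, roi) -> np.ndarray:
    """Crop a full-grid truth mask to a ROI sub-volume's grid."""
    i0 = int(round((roi.origin_mm[0] - full_volume.origin_mm[0]) / full_volume.spacing_mm[0]))
    k0 = int(round((roi.origin_mm[2] - full_volume.origin_mm[2]) / full_volume.spacing_mm[2]))
    return full_mask[i0: i0 + roi.shape[0], :, k0: k0 + roi.shape[2]]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
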