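import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import map_coordinates

import dbtvis as dv
from dbtvis.errors import DomainError, UsageError
from dbtvis.render import RenderConfig, TransferFunction, corrected_alpha


def test_nyquist_bound():
    assert dv.nyquist_bound(0.085) == 0.170
    assert dv.nyquist_bound(1.0) == 2.0
    with pytest.raises(DomainError):
        dv.nyquist_bound(0.0)


def test_auto_sampling_distance():
    assert dv.auto_sampling_distance(1) == pytest.approx(3580.5)
    # direct evaluation of the power law at a DBT-sized volume
    n = 8_000_000
    assert dv.auto_sampling_distance(n) == pytest.approx(3580.5 * n ** (-0.621), rel=1e-12)
    assert dv.auto_sampling_distance(10**7) < dv.auto_sampling_distance(10**6)
    with pytest.raises(DomainError):
        dv.auto_sampling_distance(0)


def test_study_grid_is_the_published_distance_list():
    assert dv.STUDY_SAMPLING_DISTANCES == (
        0.010, 0.025, 0.050, 0.075, 0.100, 0.145, 0.170, 0.195, 0.4, 0.6, 0.8, 1.0,
    )
    # the 0.170 entry is the Nyquist bound of the in-plane spacing
    assert dv.nyquist_bound(0.085) in dv.STUDY_SAMPLING_DISTANCES


def test_composite_ray_hand_values():
    assert dv.composite_ray([(0.7, 1.0)], 0.3, 1.0) == (0.7, 1.0)
    assert dv.composite_ray([], 1.0, 1.0) == (0.0, 0.0)
    intensity, alpha = dv.composite_ray([(1.0, 0.5), (1.0, 0.5)], 1.0, 1.0)
    assert intensity == pytest.approx(0.75)
    assert alpha == pytest.approx(0.75)
    with pytest.raises(DomainError):
        dv.composite_ray([(1.2, 0.5)], 1.0, 1.0)


def test_homogeneous_ray_alpha_invariant_under_d_halving():
    """Opacity correction keeps total opacity of a fixed-length ray d-independent."""
    alpha, unit, length = 0.37, 1.0, 8.0
    totals = []
    for d in (1.0, 0.5, 0.25, 0.125):
        n = int(round(length / d))
        _, acc = dv.composite_ray([(0.5, alpha)] * n, d, unit)
        totals.append(acc)
    expected = 1.0 - (1.0 - alpha) ** (length / unit)
    for acc in totals:
        assert acc == pytest.approx(expected, abs=1e-6)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), max_size=40),
       st.floats(0.01, 2.0))
def test_accumulated_alpha_monotone_and_bounded(samples, d):
    running = 0.0
    for k in range(1, len(samples) + 1):
        intensity, alpha = dv.composite_ray(samples[:k], d, 1.0)
        assert alpha >= running - 1e-12
        assert 0.0 <= alpha <= 1.0
        assert intensity <= alpha + 1e-12
        running = alpha


def test_homogeneous_volume_renders_uniform_image():
    vol = dv.Volume(np.full((6, 7, 8), 5.0))
    tf = TransferFunction.linear(0.0, 10.0)
    for azimuth in (0, 90):
        img = dv.render(vol, RenderConfig(azimuth=azimuth, sampling_distance=0.25, tf=tf))
        assert np.ptp(img.pixels) < 1e-9
        assert np.ptp(img.alpha) < 1e-9


def test_opaque_wall_reduces_to_slab_grays():
    """A fully opaque first y-slab makes the 90-degree view show its grays."""
    rng = np.random.default_rng(5)
    data = np.zeros((9, 6, 7))
    wall = rng.uniform(0.6, 1.0, size=(9, 7))
    data[:, 0, :] = wall
    data[:, 1, :] = wall  # two identical slabs: entry samples interpolate inside the wall
    vol = dv.Volume(data)
    tf = TransferFunction(
        gray_points=((0.0, 0.0), (1.0, 1.0)),
        opacity_points=((0.0, 0.0), (0.5, 1.0)),
    )
    img = dv.render(vol, RenderConfig(azimuth=90, sampling_distance=0.5, tf=tf))
    assert img.axes == ("x", "z")
    np.testing.assert_allclose(img.pixels, wall, atol=1e-12)
    np.testing.assert_allclose(img.alpha, 1.0)


def test_render_matches_brute_force_compositing_oracle():
    """Vectorized renderer agrees with per-pixel map_coordinates + composite_ray."""
    rng = np.random.default_rng(7)
    vol = dv.Volume(rng.uniform(size=(16, 16, 16)), spacing=(1.0, 1.0, 1.0))
    tf = TransferFunction.linear(0.0, 1.0)
    d = min(vol.spacing) / 8.0
    for azimuth, ray_axis, spanned in ((0, 2, (0, 1)), (90, 1, (0, 2))):
        img = dv.render(vol, RenderConfig(azimuth=azimuth, sampling_distance=d, tf=tf))
        extent = vol.world_extent(ray_axis)
        ts = (np.arange(int(math.ceil(extent / d - 0.5))) + 0.5) * d
        brute = np.zeros(img.pixels.shape)
        for a in range(img.pixels.shape[0]):
            for b in range(img.pixels.shape[1]):
                coords = np.zeros((3, ts.size))
                coords[spanned[0]] = a
                coords[spanned[1]] = b
                coords[ray_axis] = ts / vol.spacing[ray_axis]
                vals = map_coordinates(vol.data, coords, order=1)
                brute[a, b], _ = dv.composite_ray(
                    [(tf.gray(v), tf.alpha(v)) for v in vals], d, tf.opacity_unit_distance
                )
        rms = np.sqrt(np.mean((img.pixels - brute) ** 2))
        assert rms < 1e-3


def test_sampling_convergence_on_smooth_phantom(small_spec):
    """d=0.05 and d=0.025 renders differ by < 1% RMS of dynamic range."""
    import dataclasses

    spec = small_spec
    vol = dv.generate_phantom(dataclasses.replace(spec, noise_sigma=0.0))
    from dbtvis.sweep import study_transfer_function

    tf = study_transfer_function(spec)
    imgs = [
        dv.render(vol, RenderConfig(azimuth=90, sampling_distance=d, tf=tf))
        for d in (0.05, 0.025)
    ]
    dyn = np.ptp(imgs[1].pixels)
    rms = np.sqrt(np.mean((imgs[0].pixels - imgs[1].pixels) ** 2))
    assert rms < 0.01 * dyn


def test_render_config_validation():
    with pytest.raises(UsageError):
        RenderConfig(azimuth=45)
    with pytest.raises(DomainError):
        RenderConfig(sampling_distance=0.0)
    with pytest.raises(DomainError):
        TransferFunction(((0, 0), (1, 1)), ((0, 0.5), (1, 0.2), (2, 0.9)))


def test_corrected_alpha_limits():
    assert corrected_alpha(np.array(0.5), 1.0, 1.0) == pytest.approx(0.5)
    assert corrected_alpha(np.array(1.0), 0.01, 1.0) == pytest.approx(1.0)
    assert corrected_alpha(np.array(0.0), 2.0, 1.0) == 0.0


def test_default_tf_spans_volume_range(small_volume):
    """With no tf configured, rendering uses linear ramps over [min, max]."""
    img = dv.render(small_volume, RenderConfig(azimuth=0, sampling_distance=0.5, tf=None))
    assert img.axes == ("x", "y")
    assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0
    assert img.pixels.max() > 0.1  # the disk is visible
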