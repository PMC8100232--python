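"""ALPS index mechanics: ROI extraction, the ratio, observer averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtialps import (AxisDiffusivities, RoiMask, average_observers,
                     compute_alps, extract_axis_diffusivities, fit_tensor,
                     generate_phantom, phantom_roi_pair,
                     single_observer_result)
from dtialps.phantom import PhantomConfig

from conftest import uniform_field


def _roi(voxels, kind="projection", hemi="right"):
    return RoiMask(voxels=np.asarray(voxels), fiber_kind=kind, hemisphere=hemi)


class TestRoiMask:
    def test_rejects_empty_and_multi_slice(self):
        with pytest.raises(ValueError, match="empty"):
            RoiMask(voxels=np.empty((0, 3), dtype=int),
                    fiber_kind="projection", hemisphere="right")
        with pytest.raises(ValueError, match="single axial slice"):
            _roi([[0, 0, 0], [0, 1, 1]])

    def test_area_follows_voxel_geometry(self):
        roi = _roi([[0, 0, 1], [1, 0, 1], [2, 0, 1]])
        assert roi.area_mm2((2.0, 2.0, 2.0)) == pytest.approx(12.0)

    def test_from_label_volume_picks_single_slice(self):
        labels = np.zeros((4, 4, 5), dtype=int)
        labels[1:3, 1:3, :] = 1
        roi = RoiMask.from_label_volume(labels, 1, "projection", "right")
        assert roi.n_voxels == 4
        assert roi.slice_index == 2  # median slice of the labelled slab


class TestExtraction:
    def test_uniform_field_mean_equals_voxel_value(self):
        fld = uniform_field([1.1e-3, 0.5e-3, 0.9e-3])
        d = extract_axis_diffusivities(
            fld, _roi([[0, 0, 1], [1, 1, 1]], "projection"),
            _roi([[2, 2, 1]], "association"))
        assert d.d_xproj == pytest.approx(1.1e-3)
        assert d.d_yproj == pytest.approx(0.5e-3)
        assert d.d_xassoc == pytest.approx(1.1e-3)
        assert d.d_zassoc == pytest.approx(0.9e-3)

    def test_two_voxel_arithmetic_mean(self):
        fld = uniform_field([1.0e-3, 0.5e-3, 0.5e-3])
        fld.tensors[1, 0, 1, 0, 0] = 1.4e-3
        d = extract_axis_diffusivities(
            fld, _roi([[0, 0, 1], [1, 0, 1]], "projection"),
            _roi([[2, 2, 1]], "association"))
        assert d.d_xproj == pytest.approx(1.2e-3)

    def test_roi_outside_grid_rejected(self):
        fld = uniform_field([1e-3] * 3)
        with pytest.raises(ValueError, match="outside"):
            extract_axis_diffusivities(
                fld, _roi([[9, 0, 1]], "projection"), _roi([[0, 0, 1]], "association"))

    def test_fiber_kind_and_hemisphere_consistency(self):
        fld = uniform_field([1e-3] * 3)
        proj = _roi([[0, 0, 1]], "projection", "right")
        assoc_left = _roi([[1, 1, 1]], "association", "left")
        with pytest.raises(ValueError, match="hemisphere"):
            extract_axis_diffusivities(fld, proj, assoc_left)
        with pytest.raises(ValueError, match="projection"):
            extract_axis_diffusivities(
                fld, _roi([[0, 0, 1]], "association"), assoc_left)

    def test_clipped_voxel_inside_roi_warns(self):
        fld = uniform_field([1e-3] * 3)
        fld.clipped[0, 0, 1] = True
        with pytest.warns(RuntimeWarning, match="clipped"):
            extract_axis_diffusivities(
                fld, _roi([[0, 0, 1]], "projection"),
                _roi([[1, 1, 1]], "association"))


class TestComputeAlps:
    def test_isotropy_gives_one(self):
        d = AxisDiffusivities(1e-3, 1e-3, 1e-3, 1e-3)
        assert compute_alps(d) == pytest.approx(1.0)

    def test_printed_example_value(self):
        d = AxisDiffusivities(d_xproj=1.2e-3, d_yproj=0.7e-3,
                              d_xassoc=1.0e-3, d_zassoc=0.9e-3)
        assert compute_alps(d) == pytest.approx(1.375)

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AxisDiffusivities(1e-3, -1e-3, 1e-3, 1e-3)

    @given(dx=st.floats(0.5, 2.0), dy=st.floats(0.5, 2.0),
           da=st.floats(0.5, 2.0), dz=st.floats(0.5, 2.0),
           c=st.floats(0.01, 100.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, dx, dy, da, dz, c):
        """Global diffusivity scaling by c > 0 leaves the index unchanged."""
        d1 = AxisDiffusivities(dx * 1e-3, dy * 1e-3, da * 1e-3, dz * 1e-3)
        d2 = AxisDiffusivities(c * dx * 1e-3, c * dy * 1e-3, c * da * 1e-3,
                               c * dz * 1e-3)
        assert compute_alps(d2) == pytest.approx(compute_alps(d1), rel=1e-12)

    @given(base=st.floats(0.5, 1.5), bump=st.floats(0.01, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_x_diffusivities(self, base, bump):
        d = AxisDiffusivities(base * 1e-3, 0.7e-3, base * 1e-3, 0.9e-3)
        d_up = AxisDiffusivities((base + bump) * 1e-3, 0.7e-3, base * 1e-3,
                                 0.9e-3)
        assert compute_alps(d_up) > compute_alps(d)

    def test_isotropic_field_yields_exactly_one(self):
        fld = uniform_field([0.7e-3] * 3, grid=(6, 6, 3))
        d = extract_axis_diffusivities(
            fld, _roi([[0, 0, 1], [0, 1, 1]], "projection"),
            _roi([[3, 3, 1], [4, 3, 1]], "association"))
        assert compute_alps(d) == 1.0


class TestObserverAveraging:
    def _result(self, idx, hemi="right", sid="s1"):
        # diffusivities chosen so the index equals idx exactly
        d = AxisDiffusivities(idx * 1e-3, 1e-3, idx * 1e-3, 1e-3)
        return single_observer_result(sid, hemi, d)

    def test_mean_of_two_observers(self):
        merged = average_observers(self._result(1.4), self._result(1.6))
        assert merged.index == pytest.approx(1.5)
        assert merged.observer_indices == (pytest.approx(1.4), pytest.approx(1.6))

    def test_identical_observers_unchanged(self):
        merged = average_observers(self._result(1.3), self._result(1.3))
        assert merged.index == pytest.approx(1.3)

    def test_hemisphere_and_subject_mismatch_rejected(self):
        with pytest.raises(ValueError, match="hemisphere"):
            average_observers(self._result(1.4, hemi="right"),
                              self._result(1.6, hemi="left"))
        with pytest.raises(ValueError, match="subject"):
            average_observers(self._result(1.4, sid="a"),
                              self._result(1.6, sid="b"))


class TestPhantomIdentifiability:
    def test_noiseless_roundtrip_recovers_closed_form(self, small_noiseless_config):
        data = generate_phantom(small_noiseless_config)
        fld = fit_tensor(data.dwi, data.scheme,
                         voxel_size=small_noiseless_config.voxel_size)
        for hemi in ("right", "left"):
            proj, assoc = phantom_roi_pair(data.labels, hemi)
            idx = compute_alps(extract_axis_diffusivities(fld, proj, assoc))
            assert idx == pytest.approx(data.ground_truth_alps, abs=1e-6)

    def test_recovered_index_scale_invariant(self):
        base = PhantomConfig(grid_shape=(20, 20, 4), snr=0.0)
        scaled = PhantomConfig(grid_shape=(20, 20, 4), snr=0.0, s0=7.5,
                               lambda_parallel=base.lambda_parallel * 2,
                               lambda_perp=base.lambda_perp * 2,
                               perivascular_boost=base.perivascular_boost * 2,
                               background_diffusivity=2 * base.background_diffusivity)
        out = []
        for cfg in (base, scaled):
            data = generate_phantom(cfg)
            fld = fit_tensor(data.dwi, data.scheme, voxel_size=cfg.voxel_size)
            proj, assoc = phantom_roi_pair(data.labels, "right")
            out.append(compute_alps(extract_axis_diffusivities(fld, proj, assoc)))
        assert out[0] == pytest.approx(out[1], abs=1e-9)
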