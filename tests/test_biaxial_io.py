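"""Raw-recording conversion, cycle extraction, resampling, and dataset I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delimech.biaxial_io import (
    BiaxialRecording,
    DatasetFormatError,
    MeatDataset,
    StretchStressCurve,
    TestProtocol,
    extract_cycle,
    load_dataset,
    load_reference_dataset,
    resample_and_average,
    save_dataset,
    set_gauge_reference,
    slice_cycle,
    to_stretch_stress,
    trim_to_reference,
)


def triangular_recording(cycles=3, n_leg=20, lam_max=1.1, preload_offset=0.0):
    """Synthetic equibiaxial recording with triangular stretch cycles."""
    L = 12.0
    up = np.linspace(1.0, lam_max, n_leg, endpoint=False)
    down = np.linspace(lam_max, 1.0, n_leg, endpoint=False)
    lam = np.concatenate([np.concatenate([up, down]) for _ in range(cycles)] + [[1.0]])
    force = 144.0 * (lam - 1.0) + preload_offset  # an arbitrary monotone law
    return BiaxialRecording(
        time=np.arange(lam.size) * 0.5,
        force_x=force,
        force_y=force,
        gauge_x=lam * L,
        gauge_y=lam * L,
        thickness=1.0,
        mode_label="equibiax",
    )


class TestToStretchStress:
    def test_zero_force_gives_zero_stress(self):
        rec = triangular_recording()
        rec = rec.select(slice(0, 5))
        zero = BiaxialRecording(
            rec.time, np.zeros(5), np.zeros(5), rec.gauge_x, rec.gauge_y, 1.0, "equibiax"
        )
        cx, cy = to_stretch_stress(zero, (12.0, 12.0))
        assert np.all(cx.stress == 0) and np.all(cy.stress == 0)

    def test_identity_stretch(self):
        n = 4
        rec = BiaxialRecording(
            np.arange(n), np.ones(n), np.ones(n), np.full(n, 12.0), np.full(n, 12.0),
            1.0, "equibiax",
        )
        cx, _ = to_stretch_stress(rec, (12.0, 12.0))
        assert np.all(cx.stretch == 1.0)

    def test_unit_arithmetic(self):
        # 144 mN over 12 mm x 1 mm reference area -> 12 kPa
        n = 3
        rec = BiaxialRecording(
            np.arange(n), np.full(n, 144.0), np.full(n, 144.0),
            np.full(n, 12.0), np.full(n, 12.0), 1.0, "equibiax",
        )
        cx, cy = to_stretch_stress(rec, (12.0, 12.0))
        assert cx.stress == pytest.approx(12.0)
        assert cy.stress == pytest.approx(12.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        F=st.floats(1.0, 1e3),
        L=st.floats(5.0, 30.0),
        t=st.floats(0.3, 3.0),
    )
    def test_units_mN_mm_to_kPa(self, F, L, t):
        # dimensional consistency: P [kPa] = F [mN] / (L [mm] * t [mm])
        n = 2
        rec = BiaxialRecording(
            np.arange(n), np.full(n, F), np.full(n, F),
            np.full(n, L), np.full(n, L), t, "equibiax",
        )
        cx, _ = to_stretch_stress(rec, (L, L))
        assert cx.stress[0] == pytest.approx(F / (L * t), rel=1e-12)

    def test_invalid_geometry_rejected(self):
        rec = triangular_recording()
        with pytest.raises(ValueError):
            to_stretch_stress(rec, (0.0, 12.0))
        with pytest.raises(ValueError):
            BiaxialRecording(
                rec.time, rec.force_x, rec.force_y, rec.gauge_x, rec.gauge_y,
                -1.0, "equibiax",
            )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            BiaxialRecording(
                np.arange(5), np.zeros(4), np.zeros(5),
                np.ones(5), np.ones(5), 1.0, "equibiax",
            )


class TestGaugeReference:
    def test_already_above_preload(self):
        rec = triangular_recording(preload_offset=50.0)
        L1, L2 = set_gauge_reference(rec, TestProtocol(preload=30.0))
        assert (L1, L2) == (rec.gauge_x[0], rec.gauge_y[0])

    def test_monotone_ramp_crossing(self):
        # linear-scan oracle: first index with both forces >= preload
        force = np.linspace(0.0, 100.0, 21)
        rec = BiaxialRecording(
            np.arange(21), force, force, np.linspace(11.8, 12.2, 21),
            np.linspace(11.9, 12.3, 21), 1.0, "equibiax",
        )
        k = next(i for i in range(21) if force[i] >= 30.0)
        L1, L2 = set_gauge_reference(rec, TestProtocol(preload=30.0))
        assert (L1, L2) == (rec.gauge_x[k], rec.gauge_y[k])
        trimmed, ref = trim_to_reference(rec, TestProtocol(preload=30.0))
        assert ref == (L1, L2)
        assert len(trimmed) == 21 - k

    def test_zero_preload_uses_first_step(self):
        rec = triangular_recording()
        L1, _ = set_gauge_reference(rec, TestProtocol(preload=0.0))
        assert L1 == rec.gauge_x[0]

    def test_unreachable_preload_errors(self):
        rec = triangular_recording()
        with pytest.raises(ValueError, match="never reached"):
            set_gauge_reference(rec, TestProtocol(preload=1e6))


class TestCycleExtraction:
    def test_single_cycle_partitions(self):
        rec = triangular_recording(cycles=1)
        load = slice_cycle(rec, 1, "loading")
        unload = slice_cycle(rec, 1, "unloading")
        # the peak is shared; together the legs cover the record
        assert len(load) + len(unload) == len(rec) + 1
        assert np.all(np.diff(load.gauge_x) >= 0)
        assert np.all(np.diff(unload.gauge_x) <= 0)

    def test_third_cycle_is_last_ascending_ramp(self):
        rec = triangular_recording(cycles=3, n_leg=20)
        cx, _ = extract_cycle(rec, 3, "loading", (12.0, 12.0))
        assert cx.stretch[0] == pytest.approx(1.0)
        assert cx.stretch[-1] == pytest.approx(1.1)
        assert np.all(np.diff(cx.stretch) >= 0)

    def test_absent_cycle_errors(self):
        rec = triangular_recording(cycles=2)
        with pytest.raises(ValueError, match="absent"):
            slice_cycle(rec, 3, "loading")

    def test_hold_channel_returned_at_unit_stretch(self):
        rec = triangular_recording(cycles=1)
        held = BiaxialRecording(
            rec.time, rec.force_x, rec.force_y, rec.gauge_x, np.full(len(rec), 12.0),
            1.0, "strip-x",
        )
        _, cy = extract_cycle(held, 1, "loading", (12.0, 12.0))
        assert np.all(cy.stretch == 1.0)

    def test_conversion_commutes_with_extraction(self):
        rec = triangular_recording(cycles=3)
        ref = (12.0, 12.0)
        a = to_stretch_stress(slice_cycle(rec, 2, "unloading"), ref)
        full = to_stretch_stress(rec, ref)
        sliced = slice_cycle(rec, 2, "unloading")
        idx = np.searchsorted(rec.time, sliced.time)
        for curve, whole in zip(a, full):
            assert np.allclose(curve.stretch, whole.stretch[idx])
            assert np.allclose(curve.stress, whole.stress[idx])


class TestResampleAndAverage:
    @staticmethod
    def curve(stress_fn, lam=None, n=25):
        lam = np.linspace(1.0, 1.1, n) if lam is None else lam
        return StretchStressCurve("equibiax", "x", lam, stress_fn(lam))

    def test_single_curve_interpolated_copy(self):
        c = self.curve(lambda lam: 50 * (lam - 1))
        out = resample_and_average([c], n_points=11)
        assert out.stretch[0] == 1.0
        assert np.allclose(out.stress, 50 * (out.stretch - 1), atol=1e-12)

    def test_idempotent_on_gridded_curve(self):
        c = self.curve(lambda lam: 80 * (lam - 1) ** 1.0, n=11)
        out = resample_and_average([c], n_points=11)
        assert np.allclose(out.stretch, c.stretch)
        assert np.allclose(out.stress, c.stress)

    def test_linear_averaging(self):
        c1 = self.curve(lambda lam: 10 * (lam - 1))
        c2 = self.curve(lambda lam: 30 * (lam - 1))
        out = resample_and_average([c1, c2], n_points=11)
        assert np.allclose(out.stress, 20 * (out.stretch - 1), atol=1e-12)

    def test_symmetric_hysteresis_cancels(self):
        # loading/unloading pair split +/-10% about a neo-Hooke midline
        base = lambda lam: 126.1 * (lam - lam**-5)
        loading = self.curve(lambda lam: 1.1 * base(lam))
        unloading = self.curve(lambda lam: 0.9 * base(lam))
        out = resample_and_average([loading, unloading], n_points=11)
        assert np.allclose(out.stress, base(out.stretch), rtol=1e-3, atol=1e-3)

    def test_errors(self):
        c = self.curve(lambda lam: lam - 1)
        with pytest.raises(ValueError):
            resample_and_average([])
        with pytest.raises(ValueError):
            resample_and_average([StretchStressCurve("equibiax", "x", [1.0], [0.0])])


class TestDatasetIO:
    def test_reference_fixture_shape_and_values(self, reference):
        assert sorted(reference) == ["AC", "AH", "AP", "AT", "PD", "PH", "PP", "PT"]
        for ds in reference.values():
            assert ds.n_samples == 8
            for c in ds.iter_curves():
                assert len(c) == 11
        at = reference["AT"].curve("equibiax", "x")
        assert (at.stretch[1], at.stress[1]) == (1.01, 2.29)
        assert at.stretch[0] == 1.0 and at.stress[0] == 0.0

    def test_hold_channels_flagged(self, reference):
        ds = reference["PT"]
        assert ds.curve("strip-x", "y").is_hold
        assert not ds.curve("strip-x", "x").is_hold
        assert ds.curve("strip-y", "x").is_hold
        retained = list(ds.iter_curves(include_hold=False))
        assert len(retained) == 8

    def test_round_trip(self, reference, tmp_path):
        path = tmp_path / "ds.csv"
        save_dataset(reference["PD"], path)
        back = load_dataset(path)["PD"]
        for mode in back.curves:
            for d in ("x", "y"):
                a, b = reference["PD"].curve(mode, d), back.curve(mode, d)
                assert np.allclose(a.stretch, b.stretch)
                assert np.allclose(a.stress, b.stress)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DatasetFormatError, match="empty"):
            load_dataset(path)

    def test_bad_cells_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "product,mode,direction,stretch,stress_kPa\n"
            "XX,equibiax,x,1.00,0.00\n"
            "XX,equibiax,x,1.01,oops\n"
        )
        with pytest.raises(DatasetFormatError, match="line 3"):
            load_dataset(path)

    def test_unknown_mode_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "product,mode,direction,stretch,stress_kPa\nXX,shear,x,1.0,0.0\n"
        )
        with pytest.raises(DatasetFormatError, match="unknown mode"):
            load_dataset(path)

    def test_missing_direction_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = ["product,mode,direction,stretch,stress_kPa"]
        for mode in ("strip-x", "strip-y", "off-x", "off-y", "equibiax"):
            rows.append(f"XX,{mode},x,1.0,0.0")
            if mode != "equibiax":
                rows.append(f"XX,{mode},y,1.0,0.0")
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(DatasetFormatError, match="both directions"):
            load_dataset(path)
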