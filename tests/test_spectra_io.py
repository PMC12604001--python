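import numpy as np
import pytest

from quenchbind import (
    EEM,
    ParseError,
    Spectrum,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
    interp_at,
    read_eem,
    read_spectrum,
    read_titration,
    resample,
    write_eem,
    write_spectrum,
    write_titration,
)
from quenchbind.synthetic import GeneratorConfig, make_titration


class TestSpectrumModel:
    def test_minimal_two_point_spectrum(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("340,100\n341,99\n")
        spec = read_spectrum(p)
        assert len(spec) == 2
        assert spec.wavelength_nm.tolist() == [340.0, 341.0]
        assert spec.intensity.tolist() == [100.0, 99.0]

    def test_rows_out_of_order_are_sorted(self, tmp_path):
        ordered = tmp_path / "a.csv"
        ordered.write_text("300,1\n310,2\n320,3\n")
        shuffled = tmp_path / "b.csv"
        shuffled.write_text("320,3\n300,1\n310,2\n")
        a, b = read_spectrum(ordered), read_spectrum(shuffled)
        np.testing.assert_array_equal(a.wavelength_nm, b.wavelength_nm)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("300,1\n300,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_spectrum(p)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("300,1\n301,not_a_number\n302,3\n")
        with pytest.raises(ParseError, match=":2:"):
            read_spectrum(p)

    @pytest.mark.parametrize("delim", [",", "\t", "  "])
    def test_delimiter_autodetection(self, tmp_path, delim):
        p = tmp_path / "d.txt"
        p.write_text(f"300{delim}1\n310{delim}2\n")
        spec = read_spectrum(p)
        assert spec.intensity.tolist() == [1.0, 2.0]

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("# wavelength,intensity\n300,1\n310,2\n")
        assert len(read_spectrum(p)) == 2

    def test_single_point_file_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("300,1\n")
        with pytest.raises(ValidationError):
            read_spectrum(p)

    def test_negative_molar_absorption_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum([300, 310], [1.0, -0.5], kind="molar_absorption")

    def test_roundtrip_preserves_values(self, tmp_path):
        wl = np.linspace(300, 450, 151)
        rng = np.random.default_rng(0)
        spec = Spectrum(wl, rng.uniform(0, 1000, wl.size), kind="emission", label="x")
        p = tmp_path / "rt.csv"
        write_spectrum(spec, p)
        back = read_spectrum(p, kind="emission")
        np.testing.assert_allclose(back.wavelength_nm, spec.wavelength_nm, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, spec.intensity, rtol=1e-9)


class TestResample:
    def test_linear_midpoint(self):
        spec = Spectrum([300, 302], [0.0, 2.0])
        assert interp_at(spec, 301.0) == pytest.approx(1.0)
        out = resample(spec, [300.5, 301.0])
        np.testing.assert_allclose(out.intensity, [0.5, 1.0])

    def test_identity_on_own_grid(self):
        spec = Spectrum([300, 305, 320], [1.0, 5.0, 2.0])
        out = resample(spec, spec.wavelength_nm)
        np.testing.assert_array_equal(out.intensity, spec.intensity)

    def test_idempotent(self):
        spec = Spectrum(np.arange(300.0, 320.0), np.arange(20.0))
        grid = np.linspace(301, 318, 35)
        once = resample(spec, grid)
        twice = resample(once, grid)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_no_extrapolation(self):
        spec = Spectrum([300, 302], [0.0, 2.0])
        with pytest.raises(ValidationError):
            resample(spec, [299.0, 301.0])
        with pytest.raises(ValidationError):
            interp_at(spec, 299.0)

    def test_original_nodes_preserved_exactly(self):
        wl = np.array([300.0, 301.0, 305.0, 311.0])
        spec = Spectrum(wl, [3.0, 1.0, 4.0, 1.5])
        dense = np.union1d(wl, np.linspace(300, 311, 45))
        out = resample(spec, dense)
        idx = np.searchsorted(dense, wl)
        np.testing.assert_array_equal(out.intensity[idx], spec.intensity)


class TestTitrationIO:
    def _write(self, path, rows, header="conc_M,intensity,A_ex,A_em"):
        path.write_text(header + "\n" + "\n".join(rows) + "\n")

    def test_eleven_point_assay_table(self, tmp_path):
        conc = np.linspace(0, 50e-6, 11)
        rows = [f"{float(c)!r},{float(1000/(1+6467*c))!r},0,0" for c in conc]
        p = tmp_path / "t.csv"
        self._write(p, rows)
        series = read_titration(p, {"temperature_K": 303.0})
        assert len(series) == 11
        assert series.points[0].quencher_conc_M == 0.0
        assert series.points[0].intensity_obs == pytest.approx(1000.0)

    def test_missing_zero_concentration_rejected(self, tmp_path):
        p = tmp_path / "nozero.csv"
        self._write(p, ["1e-6,900,0,0", "2e-6,800,0,0", "3e-6,700,0,0"])
        with pytest.raises(ValidationError, match="zero-concentration"):
            read_titration(p, {"temperature_K": 298.0})

    def test_negative_concentration_rejected(self, tmp_path):
        p = tmp_path / "neg.csv"
        self._write(p, ["-1e-6,900,0,0", "0,1000,0,0", "2e-6,800,0,0"])
        with pytest.raises(ValidationError):
            read_titration(p, {"temperature_K": 298.0})

    def test_absorbance_columns_default_to_zero(self, tmp_path):
        p = tmp_path / "noA.csv"
        self._write(p, ["0,1000", "1e-6,900", "2e-6,800"], header="conc_M,intensity")
        series = read_titration(p, {"temperature_K": 298.0})
        assert np.all(series.A_ex == 0) and np.all(series.A_em == 0)

    def test_roundtrip(self, tmp_path):
        series = make_titration(GeneratorConfig(seed=3, noise_rel_sd=0.01))[0]
        p = tmp_path / "rt.csv"
        write_titration(series, p)
        back = read_titration(p, {"temperature_K": series.temperature_K,
                                  "tau0_s": series.tau0_s})
        np.testing.assert_allclose(back.conc_M, series.conc_M, rtol=1e-9)
        np.testing.assert_allclose(back.intensity_obs, series.intensity_obs, rtol=1e-9)
        np.testing.assert_allclose(back.A_ex, series.A_ex, rtol=1e-9)

    def test_series_invariants(self):
        pts = lambda cs: tuple(TitrationPoint(c, 100.0) for c in cs)
        with pytest.raises(ValidationError):
            TitrationSeries(298.0, pts([0.0, 1e-6]))  # too few
        with pytest.raises(ValidationError):
            TitrationSeries(298.0, pts([0.0, 0.0, 1e-6]))  # two F0 points
        with pytest.raises(ValidationError):
            TitrationSeries(298.0, pts([0.0, 2e-6, 1e-6]))  # not sorted


class TestEEMIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        eem = EEM(np.arange(200.0, 260.0, 10.0), np.arange(300.0, 400.0, 10.0),
                  rng.uniform(0, 100, (6, 10)))
        p = tmp_path / "eem.csv"
        write_eem(eem, p)
        back = read_eem(p)
        np.testing.assert_allclose(back.excitation_nm, eem.excitation_nm, rtol=1e-9)
        np.testing.assert_allclose(back.emission_nm, eem.emission_nm, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, eem.intensity, rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            EEM([200, 210], [300, 310, 320], np.zeros((3, 2)))

    def test_decreasing_axis_rejected(self):
        with pytest.raises(ValidationError):
            EEM([210, 200], [300, 310], np.zeros((2, 2)))
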