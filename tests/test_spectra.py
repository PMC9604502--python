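"""Spectrum representation, moments, generators and file round trips."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mcfmkm as m
from mcfmkm.exceptions import (
    DegenerateSpectrumError,
    GridRangeError,
    SpectrumParseError,
)


class TestGrid:
    def test_default_grid_span_and_resolution(self, default_grid):
        assert default_grid.n_bins == 450
        lo, hi = default_grid.span
        assert lo == pytest.approx(1e-2) and hi == pytest.approx(1e7)
        ratios = default_grid.edges[1:] / default_grid.edges[:-1]
        assert np.ptp(ratios) / ratios.mean() < 1e-12

    def test_representative_is_geometric_mean(self, default_grid):
        e = default_grid.edges
        assert np.allclose(default_grid.representative, np.sqrt(e[:-1] * e[1:]))

    def test_non_loguniform_edges_rejected(self):
        with pytest.raises(ValueError, match="logarithmically uniform"):
            m.LinealEnergyGrid(np.array([1.0, 2.0, 3.0, 4.0]))

    def test_locate_half_open_bins(self, default_grid):
        idx = default_grid.locate(default_grid.edges[5])
        assert idx == 5
        assert default_grid.locate(1e7) == 449
        with pytest.raises(GridRangeError):
            default_grid.locate(1e-3)


class TestNormalize:
    def test_scaling(self, default_grid):
        w = np.zeros(default_grid.n_bins)
        w[[10, 11]] = 2.0
        s = m.normalize(m.MicrodosimetricSpectrum(default_grid, w))
        assert s.weights[10] == pytest.approx(0.5)
        assert s.weights[11] == pytest.approx(0.5)
        assert s.total == pytest.approx(1.0, abs=1e-10)

    def test_idempotent(self, default_grid):
        s = m.generate_track_segment(50.0, default_grid)
        s2 = m.normalize(s)
        assert np.array_equal(s.weights, s2.weights)

    def test_all_zero_rejected(self, default_grid):
        with pytest.raises(DegenerateSpectrumError):
            m.MicrodosimetricSpectrum(default_grid, np.zeros(default_grid.n_bins))

    def test_negative_weight_rejected(self, default_grid):
        w = np.zeros(default_grid.n_bins)
        w[0], w[1] = 1.0, -0.1
        with pytest.raises(ValueError, match="non-negative"):
            m.MicrodosimetricSpectrum(default_grid, w)


class TestMoments:
    def test_delta_support(self):
        s = m.generate_delta(2.3)
        y_bin = s.representative_y[s.weights > 0][0]
        assert s.dose_mean_lineal_energy() == pytest.approx(y_bin)
        assert s.frequency_mean_lineal_energy() == pytest.approx(y_bin)
        # one-bin discretization: within a bin width of the request
        assert s.dose_mean_lineal_energy() == pytest.approx(2.3, rel=10 ** 0.02 - 1)

    @pytest.mark.parametrize("let", [1.0, 20.0, 100.0, 1000.0])
    def test_track_segment_closed_form_moments(self, let, default_grid):
        s = m.generate_track_segment(let, default_grid)
        assert s.frequency_mean_lineal_energy() == pytest.approx(let, rel=1e-3)
        assert s.dose_mean_lineal_energy() == pytest.approx(9 / 8 * let, rel=1e-3)

    def test_lognormal_closed_form_dose_mean(self):
        # frequency log-normal (mu, sigma) has dose mean exp(mu + 3 sigma^2 / 2)
        s = m.generate_lognormal(0.0, 1.0)
        assert s.dose_mean_lineal_energy() == pytest.approx(np.exp(1.5), rel=5e-3)
        s = m.generate_lognormal(np.log(2.3), 0.01)
        assert s.dose_mean_lineal_energy() == pytest.approx(2.3, rel=0.05)

    def test_two_point_frequency_mean(self, default_grid):
        # equal dose at y=1 and y=3: harmonic-type mean 1/(0.5 + 0.5/3) = 1.5
        w = np.zeros(default_grid.n_bins)
        w[default_grid.locate(1.0)] = 0.5
        w[default_grid.locate(3.0)] = 0.5
        s = m.MicrodosimetricSpectrum(default_grid, w)
        assert s.frequency_mean_lineal_energy() == pytest.approx(1.5, rel=0.03)

    def test_grid_refinement_convergence(self):
        # halving the bin width moves the dose mean by < 0.05%
        coarse = m.LinealEnergyGrid.default()
        fine = m.LinealEnergyGrid.log_uniform(bins_per_decade=100)
        for gen in (
            lambda g: m.generate_track_segment(37.0, g),
            lambda g: m.generate_lognormal(1.0, 0.8, g),
        ):
            yd_c = gen(coarse).dose_mean_lineal_energy()
            yd_f = gen(fine).dose_mean_lineal_energy()
            assert abs(yd_f / yd_c - 1) < 5e-4


class TestFrequencyConversion:
    def test_delta_maps_to_delta(self, default_grid):
        f = np.zeros(default_grid.n_bins)
        f[100] = 1.0
        s = m.from_frequency_distribution(f, default_grid)
        assert s.weights[100] == pytest.approx(1.0)

    def test_uniform_two_bin_frequency(self, default_grid):
        # equal event counts at y=1 and y=3 deliver dose in ratio 1:3
        f = np.zeros(default_grid.n_bins)
        i1, i3 = default_grid.locate(1.0), default_grid.locate(3.0)
        f[i1] = f[i3] = 0.5
        s = m.from_frequency_distribution(f, default_grid)
        ratio = s.weights[i3] / s.weights[i1]
        y = default_grid.representative
        assert ratio == pytest.approx(y[i3] / y[i1])
        assert s.weights[i1] + s.weights[i3] == pytest.approx(1.0)

    def test_all_zero_frequency_rejected(self, default_grid):
        with pytest.raises(DegenerateSpectrumError):
            m.from_frequency_distribution(np.zeros(default_grid.n_bins), default_grid)

    @given(
        st.lists(
            st.tuples(st.integers(0, 449), st.floats(1e-6, 1.0)),
            min_size=2,
            max_size=12,
            unique_by=lambda t: t[0],
        )
    )
    def test_dose_mean_dominates_frequency_mean(self, bins):
        # Cauchy-Schwarz: the dose weighting up-weights large y, so yD >= yF
        grid = m.LinealEnergyGrid.default()
        f = np.zeros(grid.n_bins)
        for idx, val in bins:
            f[idx] = val
        s = m.from_frequency_distribution(f, grid)
        assert s.dose_mean_lineal_energy() >= s.frequency_mean_lineal_energy() * (1 - 1e-12)


class TestGenerators:
    def test_delta_outside_span_rejected(self):
        with pytest.raises(GridRangeError):
            m.generate_delta(1e-3)

    @pytest.mark.parametrize("bad_let", [0.0, -5.0])
    def test_track_segment_nonpositive_let_rejected(self, bad_let):
        with pytest.raises(ValueError):
            m.generate_track_segment(bad_let)

    def test_track_segment_below_grid_floor_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            m.generate_track_segment(1e-9)

    @pytest.mark.parametrize("bad_sigma", [0.0, -1.0])
    def test_lognormal_nonpositive_sigma_rejected(self, bad_sigma):
        with pytest.raises(ValueError):
            m.generate_lognormal(0.0, bad_sigma)

    @pytest.mark.parametrize(
        "spectrum",
        [
            m.generate_delta(2.3),
            m.generate_track_segment(100.0),
            m.generate_lognormal(0.0, 1.0),
        ],
        ids=["delta", "track", "lognormal"],
    )
    def test_generators_emit_normalized_spectra(self, spectrum):
        assert spectrum.total == pytest.approx(1.0, abs=1e-10)


class TestFileIO:
    def test_round_trip_preserves_weights(self, tmp_path):
        s = m.generate_track_segment(100.0)
        path = tmp_path / "track.csv"
        m.write_spectrum(s, path)
        back = m.read_spectrum(path)
        np.testing.assert_allclose(back.weights, s.weights, rtol=1e-9, atol=1e-15)
        assert back.dose_mean_lineal_energy() == pytest.approx(
            s.dose_mean_lineal_energy(), rel=1e-9
        )

    def test_two_row_file_snaps_to_grid(self, tmp_path):
        path = tmp_path / "two.csv"
        path.write_text("y,w\n1,0.5\n3,0.5\n")
        s = m.read_spectrum(path)
        assert s.dose_mean_lineal_energy() == pytest.approx(2.0, rel=0.03)

    def test_delimiter_autodetection(self, tmp_path):
        for text in ("1,0.5\n3,0.5\n", "1\t0.5\n3\t0.5\n", "1 0.5\n3 0.5\n"):
            s = m.read_spectrum(io.StringIO(text))
            assert s.total == pytest.approx(1.0, abs=1e-10)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SpectrumParseError, match="no data rows"):
            m.read_spectrum(path)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("1,0.5\nfoo,bar\n", "line 2"),
            ("1,-0.5\n", "negative weight"),
            ("3,0.5\n1,0.5\n", "increasing"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, text, match):
        path = tmp_path / "bad.csv"
        path.write_text(text)
        with pytest.raises(SpectrumParseError, match=match):
            m.read_spectrum(path)

    def test_comments_and_header_tolerated(self):
        s = m.read_spectrum(io.StringIO("# comment\ny[keV/um],d\n2.3,1.0\n"))
        assert s.total == pytest.approx(1.0, abs=1e-10)
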