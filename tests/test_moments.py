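"""Spectrum moments: identities, hand arithmetic, ordering and stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from letfield import io, materials
from letfield.geometry import GeometryPoint
from letfield.moments import (
    FluenceSpectrum,
    LETResult,
    attach_uncertainty,
    compute_let,
    dose_average_let,
    track_average_let,
    track_end_terms,
)

from conftest import monoenergetic_spectrum, power_law_table


def random_spectrum(rng, delta_kev=1.0):
    n = rng.integers(2, 30)
    edges = np.sort(rng.uniform(1e-3, 6.0, size=n + 1))
    edges[0] = max(edges[0], 1e-3)
    if np.any(np.diff(edges) <= 0):
        edges = 1e-3 * np.cumprod(np.full(n + 1, 1.5))
    phi = rng.uniform(0, 1, size=n)
    if phi.max() == 0:
        phi[0] = 1.0
    return FluenceSpectrum(
        bin_edges_mev=edges,
        fluence_density=phi,
        delta_kev=delta_kev,
        track_end_fluence=float(rng.uniform(0, 1)),
    )


class TestIdentities:
    @pytest.mark.parametrize("e0", [0.005, 0.1, 2.0])
    def test_monoenergetic_returns_let_at_that_energy(self, table, e0):
        spec = monoenergetic_spectrum(e0)
        expected = table.restricted_at(e0)
        assert dose_average_let(spec, table) == pytest.approx(expected, rel=1e-12)
        assert track_average_let(spec, table) == pytest.approx(expected, rel=1e-12)

    def test_two_bin_hand_arithmetic(self):
        # equal-fluence, equal-width bins with L values exactly 1 and 3:
        # track average (1+3)/2 = 2, dose average (1+9)/(1+3) = 2.5
        edges = np.array([0.01, 0.02, 0.03])
        mids = np.sqrt(edges[:-1] * edges[1:])
        t = power_law_table(mids, [1.0, 3.0])
        spec = FluenceSpectrum(edges, np.array([1.0, 1.0]), track_end_fluence=0.0)
        assert track_average_let(spec, t) == pytest.approx(2.0, rel=1e-12)
        assert dose_average_let(spec, t) == pytest.approx(2.5, rel=1e-12)

    def test_oracle_equivalence_small_spectra(self, table):
        """≤5-bin spectra: moments equal the hand-expanded sums."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            edges = np.sort(rng.uniform(2e-3, 5.0, size=5))
            edges = np.concatenate([[1e-3], edges])
            phi = rng.uniform(0.1, 1.0, size=5)
            phi_d = float(rng.uniform(0, 1))
            spec = FluenceSpectrum(edges, phi, track_end_fluence=phi_d)
            mids = np.sqrt(edges[:-1] * edges[1:])
            widths = np.diff(edges)
            l = table.restricted_at(mids)
            s_d = table.unrestricted_at(1e-3)
            delta = 1e-3
            num_d = np.sum(l**2 * phi * widths) + s_d**2 * phi_d * delta
            den_d = np.sum(l * phi * widths) + s_d * phi_d * delta
            den_t = np.sum(phi * widths) + phi_d * delta
            assert dose_average_let(spec, table) == pytest.approx(num_d / den_d, rel=1e-12)
            assert track_average_let(spec, table) == pytest.approx(den_d / den_t, rel=1e-12)


class TestTrackEndTerms:
    def test_zero_when_no_cutoff_fluence(self, table):
        spec = monoenergetic_spectrum(0.1, track_end_fluence=0.0)
        te = track_end_terms(spec, table)
        assert te == (0.0, 0.0, 0.0)

    def test_definition(self, table):
        spec = monoenergetic_spectrum(0.1, track_end_fluence=1.0)
        te = track_end_terms(spec, table)
        s_delta = table.unrestricted_at(1e-3)
        assert te.l == pytest.approx(s_delta * 1.0 * 1e-3, rel=1e-12)
        assert te.l_sq == pytest.approx(s_delta**2 * 1e-3, rel=1e-12)
        assert te.plain == pytest.approx(1e-3, rel=1e-12)

    def test_linearity_in_cutoff_fluence(self, table):
        t1 = track_end_terms(monoenergetic_spectrum(0.1, track_end_fluence=1.0), table)
        t2 = track_end_terms(monoenergetic_spectrum(0.1, track_end_fluence=2.0), table)
        assert all(b == pytest.approx(2 * a, rel=1e-12) for a, b in zip(t1, t2))

    def test_missing_track_end_falls_back_to_first_bin(self, table, caplog):
        spec = FluenceSpectrum(np.array([1e-3, 2e-3]), np.array([3.0]))
        assert spec.phi_at_delta() == 3.0


class TestProperties:
    def test_dose_at_least_track_over_randomized_spectra(self, table):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            spec = random_spectrum(rng)
            assert dose_average_let(spec, table) >= track_average_let(spec, table) * (1 - 1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(factor=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_scale_invariance(self, table, factor):
        rng = np.random.default_rng(3)
        spec = random_spectrum(rng)
        base_d = dose_average_let(spec, table)
        base_t = track_average_let(spec, table)
        scaled = spec.scaled(factor)
        assert dose_average_let(scaled, table) == pytest.approx(base_d, rel=1e-12)
        assert track_average_let(scaled, table) == pytest.approx(base_t, rel=1e-12)

    def test_refinement_stability(self, table):
        """Halving bin widths of a smooth spectrum moves moments < 0.2%."""
        def smooth(n):
            edges = np.logspace(-3, np.log10(6.0), n + 1)
            mids = np.sqrt(edges[:-1] * edges[1:])
            phi = mids * np.exp(-mids / 0.5)
            return FluenceSpectrum(edges, phi, track_end_fluence=float(phi[0]))

        coarse, fine = smooth(100), smooth(200)
        for f in (dose_average_let, track_average_let):
            assert abs(f(fine, table) - f(coarse, table)) / f(fine, table) < 2e-3

    def test_energy_weighting_option_changes_moments(self, table):
        rng = np.random.default_rng(11)
        spec = random_spectrum(rng)
        assert dose_average_let(spec, table, weighting="energy") != pytest.approx(
            dose_average_let(spec, table), rel=1e-6
        )


class TestValidationAndErrors:
    def test_all_zero_fluence_rejected(self):
        with pytest.raises(ValueError):
            FluenceSpectrum(np.array([1e-3, 1.0]), np.array([-1.0]))

    def test_zero_fluence_moment_error(self, table):
        spec = FluenceSpectrum(
            np.array([1e-3, 1.0]), np.array([0.0]), track_end_fluence=0.0
        )
        with pytest.raises(ValueError, match="undefined moment"):
            dose_average_let(spec, table)

    def test_cutoff_mismatch_rejected(self, table):
        spec = monoenergetic_spectrum(0.1, delta_kev=2.0)
        with pytest.raises(ValueError, match="mismatch"):
            dose_average_let(spec, table)

    def test_spectrum_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FluenceSpectrum(np.array([1e-4, 1.0]), np.array([1.0]), delta_kev=1.0)

    def test_result_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            LETResult(track_average_kev_um=3.0, dose_average_kev_um=1.0, delta_kev=1.0)


class TestUncertainty:
    def test_attach_and_absolute_values(self, table):
        spec = monoenergetic_spectrum(0.1)
        res = compute_let(spec, table)
        assert res.relative_standard_uncertainty == 0.006
        res2 = attach_uncertainty(res, 0.006)
        track_u, dose_u = res2.absolute_uncertainties
        assert dose_u == pytest.approx(0.006 * res.dose_average_kev_um)
        zero = attach_uncertainty(res, 0.0)
        assert zero.absolute_uncertainties == (0.0, 0.0)
        with pytest.raises(ValueError):
            attach_uncertainty(res, 1.5)


def test_spectrum_tsv_round_trip(tmp_path, table):
    geom = GeometryPoint(2.7, 1.35, 3.35)
    edges = np.logspace(-3, 0.5, 40)
    rng = np.random.default_rng(5)
    spec = FluenceSpectrum(
        edges, rng.uniform(0, 1, 39), kind="SE", geometry=geom, track_end_fluence=0.7
    )
    path = tmp_path / "spec.tsv"
    io.write_spectrum_tsv(spec, path)
    back = io.read_spectrum_tsv(path)
    assert back.kind == "SE"
    assert back.geometry == geom
    assert back.track_end_fluence == pytest.approx(0.7)
    assert np.allclose(back.fluence_density, spec.fluence_density)
    assert dose_average_let(back, table) == pytest.approx(dose_average_let(spec, table))
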