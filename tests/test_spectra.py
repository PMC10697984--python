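"""Synthetic spectrum generator: kinematics, slowing-down, closure, orderings."""

import numpy as np
import pytest

from letfield import io, moments as mo, spectra as sp
from letfield.geometry import GeometryPoint


def narrow_photon_spectrum(k_mev, r=1.0001):
    return sp.PhotonSpectrum(
        np.array([k_mev / r, k_mev * r]), np.array([1.0 / (k_mev * (r - 1 / r))])
    )


def monoenergetic_source(table, e0=2.0):
    grid = table.energy_grid_mev
    i = np.searchsorted(grid, e0)
    q = np.zeros(len(grid) - 1)
    q[i] = 1.0 / (grid[i + 1] - grid[i])
    return sp.ElectronSourceDensity(grid, q), np.sqrt(grid[i] * grid[i + 1])


class TestPhotonSpectrum:
    def test_deterministic(self, beam):
        g = GeometryPoint(2.7, 1.35, 3.35)
        a = sp.generate_photon_spectrum(g, beam)
        b = sp.generate_photon_spectrum(g, beam)
        assert np.array_equal(a.fluence_density, b.fluence_density)

    def test_hardens_with_depth_on_axis(self, beam):
        shallow = sp.generate_photon_spectrum(GeometryPoint(2.7, 0.15, 0.0), beam)
        deep = sp.generate_photon_spectrum(GeometryPoint(2.7, 9.85, 0.0), beam)
        assert deep.mean_energy_mev() > shallow.mean_energy_mev()

    def test_softens_beyond_field_edge(self, beam):
        centre = sp.generate_photon_spectrum(GeometryPoint(2.7, 1.35, 0.0), beam)
        out = sp.generate_photon_spectrum(GeometryPoint(2.7, 1.35, 3.35), beam)
        assert out.mean_energy_mev() < centre.mean_energy_mev()

    def test_unit_fluence_normalisation(self, beam):
        s = sp.generate_photon_spectrum(GeometryPoint(10.0, 9.85, 7.0), beam)
        assert (s.fluence_density * s.bin_widths_mev).sum() == pytest.approx(1.0)


class TestComptonSource:
    def test_vanishes_above_compton_edge(self, table):
        k = 1.25
        t_max = sp.compton_edge_mev(k)
        assert t_max == pytest.approx(2 * k**2 / (0.51099895 + 2 * k), rel=1e-12)
        src = sp.compton_electron_source(narrow_photon_spectrum(k), table.energy_grid_mev)
        mids = src.midpoints_mev
        assert np.all(src.source_density[mids > t_max * 1.001] == 0)
        assert np.any(src.source_density[mids < t_max] > 0)

    def test_linear_in_photon_fluence(self, table, beam):
        ph = sp.generate_photon_spectrum(GeometryPoint(2.7, 1.35, 0.0), beam)
        doubled = sp.PhotonSpectrum(ph.bin_edges_mev, 2 * ph.fluence_density)
        a = sp.compton_electron_source(ph, table.energy_grid_mev)
        b = sp.compton_electron_source(doubled, table.energy_grid_mev)
        assert np.allclose(b.source_density, 2 * a.source_density)

    def test_nonnegative_for_default_beam(self, table, beam):
        ph = sp.generate_photon_spectrum(GeometryPoint(2.7, 1.35, 0.0), beam)
        src = sp.compton_electron_source(ph, table.energy_grid_mev)
        assert np.all(src.source_density >= 0)


class TestSlowingDown:
    def test_csda_closed_form_for_monoenergetic_primaries(self, table):
        """Primaries only: Φ(E) = N/S(E) below the source energy."""
        src, e0 = monoenergetic_source(table)
        spec = sp.slowing_down_spectrum(src, table, include_secondaries=False)
        mids = src.midpoints_mev
        below = mids < 0.9 * e0
        n_total = (src.source_density * src.bin_widths_mev).sum()
        expected = n_total / table.unrestricted_at(mids[below])
        assert np.allclose(spec.fluence_density[below], expected, rtol=1e-9)

    def test_secondaries_only_add_fluence(self, table):
        src, e0 = monoenergetic_source(table)
        prim = sp.slowing_down_spectrum(src, table, include_secondaries=False)
        full = sp.slowing_down_spectrum(src, table, include_secondaries=True)
        sel = src.midpoints_mev <= e0 / 2
        assert np.all(full.fluence_density[sel] >= prim.fluence_density[sel] * (1 - 1e-12))

    def test_nonconvergence_raises(self, table):
        src, _ = monoenergetic_source(table)
        with pytest.raises(RuntimeError, match="converge"):
            sp.slowing_down_spectrum(src, table, max_sweeps=1, tol=1e-12)

    @pytest.mark.parametrize("include_secondaries", [False, True])
    def test_energy_closure_within_2_percent(self, table, beam, include_secondaries):
        """Slowing-down closure: dissipated energy (∫ΦS dE + track end)
        equals the energy injected by all source terms."""
        ph = sp.generate_photon_spectrum(GeometryPoint(2.7, 1.35, 0.0), beam)
        src = sp.compton_electron_source(ph, table.energy_grid_mev)
        deposited, injected = sp.energy_closure(src, table, include_secondaries)
        assert deposited == pytest.approx(injected, rel=0.02)


class TestSecondaryOnly:
    def test_zero_source_gives_zero_spectrum(self, table):
        grid = table.energy_grid_mev
        src = sp.ElectronSourceDensity(grid, np.zeros(len(grid) - 1))
        spec = sp.secondary_only_spectrum(src, table)
        assert np.all(spec.fluence_density == 0)
        with pytest.raises(ValueError, match="undefined moment"):
            mo.dose_average_let(spec, table)

    def test_se_softer_than_tef(self, table, beam, geom_in_field):
        tef, se = sp.generate_case(geom_in_field, beam, table)
        assert se.mean_energy_mev() < tef.mean_energy_mev()

    def test_se_dose_average_exceeds_tef(self, table, beam, geom_in_field, geom_edge_plus_2):
        for g in (geom_in_field, geom_edge_plus_2):
            tef, se = sp.generate_case(g, beam, table)
            assert mo.dose_average_let(se, table) > mo.dose_average_let(tef, table)


class TestGenerateCase:
    def test_bitwise_identical_output(self, table, beam, geom_in_field, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for p in (p1, p2):
            tef, _ = sp.generate_case(geom_in_field, beam, table)
            io.write_spectrum_tsv(tef, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_out_of_field_let_not_below_in_field(self, table, beam):
        for depth in (1.35, 9.85, 19.9):
            centre = GeometryPoint(2.7, depth, 0.0)
            out = GeometryPoint(2.7, depth, 3.35)
            ld = {}
            for name, g in (("centre", centre), ("out", out)):
                tef, _ = sp.generate_case(g, beam, table)
                ld[name] = mo.dose_average_let(tef, table)
            assert ld["out"] >= ld["centre"]

    def test_monotone_softening_sweep(self, table):
        """More scatter ⇒ softer photons ⇒ higher TEF dose-average LET."""
        g = GeometryPoint(2.7, 1.35, 0.0)
        means, lets = [], []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            beam = sp.PhotonBeamModel(scatter_fraction_in_field=w)
            ph = sp.generate_photon_spectrum(g, beam)
            tef, _ = sp.generate_case(g, beam, table)
            means.append(ph.mean_energy_mev())
            lets.append(mo.dose_average_let(tef, table))
        assert np.all(np.diff(means) <= 0)
        assert np.all(np.diff(lets) >= 0)

    def test_noise_injection_is_seeded(self, table, geom_in_field):
        b1 = sp.PhotonBeamModel(seed=1)
        a, _ = sp.generate_case(geom_in_field, b1, table, noise_rel=0.1)
        b, _ = sp.generate_case(geom_in_field, b1, table, noise_rel=0.1)
        c, _ = sp.generate_case(geom_in_field, sp.PhotonBeamModel(seed=2), table, noise_rel=0.1)
        assert np.array_equal(a.fluence_density, b.fluence_density)
        assert not np.array_equal(a.fluence_density, c.fluence_density)

    def test_contaminant_only_near_surface(self, table):
        beam_c = sp.PhotonBeamModel(contaminant_fraction=0.2)
        beam_0 = sp.PhotonBeamModel()
        shallow = GeometryPoint(2.7, 0.15, 0.0)
        deep = GeometryPoint(2.7, 9.85, 0.0)
        t_c, _ = sp.generate_case(shallow, beam_c, table)
        t_0, _ = sp.generate_case(shallow, beam_0, table)
        assert not np.allclose(t_c.fluence_density, t_0.fluence_density)
        d_c, _ = sp.generate_case(deep, beam_c, table)
        d_0, _ = sp.generate_case(deep, beam_0, table)
        assert np.allclose(d_c.fluence_density, d_0.fluence_density)
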