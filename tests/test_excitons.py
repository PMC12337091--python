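import numpy as np
import pytest

from forsternet.core import Band, PigmentClass
from forsternet.coupling import CouplingMatrix, coupling_matrix, dipoles_for_band
from forsternet.excitons import (
    ALL_CHL_A,
    NO_CRT,
    WT,
    PigmentConfiguration,
    SiteEnergyTable,
    SiteShiftWarning,
    apply_configuration,
    build_hamiltonian,
    build_site_energy_table,
    diagonalize,
    ipr_inverse,
    ipr_summary,
    site_energy,
)
from forsternet.units import CM1_PER_EV


def simple_hamiltonian(energies, coupling_value=0.0):
    n = len(energies)
    ids = [f"s{i}" for i in range(n)]
    m = np.full((n, n), float(coupling_value))
    np.fill_diagonal(m, 0.0)
    cm = CouplingMatrix(Band.Q, ids, m)
    table = SiteEnergyTable(Band.Q, ids, np.asarray(energies, dtype=float))
    return build_hamiltonian(table, cm)


class TestSiteEnergy:
    def test_wavelength_arithmetic(self, library):
        e = site_energy(PigmentClass.CHL_A, Band.Q, library, shift_cm1=0.0)
        assert e == pytest.approx(1e7 / 662.0, rel=1e-9)  # ~15106 cm-1

    def test_crt_relaxed_state_is_bright_minus_point_eight_ev(self, library):
        e_b = site_energy(PigmentClass.CRT, Band.B, library)
        e_q = site_energy(PigmentClass.CRT, Band.Q, library, crt_rule=True)
        assert e_b - e_q == pytest.approx(0.8 * CM1_PER_EV, rel=1e-9)  # ~6452 cm-1

    def test_shift_in_ev_units(self, library):
        base = site_energy(PigmentClass.CHL_A, Band.Q, library)
        shifted = site_energy(PigmentClass.CHL_A, Band.Q, library, shift_cm1=0.05 * CM1_PER_EV)
        assert shifted - base == pytest.approx(403.3, abs=0.1)

    def test_large_shift_warns_not_raises(self, library):
        with pytest.warns(SiteShiftWarning):
            site_energy(PigmentClass.CHL_A, Band.Q, library, shift_cm1=0.15 * CM1_PER_EV)

    def test_b_shift_falls_back_to_q_shift(self, study_complex, library):
        pigments, _ = study_complex
        chl = next(p for p in pigments if p.pigment_class.is_chlorophyll)
        shifts = {(chl.site_id, Band.Q): 200.0}
        table_b = build_site_energy_table([chl], Band.B, library, shifts)
        base = site_energy(chl.pigment_class, Band.B, library, 0.0)
        assert table_b.energies_cm1[0] == pytest.approx(base + 200.0)


class TestHamiltonian:
    def test_two_site_layout(self):
        h = simple_hamiltonian([100.0, 100.0], coupling_value=5.0)
        np.testing.assert_allclose(h.matrix, [[100.0, 5.0], [5.0, 100.0]])

    def test_zero_coupling_is_diagonal(self):
        h = simple_hamiltonian([100.0, 200.0, 300.0])
        np.testing.assert_allclose(h.matrix, np.diag([100.0, 200.0, 300.0]))

    def test_order_mismatch_rejected(self):
        cm = CouplingMatrix(Band.Q, ["a", "b"], np.zeros((2, 2)))
        table = SiteEnergyTable(Band.Q, ["b", "a"], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            build_hamiltonian(table, cm)

    def test_permutation_consistency(self):
        energies = [100.0, 200.0, 300.0]
        ids = ["s0", "s1", "s2"]
        rng = np.random.default_rng(5)
        v = np.zeros((3, 3))
        iu = np.triu_indices(3, 1)
        v[iu] = rng.uniform(1, 10, 3)
        v += v.T
        h = build_hamiltonian(
            SiteEnergyTable(Band.Q, ids, np.array(energies)), CouplingMatrix(Band.Q, ids, v)
        )
        perm = [2, 0, 1]
        h_p = build_hamiltonian(
            SiteEnergyTable(Band.Q, [ids[k] for k in perm], np.array(energies)[perm]),
            CouplingMatrix(Band.Q, [ids[k] for k in perm], v[np.ix_(perm, perm)]),
        )
        np.testing.assert_allclose(h_p.matrix, h.matrix[np.ix_(perm, perm)])


class TestDiagonalize:
    def test_textbook_dimer(self):
        h = simple_hamiltonian([1000.0, 1000.0], coupling_value=50.0)
        res = diagonalize(h)
        np.testing.assert_allclose(res.eigenvalues_cm1, [950.0, 1050.0])
        np.testing.assert_allclose(res.weights, 0.5, atol=1e-12)
        np.testing.assert_allclose(res.ipr_inverse, 2.0, atol=1e-9)

    def test_decoupled_limit_localized(self):
        h = simple_hamiltonian([300.0, 100.0, 200.0])
        res = diagonalize(h)
        np.testing.assert_allclose(res.eigenvalues_cm1, [100.0, 200.0, 300.0])
        np.testing.assert_allclose(res.ipr_inverse, 1.0, atol=1e-12)

    def test_trace_conservation(self):
        rng = np.random.default_rng(11)
        energies = rng.uniform(14000, 16000, 9)
        h = simple_hamiltonian(energies, coupling_value=35.0)
        res = diagonalize(h)
        assert res.eigenvalues_cm1.sum() == pytest.approx(energies.sum(), rel=1e-12)

    def test_weight_matrix_doubly_stochastic(self):
        rng = np.random.default_rng(13)
        h = simple_hamiltonian(rng.uniform(14000, 16000, 8), coupling_value=60.0)
        res = diagonalize(h)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.weights.sum(axis=0), 1.0, atol=1e-9)

    def test_sign_convention_deterministic(self):
        h = simple_hamiltonian([1000.0, 1000.0, 1000.0], coupling_value=-30.0)
        r1 = diagonalize(h)
        r2 = diagonalize(h)
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_uniform_ring_matches_circulant_closed_form(self):
        """Degenerate ring with equal nearest-neighbour coupling: exciton
        energies are eps + 2V cos(2 pi k / N), the circulant spectrum."""
        n, eps, v = 8, 15000.0, 40.0
        ids = [f"s{i}" for i in range(n)]
        m = np.zeros((n, n))
        for i in range(n):
            m[i, (i + 1) % n] = m[(i + 1) % n, i] = v
        res = diagonalize(
            build_hamiltonian(
                SiteEnergyTable(Band.Q, ids, np.full(n, eps)), CouplingMatrix(Band.Q, ids, m)
            )
        )
        expected = np.sort(eps + 2 * v * np.cos(2 * np.pi * np.arange(n) / n))
        np.testing.assert_allclose(res.eigenvalues_cm1, expected, atol=1e-8)
        # delocalization spans the ring: every exciton well above localized
        assert res.ipr_inverse.min() > 1.5
        assert res.ipr_inverse.max() == pytest.approx(n, abs=1e-6)

    def test_nonfinite_rejected(self):
        from forsternet.excitons import ExcitonHamiltonian

        with pytest.raises(ValueError):
            ExcitonHamiltonian(Band.Q, ["a"], np.array([[np.nan]]))


class TestIprInverse:
    def test_localized_lower_bound(self):
        assert ipr_inverse(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_uniform_upper_bound(self):
        n = 11
        assert ipr_inverse(np.full(n, 1 / n)) == pytest.approx(n)

    def test_dimer_value(self):
        assert ipr_inverse(np.array([0.5, 0.5, 0.0])) == pytest.approx(2.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            ipr_inverse(np.array([0.7, 0.7]))


class TestConfigurations:
    def test_removal_count(self, study_complex):
        pigments, _ = study_complex
        out = apply_configuration(pigments, NO_CRT)
        assert len(out) == len(pigments) - 3
        assert all(p.pigment_class is not PigmentClass.CRT for p in out)

    def test_substitution_keeps_geometry(self, study_complex):
        pigments, _ = study_complex
        out = apply_configuration(pigments, ALL_CHL_A)
        assert all(p.pigment_class is not PigmentClass.CHL_B for p in out)
        for orig, new in zip(pigments, out):
            np.testing.assert_array_equal(orig.center, new.center)
            assert orig.site_id == new.site_id

    def test_self_substitution_rejected(self):
        with pytest.raises(ValueError):
            PigmentConfiguration(
                "bad", substitutions=((PigmentClass.CHL_A, PigmentClass.CHL_A),)
            )

    def test_removing_everything_rejected(self, cp24_complex):
        pigments, _ = cp24_complex
        wipe = PigmentConfiguration("wipe", removals=(PigmentClass.CHL_A, PigmentClass.CRT))
        with pytest.raises(ValueError):
            apply_configuration(pigments, wipe)

    def _mean_ipr(self, pigments, table, library, shifts, band):
        dipoles = dipoles_for_band(pigments, table, library, band)
        cm = coupling_matrix([p.site_id for p in pigments], dipoles, band)
        energies = build_site_energy_table(pigments, band, library, shifts)
        return diagonalize(build_hamiltonian(energies, cm)).ipr_inverse.mean()

    def test_homogeneous_network_more_delocalized_in_b(self, study_complex, library, shifts):
        """Replacing accessory chlorophylls by chlorophyll a homogenizes the
        B-band site energies and raises the mean delocalization."""
        pigments, table = study_complex
        wt = self._mean_ipr(pigments, table, library, shifts, Band.B)
        pure = self._mean_ipr(
            apply_configuration(pigments, ALL_CHL_A), table, library, shifts, Band.B
        )
        assert pure > wt

    def test_mean_ipr_invariant_under_relabeling(self, study_complex, library, shifts):
        pigments, table = study_complex
        base = self._mean_ipr(pigments, table, library, shifts, Band.Q)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(len(pigments)))
        shuffled = [pigments[k] for k in perm]
        again = self._mean_ipr(shuffled, table, library, shifts, Band.Q)
        assert again == pytest.approx(base, rel=1e-12)

    def test_energy_sink_ordering_in_wt(self, study_complex, library, shifts):
        """Lowest B-band excitons live mainly on Crt/accessory-Chl sites
        (red-shifted B bands), highest Q-band excitons on accessory sites."""
        pigments, table = study_complex
        dipoles = dipoles_for_band(pigments, table, library, Band.B)
        cm = coupling_matrix([p.site_id for p in pigments], dipoles, Band.B)
        energies = build_site_energy_table(pigments, Band.B, library, shifts)
        res = diagonalize(build_hamiltonian(energies, cm))
        classes = {p.site_id: p.pigment_class for p in pigments}
        lowest_sites = res.dominant_sites(0)
        assert lowest_sites, "lowest exciton has no dominant site"
        assert all(classes[s] is not PigmentClass.CHL_A for s in lowest_sites)

    def test_ipr_summary_shape(self, study_complex, library, shifts):
        pigments, table = study_complex
        results = {}
        for config in (WT, NO_CRT):
            pigs = apply_configuration(pigments, config)
            dipoles = dipoles_for_band(pigs, table, library, Band.B)
            cm = coupling_matrix([p.site_id for p in pigs], dipoles, Band.B)
            energies = build_site_energy_table(pigs, Band.B, library, shifts)
            results[(config.label, Band.B)] = diagonalize(build_hamiltonian(energies, cm))
        df = ipr_summary(results)
        assert set(df["configuration"]) == {"WT", "NO_CRT"}
        assert (df["mean_ipr_inverse"] >= 1).all()
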