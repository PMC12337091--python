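import numpy as np
import pytest
import scipy.constants as const
from hypothesis import given, settings
from hypothesis import strategies as st

from forsternet.core import Band, PigmentClass
from forsternet.coupling import (
    CouplingMatrix,
    Medium,
    TransitionDipole,
    class_pair_averages,
    coupling_matrix,
    dipoles_for_band,
    orientation_factor,
    point_dipole_coupling,
)
from forsternet.synthetic_data import LHC_MIMIC, make_toy_spectral_library
from forsternet.units import C_DIP_CM1_NM3_PER_D2


def dipole(site, direction, origin, mu=1.0, band=Band.Q):
    d = np.asarray(direction, dtype=float)
    return TransitionDipole(site, band, d / np.linalg.norm(d), mu, np.asarray(origin, dtype=float))


def first_principles_coupling_cm1(kappa, mu_i_debye, mu_j_debye, n, r_nm):
    """Independent SI oracle: kappa mu_i mu_j / (4 pi eps0 n^2 r^3) / hc."""
    debye = 1e-21 / const.c
    energy_j = (
        kappa
        * (mu_i_debye * debye)
        * (mu_j_debye * debye)
        / (4 * np.pi * const.epsilon_0 * n**2 * (r_nm * 1e-9) ** 3)
    )
    return energy_j / (const.h * const.c * 100.0)


unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).filter(lambda v: 0.1 < np.linalg.norm(v) < 1.5).map(
    lambda v: np.asarray(v) / np.linalg.norm(v)
)


class TestOrientationFactor:
    def test_collinear_head_to_tail(self):
        z = np.array([0.0, 0.0, 1.0])
        assert orientation_factor(z, z, z * 5) == pytest.approx(-2.0)

    def test_parallel_perpendicular_to_r(self):
        x = np.array([1.0, 0.0, 0.0])
        z = np.array([0.0, 0.0, 1.0])
        assert orientation_factor(x, x, z * 3) == pytest.approx(1.0)

    def test_orthogonal(self):
        x = np.array([1.0, 0.0, 0.0])
        y = np.array([0.0, 1.0, 0.0])
        z = np.array([0.0, 0.0, 1.0])
        assert orientation_factor(x, y, z) == pytest.approx(0.0)

    def test_zero_separation_rejected(self):
        z = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            orientation_factor(z, z, np.zeros(3))

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(u=unit_vectors, v=unit_vectors, r=unit_vectors)
    def test_bounded(self, u, v, r):
        assert -2.0 - 1e-9 <= orientation_factor(u, v, r * 7.3) <= 2.0 + 1e-9


class TestPointDipoleCoupling:
    def test_kernel_constant_against_first_principles(self):
        """kappa=1, mu=1 D each, n=1, R=1 nm isolates C_dip ~ 5.034."""
        z = [0.0, 0.0, 1.0]
        x = [1.0, 0.0, 0.0]
        d_i = dipole("a", x, [0, 0, 0])
        d_j = dipole("b", x, [0, 0, 10.0])  # 1 nm along z, kappa = 1
        v = point_dipole_coupling(d_i, d_j, Medium(1.0))
        assert v == pytest.approx(C_DIP_CM1_NM3_PER_D2, rel=1e-12)
        assert v == pytest.approx(first_principles_coupling_cm1(1, 1, 1, 1, 1.0), rel=1e-10)
        assert v == pytest.approx(5.034, abs=5e-3)

    def test_chlorophyll_scale_coupling(self):
        """6.45 D dipoles at 1.5 nm in n=1.4 land in the literature Q-coupling range."""
        x = [1.0, 0.0, 0.0]
        d_i = dipole("a", x, [0, 0, 0], mu=6.45)
        d_j = dipole("b", x, [0, 0, 15.0], mu=6.45)
        v = point_dipole_coupling(d_i, d_j, Medium(1.4))
        assert v == pytest.approx(31.7, abs=0.2)
        assert 20.0 <= v <= 38.0

    def test_inverse_cube_law(self):
        x = [1.0, 0.0, 0.0]
        v1 = point_dipole_coupling(dipole("a", x, [0, 0, 0]), dipole("b", x, [0, 0, 10.0]))
        v2 = point_dipole_coupling(dipole("a", x, [0, 0, 0]), dipole("b", x, [0, 0, 20.0]))
        assert v1 == pytest.approx(8 * v2, rel=1e-12)

    def test_joint_sign_flip_leaves_v(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=3)
        w = rng.normal(size=3)
        d_i = dipole("a", u, [0, 0, 0])
        d_j = dipole("b", w, [3.0, 4.0, 5.0])
        d_i_f = dipole("a", -u, [0, 0, 0])
        d_j_f = dipole("b", -w, [3.0, 4.0, 5.0])
        assert point_dipole_coupling(d_i, d_j) == pytest.approx(
            point_dipole_coupling(d_i_f, d_j_f), rel=1e-12
        )

    def test_band_mismatch_rejected(self):
        d_i = dipole("a", [1, 0, 0], [0, 0, 0], band=Band.Q)
        d_j = dipole("b", [1, 0, 0], [0, 0, 10.0], band=Band.B)
        with pytest.raises(ValueError):
            point_dipole_coupling(d_i, d_j)

    def test_coincident_origins_rejected(self):
        d_i = dipole("a", [1, 0, 0], [1.0, 1.0, 1.0])
        d_j = dipole("b", [0, 1, 0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            point_dipole_coupling(d_i, d_j)


class TestCouplingMatrix:
    def random_dipoles(self, n, seed=3):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n):
            out[f"s{i}"] = dipole(f"s{i}", rng.normal(size=3), rng.uniform(0, 40, 3), mu=5.0)
        return out

    def test_two_site_mirrored(self):
        d = self.random_dipoles(2)
        m = coupling_matrix(["s0", "s1"], d, Band.Q)
        assert m.matrix[0, 1] == m.matrix[1, 0] != 0

    def test_matches_per_pair_oracle(self):
        d = self.random_dipoles(6)
        ids = sorted(d)
        m = coupling_matrix(ids, d, Band.Q)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else point_dipole_coupling(d[ids[i]], d[ids[j]])
                assert m.matrix[i, j] == pytest.approx(expected, rel=1e-14, abs=1e-16)

    def test_permutation_equivariance(self):
        d = self.random_dipoles(5)
        ids = sorted(d)
        m = coupling_matrix(ids, d, Band.Q)
        perm = [3, 1, 4, 0, 2]
        m_p = coupling_matrix([ids[k] for k in perm], d, Band.Q)
        np.testing.assert_allclose(m_p.matrix, m.matrix[np.ix_(perm, perm)], rtol=1e-14)

    def test_missing_dipole_names_site(self):
        d = self.random_dipoles(2)
        with pytest.raises(KeyError, match="s9"):
            coupling_matrix(["s0", "s9"], d, Band.Q)

    def test_symmetry_machine_precision(self, study_complex, library):
        pigments, table = study_complex
        d = dipoles_for_band(pigments, table, library, Band.B)
        m = coupling_matrix([p.site_id for p in pigments], d, Band.B)
        np.testing.assert_array_equal(m.matrix, m.matrix.T)


class TestClassPairAverages:
    def test_single_pair(self):
        m = CouplingMatrix(Band.Q, ["a", "b"], np.array([[0.0, 10.0], [10.0, 0.0]]))
        classes = {"a": PigmentClass.CHL_A, "b": PigmentClass.CRT}
        df = class_pair_averages(m, classes, multimer_order=1)
        row = df[(df.class_i == "crt") & (df.class_j == "chl_a")].iloc[0]
        assert row["mean_V_cm-1"] == pytest.approx(10.0)
        assert row["n_pairs"] == 1

    @pytest.mark.parametrize("q,n", [(2, 2), (3, 4), (4, 3), (3, 11)])
    def test_multimer_scaling_identity(self, q, n):
        """q mutually silent monomer copies, each with n same-class sites:
        scaled average = monomer average * q(n-1)/(qn-1), exactly."""
        rng = np.random.default_rng(42)
        v_mono = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v_mono[iu] = rng.uniform(1.0, 20.0, iu[0].size)
        v_mono += v_mono.T
        total = q * n
        big = np.zeros((total, total))
        for c in range(q):
            s = slice(c * n, (c + 1) * n)
            big[s, s] = v_mono
        ids = [f"s{i}" for i in range(total)]
        m = CouplingMatrix(Band.Q, ids, big)
        classes = {i: PigmentClass.CHL_A for i in ids}
        df = class_pair_averages(m, classes, multimer_order=q)
        mono_avg = v_mono[iu].mean()
        expected = mono_avg * q * (n - 1) / (q * n - 1)
        assert df.iloc[0]["mean_V_cm-1"] == pytest.approx(expected, rel=1e-12)

    def test_absolute_dominates_signed(self):
        rng = np.random.default_rng(0)
        n = 8
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.normal(0, 5, iu[0].size)
        v += v.T
        ids = [f"s{i}" for i in range(n)]
        m = CouplingMatrix(Band.Q, ids, v)
        classes = {i: PigmentClass.CHL_A for i in ids}
        mean_abs = class_pair_averages(m, classes, mode="absolute").iloc[0]["mean_V_cm-1"]
        mean_signed = class_pair_averages(m, classes, mode="signed").iloc[0]["mean_V_cm-1"]
        assert mean_abs >= abs(mean_signed)

    def test_b_band_quadruples_q_on_identical_geometry(self, study_complex):
        """With B dipoles exactly twice the Q dipoles and the *same* axes,
        every coupling and hence every class-pair average scales by 4."""
        pigments, table = study_complex
        library = make_toy_spectral_library(LHC_MIMIC)
        d_q = dipoles_for_band(pigments, table, library, Band.Q)
        ids = [p.site_id for p in pigments]
        classes = {p.site_id: p.pigment_class for p in pigments}
        # identical geometry: reuse Q directions, double chlorophyll magnitudes
        d_b = {
            sid: TransitionDipole(sid, Band.Q, d.direction, 2.0 * d.magnitude_debye,
                                  d.origin_angstrom)
            for sid, d in d_q.items()
        }
        avg_q = class_pair_averages(coupling_matrix(ids, d_q, Band.Q), classes)
        avg_b = class_pair_averages(coupling_matrix(ids, d_b, Band.Q), classes)
        merged = avg_q.merge(avg_b, on=["class_i", "class_j"], suffixes=("_q", "_b"))
        ratios = merged["mean_V_cm-1_b"] / merged["mean_V_cm-1_q"]
        np.testing.assert_allclose(ratios, 4.0, rtol=1e-12)
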