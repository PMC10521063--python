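import numpy as np
import pytest
from _oracles import quadrature_coulomb, quadrature_overlap, random_density_model

from mqsar.density import DensityModel, GaussianShell, build_density
from mqsar.similarity import (
    carbo_index,
    coulomb_similarity,
    euclidean_distance,
    generalized_distance,
    infinite_order_distance,
    overlap_similarity,
    similarity_matrix,
)
from mqsar.structures import Atom, Molecule


def unit_shell(center, alpha=1.0, n=1.0):
    return DensityModel([GaussianShell(center, alpha, n)])


class TestOverlap:
    def test_two_unit_shells_coincident(self):
        a, b = unit_shell([0, 0, 0]), unit_shell([0, 0, 0])
        # closed form (1/(2 pi))^(3/2), cross-checked by quadrature
        assert overlap_similarity(a, b) == pytest.approx((2 * np.pi) ** -1.5, rel=1e-12)
        assert overlap_similarity(a, b) == pytest.approx(0.0634936, rel=1e-5)

    def test_distant_shells_vanish(self):
        a, b = unit_shell([0, 0, 0]), unit_shell([50.0, 0, 0])
        assert overlap_similarity(a, b) < 1e-100

    def test_symmetry_on_random_models(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = random_density_model(rng), random_density_model(rng)
            assert overlap_similarity(a, b) == pytest.approx(overlap_similarity(b, a), rel=1e-12)


class TestCoulomb:
    def test_coincident_unit_shells_closed_form(self):
        a, b = unit_shell([0, 0, 0]), unit_shell([0, 0, 0])
        assert coulomb_similarity(a, b) == pytest.approx(2 * np.sqrt(0.5 / np.pi), rel=1e-12)
        assert coulomb_similarity(a, b) == pytest.approx(0.797885, rel=1e-5)

    def test_point_charge_limit_at_10_angstrom(self):
        a, b = unit_shell([0, 0, 0]), unit_shell([10.0, 0, 0])
        assert coulomb_similarity(a, b) == pytest.approx(0.1, rel=1e-9)

    def test_bilinearity_in_electron_count(self):
        a = unit_shell([0, 0, 0], alpha=1.2, n=2.0)
        b1 = unit_shell([1.0, 0, 0], alpha=0.8, n=1.0)
        b2 = unit_shell([1.0, 0, 0], alpha=0.8, n=2.0)
        assert coulomb_similarity(a, b2) == pytest.approx(2 * coulomb_similarity(a, b1), rel=1e-12)


class TestQuadratureAgreement:
    """Analytic shell-pair sums vs an independent grid-quadrature oracle."""

    def test_overlap_and_coulomb_match_quadrature(self):
        rng = np.random.default_rng(42)
        for _ in range(4):
            a, b = random_density_model(rng), random_density_model(rng)
            zo = overlap_similarity(a, b)
            assert abs(zo - quadrature_overlap(a, b)) / abs(zo) <= 1e-6
            zc = coulomb_similarity(a, b)
            assert abs(zc - quadrature_coulomb(a, b)) / abs(zc) <= 1e-4


class TestIndices:
    def test_carbo_identity_is_one(self, water):
        m = build_density(water)
        z = overlap_similarity(m, m)
        assert carbo_index(z, z, z) == pytest.approx(1.0, abs=1e-12)

    def test_carbo_arithmetic(self):
        assert carbo_index(4.0, 9.0, 5.0) == pytest.approx(5.0 / 6.0)

    def test_carbo_bounded_by_cauchy_schwarz(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_density_model(rng), random_density_model(rng)
            c = carbo_index(
                overlap_similarity(a, a), overlap_similarity(b, b), overlap_similarity(a, b)
            )
            assert 0.0 < c <= 1.0 + 1e-12

    def test_carbo_rejects_nonpositive_self_similarity(self):
        with pytest.raises(ValueError):
            carbo_index(0.0, 1.0, 0.5)

    def test_carbo_invariant_under_uniform_electron_scaling(self):
        rng = np.random.default_rng(4)
        a, b = random_density_model(rng), random_density_model(rng)
        zaa, zbb, zab = (
            overlap_similarity(a, a),
            overlap_similarity(b, b),
            overlap_similarity(a, b),
        )
        k = 3.7  # scaling every N_e by k scales all Z by k^2
        assert carbo_index(k**2 * zaa, k**2 * zbb, k**2 * zab) == pytest.approx(
            carbo_index(zaa, zbb, zab), rel=1e-12
        )

    def test_generalized_distance_identity_and_arithmetic(self):
        assert generalized_distance(7.0, 7.0, 7.0, k=2, x=2) == 0.0
        assert generalized_distance(4.0, 9.0, 5.0, k=2, x=2) == pytest.approx(np.sqrt(3.0))
        assert generalized_distance(4.0, 9.0, 5.0, k=2, x=0) == pytest.approx(np.sqrt(13.0))

    def test_generalized_distance_rejects_negative_radicand(self):
        with pytest.raises(ValueError):
            generalized_distance(1.0, 1.0, 10.0, k=2, x=2)

    def test_infinite_order_distance(self):
        assert infinite_order_distance(4.0, 9.0) == 9.0
        assert infinite_order_distance(4.0, 4.0) == 4.0
        assert infinite_order_distance(4.0, 9.0) == infinite_order_distance(9.0, 4.0)

    def test_euclidean_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            models = [random_density_model(rng) for _ in range(3)]
            z = [[overlap_similarity(x, y) for y in models] for x in models]

            def d(i, j):
                return euclidean_distance(z[i][i], z[j][j], z[i][j])

            for i in range(3):
                assert d(i, i) == pytest.approx(0.0, abs=1e-9)
                for j in range(3):
                    assert d(i, j) == pytest.approx(d(j, i), rel=1e-12)
            assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-9


class TestRigidInvariance:
    def test_z_invariant_under_common_rigid_motion(self, water, ethane):
        from conftest import random_rotation

        rng = np.random.default_rng(6)
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, size=3)
        for zfun in (overlap_similarity, coulomb_similarity):
            z0 = zfun(build_density(water), build_density(ethane))
            z1 = zfun(
                build_density(water.transformed(R, t)),
                build_density(ethane.transformed(R, t)),
            )
            assert z1 == pytest.approx(z0, rel=1e-10)


class TestSimilarityMatrix:
    def _copies(self, water, n):
        return [
            Molecule(f"w{k}", [Atom(a.element, a.coords.copy(), atom_id=a.atom_id) for a in water.atoms], list(water.bonds))
            for k in range(n)
        ]

    def test_identical_copies_give_unit_carbo_zero_euclidean(self, water):
        sm = similarity_matrix(self._copies(water, 3), operator="overlap")
        assert np.allclose(sm.carbo, 1.0, atol=1e-10)
        assert np.allclose(sm.euclidean, 0.0, atol=1e-6)

    def test_matrix_matches_per_pair_calls(self, water, ethane):
        sm = similarity_matrix([water, ethane], operator="coulomb")
        a, b = build_density(water), build_density(ethane)
        expect = np.array(
            [
                [coulomb_similarity(a, a), coulomb_similarity(a, b)],
                [coulomb_similarity(b, a), coulomb_similarity(b, b)],
            ]
        )
        assert np.allclose(sm.Z, expect, rtol=1e-12)

    def test_symmetric_with_unit_carbo_diagonal(self, water, ethane):
        mols = [water, ethane]
        sm = similarity_matrix(mols, operator="overlap")
        assert np.allclose(sm.Z, sm.Z.T)
        assert np.allclose(np.diag(sm.carbo), 1.0)

    def test_lower_triangle_csv_export(self, water, ethane, tmp_path):
        import pandas as pd

        sm = similarity_matrix([water, ethane], operator="overlap")
        p = tmp_path / "m.csv"
        sm.to_csv(p, which="carbo")
        df = pd.read_csv(p)
        assert df.iloc[0]["water"] == 1.0  # diagonal, 4 decimals
        assert np.isnan(df.iloc[0]["ethane"])  # upper triangle blank

    def test_needs_two_molecules(self, water):
        with pytest.raises(ValueError):
            similarity_matrix([water])
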