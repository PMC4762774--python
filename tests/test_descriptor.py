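"""Distance, extension and correction matrices, spectra, XP indices."""

import numpy as np
import pytest

import xpindex as xp
from xpindex.elements import DEFAULT_ELEMENTS
from xpindex.graph import Atom, MolecularGraph


def _triatomic(angle_deg):
    """A-B-C with unit bonds and the given B angle, in the xy plane."""
    theta = np.deg2rad(angle_deg)
    atoms = [
        Atom(0, DEFAULT_ELEMENTS["C"], position=[-1.0, 0.0, 0.0], label="A"),
        Atom(1, DEFAULT_ELEMENTS["C"], position=[0.0, 0.0, 0.0], label="B"),
        Atom(2, DEFAULT_ELEMENTS["C"],
             position=[-np.cos(theta), np.sin(theta), 0.0], label="C"),
    ]
    return MolecularGraph("tri", atoms, {(0, 1, 1), (1, 2, 1)})


class TestSpatialDistanceMatrix:
    def test_bonded_pair_equals_bond_length(self):
        g = _triatomic(180.0)
        for mode in ("bond-path", "euclidean"):
            d = xp.spatial_distance_matrix(g, mode).values
            assert d[0, 1] == pytest.approx(1.0)

    def test_collinear_chain_agrees_between_modes(self):
        g = _triatomic(180.0)
        bp = xp.spatial_distance_matrix(g, "bond-path").values
        eu = xp.spatial_distance_matrix(g, "euclidean").values
        assert bp[0, 2] == pytest.approx(2.0)
        assert eu[0, 2] == pytest.approx(2.0)

    def test_bent_geometry_separates_modes(self):
        g = _triatomic(120.0)
        bp = xp.spatial_distance_matrix(g, "bond-path").values
        eu = xp.spatial_distance_matrix(g, "euclidean").values
        assert bp[0, 2] == pytest.approx(2.0)
        assert eu[0, 2] == pytest.approx(np.sqrt(3.0))  # law of cosines

    def test_missing_coordinates_named(self, xanthone):
        with pytest.raises(ValueError, match="C1"):
            xp.spatial_distance_matrix(xanthone)

    def test_disconnected_graph_rejected(self):
        atoms = [Atom(i, DEFAULT_ELEMENTS["C"], position=[float(i), 0, 0])
                 for i in range(3)]
        g = MolecularGraph("frag", atoms, {(0, 1, 1)})
        with pytest.raises(ValueError, match="disconnected"):
            xp.spatial_distance_matrix(g, "bond-path")

    def test_symmetry_and_triangle_inequality(self, dbxth_28):
        d = xp.spatial_distance_matrix(dbxth_28).values
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        n = d.shape[0]
        for k in range(n):
            assert np.all(d <= d[:, [k]] + d[[k], :] + 1e-9)


class TestExtensionAndCorrection:
    def test_hand_example_diagonal(self):
        s = xp.extension_matrix([[0, 1], [1, 0]], [2, 3], [4, 5], "diagonal")
        np.testing.assert_allclose(s, [[0, 15], [8, 0]])
        q = xp.correction_matrix(s)
        np.testing.assert_allclose(q, [[225, 0], [0, 64]])

    def test_single_atom(self):
        for strategy in ("diagonal", "literal"):
            s = xp.extension_matrix([[0.0]], [2.5], [4.0], strategy)
            np.testing.assert_allclose(s, [[0.0]])

    def test_literal_strategy_is_rank_one(self, rng):
        n = 6
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        s = xp.extension_matrix(d, rng.random(n) + 2, rng.integers(4, 9, n), "literal")
        assert np.linalg.matrix_rank(s, tol=1e-10) <= 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            xp.extension_matrix(np.zeros((3, 3)), [1, 2], [1, 2, 3])

    def test_correction_matrix_is_gram(self, rng):
        s = rng.standard_normal((7, 7))
        q = xp.correction_matrix(s)
        np.testing.assert_allclose(q, q.T, atol=1e-12)
        assert np.linalg.eigvalsh(q)[0] >= -1e-8 * abs(np.linalg.eigvalsh(q)[-1])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            xp.correction_matrix(np.zeros((2, 3)))


class TestSpectrum:
    def test_diagonal_matrix(self):
        spec = xp.spectrum(np.diag([3.0, 1.0, 2.0]))
        np.testing.assert_allclose(spec.eigenvalues, [1, 2, 3])
        assert spec.symmetric_input

    def test_symmetric_with_negative_eigenvalue(self):
        spec = xp.spectrum(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(spec.eigenvalues, [-1, 1])

    def test_nonsymmetric_with_complex_spectrum_raises(self):
        with pytest.raises(ValueError, match="imaginary"):
            xp.spectrum(np.array([[0.0, -1.0], [1.0, 0.0]]))

    def test_printed_reference_matrix_documented_discrepancy(self):
        """The literature 17x17 fixture is non-symmetric and its spectrum
        differs from the printed list; the report records, not asserts."""
        from xpindex.data import spectrum_discrepancy_report
        rep = spectrum_discrepancy_report()
        assert not rep["symmetric_as_printed"]
        assert rep["max_imag"] > 0
        assert rep["max_abs_difference"] > 1.0  # genuinely different
        assert len(rep["printed_eigenvalues"]) == 17


class TestXPIndices:
    def test_printed_28dbxth_eigenvalues(self):
        spec = xp.Spectrum(np.sort(xp.fixture_spectrum().payload), 0.0, True)
        assert xp.xp_indices(spec) == (9.3541, 58.2157)

    @pytest.mark.parametrize("values, expected", [
        ([0.0], (0.0, 0.0)),
        ([-3.0, 2.0], (3.0, 2.0)),
    ])
    def test_absolute_extremes(self, values, expected):
        assert xp.xp_indices(xp.Spectrum(np.array(values), 0.0, True)) == expected

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            xp.xp_indices(xp.Spectrum(np.array([]), 0.0, True))


class TestComputeIndices:
    def test_mirror_congeners_agree(self):
        r1 = xp.compute_indices(xp.idealized_geometry(xp.SubstitutionPattern((2, 8))))
        r2 = xp.compute_indices(xp.idealized_geometry(xp.SubstitutionPattern((1, 7))))
        assert r1.xp1 == pytest.approx(r2.xp1, rel=1e-9, abs=1e-6)
        assert r1.xp2 == pytest.approx(r2.xp2, rel=1e-9)

    def test_diagonal_strategy_psd_ordering(self, dbxth_28):
        res = xp.compute_indices(dbxth_28)
        assert res.xp1 >= 0 and res.xp2 >= res.xp1
        ev = res.spectrum.eigenvalues
        assert ev[0] >= -1e-8 * ev[-1]

    def test_literal_strategy_dominant_eigenvalue(self, dbxth_28):
        res = xp.compute_indices(dbxth_28, strategy="literal")
        ev = np.sort(np.abs(res.spectrum.eigenvalues))
        assert ev[-2] <= 1e-8 * ev[-1]

    def test_permutation_invariance(self, dbxth_28, rng):
        """Relabelling atoms leaves the spectrum, hence XP1/XP2, unchanged."""
        from dataclasses import replace
        perm = rng.permutation(dbxth_28.n_atoms)
        inv = np.argsort(perm)
        atoms = [replace(dbxth_28.atoms[j], index=i) for i, j in enumerate(perm)]
        bonds = {(int(inv[i]), int(inv[j]), o) for i, j, o in dbxth_28.bonds}
        shuffled = MolecularGraph("perm", atoms, bonds)
        a = xp.compute_indices(dbxth_28)
        b = xp.compute_indices(shuffled)
        assert a.xp2 == pytest.approx(b.xp2, rel=1e-9)
        np.testing.assert_allclose(a.spectrum.eigenvalues, b.spectrum.eigenvalues,
                                   rtol=1e-8, atol=1e-6 * a.xp2)

    def test_distance_scaling_scales_eigenvalues_quadratically(self, dbxth_28):
        for strategy in ("diagonal", "literal"):
            m = xp.descriptor_matrices(dbxth_28, strategy=strategy)
            q_scaled = xp.correction_matrix(
                xp.extension_matrix(3.0 * m.d3.values, m.e, m.v, strategy))
            np.testing.assert_allclose(np.linalg.eigvalsh(q_scaled),
                                       9.0 * np.linalg.eigvalsh(m.q),
                                       rtol=1e-9, atol=1e-6)

    def test_mean_xp2_monotone_in_bromination(self):
        """Sanity trend: heavier bromination raises the dominant eigenvalue."""
        from collections import defaultdict
        by_k = defaultdict(list)
        pats = [xp.SubstitutionPattern(())] + xp.enumerate_patterns()
        for pat in pats:
            res = xp.compute_indices(xp.idealized_geometry(pat))
            by_k[len(pat)].append(res.xp2)
        means = [np.mean(by_k[k]) for k in sorted(by_k)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_result_serializes(self, dbxth_28):
        import json
        res = xp.compute_indices(dbxth_28)
        obj = json.loads(res.to_json())
        assert obj["name"] == "2,8-DBXTH"
        assert len(obj["eigenvalues"]) == 17


class TestDistanceMatrixIO:
    def test_roundtrip(self, dbxth_28, tmp_path):
        from xpindex.descriptor import read_distance_matrix, write_distance_matrix
        dm = xp.spatial_distance_matrix(dbxth_28)
        path = tmp_path / "d.tsv"
        write_distance_matrix(path, dm, [a.label for a in dbxth_28.atoms])
        back, labels = read_distance_matrix(path)
        assert labels[:2] == ["C1", "C2"]
        np.testing.assert_allclose(back.values, dm.values, rtol=1e-9)
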