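"""Alignment mapping, Schur reduction, RMSIP/BC and clustering."""
import numpy as np
import pytest
import scipy.optimize

from flexcmp import (
    FixtureSpec,
    GappedAlignment,
    aligned_profiles,
    bhattacharyya,
    build_hessian,
    compute_modes,
    comparative_pipeline,
    deformation_energies,
    effective_hessian,
    fluctuations,
    make_family_set,
    make_structure,
    map_alignment,
    rmsip,
    schur_complement,
    similarity_matrix,
)
from flexcmp.comparative import ReducedModeSet, reduce_covariances
from flexcmp.enm import ModeSet
from flexcmp.errors import AlignmentMappingError

from conftest import rigid_body_fields, structure_from_coords, transformed
from _oracles import bhattacharyya_direct, rmsip_double_sum


def helix_coords(n):
    t = np.arange(n) * np.deg2rad(100.0)
    return np.column_stack(
        [0.23 * np.cos(t), 0.23 * np.sin(t), 0.15 * np.arange(n)]
    )


def seq_structure(sequence, structure_id="s"):
    return structure_from_coords(
        helix_coords(len(sequence)), structure_id=structure_id,
        sequence=sequence,
    )


def reduced_of(structure, alignment_records=None):
    """Identity-alignment reduction (all residues conserved) by default."""
    n = structure.n_residues
    if alignment_records is None:
        seq = structure.one_letter_sequence
        alignment_records = [("a", seq), ("b", seq)]
        structures = [structure, structure]
    aln = GappedAlignment(records=alignment_records)
    amap = map_alignment(aln, structures)
    h = build_hessian(structure)
    return effective_hessian(h, amap, 0)


class TestMapAlignment:
    def test_conserved_columns(self):
        s1 = seq_structure("ACE", "s1")
        s2 = seq_structure("ACDE", "s2")
        aln = GappedAlignment(records=[("s1", "AC-E"), ("s2", "ACDE")])
        amap = map_alignment(aln, [s1, s2])
        np.testing.assert_array_equal(amap.conserved_columns, [0, 1, 3])
        np.testing.assert_array_equal(amap.nonconserved_columns, [2])
        np.testing.assert_array_equal(amap.column_to_residue[0], [0, 1, -1, 2])
        np.testing.assert_array_equal(amap.conserved_residues(1), [0, 1, 3])

    def test_sequence_mismatch_reported(self):
        s1 = seq_structure("ACE", "s1")
        s2 = seq_structure("ACD", "s2")
        aln = GappedAlignment(records=[("s1", "ACE"), ("s2", "ACE")])
        with pytest.raises(AlignmentMappingError) as err:
            map_alignment(aln, [s1, s2])
        assert err.value.structure_id == "s2"
        assert err.value.position == 3

    def test_x_matches_anything(self):
        s1 = seq_structure("ACE", "s1")
        aln = GappedAlignment(records=[("s1", "AXE"), ("s2", "ACE")])
        map_alignment(aln, [s1, seq_structure("ACE", "s2")])

    def test_identical_records_fully_conserved(self):
        structures = [seq_structure("AGAGA", f"s{i}") for i in range(3)]
        aln = GappedAlignment(
            records=[(s.structure_id, "AGAGA") for s in structures]
        )
        amap = map_alignment(aln, structures)
        assert amap.conserved_columns.size == 5
        assert amap.nonconserved_columns.size == 0

    def test_record_count_mismatch(self):
        aln = GappedAlignment(records=[("a", "ACE"), ("b", "ACE")])
        with pytest.raises(AlignmentMappingError):
            map_alignment(aln, [seq_structure("ACE")])

    def test_no_conserved_columns_rejected(self):
        s1 = seq_structure("ACE", "s1")
        s2 = seq_structure("GGG", "s2")
        aln = GappedAlignment(records=[("s1", "ACE---"), ("s2", "---GGG")])
        with pytest.raises(AlignmentMappingError, match="conserved"):
            map_alignment(aln, [s1, s2])


class TestSchurComplement:
    def test_empty_complement_is_identity(self, blob10):
        h = build_hessian(blob10).matrix
        reduced = schur_complement(h, np.arange(h.shape[0]))
        np.testing.assert_array_equal(reduced, h)

    @pytest.mark.parametrize("trial", range(20))
    def test_energy_minimisation_oracle(self, trial):
        """(1/2) x_a^T Hred x_a equals the full quadratic energy
        numerically minimised over the dropped coordinates."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 21))
        s = make_structure(
            FixtureSpec(kind="compact_blob", n_residues=n, seed=trial)
        )
        h = build_hessian(s).matrix
        n_keep = int(rng.integers(4, n - 2))
        keep_res = rng.choice(n, size=n_keep, replace=False)
        keep = np.sort((3 * keep_res[:, None] + np.arange(3)).ravel())
        drop = np.setdiff1d(np.arange(3 * n), keep)
        reduced = schur_complement(h, keep)
        x_a = rng.normal(scale=0.01, size=keep.size)
        expected = 0.5 * x_a @ reduced @ x_a

        def full_energy(x_b):
            x = np.zeros(3 * n)
            x[keep] = x_a
            x[drop] = x_b
            return 0.5 * x @ h @ x

        def grad(x_b):
            x = np.zeros(3 * n)
            x[keep] = x_a
            x[drop] = x_b
            return (h @ x)[drop]

        res = scipy.optimize.minimize(
            full_energy, np.zeros(drop.size), jac=grad,
            hess=lambda _: h[np.ix_(drop, drop)],
            method="trust-exact", options={"gtol": 1e-14},
        )
        assert abs(res.fun - expected) < 1e-8 * abs(expected)

    def test_rigid_fields_stay_in_null_space(self, blob20):
        h = build_hessian(blob20)
        keep_res = np.arange(12)
        keep = (3 * keep_res[:, None] + np.arange(3)).ravel()
        reduced = schur_complement(h.matrix, keep)
        for v in rigid_body_fields(blob20.coordinates):
            va = v[keep]
            assert abs(va @ reduced @ va) < 1e-8 * np.linalg.norm(reduced)

    def test_reduced_system_has_six_trivial_modes(self, blob20):
        seq = blob20.one_letter_sequence
        gapped = seq[:8] + "---" + seq[11:]
        full = [("a", seq), ("b", gapped)]
        other = structure_from_coords(
            np.delete(blob20.coordinates, [8, 9, 10], axis=0),
            structure_id="b",
        )
        aln = GappedAlignment(records=full)
        amap = map_alignment(aln, [blob20, other])
        red = effective_hessian(build_hessian(blob20), amap, 0)
        assert red.modes.n_trivial == 6
        assert red.conserved_residues.size == 17


class TestAlignedProfiles:
    def _pipeline(self, structures, records):
        aln = GappedAlignment(records=records)
        amap = map_alignment(aln, structures)
        hessians = [build_hessian(s) for s in structures]
        modes = [compute_modes(h) for h in hessians]
        return amap, modes, aligned_profiles(structures, amap, modes)

    def test_identical_structures_identical_columns(self, blob20):
        twin = blob20.with_coordinates(blob20.coordinates)
        twin.structure_id = "twin"
        seq = blob20.one_letter_sequence
        _, _, (fluct, deform) = self._pipeline(
            [blob20, twin],
            [(blob20.structure_id, seq), ("twin", seq)],
        )
        np.testing.assert_allclose(
            fluct.data.iloc[:, 0], fluct.data.iloc[:, 1], atol=1e-12
        )
        np.testing.assert_allclose(
            deform.data.iloc[:, 0], deform.data.iloc[:, 1], atol=1e-12
        )

    def test_insertion_leaves_blanks(self, blob20):
        seq = blob20.one_letter_sequence
        short = structure_from_coords(
            np.delete(blob20.coordinates, [5, 6, 7], axis=0),
            structure_id="short",
        )
        gapped = seq[:5] + "---" + seq[8:]
        _, _, (fluct, _) = self._pipeline(
            [blob20, short],
            [(blob20.structure_id, seq), ("short", gapped)],
        )
        assert fluct.data.iloc[[5, 6, 7], 1].isna().all()
        assert fluct.data.iloc[:, 0].notna().all()
        assert fluct.data.drop(index=[6, 7, 8]).iloc[:, 1].notna().all()

    def test_conserved_columns_match_single_analysis(self, blob20):
        """Profiles in the table equal the single-structure profiles
        (computed from all modes) at the mapped positions."""
        seq = blob20.one_letter_sequence
        short = structure_from_coords(
            np.delete(blob20.coordinates, [0, 1], axis=0), structure_id="short"
        )
        amap, modes, (fluct, deform) = self._pipeline(
            [blob20, short],
            [(blob20.structure_id, seq), ("short", "--" + seq[2:])],
        )
        single_f = fluctuations(modes[0]).values
        np.testing.assert_allclose(
            fluct.data.iloc[:, 0].to_numpy(), single_f, atol=1e-12
        )
        single_d = deformation_energies(modes[1], short).values
        np.testing.assert_allclose(
            deform.data.iloc[2:, 1].to_numpy(), single_d, atol=1e-12
        )


def rotate_into_frame(red_b, red_a):
    """Independent frame fit: scipy's align_vectors (its own Kabsch)
    rotates B's displacement columns into A's frame for the oracles."""
    from scipy.spatial.transform import Rotation

    a = red_a.conserved_coordinates
    b = red_b.conserved_coordinates
    rot, _ = Rotation.align_vectors(a - a.mean(axis=0), b - b.mean(axis=0))
    r = rot.as_matrix()
    d = red_b.modes.cartesian_displacements
    n = d.shape[0] // 3
    return (d.T.reshape(-1, n, 3) @ r.T).reshape(-1, 3 * n).T


def orthogonal_fake_reduced(dim=40):
    """Two mode sets spanning orthogonal 10-dimensional subspaces."""
    masses = np.ones(dim // 3 + 1)[: dim // 3]

    def fake(cols):
        vecs = np.eye(dim)[:, cols]
        return ReducedModeSet(
            structure_id="fake",
            effective_hessian=np.eye(dim),
            modes=ModeSet(
                eigenvalues=np.arange(1.0, len(cols) + 1),
                vectors=vecs,
                masses=np.ones(dim // 3),
                n_trivial=0,
            ),
            conserved_residues=np.arange(dim // 3),
        )

    return fake(list(range(10))), fake(list(range(10, 20)))


class TestRmsip:
    def test_self_similarity(self, blob20):
        red = reduced_of(blob20)
        assert rmsip(red, red) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_subspaces_give_zero(self):
        a, b = orthogonal_fake_reduced(dim=42)
        assert rmsip(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        a = reduced_of(make_structure(
            FixtureSpec(kind="compact_blob", n_residues=12, seed=31)))
        s2 = make_structure(
            FixtureSpec(kind="compact_blob", n_residues=12, seed=32))
        b = reduced_of(s2)
        expected = rmsip_double_sum(
            a.modes.cartesian_displacements,
            rotate_into_frame(b, a),
        )
        assert rmsip(a, b) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_ten_modes_warns(self, dimer):
        red = reduced_of(dimer)
        with pytest.warns(UserWarning, match="non-trivial modes"):
            value = rmsip(red, red)
        assert value == pytest.approx(1.0, abs=1e-10)

    def test_rigid_motion_invariance(self, blob20):
        red = reduced_of(blob20)
        moved = reduced_of(transformed(blob20, 55))
        assert rmsip(red, moved) == pytest.approx(1.0, abs=1e-8)


class TestBhattacharyya:
    def test_self_similarity(self, blob20):
        red = reduced_of(blob20)
        assert bhattacharyya(red, red) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_and_bounds(self):
        pairs = [
            (
                reduced_of(make_structure(FixtureSpec(
                    kind="compact_blob", n_residues=10, seed=200 + i))),
                reduced_of(make_structure(FixtureSpec(
                    kind="compact_blob", n_residues=10, seed=300 + i))),
            )
            for i in range(5)
        ]
        for a, b in pairs:
            ab, ba = bhattacharyya(a, b), bhattacharyya(b, a)
            assert ab == pytest.approx(ba, abs=1e-10)
            assert 0.0 < ab <= 1.0 + 1e-9

    def test_matches_direct_determinant_oracle(self):
        a = reduced_of(make_structure(
            FixtureSpec(kind="compact_blob", n_residues=11, seed=41)))
        b = reduced_of(make_structure(
            FixtureSpec(kind="compact_blob", n_residues=11, seed=42)))
        expected = bhattacharyya_direct(
            a.modes.eigenvalues, a.modes.cartesian_displacements,
            b.modes.eigenvalues, rotate_into_frame(b, a),
        )
        assert bhattacharyya(a, b) == pytest.approx(expected, abs=1e-8)

    def test_variance_fraction_bookkeeping(self, blob20):
        red = reduced_of(blob20)
        rc = reduce_covariances(red, red)
        assert np.trace(rc.a_n) == pytest.approx(1.0, abs=1e-10)
        assert np.trace(rc.b_m) == pytest.approx(1.0, abs=1e-10)
        assert 1 <= rc.s <= rc.a_tilde.shape[0]
        weights = 1.0 / red.modes.eigenvalues
        assert weights[: rc.n].sum() >= 0.95 * weights.sum() - 1e-9
        assert weights[: rc.n - 1].sum() < 0.95 * weights.sum()

    def test_rigid_motion_invariance(self, blob20):
        red = reduced_of(blob20)
        moved = reduced_of(transformed(blob20, 56))
        assert bhattacharyya(red, moved) == pytest.approx(1.0, abs=1e-8)


class TestSimilarityMatrix:
    def test_identical_structures_all_ones(self, blob10):
        reds = [reduced_of(blob10) for _ in range(3)]
        for i, r in enumerate(reds):
            r.structure_id = f"copy{i}"
        sim = similarity_matrix(reds, "BC")
        np.testing.assert_allclose(sim.values, 1.0, atol=1e-9)
        assert sim.linkage_matrix[:, 2].max() < 1e-9  # merge heights ~ 0
        np.testing.assert_array_equal(sim.values, sim.values.T)

    def test_two_family_clustering_recovers_families(self):
        specs = [
            FixtureSpec(kind="family", n_residues=20, noise_sigma=0.02,
                        seed=601, count=5),
            FixtureSpec(kind="family", n_residues=20, noise_sigma=0.02,
                        seed=602, count=5),
        ]
        structures, aln = make_family_set(specs)
        res = comparative_pipeline(structures, aln)
        clusters = res["bc"].cut(2)
        assert len(set(clusters[:5])) == 1
        assert len(set(clusters[5:])) == 1
        assert clusters[0] != clusters[5]

    def test_bc_discriminates_spectra_that_rmsip_merges(self):
        """Two families sharing their low-mode subspaces but differing
        in how variance is distributed over those modes: RMSIP (pure
        subspace overlap) cannot tell them apart, BC (variance-weighted)
        separates them with a clearly larger within-vs-between margin."""
        members = []
        base = make_structure(FixtureSpec(kind="compact_blob",
                                          n_residues=14, seed=800))
        for i in range(10):
            # fresh small perturbations of one base fold
            rng = np.random.default_rng(810 + i)
            noisy = base.with_coordinates(
                base.coordinates
                + rng.normal(scale=0.005, size=base.coordinates.shape)
            )
            noisy.structure_id = f"m{i}"
            members.append(reduced_of(noisy))
        # family 2: same structures, but the 10 softest eigenvalues
        # reversed -> identical subspaces, different spectra
        for red in members[5:]:
            lam = red.modes.eigenvalues.copy()
            lam[:10] = lam[:10][::-1]
            red.modes.eigenvalues = lam
        bc_m = similarity_matrix(members, "BC").values
        rmsip_m = similarity_matrix(members, "RMSIP").values

        def margin(values):
            within = np.concatenate([
                values[:5, :5][np.triu_indices(5, 1)],
                values[5:, 5:][np.triu_indices(5, 1)],
            ])
            between = values[:5, 5:].ravel()
            return within.mean() - between.mean()

        assert margin(bc_m) > margin(rmsip_m) + 0.05
        assert abs(margin(rmsip_m)) < 0.02  # RMSIP merges the families
        # and BC clustering recovers them
        clusters = similarity_matrix(members, "BC").cut(2)
        assert len(set(clusters[:5])) == 1 and len(set(clusters[5:])) == 1
        assert clusters[0] != clusters[5]

    def test_bc_degrades_with_noise(self):
        """Mean BC to noisy copies decreases as sigma grows."""
        base = make_structure(
            FixtureSpec(kind="compact_blob", n_residues=16, seed=700)
        )
        seq = base.one_letter_sequence
        means = []
        for sigma in (0.01, 0.05, 0.1):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(1000 * seed + int(sigma * 1000))
                while True:  # re-draw clashing copies, as the generator does
                    coords = base.coordinates + rng.normal(
                        scale=sigma, size=base.coordinates.shape
                    )
                    from scipy.spatial.distance import pdist

                    if pdist(coords).min() >= 0.279:
                        break
                noisy = base.with_coordinates(coords)
                noisy.structure_id = "noisy"
                aln = GappedAlignment(
                    records=[(base.structure_id, seq), ("noisy", seq)]
                )
                amap = map_alignment(aln, [base, noisy])
                red_a = effective_hessian(build_hessian(base), amap, 0)
                red_b = effective_hessian(build_hessian(noisy), amap, 1)
                vals.append(bhattacharyya(red_a, red_b))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
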