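import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ankevo import (
    Structure,
    anm_modes,
    build_ensemble,
    build_hessian,
    ensemble_pca,
    iterative_superposition,
    kabsch_superpose,
    make_ensemble,
    mode_overlap,
    pc_cluster,
    read_pdb_calpha,
    write_pdb_calpha,
)
from ankevo.synthetic_data import make_ankyrin_calpha


class TestKabsch:
    def test_rotated_copy_fits_exactly(self, ankyrin2):
        rot = Rotation.from_euler("xyz", [0.4, 1.1, -0.3]).as_matrix()
        mobile = ankyrin2.coords @ rot.T
        _, rmsd = kabsch_superpose(mobile, ankyrin2.coords)
        assert rmsd < 1e-8

    def test_translation_removed(self, ankyrin2):
        _, rmsd = kabsch_superpose(ankyrin2.coords + 5.0, ankyrin2.coords)
        assert rmsd < 1e-10

    def test_fit_beats_coarse_rotation_grid(self):
        rng = np.random.default_rng(2)
        mobile = rng.normal(size=(12, 3))
        target = rng.normal(size=(12, 3))
        _, fitted = kabsch_superpose(mobile, target)
        mc = mobile - mobile.mean(axis=0)
        tc = target - target.mean(axis=0)
        best = np.inf
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        for ax in angles:
            for ay in angles:
                for az in angles:
                    r = Rotation.from_euler("xyz", [ax, ay, az]).as_matrix()
                    rmsd = np.sqrt(np.mean(np.sum((mc @ r.T - tc) ** 2, axis=1)))
                    best = min(best, rmsd)
        assert fitted <= best + 1e-12

    def test_rotation_is_proper(self):
        # near-planar points invite a reflection; fit must stay proper
        rng = np.random.default_rng(0)
        target = rng.normal(size=(10, 3))
        target[:, 2] *= 1e-6
        mobile = target[:, [1, 0, 2]]  # a reflection of the target
        moved, rmsd = kabsch_superpose(mobile, target)
        assert np.isfinite(rmsd)

    def test_too_few_shared_positions(self):
        with pytest.raises(ValueError):
            kabsch_superpose(
                np.zeros((5, 3)), np.ones((5, 3)),
                np.array([True, True, False, False, False]),
            )


class TestBuildEnsemble:
    def test_identical_copies_full_occupancy(self, ankyrin2):
        copies = [
            dataclasses.replace(ankyrin2, id=f"c{i}") for i in range(5)
        ]
        ens = build_ensemble(copies)
        assert ens.n_members == 5
        assert ens.mask.all()
        assert ens.n_positions == ankyrin2.n_residues

    def test_truncated_member_masks_or_drops_positions(self, ankyrin2):
        n = ankyrin2.n_residues
        cut = int(0.2 * n)
        short = Structure(
            "short",
            ankyrin2.residue_ids[cut:],
            ankyrin2.coords[cut:],
            None,
            ankyrin2.sequence[cut:],
        )
        full = [dataclasses.replace(ankyrin2, id=f"c{i}") for i in range(9)]
        ens = build_ensemble(full + [short], min_occupancy=0.95)
        # 1 of 10 members misses 20% of positions -> occupancy 0.9 < 0.95
        assert ens.n_positions == n - cut
        ens2 = build_ensemble(full + [short], min_occupancy=0.9)
        assert ens2.n_positions == n
        assert not ens2.mask[-1, :cut].any()

    def test_low_coverage_member_excluded(self, ankyrin2):
        tiny = Structure(
            "tiny",
            ankyrin2.residue_ids[:10],
            ankyrin2.coords[:10],
            None,
            ankyrin2.sequence[:10],
        )
        copies = [dataclasses.replace(ankyrin2, id=f"c{i}") for i in range(3)]
        ens = build_ensemble(copies + [tiny])
        assert ens.n_members == 3
        assert ens.excluded and ens.excluded[0][0] == "tiny"

    def test_multi_model_file_plus_crystal_gives_three_conformers(
        self, ankyrin2, tmp_path
    ):
        nmr = tmp_path / "nmr.pdb"
        write_pdb_calpha(
            [dataclasses.replace(ankyrin2, id="m1"),
             dataclasses.replace(ankyrin2, id="m2")], nmr
        )
        xtal = tmp_path / "xtal.pdb"
        write_pdb_calpha([ankyrin2], xtal)
        structures = read_pdb_calpha(nmr) + read_pdb_calpha(xtal)
        ens = build_ensemble(structures)
        assert ens.n_members == 3


class TestIterativeSuperposition:
    def test_identical_conformers_have_zero_rmsd(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [1.0], M=5, seed=0,
                               noise_sigma=0.0)
        ens.members[:] = ankyrin2.coords  # degenerate: all identical
        out = iterative_superposition(ens)
        np.testing.assert_allclose(out.rmsd_to_mean, 0.0, atol=1e-10)

    def test_rigid_scramble_fully_removed(self, ankyrin2):
        rng = np.random.default_rng(4)
        members = []
        for _ in range(6):
            rot = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            members.append(ankyrin2.coords @ rot.T + rng.uniform(-30, 30, 3))
        from ankevo.ensemble_pca import Ensemble

        ens = Ensemble(
            reference=ankyrin2,
            members=np.stack(members),
            mask=np.ones((6, ankyrin2.n_residues), bool),
            labels=[f"c{i}" for i in range(6)],
        )
        out = iterative_superposition(ens)
        assert np.all(out.rmsd_to_mean < 1e-6)

    def test_total_rmsd_non_increasing(self, ankyrin2):
        ens, _ = make_ensemble(
            ankyrin2, "random", [4.0, 1.0], M=12, rigid_noise=True, seed=7
        )
        totals = []
        cur = ens
        import warnings

        for _ in range(4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # forced 1-step
                cur = iterative_superposition(cur, max_iter=1)
            totals.append(float(cur.rmsd_to_mean.sum()))
        assert all(b <= a + 1e-6 for a, b in zip(totals, totals[1:]))


class TestEnsemblePCA:
    def test_single_planted_direction_recovered(self, ankyrin2):
        ens, truth = make_ensemble(ankyrin2, "random", [1.0], M=100, seed=1)
        pca = ensemble_pca(iterative_superposition(ens))
        cos = abs(pca.eigenvectors[:, 0] @ truth.directions[0])
        assert cos > 0.99
        assert pca.fractions[0] > 0.9

    def test_two_direction_variance_ratio(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [4.0, 1.0], M=500, seed=2)
        pca = ensemble_pca(iterative_superposition(ens))
        assert pca.fractions[0] == pytest.approx(0.8, abs=0.05)
        assert pca.fractions[1] == pytest.approx(0.2, abs=0.05)

    def test_projection_scores_uncorrelated(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [4.0, 1.0], M=300, seed=3)
        pca = ensemble_pca(iterative_superposition(ens))
        r = np.corrcoef(pca.projections[:, 0], pca.projections[:, 1])[0, 1]
        assert abs(r) < 0.1

    def test_fractions_sum_to_one_and_orthonormal(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [2.0, 1.0], M=30, seed=5)
        pca = ensemble_pca(ens)
        assert pca.fractions.sum() == pytest.approx(1.0)
        v = pca.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_two_members_rejected(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [1.0], M=2, seed=0)
        assert ens.n_members == 2  # the ensemble itself is valid
        with pytest.raises(ValueError, match="at least 3"):
            ensemble_pca(ens)


class TestModeOverlap:
    def test_identical_vector_sets_give_identity(self, ankyrin2):
        modes = anm_modes(build_hessian(ankyrin2))
        pca = type("P", (), {})()
        pca.eigenvectors = modes.eigenvectors[:, :3]
        rep = mode_overlap(pca, modes, n_pc=3, n_anm=3)
        np.testing.assert_allclose(rep.overlap, np.eye(3), atol=1e-10)

    def test_complete_bases_have_unit_row_sums(self, ankyrin2):
        """Squared overlaps of one PC against a complete ANM basis
        (rigid block included) sum to 1."""
        modes = anm_modes(build_hessian(ankyrin2))
        full = np.hstack([modes.eigenvectors, modes.rigid_eigenvectors])
        rng = np.random.default_rng(0)
        v = rng.normal(size=full.shape[0])
        v /= np.linalg.norm(v)
        pca = type("P", (), {"eigenvectors": v[:, None]})()
        fake = type("M", (), {"eigenvectors": full})()
        rep = mode_overlap(pca, fake, n_pc=1, n_anm=full.shape[1])
        assert np.sum(rep.overlap**2) == pytest.approx(1.0, abs=1e-8)

    def test_displacement_along_anm_mode_is_self_consistent(self, ankyrin2):
        modes = anm_modes(build_hessian(ankyrin2))
        w = modes.eigenvectors[:, 0][None, :]
        ens, _ = make_ensemble(ankyrin2, w, [1.0], M=150, seed=6)
        sup = iterative_superposition(ens)
        pca = ensemble_pca(sup)
        rep = mode_overlap(pca, modes, ens=sup)
        assert rep.overlap[0, 0] > 0.9
        assert rep.projection_r[0, 0] > 0.9

    def test_dimension_mismatch_rejected(self, ankyrin2, ankyrin7):
        modes = anm_modes(build_hessian(ankyrin7))
        ens, _ = make_ensemble(ankyrin2, "random", [1.0], M=5, seed=0)
        pca = ensemble_pca(ens)
        with pytest.raises(ValueError, match="coordinate spaces"):
            mode_overlap(pca, modes)


class TestPcCluster:
    def test_two_planted_regimes_separate(self, ankyrin2):
        rng = np.random.default_rng(9)
        n3 = ankyrin2.coords.size
        w = rng.normal(size=n3)
        w /= np.linalg.norm(w)
        members = []
        for m in range(30):
            shift = 20.0 if m < 15 else -20.0
            flat = ankyrin2.coords.reshape(-1) + (shift + rng.normal()) * w
            members.append(flat.reshape(-1, 3))
        from ankevo.ensemble_pca import Ensemble

        ens = Ensemble(
            reference=ankyrin2,
            members=np.stack(members),
            mask=np.ones((30, ankyrin2.n_residues), bool),
            labels=[f"c{i}" for i in range(30)],
        )
        pca = ensemble_pca(ens)
        labels = ["g1"] * 15 + ["g2"] * 15
        out = pc_cluster(pca, labels)
        assert out["separation"] > 0.5
        assert out["groups"]["g1"]["n"] == 15

    def test_label_permutation_preserves_geometry(self, ankyrin2):
        ens, _ = make_ensemble(ankyrin2, "random", [1.0], M=10, seed=1)
        pca = ensemble_pca(ens)
        labels = ["u"] * 5 + ["v"] * 5
        a = pc_cluster(pca, labels)
        b = pc_cluster(pca, ["v" if l == "u" else "u" for l in labels])
        assert a["separation"] == pytest.approx(b["separation"])
        np.testing.assert_allclose(
            a["groups"]["u"]["centroid"], b["groups"]["v"]["centroid"]
        )
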