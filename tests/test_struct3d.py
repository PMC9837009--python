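"""PDB ingestion, Kabsch superposition, ensemble statistics and 3D clustering."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from exoscreen import struct3d, synthdata
from exoscreen.clusterlib import ClusterParams
from exoscreen.errors import EmptyInputError, FormatError, InsufficientAtomsError
from exoscreen.struct3d import (
    DEFAULT_ATOM_SET,
    Ensemble,
    Structure3D,
    ensemble_stats,
    kabsch_rmsd,
    match_atoms,
    read_pdb_ensemble,
    rmsd_between,
    rmsd_matrix,
)

RNG = np.random.default_rng(20240917)


def make_structure(coords_per_res, model_id="m", atom_names=DEFAULT_ATOM_SET):
    atoms = tuple(
        {name: np.asarray(xyz, dtype=float) for name, xyz in res.items()}
        for res in coords_per_res
    )
    n = len(atoms)
    return Structure3D(model_id, tuple(range(1, n + 1)), tuple("A" * n), atoms)


def random_structure(n_res=6, rng=RNG, model_id="m"):
    return make_structure(
        [
            {name: rng.normal(size=3) * 5 for name in DEFAULT_ATOM_SET}
            for _ in range(n_res)
        ],
        model_id=model_id,
    )


def transform(s: Structure3D, R=None, t=None, model_id="t"):
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else t
    return make_structure(
        [{name: R @ xyz + t for name, xyz in res.items()} for res in s.atoms],
        model_id=model_id,
    )


class TestPdbIO:
    def test_round_trip_of_generated_ensemble(self, tmp_path):
        spec = synthdata.EnsembleSpec()
        synthdata.make_structure_ensembles(spec, seed=3, outdir=tmp_path)
        e = read_pdb_ensemble(tmp_path / "0.pdb")
        assert e.sequence_id == "0"
        assert e.n_models == 2
        assert e.models[0].n_residues == 19
        # the 5'-terminal residue has no phosphate
        assert "P" not in e.models[0].atoms[0]
        assert set(e.models[0].atoms[1]) == set(DEFAULT_ATOM_SET)

    def test_coordinates_preserved_to_pdb_precision(self, tmp_path):
        base = synthdata.ideal_backbone(7)
        synthdata._write_pdb(tmp_path / "x.pdb", "AAAAAAA", [base])
        e = read_pdb_ensemble(tmp_path / "x.pdb")
        for res_in, res_out in zip(base, e.models[0].atoms):
            for name, xyz in res_in.items():
                assert np.allclose(res_out[name], xyz, atol=5e-4)

    def test_file_without_model_records_is_single_model(self, tmp_path):
        base = synthdata.ideal_backbone(5)
        synthdata._write_pdb(tmp_path / "multi.pdb", "AAAAA", [base])
        body = [
            ln
            for ln in (tmp_path / "multi.pdb").read_text().splitlines()
            if not ln.startswith(("MODEL", "ENDMDL"))
        ]
        path = tmp_path / "single.pdb"
        path.write_text("\n".join(body) + "\n")
        e = read_pdb_ensemble(path)
        assert e.n_models == 1
        assert e.models[0].n_residues == 5

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(EmptyInputError):
            read_pdb_ensemble(path)


class TestMatchAtoms:
    def test_self_pairing_size(self):
        base = synthdata.ideal_backbone(19)
        s = make_structure(base)
        X, Y, n = match_atoms(s, s)
        assert n == 3 * 19 - 1  # 5'-terminal P missing
        assert np.allclose(X, Y)

    def test_random_deletions_match_key_intersection(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = random_structure(5, rng, "a")
            b = random_structure(5, rng, "b")

            def drop(s):
                return make_structure(
                    [
                        {
                            n: xyz
                            for n, xyz in res.items()
                            if rng.random() > 0.3
                        }
                        for res in s.atoms
                    ],
                    model_id=s.model_id,
                )

            da, db_ = drop(a), drop(b)
            expected = {
                (r, n)
                for r in range(5)
                for n in DEFAULT_ATOM_SET
                if n in da.atoms[r] and n in db_.atoms[r]
            }
            if len(expected) < 3:
                continue
            _, _, n = match_atoms(da, db_)
            assert n == len(expected)

    def test_too_few_atoms_raises(self):
        a = make_structure([{"P": (0, 0, 0)}])
        with pytest.raises(InsufficientAtomsError):
            match_atoms(a, a)

    def test_residue_count_mismatch(self):
        with pytest.raises(FormatError):
            match_atoms(random_structure(4), random_structure(5))


class TestKabsch:
    def test_rigid_motion_invariance_to_1e9(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            X = rng.normal(size=(10, 3)) * 4
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 10
            assert kabsch_rmsd(X, X @ R.T + t) <= 1e-9

    def test_unit_triangle_rotated_90_degrees(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        assert kabsch_rmsd(X, X @ Rz.T) <= 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        X, Y = rng.normal(size=(2, 12, 3))
        assert kabsch_rmsd(X, Y) == pytest.approx(kabsch_rmsd(Y, X), abs=1e-12)

    def test_matches_rotation_grid_oracle(self):
        # brute-force minimization over a fine axis-angle grid can approach
        # but never beat the closed-form optimum
        rng = np.random.default_rng(55)
        idx = np.arange(400)
        phi = (1 + 5**0.5) / 2
        axes = np.stack(
            [
                np.cos(2 * np.pi * idx / phi) * np.sqrt(1 - (1 - 2 * (idx + 0.5) / 400) ** 2),
                np.sin(2 * np.pi * idx / phi) * np.sqrt(1 - (1 - 2 * (idx + 0.5) / 400) ** 2),
                1 - 2 * (idx + 0.5) / 400,
            ],
            axis=1,
        )
        angles = np.linspace(0, np.pi, 91)
        for _ in range(3):
            X = rng.normal(size=(10, 3))
            Y = rng.normal(size=(10, 3))
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            best = np.inf
            for axis in axes:
                rots = Rotation.from_rotvec(np.outer(angles, axis)).as_matrix()
                diffs = Yc @ rots.transpose(0, 2, 1) - Xc  # (n_angles, 10, 3)
                rms = np.sqrt((diffs**2).sum(axis=(1, 2)) / 10)
                best = min(best, rms.min())
            closed = kabsch_rmsd(Xc, Yc)
            assert closed <= best + 1e-9
            assert best - closed <= 0.05

    def test_reflection_excluded_for_chiral_set(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        mirror = X.copy()
        mirror[:, 2] *= -1
        assert kabsch_rmsd(X, mirror) > 0.1

    def test_triangle_inequality_on_matched_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            X, Y, Z = rng.normal(size=(3, 8, 3)) * 3
            assert kabsch_rmsd(X, Z) <= kabsch_rmsd(X, Y) + kabsch_rmsd(Y, Z) + 1e-9

    def test_nan_rejected(self):
        X = np.zeros((4, 3))
        Y = X.copy()
        Y[0, 0] = np.nan
        with pytest.raises(ValueError):
            kabsch_rmsd(X, Y)

    def test_degenerate_collinear_points_still_defined(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        Y = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0], [0, 3, 0]], dtype=float)
        assert kabsch_rmsd(X, Y) <= 1e-9


class TestEnsembleStats:
    def test_two_model_convention(self):
        rng = np.random.default_rng(12)
        a = random_structure(6, rng, "1")
        b = random_structure(6, rng, "2")
        r = rmsd_between(a, b)
        stats = ensemble_stats(Ensemble("e", (a, b)))
        assert stats.avg_rmsd == stats.min_rmsd == stats.max_rmsd == pytest.approx(r)
        assert stats.sd == 0.0
        assert stats.avg_to_centroid == pytest.approx(r)
        assert stats.centroid_id == "1"

    def test_identical_models_all_zero(self):
        a = random_structure(5, model_id="1")
        b = transform(a, model_id="2")
        stats = ensemble_stats(Ensemble("e", (a, b)))
        assert stats.avg_rmsd <= 1e-9 and stats.max_rmsd <= 1e-9

    def test_single_model(self):
        stats = ensemble_stats(Ensemble("e", (random_structure(5, model_id="1"),)))
        assert stats == struct3d.EnsembleStats("e", 1, 0, 0, 0, 0, "1", 0, 0)

    def test_five_models_match_direct_recomputation(self):
        rng = np.random.default_rng(91)
        models = [random_structure(6, rng, str(i + 1)) for i in range(5)]
        stats = ensemble_stats(Ensemble("e", tuple(models)))
        vals = [
            rmsd_between(a, b) for a, b in itertools.combinations(models, 2)
        ]
        assert stats.avg_rmsd == pytest.approx(np.mean(vals))
        assert stats.sd == pytest.approx(np.std(vals))
        assert stats.min_rmsd == pytest.approx(min(vals))
        assert stats.max_rmsd == pytest.approx(max(vals))

    def test_model_order_does_not_change_statistics(self):
        rng = np.random.default_rng(14)
        models = [random_structure(5, rng, str(i + 1)) for i in range(4)]
        s1 = ensemble_stats(Ensemble("e", tuple(models)))
        s2 = ensemble_stats(Ensemble("e", tuple(reversed(models))))
        assert s1.avg_rmsd == pytest.approx(s2.avg_rmsd)
        assert s1.centroid_id == s2.centroid_id


class TestCrossEnsembleCluster:
    def test_planted_partition_recovered(self, tmp_path):
        synthdata.make_structure_ensembles(
            synthdata.EnsembleSpec(), seed=21, outdir=tmp_path
        )
        ensembles = struct3d.read_ensemble_dir(tmp_path)
        centroids = [(e.sequence_id, struct3d.centroid_model(e)) for e in ensembles]
        result, cstats, D = struct3d.cross_ensemble_cluster(centroids)
        assert result.n_clusters == 2
        members = {frozenset(m) for m in result.members.values()}
        assert frozenset(("6", "7")) in members
        sizes = sorted(len(m) for m in result.members.values())
        assert sizes == [2, 11]
        by_size = {s.n_members: s for s in cstats}
        assert by_size[2].avg_rmsd == pytest.approx(by_size[2].avg_to_centroid)

    def test_two_centroids_threshold_boundary(self):
        rng = np.random.default_rng(31)
        a = random_structure(6, rng, "a")
        b = random_structure(6, rng, "b")
        r = rmsd_between(a, b)
        below, _, _ = struct3d.cross_ensemble_cluster(
            [("a", a), ("b", b)], ClusterParams(cut=r * 1.01)
        )
        above, _, _ = struct3d.cross_ensemble_cluster(
            [("a", a), ("b", b)], ClusterParams(cut=r * 0.99)
        )
        assert below.n_clusters == 1
        assert above.n_clusters == 2

    def test_planted_three_groups_recovered_when_separated(self):
        recovered = 0
        trials = 20
        for seed in range(trials):
            spec = synthdata.EnsembleSpec(
                models_per_ensemble={str(i): 2 for i in range(9)},
                partition={
                    "background": tuple(str(i) for i in range(5)),
                    "g1": ("5", "6"),
                    "g2": ("7", "8"),
                },
                sigma=0.05,
                delta=3.0,
                sequences={},
            )
            import tempfile, pathlib

            with tempfile.TemporaryDirectory() as d:
                synthdata.make_structure_ensembles(spec, seed=seed, outdir=d)
                ensembles = struct3d.read_ensemble_dir(d)
            centroids = [
                (e.sequence_id, struct3d.centroid_model(e)) for e in ensembles
            ]
            result, _, D = struct3d.cross_ensemble_cluster(centroids)
            planted = {frozenset(v) for v in spec.partition.values()}
            within = max(
                D.get(a, b)
                for ids in spec.partition.values()
                for a in ids
                for b in ids
                if a != b
            )
            between = min(
                D.get(a, b)
                for g1, g2 in itertools.combinations(spec.partition.values(), 2)
                for a in g1
                for b in g2
            )
            if between > within:  # separation condition
                if {frozenset(m) for m in result.members.values()} == planted:
                    recovered += 1
                else:
                    pytest.fail(f"separated partition not recovered at seed {seed}")
        assert recovered > 0


def test_rmsd_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(44)
    structures = [(str(i), random_structure(5, rng, str(i))) for i in range(4)]
    D = rmsd_matrix(structures)
    assert np.allclose(D.values, D.values.T)
    assert np.all(np.diag(D.values) == 0)
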