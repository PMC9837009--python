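"""Tertiary-structure ensembles: PDB ingestion, Kabsch RMSD, and clustering.

Each candidate miRNA yields an ensemble of predicted 3D models (multi-model
PDB files, e.g. from an external prediction service).  Within each ensemble
all model pairs are superimposed with the Kabsch algorithm and summarized
(average/min/max RMSD plus a medoid "centroid" model); the centroids of all
ensembles are then compared globally and clustered by single linkage,
flagging variants whose tertiary fold diverges from the native.

Atoms are paired across structures by residue index and atom name.  The
default atom set {P, C4', C1'} covers the backbone plus the glycosidic
anchor, so structures of sequences differing by a base substitution remain
fully comparable (base atoms cannot be paired across a substitution).
Superposition is plain Kabsch over all matched atoms — no iterative outlier
rejection — which keeps the definition closed-form and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .clusterlib import ClusterParams, ClusterResult, DistanceMatrix, centroid, single_linkage
from .errors import EmptyInputError, FormatError, InsufficientAtomsError

#: Backbone + anchor atoms shared by every residue regardless of base identity.
DEFAULT_ATOM_SET = ("P", "C4'", "C1'")


@dataclass(frozen=True)
class Structure3D:
    """One 3D model: ordered residues, each a dict of atom name -> xyz (Å)."""

    model_id: str
    residue_numbers: tuple[int, ...]
    residue_names: tuple[str, ...]
    atoms: tuple[dict[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        nums = self.residue_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError(
                f"model {self.model_id!r}: residue numbers not strictly increasing"
            )
        for res in self.atoms:
            for name, xyz in res.items():
                if not np.all(np.isfinite(xyz)):
                    raise FormatError(
                        f"model {self.model_id!r}: non-finite coordinates for {name}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class Ensemble:
    """All predicted 3D models for one sequence."""

    sequence_id: str
    models: tuple[Structure3D, ...]

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyInputError(f"ensemble {self.sequence_id!r} has no models")
        counts = {m.n_residues for m in self.models}
        if len(counts) > 1:
            raise FormatError(
                f"ensemble {self.sequence_id!r}: models disagree on residue count {counts}"
            )

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class EnsembleStats:
    """Within-ensemble RMSD statistics plus the centroid model (Table-style).

    For a two-model ensemble the average, min, max and average-to-centroid
    all equal the single pairwise RMSD, because centroid statistics exclude
    the centroid's zero self-distance.
    """

    sequence_id: str
    n_models: int
    avg_rmsd: float
    sd: float
    min_rmsd: float
    max_rmsd: float
    centroid_id: str
    avg_to_centroid: float
    sd_to_centroid: float


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster RMSD statistics for the cross-ensemble comparison."""

    cluster_id: int
    members: tuple[str, ...]
    n_members: int
    avg_rmsd: float
    sd: float
    min_rmsd: float
    max_rmsd: float
    centroid_id: str
    avg_to_centroid: float
    sd_to_centroid: float


# ---------------------------------------------------------------------------
# PDB ingestion

def read_pdb_ensemble(path: str | Path, sequence_id: str | None = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    ATOM records are parsed per the fixed-width PDB standard; HETATM records
    and altLoc codes other than blank/'A' are ignored; model ids come from
    MODEL serial numbers (a file without MODEL records yields one model).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: unparseable PDB: {exc}") from exc

    models: list[Structure3D] = []
    for model in structure:
        residue_numbers: list[int] = []
        residue_names: list[str] = []
        atoms: list[dict[str, np.ndarray]] = []
        for chain in model:
            for residue in chain:
                if residue.id[0].strip():  # skip HETATM / water
                    continue
                res_atoms: dict[str, np.ndarray] = {}
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    res_atoms[atom.get_name()] = np.asarray(
                        atom.get_coord(), dtype=float
                    )
                if res_atoms:
                    residue_numbers.append(residue.id[1])
                    residue_names.append(residue.get_resname().strip())
                    atoms.append(res_atoms)
        if atoms:
            models.append(
                Structure3D(
                    model_id=str(model.serial_num if model.serial_num else model.id + 1),
                    residue_numbers=tuple(residue_numbers),
                    residue_names=tuple(residue_names),
                    atoms=tuple(atoms),
                )
            )
    if not models:
        raise EmptyInputError(f"{path}: no models with ATOM records")
    return Ensemble(sequence_id=sequence_id or path.stem, models=tuple(models))


def read_ensemble_dir(directory: str | Path) -> list[Ensemble]:
    """Read every ``*.pdb`` file in a directory (id = file stem)."""
    files = sorted(Path(directory).glob("*.pdb"), key=lambda f: (len(f.stem), f.stem))
    return [read_pdb_ensemble(f) for f in files]


# ---------------------------------------------------------------------------
# Superposition

def match_atoms(
    a: Structure3D, b: Structure3D, atom_set=DEFAULT_ATOM_SET
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair coordinates by (residue index, atom name) restricted to atom_set.

    Atoms missing on either side are dropped symmetrically.  Returns two
    (n, 3) arrays in identical order plus the pairing size; fewer than 3
    pairs raises :class:`InsufficientAtomsError`.
    """
    if a.n_residues != b.n_residues:
        raise FormatError(
            f"residue counts differ: {a.n_residues} vs {b.n_residues}"
        )
    xs, ys = [], []
    for ra, rb in zip(a.atoms, b.atoms):
        for name in atom_set:
            if name in ra and name in rb:
                xs.append(ra[name])
                ys.append(rb[name])
    n = len(xs)
    if n < 3:
        raise InsufficientAtomsError(
            f"only {n} paired atoms; rotation is under-determined"
        )
    return np.array(xs), np.array(ys), n


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD after optimal superposition (Kabsch algorithm).

    Both point sets are centered; the optimal rotation comes from the SVD of
    the covariance matrix with a determinant correction that excludes
    reflections (so a mirror image of a chiral set keeps a positive RMSD).
    Symmetric in its arguments; degenerate (collinear/coincident) sets are
    still well-defined through the SVD.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected matching (n, 3) arrays, got {X.shape}, {Y.shape}")
    if X.shape[0] < 3:
        raise InsufficientAtomsError("need at least 3 points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite coordinates in input")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt  # proper rotation mapping Yc onto Xc
    # residuals are computed explicitly: the closed-form trace expression
    # cancels catastrophically when the optimal RMSD is near zero
    diff = Yc @ R.T - Xc
    return float(np.sqrt((diff**2).sum() / X.shape[0]))


def rmsd_between(
    a: Structure3D, b: Structure3D, atom_set=DEFAULT_ATOM_SET
) -> float:
    X, Y, _ = match_atoms(a, b, atom_set)
    return kabsch_rmsd(X, Y)


# ---------------------------------------------------------------------------
# Ensemble statistics and cross-ensemble clustering

def rmsd_matrix(
    structures: list[tuple[str, Structure3D]], atom_set=DEFAULT_ATOM_SET
) -> DistanceMatrix:
    """All-against-all Kabsch RMSD over labeled structures."""
    labels = tuple(lab for lab, _ in structures)
    n = len(structures)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = rmsd_between(structures[i][1], structures[j][1], atom_set)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def ensemble_stats(e: Ensemble, atom_set=DEFAULT_ATOM_SET) -> EnsembleStats:
    """Pairwise RMSD statistics within one ensemble, plus its centroid model.

    Statistics run over the unordered model pairs; the centroid is the
    medoid of the RMSD matrix, with average/sd-to-centroid computed over the
    non-centroid models.  A single-model ensemble reports all zeros and is
    its own centroid.
    """
    if e.n_models == 1:
        only = e.models[0].model_id
        return EnsembleStats(e.sequence_id, 1, 0.0, 0.0, 0.0, 0.0, only, 0.0, 0.0)
    D = rmsd_matrix([(m.model_id, m) for m in e.models], atom_set)
    iu = np.triu_indices(D.n, k=1)
    pair_vals = D.values[iu]
    cid, avg_c, sd_c = centroid(D, D.labels)
    return EnsembleStats(
        sequence_id=e.sequence_id,
        n_models=e.n_models,
        avg_rmsd=float(pair_vals.mean()),
        sd=float(pair_vals.std()),
        min_rmsd=float(pair_vals.min()),
        max_rmsd=float(pair_vals.max()),
        centroid_id=cid,
        avg_to_centroid=avg_c,
        sd_to_centroid=sd_c,
    )


def centroid_model(e: Ensemble, atom_set=DEFAULT_ATOM_SET) -> Structure3D:
    """The ensemble's centroid (medoid) model."""
    stats = ensemble_stats(e, atom_set)
    for m in e.models:
        if m.model_id == stats.centroid_id:
            return m
    raise KeyError(stats.centroid_id)  # pragma: no cover


def cross_ensemble_cluster(
    centroids: list[tuple[str, Structure3D]],
    params: ClusterParams | None = None,
    atom_set=DEFAULT_ATOM_SET,
) -> tuple[ClusterResult, list[ClusterStats], DistanceMatrix]:
    """Globally compare ensemble centroids and cluster them by single linkage.

    Returns the partition, per-cluster RMSD statistics (average/sd/min/max,
    cluster centroid, average distance to it), and the underlying RMSD
    matrix.  Singleton clusters report zero statistics.
    """
    if len(centroids) < 2:
        raise EmptyInputError("need at least 2 centroids to compare")
    params = params or ClusterParams()
    D = rmsd_matrix(centroids, atom_set)
    result = single_linkage(D, params)
    stats: list[ClusterStats] = []
    for cid, members in result.members.items():
        if len(members) == 1:
            stats.append(
                ClusterStats(cid, members, 1, 0.0, 0.0, 0.0, 0.0, members[0], 0.0, 0.0)
            )
            continue
        sub = D.submatrix(members)
        iu = np.triu_indices(sub.n, k=1)
        vals = sub.values[iu]
        c, avg_c, sd_c = centroid(D, members)
        stats.append(
            ClusterStats(
                cluster_id=cid,
                members=members,
                n_members=len(members),
                avg_rmsd=float(vals.mean()),
                sd=float(vals.std()),
                min_rmsd=float(vals.min()),
                max_rmsd=float(vals.max()),
                centroid_id=c,
                avg_to_centroid=avg_c,
                sd_to_centroid=sd_c,
            )
        )
    return result, stats, D


# ---------------------------------------------------------------------------
# I/O

def write_ensemble_stats(
    stats: list[EnsembleStats], path: str | Path, header_lines=None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(
            "sequence_id\tn_models\tavg_rmsd\tsd\tmin_rmsd\tmax_rmsd\t"
            "centroid_id\tavg_to_centroid\tsd_to_centroid\n"
        )
        for s in stats:
            fh.write(
                f"{s.sequence_id}\t{s.n_models}\t{s.avg_rmsd:.4f}\t{s.sd:.4f}\t"
                f"{s.min_rmsd:.4f}\t{s.max_rmsd:.4f}\t{s.centroid_id}\t"
                f"{s.avg_to_centroid:.4f}\t{s.sd_to_centroid:.4f}\n"
            )


def write_cluster_stats(
    stats: list[ClusterStats], path: str | Path, header_lines=None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(
            "cluster_id\tn_members\tmembers\tavg_rmsd\tsd\tmin_rmsd\tmax_rmsd\t"
            "centroid_id\tavg_to_centroid\tsd_to_centroid\n"
        )
        for s in stats:
            fh.write(
                f"{s.cluster_id}\t{s.n_members}\t{','.join(s.members)}\t"
                f"{s.avg_rmsd:.4f}\t{s.sd:.4f}\t{s.min_rmsd:.4f}\t{s.max_rmsd:.4f}\t"
                f"{s.centroid_id}\t{s.avg_to_centroid:.4f}\t{s.sd_to_centroid:.4f}\n"
            )
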