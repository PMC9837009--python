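"""Synthetic inputs with planted ground truth for every pipeline stage.

The real workflow consumes external resources — an RBP motif database, a
homology annotation service, trained 2D predictors, and a 3D prediction
server.  This module generates offline stand-ins for all of them, each with
a machine-readable truth manifest, so the full pipeline is testable without
network access:

* motif tables in the ATtRACT column dialect, with a planted-hit manifest
  computed by an independent naive scanner at generation time;
* annotation tables mapping every gene to a homolog group of chosen size;
* Vienna dot-bracket sets emulating the study condition "most variants stay
  unfolded, two fold into mutually similar hairpins";
* multi-model PDB ensembles built from an ideal helical backbone trace
  (3 atoms per residue: P, C4', C1', matching the comparison atom set), with
  Gaussian coordinate jitter σ within each ensemble and a rigid local
  displacement of magnitude δ applied to the EXO-motif window of ensembles
  in a planted "divergent" group.  Divergence is a rigid sub-window shift —
  controlled ground truth, not RNA physics.

Generation is a pure function of (spec, seed): reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import fold2d, seqvariants
from .errors import SpecError
from .seqvariants import MIR1246, MotifWindow, RnaSequence

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Default study-condition ids: native "0" plus variants "1".."12".
STUDY_IDS = tuple(str(i) for i in range(13))
#: Ids of the two hairpin-forming / structurally divergent variants.
DIVERGENT_IDS = ("6", "7")


def study_sequences() -> dict[str, str]:
    """Native miR-1246 plus its 12 motif-window variants, keyed "0".."12".

    Variant ids here follow the deterministic enumeration order of
    :func:`exoscreen.seqvariants.enumerate_motif_variants`; they coincide
    with the published numbering only for the pinned aliases.
    """
    native = RnaSequence("0", MIR1246)
    window = MotifWindow(12, 15, "GGAG")
    out = {"0": native.residues}
    for v in seqvariants.enumerate_motif_variants(native, window):
        out[str(v.variant_id)] = v.sequence.residues
    return out


# ---------------------------------------------------------------------------
# Specs

@dataclass(frozen=True)
class MotifTableSpec:
    n_motifs: int = 30
    length_range: tuple[int, int] = (4, 7)
    #: Fraction of motifs built around a GGAG/GCAG-like core.
    core_fraction: float = 0.4
    cores: tuple[str, ...] = ("GGAG", "GCAG")
    organisms: tuple[str, ...] = ("Homo_sapiens",)
    #: Sequence against which planted hits are manifested.
    target_sequence: str = MIR1246


@dataclass(frozen=True)
class AnnotationSpec:
    #: Cyclic homolog-group sizes; genes are assigned in id order.
    group_sizes: tuple[int, ...] = (2, 1, 3)


@dataclass(frozen=True)
class HairpinGeom:
    sequence_id: str
    stem: int
    loop: int
    offset: int  # 5' flank length (nt before the first paired base)


@dataclass(frozen=True)
class DotBracketSpec:
    """Emulates the study's 2D outcome: 11 unfolded records + 2 hairpins.

    The first hairpin mirrors the reported geometry (3-bp stem, 9-nt terminal
    loop); the second is a 4-bp stem / 7-nt loop at the same offset, which
    keeps the two hairpins within 2 edits of each other while every hairpin
    stays >= 6 edits from the unfolded records.
    """

    length: int = 19
    unfolded_ids: tuple[str, ...] = tuple(
        str(i) for i in (0, 1, 2, 3, 4, 5, 8, 9, 10, 11, 12)
    )
    hairpins: tuple[HairpinGeom, ...] = (
        HairpinGeom("6", stem=3, loop=9, offset=3),
        HairpinGeom("7", stem=4, loop=7, offset=3),
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted 3D ensembles: 13 ensembles, {11 background, 2 divergent}.

    Model counts follow the study condition (10 models for the two divergent
    variants, 2 for the rest); σ is the per-coordinate Gaussian jitter and δ
    the rigid displacement applied to the motif-window residues of divergent
    ensembles.
    """

    n_residues: int = 19
    models_per_ensemble: dict[str, int] = field(
        default_factory=lambda: {
            sid: (10 if sid in DIVERGENT_IDS else 2) for sid in STUDY_IDS
        }
    )
    sigma: float = 0.1
    delta: float = 3.0
    window: tuple[int, int] = (12, 15)  # 1-based inclusive residues displaced
    #: Planted partition: group name -> member ids (must cover all ensembles).
    partition: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "background": tuple(s for s in STUDY_IDS if s not in DIVERGENT_IDS),
            "divergent": DIVERGENT_IDS,
        }
    )
    sequences: dict[str, str] = field(default_factory=study_sequences)

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.delta < 0:
            raise SpecError("sigma and delta must be >= 0")
        seen: set[str] = set()
        for ids in self.partition.values():
            for sid in ids:
                if sid in seen:
                    raise SpecError(f"id {sid!r} in more than one planted group")
                seen.add(sid)
        if seen != set(self.models_per_ensemble):
            raise SpecError("planted partition must cover all ensembles exactly once")


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    motif_table: MotifTableSpec = field(default_factory=MotifTableSpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    dotbracket: DotBracketSpec = field(default_factory=DotBracketSpec)
    ensembles: EnsembleSpec = field(default_factory=EnsembleSpec)


# ---------------------------------------------------------------------------
# Independent naive scanner (ground truth for motifscan tests)

_NAIVE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "R": "AG", "Y": "CU", "S": "CG",
    "W": "AU", "K": "GU", "M": "AC", "B": "CGU", "D": "AGU", "H": "ACU",
    "V": "ACG", "N": "ACGU",
}


def _naive_hits(pattern: str, seq: str) -> list[int]:
    """1-based start positions; deliberately independent of motifscan.scan."""
    out = []
    for start in range(len(seq) - len(pattern) + 1):
        ok = True
        for k, p in enumerate(pattern):
            if seq[start + k] not in _NAIVE_IUPAC[p]:
                ok = False
                break
        if ok:
            out.append(start + 1)
    return out


# ---------------------------------------------------------------------------
# Generators

def make_motif_table(
    spec: MotifTableSpec, seed: int, table_path: str | Path,
    manifest_path: str | Path | None = None,
) -> dict:
    """Write an ATtRACT-dialect motif TSV plus an expected-hit manifest.

    A ``core_fraction`` share of motifs embeds one of the EXO-motif cores in
    random flanks (guaranteeing hits on the target sequence's motif region);
    the rest are random patterns with occasional degenerate IUPAC codes.
    The manifest lists every hit of every generated motif on the target
    sequence, found by a naive position-by-position scanner at generation
    time, so downstream scanner tests have independent ground truth.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    degenerate = "RYSWKMN"
    rows = []
    n_core = round(spec.n_motifs * spec.core_fraction)
    for i in range(spec.n_motifs):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if i < n_core:
            # embed the core with the target's own flanking context so the
            # planted motif is guaranteed to hit the target sequence
            core = spec.cores[i % len(spec.cores)]
            extra = max(0, length - len(core))
            occ = spec.target_sequence.find(core)
            if occ >= 0:
                left = int(rng.integers(0, min(extra, occ) + 1))
                right = min(
                    extra - left,
                    len(spec.target_sequence) - occ - len(core),
                )
                start = occ - left
                pattern = spec.target_sequence[start : occ + len(core) + right]
            else:
                left = int(rng.integers(0, extra + 1))
                pattern = (
                    "".join(rng.choice(list(bases), left))
                    + core
                    + "".join(rng.choice(list(bases), extra - left))
                )
        else:
            pattern = "".join(rng.choice(list(bases), length))
            if rng.random() < 0.3:  # sprinkle one degenerate position
                pos = int(rng.integers(0, length))
                pattern = pattern[:pos] + str(rng.choice(list(degenerate))) + pattern[pos + 1 :]
        organism = spec.organisms[i % len(spec.organisms)]
        rows.append(
            {
                "Gene_name": f"RBP{i + 1}",
                "Gene_id": f"GENE{i + 1:04d}",
                "Organism": organism,
                "Motif": pattern,
                "Len": len(pattern),
                "Matrix_id": f"M{i + 1:03d}",
                "Score": f"{rng.uniform(0.5, 1.0):.3f}",
            }
        )
    with open(table_path, "w") as fh:
        fh.write("Gene_name\tGene_id\tOrganism\tMotif\tLen\tMatrix_id\tScore\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in (
                "Gene_name", "Gene_id", "Organism", "Motif", "Len", "Matrix_id", "Score"
            )) + "\n")

    manifest = {
        "target_sequence": spec.target_sequence,
        "hits": [
            {
                "motif_id": r["Matrix_id"],
                "gene_id": r["Gene_id"],
                "pattern": r["Motif"],
                "start": start,
                "end": start + len(r["Motif"]) - 1,
            }
            for r in rows
            for start in _naive_hits(r["Motif"], spec.target_sequence)
        ],
        "organism_counts": {
            org: sum(1 for r in rows if r["Organism"] == org)
            for org in spec.organisms
        },
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    return manifest


def make_annotation_table(
    spec: AnnotationSpec, gene_ids: list[str], path: str | Path
) -> dict[str, str]:
    """Map every gene id to a homolog group; group sizes cycle through spec.

    Returns the gene -> group mapping that was written.
    """
    mapping: dict[str, str] = {}
    sizes = iter_sizes = list(spec.group_sizes) or [1]
    gi = 0
    group_no = 0
    while gi < len(gene_ids):
        size = iter_sizes[group_no % len(sizes)]
        group_no += 1
        group_id = f"HG{group_no:03d}"
        for gene in gene_ids[gi : gi + size]:
            mapping[gene] = group_id
        gi += size
    with open(path, "w") as fh:
        fh.write("gene_id\thomolog_group_id\ttranscript_id\tprotein_id\tgo_terms\n")
        for i, gene in enumerate(gene_ids, start=1):
            fh.write(
                f"{gene}\t{mapping[gene]}\tTX{i:04d}\tPR{i:04d}\tGO:0003723\n"
            )
    return mapping


def _hairpin_record(
    geom: HairpinGeom, length: int, rng: np.random.Generator
) -> fold2d.SecondaryStructure:
    if geom.offset + 2 * geom.stem + geom.loop > length:
        raise SpecError(
            f"hairpin {geom.sequence_id!r}: offset {geom.offset} + 2*stem "
            f"{geom.stem} + loop {geom.loop} exceeds length {length}"
        )
    if geom.loop < fold2d.MIN_LOOP:
        raise SpecError(f"hairpin {geom.sequence_id!r}: loop < {fold2d.MIN_LOOP} nt")
    db = (
        "." * geom.offset
        + "(" * geom.stem
        + "." * geom.loop
        + ")" * geom.stem
        + "." * (length - geom.offset - 2 * geom.stem - geom.loop)
    )
    arm = "".join(rng.choice(list("ACGU"), geom.stem))
    seq_chars = list("".join(rng.choice(list("ACGU"), length)))
    for t in range(geom.stem):
        seq_chars[geom.offset + t] = arm[t]
        seq_chars[geom.offset + 2 * geom.stem + geom.loop - 1 - t] = _WC[arm[t]]
    sequence = "".join(seq_chars)
    i = geom.offset + 1
    j = geom.offset + 2 * geom.stem + geom.loop
    energy = round(fold2d.hairpin_energy(sequence, i, j, geom.stem, fold2d.EnergyParams()), 4)
    return fold2d.SecondaryStructure.from_dot_bracket(
        geom.sequence_id, db, sequence=sequence, energy=energy
    )


def make_dotbracket_set(
    spec: DotBracketSpec, seed: int, path: str | Path | None = None
) -> list[fold2d.SecondaryStructure]:
    """Generate the unfolded + hairpin dot-bracket records, optionally to file.

    Unfolded records are all-dot structures at 0.0 kcal/mol over random
    sequences; hairpin records have the requested stem/loop/offset geometry
    with Watson-Crick-complementary stem arms, scored by the packaged energy
    table.  Records are ordered by id (numeric where possible).
    """
    rng = np.random.default_rng(seed)
    structures: list[fold2d.SecondaryStructure] = []
    for sid in spec.unfolded_ids:
        sequence = "".join(rng.choice(list("ACGU"), spec.length))
        structures.append(
            fold2d.SecondaryStructure.from_dot_bracket(
                sid, "." * spec.length, sequence=sequence, energy=0.0
            )
        )
    for geom in spec.hairpins:
        structures.append(_hairpin_record(geom, spec.length, rng))

    def id_key(s: fold2d.SecondaryStructure):
        return (0, int(s.sequence_id)) if s.sequence_id.isdigit() else (1, s.sequence_id)

    structures.sort(key=id_key)
    if path is not None:
        fold2d.write_vienna(structures, path)
    return structures


# -- 3D ensembles -----------------------------------------------------------

_HELIX_RISE = 2.81  # Å per residue
_HELIX_TWIST = math.radians(32.7)
_ATOM_GEOM = {  # atom name -> (radius Å, angular offset rad)
    "P": (9.0, 0.00),
    "C4'": (8.2, 0.14),
    "C1'": (6.8, 0.28),
}


def ideal_backbone(n_residues: int) -> list[dict[str, np.ndarray]]:
    """Ideal helical coarse backbone trace; the 5'-terminal residue lacks P."""
    residues = []
    for k in range(n_residues):
        theta = k * _HELIX_TWIST
        res: dict[str, np.ndarray] = {}
        for name, (radius, offset) in _ATOM_GEOM.items():
            if name == "P" and k == 0:
                continue
            res[name] = np.array(
                [
                    radius * math.cos(theta + offset),
                    radius * math.sin(theta + offset),
                    k * _HELIX_RISE,
                ]
            )
        residues.append(res)
    return residues


def _write_pdb(path: Path, sequence: str, models: list[list[dict[str, np.ndarray]]]) -> None:
    with open(path, "w") as fh:
        for m_idx, model in enumerate(models, start=1):
            fh.write(f"MODEL     {m_idx:4d}\n")
            serial = 1
            for r_idx, res in enumerate(model, start=1):
                resname = sequence[r_idx - 1]
                for name in ("P", "C4'", "C1'"):
                    if name not in res:
                        continue
                    x, y, z = res[name]
                    name_field = name if len(name) == 4 else f" {name:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name_field} {resname:>3s} A"
                        f"{r_idx:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _align_rmsd(a: list[dict[str, np.ndarray]], b: list[dict[str, np.ndarray]]) -> float:
    """Superposition RMSD via scipy's align_vectors (generator-side check)."""
    X = np.array([res[n] for res in a for n in ("P", "C4'", "C1'") if n in res])
    Y = np.array([res[n] for res in b for n in ("P", "C4'", "C1'") if n in res])
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    _, rssd = Rotation.align_vectors(Xc, Yc)
    return float(rssd / math.sqrt(len(X)))


def make_structure_ensembles(
    spec: EnsembleSpec, seed: int, outdir: str | Path,
    manifest_path: str | Path | None = None,
) -> dict:
    """Write one multi-model PDB per ensemble plus a planted-truth manifest.

    Every model is the ideal backbone plus iid Gaussian jitter (σ per
    coordinate).  All ensembles in a planted group other than "background"
    share one rigid displacement of the motif-window residues: a
    group-specific random unit direction scaled to δ.  The manifest records
    the planted partition and the generator's own superposition RMSD between
    every pair of ensemble mean conformations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = ideal_backbone(spec.n_residues)
    lo, hi = spec.window
    window_idx = set(range(lo - 1, hi))

    # one displacement direction per non-background group, drawn first for
    # a stable stream layout
    shifts: dict[str, np.ndarray] = {}
    for group in sorted(spec.partition):
        if group == "background":
            continue
        v = rng.normal(size=3)
        shifts[group] = spec.delta * v / np.linalg.norm(v)

    group_of = {
        sid: group for group, ids in spec.partition.items() for sid in ids
    }
    means: dict[str, list[dict[str, np.ndarray]]] = {}
    files: dict[str, str] = {}
    ordered_ids = sorted(spec.models_per_ensemble, key=lambda s: (len(s), s))
    for sid in ordered_ids:
        shift = shifts.get(group_of[sid], np.zeros(3))
        mean = [
            {
                name: xyz + (shift if k in window_idx else 0.0)
                for name, xyz in res.items()
            }
            for k, res in enumerate(base)
        ]
        means[sid] = mean
        models = []
        for _ in range(spec.models_per_ensemble[sid]):
            models.append(
                [
                    {
                        name: xyz + rng.normal(scale=spec.sigma, size=3)
                        for name, xyz in res.items()
                    }
                    for res in mean
                ]
            )
        sequence = spec.sequences.get(sid, "A" * spec.n_residues)
        path = outdir / f"{sid}.pdb"
        _write_pdb(path, sequence, models)
        files[sid] = path.name

    pair_rmsd = {
        f"{a}|{b}": round(_align_rmsd(means[a], means[b]), 6)
        for i, a in enumerate(ordered_ids)
        for b in ordered_ids[i + 1 :]
    }
    manifest = {
        "partition": {g: list(ids) for g, ids in spec.partition.items()},
        "sigma": spec.sigma,
        "delta": spec.delta,
        "window": list(spec.window),
        "files": files,
        "mean_pair_rmsd": pair_rmsd,
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_bundle(spec: SynthSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input class into one directory.

    Returns paths keyed: motif_table, motif_manifest, annotation, vienna,
    pdb_dir, ensemble_manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "motif_table": outdir / "motifs.tsv",
        "motif_manifest": outdir / "motifs_manifest.json",
        "annotation": outdir / "annotation.tsv",
        "vienna": outdir / "structures.vienna",
        "pdb_dir": outdir / "ensembles",
        "ensemble_manifest": outdir / "ensembles_manifest.json",
    }
    make_motif_table(
        spec.motif_table, spec.seed, paths["motif_table"], paths["motif_manifest"]
    )
    gene_ids = [f"GENE{i + 1:04d}" for i in range(spec.motif_table.n_motifs)]
    make_annotation_table(spec.annotation, gene_ids, paths["annotation"])
    make_dotbracket_set(spec.dotbracket, spec.seed + 1, paths["vienna"])
    make_structure_ensembles(
        spec.ensembles, spec.seed + 2, paths["pdb_dir"], paths["ensemble_manifest"]
    )
    return paths
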