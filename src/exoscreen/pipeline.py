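"""Orchestration of the full in-silico screening workflow and candidate selection.

Stages run in the published order: variant enumeration -> RBP motif
scanning/summarizing/ranking -> secondary-structure prediction or ingestion
-> 2D clustering (Levenshtein + DBSCAN) -> per-ensemble 3D statistics and
cross-ensemble clustering (Kabsch RMSD + single linkage, when PDB ensembles
are supplied) -> rule-based selection of variants for wet-lab validation.

Selection encodes the published reasoning as explicit rules:

* rule 1 (``structure-divergent``): a variant that does not share a cluster
  with the native sequence in any available clustering (2D and 3D);
* rule 2 (``rbp-count-extreme``): among the remaining variants, a configured
  number of ids with the lowest and highest distinct-RBP counts;
* rule 3 (``user-pinned``): ids the analyst always wants validated.

Every artifact is a TSV (plus one JSON report) with a provenance header
embedding the configuration hash and the RNG seed; a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import clusterlib, fold2d, motifscan, seqvariants, struct3d
from .clusterlib import ClusterParams, ClusterResult
from .errors import ExoscreenError, FormatError
from .seqvariants import MIR1246, MotifWindow, RnaSequence

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class SelectionRules:
    """Configuration of the three selection rules."""

    pins: tuple[str, ...] = ()
    n_low: int = 0
    n_high: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    native_sequence: str = MIR1246
    native_id: str = "0"
    window_start: int = 12
    window_end: int = 15
    window_pattern: str = "GGAG"
    motif_table: str | None = None
    annotation: str | None = None
    organism: str | None = None
    #: 2D engine: "vienna" (ingest ``vienna_path``), "maxpair" or "mfe".
    engine: str = "vienna"
    vienna_path: str | None = None
    eps_2d: float = 4.0
    min_samples_2d: int = 2
    cut_3d: float | str = "largest-gap"
    atom_set: tuple[str, ...] = struct3d.DEFAULT_ATOM_SET
    ensembles_dir: str | None = None
    rules: SelectionRules = field(default_factory=SelectionRules)
    outdir: str = "exoscreen_out"
    seed: int = 0

    @property
    def window(self) -> MotifWindow:
        return MotifWindow(self.window_start, self.window_end, self.window_pattern)

    def config_hash(self) -> str:
        # outdir does not affect the analysis, so it is excluded: identical
        # configurations rerun elsewhere produce byte-identical artifacts
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "rules" in raw:
            raw["rules"] = SelectionRules(
                pins=tuple(str(p) for p in raw["rules"].get("pins", ())),
                n_low=int(raw["rules"].get("n_low", 0)),
                n_high=int(raw["rules"].get("n_high", 0)),
            )
        if "atom_set" in raw:
            raw["atom_set"] = tuple(raw["atom_set"])
        return cls(**raw)


@dataclass(frozen=True)
class SelectionReport:
    """Selected ids with per-id rationale tags and supporting numbers."""

    selected: tuple[str, ...]
    rationale: dict[str, tuple[str, ...]]
    support: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "rationale": {k: list(v) for k, v in self.rationale.items()},
            "support": self.support,
        }


def select_candidates(
    fold_flags: dict[str, bool],
    cluster2d: ClusterResult | None,
    cluster3d: ClusterResult | None,
    summaries: list[motifscan.RbpSummary],
    rules: SelectionRules,
    native_id: str = "0",
) -> SelectionReport:
    """Apply the three selection rules; every selected id carries >= 1 tag.

    Rule 1 selects variants structurally divergent from the native in every
    clustering that is available (noise points count as divergent — they
    share a cluster with nothing).  Rule 2 ranks the remaining variants by
    distinct-RBP count (ties by total hits, then id) and takes the
    configured number of extremes at each end.  Rule 3 adds pinned ids
    unconditionally.
    """
    by_id = {s.sequence_id: s for s in summaries}
    all_ids = sorted(
        set(fold_flags) | set(by_id), key=lambda s: (len(s), s)
    )
    if native_id not in all_ids:
        raise ExoscreenError(f"native id {native_id!r} absent from inputs")
    clusterings = [c for c in (cluster2d, cluster3d) if c is not None]

    rationale: dict[str, set[str]] = {}

    def tag(sid: str, t: str) -> None:
        rationale.setdefault(sid, set()).add(t)

    variants = [sid for sid in all_ids if sid != native_id]
    divergent: list[str] = []
    if clusterings:
        for sid in variants:
            apart = all(
                sid in c.assignments
                and (
                    c.assignments[sid] == clusterlib.NOISE
                    or c.assignments[sid] != c.assignments.get(native_id)
                )
                for c in clusterings
            )
            if apart:
                divergent.append(sid)
                tag(sid, "structure-divergent")

    remaining = [
        sid for sid in variants if sid not in divergent and sid in by_id
    ]
    if rules.n_high > 0:
        ordered = sorted(
            remaining,
            key=lambda s: (-by_id[s].n_distinct_rbps, -by_id[s].n_motif_hits, s),
        )
        for sid in ordered[: rules.n_high]:
            tag(sid, "rbp-count-extreme")
    if rules.n_low > 0:
        ordered = sorted(
            remaining,
            key=lambda s: (by_id[s].n_distinct_rbps, by_id[s].n_motif_hits, s),
        )
        for sid in ordered[: rules.n_low]:
            tag(sid, "rbp-count-extreme")
    for sid in rules.pins:
        tag(sid, "user-pinned")

    selected = tuple(sorted(rationale, key=lambda s: (len(s), s)))
    if not selected:
        logger.warning("selection rules matched no ids (empty selection)")
    support = {}
    for sid in selected:
        support[sid] = {
            "folded": bool(fold_flags.get(sid, False)),
            "cluster_2d": cluster2d.assignments.get(sid) if cluster2d else None,
            "cluster_3d": cluster3d.assignments.get(sid) if cluster3d else None,
            "n_motif_hits": by_id[sid].n_motif_hits if sid in by_id else None,
            "n_distinct_rbps": by_id[sid].n_distinct_rbps if sid in by_id else None,
        }
    return SelectionReport(
        selected=selected,
        rationale={k: tuple(sorted(v)) for k, v in rationale.items()},
        support=support,
    )


def run_insilico(config: PipelineConfig) -> dict:
    """Run every stage in order, writing one artifact per stage.

    Stages lacking inputs (no motif table, no PDB ensembles) are skipped
    with a logged notice; a stage failure aborts with the stage name and
    cause, retaining the artifacts already written.  Returns a report dict
    with the in-memory results and artifact paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"exoscreen {__version__}",
        f"seed={config.seed} config_sha256={config.config_hash()}",
    ]
    report: dict = {"artifacts": {}, "skipped": []}

    def stage(name):
        logger.info("stage %s", name)

    # -- variants -----------------------------------------------------------
    stage("variants")
    try:
        native = seqvariants.normalize_sequence(
            config.native_sequence, id=config.native_id
        )
        window = config.window
        variants = seqvariants.enumerate_motif_variants(native, window)
    except ExoscreenError as exc:
        raise ExoscreenError(f"stage variants failed: {exc}") from exc
    path = outdir / "variants.tsv"
    seqvariants.write_variant_table(variants, path, header)
    report["artifacts"]["variants"] = str(path)
    report["variants"] = variants
    sequences = [native] + [v.sequence for v in variants]
    seqvariants.write_fasta(sequences, outdir / "sequences.fasta")
    report["artifacts"]["sequences"] = str(outdir / "sequences.fasta")

    # -- motif scanning -----------------------------------------------------
    summaries: list[motifscan.RbpSummary] = []
    if config.motif_table:
        stage("scan")
        try:
            motifs = motifscan.read_motif_table(
                config.motif_table, organism=config.organism
            )
            annotation = (
                motifscan.AnnotationTable.from_tsv(config.annotation)
                if config.annotation
                else motifscan.AnnotationTable()
            )
            hits = [h for s in sequences for h in motifscan.scan(s, motifs)]
            summaries = [
                motifscan.summarize(
                    [h for h in hits if h.sequence_id == s.id], annotation, s.id
                )
                for s in sequences
            ]
            ranked = motifscan.rank(summaries)
            freq = motifscan.motif_frequency(hits, motifs)
        except ExoscreenError as exc:
            raise ExoscreenError(f"stage scan failed: {exc}") from exc
        motifscan.write_hits(hits, outdir / "hits.tsv", header)
        motifscan.write_summaries(ranked, outdir / "summary.tsv", header)
        with open(outdir / "motif_frequency.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            freq.to_csv(fh, sep="\t", index=False)
        report["artifacts"]["hits"] = str(outdir / "hits.tsv")
        report["artifacts"]["summary"] = str(outdir / "summary.tsv")
        report["artifacts"]["motif_frequency"] = str(outdir / "motif_frequency.tsv")
        report["summaries"] = ranked
    else:
        report["skipped"].append("scan")
        logger.info("no motif table configured; scan stage skipped")

    # -- secondary structure ------------------------------------------------
    stage("fold")
    try:
        if config.engine == "vienna":
            if not config.vienna_path:
                raise FormatError("engine 'vienna' requires vienna_path")
            structures = {
                s.sequence_id: s for s in fold2d.read_vienna(config.vienna_path)
            }
        elif config.engine in ("maxpair", "mfe"):
            engine = (
                fold2d.fold_maxpair if config.engine == "maxpair" else fold2d.fold_mfe_hairpin
            )
            structures = {s.id: engine(s) for s in sequences}
        else:
            raise FormatError(f"unknown 2D engine {config.engine!r}")
    except ExoscreenError as exc:
        raise ExoscreenError(f"stage fold failed: {exc}") from exc
    rows = []
    fold_flags = {}
    for sid in sorted(structures, key=lambda s: (len(s), s)):
        s = structures[sid]
        feat = fold2d.extract_hairpin_features(s, window)
        fold_flags[sid] = s.folded
        rows.append((sid, s.folded, s.energy, feat))
    fold2d.write_structure_report(rows, outdir / "structures.tsv", header)
    fold2d.write_vienna(list(structures.values()), outdir / "structures.vienna")
    report["artifacts"]["structures"] = str(outdir / "structures.tsv")
    report["structures"] = structures
    report["fold_flags"] = fold_flags

    # -- 2D clustering ------------------------------------------------------
    stage("cluster2d")
    db = {sid: structures[sid].dot_bracket for sid in sorted(structures, key=lambda s: (len(s), s))}
    D2 = clusterlib.pairwise_distances(db)
    c2 = clusterlib.dbscan(
        D2, ClusterParams(eps=config.eps_2d, min_samples=config.min_samples_2d)
    )
    clusterlib.write_distance_matrix(D2, outdir / "distances2d.tsv", header)
    clusterlib.write_assignments(c2, outdir / "clusters2d.tsv", header)
    report["artifacts"]["clusters2d"] = str(outdir / "clusters2d.tsv")
    report["cluster2d"] = c2

    # -- 3D -----------------------------------------------------------------
    c3 = None
    if config.ensembles_dir and Path(config.ensembles_dir).is_dir():
        stage("stats3d")
        try:
            ensembles = struct3d.read_ensemble_dir(config.ensembles_dir)
            stats = [struct3d.ensemble_stats(e, config.atom_set) for e in ensembles]
            centroids = [
                (e.sequence_id, struct3d.centroid_model(e, config.atom_set))
                for e in ensembles
            ]
            c3, cstats, D3 = struct3d.cross_ensemble_cluster(
                centroids, ClusterParams(cut=config.cut_3d), config.atom_set
            )
        except ExoscreenError as exc:
            raise ExoscreenError(f"stage 3d failed: {exc}") from exc
        struct3d.write_ensemble_stats(stats, outdir / "ensemble_stats.tsv", header)
        struct3d.write_cluster_stats(cstats, outdir / "clusters3d.tsv", header)
        clusterlib.write_distance_matrix(D3, outdir / "distances3d.tsv", header)
        report["artifacts"]["ensemble_stats"] = str(outdir / "ensemble_stats.tsv")
        report["artifacts"]["clusters3d"] = str(outdir / "clusters3d.tsv")
        report["ensemble_stats"] = stats
        report["cluster3d"] = c3
    else:
        report["skipped"].append("3d")
        logger.info("no PDB ensembles configured; 3D stage skipped")

    # -- selection ----------------------------------------------------------
    stage("select")
    selection = select_candidates(
        fold_flags, c2, c3, summaries, config.rules, native_id=config.native_id
    )
    report["selection"] = selection
    summary_json = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
        },
        "skipped_stages": report["skipped"],
        "n_variants": len(variants),
        "cluster2d": {
            "n_clusters": c2.n_clusters,
            "members": {str(k): list(v) for k, v in c2.members.items()},
            "noise": list(c2.noise),
        },
        "cluster3d": (
            {
                "n_clusters": c3.n_clusters,
                "members": {str(k): list(v) for k, v in c3.members.items()},
            }
            if c3 is not None
            else None
        ),
        "selection": selection.to_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary_json, fh, indent=1, sort_keys=True)
    report["artifacts"]["report"] = str(outdir / "report.json")
    return report
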