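"""RNA-binding-protein (RBP) consensus-motif scanning and per-sequence ranking.

Databases such as ATtRACT catalogue short consensus motifs bound by RBPs,
written over the degenerate IUPAC RNA alphabet.  This module parses such
tables (the ATtRACT column dialect is accepted unmodified), scans sequences
for every motif occurrence with full overlap reporting, collapses the hit
gene set to distinct homolog groups using an offline annotation table, and
ranks sequences by binding-site content.  The per-sequence summary mirrors
the two-column convention "number of consensus motifs" (total hits) and
"number of binding RBPs" (distinct homolog groups).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .seqvariants import RnaSequence

logger = logging.getLogger(__name__)

#: IUPAC degenerate RNA codes -> the set of concrete bases each matches.
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: ATtRACT download column names -> canonical names used here.
ATTRACT_COLUMN_MAP = {
    "Matrix_id": "motif_id",
    "Motif": "pattern",
    "Gene_id": "gene_id",
    "Gene_name": "gene_name",
    "Organism": "organism",
    "Score": "score",
}

REQUIRED_COLUMNS = ("motif_id", "pattern", "gene_id", "gene_name", "organism")


@dataclass(frozen=True)
class MotifRecord:
    """One consensus motif row: an IUPAC RNA pattern tied to an RBP gene."""

    motif_id: str
    pattern: str
    gene_id: str
    gene_name: str = ""
    organism: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise FormatError(f"motif {self.motif_id!r}: empty pattern")
        for ch in self.pattern:
            if ch not in IUPAC_RNA:
                raise FormatError(
                    f"motif {self.motif_id!r}: invalid IUPAC code {ch!r}"
                )


@dataclass
class AnnotationTable:
    """Offline gene annotation: homolog grouping plus optional identifiers.

    Stands in for live homology retrieval; every gene id maps to exactly one
    homolog group.  Genes absent from the table degrade gracefully to
    singleton groups during summarization.
    """

    groups: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    go_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def group_of(self, gene_id: str) -> str | None:
        return self.groups.get(gene_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
        for col in ("gene_id", "homolog_group_id"):
            if col not in df.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        table = cls()
        for _, row in df.iterrows():
            gid = row["gene_id"]
            table.groups[gid] = row["homolog_group_id"]
            if row.get("transcript_id", ""):
                table.transcripts[gid] = row["transcript_id"]
            if row.get("protein_id", ""):
                table.proteins[gid] = row["protein_id"]
            if row.get("go_terms", ""):
                table.go_terms[gid] = tuple(row["go_terms"].split(";"))
        return table


@dataclass(frozen=True)
class ScanHit:
    """One motif occurrence on one sequence (1-based inclusive coordinates)."""

    sequence_id: str
    motif_id: str
    gene_id: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class RbpSummary:
    """Per-sequence binding-site content after homolog collapsing."""

    sequence_id: str
    n_motif_hits: int
    n_distinct_rbps: int
    gene_ids: tuple[str, ...]


def matches_iupac(pattern: str, text: str) -> bool:
    """Position-by-position IUPAC match of ``text`` against ``pattern``.

    ``text`` must be concrete RNA of the same length as the pattern; when
    ``text`` itself carries degenerate codes, a match means the base sets
    intersect at every position (used for pattern-vs-pattern conflict checks).
    """
    if len(pattern) != len(text):
        return False
    for p, t in zip(pattern, text):
        if p not in IUPAC_RNA or t not in IUPAC_RNA:
            return False
        if not (IUPAC_RNA[p] & IUPAC_RNA[t]):
            return False
    return True


def find_iupac(pattern: str, residues: str) -> list[int]:
    """All 1-based start positions where ``pattern`` matches ``residues``."""
    m = len(pattern)
    sets = [IUPAC_RNA[p] for p in pattern]
    out = []
    for i in range(len(residues) - m + 1):
        if all(residues[i + k] in sets[k] for k in range(m)):
            out.append(i + 1)
    return out


def read_motif_table(
    path: str | Path,
    organism: str | None = None,
    column_map: dict[str, str] | None = None,
) -> list[MotifRecord]:
    """Parse a tab-separated motif table into :class:`MotifRecord` rows.

    Both the canonical column names (motif_id, pattern, gene_id, gene_name,
    organism, score) and the ATtRACT download dialect (Matrix_id, Motif,
    Gene_id, Gene_name, Organism, Score) are accepted; a custom
    ``column_map`` (file column -> canonical name) overrides both.  Patterns
    written over the DNA alphabet are normalized T -> U.  Rows with invalid
    IUPAC characters are skipped, counted and logged rather than aborting the
    parse; a missing required column aborts with :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    mapping = dict(ATTRACT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"motif table {path}: missing required column {col!r}")
    if organism is not None:
        df = df[df["organism"] == organism]

    records: list[MotifRecord] = []
    n_skipped = 0
    for line_no, row in df.iterrows():
        pattern = str(row["pattern"]).strip().upper().replace("T", "U")
        score = None
        if "score" in df.columns and pd.notna(row.get("score")):
            try:
                score = float(str(row["score"]).rstrip("*"))
            except ValueError:
                score = None
        try:
            records.append(
                MotifRecord(
                    motif_id=str(row["motif_id"]),
                    pattern=pattern,
                    gene_id=str(row["gene_id"]),
                    gene_name=str(row.get("gene_name", "") or ""),
                    organism=str(row.get("organism", "") or ""),
                    score=score,
                )
            )
        except FormatError as exc:
            n_skipped += 1
            logger.warning("motif table %s row %s skipped: %s", path, line_no, exc)
    if n_skipped:
        logger.warning("motif table %s: %d rows skipped", path, n_skipped)
    return records


def scan(seq: RnaSequence, motifs: list[MotifRecord]) -> list[ScanHit]:
    """Scan one sequence against a motif list with full overlap reporting.

    Every position where a pattern matches under IUPAC semantics produces one
    hit per (motif_id, gene_id) row; overlapping and self-overlapping matches
    are all reported.  Only the sense strand is scanned (mature miRNAs are
    single-stranded).  Hits are sorted by (start, motif_id).
    """
    hits: list[ScanHit] = []
    for motif in motifs:
        for start in find_iupac(motif.pattern, seq.residues):
            end = start + len(motif.pattern) - 1
            hits.append(
                ScanHit(
                    sequence_id=seq.id,
                    motif_id=motif.motif_id,
                    gene_id=motif.gene_id,
                    start=start,
                    end=end,
                    matched=seq.residues[start - 1 : end],
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_id, h.gene_id))
    return hits


def summarize(
    hits: list[ScanHit], annotation: AnnotationTable, sequence_id: str
) -> RbpSummary:
    """Collapse hits for one sequence into binding-site counts.

    ``n_motif_hits`` counts every hit; ``n_distinct_rbps`` counts distinct
    homolog groups among the hit genes.  Genes missing from the annotation
    table are logged and counted as their own singleton groups, so a sparse
    annotation degrades counts gracefully instead of failing.
    """
    own = [h for h in hits if h.sequence_id == sequence_id]
    genes = sorted({h.gene_id for h in own})
    group_ids = set()
    for gid in genes:
        grp = annotation.group_of(gid)
        if grp is None:
            logger.debug("gene %s not in annotation; treated as singleton group", gid)
            grp = f"singleton:{gid}"
        group_ids.add(grp)
    return RbpSummary(
        sequence_id=sequence_id,
        n_motif_hits=len(own),
        n_distinct_rbps=len(group_ids),
        gene_ids=tuple(genes),
    )


def rank(summaries: list[RbpSummary]) -> list[RbpSummary]:
    """Order sequences by binding-site content.

    Descending total hits, ties broken by descending distinct-RBP count, then
    ascending sequence id; stable and total.
    """
    return sorted(
        summaries,
        key=lambda s: (-s.n_motif_hits, -s.n_distinct_rbps, s.sequence_id),
    )


def motif_frequency(
    hits: list[ScanHit], motifs: list[MotifRecord]
) -> pd.DataFrame:
    """Tally the most commonly encountered motif patterns across all hits.

    Returns a DataFrame with columns ``pattern`` and ``count``, sorted by
    descending count then lexicographic pattern.  Identical patterns shared
    by several motif rows are pooled by their literal pattern string.
    """
    pattern_of = {m.motif_id: m.pattern for m in motifs}
    counts = Counter(pattern_of[h.motif_id] for h in hits if h.motif_id in pattern_of)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["pattern", "count"])


# ---------------------------------------------------------------------------
# I/O

def write_hits(hits: list[ScanHit], path: str | Path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("sequence_id\tmotif_id\tgene_id\tstart\tend\tmatched\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.motif_id}\t{h.gene_id}\t{h.start}\t{h.end}\t{h.matched}\n"
            )


def write_summaries(
    summaries: list[RbpSummary], path: str | Path, header_lines=None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("sequence_id\tn_motif_hits\tn_distinct_rbps\tgene_ids\n")
        for s in summaries:
            fh.write(
                f"{s.sequence_id}\t{s.n_motif_hits}\t{s.n_distinct_rbps}\t"
                f"{';'.join(s.gene_ids)}\n"
            )
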