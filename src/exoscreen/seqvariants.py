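"""RNA sequences, EXO-motif windows, and single-substitution variant enumeration.

The screening workflow starts from a mature miRNA (the canonical example is the
19-nt miR-1246 mimic, 5'-AAUGGAUUUUUGGAGCAGG-3') and asks how every possible
single-nucleotide substitution inside an exosome-sorting motif ("EXO-motif",
e.g. GGAG at positions 12-15) changes the molecule's protein-binding and
structural properties.  This module owns the sequence containers, the variant
enumeration, coordinate helpers, and the constrained random generator used to
design control probes that carry one EXO-motif and no other.

Coordinates in every public signature are 1-based inclusive, matching the
convention of the biological literature; internal arithmetic is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, GenerationError, InvalidAlphabetError

RNA_ALPHABET = "ACGU"
#: Fixed alternative-base iteration order used by variant numbering.
BASE_ORDER = "ACGU"

#: The native miR-1246 mimic sequence (mature, sense strand, 5'->3').
MIR1246 = "AAUGGAUUUUUGGAGCAGG"
#: The two overlapping EXO-motifs present in miR-1246 (5'-GGAGCAG-3').
EXO_MOTIFS = ("GGAG", "GCAG")

#: Published variant numbering is only pinned for three variants (A14C, G15C,
#: G15U, called 5, 6 and 7 in the source study).  Keys are internal variant ids
#: from :func:`enumerate_motif_variants` under the default scheme, values are
#: the published ids.
PAPER_VARIANT_ALIASES = {7: 5, 11: 6, 12: 7}


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidAlphabetError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in RNA_ALPHABET:
                raise InvalidAlphabetError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise CoordinateError(
                f"position {position} outside sequence {self.id!r} (length {self.length})"
            )
        return self.residues[position - 1]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class MotifWindow:
    """A 1-based inclusive window [start, end] carrying a literal RNA pattern."""

    start: int
    end: int
    pattern: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise CoordinateError(f"invalid window [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.pattern):
            raise CoordinateError(
                f"window [{self.start}, {self.end}] does not span "
                f"pattern {self.pattern!r} ({len(self.pattern)} nt)"
            )
        for ch in self.pattern:
            if ch not in RNA_ALPHABET:
                raise InvalidAlphabetError(f"window pattern contains {ch!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        """1-based positions covered by the window."""
        return range(self.start, self.end + 1)

    def validate_against(self, seq: RnaSequence) -> None:
        """Check the window fits the sequence and matches its substring."""
        if self.end > seq.length:
            raise CoordinateError(
                f"window [{self.start}, {self.end}] outside sequence "
                f"{seq.id!r} (length {seq.length})"
            )
        found = seq.residues[self.start - 1 : self.end]
        if found != self.pattern:
            raise CoordinateError(
                f"sequence {seq.id!r} carries {found!r} at "
                f"[{self.start}, {self.end}], expected {self.pattern!r}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide substitution variant of the native sequence."""

    variant_id: int
    position: int  # 1-based, inside the motif window
    ref_base: str
    alt_base: str
    sequence: RnaSequence

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")

    @property
    def label(self) -> str:
        """Compact HGVS-like label, e.g. ``G15U``."""
        return f"{self.ref_base}{self.position}{self.alt_base}"


def normalize_sequence(raw: str, id: str = "seq") -> RnaSequence:
    """Normalize raw user input into a validated :class:`RnaSequence`.

    Lowercase is uppercased, the DNA alphabet is mapped to RNA (T -> U), and
    whitespace (including internal line breaks from pasted FASTA bodies) is
    removed.  Any other character raises :class:`InvalidAlphabetError` naming
    the offending character and its 1-based position in the raw input.
    """
    out = []
    seen_any = False
    for pos, ch in enumerate(raw, start=1):
        if ch.isspace():
            continue
        up = ch.upper()
        if up == "T":
            up = "U"
        if up not in RNA_ALPHABET:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} at position {pos} in input for {id!r}"
            )
        out.append(up)
        seen_any = True
    if not seen_any:
        raise InvalidAlphabetError(f"input for {id!r} is empty after whitespace removal")
    return RnaSequence(id=id, residues="".join(out))


def enumerate_motif_variants(
    native: RnaSequence, window: MotifWindow
) -> list[VariantRecord]:
    """Enumerate every single-base substitution inside the motif window.

    Exactly ``3 * window.length`` variants are produced.  Numbering is
    deterministic: window positions are visited 5'->3' and, at each position,
    alternative bases in the fixed order A < C < G < U (skipping the native
    base); ids run from 1.  The native sequence itself (conventionally id 0)
    is not included.  :data:`PAPER_VARIANT_ALIASES` maps the ids of this
    scheme onto the published numbering where that numbering is known.
    """
    window.validate_against(native)
    variants: list[VariantRecord] = []
    vid = 1
    for position in window.positions:
        ref = native.base(position)
        for alt in BASE_ORDER:
            if alt == ref:
                continue
            residues = (
                native.residues[: position - 1] + alt + native.residues[position:]
            )
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    position=position,
                    ref_base=ref,
                    alt_base=alt,
                    sequence=RnaSequence(id=str(vid), residues=residues),
                )
            )
            vid += 1
    return variants


def pos_from_3prime(length: int, k: int) -> int:
    """Convert a 1-based index from the 3' end to a 1-based 5' position.

    ``pos_from_3prime(19, 6) == 14``: the sixth base from the 3' end of a
    19-nt sequence is base 14 from the 5' end.
    """
    if not 1 <= k <= length:
        raise CoordinateError(f"3'-index {k} out of range for length {length}")
    return length - k + 1


def generate_constrained_sequence(
    length: int,
    placed: MotifWindow,
    excluded: list[str],
    seed: int | np.random.Generator | None = None,
    id: str = "random",
    max_attempts: int = 10_000,
) -> RnaSequence:
    """Generate a random sequence carrying one placed motif and no excluded motif.

    Control probes for EXO-motif studies are random sequences of the native
    length carrying exactly one EXO-motif at its native location and no
    occurrence of any other EXO-motif anywhere.  Rejection sampling: random
    bases are drawn uniformly, the placed pattern is overlaid at its window,
    and the candidate is accepted when an IUPAC scan against ``excluded``
    yields zero hits.

    ``excluded`` patterns may use IUPAC degenerate codes.  The placed pattern
    itself must not match any excluded pattern (precondition).  Reproducible
    for a fixed integer ``seed``; raises :class:`GenerationError` after
    ``max_attempts`` rejections.
    """
    from . import motifscan  # local import: motifscan depends on this module

    if placed.end > length:
        raise CoordinateError(
            f"window [{placed.start}, {placed.end}] does not fit length {length}"
        )
    for pat in excluded:
        if motifscan.matches_iupac(pat, placed.pattern) or motifscan.matches_iupac(
            placed.pattern, pat
        ):
            raise ValueError(
                f"placed pattern {placed.pattern!r} conflicts with excluded {pat!r}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list(RNA_ALPHABET))
    for _ in range(max_attempts):
        chars = rng.choice(bases, size=length)
        chars[placed.start - 1 : placed.end] = list(placed.pattern)
        candidate = RnaSequence(id=id, residues="".join(chars))
        if not any(
            motifscan.find_iupac(pat, candidate.residues) for pat in excluded
        ):
            return candidate
    raise GenerationError(
        f"no sequence satisfying the exclusion list found in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file, normalizing each record."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(normalize_sequence(str(rec.seq), id=rec.id))
    return records


def write_fasta(sequences: list[RnaSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_variant_table(
    variants: list[VariantRecord], path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a variant TSV: variant_id, position, ref, alt, sequence."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("variant_id\tposition\tref\talt\tsequence\n")
        for v in variants:
            fh.write(
                f"{v.variant_id}\t{v.position}\t{v.ref_base}\t{v.alt_base}\t"
                f"{v.sequence.residues}\n"
            )


def load_alias_table(path: str | Path) -> dict[int, int]:
    """Load a two-column TSV mapping internal variant ids to published ids."""
    aliases: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("internal"):
                continue
            internal, published = line.split("\t")
            aliases[int(internal)] = int(published)
    return aliases
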