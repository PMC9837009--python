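"""Secondary-structure prediction, ingestion, and hairpin feature extraction.

Short mature miRNAs either stay essentially single-stranded or fold back into
a single hairpin (a stem of stacked base pairs closed by a terminal loop).
Whether a variant folds, and whether its EXO-motif sits in the loop or the
stem of that hairpin, feeds both the 2D clustering arm and the final
candidate selection.

The prediction stage is pluggable.  Two built-in engines cover testing and
toy-scale analysis:

* :func:`fold_maxpair` — classic base-pair maximization (Nussinov-style
  dynamic programming) under canonical-pair and minimum-loop constraints;
* :func:`fold_mfe_hairpin` — exhaustive single-hairpin enumeration scored by
  a simplified nearest-neighbor energy model (:class:`EnergyParams`), with
  the all-unpaired structure at 0.0 kcal/mol as the fallback whenever no
  hairpin reaches negative free energy.

For fidelity to trained external predictors, Vienna dot-bracket files are
ingested verbatim via :func:`read_vienna`.  The packaged energy table is a
deliberately small stand-in with Turner-like magnitudes: it supports sign and
ordering comparisons between hairpins, not literature ΔG reproduction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError
from .seqvariants import MotifWindow, RnaSequence

#: Canonical Watson-Crick plus wobble pairs.
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: Minimum number of unpaired bases in a terminal loop (steric constraint).
MIN_LOOP = 3


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure in dot-bracket notation.

    ``pairs`` are 1-based (i, j) with i < j, strictly nested, separated by at
    least :data:`MIN_LOOP` unpaired bases, and — when the sequence is known —
    restricted to canonical/wobble pairs.  ``energy`` is ΔG in kcal/mol when
    an engine or an ingested file provides one.
    """

    sequence_id: str
    dot_bracket: str
    pairs: tuple[tuple[int, int], ...]
    sequence: str | None = None
    energy: float | None = None

    def __post_init__(self) -> None:
        n = len(self.dot_bracket)
        if self.sequence is not None and len(self.sequence) != n:
            raise FormatError(
                f"{self.sequence_id!r}: sequence length {len(self.sequence)} != "
                f"dot-bracket length {n}"
            )
        derived = pairs_from_dot_bracket(self.dot_bracket, self.sequence_id)
        if tuple(sorted(self.pairs)) != derived:
            raise FormatError(
                f"{self.sequence_id!r}: pairs inconsistent with dot-bracket"
            )
        for i, j in self.pairs:
            if j - i - 1 < MIN_LOOP:
                raise FormatError(
                    f"{self.sequence_id!r}: pair ({i},{j}) closes a loop "
                    f"shorter than {MIN_LOOP} nt"
                )
            if self.sequence is not None:
                duo = self.sequence[i - 1] + self.sequence[j - 1]
                if duo not in CANONICAL_PAIRS:
                    raise FormatError(
                        f"{self.sequence_id!r}: non-canonical pair {duo} at ({i},{j})"
                    )

    @classmethod
    def from_dot_bracket(
        cls,
        sequence_id: str,
        dot_bracket: str,
        sequence: str | None = None,
        energy: float | None = None,
    ) -> "SecondaryStructure":
        pairs = pairs_from_dot_bracket(dot_bracket, sequence_id)
        return cls(sequence_id, dot_bracket, pairs, sequence, energy)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def folded(self) -> bool:
        return bool(self.pairs)

    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)


@dataclass(frozen=True)
class HairpinFeatures:
    """Geometry of the selected hairpin and the motif's placement in it."""

    n_hairpins: int
    stem_length: int  # base pairs in the maximal contiguous helix
    loop_length: int  # nt in the terminal loop
    motif_location: str  # one of {"loop", "stem", "mixed", "unpaired"}


def pairs_from_dot_bracket(db: str, record_id: str = "?") -> tuple[tuple[int, int], ...]:
    """Derive the (necessarily nested) 1-based pair list from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"{record_id!r}: unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"{record_id!r}: invalid character {ch!r} at {pos}")
    if stack:
        raise FormatError(f"{record_id!r}: unbalanced '(' at position {stack[-1]}")
    return tuple(sorted(pairs))


def dot_bracket_from_pairs(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def _pairable(a: str, b: str) -> bool:
    return a + b in CANONICAL_PAIRS


# ---------------------------------------------------------------------------
# Engine 1: base-pair maximization

def fold_maxpair(seq: RnaSequence, min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Maximize the number of canonical base pairs (Nussinov recursion).

    Deterministic traceback: at each subproblem the 5'-most base prefers
    pairing over staying unpaired, taking the smallest partner index that
    achieves the optimal count.
    """
    s = seq.residues
    n = len(s)
    # N[i][j]: max pairs on s[i..j], 0-based inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(s[i], s[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + right + 1)
            N[i][j] = best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            target = N[i][j]
            if target == 0:
                return
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(s[i], s[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    if inner + right + 1 == target:
                        pairs.append((i + 1, k + 1))
                        trace(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    if n > min_loop + 1:
        trace(0, n - 1)
    pairs.sort()
    return SecondaryStructure(
        sequence_id=seq.id,
        dot_bracket=dot_bracket_from_pairs(n, pairs),
        pairs=tuple(pairs),
        sequence=s,
    )


# ---------------------------------------------------------------------------
# Engine 2: simplified minimum-free-energy single hairpin

#: Pairing strengths feeding the stand-in stacking table (kcal/mol scale).
_PAIR_STRENGTH = {"GC": 1.5, "CG": 1.5, "AU": 0.9, "UA": 0.9, "GU": 0.5, "UG": 0.5}


def _default_stack() -> dict[tuple[str, str], float]:
    table = {}
    for outer in _PAIR_STRENGTH:
        for inner in _PAIR_STRENGTH:
            table[(outer, inner)] = -(_PAIR_STRENGTH[outer] + _PAIR_STRENGTH[inner])
    return table


def _default_hairpin_loop() -> dict[int, float]:
    # Turner-like magnitudes for terminal-loop initiation, kcal/mol.
    return {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.3}


@dataclass(frozen=True)
class EnergyParams:
    """Simplified nearest-neighbor-style parameters (stand-in table).

    ``stack`` maps (outer pair, inner pair) to a stacking energy <= 0;
    ``hairpin_loop`` maps loop size to an initiation penalty >= 0, extended
    logarithmically beyond the largest tabulated size; ``terminal_au_gu``
    penalizes helices closed by a weak (AU/UA/GU/UG) outermost pair.
    """

    stack: dict[tuple[str, str], float] = field(default_factory=_default_stack)
    hairpin_loop: dict[int, float] = field(default_factory=_default_hairpin_loop)
    loop_log_coeff: float = 1.1
    terminal_au_gu: float = 0.5

    def __post_init__(self) -> None:
        if any(v > 0 for v in self.stack.values()):
            raise ValueError("stacking energies must be <= 0")
        if any(v < 0 for v in self.hairpin_loop.values()):
            raise ValueError("loop penalties must be >= 0")

    def loop_penalty(self, size: int) -> float:
        if size in self.hairpin_loop:
            return self.hairpin_loop[size]
        m = max(self.hairpin_loop)
        return self.hairpin_loop[m] + self.loop_log_coeff * math.log(size / m)


def hairpin_energy(
    sequence: str, outer_i: int, outer_j: int, helix_len: int, params: EnergyParams
) -> float:
    """Score one contiguous helix + terminal loop (1-based outer pair).

    Sum of stack energies along the helix, plus the terminal-loop initiation
    penalty, plus the weak-closure penalty when the outermost pair is AU/GU.
    """
    pairs = [
        sequence[outer_i - 1 + t] + sequence[outer_j - 1 - t] for t in range(helix_len)
    ]
    energy = sum(
        params.stack[(pairs[t], pairs[t + 1])] for t in range(helix_len - 1)
    )
    loop = (outer_j - helix_len + 1) - (outer_i + helix_len - 1) - 1
    energy += params.loop_penalty(loop)
    if pairs[0] in ("AU", "UA", "GU", "UG"):
        energy += params.terminal_au_gu
    return energy


def enumerate_hairpin_candidates(
    seq: RnaSequence, min_loop: int = MIN_LOOP
) -> list[tuple[int, int, int]]:
    """All (outer_i, outer_j, helix_len) single-hairpin candidates (1-based).

    A candidate is a contiguous run of ``helix_len`` canonical pairs
    (outer_i + t, outer_j - t) whose innermost pair closes a loop of at least
    ``min_loop`` nt.
    """
    s = seq.residues
    n = len(s)
    out = []
    for i in range(1, n + 1):
        for j in range(i + min_loop + 1, n + 1):
            h = 0
            while (
                (j - h) - (i + h) - 1 >= min_loop
                and _pairable(s[i + h - 1], s[j - h - 1])
            ):
                h += 1
                out.append((i, j, h))
    return out


def fold_mfe_hairpin(
    seq: RnaSequence, params: EnergyParams | None = None, min_loop: int = MIN_LOOP
) -> SecondaryStructure:
    """Best single hairpin under the simplified energy model, or unfolded.

    All single-hairpin candidates are enumerated exhaustively and scored; the
    minimum-energy one is returned when its ΔG is negative, otherwise the
    all-unpaired structure at exactly 0.0 kcal/mol.  Ties resolve toward the
    5'-most, then smallest-span, then shortest helix candidate.
    """
    params = params or EnergyParams()
    s = seq.residues
    n = len(s)
    best: tuple[int, int, int] | None = None
    best_e = 0.0
    for i, j, h in enumerate_hairpin_candidates(seq, min_loop):
        e = hairpin_energy(s, i, j, h, params)
        if e < best_e - 1e-12:
            best, best_e = (i, j, h), e
    if best is None:
        return SecondaryStructure(
            sequence_id=seq.id, dot_bracket="." * n, pairs=(), sequence=s, energy=0.0
        )
    i, j, h = best
    pairs = tuple((i + t, j - t) for t in range(h))
    return SecondaryStructure(
        sequence_id=seq.id,
        dot_bracket=dot_bracket_from_pairs(n, pairs),
        pairs=tuple(sorted(pairs)),
        sequence=s,
        energy=round(best_e, 6),
    )


# ---------------------------------------------------------------------------
# Hairpin feature extraction

def _helix_of(pairs: set[tuple[int, int]], inner: tuple[int, int]) -> list[tuple[int, int]]:
    """Maximal contiguous helix containing the loop-closing pair, inside-out."""
    helix = [inner]
    i, j = inner
    while (i - 1, j + 1) in pairs:
        i, j = i - 1, j + 1
        helix.append((i, j))
    return helix


def extract_hairpin_features(
    s: SecondaryStructure, window: MotifWindow
) -> HairpinFeatures:
    """Locate hairpins and classify where the motif window sits.

    A hairpin is identified by its loop-closing pair (an innermost pair with
    no pair nested inside); its stem is the maximal contiguous helix around
    that pair.  When several hairpins exist the longest helix wins, ties by
    GC-pair count (when the sequence is known) then by 5'-most position.

    The motif is ``loop`` when every window position is unpaired and lies in
    the selected terminal loop, ``stem`` when every window position is
    paired, ``unpaired`` when the whole structure has no pairs, and
    ``mixed`` otherwise.
    """
    if not s.pairs:
        return HairpinFeatures(0, 0, 0, "unpaired")
    pair_set = set(s.pairs)
    innermost = [
        (i, j)
        for (i, j) in s.pairs
        if not any(i < a and b < j for (a, b) in s.pairs)
    ]

    def sort_key(closing: tuple[int, int]):
        helix = _helix_of(pair_set, closing)
        gc = 0
        if s.sequence is not None:
            gc = sum(
                1
                for (a, b) in helix
                if s.sequence[a - 1] + s.sequence[b - 1] in ("GC", "CG")
            )
        return (-len(helix), -gc, closing[0])

    selected = min(innermost, key=sort_key)
    helix = _helix_of(pair_set, selected)
    ci, cj = selected
    loop_span = set(range(ci + 1, cj))
    paired = s.paired_positions()

    win = list(window.positions)
    if all(p not in paired and p in loop_span for p in win):
        location = "loop"
    elif all(p in paired for p in win):
        location = "stem"
    else:
        location = "mixed"
    return HairpinFeatures(
        n_hairpins=len(innermost),
        stem_length=len(helix),
        loop_length=cj - ci - 1,
        motif_location=location,
    )


# ---------------------------------------------------------------------------
# Vienna dot-bracket I/O

_ENERGY_RE = re.compile(r"^([().]+)(?:\s*\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_vienna(path: str | Path) -> list[SecondaryStructure]:
    """Read Vienna-format records: '>id', sequence line, dot-bracket line.

    A trailing parenthesized number on the structure line (e.g. ``(-1.37)``)
    is parsed as the folding energy in kcal/mol.
    """
    structures: list[SecondaryStructure] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: expected '>' header at line {i + 1}")
        rec_id = line[1:].split()[0]
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated record {rec_id!r}")
        seq = lines[i + 1].strip().upper().replace("T", "U")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: record {rec_id!r} lacks a structure line")
        m = _ENERGY_RE.match(lines[i + 2].strip())
        if not m:
            raise FormatError(f"{path}: record {rec_id!r}: malformed structure line")
        db, energy_s = m.group(1), m.group(2)
        if len(db) != len(seq):
            raise FormatError(
                f"{path}: record {rec_id!r}: structure length {len(db)} != "
                f"sequence length {len(seq)}"
            )
        structures.append(
            SecondaryStructure.from_dot_bracket(
                rec_id, db, sequence=seq,
                energy=float(energy_s) if energy_s is not None else None,
            )
        )
        i += 3
    return structures


def write_vienna(structures: list[SecondaryStructure], path: str | Path) -> None:
    """Write Vienna-format records; energies are appended when present."""
    with open(path, "w") as fh:
        for s in structures:
            if s.sequence is None:
                raise FormatError(
                    f"cannot write record {s.sequence_id!r}: no sequence attached"
                )
            fh.write(f">{s.sequence_id}\n{s.sequence}\n{s.dot_bracket}")
            if s.energy is not None:
                fh.write(f" ({s.energy:g})")
            fh.write("\n")


def write_structure_report(
    rows: list[tuple[str, bool, float | None, HairpinFeatures]],
    path: str | Path,
    header_lines=None,
) -> None:
    """Structure report TSV: id, folded flag, energy, hairpin geometry."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("sequence_id\tfolded\tenergy\tstem_length\tloop_length\tmotif_location\n")
        for sid, folded, energy, feat in rows:
            e = "" if energy is None else f"{energy:g}"
            fh.write(
                f"{sid}\t{int(folded)}\t{e}\t{feat.stem_length}\t"
                f"{feat.loop_length}\t{feat.motif_location}\n"
            )
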