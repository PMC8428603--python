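"""Readers for contact/distance predictions and per-residue annotations.

Formats covered: CASP RR (plain contacts and RMODE 2 binned distances),
PSIPRED ``.ss2`` secondary structure, IUPred per-residue disorder scores,
TOPCONS consensus topology strings, ConSurf conservation grades, single-record
FASTA, and a line-oriented custom-track format defined by this package.  One
writer emits RR text (3- or 5-column).

Parsers are strict about data lines (a malformed data line is an error naming
its line number) but lenient about dialect: RR files may mix 3-column
``i j p`` and 5-column ``i j d1 d2 p`` records, headers are optional, and a
full TOPCONS results file is accepted as well as a bare topology string.

Custom-track dialect
--------------------
One instruction per line: ``start end colour [label] [slot]`` with 1-based
inclusive residue bounds, any matplotlib-parseable colour, an optional label
(default the colour name) and an optional slot hint in [-4, +4].  A ``#`` at
the start of a line begins a comment (only there, so hex colours stay
parseable); blank lines are ignored.  Later instructions win on overlaps
within one slot.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
import matplotlib
from matplotlib import colors as mcolors

from .errors import ParserError, ValidationError
from .model import (
    DEFAULT_DISTANCE_BINS,
    AnnotationTrack,
    ContactMap,
    Distogram,
    canonicalize,
)

RR_HEADER_KEYWORDS = frozenset(
    {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "END", "REMARK", "RMODE"}
)

#: Default track palettes.  Helix red and coil green follow the usual
#: secondary-structure display convention; strand yellow is this package's
#: choice.  Topology: blue outside the cell, yellow inside, light red for
#: transmembrane segments.
SS2_PALETTE = {"H": "red", "E": "yellow", "C": "green"}
TOPOLOGY_PALETTE = {
    "outside": "blue",
    "inside": "yellow",
    "membrane": "lightcoral",
    "signal": "grey",
}
DISORDER_PALETTE = {"disordered": "orange", "ordered": "lightgrey"}
IUPRED_DISORDER_THRESHOLD = 0.5


def conservation_palette() -> dict[str, str]:
    """9-step blue gradient for conservation grades; darker means more conserved."""
    cmap = matplotlib.colormaps["Blues"]
    return {
        str(g): mcolors.to_hex(cmap(0.15 + 0.8 * (g - 1) / 8)) for g in range(1, 10)
    }


@dataclass(frozen=True, slots=True)
class CustomTrackInstruction:
    """One colouring instruction for a section of a custom annotation track."""

    start: int
    end: int
    colour: str
    label: str
    slot_hint: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"start after end: {self.start} > {self.end}"
            )
        if not mcolors.is_color_like(self.colour):
            raise ValidationError(f"unparseable colour {self.colour!r}")
        if self.slot_hint is not None and not -4 <= self.slot_hint <= 4:
            raise ValidationError(f"slot hint {self.slot_hint} outside [-4, +4]")


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _check_max_index(max_index: int, seq_length: int | None, what: str) -> None:
    if seq_length is not None and max_index > seq_length:
        raise ValidationError(
            f"{what} index {max_index} exceeds sequence length {seq_length}"
        )


# ---------------------------------------------------------------------------
# RR contacts / distograms
# ---------------------------------------------------------------------------

def _is_rr_header(tokens: list[str]) -> bool:
    return tokens[0].upper() in RR_HEADER_KEYWORDS


def _is_sequence_line(line: str) -> bool:
    stripped = line.replace(" ", "")
    return stripped.isalpha()


def parse_rr_contacts(text: str, seq_length: int | None = None) -> ContactMap:
    """Parse a CASP RR contact file into a :class:`ContactMap`.

    Both the 5-column ``i j d1 d2 p`` and 3-column ``i j p`` data dialects are
    accepted, even mixed within one file.  Header lines (PFRMAT, TARGET,
    AUTHOR, METHOD, MODEL, REMARK, RMODE, END) and sequence continuation lines
    are skipped; concatenated sequence lines, when present, set the sequence
    length, otherwise the maximum residue index does.
    """
    if not text.strip():
        raise ParserError("no contacts found: empty input")
    raw: list[tuple[int, int, float]] = []
    seq_parts: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if _is_rr_header(tokens):
            continue
        if _is_sequence_line(line):
            seq_parts.append(line.replace(" ", ""))
            continue
        if len(tokens) not in (3, 5):
            raise ParserError(
                f"expected 3 or 5 fields on a data line, got {len(tokens)}", lineno
            )
        try:
            i, j = int(tokens[0]), int(tokens[1])
            score = float(tokens[-1])
        except ValueError as exc:
            raise ParserError(f"non-numeric field: {exc}", lineno) from None
        raw.append((i, j, score))
    if not raw:
        raise ParserError("no contacts found")
    sequence = "".join(seq_parts).upper() or None
    if sequence is not None and seq_length is None:
        seq_length = len(sequence)
    _check_max_index(max(max(i, j) for i, j, _ in raw), seq_length, "contact")
    return canonicalize(raw, seq_length=seq_length, sequence=sequence)


def parse_rr_distogram(
    text: str,
    bins: tuple[tuple[float, float], ...] = DEFAULT_DISTANCE_BINS,
    seq_length: int | None = None,
    require_rmode: bool = True,
) -> Distogram:
    """Parse an RMODE 2 RR file of binned inter-residue distances.

    Each data line carries ``i j p1 ... pK`` with one probability per
    configured bin.  Vectors whose sum deviates from 1 by at most 0.01 are
    renormalized; larger deviations are an error.  Set ``require_rmode`` False
    to force distogram interpretation of a file lacking the ``RMODE 2`` header.
    """
    if not text.strip():
        raise ParserError("empty input")
    if require_rmode:
        declared = any(
            line.split()[:2] == ["RMODE", "2"]
            for line in text.splitlines()
            if line.strip()
        )
        if not declared:
            raise ParserError(
                "input does not declare RMODE 2; pass require_rmode=False to force"
            )
    n_bins = len(bins)
    entries: dict[tuple[int, int], np.ndarray] = {}
    seq_parts: list[str] = []
    max_index = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if _is_rr_header(tokens):
            continue
        if _is_sequence_line(line):
            seq_parts.append(line.replace(" ", ""))
            continue
        try:
            i, j = int(tokens[0]), int(tokens[1])
            vec = np.array([float(t) for t in tokens[2:]])
        except ValueError as exc:
            raise ParserError(f"non-numeric field: {exc}", lineno) from None
        if vec.size != n_bins:
            raise ParserError(
                f"expected {n_bins} probabilities, got {vec.size}", lineno
            )
        total = vec.sum()
        if not 0.99 <= total <= 1.01:
            raise ParserError(
                f"probability vector sums to {total:.4f}, outside [0.99, 1.01]",
                lineno,
            )
        vec = vec / total
        if i == j:
            raise ParserError(f"self-pair at residue {i}", lineno)
        entries[(min(i, j), max(i, j))] = vec
        max_index = max(max_index, i, j)
    if not entries:
        raise ParserError("no distance records found")
    sequence = "".join(seq_parts).upper() or None
    if sequence is not None and seq_length is None:
        seq_length = len(sequence)
    _check_max_index(max_index, seq_length, "pair")
    return Distogram(
        seq_length=seq_length or max_index,
        bins=bins,
        entries=entries,
        sequence=sequence,
    )


def write_rr(cmap: ContactMap, dialect: str = "5col", header: bool = True) -> str:
    """Serialize a contact map as RR text (``5col``: ``i j 0 8 p``; ``3col``: ``i j p``)."""
    if dialect not in ("3col", "5col"):
        raise ValidationError(f"unknown RR dialect {dialect!r}")
    lines: list[str] = []
    if header:
        lines.append("PFRMAT RR")
        if cmap.sequence:
            lines.append(cmap.sequence)
        lines.append("MODEL 1")
    for c in cmap.contacts:
        if dialect == "5col":
            lines.append(f"{c.i} {c.j} 0 8 {c.score:.6f}")
        else:
            lines.append(f"{c.i} {c.j} {c.score:.6f}")
    if header:
        lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-residue annotation formats
# ---------------------------------------------------------------------------

def parse_psipred_ss2(text: str) -> AnnotationTrack:
    """Parse a PSIPRED ``.ss2`` file (``idx aa state pC pH pE`` rows).

    States are H (helix), E (strand) or C (coil); the track value for each
    residue is the probability of the called state.
    """
    states: list[str] = []
    values: list[float] = []
    expected = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 6:
            raise ParserError(f"expected 6 fields, got {len(tokens)}", lineno)
        try:
            idx = int(tokens[0])
            p_c, p_h, p_e = (float(t) for t in tokens[3:6])
        except ValueError as exc:
            raise ParserError(f"non-numeric field: {exc}", lineno) from None
        if idx != expected:
            raise ParserError(
                f"gap in residue numbering: expected {expected}, got {idx}", lineno
            )
        state = tokens[2]
        if state not in ("H", "E", "C"):
            raise ParserError(f"unknown secondary-structure state {state!r}", lineno)
        states.append(state)
        values.append({"C": p_c, "H": p_h, "E": p_e}[state])
        expected += 1
    if not states:
        raise ParserError("no residues in ss2 input")
    return AnnotationTrack(
        name="secondary structure",
        seq_length=len(states),
        states=states,
        values=values,
        palette=dict(SS2_PALETTE),
    )


def parse_iupred(text: str) -> AnnotationTrack:
    """Parse IUPred per-residue disorder scores (``idx aa score`` rows).

    Scores must lie in [0, 1]; residues with score >= 0.5 are labelled
    disordered (the boundary counts as disordered).
    """
    states: list[str] = []
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            score = float(tokens[-1])
        except ValueError as exc:
            raise ParserError(f"non-numeric score: {exc}", lineno) from None
        if not 0.0 <= score <= 1.0:
            raise ParserError(f"disorder score {score} outside [0, 1]", lineno)
        values.append(score)
        states.append(
            "disordered" if score >= IUPRED_DISORDER_THRESHOLD else "ordered"
        )
    if not states:
        raise ParserError("no residues in disorder input")
    return AnnotationTrack(
        name="disorder",
        seq_length=len(states),
        states=states,
        values=values,
        palette=dict(DISORDER_PALETTE),
    )


_TOPOLOGY_STATES = {"i": "inside", "o": "outside", "M": "membrane", "S": "signal"}


def parse_topcons(text: str) -> AnnotationTrack:
    """Parse a TOPCONS consensus topology string.

    Accepts either a bare per-residue string over the alphabet ``{i, o, M, S}``
    (possibly wrapped over several lines) or a full TOPCONS results file, from
    which the block following the ``TOPCONS predicted topology`` header is
    extracted.
    """
    lines = text.splitlines()
    for n, line in enumerate(lines):
        if "TOPCONS predicted topology" in line:
            block: list[str] = []
            for following in lines[n + 1:]:
                stripped = following.strip()
                if not stripped or ":" in stripped:
                    break
                block.append(stripped)
            lines = block
            break
    topology = "".join(line.strip() for line in lines if not line.startswith("#"))
    if not topology:
        raise ParserError("empty topology")
    states: list[str] = []
    for pos, char in enumerate(topology, start=1):
        if char not in _TOPOLOGY_STATES:
            raise ParserError(
                f"unknown topology character {char!r} at position {pos}"
            )
        states.append(_TOPOLOGY_STATES[char])
    return AnnotationTrack(
        name="topology",
        seq_length=len(states),
        states=states,
        palette=dict(TOPOLOGY_PALETTE),
    )


def parse_consurf(text: str) -> AnnotationTrack:
    """Parse ConSurf conservation grades (rows with residue index and grade 1-9).

    Two- and three-column layouts are accepted (``idx grade`` or
    ``idx aa grade``); rows must cover residues 1..N consecutively.
    """
    grades: list[int] = []
    expected = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            idx = int(tokens[0])
            grade = int(tokens[-1])
        except ValueError:
            # header / non-data row
            if expected == 1:
                continue
            raise ParserError("malformed grade row", lineno) from None
        if idx != expected:
            raise ParserError(
                f"gap in residue numbering: expected {expected}, got {idx}", lineno
            )
        if not 1 <= grade <= 9:
            raise ParserError(f"conservation grade {grade} outside 1-9", lineno)
        grades.append(grade)
        expected += 1
    if not grades:
        raise ParserError("no conservation grades found")
    return AnnotationTrack(
        name="conservation",
        seq_length=len(grades),
        states=[str(g) for g in grades],
        values=[float(g) for g in grades],
        palette=conservation_palette(),
    )


# ---------------------------------------------------------------------------
# custom tracks and FASTA
# ---------------------------------------------------------------------------

def parse_custom_track(text: str) -> list[CustomTrackInstruction]:
    """Parse the custom-track format (see module docstring for the dialect)."""
    instructions: list[CustomTrackInstruction] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ParserError(
                f"expected 'start end colour [label] [slot]', got {len(tokens)} fields",
                lineno,
            )
        try:
            start, end = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise ParserError(f"non-integer residue bound: {exc}", lineno) from None
        colour = tokens[2]
        rest = tokens[3:]
        slot_hint: int | None = None
        if rest:
            try:
                slot_hint = int(rest[-1])
                rest = rest[:-1]
            except ValueError:
                pass
        label = " ".join(rest) if rest else colour
        try:
            instructions.append(
                CustomTrackInstruction(start, end, colour, label, slot_hint)
            )
        except ValidationError as exc:
            raise ParserError(str(exc), lineno) from None
    return instructions


def instructions_to_track(
    instructions: list[CustomTrackInstruction],
    seq_length: int,
    name: str = "custom",
    background_label: str = "none",
) -> AnnotationTrack:
    """Expand instructions into a per-residue track; later lines win on overlap.

    Residues not covered by any instruction receive ``background_label``, whose
    palette colour is "none" (not drawn).
    """
    states = [background_label] * seq_length
    palette: dict[str, str] = {background_label: "none"}
    for ins in instructions:
        if ins.end > seq_length:
            raise ValidationError(
                f"instruction end {ins.end} exceeds sequence length {seq_length}"
            )
        for pos in range(ins.start, ins.end + 1):
            states[pos - 1] = ins.label
        palette[ins.label] = ins.colour
    return AnnotationTrack(
        name=name, seq_length=seq_length, states=states, palette=palette
    )


def parse_fasta(text: str) -> SequenceRecord:
    """Parse a single-record FASTA into ``(id, uppercase sequence)``.

    Multi-record input is an error; non-amino-acid letters are kept with a
    warning.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ParserError("no FASTA record found")
    if len(records) > 1:
        raise ParserError(
            f"expected a single FASTA record, found {len(records)}"
        )
    rec = records[0]
    sequence = "".join(str(rec.seq).split()).upper()
    odd = sorted(set(sequence) - set("ACDEFGHIKLMNPQRSTVWYBXZJUO"))
    if odd:
        warnings.warn(f"non-amino-acid characters kept in sequence: {odd}")
    return SequenceRecord(id=rec.id, sequence=sequence)
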