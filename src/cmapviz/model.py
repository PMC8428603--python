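"""Core domain types and elementary contact-map algebra.

A contact map is a sparse, symmetric set of scored residue pairs over a
sequence.  Pairs are stored once in canonical order ``i < j`` with 1-based
residue indexing (the convention of both RR files and PDB numbering), and are
queryable in either orientation.  A distogram generalizes the contact map to a
per-pair probability distribution over binned inter-residue distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Distance bins (Å) used for binned inter-residue distance predictions when
#: the input does not configure its own.  Last bin is open-ended.
DEFAULT_DISTANCE_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 4.0),
    (4.0, 6.0),
    (6.0, 8.0),
    (8.0, 10.0),
    (10.0, 12.0),
    (12.0, 14.0),
    (14.0, 16.0),
    (16.0, 18.0),
    (18.0, 20.0),
    (20.0, math.inf),
)

#: Default sequence-separation cut-off used to blank the near-diagonal region
#: of displayed maps.  Contact predictions conventionally omit sequential near
#: neighbours.
DEFAULT_DISPLAY_MIN_SEP = 5

#: Sequence separation defining a long-range contact (CASP convention).
LONG_RANGE_MIN_SEP = 23


@dataclass(frozen=True, slots=True)
class ResidueContact:
    """A scored residue pair, stored with ``i < j``."""

    i: int
    j: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.i < 1 or self.j < 1:
            raise ValidationError(
                f"residue indices must be >= 1, got ({self.i}, {self.j})"
            )
        if self.i == self.j:
            raise ValidationError(f"self-contact at residue {self.i}")
        if self.i > self.j:
            raise ValidationError(
                f"contact must be stored with i < j, got ({self.i}, {self.j})"
            )

    @property
    def separation(self) -> int:
        return self.j - self.i


class ContactMap:
    """Sparse symmetric set of scored residue contacts over one sequence.

    Parameters
    ----------
    seq_length:
        Number of residues in the underlying sequence (> 0).
    contacts:
        Iterable of :class:`ResidueContact`, already in canonical ``i < j``
        order and free of duplicates.  Use :func:`canonicalize` to build a map
        from raw, possibly redundant ``(i, j, score)`` triples.
    sequence:
        Optional amino-acid string; when given its length must equal
        ``seq_length``.
    """

    __slots__ = ("seq_length", "sequence", "_contacts")

    def __init__(
        self,
        seq_length: int,
        contacts: Iterable[ResidueContact] = (),
        sequence: str | None = None,
    ):
        if seq_length < 1:
            raise ValidationError(f"seq_length must be positive, got {seq_length}")
        if sequence is not None and len(sequence) != seq_length:
            raise ValidationError(
                f"sequence length {len(sequence)} != seq_length {seq_length}"
            )
        self.seq_length = int(seq_length)
        self.sequence = sequence
        store: dict[tuple[int, int], ResidueContact] = {}
        for c in contacts:
            if c.j > seq_length:
                raise ValidationError(
                    f"contact ({c.i}, {c.j}) exceeds sequence length {seq_length}"
                )
            key = (c.i, c.j)
            if key in store:
                raise ValidationError(f"duplicate contact ({c.i}, {c.j})")
            store[key] = c
        self._contacts = store

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._contacts)

    def __iter__(self) -> Iterator[ResidueContact]:
        return iter(self.contacts)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self._contacts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMap):
            return NotImplemented
        return (
            self.seq_length == other.seq_length
            and self._contacts == other._contacts
        )

    def __repr__(self) -> str:
        return f"ContactMap(seq_length={self.seq_length}, n_contacts={len(self)})"

    # -- queries ------------------------------------------------------------
    @property
    def contacts(self) -> tuple[ResidueContact, ...]:
        """Contacts sorted by ``(i, j)``."""
        return tuple(self._contacts[k] for k in sorted(self._contacts))

    def pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(self._contacts)

    def score(self, i: int, j: int) -> float:
        """Score of contact ``(i, j)``; symmetric in its arguments."""
        key = (min(i, j), max(i, j))
        try:
            return self._contacts[key].score
        except KeyError:
            raise KeyError(f"no contact ({i}, {j})") from None


@dataclass(slots=True)
class Distogram:
    """Per-pair probability vectors over binned inter-residue distances.

    ``bins`` are contiguous, increasing ``(lower, upper]`` intervals in Å; the
    last upper bound may be infinite.  Every probability vector is validated to
    be non-negative and to sum to 1 within 1e-6.
    """

    seq_length: int
    bins: tuple[tuple[float, float], ...] = DEFAULT_DISTANCE_BINS
    entries: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValidationError(f"seq_length must be positive, got {self.seq_length}")
        self.bins = tuple((float(lo), float(hi)) for lo, hi in self.bins)
        for k, (lo, hi) in enumerate(self.bins):
            if not lo < hi:
                raise ValidationError(f"bin {k} not increasing: ({lo}, {hi})")
            if k and not math.isclose(lo, self.bins[k - 1][1]):
                raise ValidationError(
                    f"bins not contiguous at index {k}: {self.bins[k - 1][1]} vs {lo}"
                )
        checked: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), vec in self.entries.items():
            if not 1 <= i < j <= self.seq_length:
                raise ValidationError(f"pair ({i}, {j}) invalid for length {self.seq_length}")
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (len(self.bins),):
                raise ValidationError(
                    f"pair ({i}, {j}): expected {len(self.bins)} probabilities, got {arr.size}"
                )
            if (arr < 0).any():
                raise ValidationError(f"pair ({i}, {j}): negative probability")
            if abs(arr.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"pair ({i}, {j}): probabilities sum to {arr.sum():.6f}, not 1"
                )
            checked[(i, j)] = arr
        self.entries = checked

    def expected_distance(self, i: int, j: int) -> float:
        """Mean distance under the pair's bin distribution.

        Bin midpoints are used; the open-ended last bin is represented by its
        lower edge plus 2 Å.
        """
        key = (min(i, j), max(i, j))
        vec = self.entries[key]
        mids = np.array(
            [lo + 2.0 if math.isinf(hi) else (lo + hi) / 2.0 for lo, hi in self.bins]
        )
        return float(vec @ mids)


@dataclass(frozen=True, slots=True)
class MatchClassification:
    """Three-way partition of contacts after superposing two maps.

    ``matched`` pairs occur in both maps, ``model_only`` only in the
    model-derived map, ``predicted_only`` only in the predicted map.  The three
    sets are pairwise disjoint and their union is the union of the two inputs'
    contact sets.
    """

    matched: frozenset[tuple[int, int]]
    model_only: frozenset[tuple[int, int]]
    predicted_only: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if (
            self.matched & self.model_only
            or self.matched & self.predicted_only
            or self.model_only & self.predicted_only
        ):
            raise ValidationError("classification sets must be pairwise disjoint")

    @property
    def all_pairs(self) -> frozenset[tuple[int, int]]:
        return self.matched | self.model_only | self.predicted_only


@dataclass(slots=True)
class AnnotationTrack:
    """Per-residue categorical states with an optional graded score per residue.

    ``states`` holds one label per residue (e.g. H/E/C, inside/outside/membrane,
    conservation grade "1".."9", or user-defined labels); ``values`` optionally
    holds a real score per residue; ``palette`` maps every label occurring in
    ``states`` to a colour.
    """

    name: str
    seq_length: int
    states: list[str]
    palette: dict[str, str]
    values: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.states) != self.seq_length:
            raise ValidationError(
                f"track '{self.name}': {len(self.states)} states for "
                f"seq_length {self.seq_length}"
            )
        if self.values is not None and len(self.values) != self.seq_length:
            raise ValidationError(
                f"track '{self.name}': {len(self.values)} values for "
                f"seq_length {self.seq_length}"
            )
        missing = sorted(set(self.states) - set(self.palette))
        if missing:
            raise ValidationError(
                f"track '{self.name}': no palette entry for state(s) {missing}"
            )

    def runs(self) -> list[tuple[int, int, str]]:
        """Maximal constant runs as ``(start, end, state)`` with inclusive 1-based bounds."""
        out: list[tuple[int, int, str]] = []
        start = 1
        for pos in range(2, self.seq_length + 1):
            if self.states[pos - 1] != self.states[start - 1]:
                out.append((start, pos - 1, self.states[start - 1]))
                start = pos
        out.append((start, self.seq_length, self.states[start - 1]))
        return out


# ---------------------------------------------------------------------------
# contact-map algebra
# ---------------------------------------------------------------------------

def canonicalize(
    raw: Iterable[tuple[int, int, float]],
    seq_length: int | None = None,
    sequence: str | None = None,
) -> ContactMap:
    """Build a :class:`ContactMap` from raw ``(i, j, score)`` triples.

    ``(j, i)`` is folded onto ``(i, j)`` with ``i < j``; duplicates collapse
    keeping the maximum score (predictors sometimes emit both triangle
    orders).  Self-contacts and non-positive indices are rejected.
    ``seq_length`` defaults to the maximum index seen.
    """
    best: dict[tuple[int, int], float] = {}
    max_index = 0
    for i, j, score in raw:
        if i < 1 or j < 1:
            raise ValidationError(f"residue indices must be >= 1, got ({i}, {j})")
        if i == j:
            raise ValidationError(f"self-contact at residue {i}")
        key = (min(i, j), max(i, j))
        max_index = max(max_index, key[1])
        prev = best.get(key)
        if prev is None or score > prev:
            best[key] = score
    if seq_length is None:
        if sequence is not None:
            seq_length = len(sequence)
        elif max_index:
            seq_length = max_index
        else:
            raise ValidationError("empty contact list requires explicit seq_length")
    return ContactMap(
        seq_length,
        (ResidueContact(i, j, s) for (i, j), s in best.items()),
        sequence=sequence,
    )


def filter_by_separation(cmap: ContactMap, min_sep: int) -> ContactMap:
    """Retain contacts with sequence separation ``|i - j| >= min_sep``.

    Contact maps conventionally omit sequential near neighbours, leaving the
    region on and near the diagonal blank.
    """
    if min_sep < 0:
        raise ValidationError(f"min_sep must be >= 0, got {min_sep}")
    return ContactMap(
        cmap.seq_length,
        (c for c in cmap.contacts if c.separation >= min_sep),
        sequence=cmap.sequence,
    )


def select_top(cmap: ContactMap, n: int) -> ContactMap:
    """The ``n`` highest-scoring contacts; ties break by ascending ``(i, j)``."""
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    ranked = sorted(cmap.contacts, key=lambda c: (-c.score, c.i, c.j))
    return ContactMap(cmap.seq_length, ranked[:n], sequence=cmap.sequence)


def distogram_to_contacts(
    d: Distogram, contact_max_distance: float = 8.0
) -> ContactMap:
    """Collapse a distogram to a contact map at a distance threshold.

    The score of each pair is the total probability mass in bins lying entirely
    below ``contact_max_distance``, which therefore must coincide with a bin
    boundary (no interpolation inside a bin).  Pairs with zero mass below the
    threshold are dropped.
    """
    edges = [d.bins[0][0]] + [hi for _, hi in d.bins]
    if not any(math.isclose(contact_max_distance, e) for e in edges if math.isfinite(e)):
        raise ValidationError(
            f"contact_max_distance {contact_max_distance} is not a bin boundary "
            f"of {edges}"
        )
    below = np.array([hi <= contact_max_distance + 1e-9 for _, hi in d.bins])
    contacts = []
    for (i, j), vec in d.entries.items():
        score = float(vec[below].sum())
        if score > 0.0:
            contacts.append(ResidueContact(i, j, score))
    return ContactMap(d.seq_length, contacts, sequence=d.sequence)
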