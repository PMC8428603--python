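"""Figure geometry: half-map composition and diagonal annotation tracks.

The plot is a square over residue indices ``[1, L]`` with i on x and j on y.
The two triangular halves can display different data for the same sequence
(e.g. a predicted map above the diagonal and a model-derived map below, or a
three-way match classification).  The conventionally empty band around the
diagonal hosts up to nine annotation tracks in slots numbered -4..+4, slot 0
lying on the diagonal itself; slot -k can mirror slot +k across the diagonal.

Geometry convention
-------------------
Slot ``k`` occupies the diagonal-parallel band of signed offset
``o = j - i`` in ``[k*w - w/2, k*w + w/2)`` residue units, where ``w`` is the
band width (default 2).  The half-open interval makes bands of distinct slots
disjoint.  A track's run of identical states over residues ``[a, b]`` becomes
one coloured segment: the part of the band whose diagonal position
``(i + j) / 2`` lies within ``[a - 1/2, b + 1/2]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import matplotlib
from matplotlib import colors as mcolors
from shapely.geometry import Polygon, box

from .errors import ValidationError
from .model import (
    DEFAULT_DISPLAY_MIN_SEP,
    AnnotationTrack,
    ContactMap,
    Distogram,
    MatchClassification,
    distogram_to_contacts,
)

SLOT_RANGE = tuple(range(-4, 5))
DEFAULT_BAND_WIDTH = 2.0

#: Keys accepted by the plain-text (YAML) figure configuration.
CONFIG_KEYS = (
    "mode",
    "min_sep",
    "band_width",
    "upper_colour",
    "lower_colour",
    "heatmap_metric",
    "contact_max_distance",
    "dpi",
    "tracks",
)

#: Colours of the three contact classes when a match classification is drawn:
#: black for contacts matched between the maps, red for model-only contacts,
#: grey for predicted-only contacts.
CLASSIFICATION_PALETTE = {
    "matched": "black",
    "model-only": "red",
    "predicted-only": "grey",
}

MapLike = ContactMap | MatchClassification | Distogram


@dataclass(slots=True)
class TrackSlot:
    """One of the nine addressable diagonal slots."""

    index: int
    track: AnnotationTrack | None = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.index not in SLOT_RANGE:
            raise ValidationError(
                f"slot {self.index} out of range; slots are numbered -4..+4"
            )

    @property
    def occupied(self) -> bool:
        return self.track is not None


@dataclass(frozen=True, slots=True)
class Band:
    """Placement of one diagonal band, clipped to the plot square."""

    slot: int
    offset_lo: float
    offset_hi: float
    polygon: tuple[tuple[float, float], ...]


@dataclass(frozen=True, slots=True)
class PointLayer:
    label: str
    colour: str
    points: tuple[tuple[float, float], ...]


@dataclass(frozen=True, slots=True)
class HeatCell:
    x: float
    y: float
    value: float
    colour: str


@dataclass(frozen=True, slots=True)
class CellLayer:
    label: str
    colormap: str
    vmin: float
    vmax: float
    cells: tuple[HeatCell, ...]


@dataclass(frozen=True, slots=True)
class TrackSegment:
    slot: int
    track_name: str
    label: str
    colour: str
    start: int
    end: int
    polygon: tuple[tuple[float, float], ...]


@dataclass(frozen=True, slots=True)
class LegendEntry:
    group: str
    label: str
    colour: str


@dataclass(frozen=True, slots=True)
class Scene:
    """Render-ready description of one figure: coloured primitives with coordinates."""

    seq_length: int
    point_layers: tuple[PointLayer, ...]
    cell_layers: tuple[CellLayer, ...]
    segments: tuple[TrackSegment, ...]
    legend: tuple[LegendEntry, ...]


@dataclass(slots=True)
class FigureSpec:
    """Declarative description of one contact-map figure.

    ``upper_map`` / ``lower_map`` fill the triangles above / below the
    diagonal; each may be a :class:`ContactMap`, a
    :class:`MatchClassification` or a :class:`Distogram`.  ``mode`` is
    ``"points"`` or ``"heatmap"`` (heatmap needs a distogram or a scored
    contact map).  ``min_sep`` blanks the near-diagonal region of the data
    layers; ``band_width`` sets the per-slot track width in residue units.
    """

    seq_length: int
    upper_map: MapLike | None = None
    lower_map: MapLike | None = None
    mode: str = "points"
    min_sep: int = DEFAULT_DISPLAY_MIN_SEP
    band_width: float = DEFAULT_BAND_WIDTH
    upper_colour: str = "black"
    lower_colour: str = "steelblue"
    heatmap_metric: str = "probability"  # or "expected_distance"
    contact_max_distance: float = 8.0
    slots: dict[int, TrackSlot] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValidationError(f"seq_length must be positive, got {self.seq_length}")
        if self.mode not in ("points", "heatmap"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.heatmap_metric not in ("probability", "expected_distance"):
            raise ValidationError(f"unknown heatmap metric {self.heatmap_metric!r}")
        for half in (self.upper_map, self.lower_map):
            if half is not None and _map_length(half, self.seq_length) != self.seq_length:
                raise ValidationError(
                    f"half-map length {_map_length(half, self.seq_length)} != "
                    f"figure length {self.seq_length}"
                )
        for k in SLOT_RANGE:
            self.slots.setdefault(k, TrackSlot(k))

    def occupied_slots(self) -> list[TrackSlot]:
        return [self.slots[k] for k in SLOT_RANGE if self.slots[k].occupied]


def _map_length(m: MapLike, default: int) -> int:
    if isinstance(m, (ContactMap, Distogram)):
        return m.seq_length
    return default  # MatchClassification carries no length


def assign_track(
    spec: FigureSpec,
    slot: int,
    track: AnnotationTrack,
    mirror: bool = False,
    overwrite: bool = False,
) -> FigureSpec:
    """Place ``track`` in ``slot``; with ``mirror``, slot ``-slot`` repeats it
    reflected across the diagonal.  Occupied slots are refused unless
    ``overwrite``.  Returns the (mutated) spec for chaining."""
    if slot not in SLOT_RANGE:
        raise ValidationError(
            f"slot {slot} out of range; slots are numbered -4..+4"
        )
    if track.seq_length != spec.seq_length:
        raise ValidationError(
            f"track '{track.name}' length {track.seq_length} != "
            f"figure length {spec.seq_length}"
        )
    targets = [slot] if (not mirror or slot == 0) else [slot, -slot]
    for t in targets:
        if spec.slots[t].occupied and not overwrite:
            raise ValidationError(f"slot {t} already occupied")
    spec.slots[slot] = TrackSlot(slot, track, mirrored=False)
    if mirror and slot != 0:
        spec.slots[-slot] = TrackSlot(-slot, track, mirrored=True)
    return spec


# ---------------------------------------------------------------------------
# band geometry
# ---------------------------------------------------------------------------

def _strip_polygon(lo: float, hi: float, seq_length: int) -> Polygon:
    """Region with diagonal offset j - i in [lo, hi], clipped to the plot square."""
    big = 4.0 * seq_length + 100.0
    strip = Polygon(
        [(-big, -big + lo), (big, big + lo), (big, big + hi), (-big, -big + hi)]
    )
    return strip.intersection(box(1, 1, seq_length, seq_length))


def slot_geometry(
    slot_index: int, seq_length: int, band_width: float = DEFAULT_BAND_WIDTH
) -> Band:
    """Placement of slot ``slot_index``'s diagonal band (see module docstring)."""
    if band_width <= 0:
        raise ValidationError(f"band width must be > 0, got {band_width}")
    if slot_index not in SLOT_RANGE:
        raise ValidationError(
            f"slot {slot_index} out of range; slots are numbered -4..+4"
        )
    lo = slot_index * band_width - band_width / 2.0
    hi = slot_index * band_width + band_width / 2.0
    poly = _strip_polygon(lo, hi, seq_length)
    coords = (
        tuple(poly.exterior.coords)
        if poly.geom_type == "Polygon" and poly.area > 0
        else ()
    )
    return Band(slot=slot_index, offset_lo=lo, offset_hi=hi, polygon=coords)


def cell_slot(i: int, j: int, band_width: float = DEFAULT_BAND_WIDTH) -> int | None:
    """Slot claiming cell ``(i, j)``, or None when outside the track region.

    Bands are half-open in the offset ``o = j - i`` (``k*w - w/2 <= o <
    k*w + w/2``), so every cell belongs to at most one slot.
    """
    k = math.floor((j - i) / band_width + 0.5)
    return k if k in SLOT_RANGE else None


def _segment_polygon(
    band_lo: float, band_hi: float, start: int, end: int, seq_length: int
) -> tuple[tuple[float, float], ...]:
    """Intersection of a band with the diagonal-position range of one run."""
    big = 4.0 * seq_length + 100.0
    band = Polygon(
        [
            (-big, -big + band_lo),
            (big, big + band_lo),
            (big, big + band_hi),
            (-big, -big + band_hi),
        ]
    )
    s_lo, s_hi = 2.0 * start - 1.0, 2.0 * end + 1.0  # bounds on x + y
    anti = Polygon(
        [(s_lo + big, -big), (-big, s_lo + big), (-big, s_hi + big), (s_hi + big, -big)]
    )
    poly = band.intersection(anti).intersection(box(1, 1, seq_length, seq_length))
    if poly.geom_type != "Polygon" or poly.area <= 0:
        return ()
    return tuple(poly.exterior.coords)


# ---------------------------------------------------------------------------
# scene building
# ---------------------------------------------------------------------------

def _classification_layers(
    mc: MatchClassification, half: str, min_sep: int
) -> list[PointLayer]:
    layers = []
    for label, pairs in (
        ("matched", mc.matched),
        ("model-only", mc.model_only),
        ("predicted-only", mc.predicted_only),
    ):
        pts = _half_points(pairs, half, min_sep)
        layers.append(PointLayer(label, CLASSIFICATION_PALETTE[label], pts))
    return layers


def _half_points(
    pairs, half: str, min_sep: int
) -> tuple[tuple[float, float], ...]:
    out = []
    for i, j in sorted(pairs):
        if j - i < min_sep:
            continue
        out.append((float(i), float(j)) if half == "upper" else (float(j), float(i)))
    return tuple(out)


def _heat_layer(
    m: MapLike, half: str, spec: FigureSpec, label: str
) -> CellLayer:
    if isinstance(m, Distogram):
        if spec.heatmap_metric == "expected_distance":
            values = {
                (i, j): m.expected_distance(i, j) for (i, j) in m.entries
            }
            cmap_name, vmin = "viridis_r", 0.0
            vmax = max((hi for _, hi in m.bins if math.isfinite(hi)), default=20.0) + 2.0
        else:
            as_contacts = distogram_to_contacts(m, spec.contact_max_distance)
            values = {(c.i, c.j): c.score for c in as_contacts.contacts}
            cmap_name, vmin, vmax = "viridis", 0.0, 1.0
    elif isinstance(m, ContactMap):
        values = {(c.i, c.j): c.score for c in m.contacts}
        cmap_name, vmin, vmax = "viridis", 0.0, 1.0
    else:
        raise ValidationError(
            "heatmap mode requires a distogram or a scored contact map"
        )
    cmap = matplotlib.colormaps[cmap_name]
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
    cells = []
    for (i, j), v in sorted(values.items()):
        if j - i < spec.min_sep:
            continue
        x, y = (i, j) if half == "upper" else (j, i)
        cells.append(
            HeatCell(float(x), float(y), float(v), mcolors.to_hex(cmap(norm(v))))
        )
    return CellLayer(label, cmap_name, vmin, vmax, tuple(cells))


def _half_layers(
    m: MapLike, half: str, spec: FigureSpec
) -> tuple[list[PointLayer], list[CellLayer]]:
    colour = spec.upper_colour if half == "upper" else spec.lower_colour
    if isinstance(m, MatchClassification):
        if spec.mode == "heatmap":
            raise ValidationError(
                "heatmap mode requires a distogram or a scored contact map"
            )
        return _classification_layers(m, half, spec.min_sep), []
    if spec.mode == "heatmap":
        return [], [_heat_layer(m, half, spec, f"{half} map")]
    if isinstance(m, Distogram):
        m = distogram_to_contacts(m, spec.contact_max_distance)
    return [PointLayer(f"{half} map", colour, _half_points(m.pairs(), half, spec.min_sep))], []


def build_figure(spec: FigureSpec) -> Scene:
    """Turn a :class:`FigureSpec` into a render-ready :class:`Scene`.

    The scene holds point (or heat-cell) layers for each filled half, one
    coloured segment per maximal run of identical track states per occupied
    slot, and a legend listing every (track, label) colour pair once.
    Contacts closer to the diagonal than ``spec.min_sep`` are excluded from
    the data layers.
    """
    occupied = spec.occupied_slots()
    if spec.upper_map is None and spec.lower_map is None and not occupied:
        raise ValidationError("nothing to draw")

    point_layers: list[PointLayer] = []
    cell_layers: list[CellLayer] = []
    if spec.upper_map is not None:
        pts, cells = _half_layers(spec.upper_map, "upper", spec)
        point_layers += pts
        cell_layers += cells
    if spec.lower_map is not None:
        pts, cells = _half_layers(spec.lower_map, "lower", spec)
        point_layers += pts
        cell_layers += cells

    if occupied and (point_layers or cell_layers):
        outermost = max(abs(s.index) for s in occupied)
        extent = outermost * spec.band_width + spec.band_width / 2.0
        if extent > spec.min_sep:
            warnings.warn(
                f"tracks extend to |i-j| <= {extent:g} but the blanking cut-off "
                f"is {spec.min_sep}; tracks may overlap plotted contacts"
            )

    segments: list[TrackSegment] = []
    for slot in occupied:
        band = slot_geometry(slot.index, spec.seq_length, spec.band_width)
        for start, end, state in slot.track.runs():
            colour = slot.track.palette[state]
            if colour == "none":
                continue
            poly = _segment_polygon(
                band.offset_lo, band.offset_hi, start, end, spec.seq_length
            )
            if not poly:
                continue
            segments.append(
                TrackSegment(
                    slot=slot.index,
                    track_name=slot.track.name,
                    label=state,
                    colour=colour,
                    start=start,
                    end=end,
                    polygon=poly,
                )
            )

    legend: list[LegendEntry] = []
    seen: set[tuple[str, str]] = set()
    for layer in point_layers:
        if (("map", layer.label)) not in seen and layer.points:
            seen.add(("map", layer.label))
            legend.append(LegendEntry("map", layer.label, layer.colour))
    for seg in segments:
        key = (seg.track_name, seg.label)
        if key not in seen:
            seen.add(key)
            legend.append(LegendEntry(seg.track_name, seg.label, seg.colour))

    return Scene(
        seq_length=spec.seq_length,
        point_layers=tuple(point_layers),
        cell_layers=tuple(cell_layers),
        segments=tuple(segments),
        legend=tuple(legend),
    )


@dataclass(slots=True)
class FigureConfig:
    """Figure options loaded from a plain-text (YAML) config file.

    Schema: the scalar keys ``mode``, ``min_sep``, ``band_width``,
    ``upper_colour``, ``lower_colour``, ``heatmap_metric``,
    ``contact_max_distance`` and ``dpi`` mirror :class:`FigureSpec` /
    renderer options; ``tracks`` is a list of mappings with keys ``slot``
    (required, -4..+4), ``file`` (required), ``format`` (optional: ss2,
    iupred, topcons, consurf, custom) and ``mirror`` (optional bool).
    Unset keys stay ``None`` so callers can layer command-line flags on top.
    """

    mode: str | None = None
    min_sep: int | None = None
    band_width: float | None = None
    upper_colour: str | None = None
    lower_colour: str | None = None
    heatmap_metric: str | None = None
    contact_max_distance: float | None = None
    dpi: int | None = None
    tracks: list[dict] = field(default_factory=list)


def load_figure_config(text: str) -> FigureConfig:
    """Parse a YAML figure configuration (see :class:`FigureConfig` schema)."""
    import yaml

    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse figure config: {exc}") from exc
    if data is None:
        return FigureConfig()
    if not isinstance(data, dict):
        raise ValidationError("figure config must be a mapping of options")
    unknown = sorted(set(data) - set(CONFIG_KEYS))
    if unknown:
        raise ValidationError(
            f"unknown figure config key(s) {unknown}; accepted: {list(CONFIG_KEYS)}"
        )
    tracks = data.pop("tracks", []) or []
    for entry in tracks:
        if not isinstance(entry, dict) or "slot" not in entry or "file" not in entry:
            raise ValidationError(
                "each tracks entry needs at least 'slot' and 'file' keys"
            )
        if int(entry["slot"]) not in SLOT_RANGE:
            raise ValidationError(
                f"track slot {entry['slot']} out of range; slots are numbered -4..+4"
            )
    return FigureConfig(tracks=list(tracks), **data)
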