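"""Figure geometry: slots, diagonal bands, scene building."""

import numpy as np
import pytest

from cmapviz.errors import ValidationError
from cmapviz.layout import (
    CLASSIFICATION_PALETTE,
    SLOT_RANGE,
    FigureSpec,
    assign_track,
    build_figure,
    cell_slot,
    slot_geometry,
)
from cmapviz.model import AnnotationTrack, Distogram, canonicalize
from cmapviz.compare import superpose
from cmapviz.parsers import parse_topcons
from conftest import random_contact_map


def flat_track(seq_length: int, name: str = "t", label: str = "x", colour: str = "red"):
    return AnnotationTrack(
        name=name, seq_length=seq_length, states=[label] * seq_length,
        palette={label: colour},
    )


class TestSlots:
    def test_exactly_nine_addressable_slots(self):
        spec = FigureSpec(seq_length=30)
        assert sorted(spec.slots) == list(range(-4, 5))
        assert len(SLOT_RANGE) == 9 and 0 in SLOT_RANGE

    def test_out_of_range_slot_rejected(self):
        spec = FigureSpec(seq_length=30)
        with pytest.raises(ValidationError, match="-4..\\+4"):
            assign_track(spec, 5, flat_track(30))

    def test_mirror_of_slot_zero_is_noop(self):
        spec = FigureSpec(seq_length=30)
        assign_track(spec, 0, flat_track(30), mirror=True)
        assert spec.slots[0].occupied
        assert sum(s.occupied for s in spec.slots.values()) == 1

    def test_mirror_fills_negative_slot(self):
        spec = FigureSpec(seq_length=30)
        assign_track(spec, 2, flat_track(30), mirror=True)
        assert spec.slots[2].occupied and spec.slots[-2].occupied
        assert spec.slots[-2].mirrored and not spec.slots[2].mirrored

    def test_length_mismatch_rejected(self):
        spec = FigureSpec(seq_length=60)
        with pytest.raises(ValidationError, match="length"):
            assign_track(spec, 1, flat_track(50))

    def test_occupied_slot_needs_overwrite(self):
        spec = FigureSpec(seq_length=30)
        assign_track(spec, 1, flat_track(30))
        with pytest.raises(ValidationError, match="occupied"):
            assign_track(spec, 1, flat_track(30, name="other"))
        assign_track(spec, 1, flat_track(30, name="other"), overwrite=True)
        assert spec.slots[1].track.name == "other"


class TestSlotGeometry:
    def test_slot_zero_band_centered_on_diagonal(self):
        band = slot_geometry(0, 100, 2.0)
        assert band.offset_lo == -1.0 and band.offset_hi == 1.0

    def test_positive_and_negative_slots_reflect(self):
        plus = slot_geometry(1, 100, 2.0)
        minus = slot_geometry(-1, 100, 2.0)
        assert plus.offset_lo == -minus.offset_hi
        assert plus.offset_hi == -minus.offset_lo
        # reflecting the +1 band across the diagonal gives the -1 band
        reflected = {(y, x) for x, y in plus.polygon}
        assert reflected == set(minus.polygon)

    def test_rasterized_cells_claim_at_most_one_slot(self):
        # every integer cell of a 100-residue square belongs to at most one
        # of the 9 unit-width bands
        claims = {}
        for i in range(1, 101):
            for j in range(1, 101):
                k = cell_slot(i, j, band_width=1.0)
                if k is not None:
                    assert claims.setdefault((i, j), k) == k
        offsets = {k for k in claims.values()}
        assert offsets == set(range(-4, 5))

    def test_band_width_must_be_positive(self):
        with pytest.raises(ValidationError):
            slot_geometry(0, 50, 0.0)


class TestBuildFigure:
    def test_classification_gives_black_red_grey_layers(self, rng):
        L = 60
        p = random_contact_map(rng, L, density=0.06, min_sep=6)
        m = random_contact_map(rng, L, density=0.06, min_sep=6)
        mc = superpose(p, m)
        scene = build_figure(FigureSpec(seq_length=L, upper_map=mc))
        colours = {layer.label: layer.colour for layer in scene.point_layers}
        assert colours == CLASSIFICATION_PALETTE

    def test_topology_track_run_length_segments(self):
        track = parse_topcons("ooMMMiii")
        cmap = canonicalize([(1, 8, 1.0)], seq_length=8)
        spec = FigureSpec(seq_length=8, upper_map=cmap, min_sep=5, band_width=0.5)
        assign_track(spec, 0, track)
        scene = build_figure(spec)
        slot0 = [s for s in scene.segments if s.slot == 0]
        assert [s.label for s in slot0] == ["outside", "membrane", "inside"]

    def test_segment_count_matches_run_length_oracle(self, rng):
        L = 50
        states = [str(rng.integers(0, 3)) for _ in range(L)]
        runs = 1 + sum(a != b for a, b in zip(states, states[1:]))
        track = AnnotationTrack(
            name="r", seq_length=L, states=states,
            palette={"0": "red", "1": "green", "2": "blue"},
        )
        spec = FigureSpec(seq_length=L, band_width=1.0)
        assign_track(spec, 0, track)
        scene = build_figure(spec)
        assert len([s for s in scene.segments if s.slot == 0]) == runs

    def test_blanking_excludes_near_diagonal_contacts(self):
        cmap = canonicalize([(1, 3, 1.0), (1, 20, 1.0)], seq_length=30)
        scene = build_figure(FigureSpec(seq_length=30, upper_map=cmap, min_sep=5))
        pts = scene.point_layers[0].points
        assert pts == ((1.0, 20.0),)

    def test_symmetric_spec_invariant_under_transposition(self, rng):
        cmap = random_contact_map(rng, 40, density=0.1, min_sep=6)
        scene = build_figure(
            FigureSpec(seq_length=40, upper_map=cmap, lower_map=cmap)
        )
        pts = {p for layer in scene.point_layers for p in layer.points}
        assert pts == {(y, x) for x, y in pts}

    def test_empty_spec_rejected(self):
        with pytest.raises(ValidationError, match="nothing to draw"):
            build_figure(FigureSpec(seq_length=30))

    def test_track_contact_overlap_warns(self, rng):
        cmap = random_contact_map(rng, 60, density=0.1, min_sep=6)
        spec = FigureSpec(seq_length=60, upper_map=cmap, min_sep=5)
        assign_track(spec, 4, flat_track(60))
        with pytest.warns(UserWarning, match="overlap"):
            build_figure(spec)

    def test_track_segments_stay_outside_other_slots(self):
        # geometric disjointness at the rasterized grid: cells covered by one
        # slot's segments never fall in another slot's band
        track = parse_topcons("o" * 10 + "M" * 10 + "i" * 10)
        spec = FigureSpec(seq_length=30, band_width=1.0)
        assign_track(spec, 1, track)
        assign_track(spec, -2, track)
        scene = build_figure(spec)
        from shapely.geometry import Point, Polygon

        for seg in scene.segments:
            poly = Polygon(seg.polygon)
            for i in range(1, 31):
                for j in range(1, 31):
                    if poly.contains(Point(i, j)):
                        assert cell_slot(i, j, 1.0) == seg.slot

    def test_heatmap_from_distogram_expected_distance(self):
        vec = np.zeros(10)
        vec[0] = 1.0
        d = Distogram(seq_length=30, entries={(1, 20): vec})
        spec = FigureSpec(
            seq_length=30, upper_map=d, mode="heatmap",
            heatmap_metric="expected_distance",
        )
        scene = build_figure(spec)
        cells = scene.cell_layers[0].cells
        assert len(cells) == 1
        assert cells[0].value == pytest.approx(2.0)

    def test_heatmap_rejects_classification(self, rng):
        p = random_contact_map(rng, 30, density=0.1)
        mc = superpose(p, p)
        with pytest.raises(ValidationError, match="heatmap"):
            build_figure(FigureSpec(seq_length=30, upper_map=mc, mode="heatmap"))

    def test_legend_lists_each_track_label_once(self):
        track = parse_topcons("ooMMMiiiooMMM")
        spec = FigureSpec(seq_length=13, band_width=0.5)
        assign_track(spec, 0, track)
        assign_track(spec, 1, track, overwrite=True)
        scene = build_figure(spec)
        labels = [(e.group, e.label) for e in scene.legend]
        assert len(labels) == len(set(labels)) == 3


class TestFigureConfig:
    def test_scalar_and_track_keys_loaded(self):
        from cmapviz.layout import load_figure_config

        cfg = load_figure_config(
            "mode: heatmap\nmin_sep: 8\ntracks:\n"
            "  - {slot: 0, file: topo.txt, format: topcons}\n"
            "  - {slot: 1, file: ss.ss2, mirror: true}\n"
        )
        assert cfg.mode == "heatmap" and cfg.min_sep == 8
        assert len(cfg.tracks) == 2 and cfg.tracks[1]["mirror"] is True

    def test_unknown_key_rejected(self):
        from cmapviz.layout import load_figure_config

        with pytest.raises(ValidationError, match="unknown figure config key"):
            load_figure_config("colour_scheme: dark\n")

    def test_track_entry_needs_slot_and_file(self):
        from cmapviz.layout import load_figure_config

        with pytest.raises(ValidationError, match="slot"):
            load_figure_config("tracks:\n  - {file: x.txt}\n")

    def test_empty_config_gives_all_defaults(self):
        from cmapviz.layout import load_figure_config

        cfg = load_figure_config("")
        assert cfg.mode is None and cfg.tracks == []
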