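"""Emit a :class:`~cmapviz.layout.Scene` as a static PNG or SVG image.

SVG output is deterministic byte-for-byte for a fixed scene and library
version: the SVG hash salt is pinned and no timestamp metadata is written,
so golden-file comparisons are possible.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg", force=False)

from matplotlib import pyplot as plt
from matplotlib.lines import Line2D
from matplotlib.patches import Patch, Polygon as MplPolygon

from .errors import ValidationError
from .layout import Scene

SUPPORTED_FORMATS = ("png", "svg")
_SVG_HASH_SALT = "cmapviz"


def render(scene: Scene, path: str | os.PathLike, fmt: str = "png", dpi: int = 150) -> str:
    """Draw the scene and write it to ``path``; returns the path written.

    The figure is square, with residue index i on x and j on y, origin (1, 1)
    at the bottom-left.  The legend lists every (track, label) colour pair in
    the scene.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValidationError(
            f"unknown format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    if not (scene.point_layers or scene.cell_layers or scene.segments):
        raise ValidationError("refusing to render an empty scene")

    # keep SVG text as text (searchable, stable) rather than glyph paths
    with plt.rc_context({"svg.hashsalt": _SVG_HASH_SALT, "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=(8, 8))
        try:
            L = scene.seq_length
            for layer in scene.cell_layers:
                for cell in layer.cells:
                    ax.add_patch(
                        plt.Rectangle(
                            (cell.x - 0.5, cell.y - 0.5), 1.0, 1.0,
                            facecolor=cell.colour, edgecolor="none",
                        )
                    )
            for seg in scene.segments:
                ax.add_patch(
                    MplPolygon(
                        list(seg.polygon), closed=True,
                        facecolor=seg.colour, edgecolor="none", zorder=2,
                    )
                )
            for layer in scene.point_layers:
                if not layer.points:
                    continue
                xs = [p[0] for p in layer.points]
                ys = [p[1] for p in layer.points]
                ax.scatter(xs, ys, s=6, c=layer.colour, marker="o",
                           linewidths=0, zorder=3, label=layer.label)

            handles = []
            for entry in scene.legend:
                if entry.group == "map":
                    handles.append(
                        Line2D([], [], linestyle="", marker="o", markersize=5,
                               color=entry.colour, label=entry.label)
                    )
                else:
                    handles.append(
                        Patch(facecolor=entry.colour,
                              label=f"{entry.group}: {entry.label}")
                    )
            if handles:
                ax.legend(handles=handles, loc="upper left",
                          bbox_to_anchor=(1.02, 1.0), fontsize=8, frameon=False)

            ax.set_xlim(0.5, L + 0.5)
            ax.set_ylim(0.5, L + 0.5)
            ax.set_aspect("equal")
            ax.set_xlabel("Residue i")
            ax.set_ylabel("Residue j")
            try:
                fig.savefig(
                    path, format=fmt, dpi=dpi, bbox_inches="tight",
                    metadata={"Date": None} if fmt == "svg" else None,
                )
            except OSError as exc:
                raise OSError(f"cannot write image to {path}: {exc}") from exc
        finally:
            plt.close(fig)
    return os.fspath(path)
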