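"""Stream-like visualization of colony lineages.

Each colony is drawn as a vertical stream flowing downwards in time: the
stream width at a frame is proportional to a chosen feature (by default
the colony area, normalised by the frame area so that a total width of 1
means complete confluency), and the color encodes a second feature (by
default circularity: red = round, blue = irregular).  Merging and
splitting colonies appear as converging and diverging streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StreamStyle", "StreamLayout", "layout_streams", "render_streams"]


@dataclass
class StreamStyle:
    gap: float = 0.01           # horizontal gap between adjacent streams,
                                # excluded from the width-normalisation budget
    cmap: str = "coolwarm"      # low -> blue, high -> red
    downward_time: bool = True


@dataclass
class StreamLayout:
    """Per (frame, colony): [left, right] interval and a color value in [0,1]."""

    intervals: dict = field(default_factory=dict)  # (frame, label) -> (left, right)
    colors: dict = field(default_factory=dict)     # (frame, label) -> float
    frames: list = field(default_factory=list)
    order: dict = field(default_factory=dict)      # frame -> [labels left..right]
    edges: list = field(default_factory=list)      # (parent(f,l), child(f,l), event)
    width_feature: str = "area_px"
    color_feature: str = "circularity"


def _feature(rec, name: str) -> float:
    return float(getattr(rec, name))


def layout_streams(
    graph,
    records,
    width_feature: str = "area_px",
    color_feature: str = "circularity",
    frame_shape: tuple[int, int] | None = None,
    style: StreamStyle | None = None,
) -> StreamLayout:
    """Assign each (frame, colony) a disjoint horizontal interval.

    Widths are the feature value normalised by the frame pixel count (for
    ``area_px`` the widths at a frame then sum exactly to the covered-area
    fraction); gaps between adjacent streams sit outside that budget.
    Ordering: the first frame is sorted by centroid column; later frames
    inherit the previous order, split children take the parent's slot and
    new colonies append on the right.
    """
    style = style or StreamStyle()
    rec_by_node = {(r.frame_index, r.colony_id): r for r in records}
    for node in graph.nodes:
        if node not in rec_by_node:
            raise ValueError(f"graph node {node} has no feature record")
    if frame_shape is None:
        norm = max((_feature(r, width_feature) for r in records), default=1.0) or 1.0
    else:
        norm = float(frame_shape[0] * frame_shape[1])

    cvals = [_feature(r, color_feature) for r in records]
    cmin, cmax = min(cvals), max(cvals)
    cspan = (cmax - cmin) or 1.0

    frames = sorted({f for f, _ in graph.nodes})
    layout = StreamLayout(width_feature=width_feature, color_feature=color_feature)
    layout.frames = frames
    # forward-time orientation: parent frame may precede or follow child
    # frame depending on processing direction; normalise to time order
    succ: dict = {}
    for p, c in graph.edges:
        d = graph.edges[p, c]
        a, b = (p, c) if p[0] < c[0] else (c, p)
        succ.setdefault(a, []).append((b, d["event"]))
        layout.edges.append((a, b, d["event"]))

    prev_order: list[int] = []
    for fi, f in enumerate(frames):
        labels_here = sorted(l for (fr, l) in graph.nodes if fr == f)
        if fi == 0:
            order = sorted(labels_here, key=lambda l: rec_by_node[(f, l)].centroid[1])
        else:
            order = []
            placed = set()
            for l_prev in prev_order:
                kids = [b[1] for (b, _e) in succ.get((frames[fi - 1], l_prev), [])
                        if b[0] == f]
                for k in sorted(set(kids), key=lambda l: rec_by_node[(f, l)].centroid[1]):
                    if k not in placed and k in labels_here:
                        order.append(k)
                        placed.add(k)
            for l in labels_here:  # newly appearing colonies go to the right
                if l not in placed:
                    order.append(l)
        layout.order[f] = order
        x = 0.0
        for l in order:
            w = _feature(rec_by_node[(f, l)], width_feature) / norm
            layout.intervals[(f, l)] = (x, x + w)
            layout.colors[(f, l)] = (_feature(rec_by_node[(f, l)], color_feature) - cmin) / cspan
            x += w + style.gap
        prev_order = order
    return layout


def render_streams(layout: StreamLayout, style: StreamStyle | None = None,
                   path: str | None = None):
    """Render the layout as an SVG/PNG with a downward time axis.

    Stream boundaries are interpolated between frames with a monotone
    cubic (PCHIP), so bands converge and diverge smoothly; each stream
    segment carries a ``stream-*`` group id in the SVG for inspection.
    Output is deterministic for fixed input.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from scipy.interpolate import PchipInterpolator

    style = style or StreamStyle()
    cmap = colormaps[style.cmap]
    fig, ax = plt.subplots(figsize=(7, 8))

    # group consecutive-frame presence of each label into runs
    labels = sorted({l for (_f, l) in layout.intervals})
    n_polys = 0
    for l in labels:
        fs = sorted(f for (f, ll) in layout.intervals if ll == l)
        runs: list[list[int]] = []
        for f in fs:
            if runs and f == runs[-1][-1] + 1:
                runs[-1].append(f)
            else:
                runs.append([f])
        for run in runs:
            t = np.asarray(run, dtype=float)
            left = np.asarray([layout.intervals[(f, l)][0] for f in run])
            right = np.asarray([layout.intervals[(f, l)][1] for f in run])
            col = cmap(float(np.mean([layout.colors[(f, l)] for f in run])))
            if len(run) == 1:
                tt = np.array([t[0] - 0.4, t[0] + 0.4])
                li, ri = np.repeat(left, 2), np.repeat(right, 2)
            else:
                tt = np.linspace(t[0], t[-1], 8 * (len(run) - 1) + 1)
                li = PchipInterpolator(t, left)(tt)
                ri = PchipInterpolator(t, right)(tt)
            poly = ax.fill_betweenx(tt, li, ri, color=col, linewidth=0)
            poly.set_gid(f"stream-{l}-{run[0]}")
            n_polys += 1

    ax.set_xlabel(f"width ∝ {layout.width_feature} (1 = confluent)")
    ax.set_ylabel("frame")
    if style.downward_time:
        ax.invert_yaxis()
    if layout.frames:
        ax.set_yticks(layout.frames)
    sm = plt.cm.ScalarMappable(cmap=cmap)
    sm.set_array([0, 1])
    fig.colorbar(sm, ax=ax, orientation="horizontal", pad=0.08,
                 label=layout.color_feature + " (normalised)")
    if path is not None:
        with matplotlib.rc_context({"svg.hashsalt": "colonytrack"}):
            fig.savefig(path, metadata=_clean_metadata(str(path)))
        plt.close(fig)
        return n_polys
    return fig


def _clean_metadata(path: str) -> dict:
    """Strip creation timestamps so identical inputs give identical bytes."""
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
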