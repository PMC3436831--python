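"""Colony tracking by label propagation through displacement fields.

The tracker iterates, per frame pair: fluid registration -> nearest-
neighbour warp of the previous label mask -> fresh segmentation of the new
frame (initialised by the propagated mask) -> reconciliation of propagated
and segmented masks.  Reconciliation distinguishes four cases:

one-to-one
    A segmented object overlaps exactly one propagated label and vice
    versa: the segmented shape is kept under the propagated label.
merge
    One segmented object overlaps several propagated labels: the
    propagated masks are kept (partitioning the blob) and the segmented
    outline is discarded, so fused colonies retain their identities.
split
    One propagated label overlaps several segmented objects: the
    segmented shapes are kept and every sub-object receives a fresh
    label, recording clonal inheritance.
new
    A segmented object with no propagated counterpart gets a fresh label.

Backward tracking processes the reversed sequence — forward-time fusions
become splits, which the segmentation delineates more reliably than the
warped masks — and re-indexes the output to original frame order,
exchanging the merge/split event roles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import ndimage

from .registration import RegistrationParams, register_pair
from .segmentation import SegmentationParams, active_contour_segment, fill_holes, \
    relabel_raster_order, retinex_correct, segment_colonies, tv_denoise

log = logging.getLogger(__name__)

__all__ = [
    "TrackingParams",
    "TrackGraph",
    "propagate_labels",
    "overlap_table",
    "reconcile",
    "track_sequence",
]

EVENTS = ("continue", "merge", "split", "appear")


@dataclass
class TrackingParams:
    min_overlap_px: int = 10
    direction: str = "backward"
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.min_overlap_px < 1:
            raise ValueError("min_overlap_px must be >= 1")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")


class TrackGraph:
    """Colony lineage: nodes are (frame, label), edges carry an event type."""

    def __init__(self, direction: str = "forward") -> None:
        self.g = nx.DiGraph()
        self.direction = direction

    def add_node(self, frame: int, label: int, centroid=(float("nan"), float("nan"))) -> None:
        self.g.add_node((frame, label), frame=frame, label=label,
                        centroid=(float(centroid[0]), float(centroid[1])))

    def add_edge(self, parent: tuple[int, int], child: tuple[int, int], event: str) -> None:
        if event not in EVENTS:
            raise ValueError(f"unknown event {event!r}")
        self.g.add_edge(parent, child, event=event)

    @property
    def nodes(self):
        return self.g.nodes

    @property
    def edges(self):
        return self.g.edges

    def to_json(self, path: str | Path) -> None:
        doc = {
            "direction": self.direction,
            "nodes": [
                {"id": f"{f}:{l}", "frame": int(f), "label": int(l),
                 "centroid": list(self.g.nodes[(f, l)].get("centroid", (None, None)))}
                for (f, l) in sorted(self.g.nodes)
            ],
            "edges": [
                {"parent": f"{p[0]}:{p[1]}", "child": f"{c[0]}:{c[1]}",
                 "event": self.g.edges[p, c]["event"]}
                for p, c in sorted(self.g.edges)
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackGraph":
        try:
            doc = json.loads(Path(path).read_text())
            tg = cls(direction=doc.get("direction", "forward"))
            for n in doc["nodes"]:
                c = n.get("centroid") or (float("nan"), float("nan"))
                tg.add_node(int(n["frame"]), int(n["label"]), c)
            for e in doc["edges"]:
                pf, pl = e["parent"].split(":")
                cf, cl = e["child"].split(":")
                tg.add_edge((int(pf), int(pl)), (int(cf), int(cl)), e["event"])
            return tg
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"malformed track-graph file {path}: {exc}") from exc

    def events_at(self, event: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return [(p, c) for p, c, d in self.g.edges(data=True) if d["event"] == event]


def propagate_labels(labels: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Warp an integer label mask with nearest-neighbour sampling at x - u(x).

    Label values are preserved exactly; no interpolation-invented labels.
    """
    labels = np.asarray(labels)
    if u.shape != (2, *labels.shape):
        raise ValueError("field shape does not match mask")
    h, w = labels.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    out = ndimage.map_coordinates(
        labels, np.stack([rr - u[0], cc - u[1]]), order=0, mode="nearest"
    )
    return out.astype(labels.dtype)


def overlap_table(L_hat: np.ndarray, L_seg: np.ndarray, min_overlap_px: int = 1) -> dict:
    """Shared-pixel counts {(propagated label, segmented label): n} with
    n >= min_overlap_px; background pairs excluded."""
    L_hat = np.asarray(L_hat)
    L_seg = np.asarray(L_seg)
    if L_hat.shape != L_seg.shape:
        raise ValueError("masks differ in shape")
    both = (L_hat > 0) & (L_seg > 0)
    if not both.any():
        return {}
    pairs = np.stack([L_hat[both], L_seg[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {
        (int(a), int(b)): int(n)
        for (a, b), n in zip(uniq.T, counts)
        if n >= min_overlap_px
    }


def _nearest_label_fill(blob: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Assign unlabeled pixels of `blob` to the nearest seed label inside it.

    Ties go to the smaller label id (EDT returns one nearest index; we get
    determinism by iterating labels in increasing order and keeping the
    first at equal distance).
    """
    out = np.where(blob, seeds, 0)
    missing = blob & (seeds == 0)
    if not missing.any():
        return out
    best_d = np.full(blob.shape, np.inf)
    for lab in sorted(int(v) for v in np.unique(seeds[blob]) if v > 0):
        d = ndimage.distance_transform_edt(~((seeds == lab) & blob))
        take = missing & (d < best_d - 1e-9)
        out[take] = lab
        best_d = np.minimum(best_d, d)
    return out


def reconcile(
    L_hat: np.ndarray,
    L_seg: np.ndarray,
    next_free_label: int,
    min_overlap_px: int = 10,
) -> tuple[np.ndarray, list[dict], int]:
    """Fuse propagated and freshly segmented masks into a consistent labeling.

    Returns (mask, events, next_free_label); events are dicts with keys
    ``type``, ``parents`` (propagated labels), ``children`` (labels in the
    output mask) and ``links`` (explicit parent->child label pairs; in a
    merge every parent continues under its own label inside the fused
    blob).  Mixed merge/split participation resolves merges first, then
    splits on the residual correspondences.
    """
    L_hat = np.asarray(L_hat)
    L_seg = np.asarray(L_seg)
    if L_hat.shape != L_seg.shape:
        raise ValueError("masks differ in shape")
    if next_free_label <= int(L_hat.max(initial=0)):
        raise ValueError("next_free_label must exceed all propagated labels")
    table = overlap_table(L_hat, L_seg, min_overlap_px)
    parents_of = {}  # seg label -> set of propagated labels
    children_of = {}  # propagated label -> set of seg labels
    for (a, b), _n in table.items():
        parents_of.setdefault(b, set()).add(a)
        children_of.setdefault(a, set()).add(b)

    out = np.zeros_like(L_hat, dtype=np.int32)
    events: list[dict] = []
    seg_labels = [int(v) for v in np.unique(L_seg) if v > 0]

    # pass 1: merges (segmented blob with >= 2 propagated parents)
    merged_segs = set()
    for b in seg_labels:
        parents = parents_of.get(b, set())
        if len(parents) < 2:
            continue
        merged_segs.add(b)
        blob = L_seg == b
        seeds = np.where(blob & np.isin(L_hat, list(parents)), L_hat, 0)
        out[blob] = _nearest_label_fill(blob, seeds)[blob]
        events.append({"type": "merge", "parents": sorted(parents),
                       "children": sorted(parents),
                       "links": [(a, a) for a in sorted(parents)]})

    # pass 2: splits / one-to-one / new on the residual
    for b in seg_labels:
        if b in merged_segs:
            continue
        parents = parents_of.get(b, set())
        if not parents:
            out[L_seg == b] = next_free_label
            events.append({"type": "appear", "parents": [],
                           "children": [next_free_label],
                           "links": [(None, next_free_label)]})
            next_free_label += 1
            continue
        (a,) = parents
        siblings = children_of[a]
        if len(siblings) == 1:
            out[L_seg == b] = a
            events.append({"type": "continue", "parents": [a], "children": [a],
                           "links": [(a, a)]})
        else:
            # a overlaps several segmented objects -> split; every child
            # (that was not consumed by a merge) gets a fresh label
            out[L_seg == b] = next_free_label
            events.append({"type": "split", "parents": [a],
                           "children": [next_free_label],
                           "links": [(a, next_free_label)]})
            next_free_label += 1

    return out, events, next_free_label


def _label_groups(labels: np.ndarray) -> list[set[int]]:
    """Sets of labels sharing one 8-connected foreground blob."""
    comp, n = ndimage.label(labels > 0, structure=np.ones((3, 3)))
    groups = []
    for k in range(1, n + 1):
        ids = {int(v) for v in np.unique(labels[comp == k]) if v > 0}
        if ids:
            groups.append(ids)
    return groups


def _centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = [int(v) for v in np.unique(labels) if v > 0]
    if not ids:
        return {}
    cents = ndimage.center_of_mass(labels > 0, labels, ids)
    return {i: (float(c[0]), float(c[1])) for i, c in zip(ids, cents)}


def _segment_with_init(pixels: np.ndarray, init_mask: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Re-segmentation of one frame, initialised by the propagated mask.

    The contour evolves without morphological smoothing here: the TV step
    already regularises the data, and the smoothing operator would weld
    shut narrow gaps the initialisation happens to cover — precisely the
    gaps that signal a genuine colony split.
    """
    pre = tv_denoise(retinex_correct(pixels, p.retinex_sigma), p.tv_weight, p.tv_iterations)
    init = init_mask if init_mask.any() else None
    fg = active_contour_segment(pre, init, p.ac_iterations, ac_smoothing=0)
    # single-pixel strands are fixed points of the unsmoothed evolution;
    # a 4-connected opening removes them without closing true contacts
    fg = ndimage.binary_opening(
        fg, structure=ndimage.generate_binary_structure(2, 1))
    fg = fill_holes(fg)
    from skimage import measure

    from .segmentation import _remove_small

    if p.min_object_px > 0:
        fg = _remove_small(fg, p.min_object_px)
    return relabel_raster_order(measure.label(fg, connectivity=2))


def track_sequence(frames, params: TrackingParams | None = None):
    """Track colonies over a frame sequence.

    Returns (masks, fields, graph): one label mask per frame in original
    order, one displacement field per consecutive pair (in processing
    order, attached to the earlier processed frame), and the lineage graph.
    For ``direction='backward'`` the sequence is reversed before
    processing; output masks are re-indexed to original frame order and a
    processing-order split is reported as a forward-time merge and vice
    versa (the graph's ``direction`` attribute records the processing
    direction; edges run in processing order).
    """
    p = params or TrackingParams()
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    pix = [f.pixels if hasattr(f, "pixels") else np.asarray(f, dtype=np.float64) for f in frames]
    orig_index = list(range(len(pix)))
    if p.direction == "backward":
        pix = pix[::-1]
        orig_index = orig_index[::-1]

    graph = TrackGraph(direction=p.direction)
    masks_proc: list[np.ndarray] = []
    fields: list[np.ndarray] = []

    L = segment_colonies(pix[0], p.segmentation).astype(np.int32)
    masks_proc.append(L)
    next_free = int(L.max(initial=0)) + 1
    co_resident = _label_groups(L)
    for c_id, cen in _centroids(L).items():
        graph.add_node(orig_index[0], c_id, cen)
        # initial-frame objects enter the graph without a parent

    for k in range(len(pix) - 1):
        S, T = pix[k], pix[k + 1]
        try:
            reg = register_pair(S, T, p.registration)
            u = reg.field
        except FloatingPointError as exc:
            log.warning("registration failed on pair %d->%d (%s); identity field used",
                        orig_index[k], orig_index[k + 1], exc)
            u = np.zeros((2, *S.shape))
        fields.append(u)
        L_hat = propagate_labels(L, u)
        L_seg = _segment_with_init(T, L_hat > 0, p.segmentation)
        L_new, events, next_free = reconcile(L_hat, L_seg, next_free, p.min_overlap_px)
        cents = _centroids(L_new)
        f_parent, f_child = orig_index[k], orig_index[k + 1]
        for ev in events:
            ev_type = ev["type"]
            if ev_type == "merge" and any(
                set(ev["parents"]) <= g for g in co_resident
            ):
                # the group already shared one blob: not a new fusion
                ev_type = "continue"
            if p.direction == "backward" and ev_type in ("merge", "split"):
                ev_type = "split" if ev_type == "merge" else "merge"
            for parent, child in ev["links"]:
                graph.add_node(f_child, child, cents.get(child, (np.nan, np.nan)))
                if parent is not None:
                    graph.add_edge((f_parent, parent), (f_child, child), ev_type)
        masks_proc.append(L_new)
        co_resident = _label_groups(L_new)
        L = L_new

    if p.direction == "backward":
        masks = masks_proc[::-1]
        fields = fields[::-1]
    else:
        masks = masks_proc
    return masks, fields, graph
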