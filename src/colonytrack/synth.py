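"""Synthetic colony sequences with analytic ground truth.

Emulates the appearance of phase-contrast colony images — textured,
roughly circular colonies (interior mean ~0.6) on a darker background
(~0.2), optionally with a bright halo ring — moving and growing smoothly
between frames.  Every generated sequence comes with exact ground-truth
label masks, closed-form inter-frame displacement fields and an event log
of scripted merges and splits, so registration, segmentation, tracking and
measurement can all be validated without real microscopy data.

Colony motion is composed of rigid translation plus isotropic growth
only, which keeps the truth masks analytic; rotation and swirl fields are
available separately for registration tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ColonySpec",
    "ScenarioScript",
    "GroundTruth",
    "make_textured_colony",
    "analytic_field",
    "generate_sequence",
]

BACKGROUND = 0.2
INTERIOR = 0.6


@dataclass
class ColonySpec:
    center: tuple[float, float]        # (row, col) at frame 0
    radius: float
    texture_seed: int = 0
    growth: float = 0.0                # radius increase, px/frame
    velocity: tuple[float, float] = (0.0, 0.0)  # px/frame
    colony_id: int = 0


@dataclass
class ScenarioScript:
    shape: tuple[int, int] = (160, 160)
    n_frames: int = 8
    colonies: list[ColonySpec] = field(default_factory=list)
    # scripted splits: (frame, colony_id, (offset_a, offset_b)) — at `frame`
    # the colony is replaced by two half-radius children displaced by the
    # given (row, col) offsets, which then drift apart
    splits: list[tuple] = field(default_factory=list)
    noise_sigma: float = 0.03
    halo_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        ids = [c.colony_id for c in self.colonies]
        if len(set(ids)) != len(ids):
            raise ValueError("colony ids must be unique")
        known = set(ids)
        for f, cid, _off in self.splits:
            if cid not in known:
                raise ValueError(f"split references unknown colony {cid}")
            if not 1 <= f < self.n_frames:
                raise ValueError("split frame out of range")


@dataclass
class GroundTruth:
    masks: list[np.ndarray]            # per-frame integer label masks
    fields: list[np.ndarray]           # analytic displacement t -> t+1, (2,H,W)
    events: list[dict]                 # {"frame", "type", "participants"}

    def save_events(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.events, indent=1))


def _smooth_noise(shape, rng, sigma=3.0) -> np.ndarray:
    """Band-limited texture: Gaussian-filtered white noise, unit-normalised."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    n -= n.mean()
    s = n.std() or 1.0
    return n / s


def make_textured_colony(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    texture_seed: int = 0,
    halo_amplitude: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One textured disc on a transparent (zero) canvas plus its exact mask.

    The interior texture is band-limited with contrast >= 0.3 against the
    background; the optional halo is a bright ring just outside the mask.
    """
    if radius < 3:
        raise ValueError("radius must be >= 3 px")
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    mask = d <= radius
    rng = np.random.default_rng(texture_seed)
    tex = _smooth_noise(shape, rng)
    patch = np.zeros(shape)
    patch[mask] = INTERIOR - BACKGROUND + 0.08 * tex[mask]
    if halo_amplitude > 0:
        ring = np.exp(-0.5 * ((d - radius - 2.0) / 1.5) ** 2)
        patch += halo_amplitude * ring * (~mask)
    return patch, mask


def analytic_field(
    kind: str,
    magnitude: float,
    center: tuple[float, float],
    shape: tuple[int, int],
    support_radius: float | None = None,
) -> np.ndarray:
    """Closed-form displacement fields for registration ground truth.

    translation: constant vector ``magnitude`` (a (dr, dc) pair is accepted
    via ``magnitude=(dr, dc)``); rotation: rigid rotation by ``magnitude``
    radians about ``center``; radial_growth: u = s * (x - center) inside a
    smoothly tapered support of radius ``support_radius``.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dr, dc = rr - center[0], cc - center[1]
    if kind == "translation":
        vec = (magnitude, 0.0) if np.isscalar(magnitude) else tuple(magnitude)
        return np.stack([np.full(shape, vec[0]), np.full(shape, vec[1])])
    if kind == "rotation":
        th = float(magnitude)
        ur = (np.cos(th) - 1) * dr - np.sin(th) * dc
        uc = np.sin(th) * dr + (np.cos(th) - 1) * dc
        return np.stack([ur, uc])
    if kind == "radial_growth":
        s = float(magnitude)
        u = np.stack([s * dr, s * dc])
        if support_radius is not None:
            d = np.hypot(dr, dc)
            taper = 0.5 * (1 + np.cos(np.clip(
                (d - support_radius) / (0.5 * support_radius), 0, 1) * np.pi))
            u *= taper
        return u
    raise ValueError(f"unknown field kind {kind!r}")


def _colony_state(spec: ColonySpec, t: int):
    c = (spec.center[0] + spec.velocity[0] * t, spec.center[1] + spec.velocity[1] * t)
    r = spec.radius + spec.growth * t
    return c, r


def generate_sequence(script: ScenarioScript):
    """Synthesise frames plus exact ground truth for a scenario.

    Per frame the active colonies (after applying scripted splits) are
    composited over the background, Gaussian pixel noise is added last,
    and truth masks record each colony's exact rasterised disc (overlap
    pixels go to the nearer centre).  The recorded displacement field for
    the pair (t, t+1) maps each colony's frame-(t+1) footprint back onto
    its frame-t position (translation plus isotropic scaling about the
    centre), tapered to zero away from the colonies.  Fully reproducible
    from the script's seed.

    The event log is derived from the truth masks: a ``split`` when a
    scripted split activates, a ``merge`` at the first frame two colony
    discs become connected.
    """
    rng = np.random.default_rng(script.seed)
    h, w = script.shape
    # active colony table per frame: id -> (spec, birth_frame, parent_state_fn)
    specs = {c.colony_id: c for c in script.colonies}
    next_id = max(specs, default=0) + 1
    split_by_frame: dict[int, list] = {}
    for f, cid, offs in script.splits:
        split_by_frame.setdefault(f, []).append((cid, offs))

    # state per frame: list of (id, center, radius, texture_seed)
    state: dict[int, ColonySpec] = {c.colony_id: c for c in script.colonies}
    birth: dict[int, int] = {c.colony_id: 0 for c in script.colonies}
    per_frame: list[list[tuple[int, tuple, float, int]]] = []
    events: list[dict] = []
    for t in range(script.n_frames):
        for cid, offs in split_by_frame.get(t, []):
            if cid not in state:
                continue
            parent = state.pop(cid)
            pc, pr = _colony_state(parent, t - birth[cid])
            children = []
            for off in offs:
                child = ColonySpec(
                    center=(pc[0] + off[0], pc[1] + off[1]),
                    radius=max(pr / np.sqrt(2.0), 3.0),
                    texture_seed=parent.texture_seed + next_id,
                    growth=parent.growth,
                    velocity=(parent.velocity[0] + 0.6 * np.sign(off[0]),
                              parent.velocity[1] + 0.6 * np.sign(off[1])),
                    colony_id=next_id,
                )
                state[next_id] = child
                birth[next_id] = t
                children.append(next_id)
                next_id += 1
            events.append({"frame": t, "type": "split",
                           "participants": [cid], "children": children})
        frame_state = []
        for cid, spec in sorted(state.items()):
            c, r = _colony_state(spec, t - birth[cid])
            if not (-r < c[0] < h + r and -r < c[1] < w + r):
                import logging
                logging.getLogger(__name__).warning(
                    "colony %d leaves the canvas at frame %d; clipped", cid, t)
            frame_state.append((cid, c, r, spec.texture_seed))
        per_frame.append(frame_state)

    # frames, truth masks
    frames, masks = [], []
    for t, frame_state in enumerate(per_frame):
        img = np.full((h, w), BACKGROUND)
        labels = np.zeros((h, w), dtype=np.int32)
        best_d = np.full((h, w), np.inf)
        for cid, c, r, tseed in frame_state:
            patch, mask = make_textured_colony((h, w), c, r, tseed, script.halo_amplitude)
            img = np.where(mask, BACKGROUND + patch, img + patch * (patch > 0))
            rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            d = np.hypot(rr - c[0], cc - c[1])
            take = mask & (d < best_d)
            labels[take] = cid
            best_d = np.minimum(best_d, np.where(mask, d, np.inf))
        if script.noise_sigma > 0:
            img = img + rng.normal(0.0, script.noise_sigma, (h, w))
        frames.append(np.clip(img, 0.0, 1.0))
        masks.append(labels)

    # merge events: first frame at which previously separate labels share
    # one 8-connected blob (siblings born touching at a split frame are
    # not a merge)
    def _groups(labels: np.ndarray) -> list[frozenset]:
        comp, n = ndimage.label(labels > 0, structure=np.ones((3, 3)))
        return [
            frozenset(int(v) for v in np.unique(labels[comp == k]) if v > 0)
            for k in range(1, n + 1)
        ]

    prev_groups: list[frozenset] = _groups(masks[0])
    prev_ids = {int(v) for v in np.unique(masks[0]) if v > 0}
    for t in range(1, script.n_frames):
        cur_groups = _groups(masks[t])
        for key in cur_groups:
            if len(key) < 2:
                continue
            if not key <= prev_ids:
                continue  # contains a newborn label
            if any(key <= g for g in prev_groups):
                continue  # already fused
            events.append({"frame": t, "type": "merge",
                           "participants": sorted(key), "children": sorted(key)})
        prev_groups = cur_groups
        prev_ids = {int(v) for v in np.unique(masks[t]) if v > 0}

    # analytic fields t -> t+1
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    fields = []
    id_state = {t: {cid: (c, r) for cid, c, r, _s in fs} for t, fs in enumerate(per_frame)}
    parent_of = {}
    for ev in events:
        if ev["type"] == "split":
            for ch in ev["children"]:
                parent_of[(ev["frame"], ch)] = ev["participants"][0]
    for t in range(script.n_frames - 1):
        u = np.zeros((2, h, w))
        wsum = np.zeros((h, w))
        for cid, (c1, r1) in id_state[t + 1].items():
            if cid in id_state[t]:
                c0, r0 = id_state[t][cid]
            else:
                pid = parent_of.get((t + 1, cid))
                if pid is None or pid not in id_state[t]:
                    continue
                c0, r0 = id_state[t][pid]
            scale = r1 / r0 if r0 > 0 else 1.0
            dr, dc = rr - c1[0], cc - c1[1]
            # the frame-t preimage of point x near colony cid
            pre_r = c0[0] + dr / scale
            pre_c = c0[1] + dc / scale
            d = np.hypot(dr, dc)
            wgt = 1.0 / (1.0 + np.exp((d - (r1 + 4.0)) / 2.0))
            u[0] += wgt * (rr - pre_r)
            u[1] += wgt * (cc - pre_c)
            wsum += wgt
        nz = wsum > 1e-9
        u[0][nz] /= wsum[nz]
        u[1][nz] /= wsum[nz]
        fields.append(u)

    from .image_io import ImageFrame

    image_frames = [ImageFrame(pixels=f, time_index=t) for t, f in enumerate(frames)]
    return image_frames, GroundTruth(masks=masks, fields=fields, events=events)
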