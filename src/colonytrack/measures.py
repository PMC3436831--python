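"""Structural and dynamical statistics of tracked colonies.

Global coverage, per-colony shape (area, elongation, circularity), texture
(gray-level entropy in nats) and motion (mean / standard deviation of the
within-colony displacement norm), plus per-frame quantile summaries and a
Wilcoxon rank-sum comparison of pooled features between culture conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure as sk_measure

__all__ = [
    "ColonyFeatureRecord",
    "FrameSummary",
    "covered_area_fraction",
    "colony_elongation",
    "colony_circularity",
    "colony_entropy",
    "displacement_stats",
    "measure_sequence",
    "summarize_frames",
    "compare_conditions",
]


@dataclass
class ColonyFeatureRecord:
    frame_index: int
    colony_id: int
    area_px: int
    elongation: float
    circularity: float
    entropy: float
    mean_displacement: float  # NaN when no field covers this frame
    sd_displacement: float
    centroid: tuple[float, float]


@dataclass
class FrameSummary:
    frame_index: int
    feature: str
    median: float
    q25: float
    q75: float
    n_colonies: int


def covered_area_fraction(labels: np.ndarray) -> float:
    """Fraction of the frame covered by any detected colony."""
    labels = np.asarray(labels)
    return float(np.count_nonzero(labels)) / labels.size


def _colony_pixels(labels: np.ndarray, colony_id: int) -> np.ndarray:
    mask = np.asarray(labels) == colony_id
    if not mask.any():
        raise KeyError(f"label {colony_id} not present in mask")
    return mask


def colony_elongation(labels: np.ndarray, colony_id: int) -> float:
    """Elongation xi = 1 - minor/major of the best-fit ellipse.

    Axes come from the second-order central moments of the pixel set (the
    usual 4*sqrt(eigenvalue) normalised-moment ellipse).  xi ~ 0 for a
    round colony and -> 1 as it stretches into a line; collinear pixel
    sets are capped at 1 - 1e-6.
    """
    mask = _colony_pixels(labels, colony_id)
    rr, cc = np.nonzero(mask)
    r = rr - rr.mean()
    c = cc - cc.mean()
    # +1/12 per axis: moments of a unit square pixel, stabilises thin shapes
    cov = np.array([
        [np.mean(r * r) + 1 / 12, np.mean(r * c)],
        [np.mean(r * c), np.mean(c * c) + 1 / 12],
    ])
    ev = np.linalg.eigvalsh(cov)
    major, minor = math.sqrt(max(ev[1], 0.0)), math.sqrt(max(ev[0], 0.0))
    if major <= 0:
        return 0.0
    return min(1.0 - minor / major, 1.0 - 1e-6)


def colony_circularity(labels: np.ndarray, colony_id: int) -> float:
    """Circularity gamma = 4*pi*a / p**2; 1 for a circle, -> 0 with
    increasing boundary irregularity.

    The perimeter p uses the Crofton multi-directional estimator (4
    directions); naive boundary-pixel counting would bias a disc's value
    to ~0.8.  Discretisation overshoot is capped at 1.1.
    """
    mask = _colony_pixels(labels, colony_id)
    a = int(mask.sum())
    p = float(sk_measure.perimeter_crofton(mask, directions=4))
    if p <= 0:
        return 1.1
    return min(4.0 * math.pi * a / (p * p), 1.1)


def colony_entropy(frame, labels: np.ndarray, colony_id: int, n_levels: int = 256) -> float:
    """Shannon entropy (nats) of the gray-value histogram inside a colony.

    Pixels are quantised to ``n_levels`` uniform bins over [0, 1] (the
    default matches native 8-bit data); 0*log(0) terms contribute zero.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame, dtype=np.float64)
    mask = _colony_pixels(labels, colony_id)
    vals = pixels[mask]
    bins = np.clip((vals * n_levels).astype(np.int64), 0, n_levels - 1)
    counts = np.bincount(bins, minlength=n_levels)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def displacement_stats(u: np.ndarray, labels: np.ndarray, colony_id: int) -> tuple[float, float]:
    """Mean and population standard deviation of ||u(x)|| over the colony."""
    mask = _colony_pixels(labels, colony_id)
    if u.shape != (2, *np.asarray(labels).shape):
        raise ValueError("field shape does not match mask")
    norms = np.hypot(u[0][mask], u[1][mask])
    return float(norms.mean()), float(norms.std())


def measure_sequence(frames, masks, fields, n_levels: int = 256) -> list[ColonyFeatureRecord]:
    """One record per (frame, colony); displacement features from the field
    of the pair (t, t+1) are attached to frame t, the terminal frame's
    displacement entries are NaN (missing, not zero)."""
    if len(masks) != len(frames) or len(fields) != len(frames) - 1:
        raise ValueError("frames, masks and fields are misaligned")
    records: list[ColonyFeatureRecord] = []
    for t, (frame, labels) in enumerate(zip(frames, masks)):
        ids = [int(v) for v in np.unique(labels) if v > 0]
        if not ids:
            continue
        cents = ndimage.center_of_mass(labels > 0, labels, ids)
        for cid, cen in zip(ids, cents):
            if t < len(fields):
                mean_d, sd_d = displacement_stats(fields[t], labels, cid)
            else:
                mean_d, sd_d = float("nan"), float("nan")
            records.append(
                ColonyFeatureRecord(
                    frame_index=t,
                    colony_id=cid,
                    area_px=int(np.count_nonzero(labels == cid)),
                    elongation=colony_elongation(labels, cid),
                    circularity=colony_circularity(labels, cid),
                    entropy=colony_entropy(frame, labels, cid, n_levels),
                    mean_displacement=mean_d,
                    sd_displacement=sd_d,
                    centroid=(float(cen[0]), float(cen[1])),
                )
            )
    return records


_FEATURES = {
    "area_px", "elongation", "circularity", "entropy",
    "mean_displacement", "sd_displacement",
}


def _pool(records, feature: str) -> dict[int, list[float]]:
    if feature not in _FEATURES:
        raise KeyError(f"unknown feature {feature!r}; one of {sorted(_FEATURES)}")
    by_frame: dict[int, list[float]] = {}
    for r in records:
        v = float(getattr(r, feature))
        if math.isnan(v):
            continue
        by_frame.setdefault(r.frame_index, []).append(v)
    return by_frame


def summarize_frames(records, feature: str) -> list[FrameSummary]:
    """Per-frame median and 0.25/0.75 quantiles (linear interpolation) of a
    feature over colonies; frames with no colonies are omitted."""
    out = []
    for f in sorted(_pool(records, feature)):
        vals = np.asarray(_pool(records, feature)[f])
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
        out.append(FrameSummary(f, feature, float(med), float(q25), float(q75), vals.size))
    return out


def compare_conditions(records_a, records_b, feature: str) -> dict:
    """Two-sided Wilcoxon rank-sum test on feature values pooled over the
    temporal dimension.

    Uses exact enumeration for small tie-free pools (both sizes <= 20) and
    the tie-corrected normal approximation otherwise.  Returns the
    rank-sum statistic W of pool A, the Mann-Whitney U, and the p-value.
    """
    xs = [v for vs in _pool(records_a, feature).values() for v in vs] \
        if records_a and hasattr(records_a[0], "frame_index") else list(records_a)
    ys = [v for vs in _pool(records_b, feature).values() for v in vs] \
        if records_b and hasattr(records_b[0], "frame_index") else list(records_b)
    return rank_sum_test(xs, ys)


def rank_sum_test(xs, ys) -> dict:
    """Wilcoxon rank-sum on two raw pools (helper behind compare_conditions)."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both pools must be non-empty")
    has_ties = np.unique(np.concatenate([xs, ys])).size < xs.size + ys.size
    method = "exact" if (max(xs.size, ys.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    w = float(res.statistic) + xs.size * (xs.size + 1) / 2.0
    return {
        "statistic": w,
        "u_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_a": int(xs.size),
        "n_b": int(ys.size),
        "method": method,
    }
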