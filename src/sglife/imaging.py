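"""Quantification of stress granules in fluorescence images and movies.

Per cell: granules are segmented by thresholding inside the cell mask (Otsu by
default), labeled with 8-connectivity, and size-filtered; reported are the
granule count, mean area, and a per-cell enrichment ratio (mean intensity over
granule pixels / mean intensity over the whole cell). Across frames, granule
centroids are linked by greedy nearest-neighbour assignment with a maximum
displacement, and fusion events are called when two tracks end next to a
continuing track whose area absorbs theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "GranuleSet",
    "Track",
    "segment_and_measure",
    "enrichment_score",
    "track_particles",
    "count_fusion_events",
]


@dataclass
class GranuleSet:
    """Segmented granules for one cell."""

    cell_id: int
    granule_labels: np.ndarray  # labeled image, same shape as the cell crop
    count: int
    mean_area: float  # pixels, or units^2 if pixel_size given
    areas: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Track:
    """One linked particle trajectory."""

    frames: list[int]
    positions: list[tuple[float, float]]
    areas: list[float]

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    @property
    def step_displacements(self) -> np.ndarray:
        p = np.asarray(self.positions, dtype=float)
        return np.linalg.norm(np.diff(p, axis=0), axis=1) if len(p) > 1 else np.empty(0)


def segment_and_measure(
    image: np.ndarray,
    cell_masks: np.ndarray,
    min_area: int = 4,
    threshold: str | float = "otsu",
    pixel_size: float | None = None,
) -> list[GranuleSet]:
    """Segment granules within each cell mask and measure count and mean area.

    ``cell_masks`` is a label image (0 = background, 1..n = cells).
    ``threshold`` is either 'otsu' (computed within each cell) or a fixed
    intensity. Components smaller than ``min_area`` pixels are discarded;
    connectivity is 8-connected.
    """
    image = np.asarray(image, dtype=float)
    cell_masks = np.asarray(cell_masks)
    if image.shape != cell_masks.shape:
        raise ValueError("image and cell masks must have the same shape")
    results: list[GranuleSet] = []
    scale = (pixel_size**2) if pixel_size else 1.0
    for cell_id in np.unique(cell_masks):
        if cell_id == 0:
            continue
        mask = cell_masks == cell_id
        if not mask.any():
            raise ValueError(f"cell mask {cell_id} is empty")
        pixels = image[mask]
        if threshold == "otsu":
            thr = threshold_otsu(pixels) if np.ptp(pixels) > 0 else np.inf
        else:
            thr = float(threshold)
        binary = np.zeros_like(mask)
        binary[mask] = image[mask] > thr
        labels = cc_label(binary, connectivity=2)
        areas, centroids = [], []
        keep = np.zeros_like(labels)
        next_id = 0
        for region in regionprops(labels):
            if region.area < min_area:
                continue
            next_id += 1
            keep[labels == region.label] = next_id
            areas.append(float(region.area) * scale)
            centroids.append(tuple(map(float, region.centroid)))
        results.append(GranuleSet(
            cell_id=int(cell_id),
            granule_labels=keep,
            count=next_id,
            mean_area=float(np.mean(areas)) if areas else 0.0,
            areas=areas,
            centroids=centroids,
        ))
    return results


def enrichment_score(
    target_channel: np.ndarray, granule_masks: np.ndarray, cell_mask: np.ndarray
) -> float | None:
    """Mean intensity over granule pixels / mean intensity over the whole cell.

    Returns None (missing) when the cell holds no granule pixels.
    """
    img = np.asarray(target_channel, dtype=float)
    gmask = np.asarray(granule_masks).astype(bool) & np.asarray(cell_mask).astype(bool)
    cmask = np.asarray(cell_mask).astype(bool)
    if not cmask.any():
        raise ValueError("empty cell mask")
    if not gmask.any():
        return None
    return float(img[gmask].mean() / img[cmask].mean())


def track_particles(
    frames: Sequence[Sequence[tuple]],
    max_disp: float = 10.0,
) -> tuple[list[Track], float]:
    """Greedy nearest-neighbour frame-to-frame linking of detections.

    Each frame is a sequence of detections ``(row, col)`` or
    ``(row, col, area)``. Pairs are linked closest-first under the ``max_disp``
    cap; unmatched detections start new tracks, unmatched tracks end. Returns
    the tracks and the pooled mean per-step displacement (0.0 when no steps).
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")

    def split(det):
        det = tuple(det)
        return (float(det[0]), float(det[1])), (float(det[2]) if len(det) > 2 else float("nan"))

    tracks: list[Track] = []
    active: list[Track] = []
    for pos_area in frames[0]:
        p, a = split(pos_area)
        t = Track(frames=[0], positions=[p], areas=[a])
        tracks.append(t)
        active.append(t)

    for fi in range(1, len(frames)):
        dets = [split(d) for d in frames[fi]]
        new_active: list[Track] = []
        if active and dets:
            prev = np.asarray([t.positions[-1] for t in active], dtype=float)
            cur = np.asarray([p for p, _ in dets], dtype=float)
            dist = cdist(prev, cur)
            used_t, used_d = set(), set()
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
            for ti, di in order:
                if dist[ti, di] > max_disp:
                    break
                if ti in used_t or di in used_d:
                    continue
                used_t.add(int(ti))
                used_d.add(int(di))
                tr = active[ti]
                p, a = dets[di]
                tr.frames.append(fi)
                tr.positions.append(p)
                tr.areas.append(a)
                new_active.append(tr)
        else:
            used_d = set()
        for di, (p, a) in enumerate(dets):
            if di not in used_d:
                t = Track(frames=[fi], positions=[p], areas=[a])
                tracks.append(t)
                new_active.append(t)
        active = new_active

    steps = np.concatenate([t.step_displacements for t in tracks]) if tracks else np.empty(0)
    mean_disp = float(steps.mean()) if steps.size else 0.0
    return tracks, mean_disp


def count_fusion_events(
    tracks: Sequence[Track],
    merge_radius: float = 6.0,
    area_ratio: float = 0.8,
    image_shape: tuple[int, int] | None = None,
    border_margin: float = 3.0,
) -> list[dict]:
    """Call fusion events from linked tracks.

    A fusion at frame t+1 is a track that ends at frame t with its last
    position within ``merge_radius`` of a surviving track's position at t+1,
    where the survivor's area at t+1 is at least ``area_ratio`` x (its own
    area at t + the ending track's last area). Tracks ending within
    ``border_margin`` of the image edge are excluded (particles leaving the
    field are not fusions).
    """
    events: list[dict] = []
    for dying in tracks:
        t_end = dying.end
        pos = np.asarray(dying.positions[-1])
        if image_shape is not None:
            r, c = pos
            h, w = image_shape
            if (r < border_margin or c < border_margin
                    or r > h - 1 - border_margin or c > w - 1 - border_margin):
                continue
        for survivor in tracks:
            if survivor is dying or t_end + 1 not in survivor.frames:
                continue
            k = survivor.frames.index(t_end + 1)
            if k == 0 or survivor.frames[k - 1] != t_end:
                continue  # survivor must exist at t and continue to t+1
            d = float(np.linalg.norm(np.asarray(survivor.positions[k]) - pos))
            if d > merge_radius:
                continue
            a_before = survivor.areas[k - 1]
            a_after = survivor.areas[k]
            a_dying = dying.areas[-1]
            if np.isfinite(a_after) and np.isfinite(a_before) and np.isfinite(a_dying):
                if a_after < area_ratio * (a_before + a_dying):
                    continue
            events.append({
                "frame": t_end + 1,
                "parent_end": tuple(map(float, pos)),
                "child_position": tuple(map(float, survivor.positions[k])),
                "distance": d,
            })
            break
    return events
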