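"""Focus detection and nearest-neighbour track linking.

The detector follows the classic particle-detector recipe: boxcar background
subtraction, a Gaussian matched filter, non-maximum suppression within the
spot radius, a top-percentile intensity gate plus a score cutoff, and
sub-pixel refinement by intensity-weighted centroid.  The linker is a greedy
globally-nearest-neighbour assignment between consecutive frames with a hard
displacement gate and no gap closing, so every track covers strictly
consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["DetectionParams", "SpotRecord", "Track",
           "detect_spots", "link_spots", "filter_tracks"]


@dataclass(frozen=True)
class DetectionParams:
    """Detector/linker settings.

    ``percentile`` is the retained top fraction of filtered pixel intensities
    in percent (0.1 keeps candidates brighter than 99.9% of pixels).
    ``min_track_frames`` is a strict lower bound: scored tracks must span
    more than this many consecutive frames.
    """

    radius_px: int = 4
    cutoff: float = 0.0
    percentile: float = 0.1
    max_displacement_px: float = 10.0
    min_track_frames: int = 15

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError("percentile must lie in (0, 100]")
        if self.max_displacement_px < 1:
            raise ValueError("max_displacement_px must be >= 1")


@dataclass(frozen=True)
class SpotRecord:
    frame_index: int
    x_px: float
    y_px: float
    intensity: float
    score: float


@dataclass
class Track:
    """A single focus followed over strictly consecutive frames."""

    track_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    intensity: np.ndarray
    burst_time_min: float = np.nan

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frames) != 1) and len(self.frames) > 1:
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)


def detect_spots(image: np.ndarray, params: DetectionParams) -> list[SpotRecord]:
    """Detect sub-pixel focus candidates in one frame, sorted by score.

    Pipeline: boxcar (width 2r+1) background subtraction -> Gaussian matched
    filter (sigma = r/2) -> local maxima within radius r -> keep maxima in the
    top ``percentile`` percent of filtered intensities with score > cutoff ->
    intensity-weighted centroid refinement in a (2r+1)^2 window.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    r = params.radius_px
    if min(img.shape) <= 2 * r:
        raise ValueError("radius larger than image")

    background = ndimage.uniform_filter(img, size=2 * r + 1, mode="reflect")
    resid = img - background
    filt = ndimage.gaussian_filter(resid, sigma=r / 2.0, mode="reflect")

    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    footprint = (xx * xx + yy * yy) <= r * r
    local_max = ndimage.maximum_filter(filt, footprint=footprint,
                                       mode="reflect")
    threshold = np.percentile(filt, 100.0 - params.percentile)
    candidates = np.argwhere((filt == local_max) & (filt >= threshold)
                             & (filt > params.cutoff))

    # resolve plateau ties: strongest first, suppress within one radius
    order = np.argsort([-filt[tuple(c)] for c in candidates], kind="stable")
    kept: list[tuple[int, int]] = []
    for idx in order:
        iy, ix = candidates[idx]
        if all((iy - ky) ** 2 + (ix - kx) ** 2 > r * r for ky, kx in kept):
            kept.append((int(iy), int(ix)))

    pos = np.clip(resid, 0.0, None)
    h, w = img.shape
    spots: list[SpotRecord] = []
    for iy, ix in kept:
        y0, y1 = max(0, iy - r), min(h, iy + r + 1)
        x0, x1 = max(0, ix - r), min(w, ix + r + 1)
        win = pos[y0:y1, x0:x1]
        total = win.sum()
        if total > 0:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            cy = float((win * ys).sum() / total)
            cx = float((win * xs).sum() / total)
        else:
            cy, cx = float(iy), float(ix)
        spots.append(SpotRecord(frame_index=0, x_px=cx, y_px=cy,
                                intensity=float(total),
                                score=float(filt[iy, ix])))
    spots.sort(key=lambda s: -s.score)
    return spots


def link_spots(spots_by_frame: Sequence[Sequence[SpotRecord]],
               params: DetectionParams,
               burst_time_min: float = np.nan) -> list[Track]:
    """Link per-frame spots into tracks by greedy nearest-neighbour assignment.

    For each consecutive frame pair, candidate links within the displacement
    gate are sorted by distance (ties broken by lower frame-local spot index)
    and accepted when both endpoints are still free.  Unmatched spots start
    new tracks; a track ends as soon as it finds no match (no gap closing).
    """
    open_tracks: list[list[tuple[int, SpotRecord]]] = []
    closed: list[list[tuple[int, SpotRecord]]] = []
    prev: list[SpotRecord] = []
    prev_track: list[int] = []  # index into open_tracks per previous spot
    for fi, spots in enumerate(spots_by_frame):
        spots = list(spots)
        assigned_prev: set[int] = set()
        assigned_new: set[int] = set()
        links: dict[int, int] = {}
        if prev and spots:
            pairs = []
            for i, a in enumerate(prev):
                for j, b in enumerate(spots):
                    d = np.hypot(a.x_px - b.x_px, a.y_px - b.y_px)
                    if d <= params.max_displacement_px:
                        pairs.append((d, i, j))
            pairs.sort()
            for d, i, j in pairs:
                if i in assigned_prev or j in assigned_new:
                    continue
                assigned_prev.add(i)
                assigned_new.add(j)
                links[j] = prev_track[i]
        # close tracks whose previous spot found no continuation
        still_open: set[int] = set(links.values())
        for ti in set(prev_track):
            if ti not in still_open:
                closed.append(open_tracks[ti])
        new_prev_track = []
        for j, s in enumerate(spots):
            if j in links:
                open_tracks[links[j]].append((fi, s))
                new_prev_track.append(links[j])
            else:
                open_tracks.append([(fi, s)])
                new_prev_track.append(len(open_tracks) - 1)
        prev = spots
        prev_track = new_prev_track
    closed.extend(open_tracks[ti] for ti in sorted(set(prev_track)))

    tracks = []
    for tid, chain in enumerate(sorted(closed, key=lambda c: (c[0][0],))):
        frames = np.array([fi for fi, _ in chain])
        tracks.append(Track(
            track_id=tid,
            frames=frames,
            x_px=np.array([s.x_px for _, s in chain]),
            y_px=np.array([s.y_px for _, s in chain]),
            intensity=np.array([s.intensity for _, s in chain]),
            burst_time_min=burst_time_min))
    return tracks


def filter_tracks(tracks: Sequence[Track], params: DetectionParams) -> list[Track]:
    """Keep only tracks spanning strictly more than ``min_track_frames`` frames."""
    return [t for t in tracks if len(t) > params.min_track_frames]
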