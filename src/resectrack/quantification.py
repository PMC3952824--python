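"""Background-normalized focus-intensity traces and focus-loss calling.

The intensity readout mimics a line-scan quantification: pixels along a short
horizontal line crossing the focus are summed and divided by the sum over an
equally long line in a nearby spot-free background region; the ratio is
rescaled to 100% at the first timepoint.  Because the background photobleaches
faster than the ParB focus, the raw ratio of an intact focus rises during
early acquisition before collapsing to the background level when resection
evicts ParB.

Three loss-calling rules are provided:

``intensity``
    First timepoint where the excess ratio (ratio minus the post-loss plateau)
    falls below ``threshold_fraction`` of its pre-onset level and stays there
    for ``persistence_points`` consecutive timepoints.
``detection-absence``
    First burst with no detected spot, followed by enough empty bursts.
``extrapolate``
    Anchored on the extinction of the excess ratio, then refined by fitting
    the linear fade and reporting its zero crossing (ParB eviction is linear
    in time while the resection front traverses the cassette, so the fade's
    zero crossing, not its midpoint, marks arrival at the distal end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection_tracking import SpotRecord
from .synthetic_microscopy import ImageStack

__all__ = ["IntensityTrace", "FocusLossEvent", "intensity_ratio_trace",
           "burst_average", "call_focus_loss", "call_focus_loss_intensity",
           "call_focus_loss_absence", "call_focus_loss_extrapolate"]

#: offsets tried (in units of the requested offset magnitude) when the
#: preferred background line is unusable: 8 compass directions
_COMPASS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class IntensityTrace:
    times_min: np.ndarray
    ratio_percent: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.ratio_percent = np.asarray(self.ratio_percent, float)
        if self.times_min.shape != self.ratio_percent.shape:
            raise ValueError("times and ratios must have equal length")


@dataclass(frozen=True)
class FocusLossEvent:
    channel: str
    lost: bool
    t_loss_min: Optional[float]
    method: str

    def __post_init__(self) -> None:
        if self.lost != (self.t_loss_min is not None):
            raise ValueError("t_loss must be present iff lost")


def _line_pixels(frame: np.ndarray, x: float, y: float, half: int):
    h, w = frame.shape
    iy, ix = int(round(y)), int(round(x))
    if not (0 <= iy < h and half <= ix < w - half):
        return None
    return frame[iy, ix - half: ix + half + 1]


def intensity_ratio_trace(stack: ImageStack,
                          focus_xy_px: np.ndarray,
                          line_length_px: int = 9,
                          background_offset_px: tuple[int, int] = (15, 0),
                          spots_by_frame: Optional[Sequence[Sequence[SpotRecord]]] = None,
                          min_spot_clearance_px: float = 5.0,
                          channel: str = "") -> IntensityTrace:
    """Focus/background line-sum ratio per frame, normalized to 100% at t0.

    ``focus_xy_px`` holds one (x, y) position per frame (after focus loss the
    caller carries the last tracked position forward).  The background line is
    the same horizontal length displaced by ``background_offset_px``; if that
    line leaves the image or lies too close to a detected spot, the eight
    compass displacements of the same magnitude are tried in turn.
    """
    focus_xy_px = np.asarray(focus_xy_px, float)
    if focus_xy_px.shape != (stack.n_frames, 2):
        raise ValueError("need one focus position per frame")
    half = line_length_px // 2
    mag = float(np.hypot(*background_offset_px))
    offsets = [tuple(background_offset_px)] + [
        (int(round(dx * mag)), int(round(dy * mag))) for dx, dy in _COMPASS]

    ratios = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        frame = stack.frames[k].astype(float)
        x, y = focus_xy_px[k]
        focus_line = _line_pixels(frame, x, y, half)
        if focus_line is None:
            raise ValueError(f"focus at image border in frame {k}")
        bg_line = None
        for dx, dy in offsets:
            bx, by = x + dx, y + dy
            line = _line_pixels(frame, bx, by, half)
            if line is None:
                continue
            if spots_by_frame is not None:
                spots = spots_by_frame[k]
                if any(abs(s.y_px - round(by)) <= 1
                       and (round(bx) - half - min_spot_clearance_px
                            <= s.x_px <= round(bx) + half + min_spot_clearance_px)
                       for s in spots):
                    continue
            bg_line = line
            break
        if bg_line is None:
            raise ValueError(f"no spot-free background line found in frame {k}")
        denom = bg_line.sum()
        if denom <= 0:
            raise ValueError(f"empty background line in frame {k}")
        ratios[k] = focus_line.sum() / denom
    percent = 100.0 * ratios / ratios[0]
    return IntensityTrace(stack.timestamps_min.copy(), percent, channel=channel)


def burst_average(times_min: np.ndarray, values: np.ndarray,
                  burst_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-frame values to one (burst start time, mean value) pair per burst."""
    times_min = np.asarray(times_min, float)
    values = np.asarray(values, float)
    burst_index = np.asarray(burst_index)
    bursts = np.unique(burst_index)
    t = np.array([times_min[burst_index == b][0] for b in bursts])
    v = np.array([values[burst_index == b].mean() for b in bursts])
    return t, v


def _first_run(mask: np.ndarray, length: int) -> Optional[int]:
    """Index of the first run of ``length`` consecutive True values, if any."""
    n = len(mask)
    for i in range(0, n - length + 1):
        if mask[i:i + length].all():
            return i
    return None


def _plateau_and_contrast(r: np.ndarray, baseline_points: int,
                          persistence_points: int) -> tuple[float, float]:
    pre = float(np.median(r[:baseline_points]))
    plateau = float(np.median(np.sort(r)[:persistence_points]))
    return pre, pre - plateau


def call_focus_loss_intensity(trace: IntensityTrace,
                              threshold_fraction: float = 0.5,
                              persistence_points: int = 3,
                              baseline_points: int = 3,
                              min_contrast_fraction: float = 0.2) -> FocusLossEvent:
    """Threshold rule on the excess ratio above the post-loss plateau.

    The plateau is estimated from the lowest points of the trace; a loss is
    only considered when the plateau sits at least ``min_contrast_fraction``
    of the pre-onset median below it, which keeps intensity fluctuations of
    intact foci from triggering calls.
    """
    r = trace.ratio_percent
    if len(r) < max(3, persistence_points):
        raise ValueError("trace shorter than persistence window")
    pre, contrast = _plateau_and_contrast(r, baseline_points, persistence_points)
    if contrast <= min_contrast_fraction * pre:
        return FocusLossEvent(trace.channel, False, None, "intensity")
    plateau = pre - contrast
    below = (r - plateau) < threshold_fraction * contrast
    i = _first_run(below, persistence_points)
    if i is None:
        return FocusLossEvent(trace.channel, False, None, "intensity")
    return FocusLossEvent(trace.channel, True, float(trace.times_min[i]), "intensity")


def call_focus_loss_absence(times_min: np.ndarray, present: np.ndarray,
                            persistence_points: int = 3,
                            channel: str = "") -> FocusLossEvent:
    """Loss at the first burst with no detected spot, confirmed by persistence."""
    present = np.asarray(present, bool)
    times_min = np.asarray(times_min, float)
    if len(present) < max(3, persistence_points):
        raise ValueError("presence series shorter than persistence window")
    i = _first_run(~present, persistence_points)
    if i is None:
        return FocusLossEvent(channel, False, None, "detection-absence")
    return FocusLossEvent(channel, True, float(times_min[i]), "detection-absence")


def call_focus_loss_extrapolate(trace: IntensityTrace,
                                persistence_points: int = 3,
                                baseline_points: int = 3,
                                min_contrast_fraction: float = 0.2,
                                extinct_fraction: float = 0.05) -> FocusLossEvent:
    """Loss time from the zero crossing of the linear intensity fade.

    The excess ratio of a resecting focus decays linearly to zero as the
    front traverses the cassette.  When at least two mid-fade points exist, a
    straight line is fitted to them and its zero crossing reported; when the
    fade completes between two sampled bursts, the midpoint of the bracketing
    timepoints is used.
    """
    r = trace.ratio_percent
    t = trace.times_min
    if len(r) < max(3, persistence_points):
        raise ValueError("trace shorter than persistence window")
    pre, contrast = _plateau_and_contrast(r, baseline_points, persistence_points)
    if contrast <= min_contrast_fraction * pre:
        return FocusLossEvent(trace.channel, False, None, "extrapolation")
    e = (r - (pre - contrast)) / contrast  # ~1 intact, ~0 after loss
    i_ext = _first_run(e < extinct_fraction, persistence_points)
    if i_ext is None:
        return FocusLossEvent(trace.channel, False, None, "extrapolation")
    if i_ext == 0:
        return FocusLossEvent(trace.channel, True, float(t[0]), "extrapolation")
    # mid-fade points between the last near-intact point and extinction
    hi = [j for j in range(i_ext) if e[j] >= 0.95]
    j0 = (hi[-1] + 1) if hi else 0
    mid = [j for j in range(j0, i_ext) if extinct_fraction < e[j] < 0.95]
    if len(mid) >= 2:
        slope, icpt = np.polyfit(t[mid], e[mid], 1)
        if slope < 0:
            t_loss = float(np.clip(-icpt / slope, t[mid[0]], t[i_ext]))
            return FocusLossEvent(trace.channel, True, t_loss, "extrapolation")
    t_loss = float(0.5 * (t[i_ext - 1] + t[i_ext]))
    return FocusLossEvent(trace.channel, True, t_loss, "extrapolation")


def call_focus_loss(trace: Optional[IntensityTrace] = None,
                    times_min: Optional[np.ndarray] = None,
                    present: Optional[np.ndarray] = None,
                    method: str = "intensity",
                    threshold_fraction: float = 0.5,
                    persistence_points: int = 3,
                    **kwargs) -> FocusLossEvent:
    """Dispatch to one of the loss-calling rules (see module docstring)."""
    if method == "intensity":
        if trace is None:
            raise ValueError("intensity method needs a trace")
        return call_focus_loss_intensity(trace, threshold_fraction,
                                         persistence_points, **kwargs)
    if method == "detection-absence":
        if times_min is None or present is None:
            raise ValueError("absence method needs burst times and presence flags")
        return call_focus_loss_absence(times_min, present, persistence_points,
                                       **kwargs)
    if method == "extrapolate":
        if trace is None:
            raise ValueError("extrapolate method needs a trace")
        return call_focus_loss_extrapolate(trace, persistence_points, **kwargs)
    raise ValueError(f"unknown method {method!r}")
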