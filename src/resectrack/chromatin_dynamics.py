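"""Mean-square displacement, diffusion-coefficient fits, and mobility series.

MSD is time-averaged per track, MSD(k*dt) = mean_i |r(i+k) - r(i)|^2, and the
ensemble curve is the unweighted mean over all tracks reaching that lag
(a pair-count-weighted variant is available).  The diffusion coefficient is
slope/4 of an ordinary least-squares line (with intercept) fitted to the
ensemble MSD over lags up to 2 s: for 2D tracking MSD = 4*D*tau + 4*sigma_loc^2,
so the intercept absorbs static localization noise that would otherwise bias
D upward.  Mobility can be expressed as a percentage of an uncut-locus
reference D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .detection_tracking import Track
from .synthetic_microscopy import AcquisitionParams

__all__ = ["MSDResult", "DiffusionEstimate", "compute_msd", "estimate_D",
           "windowed_D"]


@dataclass
class MSDResult:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    n_tracks: int


@dataclass
class DiffusionEstimate:
    D_um2_s: float
    intercept_um2: float
    fit_max_lag_s: float
    normalized_percent: Optional[float] = None
    D_ref_um2_s: Optional[float] = None


def compute_msd(tracks: Sequence[Track], acq: AcquisitionParams,
                max_lag_s: float = 2.0, weighted: bool = False) -> MSDResult:
    """Ensemble MSD (µm²) over lags up to ``max_lag_s``.

    Tracks are in pixel units; the acquisition record supplies the pixel size
    and the within-burst frame interval.  ``weighted=True`` weights tracks by
    their displacement-pair counts instead of averaging per-track curves
    equally.
    """
    tracks = [t for t in tracks if len(t) >= 2]
    if not tracks:
        raise ValueError("no tracks of length >= 2")
    dt = acq.frame_interval_s
    if max_lag_s < dt:
        raise ValueError("max_lag_s shorter than one frame interval")
    max_k = int(np.floor(max_lag_s / dt + 1e-9))
    px = acq.pixel_size_um

    sums = np.zeros(max_k)      # per-lag sum of per-track means (or of pairs)
    counts = np.zeros(max_k)    # tracks contributing (or pair counts)
    n_pairs = np.zeros(max_k, dtype=int)
    for t in tracks:
        x = t.x_px * px
        y = t.y_px * px
        n = len(t)
        for k in range(1, min(max_k, n - 1) + 1):
            sq = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
            n_pairs[k - 1] += sq.size
            if weighted:
                sums[k - 1] += sq.sum()
                counts[k - 1] += sq.size
            else:
                sums[k - 1] += sq.mean()
                counts[k - 1] += 1
    have = counts > 0
    lags = dt * np.arange(1, max_k + 1)
    msd = np.full(max_k, np.nan)
    msd[have] = sums[have] / counts[have]
    return MSDResult(lags_s=lags[have], msd_um2=msd[have],
                     n_pairs=n_pairs[have], n_tracks=len(tracks))


def estimate_D(msd: MSDResult, fit_max_lag_s: float = 2.0,
               D_ref: Optional[float] = None) -> DiffusionEstimate:
    """Diffusion coefficient from the short-lag slope of the ensemble MSD.

    Ordinary least squares of MSD on lag (with intercept) over lags up to
    ``fit_max_lag_s``; D = slope/4 for 2D tracking.  ``D_ref`` expresses the
    result as a percentage of a reference locus (100 * D / D_ref).
    """
    use = msd.lags_s <= fit_max_lag_s + 1e-12
    lags = msd.lags_s[use]
    vals = msd.msd_um2[use]
    if lags.size < 2:
        raise ValueError("need at least 2 lags within the fit window")
    slope, intercept = np.polyfit(lags, vals, 1)
    D = slope / 4.0
    norm = None if D_ref is None else 100.0 * D / D_ref
    return DiffusionEstimate(D_um2_s=float(D), intercept_um2=float(intercept),
                             fit_max_lag_s=fit_max_lag_s,
                             normalized_percent=norm, D_ref_um2_s=D_ref)


def windowed_D(tracks_by_burst: Mapping[float, Sequence[Track]],
               acq: AcquisitionParams,
               window_bursts: int = 1,
               fit_max_lag_s: float = 2.0,
               D_ref: Optional[float] = None
               ) -> list[tuple[float, Optional[DiffusionEstimate]]]:
    """Per-burst (or sliding window of bursts) diffusion estimates over time.

    Returns one (burst_time_min, DiffusionEstimate or None) per burst window;
    windows with no usable tracks are reported as missing rather than zero.
    """
    times = sorted(tracks_by_burst)
    out: list[tuple[float, Optional[DiffusionEstimate]]] = []
    for i in range(len(times)):
        window = times[max(0, i - window_bursts + 1): i + 1]
        tracks = [t for w in window for t in tracks_by_burst[w] if len(t) >= 2]
        if not tracks:
            out.append((times[i], None))
            continue
        try:
            msd = compute_msd(tracks, acq, max_lag_s=fit_max_lag_s)
            est = estimate_D(msd, fit_max_lag_s=fit_max_lag_s, D_ref=D_ref)
        except ValueError:
            out.append((times[i], None))
            continue
        out.append((times[i], est))
    return out
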