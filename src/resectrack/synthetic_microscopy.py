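"""Synthetic dual-channel movies of ParB/INT-labelled loci flanking an HO-induced DSB.

This module generates the ground-truth side of the pipeline: per-cell event
times (cleavage, commitment to resection, loss of the INT1 and INT2 foci),
chromatin trajectories under free (Brownian) or confined (Ornstein-Uhlenbeck)
motion, and rendered camera frames with a pixel-integrated Gaussian PSF,
Poisson shot noise, background photobleaching and Gaussian read noise.

Biology emulated
----------------
Two ParB-bound cassettes, INT1 and INT2, sit 76-1231 nt and 3400-7612 nt from
the HO cut site.  After galactose induction a fraction of cells is cleaved;
cleavage times follow a Gaussian truncated at an earliest-cleavage floor.
Resection starts after a genotype-dependent commitment lag, travels slowly to
the slow/fast phase switch and then fast, extinguishing each focus linearly
while the front traverses the cassette and completely once it reaches the
cassette's distal end.  Chromatin mobility drops to a confined regime a few
minutes after cleavage and recovers later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "AcquisitionParams",
    "MotionModel",
    "MobilitySchedule",
    "ResectionScenario",
    "RenderParams",
    "ImageStack",
    "CellGroundTruth",
    "CHANNELS",
    "simulate_trajectory",
    "simulate_trajectories",
    "sample_event_times",
    "front_position_nt",
    "focus_amplitude_fraction",
    "mobility_schedule_for",
    "render_frame",
    "generate_movie",
]

CHANNELS = ("int1", "int2")  # red (mCherry) proximal cassette, green (GFP) distal


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Physical acquisition settings of a burst time-lapse.

    Frames are acquired in bursts of ``frames_per_burst`` consecutive
    exposures spaced ``frame_interval_s`` apart; bursts repeat every
    ``burst_interval_min`` starting at ``start_min`` on the induction clock.
    """

    pixel_size_um: float = 0.065
    frame_interval_s: float = 0.2
    frames_per_burst: int = 50
    burst_interval_min: float = 5.0
    image_shape: tuple[int, int] = (64, 64)
    bit_depth: int = 16
    total_duration_min: float = 60.0
    start_min: float = 8.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.frames_per_burst < 2:
            raise ValueError("frames_per_burst must be >= 2")
        if self.burst_interval_min <= 0 or self.total_duration_min <= 0:
            raise ValueError("intervals and duration must be positive")
        if self.burst_interval_min * 60.0 < self.frames_per_burst * self.frame_interval_s:
            raise ValueError("bursts longer than the burst interval")
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("empty image shape")
        if self.bit_depth not in (8, 12, 14, 16):
            raise ValueError("unsupported bit depth")

    def burst_times_min(self) -> np.ndarray:
        """Start times (min) of every burst inside the movie."""
        return np.arange(self.start_min, self.total_duration_min + 1e-9,
                         self.burst_interval_min)

    def frame_times_min(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame timestamps (min) and the burst index of each frame."""
        bursts = self.burst_times_min()
        within = np.arange(self.frames_per_burst) * self.frame_interval_s / 60.0
        times = (bursts[:, None] + within[None, :]).ravel()
        burst_index = np.repeat(np.arange(bursts.size), self.frames_per_burst)
        return times, burst_index


@dataclass(frozen=True)
class MotionModel:
    """A single mobility regime: free Brownian or confined OU motion."""

    mode: str
    D_um2_s: float
    tau_c_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("free", "confined"):
            raise ValueError(f"unknown motion mode {self.mode!r}")
        if self.D_um2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.mode == "confined" and (self.tau_c_s is None or self.tau_c_s <= 0):
            raise ValueError("confined mode requires tau_c_s > 0")


@dataclass(frozen=True)
class MobilitySchedule:
    """Piecewise-constant mobility: ordered (start_time_min, MotionModel)."""

    segments: tuple[tuple[float, MotionModel], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty schedule")
        starts = [s for s, _ in self.segments]
        if starts[0] != 0.0:
            raise ValueError("first segment must start at 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")

    def model_at(self, t_min: float) -> MotionModel:
        model = self.segments[0][1]
        for start, m in self.segments:
            if t_min >= start:
                model = m
            else:
                break
        return model


@dataclass(frozen=True)
class ResectionScenario:
    """Cohort-level biology of one genotype scenario.

    Speeds are resection-front speeds measured from resection onset (i.e. after
    the commitment lag).  Defaults reproduce the wild-type focus-loss window of
    roughly 22-31 min with a 10-min commitment lag.
    """

    p_cut: float = 0.6
    cleavage_mean_min: float = 13.0
    cleavage_sd_min: float = 1.5
    cleavage_min_min: float = 10.0
    commitment_lag_min: float = 10.0
    v_slow_nt_min: float = 615.5
    v_fast_nt_min: float = 1900.0
    phase_switch_nt: float = 1231.0
    fast_phase_enabled: bool = False
    int1_proximal_nt: float = 76.0
    int1_distal_nt: float = 1231.0
    int2_proximal_nt: float = 3400.0
    int2_distal_nt: float = 7612.0
    confinement_onset_lag_min: float = 5.5
    recovery_time_min: float = 30.0  # minutes after cleavage
    D_free_um2_s: float = 0.019
    D_confined_um2_s: float = 0.003
    tau_c_s: float = 20.0
    tau_free_s: float = 10.0  # nuclear-territory tether used only in movies

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cut <= 1.0:
            raise ValueError("p_cut must lie in [0, 1]")
        if self.cleavage_sd_min < 0 or self.cleavage_min_min < 0:
            raise ValueError("cleavage parameters must be nonnegative")
        if self.commitment_lag_min < 0:
            raise ValueError("commitment lag must be nonnegative")
        if self.v_slow_nt_min <= 0:
            raise ValueError("slow speed must be positive")
        if self.fast_phase_enabled and self.v_fast_nt_min <= 0:
            raise ValueError("fast speed must be positive when fast phase enabled")
        for p, d in ((self.int1_proximal_nt, self.int1_distal_nt),
                     (self.int2_proximal_nt, self.int2_distal_nt)):
            if not 0 <= p < d:
                raise ValueError("cassette proximal edge must lie before distal edge")

    def span_nt(self, channel: str) -> tuple[float, float]:
        if channel == "int1":
            return self.int1_proximal_nt, self.int1_distal_nt
        if channel == "int2":
            return self.int2_proximal_nt, self.int2_distal_nt
        raise KeyError(channel)


@dataclass(frozen=True)
class RenderParams:
    """Camera/optics model used to turn focus states into pixel counts."""

    psf_sigma_px: float = 1.3
    focus_photons: float = 3000.0
    background_photons_0: float = 100.0
    bleach_tau_min: float = 20.0
    read_noise_sd: float = 3.0
    camera_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        for v in (self.focus_photons, self.background_photons_0,
                  self.bleach_tau_min, self.read_noise_sd, self.camera_gain):
            if v < 0:
                raise ValueError("render parameters must be nonnegative")


@dataclass
class ImageStack:
    """Time-ordered frames of one channel of one cell, with calibration."""

    frames: np.ndarray  # (n_frames, h, w) unsigned integer
    timestamps_min: np.ndarray
    burst_index: np.ndarray
    acquisition: AcquisitionParams
    channel: str = ""

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, h, w)")
        if len(self.timestamps_min) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class CellGroundTruth:
    """Per-cell truth: event times plus per-frame focus state and mobility."""

    cell_id: int
    cut: bool
    t_cleave_min: Optional[float]
    t_onset_min: Optional[float]
    t_loss_int1_min: Optional[float]
    t_loss_int2_min: Optional[float]
    frames: pd.DataFrame = field(default_factory=pd.DataFrame)
    # frames columns: t_min, burst, x_um, y_um, amp_int1, amp_int2, mode


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def simulate_trajectories(model: MotionModel | MobilitySchedule,
                          timestamps_min: Sequence[float],
                          start_xy_um: np.ndarray,
                          seed=None,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Simulate many trajectories over a shared time base.

    ``start_xy_um`` has shape (n_tracks, 2); the result has shape
    (n_tracks, n_times, 2).  Free segments use exact Brownian increments
    (per-axis variance 2*D*dt); confined segments use the exact discrete OU
    update x' = a + (x - a)*exp(-dt/tau) + sqrt(D*tau*(1 - exp(-2dt/tau)))*xi
    around an anchor ``a`` fixed at the position where confinement began.
    """
    t_min = np.asarray(timestamps_min, dtype=float)
    if t_min.ndim != 1 or t_min.size < 1:
        raise ValueError("timestamps must be a non-empty 1-D sequence")
    if np.any(np.diff(t_min) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    starts = np.atleast_2d(np.asarray(start_xy_um, dtype=float))
    if starts.shape[1] != 2:
        raise ValueError("start positions must be (n, 2)")
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = (model if isinstance(model, MobilitySchedule)
                else MobilitySchedule(((0.0, model),)))

    t_s = t_min * 60.0
    n_tracks = starts.shape[0]
    pos = np.empty((n_tracks, t_s.size, 2))
    pos[:, 0, :] = starts
    anchor = starts.copy()
    prev_model = schedule.model_at(t_min[0])
    for i in range(1, t_s.size):
        m = schedule.model_at(t_min[i - 1])  # model active during the step
        if m is not prev_model and m.mode == "confined":
            anchor = pos[:, i - 1, :].copy()
        prev_model = m
        dt = t_s[i] - t_s[i - 1]
        if m.mode == "free":
            sd = math.sqrt(2.0 * m.D_um2_s * dt)
            pos[:, i, :] = pos[:, i - 1, :] + rng.normal(0.0, 1.0, (n_tracks, 2)) * sd
        else:
            f = math.exp(-dt / m.tau_c_s)
            sd = math.sqrt(m.D_um2_s * m.tau_c_s * (1.0 - f * f))
            pos[:, i, :] = (anchor + (pos[:, i - 1, :] - anchor) * f
                            + rng.normal(0.0, 1.0, (n_tracks, 2)) * sd)
    return pos


def simulate_trajectory(model, timestamps_min, start_xy_um=(0.0, 0.0),
                        seed=None, rng=None) -> np.ndarray:
    """One 2D position (µm) per timestamp for a single focus."""
    out = simulate_trajectories(model, timestamps_min,
                                np.asarray(start_xy_um, float)[None, :],
                                seed=seed, rng=rng)
    return out[0]


# --------------------------------------------------------------------------
# event times and resection front
# --------------------------------------------------------------------------

def _loss_times(scenario: ResectionScenario, t_onset: float) -> tuple[float, Optional[float]]:
    t1 = t_onset + scenario.int1_distal_nt / scenario.v_slow_nt_min
    if not scenario.fast_phase_enabled:
        return t1, None
    t2 = (t_onset + scenario.phase_switch_nt / scenario.v_slow_nt_min
          + (scenario.int2_distal_nt - scenario.phase_switch_nt) / scenario.v_fast_nt_min)
    return t1, t2


def sample_event_times(scenario: ResectionScenario, n_cells: int,
                       seed=None, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw per-cell cut status and event times.

    Cleavage times are Gaussian(cleavage_mean, cleavage_sd) truncated at the
    earliest-cleavage floor by redrawing.  Returns a DataFrame with columns
    cell_id, cut, t_cleave_min, t_onset_min, t_loss_int1_min, t_loss_int2_min
    (NaN where the event does not occur).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cut = rng.random(n_cells) < scenario.p_cut
    t_cleave = np.full(n_cells, np.nan)
    if cut.any():
        draws = rng.normal(scenario.cleavage_mean_min, scenario.cleavage_sd_min,
                           int(cut.sum()))
        bad = draws < scenario.cleavage_min_min
        while bad.any():
            draws[bad] = rng.normal(scenario.cleavage_mean_min,
                                    scenario.cleavage_sd_min, int(bad.sum()))
            bad = draws < scenario.cleavage_min_min
        t_cleave[cut] = draws
    t_onset = t_cleave + scenario.commitment_lag_min
    t1 = np.full(n_cells, np.nan)
    t2 = np.full(n_cells, np.nan)
    for i in np.flatnonzero(cut):
        a, b = _loss_times(scenario, t_onset[i])
        t1[i] = a
        if b is not None:
            t2[i] = b
    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "cut": cut,
        "t_cleave_min": t_cleave,
        "t_onset_min": t_onset,
        "t_loss_int1_min": t1,
        "t_loss_int2_min": t2,
    })


def front_position_nt(t_min: float, t_onset_min: float,
                      scenario: ResectionScenario) -> float:
    """Resection-front position (nt from the cut) at time ``t_min``."""
    if t_min <= t_onset_min:
        return 0.0
    dt = t_min - t_onset_min
    t_switch = scenario.phase_switch_nt / scenario.v_slow_nt_min
    if dt <= t_switch:
        s = scenario.v_slow_nt_min * dt
    elif scenario.fast_phase_enabled:
        s = scenario.phase_switch_nt + scenario.v_fast_nt_min * (dt - t_switch)
    else:
        s = scenario.phase_switch_nt  # front halts; homology search takes over
    if not scenario.fast_phase_enabled:
        s = min(s, scenario.int1_distal_nt)
    return s


def focus_amplitude_fraction(t_min: float, t_onset_min: Optional[float],
                             scenario: ResectionScenario, channel: str) -> float:
    """Remaining fraction of a focus: ParB is evicted linearly across the span."""
    if t_onset_min is None or not np.isfinite(t_onset_min):
        return 1.0
    prox, dist = scenario.span_nt(channel)
    s = front_position_nt(t_min, t_onset_min, scenario)
    if s <= prox:
        return 1.0
    if s >= dist:
        return 0.0
    return 1.0 - (s - prox) / (dist - prox)


def mobility_schedule_for(scenario: ResectionScenario,
                          t_cleave_min: Optional[float],
                          movie: bool = True) -> MobilitySchedule:
    """Mobility schedule of one cell.

    ``movie=True`` tethers the free regime to a nuclear territory (OU with
    tau_free_s) so trajectories stay in the field of view across a one-hour
    movie; lags of a couple of seconds remain effectively Brownian.
    """
    if movie:
        free = MotionModel("confined", scenario.D_free_um2_s, scenario.tau_free_s)
    else:
        free = MotionModel("free", scenario.D_free_um2_s)
    segs: list[tuple[float, MotionModel]] = [(0.0, free)]
    if t_cleave_min is not None and np.isfinite(t_cleave_min):
        confined = MotionModel("confined", scenario.D_confined_um2_s, scenario.tau_c_s)
        segs.append((t_cleave_min + scenario.confinement_onset_lag_min, confined))
        segs.append((t_cleave_min + scenario.recovery_time_min, free))
    return MobilitySchedule(tuple(segs))


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def expected_frame(foci: Sequence[tuple[float, float, float]], t_min: float,
                   render: RenderParams, acq: AcquisitionParams) -> np.ndarray:
    """Noise-free expected photon image (float) for one channel.

    ``foci`` is a sequence of (x_um, y_um, amplitude_photons).  The PSF is a
    pixel-integrated 2D Gaussian so total flux is conserved; the background
    bleaches exponentially with movie time.
    """
    h, w = acq.image_shape
    px = acq.pixel_size_um
    if math.isfinite(render.bleach_tau_min) and render.bleach_tau_min > 0:
        bg = render.background_photons_0 * math.exp(-t_min / render.bleach_tau_min)
    else:
        bg = render.background_photons_0
    img = np.full((h, w), bg, dtype=float)
    if not foci:
        return img
    s = render.psf_sigma_px * px * math.sqrt(2.0)
    xe = np.arange(w + 1) * px
    ye = np.arange(h + 1) * px
    for x, y, amp in foci:
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(amp)):
            raise ValueError("non-finite focus state")
        if amp <= 0:
            continue
        fx = 0.5 * (erf((xe[1:] - x) / s) - erf((xe[:-1] - x) / s))
        fy = 0.5 * (erf((ye[1:] - y) / s) - erf((ye[:-1] - y) / s))
        img += amp * np.outer(fy, fx)
    return img


def render_frame(foci: Sequence[tuple[float, float, float]], t_min: float,
                 render: RenderParams, acq: AcquisitionParams,
                 seed=None, rng: Optional[np.random.Generator] = None,
                 noise: bool = True) -> np.ndarray:
    """Render one channel frame as unsigned integers clipped to bit depth.

    With ``noise=False`` (or read noise 0 and no rng) the expectation image is
    returned deterministically, rounded to integer counts.
    """
    expected = expected_frame(foci, t_min, render, acq)
    if noise:
        if rng is None:
            rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
        if render.read_noise_sd > 0:
            counts += rng.normal(0.0, render.read_noise_sd, counts.shape)
    else:
        counts = expected
    counts = counts * render.camera_gain
    top = 2 ** acq.bit_depth - 1
    return np.clip(np.rint(counts), 0, top).astype(np.uint16)


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

def generate_movie(scenario: ResectionScenario,
                   render: RenderParams,
                   acq: AcquisitionParams,
                   n_cells: int,
                   seed,
                   channels: Sequence[str] = CHANNELS
                   ) -> tuple[list[dict[str, ImageStack]], list[CellGroundTruth]]:
    """Generate one movie per cell plus the ground truth.

    Per cell: bursts of ``frames_per_burst`` frames every burst interval; both
    cassette foci share one chromatin trajectory (they are a few kb apart,
    far below the diffraction limit); channel amplitudes fade as the resection
    front traverses each cassette; mobility switches to the confined model at
    cleavage + confinement_onset_lag and back at cleavage + recovery_time.
    Randomness is split per cell so movies are reproducible cell by cell.
    """
    root = np.random.SeedSequence(seed)
    ev_ss, cells_root = root.spawn(2)
    events = sample_event_times(scenario, n_cells,
                                rng=np.random.default_rng(ev_ss))
    times, burst_index = acq.frame_times_min()
    h, w = acq.image_shape
    center = np.array([w, h], float) * acq.pixel_size_um / 2.0

    movies: list[dict[str, ImageStack]] = []
    truths: list[CellGroundTruth] = []
    for cell_ss in cells_root.spawn(n_cells):
        i = len(movies)
        traj_ss, rend_ss = cell_ss.spawn(2)
        row = events.iloc[i]
        t_cleave = float(row.t_cleave_min) if row.cut else None
        t_onset = float(row.t_onset_min) if row.cut else None
        schedule = mobility_schedule_for(scenario, t_cleave, movie=True)

        traj_rng = np.random.default_rng(traj_ss)
        start = center + traj_rng.uniform(-0.3, 0.3, 2)
        traj = simulate_trajectory(schedule, times, start, rng=traj_rng)

        amps = {ch: np.array([focus_amplitude_fraction(t, t_onset, scenario, ch)
                              for t in times]) for ch in channels}
        # label frames by regime: the nuclear-tethered baseline counts as free
        modes = ["free" if schedule.model_at(t).D_um2_s == scenario.D_free_um2_s
                 else "confined" for t in times]

        rend_rng = np.random.default_rng(rend_ss)
        stacks: dict[str, ImageStack] = {}
        for ch in channels:
            frames = np.empty((times.size, h, w), dtype=np.uint16)
            for k, t in enumerate(times):
                foci = [(traj[k, 0], traj[k, 1],
                         amps[ch][k] * render.focus_photons)]
                frames[k] = render_frame(foci, t, render, acq, rng=rend_rng)
            stacks[ch] = ImageStack(frames, times.copy(), burst_index.copy(),
                                    acq, channel=ch)

        frames_df = pd.DataFrame({
            "t_min": times, "burst": burst_index,
            "x_um": traj[:, 0], "y_um": traj[:, 1],
            "amp_int1": amps.get("int1", np.ones_like(times)),
            "amp_int2": amps.get("int2", np.ones_like(times)),
            "mode": modes,
        })
        truths.append(CellGroundTruth(
            cell_id=i, cut=bool(row.cut),
            t_cleave_min=t_cleave, t_onset_min=t_onset,
            t_loss_int1_min=float(row.t_loss_int1_min) if np.isfinite(row.t_loss_int1_min) else None,
            t_loss_int2_min=float(row.t_loss_int2_min) if np.isfinite(row.t_loss_int2_min) else None,
            frames=frames_df))
        movies.append(stacks)
    return movies, truths
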