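"""Generator correctness: trajectories against closed forms, event sampling,
and PSF rendering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import resectrack as rt
from resectrack.synthetic_microscopy import (MobilitySchedule, expected_frame,
                                             focus_amplitude_fraction,
                                             render_frame, sample_event_times,
                                             simulate_trajectories,
                                             simulate_trajectory)

DT = 0.2


# ---------------------------------------------------------------- trajectories

@given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=20),
       st.floats(-5, 5), st.floats(-5, 5))
def test_zero_diffusion_keeps_position(gaps, x0, y0):
    times = np.cumsum(np.asarray(gaps))
    for model in (rt.MotionModel("free", 0.0),
                  rt.MotionModel("confined", 0.0, tau_c_s=5.0)):
        pos = simulate_trajectory(model, times, (x0, y0), seed=0)
        assert np.allclose(pos, [x0, y0])


def test_trajectory_reproducible_and_validated():
    times = np.arange(10) * DT / 60.0 + 1.0
    m = rt.MotionModel("free", 0.019)
    a = simulate_trajectory(m, times, (0, 0), seed=42)
    b = simulate_trajectory(m, times, (0, 0), seed=42)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        simulate_trajectory(m, [1.0, 1.0], (0, 0), seed=0)
    with pytest.raises(ValueError):
        rt.MotionModel("free", -1.0)
    with pytest.raises(ValueError):
        rt.MotionModel("confined", 0.01)  # missing tau_c


def test_brownian_msd_matches_4_D_tau():
    """Ensemble MSD of the free generator agrees with 4*D*tau to 5% for
    lags up to 2 s, and single-step increments pass a chi-square test."""
    D = 0.019
    times = np.arange(10_001) * DT / 60.0
    pos = simulate_trajectories(rt.MotionModel("free", D), times,
                                np.zeros((500, 2)), seed=5)
    for k in (1, 5, 10):
        d2 = ((pos[:, k:, :] - pos[:, :-k, :]) ** 2).sum(-1)
        assert abs(d2.mean() / (4 * D * k * DT) - 1) < 0.05
    inc = np.diff(pos, axis=1)
    S = (inc ** 2).sum() / (2 * D * DT)
    lo, hi = stats.chi2.ppf([0.005, 0.995], inc.size)
    assert lo < S < hi


def test_ou_variance_and_msd_match_closed_form():
    """Confined (OU) motion: per-axis variance about the anchor reaches
    D*tau_c within 5%, and the MSD curve matches 4*D*tau_c*(1-exp(-t/tau))
    within 10% at all lags, including the plateau."""
    D, tau = 0.003, 20.0
    times = np.arange(6000) * DT / 60.0
    pos = simulate_trajectories(rt.MotionModel("confined", D, tau), times,
                                np.zeros((400, 2)), seed=9)
    var = pos[:, 3000:, :].var()
    assert abs(var / (D * tau) - 1) < 0.05
    late = pos[:, 2000:, :]
    for k in (1, 10, 50, 250, 1000, 2000):
        d2 = ((late[:, k:, :] - late[:, :-k, :]) ** 2).sum(-1)
        theory = 4 * D * tau * (1 - np.exp(-k * DT / tau))
        assert abs(d2.mean() / theory - 1) < 0.10
    plateau = ((late[:, 2000:, :] - late[:, :-2000, :]) ** 2).sum(-1).mean()
    assert abs(plateau / (4 * D * tau) - 1) < 0.10


def test_schedule_switches_anchor_on_confinement():
    free = rt.MotionModel("free", 0.019)
    conf = rt.MotionModel("confined", 0.003, 20.0)
    sched = MobilitySchedule(((0.0, free), (10.0, conf)))
    times = np.concatenate([np.arange(0, 10, 0.5), np.arange(10, 60, 0.5)])
    pos = simulate_trajectory(sched, times, (1.0, 1.0), seed=3)
    onset = np.searchsorted(times, 10.0)
    anchor = pos[onset]
    # confined segment stays within a few confinement radii of its anchor
    radius = np.sqrt(0.003 * 20.0)
    d = np.hypot(*(pos[onset:] - anchor).T)
    assert d.max() < 6 * radius


# ---------------------------------------------------------------- event times

def test_zero_lag_onset_equals_cleavage():
    scen = rt.ResectionScenario(commitment_lag_min=0.0, p_cut=1.0)
    ev = sample_event_times(scen, 50, seed=1)
    np.testing.assert_allclose(ev.t_onset_min, ev.t_cleave_min)


def test_slow_phase_duration_at_82_nt_min():
    scen = rt.ResectionScenario(p_cut=1.0, v_slow_nt_min=82.0)
    ev = sample_event_times(scen, 20, seed=2)
    np.testing.assert_allclose(ev.t_loss_int1_min - ev.t_onset_min,
                               1231.0 / 82.0, atol=1e-9)
    assert abs((ev.t_loss_int1_min - ev.t_onset_min).iloc[0] - 15.0) < 0.02


def test_fast_phase_disabled_means_no_int2_loss():
    ev = sample_event_times(rt.scenario_preset("wt"), 40, seed=3)
    assert ev.t_loss_int2_min.isna().all()


@given(st.integers(0, 1000))
def test_event_ordering_and_floor(seed):
    scen = rt.scenario_preset("yku70")
    ev = sample_event_times(scen, 10, seed=seed)
    cut = ev[ev.cut]
    assert (cut.t_cleave_min >= scen.cleavage_min_min).all()
    assert (cut.t_cleave_min <= cut.t_onset_min).all()
    assert (cut.t_onset_min < cut.t_loss_int1_min).all()
    assert (cut.t_loss_int1_min < cut.t_loss_int2_min).all()


def test_truncated_cleavage_mean_matches_analytic():
    scen = rt.ResectionScenario(p_cut=1.0, cleavage_mean_min=15.0,
                                cleavage_sd_min=2.0, cleavage_min_min=12.0)
    ev = sample_event_times(scen, 200, seed=11)
    a = (12.0 - 15.0) / 2.0
    expected = stats.truncnorm(a, np.inf, loc=15.0, scale=2.0).mean()
    assert abs(ev.t_cleave_min.mean() - expected) < 0.5


# ------------------------------------------------------------------- rendering

def test_background_only_frame_is_uniform(acq, render_noise_free):
    img = render_frame([], 5.0, render_noise_free, acq, noise=False)
    assert (img == round(render_noise_free.background_photons_0
                         * render_noise_free.camera_gain)).all()


def test_psf_peak_in_true_pixel(acq, render_noise_free):
    px = acq.pixel_size_um
    img = render_frame([((20 + 0.5) * px, (33 + 0.5) * px, 3000.0)], 0.0,
                       render_noise_free, acq, noise=False)
    iy, ix = np.unravel_index(np.argmax(img), img.shape)
    assert (iy, ix) == (33, 20)


def test_psf_flux_conserved(acq, render_noise_free):
    px = acq.pixel_size_um
    amp = 3000.0
    img = expected_frame([(32.2 * px, 30.7 * px, amp)], 0.0,
                         render_noise_free, acq)
    flux = img.sum() - render_noise_free.background_photons_0 * img.size
    assert abs(flux / amp - 1) < 0.01


def test_noisy_rendering_reproducible(acq):
    rend = rt.RenderParams()
    a = render_frame([(2.0, 2.0, 3000.0)], 0.0, rend, acq, seed=7)
    b = render_frame([(2.0, 2.0, 3000.0)], 0.0, rend, acq, seed=7)
    np.testing.assert_array_equal(a, b)
    c = render_frame([(2.0, 2.0, 3000.0)], 0.0, rend, acq, seed=8)
    assert (a != c).any()


def test_render_rejects_bad_input(acq, render_noise_free):
    with pytest.raises(ValueError):
        render_frame([(1.0, 1.0, np.nan)], 0.0, render_noise_free, acq)


# ---------------------------------------------------------------------- movies

def small_acq(**kw):
    base = dict(frames_per_burst=16, total_duration_min=30.0,
                burst_interval_min=5.0)
    base.update(kw)
    return rt.AcquisitionParams(**base)


def test_uncut_movie_retains_full_amplitude():
    movies, truths = rt.generate_movie(rt.scenario_preset("uncut"),
                                       rt.render_preset(), small_acq(), 3, 1)
    assert all(not t.cut for t in truths)
    for t in truths:
        assert (t.frames.amp_int1 == 1.0).all()
        assert (t.frames.amp_int2 == 1.0).all()


def test_wt_movie_keeps_int2_focus_everywhere():
    movies, truths = rt.generate_movie(rt.scenario_preset("wt"),
                                       rt.render_preset(),
                                       small_acq(total_duration_min=45.0),
                                       6, 2)
    for t in truths:
        assert (t.frames.amp_int2 == 1.0).all()
        assert t.t_loss_int2_min is None


def test_cut_fraction_within_binomial_range():
    _, truths = rt.generate_movie(rt.scenario_preset("wt"), rt.render_preset(),
                                  small_acq(frames_per_burst=2), 20, 4)
    n_cut = sum(t.cut for t in truths)
    assert 5 <= n_cut <= 19  # binomial 95% range at n=20, p=0.6


def test_movie_stacks_well_formed():
    movies, truths = rt.generate_movie(rt.scenario_preset("yku70"),
                                       rt.render_preset(),
                                       small_acq(burst_interval_min=2.0,
                                                 total_duration_min=16.0),
                                       2, 5)
    stack = movies[0]["int1"]
    assert stack.frames.dtype == np.uint16
    assert stack.frames.max() < 2 ** 16
    assert (np.diff(stack.timestamps_min) > 0).all()
    # amplitude fraction is linear across the cassette span
    scen = rt.scenario_preset("yku70")
    t_on = 10.0
    t_half = t_on + (scen.int1_proximal_nt
                     + 0.5 * (scen.int1_distal_nt - scen.int1_proximal_nt)
                     ) / scen.v_slow_nt_min
    assert focus_amplitude_fraction(t_half, t_on, scen, "int1") == pytest.approx(0.5)
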