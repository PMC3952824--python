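"""Detector localization and linker behaviour, including a brute-force
assignment oracle on small instances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import resectrack as rt
from resectrack.detection_tracking import (DetectionParams, SpotRecord, Track,
                                           detect_spots, filter_tracks,
                                           link_spots)
from resectrack.synthetic_microscopy import render_frame

DET = DetectionParams()


def focus_frame(points_px, acq, render, rng=None):
    px = acq.pixel_size_um
    foci = [((x + 0.5) * px, (y + 0.5) * px, 3000.0) for x, y in points_px]
    return render_frame(foci, 0.0, render, acq, rng=rng,
                        noise=rng is not None)


# ------------------------------------------------------------------- detection

def test_constant_image_has_no_spots():
    assert detect_spots(np.full((40, 40), 117.0), DET) == []


def test_detect_rejects_degenerate_input():
    with pytest.raises(ValueError):
        detect_spots(np.zeros((0, 0)), DET)
    with pytest.raises(ValueError):
        detect_spots(np.zeros((5, 5)), DET)  # radius exceeds image
    with pytest.raises(ValueError):
        detect_spots(np.full((40, 40), np.nan), DET)


def test_single_focus_localized_to_half_pixel(acq, render_noise_free):
    img = focus_frame([(12.0, 20.0)], acq, render_noise_free)
    spots = detect_spots(img, DET)
    assert len(spots) == 1
    assert abs(spots[0].x_px - 12.0) <= 0.5
    assert abs(spots[0].y_px - 20.0) <= 0.5


def test_two_separated_foci_both_found(acq, render_noise_free):
    truth = [(12.3, 20.7), (40.1, 45.6)]  # > 4*radius apart
    img = focus_frame(truth, acq, render_noise_free)
    spots = detect_spots(img, DET)
    assert len(spots) == 2
    for tx, ty in truth:
        d = min(np.hypot(s.x_px - tx, s.y_px - ty) for s in spots)
        assert d <= 0.5


def test_spots_sorted_by_score(render_noise_free):
    # larger field: the top-percentile gate keeps ~16 of 128^2 pixels, room
    # for both PSFs
    acq = rt.AcquisitionParams(image_shape=(128, 128))
    px = acq.pixel_size_um
    img = render_frame([(12.5 * px, 12.5 * px, 3000.0),
                        (45.5 * px, 45.5 * px, 1500.0)], 0.0,
                       render_noise_free, acq, noise=False)
    spots = detect_spots(img, DET)
    assert len(spots) == 2
    assert spots[0].score >= spots[1].score
    assert abs(spots[0].x_px - 12.0) < 1.0


# --------------------------------------------------------------------- linking

def chain(points, frame0=0):
    return [[SpotRecord(0, x, y, 1.0, 1.0) for x, y in pts] for pts in points]


def test_single_spot_chain_gives_one_track():
    frames = chain([[(5.0 + 0.5 * k, 7.0)] for k in range(10)])
    tracks = link_spots(frames, DET)
    assert len(tracks) == 1
    assert len(tracks[0]) == 10
    assert list(tracks[0].frames) == list(range(10))


def test_large_jump_splits_track():
    pts = [[(5.0, 5.0)]] * 5 + [[(30.0, 30.0)]] * 5
    tracks = link_spots(chain(pts), DET)
    assert sorted(len(t) for t in tracks) == [5, 5]


def test_every_spot_in_exactly_one_track():
    rng = np.random.default_rng(0)
    frames = [[SpotRecord(0, x, y, 1.0, 1.0)
               for x, y in rng.uniform(0, 50, (rng.integers(0, 5), 2))]
              for _ in range(8)]
    tracks = link_spots(frames, DET)
    seen = set()
    for t in tracks:
        for f, x in zip(t.frames, t.x_px):
            assert (f, x) not in seen
            seen.add((f, x))
    assert len(seen) == sum(len(f) for f in frames)


def oracle_pairs(prev, new, max_d):
    """Max-cardinality, then minimal-total-distance assignment by enumeration."""
    best = (-1, np.inf, [])
    idx_new = range(len(new))
    for r in range(min(len(prev), len(new)), -1, -1):
        for sub_prev in itertools.combinations(range(len(prev)), r):
            for perm in itertools.permutations(idx_new, r):
                d = [np.hypot(prev[i].x_px - new[j].x_px,
                              prev[i].y_px - new[j].y_px)
                     for i, j in zip(sub_prev, perm)]
                if any(x > max_d for x in d):
                    continue
                cand = (r, sum(d), list(zip(sub_prev, perm)))
                if (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
        if best[0] == r and best[0] >= 0:
            break
    return set(best[2])


def greedy_pairs(prev, new, max_d):
    pairs = sorted((np.hypot(a.x_px - b.x_px, a.y_px - b.y_px), i, j)
                   for i, a in enumerate(prev) for j, b in enumerate(new))
    taken_i, taken_j, out = set(), set(), set()
    for d, i, j in pairs:
        if d <= max_d and i not in taken_i and j not in taken_j:
            taken_i.add(i)
            taken_j.add(j)
            out.add((i, j))
    return out


def test_linking_matches_assignment_oracle_on_separated_spots():
    """With spots separated well beyond the displacement gate, greedy
    nearest-neighbour linking equals the minimal-total-distance assignment."""
    rng = np.random.default_rng(1)
    for trial in range(20):
        n = rng.integers(1, 6)
        base = rng.uniform(5, 200, (n, 2))
        # enforce pairwise separation > 2.5x the gate
        ok = all(np.hypot(*(base[i] - base[j])) > 25
                 for i in range(n) for j in range(i))
        if not ok:
            continue
        frames = []
        pos = base.copy()
        for _ in range(6):
            pos = pos + rng.uniform(-5, 5, pos.shape)
            frames.append([SpotRecord(0, x, y, 1.0, 1.0) for x, y in pos])
        for a, b in zip(frames, frames[1:]):
            assert greedy_pairs(a, b, 10.0) == oracle_pairs(a, b, 10.0)
        tracks = link_spots(frames, DET)
        assert len(tracks) == n
        assert all(len(t) == 6 for t in tracks)


def test_documented_greedy_counterexample():
    """Greedy linking can under-match relative to the optimal assignment:
    when one new spot is nearest to both old spots, greedy consumes it with
    the closer partner and strands the other, while the optimal assignment
    links both.  This divergence is inherent to the greedy rule."""
    prev = [SpotRecord(0, 0.0, 0.0, 1, 1), SpotRecord(0, 6.0, 0.0, 1, 1)]
    new = [SpotRecord(0, 3.0, 0.0, 1, 1), SpotRecord(0, -4.0, 0.0, 1, 1)]
    g = greedy_pairs(prev, new, 8.0)
    o = oracle_pairs(prev, new, 8.0)
    assert len(g) == 1 and len(o) == 2
    assert g == {(0, 0)}  # tie at d=3 broken by the lower previous index


# ------------------------------------------------------------------- filtering

@given(st.lists(st.integers(1, 40), max_size=8))
def test_track_filter_is_strict(lengths):
    tracks = [Track(i, np.arange(n), np.zeros(n), np.zeros(n), np.ones(n))
              for i, n in enumerate(lengths)]
    kept = filter_tracks(tracks, DET)
    assert all(len(t) > DET.min_track_frames for t in kept)
    assert len(kept) == sum(1 for n in lengths if n > 15)


def test_boundary_track_lengths():
    t15 = Track(0, np.arange(15), np.zeros(15), np.zeros(15), np.ones(15))
    t16 = Track(1, np.arange(16), np.zeros(16), np.zeros(16), np.ones(16))
    assert filter_tracks([t15], DET) == []
    assert filter_tracks([t16], DET) == [t16]
    assert filter_tracks([], DET) == []


def test_end_to_end_single_focus_burst(acq, render_noise_free):
    """A noise-free 50-frame single-focus burst yields exactly one 50-frame track."""
    rng = np.random.default_rng(6)
    times = np.arange(50) * 0.2 / 60.0
    traj = rt.simulate_trajectory(rt.MotionModel("free", 0.019), times,
                                  (2.0, 2.0), seed=2)
    frames = [render_frame([(x, y, 3000.0)], 0.0, render_noise_free, acq,
                           noise=False) for x, y in traj]
    spots = [detect_spots(f, DET) for f in frames]
    tracks = filter_tracks(link_spots(spots, DET), DET)
    assert len(tracks) == 1
    assert len(tracks[0]) == 50
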