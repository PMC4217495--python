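"""Preprocessing, detection, trace extraction, rise time and kymographs."""

import numpy as np
import pytest

from exotirf import (
    SimulationConfig,
    correct_bleaching,
    detect_events,
    extract_trace,
    kymograph,
    measure_rise_time,
    roi_side_px,
    simulate_movie,
    subtract_background,
)
from exotirf.config import colocalization_halfwidth_px
from exotirf.detect import Trace
from exotirf.synthetic import GroundTruthEvent, _gaussian_patch

from conftest import small_config

RATE, PITCH = 10.0, 0.16


def match_detections(table_like, truth, pitch=PITCH, max_dt=0.5):
    """Greedy matching of detections to ground truth within 1 um^2 / 0.5 s."""
    hw = colocalization_halfwidth_px(1.0, pitch)
    used, matches = set(), []
    for det in table_like:
        x, y, t = det.x_px, det.y_px, det.t_on_s
        hit = None
        for i, row in truth.iterrows():
            if i in used:
                continue
            if (abs(x - row.x_px) <= hw and abs(y - row.y_px) <= hw
                    and abs(t - row.t_on_s) <= max_dt):
                hit = i
                break
        if hit is not None:
            used.add(hit)
        matches.append(hit)
    return matches


class TestSubtractBackground:
    def test_blank_repeat_gives_zero(self, rng):
        blank = rng.uniform(90, 110, (32, 32))
        movie = np.repeat(blank[None], 20, axis=0)
        out = subtract_background(movie, blank_field=blank)
        assert np.allclose(out, 0.0)

    def test_constant_offset_recovered(self, rng):
        movie = rng.uniform(0, 50, (15, 16, 16))
        out = subtract_background(movie + 100.0, blank_field=np.full((16, 16), 100.0))
        assert np.allclose(out, movie, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((5, 8, 8)), blank_field=np.zeros((4, 4)))

    def test_estimator_zeroes_off_mask(self):
        cfg = small_config(background_level=200.0, bleach_fraction=0.0)
        movie, _, mask = simulate_movie(cfg, seed=3)
        out = subtract_background(movie, mask=mask)
        off = out[:, ~mask]
        # median of the clipped residual is ~0 when the estimate is centered
        assert abs(np.median(off)) < 3.0
        assert abs(off.mean()) < 8.0  # clipping at 0 leaves a small positive residue
        assert (out >= 0).all()


class TestCorrectBleaching:
    def test_no_bleaching_near_identity(self):
        cfg = small_config(n_events=0, n_events_exact=True, bleach_fraction=0.0)
        movie, _, _ = simulate_movie(cfg, seed=1)
        corrected, est = correct_bleaching(movie)
        assert abs(est.loss_fraction) < 0.01
        assert np.allclose(corrected, movie.channel(), rtol=0.02)

    def test_recovers_generator_fraction(self):
        cfg = small_config(bleach_fraction=0.10, duration_s=40.0)
        movie, truth, _ = simulate_movie(cfg, seed=5)
        exclude = np.zeros((128, 128), bool)
        for row in truth.itertuples():
            exclude[max(0, row.y_px - 12): row.y_px + 13,
                    max(0, row.x_px - 12): row.x_px + 13] = True
        _, est = correct_bleaching(movie, exclude_mask=exclude)
        assert est.loss_fraction == pytest.approx(0.10, abs=0.02)

    def test_slope_reduced_tenfold(self):
        cfg = small_config(n_events=0, n_events_exact=True, bleach_fraction=0.08,
                           duration_s=40.0)
        movie, _, _ = simulate_movie(cfg, seed=2)
        corrected, _ = correct_bleaching(movie)
        t = np.arange(movie.n_frames)
        s_raw = abs(np.polyfit(t, movie.channel().mean(axis=(1, 2)), 1)[0])
        s_cor = abs(np.polyfit(t, corrected.mean(axis=(1, 2)), 1)[0])
        assert s_cor < s_raw / 10

    def test_large_loss_warns(self, rng):
        t = np.arange(60)
        frames = (100 * np.exp(-0.02 * t))[:, None, None] * np.ones((1, 8, 8))
        frames += rng.normal(0, 0.1, frames.shape)
        with pytest.warns(UserWarning, match="50%"):
            correct_bleaching(frames)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            correct_bleaching(np.zeros((5, 8, 8)))


class TestDetectEvents:
    def test_pure_noise_false_positives(self):
        # Monte Carlo over noise-only movies: expected false positives < 1
        # per movie at the default 5-sigma threshold
        cfg = small_config(n_events=0, n_events_exact=True, bleach_fraction=0.0)
        total = 0
        for s in range(6):
            movie, _, _ = simulate_movie(cfg, seed=100 + s)
            total += len(detect_events(movie.channel(), RATE, PITCH))
        assert total < 6

    def test_single_event_localization(self, kinetics):
        cfg = small_config(n_events=1, n_events_exact=True, bleach_fraction=0.0)
        movie, truth, _ = simulate_movie(cfg, seed=8)
        dets = detect_events(movie.channel(), RATE, PITCH)
        assert len(dets) == 1
        assert abs(dets[0].x_px - truth.x_px[0]) <= 1
        assert abs(dets[0].y_px - truth.y_px[0]) <= 1
        assert abs(dets[0].t_on_s - truth.t_on_s[0]) <= 0.1 + 1e-9

    def test_recall_precision(self, basal_small):
        _, movie, truth, _ = basal_small
        dets = detect_events(movie, channel="SEP")
        matches = match_detections(dets, truth)
        tp = sum(m is not None for m in matches)
        assert tp / len(truth) >= 0.9
        assert tp / len(dets) >= 0.9

    def test_count_monotone_in_threshold(self, basal_small):
        _, movie, _, _ = basal_small
        counts = [len(detect_events(movie, channel="SEP", min_rise_sigma=s))
                  for s in (3.0, 5.0, 8.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self, basal_small):
        _, movie, _, _ = basal_small
        frames = movie.channel()
        dx, dy = 9, -6
        shifted = np.roll(np.roll(frames, dy, axis=1), dx, axis=2)
        a = detect_events(frames, RATE, PITCH)
        b = detect_events(shifted, RATE, PITCH)
        pos_a = sorted(((d.x_px + dx) % 128, (d.y_px + dy) % 128, round(d.t_on_s, 3))
                       for d in a)
        pos_b = sorted((d.x_px, d.y_px, round(d.t_on_s, 3)) for d in b)
        assert pos_a == pos_b

    def test_empty_on_constant_movie(self):
        assert detect_events(np.full((50, 32, 32), 7.0), RATE, PITCH) == []


class TestExtractTrace:
    def test_uniform_movie(self):
        movie = np.full((30, 64, 64), 42.0)
        ev = GroundTruthEvent(0, 32, 32, 1.0, "transient", 1.0)
        tr = extract_trace(movie, ev, RATE, PITCH)
        assert np.allclose(tr.spot, 42.0)
        assert np.allclose(tr.surround, 42.0)

    def test_roi_conversion(self):
        assert roi_side_px(4.0, 0.16) == 13
        assert roi_side_px(16.0, 0.16) == 25
        assert roi_side_px(1.0, 0.16) == 7

    def test_noiseless_amplitude_exact(self):
        # analytic spot: extract_trace reproduces the generating amplitude
        patch, r = _gaussian_patch(1.5, 6)
        movie = np.full((20, 64, 64), 10.0)
        movie[10:, 32 - r: 32 + r + 1, 32 - r: 32 + r + 1] += 200.0 * patch
        ev = GroundTruthEvent(0, 32, 32, 1.0, "transient", 1.0)
        tr = extract_trace(movie, ev, RATE, PITCH)
        assert tr.spot[9] == pytest.approx(10.0)
        assert tr.spot[10] == pytest.approx(210.0)

    def test_surround_sustained_increase(self, kinetics):
        cfg = small_config(n_events=1, n_events_exact=True, bleach_fraction=0.0,
                           duration_s=40.0)
        movie, truth, _ = simulate_movie(cfg, seed=23)
        ev = GroundTruthEvent(0, int(truth.x_px[0]), int(truth.y_px[0]),
                              float(truth.t_on_s[0]), "transient", 1.0)
        tr = extract_trace(movie, ev, RATE, PITCH)
        f_on = int(round(ev.t_on_s * RATE))
        pre = tr.surround[max(0, f_on - 30): f_on - 2].mean()
        post = tr.surround[f_on + 5: f_on + 35].mean()
        assert post > pre

    def test_edge_clipping_error(self):
        movie = np.zeros((15, 64, 64))
        ev = GroundTruthEvent(0, 0, 0, 0.5, "transient", 1.0)
        with pytest.raises(ValueError, match="50%"):
            extract_trace(movie, ev, RATE, PITCH)

    def test_partial_clip_warns(self):
        movie = np.zeros((15, 64, 64))
        ev = GroundTruthEvent(0, 6, 32, 0.5, "transient", 1.0)
        with pytest.warns(UserWarning, match="clipped"):
            extract_trace(movie, ev, RATE, PITCH)


def _step_trace(n=40, f_step=15, base=10.0, peak=110.0, ramp=1):
    """Step (ramp=1) or linear ramp spanning ``ramp`` frame intervals."""
    y = np.full(n, base)
    if ramp <= 1:
        y[f_step:] = peak
    else:
        y[f_step: f_step + ramp + 1] = np.linspace(base, peak, ramp + 1)
        y[f_step + ramp:] = peak
    return Trace(0, "SEP", np.arange(n) / RATE, y, y * 0, base,
                 t_on_s=f_step / RATE)


class TestRiseTime:
    def test_single_frame_step(self):
        # a one-frame step is resolution limited: 10-90% interpolation gives
        # 0.8 of the frame interval
        rise = measure_rise_time(_step_trace())
        assert rise == pytest.approx(0.08)
        assert rise <= 1.0 / RATE

    def test_linear_ramp(self):
        # 10 intermediate frames spanning 1 s: 10-90% of the ramp = 0.8 s
        tr = _step_trace(n=60, f_step=20, ramp=10)
        assert measure_rise_time(tr) == pytest.approx(0.8, abs=0.05)

    def test_peak_at_first_frame_rejected(self):
        y = np.linspace(100, 0, 30)
        tr = Trace(0, "SEP", np.arange(30) / RATE, y, y * 0, 1.0, t_on_s=0.0)
        with pytest.raises(ValueError):
            measure_rise_time(tr)

    def test_local_baseline_shields_earlier_event(self):
        # an earlier event at a nearby site raises the ROI level; the rise
        # of the second event is still measured from its own step
        n = 80
        y = np.full(n, 10.0)
        y[20:] = 60.0   # neighbor event
        y[50:] = 160.0  # the event under measurement
        tr = Trace(0, "SEP", np.arange(n) / RATE, y, y * 0, 10.0, t_on_s=5.0)
        assert measure_rise_time(tr) == pytest.approx(0.08)


class TestKymograph:
    def test_static_uniform(self):
        movie = np.full((25, 40, 40), 3.0)
        path = np.array([[5, 5], [30, 30]])
        k = kymograph(movie, path)
        assert k.shape[1] == 25
        assert np.allclose(k, 3.0)

    def test_transient_streak_duration(self, kinetics):
        cfg = small_config(n_events=1, n_events_exact=True, bleach_fraction=0.0)
        movie, truth, _ = simulate_movie(cfg, seed=8)
        x, y = int(truth.x_px[0]), int(truth.y_px[0])
        path = np.array([[max(0, x - 15), y], [min(127, x + 15), y]])
        k = kymograph(movie, path, width_px=3)
        prof = k.max(axis=0)
        bright = prof > np.median(prof) + 100
        # transient event: a streak of roughly the decay duration (~2 s
        # half-life -> a few tens of frames above half peak)
        assert 3 <= bright.sum() <= 80

    def test_persistent_band_longer_than_4s(self, kinetics):
        cfg = small_config(n_events=1, n_events_exact=True, persistent_fraction=1.0,
                           consecutive_fraction=0.0, bleach_fraction=0.0,
                           duration_s=40.0)
        movie, truth, _ = simulate_movie(cfg, seed=9)
        x, y = int(truth.x_px[0]), int(truth.y_px[0])
        path = np.array([[max(0, x - 10), y], [min(127, x + 10), y]])
        k = kymograph(movie, path, width_px=3)
        prof = k.max(axis=0)
        bright = prof > np.median(prof) + 100
        assert bright.sum() / RATE > 4.0

    def test_path_validation(self):
        movie = np.zeros((5, 20, 20))
        with pytest.raises(ValueError):
            kymograph(movie, np.array([[1, 1]]))
        with pytest.raises(ValueError):
            kymograph(movie, np.array([[0, 0], [50, 50]]))
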