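"""Dot detection, tracking, cell assignment, parity and kymographs."""

import itertools

import numpy as np
import pytest

from psboundary import (Dot, StripeLabel, assign_dots_to_cells, build_kymograph,
                        classify_expressing_cells, classify_stripe_parity,
                        detect_dots, generate_dot_movie, track_dots)
from psboundary.dots import DotTrack

from conftest import quad_row_frame


def gaussian_spot(shape, cx, cy, amp, sigma=1.5):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestDetect:
    def test_empty_image(self):
        assert detect_dots(np.zeros((20, 20)), threshold=5.0) == []

    def test_single_spot_centroid(self):
        img = gaussian_spot((11, 11), 5.0, 5.0, amp=10.0)
        dots = detect_dots(img, threshold=5.0)
        assert len(dots) == 1
        assert abs(dots[0].x - 5.0) < 0.5 and abs(dots[0].y - 5.0) < 0.5
        assert dots[0].intensity == pytest.approx(img.max())

    def test_subthreshold_spot_ignored(self):
        img = (gaussian_spot((30, 30), 8, 8, amp=10.0)
               + gaussian_spot((30, 30), 22, 22, amp=3.0))
        assert len(detect_dots(img, threshold=5.0)) == 1

    def test_min_area_filter(self):
        img = np.zeros((10, 10))
        img[2, 2] = 10.0  # single hot pixel
        assert detect_dots(img, threshold=5.0, min_area=2) == []

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            detect_dots(np.zeros((3, 3, 3)), threshold=5.0)
        with pytest.raises(ValueError):
            detect_dots(np.zeros((3, 3)), threshold=0.0)


def _min_total_matching(prev, new):
    """Brute-force minimum-total-displacement matching on tiny instances."""
    best, cost = None, np.inf
    for perm in itertools.permutations(range(len(new))):
        c = sum(np.hypot(px - new[j][0], py - new[j][1])
                for (px, py), j in zip(prev, perm))
        if c < cost:
            best, cost = perm, c
    return best


class TestTracking:
    def test_stationary_dots(self):
        dots = {f: [Dot(f, 1.0, 1.0, 5.0), Dot(f, 10.0, 1.0, 5.0)] for f in range(3)}
        tracks = track_dots(dots, max_displacement=2.0)
        assert len(tracks) == 2
        assert all(len(t.frames) == 3 for t in tracks)

    def test_moving_dot_followed(self):
        dots = {f: [Dot(f, float(f), 0.0, 5.0)] for f in range(5)}
        tracks = track_dots(dots, max_displacement=2.0)
        assert len(tracks) == 1

    def test_too_fast_dot_splits(self):
        dots = {f: [Dot(f, 5.0 * f, 0.0, 5.0)] for f in range(3)}
        assert len(track_dots(dots, max_displacement=2.0)) == 3

    def test_gap_bridging(self):
        dots = {0: [Dot(0, 1.0, 1.0, 5.0)], 1: [], 2: [Dot(2, 1.0, 1.0, 5.0)]}
        assert len(track_dots(dots, max_displacement=2.0, max_gap=1)) == 1
        assert len(track_dots(dots, max_displacement=2.0, max_gap=0)) == 2

    def test_swap_instance_matches_bruteforce(self):
        # two dots exchanging positions: greedy must equal the optimal matching
        prev = [(0.0, 0.0), (3.0, 0.0)]
        new = [(3.0, 0.0), (0.0, 0.0)]
        dots = {0: [Dot(0, *p, intensity=5.0) for p in prev],
                1: [Dot(1, *p, intensity=5.0) for p in new]}
        tracks = track_dots(dots, max_displacement=10.0)
        perm = _min_total_matching(prev, new)
        assert len(tracks) == 2
        for ti, t in enumerate(tracks):
            assert t.positions[1] == new[perm[ti]]

    def test_time_reversal_symmetric_for_stationary_input(self):
        dots = {f: [Dot(f, 1.0, 2.0, 5.0), Dot(f, 9.0, 2.0, 5.0)] for f in range(4)}
        fwd = track_dots(dots, max_displacement=1.0)
        rev = track_dots({3 - f: d for f, d in dots.items()}, max_displacement=1.0)
        key = lambda ts: sorted(tuple(t.positions[0]) for t in ts)
        assert key(fwd) == key(rev) and len(fwd) == len(rev)


class TestAssignment:
    def test_dot_at_centroid(self):
        frame = quad_row_frame(3)
        assert assign_dots_to_cells([Dot(0, 1.5, 0.5, 1.0)], frame) == [1]

    def test_far_dot_unassigned(self):
        frame = quad_row_frame(3)
        assert assign_dots_to_cells([Dot(0, 200.0, 0.5, 1.0)], frame,
                                    capture_radius=5.0) == [None]

    def test_edge_dot_nearest_centroid_tiebreak(self):
        frame = quad_row_frame(2)
        # exactly on the shared edge: equidistant centroids -> smaller cell_id
        assert assign_dots_to_cells([Dot(0, 1.0, 0.5, 1.0)], frame) == [0]

    def test_synthetic_zero_jitter_fully_recovered(self, noise_free_tissue):
        dots = generate_dot_movie(noise_free_tissue)
        frame = noise_free_tissue.frames[0]
        sub = dots[dots.frame == 0]
        got = assign_dots_to_cells(sub, frame)
        assert got == list(sub.truth_cell_id)


class TestExpressingCells:
    @staticmethod
    def _track(cell_id, frames):
        t = DotTrack(track_id=0)
        for f in frames:
            t.frames.append(f)
            t.positions.append((0.0, 0.0))
            t.intensities.append(1.0)
        t.cell_ids = [cell_id] * len(frames)
        return t

    def test_persistence_threshold(self):
        pos = self._track(7, [0, 2, 4, 6, 8])
        neg = self._track(8, [3])
        got = classify_expressing_cells([pos, neg], min_frames=3, window=(0, 9))
        assert got == {7}

    def test_no_dots_empty(self):
        assert classify_expressing_cells([], min_frames=3) == set()

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            classify_expressing_cells([], min_frames=1, window=(5, 2))


class TestParity:
    def _stripes(self, n):
        return [StripeLabel(stripe_index=i, cell_ids={i}) for i in range(n)]

    def test_alternating_brightness_calls_even_odd(self):
        out = classify_stripe_parity(self._stripes(4),
                                     {0: 10.0, 1: 5.0, 2: 10.0, 3: 5.0},
                                     ratio_threshold=1.5)
        assert [s.parity for s in out] == ["even", "odd", "even", "odd"]

    def test_uniform_brightness_unknown(self):
        out = classify_stripe_parity(self._stripes(3), {0: 7.0, 1: 7.0, 2: 7.0},
                                     ratio_threshold=1.5)
        assert all(s.parity == "unknown" for s in out)

    def test_non_alternating_ambiguous_unknown(self):
        out = classify_stripe_parity(self._stripes(4),
                                     {0: 10.0, 1: 10.0, 2: 5.0, 3: 5.0},
                                     ratio_threshold=1.5)
        assert all(s.parity == "unknown" for s in out)

    def test_forced_parity_single_class(self):
        # knockdown-like input: only the dim stripes remain
        out = classify_stripe_parity(self._stripes(3), {0: 5.0, 1: 5.0, 2: 5.0},
                                     ratio_threshold=1.5, forced_parity="odd")
        assert all(s.parity == "odd" for s in out)


class TestKymograph:
    def test_stationary_dot_single_bin_per_column(self, noise_free_tissue):
        import pandas as pd
        dots = pd.DataFrame({"frame": [0, 1, 2], "x": [5.0] * 3, "y": [1.0] * 3,
                             "intensity": [2.0] * 3})
        kymo, edges, frames = build_kymograph(dots, ap_bins=10, ap_range=(0, 10))
        nz = [np.nonzero(kymo[:, j])[0] for j in range(3)]
        assert all(len(b) == 1 for b in nz)
        assert len({b[0] for b in nz}) == 1

    def test_count_conservation(self, noise_free_tissue):
        dots = generate_dot_movie(noise_free_tissue)
        kymo, _, frames = build_kymograph(dots, ap_bins=25)
        for j, f in enumerate(frames):
            assert kymo[:, j].sum() == (dots.frame == f).sum()

    def test_intensity_mode_shows_parity_bands(self, noise_free_tissue):
        truth = noise_free_tissue.cell_truth
        dots = generate_dot_movie(noise_free_tissue)
        n_ps = int(truth.parasegment.max()) + 1
        kymo, edges, _ = build_kymograph(dots, ap_bins=n_ps, mode="intensity")
        band_mean = kymo.mean(axis=1)
        # even-numbered parasegment bands twice as bright as odd ones
        assert all(band_mean[i] > 1.5 * band_mean[i + 1] for i in range(0, n_ps - 1, 2))
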