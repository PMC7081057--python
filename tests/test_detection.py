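"""Spot detection, track linking and fold changes, checked against brute-force oracles."""

import numpy as np
import pytest

from nirdose.detection import (
    Detection,
    ImageFrame,
    compute_fold_change,
    compute_fold_changes,
    detect_cells,
    gaussian_kernel,
    gaussian_smooth,
    link_tracks,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_convolve(image, kernel):
    """Nested-loop 3x3 correlation with edge replication."""
    rows, cols = image.shape
    r = kernel.shape[0] // 2
    out = np.zeros_like(image, dtype=float)
    for i in range(rows):
        for j in range(cols):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), rows - 1)
                    jj = min(max(j + dj, 0), cols - 1)
                    acc += kernel[di + r, dj + r] * image[ii, jj]
            out[i, j] = acc
    return out


def brute_force_detect(smoothed, threshold, window):
    """Exhaustive per-pixel neighborhood scan with the row-major plateau rule."""
    rows, cols = smoothed.shape
    r = window // 2
    kept = []
    for i in range(rows):
        for j in range(cols):
            v = smoothed[i, j]
            if v <= threshold:
                continue
            patch = smoothed[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1]
            if v < patch.max():
                continue
            if any(abs(ki - i) <= r and abs(kj - j) <= r for ki, kj in kept):
                continue
            kept.append((i, j))
    return kept


def make_frame(pixels, label="pre"):
    return ImageFrame(pixels=np.asarray(pixels, dtype=float), timepoint_label=label)


def gaussian_spot(shape, center, sigma=2.0, amplitude=100.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((xx - center[1]) ** 2 + (yy - center[0]) ** 2) / (2 * sigma**2)
    )


def det(col, row, label="pre", raw=1.0):
    return Detection(col=col, row=row, intensity_raw=raw,
                     intensity_smoothed=raw, frame_label=label)


# ---------------------------------------------------------------------------
# smoothing


class TestGaussianSmooth:
    def test_kernel_is_normalized(self):
        assert gaussian_kernel().sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_unchanged(self):
        out = gaussian_smooth(make_frame(np.full((16, 16), 42.0)))
        np.testing.assert_allclose(out.pixels, 42.0, rtol=1e-12)

    def test_interior_impulse_mass_conserved(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = gaussian_smooth(make_frame(img))
        assert out.pixels[4:7, 4:7].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.pixels.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_nested_loop_convolution(self, rng):
        img = rng.uniform(0, 1000, size=(32, 32))
        out = gaussian_smooth(make_frame(img))
        expected = brute_force_convolve(img, gaussian_kernel())
        np.testing.assert_allclose(out.pixels, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# detection


class TestDetectCells:
    def test_flat_frame_below_threshold_yields_nothing(self):
        f = make_frame(np.full((20, 20), 5.0))
        assert detect_cells(f, f, threshold=10.0) == []

    def test_single_gaussian_spot_is_one_detection_at_its_peak(self):
        img = gaussian_spot((32, 32), center=(15, 18))
        sm = gaussian_smooth(make_frame(img))
        dets = detect_cells(sm, make_frame(img), threshold=10.0)
        assert len(dets) == 1
        assert (dets[0].row, dets[0].col) == (15, 18)
        assert dets[0].intensity_raw == pytest.approx(100.0)

    def test_well_separated_spots_all_recovered(self, rng):
        truth = [(r, c) for r in range(10, 250, 60) for c in range(12, 250, 60)][:20]
        img = np.zeros((256, 256))
        for r, c in truth:
            img += gaussian_spot((256, 256), (r, c))
        sm = gaussian_smooth(make_frame(img))
        dets = detect_cells(sm, make_frame(img), threshold=20.0)
        assert sorted((d.row, d.col) for d in dets) == sorted(truth)
        assert brute_force_detect(sm.pixels, 20.0, 5) == [(d.row, d.col) for d in dets]

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_neighborhood_scan_on_random_frames(self, seed):
        r = np.random.default_rng(seed)
        shape = tuple(r.integers(8, 65, size=2))
        # coarse quantization creates plateaus, exercising the tie-break rule
        img = np.round(r.uniform(0, 12, size=shape))
        f = make_frame(img)
        dets = detect_cells(f, f, threshold=6.0)
        assert [(d.row, d.col) for d in dets] == brute_force_detect(img, 6.0, 5)

    def test_plateau_emits_single_row_major_detection(self):
        img = np.zeros((12, 12))
        img[5:7, 5:7] = 9.0  # flat-topped 2x2 plateau
        f = make_frame(img)
        dets = detect_cells(f, f, threshold=1.0)
        assert [(d.row, d.col) for d in dets] == [(5, 5)]

    def test_detection_count_invariant_under_constant_offset(self, rng):
        img = rng.uniform(0, 50, size=(40, 40))
        f = make_frame(img)
        g = make_frame(img + 100.0)
        d0 = detect_cells(f, f, threshold=25.0)
        d1 = detect_cells(g, g, threshold=125.0)
        assert [(d.row, d.col) for d in d0] == [(d.row, d.col) for d in d1]

    def test_no_two_detections_share_a_window(self, rng):
        img = np.round(rng.uniform(0, 8, size=(48, 48)))
        f = make_frame(img)
        dets = detect_cells(f, f, threshold=3.0)
        pos = [(d.row, d.col) for d in dets]
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                cheb = max(abs(pos[a][0] - pos[b][0]), abs(pos[a][1] - pos[b][1]))
                assert cheb > 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            detect_cells(make_frame(np.ones((4, 4))), make_frame(np.ones((5, 5))), 0.0)

    def test_raw_intensity_read_from_unfiltered_frame(self):
        img = gaussian_spot((24, 24), (12, 12), amplitude=80.0)
        sm = gaussian_smooth(make_frame(img))
        d = detect_cells(sm, make_frame(img), threshold=5.0)[0]
        assert d.intensity_raw == pytest.approx(80.0)
        assert d.intensity_smoothed < d.intensity_raw  # filter flattens the peak


# ---------------------------------------------------------------------------
# linking


class TestLinkTracks:
    def test_identical_frames_retain_every_cell_with_zero_displacement(self):
        base = [det(10, 10), det(40, 12), det(25, 30)]
        frames = [base,
                  [det(d.col, d.row, "1min") for d in base],
                  [det(d.col, d.row, "5min") for d in base]]
        tracks = link_tracks(frames, "pre")
        assert len(tracks) == 3
        for t in tracks:
            assert t.position("pre") == t.position("1min") == t.position("5min")

    def test_cell_moving_beyond_tolerance_is_dropped(self):
        frames = [[det(10, 10), det(40, 40)],
                  [det(10, 10, "1min"), det(43, 40, "1min")]]  # moved tol+1 px
        tracks = link_tracks(frames, "pre", tolerance_px=2.0)
        assert [t.position("pre") for t in tracks] == [(10, 10)]

    def test_jittered_population_matches_unique_bruteforce_assignment(self, rng):
        # 50 cells on a 20-px grid, jitter < tolerance; 5 vanish at 1 min
        base_pos = [(20 * i + 5, 20 * j + 5) for i in range(10) for j in range(5)]
        base = [det(c, r) for c, r in base_pos]
        survivors = base_pos[:45]
        later = [
            det(c + int(rng.integers(-1, 2)), r + int(rng.integers(-1, 2)), "1min")
            for c, r in survivors
        ]
        tracks = link_tracks([base, later], "pre", tolerance_px=2.0)
        assert len(tracks) == 45
        # brute-force oracle: on this separable instance each baseline has at
        # most one candidate within tolerance, so the optimal matching is unique
        for t in tracks:
            bc, br = t.position("pre")
            cands = [
                (d.col, d.row) for d in later
                if np.hypot(d.col - bc, d.row - br) <= 2.0
            ]
            assert len(cands) == 1 and t.position("1min") == cands[0]

    def test_mutual_exclusivity_prefers_nearest(self):
        # two baseline cells, one later detection equidistant-ish: closest wins
        frames = [[det(10, 10), det(13, 10)], [det(11, 10, "1min")]]
        tracks = link_tracks(frames, "pre", tolerance_px=2.0)
        assert len(tracks) == 1
        assert tracks[0].position("pre") == (10, 10)

    def test_duplicate_timepoint_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            link_tracks([[det(1, 1)], [det(2, 2)]], "pre")

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            link_tracks([[det(1, 1, "1min")]], "pre")


# ---------------------------------------------------------------------------
# fold changes


class TestFoldChange:
    def _track(self, intensities):
        dets = {
            label: det(5, 5, label, raw=v)
            for label, v in zip(("pre", "1min", "5min"), intensities)
        }
        from nirdose.detection import CellTrack

        return CellTrack(cell_id=0, detections=dets)

    def test_constant_intensity_gives_unit_fold_changes(self):
        t = compute_fold_change(self._track([100, 100, 100]), "pre")
        assert t.fold_changes == {"pre": 1.0, "1min": 1.0, "5min": 1.0}

    def test_halved_intensity_gives_half(self):
        t = compute_fold_change(self._track([200, 100, 150]), "pre")
        assert t.fold_changes["1min"] == pytest.approx(0.5)
        assert t.fold_changes["pre"] == 1.0

    def test_nonpositive_baseline_is_excluded_with_reason(self):
        bad = self._track([0, 10, 10])
        good = self._track([50, 25, 50])
        kept = compute_fold_changes([bad, good], "pre")
        assert kept == [good]
        assert "not positive" in bad.excluded_reason

    def test_programmed_fold_recovered_from_noise_free_rendering(self):
        """A rendered cell with fold 0.8 measures 0.8 within PSF-sampling error."""
        import pandas as pd

        from nirdose.synthetic import SceneParams, render_frames

        params = SceneParams(
            frame_shape=(64, 64), noise_sd_frac=0.0, bleach_per_acquisition=0.0,
            timepoints=("pre", "1min"), seed=0,
        )
        truth = pd.DataFrame(
            [{"cell_id": 0, "col": 31.3, "row": 30.7, "amplitude": 3000.0,
              "fold_pre": 1.0, "fold_1min": 0.8}]
        )
        frames = render_frames(params, truth)
        smoothed = [gaussian_smooth(f) for f in frames]
        per_frame = [
            detect_cells(s, f, threshold=200.0)
            for s, f in zip(smoothed, frames)
        ]
        tracks = compute_fold_changes(link_tracks(per_frame, "pre"), "pre")
        assert len(tracks) == 1
        # background offset (100 counts) plus pixel quantization: < 2% error
        assert tracks[0].fold_changes["1min"] == pytest.approx(0.8, rel=0.02)

    def test_identical_frames_pipeline_returns_unit_folds(self, rng):
        img = np.zeros((64, 64))
        for r, c in [(10, 12), (30, 40), (50, 20)]:
            img += gaussian_spot((64, 64), (r, c), amplitude=500.0)
        frames = [make_frame(img, lbl) for lbl in ("pre", "1min", "5min")]
        smoothed = [gaussian_smooth(f) for f in frames]
        per_frame = [detect_cells(s, f, 50.0) for s, f in zip(smoothed, frames)]
        tracks = compute_fold_changes(link_tracks(per_frame, "pre"), "pre")
        assert len(tracks) == 3
        for t in tracks:
            assert all(v == pytest.approx(1.0) for v in t.fold_changes.values())
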