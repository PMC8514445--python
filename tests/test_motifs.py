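"""dF/F, sensory maps, convolutional NMF, templates, and motif matching."""

import numpy as np
import pytest

from mesomap.motifs import (
    compute_dff,
    convnmf,
    epoch_split,
    factorize_movie,
    make_templates,
    match_motifs,
    mbfm_from_images,
    motif_image,
    peak_map,
    stimulus_average,
)
from mesomap.synthetic import MotifSimSpec, simulate_activity


class TestComputeDff:
    def test_constant_movie_zero(self):
        movie = np.full((10, 4, 4), 50.0)
        assert np.abs(compute_dff(movie)).max() == 0.0

    def test_arithmetic(self):
        movie = np.full((5, 2, 2), 100.0)
        movie[2] = 110.0
        dff = compute_dff(movie, baseline=slice(0, 1))
        assert dff[2, 0, 0] == pytest.approx(0.10)

    def test_elementwise_oracle(self, rng):
        movie = rng.uniform(50, 150, (20, 6, 6))
        dff = compute_dff(movie)
        f0 = movie.mean(axis=0)
        assert np.abs(dff - (movie - f0) / f0).max() < 1e-12

    def test_nonpositive_baseline_error(self):
        movie = np.zeros((5, 3, 3))
        movie[:, 0, 0] = 10.0
        with pytest.raises(ValueError, match="offset"):
            compute_dff(movie)


class TestStimulusAverage:
    def test_single_event_is_raw_slice(self, rng):
        dff = rng.normal(size=(50, 4, 4))
        avg, trials = stimulus_average(dff, [20], pre=5, post=10)
        assert np.array_equal(avg, dff[15:30])
        assert trials.shape == (1, 15, 4, 4)

    def test_identical_events_average_unchanged(self, rng):
        dff = rng.normal(size=(50, 4, 4))
        avg, _ = stimulus_average(dff, [20, 20], pre=5, post=10)
        assert np.allclose(avg, dff[15:30])

    def test_planted_response_recovered(self, rng):
        amplitude = 0.5
        sigma = 0.2
        n_trials = 30
        t_len, pre, post = 40, 5, 10
        events = [10 + 20 * i for i in range(n_trials)]
        dff = rng.normal(0, sigma, (events[-1] + post + 5, 8, 8))
        for e in events:
            dff[e + 2, 4, 4] += amplitude
        avg, _ = stimulus_average(dff, events, pre=pre, post=post)
        assert abs(avg[pre + 2, 4, 4] - amplitude) < 3 * sigma / np.sqrt(n_trials)

    def test_out_of_bounds_events_listed(self, rng):
        dff = rng.normal(size=(30, 2, 2))
        with pytest.raises(ValueError, match="28"):
            stimulus_average(dff, [10, 28], pre=5, post=10)


class TestPeakMap:
    def test_hotspot_located(self):
        epoch = np.zeros((10, 16, 16))
        rr, cc = np.mgrid[0:16, 0:16]
        blob = np.exp(-((rr - 9.0) ** 2 + (cc - 5.0) ** 2) / 4.0)
        epoch[6] = blob
        sm = peak_map(epoch, stim_frame_index=3)
        assert sm.peak_px == (9, 5)
        assert np.allclose(sm.centroid_px, (9, 5), atol=0.5)

    def test_flat_epoch_tie_rule(self):
        sm = peak_map(np.zeros((5, 4, 4)), stim_frame_index=0)
        assert sm.peak_px == (0, 0)

    def test_centroid_moment_oracle(self):
        epoch = np.zeros((3, 20, 20))
        rr, cc = np.mgrid[0:20, 0:20]
        blob = np.exp(-((rr - 12.0) ** 2 + (cc - 7.0) ** 2) / 8.0)
        epoch[2] = blob
        sm = peak_map(epoch, stim_frame_index=0, centroid_fraction=0.75)
        sel = blob >= 0.75 * blob.max()
        oracle = (
            (rr[sel] * blob[sel]).sum() / blob[sel].sum(),
            (cc[sel] * blob[sel]).sum() / blob[sel].sum(),
        )
        assert np.allclose(sm.centroid_px, oracle, atol=1e-9)

    def test_only_frames_after_stimulus_counted(self):
        epoch = np.zeros((6, 4, 4))
        epoch[1, 2, 2] = 5.0  # before/at the stimulus frame
        epoch[4, 1, 1] = 1.0
        sm = peak_map(epoch, stim_frame_index=1)
        assert sm.peak_px == (1, 1)


class TestConvNMF:
    def test_zero_input_zero_factors(self):
        w, h, errs = convnmf(np.zeros((10, 40)), k=2, l=4, n_iter=5)
        assert w.sum() == 0 and h.sum() == 0 and errs.sum() == 0

    def test_nonnegativity_preserved(self, rng):
        x = rng.uniform(0, 1, (30, 60))
        w, h, _ = convnmf(x, k=2, l=5, n_iter=20, seed=1)
        assert (w >= 0).all() and (h >= 0).all()

    def test_objective_nonincreasing(self, small_scene):
        sim = MotifSimSpec(n_motifs=2, motif_frames=6, movie_frames=150,
                           occurrences=6, noise_sigma=0.1, seed=2)
        movie, _, _ = simulate_activity(small_scene, sim)
        x = movie[:, small_scene.true_mask > 0].T
        _, _, errs = convnmf(x, k=2, l=6, n_iter=40, seed=0)
        assert np.all(np.diff(errs) <= 1e-6 * errs[:-1])

    def test_planted_single_motif_recovery(self, small_scene):
        sim = MotifSimSpec(n_motifs=1, motif_frames=8, movie_frames=200,
                           occurrences=6, noise_sigma=0.0, seed=5)
        movie, _, _ = simulate_activity(small_scene, sim)
        x = movie[:, small_scene.true_mask > 0].T
        _, _, errs = convnmf(x, k=1, l=8, n_iter=100, seed=0)
        assert errs[-1] / (x**2).sum() < 0.05

    def test_penalty_discourages_duplicate_factors(self, small_scene):
        sim = MotifSimSpec(n_motifs=1, motif_frames=6, movie_frames=150,
                           occurrences=6, noise_sigma=0.05, seed=6)
        movie, _, _ = simulate_activity(small_scene, sim)
        x = movie[:, small_scene.true_mask > 0].T
        w0, _, _ = convnmf(x, k=2, l=6, n_iter=50, seed=1, lam=0.0)
        w1, _, _ = convnmf(x, k=2, l=6, n_iter=50, seed=1, lam=1e-3)
        def factor_overlap(w):
            a = w[:, 0, :].ravel()
            b = w[:, 1, :].ravel()
            if a.std() == 0 or b.std() == 0:
                return 0.0
            return abs(np.corrcoef(a, b)[0, 1])
        assert factor_overlap(w1) <= factor_overlap(w0) + 0.05

    def test_non_finite_input_error(self):
        x = np.ones((5, 20))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            convnmf(x, k=1, l=2)

    def test_negative_input_clipped_with_warning(self):
        x = np.ones((5, 20))
        x[0, 0] = -1.0
        with pytest.warns(UserWarning, match="clipped"):
            convnmf(x, k=1, l=2, n_iter=2)


def test_planted_three_motif_recovery(small_scene):
    """convNMF recovers all three planted motifs (image correlation >= 0.8)."""
    mask = small_scene.true_mask > 0
    sim = MotifSimSpec(n_motifs=3, motif_frames=8, movie_frames=300,
                       occurrences=8, amplitude=1.0, noise_sigma=0.2, seed=11)
    movie, planted, _ = simulate_activity(small_scene, sim)
    mset = factorize_movie(movie, mask, k=3, l=8, n_iter=80, seed=0)
    planted_images = [motif_image(m, mask) for m in planted]
    recovered = [motif_image(m, mask) for m in mset.motifs]
    used = set()
    for r in recovered:
        rs = [
            np.corrcoef(r[mask], p[mask])[0, 1] if j not in used else -np.inf
            for j, p in enumerate(planted_images)
        ]
        j = int(np.argmax(rs))
        assert rs[j] >= 0.8
        used.add(j)


class TestMotifImage:
    def test_single_frame_is_that_frame_normalized(self, rng):
        frame = rng.uniform(1, 5, (8, 8))
        img = motif_image(frame[None])
        expected = (frame - frame.min()) / (frame.max() - frame.min())
        assert np.allclose(img, expected)

    def test_all_zero_guard(self):
        assert motif_image(np.zeros((3, 6, 6))).sum() == 0.0

    def test_pointwise_max_of_frames(self):
        m = np.zeros((2, 4, 4))
        m[0, 1, 1] = 2.0
        m[1, 3, 2] = 2.0
        img = motif_image(m)
        assert img[1, 1] == 1.0 and img[3, 2] == 1.0

    def test_mask_zeroes_outside(self):
        m = np.ones((2, 4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        img = motif_image(m, mask)
        assert img[0, 0] == 1.0 and img.sum() == 1.0


class TestEpochSplit:
    def test_exact_division(self, rng):
        dff = rng.normal(size=(120, 2, 2))
        segs = epoch_split(dff, epoch_minutes=1.0, frame_rate=1.0)
        assert len(segs) == 2
        assert np.array_equal(np.concatenate(segs), dff)

    def test_remainder_dropped_with_warning(self, rng):
        dff = rng.normal(size=(70, 2, 2))
        with pytest.warns(UserWarning, match="trailing"):
            segs = epoch_split(dff, epoch_minutes=1.0, frame_rate=1.0)
        assert len(segs) == 1
        assert np.array_equal(segs[0], dff[:60])

    def test_too_short_recording(self, rng):
        with pytest.raises(ValueError):
            epoch_split(rng.normal(size=(10, 2, 2)), 1.0, 1.0)


class TestTemplatesAndMatching:
    def test_identical_cluster_gives_that_motif(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        templates, mbfm = make_templates([img, img, img], [0, 0, 0], n_templates=1)
        assert np.allclose(templates[0], img)
        assert np.allclose(mbfm, img)

    def test_cluster_ranking_by_size(self, rng):
        imgs = [rng.uniform(0, 1, (6, 6)) for _ in range(17)]
        labels = [0] * 10 + [1] * 5 + [2] * 2
        with pytest.warns(UserWarning):
            templates, _ = make_templates(imgs, labels, n_templates=6)
        assert len(templates) == 3
        t2, _ = make_templates(imgs, labels, n_templates=2)
        assert len(t2) == 2  # clusters 0 and 1 kept

    def test_template_mbfm_dominates_templates(self, rng):
        imgs = [rng.uniform(0, 1, (6, 6)) for _ in range(6)]
        templates, mbfm = make_templates(imgs, [0, 0, 1, 1, 2, 2], n_templates=3)
        for t in templates:
            assert (mbfm >= t - 1e-12).all()

    def test_match_identical_motif(self, rng):
        templates = [rng.uniform(0, 1, (8, 8)) for _ in range(3)]
        res = match_motifs([templates[2].copy()], templates, r_threshold=0.5)
        assert res.assignment[0] == 2
        assert res.r_matrix[0, 2] == pytest.approx(1.0)

    def test_uncorrelated_motif_unassigned(self, rng):
        templates = [np.tile(np.linspace(0, 1, 16), (16, 1))]
        noise = rng.uniform(0, 1, (16, 16))
        res = match_motifs([noise], templates, r_threshold=0.5)
        assert res.assignment[0] == -1

    def test_assignment_matches_brute_force(self, rng):
        templates = [rng.uniform(0, 1, (10, 10)) for _ in range(4)]
        news = [rng.uniform(0, 1, (10, 10)) for _ in range(12)]
        res = match_motifs(news, templates, r_threshold=0.1)
        for i, n in enumerate(news):
            rs = [np.corrcoef(n.ravel(), t.ravel())[0, 1] for t in templates]
            j = int(np.argmax(rs))
            expected = j if rs[j] >= 0.1 else -1
            assert res.assignment[i] == expected

    def test_scale_invariance(self, rng):
        templates = [rng.uniform(0, 1, (8, 8)) for _ in range(3)]
        motif = rng.uniform(0, 1, (8, 8))
        base = match_motifs([motif], templates).assignment[0]
        for s in (0.1, 3.0, 250.0):
            assert match_motifs([motif * s], templates).assignment[0] == base

    def test_zero_variance_warning(self):
        templates = [np.tile(np.linspace(0, 1, 8), (8, 1))]
        with pytest.warns(UserWarning, match="zero variance"):
            res = match_motifs([np.full((8, 8), 0.5)], templates)
        assert res.assignment[0] == -1

    def test_mbfm_idempotent_on_single_image(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        assert np.array_equal(mbfm_from_images([img]), img)
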