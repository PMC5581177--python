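import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protaxsound as ps
from protaxsound.audio import AudioClip, stft_spectrogram
from protaxsound.features import (
    block_distances,
    mel_patches,
    mfcc_frames,
    normalized_cross_correlation,
    roi_crop,
    summarize_sample,
    xcorr_features,
)
from protaxsound.segmentation import ROI


def _tone_clip(freq=2000.0, duration=1.0, sr=44100, amp=0.4):
    t = np.arange(int(duration * sr)) / sr
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sr)


class TestMfccFrames:
    def test_every_frame_has_48_parameters(self):
        clip = _tone_clip()
        frames = mfcc_frames(clip, [ROI(t0=0.1, t1=0.6, f0=1000, f1=3000)])
        assert frames.shape[1] == 48
        assert np.isfinite(frames).all()

    def test_stationary_tone_has_near_zero_deltas(self):
        clip = _tone_clip()
        frames = mfcc_frames(clip, [ROI(t0=0.2, t1=0.8, f0=1000, f1=3000)])
        # interior frames only: edge replication leaves small transients
        delta = frames[5:-5, 16:32]
        assert np.abs(delta).max() < 0.1 * np.abs(frames[5:-5, :16]).max()

    def test_frame_count_sums_over_disjoint_rois(self):
        clip = _tone_clip(duration=1.0)
        rois = [ROI(t0=0.1, t1=0.2, f0=500, f1=4000), ROI(t0=0.5, t1=0.6, f0=500, f1=4000)]
        frames = mfcc_frames(clip, rois)
        sr = clip.sample_rate
        win, hop = int(0.02 * sr), int(0.01 * sr)
        per_roi = (int(0.1 * sr) - win) // hop + 1
        assert frames.shape[0] == 2 * per_roi

    def test_all_rois_too_short_fails_with_minimum(self):
        clip = _tone_clip()
        with pytest.raises(ValueError, match="0.020"):
            mfcc_frames(clip, [ROI(t0=0.1, t1=0.105, f0=500, f1=4000)])


class TestSummarize:
    def test_output_length_is_96(self):
        frames = np.random.default_rng(0).standard_normal((7, 48))
        assert summarize_sample(frames).shape == (96,)

    def test_single_frame_has_zero_variances(self):
        s = summarize_sample(np.ones((1, 48)))
        assert np.all(s[48:] == 0.0)

    def test_two_frame_toy_matches_direct_arithmetic(self):
        f = np.zeros((2, 48))
        f[0, 0], f[1, 0] = 1.0, 3.0
        s = summarize_sample(f)
        assert s[0] == pytest.approx(2.0)           # mean
        assert s[48] == pytest.approx(1.0)          # population variance
        assert np.all(s[1:48] == 0) and np.all(s[49:] == 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample(np.empty((0, 48)))


class TestBlockDistances:
    def test_identical_summaries_give_six_zeros(self):
        s = np.random.default_rng(1).standard_normal(96)
        np.testing.assert_array_equal(block_distances(s, s), np.zeros(6))

    def test_single_coordinate_difference_hits_one_block(self):
        a = np.zeros(96)
        b = np.zeros(96)
        b[3] = 3.0  # a mean-MFCC coordinate
        d = block_distances(a, b)
        assert d[0] == pytest.approx(3.0)
        assert np.all(d[1:] == 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            block_distances(np.zeros(96), np.zeros(48))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_triangle_inequality_per_block(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.standard_normal((3, 96))
        dab, dba = block_distances(a, b), block_distances(b, a)
        np.testing.assert_allclose(dab, dba)
        dac, dcb = block_distances(a, c), block_distances(c, b)
        assert np.all(dab <= dac + dcb + 1e-9)


class TestNormalizedCrossCorrelation:
    def test_identical_images_score_one(self):
        rng = np.random.default_rng(0)
        img = np.abs(rng.standard_normal((12, 17)))
        assert normalized_cross_correlation(img, img) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.standard_normal((8, 9)))
        b = np.abs(rng.standard_normal((6, 7)))
        s1 = normalized_cross_correlation(a, b)
        s2 = normalized_cross_correlation(a * 7.3, b)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.standard_normal((5, 11)))
        b = np.abs(rng.standard_normal((9, 4)))
        assert normalized_cross_correlation(a, b) == pytest.approx(
            normalized_cross_correlation(b, a), abs=1e-12
        )

    def test_two_by_two_toy_matches_exhaustive_lag_enumeration(self):
        a = np.array([[1.0, 0.0], [0.0, 2.0]])
        b = np.array([[0.0, 3.0], [1.0, 0.0]])
        # brute force: place b at every 2-D lag over zero-padded a
        best = 0.0
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                s = 0.0
                for i in range(2):
                    for j in range(2):
                        ii, jj = i + dy, j + dx
                        if 0 <= ii < 2 and 0 <= jj < 2:
                            s += a[i, j] * b[ii, jj]
                best = max(best, s / (na * nb))
        assert normalized_cross_correlation(a, b) == pytest.approx(best, abs=1e-12)

    def test_disjoint_supports_at_admissible_lags_score_zero(self):
        # with full overlap required, supports in opposite corners never meet
        a = np.zeros((2, 2)); a[0, 0] = 1.0
        b = np.zeros((2, 2)); b[1, 1] = 1.0
        s = normalized_cross_correlation(a, b, mode="overlap", min_overlap=1.0)
        assert s == 0.0

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_cross_correlation(np.ones((2, 2)), np.zeros((2, 2)))

    def test_negative_images_rejected(self):
        with pytest.raises(ValueError):
            normalized_cross_correlation(-np.ones((2, 2)), np.ones((2, 2)))


class TestXCorrFeatures:
    def test_exact_template_copy_scores_one(self):
        rng = np.random.default_rng(3)
        bank = [np.abs(rng.standard_normal((6, 8))) for _ in range(4)]
        out = xcorr_features([bank[2].copy()], bank)
        assert out.shape == (4,)
        assert out[2] == pytest.approx(1.0, abs=1e-9)
        assert np.all((out >= 0) & (out <= 1))

    def test_empty_bank_or_query_rejected(self):
        img = np.ones((3, 3))
        with pytest.raises(ValueError):
            xcorr_features([img], [])
        with pytest.raises(ValueError):
            xcorr_features([], [img])

    def test_own_species_templates_score_higher_on_fixtures(self, library):
        crops = {}
        for spec in library[:3]:
            per = []
            for seed in (0, 1, 2):
                clip, rois = ps.synthesize_clip(spec, 1.5, 0.0, seed=seed)
                sg = stft_spectrogram(clip, 1024 / clip.sample_rate, 256 / clip.sample_rate)
                per.append(roi_crop(sg, rois[0]))
            crops[spec.species_id] = per
        bank = [crops[sp][0] for sp in sorted(crops)]
        for i, sp in enumerate(sorted(crops)):
            scores = xcorr_features(crops[sp][1:], bank)
            own = scores[i]
            other = np.delete(scores, i).mean()
            assert own > other


class TestMelPatches:
    def test_patch_shape_and_padding(self):
        clip = _tone_clip(duration=0.8)
        mel = ps.mel_log_power(clip, n_mels=32)
        patches = mel_patches(mel, [ROI(t0=0.1, t1=0.3, f0=500, f1=4000)], 1.0, 2)
        assert patches.shape == (1, 32, 100)

    def test_no_roi_rejected(self):
        clip = _tone_clip()
        mel = ps.mel_log_power(clip, n_mels=32)
        with pytest.raises(ValueError):
            mel_patches(mel, [], 1.0, 2)
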