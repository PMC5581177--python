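"""Acoustic feature families consumed by the classifiers.

Three families, all computed per audio sample (= one file's set of ROIs):

* MFCC summaries — 16 cepstral coefficients per 0.02 s frame inside the
  ROIs, with Delta and Delta-Delta temporal derivatives (48 values per
  frame), summarized by mean and population variance over all frames
  (96 values per sample).  Pairs of samples are compared by six blockwise
  Euclidean distances ({mean, variance} x {MFCC, Delta, Delta-Delta}).
* Normalized cross-correlation — peak sliding correlation between a query
  ROI crop and each reference template crop, in [0, 1], feeding the random
  forest.
* Mel patches — fixed-duration mel log-power crops around ROIs, feeding the
  convolutional network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal import fftconvolve, get_window

from .audio import AudioClip, MelSpectrogram, Spectrogram, mel_filterbank
from .segmentation import ROI

__all__ = [
    "MfccConfig",
    "mfcc_frames",
    "summarize_sample",
    "block_distances",
    "BLOCK_NAMES",
    "normalized_cross_correlation",
    "xcorr_features",
    "roi_crop",
    "mel_patches",
]

BLOCK_NAMES = (
    "mean_mfcc", "mean_delta", "mean_delta2",
    "var_mfcc", "var_delta", "var_delta2",
)


@dataclass(frozen=True)
class MfccConfig:
    """MFCC recipe.  The frame length (0.02 s) and coefficient count (16)
    are the method's fixed choices; the rest is declared here."""

    n_mfcc: int = 16
    frame_len: float = 0.020
    hop: float = 0.010
    n_filters: int = 26
    fmin: float = 0.0
    include_c0: bool = False
    lifter: int = 0                 # sinusoidal liftering; 0 disables
    delta_width: int = 2


def _frame_indices(n: int, win: int, hop: int) -> int:
    return 0 if n < win else (n - win) // hop + 1


def _delta(x: np.ndarray, width: int) -> np.ndarray:
    """Regression-slope temporal derivative over +-width frames, edge frames
    replicated.  x is (n_frames, n_coef)."""
    n = x.shape[0]
    pad = np.pad(x, ((width, width), (0, 0)), mode="edge")
    num = np.zeros_like(x)
    for k in range(1, width + 1):
        num += k * (pad[width + k : width + k + n] - pad[width - k : width - k + n])
    return num / (2 * sum(k * k for k in range(1, width + 1)))


def mfcc_frames(
    clip: AudioClip, rois: list[ROI], config: MfccConfig | None = None
) -> np.ndarray:
    """Per-frame MFCC + Delta + Delta-Delta matrix over the ROI spans.

    Frames (0.02 s, hop 0.01 s) are taken only from within the ROIs' time
    spans; derivatives are computed within each ROI with edge replication.
    Returns an (n_frames, 48) array (3 x n_mfcc columns in block order).
    """
    cfg = config or MfccConfig()
    sr = clip.sample_rate
    win = int(round(cfg.frame_len * sr))
    hop = int(round(cfg.hop * sr))
    w = get_window("hann", win, fftbins=True)
    fb, _ = mel_filterbank(sr, win, cfg.n_filters, fmin=cfg.fmin)
    lo = 0 if cfg.include_c0 else 1
    blocks = []
    for roi in rois:
        i0 = max(int(round(roi.t0 * sr)), 0)
        i1 = min(int(round(roi.t1 * sr)), clip.samples.size)
        seg = clip.samples[i0:i1]
        n_frames = _frame_indices(seg.size, win, hop)
        if n_frames == 0:
            continue
        idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
        power = np.abs(np.fft.rfft(seg[idx] * w, axis=1)) ** 2
        logmel = np.log(np.maximum(power @ fb.T, 1e-12))
        cep = dct(logmel, type=2, norm="ortho", axis=1)[:, lo : lo + cfg.n_mfcc]
        if cfg.lifter > 0:
            idx_c = np.arange(lo, lo + cfg.n_mfcc)
            cep = cep * (1 + (cfg.lifter / 2) * np.sin(np.pi * idx_c / cfg.lifter))
        d1 = _delta(cep, cfg.delta_width)
        d2 = _delta(d1, cfg.delta_width)
        blocks.append(np.hstack([cep, d1, d2]))
    if not blocks:
        min_dur = cfg.frame_len
        raise ValueError(
            f"no ROI spans a full analysis frame; shortest admissible ROI "
            f"duration is {min_dur:.3f}s"
        )
    return np.vstack(blocks)


def summarize_sample(frames: np.ndarray) -> np.ndarray:
    """Mean and population variance of each per-frame parameter.

    Layout: [mean(48) | variance(48)] with each 48 in (MFCC, Delta,
    Delta-Delta) block order — 96 values.  Population variance (divide by n)
    keeps single-frame samples defined (all variances zero).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    return np.concatenate([frames.mean(axis=0), frames.var(axis=0)])


def block_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Six blockwise Euclidean distances between two 96-dim summaries.

    Order follows :data:`BLOCK_NAMES`: mean then variance, each split into
    its MFCC / Delta / Delta-Delta 16-dim block.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size % 6:
        raise ValueError(f"summaries must share a length divisible by 6, got {a.shape}/{b.shape}")
    width = a.size // 6
    diff = (a - b).reshape(6, width)
    return np.sqrt((diff**2).sum(axis=1))


def normalized_cross_correlation(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mode: str = "cosine",
    min_overlap: float = 0.3,
) -> float:
    """Peak sliding 2-D correlation between two non-negative images.

    The images slide across each other over all 2-D lags; the score is the
    maximum normalized inner product, in [0, 1], reaching 1 exactly when the
    images are identical up to a positive scale factor.

    ``mode="cosine"`` (default) normalizes by the full norms ||A||·||B||,
    which makes the score symmetric and scale-invariant in either argument.
    ``mode="overlap"`` normalizes by ||A||·||B_overlap|| restricted to lags
    whose overlap area is at least ``min_overlap`` of the smaller image.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("images must be non-negative magnitudes")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero image: normalization undefined")
    cross = fftconvolve(a, b[::-1, ::-1], mode="full")
    if mode == "cosine":
        score = cross.max() / (na * nb)
    elif mode == "overlap":
        ones_a = np.ones_like(a)
        b_sq = fftconvolve(b[::-1, ::-1] ** 2, ones_a, mode="full")
        overlap = fftconvolve(ones_a, np.ones_like(b), mode="full")
        min_area = min_overlap * min(a.size, b.size)
        valid = overlap >= max(min_area, 1.0)
        denom = na * np.sqrt(np.maximum(b_sq, 1e-300))
        with np.errstate(invalid="ignore"):
            ratio = np.where(valid, cross / denom, -np.inf)
        score = ratio.max()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.clip(score, 0.0, 1.0))


def roi_crop(spec: Spectrogram, roi: ROI) -> np.ndarray:
    """Spectrogram submatrix covering an ROI (at least one pixel per axis)."""
    c0 = int(np.floor(roi.t0 / spec.hop))
    c1 = max(int(np.ceil(roi.t1 / spec.hop)), c0 + 1)
    r0 = int(np.floor(roi.f0 / spec.df))
    r1 = max(int(np.ceil(roi.f1 / spec.df)), r0 + 1)
    return spec.values[max(r0, 0) : r1, max(c0, 0) : c1]


def xcorr_features(
    query_crops: list[np.ndarray],
    reference_bank: list[np.ndarray],
    mode: str = "cosine",
) -> np.ndarray:
    """Cross-correlation feature vector of a query against a template bank.

    Entry ``j`` is the maximum over the query's ROI crops of the normalized
    cross-correlation with reference template ``j`` (max preserves the best
    template match when a query holds several vocalization elements).
    """
    if not reference_bank:
        raise ValueError("reference bank is empty")
    if not query_crops:
        raise ValueError("query has no ROI crops")
    out = np.zeros(len(reference_bank))
    for j, ref in enumerate(reference_bank):
        out[j] = max(
            normalized_cross_correlation(q, ref, mode=mode) for q in query_crops
        )
    return out


def mel_patches(
    mel: MelSpectrogram,
    rois: list[ROI],
    patch_duration: float = 1.0,
    max_patches: int = 2,
) -> np.ndarray:
    """Fixed-duration mel crops centered on the highest-energy ROIs.

    The clip's per-band median (a noise-floor estimate under the same
    stationary-background assumption as the segmentation) is subtracted and
    the result clipped at zero before cropping, so patches carry the
    vocalization rather than the noise floor.  Returns
    (n_patches, n_mels, n_frames) with shorter spans zero-padded.
    """
    n_frames = int(round(patch_duration / mel.hop))
    total = mel.values.shape[1]
    denoised = np.clip(mel.values - np.median(mel.values, axis=1, keepdims=True), 0, None)
    energies = []
    for roi in rois:
        j0 = int(np.floor(roi.t0 / mel.hop))
        j1 = max(int(np.ceil(roi.t1 / mel.hop)), j0 + 1)
        e = float(denoised[:, max(j0, 0) : min(j1, total)].sum()) if j0 < total else -np.inf
        energies.append((e, roi))
    energies.sort(key=lambda p: -p[0])
    patches = []
    for _, roi in energies[:max_patches]:
        center = int(round((roi.t0 + roi.t1) / 2 / mel.hop))
        j0 = max(center - n_frames // 2, 0)
        crop = denoised[:, j0 : j0 + n_frames]
        if crop.shape[1] < n_frames:
            crop = np.pad(crop, ((0, 0), (0, n_frames - crop.shape[1])))
        patches.append(crop)
    if not patches:
        raise ValueError("no ROI to crop a mel patch from")
    return np.stack(patches)
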