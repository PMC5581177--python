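"""Audio I/O and time-frequency transforms.

Every downstream stage (segmentation, MFCC, cross-correlation, mel patches)
consumes the containers defined here.  Axis conventions: a spectrogram pixel
``[i, j]`` covers the half-open physical cell
``[freqs[i], freqs[i] + df) x [times[j], times[j] + hop)``, so pixel->physical
round trips are exact to one bin/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = [
    "AudioClip",
    "Spectrogram",
    "MelSpectrogram",
    "load_audio",
    "save_wav",
    "resample",
    "stft_spectrogram",
    "mel_log_power",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
]

LOG_FLOOR_DB = -100.0


@dataclass
class AudioClip:
    """Mono audio samples in [-1, 1] at a known sampling rate."""

    samples: np.ndarray
    sample_rate: int
    path: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip holds mono audio (1-D samples)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Spectrogram:
    """Linear-frequency STFT magnitude with calibrated axes.

    ``values`` is (n_bins, n_frames), ``times`` holds frame start times in
    seconds and ``freqs`` bin start frequencies in Hz.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    window_len: float
    hop: float
    window: str = "hann"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (bins x frames)")
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("axis lengths do not match value matrix shape")
        if np.any(self.values < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def df(self) -> float:
        """Frequency bin width in Hz."""
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else float(self.freqs[0] or 1.0)

    def time_to_frame(self, t: float) -> int:
        return int(np.clip(round(t / self.hop), 0, self.times.size - 1))

    def freq_to_bin(self, f: float) -> int:
        return int(np.clip(round(f / self.df), 0, self.freqs.size - 1))


@dataclass
class MelSpectrogram:
    """Mel-band log-power matrix (bands x frames), 10 ms hop by default."""

    values: np.ndarray
    hop: float
    band_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel log-power values must be finite (log floor applied)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.hop


def load_audio(path: str, target_rate: int | None = None) -> AudioClip:
    """Read a WAV file as a mono clip with samples scaled to [-1, 1].

    Stereo channels are mixed by their mean.  Integer PCM (16/24/32-bit) is
    scaled by its full-scale value; float data is taken as-is.  If
    ``target_rate`` differs from the file rate the clip is resampled with a
    polyphase filter so all clips share one axis calibration.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise ValueError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio file: {path!r}")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        samples = data.astype(np.float64) / (float(np.iinfo(data.dtype).max) + 1.0)
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    clip = AudioClip(samples, int(rate), path=path)
    if target_rate is not None and target_rate != clip.sample_rate:
        clip = resample(clip, target_rate)
    return clip


def save_wav(path: str, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (x * 32767.0).astype(np.int16))


def resample(clip: AudioClip, rate: int) -> AudioClip:
    """Polyphase resampling to ``rate`` Hz."""
    if rate == clip.sample_rate:
        return clip
    g = np.gcd(rate, clip.sample_rate)
    out = resample_poly(clip.samples, rate // g, clip.sample_rate // g)
    return AudioClip(np.clip(out, -1.0, 1.0), rate, path=clip.path)


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """(n_frames, win) view; frame count = floor((n - win) / hop) + 1."""
    if x.size < win:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one window ({win} samples)"
        )
    return sliding_window_view(x, win)[::hop]


def stft_spectrogram(
    clip: AudioClip,
    window_len: float | None = None,
    hop: float | None = None,
    window: str = "hann",
) -> Spectrogram:
    """Magnitude STFT of a clip.

    Defaults follow common bioacoustics practice: a 512-sample Hann window
    with 50% overlap (at 44.1 kHz: ~11.6 ms / ~5.8 ms hop).
    """
    sr = clip.sample_rate
    n_win = 512 if window_len is None else int(round(window_len * sr))
    n_hop = n_win // 2 if hop is None else int(round(hop * sr))
    if not (n_win >= n_hop > 0):
        raise ValueError("require window_len >= hop > 0")
    frames = _frame(clip.samples, n_win, n_hop)
    w = get_window(window, n_win, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * w, axis=1)).T
    times = np.arange(frames.shape[0]) * (n_hop / sr)
    freqs = np.fft.rfftfreq(n_win, 1.0 / sr)
    return Spectrogram(mag, times, freqs, n_win / sr, n_hop / sr, window)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int, n_fft: int, n_mels: int, fmin: float = 0.0, fmax: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank.

    Returns (weights of shape (n_mels, n_fft//2 + 1), band center freqs Hz).
    """
    fmax = sample_rate / 2 if fmax is None else fmax
    pts = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    bins = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        lo, mid, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb, pts[1:-1]


def mel_log_power(
    clip: AudioClip,
    hop: float = 0.010,
    n_mels: int = 32,
    window_len: float = 0.020,
) -> MelSpectrogram:
    """Mel-scaled log-power spectrogram sampled every ``hop`` seconds.

    Power spectra from a Hann-windowed STFT are pooled through a triangular
    mel filterbank and converted to dB with a floor that keeps values finite
    for silent input.
    """
    if n_mels < 8:
        raise ValueError("n_mels must be at least 8")
    sr = clip.sample_rate
    n_win = int(round(window_len * sr))
    n_hop = int(round(hop * sr))
    frames = _frame(clip.samples, n_win, n_hop)
    w = get_window("hann", n_win, fftbins=True)
    power = np.abs(np.fft.rfft(frames * w, axis=1)) ** 2
    fb, centers = mel_filterbank(sr, n_win, n_mels)
    mel_power = power @ fb.T
    log_mel = 10.0 * np.log10(np.maximum(mel_power, 10.0 ** (LOG_FLOOR_DB / 10.0)))
    return MelSpectrogram(log_mel.T, n_hop / sr, centers)
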