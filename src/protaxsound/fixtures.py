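"""Synthetic multi-species vocalization fixtures with ground-truth ROIs.

The generator renders each species as a short motif of linear-frequency-sweep
tone elements with Hann amplitude envelopes, placed in optional white (or
pink) background noise.  This is deliberately not realistic birdsong: it is
the simplest signal family whose spectrogram shape is species-identifiable,
which is what the segmentation, feature and classification stages need to be
exercised end to end without external recordings.

Every rendition is deterministic given its seed, and the returned ROIs bound
the rendered elements exactly (half-open time/frequency intervals), so the
truth table can score the automated segmentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip, save_wav
from .segmentation import ROI

__all__ = [
    "ToneElement",
    "SpeciesSpec",
    "FixtureDataset",
    "DEFAULT_RANGES",
    "generate_species_library",
    "synthesize_clip",
    "generate_dataset",
]


@dataclass(frozen=True)
class ToneElement:
    """One motif element: a linear sweep at ``center_freq`` (Hz) of
    ``duration`` s, sweeping ``sweep_rate`` Hz/s, with ``bandwidth`` Hz of
    sideband spread, followed by ``gap`` s of silence."""

    center_freq: float
    bandwidth: float
    duration: float
    sweep_rate: float
    gap: float


@dataclass(frozen=True)
class SpeciesSpec:
    """A species' motif plus rendition-to-rendition variability."""

    species_id: str
    motif: tuple[ToneElement, ...]
    jitter: float = 0.05
    amplitude: float = 0.5

    def validate(self, sample_rate: int) -> None:
        nyq = sample_rate / 2
        for el in self.motif:
            f_lo = el.center_freq - abs(el.sweep_rate) * el.duration / 2 - el.bandwidth / 2
            f_hi = el.center_freq + abs(el.sweep_rate) * el.duration / 2 + el.bandwidth / 2
            if not (0 < f_lo and f_hi < nyq):
                raise ValueError(
                    f"{self.species_id}: element band [{f_lo:.0f}, {f_hi:.0f}] Hz "
                    f"outside (0, {nyq:.0f})"
                )
            if el.duration <= 0:
                raise ValueError("element durations must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    def motif_duration(self) -> float:
        return sum(el.duration + el.gap for el in self.motif)


# Parameter ranges the library sampler draws from.  Chosen to sit inside the
# passband of a 44.1 kHz recording and to give motifs that overlap enough in
# frequency to make classification non-trivial.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "center_freq": (1500.0, 7500.0),
    "bandwidth": (100.0, 400.0),
    "duration": (0.08, 0.25),
    "sweep_rate": (-4000.0, 4000.0),
    "gap": (0.05, 0.15),
}

#: Minimum pairwise distance between motifs in normalized parameter space.
SEPARATION_FLOOR = 0.6

_N_ELEMENTS = 3
_SCALES = {  # normalization per parameter for the separation metric
    "center_freq": 1000.0,
    "bandwidth": 300.0,
    "duration": 0.1,
    "sweep_rate": 2000.0,
    "gap": 0.1,
}


def _motif_vector(motif: tuple[ToneElement, ...]) -> np.ndarray:
    vals = []
    for el in motif:
        for name in ("center_freq", "bandwidth", "duration", "sweep_rate", "gap"):
            vals.append(getattr(el, name) / _SCALES[name])
    return np.asarray(vals)


def generate_species_library(
    n_species: int,
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    jitter: float = 0.05,
    separation: float = SEPARATION_FLOOR,
    sample_rate: int = 44100,
    max_attempts: int = 200,
) -> list[SpeciesSpec]:
    """Draw ``n_species`` pairwise-distinct motif specs.

    Distinctness is enforced as a floor on the Euclidean distance between
    normalized motif parameter vectors; if the requested number of species
    cannot be separated within the ranges the call fails explicitly rather
    than silently returning near-duplicates.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    specs: list[SpeciesSpec] = []
    vectors: list[np.ndarray] = []
    for i in range(n_species):
        for _ in range(max_attempts):
            motif = tuple(
                ToneElement(
                    center_freq=rng.uniform(*ranges["center_freq"]),
                    bandwidth=rng.uniform(*ranges["bandwidth"]),
                    duration=rng.uniform(*ranges["duration"]),
                    sweep_rate=rng.uniform(*ranges["sweep_rate"]),
                    gap=rng.uniform(*ranges["gap"]),
                )
                for _ in range(_N_ELEMENTS)
            )
            vec = _motif_vector(motif)
            if all(np.linalg.norm(vec - v) >= separation for v in vectors):
                spec = SpeciesSpec(f"sp{i + 1:03d}", motif, jitter=jitter)
                spec.validate(sample_rate)
                specs.append(spec)
                vectors.append(vec)
                break
        else:
            raise ValueError(
                f"could not place species {i + 1}/{n_species} with pairwise "
                f"separation >= {separation} inside the given ranges"
            )
    return specs


def _render_element(el: ToneElement, sr: int, amplitude: float) -> np.ndarray:
    n = int(round(el.duration * sr))
    t = np.arange(n) / sr
    f_start = el.center_freq - el.sweep_rate * el.duration / 2
    phase = 2 * np.pi * (f_start * t + 0.5 * el.sweep_rate * t**2)
    env = np.hanning(n)
    tone = np.sin(phase)
    # sidebands realize the nominal bandwidth without changing the sweep shape
    if el.bandwidth > 0:
        off = 2 * np.pi * (el.bandwidth / 2) * t
        tone = tone + 0.4 * np.sin(phase + off) + 0.4 * np.sin(phase - off)
        tone /= 1.8
    return amplitude * env * tone


def _element_roi(el: ToneElement, t_start: float, nyquist: float) -> tuple[float, float, float, float]:
    half_sweep = abs(el.sweep_rate) * el.duration / 2
    f0 = max(0.0, el.center_freq - half_sweep - el.bandwidth / 2)
    f1 = min(nyquist, el.center_freq + half_sweep + el.bandwidth / 2)
    return t_start, t_start + el.duration, f0, f1


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    out = np.fft.irfft(spec / np.sqrt(f), n)
    return out / out.std()


def synthesize_clip(
    spec: SpeciesSpec,
    duration: float = 1.5,
    noise_level: float = 0.0,
    seed: int = 0,
    sample_rate: int = 44100,
    noise_color: str = "white",
) -> tuple[AudioClip, list[ROI]]:
    """Render one motif rendition into a clip and return it with truth ROIs.

    Element parameters are jittered multiplicatively (relative sd =
    ``spec.jitter``), the motif start time is drawn uniformly within the
    margin the duration allows, and noise is added at linear amplitude
    ``noise_level``.
    """
    spec.validate(sample_rate)
    rng = np.random.default_rng(seed)
    motif_dur = spec.motif_duration() * (1 + 4 * spec.jitter)
    if duration < motif_dur:
        raise ValueError(
            f"duration {duration:.3f}s too short for motif of {spec.species_id}; "
            f"need at least {motif_dur:.3f}s"
        )
    n = int(round(duration * sample_rate))
    x = np.zeros(n)
    nyq = sample_rate / 2

    def jit(v: float, lo: float | None = None) -> float:
        out = v * (1 + spec.jitter * rng.standard_normal())
        return max(out, lo) if lo is not None else out

    t = rng.uniform(0.0, max(duration - motif_dur, 0.0))
    rois: list[ROI] = []
    for el in spec.motif:
        el_j = ToneElement(
            center_freq=jit(el.center_freq, 50.0),
            bandwidth=jit(el.bandwidth, 10.0),
            duration=jit(el.duration, 0.02),
            sweep_rate=jit(el.sweep_rate) if el.sweep_rate else 0.0,
            gap=jit(el.gap, 0.0),
        )
        tone = _render_element(el_j, sample_rate, spec.amplitude)
        i0 = int(round(t * sample_rate))
        i1 = min(i0 + tone.size, n)
        x[i0:i1] += tone[: i1 - i0]
        t0, t1, f0, f1 = _element_roi(el_j, t, nyq)
        rois.append(ROI(t0=t0, t1=min(t1, duration), f0=f0, f1=f1, label=spec.species_id))
        t += el_j.duration + el_j.gap
    if noise_level > 0:
        noise = _pink_noise(n, rng) if noise_color == "pink" else rng.standard_normal(n)
        x += noise_level * noise
    clip = AudioClip(np.clip(x, -1.0, 1.0), sample_rate)
    return clip, rois


@dataclass
class FixtureDataset:
    """An on-disk or in-memory labeled fixture collection."""

    clips: list[AudioClip]
    truth: pd.DataFrame  # file, species_id, author, day, t0, t1, f0, f1 (one row per ROI)
    metadata: pd.DataFrame  # file, species_id, author, day (one row per clip)
    seed: int
    noise_level: float
    out_dir: str | None = None
    species: list[SpeciesSpec] = field(default_factory=list)


def generate_dataset(
    n_species: int,
    clips_per_species: int,
    noise_level: float = 0.05,
    seed: int = 0,
    out_dir: str | None = None,
    duration: float = 1.5,
    sample_rate: int = 44100,
    species: list[SpeciesSpec] | None = None,
    session_size: int = 2,
) -> FixtureDataset:
    """Generate ``n_species x clips_per_species`` labeled clips.

    Clips are grouped into synthetic recording "sessions" of up to
    ``session_size`` consecutive clips sharing an author and day, so the
    grouped cross-validation rule (same author + day never split across
    folds) is exercised.  With ``out_dir`` set, WAV files and a
    ``truth.csv`` table are written; otherwise everything stays in memory.
    """
    if clips_per_species < 1:
        raise ValueError("clips_per_species must be >= 1")
    ss = np.random.SeedSequence(seed)
    lib_seed, clip_seed0 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if species is None:
        species = generate_species_library(n_species, lib_seed, sample_rate=sample_rate)
    authors = [f"author{j}" for j in range(1, 4)]
    rng = np.random.default_rng(clip_seed0)

    clips: list[AudioClip] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []
    k = 0
    for si, spec in enumerate(species[:n_species]):
        for c in range(clips_per_species):
            session = c // session_size
            author = authors[(si + session) % len(authors)]
            day = f"2017-01-{(session % 28) + 1:02d}"
            clip, rois = synthesize_clip(
                spec, duration, noise_level, seed=int(rng.integers(2**31)),
                sample_rate=sample_rate,
            )
            fname = f"{spec.species_id}_{c:03d}.wav"
            clips.append(clip)
            meta_rows.append(
                {"file": fname, "species_id": spec.species_id, "author": author, "day": day}
            )
            for roi in rois:
                truth_rows.append(
                    {
                        "file": fname, "species_id": spec.species_id,
                        "author": author, "day": day,
                        "t0": roi.t0, "t1": roi.t1, "f0": roi.f0, "f1": roi.f1,
                    }
                )
            k += 1
    truth = pd.DataFrame(truth_rows)
    meta = pd.DataFrame(meta_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for clip, row in zip(clips, meta_rows):
            save_wav(str(out / row["file"]), clip)
        truth.to_csv(out / "truth.csv", index=False, quoting=csv.QUOTE_MINIMAL)
        meta.to_csv(out / "metadata.csv", index=False)
    return FixtureDataset(
        clips=clips, truth=truth, metadata=meta, seed=seed,
        noise_level=noise_level, out_dir=out_dir, species=list(species[:n_species]),
    )
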