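"""End-to-end orchestration: reference building, training, scanning, benchmarking.

The flow mirrors field practice: reference audio is segmented into ROIs,
three feature families are extracted per sample, two base classifiers are
trained, leave-one-out training events parameterize the calibration model,
and field audio is scanned file by file into query samples that receive
calibrated membership probabilities over species plus "unknown".

Base-classifier probabilities used inside training events are produced
out-of-fold (grouped inner folds within the training data), so no reference
sample is scored by a provider that saw it — the leave-one-out rule at
provider level, at fold granularity.  Cross-correlation features of
a reference sample against templates cut from the sample itself are imputed
from the same species' other templates for the same reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import AudioClip, load_audio, mel_log_power, stft_spectrogram
from .classifiers import MelPatchCNN, XCorrRandomForest
from .evaluation import (
    make_cv_folds,
    reliability_curve,
    reliability_from_results,
    species_calibration_pvalues,
    top1_accuracy,
)
from .features import mel_patches, roi_crop, xcorr_features
from .features import mfcc_frames, summarize_sample
from .fixtures import generate_dataset, generate_species_library, synthesize_clip
from .protax import (
    UNKNOWN,
    ClassificationResult,
    ProtaxCalibrator,
    ReferenceDatabase,
    build_predictors,
    generate_training_events,
)
from .segmentation import ROI, denoise_median, extract_rois

logger = logging.getLogger("protaxsound")

__all__ = [
    "PipelineConfig",
    "PreparedSample",
    "prepare_clip",
    "TrainedBundle",
    "train_bundle",
    "classify_sample",
    "scan_field_audio",
    "run_experiment",
    "ExperimentReport",
    "VARIANTS",
]

#: predictor subsets for the model-comparison experiment
VARIANTS: dict[str, list[bool]] = {
    "mfcc": [True] * 6 + [False, False],
    "rf": [False] * 6 + [True, False],
    "cn": [False] * 6 + [False, True],
    "combined": [True] * 8,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every front-end and model default in one place."""

    sample_rate: int = 44100
    stft_window: int = 1024         # samples (Hann window)
    stft_hop: int = 256
    median_factor: float = 3.0
    min_area: int = 16              # pixels
    merge_gap: float = 0.05         # s
    n_mels: int = 32
    patch_duration: float = 1.0     # s
    max_patches: int = 1
    max_query_crops: int = 2
    templates_per_species: int = 2
    rf_trees: int = 300
    cnn_epochs: int = 40
    cnn_filters: tuple = (12, 24)
    inner_folds: int = 3            # provider OOF folds inside training data
    prior_sd: float = 10.0
    eps: float = 0.001
    query_mode: str = "whole_file"  # or "gap_split"
    gap_threshold: float = 0.3      # s of silence splitting query samples


@dataclass
class PreparedSample:
    """Everything the classifiers need for one query/reference sample."""

    sample_id: str
    summary: np.ndarray             # 96-dim MFCC summary
    crops: list[np.ndarray]         # spectrogram ROI crops (for NCC)
    patches: np.ndarray             # (k, n_mels, n_frames) mel patches
    rois: list[ROI]
    species: str | None = None


def prepare_clip(
    clip: AudioClip, cfg: PipelineConfig, sample_id: str, species: str | None = None
) -> PreparedSample | None:
    """Segment a clip and extract all feature families.

    Returns None when segmentation finds no ROI (a "no detection", not an
    error).
    """
    sr = clip.sample_rate
    spec = stft_spectrogram(clip, cfg.stft_window / sr, cfg.stft_hop / sr)
    mask = denoise_median(spec, cfg.median_factor)
    rois = extract_rois(spec, mask, cfg.min_area, cfg.merge_gap, file=sample_id)
    if not rois:
        return None
    try:
        frames = mfcc_frames(clip, rois)
    except ValueError:
        return None  # every ROI shorter than one analysis frame
    summary = summarize_sample(frames)
    crops = [roi_crop(spec, r) for r in rois]
    order = np.argsort([-c.sum() for c in crops], kind="stable")
    crops = [crops[i] for i in order[: cfg.max_query_crops]]
    mel = mel_log_power(clip, n_mels=cfg.n_mels)
    patches = mel_patches(mel, rois, cfg.patch_duration, cfg.max_patches)
    return PreparedSample(sample_id, summary, crops, patches, rois, species)


@dataclass
class TrainedBundle:
    """A trained model bundle: everything needed to classify new queries."""

    config: PipelineConfig
    refdb: ReferenceDatabase
    templates: list[np.ndarray]         # template crops, fixed order
    template_sources: list[str]         # sample_id each template came from
    rf: XCorrRandomForest
    cnn: MelPatchCNN
    calibrator: ProtaxCalibrator
    sentinel: np.ndarray                # per-block missing-reference distance
    seed: int
    version: int = 1
    events: list = field(default_factory=list)  # leave-one-out training events
    # fold-trained provider models; one of them feeds the calibrated
    # predictors so prediction-time probabilities match the out-of-fold
    # distribution the calibrator was trained on
    inner_rfs: list = field(default_factory=list)
    inner_cnns: list = field(default_factory=list)

    def provider_probs(self, sample: PreparedSample) -> tuple[np.ndarray, np.ndarray]:
        """(rf, cn) class-probability vectors for the calibrated predictors.

        A single fold-trained provider is used, so a new query is scored by a
        model of the same strength (trained on the same fraction of data,
        query unseen) as the out-of-fold probabilities inside the training
        events; averaging several providers would smooth the probabilities
        into a distribution the calibrator never saw.
        """
        species = self.refdb.species
        xx = _sample_xcorr(sample, self.templates)[None, :]
        rf_p = _aligned_rf_probs(self.inner_rfs[0], xx, species)[0]
        cn_p = _sample_level_cnn_probs(self.inner_cnns[0], [sample], species)[0]
        return rf_p, cn_p


def _sample_xcorr(sample: PreparedSample, templates: list[np.ndarray]) -> np.ndarray:
    return xcorr_features(sample.crops, templates)


def _impute_own_templates(
    X: np.ndarray, samples: list[PreparedSample], template_sources: list[str],
    template_species: list[str],
) -> np.ndarray:
    """Replace scores against a sample's own templates by the mean score
    against the same species' other templates (0.5 if none)."""
    X = X.copy()
    for i, s in enumerate(samples):
        own = [j for j, src in enumerate(template_sources) if src == s.sample_id]
        for j in own:
            peers = [
                k for k, sp in enumerate(template_species)
                if sp == template_species[j] and template_sources[k] != s.sample_id
            ]
            X[i, j] = X[i, peers].mean() if peers else 0.5
    return X


def _sample_level_cnn_probs(
    cnn: MelPatchCNN, samples: list[PreparedSample], species: list[str]
) -> np.ndarray:
    out = np.zeros((len(samples), len(species)))
    col = {sp: i for i, sp in enumerate(cnn.classes_)}
    for i, s in enumerate(samples):
        p = cnn.predict_proba(s.patches)
        for sp_i, sp in enumerate(species):
            if sp in col:
                out[i, sp_i] = p[col[sp]]
    rowsum = out.sum(axis=1, keepdims=True)
    return np.divide(out, rowsum, out=np.full_like(out, 1.0 / len(species)),
                     where=rowsum > 0)


def _aligned_rf_probs(rf: XCorrRandomForest, X: np.ndarray, species: list[str]) -> np.ndarray:
    raw = rf.predict_proba(X)
    out = np.zeros((X.shape[0], len(species)))
    col = {sp: i for i, sp in enumerate(rf.classes_)}
    for sp_i, sp in enumerate(species):
        if sp in col:
            out[:, sp_i] = raw[:, col[sp]]
    return out


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def train_bundle(
    samples: list[PreparedSample],
    metadata: pd.DataFrame,
    cfg: PipelineConfig,
    seed: int = 0,
) -> TrainedBundle:
    """Train base classifiers and the calibrator from reference samples.

    ``metadata`` needs one row per sample (species_id, author, day) in the
    same order.  Grouped inner-fold CV supplies the out-of-fold provider
    probabilities behind the leave-one-out training events.
    """
    species = sorted({s.species for s in samples if s.species})
    refdb = ReferenceDatabase(
        sample_ids=[s.sample_id for s in samples],
        species_of=np.asarray([s.species for s in samples]),
        summaries=np.stack([s.summary for s in samples]),
        species=species,
        metadata=metadata,
    )
    templates, template_sources, template_species = [], [], []
    for sp in species:
        idx = [i for i, s in enumerate(samples) if s.species == sp]
        for i in idx[: cfg.templates_per_species]:
            templates.append(samples[i].crops[0])
            template_sources.append(samples[i].sample_id)
            template_species.append(sp)
    Xx_raw = np.stack([_sample_xcorr(s, templates) for s in samples])
    Xx = _impute_own_templates(Xx_raw, samples, template_sources, template_species)
    y = np.asarray([s.species for s in samples])

    seeds = _seed_stream(seed, 6)
    inner = make_cv_folds(metadata, k=cfg.inner_folds, seed=seeds[0])
    rf_oof = np.zeros((len(samples), len(species)))
    cn_oof = np.zeros((len(samples), len(species)))
    inner_rfs, inner_cnns = [], []
    for f in range(cfg.inner_folds):
        tr, te = np.flatnonzero(inner != f), np.flatnonzero(inner == f)
        rf_f = XCorrRandomForest(n_estimators=cfg.rf_trees, random_state=seeds[1] + f)
        rf_f.fit(Xx[tr], y[tr])
        rf_oof[te] = _aligned_rf_probs(rf_f, Xx[te], species)
        patches_tr = np.concatenate([samples[i].patches for i in tr])
        labels_tr = np.concatenate([[y[i]] * len(samples[i].patches) for i in tr])
        cnn_f = MelPatchCNN(filters=cfg.cnn_filters, epochs=cfg.cnn_epochs,
                            random_state=seeds[2] + f)
        cnn_f.fit(patches_tr, labels_tr)
        cn_oof[te] = _sample_level_cnn_probs(cnn_f, [samples[i] for i in te], species)
        inner_rfs.append(rf_f)
        inner_cnns.append(cnn_f)

    dm = refdb.block_distance_matrices()
    events = generate_training_events(refdb, rf_oof, cn_oof, eps=cfg.eps,
                                      dist_matrices=dm)
    calibrator = ProtaxCalibrator(prior_sd=cfg.prior_sd, eps=cfg.eps,
                                  seed=seeds[3]).fit(events)
    if not calibrator.converged_:
        logger.warning("calibration fit did not converge")

    rf = XCorrRandomForest(n_estimators=cfg.rf_trees, random_state=seeds[4]).fit(Xx, y)
    patches_all = np.concatenate([s.patches for s in samples])
    labels_all = np.concatenate([[s.species] * len(s.patches) for s in samples])
    cnn = MelPatchCNN(filters=cfg.cnn_filters, epochs=cfg.cnn_epochs,
                      random_state=seeds[5]).fit(patches_all, labels_all)
    sentinel = dm.reshape(6, -1).max(axis=1)
    return TrainedBundle(cfg, refdb, templates, template_sources, rf, cnn,
                         calibrator, sentinel, seed, events=events,
                         inner_rfs=inner_rfs, inner_cnns=inner_cnns)


def classify_sample(bundle: TrainedBundle, sample: PreparedSample) -> ClassificationResult:
    """Calibrated membership probabilities for one prepared query sample."""
    rf_p, cn_p = bundle.provider_probs(sample)
    X = build_predictors(sample.summary, bundle.refdb, rf_p, cn_p,
                         eps=bundle.config.eps, sentinel=bundle.sentinel)
    return bundle.calibrator.classify(sample.sample_id, X, bundle.refdb.species)


def _split_queries(sample: PreparedSample, cfg: PipelineConfig) -> list[PreparedSample]:
    """Gap-split mode: break a file's ROIs into query samples at silences
    longer than the configured threshold."""
    if cfg.query_mode != "gap_split" or len(sample.rois) < 2:
        return [sample]
    rois = sorted(sample.rois, key=lambda r: r.t0)
    groups: list[list[ROI]] = [[rois[0]]]
    for r in rois[1:]:
        if r.t0 - max(x.t1 for x in groups[-1]) > cfg.gap_threshold:
            groups.append([r])
        else:
            groups[-1].append(r)
    if len(groups) == 1:
        return [sample]
    out = []
    for gi, grp in enumerate(groups):
        keep = [i for i, r in enumerate(sample.rois) if r in grp]
        out.append(
            replace(
                sample,
                sample_id=f"{sample.sample_id}#q{gi}",
                rois=grp,
                crops=[sample.crops[i] for i in keep if i < len(sample.crops)] or sample.crops,
            )
        )
    return out


def scan_field_audio(
    paths: list[str], bundle: TrainedBundle, cfg: PipelineConfig | None = None
) -> tuple[list[ClassificationResult], list[str]]:
    """Scan field recordings: denoise, segment, classify each query sample.

    Returns (results, no_detection_files).  Silent or ROI-free files are
    reported as "no detection", never as errors.
    """
    cfg = cfg or bundle.config
    results: list[ClassificationResult] = []
    silent: list[str] = []
    for path in paths:
        clip = load_audio(path, target_rate=cfg.sample_rate)
        prepared = prepare_clip(clip, cfg, sample_id=path)
        if prepared is None:
            logger.info("no detection in %s", path)
            silent.append(path)
            continue
        for query in _split_queries(prepared, cfg):
            results.append(classify_sample(bundle, query))
    return results, silent


# ---------------------------------------------------------------------------
# benchmark experiment (model-variant comparison on synthetic fixtures)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Pooled cross-validated comparison of predictor-set variants."""

    summary: pd.DataFrame               # one row per variant
    raw_summary: pd.DataFrame           # raw RF / raw CN reliability
    results: dict                       # variant -> list[ClassificationResult]
    truth: list[str]
    outgroup_results: dict              # variant -> list[ClassificationResult]
    species_pvalues: pd.DataFrame
    unknown_prob_outgroup: float
    unknown_prob_indb: float
    seed: int
    n_queries: int


def run_experiment(
    n_species: int = 10,
    clips_per_species: int = 50,
    noise_level: float = 0.3,
    seed: int = 0,
    variants: tuple = ("mfcc", "rf", "cn", "combined"),
    n_folds: int = 5,
    n_outgroup: int = 2,
    outgroup_clips: int = 10,
    cfg: PipelineConfig | None = None,
    clip_duration: float = 2.0,
    jitter: float = 0.12,
) -> ExperimentReport:
    """Grouped k-fold comparison of calibration variants on synthetic audio.

    Generates a multi-species fixture benchmark, runs the full front end,
    trains per fold, classifies every held-out sample once, and pools
    queries across folds.  Out-of-database ("outgroup") species are scanned
    with every fold's bundle to probe the unknown-species outcome.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; known: {sorted(VARIANTS)}")
    cfg = cfg or PipelineConfig()
    seeds = _seed_stream(seed, 4)
    library = generate_species_library(
        n_species + n_outgroup, seeds[0], sample_rate=cfg.sample_rate, jitter=jitter
    )
    dataset = generate_dataset(
        n_species, clips_per_species, noise_level=noise_level, seed=seeds[1],
        duration=clip_duration, sample_rate=cfg.sample_rate,
        species=library[:n_species],
    )
    prepared: list[PreparedSample] = []
    meta_rows: list[dict] = []
    for clip, row in zip(dataset.clips, dataset.metadata.to_dict("records")):
        s = prepare_clip(clip, cfg, row["file"], species=row["species_id"])
        if s is None:
            logger.info("benchmark clip %s produced no ROI; skipped", row["file"])
            continue
        prepared.append(s)
        meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows)

    out_samples: list[PreparedSample] = []
    rng = np.random.default_rng(seeds[2])
    for spec in library[n_species:]:
        for c in range(outgroup_clips):
            clip, _ = synthesize_clip(spec, clip_duration, noise_level,
                                      seed=int(rng.integers(2**31)),
                                      sample_rate=cfg.sample_rate)
            s = prepare_clip(clip, cfg, f"{spec.species_id}_out{c:03d}",
                             species=spec.species_id)
            if s is not None:
                out_samples.append(s)

    folds = make_cv_folds(metadata, k=n_folds, seed=seeds[3])
    results: dict[str, list[ClassificationResult]] = {v: [] for v in variants}
    out_results: dict[str, list[ClassificationResult]] = {v: [] for v in variants}
    truth: list[str] = []
    raw_rf_top, raw_rf_hit, raw_cn_top, raw_cn_hit = [], [], [], []
    raw_rf_acc_n = 0

    for f in range(n_folds):
        tr = [i for i in range(len(prepared)) if folds[i] != f]
        te = [i for i in range(len(prepared)) if folds[i] == f]
        bundle = train_bundle([prepared[i] for i in tr], metadata.iloc[tr],
                              cfg, seed=seeds[3] * (f + 1) % (2**31))
        # refit per-variant on this fold's stored events; the expensive
        # front end and provider training are not redone
        calibrators = {"combined": bundle.calibrator}
        for v in variants:
            if v == "combined":
                continue
            calibrators[v] = ProtaxCalibrator(
                prior_sd=cfg.prior_sd, eps=cfg.eps, predictor_mask=VARIANTS[v],
            ).fit(bundle.events)

        species = bundle.refdb.species
        for i in te:
            s = prepared[i]
            rf_p, cn_p = bundle.provider_probs(s)
            X = build_predictors(s.summary, bundle.refdb, rf_p, cn_p,
                                 eps=cfg.eps, sentinel=bundle.sentinel)
            truth.append(s.species)
            for v in variants:
                results[v].append(
                    calibrators[v].classify(s.sample_id, X, species)
                )
            # raw baselines: the standalone full-data classifiers, used the
            # way a practitioner would use them directly
            xx = _sample_xcorr(s, bundle.templates)[None, :]
            rf_raw = _aligned_rf_probs(bundle.rf, xx, species)[0]
            cn_raw = _sample_level_cnn_probs(bundle.cnn, [s], species)[0]
            raw_rf_top.append(rf_raw.max())
            raw_rf_hit.append(species[int(rf_raw.argmax())] == s.species)
            raw_cn_top.append(cn_raw.max())
            raw_cn_hit.append(species[int(cn_raw.argmax())] == s.species)
        for s in out_samples:
            rf_p, cn_p = bundle.provider_probs(s)
            X = build_predictors(s.summary, bundle.refdb, rf_p, cn_p,
                                 eps=cfg.eps, sentinel=bundle.sentinel)
            for v in variants:
                out_results[v].append(
                    calibrators[v].classify(s.sample_id, X, species)
                )

    rows = []
    out_truth = [UNKNOWN] * len(out_results[variants[0]])
    for v in variants:
        curve = reliability_from_results(results[v], truth)
        # open-set pool: in-database queries plus the outgroup queries whose
        # correct answer is "unknown" — the population the model is built for
        pool_res = results[v] + out_results[v]
        pool_truth = truth + out_truth
        pool_indb = [True] * len(truth) + [False] * len(out_truth)
        open_curve = reliability_from_results(pool_res, pool_truth, pool_indb)
        rows.append(
            {
                "variant": v,
                "accuracy": top1_accuracy(results[v], truth),
                "reliability_deviation": curve.deviation,
                "mean_top_probability": float(np.mean(curve.p_sorted)),
                "accuracy_open": top1_accuracy(pool_res, pool_truth, pool_indb),
                "reliability_deviation_open": open_curve.deviation,
            }
        )
    summary = pd.DataFrame(rows)
    rf_curve = reliability_curve(np.asarray(raw_rf_top), np.asarray(raw_rf_hit))
    cn_curve = reliability_curve(np.asarray(raw_cn_top), np.asarray(raw_cn_hit))
    raw_summary = pd.DataFrame(
        [
            {"classifier": "raw_rf", "accuracy": float(np.mean(raw_rf_hit)),
             "suggested_accuracy": float(np.mean(raw_rf_top)),
             "reliability_deviation": rf_curve.deviation},
            {"classifier": "raw_cn", "accuracy": float(np.mean(raw_cn_hit)),
             "suggested_accuracy": float(np.mean(raw_cn_top)),
             "reliability_deviation": cn_curve.deviation},
        ]
    )
    pv = species_calibration_pvalues(
        results[variants[-1]], truth, seed=seeds[3]
    ) if variants else []
    pvalues = pd.DataFrame(
        [{"species": c.species, "n": c.n, "k": c.k, "p_value": c.p_value} for c in pv]
    )
    best = variants[-1]
    unk_out = float(np.mean([r.probabilities[-1] for r in out_results[best]])) \
        if out_results[best] else float("nan")
    unk_in = float(np.mean([r.probabilities[-1] for r in results[best]]))
    return ExperimentReport(
        summary=summary, raw_summary=raw_summary, results=results, truth=truth,
        outgroup_results=out_results, species_pvalues=pvalues,
        unknown_prob_outgroup=unk_out, unknown_prob_indb=unk_in,
        seed=seed, n_queries=len(truth),
    )
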