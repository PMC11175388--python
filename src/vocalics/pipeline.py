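"""Stage orchestration: extract, train, evaluate, predict, report, simulate.

Audio is processed one slice at a time (the features of a slice only depend
on that slice), so features stream out as slices complete and no audio needs
to be retained once a slice has been summarized. WAV input is memory-mapped
and each 180 s window is canonicalized (mono, 16 kHz) independently, which
makes chunked and whole-file runs identical by construction.

Every artifact-writing stage also writes a run manifest (config digest, seed,
input digests) so reruns can be checked for identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import acoustics, models, reports
from .config import PipelineConfig
from .conversation import (
    DEFAULT_ROLE_MAP,
    SAMPLE_RATE,
    Role,
    Slice,
    VisitRecord,
    AUDIO_SLACK_S,
    canonicalize_audio,
    clip_turns,
    read_rttm,
    slice_bounds,
)
from .models import ALL_TARGETS, SignalTarget, TrainedSignalModel
from .simulate import Corpus, ScenarioParams, generate_corpus

log = logging.getLogger(__name__)

KEY_COLUMNS = ["visit_id", "slice_index", "provider_id"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: PipelineConfig,
                   inputs: Mapping[str, str | Path]) -> None:
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "inputs": {k: _file_digest(v) for k, v in inputs.items()},
    }
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# extract


def visit_feature_rows(visit: VisitRecord, config: PipelineConfig,
                       slices: Iterable[Slice] | None = None) -> list[dict]:
    """Per-slice 178-feature rows (plus keys and flags) for a loaded visit."""
    from .conversation import segment_slices

    rows = []
    if slices is None:
        slices = segment_slices(visit, config.slice_len_s, config.min_final_slice_s)
    for sl in slices:
        feats = acoustics.slice_feature_vector(
            sl,
            visit,
            min_overlap_s=config.min_overlap_s,
            min_gap_s=config.min_gap_s,
            frame_len_s=config.frame_len_ms / 1000.0,
            hop_s=config.hop_ms / 1000.0,
            rolloff_percentile=config.rolloff_percentile / 100.0,
            n_mfcc=config.n_mfcc,
        )
        row = {"visit_id": visit.visit_id, "slice_index": sl.index,
               "provider_id": visit.provider_id}
        row.update(feats)
        rows.append(row)
    return rows


def run_extract(
    wav_path: str | Path,
    rttm_path: str | Path,
    metadata_row: Mapping[str, object],
    config: PipelineConfig | None = None,
    role_map: Mapping[str, Role | str] | None = None,
) -> pd.DataFrame:
    """Chunked feature extraction: one 180 s window in memory at a time.

    The WAV file is memory-mapped; each slice window is read, canonicalized
    and summarized independently, then its audio is dropped (unless
    ``config.retain_audio``, which only affects retention, never the
    features).
    """
    config = config or PipelineConfig()
    try:
        rate, data = wavfile.read(wav_path, mmap=True)
    except Exception as exc:
        raise StageError(f"extract: cannot read WAV {wav_path}: {exc}") from exc
    try:
        turns = read_rttm(rttm_path, role_map or DEFAULT_ROLE_MAP)
    except FileNotFoundError as exc:
        raise StageError(f"extract: RTTM file missing: {rttm_path}") from exc
    except ValueError as exc:
        raise StageError(f"extract: {exc}") from exc
    duration_s = data.shape[0] / rate
    for t in turns:
        if t.end_s > duration_s + AUDIO_SLACK_S:
            raise StageError(
                f"extract: turn [{t.start_s}, {t.end_s}) extends past audio end "
                f"({duration_s:.3f} s)"
            )
    rows = []
    retained: list[np.ndarray] = []
    bounds = slice_bounds(duration_s, config.slice_len_s, config.min_final_slice_s)
    for index, (s0, s1) in enumerate(bounds):
        window = np.asarray(data[round(s0 * rate) : round(s1 * rate)])
        audio = canonicalize_audio(window, rate, SAMPLE_RATE, name=str(wav_path))
        local = [
            # shift into window-local time so sample indices match the window
            t
            for t in clip_turns(turns, s0, s1)
        ]
        shifted = [type(t)(t.role, t.start_s - s0, t.end_s - s0) for t in local]
        mini = VisitRecord(
            visit_id=str(metadata_row["visit_id"]),
            provider_id=str(metadata_row["provider_id"]),
            patient_meta={},
            sample_rate_hz=SAMPLE_RATE,
            audio=audio,
            turns=shifted,
        )
        sl = Slice(mini.visit_id, index, 0.0, s1 - s0, shifted)
        row = visit_feature_rows(mini, config, slices=[sl])[0]
        row["slice_index"] = index
        rows.append(row)
        if config.retain_audio:
            retained.append(audio)
        del audio
    frame = pd.DataFrame(rows)
    if config.retain_audio:
        frame.attrs["slice_audio"] = retained
    return frame


def corpus_features(corpus: Corpus, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Extract features for every visit of a synthetic corpus, one visit's
    audio in memory at a time."""
    config = config or PipelineConfig()
    rows = []
    for spec in corpus.visits:
        visit = corpus.visit_record(spec)
        rows.extend(visit_feature_rows(visit, config))
        del visit
    return pd.DataFrame(rows)


def check_feature_schema(features: pd.DataFrame) -> None:
    expected = acoustics.feature_columns()
    present = [c for c in features.columns if c not in KEY_COLUMNS
               and not c.endswith("low_speech_flag")]
    missing = sorted(set(expected) - set(present))
    extra = sorted(set(present) - set(expected))
    if missing or extra:
        raise StageError(
            f"feature schema mismatch: missing columns {missing}, unexpected {extra}"
        )


# ---------------------------------------------------------------------------
# train / evaluate / predict


def run_evaluate(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    targets: Iterable[SignalTarget] = ALL_TARGETS,
    config: PipelineConfig | None = None,
) -> dict[SignalTarget, dict[str, models.EvaluationReport]]:
    """LOSO-evaluate every configured family on every requested target."""
    config = config or PipelineConfig()
    check_feature_schema(features)
    out: dict[SignalTarget, dict[str, models.EvaluationReport]] = {}
    for target in targets:
        dataset = models.build_training_set(features, labels, target)
        out[target] = {
            family: models.loso_evaluate(
                dataset, family, target,
                grid=config.model_grids.get(family), seed=config.seed,
            )
            for family in config.families
        }
    return out


def run_train(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    targets: Iterable[SignalTarget] = ALL_TARGETS,
    config: PipelineConfig | None = None,
    evaluations: dict[SignalTarget, dict[str, models.EvaluationReport]] | None = None,
) -> dict[SignalTarget, TrainedSignalModel]:
    """Fit one final model per target on all data, choosing the family by
    mean LOSO macro-F1 when evaluations are supplied (else the first
    configured family)."""
    config = config or PipelineConfig()
    check_feature_schema(features)
    fitted = {}
    for target in targets:
        dataset = models.build_training_set(features, labels, target)
        if evaluations and target in evaluations:
            family = models.select_model(evaluations[target].values())
        else:
            family = config.families[0]
        fitted[target] = models.train_signal_model(
            dataset, family, target,
            grid=config.model_grids.get(family), seed=config.seed,
        )
    return fitted


def run_predict(
    fitted: Mapping[SignalTarget, TrainedSignalModel], features: pd.DataFrame
) -> pd.DataFrame:
    """Predict neutral/high per slice for every fitted target."""
    out = features[[c for c in KEY_COLUMNS if c in features.columns]].copy()
    for target, model in fitted.items():
        out[target.column] = models.predict_slices(model, features)
    return out


# ---------------------------------------------------------------------------
# report


def run_report(
    predictions: pd.DataFrame, metadata: pd.DataFrame
) -> dict[str, reports.VisitReport]:
    """Build one visit report per visit from per-slice class predictions."""
    meta_by_visit = metadata.set_index("visit_id")
    out = {}
    for visit_id, group in predictions.groupby("visit_id", sort=True):
        group = group.sort_values("slice_index")
        meta = meta_by_visit.loc[visit_id]
        slice_classes = {
            target: list(group[target.column])
            for target in ALL_TARGETS
            if target.column in group.columns
        }
        out[str(visit_id)] = reports.visit_report(
            slice_classes,
            visit_id=str(visit_id),
            provider_id=str(meta["provider_id"]),
            patient_meta={
                "gender": str(meta.get("gender", "")),
                "race": str(meta.get("race", "")),
                "age": int(meta.get("age", 0) or 0),
            },
        )
    return out


# ---------------------------------------------------------------------------
# simulate


def run_simulate(params: ScenarioParams, out_dir: str | Path | None = None) -> Corpus:
    corpus = generate_corpus(params)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus
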