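"""Domain model for two-speaker clinic visits.

A visit is a mono waveform plus a table of speaker turns ("who spoke when"),
obtained from an external diarizer and exchanged as NIST RTTM. All time
arithmetic uses half-open intervals ``[start_s, end_s)`` in seconds. Audio is
canonicalized to 16 kHz mono float in [-1, 1]; 16 kHz fixes the framewise
feature dimensions downstream and is the standard rate for speech analysis.

Visits are cut into successive three-minute *slices*, the unit at which
social-signal affect is coded and predicted.
"""

from __future__ import annotations

import logging
import math
import wave
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

SAMPLE_RATE = 16_000
#: same-role diarizer segments closer than this are merged (diarizer jitter)
MERGE_GAP_S = 0.1
#: a turn may end at most this far past the audio end before we call it an error
AUDIO_SLACK_S = 0.5

SLICE_LEN_S = 180.0
MIN_FINAL_SLICE_S = 60.0


class Role(str, Enum):
    PROVIDER = "provider"
    PATIENT = "patient"


ROLES = (Role.PROVIDER, Role.PATIENT)


class RTTMError(ValueError):
    """Malformed or unmappable RTTM content."""


class VisitError(ValueError):
    """Inconsistent visit data (e.g. turns outside the audio)."""


@dataclass(frozen=True)
class Turn:
    """One speaker's contiguous speech interval, half-open ``[start_s, end_s)``."""

    role: Role
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"turn must have positive duration, got [{self.start_s}, {self.end_s})"
            )
        if self.start_s < 0:
            raise ValueError(f"turn start must be non-negative, got {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class VisitRecord:
    """A loaded visit: metadata, canonical audio, and the ordered turn table."""

    visit_id: str
    provider_id: str
    patient_meta: dict
    sample_rate_hz: int
    audio: np.ndarray
    turns: list[Turn]

    @property
    def duration_s(self) -> float:
        return len(self.audio) / self.sample_rate_hz

    def validate(self) -> None:
        dur = self.duration_s
        prev = {r: -math.inf for r in ROLES}
        last_start = -math.inf
        for t in self.turns:
            if t.start_s < last_start:
                raise VisitError("turns are not sorted by start time")
            last_start = t.start_s
            if t.start_s < prev[t.role]:
                raise VisitError(f"overlapping same-role turns for {t.role.value}")
            prev[t.role] = t.end_s
            if t.end_s > dur + AUDIO_SLACK_S:
                raise VisitError(
                    f"turn [{t.start_s}, {t.end_s}) extends past audio end "
                    f"({dur:.3f} s) by more than {AUDIO_SLACK_S} s"
                )


@dataclass
class Slice:
    """A successive window of a visit with turns clipped to its bounds."""

    visit_id: str
    index: int
    start_s: float
    end_s: float
    turns: list[Turn]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# RTTM


def _merge_same_role(turns: Sequence[Turn], gap_s: float = MERGE_GAP_S) -> list[Turn]:
    """Merge same-role segments separated by less than ``gap_s`` seconds."""
    merged: list[Turn] = []
    by_role: dict[Role, list[Turn]] = {r: [] for r in ROLES}
    for t in sorted(turns, key=lambda t: (t.start_s, t.end_s)):
        bucket = by_role[t.role]
        if bucket and t.start_s - bucket[-1].end_s < gap_s:
            bucket[-1] = replace(bucket[-1], end_s=max(bucket[-1].end_s, t.end_s))
        else:
            bucket.append(t)
    for bucket in by_role.values():
        merged.extend(bucket)
    merged.sort(key=lambda t: (t.start_s, t.end_s))
    return merged


def read_rttm(path: str | Path, role_map: Mapping[str, Role | str]) -> list[Turn]:
    """Parse a NIST RTTM file into a sorted, jitter-merged turn list.

    Parameters
    ----------
    path
        RTTM file with ``SPEAKER <file> <chan> <tbeg> <tdur> <NA> <NA> <name>
        <NA> <NA>`` records.
    role_map
        Maps each RTTM speaker name to a :class:`Role`.
    """
    roles = {k: Role(v) for k, v in role_map.items()}
    turns: list[Turn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            fields = line.split()
            if len(fields) < 8 or fields[0] != "SPEAKER":
                raise RTTMError(f"{path}:{lineno}: malformed RTTM line: {line!r}")
            try:
                tbeg, tdur = float(fields[3]), float(fields[4])
            except ValueError as exc:
                raise RTTMError(f"{path}:{lineno}: non-numeric time field") from exc
            if tdur <= 0:
                raise RTTMError(f"{path}:{lineno}: non-positive duration {tdur}")
            name = fields[7]
            if name not in roles:
                raise RTTMError(
                    f"{path}:{lineno}: speaker label {name!r} not in role map "
                    f"{sorted(roles)}"
                )
            turns.append(Turn(roles[name], tbeg, tbeg + tdur))
    return _merge_same_role(turns)


def write_rttm(turns: Iterable[Turn], file_id: str, path: str | Path) -> None:
    """Write turns as RTTM ``SPEAKER`` records, one per turn, ms precision."""
    with open(path, "w") as fh:
        for t in sorted(turns, key=lambda t: (t.start_s, t.end_s)):
            fh.write(
                f"SPEAKER {file_id} 1 {t.start_s:.3f} {t.duration_s:.3f} "
                f"<NA> <NA> {t.role.value} <NA> <NA>\n"
            )


DEFAULT_ROLE_MAP = {r.value: r for r in ROLES}


# ---------------------------------------------------------------------------
# Audio


def read_wav_mono(path: str | Path, target_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Read a PCM or float WAV as mono float32 at ``target_rate``.

    Multi-channel input is mixed down with a logged warning. Integer PCM is
    scaled to [-1, 1].
    """
    rate, data = wavfile.read(path)
    return canonicalize_audio(data, rate, target_rate, name=str(path))


def canonicalize_audio(
    data: np.ndarray, rate: int, target_rate: int = SAMPLE_RATE, name: str = "<array>"
) -> np.ndarray:
    if data.ndim == 2:
        log.warning("%s: mixing %d channels down to mono", name, data.shape[1])
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float32)
    if rate != target_rate:
        g = math.gcd(rate, target_rate)
        data = resample_poly(data, target_rate // g, rate // g).astype(np.float32)
    return data


def write_wav(path: str | Path, audio: np.ndarray, rate: int = SAMPLE_RATE) -> None:
    """Write float audio in [-1, 1] as 16-bit PCM WAV."""
    pcm = np.clip(audio, -1.0, 1.0)
    wavfile.write(path, rate, (pcm * 32767.0).astype(np.int16))


def wav_duration_s(path: str | Path) -> float:
    with wave.open(str(path), "rb") as wf:
        return wf.getnframes() / wf.getframerate()


def load_visit(
    wav_path: str | Path,
    rttm_path: str | Path,
    metadata_row: Mapping[str, object],
    role_map: Mapping[str, Role | str] | None = None,
) -> VisitRecord:
    """Assemble a :class:`VisitRecord` from a WAV file, RTTM file and metadata.

    Audio is resampled to 16 kHz mono; turn times are validated against the
    audio duration (a turn may overrun the audio end by at most 0.5 s, and is
    clipped to it).
    """
    audio = read_wav_mono(wav_path)
    turns = read_rttm(rttm_path, role_map or DEFAULT_ROLE_MAP)
    dur = len(audio) / SAMPLE_RATE
    clipped: list[Turn] = []
    for t in turns:
        if t.end_s > dur + AUDIO_SLACK_S:
            raise VisitError(
                f"turn [{t.start_s}, {t.end_s}) extends {t.end_s - dur:.3f} s past "
                f"audio end ({dur:.3f} s)"
            )
        clipped.append(replace(t, end_s=min(t.end_s, dur)) if t.end_s > dur else t)
    visit = VisitRecord(
        visit_id=str(metadata_row["visit_id"]),
        provider_id=str(metadata_row["provider_id"]),
        patient_meta={
            "gender": str(metadata_row.get("gender", "")),
            "race": str(metadata_row.get("race", "")),
            "age": int(metadata_row.get("age", 0) or 0),
        },
        sample_rate_hz=SAMPLE_RATE,
        audio=audio,
        turns=clipped,
    )
    visit.validate()
    return visit


# ---------------------------------------------------------------------------
# Slicing


def clip_turns(turns: Iterable[Turn], start_s: float, end_s: float) -> list[Turn]:
    """Intersect turns with ``[start_s, end_s)``, dropping empty intersections."""
    out = []
    for t in turns:
        s, e = max(t.start_s, start_s), min(t.end_s, end_s)
        if e > s:
            out.append(Turn(t.role, s, e))
    return out


def slice_bounds(
    duration_s: float,
    slice_len_s: float = SLICE_LEN_S,
    min_final_slice_s: float = MIN_FINAL_SLICE_S,
) -> list[tuple[float, float]]:
    """Successive ``slice_len_s`` windows from 0; a trailing partial window is
    retained iff it is at least ``min_final_slice_s`` long."""
    bounds = []
    n_full = int(duration_s // slice_len_s)
    for i in range(n_full):
        bounds.append((i * slice_len_s, (i + 1) * slice_len_s))
    tail = duration_s - n_full * slice_len_s
    if tail >= min_final_slice_s:
        bounds.append((n_full * slice_len_s, duration_s))
    return bounds


def segment_slices(
    visit: VisitRecord,
    slice_len_s: float = SLICE_LEN_S,
    min_final_slice_s: float = MIN_FINAL_SLICE_S,
) -> list[Slice]:
    """Cut a visit into successive slices with boundary-clipped turns.

    A turn spanning a slice boundary contributes its intersection to each
    neighbouring slice.
    """
    return [
        Slice(visit.visit_id, i, s, e, clip_turns(visit.turns, s, e))
        for i, (s, e) in enumerate(
            slice_bounds(visit.duration_s, slice_len_s, min_final_slice_s)
        )
    ]
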