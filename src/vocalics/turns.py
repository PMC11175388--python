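"""Turn-dynamics analytics: interruptions, pauses, floor time, slice features.

Every cross-role overlap of turns is marked as an interruption (a deliberate
computational simplification — no cooperative/intrusive typing) and attributed
to the later-starting speaker. A silent gap between consecutive turns of at
least ``min_gap_s`` is a pause, attributed to the speaker who breaks it.

``turn_features`` distils these events into the 26-entry turn-based feature
block (13 per role). Statistics over empty sets are 0 rather than missing so
the feature vector has constant length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .conversation import ROLES, Role, Slice, Turn

log = logging.getLogger(__name__)

MIN_OVERLAP_S = 0.1
MIN_GAP_S = 0.3

#: per-role turn feature names, in canonical order
TURN_FEATURE_NAMES = (
    "talk_time_s",
    "talk_time_fraction",
    "n_turns",
    "mean_turn_dur_s",
    "sd_turn_dur_s",
    "max_turn_dur_s",
    "n_interruptions_initiated",
    "interruption_rate",
    "mean_post_interruption_turn_dur_s",
    "n_pauses_before_own_turns",
    "mean_pause_before_own_turns_s",
    "max_pause_before_own_turns_s",
    "solo_floor_fraction",
)
N_TURN_FEATURES = 2 * len(TURN_FEATURE_NAMES)  # 26


@dataclass(frozen=True)
class InterruptionEvent:
    """A maximal cross-role overlap region, attributed to the later starter."""

    interrupter: Role
    interrupted: Role
    start_s: float
    end_s: float
    #: duration of the interrupting speaker's turn (for post-interruption stats)
    interrupter_turn_dur_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PauseEvent:
    """A maximal silent gap bounded by speech, attributed to the next speaker."""

    next_speaker: Role
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _role_intervals(turns: list[Turn], role: Role) -> list[tuple[float, float]]:
    return sorted((t.start_s, t.end_s) for t in turns if t.role == role)


def detect_interruptions(
    turns: list[Turn], min_overlap_s: float = MIN_OVERLAP_S
) -> list[InterruptionEvent]:
    """Find maximal cross-role overlap regions of at least ``min_overlap_s``.

    The interrupter is the speaker whose turn started strictly later; an exact
    simultaneous start is attributed to the patient (and logged).
    """
    prov = [t for t in turns if t.role == Role.PROVIDER]
    pat = [t for t in turns if t.role == Role.PATIENT]
    raw: list[tuple[float, float, Role, float]] = []  # start, end, interrupter, turn dur
    for p in prov:
        for a in pat:
            s, e = max(p.start_s, a.start_s), min(p.end_s, a.end_s)
            if e <= s:
                continue
            if a.start_s > p.start_s:
                who, dur = Role.PATIENT, a.duration_s
            elif p.start_s > a.start_s:
                who, dur = Role.PROVIDER, p.duration_s
            else:
                log.debug("simultaneous turn start at %.3f s; attributing to patient", s)
                who, dur = Role.PATIENT, a.duration_s
            raw.append((s, e, who, dur))
    raw.sort(key=lambda r: r[0])
    # merge touching overlap fragments into maximal regions; attribution follows
    # the earliest fragment of the region
    merged: list[list] = []
    for s, e, who, dur in raw:
        if merged and s <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, who, dur])
    return [
        InterruptionEvent(
            interrupter=who,
            interrupted=Role.PATIENT if who == Role.PROVIDER else Role.PROVIDER,
            start_s=s,
            end_s=e,
            interrupter_turn_dur_s=dur,
        )
        for s, e, who, dur in merged
        # tolerance keeps ms-quantized durations that equal the threshold
        # from being dropped by float rounding
        if e - s >= min_overlap_s - 1e-9
    ]


def detect_pauses(turns: list[Turn], min_gap_s: float = MIN_GAP_S) -> list[PauseEvent]:
    """Find maximal silent gaps of at least ``min_gap_s`` bounded by speech.

    ``next_speaker`` is the role of the first turn starting after the gap.
    """
    if len(turns) < 2:
        return []
    ordered = sorted(turns, key=lambda t: (t.start_s, t.end_s))
    events: list[PauseEvent] = []
    frontier = ordered[0].end_s
    for t in ordered[1:]:
        if t.start_s - frontier >= min_gap_s - 1e-9:
            events.append(PauseEvent(t.role, frontier, t.start_s))
        frontier = max(frontier, t.end_s)
    return events


def _union_length(intervals: list[tuple[float, float]]) -> float:
    total, frontier = 0.0, -np.inf
    for s, e in sorted(intervals):
        if s > frontier:
            total += e - s
            frontier = e
        elif e > frontier:
            total += e - frontier
            frontier = e
    return total


def _intersection_length(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> float:
    total = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def floor_decomposition(sl: Slice) -> dict[str, float]:
    """Split a slice's duration into solo-provider, solo-patient, overlap and
    silence seconds. The four components sum to the slice length exactly."""
    prov = _role_intervals(sl.turns, Role.PROVIDER)
    pat = _role_intervals(sl.turns, Role.PATIENT)
    lp, la = _union_length(prov), _union_length(pat)
    overlap = _intersection_length(prov, pat)
    both = lp + la - overlap
    return {
        "solo_provider_s": lp - overlap,
        "solo_patient_s": la - overlap,
        "overlap_s": overlap,
        "silence_s": sl.duration_s - both,
    }


def _safe_mean(xs: list[float]) -> float:
    return float(np.mean(xs)) if xs else 0.0


def turn_features(
    sl: Slice,
    min_overlap_s: float = MIN_OVERLAP_S,
    min_gap_s: float = MIN_GAP_S,
) -> dict[str, float]:
    """The 26 turn-based features of a slice, keyed ``turn.<role>.<name>``."""
    ordered = sorted(sl.turns, key=lambda t: (t.start_s, t.end_s))
    interruptions = detect_interruptions(ordered, min_overlap_s)
    pauses = detect_pauses(ordered, min_gap_s)
    floor = floor_decomposition(sl)
    length = sl.duration_s
    feats: dict[str, float] = {}
    for role in ROLES:
        durs = [t.duration_s for t in ordered if t.role == role]
        talk = float(sum(durs))
        inits = [e for e in interruptions if e.interrupter == role]
        own_pauses = [e for e in pauses if e.next_speaker == role]
        block = {
            "talk_time_s": talk,
            "talk_time_fraction": talk / length if length > 0 else 0.0,
            "n_turns": float(len(durs)),
            "mean_turn_dur_s": _safe_mean(durs),
            "sd_turn_dur_s": float(np.std(durs)) if len(durs) > 1 else 0.0,
            "max_turn_dur_s": float(max(durs)) if durs else 0.0,
            "n_interruptions_initiated": float(len(inits)),
            "interruption_rate": len(inits) / max(1, len(durs)),
            "mean_post_interruption_turn_dur_s": _safe_mean(
                [e.interrupter_turn_dur_s for e in inits]
            ),
            "n_pauses_before_own_turns": float(len(own_pauses)),
            "mean_pause_before_own_turns_s": _safe_mean(
                [e.duration_s for e in own_pauses]
            ),
            "max_pause_before_own_turns_s": (
                float(max(e.duration_s for e in own_pauses)) if own_pauses else 0.0
            ),
            "solo_floor_fraction": (
                floor[f"solo_{role.value}_s"] / length if length > 0 else 0.0
            ),
        }
        for name in TURN_FEATURE_NAMES:
            feats[f"turn.{role.value}.{name}"] = block[name]
    return feats


def turn_feature_columns() -> list[str]:
    return [f"turn.{r.value}.{n}" for r in ROLES for n in TURN_FEATURE_NAMES]
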