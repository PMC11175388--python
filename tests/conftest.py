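"""Shared fixtures: small synthetic corpora and interval-scan oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vocalics import pipeline
from vocalics.conversation import Role, Turn
from vocalics.models import ALL_TARGETS
from vocalics.simulate import ScenarioParams, generate_corpus

GRID_RES_S = 0.001


# ---------------------------------------------------------------------------
# 1 ms grid-scan oracles, deliberately brute force and independent of the
# interval arithmetic they check


def _occupancy(turns, role, duration_s):
    n = int(round(duration_s / GRID_RES_S))
    occ = np.zeros(n, dtype=bool)
    for t in turns:
        if t.role == role:
            occ[int(round(t.start_s / GRID_RES_S)) : int(round(t.end_s / GRID_RES_S))] = True
    return occ


def _runs(mask):
    """(start, end) index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def grid_overlap_regions(turns, duration_s, min_overlap_s):
    both = _occupancy(turns, Role.PROVIDER, duration_s) & _occupancy(
        turns, Role.PATIENT, duration_s
    )
    return [
        (s * GRID_RES_S, e * GRID_RES_S)
        for s, e in _runs(both)
        if (e - s) * GRID_RES_S >= min_overlap_s - GRID_RES_S / 2
    ]


def grid_pause_regions(turns, duration_s, min_gap_s):
    speech = _occupancy(turns, Role.PROVIDER, duration_s) | _occupancy(
        turns, Role.PATIENT, duration_s
    )
    runs = _runs(~speech)
    # keep only gaps bounded by speech on both sides
    n = len(speech)
    return [
        (s * GRID_RES_S, e * GRID_RES_S)
        for s, e in runs
        if s > 0 and e < n and (e - s) * GRID_RES_S >= min_gap_s - GRID_RES_S / 2
    ]


def grid_floor_seconds(turns, duration_s):
    p = _occupancy(turns, Role.PROVIDER, duration_s)
    a = _occupancy(turns, Role.PATIENT, duration_s)
    return {
        "solo_provider_s": float((p & ~a).sum()) * GRID_RES_S,
        "solo_patient_s": float((a & ~p).sum()) * GRID_RES_S,
        "overlap_s": float((p & a).sum()) * GRID_RES_S,
        "silence_s": float((~p & ~a).sum()) * GRID_RES_S,
    }


def random_turn_set(rng, duration_s=60.0, max_turns_per_role=20):
    """Random valid turn set: same-role non-overlap, cross-role overlap allowed.

    All times on the 1 ms grid so the grid oracle is exact.
    """
    turns = []
    for role in (Role.PROVIDER, Role.PATIENT):
        t = 0.0
        for _ in range(int(rng.integers(1, max_turns_per_role + 1))):
            t += round(float(rng.uniform(0.0, 3.0)), 3)
            dur = round(float(rng.uniform(0.2, 5.0)), 3)
            if t + dur > duration_s:
                break
            turns.append(Turn(role, round(t, 3), round(t + dur, 3)))
            t += dur + 0.11  # stay above the same-role merge threshold
    turns.sort(key=lambda t: (t.start_s, t.end_s))
    return turns


# ---------------------------------------------------------------------------
# corpora


@pytest.fixture(scope="session")
def tiny_params():
    return ScenarioParams(
        n_providers=3, visits_per_provider=2, visit_duration_s=360.0, seed=42
    )


@pytest.fixture(scope="session")
def tiny_corpus(tiny_params):
    return generate_corpus(tiny_params)


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    return pipeline.corpus_features(tiny_corpus)


@pytest.fixture(scope="session")
def tiny_labels(tiny_corpus):
    return pd.DataFrame(tiny_corpus.label_rows())


def one_signal_marginals(column, p_high=0.5):
    """All targets pinned to neutral except ``column`` at 50/50 neutral/high."""
    marg = {t.column: {"neutral": 1.0} for t in ALL_TARGETS}
    marg[column] = {"neutral": 1.0 - p_high, "high": p_high}
    return marg
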