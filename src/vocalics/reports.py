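"""Dashboard report data: score expansion, visit, comparison and population views.

Predicted classes are re-expanded to the 1–6 affect scale the RIAS coding
uses: low → 1.5, neutral → 3, high → 5. A visit's *overall affect* for a role
is the mean of its four per-signal visit means. Reports are plain JSON with a
versioned schema so any front end can render them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import MODEL_ROLES, SIGNALS, SignalTarget

EXPANSION = {"low": 1.5, "neutral": 3.0, "high": 5.0}

#: patient-centered direction per signal and role; provider dominance is the
#: one signal where *low* is desired
DESIRED_HIGH = {
    (signal, role): not (signal == "dominance" and role == "provider")
    for signal in SIGNALS
    for role in MODEL_ROLES
}


def expand_score(cls: str) -> float:
    """Map a predicted class to its RIAS-scale score (low 1.5, neutral 3, high 5)."""
    try:
        return EXPANSION[cls]
    except KeyError:
        raise ValueError(
            f"unknown affect class {cls!r}; expected one of {sorted(EXPANSION)}"
        ) from None


def expand_scores(classes: Sequence[str]) -> list[float]:
    """Expand a per-slice class sequence to RIAS-scale scores."""
    return [expand_score(c) for c in classes]


@dataclass
class VisitReport:
    visit_id: str
    provider_id: str
    patient_meta: dict
    n_slices: int
    #: per role: {"overall_affect": float, "signal_means": {signal: float},
    #:            "time_series": {signal: [float]}, "flags": {signal: bool}}
    roles: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "visit_report.v1",
            "visit_id": self.visit_id,
            "provider_id": self.provider_id,
            "patient_meta": self.patient_meta,
            "n_slices": self.n_slices,
            "roles": self.roles,
        }


def visit_report(
    slice_classes: Mapping[SignalTarget, Sequence[str]],
    visit_id: str,
    provider_id: str,
    patient_meta: Mapping[str, object] | None = None,
) -> VisitReport:
    """Aggregate per-slice predicted classes into one visit's dashboard data.

    ``slice_classes`` maps each of the 8 targets to that visit's slice-ordered
    class sequence. Per signal, slice classes are expanded to scores and
    averaged; a role's overall affect is the mean of its four signal means.
    A flag is set when a signal's mean deviates from the patient-centered
    direction (provider dominance above 3; any other signal below 3).
    """
    lengths = {len(v) for v in slice_classes.values()}
    if not slice_classes or lengths == {0}:
        raise ValueError("visit report needs at least one slice of predictions")
    if len(lengths) != 1:
        raise ValueError(f"inconsistent slice counts across targets: {sorted(lengths)}")
    n_slices = lengths.pop()
    roles: dict[str, dict] = {}
    for role in MODEL_ROLES:
        series = {}
        means = {}
        flags = {}
        for signal in SIGNALS:
            classes = slice_classes[SignalTarget(signal, role)]
            scores = expand_scores(classes)
            series[signal] = scores
            means[signal] = float(np.mean(scores))
            if DESIRED_HIGH[(signal, role)]:
                flags[signal] = means[signal] < 3.0
            else:
                flags[signal] = means[signal] > 3.0
        roles[role] = {
            "overall_affect": float(np.mean(list(means.values()))),
            "signal_means": means,
            "time_series": series,
            "flags": flags,
        }
    return VisitReport(
        visit_id=visit_id,
        provider_id=provider_id,
        patient_meta=dict(patient_meta or {}),
        n_slices=n_slices,
        roles=roles,
    )


def compare_visits(a: VisitReport, b: VisitReport) -> dict:
    """Side-by-side comparison of two visits of the same provider.

    Deltas are a − b; time series are reported as-is for aligned plotting.
    """
    if a.provider_id != b.provider_id:
        raise ValueError(
            f"can only compare visits of one provider, got {a.provider_id!r} "
            f"and {b.provider_id!r}"
        )
    comparison = {
        "schema": "comparison.v1",
        "provider_id": a.provider_id,
        "visit_a": a.to_dict(),
        "visit_b": b.to_dict(),
        "deltas": {},
    }
    for role in MODEL_ROLES:
        ra, rb = a.roles[role], b.roles[role]
        comparison["deltas"][role] = {
            "overall_affect": ra["overall_affect"] - rb["overall_affect"],
            "signal_means": {
                s: ra["signal_means"][s] - rb["signal_means"][s] for s in SIGNALS
            },
        }
    return comparison


def _matches(meta: Mapping[str, object], flt: Mapping[str, object]) -> bool:
    if "gender" in flt and str(meta.get("gender")) != str(flt["gender"]):
        return False
    if "race" in flt and str(meta.get("race")) != str(flt["race"]):
        return False
    if "age_range" in flt:
        lo, hi = flt["age_range"]
        age = int(meta.get("age", -1))
        if not (lo <= age <= hi):
            return False
    return True


def _group_means(reports: list[VisitReport]) -> dict:
    if not reports:
        return {"empty": True, "n_visits": 0}
    out: dict = {"empty": False, "n_visits": len(reports), "roles": {}}
    for role in MODEL_ROLES:
        out["roles"][role] = {
            "overall_affect": float(
                np.mean([r.roles[role]["overall_affect"] for r in reports])
            ),
            "signal_means": {
                s: float(np.mean([r.roles[role]["signal_means"][s] for r in reports]))
                for s in SIGNALS
            },
        }
    return out


def population_summary(
    reports: Iterable[VisitReport], flt: Mapping[str, object]
) -> dict:
    """Mean affect for visits matching a demographic filter vs all others.

    The filter may constrain ``gender``, ``race`` and ``age_range``
    (inclusive ``[min, max]``). No time-series aggregation: visits progress
    differently, so an averaged time series would mislead.
    """
    reports = list(reports)
    matching = [r for r in reports if _matches(r.patient_meta, flt)]
    complement = [r for r in reports if not _matches(r.patient_meta, flt)]
    return {
        "schema": "population.v1",
        "filter": dict(flt),
        "n_visits": len(reports),
        "matching": _group_means(matching),
        "complement": _group_means(complement),
    }


def write_report(report: dict | VisitReport, path) -> None:
    payload = report.to_dict() if isinstance(report, VisitReport) else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
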