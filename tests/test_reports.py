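"""Score expansion and visit/comparison/population report aggregation."""

import numpy as np
import pytest

from vocalics.models import ALL_TARGETS, MODEL_ROLES, SIGNALS, SignalTarget
from vocalics.reports import (
    compare_visits,
    expand_score,
    expand_scores,
    population_summary,
    visit_report,
)


class TestExpansion:
    @pytest.mark.parametrize(
        "cls,score", [("low", 1.5), ("neutral", 3.0), ("high", 5.0)]
    )
    def test_mapping(self, cls, score):
        assert expand_score(cls) == score

    def test_sequence(self):
        assert expand_scores(["neutral", "high", "neutral"]) == [3.0, 5.0, 3.0]

    def test_unknown_class(self):
        with pytest.raises(ValueError, match="medium"):
            expand_score("medium")


def classes_for(visit_classes):
    """Broadcast one class sequence (or a per-signal dict) to all 8 targets."""
    out = {}
    for target in ALL_TARGETS:
        if isinstance(visit_classes, dict):
            out[target] = list(visit_classes.get(target, visit_classes["default"]))
        else:
            out[target] = list(visit_classes)
    return out


class TestVisitReport:
    def test_overall_is_mean_of_signal_means(self):
        per_signal = {
            SignalTarget("dominance", "provider"): ["high"],
            SignalTarget("interactiveness", "provider"): ["neutral"],
            SignalTarget("engagement", "provider"): ["high"],
            SignalTarget("warmth", "provider"): ["neutral"],
            "default": ["neutral"],
        }
        report = visit_report(classes_for(per_signal), "v1", "p1")
        assert report.roles["provider"]["overall_affect"] == pytest.approx(4.0)
        assert report.roles["patient"]["overall_affect"] == pytest.approx(3.0)

    def test_all_neutral_no_flags(self):
        report = visit_report(classes_for(["neutral", "neutral"]), "v1", "p1")
        for role in MODEL_ROLES:
            assert report.roles[role]["overall_affect"] == 3.0
            assert not any(report.roles[role]["flags"].values())

    def test_provider_dominance_flagged_when_high(self):
        report = visit_report(classes_for(["high"]), "v1", "p1")
        assert report.roles["provider"]["flags"]["dominance"] is True
        # high is the desired direction everywhere else
        assert not report.roles["patient"]["flags"]["dominance"]
        assert not report.roles["provider"]["flags"]["warmth"]

    def test_low_means_flag_desired_high_signals(self):
        per_signal = {SignalTarget("warmth", "patient"): ["low"], "default": ["neutral"]}
        report = visit_report(classes_for(per_signal), "v1", "p1")
        assert report.roles["patient"]["flags"]["warmth"] is True

    def test_slice_order_permutation_invariant_means(self):
        rng = np.random.default_rng(0)
        seq = list(rng.choice(["neutral", "high"], size=9))
        r1 = visit_report(classes_for(seq), "v1", "p1")
        r2 = visit_report(classes_for(seq[::-1]), "v1", "p1")
        for role in MODEL_ROLES:
            assert r1.roles[role]["signal_means"] == r2.roles[role]["signal_means"]

    def test_recomputation_oracle(self):
        rng = np.random.default_rng(4)
        classes = {
            t: list(rng.choice(["low", "neutral", "high"], size=7)) for t in ALL_TARGETS
        }
        report = visit_report(classes, "v1", "p1")
        score = {"low": 1.5, "neutral": 3.0, "high": 5.0}
        for role in MODEL_ROLES:
            means = [
                np.mean([score[c] for c in classes[SignalTarget(s, role)]])
                for s in SIGNALS
            ]
            assert report.roles[role]["overall_affect"] == pytest.approx(
                np.mean(means), abs=1e-9
            )
            assert 1.5 <= report.roles[role]["overall_affect"] <= 5.0

    def test_empty_predictions_error(self):
        with pytest.raises(ValueError):
            visit_report({t: [] for t in ALL_TARGETS}, "v1", "p1")


class TestComparison:
    def _report(self, seq, visit_id="v1", provider="p1"):
        return visit_report(classes_for(seq), visit_id, provider)

    def test_identity_zero_deltas(self):
        a = self._report(["high", "neutral"])
        cmp = compare_visits(a, a)
        for role in MODEL_ROLES:
            assert cmp["deltas"][role]["overall_affect"] == 0.0
            assert all(v == 0.0 for v in cmp["deltas"][role]["signal_means"].values())

    def test_overall_delta(self):
        a = self._report(["high"])  # overall 5
        b = self._report(["neutral"], visit_id="v2")  # overall 3
        assert compare_visits(a, b)["deltas"]["provider"]["overall_affect"] == 2.0

    def test_antisymmetry(self):
        a = self._report(["high", "neutral", "high"])
        b = self._report(["neutral", "neutral", "high"], visit_id="v2")
        ab, ba = compare_visits(a, b), compare_visits(b, a)
        for role in MODEL_ROLES:
            assert ab["deltas"][role]["overall_affect"] == pytest.approx(
                -ba["deltas"][role]["overall_affect"]
            )
            for s in SIGNALS:
                assert ab["deltas"][role]["signal_means"][s] == pytest.approx(
                    -ba["deltas"][role]["signal_means"][s]
                )

    def test_different_providers_rejected(self):
        a = self._report(["high"])
        b = visit_report(classes_for(["high"]), "v2", "OTHER")
        with pytest.raises(ValueError, match="provider"):
            compare_visits(a, b)


class TestPopulation:
    def _report(self, seq, visit_id, meta):
        r = visit_report(classes_for(seq), visit_id, "p1", patient_meta=meta)
        return r

    def test_group_and_complement_means(self):
        a = self._report(["neutral"], "v1", {"gender": "female", "race": "white", "age": 40})
        b = self._report(["high"], "v2", {"gender": "male", "race": "white", "age": 70})
        summary = population_summary([a, b], {"gender": "female"})
        assert summary["matching"]["roles"]["provider"]["overall_affect"] == 3.0
        assert summary["complement"]["roles"]["provider"]["overall_affect"] == 5.0

    def test_filter_matching_all(self):
        a = self._report(["neutral"], "v1", {"gender": "female", "age": 40})
        summary = population_summary([a], {"gender": "female"})
        assert summary["complement"]["empty"] is True

    def test_age_range_inclusive(self):
        a = self._report(["neutral"], "v1", {"age": 40})
        b = self._report(["high"], "v2", {"age": 41})
        summary = population_summary([a, b], {"age_range": (18, 40)})
        assert summary["matching"]["n_visits"] == 1

    @pytest.mark.parametrize("flt", [{}, {"gender": "female"}, {"age_range": (30, 60)}])
    def test_conservation(self, flt):
        rng = np.random.default_rng(9)
        reports = [
            self._report(
                list(rng.choice(["neutral", "high"], size=3)),
                f"v{i}",
                {"gender": rng.choice(["female", "male"]),
                 "race": "white", "age": int(rng.integers(20, 90))},
            )
            for i in range(12)
        ]
        summary = population_summary(reports, flt)
        assert (
            summary["matching"]["n_visits"] + summary["complement"]["n_visits"] == 12
        )

    def test_brute_force_group_means(self):
        rng = np.random.default_rng(11)
        reports = []
        for i in range(10):
            meta = {"gender": rng.choice(["female", "male"]), "age": 50}
            reports.append(
                self._report(list(rng.choice(["neutral", "high"], size=4)), f"v{i}", meta)
            )
        summary = population_summary(reports, {"gender": "female"})
        members = [r for r in reports if r.patient_meta["gender"] == "female"]
        if members:
            expected = np.mean([r.roles["provider"]["overall_affect"] for r in members])
            assert summary["matching"]["roles"]["provider"]["overall_affect"] == (
                pytest.approx(expected)
            )
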