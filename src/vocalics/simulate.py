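"""Synthetic two-speaker visit generator with latent social-signal classes.

Real clinic recordings are private, so the pipeline is exercised on simulated
dyads whose turn dynamics and prosody are driven by per-slice latent classes
of the eight social-signal targets. The generator plants exactly the vocal
cues the literature associates with each signal, and nothing content-based:

* **dominance** (role r high): r's talk share, interruption probability and
  vocal intensity shift up;
* **warmth** (r high): r's pitch variability shifts down, r's response
  latency up;
* **interactiveness** (r high): more, briefer turns and fewer pauses;
* **engagement** (r high): faster responses between turns and more reliable
  speaker alternation.

Shifts scale linearly with ``effect_strength`` (0 = null model: classes are
independent of the features); a *low* class applies the opposite shift.
Conflicting shifts combine additively.

Turns come from an alternating-renewal process: speakers alternate with a
configurable probability, turn lengths are exponential with per-role means
rescaled so the expected provider talk share matches the profile, and a turn
either interrupts (starts before the current turn ends) or follows a gamma
response-latency gap. Audio renders each turn as a 3-harmonic complex with
per-turn F0 drawn from the role's pitch distribution over a -30 dB noise
floor. All sampling is reproducible from the scenario seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .conversation import (
    SAMPLE_RATE,
    Role,
    Turn,
    VisitRecord,
    write_rttm,
    write_wav,
)
from .models import ALL_TARGETS, SignalTarget

PROVIDER, PATIENT = Role.PROVIDER.value, Role.PATIENT.value


def _roledict(provider: float, patient: float) -> dict[str, float]:
    return {PROVIDER: provider, PATIENT: patient}


@dataclass
class DynamicsProfile:
    """Parameters of one slice's conversational dynamics and prosody."""

    provider_talk_share: float = 0.55
    turns_per_min: float = 16.0
    mean_turn_s: dict[str, float] = field(default_factory=lambda: _roledict(4.0, 3.0))
    interruption_prob: dict[str, float] = field(
        default_factory=lambda: _roledict(0.06, 0.06)
    )
    response_latency_s: dict[str, float] = field(
        default_factory=lambda: _roledict(0.8, 0.8)
    )
    alternation_prob: float = 0.8
    f0_mean_hz: dict[str, float] = field(default_factory=lambda: _roledict(120.0, 210.0))
    f0_sd_hz: dict[str, float] = field(default_factory=lambda: _roledict(15.0, 20.0))
    intensity_offset_db: dict[str, float] = field(default_factory=lambda: _roledict(0.0, 0.0))

    def copy(self) -> "DynamicsProfile":
        return replace(
            self,
            mean_turn_s=dict(self.mean_turn_s),
            interruption_prob=dict(self.interruption_prob),
            response_latency_s=dict(self.response_latency_s),
            f0_mean_hz=dict(self.f0_mean_hz),
            f0_sd_hz=dict(self.f0_sd_hz),
            intensity_offset_db=dict(self.intensity_offset_db),
        )


#: per-unit-effect parameter shifts for a *high* class of each signal
SHIFT_TALK_SHARE = 0.12
SHIFT_INTERRUPTION = 0.08
SHIFT_INTENSITY_DB = 4.0
SHIFT_F0_SD = -10.0
SHIFT_WARMTH_LATENCY = 0.4
SHIFT_TURNS_PER_MIN = 6.0
SHIFT_MEAN_TURN = -1.6
SHIFT_INTERACT_LATENCY = -0.3
SHIFT_ENGAGE_LATENCY = -0.45
SHIFT_ALTERNATION = 0.15


def _class_sign(cls: str) -> float:
    return {"high": 1.0, "neutral": 0.0, "low": -1.0}[cls]


def profile_from_classes(
    classes: dict[SignalTarget, str],
    effect_strength: float = 1.0,
    base: DynamicsProfile | None = None,
) -> DynamicsProfile:
    """Shift a base profile per the latent classes of the eight targets.

    All-neutral classes (or zero effect strength) return the base unchanged;
    shifts from different signals combine additively and are clamped to
    physically sensible ranges at the end.
    """
    p = (base or DynamicsProfile()).copy()
    es = float(effect_strength)
    for target, cls in classes.items():
        s = _class_sign(cls) * es
        if s == 0.0:
            continue
        role = target.role
        if target.signal == "dominance":
            direction = 1.0 if role == PROVIDER else -1.0
            p.provider_talk_share += direction * SHIFT_TALK_SHARE * s
            p.interruption_prob[role] += SHIFT_INTERRUPTION * s
            p.intensity_offset_db[role] += SHIFT_INTENSITY_DB * s
        elif target.signal == "warmth":
            p.f0_sd_hz[role] += SHIFT_F0_SD * s
            p.response_latency_s[role] += SHIFT_WARMTH_LATENCY * s
        elif target.signal == "interactiveness":
            p.turns_per_min += SHIFT_TURNS_PER_MIN * s
            p.mean_turn_s[role] += SHIFT_MEAN_TURN * s
            p.response_latency_s[role] += SHIFT_INTERACT_LATENCY * s
        elif target.signal == "engagement":
            p.response_latency_s[role] += SHIFT_ENGAGE_LATENCY * s
            p.alternation_prob += SHIFT_ALTERNATION * s
        else:  # pragma: no cover - targets are fixed
            raise ValueError(f"unknown signal {target.signal!r}")
    p.provider_talk_share = float(np.clip(p.provider_talk_share, 0.1, 0.9))
    p.alternation_prob = float(np.clip(p.alternation_prob, 0.2, 0.98))
    p.turns_per_min = max(2.0, p.turns_per_min)
    for role in (PROVIDER, PATIENT):
        p.mean_turn_s[role] = max(0.8, p.mean_turn_s[role])
        p.interruption_prob[role] = float(np.clip(p.interruption_prob[role], 0.0, 0.6))
        p.response_latency_s[role] = max(0.05, p.response_latency_s[role])
        p.f0_sd_hz[role] = max(1.0, p.f0_sd_hz[role])
    return p


def sample_turn_sequence(
    profile: DynamicsProfile,
    duration_s: float,
    rng: np.random.Generator,
) -> list[Turn]:
    """Draw one slice's turn sequence from the alternating-renewal process.

    Turn times are quantized to milliseconds so the WAV/RTTM round trip is
    exact; same-role turns are separated by at least 0.15 s (above the
    diarizer-jitter merge threshold).
    """
    share = profile.provider_talk_share
    m_bar = (profile.mean_turn_s[PROVIDER] + profile.mean_turn_s[PATIENT]) / 2.0
    eff_mean = {PROVIDER: 2.0 * share * m_bar, PATIENT: 2.0 * (1.0 - share) * m_bar}
    speaker = PROVIDER if rng.random() < 0.5 else PATIENT
    # start past the merge threshold so turns in consecutive slices never sit
    # closer than the diarizer-jitter merge rule
    t = float(rng.uniform(0.2, 1.0))
    last_end = {PROVIDER: -1.0, PATIENT: -1.0}
    turns: list[Turn] = []
    while t < duration_s:
        dur = float(np.clip(rng.exponential(eff_mean[speaker]), 0.3, 25.0))
        start = max(t, last_end[speaker] + 0.15)
        end = min(start + dur, duration_s)
        start_q, end_q = round(start, 3), round(end, 3)
        if end_q - start_q >= 0.05 and start_q < duration_s:
            turns.append(Turn(Role(speaker), start_q, end_q))
            last_end[speaker] = end_q
        other = PATIENT if speaker == PROVIDER else PROVIDER
        next_speaker = other if rng.random() < profile.alternation_prob else speaker
        if (
            next_speaker != speaker
            and rng.random() < profile.interruption_prob[next_speaker]
        ):
            overlap = min(float(rng.uniform(0.2, 1.5)), 0.6 * dur)
            t_next = max(start + dur - overlap, start + 0.05)
        else:
            gap = float(rng.gamma(2.0, profile.response_latency_s[next_speaker] / 2.0))
            floor = 0.15 if next_speaker == speaker else 0.05
            t_next = start + dur + max(gap, floor)
        t, speaker = t_next, next_speaker
    turns.sort(key=lambda u: (u.start_s, u.end_s))
    return turns


BASE_AMPLITUDE = 0.1
NOISE_DB = -30.0
HARMONIC_AMPS = (1.0, 0.5, 0.25)
EDGE_S = 0.010


def synthesize_audio(
    turns: list[Turn],
    profile: DynamicsProfile,
    duration_s: float,
    rng: np.random.Generator,
    sample_rate_hz: int = SAMPLE_RATE,
) -> np.ndarray:
    """Render turns as harmonic complexes over a white-noise floor.

    Each turn carries a constant per-turn F0 drawn from the role's pitch
    distribution, three harmonics, a raised-cosine 10 ms fade at each edge
    and an amplitude set by the role's intensity offset. Overlapping turns
    mix additively.
    """
    sr = sample_rate_hz
    n = round(duration_s * sr)
    noise_amp = BASE_AMPLITUDE * 10.0 ** (NOISE_DB / 20.0)
    wave = (noise_amp * rng.standard_normal(n)).astype(np.float32)
    norm = sum(HARMONIC_AMPS)
    edge = round(EDGE_S * sr)
    for turn in turns:
        role = turn.role.value
        f0 = float(
            np.clip(rng.normal(profile.f0_mean_hz[role], profile.f0_sd_hz[role]), 60.0, 480.0)
        )
        amp = BASE_AMPLITUDE * 10.0 ** (profile.intensity_offset_db[role] / 20.0)
        i0, i1 = round(turn.start_s * sr), min(round(turn.end_s * sr), n)
        m = i1 - i0
        if m <= 0:
            continue
        tt = np.arange(m) / sr
        sig = np.zeros(m)
        for h, a in enumerate(HARMONIC_AMPS, start=1):
            sig += (a / norm) * np.sin(2.0 * np.pi * h * f0 * tt + rng.uniform(0, 2 * np.pi))
        if m > 2 * edge:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
            sig[:edge] *= ramp
            sig[-edge:] *= ramp[::-1]
        wave[i0:i1] += (amp * sig).astype(np.float32)
    peak = np.abs(wave).max()
    if peak > 1.0:
        wave /= peak
    return wave


DEFAULT_MARGINALS = {"low": 0.05, "neutral": 0.50, "high": 0.45}


@dataclass
class ScenarioParams:
    """Scenario for a synthetic corpus.

    Defaults mirror a realistic clinic corpus: 10 providers with 10 visits
    each, 30-minute visits (10 three-minute slices). ``class_marginals`` maps
    a target column (e.g. ``provider_dominance``) to class probabilities;
    targets not listed use ``default_marginals``. ``effect_strength`` 0 is
    the null model in which classes carry no signal.
    """

    n_providers: int = 10
    visits_per_provider: int = 10
    visit_duration_s: float = 1800.0
    class_marginals: dict[str, dict[str, float]] = field(default_factory=dict)
    default_marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    effect_strength: float = 1.0
    seed: int = 0
    base_profile: DynamicsProfile = field(default_factory=DynamicsProfile)
    slice_len_s: float = 180.0

    def marginals_for(self, target: SignalTarget) -> dict[str, float]:
        return self.class_marginals.get(target.column, self.default_marginals)


RAW_SCORES = {"low": (1, 2), "neutral": (3,), "high": (4, 5, 6)}

GENDERS, GENDER_P = ("female", "male"), (0.566, 0.434)
RACES, RACE_P = ("white", "black", "asian", "hispanic"), (0.748, 0.10, 0.05, 0.102)


@dataclass
class VisitSpec:
    """One synthetic visit: structure and labels; audio is rendered lazily."""

    visit_id: str
    provider_id: str
    patient_meta: dict
    duration_s: float
    slice_classes: list[dict[SignalTarget, str]]
    slice_profiles: list[DynamicsProfile]
    turns: list[Turn]
    labels: list[dict]
    audio_seed: tuple[int, ...]


class Corpus:
    """A generated scenario: visit specs plus writers and lazy audio."""

    def __init__(self, params: ScenarioParams, visits: list[VisitSpec]):
        self.params = params
        self.visits = visits

    def visit_record(self, spec: VisitSpec) -> VisitRecord:
        """Synthesize the visit's waveform (deterministic per spec seed)."""
        rng = np.random.default_rng(spec.audio_seed)
        sr = SAMPLE_RATE
        wave = np.zeros(round(spec.duration_s * sr), dtype=np.float32)
        slice_len = self.params.slice_len_s
        for k, profile in enumerate(spec.slice_profiles):
            s0 = k * slice_len
            s1 = min(s0 + slice_len, spec.duration_s)
            local = [
                Turn(t.role, round(t.start_s - s0, 3), round(t.end_s - s0, 3))
                for t in spec.turns
                if s0 <= t.start_s < s1
            ]
            chunk = synthesize_audio(local, profile, s1 - s0, rng, sr)
            i0 = round(s0 * sr)
            wave[i0 : i0 + len(chunk)] = chunk
        return VisitRecord(
            visit_id=spec.visit_id,
            provider_id=spec.provider_id,
            patient_meta=spec.patient_meta,
            sample_rate_hz=sr,
            audio=wave,
            turns=list(spec.turns),
        )

    def label_rows(self) -> list[dict]:
        return [row for spec in self.visits for row in spec.labels]

    def metadata_rows(self) -> list[dict]:
        return [
            {
                "visit_id": spec.visit_id,
                "provider_id": spec.provider_id,
                "gender": spec.patient_meta["gender"],
                "race": spec.patient_meta["race"],
                "age": spec.patient_meta["age"],
            }
            for spec in self.visits
        ]

    def write(self, out_dir: str | Path) -> None:
        """Write WAV + RTTM per visit plus metadata.csv and labels.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for spec in self.visits:
            record = self.visit_record(spec)
            write_wav(out / f"{spec.visit_id}.wav", record.audio)
            write_rttm(spec.turns, spec.visit_id, out / f"{spec.visit_id}.rttm")
        _write_csv(out / "metadata.csv", self.metadata_rows())
        _write_csv(out / "labels.csv", self.label_rows())


def _write_csv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def _draw_class(marginals: dict[str, float], rng: np.random.Generator) -> str:
    names = ("low", "neutral", "high")
    p = np.array([marginals.get(c, 0.0) for c in names], dtype=float)
    p /= p.sum()
    return names[rng.choice(3, p=p)]


def generate_corpus(params: ScenarioParams) -> Corpus:
    """Generate a reproducible corpus of synthetic visits.

    Per slice, latent classes are drawn for the eight targets, the dynamics
    profile is shifted accordingly, a turn sequence is sampled, and raw 1–6
    labels are emitted (neutral → 3; high → uniform over 4–6; low → uniform
    over 1–2) so the label-clustering step is exercised across its domain.
    """
    visits: list[VisitSpec] = []
    n_slices = max(1, int(np.ceil(params.visit_duration_s / params.slice_len_s)))
    for pi in range(params.n_providers):
        provider_id = f"prov{pi:02d}"
        for vi in range(params.visits_per_provider):
            visit_id = f"{provider_id}_v{vi:02d}"
            rng = np.random.default_rng([params.seed, 101, pi, vi])
            meta = {
                "gender": GENDERS[rng.choice(2, p=GENDER_P)],
                "race": RACES[rng.choice(4, p=RACE_P)],
                "age": int(np.clip(rng.normal(50.0, 12.0), 18, 90)),
            }
            slice_classes: list[dict[SignalTarget, str]] = []
            slice_profiles: list[DynamicsProfile] = []
            all_turns: list[Turn] = []
            labels: list[dict] = []
            for k in range(n_slices):
                classes = {
                    t: _draw_class(params.marginals_for(t), rng) for t in ALL_TARGETS
                }
                profile = profile_from_classes(
                    classes, params.effect_strength, params.base_profile
                )
                s0 = k * params.slice_len_s
                s1 = min(s0 + params.slice_len_s, params.visit_duration_s)
                local = sample_turn_sequence(profile, s1 - s0, rng)
                all_turns.extend(
                    Turn(t.role, round(t.start_s + s0, 3), round(t.end_s + s0, 3))
                    for t in local
                )
                row = {"visit_id": visit_id, "slice_index": k, "provider_id": provider_id}
                for target, cls in classes.items():
                    row[target.column] = int(rng.choice(RAW_SCORES[cls]))
                labels.append(row)
                slice_classes.append(classes)
                slice_profiles.append(profile)
            all_turns.sort(key=lambda t: (t.start_s, t.end_s))
            visits.append(
                VisitSpec(
                    visit_id=visit_id,
                    provider_id=provider_id,
                    patient_meta=meta,
                    duration_s=params.visit_duration_s,
                    slice_classes=slice_classes,
                    slice_profiles=slice_profiles,
                    turns=all_turns,
                    labels=labels,
                    audio_seed=(params.seed, 202, pi, vi),
                )
            )
    return Corpus(params, visits)
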