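"""Framewise vocalic tracks and the 178-dimensional slice feature vector.

Per slice, all of one speaker's clipped turns are appended into a single
utterance (short turns alone carry too little spectral information), and 19
framewise tracks are computed on 25 ms frames with a 10 ms hop:

* ``mfcc_01`` .. ``mfcc_13`` — the first 13 mel-frequency cepstral
  coefficients (vocal-tract shape for the low orders, source detail above);
* ``spectral_centroid_hz`` — energy-weighted mean frequency;
* ``spectral_rolloff_hz`` — the frequency below which 85% of spectral energy
  lies, a per-frame measure of spectral spread;
* ``pitch_hz`` — autocorrelation F0 in 75–500 Hz, 0 on unvoiced frames;
* ``rms_energy`` — root-mean-square amplitude per frame;
* ``zero_crossing_rate`` — sign changes per second;
* ``intensity_db`` — 10·log10 of the frame mean square power (a loudness
  proxy on a dB scale).

Each track is summarized by mean, sd, min and max (pitch over voiced frames
only), giving 76 speech features per role, 152 per slice; together with the
26 turn-based features this is the 178-feature slice vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .conversation import ROLES, Role, Slice, VisitRecord
from .turns import turn_feature_columns, turn_features

FRAME_LEN_S = 0.025
HOP_S = 0.010
N_MFCC = 13
N_MELS = 26
ROLLOFF_PERCENTILE = 0.85
PITCH_FMIN_HZ = 75.0
PITCH_FMAX_HZ = 500.0
VOICING_THRESHOLD = 0.3
EPS = 1e-10
#: below this much speech in a slice the spectral summaries are meaningless
MIN_SPEECH_S = 0.5

TRACK_NAMES = tuple(
    [f"mfcc_{i:02d}" for i in range(1, N_MFCC + 1)]
    + [
        "spectral_centroid_hz",
        "spectral_rolloff_hz",
        "pitch_hz",
        "rms_energy",
        "zero_crossing_rate",
        "intensity_db",
    ]
)
STAT_NAMES = ("mean", "sd", "min", "max")
N_SPEECH_FEATURES = 2 * len(TRACK_NAMES) * len(STAT_NAMES)  # 152
N_FEATURES = 26 + N_SPEECH_FEATURES  # 178


@dataclass
class SpeakerSliceAudio:
    """One role's concatenated within-slice speech at 16 kHz."""

    role: Role
    waveform: np.ndarray
    total_speech_s: float


@dataclass
class FrameTracks:
    """Framewise track matrix: ``data[name]`` is a (n_frames,) array."""

    data: dict[str, np.ndarray]
    n_frames: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]


def concatenate_speaker_audio(
    sl: Slice, visit: VisitRecord, role: Role
) -> SpeakerSliceAudio:
    """Append the audio of a role's clipped turns in temporal order.

    Regions where the two speakers overlap are included for both roles: the
    recording is single-channel, so the mixed signal is the best available
    stand-in for either voice there.
    """
    sr = visit.sample_rate_hz
    pieces = []
    total = 0.0
    for t in sorted(sl.turns, key=lambda t: t.start_s):
        if t.role != role:
            continue
        i0, i1 = round(t.start_s * sr), round(t.end_s * sr)
        pieces.append(visit.audio[i0:i1])
        total += t.duration_s
    wav = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.float32)
    return SpeakerSliceAudio(role=role, waveform=wav, total_speech_s=total)


def _frame(signal: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if len(signal) < frame_len:
        return np.zeros((0, frame_len), dtype=np.float32)
    return np.lib.stride_tricks.sliding_window_view(signal, frame_len)[::hop]


def _mel_filterbank(n_mels: int, n_fft: int, sr: int) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sr / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sr).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def _autocorr_pitch(
    frames: np.ndarray, sr: int, fmin: float, fmax: float, threshold: float
) -> np.ndarray:
    """Framewise F0 by biased autocorrelation with parabolic peak refinement."""
    n, flen = frames.shape
    if n == 0:
        return np.zeros(0)
    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(flen - 1, int(np.ceil(sr / fmin)))
    if lag_max <= lag_min:
        return np.zeros(n)
    nfft = scipy.fft.next_fast_len(flen + lag_max + 1)
    spec = scipy.fft.rfft(frames, n=nfft, axis=1)
    ac = scipy.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 1]
    r0 = ac[:, 0]
    norm = np.where(r0 > EPS, r0, 1.0)
    acn = ac / norm[:, None]
    window = acn[:, lag_min : lag_max + 1]
    best = np.argmax(window, axis=1) + lag_min
    peak = np.take_along_axis(acn, best[:, None], axis=1)[:, 0]
    voiced = (peak >= threshold) & (r0 > EPS)
    # parabolic interpolation around the integer-lag peak
    lag = best.astype(float)
    interior = (best > lag_min) & (best < lag_max)
    b = best[interior]
    rows = np.nonzero(interior)[0]
    # the biased estimator tapers as (1 - lag/flen); undo it locally so the
    # parabolic vertex is not skewed toward smaller lags
    ym1 = acn[rows, b - 1] * flen / (flen - (b - 1))
    y0 = acn[rows, b] * flen / (flen - b)
    yp1 = acn[rows, b + 1] * flen / (flen - (b + 1))
    denom = ym1 - 2 * y0 + yp1
    delta = np.where(np.abs(denom) > EPS, 0.5 * (ym1 - yp1) / denom, 0.0)
    lag[interior] = b + np.clip(delta, -0.5, 0.5)
    f0 = np.where(voiced, sr / np.maximum(lag, 1.0), 0.0)
    return np.where((f0 >= fmin) & (f0 <= fmax), f0, 0.0)


def extract_tracks(
    audio: SpeakerSliceAudio,
    sample_rate_hz: int = 16_000,
    frame_len_s: float = FRAME_LEN_S,
    hop_s: float = HOP_S,
    rolloff_percentile: float = ROLLOFF_PERCENTILE,
    n_mfcc: int = N_MFCC,
) -> FrameTracks:
    """Compute the 19 framewise tracks on a speaker's concatenated audio."""
    sr = sample_rate_hz
    flen, hop = round(frame_len_s * sr), round(hop_s * sr)
    signal = np.asarray(audio.waveform, dtype=np.float32)
    frames = _frame(signal, flen, hop)
    n = frames.shape[0]
    if n == 0:
        return FrameTracks({name: np.zeros(0) for name in TRACK_NAMES}, 0)

    window = np.hanning(flen).astype(np.float32)
    nfft = int(2 ** np.ceil(np.log2(flen)))
    spec = scipy.fft.rfft(frames * window, n=nfft, axis=1)
    power = (np.abs(spec) ** 2).astype(np.float64)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sr)

    fb = _mel_filterbank(N_MELS, nfft, sr)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, EPS))
    mfcc = scipy.fft.dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_mfcc]

    total_power = power.sum(axis=1)
    safe_total = np.where(total_power > EPS, total_power, 1.0)
    centroid = np.where(
        total_power > EPS, (power * freqs[None, :]).sum(axis=1) / safe_total, 0.0
    )
    cum = np.cumsum(power, axis=1)
    target = rolloff_percentile * total_power
    roll_idx = np.argmax(cum >= target[:, None], axis=1)
    rolloff = np.where(total_power > EPS, freqs[roll_idx], 0.0)

    pitch = _autocorr_pitch(frames, sr, PITCH_FMIN_HZ, PITCH_FMAX_HZ, VOICING_THRESHOLD)

    mean_sq = np.mean(np.square(frames), axis=1, dtype=np.float64)
    rms = np.sqrt(mean_sq)
    sign_changes = np.abs(np.diff(np.signbit(frames).astype(np.int8), axis=1)).sum(
        axis=1
    )
    zcr = sign_changes / frame_len_s
    intensity = 10.0 * np.log10(mean_sq + EPS)

    data = {f"mfcc_{i + 1:02d}": mfcc[:, i] for i in range(n_mfcc)}
    data.update(
        spectral_centroid_hz=centroid,
        spectral_rolloff_hz=rolloff,
        pitch_hz=pitch,
        rms_energy=rms,
        zero_crossing_rate=zcr.astype(float),
        intensity_db=intensity,
    )
    return FrameTracks(data, n)


def summarize_tracks(tracks: FrameTracks) -> dict[str, float]:
    """Mean/sd/min/max per track; pitch statistics use voiced frames only.

    Zero-frame input yields an all-zero summary (the caller sets the
    low-speech flag).
    """
    out: dict[str, float] = {}
    for name in TRACK_NAMES:
        values = tracks[name]
        if name == "pitch_hz":
            values = values[values > 0]
        if values.size == 0:
            stats = dict.fromkeys(STAT_NAMES, 0.0)
        else:
            stats = {
                "mean": float(values.mean()),
                "sd": float(values.std()),
                "min": float(values.min()),
                "max": float(values.max()),
            }
        for stat in STAT_NAMES:
            out[f"{name}.{stat}"] = stats[stat]
    return out


def speech_feature_columns() -> list[str]:
    return [
        f"speech.{r.value}.{t}.{s}" for r in ROLES for t in TRACK_NAMES for s in STAT_NAMES
    ]


def feature_columns() -> list[str]:
    """Canonical ordering of the 178 counted features."""
    return turn_feature_columns() + speech_feature_columns()


def flag_columns() -> list[str]:
    return [f"speech.{r.value}.low_speech_flag" for r in ROLES]


def slice_feature_vector(
    sl: Slice,
    visit: VisitRecord,
    min_overlap_s: float = 0.1,
    min_gap_s: float = 0.3,
    frame_len_s: float = FRAME_LEN_S,
    hop_s: float = HOP_S,
    rolloff_percentile: float = ROLLOFF_PERCENTILE,
    n_mfcc: int = N_MFCC,
) -> dict[str, float]:
    """The full 178-feature vector of a slice plus per-role low-speech flags.

    A role with under ``MIN_SPEECH_S`` of speech gets zeroed speech features
    and its flag set; the flags are not counted among the 178.
    """
    feats = turn_features(sl, min_overlap_s, min_gap_s)
    for role in ROLES:
        audio = concatenate_speaker_audio(sl, visit, role)
        if audio.total_speech_s < MIN_SPEECH_S:
            summary = {f"{t}.{s}": 0.0 for t in TRACK_NAMES for s in STAT_NAMES}
            flag = 1.0
        else:
            tracks = extract_tracks(
                audio,
                sample_rate_hz=visit.sample_rate_hz,
                frame_len_s=frame_len_s,
                hop_s=hop_s,
                rolloff_percentile=rolloff_percentile,
                n_mfcc=n_mfcc,
            )
            summary = summarize_tracks(tracks)
            flag = 1.0 if tracks.n_frames == 0 else 0.0
        for key, value in summary.items():
            feats[f"speech.{role.value}.{key}"] = value
        feats[f"speech.{role.value}.low_speech_flag"] = flag
    return feats
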