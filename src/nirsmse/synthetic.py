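"""Seedable synthetic fNIRS cohorts.

Each session is built from three additive components per channel:

* a neural component — power-law (``1/f^beta``) noise whose exponent encodes
  the condition-dependent complexity, with a participant-level random effect;
* systemic quasi-sinusoidal artifacts (cardiac, respiratory, Mayer waves),
  drawn with independent phase/frequency jitter per channel;
* a low-rank skin-blood-flow (SBF) component: ``sbf_rank`` latent slow
  series mixed across channels through an orthonormal spatial matrix, shared
  between the rest and task segments of a session.

Fatigue self-reports are planted with a Gaussian-copula monotone link to the
session's realized spectral exponent, so that the rank correlation between
planted complexity and fatigue approximates a per-condition target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = [
    "CHANNEL_LABELS",
    "DEFAULT_MEDIA",
    "CohortSpec",
    "NirsSession",
    "generate_colored_noise",
    "generate_systemic_artifacts",
    "generate_cohort",
]

CHANNEL_LABELS: tuple[str, ...] = ("L1", "L3", "R1", "R3")
DEFAULT_MEDIA: tuple[str, ...] = ("speaker", "video_chat", "telenoid", "face_to_face")

#: Spectral exponent of the neural component during rest (eyes closed,
#: no task drive); shared by all conditions.
REST_BETA = 1.5

#: Centre frequencies (Hz) of the systemic artifacts.
ARTIFACT_FREQS_HZ: dict[str, float] = {
    "cardiac": 1.1,
    "respiratory": 0.3,
    "mayer": 0.1,
}

# Condition exponents live on the decreasing limb of the averaged-MSE
# response under the 0.01-0.6 Hz preprocessing chain (beta up -> averaged
# MSE down), so the telenoid/face-to-face sessions come out most complex.
_DEFAULT_SPECTRAL_EXPONENTS: dict[str, float] = {
    "speaker": 1.70,
    "video_chat": 1.85,
    "telenoid": 1.50,
    "face_to_face": 1.55,
}

_DEFAULT_ARTIFACT_AMPLITUDES: dict[str, float] = {
    "cardiac": 0.25,
    "respiratory": 0.15,
    "mayer": 0.05,
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort (participants x media sessions)."""

    n_participants: int = 16
    sampling_rate_hz: float = 10.0
    rest_duration_s: float = 60.0
    task_duration_s: float = 180.0
    media: tuple[str, ...] = DEFAULT_MEDIA
    spectral_exponents: Mapping[str, float] | None = None
    artifact_amplitudes: Mapping[str, float] | None = None
    sbf_rank: int = 3
    sbf_amplitude: float = 1.0
    fatigue_link: Mapping[str, float] | None = None
    participant_effect_sd: float = 0.3
    session_noise_sd: float = 0.05
    missing_fatigue: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be > 0")
        if not (self.rest_duration_s > 0 and self.task_duration_s > 0):
            raise ValueError("durations must be > 0")
        media = tuple(self.media)
        if len(media) < 1 or len(set(media)) != len(media):
            raise ValueError("media must be a non-empty list of unique labels")
        object.__setattr__(self, "media", media)
        exps = dict(_DEFAULT_SPECTRAL_EXPONENTS if self.spectral_exponents is None
                    else self.spectral_exponents)
        link = {m: 0.0 for m in media}
        if self.fatigue_link is None:
            if "telenoid" in link:
                link["telenoid"] = -0.57
        else:
            link.update(self.fatigue_link)
        for name, mapping in (("spectral_exponents", exps), ("fatigue_link", link)):
            extra = set(mapping) - set(media)
            if extra:
                raise ValueError(f"{name} references conditions not in media: {sorted(extra)}")
        missing = set(media) - set(exps)
        if missing:
            raise ValueError(f"spectral_exponents missing conditions: {sorted(missing)}")
        for m, rho in link.items():
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"fatigue_link[{m!r}]={rho} outside [-1, 1]")
        amps = dict(_DEFAULT_ARTIFACT_AMPLITUDES if self.artifact_amplitudes is None
                    else self.artifact_amplitudes)
        unknown = set(amps) - set(ARTIFACT_FREQS_HZ)
        if unknown:
            raise ValueError(f"unknown artifact names: {sorted(unknown)}")
        if not (0 <= self.sbf_rank <= len(CHANNEL_LABELS)):
            raise ValueError(f"sbf_rank must lie in [0, {len(CHANNEL_LABELS)}]")
        if self.sbf_amplitude < 0:
            raise ValueError("sbf_amplitude must be >= 0")
        if not (0 <= self.missing_fatigue <= self.n_participants):
            raise ValueError("missing_fatigue must lie in [0, n_participants]")
        object.__setattr__(self, "spectral_exponents", exps)
        object.__setattr__(self, "fatigue_link", link)
        object.__setattr__(self, "artifact_amplitudes", amps)

    @property
    def n_rest(self) -> int:
        return int(round(self.rest_duration_s * self.sampling_rate_hz))

    @property
    def n_task(self) -> int:
        return int(round(self.task_duration_s * self.sampling_rate_hz))


@dataclass
class NirsSession:
    """One participant x medium recording (total-hemoglobin, a.u.)."""

    participant_id: str
    medium: str
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    rest: np.ndarray  # channels x n_rest
    task: np.ndarray  # channels x n_task
    fatigue_score: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rest = np.asarray(self.rest, dtype=np.float64)
        self.task = np.asarray(self.task, dtype=np.float64)
        if self.rest.ndim != 2 or self.task.ndim != 2:
            raise ValueError("rest and task must be channels x samples matrices")
        if self.rest.shape[0] != self.task.shape[0]:
            raise ValueError("rest and task must have the same channel count")
        if self.rest.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match the matrix row count")
        if self.fatigue_score is not None and not (1 <= self.fatigue_score <= 8):
            raise ValueError(f"fatigue_score {self.fatigue_score} outside [1, 8]")

    def channel(self, label: str, phase: str = "task") -> np.ndarray:
        """Return one channel's series for ``phase`` in {'rest', 'task'}."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}; have {self.channel_labels}")
        if phase not in ("rest", "task"):
            raise ValueError(f"phase must be 'rest' or 'task', got {phase!r}")
        return (self.rest if phase == "rest" else self.task)[idx]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_colored_noise(n: int, beta: float, seed) -> np.ndarray:
    """Zero-mean, unit-variance series with power spectrum ``1/f^beta``.

    Synthesized in the frequency domain with a deterministic amplitude
    spectrum and uniformly random phases, so each realization carries the
    exact target spectral exponent.
    """
    if not np.isfinite(beta) or not (0.0 <= beta <= 2.0):
        raise ValueError(f"beta must be finite and in [0, 2], got {beta}")
    n = int(n)
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = _as_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, freqs.shape[0])
    spectrum = amp * np.exp(1j * phase)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = amp[-1] * np.cos(phase[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def generate_systemic_artifacts(
    n: int,
    fs: float,
    amplitudes: Mapping[str, float],
    seed,
) -> np.ndarray:
    """Sum of amplitude-scaled quasi-sinusoids (cardiac, respiratory, Mayer).

    Each component gets a small random frequency jitter (+-5% of centre) and
    a random phase. Frequencies of active components must stay below fs/2.
    """
    n = int(n)
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if not (fs > 0):
        raise ValueError("fs must be > 0")
    unknown = set(amplitudes) - set(ARTIFACT_FREQS_HZ)
    if unknown:
        raise ValueError(f"unknown artifact names: {sorted(unknown)}")
    rng = _as_rng(seed)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for name in ("cardiac", "respiratory", "mayer"):  # fixed draw order
        centre = ARTIFACT_FREQS_HZ[name]
        # jitter and phase drawn unconditionally so the stream is identical
        # whichever amplitudes are active
        freq = centre * (1.0 + 0.05 * rng.uniform(-1.0, 1.0))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = float(amplitudes.get(name, 0.0))
        if amp == 0.0:
            continue
        if freq >= fs / 2:
            raise ValueError(
                f"{name} artifact at {freq:.3f} Hz violates the Nyquist "
                f"limit {fs / 2:.3f} Hz"
            )
        out += amp * np.sin(2.0 * np.pi * freq * t + phase)
    return out


def _orthonormal_mixing(rng: np.random.Generator, n_channels: int, rank: int) -> np.ndarray:
    if rank == 0:
        return np.zeros((n_channels, 0))
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, rank)))
    return q[:, :rank]


def _plant_fatigue(
    rng: np.random.Generator,
    complexity: np.ndarray,
    rho_target: float,
) -> np.ndarray:
    """Integer 1..8 scores with Spearman ~ rho_target against complexity."""
    n = complexity.shape[0]
    # Gaussian copula: a Pearson rho_g between normal scores yields
    # Spearman 6/pi * arcsin(rho_g/2); invert for the target.
    rho_g = 2.0 * math.sin(math.pi * rho_target / 6.0)
    z = ndtri((rankdata(complexity) - 0.5) / n)
    latent = rho_g * z + math.sqrt(max(0.0, 1.0 - rho_g**2)) * rng.standard_normal(n)
    scores = 1 + np.floor(8.0 * ndtr(latent)).astype(int)
    return np.clip(scores, 1, 8)


def _rank_z(x: np.ndarray) -> np.ndarray:
    return ndtri((rankdata(x) - 0.5) / len(x))


def _mse_anchor(sessions: Sequence[NirsSession], fallback: np.ndarray) -> np.ndarray:
    """Latent that fatigue is planted against for linked conditions.

    Blend of the trait complexity and its measured expression — the
    averaged MSE of each session under the default analysis chain — so the
    planted link targets what the downstream analysis actually observes.
    Falls back to the planted complexity alone when the sessions cannot
    support the default scale range (e.g. very short test cohorts).
    """
    import warnings as _warnings

    # imported here: the preprocessing/entropy modules sit above this one
    from .entropy import MseParams, multiscale_entropy
    from .preprocessing import FilterSpec, preprocess_session

    try:
        vals = []
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for s in sessions:
                processed = preprocess_session(s, FilterSpec(), n_components=3)
                prof = multiscale_entropy(
                    processed.channel("L3", "task"), MseParams(), channel="L3"
                )
                if not np.isfinite(prof.averaged_mse):
                    return np.asarray(fallback, dtype=float)
                vals.append(prof.averaged_mse)
        return 0.35 * _rank_z(np.asarray(fallback, dtype=float)) + 0.65 * _rank_z(np.asarray(vals))
    except (ValueError, KeyError):
        return np.asarray(fallback, dtype=float)


def generate_cohort(spec: CohortSpec) -> list[NirsSession]:
    """Generate ``n_participants x len(media)`` sessions, deterministically.

    A participant-level complexity effect (plus small session noise) shifts
    the session's spectral exponent *down* from the condition's value;
    under the default preprocessing chain the averaged MSE is monotone
    decreasing in the exponent over the operative range, so higher planted
    complexity means higher expected averaged MSE.
    ``meta['planted_complexity']`` records this latent and
    ``meta['planted_beta']`` the realized exponent.

    ``fatigue_link`` targets the Spearman correlation between *averaged
    MSE* and fatigue. For conditions with a non-zero link the scores are
    therefore planted against the sessions' measured averaged MSE (default
    analysis chain, channel L3), falling back to the planted complexity
    when sessions are too short to support the default scale range.
    """
    rng = np.random.default_rng(spec.seed)
    n_ch = len(CHANNEL_LABELS)
    n_rest, n_task = spec.n_rest, spec.n_task
    n_full = n_rest + n_task

    participant_effects = rng.standard_normal(spec.n_participants)
    missing_ids = set(
        rng.choice(spec.n_participants, size=spec.missing_fatigue, replace=False).tolist()
    )

    sessions: list[NirsSession] = []
    by_medium: dict[str, list[NirsSession]] = {m: [] for m in spec.media}
    complexity: dict[str, np.ndarray] = {m: np.empty(spec.n_participants) for m in spec.media}
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        for medium in spec.media:
            comp = (spec.participant_effect_sd * participant_effects[i]
                    + spec.session_noise_sd * rng.standard_normal())
            beta = float(np.clip(spec.spectral_exponents[medium] - comp, 0.0, 2.0))
            complexity[medium][i] = comp

            rest = np.empty((n_ch, n_rest))
            task = np.empty((n_ch, n_task))
            for c in range(n_ch):
                rest[c] = generate_colored_noise(n_rest, REST_BETA, rng)
                task[c] = generate_colored_noise(n_task, beta, rng)
                art = generate_systemic_artifacts(
                    n_full, spec.sampling_rate_hz, spec.artifact_amplitudes, rng
                )
                rest[c] += art[:n_rest]
                task[c] += art[n_rest:]
            if spec.sbf_rank > 0 and spec.sbf_amplitude > 0:
                latents = np.stack([
                    generate_colored_noise(n_full, 1.8, rng)
                    for _ in range(spec.sbf_rank)
                ])
                mixing = _orthonormal_mixing(rng, n_ch, spec.sbf_rank)
                sbf = spec.sbf_amplitude * (mixing @ latents)
                rest += sbf[:, :n_rest]
                task += sbf[:, n_rest:]

            session = NirsSession(
                participant_id=pid,
                medium=medium,
                sampling_rate_hz=spec.sampling_rate_hz,
                channel_labels=CHANNEL_LABELS,
                rest=rest,
                task=task,
                fatigue_score=None,  # filled below
                meta={"planted_complexity": comp, "planted_beta": beta},
            )
            sessions.append(session)
            by_medium[medium].append(session)

    # plant fatigue per condition; anchor on the measured averaged MSE for
    # linked conditions so the link targets what the analysis will see
    fatigue: dict[str, np.ndarray] = {}
    for medium in spec.media:
        rho = spec.fatigue_link[medium]
        anchor = complexity[medium]
        if rho != 0.0:
            anchor = _mse_anchor(by_medium[medium], fallback=anchor)
        fatigue[medium] = _plant_fatigue(rng, anchor, rho)
    for s in sessions:
        idx = int(s.participant_id[1:]) - 1
        if idx not in missing_ids:
            s.fatigue_score = int(fatigue[s.medium][idx])
    return sessions
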