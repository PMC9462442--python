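"""Synthetic dyadic sessions with controllable cross-turn coupling.

The generator emulates the structure the synchrony measures operate on —
alternating speaker turns, frame-level vocal feature matrices, word tokens —
without imitating real speech acoustics.  Coupling works at the turn-summary
level, which is exactly the across-turn dependence the measures claim to
detect:

* **vocal**: each turn's frames follow a per-feature AR(1) process with a
  turn-level mean, scale, and AR coefficient.  With coupling ``gamma`` the
  responding turn's mean/scale/AR parameters interpolate toward the
  preceding turn's realized summary (``gamma = 0`` -> fully independent
  turns; ``gamma = 1`` -> parameters copied, so consecutive turns share
  level, spread and complexity profile).
* **lexical**: each turn draws tokens from one topic's vocabulary; the
  topic persists across adjacent turns with probability ``gamma`` and
  resamples uniformly otherwise.

At ``gamma = 0`` every turn is an i.i.d. draw from one global distribution,
so within-session and cross-session pairs are exchangeable — the null the
validation protocol needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session_pipeline import SessionData
from .transcript_io import FrameFeatureMatrix, Session, Turn

__all__ = ["DyadSimConfig", "simulate_session", "simulate_cohort"]

_FRAME_HOP_S = 0.010
_FRAME_LEN_S = 0.025

_SPECTRAL_NAMES = tuple(f"mfcc{i}" for i in range(1, 16))
_PROSODIC_NAMES = ("pitch_hz", "intensity_db", "jitter", "shimmer")


@dataclass(frozen=True)
class DyadSimConfig:
    """Study-condition knobs for the simulator.

    gamma_vocal / gamma_lexical: cross-turn coupling strength in [0, 1]
        per modality (``gamma`` in the docs).
    turns_per_session: inclusive range of turn counts (>= 10 keeps every
        generated session eligible for aggregation).
    frames_per_turn: inclusive range of frames per turn (120-240 frames at
        a 10 ms hop, i.e. 1.2-2.4 s turns — typical conversational
        exchanges, and long enough for stable sample-entropy estimates).
    tokens_per_turn: inclusive range of word counts per turn.
    n_topics / words_per_topic: lexical topic structure; adjacent same-topic
        turns share vocabulary, which is what WMD picks up.
    group_effect: downward shift of both couplings in the "case" group of a
        simulated cohort (cases are the less-synchronous group).
    """

    n_sessions: int = 20
    turns_per_session: tuple[int, int] = (12, 20)
    frames_per_turn: tuple[int, int] = (120, 240)
    tokens_per_turn: tuple[int, int] = (4, 12)
    d_spectral: int = 15
    d_prosodic: int = 4
    gamma_vocal: float = 0.0
    gamma_lexical: float = 0.0
    n_topics: int = 8
    words_per_topic: int = 12
    mean_sd: float = 1.0
    log_scale_sd: float = 0.3
    ar_range: tuple[float, float] = (0.05, 0.95)
    group_labels: tuple[str, str] = ("ASD", "non-ASD")
    group_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (self.gamma_vocal, self.gamma_lexical):
            if not 0.0 <= g <= 1.0:
                raise ValueError("coupling gamma must lie in [0, 1]")
        if self.group_effect < 0:
            raise ValueError("group_effect must be >= 0")
        if self.turns_per_session[0] < 2:
            raise ValueError("need at least 2 turns per session")

    @property
    def d_total(self) -> int:
        return self.d_spectral + self.d_prosodic

    def vocab(self) -> list[list[str]]:
        return [
            [f"w{t}_{i}" for i in range(self.words_per_topic)]
            for t in range(self.n_topics)
        ]


def _turn_params(cfg: DyadSimConfig, rng: np.random.Generator):
    """Independent draw of one turn's (mean, log-scale, AR coef) vectors."""
    d = cfg.d_total
    mu = rng.normal(0.0, cfg.mean_sd, size=d)
    log_s = rng.normal(0.0, cfg.log_scale_sd, size=d)
    phi = rng.uniform(*cfg.ar_range, size=d)
    return mu, log_s, phi


def _ar1_frames(mu, log_s, phi, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) frames: x_k = mu + s * z_k, z_k = phi z_{k-1} + e."""
    d = len(mu)
    innov_sd = np.sqrt(1.0 - phi**2)
    z = np.empty((n_frames, d))
    z[0] = rng.standard_normal(d)
    eps = rng.standard_normal((n_frames - 1, d)) if n_frames > 1 else None
    for k in range(1, n_frames):
        z[k] = phi * z[k - 1] + innov_sd * eps[k - 1]
    return mu + np.exp(log_s) * z


def simulate_session(
    cfg: DyadSimConfig,
    rng: np.random.Generator | None = None,
    session_id: str = "sim0",
    label: str | None = None,
    covariates: dict | None = None,
) -> SessionData:
    """One alternating-speaker session with coupled turn dynamics.

    Speaker roles alternate A, B, A, ...  Every turn after the first
    interpolates its feature-process parameters toward the *realized*
    summary (empirical mean, empirical log-std, generating AR coefficient)
    of the preceding turn with weight ``gamma_vocal``, and keeps the
    preceding topic with probability ``gamma_lexical``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_turns = int(rng.integers(cfg.turns_per_session[0], cfg.turns_per_session[1] + 1))
    vocab = cfg.vocab()

    turns: list[Turn] = []
    features: dict[int, dict[str, FrameFeatureMatrix]] = {}
    t_clock = 0.0
    prev_summary = None  # (emp_mean, emp_log_std, phi) of previous turn
    topic = int(rng.integers(cfg.n_topics))

    for k in range(n_turns):
        speaker = "AB"[k % 2]
        mu, log_s, phi = _turn_params(cfg, rng)
        if prev_summary is not None and cfg.gamma_vocal > 0:
            g = cfg.gamma_vocal
            mu = (1 - g) * mu + g * prev_summary[0]
            log_s = (1 - g) * log_s + g * prev_summary[1]
            phi = (1 - g) * phi + g * prev_summary[2]
        n_frames = int(rng.integers(cfg.frames_per_turn[0], cfg.frames_per_turn[1] + 1))
        frames = _ar1_frames(mu, log_s, phi, n_frames, rng)
        prev_summary = (
            frames.mean(axis=0),
            np.log(np.maximum(frames.std(axis=0), 1e-8)),
            phi,
        )

        if k > 0 and rng.random() >= cfg.gamma_lexical:
            topic = int(rng.integers(cfg.n_topics))
        n_tok = int(rng.integers(cfg.tokens_per_turn[0], cfg.tokens_per_turn[1] + 1))
        tokens = tuple(vocab[topic][i] for i in rng.integers(cfg.words_per_topic, size=n_tok))

        dur = n_frames * _FRAME_HOP_S + _FRAME_LEN_S
        turns.append(
            Turn(
                session_id=session_id,
                turn_index=k,
                speaker=speaker,
                start_s=round(t_clock, 4),
                end_s=round(t_clock + dur, 4),
                tokens=tokens,
            )
        )
        t_clock += dur + float(rng.uniform(0.1, 0.5))

        features[k] = {
            "spectral": FrameFeatureMatrix(
                frames[:, : cfg.d_spectral], _SPECTRAL_NAMES[: cfg.d_spectral],
                _FRAME_HOP_S, _FRAME_LEN_S,
            ),
            "prosodic": FrameFeatureMatrix(
                frames[:, cfg.d_spectral :], _PROSODIC_NAMES[: cfg.d_prosodic],
                _FRAME_HOP_S, _FRAME_LEN_S,
            ),
        }

    covs = dict(covariates or {})
    covs.setdefault(
        "speaker_ids", {"A": f"{session_id}:child", "B": f"{session_id}:clinician"}
    )
    session = Session(session_id=session_id, turns=tuple(turns), label=label, covariates=covs)
    return SessionData(session=session, features=features)


def _age_group(age: float) -> str:
    if age < 7.5:
        return "2.5-7.5"
    if age < 10.0:
        return "7.5-10"
    return ">=10"


def simulate_cohort(
    cfg: DyadSimConfig,
    n_per_group: tuple[int, int] | None = None,
) -> list[SessionData]:
    """Two labeled groups whose coupling differs by ``group_effect``.

    The first (case) group's vocal and lexical couplings are the config
    values minus ``group_effect`` (clipped to [0, 1]); the second (control)
    group uses the config values as-is.  Covariates: ``age_years`` uniform
    over 3.5-13 y, ``age_group`` derived, ``gender`` ~ 75% male (the
    skew typical of clinic-referred cohorts), ``subtask`` alternating.
    """
    n_case, n_ctrl = n_per_group or (cfg.n_sessions // 2, cfg.n_sessions - cfg.n_sessions // 2)
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("each group needs at least one session")
    rng = np.random.default_rng(cfg.seed)
    out: list[SessionData] = []
    specs = [(cfg.group_labels[0], n_case, True), (cfg.group_labels[1], n_ctrl, False)]
    i = 0
    for label, count, shifted in specs:
        gcfg = cfg
        if shifted and cfg.group_effect > 0:
            gcfg = replace(
                cfg,
                gamma_vocal=float(np.clip(cfg.gamma_vocal - cfg.group_effect, 0, 1)),
                gamma_lexical=float(np.clip(cfg.gamma_lexical - cfg.group_effect, 0, 1)),
            )
        for _ in range(count):
            age = float(rng.uniform(3.5, 13.0))
            covs = {
                "age_years": round(age, 2),
                "age_group": _age_group(age),
                "gender": "male" if rng.random() < 0.75 else "female",
                "subtask": ("emotions", "social")[i % 2],
            }
            out.append(
                simulate_session(gcfg, rng, session_id=f"sim{i:03d}", label=label, covariates=covs)
            )
            i += 1
    return out
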