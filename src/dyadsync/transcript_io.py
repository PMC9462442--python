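"""Turn/session data model and transcript / feature-matrix I/O.

The native transcript format is a minimal TSV with columns
``session_id, speaker, start_s, end_s, text`` (times in seconds, half-open
intervals ``[start_s, end_s)``).  JSON (a list of row objects with the same
keys) and NIST RTTM (``SPEAKER`` rows, token-less turns) are also accepted.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Turn",
    "Session",
    "FrameFeatureMatrix",
    "TranscriptParseError",
    "read_transcript",
    "write_transcript",
    "read_feature_csv",
    "write_feature_csv",
    "merge_adjacent_same_speaker",
    "tokenize",
]

SPEAKERS = ("A", "B")

_PUNCT = string.punctuation


class TranscriptParseError(ValueError):
    """Raised when a transcript or feature file cannot be parsed."""


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip leading/trailing punctuation.

    Tokens that are pure punctuation vanish; the deterministic rule keeps
    the pipeline independent of any embedding backend's own tokenizer.
    """
    out = []
    for raw in text.lower().split():
        tok = raw.strip(_PUNCT)
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class Turn:
    """One speaker's maximal contiguous utterance.

    ``speaker`` is the dyad role ("A" or "B"; e.g. child/clinician).
    ``audio_ref`` optionally points at ``path`` or ``path:channel``.
    """

    session_id: str
    turn_index: int
    speaker: str
    start_s: float
    end_s: float
    tokens: tuple[str, ...] = ()
    audio_ref: str | None = None

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise ValueError(f"speaker must be one of {SPEAKERS}, got {self.speaker!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"turn {self.turn_index} of {self.session_id}: "
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Session:
    """An ordered sequence of turns from one dyadic interaction."""

    session_id: str
    turns: tuple[Turn, ...]
    label: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        turns = tuple(self.turns)
        if not turns:
            raise ValueError(f"session {self.session_id!r} has no turns")
        for t in turns:
            if t.session_id != self.session_id:
                raise ValueError(
                    f"turn {t.turn_index} belongs to {t.session_id!r}, "
                    f"not {self.session_id!r}"
                )
        idx = [t.turn_index for t in turns]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"session {self.session_id!r}: turn_index must strictly increase")
        object.__setattr__(self, "turns", turns)

    @property
    def n_turns(self) -> int:
        return len(self.turns)

    def speaker_ids(self) -> frozenset:
        """Real-world identities behind roles A/B, for disjointness checks.

        Defaults to session-scoped identities when the ``speaker_ids``
        covariate is absent, so distinct sessions are assumed to involve
        distinct people unless stated otherwise.
        """
        ids = self.covariates.get("speaker_ids")
        if ids:
            return frozenset(ids.values())
        return frozenset(f"{self.session_id}:{s}" for s in SPEAKERS)


@dataclass(frozen=True)
class FrameFeatureMatrix:
    """T x d frame-level feature time series with frame-rate metadata."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    frame_hop_s: float = 0.010
    frame_len_s: float = 0.025

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"feature matrix must be T x d with T,d >= 1, got shape {v.shape}")
        names = tuple(self.feature_names)
        if len(names) != v.shape[1]:
            raise ValueError(
                f"{len(names)} feature names for {v.shape[1]} columns"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# transcript reading
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["session_id", "speaker", "start_s", "end_s", "text"]


def _rows_to_session(rows: list[dict], origin: str) -> Session:
    if not rows:
        raise TranscriptParseError(f"{origin}: no turns")
    session_ids = {r["session_id"] for r in rows}
    if len(session_ids) != 1:
        raise TranscriptParseError(
            f"{origin}: expected a single session, found {sorted(session_ids)}"
        )
    rows = sorted(rows, key=lambda r: (r["start_s"], r["end_s"]))
    # overlapping same-speaker rows indicate a malformed transcript
    last_end: dict[str, float] = {}
    for r in rows:
        sp = r["speaker"]
        if sp in last_end and r["start_s"] < last_end[sp] - 1e-9:
            raise TranscriptParseError(
                f"{origin}: overlapping rows for speaker {sp} at t={r['start_s']}"
            )
        last_end[sp] = r["end_s"]
    turns = tuple(
        Turn(
            session_id=r["session_id"],
            turn_index=i,
            speaker=r["speaker"],
            start_s=r["start_s"],
            end_s=r["end_s"],
            tokens=tuple(tokenize(r.get("text", "") or "")),
            audio_ref=r.get("audio_ref"),
        )
        for i, r in enumerate(rows)
    )
    return Session(session_id=rows[0]["session_id"], turns=turns)


def _parse_tsv(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise TranscriptParseError(f"{path}: no turns")
        cols = header.rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS if c not in cols]
        if missing:
            raise TranscriptParseError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(cols):
                parts += [""] * (len(cols) - len(parts))
            rec = dict(zip(cols, parts))
            try:
                rows.append(
                    {
                        "session_id": rec["session_id"],
                        "speaker": rec["speaker"],
                        "start_s": float(rec["start_s"]),
                        "end_s": float(rec["end_s"]),
                        "text": rec.get("text", ""),
                        "audio_ref": rec.get("audio_ref") or None,
                    }
                )
            except (KeyError, ValueError) as exc:
                raise TranscriptParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return rows


def _parse_json(path: Path) -> list[dict]:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TranscriptParseError(f"{path}: invalid JSON ({exc})") from exc
    if isinstance(data, dict) and "turns" in data:
        data = data["turns"]
    if not isinstance(data, list):
        raise TranscriptParseError(f"{path}: expected a list of turn objects")
    rows = []
    for i, rec in enumerate(data):
        try:
            rows.append(
                {
                    "session_id": str(rec["session_id"]),
                    "speaker": str(rec["speaker"]),
                    "start_s": float(rec["start_s"]),
                    "end_s": float(rec["end_s"]),
                    "text": rec.get("text", ""),
                    "audio_ref": rec.get("audio_ref"),
                }
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise TranscriptParseError(f"{path}: turn {i}: malformed ({exc})") from exc
    return rows


def _parse_rttm(path: Path) -> list[dict]:
    """NIST RTTM: ``SPEAKER file chan onset dur <NA> <NA> name <NA> [<NA>]``.

    Speaker names are mapped to roles A/B in order of first appearance;
    turns are token-less (RTTM carries no words).
    """
    rows = []
    role: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(";"):
                continue
            parts = line.split()
            if parts[0] != "SPEAKER":
                continue
            if len(parts) < 8:
                raise TranscriptParseError(f"{path}:{lineno}: malformed RTTM row")
            try:
                onset, dur = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise TranscriptParseError(f"{path}:{lineno}: malformed RTTM row ({exc})") from exc
            name = parts[7]
            if name not in role:
                if len(role) >= 2:
                    raise TranscriptParseError(
                        f"{path}:{lineno}: more than two speakers ({name!r})"
                    )
                role[name] = SPEAKERS[len(role)]
            rows.append(
                {
                    "session_id": parts[1],
                    "speaker": role[name],
                    "start_s": onset,
                    "end_s": onset + dur,
                    "text": "",
                    "audio_ref": None,
                }
            )
    return rows


_DIALECTS = {"tsv": _parse_tsv, "json": _parse_json, "rttm": _parse_rttm}


def read_transcript(path, dialect: str | None = None) -> Session:
    """Read a single-session transcript into a :class:`Session`.

    ``dialect`` is one of ``tsv``/``json``/``rttm``; inferred from the file
    suffix when omitted.  Turns come back sorted by onset with whitespace
    tokenization applied (see :func:`tokenize`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {".tsv": "tsv", ".json": "json", ".rttm": "rttm"}.get(path.suffix.lower())
        if dialect is None:
            raise TranscriptParseError(f"{path}: cannot infer dialect from suffix")
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _rows_to_session(_DIALECTS[dialect](path), str(path))


def write_transcript(session: Session, path) -> None:
    """Write a Session in the native TSV dialect (round-trips with read)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS + ["audio_ref"]) + "\n")
        for t in session.turns:
            fh.write(
                "\t".join(
                    [
                        t.session_id,
                        t.speaker,
                        repr(t.start_s),
                        repr(t.end_s),
                        " ".join(t.tokens),
                        t.audio_ref or "",
                    ]
                )
                + "\n"
            )


def merge_adjacent_same_speaker(session: Session) -> Session:
    """Concatenate consecutive same-speaker turns so speakers alternate.

    Tokens are appended and the time span unioned.  Idempotent; a session
    that already alternates is returned unchanged in content.
    """
    merged: list[Turn] = []
    for t in session.turns:
        if merged and merged[-1].speaker == t.speaker:
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end_s=max(prev.end_s, t.end_s),
                tokens=prev.tokens + t.tokens,
            )
        else:
            merged.append(t)
    turns = tuple(replace(t, turn_index=i) for i, t in enumerate(merged))
    return replace(session, turns=turns)


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------


def read_feature_csv(
    path,
    frame_hop_s: float = 0.010,
    frame_len_s: float = 0.025,
    allow_nan: bool = False,
) -> FrameFeatureMatrix:
    """Read a T x d feature matrix from CSV (one header row of names)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TranscriptParseError(f"{path}: empty matrix") from exc
    if df.shape[0] == 0:
        raise TranscriptParseError(f"{path}: empty matrix")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise TranscriptParseError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any() and not allow_nan:
        r, c = map(int, np.argwhere(np.isnan(values))[0])
        raise TranscriptParseError(
            f"{path}: NaN at row {r + 2}, column {df.columns[c]!r} (pass allow_nan to accept)"
        )
    return FrameFeatureMatrix(
        values=values,
        feature_names=tuple(str(c) for c in df.columns),
        frame_hop_s=frame_hop_s,
        frame_len_s=frame_len_s,
    )


def write_feature_csv(mat: FrameFeatureMatrix, path) -> None:
    pd.DataFrame(mat.values, columns=list(mat.feature_names)).to_csv(path, index=False)
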