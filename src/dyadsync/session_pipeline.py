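"""Turn pairing, eligibility filtering, and per-session feature assembly.

The unit of synchrony computation is the *turn-pair*: two consecutive turns
by different speakers.  Per pair, five measures are computed —
``dtwd_spectral``, ``scdc_spectral``, ``dtwd_prosodic``, ``scdc_prosodic``
(vocal) and ``wmd`` (lexical) — all oriented so larger = less synchronous.
Pairs are then collected into N contiguous segments and each segment's
per-measure mean forms the session's classification features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexical_synchrony import EmbeddingProvider, embed_turn, wmd
from .transcript_io import FrameFeatureMatrix, Session, Turn
from .vocal_synchrony import (
    SampEnConfig,
    complexity_vector,
    dtw_distance,
    scdc,
    znormalize,
)

__all__ = [
    "MEASURES",
    "STREAMS",
    "TurnPair",
    "SynchronyRecord",
    "SessionFeatures",
    "SessionData",
    "PipelineConfig",
    "make_turn_pairs",
    "filter_sessions",
    "compute_pair_records",
    "aggregate_segments",
    "build_session_features",
    "features_frame",
]

logger = logging.getLogger(__name__)

STREAMS = ("spectral", "prosodic")
MEASURES = ("dtwd_spectral", "scdc_spectral", "dtwd_prosodic", "scdc_prosodic", "wmd")

MIN_TURNS = 10  # sessions with fewer turns carry too little signal to aggregate


@dataclass(frozen=True)
class TurnPair:
    """Two turns compared by the synchrony measures.

    ``regular`` pairs are adjacent cross-speaker turns of one session;
    ``random`` pairs draw their turns from two different sessions with
    disjoint speakers (the validation control).
    """

    session_id: str
    pair_index: int
    turn_a: Turn
    turn_b: Turn
    kind: str = "regular"

    def __post_init__(self) -> None:
        if self.kind not in ("regular", "random"):
            raise ValueError(f"kind must be regular|random, got {self.kind!r}")
        if self.kind == "regular" and self.turn_a.speaker == self.turn_b.speaker:
            raise ValueError("regular pair must span two speakers")


@dataclass(frozen=True)
class SynchronyRecord:
    session_id: str
    pair_index: int
    measure: str
    value: float
    valid: bool
    kind: str = "regular"


@dataclass(frozen=True)
class SessionFeatures:
    """N-segment x M-measure mean matrix plus label and covariates."""

    session_id: str
    segment_means: np.ndarray  # (N, M)
    measures: tuple[str, ...]
    label: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sm = np.asarray(self.segment_means, dtype=float)
        if sm.ndim != 2 or sm.shape[1] != len(self.measures):
            raise ValueError("segment_means must be N x len(measures)")
        if not np.isfinite(sm).all():
            raise ValueError(f"session {self.session_id}: non-finite segment means")
        object.__setattr__(self, "segment_means", sm)

    def vector(self, measure_subset: tuple[str, ...] | None = None) -> np.ndarray:
        """Flattened feature vector, optionally restricted to some measures."""
        if measure_subset is None:
            return self.segment_means.ravel(order="F")
        cols = [self.measures.index(m) for m in measure_subset]
        return self.segment_means[:, cols].ravel(order="F")


@dataclass
class SessionData:
    """A session plus its per-turn feature matrices, keyed by turn_index."""

    session: Session
    features: dict[int, dict[str, FrameFeatureMatrix]]

    @property
    def session_id(self) -> str:
        return self.session.session_id


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the measure-computation stage.

    normalize_dtw: divide DTW cost by optimal path length (on by default;
        raw cost grows with turn length, confounding synchrony with
        verbosity).
    znorm_features: z-score each turn's features with its session-and-
        speaker statistics before DTW.
    n_segments: number of contiguous pair blocks per session.
    """

    sampen: SampEnConfig = field(default_factory=SampEnConfig)
    normalize_dtw: bool = True
    znorm_features: bool = True
    n_segments: int = 5


def make_turn_pairs(session: Session) -> list[TurnPair]:
    """Adjacent cross-speaker pairs (k, k+1); count = n_turns - 1.

    Both directions of initiation are included (A->B and B->A pairs).
    The session must already alternate speakers (see
    :func:`dyadsync.transcript_io.merge_adjacent_same_speaker`).
    """
    turns = session.turns
    return [
        TurnPair(session.session_id, k, turns[k], turns[k + 1])
        for k in range(len(turns) - 1)
    ]


def filter_sessions(sessions: list[Session], min_turns: int = MIN_TURNS) -> list[Session]:
    """Drop sessions with fewer than ``min_turns`` turns."""
    kept = [s for s in sessions if s.n_turns >= min_turns]
    dropped = len(sessions) - len(kept)
    if dropped:
        logger.info("discarded %d/%d sessions with < %d turns", dropped, len(sessions), min_turns)
    if not kept:
        raise ValueError("no eligible sessions")
    return kept


def _speaker_stats(sd: SessionData) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Per (speaker, stream) feature mean/std over the whole session."""
    stats = {}
    for stream in STREAMS:
        for speaker in ("A", "B"):
            blocks = [
                sd.features[t.turn_index][stream].values
                for t in sd.session.turns
                if t.speaker == speaker and stream in sd.features.get(t.turn_index, {})
            ]
            if blocks:
                cat = np.concatenate(blocks, axis=0)
                stats[(speaker, stream)] = (cat.mean(axis=0), cat.std(axis=0))
    return stats


def compute_pair_records(
    pairs: list[TurnPair],
    data: dict[str, SessionData],
    provider: EmbeddingProvider | None = None,
    cfg: PipelineConfig | None = None,
) -> list[SynchronyRecord]:
    """Compute all five measures for each turn-pair.

    ``data`` maps session_id -> SessionData and must cover every session a
    pair's turns come from (random pairs span two).  Pairs whose value is
    undefined for a measure (too-short series for sample entropy, empty
    token list for WMD, zero-norm complexity vector) yield invalid records
    that downstream aggregation excludes.
    """
    cfg = cfg or PipelineConfig()
    stats_cache: dict[str, dict] = {}
    cv_cache: dict[tuple[str, int, str], object] = {}

    def turn_matrix(turn: Turn, stream: str) -> np.ndarray | None:
        sd = data.get(turn.session_id)
        if sd is None:
            raise KeyError(f"no feature data for session {turn.session_id!r}")
        mat = sd.features.get(turn.turn_index, {}).get(stream)
        if mat is None:
            return None
        values = mat.values
        if cfg.znorm_features:
            if turn.session_id not in stats_cache:
                stats_cache[turn.session_id] = _speaker_stats(sd)
            st = stats_cache[turn.session_id].get((turn.speaker, stream))
            if st is not None:
                values = znormalize(values, *st)
        return values

    records: list[SynchronyRecord] = []

    def add(pair: TurnPair, measure: str, value: float | None) -> None:
        ok = value is not None and np.isfinite(value)
        records.append(
            SynchronyRecord(
                pair.session_id, pair.pair_index, measure,
                float(value) if ok else np.nan, bool(ok), pair.kind,
            )
        )

    for pair in pairs:
        for stream in STREAMS:
            xa = turn_matrix(pair.turn_a, stream)
            xb = turn_matrix(pair.turn_b, stream)
            if xa is None or xb is None:
                add(pair, f"dtwd_{stream}", None)
                add(pair, f"scdc_{stream}", None)
                continue
            add(pair, f"dtwd_{stream}", dtw_distance(xa, xb, cfg.normalize_dtw).distance)

            def cvec(turn: Turn, values: np.ndarray):
                key = (turn.session_id, turn.turn_index, stream)
                if key not in cv_cache:
                    try:
                        cv_cache[key] = complexity_vector(values, cfg.sampen)
                    except ValueError:
                        cv_cache[key] = None
                return cv_cache[key]

            ca, cb = cvec(pair.turn_a, xa), cvec(pair.turn_b, xb)
            res = scdc(ca, cb) if ca is not None and cb is not None else None
            add(pair, f"scdc_{stream}", res.distance if res else None)
        if provider is not None:
            if pair.turn_a.tokens and pair.turn_b.tokens:
                e1 = embed_turn(pair.turn_a.tokens, provider)
                e2 = embed_turn(pair.turn_b.tokens, provider)
                add(pair, "wmd", wmd(e1, e2).distance)
            else:
                add(pair, "wmd", None)
    return records


def _segment_sizes(n_pairs: int, n_segments: int) -> list[int]:
    q, r = divmod(n_pairs, n_segments)
    return [q + 1] * r + [q] * (n_segments - r)


def aggregate_segments(
    records: list[SynchronyRecord],
    n_segments: int,
    session: Session | None = None,
) -> SessionFeatures:
    """Collect one session's pair records into N contiguous segment means.

    Pairs are split by pair count into near-equal blocks (earlier blocks
    absorb the remainder); each block's per-measure mean is taken over the
    valid records only.  Errors if the session has fewer pairs than
    segments or some segment ends up with no valid value for a measure.
    """
    if not records:
        raise ValueError("no records to aggregate")
    session_ids = {r.session_id for r in records}
    if len(session_ids) != 1:
        raise ValueError(f"records span multiple sessions: {sorted(session_ids)}")
    sid = records[0].session_id
    measures = tuple(m for m in MEASURES if any(r.measure == m for r in records))
    pair_order = sorted({r.pair_index for r in records})
    n_valid = {m: sum(r.valid for r in records if r.measure == m) for m in measures}
    if any(v < n_segments for v in n_valid.values()):
        worst = min(n_valid, key=n_valid.get)
        raise ValueError(
            f"session {sid}: only {n_valid[worst]} valid {worst} pairs "
            f"for {n_segments} segments"
        )
    sizes = _segment_sizes(len(pair_order), n_segments)
    seg_of_pair: dict[int, int] = {}
    pos = 0
    for seg, size in enumerate(sizes):
        for p in pair_order[pos : pos + size]:
            seg_of_pair[p] = seg
        pos += size

    sums = np.zeros((n_segments, len(measures)))
    counts = np.zeros((n_segments, len(measures)))
    mcol = {m: j for j, m in enumerate(measures)}
    for r in records:
        if r.valid and r.measure in mcol:
            sums[seg_of_pair[r.pair_index], mcol[r.measure]] += r.value
            counts[seg_of_pair[r.pair_index], mcol[r.measure]] += 1
    if (counts == 0).any():
        seg, j = map(int, np.argwhere(counts == 0)[0])
        raise ValueError(f"session {sid}: segment {seg} has no valid {measures[j]} value")
    return SessionFeatures(
        session_id=sid,
        segment_means=sums / counts,
        measures=measures,
        label=session.label if session else None,
        covariates=dict(session.covariates) if session else {},
    )


def build_session_features(
    cohort: list[SessionData],
    provider: EmbeddingProvider | None = None,
    cfg: PipelineConfig | None = None,
) -> list[SessionFeatures]:
    """End-to-end per-session features for a cohort of SessionData."""
    cfg = cfg or PipelineConfig()
    data = {sd.session_id: sd for sd in cohort}
    out = []
    for sd in cohort:
        pairs = make_turn_pairs(sd.session)
        records = compute_pair_records(pairs, data, provider, cfg)
        out.append(aggregate_segments(records, cfg.n_segments, sd.session))
    return out


def features_frame(features: list[SessionFeatures]) -> pd.DataFrame:
    """One row per session: id, label, covariates, then seg{k}_{measure}."""
    rows = []
    for sf in features:
        row: dict = {"session_id": sf.session_id, "label": sf.label}
        for key, val in sf.covariates.items():
            if key != "speaker_ids":
                row[key] = val
        for j, m in enumerate(sf.measures):
            for k in range(sf.segment_means.shape[0]):
                row[f"seg{k + 1}_{m}"] = sf.segment_means[k, j]
        rows.append(row)
    return pd.DataFrame(rows)
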