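"""Regular-vs-random turn-pair validation of the synchrony measures.

A measure that captures real coordination should score adjacent turn-pairs
from one interaction (*regular*) as more synchronous than pairs assembled
from two different interactions with no shared speakers (*random*).  The
protocol builds equal-length lists of regular and random pair values,
pairs them by index, and runs a two-sided paired t-test per measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .lexical_synchrony import EmbeddingProvider
from .session_pipeline import (
    MEASURES,
    PipelineConfig,
    SessionData,
    SynchronyRecord,
    TurnPair,
    compute_pair_records,
    make_turn_pairs,
)
from .transcript_io import Session

__all__ = [
    "PairedValidationResult",
    "make_random_pairs",
    "paired_test",
    "run_validation",
    "null_calibration",
]


@dataclass(frozen=True)
class PairedValidationResult:
    measure: str
    n_pairs: int
    mean_regular: float
    mean_random: float
    statistic: float
    p_value: float
    direction_ok: bool


def make_random_pairs(
    sessions: list[Session],
    n: int,
    seed: int,
    length_matched: bool = False,
) -> list[TurnPair]:
    """Draw ``n`` cross-session turn-pairs with disjoint speakers.

    Each pair picks two different sessions whose speaker identities do not
    overlap, then one turn from each, uniformly.  With ``length_matched``
    the second turn is the candidate whose duration is closest to the
    first's (a sensitivity-analysis option; off by default).  Reproducible
    under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [s.speaker_ids() for s in sessions]
    legal = [
        (i, j)
        for i in range(len(sessions))
        for j in range(len(sessions))
        if i != j and not (ids[i] & ids[j])
    ]
    if n > 0 and not legal:
        raise ValueError("no two sessions with disjoint speakers available")
    pairs: list[TurnPair] = []
    for k in range(n):
        i, j = legal[int(rng.integers(len(legal)))]
        ta = sessions[i].turns[int(rng.integers(sessions[i].n_turns))]
        cand = sessions[j].turns
        if length_matched:
            durs = np.array([abs(t.duration_s - ta.duration_s) for t in cand])
            tb = cand[int(np.argmin(durs))]
        else:
            tb = cand[int(rng.integers(len(cand)))]
        pairs.append(TurnPair("random", k, ta, tb, kind="random"))
    return pairs


def paired_test(
    regular_values: np.ndarray,
    random_values: np.ndarray,
    measure: str = "",
) -> PairedValidationResult:
    """Two-sided paired t-test on index-matched regular/random values.

    ``direction_ok`` is True when mean(regular) < mean(random), i.e. real
    pairs look more synchronous under a distance-type measure.  Errors on
    unequal lengths, k < 2, non-finite values, or zero-variance
    differences (degenerate paired sample).
    """
    reg = np.asarray(regular_values, dtype=float).ravel()
    ran = np.asarray(random_values, dtype=float).ravel()
    if reg.shape != ran.shape:
        raise ValueError("regular and random value lists must have equal length")
    if len(reg) < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.isfinite(reg).all() and np.isfinite(ran).all()):
        raise ValueError("paired test requires finite values")
    diffs = reg - ran
    if np.std(diffs) == 0.0:
        raise ValueError("degenerate paired sample: zero-variance differences")
    t, p = scipy.stats.ttest_rel(reg, ran)
    return PairedValidationResult(
        measure=measure,
        n_pairs=len(reg),
        mean_regular=float(reg.mean()),
        mean_random=float(ran.mean()),
        statistic=float(t),
        p_value=float(p),
        direction_ok=bool(reg.mean() < ran.mean()),
    )


def null_calibration(
    n_replicates: int = 1000,
    k: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the paired test under the null.

    Draws ``n_replicates`` independent pairs of k-vectors from one common
    distribution (lognormal, mimicking the right-skewed shape of distance
    values) and reports the fraction of replicates rejected at ``alpha``.
    A calibrated test lands near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        reg = rng.lognormal(0.0, 0.5, size=k)
        ran = rng.lognormal(0.0, 0.5, size=k)
        if paired_test(reg, ran).p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def _values_by_measure(records: list[SynchronyRecord]) -> dict[str, list[tuple[int, float]]]:
    out: dict[str, list[tuple[int, float]]] = {}
    for r in records:
        if r.valid:
            out.setdefault(r.measure, []).append((r.pair_index, r.value))
    return out


def run_validation(
    cohort: list[SessionData],
    n_pairs: int,
    seed: int,
    provider: EmbeddingProvider | None = None,
    cfg: PipelineConfig | None = None,
    length_matched: bool = False,
) -> dict[str, PairedValidationResult]:
    """Full protocol on a cohort: one paired test per available measure.

    Collects all regular pairs of the cohort and ``n_pairs`` random
    cross-session pairs, computes every measure on both, subsamples each
    measure's value lists to a common length k (seeded), pairs them by
    index, and tests.
    """
    cfg = cfg or PipelineConfig()
    data = {sd.session_id: sd for sd in cohort}
    sessions = [sd.session for sd in cohort]

    regular = [p for sd in cohort for p in make_turn_pairs(sd.session)]
    random_pairs = make_random_pairs(sessions, n_pairs, seed, length_matched)
    reg_records = compute_pair_records(regular, data, provider, cfg)
    ran_records = compute_pair_records(random_pairs, data, provider, cfg)

    reg_vals = _values_by_measure(reg_records)
    # regular pairs share pair_index across sessions; re-key sequentially
    ran_vals = _values_by_measure(ran_records)
    rng = np.random.default_rng(seed + 1)
    results: dict[str, PairedValidationResult] = {}
    for measure in MEASURES:
        if measure == "wmd" and provider is None:
            continue
        reg = np.array([v for _, v in reg_vals.get(measure, [])])
        ran = np.array([v for _, v in ran_vals.get(measure, [])])
        k = min(len(reg), len(ran))
        if k < 2:
            continue
        reg = reg[rng.choice(len(reg), size=k, replace=False)] if len(reg) > k else reg
        ran = ran[rng.choice(len(ran), size=k, replace=False)] if len(ran) > k else ran
        results[measure] = paired_test(reg, ran, measure=measure)
    return results
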