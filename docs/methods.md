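# Methods

## The measurement model

All three synchrony measures operate on the *turn-pair*: two consecutive
maximal utterances by the two speakers of a dyad. A session is first merged
so adjacent same-speaker segments become one turn (back-channels are thus
absorbed into the surrounding turn — a modeling choice, since transcription
conventions differ on whether they count as turns), giving a strictly
alternating A/B sequence; pair k is (turn k, turn k+1), so an n-turn session
yields n−1 pairs covering both directions of initiation. Sessions with fewer
than 10 turns are discarded: turn-level measures are noisy and need enough
pairs to average out local irregularities.

### DTW distance (vocal)

Classic dynamic time warping with steps {(1,0), (0,1), (1,1)}, no band
constraint and no slope weights; local cost is the Euclidean distance
between frame vectors. Two deliberate additions to the textbook recipe:

* **Path-length normalization (default on).** Raw cumulative cost grows
  with turn length, so longer turns would look less synchronous purely by
  being longer. We divide by the optimal path length H (backtracking breaks
  ties diagonal-first, then toward the X axis — any fixed rule works, it
  only needs to be deterministic). Raw cost remains available.
* **Per-session, per-speaker z-normalization (default on).** Features on
  physical scales (pitch in Hz vs jitter in ratios) would otherwise
  dominate the Euclidean cost. Each turn's matrix is standardized against
  the statistics of all of that speaker's frames in that session, so
  within-session contrasts are preserved while scales equalize.

### Sample-entropy complexity cosine (vocal)

Sample entropy S_e = −ln(E_{m+1}(r)/E_m(r)) with m = 2 and
r = 0.25 × the population standard deviation of the individual series.
Conventions, fixed once and mirrored exactly by the brute-force oracle in
the tests: ordered template pairs i ≠ j; strict Chebyshev inequality < r;
both template lengths use starting indices i < T − m (so every m-template
has an (m+1)-extension); a zero-variance series returns 0 (perfectly
regular); zero match count at either length, or T < m + 2, is *undefined*
and the feature is masked rather than imputed. Per-feature entropies form a
complexity vector per turn; the pair's similarity is the squared cosine σ
over jointly valid features. σ is scale-invariant by construction (r is
proportional to each series' own std, and the cosine ignores vector
magnitude). Because σ is a similarity while DTWD and WMD are distances, the
pipeline reports 1 − σ; the monotone flip does not affect rank-based or
margin-based downstream analyses but keeps every column oriented
"larger = less synchronous".

### Word mover's distance (lexical)

Uniform word masses (1/m, 1/n); repeated tokens keep separate mass units,
matching the behavior of contextual embedding backends where the same word
in two positions embeds differently. The transport problem is solved as an
exact LP (HiGHS); conversational turns are tens of words, so exactness
costs nothing and avoids entropic-regularization bias. The plan's marginals
are checked to 1e-8 on every solve. The embedding backend is an interface:
the default fixture provider maps token → keyed-hash-seeded unit Gaussian
vector (768-d by default, mirroring transformer-base hidden size), which is
deterministic, offline, and non-contextual; a contextual transformer
backend can be supplied through the same `embed(tokens)` contract.

## Aggregation and classification

Pairs are collected into N contiguous blocks by *pair count* (not wall
time), earlier blocks absorbing the remainder, and each block's per-measure
mean over valid pairs becomes one feature; N defaults to 5 and is logged.
Invalid pairs (undefined entropy, empty token list, zero-norm complexity
vector) are excluded from means, never imputed. Classification uses
repeated stratified 5-fold CV (10 repeats — small cohorts need the repeats
to stabilize fold-level F1), standardization fit on training folds only,
SVM defaults C = 1 and RBF γ = 1/(d·var), and macro-F1 (the unweighted mean
of per-class F1; the majority baseline then has the closed form
2p/(C(1+p)) for majority prevalence p, e.g. 0.375 at a 60/40 binary split).
The two-way ANOVA fits `score ~ C(age_group) * C(gender)` and errors on
cells with fewer than two observations rather than silently dropping the
interaction.

## Validation protocol

Regular pairs (adjacent, within session) are tested against random pairs
(one turn each from two different sessions with no shared speaker) with a
two-sided paired t-test per measure; lists are subsampled to a common
length k and paired by index — the pairing is arbitrary but fixed under the
seed, which is exactly what a paired design over two exchangeable samples
requires. A length-matched random-pair option exists for sensitivity
analysis but is off by default. Calibration is checked by drawing both
lists from one lognormal distribution (distance values are right-skewed):
the empirical type-I error at α = 0.05 over 1000 replicates of k = 100
should land near α.

## The synthetic dyad generator

The generator produces the *structure* the measures consume — alternating
turns, T×d frame matrices, token lists — with coupling injected at the
turn-summary level, because that is the across-turn dependence the measures
claim to detect:

* Each turn's frames are per-feature stationary AR(1) with a turn-level
  mean μ, scale s, and AR coefficient φ drawn i.i.d. per turn. With
  coupling γ, every turn after the first interpolates (μ, log s, φ) toward
  the *realized* summary (empirical mean, empirical log-std, generating φ)
  of the preceding turn with weight γ. Mean/scale coupling drives DTWD;
  φ-coupling aligns the complexity profile and drives SCDC (sample entropy
  is shift- and scale-invariant, so only φ matters there).
* Each turn draws 4–12 tokens from one of 8 topic vocabularies; the topic
  persists to the next turn with probability γ. Shared topics mean shared
  tokens, which is what WMD detects under any embedding that separates
  vocabulary items.

At γ = 0 every turn is an i.i.d. draw from one global distribution, making
within-session and cross-session pairs exchangeable — the exact null of the
validation protocol. Defaults: 12–20 turns per session (all sessions
eligible), 120–240 frames per turn (1.2–2.4 s at the 10 ms hop — typical
conversational turns, and long enough for stable m = 2 entropy estimates;
much shorter turns make SampEn so noisy that complexity coupling is
swamped by estimation error, a real limitation of the measure on clipped
utterances), φ ∈ [0.05, 0.95], turn means ~ N(0, 1), log-scales
~ N(0, 0.3). Cohorts assign the case group a coupling lowered by
`group_effect` in both modalities, uniform ages 3.5–13 y bucketed into
three groups, ~75% male (clinic-referral skew), and alternating subtask
tags.

What the generator does **not** emulate: real speech acoustics (the frame
matrices are abstract AR processes, not MFCCs of audio), disfluencies, ASR
or diarization errors, overlapping speech, subtask-dependent semantics, or
any relation between vocal and lexical channels beyond their shared γ.
Passing tests therefore show that the measures detect turn-level coupling
of the kind simulated — not that clinical group differences of any
particular size are recoverable from real recordings.

## Numerical choices and degenerate inputs

* DTW DP runs in a compiled kernel when numba is importable, with an
  identical pure-Python fallback; results are bitwise-equal paths apart.
* Sample entropy uses O(T²) exact template counting (cdist Chebyshev); no
  approximate neighbor search.
* WMD LP failures (which the uniform-marginal problem should never produce)
  raise with solver diagnostics rather than returning a sentinel.
* Pitch: autocorrelation with parabolic lag interpolation, voicing
  threshold 0.45 on the normalized peak, search range 60–500 Hz; unvoiced
  gaps linearly interpolated, edges held, then 5-frame median smoothing.
  Jitter/shimmer are per-frame difference approximations, not per-period
  measurements — adequate for contrasts, not for clinical voice metrics.
* MFCC: 26-filter mel bank, DCT-II orthonormal, coefficients 1–15 (C0
  excluded to reduce the loudness confound; configurable), log floored at
  1e-10 so silence stays finite.
* All stochastic components take explicit seeds; identical seeds give
  bit-identical outputs end to end.

## Known limitations

The fixture embedding provider has no semantics: WMD under it measures
vocabulary overlap, not meaning. The σ vs 1 − σ orientation choice is
documented rather than empirically settled (a monotone transform cannot be
identified from downstream classification alone). The ANOVA assumes
homoscedastic, roughly normal cell residuals; fold-level F1 values violate
independence assumptions if folds overlap, so its p-values are descriptive.
Problem sizes in the test and acceptance runs (36-session validation
cohorts, 500 pairs, 60+60-session classification cohorts) were chosen to
make the stochastic checks decisive at their stated thresholds while
keeping a full run in the minutes range on one CPU.
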