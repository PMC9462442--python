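"""Frame-level vocal feature extraction.

Spectral stream: 15 mel-frequency cepstral coefficients (26-filter mel bank,
coefficients 1-15, C0 excluded to reduce the loudness confound).  Prosodic
stream: pitch (autocorrelation F0 with voicing decision, unvoiced regions
interpolated), intensity (frame log-energy in dB), and per-frame jitter and
shimmer approximations.  Framing uses a 25 ms Hamming window hopped every
10 ms by default.

Precomputed per-turn feature CSVs are an equally supported input path (see
:func:`dyadsync.transcript_io.read_feature_csv`), so any external extractor
can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.io.wavfile
import scipy.signal

from .transcript_io import FrameFeatureMatrix

__all__ = [
    "FeatureConfig",
    "read_wav",
    "frame_signal",
    "extract_spectral",
    "extract_prosodic",
    "smooth_unvoiced",
    "NoVoicedFramesError",
]

_EPS = 1e-10


class NoVoicedFramesError(ValueError):
    """The turn contains no voiced frames; pitch is undefined."""


@dataclass(frozen=True)
class FeatureConfig:
    """Framing and feature parameters.

    frame_len_s / frame_hop_s: analysis window length and hop, seconds.
    n_mfcc: number of cepstral coefficients kept (C1..Cn, C0 excluded).
    n_mels: mel filterbank size.
    f0_min, f0_max: pitch search range, Hz.
    voicing_threshold: minimum normalized autocorrelation peak for a frame
        to count as voiced.
    """

    frame_len_s: float = 0.025
    frame_hop_s: float = 0.010
    window: str = "hamming"
    n_mfcc: int = 15
    n_mels: int = 26
    f0_min: float = 60.0
    f0_max: float = 500.0
    voicing_threshold: float = 0.45
    median_smooth_frames: int = 5

    def __post_init__(self) -> None:
        if self.frame_hop_s > self.frame_len_s:
            raise ValueError("frame_hop_s must not exceed frame_len_s")
        if self.n_mfcc < 1:
            raise ValueError("n_mfcc must be >= 1")


def read_wav(path, channel: int | None = None) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file, returning (float waveform in [-1, 1], rate)."""
    rate, data = scipy.io.wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, channel if channel is not None else 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(rate)


def frame_signal(audio: np.ndarray, sr: int, cfg: FeatureConfig) -> np.ndarray:
    """Slice audio into overlapping frames (n_frames x frame_len samples)."""
    audio = np.asarray(audio, dtype=float).ravel()
    flen = int(round(cfg.frame_len_s * sr))
    hop = int(round(cfg.frame_hop_s * sr))
    if len(audio) < flen:
        raise ValueError("turn shorter than one frame")
    n = (len(audio) - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return audio[idx]


def _mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular mel filters on the rfft bin grid (n_mels x n_bins)."""
    n_bins = n_fft // 2 + 1
    freqs = np.linspace(0.0, sr / 2.0, n_bins)
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(sr / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(mid - lo, _EPS)
        down = (hi - freqs) / max(hi - mid, _EPS)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def extract_spectral(audio: np.ndarray, sr: int, cfg: FeatureConfig | None = None) -> FrameFeatureMatrix:
    """MFCC matrix (T x n_mfcc) for one turn's audio.

    Frames -> Hamming window -> power spectrum -> mel filterbank ->
    log -> DCT-II (orthonormal); coefficients 1..n_mfcc are returned.
    Log energies are floored so silence yields finite rows.
    """
    cfg = cfg or FeatureConfig()
    frames = frame_signal(audio, sr, cfg)
    win = scipy.signal.get_window(cfg.window, frames.shape[1], fftbins=False)
    n_fft = int(2 ** np.ceil(np.log2(frames.shape[1])))
    spec = np.abs(scipy.fft.rfft(frames * win, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(sr, n_fft, cfg.n_mels)
    logmel = np.log(np.maximum(spec @ fb.T, _EPS))
    cep = scipy.fft.dct(logmel, type=2, axis=1, norm="ortho")
    values = cep[:, 1 : cfg.n_mfcc + 1]
    names = tuple(f"mfcc{i}" for i in range(1, cfg.n_mfcc + 1))
    return FrameFeatureMatrix(values, names, cfg.frame_hop_s, cfg.frame_len_s)


def _frame_f0(frames: np.ndarray, sr: int, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation pitch per frame -> (f0 Hz, voiced mask)."""
    flen = frames.shape[1]
    lag_min = max(2, int(sr / cfg.f0_max))
    lag_max = min(flen - 2, int(sr / cfg.f0_min))
    x = frames - frames.mean(axis=1, keepdims=True)
    n_fft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = scipy.fft.rfft(x, n=n_fft, axis=1)
    ac = scipy.fft.irfft(spec * np.conj(spec), n=n_fft, axis=1)[:, :flen]
    ac0 = np.maximum(ac[:, 0], _EPS)
    norm_ac = ac / ac0[:, None]
    if lag_max <= lag_min:
        return np.zeros(len(frames)), np.zeros(len(frames), dtype=bool)
    search = norm_ac[:, lag_min : lag_max + 1]
    best = np.argmax(search, axis=1)
    peak = search[np.arange(len(frames)), best]
    lags = (lag_min + best).astype(float)
    # parabolic interpolation around the peak for sub-sample lag precision
    li = lag_min + best
    ok = (li > lag_min) & (li < lag_max)
    if ok.any():
        l0 = norm_ac[ok, li[ok] - 1]
        l1 = norm_ac[ok, li[ok]]
        l2 = norm_ac[ok, li[ok] + 1]
        denom = l0 - 2 * l1 + l2
        shift = np.where(np.abs(denom) > _EPS, 0.5 * (l0 - l2) / denom, 0.0)
        lags[ok] = li[ok] + np.clip(shift, -0.5, 0.5)
    f0 = sr / lags
    energy = ac0 / flen
    voiced = (peak >= cfg.voicing_threshold) & (energy > 1e-8)
    return np.where(voiced, f0, 0.0), voiced


def smooth_unvoiced(pitch: np.ndarray, voiced: np.ndarray, median_window: int = 5) -> np.ndarray:
    """Fill unvoiced gaps in a pitch track, then median-smooth.

    Interior gaps are linearly interpolated between flanking voiced values;
    leading/trailing gaps hold the nearest voiced value.  A median filter of
    ``median_window`` frames is applied after filling (skipped when the
    track is shorter than the window).
    """
    pitch = np.asarray(pitch, dtype=float)
    voiced = np.asarray(voiced, dtype=bool)
    if pitch.shape != voiced.shape:
        raise ValueError("pitch and voicing mask must have equal length")
    if not voiced.any():
        raise NoVoicedFramesError("no voiced frames")
    t = np.arange(len(pitch))
    filled = np.interp(t, t[voiced], pitch[voiced])
    if median_window > 1 and len(filled) >= median_window:
        filled = scipy.signal.medfilt(filled, kernel_size=median_window | 1)
    return filled


def extract_prosodic(audio: np.ndarray, sr: int, cfg: FeatureConfig | None = None) -> FrameFeatureMatrix:
    """Prosodic matrix (T x 4): pitch_hz, intensity_db, jitter, shimmer.

    Pitch is autocorrelation F0 with unvoiced regions filled by
    :func:`smooth_unvoiced`.  Intensity is frame log-energy in dB re full
    scale.  Jitter is |dF0|/F0 between consecutive frames of the smoothed
    track; shimmer is |d(peak amplitude)|/amplitude between consecutive
    frames.  Both are per-frame approximations of the classic per-period
    definitions.

    Raises :class:`NoVoicedFramesError` when no frame is voiced; callers
    exclude such turns.
    """
    cfg = cfg or FeatureConfig()
    frames = frame_signal(audio, sr, cfg)
    f0, voiced = _frame_f0(frames, sr, cfg)
    pitch = smooth_unvoiced(f0, voiced, cfg.median_smooth_frames)

    energy = np.mean(frames**2, axis=1)
    intensity = 10.0 * np.log10(np.maximum(energy, 1e-12))

    jitter = np.zeros(len(pitch))
    jitter[1:] = np.abs(np.diff(pitch)) / np.maximum(pitch[1:], _EPS)

    amp = np.max(np.abs(frames), axis=1)
    shimmer = np.zeros(len(amp))
    shimmer[1:] = np.abs(np.diff(amp)) / np.maximum(amp[1:], _EPS)

    values = np.column_stack([pitch, intensity, jitter, shimmer])
    names = ("pitch_hz", "intensity_db", "jitter", "shimmer")
    return FrameFeatureMatrix(values, names, cfg.frame_hop_s, cfg.frame_len_s)
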