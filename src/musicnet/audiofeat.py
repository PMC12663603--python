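"""Audio descriptors of tonal and rhythmic clarity, and ordinal complexity.

Three classic music-information-retrieval features describe a piece:

- **chromagram** — FFT magnitude energy mapped to the 12 pitch classes by
  nearest-semitone assignment on a log-frequency axis (frame 200 ms, hop 5%).
- **key clarity** — the maximum Pearson correlation between a windowed mean
  chroma vector and the 24 Krumhansl-Kessler major/minor key profiles
  (window 5 s, hop 33% of the window).
- **pulse clarity** — the maximum of the normalized autocorrelation of a
  half-wave-rectified frame-energy onset envelope within a musical tempo lag
  range (window 5 s, hop 33%).

Complexity is quantified with Bandt-Pompe permutation entropy: the Shannon
entropy of the distribution of ordinal (rank-order) patterns of length ``m``
(default 7) in the raw sample series, computed per 60-s segment.  Ties are
broken by temporal order (the Bandt-Pompe convention); entropy uses the
natural log by default with a base option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "Chromagram",
    "PermDistribution",
    "SegmentEntropyProfile",
    "read_wav",
    "write_wav",
    "chromagram",
    "key_clarity",
    "pulse_clarity",
    "onset_envelope",
    "ordinal_pattern_distribution",
    "permutation_entropy",
    "segment_entropy_profile",
    "KK_MAJOR",
    "KK_MINOR",
]

# Krumhansl-Kessler probe-tone key profiles (major and minor templates,
# starting at the tonic); the 24 key profiles are their 12 rotations.
KK_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KK_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)

PITCH_CLASSES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]


@dataclass
class AudioSignal:
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Chromagram:
    energies: np.ndarray  # 12 x F, pitch class (C..B) x frame
    frame_times: np.ndarray  # seconds, frame centers
    frame_length_s: float
    hop_s: float


@dataclass
class PermDistribution:
    m: int
    delay: int
    patterns: np.ndarray  # observed patterns, each a length-m permutation
    counts: np.ndarray
    probabilities: np.ndarray


@dataclass
class SegmentEntropyProfile:
    segment_length_s: float
    entropies: np.ndarray
    segment_starts_s: np.ndarray
    m: int
    log_base: float | None  # None = natural log


def read_wav(path) -> AudioSignal:
    """Read a WAV file; stereo is downmixed to mono by channel averaging."""
    sr, data = wavfile.read(path)
    scale = 32768.0 if np.issubdtype(data.dtype, np.integer) else 1.0
    data = np.asarray(data, dtype=float) / scale
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(data, float(sr))


def write_wav(path, signal: AudioSignal) -> None:
    """Write PCM 16-bit mono WAV, peak-normalized only if clipping would occur."""
    x = signal.samples
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, int(signal.sample_rate), (x * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Chromagram and clarity features


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_len) // hop
    if n_frames < 1:
        raise ValueError("signal shorter than one frame")
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def chromagram(
    signal: AudioSignal,
    frame_length_s: float = 0.2,
    hop_fraction: float = 0.05,
    f_min: float = 55.0,
    f_max: float | None = None,
    tuning_ref: float = 440.0,
) -> Chromagram:
    """Pitch-class energy distribution over time.

    Per frame, the FFT magnitude-squared spectrum between ``f_min`` and
    ``f_max`` is routed to the 12 pitch classes: each bin is assigned to the
    pitch class of its nearest semitone on a log2 axis referenced to the
    tuning frequency (A4 = ``tuning_ref``).
    """
    sr = signal.sample_rate
    nyquist = sr / 2.0
    f_max = min(f_max if f_max is not None else 2000.0, nyquist)
    if not (0 < f_min < f_max <= nyquist):
        raise ValueError("need 0 < f_min < f_max <= Nyquist")
    frame_len = int(round(frame_length_s * sr))
    hop = max(1, int(round(frame_len * hop_fraction)))
    frames = _frame_signal(signal.samples, frame_len, hop)

    freqs = np.fft.rfftfreq(frame_len, d=1.0 / sr)
    band = (freqs >= f_min) & (freqs <= f_max)
    # semitone number relative to A4, then pitch class with A -> index 9
    semis = np.round(12.0 * np.log2(freqs[band] / tuning_ref)).astype(int)
    pc = (semis + 9) % 12
    route = np.zeros((band.sum(), 12))
    route[np.arange(band.sum()), pc] = 1.0

    energies = np.empty((12, frames.shape[0]))
    chunk = 4096
    for i in range(0, frames.shape[0], chunk):
        spec = np.abs(np.fft.rfft(frames[i : i + chunk], axis=1)) ** 2
        energies[:, i : i + chunk] = (spec[:, band] @ route).T
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2.0) / sr
    return Chromagram(energies, times, frame_len / sr, hop / sr)


def _windowed_starts(n: int, win: int, hop: int) -> np.ndarray:
    if n < win:
        raise ValueError("fewer frames than one window")
    return np.arange(0, n - win + 1, hop)


def key_clarity(
    chroma: Chromagram, window_s: float = 5.0, hop_fraction: float = 0.33
) -> np.ndarray:
    """Per-window tonal clarity: max Pearson r against the 24 key profiles.

    Windows of ``window_s`` advance by ``hop_fraction`` of the window.  A
    window whose mean chroma has zero variance yields clarity 0.
    """
    frames_per_win = max(1, int(round(window_s / chroma.hop_s)))
    hop = max(1, int(round(frames_per_win * hop_fraction)))
    starts = _windowed_starts(chroma.energies.shape[1], frames_per_win, hop)

    profiles = np.stack(
        [np.roll(KK_MAJOR, k) for k in range(12)]
        + [np.roll(KK_MINOR, k) for k in range(12)]
    )
    pz = (profiles - profiles.mean(axis=1, keepdims=True)) / profiles.std(
        axis=1, keepdims=True
    )
    out = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        v = chroma.energies[:, s0 : s0 + frames_per_win].mean(axis=1)
        sd = v.std()
        if sd == 0:
            out[i] = 0.0
            continue
        vz = (v - v.mean()) / sd
        out[i] = (pz @ vz).max() / 12.0
    return out


def onset_envelope(
    signal: AudioSignal, frame_s: float = 0.02, hop_s: float = 0.01
) -> tuple[np.ndarray, float]:
    """Half-wave-rectified frame-energy difference at rate 1/hop_s Hz."""
    frame_len = int(round(frame_s * signal.sample_rate))
    hop = int(round(hop_s * signal.sample_rate))
    frames = _frame_signal(signal.samples, frame_len, hop)
    energy = (frames**2).mean(axis=1)
    env = np.maximum(np.diff(energy, prepend=energy[0]), 0.0)
    return env, 1.0 / hop_s


def pulse_clarity(
    signal: AudioSignal,
    window_s: float = 5.0,
    hop_fraction: float = 0.33,
    lag_range_s: tuple[float, float] = (0.25, 2.0),
) -> np.ndarray:
    """Per-window rhythmic clarity: peak of the onset-envelope autocorrelation.

    The envelope is mean-removed and variance-normalized per window; clarity
    is the maximum normalized autocorrelation within the tempo lag range
    (default 0.25-2 s, i.e. 240-30 BPM).  A constant envelope yields 0.
    """
    if window_s < 2 * lag_range_s[1]:
        raise ValueError("window must cover at least twice the maximum lag")
    env, env_rate = onset_envelope(signal)
    win = int(round(window_s * env_rate))
    hop = max(1, int(round(win * hop_fraction)))
    lag_lo = max(1, int(round(lag_range_s[0] * env_rate)))
    lag_hi = int(round(lag_range_s[1] * env_rate))
    starts = _windowed_starts(len(env), win, hop)
    out = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        w = env[s0 : s0 + win]
        w = w - w.mean()
        denom = (w**2).sum()
        if denom == 0:
            out[i] = 0.0
            continue
        ac = np.correlate(w, w, mode="full")[len(w) - 1 :] / denom
        out[i] = ac[lag_lo : lag_hi + 1].max()
    return out


# ---------------------------------------------------------------------------
# Permutation entropy


def ordinal_pattern_distribution(
    series, m: int = 7, delay: int = 1
) -> PermDistribution:
    """Distribution of ordinal patterns of order ``m`` in a series.

    Each delay vector ``(x_t, x_{t+d}, ..., x_{t+(m-1)d})`` is mapped to the
    permutation that sorts it ascending; ties resolve by temporal order
    (stable sort), so a constant series yields the identity pattern.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n_vec = len(x) - (m - 1) * delay
    if n_vec < 1:
        raise ValueError(f"series too short for m={m}, delay={delay}")
    if delay == 1:
        vecs = sliding_window_view(x, m)
    else:
        idx = np.arange(n_vec)[:, None] + delay * np.arange(m)[None, :]
        vecs = x[idx]
    perms = np.argsort(vecs, axis=1, kind="stable")
    # encode each permutation as an integer in base m
    base = m ** np.arange(m - 1, -1, -1)
    codes = perms @ base
    uniq, counts = np.unique(codes, return_counts=True)
    # decode back to explicit permutations for reporting
    patterns = np.empty((len(uniq), m), dtype=int)
    rem = uniq.copy()
    for j, b in enumerate(base):
        patterns[:, j], rem = np.divmod(rem, b)
    return PermDistribution(
        m=m,
        delay=delay,
        patterns=patterns,
        counts=counts,
        probabilities=counts / counts.sum(),
    )


def permutation_entropy(
    dist: PermDistribution, log_base: float | None = None
) -> float:
    """Shannon entropy H = -sum p log p over observed ordinal patterns.

    Natural log by default; pass ``log_base=2`` for bits.  H lies in
    [0, log(m!)] and is 0 iff a single pattern occurs.
    """
    p = dist.probabilities
    h = float(-(p * np.log(p)).sum())
    if log_base is not None:
        h /= np.log(log_base)
    return max(h, 0.0)


def segment_entropy_profile(
    signal: AudioSignal,
    segment_length_s: float = 60.0,
    m: int = 7,
    delay: int = 1,
    log_base: float | None = None,
) -> SegmentEntropyProfile:
    """Permutation entropy of each full ``segment_length_s`` chunk of audio.

    A trailing partial segment is dropped.  A 5-minute piece with the 60-s
    default yields exactly five entropy values.
    """
    seg_len = int(round(segment_length_s * signal.sample_rate))
    n_seg = len(signal.samples) // seg_len
    if n_seg < 1:
        raise ValueError("signal shorter than one segment")
    ent = np.empty(n_seg)
    for i in range(n_seg):
        seg = signal.samples[i * seg_len : (i + 1) * seg_len]
        ent[i] = permutation_entropy(
            ordinal_pattern_distribution(seg, m=m, delay=delay), log_base=log_base
        )
    starts = np.arange(n_seg) * seg_len / signal.sample_rate
    return SegmentEntropyProfile(segment_length_s, ent, starts, m, log_base)
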