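"""Recording preprocessing, spectrograms and song segmentation.

The preprocessing chain mirrors a conventional bioacoustic workflow:
resample to 22.05 kHz, normalise the peak to 85% full scale, then apply a
spectral-gating noise-reduction filter (STFT size 512, magnitude bins below
-40 dBFS attenuated by 90 dB, overlap-add reconstruction).  Spectrograms
use a 256-point FFT with a Hamming window at 50% overlap.  Songs are cut
from a recording by a smoothed-RMS energy gate: maximal above-threshold
runs separated by a minimum silent gap become segments, and segments
shorter than a minimum song duration are flagged ``fragmented`` and
excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Spectrogram",
    "SpectrogramParams",
    "SongSegment",
    "preprocess",
    "compute_spectrogram",
    "segment_songs",
    "song_rate",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class SpectrogramParams:
    fft_size: int = 256
    window: str = "hamming"
    overlap: float = 0.5
    resample_rate: int = 22050
    normalize_peak: float = 0.85
    nr_fft: int = 512
    nr_threshold_db: float = -40.0
    nr_attenuation_db: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        for n in (self.fft_size, self.nr_fft):
            if n < 2 or (n & (n - 1)) != 0:
                raise ValueError("FFT sizes must be powers of two")

    @property
    def hop(self) -> int:
        return int(self.fft_size * (1.0 - self.overlap))


@dataclass
class Recording:
    samples: np.ndarray
    sample_rate: int
    bird_id: str = ""
    taxon_label: str = ""
    locality: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Spectrogram:
    matrix: np.ndarray  # time x frequency magnitudes
    time_step: float
    freq_step: float
    params: SpectrogramParams

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SongSegment:
    segment_id: str
    start_s: float
    end_s: float
    samples: np.ndarray
    sample_rate: int
    spectrogram: Spectrogram | None = None
    quality_flags: set[str] = field(default_factory=set)

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def excluded(self) -> bool:
        return bool(self.quality_flags)


def read_wav(path: str | Path, **meta: str) -> Recording:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Recording(np.asarray(data, dtype=float), int(rate), **meta)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """PCM 16-bit output; amplitudes clipped to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (x * 32767.0).astype(np.int16))


def _spectral_gate(x: np.ndarray, params: SpectrogramParams) -> np.ndarray:
    """Attenuate STFT magnitude bins below the threshold (dB re full scale)."""
    nfft = params.nr_fft
    if len(x) < nfft:
        return x.copy()
    win = signal.get_window("hann", nfft)
    sft = signal.ShortTimeFFT(win, hop=nfft // 2, fs=1.0, mfft=nfft)
    X = sft.stft(x)
    # dB reference: bin magnitude of a full-scale sine (window gain / 2)
    ref = win.sum() / 2.0
    thresh = ref * 10.0 ** (params.nr_threshold_db / 20.0)
    gain = 10.0 ** (-params.nr_attenuation_db / 20.0)
    mask = np.abs(X) < thresh
    X = np.where(mask, X * gain, X)
    y = sft.istft(X, k1=len(x))
    return np.real(y[: len(x)])


def preprocess(recording: Recording, params: SpectrogramParams | None = None) -> Recording:
    """Resample, peak-normalise and noise-reduce a recording.

    Zero-signal input is passed through unchanged (normalisation guard).
    """
    params = params or SpectrogramParams()
    x = recording.samples
    if x.size == 0:
        raise ValueError("empty recording")
    if recording.sample_rate != params.resample_rate:
        ratio = Fraction(params.resample_rate, recording.sample_rate).limit_denominator(10000)
        x = signal.resample_poly(x, ratio.numerator, ratio.denominator)
    peak = np.abs(x).max()
    if peak > 0:
        x = x * (params.normalize_peak / peak)
        x = _spectral_gate(x, params)
        # gating removes only sub-threshold energy; re-pin the peak exactly
        peak2 = np.abs(x).max()
        if peak2 > 0:
            x = x * (params.normalize_peak / peak2)
    return replace(recording, samples=x, sample_rate=params.resample_rate)


def compute_spectrogram(
    samples: np.ndarray, params: SpectrogramParams | None = None,
    sample_rate: int | None = None,
) -> Spectrogram:
    """Magnitude STFT (time x frequency), Hamming window, hop from overlap."""
    params = params or SpectrogramParams()
    sr = sample_rate or params.resample_rate
    x = np.asarray(samples, dtype=float)
    if len(x) < params.fft_size:
        raise ValueError(
            f"input ({len(x)} samples) shorter than FFT size {params.fft_size}"
        )
    win = signal.get_window(params.window, params.fft_size)
    sft = signal.ShortTimeFFT(win, hop=params.hop, fs=sr, mfft=params.fft_size)
    mag = np.abs(sft.stft(x)).T  # -> time x frequency
    return Spectrogram(
        matrix=mag,
        time_step=params.hop / sr,
        freq_step=sr / params.fft_size,
        params=params,
    )


def _rms_envelope_db(x: np.ndarray, sr: int, frame_s: float = 0.01,
                     smooth_s: float = 0.05) -> tuple[np.ndarray, float]:
    """Smoothed frame RMS in dB re full scale; returns (env_db, frame_s)."""
    hop = max(1, int(round(frame_s * sr)))
    n_frames = len(x) // hop
    if n_frames == 0:
        return np.empty(0), frame_s
    sq = x[: n_frames * hop] ** 2
    frame_ms = sq.reshape(n_frames, hop).mean(axis=1)
    k = max(1, int(round(smooth_s / frame_s)))
    kernel = np.ones(k) / k
    sm = np.convolve(frame_ms, kernel, mode="same")
    return 10.0 * np.log10(np.maximum(sm, 1e-20)), hop / sr


def segment_songs(
    recording: Recording,
    silence_threshold_db: float = -45.0,
    min_gap_s: float = 0.3,
    min_song_s: float = 0.5,
) -> list[SongSegment]:
    """Energy-gate segmentation into candidate songs.

    Maximal runs of frames above ``silence_threshold_db`` (dB re full
    scale), merged across silent gaps shorter than ``min_gap_s``; runs
    shorter than ``min_song_s`` are returned flagged ``fragmented``.
    """
    if min_gap_s <= 0 or min_song_s <= 0:
        raise ValueError("gap and song duration thresholds must be positive")
    env_db, step = _rms_envelope_db(recording.samples, recording.sample_rate)
    if env_db.size == 0:
        return []
    active = env_db > silence_threshold_db
    # raw runs of activity
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    runs = list(zip(edges[0::2], edges[1::2]))  # [start, end) frame indices
    if not runs:
        return []
    # merge runs separated by silence shorter than min_gap_s
    merged = [list(runs[0])]
    min_gap_frames = int(round(min_gap_s / step))
    for a, b in runs[1:]:
        if a - merged[-1][1] < min_gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    segments = []
    sr = recording.sample_rate
    for i, (a, b) in enumerate(merged):
        start_s, end_s = a * step, b * step
        seg = SongSegment(
            segment_id=f"{recording.bird_id or 'rec'}_s{i:04d}",
            start_s=start_s,
            end_s=end_s,
            samples=recording.samples[int(start_s * sr): int(end_s * sr)],
            sample_rate=sr,
        )
        if seg.duration < min_song_s:
            seg.quality_flags.add("fragmented")
        segments.append(seg)
    return segments


def song_rate(recording: Recording, segments: list[SongSegment]) -> float:
    """Non-excluded songs per minute of recording."""
    if recording.duration <= 0:
        raise ValueError("zero-duration recording")
    n = sum(1 for s in segments if not s.excluded)
    return n / (recording.duration / 60.0)
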