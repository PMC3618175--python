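"""Template extraction and spectrogram image cross-correlation.

A catalogue song type is represented by one or two 0.5-s templates cut
from the loudest (maximum-RMS) section of its reference rendering.  A
segmented song is compared with a template by sliding the template
spectrogram along the song's time axis (frequency axes aligned, no
frequency shifting) and taking, at each lag, the zero-mean normalised 2-D
correlation of the overlapping patch; the match score is the maximum over
lags, in [-1, 1].  Scores are invariant to overall amplitude scaling and a
template scores exactly 1 against the recording it was cut from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .audio_pipeline import Spectrogram, SpectrogramParams, compute_spectrogram

__all__ = [
    "Template",
    "MatchResult",
    "extract_template",
    "cross_correlate",
    "rank_templates",
    "TEMPLATE_DURATION_S",
    "DEFAULT_ACCEPT_THRESHOLD",
]

TEMPLATE_DURATION_S = 0.5
#: minimum score for the automated branch to accept a candidate match
DEFAULT_ACCEPT_THRESHOLD = 0.6


@dataclass
class Template:
    template_id: str
    song_type_id: str
    spectrogram: Spectrogram
    source_window: tuple[float, float]
    samples: np.ndarray | None = None
    part: str | None = None  # dominant song part inside the window, if known


@dataclass
class MatchResult:
    song_segment_id: str
    ranked: list[tuple[str, float]]          # (template_id, score), descending
    type_scores: dict[str, float]            # per song type: max over templates
    best_song_type_id: str | None
    best_score: float


def extract_template(
    samples: np.ndarray,
    sample_rate: int,
    song_type_id: str,
    params: SpectrogramParams | None = None,
    n_templates: int = 1,
    duration_s: float = TEMPLATE_DURATION_S,
    part_lookup=None,
    allowed_parts: tuple[str, ...] | None = None,
) -> list[Template]:
    """Cut the loudest ``duration_s`` window(s) from a rendering.

    The window maximising RMS amplitude is found by an exhaustive
    hop-aligned scan; ties go to the earliest window.  With
    ``n_templates=2`` (song types built from two repetitive phrases) the
    second template is the loudest window not overlapping the first; when
    fewer non-overlapping windows exist, fewer templates are returned.
    ``part_lookup``, if given, maps a time (s) to a song-part name and is
    used to tag each template with the part at its window centre;
    ``allowed_parts`` restricts candidate windows to those centred on the
    listed parts (falling back to all windows if none qualify).
    """
    params = params or SpectrogramParams()
    x = np.asarray(samples, dtype=float)
    win_len = int(round(duration_s * sample_rate))
    if len(x) < win_len:
        raise ValueError(
            f"rendering ({len(x)/sample_rate:.2f} s) shorter than template "
            f"duration {duration_s} s"
        )
    hop = params.hop
    csum = np.concatenate(([0.0], np.cumsum(x**2)))
    starts = np.arange(0, len(x) - win_len + 1, hop)
    energy = csum[starts + win_len] - csum[starts]
    if allowed_parts and part_lookup is not None:
        centre_ok = np.array(
            [part_lookup((s + win_len / 2) / sample_rate) in allowed_parts
             for s in starts]
        )
        if centre_ok.any():
            energy = np.where(centre_ok, energy, -1.0)
    # quantise so float-roundoff-equal energies tie, then stable-sort:
    # ties go to the earliest window
    emax = energy.max()
    if emax > 0:
        energy = np.round(energy / emax, 9)
    order = np.argsort(-energy, kind="stable")
    chosen: list[int] = []
    for idx in order:
        if energy[idx] < 0:
            break
        s = starts[idx]
        if all(abs(s - c) >= win_len for c in chosen):
            chosen.append(int(s))
        if len(chosen) == n_templates:
            break
    # the template spectrogram is a frame-slice of the source rendering's
    # spectrogram, so a template matched against its own source scores 1.0
    spec_full = compute_spectrogram(x, params, sample_rate)
    n_frames_t = max(1, int(round(duration_s * sample_rate / hop)))
    templates = []
    for k, s in enumerate(sorted(chosen)):
        seg = x[s: s + win_len]
        window = (s / sample_rate, (s + win_len) / sample_rate)
        part = part_lookup((window[0] + window[1]) / 2) if part_lookup else None
        k0 = s // hop
        k1 = min(k0 + n_frames_t, spec_full.n_frames)
        excerpt = Spectrogram(
            matrix=spec_full.matrix[k0:k1].copy(),
            time_step=spec_full.time_step,
            freq_step=spec_full.freq_step,
            params=params,
        )
        templates.append(
            Template(
                template_id=f"{song_type_id}_t{k}",
                song_type_id=song_type_id,
                spectrogram=excerpt,
                source_window=window,
                samples=seg,
                part=part,
            )
        )
    return templates


def _check_compatible(song: Spectrogram, template: Spectrogram) -> None:
    if song.params != template.params:
        raise ValueError("song and template spectrogram parameters differ")
    if song.n_freqs != template.n_freqs:
        raise ValueError("frequency axes differ")


def cross_correlate(
    song_spec: Spectrogram,
    template_spec: Spectrogram,
    return_lag: bool = False,
    min_overlap_frac: float = 0.5,
) -> float | tuple[float, float]:
    """Maximum zero-mean normalised correlation over time lags.

    Full-overlap lags are computed vectorised (FFT numerator, sliding-sum
    normalisation); edge lags with at least ``min_overlap_frac`` of the
    template overlapping are normalised on the overlapping region only.
    Returns the maximum score, optionally with the best lag in seconds
    (time of the template start within the song).
    """
    _check_compatible(song_spec, template_spec)
    S = song_spec.matrix.astype(np.float64)
    T = template_spec.matrix.astype(np.float64)
    nT, nS = T.shape[0], S.shape[0]
    if nS < nT:
        raise ValueError("song shorter than template")

    T0 = T - T.mean()
    tnorm = np.sqrt((T0**2).sum())
    best_score, best_lag = -1.0, 0

    if tnorm > 0:
        # full-overlap lags 0 .. nS-nT
        num = _sig.correlate(S, T0, mode="valid", method="fft").ravel()
        rows = S.sum(axis=1)
        rows2 = (S**2).sum(axis=1)
        c1 = np.concatenate(([0.0], np.cumsum(rows)))
        c2 = np.concatenate(([0.0], np.cumsum(rows2)))
        L = nS - nT + 1
        ws = c1[nT:] - c1[:L]
        wss = c2[nT:] - c2[:L]
        npix = nT * S.shape[1]
        var = np.maximum(wss - ws**2 / npix, 0.0)
        denom = np.sqrt(var) * tnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom > 1e-12, num / np.maximum(denom, 1e-300), 0.0)
        i = int(np.argmax(scores))
        best_score, best_lag = float(scores[i]), i

        # edge lags with partial overlap
        min_ov = max(2, int(np.ceil(min_overlap_frac * nT)))
        for lag in range(-(nT - min_ov), 0):
            sc = _partial_score(S, T, lag)
            if sc > best_score:
                best_score, best_lag = sc, lag
        for lag in range(nS - nT + 1, nS - min_ov + 1):
            sc = _partial_score(S, T, lag)
            if sc > best_score:
                best_score, best_lag = sc, lag

    best_score = float(np.clip(best_score, -1.0, 1.0))
    if return_lag:
        return best_score, best_lag * song_spec.time_step
    return best_score


def _partial_score(S: np.ndarray, T: np.ndarray, lag: int) -> float:
    """Zero-mean normalised correlation on the overlapping region only."""
    nT, nS = T.shape[0], S.shape[0]
    s0, s1 = max(lag, 0), min(lag + nT, nS)
    t0, t1 = s0 - lag, s1 - lag
    sp = S[s0:s1]
    tp = T[t0:t1]
    sp0 = sp - sp.mean()
    tp0 = tp - tp.mean()
    denom = np.sqrt((sp0**2).sum() * (tp0**2).sum())
    if denom <= 1e-12:
        return 0.0
    return float((sp0 * tp0).sum() / denom)


def rank_templates(
    song_spec: Spectrogram,
    templates: list[Template],
    song_segment_id: str = "",
    top_k: int | None = None,
) -> MatchResult:
    """Score every catalogue template against one song spectrogram.

    The per-song-type score is the maximum over that type's templates.
    Ties are broken towards the lexicographically lower template id (and
    song type id), so ranking is invariant to catalogue order.
    """
    if not templates:
        raise ValueError("empty catalogue")
    scored = []
    for t in sorted(templates, key=lambda t: t.template_id):
        scored.append((t.template_id, cross_correlate(song_spec, t.spectrogram), t.song_type_id))
    scored.sort(key=lambda r: (-r[1], r[0]))
    type_scores: dict[str, float] = {}
    for tid, sc, sty in scored:
        if sty not in type_scores or sc > type_scores[sty]:
            type_scores[sty] = sc
    best_type = min(
        type_scores, key=lambda sty: (-type_scores[sty], sty)
    )
    ranked = [(tid, sc) for tid, sc, _ in scored]
    if top_k is not None:
        ranked = ranked[:top_k]
    return MatchResult(
        song_segment_id=song_segment_id,
        ranked=ranked,
        type_scores=type_scores,
        best_song_type_id=best_type,
        best_score=type_scores[best_type],
    )
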