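"""Five-category song assignment and per-bird repertoire summaries.

Each non-excluded song receives exactly one of five labels by a decision
cascade over (a) how much of the best-matching catalogue song type's
element sequence it reproduces and (b) its song organisation:

1. ``LM_CATALOGUE``          — reproduces >= 95% of the catalogue type's
   collapsed element sequence;
2. ``LM_PARTIAL_CATALOGUE``  — >= 75%;
3. ``LM``                    — not assignable to a catalogue type, but shows
   the four-part Common Nightingale organisation (alpha-beta-gamma-omega)
   and contains recognisable catalogue gamma parts;
4. ``LL``                    — Thrush Nightingale organisation (begins with
   a repeated part, no beta, no omega) and no catalogue gamma parts;
5. ``UNCLEAR``               — anything else, including songs without
   Common Nightingale organisation but with recognisable gamma parts.

Element-sequence resemblance is the longest-common-subsequence length
divided by the catalogue sequence length, both sequences taken with
adjacent repetitions collapsed — repetition counts never influence the
assignment.  Labels 1-3 form the 'Identified' group (songs of Common
Nightingale origin); 'LL' and 'UNCLEAR' form 'Not identified'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .audio_pipeline import Recording, SongSegment, song_rate as _song_rate
from .song_matching import DEFAULT_ACCEPT_THRESHOLD, MatchResult, Template, cross_correlate

__all__ = [
    "CategoryLabel",
    "OrganizationResult",
    "RepertoireSummary",
    "IDENTIFIED_LABELS",
    "collapse_repeats",
    "element_resemblance",
    "detect_organization",
    "assign_category",
    "summarize_bird",
]


class CategoryLabel(str, Enum):
    LM_CATALOGUE = "LM_CATALOGUE"
    LM_PARTIAL_CATALOGUE = "LM_PARTIAL_CATALOGUE"
    LM = "LM"
    LL = "LL"
    UNCLEAR = "UNCLEAR"
    EXCLUDED = "EXCLUDED"


IDENTIFIED_LABELS = frozenset(
    {CategoryLabel.LM_CATALOGUE, CategoryLabel.LM_PARTIAL_CATALOGUE, CategoryLabel.LM}
)

LM_PARTS_IN_ORDER = ("alpha", "beta", "gamma", "omega")


@dataclass(frozen=True)
class OrganizationResult:
    organization: str  # "LM_ORG", "LL_ORG" or "NEITHER"
    has_catalogue_gamma: bool


@dataclass
class RepertoireSummary:
    bird_id: str
    counts: dict[CategoryLabel, int]
    n_songs: int  # non-excluded
    n_excluded: int
    proportion_identified: float
    song_rate: float
    mixed_singer: bool
    repertoire_class: str  # "pure_LM", "pure_LL", "mixed", "other"


def collapse_repeats(element_sequence: Sequence[str]) -> list[str]:
    """Collapse maximal runs of identical adjacent labels to one."""
    out: list[str] = []
    for e in element_sequence:
        if not out or out[-1] != e:
            out.append(e)
    return out


def element_resemblance(
    song_elements: Sequence[str], catalogue_elements: Sequence[str]
) -> float:
    """LCS(song, catalogue) / len(catalogue), on collapsed sequences.

    Encodes both element identity and order: reordered elements do not
    count towards the resemblance.
    """
    cat = list(catalogue_elements)
    if not cat:
        raise ValueError("catalogue element sequence is empty")
    song = list(song_elements)
    if not song:
        return 0.0
    # O(len(song) * len(cat)) LCS table, rolling rows
    prev = [0] * (len(cat) + 1)
    for s in song:
        cur = [0] * (len(cat) + 1)
        for j, c in enumerate(cat, start=1):
            cur[j] = prev[j - 1] + 1 if s == c else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1] / len(cat)


def detect_organization(
    elements: Sequence[tuple[str, str, int]],
    song_spec=None,
    gamma_templates: Sequence[Template] | None = None,
    gamma_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
) -> OrganizationResult:
    """Classify the song organisation and test for catalogue gamma parts.

    ``elements`` is the song's element log: (label, part, repetitions)
    triples in singing order (parts from the synthesis truth log, or from
    a best-effort glyph decoder).  LM organisation requires all four parts
    alpha-beta-gamma-omega present in order; LL organisation requires the
    song to begin with a repeated element and to contain neither a beta
    nor an omega part.  ``has_catalogue_gamma`` is true iff any gamma-part
    catalogue template cross-correlates above ``gamma_threshold`` anywhere
    in the song spectrogram (false when no spectrogram/templates given).
    """
    parts = [p for _, p, _ in elements]
    org = "NEITHER"
    if elements:
        # LM: the four canonical parts all present, first occurrences in order
        firsts = [parts.index(p) for p in LM_PARTS_IN_ORDER if p in parts]
        if len(firsts) == 4 and firsts == sorted(firsts):
            org = "LM_ORG"
        else:
            starts_repeated = elements[0][2] >= 2 or (
                len(elements) > 1 and elements[1][0] == elements[0][0]
            )
            if starts_repeated and "beta" not in parts and "omega" not in parts:
                org = "LL_ORG"

    has_gamma = False
    if song_spec is not None and gamma_templates:
        for t in gamma_templates:
            if t.part != "gamma":
                continue
            try:
                if cross_correlate(song_spec, t.spectrogram) >= gamma_threshold:
                    has_gamma = True
                    break
            except ValueError:  # song shorter than template
                continue
    return OrganizationResult(org, has_gamma)


def assign_category(
    resemblance: float,
    organization: OrganizationResult,
    full_threshold: float = 0.95,
    partial_threshold: float = 0.75,
) -> CategoryLabel:
    """Decision cascade mapping resemblance + organisation to a label."""
    if not 0 < partial_threshold < full_threshold <= 1:
        raise ValueError("thresholds must satisfy 0 < partial < full <= 1")
    if resemblance >= full_threshold:
        return CategoryLabel.LM_CATALOGUE
    if resemblance >= partial_threshold:
        return CategoryLabel.LM_PARTIAL_CATALOGUE
    if organization.organization == "LM_ORG" and organization.has_catalogue_gamma:
        return CategoryLabel.LM
    if organization.organization == "LL_ORG" and not organization.has_catalogue_gamma:
        return CategoryLabel.LL
    return CategoryLabel.UNCLEAR


def summarize_bird(
    labels: Sequence[CategoryLabel],
    recording: Recording,
    segments: Sequence[SongSegment] | None = None,
    bird_id: str | None = None,
    identified_labels: frozenset = IDENTIFIED_LABELS,
) -> RepertoireSummary:
    """Aggregate one bird's labels into a repertoire summary.

    ``labels`` holds one label per segment (EXCLUDED allowed);
    ``proportion_identified`` is over non-excluded songs only.  A bird
    with both Identified and LL songs is a mixed singer.
    """
    counts = {c: 0 for c in CategoryLabel}
    for lab in labels:
        counts[CategoryLabel(lab)] += 1
    n_excluded = counts[CategoryLabel.EXCLUDED]
    n_songs = len(labels) - n_excluded
    if n_songs == 0:
        raise ValueError("all segments excluded: nothing to summarise")
    n_ident = sum(counts[c] for c in identified_labels)
    prop = n_ident / n_songs
    mixed = n_ident > 0 and counts[CategoryLabel.LL] > 0
    if prop == 1.0:
        rep_class = "pure_LM"
    elif n_ident == 0 and counts[CategoryLabel.LL] == n_songs:
        rep_class = "pure_LL"
    elif mixed:
        rep_class = "mixed"
    else:
        rep_class = "other"
    if segments is not None:
        rate = _song_rate(recording, list(segments))
    else:
        if recording.duration <= 0:
            raise ValueError("zero-duration recording")
        rate = n_songs / (recording.duration / 60.0)
    return RepertoireSummary(
        bird_id=bird_id or recording.bird_id,
        counts=counts,
        n_songs=n_songs,
        n_excluded=n_excluded,
        proportion_identified=prop,
        song_rate=rate,
        mixed_singer=mixed,
        repertoire_class=rep_class,
    )
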