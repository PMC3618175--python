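"""Synthetic study data: songs, recordings, genotypes and mtDNA.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage runs without
field data.

*Songs.*  Two species-specific grammars emit song types as ordered
sequences of acoustic elements with part annotations.  The Common
Nightingale (LM) grammar always produces the canonical four parts —
a soft alpha intro, a beta whistle series, a loud repeated gamma section
and a terminal omega element.  The Thrush Nightingale (LL) grammar always
begins with a repeated head element and emits no beta and no omega part.
A song type's identity is its collapsed element sequence (adjacent
repetitions removed); repetition counts are re-drawn at every rendering
from a truncated geometric distribution, so renderings of one type vary
in length but never in collapsed sequence.  Elements are synthesised as
simple glyphs (whistle, sweep, trill-pulse, buzz, click) in distinct
frequency bands, which keeps distinct labels separable by spectrogram
correlation without attempting realistic timbre.

*Genotypes.*  Pedigree categories (pure species, F1, F2, and first- to
third-generation backcrosses in both directions) are produced by explicit
gene-dropping: founder gene copies are drawn from the per-species allele
frequencies, hybrid gametes by fair per-locus segregation, loci
independent.  Z-linked loci follow avian sex chromosomes: ZZ males carry
two copies, ZW females one.  The hybrid parent of every backcross is
male, consistent with Haldane's-rule sterility of F1 females.

*mtDNA.*  Two reference haplotypes differing at a configurable number of
fixed sites (default 10 over 193 bp), with optional per-site query noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .audio_pipeline import Recording, SpectrogramParams, write_wav
from .hybrid_genetics import GenotypeRecord, LocusSpec, REFERENCE_LOCI
from .song_matching import Template, extract_template

__all__ = [
    "ElementToken",
    "SongUnit",
    "SongType",
    "SongGrammar",
    "RenderedElement",
    "RenderedSong",
    "Catalogue",
    "RepertoireSpec",
    "SimulatedRecording",
    "PedigreeSpec",
    "MtdnaReference",
    "default_lm_grammar",
    "default_ll_grammar",
    "build_catalogue",
    "render_song",
    "simulate_recording",
    "simulate_genotypes",
    "simulate_mtdna",
    "sample_mtdna_query",
    "write_catalogue",
    "write_truth_tsv",
    "write_mtdna_fasta",
    "PEDIGREE_CATEGORIES",
]

GLYPHS = ("whistle", "sweep", "trill-pulse", "buzz", "click")

PEDIGREE_CATEGORIES = (
    "PureLM", "PureLL", "F1", "F2",
    "BC1_LM", "BC1_LL", "BC2_LM", "BC2_LL", "BC3_LM", "BC3_LL",
)


@dataclass(frozen=True)
class ElementToken:
    label: str
    glyph: str
    freq_lo: float
    freq_hi: float
    duration: float
    amplitude: float
    mod_rate: float = 0.0  # pulse/AM rate in Hz; 0 = glyph default

    def __post_init__(self) -> None:
        if self.glyph not in GLYPHS:
            raise ValueError(f"unknown glyph {self.glyph!r}")
        if not self.freq_lo < self.freq_hi:
            raise ValueError("freq_lo must be < freq_hi")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")


@dataclass(frozen=True)
class SongUnit:
    """One element slot of a song type: the element, its part, and the
    repetition range (reps re-drawn per rendering when min < max)."""

    token: ElementToken
    part: str
    min_reps: int
    max_reps: int

    @property
    def repetitive(self) -> bool:
        return self.min_reps >= 3


@dataclass(frozen=True)
class SongType:
    song_type_id: str
    species: str
    units: tuple[SongUnit, ...]

    @property
    def collapsed_sequence(self) -> tuple[str, ...]:
        out: list[str] = []
        for u in self.units:
            if not out or out[-1] != u.token.label:
                out.append(u.token.label)
        return tuple(out)

    @property
    def n_repetitive_phrases(self) -> int:
        return len({u.token.label for u in self.units if u.repetitive})


@dataclass(frozen=True)
class PartTemplate:
    """Per-part recipe: the element pool and how many distinct elements and
    repetitions a song type drawn from this grammar uses."""

    name: str
    pool: tuple[ElementToken, ...]
    n_elements: tuple[int, int]   # distinct elements per song type
    reps: tuple[int, int]         # repetition range per element
    variable_reps: bool = True


@dataclass(frozen=True)
class SongGrammar:
    species: str  # "LM" or "LL"
    parts: tuple[PartTemplate, ...]

    def __post_init__(self) -> None:
        labels = [t.label for p in self.parts for t in p.pool]
        if len(labels) != len(set(labels)):
            raise ValueError("element labels must be unique within a grammar")
        part_names = [p.name for p in self.parts]
        if self.species == "LM":
            if part_names != ["alpha", "beta", "gamma", "omega"]:
                raise ValueError("LM grammar must emit alpha, beta, gamma, omega")
        elif self.species == "LL":
            if "beta" in part_names or "omega" in part_names:
                raise ValueError("LL grammar must not emit beta or omega parts")
            if self.parts[0].reps[0] < 2:
                raise ValueError("LL songs must begin with a repeated element")
        else:
            raise ValueError(f"unknown species {self.species!r}")

    @property
    def alphabet(self) -> tuple[ElementToken, ...]:
        return tuple(t for p in self.parts for t in p.pool)

    def sample_song_type(self, type_id: str, rng: np.random.Generator) -> SongType:
        units: list[SongUnit] = []
        for part in self.parts:
            k = int(rng.integers(part.n_elements[0], part.n_elements[1] + 1))
            idx = rng.choice(len(part.pool), size=min(k, len(part.pool)), replace=False)
            for i in idx:
                lo, hi = part.reps
                base = lo if lo == hi else int(rng.integers(lo, hi + 1))
                units.append(
                    SongUnit(
                        token=part.pool[int(i)],
                        part=part.name,
                        min_reps=lo if part.variable_reps else base,
                        max_reps=hi if part.variable_reps else base,
                    )
                )
        return SongType(type_id, self.species, tuple(units))


def _band(i: int, n: int, lo: float, hi: float, width: float) -> tuple[float, float]:
    c = lo + (hi - lo) * (i + 0.5) / n
    return (c - width / 2, c + width / 2)


def default_lm_grammar() -> SongGrammar:
    """Default Common Nightingale grammar: 3 alpha / 6 beta / 30 gamma /
    3 omega elements.  The gamma pool is deliberately large (distinct
    frequency bands and pulse/AM rates) because catalogue song types are
    identified chiefly by their loud gamma phrase; a rich gamma alphabet is
    what makes distinct song types separable by template correlation."""
    alpha = tuple(
        ElementToken(f"La{i}", "whistle", *_band(i, 3, 2000, 3200, 300), 0.12, 0.35)
        for i in range(3)
    )
    beta = tuple(
        ElementToken(
            f"Lb{i}", "sweep" if i % 2 else "whistle",
            *_band(i, 6, 3400, 5800, 350), 0.10, 0.45,
        )
        for i in range(6)
    )
    gamma = tuple(
        ElementToken(
            f"Lg{i:02d}", "trill-pulse" if i % 2 == 0 else "buzz",
            *_band(i, 30, 6000, 10200, 300), 0.06, 1.0,
            mod_rate=16.0 + 1.0 * i,
        )
        for i in range(30)
    )
    omega = tuple(
        ElementToken(f"Lo{i}", "click" if i == 0 else "whistle",
                     *_band(i, 3, 1200, 1900, 250), 0.10, 0.5)
        for i in range(3)
    )
    return SongGrammar(
        "LM",
        (
            PartTemplate("alpha", alpha, (1, 1), (1, 2)),
            PartTemplate("beta", beta, (2, 2), (2, 4)),
            PartTemplate("gamma", gamma, (2, 2), (3, 4)),
            PartTemplate("omega", omega, (1, 1), (1, 1), variable_reps=False),
        ),
    )


def default_ll_grammar() -> SongGrammar:
    """Default Thrush Nightingale grammar: repeated head, middle series,
    terminal trill; no beta, no omega.  All bands lie below the LM gamma
    band, so heterospecific songs do not spuriously trip the catalogue
    gamma detector."""
    head = tuple(
        ElementToken(f"Th{i}", "whistle", *_band(i, 3, 2500, 3800, 280), 0.11, 0.8)
        for i in range(3)
    )
    middle = tuple(
        ElementToken(
            f"Tm{i}", "sweep" if i % 2 else "buzz",
            *_band(i, 6, 4200, 5600, 300), 0.12, 0.75,
            mod_rate=70.0 + 5.0 * i,
        )
        for i in range(6)
    )
    trill = tuple(
        ElementToken(f"Tt{i}", "trill-pulse", *_band(i, 4, 3000, 4400, 320),
                     0.08, 1.0, mod_rate=22.0 + 3.0 * i)
        for i in range(4)
    )
    return SongGrammar(
        "LL",
        (
            PartTemplate("head", head, (1, 1), (3, 6)),
            PartTemplate("middle", middle, (2, 3), (1, 3)),
            PartTemplate("trill", trill, (1, 1), (4, 8)),
        ),
    )


# ---------------------------------------------------------------------------
# Element / song synthesis

def _envelope(n: int, sr: int, ramp_s: float = 0.008) -> np.ndarray:
    r = min(max(int(ramp_s * sr), 1), n // 2)
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, r)))
    env[:r] = ramp
    env[-r:] = ramp[::-1]
    return env


def _synth_element(token: ElementToken, sr: int, rng: np.random.Generator,
                   tempo_factor: float = 1.0) -> np.ndarray:
    dur = token.duration * tempo_factor
    n = max(int(dur * sr), 8)
    t = np.arange(n) / sr
    f0, f1 = token.freq_lo, token.freq_hi
    fc = 0.5 * (f0 + f1)
    if token.glyph == "whistle":
        freq = np.full(n, fc) + 0.15 * (f1 - f0) * np.sin(2 * np.pi * 5 * t)
        x = np.sin(2 * np.pi * np.cumsum(freq) / sr)
    elif token.glyph == "sweep":
        freq = np.linspace(f0, f1, n)
        x = np.sin(2 * np.pi * np.cumsum(freq) / sr)
    elif token.glyph == "trill-pulse":
        rate = token.mod_rate or 30.0
        x = np.sin(2 * np.pi * fc * t)
        x *= 0.5 * (1 + np.sign(np.sin(2 * np.pi * rate * t)))  # on/off pulses
    elif token.glyph == "buzz":
        rate = token.mod_rate or 90.0
        x = np.sin(2 * np.pi * fc * t) * (0.55 + 0.45 * np.sin(2 * np.pi * rate * t))
    elif token.glyph == "click":
        x = rng.standard_normal(n)
        # crude band-limit by modulating noise onto the carrier
        x = x * np.sin(2 * np.pi * fc * t)
    else:  # pragma: no cover - guarded by ElementToken
        raise AssertionError(token.glyph)
    return token.amplitude * _envelope(n, sr) * x


@dataclass(frozen=True)
class RenderedElement:
    label: str
    part: str
    reps: int
    start_s: float
    end_s: float


@dataclass
class RenderedSong:
    samples: np.ndarray
    sample_rate: int
    song_type_id: str
    element_log: list[RenderedElement]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def part_lookup(self) -> Callable[[float], str | None]:
        log = self.element_log

        def lookup(time_s: float) -> str | None:
            best, best_d = None, np.inf
            for e in log:
                if e.start_s <= time_s <= e.end_s:
                    return e.part
                d = min(abs(time_s - e.start_s), abs(time_s - e.end_s))
                if d < best_d:
                    best, best_d = e.part, d
            return best

        return lookup


def _trunc_geometric(rng: np.random.Generator, lo: int, hi: int, p: float = 0.45) -> int:
    """Truncated geometric repetition count on {lo..hi}."""
    if lo >= hi:
        return lo
    k = lo + int(rng.geometric(p)) - 1
    return min(k, hi)


def render_song(
    song_type: SongType,
    tempo_jitter: float = 0.0,
    noise_db: float = -np.inf,
    seed: int = 0,
    sample_rate: int = 22050,
) -> RenderedSong:
    """Synthesise one rendering of a song type.

    Repetition counts of variable units are re-drawn per rendering;
    ``tempo_jitter`` scales element and gap durations by a uniform factor
    in [1-j, 1+j]; ``noise_db`` adds white noise at that level relative to
    the song's peak (-inf = clean).  Deterministic for a fixed seed.
    """
    if not 0 <= tempo_jitter < 1:
        raise ValueError("tempo_jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sr = sample_rate
    pieces: list[np.ndarray] = []
    log: list[RenderedElement] = []
    pos = 0
    intra_gap, unit_gap, part_gap = 0.015, 0.045, 0.08
    prev_part = None
    for unit in song_type.units:
        factor = 1.0 + (rng.uniform(-tempo_jitter, tempo_jitter) if tempo_jitter else 0.0)
        reps = _trunc_geometric(rng, unit.min_reps, unit.max_reps)
        gap = part_gap if (prev_part is not None and unit.part != prev_part) else unit_gap
        gap_n = int(gap * factor * sr)
        if pieces:
            pieces.append(np.zeros(gap_n))
            pos += gap_n
        start = pos
        for r in range(reps):
            x = _synth_element(unit.token, sr, rng, factor)
            pieces.append(x)
            pos += len(x)
            if r < reps - 1:
                g = int(intra_gap * factor * sr)
                pieces.append(np.zeros(g))
                pos += g
        log.append(
            RenderedElement(unit.token.label, unit.part, reps, start / sr, pos / sr)
        )
        prev_part = unit.part
    x = np.concatenate(pieces) if pieces else np.zeros(1)
    peak = np.abs(x).max()
    if peak > 0:
        x = x * (0.7 / peak)
    if np.isfinite(noise_db):
        x = x + 0.7 * 10.0 ** (noise_db / 20.0) * rng.standard_normal(len(x))
    return RenderedSong(x, sr, song_type.song_type_id, log)


# ---------------------------------------------------------------------------
# Catalogue

@dataclass
class Catalogue:
    song_types: list[SongType]
    templates: list[Template]
    renderings: dict[str, RenderedSong]
    grammar: SongGrammar
    params: SpectrogramParams

    def type_by_id(self, song_type_id: str) -> SongType:
        for st in self.song_types:
            if st.song_type_id == song_type_id:
                return st
        raise KeyError(song_type_id)

    @property
    def gamma_templates(self) -> list[Template]:
        return [t for t in self.templates if t.part == "gamma"]


def build_catalogue(
    n_song_types: int,
    grammar: SongGrammar | None = None,
    seed: int = 0,
    params: SpectrogramParams | None = None,
) -> Catalogue:
    """Build a reference catalogue of distinct Common Nightingale song types.

    Distinctness means no two song types share a collapsed element
    sequence.  Each type gets a clean reference rendering and one 0.5-s
    maximum-amplitude template — two non-overlapping templates when the
    type contains two different repetitive phrases.  Raises when the
    grammar's alphabet cannot supply ``n_song_types`` distinct sequences.
    """
    if n_song_types < 1:
        raise ValueError("n_song_types must be >= 1")
    grammar = grammar or default_lm_grammar()
    if grammar.species != "LM":
        raise ValueError("the catalogue is built from the LM (Common Nightingale) grammar")
    params = params or SpectrogramParams()
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, ...]] = set()
    seen_phrases: set[frozenset[str]] = set()
    song_types: list[SongType] = []
    misses = 0
    while len(song_types) < n_song_types:
        st = grammar.sample_song_type(f"A{len(song_types) + 1:03d}", rng)
        key = st.collapsed_sequence
        # each catalogue type must also carry a unique loud-phrase (gamma)
        # signature: templates are cut from the loudest section, so types
        # sharing it would be indistinguishable by template correlation
        phrase_key = tuple(u.token.label for u in st.units if u.repetitive)
        if key in seen or phrase_key in seen_phrases:
            misses += 1
            if misses > 200 + 50 * n_song_types:
                raise ValueError(
                    f"grammar alphabet too small to generate {n_song_types} "
                    f"distinct song types (got {len(song_types)})"
                )
            continue
        seen.add(key)
        seen_phrases.add(phrase_key)
        song_types.append(st)
    templates: list[Template] = []
    renderings: dict[str, RenderedSong] = {}
    for st in song_types:
        rend = render_song(st, tempo_jitter=0.0, noise_db=-np.inf,
                           seed=int(rng.integers(2**31)), sample_rate=params.resample_rate)
        renderings[st.song_type_id] = rend
        n_templ = 2 if st.n_repetitive_phrases >= 2 else 1
        templates.extend(
            extract_template(
                rend.samples, rend.sample_rate, st.song_type_id, params,
                n_templates=n_templ, part_lookup=rend.part_lookup(),
                allowed_parts=("gamma",),
            )
        )
    return Catalogue(song_types, templates, renderings, grammar, params)


# ---------------------------------------------------------------------------
# Recordings

@dataclass
class RepertoireSpec:
    """Per-bird repertoire: song-type pools per species of origin and the
    probability that any one song is drawn from the LM pool."""

    lm_pool: list[SongType] = field(default_factory=list)
    ll_pool: list[SongType] = field(default_factory=list)
    mixing_proportion: float = 0.0  # P(song is of LM origin)

    def __post_init__(self) -> None:
        if not 0 <= self.mixing_proportion <= 1:
            raise ValueError("mixing_proportion must be in [0, 1]")
        if self.mixing_proportion > 0 and not self.lm_pool:
            raise ValueError("mixing_proportion > 0 requires a non-empty LM pool")
        if self.mixing_proportion < 1 and not self.ll_pool:
            raise ValueError("mixing_proportion < 1 requires a non-empty LL pool")


@dataclass
class SimulatedRecording:
    recording: Recording
    truth: pd.DataFrame
    element_logs: list[list[RenderedElement]]


def simulate_recording(
    repertoire_spec: RepertoireSpec,
    duration_min: float,
    song_rate_per_min: float,
    seed: int = 0,
    noise_db: float = -30.0,
    tempo_jitter: float = 0.05,
    min_gap_s: float = 1.0,
    sample_rate: int = 22050,
    bird_id: str = "bird",
) -> SimulatedRecording:
    """Synthesise one bird's recording plus its ground-truth table.

    The number of songs is duration x rate (rounded); songs are placed in
    order with silent gaps of at least ``min_gap_s`` (default 1 s, so
    energy segmentation of clean audio is unambiguous), the remaining
    silence spread randomly over the gaps.  Fails when the requested rate
    leaves no room for the minimum gaps.
    """
    if duration_min <= 0 or song_rate_per_min < 0:
        raise ValueError("duration and song rate must be positive")
    rng = np.random.default_rng(seed)
    sr = sample_rate
    n_songs = int(round(duration_min * song_rate_per_min))
    total_samples = int(duration_min * 60 * sr)
    rendered: list[RenderedSong] = []
    rows = []
    for i in range(n_songs):
        from_lm = rng.random() < repertoire_spec.mixing_proportion
        pool = repertoire_spec.lm_pool if from_lm else repertoire_spec.ll_pool
        st = pool[int(rng.integers(len(pool)))]
        rend = render_song(
            st, tempo_jitter=tempo_jitter, noise_db=-np.inf,
            seed=int(rng.integers(2**31)), sample_rate=sr,
        )
        rendered.append(rend)
        rows.append({"song_index": i, "song_type_id": st.song_type_id,
                     "species": st.species})
    song_samples = sum(len(r.samples) for r in rendered)
    n_gaps = n_songs + 1
    slack = total_samples - song_samples - n_gaps * int(min_gap_s * sr)
    if n_songs > 0 and slack < 0:
        raise ValueError(
            "song_rate x duration exceeds what the minimum silence gaps permit"
        )
    if n_songs > 0:
        w = rng.dirichlet(np.ones(n_gaps))
        gaps = (int(min_gap_s * sr) + (w * slack)).astype(int)
    else:
        gaps = np.array([total_samples])
    x = np.zeros(total_samples)
    pos = 0
    logs: list[list[RenderedElement]] = []
    for i, rend in enumerate(rendered):
        pos += int(gaps[i])
        end = min(pos + len(rend.samples), total_samples)
        x[pos:end] = rend.samples[: end - pos]
        start_s = pos / sr
        rows[i]["start_s"] = start_s
        rows[i]["end_s"] = end / sr
        rows[i]["elements"] = ",".join(
            f"{e.label}:{e.part}:{e.reps}" for e in rend.element_log
        )
        collapsed: list[str] = []
        for e in rend.element_log:
            if not collapsed or collapsed[-1] != e.label:
                collapsed.append(e.label)
        rows[i]["collapsed"] = "|".join(collapsed)
        logs.append(
            [replace(e, start_s=e.start_s + start_s, end_s=e.end_s + start_s)
             for e in rend.element_log]
        )
        pos = end
    if np.isfinite(noise_db):
        x = x + 0.7 * 10.0 ** (noise_db / 20.0) * rng.standard_normal(len(x))
    truth = pd.DataFrame(
        rows,
        columns=["song_index", "song_type_id", "species", "start_s", "end_s",
                 "elements", "collapsed"],
    )
    rec = Recording(x, sr, bird_id=bird_id)
    return SimulatedRecording(rec, truth, logs)


# ---------------------------------------------------------------------------
# Genotypes (gene dropping)

@dataclass(frozen=True)
class PedigreeSpec:
    category: str
    sex: str = "male_ZZ"
    maternal_species: str = "LL"  # mtDNA lineage of the F1 founder cross

    def __post_init__(self) -> None:
        if self.category not in PEDIGREE_CATEGORIES:
            raise ValueError(f"unknown pedigree category {self.category!r}")
        if self.sex not in ("male_ZZ", "female_ZW"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.maternal_species not in ("LM", "LL"):
            raise ValueError("maternal_species must be 'LM' or 'LL'")


_Genome = dict[str, list[str]]


def _draw_copy(locus: LocusSpec, species: str, rng: np.random.Generator) -> str:
    f = locus.frequencies(species)
    return locus.alleles[0] if rng.random() < f[0] else locus.alleles[1]


def _founder(species: str, sex: str, loci: Sequence[LocusSpec],
             rng: np.random.Generator) -> _Genome:
    g: _Genome = {}
    for locus in loci:
        n = 1 if (locus.chromosome_class == "Z" and sex == "female_ZW") else 2
        g[locus.name] = [_draw_copy(locus, species, rng) for _ in range(n)]
    return g


def _cross(father: _Genome, mother: _Genome, offspring_sex: str,
           loci: Sequence[LocusSpec], rng: np.random.Generator) -> _Genome:
    g: _Genome = {}
    for locus in loci:
        pat = father[locus.name][int(rng.integers(2))]  # fair segregation
        if locus.chromosome_class == "Z":
            if offspring_sex == "male_ZZ":
                g[locus.name] = [pat, mother[locus.name][0]]
            else:  # daughter: Z from father, W from mother
                g[locus.name] = [pat]
        else:
            mat = mother[locus.name][int(rng.integers(len(mother[locus.name])))]
            g[locus.name] = [pat, mat]
    return g


def _other(species: str) -> str:
    return "LM" if species == "LL" else "LL"


def _drop_individual(category: str, sex: str, maternal_species: str,
                     loci: Sequence[LocusSpec], rng: np.random.Generator) -> _Genome:
    if category == "PureLM":
        return _founder("LM", sex, loci, rng)
    if category == "PureLL":
        return _founder("LL", sex, loci, rng)
    if category == "F1":
        mother = _founder(maternal_species, "female_ZW", loci, rng)
        father = _founder(_other(maternal_species), "male_ZZ", loci, rng)
        return _cross(father, mother, sex, loci, rng)
    # internal hybrid ancestors get a random cross direction: both
    # directions occur in nature, and a fixed direction would make the
    # single Z of an F1 mother deterministic, skewing Z-linked genotype
    # frequencies in F2 away from the 1/4-1/2-1/4 class definition
    def _rand_dir() -> str:
        return "LL" if rng.random() < 0.5 else "LM"

    if category == "F2":
        father = _drop_individual("F1", "male_ZZ", _rand_dir(), loci, rng)
        mother = _drop_individual("F1", "female_ZW", _rand_dir(), loci, rng)
        return _cross(father, mother, sex, loci, rng)
    if category.startswith("BC"):
        gen = int(category[2])
        target = category[-2:]
        father_cat = "F1" if gen == 1 else f"BC{gen - 1}_{target}"
        father = _drop_individual(father_cat, "male_ZZ", _rand_dir(), loci, rng)
        mother = _founder(target, "female_ZW", loci, rng)
        return _cross(father, mother, sex, loci, rng)
    raise ValueError(f"unknown pedigree category {category!r}")


def simulate_genotypes(
    spec: PedigreeSpec,
    loci: Sequence[LocusSpec] = REFERENCE_LOCI,
    n: int = 1,
    seed: int = 0,
) -> list[GenotypeRecord]:
    """Gene-drop ``n`` independent individuals of one pedigree category."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        g = _drop_individual(spec.category, spec.sex, spec.maternal_species, loci, rng)
        calls = {name: tuple(sorted(alleles)) for name, alleles in g.items()}
        out.append(GenotypeRecord(f"{spec.category}_{i:05d}", spec.sex, calls))
    return out


# ---------------------------------------------------------------------------
# mtDNA

@dataclass(frozen=True)
class MtdnaReference:
    ref_LM: str
    ref_LL: str
    sites: pd.DataFrame  # position, allele_LM, allele_LL


_BASES = "ACGT"


def simulate_mtdna(
    n_diagnostic: int = 10,
    length_bp: int = 193,
    seed: int = 0,
) -> MtdnaReference:
    """Two reference haplotypes differing at exactly ``n_diagnostic`` fixed
    positions along a ``length_bp`` fragment."""
    if n_diagnostic > length_bp:
        raise ValueError("n_diagnostic must be <= length_bp")
    rng = np.random.default_rng(seed)
    base = rng.choice(list(_BASES), size=length_bp)
    ref_lm = base.copy()
    ref_ll = base.copy()
    pos = np.sort(rng.choice(length_bp, size=n_diagnostic, replace=False))
    rows = []
    for p in pos:
        alt = rng.choice([b for b in _BASES if b != ref_lm[p]])
        ref_ll[p] = alt
        rows.append({"position": int(p), "allele_LM": str(ref_lm[p]),
                     "allele_LL": str(alt)})
    sites = pd.DataFrame(rows, columns=["position", "allele_LM", "allele_LL"])
    return MtdnaReference("".join(ref_lm), "".join(ref_ll), sites)


def sample_mtdna_query(
    refs: MtdnaReference, species: str, noise_rate: float = 0.0, seed: int = 0
) -> str:
    """A query sequence equal to the species reference plus independent
    per-site substitution noise at ``noise_rate`` (default none)."""
    ref = refs.ref_LM if species == "LM" else refs.ref_LL
    if noise_rate == 0:
        return ref
    rng = np.random.default_rng(seed)
    seq = list(ref)
    for i in range(len(seq)):
        if rng.random() < noise_rate:
            seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
    return "".join(seq)


# ---------------------------------------------------------------------------
# On-disk formats

def write_catalogue(catalogue: Catalogue, directory: str | Path) -> None:
    """Catalogue directory: one WAV per template plus a TSV manifest and a
    song-type table (id, species, collapsed sequence, parts)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in catalogue.templates:
        if t.samples is not None:
            write_wav(d / f"{t.template_id}.wav", t.samples,
                      catalogue.params.resample_rate)
        rows.append({
            "template_id": t.template_id,
            "song_type_id": t.song_type_id,
            "window_start_s": t.source_window[0],
            "window_end_s": t.source_window[1],
            "part": t.part or "",
        })
    pd.DataFrame(rows).to_csv(d / "manifest.tsv", sep="\t", index=False)
    st_rows = [
        {
            "song_type_id": st.song_type_id,
            "species": st.species,
            "collapsed": "|".join(st.collapsed_sequence),
            "parts": "|".join(u.part for u in st.units),
        }
        for st in catalogue.song_types
    ]
    pd.DataFrame(st_rows).to_csv(d / "song_types.tsv", sep="\t", index=False)


def write_truth_tsv(sim: SimulatedRecording, path: str | Path) -> None:
    sim.truth.to_csv(path, sep="\t", index=False)


def write_mtdna_fasta(refs: MtdnaReference, path: str | Path,
                      queries: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(refs.ref_LM), id="ref_LM", description="reference haplotype LM"),
        SeqRecord(Seq(refs.ref_LL), id="ref_LL", description="reference haplotype LL"),
    ]
    for name, seq in (queries or {}).items():
        records.append(SeqRecord(Seq(seq), id=name, description="query"))
    SeqIO.write(records, str(path), "fasta")
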