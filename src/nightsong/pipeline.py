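"""End-to-end orchestration: generate -> segment -> match -> categorise ->
summarise -> genetics -> stats.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` keyed on the stage name (CRC32), so every
stage is independently reproducible and every derived seed is logged in
the run log.  All outputs are TSV/JSON (plus WAV/FASTA when audio export
is requested), byte-reproducible under a fixed config and seed.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio_pipeline import (
    Recording,
    SongSegment,
    SpectrogramParams,
    compute_spectrogram,
    preprocess,
    segment_songs,
    write_wav,
)
from .hybrid_genetics import (
    REFERENCE_LOCI,
    assign_maternal_lineage,
    posterior_hybrid_class,
    write_genotypes_tsv,
    write_loci_tsv,
    write_posteriors_tsv,
)
from .song_categories import (
    CategoryLabel,
    assign_category,
    collapse_repeats,
    detect_organization,
    element_resemblance,
    summarize_bird,
)
from .song_matching import DEFAULT_ACCEPT_THRESHOLD, rank_templates
from .stats import mann_whitney_exact, quasibinomial_glm_f
from .synthetic_data import (
    Catalogue,
    PedigreeSpec,
    RenderedElement,
    RepertoireSpec,
    SimulatedRecording,
    build_catalogue,
    default_ll_grammar,
    sample_mtdna_query,
    simulate_genotypes,
    simulate_mtdna,
    simulate_recording,
    write_catalogue,
)

__all__ = [
    "BirdSpec",
    "RunConfig",
    "default_demo_cohort",
    "field_design_cohort",
    "stage_seed",
    "classify_recording",
    "run_demo",
]


@dataclass(frozen=True)
class BirdSpec:
    bird_id: str
    taxon: str        # "LM", "LL" or "F1"
    region: str       # "allopatry" or "sympatry"
    mixing_proportion: float  # P(a song is of LM origin)
    duration_min: float = 1.0
    song_rate: float = 8.0


@dataclass
class RunConfig:
    seed: int = 0
    catalogue_size: int = 12
    ll_pool_size: int = 8
    repertoire_size: int = 5   # song types drawn per bird per species pool
    full_threshold: float = 0.95
    partial_threshold: float = 0.75
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD
    noise_db: float = -30.0
    tempo_jitter: float = 0.05
    cohort: list[BirdSpec] = field(default_factory=list)
    loci: Sequence = REFERENCE_LOCI
    params: SpectrogramParams = field(default_factory=SpectrogramParams)
    write_audio: bool = False
    outdir: str | Path = "results/demo"

    def __post_init__(self) -> None:
        if not (0 < self.partial_threshold < self.full_threshold <= 1):
            raise ValueError("need 0 < partial_threshold < full_threshold <= 1")
        if not (0 < self.accept_threshold <= 1):
            raise ValueError("accept_threshold must be in (0, 1]")


def default_demo_cohort() -> list[BirdSpec]:
    """A down-scaled cohort covering every group of the study design:
    allopatric/sympatric birds of both species plus F1-intermediate males.
    Song rates follow the species means (7.2 vs 9.8 songs/min)."""
    birds = []
    for i in range(3):
        birds.append(BirdSpec(f"LM_allo_{i}", "LM", "allopatry", 1.0, 1.0, 9.8))
    for i in range(2):
        birds.append(BirdSpec(f"LM_symp_{i}", "LM", "sympatry", 1.0, 1.0, 9.8))
    for i in range(2):
        birds.append(BirdSpec(f"LL_allo_{i}", "LL", "allopatry", 0.0, 1.0, 7.2))
    for i, mix in enumerate((0.0, 0.3, 0.62)):
        birds.append(BirdSpec(f"LL_symp_{i}", "LL", "sympatry", mix, 1.0, 7.2))
    for i, mix in enumerate((0.9, 1.0)):
        birds.append(BirdSpec(f"F1_symp_{i}", "F1", "sympatry", mix, 1.0, 8.5))
    return birds


def field_design_cohort(duration_min: float = 20.0) -> list[BirdSpec]:
    """The full study design: 11 allopatric + 8 sympatric Common
    Nightingales, 8 allopatric + 9 sympatric Thrush Nightingales, and 5
    intermediate-phenotype (F1) males.  Mixing proportions for sympatric
    Thrush Nightingales span pure (0) through heavily mixed (0.94) to an
    all-heterospecific repertoire (1.0)."""
    birds = []
    for i in range(11):
        birds.append(BirdSpec(f"LM_allo_{i:02d}", "LM", "allopatry", 1.0, duration_min, 9.8))
    for i in range(8):
        birds.append(BirdSpec(f"LM_symp_{i:02d}", "LM", "sympatry", 1.0, duration_min, 9.8))
    for i in range(8):
        birds.append(BirdSpec(f"LL_allo_{i:02d}", "LL", "allopatry", 0.0, duration_min, 7.2))
    mixes = (0.0, 0.07, 0.25, 0.45, 0.62, 0.75, 0.85, 0.94, 1.0)
    for i, mix in enumerate(mixes):
        birds.append(BirdSpec(f"LL_symp_{i:02d}", "LL", "sympatry", mix, duration_min, 7.2))
    for i, mix in enumerate((0.86, 0.99, 1.0, 1.0, 1.0)):
        birds.append(BirdSpec(f"F1_symp_{i:02d}", "F1", "sympatry", mix, duration_min, 8.5))
    return birds


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed and the stage
    name; logged in the run log so every stage can be replayed alone."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Song-side classification of one recording

def _align_truth(segments: list[SongSegment], sim: SimulatedRecording
                 ) -> list[list[RenderedElement]]:
    """For each segment, the truth element logs of the songs it overlaps."""
    out: list[list[RenderedElement]] = []
    for seg in segments:
        logs: list[RenderedElement] = []
        for i, row in sim.truth.iterrows():
            if row.start_s < seg.end_s and row.end_s > seg.start_s:
                logs.extend(sim.element_logs[int(row.song_index)])
        out.append(sorted(logs, key=lambda e: e.start_s))
    return out


def classify_recording(
    sim: SimulatedRecording,
    catalogue: Catalogue,
    config: RunConfig,
) -> tuple[list[CategoryLabel], list[SongSegment], pd.DataFrame]:
    """Segment, match and categorise one bird's recording.

    Returns (labels, segments, match table).  Element sequences come from
    the synthesis truth log (the spectrogram-reading step a human scorer
    performs); template matching and gamma detection run on the audio.
    """
    cleaned = preprocess(sim.recording, config.params)
    segments = segment_songs(cleaned)
    truth_logs = _align_truth(segments, sim)
    type_seq = {
        st.song_type_id: list(st.collapsed_sequence) for st in catalogue.song_types
    }
    labels: list[CategoryLabel] = []
    match_rows = []
    gamma_templates = catalogue.gamma_templates
    for seg, log in zip(segments, truth_logs):
        if seg.excluded or not log:
            labels.append(CategoryLabel.EXCLUDED)
            continue
        spec = compute_spectrogram(seg.samples, config.params)
        match = rank_templates(spec, catalogue.templates, seg.segment_id)
        song_elems = collapse_repeats([e.label for e in log])
        # candidate catalogue types: top-k by correlation score above the
        # acceptance threshold; the assigned type is the candidate whose
        # element sequence the song resembles most (the automated stand-in
        # for the visual inspection of the best-matching candidates)
        candidates = sorted(
            (sty for sty, sc in match.type_scores.items()
             if sc >= config.accept_threshold),
            key=lambda sty: (-match.type_scores[sty], sty),
        )[:5]
        resemblance = max(
            (element_resemblance(song_elems, type_seq[sty]) for sty in candidates),
            default=0.0,
        )
        org = detect_organization(
            [(e.label, e.part, e.reps) for e in log],
            song_spec=spec,
            gamma_templates=gamma_templates,
            gamma_threshold=config.accept_threshold,
        )
        label = assign_category(
            resemblance, org, config.full_threshold, config.partial_threshold
        )
        labels.append(label)
        for rank, (tid, score) in enumerate(match.ranked[:5]):
            match_rows.append({
                "segment_id": seg.segment_id,
                "rank": rank + 1,
                "template_id": tid,
                "score": round(score, 6),
            })
    match_df = pd.DataFrame(
        match_rows, columns=["segment_id", "rank", "template_id", "score"]
    )
    return labels, segments, match_df


# ---------------------------------------------------------------------------
# Demo run

def _sample_ll_pool(n: int, seed: int) -> list:
    grammar = default_ll_grammar()
    rng = np.random.default_rng(seed)
    seen, pool = set(), []
    misses = 0
    while len(pool) < n:
        st = grammar.sample_song_type(f"T{len(pool) + 1:03d}", rng)
        if st.collapsed_sequence in seen:
            misses += 1
            if misses > 200 + 50 * n:
                raise ValueError("LL grammar cannot supply that many distinct types")
            continue
        seen.add(st.collapsed_sequence)
        pool.append(st)
    return pool


def _stats_report(per_bird: pd.DataFrame) -> dict:
    """The comparisons of the study design, on the per-bird summary table."""
    report: dict[str, dict] = {}

    ll = per_bird[per_bird.taxon == "LL"]
    lm = per_bird[per_bird.taxon == "LM"]
    if len(ll) and len(lm):
        mw = mann_whitney_exact(ll.song_rate.to_numpy(), lm.song_rate.to_numpy())
        report["song_rate_LL_vs_LM"] = {
            "test": "mann_whitney_exact", "U": mw.U, "p": mw.p_value,
            "exact": mw.exact, "n1": mw.n_x, "n2": mw.n_y,
        }

    def glm(name: str, df: pd.DataFrame, group_col: str) -> None:
        if df[group_col].nunique() < 2 or len(df) < df[group_col].nunique() + 2:
            report[name] = {"test": "quasibinomial_glm_f", "skipped": "too few birds"}
            return
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = quasibinomial_glm_f(
                    df.rename(columns={group_col: "group"})[
                        ["n_identified", "n_songs", "group"]
                    ].rename(columns={"n_identified": "successes", "n_songs": "total"})
                )
            report[name] = {
                "test": "quasibinomial_glm_f", "F": res.F, "df1": res.df1,
                "df2": res.df2, "p": res.p_value, "dispersion": res.dispersion,
            }
        except (ValueError, RuntimeError) as exc:
            report[name] = {"test": "quasibinomial_glm_f", "skipped": str(exc)}

    glm("identified_LL_sympatry_vs_allopatry", ll, "region")
    symp = per_bird[per_bird.region == "sympatry"]
    glm("identified_sympatric_LL_vs_LM",
        symp[symp.taxon.isin(["LL", "LM"])], "taxon")
    glm("identified_LM_sympatry_vs_allopatry", lm, "region")
    glm("identified_F1_vs_sympatric_LL",
        symp[symp.taxon.isin(["F1", "LL"])], "taxon")
    return report


def run_demo(config: RunConfig) -> dict:
    """Run the whole pipeline on a synthetic cohort and write the report
    bundle (per-bird TSV, match TSV, posterior TSV, stats JSON, run log).
    Returns the report as a dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("catalogue", "ll_pool", "recordings", "genotypes", "mtdna")
    }
    import scipy

    from . import __version__

    log: dict = {"seed": config.seed, "stage_seeds": seeds,
                 "n_birds": len(config.cohort),
                 "versions": {"nightsong": __version__,
                              "numpy": np.__version__,
                              "scipy": scipy.__version__}}

    if not config.cohort:
        warnings.warn("empty cohort: writing an empty report")
        pd.DataFrame().to_csv(out / "per_bird.tsv", sep="\t", index=False)
        (out / "stats.json").write_text(json.dumps({}, indent=2))
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        return {"per_bird": pd.DataFrame(), "stats": {}, "log": log}

    catalogue = build_catalogue(config.catalogue_size, seed=seeds["catalogue"],
                                params=config.params)
    if config.write_audio:
        write_catalogue(catalogue, out / "catalogue")
    ll_pool = _sample_ll_pool(config.ll_pool_size, seeds["ll_pool"])
    rng = np.random.default_rng(seeds["recordings"])

    per_bird_rows = []
    match_frames = []
    truth_frames = []
    exclusions = {}
    for bird in config.cohort:
        k = min(config.repertoire_size, config.catalogue_size)
        lm_types = [catalogue.song_types[int(i)]
                    for i in rng.choice(config.catalogue_size, k, replace=False)]
        kl = min(config.repertoire_size, config.ll_pool_size)
        ll_types = [ll_pool[int(i)]
                    for i in rng.choice(config.ll_pool_size, kl, replace=False)]
        spec = RepertoireSpec(
            lm_pool=lm_types if bird.mixing_proportion > 0 else [],
            ll_pool=ll_types if bird.mixing_proportion < 1 else [],
            mixing_proportion=bird.mixing_proportion,
        )
        sim = simulate_recording(
            spec, bird.duration_min, bird.song_rate,
            seed=int(rng.integers(2**31)), noise_db=config.noise_db,
            tempo_jitter=config.tempo_jitter, bird_id=bird.bird_id,
        )
        if config.write_audio:
            (out / "audio").mkdir(exist_ok=True)
            write_wav(out / "audio" / f"{bird.bird_id}.wav",
                      sim.recording.samples, sim.recording.sample_rate)
        try:
            labels, segments, match_df = classify_recording(sim, catalogue, config)
            summary = summarize_bird(labels, sim.recording, segments, bird.bird_id)
        except ValueError as exc:
            warnings.warn(f"skipping bird {bird.bird_id}: {exc}")
            exclusions[bird.bird_id] = str(exc)
            continue
        match_frames.append(match_df.assign(bird_id=bird.bird_id))
        truth_frames.append(sim.truth.assign(bird_id=bird.bird_id))
        row = {
            "bird_id": bird.bird_id, "taxon": bird.taxon, "region": bird.region,
            "true_mixing": bird.mixing_proportion,
            "n_songs": summary.n_songs, "n_excluded": summary.n_excluded,
            "proportion_identified": round(summary.proportion_identified, 6),
            "song_rate": round(summary.song_rate, 4),
            "mixed_singer": summary.mixed_singer,
            "repertoire_class": summary.repertoire_class,
        }
        for c in CategoryLabel:
            row[f"n_{c.value}"] = summary.counts[c]
        row["n_identified"] = (
            summary.counts[CategoryLabel.LM_CATALOGUE]
            + summary.counts[CategoryLabel.LM_PARTIAL_CATALOGUE]
            + summary.counts[CategoryLabel.LM]
        )
        per_bird_rows.append(row)

    per_bird = pd.DataFrame(per_bird_rows)
    per_bird.to_csv(out / "per_bird.tsv", sep="\t", index=False)
    if match_frames:
        pd.concat(match_frames).to_csv(out / "matches.tsv", sep="\t", index=False)
        pd.concat(truth_frames).to_csv(out / "truth.tsv", sep="\t", index=False)

    # genetics: one genotyped individual per bird, mtDNA for the F1 males
    specs = {"LM": PedigreeSpec("PureLM"), "LL": PedigreeSpec("PureLL"),
             "F1": PedigreeSpec("F1", maternal_species="LL")}
    records = []
    grng = np.random.default_rng(seeds["genotypes"])
    for bird in config.cohort:
        rec = simulate_genotypes(specs[bird.taxon], config.loci, 1,
                                 seed=int(grng.integers(2**31)))[0]
        rec.individual_id = bird.bird_id
        records.append(rec)
    write_genotypes_tsv(records, out / "genotypes.tsv")
    write_loci_tsv(list(config.loci), out / "loci.tsv")
    posteriors = [posterior_hybrid_class(r, config.loci) for r in records]
    write_posteriors_tsv(posteriors, out / "posteriors.tsv")

    refs = simulate_mtdna(seed=seeds["mtdna"])
    mtdna_rows = []
    for bird in config.cohort:
        if bird.taxon != "F1":
            continue
        q = sample_mtdna_query(refs, "LL")  # F1s descend from LL mothers
        a = assign_maternal_lineage(q, refs.ref_LM, refs.ref_LL)
        mtdna_rows.append({"bird_id": bird.bird_id, "maternal_species": a.species,
                           "matched_sites": a.matched_sites,
                           "total_sites": a.total_sites})
    pd.DataFrame(mtdna_rows, columns=["bird_id", "maternal_species",
                                      "matched_sites", "total_sites"]
                 ).to_csv(out / "maternal_lineage.tsv", sep="\t", index=False)

    stats_report = _stats_report(per_bird) if len(per_bird) else {}
    (out / "stats.json").write_text(json.dumps(stats_report, indent=2, sort_keys=True))

    # aggregate report mirroring the taxon x region grouping
    agg = {}
    if len(per_bird):
        for (taxon, region), grp in per_bird.groupby(["taxon", "region"]):
            agg[f"{taxon}_{region}"] = {
                "n_birds": int(len(grp)),
                "mean_proportion_identified": float(grp.proportion_identified.mean()),
                "n_mixed_singers": int(grp.mixed_singer.sum()),
            }
    (out / "aggregate.json").write_text(json.dumps(agg, indent=2, sort_keys=True))

    log["exclusions"] = exclusions
    log["n_classified_birds"] = int(len(per_bird))
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"per_bird": per_bird, "stats": stats_report, "aggregate": agg,
            "posteriors": posteriors, "log": log}
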