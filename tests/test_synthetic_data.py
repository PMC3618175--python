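"""Generator properties: catalogue distinctness/determinism, rendering,
recording truth tables, gene-dropping expectations, mtDNA references."""

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from nightsong.hybrid_genetics import REFERENCE_LOCI, assign_maternal_lineage
from nightsong.synthetic_data import (
    ElementToken,
    PartTemplate,
    PedigreeSpec,
    RepertoireSpec,
    SongGrammar,
    build_catalogue,
    default_ll_grammar,
    default_lm_grammar,
    render_song,
    sample_mtdna_query,
    simulate_genotypes,
    simulate_mtdna,
    simulate_recording,
    write_catalogue,
    write_mtdna_fasta,
)

DIAGNOSTIC = [l for l in REFERENCE_LOCI if l.is_diagnostic]


class TestGrammars:
    def test_lm_grammar_emits_all_four_parts(self, lm_grammar):
        rng = np.random.default_rng(0)
        st = lm_grammar.sample_song_type("X", rng)
        assert [p.name for p in lm_grammar.parts] == ["alpha", "beta", "gamma", "omega"]
        assert {u.part for u in st.units} == {"alpha", "beta", "gamma", "omega"}

    def test_ll_grammar_shape(self, ll_grammar):
        rng = np.random.default_rng(0)
        st = ll_grammar.sample_song_type("X", rng)
        parts = {u.part for u in st.units}
        assert "beta" not in parts and "omega" not in parts
        # always begins with a repeated element
        assert st.units[0].min_reps >= 2

    def test_duplicate_labels_rejected(self):
        tok = ElementToken("e", "whistle", 1000, 2000, 0.1, 0.5)
        with pytest.raises(ValueError, match="unique"):
            SongGrammar(
                "LL",
                (
                    PartTemplate("head", (tok,), (1, 1), (3, 4)),
                    PartTemplate("mid", (tok,), (1, 1), (1, 1)),
                ),
            )

    def test_element_token_invariants(self):
        with pytest.raises(ValueError):
            ElementToken("bad", "whistle", 2000, 1000, 0.1, 0.5)
        with pytest.raises(ValueError):
            ElementToken("bad", "nope", 1000, 2000, 0.1, 0.5)


class TestCatalogue:
    def test_distinctness_and_count(self, catalogue8):
        seqs = [st.collapsed_sequence for st in catalogue8.song_types]
        assert len(catalogue8.song_types) == 8
        assert len(set(seqs)) == 8
        assert 8 <= len(catalogue8.templates) <= 16

    def test_determinism(self):
        a = build_catalogue(6, seed=42)
        b = build_catalogue(6, seed=42)
        assert [s.collapsed_sequence for s in a.song_types] == [
            s.collapsed_sequence for s in b.song_types
        ]
        for ta, tb in zip(a.templates, b.templates):
            assert ta.source_window == tb.source_window
            np.testing.assert_array_equal(ta.spectrogram.matrix, tb.spectrogram.matrix)
        for sid in a.renderings:
            np.testing.assert_array_equal(
                a.renderings[sid].samples, b.renderings[sid].samples
            )

    def test_single_type_catalogue_self_match(self, params):
        from nightsong.audio_pipeline import compute_spectrogram
        from nightsong.song_matching import cross_correlate

        cat = build_catalogue(1, seed=3)
        assert len(cat.song_types) == 1
        rend = cat.renderings[cat.song_types[0].song_type_id]
        spec = compute_spectrogram(rend.samples, params)
        score = cross_correlate(spec, cat.templates[0].spectrogram)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_full_scale_catalogue(self):
        cat = build_catalogue(425, seed=7)
        assert len(cat.song_types) == 425
        assert 425 <= len(cat.templates) <= 850
        assert len({s.collapsed_sequence for s in cat.song_types}) == 425

    def test_alphabet_too_small_fails(self):
        tiny = SongGrammar(
            "LM",
            (
                PartTemplate(
                    "alpha",
                    (ElementToken("a0", "whistle", 2000, 2300, 0.12, 0.35),),
                    (1, 1), (1, 2),
                ),
                PartTemplate(
                    "beta",
                    (ElementToken("b0", "whistle", 3000, 3300, 0.1, 0.45),),
                    (1, 1), (2, 4),
                ),
                PartTemplate(
                    "gamma",
                    tuple(
                        ElementToken(f"g{i}", "buzz", 6000 + 500 * i,
                                     6300 + 500 * i, 0.06, 1.0)
                        for i in range(2)
                    ),
                    (2, 2), (3, 4),
                ),
                PartTemplate(
                    "omega",
                    (ElementToken("o0", "click", 1200, 1500, 0.1, 0.5),),
                    (1, 1), (1, 1), variable_reps=False,
                ),
            ),
        )
        with pytest.raises(ValueError, match="too small"):
            build_catalogue(10, tiny, seed=0)

    def test_catalogue_directory_round_trip(self, catalogue8, tmp_path):
        write_catalogue(catalogue8, tmp_path / "cat")
        manifest = pd.read_csv(tmp_path / "cat" / "manifest.tsv", sep="\t")
        assert len(manifest) == len(catalogue8.templates)
        assert set(manifest.columns) >= {
            "template_id", "song_type_id", "window_start_s", "window_end_s",
        }
        types = pd.read_csv(tmp_path / "cat" / "song_types.tsv", sep="\t")
        assert len(types) == 8


class TestRenderSong:
    def test_deterministic_under_fixed_seed(self, catalogue8):
        st = catalogue8.song_types[0]
        a = render_song(st, 0.1, -30.0, seed=5)
        b = render_song(st, 0.1, -30.0, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.element_log == b.element_log

    def test_tempo_jitter_preserves_collapsed_sequence(self, catalogue8):
        st = catalogue8.song_types[1]
        for seed in range(5):
            rend = render_song(st, tempo_jitter=0.1, seed=seed)
            collapsed = []
            for e in rend.element_log:
                if not collapsed or collapsed[-1] != e.label:
                    collapsed.append(e.label)
            assert tuple(collapsed) == st.collapsed_sequence

    def test_repetition_counts_vary_across_renderings(self, catalogue8):
        st = catalogue8.song_types[0]
        reps = {
            tuple(e.reps for e in render_song(st, seed=s).element_log)
            for s in range(12)
        }
        assert len(reps) > 1

    def test_invalid_jitter_rejected(self, catalogue8):
        with pytest.raises(ValueError):
            render_song(catalogue8.song_types[0], tempo_jitter=1.5)


class TestSimulateRecording:
    def test_song_count_and_truth_species(self, catalogue8, ll_grammar):
        rng = np.random.default_rng(2)
        ll_types = [ll_grammar.sample_song_type(f"T{i}", rng) for i in range(4)]
        spec = RepertoireSpec(ll_pool=ll_types, mixing_proportion=0.0)
        sim = simulate_recording(spec, duration_min=2.0, song_rate_per_min=8.0,
                                 seed=0)
        assert len(sim.truth) == 16
        assert (sim.truth.species == "LL").all()
        assert sim.recording.duration == pytest.approx(120.0, abs=0.01)
        # songs are time-ordered and non-overlapping with >= 1 s gaps
        gaps = sim.truth.start_s.to_numpy()[1:] - sim.truth.end_s.to_numpy()[:-1]
        assert (gaps >= 0.99).all()

    def test_mixing_proportion_recovered(self, catalogue8, ll_grammar):
        rng = np.random.default_rng(3)
        ll_types = [ll_grammar.sample_song_type(f"T{i}", rng) for i in range(4)]
        spec = RepertoireSpec(
            lm_pool=list(catalogue8.song_types),
            ll_pool=ll_types,
            mixing_proportion=0.62,
        )
        sim = simulate_recording(spec, duration_min=10.0, song_rate_per_min=15.0,
                                 seed=1, noise_db=-np.inf)
        frac = (sim.truth.species == "LM").mean()
        n = len(sim.truth)
        assert n == 150
        assert abs(frac - 0.62) < 3 * np.sqrt(0.62 * 0.38 / n)

    def test_rate_exceeding_gaps_fails(self, catalogue8):
        spec = RepertoireSpec(lm_pool=list(catalogue8.song_types),
                              mixing_proportion=1.0)
        with pytest.raises(ValueError, match="exceed"):
            simulate_recording(spec, duration_min=1.0, song_rate_per_min=40.0,
                               seed=0)


class TestSimulateGenotypes:
    def test_f1_heterozygous_at_diagnostic_loci(self):
        recs = simulate_genotypes(PedigreeSpec("F1"), DIAGNOSTIC, n=50, seed=0)
        for r in recs:
            for locus in DIAGNOSTIC:
                g = r.calls[locus.name]
                assert g[0] != g[1], locus.name

    def test_pure_lm_hardy_weinberg_at_lu10(self):
        lu10 = [l for l in REFERENCE_LOCI if l.name == "Lu10"]
        recs = simulate_genotypes(PedigreeSpec("PureLM"), lu10, n=8000, seed=1)
        het = np.mean([r.calls["Lu10"][0] != r.calls["Lu10"][1] for r in recs])
        assert het == pytest.approx(2 * 0.8 * 0.2, abs=0.02)

    def test_bc2_mean_heterozygosity_quarter(self):
        loci = tuple(
            DIAGNOSTIC[i % len(DIAGNOSTIC)].__class__(
                f"D{i:02d}", "autosomal", float(i), ("A", "B"),
                (1.0, 0.0), (0.0, 1.0),
            )
            for i in range(12)
        )
        recs = simulate_genotypes(PedigreeSpec("BC2_LL"), loci, n=4000, seed=2)
        fracs = [
            np.mean([g[0] != g[1] for g in r.calls.values()]) for r in recs
        ]
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.01)

    def test_female_zw_single_z_copy(self):
        recs = simulate_genotypes(
            PedigreeSpec("F1", sex="female_ZW"), REFERENCE_LOCI, n=5, seed=3
        )
        for r in recs:
            for locus in REFERENCE_LOCI:
                expected = 1 if locus.chromosome_class == "Z" else 2
                assert len(r.calls[locus.name]) == expected

    def test_determinism(self):
        a = simulate_genotypes(PedigreeSpec("BC1_LM"), REFERENCE_LOCI, n=10, seed=9)
        b = simulate_genotypes(PedigreeSpec("BC1_LM"), REFERENCE_LOCI, n=10, seed=9)
        assert [r.calls for r in a] == [r.calls for r in b]


class TestMtdna:
    def test_defaults_ten_fixed_differences(self):
        refs = simulate_mtdna(seed=0)
        assert len(refs.ref_LM) == len(refs.ref_LL) == 193
        diffs = sum(a != b for a, b in zip(refs.ref_LM, refs.ref_LL))
        assert diffs == 10
        assert len(refs.sites) == 10

    def test_zero_diagnostic_sites_indeterminate(self):
        refs = simulate_mtdna(n_diagnostic=0, seed=1)
        assert refs.ref_LM == refs.ref_LL
        a = assign_maternal_lineage(refs.ref_LM, refs.ref_LM, refs.ref_LL)
        assert a.species == "indeterminate"

    def test_clean_query_assigned_with_full_support(self):
        refs = simulate_mtdna(seed=2)
        q = sample_mtdna_query(refs, "LL")
        a = assign_maternal_lineage(q, refs.ref_LM, refs.ref_LL)
        assert a.species == "LL"
        assert (a.matched_sites, a.total_sites) == (10, 10)

    def test_noisy_query_majority_still_wins(self):
        refs = simulate_mtdna(seed=3)
        q = sample_mtdna_query(refs, "LM", noise_rate=0.02, seed=4)
        a = assign_maternal_lineage(q, refs.ref_LM, refs.ref_LL)
        assert a.species == "LM"

    def test_fasta_round_trip(self, tmp_path):
        refs = simulate_mtdna(seed=5)
        p = tmp_path / "mt.fasta"
        write_mtdna_fasta(refs, p, queries={"h1": sample_mtdna_query(refs, "LL")})
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(p), "fasta")}
        assert records["ref_LM"] == refs.ref_LM
        assert records["ref_LL"] == refs.ref_LL
        assert records["h1"] == refs.ref_LL
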