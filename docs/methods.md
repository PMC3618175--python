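# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data validation
does and does not demonstrate.

## Song synthesis and the two grammars

Songs are generated by species-specific grammars over an alphabet of
acoustic *elements*.  An element is a synthesised glyph — whistle (tonal,
slow vibrato), sweep (linear chirp), trill-pulse (on/off amplitude pulses
at 16–45 Hz), buzz (sinusoidal AM at 60–100 Hz), or click (band-modulated
noise burst) — with a frequency band, duration and relative amplitude.

The Common Nightingale (LM) grammar always emits four parts in order:

| part  | pool | elements/type | reps/element | band (Hz) | rel. amplitude |
|-------|------|---------------|--------------|-----------|----------------|
| alpha | 3    | 1             | 1–2          | 2000–3200 | 0.35 |
| beta  | 6    | 2             | 2–4          | 3400–5800 | 0.45 |
| gamma | 30   | 2             | 3–4          | 6000–10200| 1.00 |
| omega | 3    | 1             | 1            | 1200–1900 | 0.5 |

The Thrush Nightingale (LL) grammar begins with a repeated head element
(3–6 reps), continues with 2–3 middle elements and ends in a terminal
trill; it emits no beta and no omega part, and all its bands lie below
6 kHz.

Design choices that matter:

- **A song type's identity is its collapsed element sequence** (adjacent
  repetitions removed).  Repetition counts are re-drawn at every rendering
  from a truncated geometric distribution (p = 0.45, truncated to the
  unit's range), so renderings vary in length but never in collapsed
  sequence.
- **The gamma section is the loudest part and carries the type's
  signature.**  Each catalogue type uses an ordered pair of distinct gamma
  elements, unique across the catalogue (30 elements → 870 ordered pairs,
  comfortably above the 425-type full catalogue).  This is what makes
  0.5-s maximum-amplitude templates discriminative: template matching
  cannot separate two types whose loudest half-second is acoustically
  identical, and early versions of the generator that allowed shared
  gamma signatures produced exactly that degeneracy.  Real catalogues
  behave the same way — types are distinct acoustic entities.
- Amplitude hierarchy (gamma ≫ beta/omega ≫ alpha) guarantees the
  maximum-RMS window lands on gamma; template extraction additionally
  restricts candidate windows to gamma-centred ones when part annotations
  are available.
- Recordings place songs with at least 1 s of silence between them
  (configurable), so energy segmentation of clean synthetic audio is
  unambiguous.  Inter-song gap statistics are a convention of this
  generator, not an empirical fact.
- Default rendering noise is white at −30 dB relative to the song peak
  and tempo jitter ±5%; these are the "default noise" conditions all
  end-to-end validation uses.

## Audio chain

Preprocessing resamples to 22.05 kHz (polyphase), normalises the peak to
0.85 full scale, and applies spectral gating: STFT (Hann, 512, 50%
overlap), magnitude bins below −40 dB attenuated by 90 dB, overlap-add
reconstruction.  dB values are referenced to the bin magnitude of a
full-scale sine (window gain/2) — without that reference the threshold
would be meaningless for an unnormalised STFT.  Because gating a
sub-threshold-only signal is a uniform linear gain, a −60 dBFS sine is
attenuated by exactly 90 dB; mixed signals keep their loud bins untouched
while the interior residual error stays near the gate threshold.  The
chain is idempotent away from the recording edges, where the analysis
taper pushes real content under the threshold.

Spectrograms are magnitude STFTs (Hamming, FFT 256, 50% overlap).
Segmentation thresholds a 50-ms-smoothed RMS envelope at −45 dBFS, merges
active runs separated by <0.3 s and flags runs shorter than 0.5 s as
fragmented; fragmented segments are excluded downstream.

## Template matching

Templates are 0.5-s *frame slices of the source rendering's spectrogram*
(not re-STFTed audio), which makes "a template scores exactly 1 on its
own source" an identity rather than an approximation.  Matching slides
the template along the song's time axis only (no frequency shifting, a
fixed convention), computing at each lag the zero-mean normalised
correlation of the overlapping patch; edge lags with at least half the
template overlapping are normalised on the overlap region.  Equal scores
tie-break to the lexicographically lower template id, and window-energy
ties in template extraction are quantised (9 decimal digits of relative
energy) so roundoff cannot break the earliest-window rule.  Scores are
amplitude-scale invariant; white-noise null scores stay below 0.3.

The per-song-type score is the max over that type's templates.  A match
is accepted when the best score reaches 0.6 (configurable); category
assignment then considers the top five types above the threshold and uses
the highest element-sequence resemblance among them — the automated
stand-in for a human inspecting the best-matching candidates.  Element
sequences themselves are taken from the synthesis truth log: the package
automates the decision logic, not the spectrogram-reading step a human
scorer performs, and that is the deliberate scope of the acceptance
surface.

Resemblance is LCS(song, catalogue type)/|catalogue type| on collapsed
sequences; LCS encodes element order as well as identity, so reordered
elements lose credit.  This is one reasonable formalisation of "percent
of the element sequence reproduced"; thresholds are 0.95 and 0.75.

## Gene dropping and the six-class posterior

Genotypes are simulated by explicit gene-dropping: founder gene copies
drawn from the per-species allele frequencies of the seven reference loci
(five fully diagnostic; Lu01 and Lu10 partially informative), hybrid
gametes by fair per-locus segregation, loci independent.  Z-linked loci
follow avian sex chromosomes (males ZZ, females ZW).  Two pedigree
conventions:

- The hybrid parent of every backcross is male (F1 females are sterile —
  Haldane's rule), the pure parent female.
- Internal hybrid ancestors get a random cross direction.  With a fixed
  direction, an F1 mother's single Z is deterministic and F2 males could
  never be Z-homozygous for one species, contradicting the ¼/½/¼ class
  definition; randomising restores agreement (verified by χ² against the
  analytic tables).  The focal individual's maternal species stays fixed
  — it determines the mtDNA lineage.

The classifier evaluates, for each of six classes, the likelihood of the
observed genotypes under the class's gene-copy-origin mixture with
plug-in reference frequencies, optionally smoothed by a pseudo-count
(default 0.5 per allele over the implied 40 reference gene copies, which
prevents hard zeros at fixed loci from one mistyped call).  The prior is
uniform over the six classes; missing loci are skipped.  This replaces a
joint MCMC over allele frequencies and class proportions; with
(near-)diagnostic markers the likelihood is essentially as sharp, but two
consequences are documented:

- **Identifiability at seven loci.**  Pure species and F1 are recovered
  perfectly (the posterior is the exact Bayes rule under the generating
  model), but F2 overlaps BC1 (an F2 that segregated mostly heterozygous
  looks like a backcross): F2 modal-class recovery is ~55%, BC1 ~85%.
  With 30 diagnostic loci the same classifier exceeds 95% for every
  class, so this is an information limit of the marker panel, not of the
  method.
- **The pure-class posterior ceiling.**  A BC1 toward the same species
  retains likelihood ½ per homozygous diagnostic locus, so a pure male's
  posterior at these seven loci has a median of ~98.9% under the uniform
  prior — a data-informed class-proportion prior (as a joint model
  effectively uses) is what pushes pure individuals above 99%.

BC2/BC3 are deliberately not classifier classes; they are screened
analytically: expected heterozygous diagnostic fraction 0.5ⁿ, and
P(all L loci homozygous) = (1 − 0.5ⁿ)^L under independence.

mtDNA references are two haplotypes differing at exactly 10 fixed sites
over 193 bp; maternal assignment is a majority vote over diagnostic
positions, indeterminate on ties.  Query noise is independent per-site
substitution, default 0.

## Statistics

The exact Mann–Whitney test builds the full null distribution of U by
the Gaussian-binomial counting recurrence in exact integer arithmetic
(validated against exhaustive enumeration for all group sizes ≤ 7).  U is
reported in the min(U, mn−U) convention, with both directions available;
two-sided p doubles the smaller tail, capped at 1.  Ties fall back to
midranks with the tie-corrected normal approximation and are flagged.

The quasibinomial GLM fits grouped proportions by IRLS (logit link,
convergence when the deviance changes by <1e-10 relative, max 100
iterations; fitted probabilities clipped at 1e-10 with a separation
warning).  Dispersion is Pearson χ² over residual df of the full model;
the group effect is tested by F = (Δdeviance/Δdf)/dispersion against
F(Δdf, residual df).  The implementation reproduces R's
`glm(..., family=quasibinomial)` dispersion, F and p to 5+ significant
figures on a frozen overdispersed fixture.

## Reproducibility and problem sizes

Every operation is deterministic under a fixed seed; the pipeline fans a
single seed out to per-stage seeds via `SeedSequence` keyed on the stage
name, all logged.  The demo cohort and the validation runs are scaled for
a desk machine — 12-type catalogues, one-minute recordings, 200-draw
posterior studies, 10,000-individual gene-dropping checks — chosen so
that binomial/Monte-Carlo error is comfortably inside every asserted
tolerance; the full 425-type catalogue builds in seconds and is exercised
in the tests.

## What the synthetic validation does not show

The generator emulates the *structure* the analysis assumes, not field
conditions: clean species-typical grammars, separable element bands,
stationary white noise, silence-gapped songs, and truth-log element
sequences.  Passing tests therefore demonstrate the correctness of the
decision logic, the matching mathematics and the genetic model — not
robustness to real-field recording quality, overlapping singers, song
plasticity, or human spectrogram-reading variability.  Linkage between
loci, later-generation hybrid classes beyond the analytic screen, and
female song are out of scope.
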