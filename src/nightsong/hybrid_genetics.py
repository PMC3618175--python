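"""Hybrid-category inference from species-informative SNPs.

Implements a six-class genotype-category classifier in the style of
NewHybrids, but with plug-in reference allele frequencies instead of MCMC
joint estimation: each class (pure species, F1, F2, first-generation
backcross in either direction) is defined by its distribution over the
species-of-origin of the two gene copies at a locus, and the likelihood of
an observed genotype is the origin-mixture over random draws from the
per-species allele-frequency vectors.  Because the reference markers are
(near-)diagnostic, the plug-in likelihood is essentially as informative as
the full joint model.

Also provides the analytic backcross heterozygosity screen (a BC_n
individual is expected to be heterozygous at a fraction 0.5**n of fully
diagnostic loci), a small linkage-map utility, and maternal-lineage
assignment from diagnostic mtDNA sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusSpec",
    "GenotypeRecord",
    "HybridClassPosterior",
    "MaternalAssignment",
    "HYBRID_CLASSES",
    "REFERENCE_LOCI",
    "genotype_class_freqs",
    "posterior_hybrid_class",
    "backcross_het_expectation",
    "prob_all_homozygous",
    "map_distance_cm",
    "assign_maternal_lineage",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_loci_tsv",
    "write_loci_tsv",
    "write_posteriors_tsv",
]

#: The six genotype categories the classifier distinguishes.  Later-generation
#: backcrosses (BC2, BC3) are deliberately not classes; they are handled by the
#: heterozygosity screen (`backcross_het_expectation`, `prob_all_homozygous`).
HYBRID_CLASSES: tuple[str, ...] = ("PureLM", "PureLL", "F1", "F2", "BC1_LM", "BC1_LL")

#: Distribution of the ordered pair of gene-copy origins for a diploid locus,
#: as P(LM/LM), P(LM/LL one copy each), P(LL/LL).
_DIPLOID_ORIGIN: dict[str, tuple[float, float, float]] = {
    "PureLM": (1.0, 0.0, 0.0),
    "PureLL": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1_LM": (0.5, 0.5, 0.0),
    "BC1_LL": (0.0, 0.5, 0.5),
}

#: P(single gene copy is of LM origin), for Z-linked loci in ZW females.
#: Hybrid classes use the origin-marginal of the diploid definition.
_HAPLOID_ORIGIN_LM: dict[str, float] = {
    "PureLM": 1.0,
    "PureLL": 0.0,
    "F1": 0.5,
    "F2": 0.5,
    "BC1_LM": 0.75,
    "BC1_LL": 0.25,
}


@dataclass(frozen=True)
class LocusSpec:
    """A biallelic species-informative locus.

    ``freq_LM`` / ``freq_LL`` give the frequencies of ``alleles[0]`` and
    ``alleles[1]`` in the two reference species, estimated from allopatric
    reference samples.  ``position_mb`` is the position in the zebra finch
    genome and is informational only.
    """

    name: str
    chromosome_class: str  # "autosomal" or "Z"
    position_mb: float
    alleles: tuple[str, str]
    freq_LM: tuple[float, float]
    freq_LL: tuple[float, float]

    def __post_init__(self) -> None:
        if self.chromosome_class not in ("autosomal", "Z"):
            raise ValueError(f"unknown chromosome class {self.chromosome_class!r}")
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError("a locus needs two distinct alleles")
        for fr in (self.freq_LM, self.freq_LL):
            if any(f < 0 or f > 1 for f in fr):
                raise ValueError(f"allele frequencies outside [0,1] at {self.name}")
            if not math.isclose(sum(fr), 1.0, abs_tol=1e-9):
                raise ValueError(f"allele frequencies at {self.name} do not sum to 1")

    @property
    def is_diagnostic(self) -> bool:
        """True iff each species is fixed for a different allele."""
        return (self.freq_LM[0] == 1.0 and self.freq_LL[1] == 1.0) or (
            self.freq_LM[1] == 1.0 and self.freq_LL[0] == 1.0
        )

    def frequencies(self, species: str) -> tuple[float, float]:
        if species == "LM":
            return self.freq_LM
        if species == "LL":
            return self.freq_LL
        raise ValueError(f"unknown species {species!r}")

    def smoothed(self, pseudo_count: float, ref_gene_copies: int = 40) -> "LocusSpec":
        """Return a copy with `pseudo_count` added per allele to the implied
        reference allele counts (default 2N = 40 gene copies per species)."""
        if pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")
        if pseudo_count == 0:
            return self

        def _sm(fr: tuple[float, float]) -> tuple[float, float]:
            tot = ref_gene_copies + 2 * pseudo_count
            return (
                (fr[0] * ref_gene_copies + pseudo_count) / tot,
                (fr[1] * ref_gene_copies + pseudo_count) / tot,
            )

        return LocusSpec(
            self.name,
            self.chromosome_class,
            self.position_mb,
            self.alleles,
            _sm(self.freq_LM),
            _sm(self.freq_LL),
        )

    def swapped_species(self) -> "LocusSpec":
        return LocusSpec(
            self.name,
            self.chromosome_class,
            self.position_mb,
            self.alleles,
            self.freq_LL,
            self.freq_LM,
        )


#: The seven reference loci with their published per-species allele
#: frequencies (reference sample: 20 allopatric individuals per species).
#: Five of the seven are fully diagnostic; Lu01 and Lu10 are partially
#: informative.
REFERENCE_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("ADAMTS6", "Z", 50.7, ("T", "C"), (1.0, 0.0), (0.0, 1.0)),
    LocusSpec("SPINZ-2", "Z", 7.5, ("A", "G"), (1.0, 0.0), (0.0, 1.0)),
    LocusSpec("TG5287", "Z", 64.5, ("G", "A"), (1.0, 0.0), (0.0, 1.0)),
    LocusSpec("Lu01", "autosomal", 18.5, ("G", "T"), (0.95, 0.05), (0.025, 0.975)),
    LocusSpec("Lu03", "autosomal", 47.1, ("T", "C"), (1.0, 0.0), (0.0, 1.0)),
    LocusSpec("Lu04", "autosomal", 55.0, ("G", "T"), (1.0, 0.0), (0.0, 1.0)),
    LocusSpec("Lu10", "autosomal", 64.8, ("T", "C"), (0.8, 0.2), (0.05, 0.95)),
)


@dataclass
class GenotypeRecord:
    """Per-individual diploid calls.  ``calls`` maps locus name to an
    unordered allele tuple: length 2 normally, length 1 for Z-linked loci in
    ZW females; a missing locus is simply absent (or maps to None)."""

    individual_id: str
    sex: str  # "male_ZZ" or "female_ZW"
    calls: dict[str, tuple[str, ...] | None] = field(default_factory=dict)

    def call(self, locus: str) -> tuple[str, ...] | None:
        g = self.calls.get(locus)
        if g is None:
            return None
        return tuple(sorted(g))


@dataclass
class HybridClassPosterior:
    individual_id: str
    posterior: dict[str, float]
    loglik: pd.DataFrame  # loci x classes, per-locus log-likelihoods
    n_loci_used: int

    @property
    def modal_class(self) -> str:
        # deterministic tie-break: class order as declared
        best = max(self.posterior.values())
        for c in HYBRID_CLASSES:
            if self.posterior[c] == best:
                return c
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class MaternalAssignment:
    species: str  # "LM", "LL" or "indeterminate"
    matched_sites: int
    total_sites: int


def _is_z_haploid(locus: LocusSpec, sex: str) -> bool:
    if sex not in ("male_ZZ", "female_ZW"):
        raise ValueError(f"unknown sex {sex!r}")
    return locus.chromosome_class == "Z" and sex == "female_ZW"


def genotype_class_freqs(
    hybrid_class: str, locus: LocusSpec, sex: str = "male_ZZ"
) -> dict[tuple[str, ...], float]:
    """Genotype probability table for one class at one locus.

    Diploid genotypes are unordered sorted allele pairs; Z-linked loci in
    ZW females are single-copy and keyed by 1-tuples.  Probabilities sum
    to 1 over the table.
    """
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}")
    a, b = locus.alleles
    p_lm = dict(zip(locus.alleles, locus.freq_LM))
    p_ll = dict(zip(locus.alleles, locus.freq_LL))

    if _is_z_haploid(locus, sex):
        w_lm = _HAPLOID_ORIGIN_LM[hybrid_class]
        return {
            (x,): w_lm * p_lm[x] + (1 - w_lm) * p_ll[x] for x in (a, b)
        }

    w_mm, w_ml, w_ll = _DIPLOID_ORIGIN[hybrid_class]
    table: dict[tuple[str, ...], float] = {}
    for g in ((a, a), (a, b), (b, b)):
        x, y = g
        # ordered-pair expansion; heterozygote counts both orders
        def pair(p1: Mapping[str, float], p2: Mapping[str, float]) -> float:
            pr = p1[x] * p2[y]
            if x != y:
                pr += p1[y] * p2[x]
            return pr

        table[tuple(sorted(g))] = (
            w_mm * pair(p_lm, p_lm) + w_ml * pair(p_lm, p_ll) + w_ll * pair(p_ll, p_ll)
        )
    return table


def posterior_hybrid_class(
    record: GenotypeRecord,
    loci: Sequence[LocusSpec] = REFERENCE_LOCI,
    prior: Mapping[str, float] | None = None,
    pseudo_count: float = 0.5,
    ref_gene_copies: int = 40,
) -> HybridClassPosterior:
    """Posterior over the six genotype categories for one individual.

    posterior(class) ∝ prior(class) · Π_loci P(genotype | class), with
    reference frequencies smoothed by ``pseudo_count`` added to each allele's
    implied reference count (``ref_gene_copies`` copies per species; pass
    ``pseudo_count=0`` for the unsmoothed closed-form behaviour).  Missing
    loci are skipped; an all-missing record is an error.
    """
    if prior is None:
        prior = {c: 1.0 / len(HYBRID_CLASSES) for c in HYBRID_CLASSES}
    loglik_rows = {}
    n_used = 0
    for locus in loci:
        g = record.call(locus.name)
        if g is None:
            continue
        expected_len = 1 if _is_z_haploid(locus, record.sex) else 2
        if len(g) != expected_len:
            raise ValueError(
                f"{record.individual_id}: call {g} at {locus.name} inconsistent "
                f"with sex {record.sex}"
            )
        sm = locus.smoothed(pseudo_count, ref_gene_copies)
        row = {}
        for cls in HYBRID_CLASSES:
            table = genotype_class_freqs(cls, sm, record.sex)
            pr = table.get(g)
            if pr is None:
                raise ValueError(f"allele(s) {g} not in alphabet of {locus.name}")
            row[cls] = math.log(pr) if pr > 0 else -math.inf
        loglik_rows[locus.name] = row
        n_used += 1
    if n_used == 0:
        raise ValueError(f"{record.individual_id}: no non-missing loci")

    loglik = pd.DataFrame.from_dict(loglik_rows, orient="index")[list(HYBRID_CLASSES)]
    with np.errstate(invalid="ignore"):
        total = loglik.sum(axis=0) + np.log([prior[c] for c in HYBRID_CLASSES])
    total = total.to_numpy(dtype=float)
    finite = np.isfinite(total)
    if not finite.any():
        raise ValueError(f"{record.individual_id}: zero likelihood under every class")
    shifted = np.where(finite, total - total[finite].max(), -np.inf)
    w = np.exp(shifted)
    w /= w.sum()
    posterior = dict(zip(HYBRID_CLASSES, w.tolist()))
    return HybridClassPosterior(record.individual_id, posterior, loglik, n_used)


def backcross_het_expectation(generation: int) -> float:
    """Expected fraction of heterozygous fully-diagnostic loci in a BC_n
    backcross: 0.5**n (BC1 0.5, BC2 0.25, BC3 0.125)."""
    if not isinstance(generation, (int, np.integer)) or generation < 1:
        raise ValueError("backcross generation must be an integer >= 1")
    return 0.5**generation


def prob_all_homozygous(generation: int, n_diagnostic_loci: int) -> float:
    """P(a BC_n individual is homozygous at all L independent diagnostic
    loci) = (1 - 0.5**n)**L.  Quantifies how unlikely an observed
    all-homozygous multilocus genotype is under a backcross hypothesis."""
    if n_diagnostic_loci < 1:
        raise ValueError("need at least one diagnostic locus")
    return (1.0 - backcross_het_expectation(generation)) ** n_diagnostic_loci


def map_distance_cm(
    separation_mb: float, rate_cm_per_mb: float, rounded: bool = False
) -> float:
    """Genetic map distance implied by a physical separation and a constant
    recombination rate.  ``rounded=True`` returns the nearest whole cM."""
    if separation_mb < 0 or rate_cm_per_mb < 0:
        raise ValueError("separation and rate must be non-negative")
    d = separation_mb * rate_cm_per_mb
    return float(round(d)) if rounded else d


def assign_maternal_lineage(
    query_seq: str, ref_LM: str, ref_LL: str
) -> MaternalAssignment:
    """Assign the maternal species of a query mtDNA sequence by majority
    vote over the diagnostic sites (positions where the two references
    differ).  Ties or absence of diagnostic sites give 'indeterminate'."""
    if not (len(query_seq) == len(ref_LM) == len(ref_LL)):
        raise ValueError("query and reference sequences must be aligned/equal length")
    q, m, l = query_seq.upper(), ref_LM.upper(), ref_LL.upper()
    diag = [i for i in range(len(m)) if m[i] != l[i]]
    if not diag:
        return MaternalAssignment("indeterminate", 0, 0)
    votes_lm = sum(1 for i in diag if q[i] == m[i])
    votes_ll = sum(1 for i in diag if q[i] == l[i])
    if votes_lm > votes_ll:
        return MaternalAssignment("LM", votes_lm, len(diag))
    if votes_ll > votes_lm:
        return MaternalAssignment("LL", votes_ll, len(diag))
    return MaternalAssignment("indeterminate", votes_lm, len(diag))


# ---------------------------------------------------------------------------
# Tabular I/O (TSV formats shared with the synthetic-data generator)

def write_genotypes_tsv(records: Iterable[GenotypeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for locus, g in sorted(rec.calls.items()):
            if g is None:
                continue
            rows.append(
                {
                    "individual": rec.individual_id,
                    "sex": rec.sex,
                    "locus": locus,
                    "allele1": g[0],
                    "allele2": g[1] if len(g) > 1 else "",
                }
            )
    pd.DataFrame(rows, columns=["individual", "sex", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotypes_tsv(path: str | Path) -> list[GenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, GenotypeRecord] = {}
    for row in df.itertuples(index=False):
        rec = out.setdefault(row.individual, GenotypeRecord(row.individual, row.sex))
        alleles = (row.allele1,) if row.allele2 == "" else (row.allele1, row.allele2)
        rec.calls[row.locus] = tuple(sorted(alleles))
    return list(out.values())


def write_loci_tsv(loci: Sequence[LocusSpec], path: str | Path) -> None:
    rows = [
        {
            "name": lc.name,
            "chromosome": lc.chromosome_class,
            "position_mb": lc.position_mb,
            "allele1": lc.alleles[0],
            "allele2": lc.alleles[1],
            "freq_LM_allele1": lc.freq_LM[0],
            "freq_LL_allele1": lc.freq_LL[0],
        }
        for lc in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path: str | Path) -> list[LocusSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        LocusSpec(
            str(r.name_),
            str(r.chromosome),
            float(r.position_mb),
            (str(r.allele1), str(r.allele2)),
            (float(r.freq_LM_allele1), 1.0 - float(r.freq_LM_allele1)),
            (float(r.freq_LL_allele1), 1.0 - float(r.freq_LL_allele1)),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_posteriors_tsv(
    posteriors: Sequence[HybridClassPosterior], path: str | Path
) -> None:
    rows = []
    for p in posteriors:
        row = {"individual": p.individual_id, "n_loci": p.n_loci_used}
        row.update({c: p.posterior[c] for c in HYBRID_CLASSES})
        row["modal_class"] = p.modal_class
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
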