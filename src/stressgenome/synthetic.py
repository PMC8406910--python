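"""Seeded generators for every input the pipeline consumes, with planted
ground truth.

These stand in for the study's deposited data at desk scale: a 16-sample
salinity time course (2 salinities x 4 time points x 3 replicates, batches
laid out 2,1,2 within each condition), a 3-vs-3 anoxia contrast,
NB-distributed counts with planted log-fold-changes and gene-wise batch
shifts, orthogroup tables with planted expansions/contractions, scaffold
sets with planted mitochondrial-like and alien contaminants, and term maps
with planted enriched terms. Library sizes are drawn log-uniform between
0.5 and 2 million reads — far below real sequencing depth; this is a
deliberately scaled-down emulation.

Every generator is a pure function of its seed: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval
from .model import (
    CountExperiment,
    Gene,
    GenomeAnnotation,
    HitRecord,
    OrthoCountTable,
    SampleAnnotation,
    ScaffoldHitTable,
    TermMap,
    Transcript,
)

LOG2 = np.log(2.0)

DEFAULT_SPECIES = ("A_franciscana", "D_pulex", "L_arcticus", "E_texana")


@dataclass
class SimSpec:
    """Parameters of the count-experiment generator."""

    seed: int = 0
    n_genes: int = 2_000
    design: str = "salinity"          # or "anoxia"
    dispersion: float = 0.1
    frac_de: float = 0.1
    logfc_magnitude: float = 2.0      # log2 units
    batch_logfc_sd: float = 0.1      # sd of gene-wise batch shifts, log2 units
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    genewise_dispersion_sd: float = 0.0  # log-normal sd of per-gene dispersion

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.design not in ("salinity", "anoxia"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("invalid lib_size_range")


@dataclass
class GroundTruth:
    """Planted truth for whichever generator produced it."""

    de_gene_ids: set[str] = field(default_factory=set)
    coefficients: Optional[pd.DataFrame] = None  # genes x design columns, log2
    expanded: set[str] = field(default_factory=set)
    contracted: set[str] = field(default_factory=set)
    unique_pairs: set[str] = field(default_factory=set)
    mito_scaffolds: set[str] = field(default_factory=set)
    alien_scaffolds: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)
    test_gene_ids: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# RNA-seq count experiments
# ---------------------------------------------------------------------------

def salinity_layout() -> list[SampleAnnotation]:
    """The 16-sample salinity design: 2 salinities x 4 time points x 2
    replicates per condition, replicate batches 2, 1 (in that order) within
    every condition, so batch is balanced against every contrast."""
    samples = []
    counter = 0
    for salinity in ("low", "high"):
        for time in (15, 30, 45, 60):
            for rep, batch in enumerate((2, 1), start=1):
                counter += 1
                samples.append(
                    SampleAnnotation(
                        sample_id=f"SIM{counter:03d}_{salinity}_{time}min_r{rep}",
                        life_stage="nauplii",
                        time_min=time,
                        salinity=salinity,
                        batch=batch,
                        light="light",
                    )
                )
    return samples


def anoxia_layout() -> list[SampleAnnotation]:
    """Three anoxic vs three normoxic (hydrated) cyst libraries."""
    samples = []
    for i in range(1, 4):
        samples.append(SampleAnnotation(f"SIMANX{i:02d}_anoxia", "cysts", oxygen="anoxia"))
    for i in range(1, 4):
        samples.append(SampleAnnotation(f"SIMNOX{i:02d}_normoxia", "cysts", oxygen="normoxia"))
    return samples


def _design_matrix(samples: Sequence[SampleAnnotation], design: str) -> pd.DataFrame:
    from .de import build_anoxia_design, build_design

    return build_design(samples) if design == "salinity" else build_anoxia_design(samples)


def simulate_count_experiment(spec: SimSpec) -> tuple[CountExperiment, GroundTruth]:
    """NB counts under the study design with planted treatment effects.

    The log mean per gene and sample is baseline + offset(log library size)
    + the design linear predictor; treatment coefficients of DE genes are
    ``±logfc_magnitude`` on the main salinity effect, one interaction, or
    both. Batch shifts are drawn per gene from N(0, batch_logfc_sd).
    """
    rng = np.random.default_rng(spec.seed)
    samples = salinity_layout() if spec.design == "salinity" else anoxia_layout()
    design = _design_matrix(samples, spec.design)
    X = design.to_numpy()
    gene_ids = [f"AFGENE{i:05d}" for i in range(spec.n_genes)]

    beta = pd.DataFrame(0.0, index=gene_ids, columns=design.columns)  # log2 scale
    if spec.design == "salinity":
        beta["batch2"] = rng.normal(0.0, spec.batch_logfc_sd, spec.n_genes)
        # mild time trends in a random 10% of genes keep the time columns honest
        timers = rng.random(spec.n_genes) < 0.10
        for col in ("time30", "time45", "time60"):
            beta.loc[timers, col] = rng.normal(0.0, 0.5, int(timers.sum()))

    n_de = int(round(spec.frac_de * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    de_ids = {gene_ids[i] for i in de_idx}
    effect_cols = (
        ["salinity_high", "salinity:time30", "salinity:time45", "salinity:time60"]
        if spec.design == "salinity"
        else ["anoxia"]
    )
    for i in de_idx:
        sign = rng.choice([-1.0, 1.0])
        if spec.design == "anoxia":
            beta.iloc[i, beta.columns.get_loc("anoxia")] = sign * spec.logfc_magnitude
            continue
        kind = rng.choice(["main", "interaction", "both"])
        if kind in ("main", "both"):
            beta.iloc[i, beta.columns.get_loc("salinity_high")] = sign * spec.logfc_magnitude
        if kind in ("interaction", "both"):
            col = rng.choice(["salinity:time30", "salinity:time45", "salinity:time60"])
            beta.iloc[i, beta.columns.get_loc(col)] = sign * spec.logfc_magnitude

    lo, hi = spec.lib_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    base_cpm = np.exp(rng.normal(np.log(30.0), 1.2, spec.n_genes))
    log_mu = (
        np.log(base_cpm)[:, None]
        + np.log(lib_sizes / 1e6)[None, :]
        + (beta.to_numpy() @ X.T) * LOG2
    )
    mu = np.exp(log_mu)

    if spec.genewise_dispersion_sd > 0:
        phi = spec.dispersion * np.exp(
            rng.normal(0.0, spec.genewise_dispersion_sd, spec.n_genes)
        )
    else:
        phi = np.full(spec.n_genes, spec.dispersion)

    counts = np.empty(mu.shape, dtype=np.int64)
    poisson = phi < 1e-8
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson][:, None]
        p = r / (r + mu[~poisson])
        counts[~poisson] = rng.negative_binomial(r, p)

    frame = pd.DataFrame(counts, index=gene_ids, columns=[s.sample_id for s in samples])
    truth = GroundTruth(de_gene_ids=de_ids, coefficients=beta)
    return CountExperiment(frame, samples), truth


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

def simulate_ortho_table(seed: int, n_orthogroups: int = 500,
                         species_list: Sequence[str] = DEFAULT_SPECIES,
                         n_expanded: int = 10, n_contracted: int = 5,
                         n_unique_pairs: int = 0,
                         unique_partner: Optional[str] = None,
                         min_focal: int = 5, ratio: int = 3,
                         ) -> tuple[OrthoCountTable, GroundTruth]:
    """Orthogroup counts with planted expansions and contractions.

    Planted expansions have focal count >= ``min_focal`` and >= ``ratio``
    times every comparator; contractions the converse; background groups
    violate the rule against every comparator by construction. Optional
    "unique pair" groups are present only in the focal species and one
    named partner, with focal counts below ``min_focal`` so they never enter
    expansion calls.
    """
    focal = species_list[0]
    comparators = [s for s in species_list[1:]]
    if not comparators:
        raise ValueError("species_list needs at least one comparator")
    n_planted = n_expanded + n_contracted + n_unique_pairs
    if n_planted > n_orthogroups:
        raise ValueError("requested plantings exceed n_orthogroups")
    if n_unique_pairs and unique_partner is None:
        unique_partner = comparators[-1]
    if unique_partner is not None and unique_partner not in comparators:
        raise ValueError(f"unique partner {unique_partner!r} not a comparator")

    rng = np.random.default_rng(seed)
    og_ids = [f"OG{i:07d}" for i in range(n_orthogroups)]
    kinds = (["expanded"] * n_expanded + ["contracted"] * n_contracted
             + ["unique_pair"] * n_unique_pairs
             + ["background"] * (n_orthogroups - n_planted))
    rng.shuffle(kinds)

    counts = pd.DataFrame(0, index=og_ids, columns=list(species_list), dtype=int)
    truth = GroundTruth()
    for og, kind in zip(og_ids, kinds):
        if kind == "expanded":
            nf = int(rng.integers(max(min_focal, 6), 31))
            counts.loc[og, focal] = nf
            for j, comp in enumerate(comparators):
                # first comparator kept present so that focal+partner-only
                # presence patterns occur exactly where planted
                lo_count = 1 if j == 0 else 0
                counts.loc[og, comp] = int(rng.integers(lo_count, nf // ratio + 1))
            truth.expanded.add(og)
        elif kind == "contracted":
            nf = int(rng.integers(min_focal, min_focal + 4))
            counts.loc[og, focal] = nf
            for comp in comparators:
                counts.loc[og, comp] = int(rng.integers(ratio * nf, ratio * nf + 21))
            truth.contracted.add(og)
        elif kind == "unique_pair":
            counts.loc[og, focal] = int(rng.integers(1, min_focal))
            counts.loc[og, unique_partner] = int(rng.integers(1, 6))
            truth.unique_pairs.add(og)
        else:
            if rng.random() < 0.3:  # too few focal genes for any call
                nf = int(rng.integers(0, min_focal))
                counts.loc[og, focal] = nf
                for j, comp in enumerate(comparators):
                    lo_count = 1 if (j == 0 and nf > 0) else 0
                    counts.loc[og, comp] = int(rng.integers(lo_count, 11))
            else:  # focal eligible but every comparator inside the dead zone
                nf = int(rng.integers(min_focal, 21))
                counts.loc[og, focal] = nf
                for comp in comparators:
                    counts.loc[og, comp] = int(rng.integers(nf // ratio + 1, ratio * nf))

    focal_genes = {
        og: [f"AF_{og}_{i:02d}" for i in range(int(counts.loc[og, focal]))]
        for og in og_ids
    }
    table = OrthoCountTable(counts, focal, focal_genes)
    return table, truth


# ---------------------------------------------------------------------------
# Scaffold fixtures with planted contaminants
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(bases[rng.choice(4, size=length, p=probs)])


def simulate_scaffolds(seed: int, n_scaffolds: int = 20, n_mito_like: int = 3,
                       n_alien: int = 5, gc: float = 0.34,
                       ) -> tuple[GenomeAnnotation, dict[str, str],
                                  ScaffoldHitTable, ScaffoldHitTable, GroundTruth]:
    """Scaffold set with planted mitochondrial-like and alien contaminants.

    Returns the annotation, FASTA sequences, a mitochondrial hit table
    (keyed by gene id) and an alien-screen hit table (keyed by scaffold id,
    with query coordinates), plus the planted truth. Mito-like scaffolds
    are <= 15,822 bp with every gene hitting a mitochondrial protein at bit
    score >= 50; alien scaffolds are <= 5 kb with exclusively
    non-invertebrate hits at >= 70% identity; clean scaffolds always carry
    an invertebrate hit.
    """
    if n_mito_like + n_alien > n_scaffolds:
        raise ValueError("contaminant count exceeds scaffold count")
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    sequences: dict[str, str] = {}
    mito_records: list[HitRecord] = []
    alien_records: list[HitRecord] = []
    truth = GroundTruth()

    def add_genes(sid: str, length: int, n: int, prefix: str) -> list[str]:
        ids = []
        cursor = 0
        for k in range(n):
            span = int(rng.integers(300, max(400, length // (n + 1))))
            start = cursor + int(rng.integers(10, 200))
            end = min(start + span, length - 1)
            if end <= start + 50:
                break
            gid = f"{prefix}{sid}_g{k}"
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2,
                                      replace=False)) if n_exons > 1 else np.array([])
            bounds = [start, *cuts.tolist(), end]
            exons = [
                Interval(sid, bounds[2 * j], bounds[2 * j + 1])
                for j in range(n_exons)
            ]
            tr = Transcript(f"{gid}.t1", exons)
            genes[gid] = Gene(gid, sid, start, end, "+", {tr.transcript_id: tr})
            ids.append(gid)
            cursor = end
        return ids

    kinds = (["mito"] * n_mito_like + ["alien"] * n_alien
             + ["clean"] * (n_scaffolds - n_mito_like - n_alien))
    rng.shuffle(kinds)
    for i, kind in enumerate(kinds):
        sid = f"scaffold{i:04d}"
        if kind == "mito":
            length = int(rng.integers(2_000, 15_823))
            lengths[sid] = length
            sequences[sid] = _random_sequence(rng, length, gc)
            for gid in add_genes(sid, length, int(rng.integers(1, 4)), "MT"):
                mito_records.append(
                    HitRecord(gid, f"mito_prot_{rng.integers(1, 14)}",
                              float(rng.uniform(60, 99)), float(rng.uniform(50, 200)),
                              "mitochondrial-gene", 0, 100)
                )
            truth.mito_scaffolds.add(sid)
        elif kind == "alien":
            length = int(rng.integers(1_000, 5_001))
            lengths[sid] = length
            sequences[sid] = _random_sequence(rng, length, 0.5)
            n_hits = int(rng.integers(1, 4))
            for k in range(n_hits):
                lo = int(rng.integers(0, max(1, length - 200)))
                hi = min(length, lo + int(rng.integers(100, 400)))
                group = str(rng.choice(["bacteria", "fungi", "viral"]))
                alien_records.append(
                    HitRecord(sid, f"{group}_prot_{k}", float(rng.uniform(70, 100)),
                              float(rng.uniform(60, 300)), group, lo, hi)
                )
            truth.alien_scaffolds.add(sid)
        else:
            length = int(rng.integers(16_000, 40_000))
            lengths[sid] = length
            sequences[sid] = _random_sequence(rng, length, gc)
            add_genes(sid, length, int(rng.integers(1, 4)), "NUC")
            lo = int(rng.integers(0, length - 500))
            hi = lo + int(rng.integers(150, 500))
            alien_records.append(
                HitRecord(sid, "invert_prot", float(rng.uniform(40, 100)),
                          float(rng.uniform(60, 300)), "invertebrate", lo, hi)
            )

    annotation = GenomeAnnotation(lengths, genes)
    return (annotation, sequences, ScaffoldHitTable(mito_records),
            ScaffoldHitTable(alien_records), truth)


# ---------------------------------------------------------------------------
# Term maps with planted enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichedTermSpec:
    test_rate: float          # annotation rate inside the designated test set
    background_rate: float    # annotation rate outside it

    def __post_init__(self) -> None:
        if self.background_rate > 0 and self.test_rate < 4 * self.background_rate:
            raise ValueError("planted enrichment requires test rate >= 4x background")


def simulate_term_map(seed: int, genes: Sequence[str], n_terms: int = 50,
                      enriched_terms_spec: Sequence[EnrichedTermSpec] = (),
                      test_fraction: float = 0.2,
                      null_rate_range: tuple[float, float] = (0.02, 0.15),
                      ) -> tuple[TermMap, GroundTruth]:
    """Gene->term map over an acyclic term DAG with planted enriched terms.

    A ``test_fraction`` of the genes is designated as the test set; planted
    terms annotate test genes at ``test_rate`` and the rest at
    ``background_rate`` (at least 4x lower); null terms annotate both at a
    common rate drawn from ``null_rate_range``.
    """
    if len(enriched_terms_spec) > n_terms:
        raise ValueError("more enriched terms than terms")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_test = max(1, int(round(test_fraction * len(genes))))
    test_idx = rng.choice(len(genes), size=n_test, replace=False)
    test_set = {genes[i] for i in test_idx}

    term_ids = [f"TERM:{i:07d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {}
    for i in range(1, n_terms):  # parent always has a smaller index: acyclic
        if rng.random() < 0.7:
            parents[term_ids[i]] = {term_ids[int(rng.integers(0, i))]}
    names = {t: f"synthetic process {i}" for i, t in enumerate(term_ids)}
    namespaces = {t: "biological_process" for t in term_ids}

    enriched_ids = list(rng.choice(term_ids, size=len(enriched_terms_spec), replace=False))
    rates: dict[str, tuple[float, float]] = {}
    for term, espec in zip(enriched_ids, enriched_terms_spec):
        rates[term] = (espec.test_rate, espec.background_rate)
    for term in term_ids:
        if term not in rates:
            r = float(rng.uniform(*null_rate_range))
            rates[term] = (r, r)

    gene_terms: dict[str, set[str]] = {g: set() for g in genes}
    for term in term_ids:
        test_rate, bg_rate = rates[term]
        for g in genes:
            rate = test_rate if g in test_set else bg_rate
            if rng.random() < rate:
                gene_terms[g].add(term)

    tm = TermMap(gene_terms, parents, names, namespaces)
    tm.validate_acyclic()
    truth = GroundTruth(enriched_terms=set(enriched_ids), test_gene_ids=test_set)
    return tm, truth
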