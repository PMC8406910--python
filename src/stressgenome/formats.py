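"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open; each reader normalizes its
format's native convention on the way in (GFF3 and RepeatMasker tables are
1-based inclusive, BED is already half-open) and each writer converts back
on the way out. Strand is parsed and carried but ignored by downstream
accounting.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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

logger = logging.getLogger(__name__)

# Standard tabular BLAST (outfmt 6) columns plus one appended taxon-group label.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "taxon_group",
]

SAMPLE_COLUMNS = ["sample_id", "life_stage", "time_min", "salinity", "light", "batch", "oxygen"]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, fasta_path: str | Path | None = None) -> GenomeAnnotation:
    """Read gene/mRNA/exon structure from GFF3 (parsed with gffutils).

    Scaffold lengths come from ``##sequence-region`` directives, or from a
    companion FASTA when given. Exons whose span escapes their gene are
    rejected with a logged warning; an exon or mRNA without a Parent is an
    error. GFF3's 1-based inclusive coordinates become 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    scaffold_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            scaffold_lengths[parts[1]] = int(parts[3])

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    transcript_gene: dict[str, str] = {}
    pending_exons: list[tuple[str, Interval]] = []

    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: gene without ID at {f.seqid}:{f.start}")
        genes[gid] = Gene(gid, f.seqid, f.start - 1, f.end, f.strand or ".")
    for ftype in ("mRNA", "transcript"):
        for f in db.features_of_type(ftype):
            tid = f.attributes.get("ID", [None])[0]
            parent = f.attributes.get("Parent", [None])[0]
            if tid is None or parent is None:
                raise ValueError(f"{path}: mRNA needs ID and Parent at {f.seqid}:{f.start}")
            transcripts[tid] = Transcript(tid)
            transcript_gene[tid] = parent
    for f in db.features_of_type("exon"):
        parent = f.attributes.get("Parent", [None])[0]
        if parent is None:
            raise ValueError(f"{path}: exon without Parent at {f.seqid}:{f.start}")
        pending_exons.append((parent, Interval(f.seqid, f.start - 1, f.end)))

    for tid, tr in transcripts.items():
        gid = transcript_gene[tid]
        if gid not in genes:
            raise ValueError(f"transcript {tid} references unknown gene {gid}")
        genes[gid].transcripts[tid] = tr

    for parent, exon in pending_exons:
        if parent in transcripts:
            gene = genes[transcript_gene[parent]]
            target = transcripts[parent]
        elif parent in genes:  # exons attached directly to a gene
            gene = genes[parent]
            implicit = f"{parent}.t1"
            target = gene.transcripts.setdefault(implicit, Transcript(implicit))
        else:
            raise ValueError(f"exon Parent {parent!r} matches no gene or transcript")
        if exon.start < gene.start or exon.end > gene.end or exon.scaffold_id != gene.scaffold_id:
            logger.warning(
                "rejecting exon [%d, %d) on %s outside gene %s span [%d, %d)",
                exon.start, exon.end, exon.scaffold_id, gene.gene_id, gene.start, gene.end,
            )
            continue
        target.exons.append(exon)

    for gene in genes.values():
        for tr in gene.transcripts.values():
            tr.exons.sort()

    if fasta_path is not None:
        for sid, seq in read_fasta(fasta_path).items():
            scaffold_lengths.setdefault(sid, len(seq))
    for gene in genes.values():
        if gene.scaffold_id not in scaffold_lengths:
            scaffold_lengths[gene.scaffold_id] = gene.end

    annotation = GenomeAnnotation(scaffold_lengths, genes)
    annotation.validate_bounds()
    return annotation


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid in sorted(annotation.scaffold_lengths):
            fh.write(f"##sequence-region {sid} 1 {annotation.scaffold_lengths[sid]}\n")
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            fh.write(
                f"{gene.scaffold_id}\tstressgenome\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gid}\n"
            )
            for tid in sorted(gene.transcripts):
                tr = gene.transcripts[tid]
                fh.write(
                    f"{gene.scaffold_id}\tstressgenome\tmRNA\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\tID={tid};Parent={gid}\n"
                )
                for i, exon in enumerate(tr.exons, start=1):
                    fh.write(
                        f"{exon.scaffold_id}\tstressgenome\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{gene.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / repeat intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """BED3: already 0-based half-open."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            sid, start, end = line.split()[:3]
            out.append(Interval(sid, int(start), int(end)))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\n")


def read_repeat_intervals(path: str | Path) -> list[Interval]:
    """RepeatMasker-style interval table: scaffold, begin, end (1-based inclusive)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] in ("SW", "score"):  # RepeatMasker .out header lines
                continue
            sid, begin, end = fields[0], int(fields[1]), int(fields[2])
            out.append(Interval(sid, begin - 1, end))
    return out


def write_repeat_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tbegin\tend\n")
        for iv in intervals:
            fh.write(f"{iv.scaffold_id}\t{iv.start + 1}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Homology hit tables
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> ScaffoldHitTable:
    """Tabular BLAST (12 columns) plus one appended taxon-group column.

    Query coordinates are normalized to 0-based half-open with start < end
    (blastx reports minus-frame hits with qstart > qend).
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise ValueError(
                    f"{path}:{line_no}: expected {len(HIT_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-numeric field ({exc})") from None
            lo, hi = min(qstart, qend), max(qstart, qend)
            records.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pident,
                    bit_score=bitscore,
                    subject_group=fields[12],
                    q_start=lo - 1,
                    q_end=hi,
                )
            )
    return ScaffoldHitTable(records)


def write_hits(table: ScaffoldHitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.records:
            qs = r.q_start + 1 if r.q_start is not None else 1
            qe = r.q_end if r.q_end is not None else 1
            span = qe - qs + 1
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pct_identity:.1f}\t{span}\t0\t0\t"
                f"{qs}\t{qe}\t1\t{span}\t1e-10\t{r.bit_score:.1f}\t{r.subject_group}\n"
            )


# ---------------------------------------------------------------------------
# Count matrices and sample annotation
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")

    def opt(value, cast=str):
        if pd.isna(value) or value in ("", "NA"):
            return None
        return cast(value)

    return [
        SampleAnnotation(
            sample_id=row["sample_id"],
            life_stage=row["life_stage"],
            time_min=opt(row["time_min"], int),
            salinity=opt(row["salinity"]),
            batch=opt(row["batch"], int),
            oxygen=opt(row["oxygen"]),
            light=opt(row["light"]),
        )
        for _, row in df.iterrows()
    ]


def write_sample_table(samples: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "life_stage": s.life_stage,
                "time_min": "NA" if s.time_min is None else s.time_min,
                "salinity": s.salinity or "NA",
                "light": s.light or "NA",
                "batch": "NA" if s.batch is None else s.batch,
                "oxygen": s.oxygen or "NA",
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path_counts: str | Path, path_samples: str | Path) -> CountExperiment:
    """Counts TSV (gene x sample) joined to a sample-annotation table.

    Count columns are reordered to the sample table; a sample present in one
    file but not the other is an error, as are negative or fractional counts.
    """
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    samples = read_sample_table(path_samples)
    sample_ids = [s.sample_id for s in samples]
    missing = set(sample_ids) - set(counts.columns)
    if missing:
        raise ValueError(f"samples absent from count matrix: {sorted(missing)}")
    extra = set(counts.columns) - set(sample_ids)
    if extra:
        raise ValueError(f"count columns absent from sample table: {sorted(extra)}")
    counts = counts[sample_ids]
    if counts.isna().any().any():
        raise ValueError("missing values in count matrix")
    return CountExperiment(counts, samples)


def write_counts(experiment: CountExperiment, path_counts: str | Path,
                 path_samples: str | Path | None = None) -> None:
    out = experiment.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path_counts, sep="\t")
    if path_samples is not None:
        write_sample_table(experiment.samples, path_samples)


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

def read_ortho_counts(path: str | Path, focal_species: str,
                      membership_path: str | Path | None = None) -> OrthoCountTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    focal_genes: dict[str, list[str]] = {}
    if membership_path is not None:
        with open(membership_path) as fh:
            header = fh.readline()
            for line in fh:
                og, genes = line.rstrip("\n").split("\t")
                focal_genes[og] = genes.split(",") if genes else []
    return OrthoCountTable(counts, focal_species, focal_genes)


def write_ortho_counts(table: OrthoCountTable, path: str | Path,
                       membership_path: str | Path | None = None) -> None:
    out = table.counts.copy()
    out.index.name = "orthogroup_id"
    out.to_csv(path, sep="\t")
    if membership_path is not None:
        with open(membership_path, "w") as fh:
            fh.write("orthogroup_id\tfocal_genes\n")
            for og in table.counts.index:
                fh.write(f"{og}\t{','.join(table.focal_genes.get(og, []))}\n")


# ---------------------------------------------------------------------------
# Term maps (gene -> term TSV, parent-child TSV, OBO-lite)
# ---------------------------------------------------------------------------

def read_term_map(map_path: str | Path,
                  parents_path: str | Path | None = None) -> TermMap:
    gene_terms: dict[str, set[str]] = {}
    with open(map_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.split()[:2]
            gene_terms.setdefault(gene, set()).add(term)
    parents: dict[str, set[str]] = {}
    if parents_path is not None:
        with open(parents_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                child, parent = line.split()[:2]
                parents.setdefault(child, set()).add(parent)
    tm = TermMap(gene_terms, parents)
    tm.validate_acyclic()
    return tm


def write_term_map(term_map: TermMap, map_path: str | Path,
                   parents_path: str | Path | None = None) -> None:
    with open(map_path, "w") as fh:
        for gene in sorted(term_map.gene_terms):
            for term in sorted(term_map.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    if parents_path is not None:
        with open(parents_path, "w") as fh:
            for child in sorted(term_map.parents):
                for parent in sorted(term_map.parents[child]):
                    fh.write(f"{child}\t{parent}\n")


def read_obo_lite(path: str | Path) -> TermMap:
    """OBO with id/name/namespace/is_a stanzas only; annotations left empty."""
    import obonet

    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", term)
        if "namespace" in data:
            namespaces[term] = data["namespace"]
        parents[term] = set(data.get("is_a", []))
    tm = TermMap({}, parents, names, namespaces)
    tm.validate_acyclic()
    return tm


def write_obo_lite(term_map: TermMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(term_map.all_terms()):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term_map.names.get(term, term)}\n")
            if term in term_map.namespaces:
                fh.write(f"namespace: {term_map.namespaces[term]}\n")
            for parent in sorted(term_map.parents.get(term, ())):
                fh.write(f"is_a: {parent}\n")
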