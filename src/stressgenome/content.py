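"""Genome structural accounting: exonic/intronic/intergenic occupancy,
repeat fraction, GC content and per-gene structure statistics.

Composition uses the union rule: exonic bases are the union of all exon
intervals over all transcripts; intronic bases are the union of gene spans
minus the exonic union; everything else (including assembly gaps) is
intergenic. Per-gene statistics instead use one representative transcript
per gene — the one with the longest summed exon length — since "exons per
gene" is a property of a single gene structure, not of occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .intervals import Interval, merge_spans, union_length
from .model import GenomeAnnotation


@dataclass
class CompositionSummary:
    total_bp: int
    exonic_bp: int
    intronic_bp: int
    intergenic_bp: int
    repeat_bp: Optional[int] = None
    gc_fraction: Optional[float] = None
    mean_exons_per_gene: Optional[float] = None
    mean_intron_len_bp: Optional[float] = None
    no_introns: bool = False  # set when the annotation contains no multi-exon gene

    def __post_init__(self) -> None:
        if self.exonic_bp + self.intronic_bp + self.intergenic_bp != self.total_bp:
            raise ValueError("composition classes do not partition the genome")

    @property
    def exonic_fraction(self) -> float:
        return self.exonic_bp / self.total_bp

    @property
    def intronic_fraction(self) -> float:
        return self.intronic_bp / self.total_bp

    @property
    def repeat_fraction(self) -> Optional[float]:
        return None if self.repeat_bp is None else self.repeat_bp / self.total_bp


def compute_composition(annotation: GenomeAnnotation,
                        scaffold_lengths: Mapping[str, int] | None = None) -> CompositionSummary:
    """Partition every base into exonic, intronic or intergenic.

    Overlapping and nested genes are resolved by the union rule, so the three
    classes partition the genome exactly (integer arithmetic, no rounding).
    """
    lengths = dict(scaffold_lengths) if scaffold_lengths is not None else annotation.scaffold_lengths
    total = sum(lengths.values())

    exon_spans: dict[str, list[tuple[int, int]]] = {}
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes.values():
        if gene.scaffold_id not in lengths:
            raise ValueError(f"gene {gene.gene_id} on unknown scaffold {gene.scaffold_id}")
        if gene.end > lengths[gene.scaffold_id]:
            raise ValueError(
                f"gene {gene.gene_id} out of bounds on scaffold {gene.scaffold_id}"
            )
        gene_spans.setdefault(gene.scaffold_id, []).append((gene.start, gene.end))
        for exon in gene.all_exons():
            if exon.end > lengths[exon.scaffold_id]:
                raise ValueError(f"exon out of bounds on scaffold {exon.scaffold_id}")
            exon_spans.setdefault(exon.scaffold_id, []).append((exon.start, exon.end))

    exonic = sum(union_length(spans) for spans in exon_spans.values())
    genic = sum(union_length(spans) for spans in gene_spans.values())
    intronic = genic - exonic
    intergenic = total - genic

    mean_exons, mean_intron, no_introns = gene_stats(annotation) if annotation.genes else (None, None, False)
    return CompositionSummary(
        total_bp=total,
        exonic_bp=exonic,
        intronic_bp=intronic,
        intergenic_bp=intergenic,
        mean_exons_per_gene=mean_exons,
        mean_intron_len_bp=mean_intron,
        no_introns=no_introns,
    )


def repeat_fraction(masked_intervals: Iterable[Interval],
                    scaffold_lengths: Mapping[str, int]) -> float:
    """Fraction of the genome covered by the union of masked intervals.

    Duplicated or overlapping intervals are never double-counted.
    """
    total = sum(scaffold_lengths.values())
    spans: dict[str, list[tuple[int, int]]] = {}
    for iv in masked_intervals:
        if iv.scaffold_id not in scaffold_lengths:
            raise ValueError(f"masked interval on unknown scaffold {iv.scaffold_id}")
        if iv.end > scaffold_lengths[iv.scaffold_id]:
            raise ValueError(f"masked interval out of bounds on {iv.scaffold_id}")
        spans.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
    masked = sum(union_length(s) for s in spans.values())
    return masked / total


def gene_stats(annotation: GenomeAnnotation) -> tuple[float, float, bool]:
    """Mean exons per gene and mean intron length over the annotation.

    Uses each gene's representative transcript. Introns are the gaps between
    consecutive exons; single-exon genes contribute no introns. The mean
    intron length is averaged over introns, not over genes. When no gene has
    an intron the mean is reported as 0.0 with the ``no_introns`` flag set.
    """
    if not annotation.genes:
        raise ValueError("annotation contains no genes")
    n_exons = 0
    intron_lengths: list[int] = []
    for gene in annotation.genes.values():
        tr = gene.representative_transcript()
        n_exons += len(tr.exons)
        intron_lengths.extend(iv.length for iv in tr.introns())
    mean_exons = n_exons / len(annotation.genes)
    if intron_lengths:
        return mean_exons, sum(intron_lengths) / len(intron_lengths), False
    return mean_exons, 0.0, True


def gc_content(sequences: Mapping[str, str]) -> float:
    """(G+C)/(A+C+G+T); N and other ambiguity codes excluded from the denominator."""
    gc = at = 0
    for seq in sequences.values():
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in input")
    return gc / (gc + at)


def per_scaffold_composition(annotation: GenomeAnnotation) -> "pd.DataFrame":
    """Per-scaffold exonic/intronic/intergenic table (for reports)."""
    import pandas as pd

    rows = []
    genes_by_scaffold = annotation.genes_by_scaffold()
    for sid, length in sorted(annotation.scaffold_lengths.items()):
        genes = genes_by_scaffold.get(sid, [])
        exon_spans = [(e.start, e.end) for g in genes for e in g.all_exons()]
        gene_spans = [(g.start, g.end) for g in genes]
        exonic = union_length(exon_spans)
        genic = union_length(gene_spans)
        rows.append(
            {
                "scaffold_id": sid,
                "length_bp": length,
                "n_genes": len(genes),
                "exonic_bp": exonic,
                "intronic_bp": genic - exonic,
                "intergenic_bp": length - genic,
            }
        )
    return pd.DataFrame(rows)
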