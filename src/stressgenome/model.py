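"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .intervals import Interval, merge_spans


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)

    def exon_span_bp(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[Interval]:
        """Gaps between consecutive (merged) exons of this transcript."""
        if len(self.exons) < 2:
            return []
        spans = merge_spans((e.start, e.end) for e in self.exons)
        sid = self.exons[0].scaffold_id
        return [
            Interval(sid, spans[i][1], spans[i + 1][0])
            for i in range(len(spans) - 1)
            if spans[i + 1][0] > spans[i][1]
        ]


@dataclass
class Gene:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def representative_transcript(self) -> Transcript:
        """Transcript with the longest summed exon length (ties by id)."""
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return max(
            self.transcripts.values(),
            key=lambda t: (t.exon_span_bp(), t.transcript_id),
        )

    def all_exons(self) -> list[Interval]:
        return [e for t in self.transcripts.values() for e in t.exons]


@dataclass
class GenomeAnnotation:
    """Scaffold lengths plus gene/transcript/exon structure."""

    scaffold_lengths: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)

    def genes_on(self, scaffold_id: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.scaffold_id == scaffold_id]

    def genes_by_scaffold(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {sid: [] for sid in self.scaffold_lengths}
        for g in self.genes.values():
            out.setdefault(g.scaffold_id, []).append(g)
        return out

    def validate_bounds(self) -> None:
        for g in self.genes.values():
            limit = self.scaffold_lengths.get(g.scaffold_id)
            if limit is not None and g.end > limit:
                raise ValueError(
                    f"gene {g.gene_id} extends to {g.end} beyond scaffold "
                    f"{g.scaffold_id} length {limit}"
                )


@dataclass(frozen=True)
class HitRecord:
    """One homology hit; ``q_start``/``q_end`` are 0-based half-open on the query."""

    query_id: str
    subject_id: str
    pct_identity: float
    bit_score: float
    subject_group: str
    q_start: Optional[int] = None
    q_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score {self.bit_score}")


@dataclass
class ScaffoldHitTable:
    records: list[HitRecord] = field(default_factory=list)

    def by_query(self) -> dict[str, list[HitRecord]]:
        groups: dict[str, list[HitRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.query_id, []).append(rec)
        return groups

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SampleAnnotation:
    """One RNA-seq library and its experimental factors.

    ``salinity`` experiments carry ``time_min`` and ``batch``; anoxia samples
    carry ``oxygen`` and no salinity/time.
    """

    sample_id: str
    life_stage: str
    time_min: Optional[int] = None
    salinity: Optional[str] = None
    batch: Optional[int] = None
    oxygen: Optional[str] = None
    light: Optional[str] = None

    VALID_TIMES = (15, 30, 45, 60)

    def __post_init__(self) -> None:
        if self.time_min is not None and self.time_min not in self.VALID_TIMES:
            raise ValueError(f"time_min {self.time_min} not in {self.VALID_TIMES}")
        if self.salinity is not None and self.salinity not in ("low", "high"):
            raise ValueError(f"salinity must be low/high, got {self.salinity!r}")
        if self.oxygen is not None and self.oxygen not in ("anoxia", "normoxia"):
            raise ValueError(f"oxygen must be anoxia/normoxia, got {self.oxygen!r}")
        if self.salinity is not None and (self.time_min is None or self.batch is None):
            raise ValueError(f"salinity sample {self.sample_id} needs time_min and batch")


@dataclass
class CountExperiment:
    """Gene x sample integer counts aligned with a sample-annotation table."""

    counts: pd.DataFrame
    samples: list[SampleAnnotation]

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValueError("count columns do not match sample annotation order")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts")
        if (values != values.astype(int)).any():
            raise ValueError("fractional counts")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class OrthoCountTable:
    """Orthogroup x species gene counts with a designated focal species."""

    counts: pd.DataFrame  # index: orthogroup ids, columns: species
    focal_species: str
    focal_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.focal_species not in self.counts.columns:
            raise ValueError(f"focal species {self.focal_species!r} not in table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative orthogroup counts")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def comparators(self) -> list[str]:
        return [s for s in self.species if s != self.focal_species]


@dataclass
class TermMap:
    """Gene -> term annotations plus an acyclic parent (is_a) relation."""

    gene_terms: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def all_terms(self) -> set[str]:
        terms = set(self.parents)
        for ps in self.parents.values():
            terms |= ps
        for ts in self.gene_terms.values():
            terms |= ts
        return terms

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following parent links (term excluded)."""
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
        return seen

    def descendants(self, term: str) -> set[str]:
        children: dict[str, set[str]] = {}
        for child, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(child)
        seen: set[str] = set()
        stack = list(children.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(children.get(t, ()))
        return seen

    def validate_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cyclic term parent relation: {cycle}")

    def propagated(self) -> "TermMap":
        """Close gene annotations under the parent relation (true-path rule)."""
        closed = {
            gene: terms | set().union(*(self.ancestors(t) for t in terms))
            if terms
            else set()
            for gene, terms in self.gene_terms.items()
        }
        return TermMap(closed, self.parents, self.names, self.namespaces)


def presence_matrix(table: OrthoCountTable) -> pd.DataFrame:
    """Boolean orthogroup x species presence (count > 0)."""
    return table.counts > 0
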