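"""Shared fixtures: random annotation generators and per-base oracles."""

from __future__ import annotations

import numpy as np
import pytest

from stressgenome.intervals import Interval
from stressgenome.model import Gene, GenomeAnnotation, Transcript


def random_annotation(rng: np.random.Generator, n_scaffolds: int = 3,
                      max_len: int = 2_000, max_genes: int = 4,
                      allow_overlap: bool = True) -> GenomeAnnotation:
    """A small random annotation; genes may overlap and nest."""
    lengths: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    for s in range(n_scaffolds):
        sid = f"s{s}"
        length = int(rng.integers(200, max_len))
        lengths[sid] = length
        n_genes = int(rng.integers(0, max_genes + 1))
        for g in range(n_genes):
            start = int(rng.integers(0, length - 60))
            end = int(rng.integers(start + 50, min(length, start + 600) + 1))
            gid = f"{sid}gene{g}"
            n_tx = int(rng.integers(1, 3))
            transcripts = {}
            for t in range(n_tx):
                n_exons = int(rng.integers(1, 4))
                cut_pool = np.arange(start + 1, end)
                cuts = np.sort(rng.choice(cut_pool, size=2 * n_exons - 2, replace=False)) \
                    if n_exons > 1 else np.array([], dtype=int)
                bounds = [start, *cuts.tolist(), end]
                exons = [Interval(sid, bounds[2 * j], bounds[2 * j + 1])
                         for j in range(n_exons)]
                tid = f"{gid}.t{t}"
                transcripts[tid] = Transcript(tid, exons)
            genes[gid] = Gene(gid, sid, start, end, "+", transcripts)
    return GenomeAnnotation(lengths, genes)


def perbase_composition(annotation: GenomeAnnotation) -> tuple[int, int, int]:
    """Label every base independently: exon > intron > intergenic."""
    exonic = intronic = intergenic = 0
    by_scaffold = annotation.genes_by_scaffold()
    for sid, length in annotation.scaffold_lengths.items():
        label = np.zeros(length, dtype=np.int8)  # 0 intergenic, 1 intron, 2 exon
        for gene in by_scaffold.get(sid, []):
            label[gene.start:gene.end] = np.maximum(label[gene.start:gene.end], 1)
        for gene in by_scaffold.get(sid, []):
            for exon in gene.all_exons():
                label[exon.start:exon.end] = 2
        exonic += int((label == 2).sum())
        intronic += int((label == 1).sum())
        intergenic += int((label == 0).sum())
    return exonic, intronic, intergenic


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)
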