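"""I/O round trips and coordinate-convention checks."""

import numpy as np
import pytest

from stressgenome import formats
from stressgenome.intervals import Interval, gaps_between, merge_spans, union_length
from stressgenome.synthetic import (
    SimSpec,
    simulate_count_experiment,
    simulate_scaffolds,
    simulate_term_map,
)

from conftest import random_annotation

GFF = """##gff-version 3
##sequence-region chr1 1 100
chr1\tsrc\tgene\t1\t60\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t60\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t1\t10\t.\t+\t.\tID=e1;Parent=g1.t1
chr1\tsrc\texon\t50\t60\t.\t+\t.\tID=e2;Parent=g1.t1
"""


def test_gff3_one_based_inclusive_becomes_half_open(tmp_path):
    path = tmp_path / "a.gff3"
    path.write_text(GFF)
    ann = formats.read_gff3(path)
    assert ann.scaffold_lengths == {"chr1": 100}
    gene = ann.genes["g1"]
    assert (gene.start, gene.end) == (0, 60)
    exons = gene.transcripts["g1.t1"].exons
    assert [(e.start, e.end) for e in exons] == [(0, 10), (49, 60)]
    assert exons[0].length == 10
    # two exons -> one intron
    assert len(gene.transcripts["g1.t1"].introns()) == 1


def test_gff3_exon_outside_gene_rejected_with_warning(tmp_path, caplog):
    bad = GFF + "chr1\tsrc\texon\t70\t80\t.\t+\t.\tID=e3;Parent=g1.t1\n"
    path = tmp_path / "b.gff3"
    path.write_text(bad)
    with caplog.at_level("WARNING"):
        ann = formats.read_gff3(path)
    assert "rejecting exon" in caplog.text
    assert len(ann.genes["g1"].transcripts["g1.t1"].exons) == 2


def test_gff3_missing_parent_is_error(tmp_path):
    bad = GFF.replace("ID=e1;Parent=g1.t1", "ID=e1")
    path = tmp_path / "c.gff3"
    path.write_text(bad)
    with pytest.raises(ValueError, match="Parent"):
        formats.read_gff3(path)


def test_gff3_round_trip(tmp_path, rng):
    ann = random_annotation(rng)
    out = tmp_path / "rt.gff3"
    formats.write_gff3(ann, out)
    again = formats.read_gff3(out)
    assert again == ann


def test_fasta_and_bed_round_trip(tmp_path, rng):
    seqs = {"s1": "ACGTNACGT", "s2": "GGGCCC"}
    fpath = tmp_path / "x.fasta"
    formats.write_fasta(seqs, fpath)
    assert formats.read_fasta(fpath) == seqs

    ivs = [Interval("s1", 0, 5), Interval("s2", 2, 6)]
    bpath = tmp_path / "x.bed"
    formats.write_bed(ivs, bpath)
    assert formats.read_bed(bpath) == ivs

    rpath = tmp_path / "x.repeats.tsv"
    formats.write_repeat_intervals(ivs, rpath)
    assert formats.read_repeat_intervals(rpath) == ivs


def test_hits_reader_values_grouping_and_errors(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "sc1\tprotA\t70.0\t100\t1\t0\t1\t100\t1\t100\t1e-20\t60.5\tbacteria\n"
        "sc1\tprotB\t85.0\t50\t1\t0\t200\t151\t1\t50\t1e-10\t55.0\tfungi\n"
        "sc2\tprotC\t95.0\t80\t0\t0\t10\t89\t1\t80\t1e-30\t120.0\tinvertebrate\n"
    )
    table = formats.read_hits(path)
    assert len(table) == 3
    groups = table.by_query()
    assert set(groups) == {"sc1", "sc2"}
    rec = groups["sc1"][0]
    assert rec.pct_identity == 70.0 and rec.bit_score == 60.5
    assert (rec.q_start, rec.q_end) == (0, 100)  # 1-based inclusive -> half-open
    # minus-frame hit normalized to start < end
    assert (groups["sc1"][1].q_start, groups["sc1"][1].q_end) == (150, 200)

    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert len(formats.read_hits(empty)) == 0

    bad = tmp_path / "bad.tsv"
    bad.write_text("sc1\tp\tNOTNUM\t1\t1\t0\t1\t5\t1\t5\t1e-5\t60\tbacteria\n")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        formats.read_hits(bad)


def test_hits_round_trip(tmp_path):
    _, _, mito, alien, _ = simulate_scaffolds(seed=11, n_scaffolds=8, n_mito_like=2, n_alien=2)
    for table in (mito, alien):
        path = tmp_path / "rt.tsv"
        formats.write_hits(table, path)
        again = formats.read_hits(path)
        assert [(r.query_id, r.subject_group, r.q_start, r.q_end) for r in again.records] \
            == [(r.query_id, r.subject_group, r.q_start, r.q_end) for r in table.records]


class TestCounts:
    def test_salinity_fixture_has_16_samples_with_both_batches(self, tmp_path):
        exp, _ = simulate_count_experiment(SimSpec(seed=0, n_genes=30))
        formats.write_counts(exp, tmp_path / "c.tsv", tmp_path / "s.tsv")
        again = formats.read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert len(again.samples) == 16
        assert {s.batch for s in again.samples} == {1, 2}
        assert again.counts.equals(exp.counts)
        assert again.samples == exp.samples

    def test_duplicate_gene_id_is_error(self, tmp_path):
        exp, _ = simulate_count_experiment(SimSpec(seed=0, n_genes=5))
        formats.write_counts(exp, tmp_path / "c.tsv", tmp_path / "s.tsv")
        lines = (tmp_path / "c.tsv").read_text().splitlines()
        lines.append(lines[1])  # repeat a gene row
        (tmp_path / "c.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            formats.read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")

    def test_sample_mismatch_is_error(self, tmp_path):
        exp, _ = simulate_count_experiment(SimSpec(seed=0, n_genes=5))
        formats.write_counts(exp, tmp_path / "c.tsv", tmp_path / "s.tsv")
        # drop one sample from the annotation only
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        (tmp_path / "s.tsv").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="absent"):
            formats.read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")

    def test_negative_and_fractional_counts_rejected(self, tmp_path):
        exp, _ = simulate_count_experiment(SimSpec(seed=0, n_genes=5))
        formats.write_counts(exp, tmp_path / "c.tsv", tmp_path / "s.tsv")
        text = (tmp_path / "c.tsv").read_text()
        first_value = text.splitlines()[1].split("\t")[1]
        (tmp_path / "c.tsv").write_text(text.replace(f"\t{first_value}\t", "\t-3\t", 1))
        with pytest.raises(ValueError, match="negative"):
            formats.read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")


def test_term_map_round_trip_and_obo(tmp_path):
    tm, _ = simulate_term_map(3, [f"g{i}" for i in range(40)], n_terms=15)
    formats.write_term_map(tm, tmp_path / "map.tsv", tmp_path / "par.tsv")
    again = formats.read_term_map(tmp_path / "map.tsv", tmp_path / "par.tsv")
    assert {g: t for g, t in again.gene_terms.items() if t} \
        == {g: t for g, t in tm.gene_terms.items() if t}
    assert again.parents == {c: p for c, p in tm.parents.items() if p}

    formats.write_obo_lite(tm, tmp_path / "terms.obo")
    ont = formats.read_obo_lite(tmp_path / "terms.obo")
    assert {c: p for c, p in ont.parents.items() if p} == {c: p for c, p in tm.parents.items() if p}
    assert all(ont.names[t] == tm.names[t] for t in tm.names)


def test_cyclic_parent_relation_rejected(tmp_path):
    (tmp_path / "map.tsv").write_text("g1\tA\n")
    (tmp_path / "par.tsv").write_text("A\tB\nB\tA\n")
    with pytest.raises(ValueError, match="cyclic"):
        formats.read_term_map(tmp_path / "map.tsv", tmp_path / "par.tsv")


class TestIntervalPrimitives:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval("s", 5, 5)
        with pytest.raises(ValueError):
            Interval("s", -1, 4)

    def test_merge_and_union_against_perbase(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            spans = []
            grid = np.zeros(300, dtype=bool)
            for _ in range(n):
                a = int(rng.integers(0, 290))
                b = int(rng.integers(a + 1, 300))
                spans.append((a, b))
                grid[a:b] = True
            assert union_length(spans) == int(grid.sum())
            merged = merge_spans(spans)
            assert all(m0 < m1 for m0, m1 in merged)
            assert all(merged[i][1] < merged[i + 1][0] for i in range(len(merged) - 1))
            gaps = gaps_between(spans, 0, 300)
            assert sum(b - a for a, b in gaps) == 300 - int(grid.sum())
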