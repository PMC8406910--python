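#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes count matrices (salinity + anoxia), an orthogroup table, scaffold
fixtures (GFF3/FASTA/hit tables/repeat BED) and a term map, with the
planted truth alongside, under results/inputs/.
"""

import argparse
from pathlib import Path

import numpy as np

from stressgenome import formats, synthetic
from stressgenome.intervals import Interval

SPECIES = ["A_franciscana", "D_pulex", "L_arcticus", "E_texana", "H_dujardini"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    def sub(k: int) -> int:
        return (args.seed + 1_000_003 * (k + 1)) % (2**31)

    for design in ("salinity", "anoxia"):
        spec = synthetic.SimSpec(seed=sub(0 if design == "salinity" else 1),
                                 design=design)
        exp, truth = synthetic.simulate_count_experiment(spec)
        formats.write_counts(exp, out / f"{design}_counts.tsv",
                             out / f"{design}_samples.tsv")
        (out / f"{design}_de_truth.txt").write_text(
            "".join(f"{g}\n" for g in sorted(truth.de_gene_ids)))
        print(f"{design}: {exp.counts.shape[0]} genes x {exp.counts.shape[1]} samples, "
              f"{len(truth.de_gene_ids)} planted DE genes")

    table, otruth = synthetic.simulate_ortho_table(
        sub(2), n_orthogroups=500, species_list=SPECIES,
        n_expanded=15, n_contracted=8, n_unique_pairs=10,
        unique_partner="H_dujardini")
    formats.write_ortho_counts(table, out / "orthogroups.tsv",
                               out / "orthogroup_genes.tsv")
    with open(out / "ortho_truth.tsv", "w") as fh:
        fh.write("orthogroup_id\tplanted\n")
        for og in sorted(otruth.expanded):
            fh.write(f"{og}\texpanded\n")
        for og in sorted(otruth.contracted):
            fh.write(f"{og}\tcontracted\n")
        for og in sorted(otruth.unique_pairs):
            fh.write(f"{og}\tunique_pair\n")
    print(f"orthogroups: 500 groups, {len(otruth.expanded)} expanded / "
          f"{len(otruth.contracted)} contracted / {len(otruth.unique_pairs)} "
          "focal+tardigrade-only planted")

    ann, seqs, mito, alien, struth = synthetic.simulate_scaffolds(
        sub(3), n_scaffolds=30, n_mito_like=5, n_alien=6)
    formats.write_gff3(ann, out / "scaffolds.gff3")
    formats.write_fasta(seqs, out / "scaffolds.fasta")
    formats.write_hits(mito, out / "mito_hits.tsv")
    formats.write_hits(alien, out / "alien_hits.tsv")
    with open(out / "contaminant_truth.tsv", "w") as fh:
        fh.write("scaffold_id\tplanted\n")
        for s in sorted(struth.mito_scaffolds):
            fh.write(f"{s}\tmitochondrial\n")
        for s in sorted(struth.alien_scaffolds):
            fh.write(f"{s}\talien\n")

    rng = np.random.default_rng(sub(4))
    repeats = []
    for sid, length in sorted(ann.scaffold_lengths.items()):
        for _ in range(int(rng.integers(2, 8))):
            lo = int(rng.integers(0, max(1, length - 200)))
            hi = min(length, lo + int(rng.integers(50, 2_000)))
            if hi > lo:
                repeats.append(Interval(sid, lo, hi))
    formats.write_bed(repeats, out / "repeats.bed")
    print(f"scaffolds: {len(ann.scaffold_lengths)} scaffolds, "
          f"{len(struth.mito_scaffolds)} mito-like + {len(struth.alien_scaffolds)} "
          "alien planted")

    genes = [f"AFGENE{i:05d}" for i in range(2_000)]
    tm, ttruth = synthetic.simulate_term_map(
        sub(5), genes, n_terms=60,
        enriched_terms_spec=[synthetic.EnrichedTermSpec(0.4, 0.05)] * 5)
    formats.write_term_map(tm, out / "gene_terms.tsv", out / "term_parents.tsv")
    formats.write_obo_lite(tm, out / "terms.obo")
    (out / "term_test_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(ttruth.test_gene_ids)))
    (out / "enriched_term_truth.txt").write_text(
        "".join(f"{t}\n" for t in sorted(ttruth.enriched_terms)))
    print(f"terms: 60 terms over 2000 genes, {len(ttruth.enriched_terms)} planted enriched")


if __name__ == "__main__":
    main()
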