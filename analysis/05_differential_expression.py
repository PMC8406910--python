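#!/usr/bin/env python
"""Stage-wise NB differential expression under both study designs.

Salinity: CPM filter (<3 in over 14/16 samples), TMM offsets, the
9-coefficient batch+salinity+time+interaction GLM, omnibus LRT screening
with BH FDR, then per-contrast confirmation at the screening-adjusted
level. Anoxia: the simple 3-vs-3 two-group model. Recall/precision are
measured against the planted DE genes.
"""

import argparse
from pathlib import Path

from stressgenome import formats
from stressgenome.de import run_anoxia, run_salinity


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for design, runner in (("salinity", run_salinity), ("anoxia", run_anoxia)):
        exp = formats.read_counts(args.indir / f"{design}_counts.tsv",
                                  args.indir / f"{design}_samples.tsv")
        out = runner(exp)
        out.table.to_csv(args.outdir / f"de_{design}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        truth = {line.strip()
                 for line in open(args.indir / f"{design}_de_truth.txt")}
        de = set(out.de_gene_ids)
        n_up = sum(1 for r in out.results if r.direction == "up")
        n_down = sum(1 for r in out.results if r.direction == "down")
        print(f"{design}: {exp.counts.shape[0]} genes, {len(out.kept_genes)} kept "
              f"after CPM filter, common dispersion {out.common_dispersion:.3f}")
        print(f"  {len(de)} DE ({n_up} up / {n_down} down); planted {len(truth)}; "
              f"recall {len(de & truth) / len(truth):.2f}, "
              f"precision {len(de & truth) / max(len(de), 1):.2f}")


if __name__ == "__main__":
    main()
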