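#!/usr/bin/env python
"""Flag mitochondrial and alien scaffolds and compare with the planted truth.

Mitochondrial rule: scaffold <= 15,822 bp whose every gene hits a
mitochondrial protein at bit score >= 50. Alien rule: exclusively
non-invertebrate hits at >= 70% identity with no alien-free stretch over
5 kb.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressgenome import formats
from stressgenome.decontam import decontaminate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ann = formats.read_gff3(args.indir / "scaffolds.gff3")
    mito_hits = formats.read_hits(args.indir / "mito_hits.tsv")
    alien_hits = formats.read_hits(args.indir / "alien_hits.tsv")
    flags = decontaminate(ann, mito_hits, alien_hits)

    rows = [{"scaffold_id": s, "flag": "mitochondrial"}
            for s in sorted(flags["mitochondrial"])]
    rows += [{"scaffold_id": s, "flag": "alien"} for s in sorted(flags["alien"])]
    pd.DataFrame(rows, columns=["scaffold_id", "flag"]).to_csv(
        args.outdir / "decontam_flags.tsv", sep="\t", index=False)
    (args.outdir / "clean_scaffolds.txt").write_text(
        "".join(f"{s}\n" for s in sorted(flags["clean"])))

    truth = pd.read_csv(args.indir / "contaminant_truth.tsv", sep="\t")
    planted_mito = set(truth.loc[truth.planted == "mitochondrial", "scaffold_id"])
    planted_alien = set(truth.loc[truth.planted == "alien", "scaffold_id"])
    print(f"mitochondrial: flagged {len(flags['mitochondrial'])}, planted "
          f"{len(planted_mito)}, exact match: {flags['mitochondrial'] == planted_mito}")
    print(f"alien:         flagged {len(flags['alien'])}, planted "
          f"{len(planted_alien)}, exact match: {flags['alien'] == planted_alien}")
    print(f"{len(flags['clean'])} scaffolds retained")


if __name__ == "__main__":
    main()
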