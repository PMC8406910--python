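#!/usr/bin/env python
"""Orthogroup expansion/contraction calling, branchiopod Venn regions and
extremophile-shared (focal + tardigrade only) orthogroups, compared with
the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from stressgenome import formats
from stressgenome.ortho import (
    call_expansion,
    calls_to_frame,
    shared_unique,
    summarize_calls,
    venn_partition,
)

BRANCHIOPODS = ["A_franciscana", "D_pulex", "L_arcticus", "E_texana"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = formats.read_ortho_counts(
        args.indir / "orthogroups.tsv", "A_franciscana",
        membership_path=args.indir / "orthogroup_genes.tsv")

    calls = call_expansion(table)
    calls_to_frame(calls).to_csv(args.outdir / "ortho_calls.tsv", sep="\t", index=False)
    counts = summarize_calls(calls)

    truth = pd.read_csv(args.indir / "ortho_truth.tsv", sep="\t")
    planted_exp = set(truth.loc[truth.planted == "expanded", "orthogroup_id"])
    planted_con = set(truth.loc[truth.planted == "contracted", "orthogroup_id"])
    planted_pairs = set(truth.loc[truth.planted == "unique_pair", "orthogroup_id"])
    called_exp = {c.orthogroup_id for c in calls if c.consensus_status == "expanded_vs_all"}
    called_con = {c.orthogroup_id for c in calls
                  if c.consensus_status == "contracted_vs_all"}
    n = len(table.counts)
    print(f"{n} orthogroups: {counts['expanded_vs_all']} expanded "
          f"({counts['expanded_vs_all'] / n:.1%}), {counts['contracted_vs_all']} "
          f"contracted ({counts['contracted_vs_all'] / n:.2%}) vs all comparators")
    print(f"expanded match planted:   {called_exp == planted_exp}")
    print(f"contracted match planted: {called_con == planted_con}")

    regions = venn_partition(table, BRANCHIOPODS)
    pd.DataFrame(
        [{"region": "&".join(sorted(k)), "n_orthogroups": v}
         for k, v in sorted(regions.items(), key=lambda kv: "&".join(sorted(kv[0])))]
    ).to_csv(args.outdir / "ortho_venn.tsv", sep="\t", index=False)
    union = int((table.counts[BRANCHIOPODS] > 0).any(axis=1).sum())
    print(f"Venn over {len(BRANCHIOPODS)} branchiopods: regions sum to "
          f"{sum(regions.values())} = union {union}")

    pairs = shared_unique(table, {"A_franciscana", "H_dujardini"},
                          set(BRANCHIOPODS[1:]))
    (args.outdir / "ortho_shared_unique.txt").write_text(
        "".join(f"{og}\n" for og in sorted(pairs)))
    print(f"focal+H_dujardini-only orthogroups: {len(pairs)} found, "
          f"match planted: {set(pairs) == planted_pairs}")


if __name__ == "__main__":
    main()
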