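"""End-to-end demo pipeline on synthetic data.

Generates every input with planted truth, runs all downstream stages at
their default (study) thresholds, and writes TSV reports plus a summary
and a planted-truth comparison. Output is byte-identical across re-runs
at a fixed seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import content, decontam, enrich, formats, ortho, synthetic
from .config import PipelineConfig
from .de import run_anoxia, run_salinity
from .intervals import Interval

logger = logging.getLogger(__name__)


def _subseed(base: int, k: int) -> int:
    return (base + 1_000_003 * (k + 1)) % (2**31)


def run_demo(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    summary: dict[str, float | int | str] = {}
    truth_rows: list[dict] = []

    # --- synthetic inputs -------------------------------------------------
    logger.info("simulating inputs (seed %d)", seed)
    sal_spec = synthetic.SimSpec(**{**config.simulate.__dict__,
                                    "seed": _subseed(seed, 0), "design": "salinity"})
    anx_spec = synthetic.SimSpec(**{**config.simulate.__dict__,
                                    "seed": _subseed(seed, 1), "design": "anoxia",
                                    "n_genes": config.simulate.n_genes})
    sal_exp, sal_truth = synthetic.simulate_count_experiment(sal_spec)
    anx_exp, anx_truth = synthetic.simulate_count_experiment(anx_spec)
    formats.write_counts(sal_exp, inputs / "salinity_counts.tsv", inputs / "salinity_samples.tsv")
    formats.write_counts(anx_exp, inputs / "anoxia_counts.tsv", inputs / "anoxia_samples.tsv")

    species = list(synthetic.DEFAULT_SPECIES) + ["H_dujardini"]
    table, ortho_truth = synthetic.simulate_ortho_table(
        _subseed(seed, 2), n_orthogroups=400, species_list=species,
        n_expanded=12, n_contracted=6, n_unique_pairs=8, unique_partner="H_dujardini",
        min_focal=config.ortho.min_focal, ratio=int(config.ortho.ratio),
    )
    formats.write_ortho_counts(table, inputs / "orthogroups.tsv", inputs / "orthogroup_genes.tsv")

    annotation, sequences, mito_hits, alien_hits, scaf_truth = synthetic.simulate_scaffolds(
        _subseed(seed, 3), n_scaffolds=24, n_mito_like=4, n_alien=5,
    )
    formats.write_gff3(annotation, inputs / "scaffolds.gff3")
    formats.write_fasta(sequences, inputs / "scaffolds.fasta")
    formats.write_hits(mito_hits, inputs / "mito_hits.tsv")
    formats.write_hits(alien_hits, inputs / "alien_hits.tsv")

    rng = np.random.default_rng(_subseed(seed, 4))
    repeats = []
    for sid, length in sorted(annotation.scaffold_lengths.items()):
        n = int(rng.integers(2, 8))
        for _ in range(n):
            lo = int(rng.integers(0, max(1, length - 200)))
            hi = min(length, lo + int(rng.integers(50, 2_000)))
            if hi > lo:
                repeats.append(Interval(sid, lo, hi))
    formats.write_bed(repeats, inputs / "repeats.bed")

    # --- genome content ---------------------------------------------------
    comp = content.compute_composition(annotation)
    gc = content.gc_content(sequences)
    rep_frac = content.repeat_fraction(repeats, annotation.scaffold_lengths)
    pd.DataFrame([
        {
            "total_bp": comp.total_bp, "exonic_bp": comp.exonic_bp,
            "intronic_bp": comp.intronic_bp, "intergenic_bp": comp.intergenic_bp,
            "exonic_fraction": round(comp.exonic_fraction, 6),
            "intronic_fraction": round(comp.intronic_fraction, 6),
            "repeat_fraction": round(rep_frac, 6),
            "gc_fraction": round(gc, 6),
            "mean_exons_per_gene": round(comp.mean_exons_per_gene, 4),
            "mean_intron_len_bp": round(comp.mean_intron_len_bp, 2),
        }
    ]).to_csv(outdir / "content_summary.tsv", sep="\t", index=False)
    content.per_scaffold_composition(annotation).to_csv(
        outdir / "content_per_scaffold.tsv", sep="\t", index=False)
    summary["gc_fraction"] = round(gc, 6)
    summary["repeat_fraction"] = round(rep_frac, 6)

    # --- decontamination --------------------------------------------------
    flags = decontam.decontaminate(annotation, mito_hits, alien_hits, config.decontam)
    rows = [{"scaffold_id": s, "flag": "mitochondrial"} for s in sorted(flags["mitochondrial"])]
    rows += [{"scaffold_id": s, "flag": "alien"} for s in sorted(flags["alien"])]
    pd.DataFrame(rows, columns=["scaffold_id", "flag"]).to_csv(
        outdir / "decontam_flags.tsv", sep="\t", index=False)
    with open(outdir / "clean_scaffolds.txt", "w") as fh:
        fh.writelines(f"{s}\n" for s in sorted(flags["clean"]))
    summary["n_mito_flagged"] = len(flags["mitochondrial"])
    summary["n_alien_flagged"] = len(flags["alien"])
    truth_rows.append({"stage": "decontam_mito", "planted": len(scaf_truth.mito_scaffolds),
                       "recovered": len(flags["mitochondrial"] & scaf_truth.mito_scaffolds),
                       "called": len(flags["mitochondrial"])})
    truth_rows.append({"stage": "decontam_alien", "planted": len(scaf_truth.alien_scaffolds),
                       "recovered": len(flags["alien"] & scaf_truth.alien_scaffolds),
                       "called": len(flags["alien"])})

    # --- orthogroups ------------------------------------------------------
    calls = ortho.call_expansion(table, config.ortho.min_focal, config.ortho.ratio,
                                 config.ortho.zero_comparator_as_unique)
    ortho.calls_to_frame(calls).to_csv(outdir / "ortho_calls.tsv", sep="\t", index=False)
    call_counts = ortho.summarize_calls(calls)
    expanded = {c.orthogroup_id for c in calls if c.consensus_status == "expanded_vs_all"}
    contracted = {c.orthogroup_id for c in calls if c.consensus_status == "contracted_vs_all"}
    summary["n_expanded"] = len(expanded)
    summary["n_contracted"] = len(contracted)
    truth_rows.append({"stage": "ortho_expanded", "planted": len(ortho_truth.expanded),
                       "recovered": len(expanded & ortho_truth.expanded),
                       "called": len(expanded)})
    truth_rows.append({"stage": "ortho_contracted", "planted": len(ortho_truth.contracted),
                       "recovered": len(contracted & ortho_truth.contracted),
                       "called": len(contracted)})

    branchiopods = list(synthetic.DEFAULT_SPECIES)
    regions = ortho.venn_partition(table, branchiopods)
    pd.DataFrame(
        [{"region": "&".join(sorted(k)), "n_orthogroups": v}
         for k, v in sorted(regions.items(), key=lambda kv: "&".join(sorted(kv[0])))]
    ).to_csv(outdir / "ortho_venn.tsv", sep="\t", index=False)

    unique = ortho.shared_unique(table, {"A_franciscana", "H_dujardini"},
                                 set(branchiopods[1:]))
    with open(outdir / "ortho_shared_unique.txt", "w") as fh:
        fh.writelines(f"{og}\n" for og in sorted(unique))
    truth_rows.append({"stage": "ortho_unique_pairs", "planted": len(ortho_truth.unique_pairs),
                       "recovered": len(set(unique) & ortho_truth.unique_pairs),
                       "called": len(unique)})

    # --- differential expression ------------------------------------------
    logger.info("running salinity DE")
    sal_out = run_salinity(sal_exp, config.de)
    sal_out.table.to_csv(outdir / "de_salinity.tsv", sep="\t", index=False,
                         float_format="%.6g")
    logger.info("running anoxia DE")
    anx_out = run_anoxia(anx_exp, config.de)
    anx_out.table.to_csv(outdir / "de_anoxia.tsv", sep="\t", index=False,
                         float_format="%.6g")
    sal_de = set(sal_out.de_gene_ids)
    anx_de = set(anx_out.de_gene_ids)
    summary["n_de_salinity"] = len(sal_de)
    summary["n_de_anoxia"] = len(anx_de)
    summary["n_de_anoxia_up"] = sum(1 for r in anx_out.results if r.direction == "up")
    summary["n_de_anoxia_down"] = sum(1 for r in anx_out.results if r.direction == "down")
    truth_rows.append({"stage": "de_salinity", "planted": len(sal_truth.de_gene_ids),
                       "recovered": len(sal_de & sal_truth.de_gene_ids),
                       "called": len(sal_de)})
    truth_rows.append({"stage": "de_anoxia", "planted": len(anx_truth.de_gene_ids),
                       "recovered": len(anx_de & anx_truth.de_gene_ids),
                       "called": len(anx_de)})

    # --- enrichment -------------------------------------------------------
    genes = list(sal_exp.counts.index)
    term_map, term_truth = synthetic.simulate_term_map(
        _subseed(seed, 5), genes, n_terms=60,
        enriched_terms_spec=[synthetic.EnrichedTermSpec(0.4, 0.05)] * 5,
    )
    formats.write_term_map(term_map, inputs / "gene_terms.tsv", inputs / "term_parents.tsv")
    results = enrich.fisher_asymmetric(term_truth.test_gene_ids, genes, term_map,
                                       propagate=config.enrich.propagate,
                                       direction=config.enrich.direction)
    enrich.results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t",
                                            index=False, float_format="%.6g")
    hits = {r.term_id for r in results if r.fdr <= config.enrich.alpha}
    summary["n_enriched_terms"] = len(hits)
    truth_rows.append({"stage": "enrichment", "planted": len(term_truth.enriched_terms),
                       "recovered": len(hits & term_truth.enriched_terms),
                       "called": len(hits)})

    # --- summaries --------------------------------------------------------
    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_comparison.tsv", sep="\t", index=False)
    pd.DataFrame([dict(call_counts)]).to_csv(outdir / "ortho_consensus_counts.tsv",
                                             sep="\t", index=False)
    logger.info("demo written to %s", outdir)
    return outdir
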