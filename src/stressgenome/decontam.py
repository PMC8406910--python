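"""Assembly decontamination: flag mitochondrial and alien scaffolds.

Two independent homology-based rules remove non-nuclear sequence from the
assembly while keeping anything that could be a genuine arthropod locus:

* **mitochondrial** — a scaffold no longer than the mitochondrial genome
  (15,822 bp for the brine shrimp) whose every gene has a confident hit
  (bit score >= 50) against the mitochondrial gene set;
* **alien** — a scaffold whose protein hits are exclusively
  non-invertebrate at >= 70% identity, with no invertebrate hit at any
  identity, and no alien-hit-free stretch longer than 5 kb. A scaffold with
  no hits at all is retained: "100% non-invertebrate" cannot be established
  from nothing.

The 5 kb clause is read as a coverage condition (no gap between consecutive
alien hits, or between a hit and a scaffold end, exceeding the window); the
alternative reading — only scaffolds shorter than 5 kb are eligible — is
selectable via ``alien_rule_is_max_scaffold_len``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .intervals import gaps_between
from .model import GenomeAnnotation, ScaffoldHitTable

MITO_GROUP = "mitochondrial-gene"
INVERTEBRATE_GROUP = "invertebrate"


@dataclass
class DecontamRuleSet:
    mito_max_len_bp: int = 15_822
    min_bit_score: float = 50.0
    alien_min_identity_pct: float = 70.0
    alien_window_bp: int = 5_000
    alien_rule_is_max_scaffold_len: bool = False

    def __post_init__(self) -> None:
        for name in ("mito_max_len_bp", "min_bit_score", "alien_min_identity_pct", "alien_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def flag_mitochondrial(annotation: GenomeAnnotation, hits: ScaffoldHitTable,
                       rules: DecontamRuleSet | None = None) -> set[str]:
    """Scaffolds whose genes all look mitochondrial.

    ``hits`` is keyed by focal gene id; a gene counts as mitochondrial when
    it has at least one hit labelled ``mitochondrial-gene`` with bit score at
    or above the threshold. A scaffold is flagged iff it is within the
    length bound, carries at least one gene, and every one of its genes is
    mitochondrial by that criterion.
    """
    rules = rules or DecontamRuleSet()
    gene_hits = hits.by_query()
    flagged: set[str] = set()
    for sid, genes in annotation.genes_by_scaffold().items():
        if not genes:
            continue
        if sid not in annotation.scaffold_lengths:
            raise ValueError(f"scaffold {sid} has genes but no recorded length")
        if annotation.scaffold_lengths[sid] > rules.mito_max_len_bp:
            continue
        if all(
            any(
                h.subject_group == MITO_GROUP and h.bit_score >= rules.min_bit_score
                for h in gene_hits.get(g.gene_id, ())
            )
            for g in genes
        ):
            flagged.add(sid)
    return flagged


def flag_alien(scaffold_lengths: Mapping[str, int], hits: ScaffoldHitTable,
               rules: DecontamRuleSet | None = None) -> set[str]:
    """Scaffolds supported only by non-invertebrate protein hits.

    ``hits`` is keyed by scaffold id and must carry query coordinates.
    """
    rules = rules or DecontamRuleSet()
    flagged: set[str] = set()
    for sid, scaffold_hits in hits.by_query().items():
        if sid not in scaffold_lengths:
            raise ValueError(f"hit on unknown scaffold {sid}")
        length = scaffold_lengths[sid]
        for h in scaffold_hits:
            if h.q_start is None or h.q_end is None:
                raise ValueError(f"alien flagging needs query coordinates (scaffold {sid})")
            if h.q_end > length:
                raise ValueError(
                    f"hit coordinates [{h.q_start}, {h.q_end}) beyond scaffold {sid} "
                    f"length {length}"
                )
        if any(h.subject_group == INVERTEBRATE_GROUP for h in scaffold_hits):
            continue  # a single invertebrate hit at any identity retains the scaffold
        alien = [
            h for h in scaffold_hits
            if h.subject_group != INVERTEBRATE_GROUP
            and h.pct_identity >= rules.alien_min_identity_pct
        ]
        if not alien:
            continue
        if rules.alien_rule_is_max_scaffold_len:
            if length <= rules.alien_window_bp:
                flagged.add(sid)
            continue
        gaps = gaps_between([(h.q_start, h.q_end) for h in alien], 0, length)
        if all(end - start <= rules.alien_window_bp for start, end in gaps):
            flagged.add(sid)
    return flagged


def decontaminate(annotation: GenomeAnnotation, mito_hits: ScaffoldHitTable,
                  alien_hits: ScaffoldHitTable,
                  rules: DecontamRuleSet | None = None) -> dict[str, set[str]]:
    """Run both rules; returns {'mitochondrial': ids, 'alien': ids, 'clean': ids}."""
    rules = rules or DecontamRuleSet()
    mito = flag_mitochondrial(annotation, mito_hits, rules)
    alien = flag_alien(annotation.scaffold_lengths, alien_hits, rules)
    clean = set(annotation.scaffold_lengths) - mito - alien
    return {"mitochondrial": mito, "alien": alien, "clean": clean}
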