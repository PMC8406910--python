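"""Orthogroup expansion/contraction calling and multi-species set algebra.

The calling rule: an orthogroup with focal-species count ``N_x`` and
comparator count ``N_y`` is *expanded* against that comparator when
``N_x >= min_focal`` and ``N_x >= ratio * N_y``, and *contracted* when
``N_x >= min_focal`` and ``ratio * N_x <= N_y`` (defaults: min_focal=5,
ratio=3). A comparator count of zero with a qualifying focal count is
called expanded (the literal rule; presence/absence families behave the
same way); ``zero_comparator_as_unique=True`` instead routes those calls to
a separate ``focal_unique`` status.

Because the ratio exceeds 1, no orthogroup can be simultaneously expanded
and contracted against the same comparator; this is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import OrthoCountTable, presence_matrix

PAIR_STATUSES = ("expanded", "contracted", "focal_unique", "none")
CONSENSUS_STATUSES = ("expanded_vs_all", "contracted_vs_all", "mixed", "none")


@dataclass
class ExpansionCall:
    orthogroup_id: str
    per_comparator: dict[str, str]  # comparator species -> pairwise status
    consensus_status: str

    def status_vs(self, species: str) -> str:
        return self.per_comparator[species]


def _pair_status(n_focal: int, n_comp: int, min_focal: int, ratio: float,
                 zero_comparator_as_unique: bool) -> str:
    if n_focal < min_focal:
        return "none"
    expanded = n_focal >= ratio * n_comp
    contracted = ratio * n_focal <= n_comp
    assert not (expanded and contracted), "rule cannot call both directions"
    if expanded:
        if n_comp == 0 and zero_comparator_as_unique:
            return "focal_unique"
        return "expanded"
    if contracted:
        return "contracted"
    return "none"


def call_expansion(table: OrthoCountTable, min_focal: int = 5, ratio: float = 3.0,
                   zero_comparator_as_unique: bool = False) -> list[ExpansionCall]:
    """Pairwise and consensus expansion/contraction calls for every orthogroup."""
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    comparators = table.comparators
    if not comparators:
        raise ValueError("table has no comparator species")
    focal = table.counts[table.focal_species]
    calls: list[ExpansionCall] = []
    for og in table.counts.index:
        n_focal = int(focal.loc[og])
        per_comp = {
            comp: _pair_status(n_focal, int(table.counts.loc[og, comp]),
                               min_focal, ratio, zero_comparator_as_unique)
            for comp in comparators
        }
        statuses = set(per_comp.values())
        if statuses <= {"expanded", "focal_unique"} and statuses & {"expanded", "focal_unique"}:
            consensus = "expanded_vs_all"
        elif statuses == {"contracted"}:
            consensus = "contracted_vs_all"
        elif statuses == {"none"}:
            consensus = "none"
        else:
            consensus = "mixed"
        calls.append(ExpansionCall(str(og), per_comp, consensus))
    return calls


def calls_to_frame(calls: Sequence[ExpansionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"orthogroup_id": c.orthogroup_id, "consensus_status": c.consensus_status}
        row.update({f"vs_{sp}": st for sp, st in c.per_comparator.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def venn_partition(table: OrthoCountTable | pd.DataFrame,
                   species_subset: Sequence[str]) -> dict[frozenset[str], int]:
    """Count orthogroups in every region of the k-species Venn diagram.

    A region is the set of species in which the orthogroup is present
    (count > 0) among ``species_subset``; all 2^k - 1 non-empty regions are
    returned, and the counts sum to the number of orthogroups present in at
    least one of the selected species.
    """
    if not (2 <= len(species_subset) <= 5):
        raise ValueError("venn_partition supports 2-5 species")
    if len(set(species_subset)) != len(species_subset):
        raise ValueError("duplicate species in subset")
    presence = (
        presence_matrix(table) if isinstance(table, OrthoCountTable) else table.astype(bool)
    )
    missing = set(species_subset) - set(presence.columns)
    if missing:
        raise ValueError(f"unknown species: {sorted(missing)}")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(species_subset) + 1):
        for combo in combinations(species_subset, r):
            regions[frozenset(combo)] = 0
    sub = presence[list(species_subset)]
    for _, row in sub.iterrows():
        present = frozenset(sp for sp in species_subset if row[sp])
        if present:
            regions[present] += 1
    return regions


def shared_unique(table: OrthoCountTable, must_have: Iterable[str],
                  must_lack: Iterable[str]) -> list[str]:
    """Orthogroups present in every ``must_have`` species and absent from all
    ``must_lack`` species."""
    have, lack = set(must_have), set(must_lack)
    if have & lack:
        raise ValueError(f"species in both sets: {sorted(have & lack)}")
    unknown = (have | lack) - set(table.species)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    presence = presence_matrix(table)
    mask = pd.Series(True, index=presence.index)
    for sp in have:
        mask &= presence[sp]
    for sp in lack:
        mask &= ~presence[sp]
    return [str(og) for og in presence.index[mask]]


def de_overlap_fraction(calls: Sequence[ExpansionCall], table: OrthoCountTable,
                        de_gene_ids: Iterable[str],
                        statuses: tuple[str, ...] = ("expanded_vs_all", "contracted_vs_all"),
                        ) -> float:
    """Fraction of focal genes in expanded/contracted orthogroups that are DE."""
    de = set(de_gene_ids)
    genes: set[str] = set()
    for c in calls:
        if c.consensus_status in statuses:
            genes.update(table.focal_genes.get(c.orthogroup_id, ()))
    if not genes:
        return 0.0
    return len(genes & de) / len(genes)


def summarize_calls(calls: Sequence[ExpansionCall]) -> Mapping[str, int]:
    counts = {status: 0 for status in CONSENSUS_STATUSES}
    for c in calls:
        counts[c.consensus_status] += 1
    return counts
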