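"""Enrichment: hypergeometric oracle, BH oracle, asymmetry, DAG reduction."""

from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from stressgenome.enrich import (
    _tail_p,
    bh_adjust,
    fisher_asymmetric,
    reduce_most_specific,
)
from stressgenome.model import TermMap
from stressgenome.synthetic import EnrichedTermSpec, simulate_term_map


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by direct enumeration with exact binomial coefficients."""
    M, n, N = a + b + c + d, a + c, a + b
    if M == 0 or n == 0 or N == 0:
        return 1.0
    total = comb(M, N)
    acc = 0
    for k in range(a, min(n, N) + 1):
        if N - k <= M - n:
            acc += comb(n, k) * comb(M - n, N - k)
    return acc / total


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """O(n^2) step-up: adj_i = min(1, min_{rank >= i} p_(j) * m / j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [p[order[r - 1]] * m / r for r in range(rank, m + 1)]
        out[idx] = min(1.0, min(candidates))
    return out


def test_tail_p_matches_enumeration_on_small_tables(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
        assert _tail_p(a, b, c, d, "over") == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), abs=1e-12)


def test_tail_p_matches_scipy_one_sided_fisher(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        expected = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert _tail_p(a, b, c, d, "over") == pytest.approx(expected, rel=1e-9)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computable_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_share_adjusted_value(self):
        out = bh_adjust([0.5, 0.5, 0.01])
        assert out[0] == out[1]

    def test_random_vectors_match_bruteforce_exactly(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 51))
            p = rng.random(n)
            assert np.array_equal(bh_adjust(p), bh_oracle(p))

    def test_fdr_never_below_p(self, rng):
        p = rng.random(40)
        assert (bh_adjust(p) >= p * (1 - 1e-15)).all()


def _flat_map(annotations: dict[str, set[str]], parents=None) -> TermMap:
    return TermMap(annotations, parents or {})


class TestFisherAsymmetric:
    def test_term_annotating_nothing_gets_p_one(self):
        tm = _flat_map({"g1": set(), "g2": set()}, parents={"T1": set()})
        res = fisher_asymmetric(["g1"], ["g1", "g2"], tm, propagate=False)
        assert all(r.p_value == 1.0 for r in res)

    def test_empty_test_set_is_error(self):
        tm = _flat_map({"g1": {"T"}})
        with pytest.raises(ValueError):
            fisher_asymmetric([], ["g1"], tm)

    def test_shared_genes_removed_from_reference_only(self):
        genes = {f"g{i}": set() for i in range(20)}
        for i in range(5):
            genes[f"g{i}"] = {"T"}
        tm = _flat_map(genes)
        test = [f"g{i}" for i in range(5)]          # all annotated, all also in ref
        res = fisher_asymmetric(test, list(genes), tm, propagate=False)
        r = next(r for r in res if r.term_id == "T")
        assert (r.a, r.c) == (5, 0)                  # zero values in the reference set
        assert r.b == 0 and r.d == 15

    def test_degenerate_test_equals_reference(self):
        genes = {f"g{i}": ({"T"} if i < 3 else set()) for i in range(6)}
        tm = _flat_map(genes)
        res = fisher_asymmetric(list(genes), list(genes), tm, propagate=False)
        r = next(r for r in res if r.term_id == "T")
        assert (r.c, r.d) == (0, 0)
        assert 0.0 <= r.p_value <= 1.0

    def test_asymmetry_inert_when_sets_disjoint(self, rng):
        genes = [f"g{i}" for i in range(60)]
        annotations = {g: ({"T"} if rng.random() < 0.3 else set()) for g in genes}
        tm = _flat_map(annotations)
        test, ref = genes[:20], genes[20:]
        res = fisher_asymmetric(test, ref, tm, propagate=False)
        r = next(r for r in res if r.term_id == "T")
        a = sum(1 for g in test if "T" in annotations[g])
        c = sum(1 for g in ref if "T" in annotations[g])
        expected = fisher_exact([[a, 20 - a], [c, 40 - c]], alternative="greater")[1]
        assert r.p_value == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_gene_id_permutation(self, rng):
        genes = [f"g{i}" for i in range(40)]
        annotations = {g: ({"T"} if rng.random() < 0.4 else set()) for g in genes}
        tm = _flat_map(annotations)
        test = genes[:10]
        p1 = {r.term_id: r.p_value for r in fisher_asymmetric(test, genes, tm, propagate=False)}
        renamed = {f"x_{g}": t for g, t in annotations.items()}
        tm2 = _flat_map(renamed)
        p2 = {r.term_id: r.p_value
              for r in fisher_asymmetric([f"x_{g}" for g in test],
                                         list(renamed), tm2, propagate=False)}
        assert p1 == p2

    def test_propagation_closes_annotations_upward(self):
        tm = TermMap({"g1": {"child"}, "g2": set()},
                     parents={"child": {"parent"}})
        res = fisher_asymmetric(["g1"], ["g1", "g2"], tm, propagate=True)
        parent = next(r for r in res if r.term_id == "parent")
        assert parent.a == 1

    def test_fully_discriminating_term_is_minimal_p(self):
        genes = {f"t{i}": {"HIT"} for i in range(10)}
        genes.update({f"b{i}": set() for i in range(50)})
        tm = _flat_map(genes)
        res = fisher_asymmetric([f"t{i}" for i in range(10)], list(genes), tm,
                                propagate=False)
        best = min(res, key=lambda r: r.p_value)
        assert best.term_id == "HIT"


class TestReduceMostSpecific:
    def _results(self, fdrs: dict[str, float]):
        from stressgenome.enrich import EnrichmentResult

        return [EnrichmentResult(t, 1, 1, 1, 1, f, fdr=f) for t, f in fdrs.items()]

    def test_child_shadows_significant_parent(self):
        tm = TermMap({}, parents={"child": {"parent"}})
        kept = reduce_most_specific(self._results({"parent": 0.01, "child": 0.02}), tm)
        assert [r.term_id for r in kept] == ["child"]

    def test_parent_kept_when_child_not_significant(self):
        tm = TermMap({}, parents={"child": {"parent"}})
        kept = reduce_most_specific(self._results({"parent": 0.01, "child": 0.50}), tm)
        assert [r.term_id for r in kept] == ["parent"]

    def test_random_dag_matches_descendant_scan(self, rng):
        for _ in range(30):
            n = 20
            terms = [f"T{i}" for i in range(n)]
            parents = {terms[i]: {terms[int(rng.integers(0, i))]}
                       for i in range(1, n) if rng.random() < 0.6}
            tm = TermMap({}, parents=parents)
            fdrs = {t: float(rng.random()) * 0.2 for t in terms}
            kept = {r.term_id for r in reduce_most_specific(self._results(fdrs), tm)}
            sig = {t for t, f in fdrs.items() if f <= 0.05}
            expected = {t for t in sig if not (tm.descendants(t) & sig)}
            assert kept == expected


def test_null_term_maps_rarely_yield_significance():
    """With equal annotation rates everywhere, terms reaching FDR <= 0.05
    should appear in at most ~5% of simulated datasets."""
    genes = [f"g{i}" for i in range(300)]
    n_seeds = 120
    hits = 0
    for seed in range(n_seeds):
        tm, truth = simulate_term_map(seed, genes, n_terms=25, enriched_terms_spec=())
        res = fisher_asymmetric(truth.test_gene_ids, genes, tm, propagate=False)
        if any(r.fdr <= 0.05 for r in res):
            hits += 1
    rate = hits / n_seeds
    se = np.sqrt(0.05 * 0.95 / n_seeds)
    assert rate <= 0.05 + 3 * se


def test_planted_enrichment_recovered():
    genes = [f"g{i}" for i in range(500)]
    tm, truth = simulate_term_map(
        77, genes, n_terms=40,
        enriched_terms_spec=[EnrichedTermSpec(0.5, 0.05)] * 4)
    res = fisher_asymmetric(truth.test_gene_ids, genes, tm, propagate=False)
    called = {r.term_id for r in res if r.fdr <= 0.05}
    assert truth.enriched_terms <= called
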