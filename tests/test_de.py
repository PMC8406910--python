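"""DE stage: CPM, filtering, TMM (with edgeR oracle), design, stage-wise."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from stressgenome.de import (
    CONTRAST_NAMES,
    DEConfig,
    _holm,
    build_anoxia_design,
    build_design,
    cpm,
    filter_noninformative,
    run_anoxia,
    run_salinity,
    salinity_contrasts,
    stagewise,
    tmm_factors,
)
from stressgenome.model import SampleAnnotation
from stressgenome.synthetic import (
    SimSpec,
    anoxia_layout,
    salinity_layout,
    simulate_count_experiment,
)


class TestCPMAndFilter:
    def test_cpm_formula(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)).astype(int))
        lib = counts.sum(axis=0)
        out = cpm(counts)
        assert np.allclose(out.to_numpy(),
                           counts.to_numpy() * 1e6 / lib.to_numpy()[None, :])
        assert cpm(pd.DataFrame([[10]]), pd.Series([10**6])).iloc[0, 0] == 10.0
        assert cpm(pd.DataFrame([[0]]), pd.Series([10**6])).iloc[0, 0] == 0.0

    def test_filter_is_strictly_over(self):
        """CPM >= 3 in exactly 2 of 16 samples -> 14 low, kept; 1 of 16 -> removed."""
        lib = pd.Series([10**6] * 16)
        kept_row = [3] * 2 + [0] * 14       # 14 low, not > 14
        removed_row = [3] * 1 + [0] * 15    # 15 low
        counts = pd.DataFrame([kept_row, removed_row], index=["keep", "drop"])
        kept = filter_noninformative(counts, 3.0, 14, lib_sizes=lib)
        assert list(kept) == ["keep"]

    def test_zero_threshold_keeps_everything(self, rng):
        counts = pd.DataFrame(rng.integers(0, 5, (30, 6)).astype(int))
        counts.iloc[0] = 0
        kept = filter_noninformative(counts + 0, 0.0, 3,
                                     lib_sizes=pd.Series([10**6] * 6))
        assert len(kept) == 30

    def test_anoxia_default_threshold(self):
        lib = pd.Series([10**6] * 6)
        counts = pd.DataFrame([[3, 3, 3, 0, 0, 0],   # 3 low, kept
                               [3, 3, 0, 0, 0, 0]],  # 4 low, removed
                              index=["keep", "drop"])
        assert list(filter_noninformative(counts, 3.0, 3, lib_sizes=lib)) == ["keep"]


class TestTMM:
    def test_identical_libraries(self, rng):
        col = rng.integers(1, 500, 200).astype(int)
        counts = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_pure_depth_change(self, rng):
        col = rng.integers(1, 500, 200).astype(int)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_planted_composition_shift_recovered(self, rng):
        mu = rng.gamma(5.0, 50.0, 1_000) + 1.0
        mu_b = mu.copy()
        mu_b[:100] *= 8  # 10% of genes 8x up in library b
        counts = pd.DataFrame({"a": rng.poisson(mu), "b": rng.poisson(mu_b)})
        f = tmm_factors(counts)
        # library b gained spurious depth ~0.9 + 0.1*8 = 1.7; TMM must undo it
        lib_ratio = counts["b"].sum() / counts["a"].sum()
        assert f["b"] / f["a"] * lib_ratio == pytest.approx(1.0, rel=0.02)

    def test_matches_edgeR_calcNormFactors(self, tmp_path, rng):
        """Independent oracle: edgeR's reference implementation via Rscript."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(400, 5)).astype(int),
            columns=list("ABCDE"))
        counts.iloc[:40, 2] *= 6
        path = tmp_path / "m.tsv"
        counts.to_csv(path, sep="\t", index=False)
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}"));'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        edger = np.array([float(v) for v in out.stdout.split()])
        assert tmm_factors(counts).to_numpy() == pytest.approx(edger, rel=1e-6)

    def test_all_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


class TestDesign:
    def test_reference_sample_row(self):
        s = SampleAnnotation("r", "nauplii", 15, "low", 1)
        row = build_design([s]).iloc[0]
        assert row.tolist() == [1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_batch2_high_45min_row(self):
        s = SampleAnnotation("x", "nauplii", 45, "high", 2)
        row = build_design([s]).iloc[0]
        assert row.tolist() == [1, 1, 1, 0, 1, 0, 0, 1, 0]

    def test_full_layout_has_rank_nine(self):
        X = build_design(salinity_layout())
        assert X.shape == (16, 9)
        assert np.linalg.matrix_rank(X.to_numpy()) == 9

    def test_anoxia_design_two_columns(self):
        X = build_anoxia_design(anoxia_layout())
        assert X.shape == (6, 2)
        assert X["anoxia"].sum() == 3

    def test_contrast_matrix(self):
        C = salinity_contrasts()
        assert C.loc["salinity_15", "salinity_high"] == 1.0
        assert C.loc["salinity_30", "salinity:time30"] == 1.0
        assert C.loc["salinity_avg", "salinity:time45"] == 0.25
        assert (C.loc["salinity_avg"].sum()) == pytest.approx(1.75)


class TestStagewise:
    def _frames(self, omnibus, contrast_p=None, log2fc=None):
        genes = [f"g{i}" for i in range(len(omnibus))]
        omn = pd.Series(omnibus, index=genes)
        cp = pd.DataFrame(
            contrast_p if contrast_p is not None else np.ones((len(genes), 5)),
            index=genes, columns=CONTRAST_NAMES)
        fc = pd.DataFrame(
            log2fc if log2fc is not None else np.ones((len(genes), 5)),
            index=genes, columns=CONTRAST_NAMES)
        return omn, cp, fc

    def test_nothing_screened_nothing_confirmed(self):
        omn, cp, fc = self._frames([0.8, 0.9, 0.7])
        results = stagewise(omn, cp, fc)
        assert all(not r.screened and not r.confirmed for r in results)

    def test_confirmation_at_screening_adjusted_level(self):
        # gene g0 screened; alpha_adj = largest BH-rejected raw omnibus p
        omn, cp, fc = self._frames(
            [0.001, 0.9, 0.9, 0.9],
            contrast_p=np.array([[0.0001, 0.5, 0.5, 0.5, 0.0001]] + [[1.0] * 5] * 3),
            log2fc=np.array([[2.0] * 5] + [[0.0] * 5] * 3))
        results = stagewise(omn, cp, fc, alpha=0.05)
        r0 = results[0]
        assert r0.screened
        assert set(r0.confirmed) == {"salinity_15", "salinity_avg"}
        assert r0.direction == "up"

    def test_direction_follows_average_effect_sign(self):
        omn, cp, fc = self._frames([0.0001], log2fc=np.array([[-1.0] * 5]))
        assert stagewise(omn, cp, fc)[0].direction == "down"

    def test_holm_stepdown(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        rejected = _holm(p, 0.05)
        # Holm at 0.05 over 4: 0.005<=0.0125, 0.01<=0.0167, 0.03>0.025 stop
        assert rejected.tolist() == [True, False, False, True]


class TestPipelines:
    def test_salinity_recovers_planted_genes(self):
        exp, truth = simulate_count_experiment(SimSpec(seed=4, n_genes=400))
        out = run_salinity(exp)
        de = set(out.de_gene_ids)
        recall = len(de & truth.de_gene_ids) / len(truth.de_gene_ids)
        assert recall >= 0.8
        fdr = len(de - truth.de_gene_ids) / max(len(de), 1)
        assert fdr <= 0.2

    def test_anoxia_recovers_planted_two_fold_genes(self):
        exp, truth = simulate_count_experiment(
            SimSpec(seed=8, n_genes=300, design="anoxia", logfc_magnitude=2.0))
        out = run_anoxia(exp)
        de = set(out.de_gene_ids)
        recall = len(de & truth.de_gene_ids) / len(truth.de_gene_ids)
        assert recall >= 0.7
        ups = [r for r in out.results if r.direction == "up"]
        downs = [r for r in out.results if r.direction == "down"]
        assert len(ups) + len(downs) == len(de)

    def test_anoxia_threshold_one_reports_everything(self):
        exp, _ = simulate_count_experiment(
            SimSpec(seed=1, n_genes=50, design="anoxia", frac_de=0.0))
        out = run_anoxia(exp, p_threshold=1.0)
        assert len(out.de_gene_ids) == len(out.results)

    def test_identical_groups_yield_few_calls(self):
        exp, _ = simulate_count_experiment(
            SimSpec(seed=21, n_genes=300, design="anoxia", frac_de=0.0))
        out = run_anoxia(exp)
        assert len(out.de_gene_ids) <= 3

    def test_pipeline_is_deterministic(self):
        exp, _ = simulate_count_experiment(SimSpec(seed=2, n_genes=120))
        t1 = run_salinity(exp).table
        t2 = run_salinity(exp).table
        pd.testing.assert_frame_equal(t1, t2)


def test_low_dispersion_large_library_ratio_near_planted():
    """Planted main salinity effect of 1 log2 unit: empirical high/low CPM
    ratio at 15 min within 5% of 2."""
    spec = SimSpec(seed=6, n_genes=600, dispersion=1e-10, frac_de=0.5,
                   logfc_magnitude=1.0, lib_size_range=(50_000_000, 50_000_000))
    exp, truth = simulate_count_experiment(spec)
    beta = truth.coefficients
    main_only = beta.index[(beta["salinity_high"] == 1.0)
                           & (beta[["salinity:time30", "salinity:time45",
                                    "salinity:time60"]] == 0).all(axis=1)]
    assert len(main_only) > 10
    c = cpm(exp.counts)
    low15 = [s.sample_id for s in exp.samples if s.salinity == "low" and s.time_min == 15]
    high15 = [s.sample_id for s in exp.samples if s.salinity == "high" and s.time_min == 15]
    ratio = c.loc[main_only, high15].mean(axis=1) / c.loc[main_only, low15].mean(axis=1)
    assert np.median(ratio) == pytest.approx(2.0, rel=0.05)
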