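"""Differential expression: CPM filtering, TMM normalization, the
9-coefficient salinity design, omnibus screening and stage-wise
confirmation, plus the simple two-group anoxia contrast.

Salinity model (reference levels: batch 1, low salinity, 15 min)::

    log mu = o + b0 + bB*XB + bS*XS + bT30*XT30 + bT45*XT45 + bT60*XT60
               + bS:T30*XS*XT30 + bS:T45*XS*XT45 + bS:T60*XS*XT60

The contrasts of interest are the salinity effect at each time point
(bS, bS+bS:T30, bS+bS:T45, bS+bS:T60) and the average effect over all time
points (bS + mean of the interactions). Because the design is complex, a
stage-wise procedure is used: an omnibus likelihood-ratio test of all four
salinity-related coefficients screens genes with BH FDR control; within
screened genes the individual contrasts are confirmed with a Holm
correction at the screening-adjusted level. The test statistic is a
likelihood-ratio chi-square throughout; dispersions are Cox-Reid APL
estimates shrunk toward a common value (see :mod:`stressgenome.nbglm`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import nbglm
from .enrich import bh_adjust
from .model import CountExperiment, SampleAnnotation

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)

DESIGN_COLUMNS = [
    "intercept", "batch2", "salinity_high", "time30", "time45", "time60",
    "salinity:time30", "salinity:time45", "salinity:time60",
]
CONTRAST_NAMES = ["salinity_15", "salinity_30", "salinity_45", "salinity_60", "salinity_avg"]


@dataclass
class DEConfig:
    cpm_threshold: float = 3.0
    max_low_salinity: int = 14   # gene removed when CPM < threshold in MORE than this many of 16
    max_low_anoxia: int = 3      # likewise, out of 6
    alpha: float = 0.05
    prior_df: float = 10.0
    anoxia_use_adjusted_p: bool = True
    max_iter: int = 60
    genewise_dispersion: bool = True  # False: share the common dispersion (fast path)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million, no prior count."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e6 / lib_sizes


def filter_noninformative(counts: pd.DataFrame, cpm_threshold: float = 3.0,
                          max_low: int = 14,
                          lib_sizes: Optional[pd.Series] = None) -> pd.Index:
    """Genes kept after the low-expression filter.

    A gene is removed iff its CPM falls below the threshold in strictly more
    than ``max_low`` samples ("over 14 out of 16" / "over 3 out of 6").
    """
    if max_low >= counts.shape[1]:
        raise ValueError("max_low must be smaller than the number of samples")
    n_low = (cpm(counts, lib_sizes) < cpm_threshold).sum(axis=1)
    return counts.index[n_low <= max_low]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float,
              sum_trim: float, weighted: bool) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, var = log_r[keep], abs_e[keep], var[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r, rank_e = rankdata(log_r), rankdata(abs_e)
    trim = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not trim.any():
        return 1.0
    w = 1.0 / var[trim] if weighted else np.ones(trim.sum())
    return float(2.0 ** (np.sum(w * log_r[trim]) / np.sum(w)))


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30,
                sum_trim: float = 0.05, weighted: bool = True) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference library is the one whose CPM upper quartile is closest to
    the mean upper quartile. Per library, M (log fold) and A (log abundance)
    values against the reference are computed over genes with nonzero counts
    in both; the top/bottom ``logratio_trim`` of M and ``sum_trim`` of A are
    discarded and the factor is 2 to the precision-weighted mean of the
    surviving M values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        empties = counts.columns[lib <= 0].tolist()
        raise ValueError(f"libraries with all-zero counts: {empties}")
    uq = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_pair(x[:, j], x[:, ref_idx], logratio_trim, sum_trim, weighted)
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Designs and contrasts
# ---------------------------------------------------------------------------

def build_design(samples: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Salinity design matrix with the 9 fixed columns.

    Reference levels: batch 1, low salinity, 15 min. Indicator products give
    the salinity-by-time interactions.
    """
    rows = []
    for s in samples:
        if s.salinity is None or s.time_min is None or s.batch is None:
            raise ValueError(f"sample {s.sample_id} lacks salinity/time/batch factors")
        xs = 1.0 if s.salinity == "high" else 0.0
        t30 = 1.0 if s.time_min == 30 else 0.0
        t45 = 1.0 if s.time_min == 45 else 0.0
        t60 = 1.0 if s.time_min == 60 else 0.0
        rows.append([
            1.0, 1.0 if s.batch == 2 else 0.0, xs, t30, t45, t60,
            xs * t30, xs * t45, xs * t60,
        ])
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS,
                          index=[s.sample_id for s in samples])
    # rank check only meaningful once there are enough samples to fit
    if len(rows) >= len(DESIGN_COLUMNS) and \
            np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("salinity design is rank deficient for this sample layout")
    return design


def build_anoxia_design(samples: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Two-column design: intercept + anoxia indicator (no batch term)."""
    rows = []
    for s in samples:
        if s.oxygen is None:
            raise ValueError(f"sample {s.sample_id} lacks an oxygen factor")
        rows.append([1.0, 1.0 if s.oxygen == "anoxia" else 0.0])
    return pd.DataFrame(rows, columns=["intercept", "anoxia"],
                        index=[s.sample_id for s in samples])


def salinity_contrasts() -> pd.DataFrame:
    """Contrast matrix (5 x 9): salinity effect per time point and on average."""
    C = np.zeros((5, 9))
    iS, i30, i45, i60 = 2, 6, 7, 8
    C[0, iS] = 1.0
    C[1, iS] = 1.0; C[1, i30] = 1.0
    C[2, iS] = 1.0; C[2, i45] = 1.0
    C[3, iS] = 1.0; C[3, i60] = 1.0
    C[4, iS] = 1.0; C[4, [i30, i45, i60]] = 1.0 / 4.0
    return pd.DataFrame(C, index=CONTRAST_NAMES, columns=DESIGN_COLUMNS)


SALINITY_NULL_COLUMNS = ["salinity_high", "salinity:time30", "salinity:time45", "salinity:time60"]


# ---------------------------------------------------------------------------
# Stage-wise testing
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    gene_id: str
    omnibus_p: float
    padj_screen: float
    log2fc: dict[str, float]          # per contrast, log2 scale
    contrast_p: dict[str, float]
    screened: bool = False
    confirmed: list[str] = field(default_factory=list)
    direction: str = "none"           # sign of the average effect, screened genes only


def _holm(p: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejections of Holm's step-down procedure at level alpha."""
    m = p.size
    order = np.argsort(p)
    rejected = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            rejected[idx] = True
        else:
            break
    return rejected


def stagewise(omnibus_p: pd.Series, contrast_p: pd.DataFrame,
              log2fc: pd.DataFrame, alpha: float = 0.05) -> list[DEResult]:
    """Screening (BH on omnibus p) then per-gene confirmation of contrasts.

    Confirmation happens only within screened genes, at the family level
    equal to the largest raw omnibus p-value that BH rejected, with a Holm
    correction over the contrasts inside each gene. Direction comes from
    the sign of the average-effect estimate.
    """
    padj = pd.Series(bh_adjust(omnibus_p.to_numpy()), index=omnibus_p.index)
    screened_mask = padj < alpha
    alpha_adj = float(omnibus_p[screened_mask].max()) if screened_mask.any() else 0.0

    results: list[DEResult] = []
    for gene in omnibus_p.index:
        res = DEResult(
            gene_id=str(gene),
            omnibus_p=float(omnibus_p[gene]),
            padj_screen=float(padj[gene]),
            log2fc={c: float(log2fc.loc[gene, c]) for c in log2fc.columns},
            contrast_p={c: float(contrast_p.loc[gene, c]) for c in contrast_p.columns},
        )
        if screened_mask[gene]:
            res.screened = True
            pvec = contrast_p.loc[gene].to_numpy()
            rejected = _holm(pvec, alpha_adj)
            res.confirmed = [c for c, r in zip(contrast_p.columns, rejected) if r]
            avg = log2fc.loc[gene, "salinity_avg"] if "salinity_avg" in log2fc.columns \
                else log2fc.loc[gene].iloc[-1]
            res.direction = "up" if avg > 0 else "down"
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------

@dataclass
class DEPipelineOutput:
    results: list[DEResult]
    table: pd.DataFrame
    kept_genes: pd.Index
    tmm: pd.Series
    common_dispersion: float
    n_nonconverged: int

    @property
    def de_gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.results if r.screened]


def _prepare(experiment: CountExperiment, cfg: DEConfig, max_low: int):
    kept = filter_noninformative(experiment.counts, cfg.cpm_threshold, max_low)
    counts = experiment.counts.loc[kept]
    lib = experiment.counts.sum(axis=0)  # library sizes from the full matrix
    tmm = tmm_factors(counts)
    offsets = np.log((lib * tmm).to_numpy(dtype=float))
    return counts, kept, tmm, offsets


def _dispersions(y: np.ndarray, X: np.ndarray, offsets: np.ndarray, cfg: DEConfig):
    common = nbglm.common_dispersion(y, X, offsets)
    if not cfg.genewise_dispersion:
        return common, np.full(y.shape[0], common)
    phi = nbglm.genewise_dispersion(y, X, offsets, common, prior_df=cfg.prior_df)
    return common, phi


def run_salinity(experiment: CountExperiment, cfg: DEConfig | None = None) -> DEPipelineOutput:
    """Filter, normalize, fit the 9-coefficient model, screen and confirm."""
    cfg = cfg or DEConfig()
    counts, kept, tmm, offsets = _prepare(experiment, cfg, cfg.max_low_salinity)
    design = build_design(experiment.samples)
    X = design.to_numpy()
    X_reduced = design.drop(columns=SALINITY_NULL_COLUMNS).to_numpy()
    y = counts.to_numpy(dtype=float)

    common, phi = _dispersions(y, X, offsets, cfg)
    fit = nbglm.fit_glm(y, X, offsets, phi, max_iter=cfg.max_iter)
    n_bad = int((~fit.converged).sum())
    if n_bad:
        logger.warning("excluding %d non-converged genes from testing", n_bad)
    ok = fit.converged

    _, omnibus = nbglm.lrt_pvalues(y[ok], X, X_reduced, offsets, phi[ok])
    contrasts = salinity_contrasts()
    est, pvals = nbglm.wald_contrasts(
        nbglm.GLMFit(fit.beta[ok], fit.mu[ok], fit.loglik[ok], fit.converged[ok],
                     fit.xtwx[ok], phi[ok]),
        contrasts.to_numpy(),
    )
    genes = counts.index[ok]
    omnibus_s = pd.Series(omnibus, index=genes, name="omnibus_p")
    contrast_p = pd.DataFrame(pvals, index=genes, columns=CONTRAST_NAMES)
    log2fc = pd.DataFrame(est / LOG2, index=genes, columns=CONTRAST_NAMES)

    results = stagewise(omnibus_s, contrast_p, log2fc, alpha=cfg.alpha)
    table = _results_table(results)
    return DEPipelineOutput(results, table, kept, tmm, common, n_bad)


def run_anoxia(experiment: CountExperiment, cfg: DEConfig | None = None,
               p_threshold: float | None = None) -> DEPipelineOutput:
    """Two-group anoxia-vs-normoxia NB GLM with a single contrast."""
    cfg = cfg or DEConfig()
    threshold = cfg.alpha if p_threshold is None else p_threshold
    counts, kept, tmm, offsets = _prepare(experiment, cfg, cfg.max_low_anoxia)
    design = build_anoxia_design(experiment.samples)
    X = design.to_numpy()
    X_reduced = X[:, :1]
    y = counts.to_numpy(dtype=float)

    common, phi = _dispersions(y, X, offsets, cfg)
    fit = nbglm.fit_glm(y, X, offsets, phi, max_iter=cfg.max_iter)
    n_bad = int((~fit.converged).sum())
    if n_bad:
        logger.warning("excluding %d non-converged genes from testing", n_bad)
    ok = fit.converged

    _, pvals = nbglm.lrt_pvalues(y[ok], X, X_reduced, offsets, phi[ok])
    genes = counts.index[ok]
    padj = bh_adjust(pvals)
    log2fc_vals = fit.beta[ok, 1] / LOG2
    effective = padj if cfg.anoxia_use_adjusted_p else pvals

    results = []
    for i, gene in enumerate(genes):
        sig = bool(effective[i] < threshold)
        results.append(
            DEResult(
                gene_id=str(gene),
                omnibus_p=float(pvals[i]),
                padj_screen=float(padj[i]),
                log2fc={"anoxia": float(log2fc_vals[i])},
                contrast_p={"anoxia": float(pvals[i])},
                screened=sig,
                confirmed=["anoxia"] if sig else [],
                direction=("up" if log2fc_vals[i] > 0 else "down") if sig else "none",
            )
        )
    table = _results_table(results)
    return DEPipelineOutput(results, table, kept, tmm, common, n_bad)


def _results_table(results: Sequence[DEResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {
            "gene_id": r.gene_id,
            "omnibus_p": r.omnibus_p,
            "padj_screen": r.padj_screen,
            "screened": r.screened,
            "direction": r.direction,
            "confirmed": ",".join(r.confirmed),
        }
        for c, v in r.log2fc.items():
            row[f"log2fc_{c}"] = v
        for c, v in r.contrast_p.items():
            row[f"p_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
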