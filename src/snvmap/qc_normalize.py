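"""The five preprocessing steps, with per-step QC reporting and plots.

Applied in printed order, once, without iteration:

1. remove genes mutated in fewer than ``min_cells_per_gene`` cells;
2. remove cells with fewer than ``min_genes_per_cell`` mutated genes;
3. remove outlier cells whose mutated-gene count strictly exceeds the
   ``upper_percentile``-th percentile (linear interpolation) of the
   currently retained cells;
4. normalize each cell's counts to a common target total (the median of
   per-cell totals by default), then log1p;
5. select the top ``n_hvg`` highly variable genes by within-mean-bin
   normalized dispersion, and regress out total counts per cell.

A gene may fall below the step-1 support threshold after cells are removed
in steps 2-3; the filter is deliberately not re-applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .errors import SnvmapError, UserInputError
from .variant_ingest import MutationMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filter report
# ---------------------------------------------------------------------------


@dataclass
class FilterStep:
    name: str
    n_cells_before: int
    n_cells_after: int
    n_genes_before: int
    n_genes_after: int
    removed_cells: List[str] = field(default_factory=list)
    removed_genes: List[str] = field(default_factory=list)
    threshold: Optional[float] = None


@dataclass
class FilterReport:
    """Per-step accounting of the QC chain.

    Before/after counts telescope: each step's "before" equals the previous
    step's "after". ``mean_retained_per_cell`` is the mean retained variant
    count per cell on the post-filter count matrix (the per-dataset
    "mean non-synonymous SNVs" statistic when only that class was ingested).
    """

    steps: List[FilterStep] = field(default_factory=list)
    mean_retained_per_cell: Optional[float] = None
    per_patient_gene_counts: Dict[str, int] = field(default_factory=dict)

    def add(self, step: FilterStep) -> None:
        if self.steps:
            prev = self.steps[-1]
            if (
                step.n_cells_before != prev.n_cells_after
                or step.n_genes_before != prev.n_genes_after
            ):
                raise SnvmapError("filter report does not telescope")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "n_cells_before": s.n_cells_before,
                    "n_cells_after": s.n_cells_after,
                    "n_genes_before": s.n_genes_before,
                    "n_genes_after": s.n_genes_after,
                    "n_cells_removed": len(s.removed_cells),
                    "n_genes_removed": len(s.removed_genes),
                    "threshold": "" if s.threshold is None else s.threshold,
                }
                for s in self.steps
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "steps": [
                {
                    "step": s.name,
                    "n_cells_before": s.n_cells_before,
                    "n_cells_after": s.n_cells_after,
                    "n_genes_before": s.n_genes_before,
                    "n_genes_after": s.n_genes_after,
                    "removed_cells": s.removed_cells,
                    "removed_genes": s.removed_genes,
                    "threshold": s.threshold,
                }
                for s in self.steps
            ],
            "mean_retained_per_cell": self.mean_retained_per_cell,
            "per_patient_gene_counts": self.per_patient_gene_counts,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _subset(m: MutationMatrix, cell_mask=None, gene_mask=None) -> MutationMatrix:
    counts = m.counts
    cells = m.cell_ids
    genes = m.gene_ids
    ann = m.cell_annotations
    if gene_mask is not None:
        counts = counts[:, gene_mask]
        genes = [g for g, k in zip(genes, gene_mask) if k]
    if cell_mask is not None:
        counts = counts[cell_mask, :]
        cells = [c for c, k in zip(cells, cell_mask) if k]
        ann = ann.loc[cell_mask]
    return MutationMatrix(
        counts=sp.csr_matrix(counts), cell_ids=cells, gene_ids=genes, cell_annotations=ann.copy()
    )


# ---------------------------------------------------------------------------
# steps 1-3: filters
# ---------------------------------------------------------------------------


def gene_support(m: MutationMatrix) -> np.ndarray:
    """Number of cells in which each gene is mutated (nonzero count)."""
    return np.asarray((m.counts > 0).sum(axis=0)).ravel()


def genes_per_cell(m: MutationMatrix) -> np.ndarray:
    """Number of mutated (nonzero) genes per cell."""
    return np.asarray((m.counts > 0).sum(axis=1)).ravel()


def filter_genes_min_cells(m: MutationMatrix, k: int) -> MutationMatrix:
    """Step 1: retain genes mutated in at least ``k`` cells."""
    if k < 1:
        raise UserInputError("min cells per gene must be >= 1")
    if k > m.n_cells:
        raise UserInputError(
            f"min_cells_per_gene={k} exceeds the number of cells ({m.n_cells})"
        )
    mask = gene_support(m) >= k
    if not mask.any():
        raise UserInputError(f"all genes filtered at min_cells_per_gene={k}")
    return _subset(m, gene_mask=mask)


def filter_cells_min_genes(m: MutationMatrix, k: int) -> MutationMatrix:
    """Step 2: retain cells with at least ``k`` mutated genes
    (cells with fewer than ``k`` are excluded, so exactly ``k`` is kept)."""
    if k < 1:
        raise UserInputError("min genes per cell must be >= 1")
    mask = genes_per_cell(m) >= k
    if not mask.any():
        raise UserInputError(f"no cells passed min_genes_per_cell={k}")
    return _subset(m, cell_mask=mask)


def upper_percentile_threshold(m: MutationMatrix, p: float) -> float:
    """The p-th percentile (linear interpolation) of per-cell mutated-gene
    counts over the currently retained cells."""
    if not (0 < p <= 100):
        raise UserInputError("percentile must be in (0, 100]")
    return float(np.percentile(genes_per_cell(m), p, method="linear"))


def filter_cells_upper_percentile(m: MutationMatrix, p: float) -> MutationMatrix:
    """Step 3: drop outlier cells whose mutated-gene count strictly exceeds
    the p-th percentile of all retained cells."""
    if m.n_cells < 2:
        return m
    t = upper_percentile_threshold(m, p)
    mask = genes_per_cell(m) <= t
    return _subset(m, cell_mask=mask)


# ---------------------------------------------------------------------------
# steps 4-5: normalization, log, HVG, regress-out
# ---------------------------------------------------------------------------


def normalize_total(
    X: np.ndarray, target_sum: Union[float, str] = "median"
) -> Tuple[np.ndarray, float]:
    """Scale each cell (row) so its total equals ``target_sum``.

    With ``target_sum="median"`` the target is the median of the
    pre-normalization per-cell totals. Returns (normalized matrix, target).
    """
    X = np.asarray(X, dtype=np.float64)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise SnvmapError("all-zero cell reached normalization (internal invariant)")
    target = float(np.median(totals)) if target_sum == "median" else float(target_sum)
    if target <= 0:
        raise UserInputError("target_sum must be positive")
    return X * (target / totals)[:, None], target


def log1p(values: np.ndarray) -> np.ndarray:
    """Elementwise natural log(1 + x); rejects negative input."""
    values = np.asarray(values, dtype=np.float64)
    if values.size and values.min() < 0:
        raise SnvmapError("log1p requires non-negative values")
    return np.log1p(values)


def select_hvg(
    values: np.ndarray,
    n: int,
    gene_ids: Optional[List[str]] = None,
    n_bins: int = 20,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Select the top ``n`` highly variable genes by normalized dispersion.

    On the expm1 scale of the log-normalized input, per-gene dispersion is
    variance/mean. Genes are placed into ``n_bins`` equal-count bins of mean
    (contiguous chunks of the mean-sorted gene list, ties by gene order, so
    the binning is a pure function of the mean ranking) and the log
    dispersion is z-scored within each bin; the top ``n`` genes by that
    normalized dispersion are selected, ties broken by stable input gene
    order. Bins holding a single gene (or with zero spread) get z = 0.

    Returns (boolean selection mask, dispersion table for plotting).
    """
    if n < 1:
        raise UserInputError("n_hvg must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    n_genes = values.shape[1]
    if n_genes < 2:
        raise UserInputError("highly-variable-gene selection needs at least 2 genes")
    raw = np.expm1(values)
    mean = raw.mean(axis=0)
    var = raw.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    log_mean = np.log1p(mean)
    with np.errstate(divide="ignore"):
        log_disp = np.where(dispersion > 0, np.log(np.where(dispersion > 0, dispersion, 1.0)), 0.0)

    # rank-based equal-count bins: chunk the mean-sorted gene list
    order_by_mean = np.lexsort((np.arange(n_genes), log_mean))
    bins = pd.Series(np.empty(n_genes, dtype=int))
    for b, chunk in enumerate(np.array_split(order_by_mean, min(n_bins, n_genes))):
        bins.iloc[chunk] = b
    z = np.zeros(n_genes)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins.values == b)
        if len(idx) < 2:
            continue  # single-gene bin: z stays 0
        mu = log_disp[idx].mean()
        sd = log_disp[idx].std(ddof=1)
        if sd > 0:
            z[idx] = (log_disp[idx] - mu) / sd

    k = min(n, n_genes)
    order = np.argsort(-z, kind="stable")  # stable: ties keep input gene order
    selected = np.zeros(n_genes, dtype=bool)
    selected[order[:k]] = True

    table = pd.DataFrame(
        {
            "mean": mean,
            "dispersion": dispersion,
            "log_mean": log_mean,
            "log_dispersion": log_disp,
            "dispersion_norm": z,
            "bin": bins.values,
            "highly_variable": selected,
        },
        index=gene_ids if gene_ids is not None else pd.RangeIndex(n_genes),
    )
    return selected, table


def regress_out_total(values: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Replace each gene's values by residuals of OLS on (intercept, total).

    The residuals of every gene are orthogonal to the covariate
    (|Pearson r| < 1e-8). A constant covariate makes the slope undefined,
    so the input is returned unchanged with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    totals = np.asarray(totals, dtype=np.float64).ravel()
    if totals.shape[0] != values.shape[0]:
        raise SnvmapError("covariate length must equal the number of cells")
    if np.any(totals <= 0):
        raise SnvmapError("totals must be strictly positive")
    if np.ptp(totals) == 0:
        logger.warning("constant total-count covariate: regress-out skipped")
        return values.copy()
    A = np.column_stack([np.ones_like(totals), totals])
    beta, *_ = np.linalg.lstsq(A, values, rcond=None)
    return values - A @ beta


def scale_genes(values: np.ndarray) -> np.ndarray:
    """Optional unit-variance scaling per gene (zero-variance genes stay 0)."""
    values = np.asarray(values, dtype=np.float64)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


# ---------------------------------------------------------------------------
# full QC chain
# ---------------------------------------------------------------------------


@dataclass
class QCResult:
    matrix: MutationMatrix            # post-filter counts (steps 1-3)
    values: np.ndarray                # processed values on HVG subset
    hvg_mask: np.ndarray
    dispersion_table: pd.DataFrame
    report: FilterReport
    totals: np.ndarray                # pre-normalization per-cell totals
    normalization_target: float
    raw_matrix_shape: Tuple[int, int]
    config: PipelineConfig


def run_qc(m: MutationMatrix, config: Optional[PipelineConfig] = None) -> QCResult:
    """Run the full five-step chain and assemble the filter report."""
    cfg = config or PipelineConfig()
    report = FilterReport()
    raw_shape = (m.n_cells, m.n_genes)

    def record(name, before, after, threshold=None):
        report.add(
            FilterStep(
                name=name,
                n_cells_before=before.n_cells,
                n_cells_after=after.n_cells,
                n_genes_before=before.n_genes,
                n_genes_after=after.n_genes,
                removed_cells=sorted(set(before.cell_ids) - set(after.cell_ids)),
                removed_genes=sorted(set(before.gene_ids) - set(after.gene_ids)),
                threshold=threshold,
            )
        )

    m1 = filter_genes_min_cells(m, cfg.min_cells_per_gene)
    record("filter_genes_min_cells", m, m1, float(cfg.min_cells_per_gene))

    if cfg.percentile_before_min_genes:
        t = upper_percentile_threshold(m1, cfg.upper_percentile)
        m2 = filter_cells_upper_percentile(m1, cfg.upper_percentile)
        record("filter_cells_upper_percentile", m1, m2, t)
        m3 = filter_cells_min_genes(m2, cfg.min_genes_per_cell)
        record("filter_cells_min_genes", m2, m3, float(cfg.min_genes_per_cell))
    else:
        m2 = filter_cells_min_genes(m1, cfg.min_genes_per_cell)
        record("filter_cells_min_genes", m1, m2, float(cfg.min_genes_per_cell))
        t = upper_percentile_threshold(m2, cfg.upper_percentile)
        m3 = filter_cells_upper_percentile(m2, cfg.upper_percentile)
        record("filter_cells_upper_percentile", m2, m3, t)

    counts = m3.counts.toarray().astype(np.float64)
    totals = counts.sum(axis=1)
    report.mean_retained_per_cell = float(totals.mean())

    X, target = normalize_total(counts, cfg.target_sum)
    X = log1p(X)
    hvg_mask, disp_table = select_hvg(X, cfg.n_hvg, gene_ids=m3.gene_ids)
    record_hvg = FilterStep(
        name="select_hvg",
        n_cells_before=m3.n_cells,
        n_cells_after=m3.n_cells,
        n_genes_before=m3.n_genes,
        n_genes_after=int(hvg_mask.sum()),
        removed_genes=[g for g, k in zip(m3.gene_ids, hvg_mask) if not k],
        threshold=float(cfg.n_hvg),
    )
    report.steps.append(record_hvg)

    Xh = X[:, hvg_mask]
    Xh = regress_out_total(Xh, totals)
    if cfg.scale:
        Xh = scale_genes(Xh)

    per_patient: Dict[str, int] = {}
    if "sample_id" in m3.cell_annotations:
        gp = (m3.counts > 0).toarray()
        for pat, idx in m3.cell_annotations.groupby("sample_id").indices.items():
            per_patient[str(pat)] = int(gp[idx].any(axis=0).sum())
    report.per_patient_gene_counts = per_patient

    return QCResult(
        matrix=m3,
        values=Xh,
        hvg_mask=hvg_mask,
        dispersion_table=disp_table,
        report=report,
        totals=totals,
        normalization_target=target,
        raw_matrix_shape=raw_shape,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# QC plots
# ---------------------------------------------------------------------------


def _import_plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def fig_cells_per_gene(m_raw: MutationMatrix, cutoff: int):
    """Histogram of mutated cells per gene with the step-1 cutoff line."""
    plt = _import_plt()
    support = gene_support(m_raw)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(support, bins=min(50, max(10, int(support.max()) + 1)), color="#4878d0")
    ax.axvline(cutoff, color="red", linestyle="--", label=f"cutoff = {cutoff}")
    ax.set_xlabel("mutated cells per gene")
    ax.set_ylabel("number of genes")
    ax.set_title("Gene support distribution")
    ax.legend()
    fig.tight_layout()
    return fig


def fig_genes_per_cell(m_after_gene_filter: MutationMatrix, lower: int, upper: float):
    """Histogram of mutated genes per cell with lower and upper cutoff lines."""
    plt = _import_plt()
    gpc = genes_per_cell(m_after_gene_filter)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(gpc, bins=min(50, max(10, len(gpc) // 2 + 1)), color="#4878d0")
    ax.axvline(lower, color="red", linestyle="--", label=f"lower cutoff = {lower}")
    ax.axvline(upper, color="orange", linestyle="--", label=f"upper cutoff = {upper:.1f}")
    ax.set_xlabel("mutated genes per cell")
    ax.set_ylabel("number of cells")
    ax.set_title("Per-cell mutated-gene distribution")
    ax.legend()
    fig.tight_layout()
    return fig


def fig_hvg_dispersion(dispersion_table: pd.DataFrame):
    """Mean-dispersion scatter; selected highly variable genes in black."""
    plt = _import_plt()
    t = dispersion_table
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = t["highly_variable"].values
    ax.scatter(t["log_mean"][~sel], t["dispersion_norm"][~sel], s=8, c="#bbbbbb",
               label="other genes")
    ax.scatter(t["log_mean"][sel], t["dispersion_norm"][sel], s=8, c="black",
               label="highly variable")
    ax.set_xlabel("mean mutation load (log scale)")
    ax.set_ylabel("normalized dispersion")
    ax.set_title("Highly variable gene selection")
    ax.legend()
    fig.tight_layout()
    return fig


def qc_plots(qc: QCResult, m_raw: MutationMatrix, out_dir, dpi: Optional[int] = None) -> Dict[str, Path]:
    """Write the three per-step QC figures with deterministic file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dpi = dpi or qc.config.dpi
    cfg = qc.config
    # matrix state after the gene filter, for the per-cell histogram
    m1 = filter_genes_min_cells(m_raw, cfg.min_cells_per_gene)
    upper = next(
        s.threshold for s in qc.report.steps if s.name == "filter_cells_upper_percentile"
    )
    figs = {
        "cells_per_gene.png": fig_cells_per_gene(m_raw, cfg.min_cells_per_gene),
        "genes_per_cell.png": fig_genes_per_cell(m1, cfg.min_genes_per_cell, upper),
        "hvg_dispersion.png": fig_hvg_dispersion(qc.dispersion_table),
    }
    paths = {}
    for name, fig in figs.items():
        p = out_dir / name
        fig.savefig(p, dpi=dpi, metadata={"Software": "snvmap"})
        paths[name] = p
        _close(fig)
    return paths


def _close(fig) -> None:
    import matplotlib.pyplot as plt

    plt.close(fig)
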