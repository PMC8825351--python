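"""Expression QC, normalization, differential expression, and signature
scoring for MLR+/MLR- comparisons.

The QC thresholds are the ones standard for droplet scRNA-seq T-cell data:
genes kept when detected in at least 5 cells, cells kept with 500-6,000
genes detected (closed interval), 1,800-40,000 transcripts (closed), and a
mitochondrial fraction strictly below 5%.  Differential expression between
MLR+ and MLR- cells is a per-gene two-sided Wilcoxon rank-sum test on
normalized values with Bonferroni adjustment by default (Benjamini-Hochberg
optional); adjusted p < 0.05 is called significant.  Signature scoring is a
signed z-score average per cell, compared between groups with a Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tenx_io import annotate_cell_qc

__all__ = [
    "QCThresholds",
    "QCReport",
    "SignedSignature",
    "qc_filter",
    "normalize",
    "wilcoxon_de",
    "signature_score",
    "compare_scores",
    "read_gmt",
]

LOGFC_EPS = 1e-9


@dataclass(frozen=True)
class QCThresholds:
    min_cells_per_gene: int = 5
    min_genes: int = 500
    max_genes: int = 6000
    min_counts: int = 1800
    max_counts: int = 40000
    max_mito: float = 0.05  # strict upper bound

    def __post_init__(self) -> None:
        if not (0 <= self.min_genes <= self.max_genes):
            raise ValueError("need 0 <= min_genes <= max_genes")
        if not (0 <= self.min_counts <= self.max_counts):
            raise ValueError("need 0 <= min_counts <= max_counts")
        if not (0 <= self.max_mito <= 1):
            raise ValueError("max_mito must be a fraction in [0,1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_out: int
    n_genes_out: int
    removed_by: dict[str, int] = field(default_factory=dict)


def qc_filter(
    adata: ad.AnnData, thr: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, QCReport]:
    """Apply gene-level then cell-level QC filters.

    Genes detected in fewer than ``min_cells_per_gene`` cells are dropped
    first; cell metrics (genes detected, total counts, mito fraction) are
    then recomputed on the reduced gene set before the cell filters run.
    Gene/count bounds are closed intervals; the mito bound is strict.
    ``removed_by`` tallies cells failing each criterion (a cell may fail
    several).
    """
    X = sp.csr_matrix(adata.X)
    n_cells_in, n_genes_in = X.shape
    gene_ncells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = gene_ncells >= thr.min_cells_per_gene
    out = adata[:, keep_genes].copy()
    annotate_cell_qc(out, mito_prefixes=_mito_prefixes(adata))

    n_genes = out.obs["n_genes"].to_numpy()
    totals = out.obs["total_counts"].to_numpy()
    mito = out.obs["pct_mito"].to_numpy()
    fails = {
        "low_genes": n_genes < thr.min_genes,
        "high_genes": n_genes > thr.max_genes,
        "low_counts": totals < thr.min_counts,
        "high_counts": totals > thr.max_counts,
        "high_mito": mito >= thr.max_mito,
    }
    keep_cells = ~np.logical_or.reduce(list(fails.values()))
    report = QCReport(
        n_cells_in=n_cells_in,
        n_genes_in=n_genes_in,
        n_cells_out=int(keep_cells.sum()),
        n_genes_out=int(keep_genes.sum()),
        removed_by={k: int(v.sum()) for k, v in fails.items()},
    )
    if not keep_cells.any():
        raise ValueError(f"QC removed every cell; per-criterion tally: {report.removed_by}")
    return out[keep_cells].copy(), report


def _mito_prefixes(adata: ad.AnnData) -> tuple[str, ...]:
    from .tenx_io import DEFAULT_MITO_PREFIXES

    return tuple(adata.uns.get("mito_prefixes", DEFAULT_MITO_PREFIXES))


def normalize(adata: ad.AnnData, method: str = "logcp10k", theta: float = 100.0) -> ad.AnnData:
    """Normalize a QC-filtered count matrix.

    ``logcp10k`` (default): per-cell scaling to 10,000 counts then
    log(1 + x).  ``pearson``: analytic Pearson residuals under a
    negative-binomial null with fixed dispersion ``theta``, clipped at
    sqrt(n_cells).  The method used is recorded in ``.uns["normalization"]``.
    """
    X = sp.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValueError("zero-count cell; run qc_filter first")
    out = adata.copy()
    if method == "logcp10k":
        scaled = sp.diags(1e4 / totals) @ X
        scaled.data = np.log1p(scaled.data)
        out.X = scaled
    elif method == "pearson":
        dense = np.asarray(X.todense())
        gene_tot = dense.sum(axis=0)
        grand = dense.sum()
        mu = np.outer(totals, gene_tot) / grand
        resid = (dense - mu) / np.sqrt(mu + mu**2 / theta)
        clip = np.sqrt(dense.shape[0])
        out.X = np.clip(resid, -clip, clip)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    out.uns["normalization"] = method
    return out


def wilcoxon_de(
    adata: ad.AnnData,
    labels: Sequence[str] | np.ndarray,
    group_a: str = "MLR_plus",
    group_b: str = "MLR_minus",
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    Uses the normal approximation with tie correction.  log2 fold change is
    computed on de-logged means: log2((mean(expm1 a)+eps)/(mean(expm1 b)+eps)).
    Returns a gene-indexed frame sorted by p with columns pct_a, pct_b,
    log2_fc, p, p_adj, significant.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != adata.n_obs:
        raise ValueError("labels length != number of cells")
    mask_a = labels == group_a
    mask_b = labels == group_b
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"need >= 3 cells per group, got {int(mask_a.sum())} vs {int(mask_b.sum())}"
        )
    X = sp.csr_matrix(adata.X)
    A = np.asarray(X[mask_a].todense())
    B = np.asarray(X[mask_b].todense())
    res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=np.float64)
    p = np.where(np.isnan(p), 1.0, p)  # all-tied (constant) genes carry no evidence
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2_fc = np.log2((mean_a + LOGFC_EPS) / (mean_b + LOGFC_EPS))
    if adjust == "bonferroni":
        p_adj = np.minimum(p * adata.n_vars, 1.0)
    elif adjust in ("bh", "fdr_bh"):
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df = pd.DataFrame(
        {
            "pct_a": (A > 0).mean(axis=0),
            "pct_b": (B > 0).mean(axis=0),
            "log2_fc": log2_fc,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=pd.Index(adata.var_names, name="gene"),
    )
    return df.sort_values("p", kind="mergesort")


@dataclass(frozen=True)
class SignedSignature:
    name: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("a gene appears in both the positive and negative set")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def signature_score(
    adata: ad.AnnData, signature: SignedSignature
) -> tuple[pd.Series, int]:
    """Per-cell signed signature score on z-scored normalized expression.

    score_c = (sum over present positive genes of z_gc
               - sum over present negative genes of z_gc) / n_present.
    Genes absent from the matrix are dropped (their count is returned);
    genes with zero variance contribute 0.
    """
    var_index = pd.Index(adata.var_names)
    pos = [g for g in sorted(signature.positive) if g in var_index]
    neg = [g for g in sorted(signature.negative) if g in var_index]
    missing = (len(signature.positive) - len(pos)) + (len(signature.negative) - len(neg))
    if not pos and not neg:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    X = np.asarray(sp.csr_matrix(adata.X).todense())
    cols = [var_index.get_loc(g) for g in pos + neg]
    sub = X[:, cols]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    signs = np.array([1.0] * len(pos) + [-1.0] * len(neg))
    scores = (z * signs).sum(axis=1) / len(cols)
    return pd.Series(scores, index=adata.obs_names, name=signature.name), missing


def compare_scores(
    scores: pd.Series | np.ndarray, labels: Sequence[str] | np.ndarray,
    group_a: str = "MLR_plus", group_b: str = "MLR_minus",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-cell scores between two groups."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    a = scores[labels == group_a]
    b = scores[labels == group_b]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(stat), float(p)
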