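"""Conserved differential-expression signatures across independent comparisons.

Given per-gene log2 fold changes from k >= 2 independent VHL-loss-vs-wildtype
comparisons (different models, cohorts or platforms), a gene with a conserved
effect shows a consistent mean shift relative to its between-comparison
scatter.  The concordance statistic is a signal-to-noise ratio

    SNR = mean(log2FC)^2 / var(log2FC, ddof=1)

computed per feature across the k comparisons; the top-ranked features form
the conserved signature.  The same statistic applies unchanged to gene-set
NES matrices.  Helpers cover the display pipeline (column z-scaling, Ward
leaf ordering), the pre-ranked GSEA metric, and single-cell QC gates.
"""
from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def build_comparison_matrix(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Inner-join per-comparison (feature_id, log2fc) tables into a wide matrix.

    Features absent from any comparison are excluded; the excluded count is
    logged.  Duplicate feature ids within a comparison are an error.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 comparisons")
    cols = {}
    for cid, df in tables.items():
        if df["feature_id"].duplicated().any():
            raise ValueError(f"duplicate feature_id in comparison {cid!r}")
        cols[cid] = df.set_index("feature_id")["log2fc"]
    wide = pd.DataFrame(cols)
    full = wide.dropna()
    if len(full) < len(wide):
        logger.info("excluded %d features absent from >=1 comparison",
                    len(wide) - len(full))
    return full


def snr_concordance(matrix: pd.DataFrame, variance_floor: float = 1e-8) -> pd.DataFrame:
    """Per-feature concordance SNR across comparisons (matrix columns).

    Returns a frame indexed like ``matrix`` with columns ``snr``,
    ``mean_log2fc`` and ``direction`` (sign of the mean; ``flat`` at exactly
    zero).  Zero-variance features take ``snr = mean^2 / variance_floor`` so
    the ordering stays total and finite.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("matrix must be features x k comparisons with k >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):  # variance_floor=0 opt-in
        snr = mean ** 2 / np.maximum(var, variance_floor)
    direction = np.select([mean > 0, mean < 0], ["up", "down"], default="flat")
    return pd.DataFrame(
        {"snr": snr, "mean_log2fc": mean, "direction": direction},
        index=matrix.index if isinstance(matrix, pd.DataFrame) else None,
    )


def select_top_concordant(rankings: pd.DataFrame, k: int) -> list:
    """Top-k feature ids by SNR (descending).

    Ties break by |mean_log2fc| descending, then feature id lexicographically,
    so the selection is reproducible.
    """
    if k > len(rankings):
        raise ValueError(f"k={k} exceeds the {len(rankings)} scored features")
    order = rankings.assign(
        _absmean=rankings["mean_log2fc"].abs(),
        _fid=rankings.index.astype(str),
    ).sort_values(["snr", "_absmean", "_fid"], ascending=[False, False, True],
                  kind="mergesort")
    return list(order.index[:k])


def zscale_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sample sd 1); constant columns become zeros."""
    X = matrix.astype(float)
    if len(X) < 2:
        raise ValueError("need >= 2 rows to z-scale")
    sd = X.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant column(s) z-scaled to all zeros")
    sd = sd.where(~flat, 1.0)
    out = (X - X.mean(axis=0)) / sd
    out.loc[:, flat] = 0.0
    return out


def ward_leaf_order(matrix: pd.DataFrame) -> np.ndarray:
    """Row permutation given by the leaf order of a Ward dendrogram.

    Euclidean distances on the rows; Ward's minimum-variance merge criterion.
    """
    X = np.asarray(matrix, dtype=float)
    if len(X) < 2:
        raise ValueError("need >= 2 rows to cluster")
    return leaves_list(linkage(X, method="ward"))


def gsea_rank_metric(log2fc, p_value=None):
    """Pre-ranked GSEA metric: sign(log2fc) * -log10(p), or log2fc when p is missing.

    ``p = 1`` maps to 0; ``p <= 0`` is rejected.  Accepts scalars or arrays
    (missing p encoded as NaN).
    """
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(np.nan if p_value is None else p_value, dtype=float)
    p = np.broadcast_to(p, lfc.shape) if lfc.ndim else p
    present = ~np.isnan(p)
    pv = np.where(present, p, 0.5)  # placeholder where missing
    if np.any(present & ((pv <= 0) | (pv > 1))):
        raise ValueError("p-values must lie in (0, 1]")
    metric = np.where(present, np.sign(lfc) * -np.log10(pv), lfc)
    return metric if metric.ndim else float(metric)


def cell_qc_filter(
    cells: pd.DataFrame,
    min_total_counts: int = 2000,
    min_genes: int = 1000,
    max_pct_mito: float = 20.0,
) -> pd.DataFrame:
    """Single-cell QC gate: counts > 2000, genes > 1000, mito% < 20 (all strict)."""
    for col in ("total_counts", "n_genes", "pct_mito"):
        if not np.all(np.isfinite(cells[col].to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in {col}")
    keep = (
        (cells["total_counts"] > min_total_counts)
        & (cells["n_genes"] > min_genes)
        & (cells["pct_mito"] < max_pct_mito)
    )
    logger.info("cell QC kept %d / %d cells", int(keep.sum()), len(cells))
    return cells[keep].copy()


class ConcordanceRanker(BaseEstimator):
    """Feature selector ranking features by cross-comparison concordance SNR.

    ``fit`` accepts either a wide features-x-comparisons DataFrame of log2
    fold changes (or NES values) or a mapping of per-comparison tables, scores
    every feature, and selects the ``top_k`` most concordant.  ``transform``
    restricts a matrix to the selected features in rank order.

    Attributes
    ----------
    ranking_ : DataFrame with snr, mean_log2fc, direction and rank.
    selected_features_ : list of the top_k feature ids in rank order.
    """

    def __init__(self, top_k: int = 200, variance_floor: float = 1e-8):
        self.top_k = top_k
        self.variance_floor = variance_floor

    def fit(self, X, y=None):
        matrix = X if isinstance(X, pd.DataFrame) else build_comparison_matrix(X)
        scores = snr_concordance(matrix, variance_floor=self.variance_floor)
        selected = select_top_concordant(scores, self.top_k)
        rank = pd.Series(np.arange(1, len(selected) + 1), index=selected)
        self.matrix_ = matrix
        self.ranking_ = scores.assign(rank=rank.reindex(scores.index))
        self.selected_features_ = selected
        self.n_features_in_ = len(matrix)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Selected features (rank order) of ``X`` (default: the fitted matrix)."""
        if not hasattr(self, "selected_features_"):
            raise RuntimeError("ConcordanceRanker is not fitted")
        matrix = self.matrix_ if X is None else (
            X if isinstance(X, pd.DataFrame) else build_comparison_matrix(X)
        )
        return matrix.loc[self.selected_features_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()

    def display_order(self, zscale: bool = True) -> pd.DataFrame:
        """Selected submatrix, column z-scaled then Ward-leaf-ordered (heatmap layout)."""
        sub = self.transform()
        if zscale:
            sub = zscale_columns(sub)
        return sub.iloc[ward_leaf_order(sub)]
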