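"""Ranking evaluation: precision@K, fold enrichment, and bi-clustering.

Given a gold standard of known indications, a disease's ranked drug list is
scored two ways:

* precision@K — the fraction of the top K drugs that are known indications;
* fold enrichment — the ranked list is cut into consecutive bins of fixed
  size (the last bin keeps the remainder) and each bin's gold-standard
  density is divided by the overall density:  FE = (n/m) / (N/M).  A
  well-calibrated score shows FE decreasing down the bins; ``fe_trend``
  summarizes that with the least-squares slope of FE against bin order.

``bicluster`` groups co-varying drugs and diseases in the score matrix by
spectral co-clustering, for heat-map style presentation of related blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralCoclustering

logger = logging.getLogger(__name__)

__all__ = [
    "FEResult",
    "precision_at_k",
    "fold_enrichment",
    "fe_trend",
    "bicluster",
]


def precision_at_k(ranked: Sequence[str], gold: set[str], k: int) -> float:
    """Fraction of the top-k ranked drugs present in the gold standard."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} outside [1, {len(ranked)}]")
    return len(set(ranked[:k]) & set(gold)) / k


@dataclass(frozen=True)
class FEResult:
    """Per-bin fold-enrichment scores for one ranked list."""

    group_sizes: tuple[int, ...]   # m_g
    gold_counts: tuple[int, ...]   # n_g
    fe: tuple[float, ...]          # (n_g/m_g) / (N/M)
    n_gold: int                    # N, gold drugs present among ranked
    n_ranked: int                  # M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.arange(1, len(self.fe) + 1),
                "m": self.group_sizes,
                "n": self.gold_counts,
                "FE": self.fe,
            }
        )


def fold_enrichment(
    ranked: Sequence[str], gold: set[str], group_size: int
) -> FEResult:
    """Bin the ranked list from the top and compute FE = (n/m)/(N/M) per bin.

    Bins are consecutive groups of ``group_size``; the final bin holds the
    remainder.  Gold drugs absent from the ranked universe are dropped from
    N with a logged count.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked list is empty")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    universe = set(ranked)
    gold_present = set(gold) & universe
    dropped = len(set(gold)) - len(gold_present)
    if dropped:
        logger.info("dropped %d gold drugs absent from the ranked universe", dropped)
    N = len(gold_present)
    M = len(ranked)
    if N == 0:
        raise ValueError("no gold-standard drugs among the ranked list (N = 0)")

    sizes, counts, fes = [], [], []
    overall = N / M
    for start in range(0, M, group_size):
        chunk = ranked[start:start + group_size]
        m = len(chunk)
        n = len(set(chunk) & gold_present)
        sizes.append(m)
        counts.append(n)
        fes.append((n / m) / overall)
    return FEResult(
        group_sizes=tuple(sizes),
        gold_counts=tuple(counts),
        fe=tuple(fes),
        n_gold=N,
        n_ranked=M,
    )


def fe_trend(fe: FEResult) -> float:
    """Least-squares slope of FE against bin order 1..G (negative is good)."""
    if len(fe.fe) < 2:
        raise ValueError("need at least 2 bins to fit a trend")
    x = np.arange(1, len(fe.fe) + 1, dtype=float)
    slope, _ = np.polyfit(x, np.asarray(fe.fe), 1)
    return float(slope)


def bicluster(
    matrix: pd.DataFrame,
    n_row_clusters: int,
    n_col_clusters: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Spectral co-clustering of the score matrix.

    Returns (row order, column order, row labels, column labels) where the
    orders sort rows/columns by cluster membership (stable within cluster).
    Co-clustering assigns rows and columns to a *shared* set of clusters,
    so ``n_row_clusters`` must equal ``n_col_clusters``.  Scores are shifted
    to be nonnegative before clustering, as the spectral method requires.
    A constant matrix is degenerate: identity orders are returned with a
    warning.
    """
    if matrix.empty:
        raise ValueError("score matrix is empty")
    if n_row_clusters != n_col_clusters:
        raise ValueError("co-clustering requires equal row and column cluster counts")
    k = n_row_clusters
    if k > min(matrix.shape):
        raise ValueError("more clusters than rows or columns")
    A = matrix.to_numpy(dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("score matrix has non-finite entries")
    if np.ptp(A) == 0:
        logger.warning("constant score matrix; returning identity orders")
        return (
            np.arange(A.shape[0]),
            np.arange(A.shape[1]),
            np.zeros(A.shape[0], dtype=int),
            np.zeros(A.shape[1], dtype=int),
        )
    # shift to strictly positive; spectral co-clustering needs nonnegative data
    A = A - A.min() + 1e-6 * np.ptp(A)
    model = SpectralCoclustering(n_clusters=k, random_state=seed)
    model.fit(A)
    row_labels = model.row_labels_
    col_labels = model.column_labels_
    row_order = np.argsort(row_labels, kind="stable")
    col_order = np.argsort(col_labels, kind="stable")
    return row_order, col_order, row_labels, col_labels


def write_clustered_matrix(
    matrix: pd.DataFrame,
    row_order: np.ndarray,
    col_order: np.ndarray,
    path: str | Path,
) -> pd.DataFrame:
    """Write the cluster-reordered score matrix as CSV; returns the frame."""
    out = matrix.iloc[row_order, col_order]
    out.to_csv(path)
    return out


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Optional heat map of a (reordered) score matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(4, 0.2 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="repurposing possibility score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
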