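"""Symmetrized-KL divergences between latent Gaussians and hierarchical clustering.

Each cell's latent representation is a 32-dimensional diagonal Gaussian. The
Kullback–Leibler divergence between two such distributions has a closed form;
its symmetrized version sKL = ½(KL(P‖Q) + KL(Q‖P)) is the dissimilarity used
for agglomerative clustering. sKL is symmetric and non-negative but not a
metric (no triangle inequality), so clustering operates on the precomputed
divergence matrix with average linkage — the common choice for non-metric
dissimilarities, and one whose merge heights are monotone — and never relies
on metric-tree accelerations. All divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import TraceMatrix
from .vae import LatentGaussian, LatentTable


def kl_diag_gauss(p: LatentGaussian, q: LatentGaussian) -> float:
    """KL(p‖q) between diagonal Gaussians, in nats.

    0.5 · Σ_i [ ln(var_q,i / var_p,i) + var_p,i / var_q,i
                + (mu_p,i − mu_q,i)² / var_q,i − 1 ]
    """
    if p.mu.shape != q.mu.shape:
        raise ValueError("dimension mismatch")
    return float(
        0.5
        * np.sum(
            np.log(q.var / p.var) + p.var / q.var + (p.mu - q.mu) ** 2 / q.var - 1.0
        )
    )


def skl(p: LatentGaussian, q: LatentGaussian) -> float:
    """Symmetrized KL divergence ½(KL(p‖q) + KL(q‖p)), in nats."""
    return 0.5 * (kl_diag_gauss(p, q) + kl_diag_gauss(q, p))


@dataclass
class DivergenceMatrix:
    """Symmetric non-negative pairwise sKL matrix with zero diagonal."""

    values: np.ndarray  # (n, n)
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("divergence matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("divergence matrix must be finite")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def pairwise(table: LatentTable) -> DivergenceMatrix:
    """All-pairs sKL between the table's latent Gaussians (vectorised).

    In the symmetrized divergence the log-variance terms cancel:
    sKL = ¼ Σ_k [ v_i/v_j + v_j/v_i − 2 + (mu_i − mu_j)² (1/v_i + 1/v_j) ].
    """
    if len(table) < 2:
        raise ValueError("pairwise divergence requires at least 2 cells")
    mu = np.asarray(table.mu, dtype=float)
    var = np.asarray(table.var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    inv = 1.0 / var
    ratio = var @ inv.T  # Σ_k v_i,k / v_j,k
    sq_over = (mu**2) @ inv.T - 2.0 * mu @ (mu * inv).T + ((mu**2) * inv).sum(axis=1)[None, :]
    d = mu.shape[1]
    D = 0.25 * (ratio + ratio.T - 2.0 * d * np.ones_like(ratio) + sq_over + sq_over.T)
    D = np.clip(0.5 * (D + D.T), 0.0, None)  # symmetrise fp noise, clamp
    np.fill_diagonal(D, 0.0)
    return DivergenceMatrix(values=D, cell_ids=np.asarray(table.cell_ids))


@dataclass
class ClusterTree:
    """Agglomerative merge sequence in scipy linkage-matrix form."""

    linkage_matrix: np.ndarray  # (n−1, 4): left, right, height (nats), size
    cell_ids: np.ndarray
    method: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.linkage_matrix) + 1

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_table(self, path) -> None:
        pd.DataFrame(
            self.linkage_matrix, columns=["left", "right", "height_nats", "size"]
        ).to_csv(path, index=False)


@dataclass
class ClusterAssignment:
    """Flat labeling from a tree cut; labels contiguous from 1."""

    labels: np.ndarray
    cell_ids: np.ndarray
    threshold: float | None = None
    k: int | None = None

    @property
    def counts(self) -> dict[int, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_csv(self, path) -> None:
        pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels}).to_csv(
            path, index=False
        )


def agglomerate(D: DivergenceMatrix, method: str = "average") -> ClusterTree:
    """Agglomerative clustering on the precomputed divergence matrix."""
    if method not in ("average", "complete", "single"):
        raise ValueError("linkage must be average, complete, or single")
    if len(D) < 2:
        raise ValueError("clustering requires at least 2 cells")
    Z = linkage(D.condensed(), method=method)
    return ClusterTree(linkage_matrix=Z, cell_ids=D.cell_ids, method=method)


def cut(
    tree: ClusterTree,
    threshold: float | None = None,
    k: int | None = None,
) -> ClusterAssignment:
    """Flat clusters from a threshold (severs merges above it) or a count k."""
    if (threshold is None) == (k is None):
        raise ValueError("give exactly one of threshold or k")
    if k is not None:
        if not 1 <= k <= tree.n_leaves:
            raise ValueError(f"k must be in [1, {tree.n_leaves}]")
        raw = fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    else:
        raw = fcluster(tree.linkage_matrix, t=threshold, criterion="distance")
    # relabel contiguous from 1 in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterAssignment(
        labels=labels + 1, cell_ids=tree.cell_ids, threshold=threshold, k=k
    )


@dataclass
class ClusterSummary:
    """Per-cluster counts, mean traces, and coarse channel descriptors."""

    table: pd.DataFrame  # one row per (cluster, channel)
    mean_traces: dict[int, np.ndarray]  # cluster -> (channels, T)
    counts: dict[int, int]
    channel_order: tuple[str, ...]
    time: np.ndarray


def _tercile(values: np.ndarray) -> np.ndarray:
    """Rank each value into terciles low/mid/high across clusters."""
    if len(values) == 1:
        return np.array(["mid"])
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return np.array(
        ["low" if v <= q1 else ("high" if v > q2 else "mid") for v in values]
    )


def summarize(assignment: ClusterAssignment, matrix: TraceMatrix) -> ClusterSummary:
    """Table-1-style report: per-cluster size, mean traces, channel descriptors.

    Descriptors per (cluster, channel): mean intensity level and its tercile
    across clusters, a monotone-decay flag (smoothed mean trace non-increasing
    within 2% of its range), and the peak time when the maximum exceeds both
    endpoints by 10% of the range.
    """
    if len(assignment.labels) != len(matrix):
        raise ValueError("assignment and matrix are misaligned")
    clusters = np.unique(assignment.labels)
    mean_traces = {}
    rows = []
    for c in clusters:
        members = matrix.data[assignment.labels == c]
        mean_traces[int(c)] = members.mean(axis=0)
    for ch_idx, ch_name in enumerate(matrix.channel_order):
        levels = np.array([mean_traces[int(c)][ch_idx].mean() for c in clusters])
        tercs = _tercile(levels)
        for c, level, terc in zip(clusters, levels, tercs):
            tr = mean_traces[int(c)][ch_idx]
            rng_ = float(tr.max() - tr.min())
            tol = 0.02 * rng_ if rng_ > 0 else 0.0
            decaying = bool(np.all(np.diff(_smooth(tr)) <= tol)) and tr[0] > tr[-1]
            peak_i = int(np.argmax(tr))
            margin = 0.1 * rng_
            has_peak = (
                rng_ > 0
                and tr[peak_i] > tr[0] + margin
                and tr[peak_i] > tr[-1] + margin
            )
            rows.append(
                {
                    "cluster": int(c),
                    "channel": ch_name,
                    "n_cells": int((assignment.labels == c).sum()),
                    "mean_level": float(level),
                    "level_tercile": terc,
                    "monotone_decay": decaying,
                    "peak_time": float(matrix.time[peak_i]) if has_peak else np.nan,
                }
            )
    return ClusterSummary(
        table=pd.DataFrame(rows),
        mean_traces=mean_traces,
        counts=assignment.counts,
        channel_order=matrix.channel_order,
        time=matrix.time,
    )


def _smooth(y: np.ndarray, w: int = 25) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="valid")
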