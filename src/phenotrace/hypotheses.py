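"""Hypothesis-testing procedures on clustered cell behaviors.

Three analyses connect the latent-space phenotypes to biology:

1. Calcium-peak sharpness vs cell fate: PCA on max-normalised impact-site
   calcium traces yields a one-number sharpness score (the first PC
   coordinate, sign-oriented toward early-time intensity); a two-sample
   Kolmogorov–Smirnov test compares dead vs viable score distributions.
2. Late-death timing vs distance: for cells whose nuclear membrane
   permeability peaks more than one hour after impact, death time is
   regressed on Euclidean distance to the impact site and the slope tested
   with the regression F-test.
3. Mitochondrial polarity vs distance: a KS test compares the
   distance-to-impact distributions of high- vs low-TMRM cells.

An impact-signature report joins long-term clusters with their members'
peracute impact calcium traces and positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .cluster import ClusterAssignment, ClusterSummary
from .preprocess import TraceMatrix


@dataclass
class SharpnessResult:
    scores: np.ndarray  # PC1 coordinate per kept cell, sign-oriented
    pc1_evr: float
    kept: np.ndarray  # indices of traces that could be normalised
    dropped: np.ndarray  # zero-max traces, excluded and flagged
    degenerate: bool = False  # all traces identical


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    sample_sizes: dict[str, int]
    config: dict[str, Any] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sample_sizes": self.sample_sizes,
            "config": self.config,
            **self.extras,
        }


def sharpness_scores(
    impact_calcium: np.ndarray, normalize: str = "max"
) -> SharpnessResult:
    """Peak-sharpness score per impact-site cell.

    Traces are normalised (divided by their maximum by default; ``zscore``
    is available), centered PCA is fit, and the first PC coordinate is the
    score. The PC sign is arbitrary, so it is oriented so that higher scores
    correlate positively with mean intensity in the first quarter of the
    window (sharp early peaks score high).
    """
    X = np.asarray(impact_calcium, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need >= 2 equal-length traces")
    maxima = X.max(axis=1)
    kept = np.flatnonzero(maxima > 0)
    dropped = np.flatnonzero(maxima <= 0)
    Xk = X[kept]
    if normalize == "max":
        Xn = Xk / Xk.max(axis=1, keepdims=True)
    elif normalize == "zscore":
        sd = Xk.std(axis=1, keepdims=True)
        Xn = (Xk - Xk.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    else:
        raise ValueError("normalize must be 'max' or 'zscore'")

    if len(Xn) < 2 or np.allclose(Xn, Xn[0]):
        return SharpnessResult(
            scores=np.zeros(len(Xn)),
            pc1_evr=0.0,
            kept=kept,
            dropped=dropped,
            degenerate=True,
        )
    pca = PCA(n_components=1).fit(Xn)
    scores = pca.transform(Xn)[:, 0]
    early = Xn[:, : Xn.shape[1] // 4].mean(axis=1)
    corr = np.corrcoef(scores, early)[0, 1]
    if corr < 0:
        scores = -scores
    return SharpnessResult(
        scores=scores,
        pc1_evr=float(pca.explained_variance_ratio_[0]),
        kept=kept,
        dropped=dropped,
    )


def label_fate(
    summary: ClusterSummary,
    assignment: ClusterAssignment,
    nmp_rule: float | None = None,
    nmp_channel: str = "nmp",
) -> tuple[np.ndarray, bool]:
    """Dead/viable labels per cell from cluster-level NMP.

    A cluster is dead when the maximum of its mean NMP trace exceeds
    ``nmp_rule``; the default rule is the midpoint between the lowest and
    highest cluster-level NMP maxima in the dataset. Cells inherit their
    cluster's label. Returns ``(labels, flagged)`` where ``flagged`` marks a
    degenerate case (single cluster or a single fate class).
    """
    ch = summary.channel_order.index(nmp_channel)
    clusters = sorted(summary.mean_traces)
    nmp_max = {c: float(summary.mean_traces[c][ch].max()) for c in clusters}
    if nmp_rule is None:
        lo, hi = min(nmp_max.values()), max(nmp_max.values())
        nmp_rule = 0.5 * (lo + hi)
    cluster_fate = {c: ("dead" if nmp_max[c] > nmp_rule else "viable") for c in clusters}
    labels = np.array([cluster_fate[int(c)] for c in assignment.labels])
    flagged = len(clusters) < 2 or len(set(cluster_fate.values())) < 2
    return labels, flagged


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Uses the exact null distribution when n·m ≤ 10⁴ and the asymptotic
    approximation otherwise. Returns (D, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def sharpness_fate_test(
    impact_calcium: np.ndarray, dead: np.ndarray, normalize: str = "max"
) -> TestReport:
    """KS test of sharpness scores, dead vs viable cells."""
    res = sharpness_scores(impact_calcium, normalize=normalize)
    dead = np.asarray(dead, dtype=bool)[res.kept]
    d_scores = res.scores[dead]
    v_scores = res.scores[~dead]
    D, p = ks_two_sample(d_scores, v_scores)
    return TestReport(
        test="sharpness_fate_ks",
        statistic=D,
        p_value=p,
        sample_sizes={"dead": len(d_scores), "viable": len(v_scores)},
        config={"normalize": normalize},
        extras={
            "pc1_evr": res.pc1_evr,
            "dead_median": float(np.median(d_scores)),
            "viable_median": float(np.median(v_scores)),
        },
    )


def death_times(
    matrix: TraceMatrix, nmp_channel: str = "nmp"
) -> np.ndarray:
    """Per-cell death time (hours): time of maximum NMP signal."""
    ch = matrix.channel_order.index(nmp_channel)
    return matrix.time[np.argmax(matrix.data[:, ch, :], axis=1)]


def late_death_regression(
    matrix: TraceMatrix,
    impact_xy: tuple[float, float],
    late_cutoff_h: float = 1.0,
    mask: np.ndarray | None = None,
) -> TestReport:
    """F-test for association of late-death timing with distance to impact.

    Death time is the time a cell's NMP channel reaches its maximum; cells
    with death time > ``late_cutoff_h`` (and in ``mask``, if given — e.g.
    members of late-death clusters) enter a simple linear regression of death
    time on Euclidean distance to the impact point. The reported F statistic
    is the overall regression F of the single-covariate model, which equals
    the squared t statistic of the slope.
    """
    times = death_times(matrix)
    dist = np.hypot(
        matrix.positions[:, 0] - impact_xy[0], matrix.positions[:, 1] - impact_xy[1]
    )
    sel = times > late_cutoff_h
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    x, y = dist[sel], times[sel]
    if len(x) < 3:
        return TestReport(
            test="late_death_f",
            statistic=float("nan"),
            p_value=float("nan"),
            sample_sizes={"late_death_cells": int(len(x))},
            config={"late_cutoff_h": late_cutoff_h, "insufficient_data": True},
        )
    lr = stats.linregress(x, y)
    t_stat = lr.slope / lr.stderr if lr.stderr > 0 else float("inf")
    return TestReport(
        test="late_death_f",
        statistic=float(t_stat**2),
        p_value=float(lr.pvalue),
        sample_sizes={"late_death_cells": int(len(x))},
        config={"late_cutoff_h": late_cutoff_h},
        extras={"slope_h_per_um": float(lr.slope), "intercept_h": float(lr.intercept)},
    )


def mito_distance_test(
    tmrm_labels: np.ndarray,
    positions: np.ndarray,
    impact_xy: tuple[float, float],
) -> TestReport:
    """KS test comparing distance-to-impact of high- vs low-TMRM cells."""
    tmrm_labels = np.asarray(tmrm_labels)
    positions = np.asarray(positions, dtype=float)
    dist = np.hypot(positions[:, 0] - impact_xy[0], positions[:, 1] - impact_xy[1])
    high = dist[tmrm_labels == "high"]
    low = dist[tmrm_labels == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both TMRM groups must be non-empty")
    D, p = ks_two_sample(high, low)
    return TestReport(
        test="mito_distance_ks",
        statistic=D,
        p_value=p,
        sample_sizes={"high": len(high), "low": len(low)},
        extras={
            "high_median_um": float(np.median(high)),
            "low_median_um": float(np.median(low)),
        },
    )


def impact_signature_report(
    assignment: ClusterAssignment,
    impact_calcium: np.ndarray,
    matrix: TraceMatrix,
) -> dict[int, dict]:
    """Joined per-cluster view: mean impact calcium, mean long-term traces,
    member positions. ``assignment`` and ``impact_calcium`` are over the
    impact-site cells whose long-term traces form ``matrix`` (row-aligned).
    """
    impact_calcium = np.asarray(impact_calcium, dtype=float)
    if len(assignment.labels) == 0:
        raise ValueError("no impact-site cells to report on")
    if not len(assignment.labels) == len(impact_calcium) == len(matrix):
        raise ValueError("assignment, impact traces, and matrix are misaligned")
    report = {}
    for c in np.unique(assignment.labels):
        sel = assignment.labels == c
        report[int(c)] = {
            "n_cells": int(sel.sum()),
            "mean_impact_calcium": impact_calcium[sel].mean(axis=0),
            "mean_long_term": matrix.data[sel].mean(axis=0),
            "positions": matrix.positions[sel] if matrix.positions is not None else None,
        }
    return report
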