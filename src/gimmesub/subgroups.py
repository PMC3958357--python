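"""Similarity-based subgroup detection with data-driven thresholding.

Individuals are represented by the vector of their contemporaneous
group-path betas.  Pairwise Pearson correlations of these vectors form
an N×N similarity matrix X, binarized at a threshold r (A_ij = 1 iff
X_ij >= r).  The threshold is selected by scanning r over [0, 1] in 0.01
steps: at each r, 100 randomized modularity runs quantify the stability
of Q (its standard deviation across runs) and the reachability of the
graph (mean size of each node's connected component minus one).  The
elbow of the reachability curve — the point of greatest perpendicular
distance from the chord joining its endpoints — marks where the network
fragments; the selected r* is the most stable threshold strictly before
that drop, ties broken by the highest r and then the highest mean Q.
The final partition is the modal partition across the runs at r*.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components

from .modularity import Partition, modularity_partition, modularity_q

__all__ = [
    "SimilarityNetwork", "ThresholdScan",
    "vectorize_betas", "build_similarity", "binarize", "reachability",
    "scan_thresholds", "find_reachability_drop", "select_threshold",
    "detect_subgroups", "detect_subgroups_from_betas", "matched_accuracy",
]

DEFAULT_GRID = np.round(np.arange(0, 101) * 0.01, 2)


@dataclass
class SimilarityNetwork:
    """Inter-individual correlation matrix and its binarized adjacency."""

    X: np.ndarray
    r: float | None = None
    A: np.ndarray | None = None
    flagged: list[int] = field(default_factory=list)


@dataclass
class ThresholdScan:
    """Results of the threshold scan over the r grid."""

    grid: np.ndarray
    Q: np.ndarray               # (n_grid, runs)
    q_std: np.ndarray           # (n_grid,)
    reach: np.ndarray           # (n_grid,) mean reachability
    edgeless: np.ndarray        # (n_grid,) bool
    partitions: list[list[Partition]] = field(repr=False, default_factory=list)
    drop_index: int | None = None
    selected_r: float | None = None

    @property
    def q_mean(self) -> np.ndarray:
        return self.Q.mean(axis=1)


# ---------------------------------------------------------------------------
# similarity network construction
# ---------------------------------------------------------------------------


def vectorize_betas(maps) -> np.ndarray:
    """N×k matrix of contemporaneous group-path betas, canonically ordered.

    Only group-level contemporaneous paths enter; lagged and
    individual-level paths are excluded.  Columns follow row-major order
    over (target, source) ROI pairs.
    """
    return maps.group_beta_matrix()


def build_similarity(beta_matrix: np.ndarray) -> SimilarityNetwork:
    """Pearson-correlation similarity of individuals' beta vectors."""
    B = np.asarray(beta_matrix, dtype=float)
    if B.ndim != 2 or B.shape[1] < 2:
        raise ValueError("need an N×k beta matrix with k >= 2")
    if np.isnan(B).any():
        raise ValueError("beta matrix contains missing entries")
    sd = B.std(axis=1)
    flagged = list(np.where(sd == 0)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.corrcoef(B)
    for i in flagged:
        warnings.warn(f"individual {i} has a zero-variance beta vector; "
                      "its similarities are undefined")
        X[i, :] = np.nan
        X[:, i] = np.nan
    np.fill_diagonal(X, np.nan)
    return SimilarityNetwork(X=X, flagged=flagged)


def binarize(X: np.ndarray, r: float) -> np.ndarray:
    """A_ij = 1 iff X_ij >= r (i != j); symmetric, zero diagonal."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("threshold r must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        A = (X >= r).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def reachability(A: np.ndarray) -> float:
    """Mean, over nodes, of the number of other nodes each can reach."""
    n = A.shape[0]
    if n == 0:
        return 0.0
    _, comp = connected_components(A, directed=False)
    sizes = np.bincount(comp)
    return float(np.mean(sizes[comp] - 1))


# ---------------------------------------------------------------------------
# threshold scan and selection
# ---------------------------------------------------------------------------


def scan_thresholds(
    X: np.ndarray,
    runs: int = 100,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
    keep_partitions: bool = True,
) -> ThresholdScan:
    """Binarize and run randomized modularity `runs` times at every r."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    n = X.shape[0]
    Q = np.zeros((len(grid), runs))
    reach = np.zeros(len(grid))
    edgeless = np.zeros(len(grid), dtype=bool)
    partitions: list[list[Partition]] = []
    for gi, r in enumerate(grid):
        A = binarize(X, r)
        reach[gi] = reachability(A)
        if A.sum() == 0:
            edgeless[gi] = True
            parts = [Partition(labels=np.arange(n), Q=0.0) for _ in range(runs)]
        else:
            parts = [modularity_partition(A, rng) for _ in range(runs)]
            Q[gi] = [p.Q for p in parts]
        partitions.append(parts if keep_partitions else [])
    scan = ThresholdScan(
        grid=grid, Q=Q, q_std=Q.std(axis=1), reach=reach,
        edgeless=edgeless, partitions=partitions,
    )
    scan.drop_index = find_reachability_drop(scan.reach)
    return scan


def find_reachability_drop(reach_curve: np.ndarray) -> int:
    """Index of greatest perpendicular distance from the endpoint chord.

    The chord joins the first and last points of the mean-reachability
    curve; the returned index marks where reachability falls away from
    it.  Ties break toward the smallest index; a perfectly linear curve
    has no drop and returns the last index with a warning.
    """
    y = np.asarray(reach_curve, dtype=float)
    if y.size < 3:
        raise ValueError("reachability curve needs at least 3 points")
    x = np.arange(y.size, dtype=float)
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    # distance from (x,y) to the line through (x0,y0)-(x1,y1)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist = dist / np.hypot(y1 - y0, x1 - x0)
    if np.allclose(dist, 0.0):
        warnings.warn("flat/linear reachability curve: no drop detected")
        return int(y.size - 1)
    return int(np.argmax(dist))


#: std(Q) below this is summation-order noise from runs that found the
#: identical partition, and counts as exactly stable.
STABILITY_TOL = 1e-10


def select_threshold(scan: ThresholdScan) -> float:
    """Most stable threshold strictly before the reachability drop.

    Minimal std(Q) wins; ties break to the highest r, then highest mean Q.
    Standard deviations below ``STABILITY_TOL`` are treated as zero so the
    tie-break operates on genuinely stable thresholds rather than on
    floating-point accumulation noise.  Edgeless grid points are never
    eligible.
    """
    if scan.drop_index is None:
        scan.drop_index = find_reachability_drop(scan.reach)
    eligible = [i for i in range(scan.drop_index) if not scan.edgeless[i]]
    if not eligible:
        raise ValueError(
            "no eligible thresholds before the reachability drop "
            f"(drop index {scan.drop_index}); similarity network too sparse"
        )
    q_mean = scan.q_mean
    q_std = np.where(scan.q_std < STABILITY_TOL, 0.0, scan.q_std)
    best = min(eligible, key=lambda i: (q_std[i], -scan.grid[i], -q_mean[i]))
    scan.selected_r = float(scan.grid[best])
    return scan.selected_r


def _modal_partition(parts: list[Partition]) -> Partition:
    counts = Counter(p.canonical() for p in parts)
    top = max(counts.values())
    tied = [c for c, k in counts.items() if k == top]
    by_canon = {}
    for p in parts:
        by_canon.setdefault(p.canonical(), p)
    return max((by_canon[c] for c in tied), key=lambda p: p.Q)


def detect_subgroups_from_betas(
    beta_matrix: np.ndarray,
    runs: int = 100,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
) -> tuple[Partition, ThresholdScan, SimilarityNetwork]:
    """Similarity → threshold scan → selection → final modal partition."""
    net = build_similarity(beta_matrix)
    scan = scan_thresholds(net.X, runs=runs, rng=rng, grid=grid)
    r_star = select_threshold(scan)
    gi = int(np.where(np.isclose(scan.grid, r_star))[0][0])
    part = _modal_partition(scan.partitions[gi])
    net.r = r_star
    net.A = binarize(net.X, r_star)
    return part, scan, net


def detect_subgroups(
    maps,
    runs: int = 100,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
) -> tuple[Partition, ThresholdScan, SimilarityNetwork]:
    """Full subgrouping pipeline on a fitted :class:`ConnectivityMapSet`."""
    return detect_subgroups_from_betas(vectorize_betas(maps), runs=runs,
                                       rng=rng, grid=grid)


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------


def matched_accuracy(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Fraction correctly placed under maximum-overlap one-to-one matching.

    Detected communities are matched to true subgroups by Hungarian
    assignment on the contingency table; members of unmatched communities
    score incorrect.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have the same length")
    tu, ti = np.unique(t, return_inverse=True)
    pu, pi = np.unique(p, return_inverse=True)
    table = np.zeros((tu.size, pu.size), dtype=int)
    np.add.at(table, (ti, pi), 1)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / t.size)
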