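"""Monte Carlo generator for subgroup-structured directed connectivity data.

Each simulated individual follows a structural vector autoregression

    y_t = A y_t + Phi y_{t-1} + zeta_t,   zeta_t ~ N(0, noise_sd^2 I),

i.e. the reduced form y_t = (I - A)^{-1} (Phi y_{t-1} + zeta_t).  A holds
contemporaneous directed paths (zero diagonal), Phi the lag-1 paths with
autoregressive effects on its diagonal.  The sample is structured into
subgroups: every individual shares a common set of contemporaneous group
paths and autoregressive effects; within each subgroup three of the group
paths deviate from the common weight by +/- `deviation`, and one
subgroup-specific "unique" path is present for a random (Bernoulli)
subset of the subgroup's members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TimeSeriesPanel

Path = tuple[int, int]  # (target ROI, source ROI)

#: Default 9 shared contemporaneous paths: a chain i -> i+1 over 10 ROIs.
DEFAULT_GROUP_PATHS: list[Path] = [(i + 1, i) for i in range(9)]

#: Default subgroup-unique contemporaneous paths, one per subgroup.
DEFAULT_UNIQUE_PATHS: list[Path] = [(5, 0), (6, 1), (7, 2), (8, 3)]


def _default_deviations(n_subgroups: int, group_paths: list[Path]) -> list[list[tuple[Path, int]]]:
    """Assign each subgroup a window of 3 deviant paths, stride 2.

    Consecutive subgroups share one deviant path (same sign), giving
    moderately correlated neighbouring subgroup profiles — individuals
    are similar across the sample yet clearly closest to their own
    subgroup, the regime in which the data-driven threshold settles
    around 0.5-0.6.  Sign pattern (+, -, +) within each window; the
    pattern flips on each wrap around the path list so triples landing
    on the same paths still differ.
    """
    k = len(group_paths)
    signs = (1, -1, 1)
    out = []
    for g in range(n_subgroups):
        flip = (-1) ** ((2 * g) // k)
        triple = [(group_paths[(2 * g + j) % k], flip * signs[j]) for j in range(3)]
        out.append(triple)
    return out


@dataclass
class SimulationDesign:
    """Parameters of the subgroup-structured simulation.

    Defaults reproduce the validation design: 100 individuals in 4 equal
    subgroups, 10 ROIs observed for 200 scans, autoregressive weight 0.60,
    9 shared contemporaneous paths of weight 0.50 of which 3 per subgroup
    deviate by +/-0.20, and one subgroup-unique path present with
    probability 0.5 per individual.
    """

    n_individuals: int = 100
    n_rois: int = 10
    n_timepoints: int = 200
    ar_weight: float = 0.60
    base_beta: float = 0.50
    deviation: float = 0.20
    group_paths: list[Path] = field(default_factory=lambda: list(DEFAULT_GROUP_PATHS))
    n_subgroups: int = 4
    subgroup_deviations: list[list[tuple[Path, int]]] | None = None
    unique_paths: list[Path] = field(default_factory=lambda: list(DEFAULT_UNIQUE_PATHS))
    unique_beta: float | None = None  # defaults to base_beta
    unique_prob: float = 0.5
    noise_sd: float = 1.0
    burn_in: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        self.group_paths = [tuple(pq) for pq in self.group_paths]
        self.unique_paths = [tuple(pq) for pq in self.unique_paths]
        if self.subgroup_deviations is None:
            self.subgroup_deviations = _default_deviations(self.n_subgroups, self.group_paths)
        else:
            self.subgroup_deviations = [
                [(tuple(pq), int(s)) for pq, s in dev] for dev in self.subgroup_deviations
            ]
        if self.unique_beta is None:
            self.unique_beta = self.base_beta
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        p = self.n_rois
        gset = set(self.group_paths)
        if len(gset) != len(self.group_paths):
            raise ValueError("group_paths contains duplicates")
        for i, j in self.group_paths:
            if i == j or not (0 <= i < p and 0 <= j < p):
                raise ValueError(f"invalid group path ({i}, {j})")
        if len(self.subgroup_deviations) != self.n_subgroups:
            raise ValueError("need one deviation triple per subgroup")
        for g, dev in enumerate(self.subgroup_deviations):
            if len(dev) != 3:
                raise ValueError(f"subgroup {g}: exactly 3 deviant paths required")
            for pq, s in dev:
                if pq not in gset:
                    raise ValueError(f"subgroup {g}: deviant path {pq} not a group path")
                if s not in (-1, 1):
                    raise ValueError(f"subgroup {g}: deviation sign must be +1 or -1")
        triples = [frozenset(dev) for dev in self.subgroup_deviations]
        if len(set(triples)) != len(triples):
            raise ValueError("subgroup deviation patterns must be pairwise distinct")
        if len(self.unique_paths) != self.n_subgroups:
            raise ValueError("need one unique path per subgroup")
        for g, pq in enumerate(self.unique_paths):
            if pq in gset:
                raise ValueError(f"subgroup {g}: unique path {pq} must not be a group path")
            i, j = pq
            if i == j or not (0 <= i < p and 0 <= j < p):
                raise ValueError(f"subgroup {g}: invalid unique path {pq}")
        if self.n_individuals % self.n_subgroups:
            raise ValueError("n_individuals must divide evenly into the subgroups")
        if not 0.0 <= self.unique_prob <= 1.0:
            raise ValueError("unique_prob must be a probability")
        # every subgroup's implied system (with and without the unique
        # path) must be stable and have invertible (I - A)
        for g in range(self.n_subgroups):
            for uniq in (False, True):
                A, Phi = self.true_matrices(g, include_unique=uniq)
                self._check_stable(A, Phi, g)

    @staticmethod
    def _check_stable(A: np.ndarray, Phi: np.ndarray, subgroup: int) -> None:
        p = A.shape[0]
        ImA = np.eye(p) - A
        if abs(np.linalg.det(ImA)) < 1e-10:
            raise ValueError(f"subgroup {subgroup}: (I - A) is singular")
        rho = np.max(np.abs(np.linalg.eigvals(np.linalg.solve(ImA, Phi))))
        if rho >= 1.0:
            raise ValueError(
                f"subgroup {subgroup}: unstable system, spectral radius "
                f"{rho:.3f} of the reduced-form lag matrix is >= 1"
            )

    # -- ground-truth maps ------------------------------------------------

    def true_matrices(self, subgroup: int, include_unique: bool) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, Phi) weight matrices for one member of `subgroup`."""
        p = self.n_rois
        A = np.zeros((p, p))
        for i, j in self.group_paths:
            A[i, j] = self.base_beta
        for (i, j), s in self.subgroup_deviations[subgroup]:
            A[i, j] = self.base_beta + s * self.deviation
        if include_unique:
            i, j = self.unique_paths[subgroup]
            A[i, j] = self.unique_beta
        Phi = np.eye(p) * self.ar_weight
        return A, Phi

    @property
    def subgroup_size(self) -> int:
        return self.n_individuals // self.n_subgroups

    def subgroup_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_subgroups), self.subgroup_size)


@dataclass
class GroundTruth:
    """True generating structure of a simulated panel."""

    labels: np.ndarray  # subgroup index per individual
    true_A: list[np.ndarray]
    true_Phi: list[np.ndarray]
    has_unique: np.ndarray  # bool per individual


def simulate_series(
    A: np.ndarray,
    Phi: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate a T×p series from y_t = (I-A)^{-1}(Phi y_{t-1} + zeta_t).

    The initial state is zero and `burn_in` leading samples are discarded
    to remove the transient.
    """
    p = A.shape[0]
    SimulationDesign._check_stable(A, Phi, subgroup=-1)
    B = np.linalg.inv(np.eye(p) - A)
    BPhi = B @ Phi
    total = n_timepoints + burn_in
    innov = rng.normal(scale=noise_sd, size=(total, p)) @ B.T
    y = np.zeros((total, p))
    prev = np.zeros(p)
    for t in range(total):
        prev = BPhi @ prev + innov[t]
        y[t] = prev
    return y[burn_in:]


def generate_individual(
    design: SimulationDesign,
    subgroup: int,
    rng: np.random.Generator,
    include_unique: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Generate one individual's series from the design.

    Returns ``(series, A, Phi, has_unique)``.  When `include_unique` is
    None the unique path is present with probability ``unique_prob``.
    """
    if include_unique is None:
        include_unique = bool(rng.random() < design.unique_prob)
    A, Phi = design.true_matrices(subgroup, include_unique=include_unique)
    ts = simulate_series(
        A, Phi, design.n_timepoints, rng,
        noise_sd=design.noise_sd, burn_in=design.burn_in,
    )
    return ts, A, Phi, include_unique


def generate_panel(
    design: SimulationDesign,
    rng: np.random.Generator | int | None = None,
) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Generate the full panel of individuals with ground truth labels."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = design.subgroup_labels()
    ids, series, true_A, true_Phi, has_unique = [], [], [], [], []
    for n, g in enumerate(labels):
        ts, A, Phi, uniq = generate_individual(design, int(g), rng)
        ids.append(f"ind{n:03d}")
        series.append(ts)
        true_A.append(A)
        true_Phi.append(Phi)
        has_unique.append(uniq)
    panel = TimeSeriesPanel(ids=ids, series=series)
    truth = GroundTruth(
        labels=labels.copy(),
        true_A=true_A,
        true_Phi=true_Phi,
        has_unique=np.asarray(has_unique, dtype=bool),
    )
    return panel, truth


def stationary_covariance(A: np.ndarray, Phi: np.ndarray, noise_sd: float = 1.0) -> np.ndarray:
    """Analytic stationary covariance of the reduced-form VAR.

    Solves the discrete Lyapunov equation ``S = M S M' + V`` with
    ``M = (I-A)^{-1} Phi`` and ``V = noise_sd^2 (I-A)^{-1} (I-A)^{-T}``.
    """
    from scipy.linalg import solve_discrete_lyapunov

    p = A.shape[0]
    B = np.linalg.inv(np.eye(p) - A)
    M = B @ Phi
    V = noise_sd**2 * B @ B.T
    return solve_discrete_lyapunov(M, V)
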