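"""Group Iterative Multiple Model Estimation (GIMME).

Two-stage structural search over uSEM paths:

1. *Group search* — iteratively free the candidate path whose modification
   index exceeds the Bonferroni-corrected chi-square(1) critical value for
   the largest number of individuals, as long as that count reaches the
   majority criterion ``gamma * N``; afterwards prune group paths that are
   non-significant for too many individuals.
2. *Individual search* — per individual, starting from the group map,
   free the largest-MI path until the model reaches excellent fit (two of
   four index rules) or no candidate clears the corrected threshold; then
   prune non-significant individual-level (never group-level) paths.

Autoregressive (Phi diagonal) paths are freed a priori for every
individual and are never pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import TimeSeriesPanel
from .simulate import GroundTruth
from .usem import (
    ConvergenceError,
    FitIndexSet,
    USEMFit,
    USEMSpec,
    _fit_from_moments,
    _Moments,
    _pack,
    _standardize,
    embed_lag,
    fit_indices,
    modification_indices,
)

log = logging.getLogger(__name__)

__all__ = ["GroupMap", "IndividualMap", "ConnectivityMapSet",
           "run_group_search", "run_individual_search", "run_gimme",
           "connection_recovery"]


@dataclass
class GroupMap:
    """Boolean masks of group-level paths plus the search history."""

    group_A: np.ndarray
    group_Phi: np.ndarray
    add_history: list[tuple[tuple[str, int, int], int, int]] = field(default_factory=list)
    pruned: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.group_A.shape[0]

    def contemporaneous_paths(self) -> list[tuple[int, int]]:
        """Group-level contemporaneous (A) paths in canonical row-major order."""
        return [(i, j) for i, j in zip(*np.where(self.group_A))]

    def to_spec(self) -> USEMSpec:
        return USEMSpec(self.p, self.group_A.copy(), self.group_Phi.copy())


@dataclass
class IndividualMap:
    """Final fitted model for one individual."""

    id: str
    fit: USEMFit
    indiv_A: np.ndarray  # individual-specific contemporaneous paths
    indiv_Phi: np.ndarray
    indices: FitIndexSet


@dataclass
class ConnectivityMapSet:
    """Group map plus per-individual fitted connectivity maps."""

    group: GroupMap
    individuals: list[IndividualMap]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def group_beta_matrix(self) -> np.ndarray:
        """N×k matrix of contemporaneous group-path betas (row-major paths)."""
        paths = self.group.contemporaneous_paths()
        if len(paths) < 2:
            raise ValueError(
                f"group map has {len(paths)} contemporaneous paths; "
                "at least 2 are needed to correlate beta vectors"
            )
        return np.array([
            [im.fit.A_hat[i, j] for i, j in paths] for im in self.individuals
        ])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


class _Individual:
    """Cached lag-embedded moments and the latest fit for one individual."""

    def __init__(self, sid: str, ts: np.ndarray, p: int, standardize: bool = False):
        self.id = sid
        pairs, _ = embed_lag(_standardize(ts) if standardize else np.asarray(ts, float))
        self.moments = _Moments(pairs, p)
        self.fit: USEMFit | None = None

    def refit(self, spec: USEMSpec, compute_se: bool = False) -> USEMFit:
        start = None
        if self.fit is not None:
            start = _pack(self.fit.A_hat, self.fit.Phi_hat, spec)
        self.fit = _fit_from_moments(self.moments, spec, start=start,
                                     compute_se=compute_se)
        return self.fit


def _bonferroni_crit(alpha: float, n_candidates: int) -> float:
    return float(stats.chi2.isf(alpha / max(n_candidates, 1), 1))


def _prepare(panel: TimeSeriesPanel, standardize: bool = False) -> tuple[list[_Individual], list[str]]:
    people, excluded = [], []
    p = panel.n_rois
    for sid, ts in panel:
        try:
            people.append(_Individual(sid, ts, p, standardize=standardize))
        except ValueError as err:
            log.warning("excluding %s: %s", sid, err)
            excluded.append(sid)
    if len(people) < 2:
        raise ValueError("group search needs at least 2 usable individuals")
    return people, excluded


# ---------------------------------------------------------------------------
# group-level search
# ---------------------------------------------------------------------------


def run_group_search(
    panel: TimeSeriesPanel,
    gamma: float = 0.75,
    alpha: float = 0.05,
    max_paths: int | None = None,
    standardize: bool = False,
) -> GroupMap:
    """Build the map of directed paths significant for the majority."""
    if not 0.5 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0.5, 1]")
    p = panel.n_rois
    people, excluded = _prepare(panel, standardize)
    spec = USEMSpec.ar_only(p)
    gmap = GroupMap(group_A=spec.free_A.copy(), group_Phi=spec.free_Phi.copy())
    if max_paths is None:
        max_paths = p * p + p * (p - 1)

    max_free = p * p + p * (p + 1) // 2 - p  # identification limit (df >= 0)
    for iteration in range(max_paths):
        if spec.n_free >= max_free:
            break
        cands = spec.candidates()
        if not cands:
            break
        crit = _bonferroni_crit(alpha, len(cands))
        counts = {c: 0 for c in cands}
        mi_sums = {c: 0.0 for c in cands}
        usable = []
        for person in people:
            try:
                fit = person.refit(spec)
            except ConvergenceError as err:
                log.warning("group search: excluding %s (%s)", person.id, err)
                excluded.append(person.id)
                continue
            usable.append(person)
            for c, (mi, _epc) in modification_indices(fit, spec).items():
                mi_sums[c] += mi
                if mi > crit:
                    counts[c] += 1
        people = usable
        n = len(people)
        best = max(cands, key=lambda c: (counts[c], mi_sums[c]))
        if counts[best] < gamma * n or counts[best] == 0:
            break
        kind, i, j = best
        (spec.free_A if kind == "A" else spec.free_Phi)[i, j] = True
        gmap.add_history.append((best, counts[best], iteration))
        log.info("group add %s (%d/%d individuals)", best, counts[best], n)

    # prune group paths non-significant for more than (1-gamma)*N individuals
    while True:
        for person in people:
            person.refit(spec, compute_se=True)
        n = len(people)
        added = [path for path, _c, _i in gmap.add_history
                 if path not in gmap.pruned]
        worst, worst_count = None, 0
        for kind, i, j in added:
            nonsig = sum(person.fit.p_value(kind, i, j) > alpha
                         for person in people)
            if nonsig > (1.0 - gamma) * n and nonsig > worst_count:
                worst, worst_count = (kind, i, j), nonsig
        if worst is None:
            break
        kind, i, j = worst
        (spec.free_A if kind == "A" else spec.free_Phi)[i, j] = False
        gmap.pruned.append(worst)
        log.info("group prune %s (non-significant for %d/%d)", worst, worst_count, n)

    gmap.group_A = spec.free_A.copy()
    gmap.group_Phi = spec.free_Phi.copy()
    return gmap


# ---------------------------------------------------------------------------
# individual-level search
# ---------------------------------------------------------------------------


def _individual_search(
    person: _Individual,
    gmap: GroupMap,
    null_fit: USEMFit,
    alpha: float,
    rules_needed: int = 2,
) -> IndividualMap:
    p = gmap.p
    spec = gmap.to_spec()
    fit = person.refit(spec)
    max_extra = p * p + p * (p - 1)
    max_free = p * p + p * (p + 1) // 2 - p  # identification limit (df >= 0)
    for _ in range(max_extra):
        if fit_indices(fit, null_fit).excellent(rules_needed):
            break
        if spec.n_free >= max_free:
            break
        cands = spec.candidates()
        if not cands:
            break
        crit = _bonferroni_crit(alpha, len(cands))
        mis = modification_indices(fit, spec)
        accepted = False
        for cand in sorted(mis, key=lambda c: mis[c][0], reverse=True):
            if mis[cand][0] <= crit:
                break
            kind, i, j = cand
            trial = spec.copy()
            (trial.free_A if kind == "A" else trial.free_Phi)[i, j] = True
            try:
                fit = person.refit(trial)
            except ConvergenceError as err:
                log.warning("%s: step freeing %s rejected (%s)", person.id, cand, err)
                continue
            spec = trial
            accepted = True
            break
        if not accepted:
            break

    # prune non-significant individual-level paths (never group-level, never AR)
    while True:
        fit = person.refit(spec, compute_se=True)
        indiv = [("A", i, j) for i, j in zip(*np.where(spec.free_A & ~gmap.group_A))]
        indiv += [("Phi", i, j) for i, j in zip(*np.where(spec.free_Phi & ~gmap.group_Phi))]
        worst, worst_p = None, alpha
        for kind, i, j in indiv:
            pv = fit.p_value(kind, i, j)
            if pv > worst_p:
                worst, worst_p = (kind, i, j), pv
        if worst is None:
            break
        kind, i, j = worst
        (spec.free_A if kind == "A" else spec.free_Phi)[i, j] = False

    return IndividualMap(
        id=person.id,
        fit=fit,
        indiv_A=spec.free_A & ~gmap.group_A,
        indiv_Phi=spec.free_Phi & ~gmap.group_Phi,
        indices=fit_indices(fit, null_fit),
    )


def run_individual_search(
    panel: TimeSeriesPanel,
    group_map: GroupMap,
    alpha: float = 0.05,
    rules_needed: int = 2,
    standardize: bool = False,
) -> ConnectivityMapSet:
    """Fit individual-level maps seeded by the group map."""
    people, excluded = _prepare(panel, standardize)
    null_spec = USEMSpec.ar_only(group_map.p)
    results = []
    for person in people:
        null_fit = _fit_from_moments(person.moments, null_spec, compute_se=False)
        person.fit = None  # restart from the group map, not the null model
        try:
            results.append(_individual_search(person, group_map, null_fit,
                                              alpha, rules_needed))
        except ConvergenceError as err:
            log.warning("individual search: excluding %s (%s)", person.id, err)
            excluded.append(person.id)
    return ConnectivityMapSet(group=group_map, individuals=results,
                              excluded=excluded)


def run_gimme(
    panel: TimeSeriesPanel,
    gamma: float = 0.75,
    alpha: float = 0.05,
    rules_needed: int = 2,
    standardize: bool = False,
) -> ConnectivityMapSet:
    """Full GIMME: group search followed by individual search."""
    gmap = run_group_search(panel, gamma=gamma, alpha=alpha,
                            standardize=standardize)
    return run_individual_search(panel, gmap, alpha=alpha,
                                 rules_needed=rules_needed,
                                 standardize=standardize)


# ---------------------------------------------------------------------------
# recovery scoring against ground truth
# ---------------------------------------------------------------------------


def connection_recovery(maps: ConnectivityMapSet, truth: GroundTruth) -> float:
    """Fraction of true connections recovered with correct presence+direction.

    Pooled over all individuals: a true path (contemporaneous or lagged,
    including autoregressive effects) counts as recovered when the exact
    directed element is free in that individual's final model.
    """
    correct = total = 0
    for im, A_true, Phi_true in zip(maps.individuals, truth.true_A, truth.true_Phi):
        est_A = im.fit.spec.free_A
        est_Phi = im.fit.spec.free_Phi
        for i, j in zip(*np.where(A_true != 0)):
            total += 1
            correct += bool(est_A[i, j])
        for i, j in zip(*np.where(Phi_true != 0)):
            total += 1
            correct += bool(est_Phi[i, j])
    return correct / total if total else float("nan")
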