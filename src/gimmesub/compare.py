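"""Comparison of group-path connection weights across subgroups.

For every group-level contemporaneous path, an omnibus one-way ANOVA
tests for any difference across detected subgroups, and per-subgroup
contrasts (subgroup mean vs the pooled mean of all other subgroups,
two-sample t) localize which subgroup is higher or lower.  False
discovery rate control uses Storey q-values (smoother pi0 estimate)
across all path×subgroup contrasts jointly; Benjamini-Hochberg is
available as a fallback.  A traditional two-group diagnostic comparison
(e.g. patients vs controls) is provided for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .modularity import Partition

__all__ = ["PathComparisonTable", "compare_subgroup_paths",
           "diagnostic_comparison", "fdr_correct"]


@dataclass
class PathComparisonTable:
    """Per-(path, subgroup) contrasts plus per-path omnibus ANOVA."""

    contrasts: pd.DataFrame
    omnibus: pd.DataFrame
    alpha: float


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0."""
    m = p.size
    if m < 20:
        return 1.0  # too few tests for a stable estimate
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > L).sum() / (m * (1.0 - L)) for L in lam])
    try:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    except Exception:
        pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, 1.0 / m, 1.0))


def fdr_correct(
    pvalues,
    alpha: float = 0.05,
    method: str = "storey",
) -> np.ndarray:
    """q-values for a family of p-values.

    `method="storey"` (default) estimates pi0 by the smoother method and
    returns Storey q-values; `method="bh"` returns Benjamini-Hochberg
    adjusted p-values (pi0 fixed at 1).  NaN p-values propagate to NaN
    q-values and are excluded from the family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pv.size == 0:
        return out
    if method == "bh":
        from statsmodels.stats.multitest import multipletests
        out[mask] = multipletests(pv, alpha=alpha, method="fdr_bh")[1]
        return out
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    m = pv.size
    pi0 = _storey_pi0(pv)
    order = np.argsort(pv)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(pi0 * m * pv[idx] / rank, prev)
        q[idx] = val
        prev = val
    out[mask] = q
    return out


def _path_names(k: int, paths=None) -> list[str]:
    if paths is not None:
        return [f"{j}->{i}" for i, j in paths]
    return [f"path{c}" for c in range(k)]


def compare_subgroup_paths(
    betas: np.ndarray,
    partition: Partition | np.ndarray,
    alpha: float = 0.05,
    method: str = "storey",
    paths=None,
) -> PathComparisonTable:
    """Each subgroup vs the average of the others, per group path.

    Per path: omnibus one-way ANOVA across subgroups.  Per (path,
    subgroup): two-sample t of the subgroup's betas against all other
    individuals pooled.  FDR is applied jointly across all contrasts;
    verdicts are `higher`/`lower` by the sign of the mean difference at
    q <= alpha, `similar` otherwise, `untestable` for singleton
    subgroups.
    """
    B = np.asarray(betas, dtype=float)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if B.shape[0] != labels.size:
        raise ValueError("betas rows and partition labels must align")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 subgroups to compare")
    sizes = {g: int((labels == g).sum()) for g in groups}
    if all(s < 2 for s in sizes.values()):
        raise ValueError("every subgroup is a singleton; nothing testable")
    names = _path_names(B.shape[1], paths)

    omni_rows = []
    for c, name in enumerate(names):
        samples = [B[labels == g, c] for g in groups if sizes[g] >= 2]
        if len(samples) >= 2:
            if np.ptp(B[:, c]) == 0:  # constant path: no difference to test
                F, pv = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore"):
                    F, pv = stats.f_oneway(*samples)
        else:
            F, pv = np.nan, np.nan
        omni_rows.append({"path": name, "F": F, "p_value": pv})
    omnibus = pd.DataFrame(omni_rows)

    rows = []
    for c, name in enumerate(names):
        for g in groups:
            mask = labels == g
            x, rest = B[mask, c], B[~mask, c]
            if sizes[g] < 2 or rest.size < 2:
                t, pv = np.nan, np.nan
            elif x.std() == 0 and rest.std() == 0 and x.mean() == rest.mean():
                t, pv = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore"):
                    t, pv = stats.ttest_ind(x, rest, equal_var=True)
            rows.append({
                "path": name, "subgroup": g,
                "subgroup_mean": float(x.mean()),
                "others_mean": float(rest.mean()),
                "t_stat": float(t) if np.isfinite(t) else np.nan,
                "p_value": float(pv) if np.isfinite(pv) else np.nan,
            })
    contrasts = pd.DataFrame(rows)
    contrasts["q_value"] = fdr_correct(contrasts["p_value"].to_numpy(),
                                       alpha=alpha, method=method)

    def _verdict(row):
        if np.isnan(row.p_value):
            return "untestable"
        if row.q_value > alpha:
            return "similar"
        return "higher" if row.subgroup_mean > row.others_mean else "lower"

    contrasts["verdict"] = [_verdict(r) for r in contrasts.itertuples()]
    return PathComparisonTable(contrasts=contrasts, omnibus=omnibus, alpha=alpha)


def diagnostic_comparison(
    betas: np.ndarray,
    labels,
    alpha: float = 0.05,
    method: str = "storey",
    paths=None,
) -> pd.DataFrame:
    """Traditional two-group (diagnostic) comparison of path weights."""
    B = np.asarray(betas, dtype=float)
    lab = np.asarray(labels)
    values = np.unique(lab)
    if values.size != 2:
        raise ValueError("diagnostic comparison requires exactly two labels")
    a, b = values
    names = _path_names(B.shape[1], paths)
    rows = []
    for c, name in enumerate(names):
        x, y = B[lab == a, c], B[lab == b, c]
        t, pv = stats.ttest_ind(x, y, equal_var=True)
        rows.append({
            "path": name,
            f"mean_{a}": float(x.mean()), f"mean_{b}": float(y.mean()),
            "t_stat": float(t), "p_value": float(pv),
        })
    table = pd.DataFrame(rows)
    table["q_value"] = fdr_correct(table["p_value"].to_numpy(),
                                   alpha=alpha, method=method)
    table["significant"] = table["q_value"] <= alpha
    return table
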