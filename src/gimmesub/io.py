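"""File I/O and motion scrubbing.

Time series are exchanged as delimited text, one file per individual
(rows = scans, columns = ROIs); missing frames are NaN/NA placeholder
rows so temporal ordering is retained.  Head-motion scrubbing follows
the framewise-displacement rule: FD_i is the sum of absolute backward
differences of the six rigid-body realignment parameters, and frames
with FD above threshold (default 0.2 mm) are replaced by placeholders.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import TimeSeriesPanel

__all__ = ["load_panel", "save_panel", "compute_fd", "scrub_frames",
           "write_edge_list", "write_matrix", "write_partition"]

_EXTENSIONS = (".tsv", ".csv", ".txt", ".dat")


def _read_series(path: Path) -> np.ndarray:
    sep = "," if path.suffix == ".csv" else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, comment="#",
                     na_values=["NA", "NaN", "nan", "."])
    # tolerate a header line of ROI names
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep=sep, comment="#",
                         na_values=["NA", "NaN", "nan", "."])
    return df.to_numpy(dtype=float)


def load_panel(
    directory: str | Path,
    roi_labels: list[str] | None = None,
) -> TimeSeriesPanel:
    """Load every delimited time-series file in a directory.

    File stems become individual IDs.  All files must have the same
    number of columns; offenders are listed in the error.
    """
    directory = Path(directory)
    files = sorted(f for f in directory.iterdir()
                   if f.suffix.lower() in _EXTENSIONS and f.is_file())
    if not files:
        raise FileNotFoundError(f"no time-series files found in {directory}")
    ids, series = [], []
    for f in files:
        ids.append(f.stem)
        series.append(_read_series(f))
    p_counts = {sid: ts.shape[1] for sid, ts in zip(ids, series)}
    p_mode = max(set(p_counts.values()), key=list(p_counts.values()).count)
    bad = [sid for sid, p in p_counts.items() if p != p_mode]
    if bad:
        raise ValueError(
            f"inconsistent ROI counts: expected {p_mode} columns, "
            f"offending files: {', '.join(bad)}"
        )
    return TimeSeriesPanel(ids=ids, series=series,
                           roi_labels=list(roi_labels or []))


def save_panel(panel: TimeSeriesPanel, directory: str | Path) -> None:
    """Write one TSV per individual (NaN as 'NA')."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, ts in panel:
        pd.DataFrame(ts).to_csv(directory / f"{sid}.tsv", sep="\t",
                                header=False, index=False, na_rep="NA")


def compute_fd(realignment: np.ndarray) -> np.ndarray:
    """Framewise displacement from 6 rigid-body realignment parameters.

    FD_i = |dx| + |dy| + |dz| + |dalpha| + |dbeta| + |dgamma| of the
    backward differences; FD_1 is defined as 0.  Rotation parameters are
    assumed already expressed in mm.
    """
    r = np.asarray(realignment, dtype=float)
    if r.ndim != 2 or r.shape[1] != 6:
        raise ValueError(f"expected T×6 realignment parameters, got {r.shape}")
    if r.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    fd = np.zeros(r.shape[0])
    fd[1:] = np.abs(np.diff(r, axis=0)).sum(axis=1)
    return fd


def scrub_frames(
    series: np.ndarray,
    fd: np.ndarray,
    threshold: float = 0.2,
) -> np.ndarray:
    """Replace frames with FD > threshold (mm) by placeholder NaN rows."""
    ts = np.asarray(series, dtype=float).copy()
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise ValueError("FD values must align with the series frames")
    ts[fd > threshold] = np.nan
    return ts


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def write_edge_list(maps, path: str | Path) -> None:
    """All estimated paths as a long table.

    Columns: individual, source, target, lag (0 contemporaneous /
    1 lagged), beta, level (group / individual).
    """
    rows = []
    g = maps.group
    for im in maps.individuals:
        for i, j in zip(*np.where(im.fit.spec.free_A)):
            rows.append((im.id, int(j), int(i), 0, im.fit.A_hat[i, j],
                         "group" if g.group_A[i, j] else "individual"))
        for i, j in zip(*np.where(im.fit.spec.free_Phi)):
            rows.append((im.id, int(j), int(i), 1, im.fit.Phi_hat[i, j],
                         "group" if g.group_Phi[i, j] else "individual"))
    df = pd.DataFrame(rows, columns=["individual", "source", "target",
                                     "lag", "beta", "level"])
    df.to_csv(path, sep="\t", index=False)


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(M).to_csv(path, sep="\t", header=False, index=False,
                           na_rep="NA")


def write_partition(ids, labels, path: str | Path) -> None:
    pd.DataFrame({"individual": ids, "community": labels}).to_csv(
        path, sep="\t", index=False)
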