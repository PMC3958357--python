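"""Core container for per-individual ROI time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesPanel:
    """A collection of per-individual T×p ROI time series.

    Missing frames (e.g. scrubbed for head motion) are encoded as rows of
    NaN so that the temporal ordering of scans is retained.  All
    individuals must share the same number of ROIs and the same ROI
    ordering; series lengths may differ.
    """

    ids: list[str]
    series: list[np.ndarray]
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.series):
            raise ValueError("ids and series must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual IDs must be unique")
        if self.series:
            p = self.series[0].shape[1]
            for sid, ts in zip(self.ids, self.series):
                if ts.ndim != 2 or ts.shape[1] != p:
                    raise ValueError(
                        f"individual {sid!r} has {ts.shape} series; "
                        f"expected a T×{p} matrix"
                    )
        if not self.roi_labels and self.series:
            self.roi_labels = [f"ROI{j}" for j in range(self.series[0].shape[1])]

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_rois(self) -> int:
        return self.series[0].shape[1] if self.series else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.series))
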