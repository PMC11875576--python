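"""Container for one subject's ROI time-series matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

MIN_TIMEPOINTS = 8


@dataclass
class RoiTimeSeries:
    """A real-valued (time points x ROIs) matrix with sampling metadata.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the matrix belongs to.
    data : ndarray, shape (m, n)
        BOLD-like signal, rows are time points, columns are ROIs.
        Requires m >= 8, n >= 2 and all values finite.
    tr : float
        Sampling interval in seconds (> 0). Resting-state fMRI studies
        call this the repetition time.
    roi_labels : list of str, optional
        One label per ROI; defaults to ``ROI_1 .. ROI_n``.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be a 2-D (time x ROI) matrix")
        m, n = self.data.shape
        if m < MIN_TIMEPOINTS:
            raise InvalidArgumentError(f"need at least {MIN_TIMEPOINTS} time points, got {m}")
        if n < 2:
            raise InvalidArgumentError(f"need at least 2 ROIs, got {n}")
        if not np.isfinite(self.data).all():
            raise InvalidArgumentError(f"non-finite values in data of subject {self.subject_id!r}")
        if self.tr <= 0:
            raise InvalidArgumentError(f"tr must be positive, got {self.tr}")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i + 1}" for i in range(n)]
        if len(self.roi_labels) != n:
            raise InvalidArgumentError("roi_labels length does not match the number of ROIs")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]
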