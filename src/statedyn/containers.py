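"""Core in-memory containers: parcellated time series and event tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CATEGORIES

EVENT_COLUMNS = ("onset", "duration", "category", "liking", "familiarity")


@dataclass
class ParcellatedTimeSeries:
    """One subject's ROI x volume matrix with acquisition metadata.

    ``data`` has shape (n_rois, n_volumes).  ``normalized`` records whether
    each ROI row has been z-scored; ``constant_rois`` lists rows that had
    zero variance and were set to zero during normalisation.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float
    roi_labels: list[str] | None = None
    normalized: bool = False
    constant_rois: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_volumes) matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at ROI {bad[0]}, volume {bad[1]} "
                f"for subject {self.subject_id}"
            )

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


class EventTable:
    """Excerpt onsets/durations/categories with 4-point Likert ratings.

    Wraps a DataFrame with columns onset, duration (seconds), category
    (self_selected / popular / novel), liking and familiarity (integers
    1-4, NaN when missing).  Windows must be ordered and non-overlapping.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        frame = frame.loc[:, list(EVENT_COLUMNS)]
        frame["onset"] = frame["onset"].astype(float)
        frame["duration"] = frame["duration"].astype(float)
        for col in ("liking", "familiarity"):
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        self.frame = frame
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            return
        if (f["duration"] <= 0).any():
            raise ValueError("event durations must be positive")
        onsets = f["onset"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        ends = onsets + f["duration"].to_numpy()
        if np.any(onsets[1:] < ends[:-1] - 1e-9):
            i = int(np.argmax(onsets[1:] < ends[:-1] - 1e-9))
            raise ValueError(
                f"events {i} and {i + 1} overlap "
                f"(end {ends[i]:.3f} s > onset {onsets[i + 1]:.3f} s)"
            )
        bad = set(f["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        for col in ("liking", "familiarity"):
            vals = f[col].dropna()
            if len(vals) and not vals.isin([1, 2, 3, 4]).all():
                offending = vals[~vals.isin([1, 2, 3, 4])]
                row = int(offending.index[0])
                raise ValueError(
                    f"{col} rating {offending.iloc[0]!r} in row {row} is "
                    "outside the 4-point scale {1,2,3,4}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, EventTable) and self.frame.equals(other.frame)

    def with_ratings(
        self, liking: np.ndarray, familiarity: np.ndarray
    ) -> "EventTable":
        f = self.frame.copy()
        f["liking"] = np.asarray(liking, dtype=float)
        f["familiarity"] = np.asarray(familiarity, dtype=float)
        return EventTable(f)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for c in self.frame["category"]:
            counts[c] += 1
        return counts

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame({c: [] for c in EVENT_COLUMNS}))
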