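"""In-memory containers for parcellated BOLD data and dFC results.

The containers validate their invariants on construction and raise
:class:`~multidfc.errors.ValidationError` instead of silently repairing
anything.  Time is always indexed in TR units (the repetition time of the
scan); ``time_stamps`` may be fractional because tapered sliding windows
are centred between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Maximum allowed asymmetry |A - A.T| of an FC slice.
SYMMETRY_TOL = 1e-10

#: The seven estimator identifiers, in canonical order.
METHOD_IDS = ("SW", "TF", "CAP", "SWC", "CHMM", "DHMM", "WL")


def _as_str_array(x, name: str, length: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=str)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if length is not None and arr.size != length:
        raise ValidationError(f"{name} has length {arr.size}, expected {length}")
    return arr


@dataclass
class AtlasTable:
    """Atlas rows (roi_id, rsn_label, hemisphere); order defines column order.

    ROIs whose ``rsn_label`` equals the sentinel ``"None"`` belong to no
    resting-state network and are dropped by
    :func:`multidfc.preprocess.exclude_unassigned_rois`.
    """

    roi_ids: np.ndarray
    rsn_labels: np.ndarray
    hemispheres: np.ndarray

    def __post_init__(self) -> None:
        self.roi_ids = _as_str_array(self.roi_ids, "roi_ids")
        n = self.roi_ids.size
        self.rsn_labels = _as_str_array(self.rsn_labels, "rsn_labels", n)
        self.hemispheres = _as_str_array(self.hemispheres, "hemispheres", n)
        if n == 0:
            raise ValidationError("atlas has no rows")
        if len(set(self.roi_ids)) != n:
            dupes = sorted({r for r in self.roi_ids if list(self.roi_ids).count(r) > 1})
            raise ValidationError(f"duplicate roi_id(s): {dupes}")
        if any(label == "" for label in self.rsn_labels):
            raise ValidationError("empty rsn_label; use the sentinel 'None'")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise ValidationError(f"unknown hemisphere token(s): {sorted(bad)}")

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    def subset(self, index: np.ndarray) -> "AtlasTable":
        return AtlasTable(self.roi_ids[index], self.rsn_labels[index], self.hemispheres[index])


@dataclass
class ParcellatedTimeSeries:
    """One subject's T x R BOLD matrix with TR and ROI/RSN/hemisphere labels."""

    subject_id: str
    tr_seconds: float
    values: np.ndarray
    roi_labels: np.ndarray
    rsn_labels: np.ndarray
    hemispheres: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time-series values must be a T x R matrix")
        if self.values.shape[0] < 2:
            raise ValidationError("need at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time series contains NaN/Inf")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        r = self.values.shape[1]
        self.roi_labels = _as_str_array(self.roi_labels, "roi_labels", r)
        self.rsn_labels = _as_str_array(self.rsn_labels, "rsn_labels", r)
        self.hemispheres = _as_str_array(self.hemispheres, "hemispheres", r)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "ParcellatedTimeSeries":
        """Copy with the data matrix replaced (same labels)."""
        return ParcellatedTimeSeries(
            self.subject_id, self.tr_seconds, values,
            self.roi_labels, self.rsn_labels, self.hemispheres,
        )

    def select_columns(self, index: np.ndarray) -> "ParcellatedTimeSeries":
        """Copy restricted to the ROI columns in ``index`` (order preserved)."""
        return ParcellatedTimeSeries(
            self.subject_id, self.tr_seconds, self.values[:, index],
            self.roi_labels[index], self.rsn_labels[index], self.hemispheres[index],
        )


def check_symmetric_stack(values: np.ndarray, tol: float = SYMMETRY_TOL) -> None:
    """Raise unless every (..., R, R) slice is symmetric within ``tol``."""
    asym = np.max(np.abs(values - np.swapaxes(values, -1, -2)))
    if asym > tol:
        raise ValidationError(f"FC slices asymmetric: max |A - A.T| = {asym:.3g} > {tol:g}")


@dataclass
class DfcMatrix:
    """One (subject, method) dFC result: T' symmetric R x R FC matrices."""

    subject_id: str
    method_id: str
    time_stamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValidationError("dFC values must have shape (T', R, R)")
        if self.time_stamps.shape != (self.values.shape[0],):
            raise ValidationError("time_stamps length must match the number of slices")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dFC values contain NaN/Inf")
        check_symmetric_stack(self.values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class DfcArray:
    """Standardized 5-way array dFC(subject, method, time, ROI, ROI)."""

    values: np.ndarray
    subject_ids: np.ndarray
    method_ids: np.ndarray
    time_stamps: np.ndarray
    roi_labels: np.ndarray
    rsn_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[3] != self.values.shape[4]:
            raise ValidationError("DfcArray values must have shape (S, M, T, R, R)")
        s, m, t, r, _ = self.values.shape
        self.subject_ids = _as_str_array(self.subject_ids, "subject_ids", s)
        self.method_ids = _as_str_array(self.method_ids, "method_ids", m)
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        if self.time_stamps.shape != (t,):
            raise ValidationError("time_stamps length must equal the time axis")
        self.roi_labels = _as_str_array(self.roi_labels, "roi_labels", r)
        self.rsn_labels = _as_str_array(self.rsn_labels, "rsn_labels", r)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("DfcArray contains NaN/Inf")
        check_symmetric_stack(self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_rois(self) -> int:
        return self.values.shape[3]

    def to_connections(self) -> np.ndarray:
        """Lower-triangle connection values, shape (S, M, T, R(R-1)/2)."""
        r = self.n_rois
        i, j = np.tril_indices(r, k=-1)
        return self.values[..., i, j]


@dataclass
class StateSet:
    """Group-level FC states of one state-based method."""

    method_id: str
    state_fc: np.ndarray
    fit_seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_fc = np.asarray(self.state_fc, dtype=float)
        if self.state_fc.ndim != 3 or self.state_fc.shape[1] != self.state_fc.shape[2]:
            raise ValidationError("state_fc must have shape (K, R, R)")
        if self.state_fc.shape[0] < 2:
            raise ValidationError("need at least 2 states")
        check_symmetric_stack(self.state_fc)

    @property
    def n_states(self) -> int:
        return self.state_fc.shape[0]

    @property
    def n_rois(self) -> int:
        return self.state_fc.shape[1]


@dataclass
class StateTimeCourse:
    """Per-subject state label sequence; labels are 1-based in {1..K}."""

    subject_id: str
    labels: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty vector")
        if self.labels.min() < 1 or self.labels.max() > self.n_states:
            raise ValidationError(
                f"labels outside 1..{self.n_states}: range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def fractional_occupancy(self) -> np.ndarray:
        counts = np.bincount(self.labels - 1, minlength=self.n_states)
        return counts / self.labels.size
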