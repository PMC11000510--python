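"""Subject-level conditioning of parcellated BOLD series.

The pipeline mirrors the standard resting-state preparation: drop ROIs
that belong to no resting-state network, optionally downsample the ROI set
with uniform RSN/hemisphere coverage, high-pass filter, and z-standardize
each ROI time course.  All steps are deterministic and order-preserving.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import AtlasTable, ParcellatedTimeSeries
from .errors import ParameterError, ValidationError

#: Sentinel RSN label marking ROIs outside every network.
UNASSIGNED = "None"


def exclude_unassigned_rois(
    ts: ParcellatedTimeSeries, atlas: AtlasTable
) -> ParcellatedTimeSeries:
    """Remove columns whose atlas RSN label is the sentinel ``"None"``."""
    if atlas.n_rois != ts.n_rois:
        raise ValidationError(
            f"atlas has {atlas.n_rois} rows but time series has {ts.n_rois} columns"
        )
    keep = np.flatnonzero(atlas.rsn_labels != UNASSIGNED)
    if keep.size == 0:
        raise ValidationError("every ROI is unassigned; nothing left after exclusion")
    return ts.select_columns(keep)


def uniform_roi_selection(atlas: AtlasTable, n_target: int) -> np.ndarray:
    """Deterministic ROI index selection with proportional RSN quotas.

    Each RSN receives a quota proportional to its size, rounded to an even
    number so both hemispheres contribute equally; within each
    (RSN, hemisphere) block, ROIs are taken at evenly spaced index
    positions.  RSNs with no ROI in one hemisphere are dropped with a
    warning.  Total selected is <= ``n_target``.
    """
    if n_target > atlas.n_rois:
        raise ParameterError(f"n_target {n_target} exceeds available {atlas.n_rois} ROIs")
    if n_target < 2:
        raise ParameterError("n_target must be at least 2")

    rsns = list(dict.fromkeys(atlas.rsn_labels))
    blocks: dict[str, dict[str, np.ndarray]] = {}
    for rsn in rsns:
        in_rsn = atlas.rsn_labels == rsn
        left = np.flatnonzero(in_rsn & (atlas.hemispheres == "L"))
        right = np.flatnonzero(in_rsn & (atlas.hemispheres == "R"))
        if left.size == 0 or right.size == 0:
            warnings.warn(f"RSN {rsn!r} lacks ROIs in one hemisphere; dropped")
            continue
        blocks[rsn] = {"L": left, "R": right}
    if not blocks:
        raise ValidationError("no RSN has ROIs in both hemispheres")

    total = sum(b["L"].size + b["R"].size for b in blocks.values())
    ideal = {r: n_target * (b["L"].size + b["R"].size) / total for r, b in blocks.items()}
    cap = {r: 2 * min(b["L"].size, b["R"].size) for r, b in blocks.items()}
    quota = {
        r: int(np.clip(2 * (int(ideal[r]) // 2), 2, cap[r])) for r in blocks
    }
    # many tiny RSNs can overshoot via the 2-ROI floor; trim largest excess
    while sum(quota.values()) > n_target:
        excesses = [(quota[r] - ideal[r], r) for r in blocks if quota[r] > 2]
        if not excesses:
            break
        _, pick = max(excesses, key=lambda d: (d[0], d[1]))
        quota[pick] -= 2
    # top up two at a time (one per hemisphere) toward the largest deficit
    while sum(quota.values()) + 2 <= n_target:
        deficits = [
            (ideal[r] - quota[r], r) for r in blocks if quota[r] + 2 <= cap[r]
        ]
        if not deficits:
            break
        _, pick = max(deficits, key=lambda d: (d[0], d[1]))
        quota[pick] += 2

    selected: list[int] = []
    for rsn in blocks:
        per_hemi = quota[rsn] // 2
        for hemi in ("L", "R"):
            idx = blocks[rsn][hemi]
            pos = np.round(np.linspace(0, idx.size - 1, per_hemi)).astype(int)
            selected.extend(idx[pos].tolist())
    return np.array(sorted(selected), dtype=int)


def select_uniform_rois(
    ts: ParcellatedTimeSeries, atlas: AtlasTable, n_target: int
) -> ParcellatedTimeSeries:
    """Downsample the ROI set to ~``n_target`` columns (see
    :func:`uniform_roi_selection`); identity when ``n_target == R``."""
    if atlas.n_rois != ts.n_rois:
        raise ValidationError("atlas/time-series ROI count mismatch")
    if n_target == ts.n_rois:
        return ts
    index = uniform_roi_selection(atlas, n_target)
    return ts.select_columns(index)


def highpass_filter(
    ts: ParcellatedTimeSeries, cutoff_hz: float = 0.01, order: int = 5
) -> ParcellatedTimeSeries:
    """Zero-phase Butterworth high-pass along the time axis.

    Implemented as a forward-backward (``sosfiltfilt``) 5th-order filter,
    so the effective attenuation is the squared magnitude response and no
    phase distortion is introduced.
    """
    nyquist = 0.5 / ts.tr_seconds
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    sos = butter(order, cutoff_hz, btype="highpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = sosfiltfilt(sos, ts.values, axis=0)
    return ts.with_values(filtered)


def z_standardize(ts: ParcellatedTimeSeries) -> ParcellatedTimeSeries:
    """Standardize each ROI column to mean 0, population (1/T) SD 1."""
    mean = ts.values.mean(axis=0)
    sd = ts.values.std(axis=0)  # population convention
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ts.roi_labels[zero].tolist()
        raise ValidationError(f"zero-variance ROI column(s): {names}")
    return ts.with_values((ts.values - mean) / sd)
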