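"""Shared dFC array model: vectorization, rank normalization, downsampling.

Every similarity and variance computation in the toolbox operates on the
off-diagonal lower triangle of the FC matrices (the diagonal is
method-dependent and carries no connectivity information).  The connection
order is the row-major order of index pairs (i, j) with i > j, so for R
ROIs there are R(R-1)/2 connections (4560 for R = 96).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .containers import DfcArray, DfcMatrix, check_symmetric_stack
from .errors import AssemblyError, ParameterError, ValidationError


def n_connections(n_rois: int) -> int:
    """Number of off-diagonal lower-triangle connections, R(R-1)/2."""
    return n_rois * (n_rois - 1) // 2


def connection_indices(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices (i > j) of the connections in canonical order."""
    return np.tril_indices(n_rois, k=-1)


def vectorize_lower_triangle(fc: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Vectorize a symmetric R x R FC matrix into its R(R-1)/2 connections.

    Raises if the matrix is asymmetric beyond ``tol``.  The diagonal is
    excluded.  Also accepts a stack (..., R, R), vectorizing each slice.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim < 2 or fc.shape[-1] != fc.shape[-2]:
        raise ValidationError("expected a square FC matrix or stack thereof")
    check_symmetric_stack(fc, tol)
    i, j = connection_indices(fc.shape[-1])
    return fc[..., i, j]


def devectorize(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` with a constant diagonal."""
    vec = np.asarray(vec, dtype=float)
    c = vec.shape[-1]
    r = int(round((1 + np.sqrt(1 + 8 * c)) / 2))
    if n_connections(r) != c:
        raise ValidationError(f"length {c} is not R(R-1)/2 for any integer R")
    i, j = connection_indices(r)
    out = np.zeros(vec.shape[:-1] + (r, r), dtype=float)
    out[..., i, j] = vec
    out[..., j, i] = vec
    idx = np.arange(r)
    out[..., idx, idx] = diag
    return out


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Jointly rank all values (average rank for ties) and rescale to [0, 1].

    Applied per (subject, method) to the T' x C connection values before any
    cross-method variance comparison, so that methods with very different
    value distributions become comparable -- the same rank transform that
    underlies Spearman correlation.  All-equal input maps to 0.5.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("rank_normalize requires finite values")
    flat = values.ravel()
    n = flat.size
    if n == 1:
        return np.full_like(values, 0.5)
    ranks = rankdata(flat, method="average")
    return ((ranks - 1.0) / (n - 1.0)).reshape(values.shape)


def temporal_downsample(dfc: DfcMatrix, target_stamps: np.ndarray) -> DfcMatrix:
    """Downsample a per-TR dFC matrix onto a coarser time grid.

    Each output slice is the source slice whose time stamp is nearest to the
    target stamp (ties resolved toward the earlier stamp).  Used to bring
    per-TR methods (TF, CAP, CHMM, WL) onto the sliding-window grid before
    assembly into the common array.
    """
    target = np.asarray(target_stamps, dtype=float)
    src = dfc.time_stamps
    if target.min() < src.min() - 0.5 or target.max() > src.max() + 0.5:
        raise ParameterError(
            f"target stamps [{target.min()}, {target.max()}] outside source "
            f"range [{src.min()}, {src.max()}]"
        )
    # nearest source stamp; ties (exact .5 midpoints) go to the earlier one
    d = np.abs(src[None, :] - target[:, None])
    # argmin returns the first (earlier) index on exact ties
    pick = np.argmin(d, axis=1)
    return DfcMatrix(dfc.subject_id, dfc.method_id, target, dfc.values[pick])


def assembly_manifest(
    subject_ids: Sequence[str], method_ids: Sequence[str]
) -> list[tuple[str, str]]:
    """The (subject, method) cells a complete dFC array must contain."""
    return [(str(s), str(m)) for s in subject_ids for m in method_ids]


def assemble_dfc_array(
    matrices: Sequence[DfcMatrix],
    roi_labels: np.ndarray,
    rsn_labels: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    method_ids: Sequence[str] | None = None,
) -> DfcArray:
    """Assemble per-(subject, method) dFC matrices into the 5-way array.

    All matrices must share one time grid (apply :func:`temporal_downsample`
    first).  Raises :class:`AssemblyError` listing any missing cells.
    """
    if not matrices:
        raise AssemblyError("no dFC matrices to assemble")
    if subject_ids is None:
        subject_ids = list(dict.fromkeys(m.subject_id for m in matrices))
    if method_ids is None:
        method_ids = list(dict.fromkeys(m.method_id for m in matrices))
    cell = {(m.subject_id, m.method_id): m for m in matrices}
    missing = [sm for sm in assembly_manifest(subject_ids, method_ids) if sm not in cell]
    if missing:
        raise AssemblyError(f"missing (subject, method) cells: {missing}")

    ref = matrices[0]
    stamps = ref.time_stamps
    for m in matrices:
        if m.time_stamps.shape != stamps.shape or not np.allclose(m.time_stamps, stamps):
            raise AssemblyError(
                f"time grid of ({m.subject_id}, {m.method_id}) does not match "
                f"({ref.subject_id}, {ref.method_id}); downsample first"
            )
        if m.n_rois != ref.n_rois:
            raise AssemblyError("ROI count differs across matrices")

    s, mth = len(subject_ids), len(method_ids)
    t, r = ref.n_timepoints, ref.n_rois
    values = np.empty((s, mth, t, r, r), dtype=float)
    for a, sid in enumerate(subject_ids):
        for b, mid in enumerate(method_ids):
            values[a, b] = cell[(sid, mid)].values
    return DfcArray(values, list(subject_ids), list(method_ids), stamps,
                    roi_labels, rsn_labels)


def dfc_array_from_connections(
    conn: np.ndarray,
    subject_ids: Sequence[str],
    method_ids: Sequence[str],
    time_stamps: np.ndarray | None = None,
    roi_labels: Sequence[str] | None = None,
    rsn_labels: Sequence[str] | None = None,
    diag: float = 1.0,
) -> DfcArray:
    """Build a DfcArray from connection values of shape (S, M, T, C)."""
    conn = np.asarray(conn, dtype=float)
    if conn.ndim != 4:
        raise ValidationError("expected connection values of shape (S, M, T, C)")
    values = devectorize(conn, diag=diag)
    r = values.shape[-1]
    if time_stamps is None:
        time_stamps = np.arange(conn.shape[2], dtype=float)
    if roi_labels is None:
        roi_labels = [f"roi{i:03d}" for i in range(r)]
    if rsn_labels is None:
        rsn_labels = ["net0"] * r
    return DfcArray(values, list(subject_ids), list(method_ids),
                    time_stamps, list(roi_labels), list(rsn_labels))
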