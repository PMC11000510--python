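"""Ground-truth scoring helpers: Hungarian state matching, label accuracy,
and pattern cosines.

Recovered states carry arbitrary indices (and, for dictionary atoms,
arbitrary signs), so every score first aligns estimated states with the
planted ones by optimal one-to-one assignment before comparing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import vectorize_lower_triangle
from .errors import ParameterError


def covariance_to_correlation(cov: np.ndarray) -> np.ndarray:
    """Rescale a covariance matrix (or stack) to unit diagonal.

    State covariances estimated on globally standardized data carry
    state-dependent diagonal scale; correlation space is the
    scale-invariant arena for comparing them with planted structure.
    """
    cov = np.asarray(cov, dtype=float)
    d = np.sqrt(np.einsum("...ii->...i", cov))
    return cov / (d[..., :, None] * d[..., None, :])


def match_state_fc(
    true_fc: np.ndarray, est_fc: np.ndarray
) -> tuple[np.ndarray, float]:
    """Hungarian-match estimated state FC matrices to planted ones by
    lower-triangle Pearson correlation.

    Returns ``(perm, mean_corr)`` where ``perm[k]`` is the estimated state
    matched to planted state k and ``mean_corr`` the mean matched
    correlation.
    """
    tv = vectorize_lower_triangle(np.asarray(true_fc, dtype=float))
    ev = vectorize_lower_triangle(np.asarray(est_fc, dtype=float))
    if tv.shape[0] > ev.shape[0]:
        raise ParameterError("fewer estimated states than planted states")
    corr = np.corrcoef(np.vstack([tv, ev]))[: tv.shape[0], tv.shape[0]:]
    row, col = linear_sum_assignment(-corr)
    return col, float(corr[row, col].mean())


def label_accuracy(true_labels: np.ndarray, est_labels: np.ndarray) -> float:
    """Best-permutation agreement between two 1-based label sequences."""
    t = np.asarray(true_labels, dtype=int)
    e = np.asarray(est_labels, dtype=int)
    if t.shape != e.shape:
        raise ParameterError("label sequences must have equal length")
    kt, ke = t.max(), e.max()
    confusion = np.zeros((kt, ke))
    np.add.at(confusion, (t - 1, e - 1), 1.0)
    row, col = linear_sum_assignment(-confusion)
    return float(confusion[row, col].sum() / t.size)


def match_patterns(
    true_patterns: np.ndarray, est_patterns: np.ndarray, sign_invariant: bool = True
) -> tuple[np.ndarray, float]:
    """Hungarian-match pattern vectors (rows) by |cosine|.

    Returns ``(perm, mean_abs_cosine)``.  With ``sign_invariant`` the
    cosine magnitude is used, matching methods whose patterns have
    arbitrary polarity (dictionary atoms, centroids of +-patterns).
    """
    t = np.asarray(true_patterns, dtype=float)
    e = np.asarray(est_patterns, dtype=float)
    tn = t / np.linalg.norm(t, axis=1, keepdims=True)
    en = e / np.linalg.norm(e, axis=1, keepdims=True)
    cos = tn @ en.T
    score = np.abs(cos) if sign_invariant else cos
    row, col = linear_sum_assignment(-score)
    return col, float(score[row, col].mean())


def majority_window_labels(
    labels: np.ndarray, starts: np.ndarray, window_len: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Ground-truth label of each window: the (taper-weighted) majority
    state among the TRs the window covers."""
    labels = np.asarray(labels, dtype=int)
    k = labels.max()
    out = np.empty(starts.size, dtype=int)
    w = np.ones(window_len) if weights is None else np.asarray(weights, dtype=float)
    for idx, s in enumerate(starts):
        seg = labels[s : s + window_len]
        votes = np.zeros(k)
        np.add.at(votes, seg - 1, w[: seg.size])
        out[idx] = int(np.argmax(votes)) + 1
    return out
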