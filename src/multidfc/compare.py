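"""Method-comparison framework: similarity at four levels, hierarchical
method grouping, variance decomposition, and a time-shuffled null.

Similarity between each pair of methods is computed per subject and then
averaged across subjects:

* overall   -- metric between the flattened T x C connection arrays;
* spatial   -- metric between the C-length FC vectors at each time point,
               averaged over time, then subjects;
* temporal  -- metric between the T-length time courses of each
               connection, averaged over connections, then subjects
               (zero-variance time courses are excluded, never imputed);
* intersubject -- per method, the S(S-1)/2 correlations between subjects'
               flattened dFC; then the metric between methods'
               intersubject-correlation vectors.

Metrics: Spearman (Pearson on average ranks), Pearson, Euclidean distance,
and mutual information (rank transform, 10 equal-frequency bins, bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .containers import DfcArray
from .core import rank_normalize
from .errors import ParameterError, ValidationError

METRICS = ("spearman", "pearson", "euclidean", "mutual_information")
CORRELATION_METRICS = ("spearman", "pearson")

LEVELS = ("overall", "spatial", "temporal", "intersubject")


@dataclass
class SimilarityResult:
    """Method x method similarity matrix at one comparison level."""

    level: str
    metric: str
    matrix: np.ndarray
    method_ids: np.ndarray
    per_subject: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.method_ids = np.asarray(self.method_ids, dtype=str)
        m = self.method_ids.size
        if self.matrix.shape != (m, m):
            raise ValidationError("similarity matrix shape mismatch")


@dataclass
class MethodGrouping:
    """Ward-linkage grouping of methods at 0.7 x the maximum merge height."""

    linkage_matrix: np.ndarray
    cutoff: float
    group_labels: np.ndarray
    method_ids: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.group_labels.max())

    def groups(self) -> list[set[str]]:
        return [
            {str(m) for m in self.method_ids[self.group_labels == g]}
            for g in range(1, self.n_groups + 1)
        ]


@dataclass
class VarianceRatios:
    """Variance of dFC over method vs. over time vs. over subject."""

    var_time: np.ndarray      # (S, C): variance over time, averaged over method
    var_method: np.ndarray    # (S, C): variance over method, averaged over time
    var_subj: np.ndarray      # (C,):   variance over subject, avg over time+method
    var_method_conn: np.ndarray  # (C,): variance over method, avg over time+subject
    mean_ratio_method_time: float
    mean_ratio_sd_method_time: float
    mean_ratio_method_subj: float
    mean_ratio_sd_method_subj: float
    rsn_pair_ratio: np.ndarray   # (n_rsn, n_rsn): mean-variance ratio - 1
    rsn_names: np.ndarray


# ---------------------------------------------------------------------------
# metric primitives

def mutual_information_metric(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Mutual information (bits) after rank transform and equal-frequency
    binning.  Identical vectors give log2(bins) when the length is a
    multiple of ``bins``."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError("vectors must have equal length")
    n = x.size
    if n < bins * bins:
        warnings.warn(f"MI estimate unstable: n={n} < bins^2={bins * bins}")
    bx = ((rankdata(x, method="ordinal") - 1) * bins) // n
    by = ((rankdata(y, method="ordinal") - 1) * bins) // n
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx.astype(int), by.astype(int)), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, -1, x)


def _normalized_rows(x: np.ndarray) -> np.ndarray:
    """Center and unit-normalize the last axis; zero-variance rows -> NaN."""
    xc = x - x.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(xc, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return xc / norm


def _pairwise_from_rows(rows: np.ndarray, metric: str, bins: int = 10) -> np.ndarray:
    """(M, L) row vectors -> (M, M) similarity/distance matrix."""
    m = rows.shape[0]
    if metric in CORRELATION_METRICS:
        data = _rank_rows(rows) if metric == "spearman" else rows
        z = _normalized_rows(data)
        out = z @ z.T
        np.fill_diagonal(out, 1.0)
        return np.clip((out + out.T) / 2.0, -1.0, 1.0)
    if metric == "euclidean":
        sq = ((rows[:, None, :] - rows[None]) ** 2).sum(-1)
        return np.sqrt(np.maximum(sq, 0.0))
    if metric == "mutual_information":
        out = np.empty((m, m))
        for i in range(m):
            out[i, i] = mutual_information_metric(rows[i], rows[i], bins)
            for j in range(i):
                out[i, j] = out[j, i] = mutual_information_metric(rows[i], rows[j], bins)
        return out
    raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")


# ---------------------------------------------------------------------------
# similarity levels

def overall_similarity(arr: DfcArray, metric: str = "spearman") -> SimilarityResult:
    """Per subject, compare the flattened (T x C) arrays of each method
    pair; average the M x M matrix over subjects."""
    _check_metric(metric)
    conn = arr.to_connections()
    s, m = conn.shape[:2]
    per_subject = np.empty((s, m, m))
    for a in range(s):
        rows = conn[a].reshape(m, -1)
        if metric in CORRELATION_METRICS and np.any(rows.std(axis=1) == 0):
            warnings.warn("constant flattened dFC vector; correlation undefined")
        per_subject[a] = _pairwise_from_rows(rows, metric)
    return SimilarityResult(
        "overall", metric, per_subject.mean(axis=0), arr.method_ids, per_subject
    )


def spatial_similarity(arr: DfcArray, metric: str = "spearman") -> SimilarityResult:
    """Metric between the two C-length FC vectors of each method pair at
    each time point; averaged over time, then subjects."""
    _check_metric(metric)
    conn = arr.to_connections()
    s, m, t, _ = conn.shape
    per_subject = np.empty((s, m, m))
    for a in range(s):
        if metric in CORRELATION_METRICS:
            data = (
                np.apply_along_axis(rankdata, -1, conn[a])
                if metric == "spearman"
                else conn[a]
            )
            z = _normalized_rows(data)  # (m, t, c)
            sims = np.einsum("itc,jtc->ijt", np.nan_to_num(z), np.nan_to_num(z))
            mat = sims.mean(axis=-1)
            np.fill_diagonal(mat, 1.0)
            per_subject[a] = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
        else:
            acc = np.zeros((m, m))
            for k in range(t):
                acc += _pairwise_from_rows(conn[a, :, k, :], metric)
            per_subject[a] = acc / t
    return SimilarityResult(
        "spatial", metric, per_subject.mean(axis=0), arr.method_ids, per_subject
    )


def temporal_similarity(arr: DfcArray, metric: str = "spearman") -> SimilarityResult:
    """Metric between the T-length time courses of each connection;
    averaged over connections (NaN excluded), then subjects."""
    _check_metric(metric)
    conn = arr.to_connections()  # (s, m, t, c)
    s, m, t, c = conn.shape
    per_subject = np.empty((s, m, m))
    excluded = 0
    for a in range(s):
        series = np.moveaxis(conn[a], 1, 2)  # (m, c, t)
        if metric in CORRELATION_METRICS:
            data = (
                np.apply_along_axis(rankdata, -1, series)
                if metric == "spearman"
                else series
            )
            z = _normalized_rows(data)  # NaN rows where variance is zero
            sims = np.einsum("ict,jct->ijc", np.nan_to_num(z), np.nan_to_num(z))
            bad = np.isnan(z).any(axis=-1)  # (m, c)
            pair_bad = bad[:, None, :] | bad[None, :, :]
            excluded += int(pair_bad.sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mat = np.nanmean(np.where(pair_bad, np.nan, sims), axis=-1)
            if np.any(np.isnan(mat)):
                warnings.warn(
                    "temporal similarity undefined for some method pair "
                    "(every connection excluded); recorded as NaN"
                )
            np.fill_diagonal(mat, 1.0)
            per_subject[a] = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
        else:
            acc = np.zeros((m, m))
            for k in range(c):
                acc += _pairwise_from_rows(series[:, k, :], metric)
            per_subject[a] = acc / c
    return SimilarityResult(
        "temporal",
        metric,
        per_subject.mean(axis=0),
        arr.method_ids,
        per_subject,
        info={"excluded_connection_pairs": excluded},
    )


def intersubject_similarity(
    arr: DfcArray, metric: str = "spearman", feature: str = "dfc"
) -> SimilarityResult:
    """Similarity of the methods' intersubject-correlation structure.

    Per method, Pearson correlations between all S(S-1)/2 subject pairs of
    flattened dFC are computed; the metric is then applied between the
    methods' intersubject-correlation vectors.  ``feature='fo'`` uses the
    fractional-occupancy-like column-mean feature instead of the full
    flattened dFC (see methods note).
    """
    _check_metric(metric)
    conn = arr.to_connections()
    s, m = conn.shape[:2]
    if s < 3:
        raise ParameterError("intersubject similarity requires at least 3 subjects")
    iu = np.triu_indices(s, k=1)
    vectors = np.empty((m, iu[0].size))
    for b in range(m):
        if feature == "dfc":
            flat = conn[:, b].reshape(s, -1)
        elif feature == "fo":
            flat = conn[:, b].mean(axis=-1)  # (s, t) temporal profile
        else:
            raise ParameterError("feature must be 'dfc' or 'fo'")
        corr = np.corrcoef(flat)
        vectors[b] = corr[iu]
    matrix = _pairwise_from_rows(vectors, metric)
    return SimilarityResult("intersubject", metric, matrix, arr.method_ids, None)


SIMILARITY_LEVELS = {
    "overall": overall_similarity,
    "spatial": spatial_similarity,
    "temporal": temporal_similarity,
    "intersubject": intersubject_similarity,
}


# ---------------------------------------------------------------------------
# grouping and variance decomposition

def similarity_to_distance(sim: SimilarityResult) -> np.ndarray:
    """Convert a similarity matrix to a clustering distance matrix:
    1 - corr for correlation metrics, raw distance for Euclidean, and
    max(MI) - MI for mutual information."""
    mat = sim.matrix
    if np.any(np.isnan(mat)):
        raise ValidationError(
            "similarity matrix contains NaN; recompute or impute before grouping"
        )
    if sim.metric in CORRELATION_METRICS:
        dist = 1.0 - mat
    elif sim.metric == "euclidean":
        dist = mat.copy()
    else:
        dist = mat.max() - mat
    np.fill_diagonal(dist, 0.0)
    return np.maximum((dist + dist.T) / 2.0, 0.0)


def group_methods(sim: SimilarityResult, cutoff_fraction: float = 0.7) -> MethodGrouping:
    """Ward hierarchical clustering of methods with flat groups cut at
    ``cutoff_fraction`` x the maximum merge height."""
    dist = similarity_to_distance(sim)
    z = linkage(squareform(dist, checks=False), method="ward")
    condensed = squareform(dist, checks=False)
    if np.ptp(condensed) < 1e-12:
        # perfectly uniform similarity carries no structure: one group
        cutoff = float(z[:, 2].max())
        labels = np.ones(sim.method_ids.size, dtype=int)
        return MethodGrouping(z, cutoff, labels, sim.method_ids)
    cutoff = cutoff_fraction * z[:, 2].max()
    labels = fcluster(z, t=cutoff, criterion="distance")
    return MethodGrouping(z, float(cutoff), labels, sim.method_ids)


def variance_decomposition(arr: DfcArray) -> VarianceRatios:
    """Variance of rank-normalized dFC over method vs. time vs. subject.

    Values are first rank-normalized jointly over time x connections within
    each (subject, method) so different value distributions become
    comparable.  Variances use the unbiased (ddof = 1) convention -- with
    only 7 methods the 1/n convention would bias the method variance down
    by (M-1)/M and break the exchangeability null.  Ratio summaries
    average the per-cell ratios; cells with zero denominator are excluded.
    The RSN-pair matrix averages the variances over the connections within
    each RSN pair before taking the ratio, minus 1.
    """
    conn = arr.to_connections()
    s, m, t, c = conn.shape
    if m < 2 or t < 2:
        raise ParameterError("variance decomposition needs >= 2 methods and time points")
    ranked = np.empty_like(conn)
    for a in range(s):
        for b in range(m):
            ranked[a, b] = rank_normalize(conn[a, b])

    var_time = ranked.var(axis=2, ddof=1).mean(axis=1)          # (s, c)
    var_method = ranked.var(axis=1, ddof=1).mean(axis=1)        # (s, c)
    var_subj = (
        ranked.var(axis=0, ddof=1).mean(axis=(0, 1)) if s > 1 else np.zeros(c)
    )
    var_method_conn = ranked.var(axis=1, ddof=1).mean(axis=(0, 1))  # (c,)

    def _mean_ratio(num: np.ndarray, den: np.ndarray) -> float:
        ok = den > 0
        if not np.any(ok):
            return float("nan")
        return float(np.mean(num[ok] / den[ok]))

    ratios = VarianceRatios(
        var_time=var_time,
        var_method=var_method,
        var_subj=var_subj,
        var_method_conn=var_method_conn,
        mean_ratio_method_time=_mean_ratio(var_method, var_time),
        mean_ratio_sd_method_time=_mean_ratio(np.sqrt(var_method), np.sqrt(var_time)),
        mean_ratio_method_subj=(
            _mean_ratio(var_method_conn, var_subj) if s > 1 else float("nan")
        ),
        mean_ratio_sd_method_subj=(
            _mean_ratio(np.sqrt(var_method_conn), np.sqrt(var_subj))
            if s > 1
            else float("nan")
        ),
        rsn_pair_ratio=np.empty(0),
        rsn_names=np.empty(0, dtype=str),
    )

    rsns = list(dict.fromkeys(arr.rsn_labels))
    i, j = np.tril_indices(arr.n_rois, k=-1)
    conn_rsn_i = np.asarray([rsns.index(arr.rsn_labels[a]) for a in i])
    conn_rsn_j = np.asarray([rsns.index(arr.rsn_labels[b]) for b in j])
    n_rsn = len(rsns)
    pair_mat = np.full((n_rsn, n_rsn), np.nan)
    for p in range(n_rsn):
        for q in range(p + 1):
            mask = ((conn_rsn_i == p) & (conn_rsn_j == q)) | (
                (conn_rsn_i == q) & (conn_rsn_j == p)
            )
            if not np.any(mask):
                continue
            vm = var_method[:, mask].mean()
            vt = var_time[:, mask].mean()
            if vt > 0:
                pair_mat[p, q] = pair_mat[q, p] = vm / vt - 1.0
    ratios.rsn_pair_ratio = pair_mat
    ratios.rsn_names = np.asarray(rsns, dtype=str)
    return ratios


def time_shuffle_null(
    arr: DfcArray,
    n_perm: int = 100,
    seed: int = 0,
    metric: str = "spearman",
) -> dict:
    """Permutation null for overall similarity that preserves occupancy.

    Each permutation independently shuffles the time axis of every
    (subject, method) slice -- a pure time permutation, so state
    fractional occupancy is preserved exactly -- and recomputes the
    subject-averaged overall similarity.  One-sided p-values use the
    add-one convention: p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    observed = overall_similarity(arr, metric).matrix
    conn = arr.to_connections()
    s, m, t, c = conn.shape
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, m, m))
    for p in range(n_perm):
        shuffled = np.empty_like(conn)
        for a in range(s):
            for b in range(m):
                shuffled[a, b] = conn[a, b, rng.permutation(t)]
        per_subject = np.empty((s, m, m))
        for a in range(s):
            per_subject[a] = _pairwise_from_rows(shuffled[a].reshape(m, -1), metric)
        null[p] = per_subject.mean(axis=0)
    exceed = (null >= observed[None]).sum(axis=0)
    p_values = (1.0 + exceed) / (n_perm + 1.0)
    return {"observed": observed, "null": null, "p_values": p_values,
            "method_ids": arr.method_ids}
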