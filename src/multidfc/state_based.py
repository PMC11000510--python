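"""State-based dFC estimators under a group-fit / subject-apply contract.

All five methods assume a finite set of group-level FC states that recur
over time and across subjects.  ``fit`` consumes the time series of every
subject (concatenated where the model requires it, with no transition
counted across subject boundaries), producing a :class:`StateSet` of K
state FC matrices; ``apply`` assigns each time point of one subject to a
state by the method's native rule and places the state FC matrix at those
time points to build the subject's dFC matrix.

Methods
    CAP   two-level k-means on per-TR activity vectors; state FC = outer
          product of the group centroid with itself (rank 1).
    SWC   two-level k-means on vectorized sliding-window FC; state FC =
          centroid devectorized with unit diagonal; 38-window grid.
    CHMM  Gaussian hidden Markov model on the BOLD series; state FC = the
          state covariance; Viterbi state time courses.
    DHMM  categorical HMM whose observation symbols are SWC state labels
          (n_obs = round(K * 16/24) symbols); state FC = mean of the
          clustering-method dFC slices assigned to each hidden state.
    WL    k-SVD sparse dictionary learning with one atom per time point;
          state FC = outer product of the atom (rank 1).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from hmmlearn.hmm import CategoricalHMM, GaussianHMM
from sklearn.cluster import KMeans

from .containers import DfcMatrix, ParcellatedTimeSeries, StateSet, StateTimeCourse
from .core import devectorize, vectorize_lower_triangle
from .errors import FitError, ParameterError, ValidationError
from .state_free import TaperedWindow, make_tapered_window, sliding_window_dfc

DEFAULT_N_STATES = 12
DEFAULT_SUBJECT_CLUSTERS = 20
OBS_TO_STATE_RATIO = 16.0 / 24.0


def fractional_occupancy(labels: np.ndarray, n_states: int) -> np.ndarray:
    """FO[k] = fraction of time points with (1-based) label k; sums to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > n_states:
        raise ValidationError(f"labels outside 1..{n_states}")
    return np.bincount(labels - 1, minlength=n_states) / labels.size


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def two_level_kmeans(
    samples_per_subject: Sequence[np.ndarray],
    k_subject: int = DEFAULT_SUBJECT_CLUSTERS,
    k_group: int = DEFAULT_N_STATES,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Two-stage k-means: subject-level centroids, then group clustering.

    Stage 1 clusters each subject's samples into ``k_subject`` centroids
    (lowered with a warning when a subject has fewer samples); stage 2
    clusters the pooled centroids into ``k_group`` group centroids.  Every
    original sample is then assigned to its nearest group centroid
    (Euclidean).  Returns ``(group_centroids, labels_per_subject)`` with
    0-based labels.
    """
    if k_group < 2:
        raise ParameterError("k_group must be at least 2")
    seeds = _child_seeds(seed, len(samples_per_subject) + 1)
    pooled = []
    for s, samples in enumerate(samples_per_subject):
        samples = np.asarray(samples, dtype=float)
        k = k_subject
        if samples.shape[0] < k_subject:
            k = samples.shape[0]
            warnings.warn(
                f"subject {s}: only {k} samples; lowering k_subject from {k_subject}"
            )
        km = KMeans(n_clusters=k, n_init=10, random_state=seeds[s])
        km.fit(samples)
        pooled.append(km.cluster_centers_)
    pooled = np.vstack(pooled)
    if k_group > pooled.shape[0]:
        raise ParameterError(
            f"k_group={k_group} exceeds {pooled.shape[0]} pooled subject centroids"
        )
    km_group = KMeans(n_clusters=k_group, n_init=10, random_state=seeds[-1])
    km_group.fit(pooled)
    centroids = km_group.cluster_centers_
    labels = [
        np.argmin(
            ((np.asarray(s, dtype=float)[:, None, :] - centroids[None]) ** 2).sum(-1),
            axis=1,
        )
        for s in samples_per_subject
    ]
    return centroids, labels


def _nearest_centroid(samples: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d = ((samples[:, None, :] - centroids[None]) ** 2).sum(-1)
    return np.argmin(d, axis=1)


class _StateBasedEstimator:
    """Shared fit/apply plumbing for the five state-based methods."""

    method_id: str = ""

    def __init__(self, n_states: int = DEFAULT_N_STATES, seed: int = 0) -> None:
        if n_states < 2:
            raise ParameterError("n_states must be at least 2")
        self.n_states = n_states
        self.seed = seed
        self.state_set_: StateSet | None = None

    # -- subclass hooks -------------------------------------------------
    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        raise NotImplementedError

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        """Return (0-based labels, time stamps) for one subject."""
        raise NotImplementedError

    # -- public contract ------------------------------------------------
    def fit(self, ts_list: Sequence[ParcellatedTimeSeries]) -> "_StateBasedEstimator":
        if not ts_list:
            raise ParameterError("fit requires at least one subject")
        self._fit_impl(ts_list)
        return self

    def _check_fitted(self) -> StateSet:
        if self.state_set_ is None:
            raise FitError(f"{self.method_id}: call fit before apply")
        return self.state_set_

    def apply(
        self, ts: ParcellatedTimeSeries
    ) -> tuple[StateTimeCourse, DfcMatrix]:
        """Assign each time point of one subject to a group state and place
        the state FC matrix at those time points."""
        state_set = self._check_fitted()
        if ts.n_rois != state_set.n_rois:
            raise ValidationError(
                f"{self.method_id}: model has {state_set.n_rois} ROIs, "
                f"subject has {ts.n_rois}"
            )
        labels0, stamps = self._assign(ts)
        course = StateTimeCourse(ts.subject_id, labels0 + 1, state_set.n_states)
        dfc = DfcMatrix(
            ts.subject_id, self.method_id, stamps, state_set.state_fc[labels0]
        )
        return course, dfc


class CAP(_StateBasedEstimator):
    """Coactivation patterns: k-means on per-TR activity vectors."""

    method_id = "CAP"

    def __init__(
        self,
        n_states: int = DEFAULT_N_STATES,
        n_subject_clusters: int = DEFAULT_SUBJECT_CLUSTERS,
        seed: int = 0,
    ) -> None:
        super().__init__(n_states, seed)
        self.n_subject_clusters = n_subject_clusters

    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        samples = [ts.values for ts in ts_list]
        centroids, _ = two_level_kmeans(
            samples, self.n_subject_clusters, self.n_states, self.seed
        )
        self.centroids_ = centroids
        state_fc = np.einsum("ki,kj->kij", centroids, centroids)
        self.state_set_ = StateSet(self.method_id, state_fc, self.seed)

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        labels = _nearest_centroid(ts.values, self.centroids_)
        return labels, np.arange(ts.n_timepoints, dtype=float)


class SWC(_StateBasedEstimator):
    """Sliding-window + clustering: k-means on vectorized window FC."""

    method_id = "SWC"

    def __init__(
        self,
        n_states: int = DEFAULT_N_STATES,
        n_subject_clusters: int = DEFAULT_SUBJECT_CLUSTERS,
        window: TaperedWindow | None = None,
        seed: int = 0,
    ) -> None:
        super().__init__(n_states, seed)
        self.n_subject_clusters = n_subject_clusters
        self.window = window if window is not None else make_tapered_window()

    def _window_features(
        self, ts: ParcellatedTimeSeries
    ) -> tuple[np.ndarray, np.ndarray]:
        sw = sliding_window_dfc(ts, self.window)
        return vectorize_lower_triangle(sw.values), sw.time_stamps

    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        feats = [self._window_features(ts)[0] for ts in ts_list]
        centroids, _ = two_level_kmeans(
            feats, self.n_subject_clusters, self.n_states, self.seed
        )
        self.centroids_ = centroids
        state_fc = devectorize(centroids, diag=1.0)
        self.state_set_ = StateSet(self.method_id, state_fc, self.seed)

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        feats, stamps = self._window_features(ts)
        return _nearest_centroid(feats, self.centroids_), stamps


class CHMM(_StateBasedEstimator):
    """Gaussian HMM on the BOLD series; state FC = state covariance."""

    method_id = "CHMM"

    def __init__(
        self,
        n_states: int = DEFAULT_N_STATES,
        n_iter: int = 100,
        tol: float = 1e-3,
        n_init: int = 5,
        seed: int = 0,
    ) -> None:
        super().__init__(n_states, seed)
        self.n_iter = n_iter
        self.tol = tol
        self.n_init = n_init

    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        # Baum-Welch is initialization-sensitive (covariance-only regimes
        # give k-means mean-initialization nothing to work with), so run
        # several EM starts and keep the highest final log-likelihood.
        x = np.vstack([ts.values for ts in ts_list])
        lengths = [ts.n_timepoints for ts in ts_list]
        best, best_ll, best_meta = None, -np.inf, None
        last_err: Exception | None = None
        for attempt, s in enumerate(_child_seeds(self.seed, self.n_init)):
            model = GaussianHMM(
                n_components=self.n_states,
                covariance_type="full",
                n_iter=self.n_iter,
                tol=self.tol,
                random_state=s,
                min_covar=1e-3,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(x, lengths)
                    ll = model.score(x, lengths)
            except (ValueError, np.linalg.LinAlgError) as err:
                last_err = err
                continue
            if ll > best_ll:
                best, best_ll = model, ll
                best_meta = {
                    "converged": bool(model.monitor_.converged),
                    "iterations": int(model.monitor_.iter),
                    "attempt": attempt,
                    "log_likelihood": float(ll),
                }
        if best is None:
            raise FitError(f"CHMM fit failed in all {self.n_init} starts: {last_err}")
        covs = best.covars_.copy()
        for k in range(self.n_states):
            if np.linalg.eigvalsh(covs[k])[0] <= 0:
                covs[k] += 1e-6 * np.eye(covs.shape[1])
            if np.linalg.eigvalsh(covs[k])[0] <= 0:
                raise FitError("non-SPD state covariance after ridge")
        self.model_ = best
        self.state_set_ = StateSet(self.method_id, covs, self.seed, metadata=best_meta)

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        labels = self.model_.predict(ts.values)  # Viterbi decoding
        return labels, np.arange(ts.n_timepoints, dtype=float)


class DHMM(_StateBasedEstimator):
    """Categorical HMM on SWC state label sequences.

    The number of observation symbols follows the 16/24 observation-to-state
    ratio: ``n_obs = round(n_states * 16/24)`` (8 symbols for 12 states).
    Hidden states left empty by Viterbi decoding are dropped with a warning
    and the remaining states renumbered (recorded in metadata).
    """

    method_id = "DHMM"

    def __init__(
        self,
        n_states: int = DEFAULT_N_STATES,
        obs_to_state_ratio: float = OBS_TO_STATE_RATIO,
        n_obs: int | None = None,
        n_subject_clusters: int = DEFAULT_SUBJECT_CLUSTERS,
        window: TaperedWindow | None = None,
        n_iter: int = 100,
        seed: int = 0,
    ) -> None:
        super().__init__(n_states, seed)
        if n_obs is None:
            n_obs = max(2, int(round(n_states * obs_to_state_ratio)))
        self.n_obs = n_obs
        seeds = _child_seeds(seed, 2)
        self.swc_ = SWC(
            n_states=n_obs,
            n_subject_clusters=n_subject_clusters,
            window=window,
            seed=seeds[0],
        )
        self.n_iter = n_iter
        self._hmm_seed = seeds[1]

    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        self.swc_.fit(ts_list)
        obs, window_dfc, lengths = [], [], []
        for ts in ts_list:
            labels0, _ = self.swc_._assign(ts)
            obs.append(labels0)
            window_dfc.append(self.swc_.state_set_.state_fc[labels0])
            lengths.append(labels0.size)
        x = np.concatenate(obs)[:, None]
        model = CategoricalHMM(
            n_components=self.n_states,
            n_iter=self.n_iter,
            random_state=self._hmm_seed,
        )
        model.n_features = self.n_obs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, lengths)
        self.model_ = model

        hidden = np.concatenate([model.predict(o[:, None]) for o in obs])
        slices = np.concatenate(window_dfc, axis=0)
        r = slices.shape[1]
        occupied = sorted(set(hidden.tolist()))
        if len(occupied) < 2:
            raise FitError("DHMM decoding collapsed onto a single hidden state")
        dropped = [k for k in range(self.n_states) if k not in occupied]
        if dropped:
            warnings.warn(f"DHMM: dropping empty hidden state(s) {dropped}")
        state_fc = np.stack([slices[hidden == k].mean(axis=0) for k in occupied])
        self._relabel = {old: new for new, old in enumerate(occupied)}
        self.state_set_ = StateSet(
            self.method_id,
            state_fc,
            self.seed,
            metadata={"dropped_states": dropped, "n_obs": self.n_obs},
        )

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        obs, stamps = self.swc_._assign(ts)
        hidden = self.model_.predict(obs[:, None])
        # map decoded hidden states through the post-fit renumbering;
        # states unseen at fit time collapse to the nearest occupied one
        occupied = np.array(sorted(self._relabel), dtype=int)
        snapped = occupied[np.argmin(np.abs(hidden[:, None] - occupied[None]), axis=1)]
        labels = np.array([self._relabel[int(k)] for k in snapped])
        return labels, stamps


def ksvd_one_sparse(
    x: np.ndarray, n_atoms: int, seed: int = 0, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """k-SVD with hard sparsity T0 = 1 (one atom per sample).

    ``x`` has samples in rows.  Alternates (a) assigning each sample to the
    atom maximizing |<d_k, x>| with coefficient <d_k, x>, and (b) updating
    each atom (and its coefficients) as the leading singular pair of its
    assigned samples.  Both steps are monotone in the reconstruction error
    ||X - D M^T||_F^2, which is tracked per iteration.  Dead atoms are
    reinitialized from the currently worst-represented sample.

    Returns ``(dictionary (R, K) with unit-norm columns, coefficients,
    0-based labels, info)``.
    """
    x = np.asarray(x, dtype=float)
    n, r = x.shape
    if n_atoms < 1 or n_atoms > n:
        raise ParameterError("n_atoms must be in 1..n_samples")
    rng = np.random.default_rng(seed)
    init = rng.choice(n, size=n_atoms, replace=False)
    d = x[init].T.copy()
    norms = np.linalg.norm(d, axis=0)
    norms[norms == 0] = 1.0
    d /= norms

    total_energy = float((x**2).sum())
    objective: list[float] = []
    labels = np.full(n, -1)
    coef = np.zeros(n)
    for _ in range(max_iter):
        proj = x @ d
        new_labels = np.argmax(np.abs(proj), axis=1)
        coef = proj[np.arange(n), new_labels]
        err = total_energy - float((coef**2).sum())
        objective.append(err)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(n_atoms):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                resid = (x**2).sum(axis=1) - coef**2
                worst = int(np.argmax(resid))
                atom = x[worst]
                nrm = np.linalg.norm(atom)
                d[:, k] = atom / nrm if nrm > 0 else d[:, k]
                continue
            block = x[members]
            # leading singular pair of the member block
            u, s, vt = np.linalg.svd(block.T, full_matrices=False)
            d[:, k] = u[:, 0]
            coef[members] = s[0] * vt[0]
        if len(objective) > 1 and abs(objective[-2] - objective[-1]) < tol:
            break

    # sign convention: largest-magnitude element of each atom positive
    for k in range(n_atoms):
        j = int(np.argmax(np.abs(d[:, k])))
        if d[j, k] < 0:
            d[:, k] = -d[:, k]
    proj = x @ d
    labels = np.argmax(np.abs(proj), axis=1)
    coef = proj[np.arange(n), labels]
    info = {"objective": objective, "iterations": len(objective)}
    return d, coef, labels, info


class WL(_StateBasedEstimator):
    """Window-less method: one-sparse k-SVD dictionary learning."""

    method_id = "WL"

    def __init__(
        self, n_states: int = DEFAULT_N_STATES, max_iter: int = 50, seed: int = 0
    ) -> None:
        super().__init__(n_states, seed)
        self.max_iter = max_iter

    def _fit_impl(self, ts_list: Sequence[ParcellatedTimeSeries]) -> None:
        x = np.vstack([ts.values for ts in ts_list])
        d, _, _, info = ksvd_one_sparse(x, self.n_states, self.seed, self.max_iter)
        self.dictionary_ = d
        state_fc = np.einsum("ik,jk->kij", d, d)
        self.state_set_ = StateSet(self.method_id, state_fc, self.seed, metadata=info)

    def _assign(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        proj = ts.values @ self.dictionary_
        labels = np.argmax(np.abs(proj), axis=1)
        return labels, np.arange(ts.n_timepoints, dtype=float)


STATE_BASED_ESTIMATORS = {
    "CAP": CAP,
    "SWC": SWC,
    "CHMM": CHMM,
    "DHMM": DHMM,
    "WL": WL,
}
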