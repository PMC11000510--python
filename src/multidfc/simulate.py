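"""Synthetic BOLD generator with planted connectivity states.

The generator emulates the data regime the toolbox targets: multi-subject
parcellated resting-state BOLD (T = 1,200 TRs at TR = 0.72 s by default)
whose connectivity switches between K latent states according to a
first-order Markov chain.  Each state is a multivariate Gaussian with its
own mean activity pattern and covariance (built from within/between-RSN
correlation blocks), plus isotropic observation noise.  A stationary
(K = 1) variant provides the null against which dFC fluctuations can be
judged.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DfcArray, ParcellatedTimeSeries
from .core import dfc_array_from_connections, n_connections
from .errors import ParameterError, ValidationError

DEFAULT_TR_SECONDS = 0.72


def make_block_covariance(
    rsn_sizes: list[int] | np.ndarray,
    within_r: float = 0.5,
    between_r: float = 0.0,
    eig_floor: float = 1e-6,
) -> np.ndarray:
    """Correlation matrix with within-RSN blocks at ``within_r`` and
    ``between_r`` elsewhere, unit diagonal, SPD enforced by an eigenvalue
    floor followed by diagonal renormalization."""
    if not (abs(within_r) < 1 and abs(between_r) < 1 and within_r >= between_r):
        raise ParameterError("require |r| < 1 and within_r >= between_r")
    sizes = np.asarray(rsn_sizes, dtype=int)
    r = int(sizes.sum())
    mat = np.full((r, r), between_r)
    start = 0
    for size in sizes:
        mat[start : start + size, start : start + size] = within_r
        start += size
    np.fill_diagonal(mat, 1.0)
    vals, vecs = np.linalg.eigh(mat)
    if vals[0] < eig_floor:
        vals = np.maximum(vals, eig_floor)
        mat = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise ValidationError("block covariance not SPD after repair")
    return (mat + mat.T) / 2.0


@dataclass
class SyntheticSpec:
    """Parameters of the Markov-switching Gaussian BOLD generator."""

    n_subjects: int
    n_rois: int
    n_states: int
    transition: np.ndarray
    state_covariances: np.ndarray
    state_means: np.ndarray
    rsn_partition: np.ndarray
    n_timepoints: int = 1200
    tr_seconds: float = DEFAULT_TR_SECONDS
    observation_noise_sd: float = 0.1
    hemispheres: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.rsn_partition = np.asarray(self.rsn_partition, dtype=str)
        k, r = self.n_states, self.n_rois
        if self.transition.shape != (k, k) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ) or np.any(self.transition < 0):
            raise ParameterError("transition must be a K x K row-stochastic matrix")
        if self.state_covariances.shape != (k, r, r):
            raise ParameterError("state_covariances must have shape (K, R, R)")
        for cov in self.state_covariances:
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ParameterError("state covariances must be SPD")
        if self.state_means.shape != (k, r):
            raise ParameterError("state_means must have shape (K, R)")
        if self.rsn_partition.shape != (r,):
            raise ParameterError("rsn_partition must label every ROI exactly once")
        if self.observation_noise_sd < 0:
            raise ParameterError("observation_noise_sd must be >= 0")
        if self.hemispheres is None:
            # alternate L/R so hemisphere-balanced selection stays exercised
            self.hemispheres = np.asarray(
                ["L" if i % 2 == 0 else "R" for i in range(r)], dtype=str
            )

    @property
    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


def _simulate_chain(
    rng: np.random.Generator, transition: np.ndarray, pi: np.ndarray, n: int
) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    labels[0] = rng.choice(transition.shape[0], p=pi)
    for t in range(1, n):
        labels[t] = rng.choice(transition.shape[0], p=transition[labels[t - 1]])
    return labels


def generate_markov_bold(
    spec: SyntheticSpec,
) -> tuple[list[ParcellatedTimeSeries], list[np.ndarray]]:
    """Simulate every subject's BOLD series and return the hidden state
    labels (1-based) alongside.

    The chain starts from its stationary distribution; at each TR the
    observation is drawn from the active state's Gaussian plus isotropic
    noise.  Deterministic given ``spec.seed``.
    """
    pi = spec.stationary_distribution
    chols = np.stack([np.linalg.cholesky(c) for c in spec.state_covariances])
    roi_labels = [f"roi{i:03d}" for i in range(spec.n_rois)]
    subjects, truths = [], []
    ss = np.random.SeedSequence(spec.seed)
    for s, child in enumerate(ss.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        labels = _simulate_chain(rng, spec.transition, pi, spec.n_timepoints)
        z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
        values = np.einsum("tj,tij->ti", z, chols[labels])
        values += spec.state_means[labels]
        if spec.observation_noise_sd > 0:
            values += spec.observation_noise_sd * rng.standard_normal(values.shape)
        subjects.append(
            ParcellatedTimeSeries(
                f"sub-{s:03d}", spec.tr_seconds, values,
                roi_labels, spec.rsn_partition, spec.hemispheres,
            )
        )
        truths.append(labels + 1)
    return subjects, truths


def generate_stationary_bold(spec: SyntheticSpec) -> list[ParcellatedTimeSeries]:
    """Single-state (stationary) Gaussian BOLD; the dFC null."""
    if spec.n_states != 1:
        raise ParameterError("stationary generator requires n_states == 1")
    subjects, _ = generate_markov_bold(spec)
    return subjects


# ---------------------------------------------------------------------------
# ready-made specs at the default study conditions

def default_rsn_partition(n_rois: int, n_rsns: int = 3) -> np.ndarray:
    """ROIs split into ``n_rsns`` contiguous, nearly equal RSN blocks."""
    sizes = [n_rois // n_rsns + (1 if i < n_rois % n_rsns else 0) for i in range(n_rsns)]
    labels = []
    for i, size in enumerate(sizes):
        labels.extend([f"net{i}"] * size)
    return np.asarray(labels, dtype=str)


def markov_covariance_spec(
    n_subjects: int = 10,
    n_rois: int = 12,
    n_states: int = 3,
    n_timepoints: int = 1200,
    self_transition: float = 0.95,
    within_r: float = 0.9,
    off_state_r: float = 0.1,
    observation_noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticSpec:
    """Covariance-contrast fixture: state k strengthens the k-th RSN block.

    States share zero means and differ only in which RSN block carries the
    strong within-block correlation, so recovery exercises the
    second-order (covariance-sensitive) methods.
    """
    partition = default_rsn_partition(n_rois, n_states)
    sizes = [int((partition == f"net{i}").sum()) for i in range(n_states)]
    covs = []
    for k in range(n_states):
        rs = [within_r if i == k else off_state_r for i in range(n_states)]
        mat = np.zeros((n_rois, n_rois))
        start = 0
        for i, size in enumerate(sizes):
            mat[start : start + size, start : start + size] = rs[i]
            start += size
        np.fill_diagonal(mat, 1.0)
        vals, vecs = np.linalg.eigh(mat)
        if vals[0] < 1e-6:
            vals = np.maximum(vals, 1e-6)
            mat = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(mat))
            mat = mat / np.outer(d, d)
        covs.append((mat + mat.T) / 2.0)
    transition = np.full((n_states, n_states), (1 - self_transition) / (n_states - 1))
    np.fill_diagonal(transition, self_transition)
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        n_states=n_states,
        transition=transition,
        state_covariances=np.stack(covs),
        state_means=np.zeros((n_states, n_rois)),
        rsn_partition=partition,
        n_timepoints=n_timepoints,
        observation_noise_sd=observation_noise_sd,
        seed=seed,
    )


def markov_mean_pattern_spec(
    n_subjects: int = 10,
    n_rois: int = 12,
    n_states: int = 3,
    n_timepoints: int = 1200,
    self_transition: float = 0.95,
    amplitude: float = 3.0,
    noise_sd: float = 0.3,
    sign_flips: bool = False,
    seed: int = 0,
) -> SyntheticSpec:
    """First-order fixture: states differ by orthogonal mean activity
    patterns (one RSN block active per state) over near-isotropic noise.

    With ``sign_flips`` the pattern polarity alternates between two states
    per block (2K states), which keeps every column zero-mean -- the
    appropriate regime for the dictionary-learning (WL) method whose atom
    assignment is sign-invariant.
    """
    partition = default_rsn_partition(n_rois, n_states)
    patterns = np.zeros((n_states, n_rois))
    for k in range(n_states):
        block = partition == f"net{k}"
        patterns[k, block] = amplitude / np.sqrt(block.sum())
    if sign_flips:
        means = np.vstack([patterns, -patterns])
        k_eff = 2 * n_states
    else:
        means = patterns
        k_eff = n_states
    transition = np.full((k_eff, k_eff), (1 - self_transition) / (k_eff - 1))
    np.fill_diagonal(transition, self_transition)
    covs = np.stack([noise_sd**2 * np.eye(n_rois)] * k_eff)
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        n_states=k_eff,
        transition=transition,
        state_covariances=covs,
        state_means=means,
        rsn_partition=partition,
        n_timepoints=n_timepoints,
        observation_noise_sd=0.0,
        seed=seed,
    )


def stationary_spec(
    n_subjects: int = 10,
    n_rois: int = 12,
    n_timepoints: int = 1200,
    within_r: float = 0.5,
    seed: int = 0,
) -> SyntheticSpec:
    """K = 1 stationary null with a fixed block-correlation structure."""
    partition = default_rsn_partition(n_rois, 3)
    sizes = [int((partition == lab).sum()) for lab in dict.fromkeys(partition)]
    cov = make_block_covariance(sizes, within_r=within_r, between_r=0.0)
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_rois=n_rois,
        n_states=1,
        transition=np.ones((1, 1)),
        state_covariances=cov[None],
        state_means=np.zeros((1, n_rois)),
        rsn_partition=partition,
        n_timepoints=n_timepoints,
        observation_noise_sd=0.0,
        seed=seed,
    )


def make_method_group_fixture(
    seed: int = 0,
    n_subjects: int = 6,
    n_timepoints: int = 38,
    n_rois: int = 12,
    blocks: tuple[int, ...] = (3, 2, 2),
    noise_sd: float = 0.2,
) -> DfcArray:
    """Synthetic 7-method dFC array with a planted block similarity
    structure: methods within a block share a latent dFC (per subject) and
    differ only by independent Gaussian noise."""
    if sum(blocks) != 7:
        raise ParameterError("blocks must sum to 7 methods")
    rng = np.random.default_rng(seed)
    c = n_connections(n_rois)
    method_ids, conn = [], []
    for b, size in enumerate(blocks):
        latent = rng.standard_normal((n_subjects, n_timepoints, c))
        for i in range(size):
            method_ids.append(f"m{b}{i}")
            conn.append(latent + noise_sd * rng.standard_normal(latent.shape))
    conn = np.stack(conn, axis=1)  # (s, 7, t, c)
    subject_ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    return dfc_array_from_connections(
        conn, subject_ids, method_ids,
        rsn_labels=default_rsn_partition(n_rois, 3),
    )
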