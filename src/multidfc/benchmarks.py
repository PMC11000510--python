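"""Simulate-and-recover benchmarks for the state-based estimators.

These routines generate Markov-switching BOLD with planted states,
run the estimators end to end, and score recovery after Hungarian
matching.  Two fixtures are used, matching how the methods encode states:

* covariance fixture -- states share zero means and differ in which RSN
  block carries strong within-block correlation; scores SWC and CHMM
  (second-order methods).  State dwell is set long relative to the
  sliding window (self-transition 0.99, mean dwell 100 TRs vs the 78-TR
  window): with shorter dwells the windows straddle state changes and no
  clustering of window FC can recover the planted states.
* mean-pattern fixture -- states differ by orthogonal mean activity
  patterns; scores CAP and WL (first-order methods) at self-transition
  0.95.  CAP centroids are scored against the conditional mean of the
  standardized data under the true labels (global z-scoring shifts the
  raw planted pattern); WL atoms are scored against the planted patterns,
  which survive standardization because the sign-flipping design keeps
  every column zero-mean.
"""

from __future__ import annotations

import numpy as np

from .preprocess import z_standardize
from .simulate import (generate_markov_bold, markov_covariance_spec,
                       markov_mean_pattern_spec)
from .state_based import CAP, CHMM, SWC, WL
from .state_free import make_tapered_window, window_starts
from .validation import (covariance_to_correlation, label_accuracy,
                         majority_window_labels, match_patterns,
                         match_state_fc)


def _seed_pair(base_seed: int, index: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([base_seed, index])
    a, b = ss.generate_state(2)
    return int(a) % (2**31 - 1), int(b) % (2**31 - 1)


def second_order_recovery(
    base_seed: int = 0,
    n_seeds: int = 5,
    n_subjects: int = 10,
    n_rois: int = 12,
    n_timepoints: int = 1200,
    n_states: int = 3,
    self_transition: float = 0.99,
) -> dict:
    """SWC and CHMM recovery scores on the covariance-contrast fixture."""
    window = make_tapered_window()
    scores = {k: [] for k in ("swc_state_corr", "swc_label_acc",
                              "chmm_state_corr", "chmm_label_acc")}
    for i in range(n_seeds):
        data_seed, fit_seed = _seed_pair(base_seed, i)
        spec = markov_covariance_spec(
            n_subjects=n_subjects, n_rois=n_rois, n_states=n_states,
            n_timepoints=n_timepoints, self_transition=self_transition,
            seed=data_seed,
        )
        ts_list, truths = generate_markov_bold(spec)
        ts_list = [z_standardize(ts) for ts in ts_list]

        swc = SWC(n_states=n_states, n_subject_clusters=10, seed=fit_seed)
        swc.fit(ts_list)
        starts = window_starts(n_timepoints, window)
        gt, est = [], []
        for ts, truth in zip(ts_list, truths):
            course, _ = swc.apply(ts)
            gt.append(majority_window_labels(truth, starts, window.length,
                                             window.weights))
            est.append(course.labels)
        scores["swc_label_acc"].append(
            label_accuracy(np.concatenate(gt), np.concatenate(est))
        )
        scores["swc_state_corr"].append(
            match_state_fc(spec.state_covariances, swc.state_set_.state_fc)[1]
        )

        chmm = CHMM(n_states=n_states, seed=fit_seed).fit(ts_list)
        est = np.concatenate([chmm.apply(ts)[0].labels for ts in ts_list])
        scores["chmm_label_acc"].append(
            label_accuracy(np.concatenate(truths), est)
        )
        scores["chmm_state_corr"].append(
            match_state_fc(
                spec.state_covariances,
                covariance_to_correlation(chmm.state_set_.state_fc),
            )[1]
        )
    return {k: float(np.mean(v)) for k, v in scores.items()}


def first_order_recovery(
    base_seed: int = 0,
    n_seeds: int = 5,
    n_subjects: int = 10,
    n_rois: int = 12,
    n_timepoints: int = 1200,
    n_states: int = 3,
    self_transition: float = 0.95,
) -> dict:
    """CAP and WL pattern-recovery scores on the mean-pattern fixture."""
    scores = {"cap_pattern_cosine": [], "wl_atom_cosine": []}
    for i in range(n_seeds):
        data_seed, fit_seed = _seed_pair(base_seed, 1000 + i)

        spec_cap = markov_mean_pattern_spec(
            n_subjects=n_subjects, n_rois=n_rois, n_states=n_states,
            n_timepoints=n_timepoints, self_transition=self_transition,
            sign_flips=False, seed=data_seed,
        )
        ts_list, truths = generate_markov_bold(spec_cap)
        ts_list = [z_standardize(ts) for ts in ts_list]
        cap = CAP(n_states=n_states, n_subject_clusters=10, seed=fit_seed)
        cap.fit(ts_list)
        x = np.vstack([ts.values for ts in ts_list])
        labels = np.concatenate(truths)
        oracle = np.stack(
            [x[labels == k].mean(0) for k in range(1, n_states + 1)]
        )
        scores["cap_pattern_cosine"].append(
            match_patterns(oracle, cap.centroids_, sign_invariant=False)[1]
        )

        spec_wl = markov_mean_pattern_spec(
            n_subjects=n_subjects, n_rois=n_rois, n_states=n_states,
            n_timepoints=n_timepoints, self_transition=self_transition,
            sign_flips=True, seed=data_seed,
        )
        ts_list, _ = generate_markov_bold(spec_wl)
        ts_list = [z_standardize(ts) for ts in ts_list]
        wl = WL(n_states=n_states, seed=fit_seed).fit(ts_list)
        scores["wl_atom_cosine"].append(
            match_patterns(spec_wl.state_means[:n_states], wl.dictionary_.T)[1]
        )
    return {k: float(np.mean(v)) for k, v in scores.items()}
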