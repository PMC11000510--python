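"""End-to-end orchestration: run estimators and standardize their outputs.

``estimate_dfc`` runs one method for every subject (group-fitting the
state-based methods first); ``run_pipeline`` runs a set of methods and
assembles everything onto the sliding-window time grid as one
:class:`DfcArray`.  Per-TR methods (TF, CAP, CHMM, WL) are nearest-TR
downsampled onto the 38-point window-centre grid; SW, SWC and DHMM are
already on it.
"""

from __future__ import annotations

from typing import Sequence

from .config import RunConfig
from .containers import METHOD_IDS, DfcArray, DfcMatrix, ParcellatedTimeSeries
from .core import assemble_dfc_array, temporal_downsample
from .errors import ParameterError
from .state_based import CAP, CHMM, DHMM, SWC, WL, _child_seeds
from .state_free import make_tapered_window, sliding_window_dfc, sliding_window_grid, \
    wavelet_coherence_dfc

#: Methods whose native grid is one FC matrix per TR.
PER_TR_METHODS = ("TF", "CAP", "CHMM", "WL")


def _window(config: RunConfig):
    return make_tapered_window(
        config.window_len_tr, config.taper_sigma_tr, config.step_tr
    )


def estimate_dfc(
    method: str,
    ts_list: Sequence[ParcellatedTimeSeries],
    config: RunConfig | None = None,
) -> list[DfcMatrix]:
    """Run one dFC method on every subject; state-based methods are fitted
    at the group level first, then applied per subject."""
    if config is None:
        config = RunConfig()
    if method not in METHOD_IDS:
        raise ParameterError(
            f"unknown method {method!r}; valid names: {list(METHOD_IDS)}"
        )
    seed = _child_seeds(config.seed, len(METHOD_IDS))[METHOD_IDS.index(method)]
    window = _window(config)
    if method == "SW":
        return [sliding_window_dfc(ts, window) for ts in ts_list]
    if method == "TF":
        return [
            wavelet_coherence_dfc(ts, config.n_scales, config.coi_mask)
            for ts in ts_list
        ]
    if method == "CAP":
        est = CAP(config.n_states, config.n_subject_clusters, seed=seed)
    elif method == "SWC":
        est = SWC(config.n_states, config.n_subject_clusters, window, seed=seed)
    elif method == "CHMM":
        est = CHMM(config.n_states, seed=seed)
    elif method == "DHMM":
        est = DHMM(
            config.n_states,
            obs_to_state_ratio=config.obs_to_state_ratio,
            n_subject_clusters=config.n_subject_clusters,
            window=window,
            seed=seed,
        )
    else:  # WL
        est = WL(config.n_states, seed=seed)
    est.fit(ts_list)
    return [est.apply(ts)[1] for ts in ts_list]


def run_pipeline(
    ts_list: Sequence[ParcellatedTimeSeries],
    config: RunConfig | None = None,
    methods: Sequence[str] | None = None,
) -> DfcArray:
    """Run several methods and assemble the standardized dFC array."""
    if config is None:
        config = RunConfig()
    if methods is None:
        methods = config.methods
    grid = sliding_window_grid(ts_list[0].n_timepoints, _window(config))
    matrices: list[DfcMatrix] = []
    for method in methods:
        for dfc in estimate_dfc(method, ts_list, config):
            if method in PER_TR_METHODS:
                dfc = temporal_downsample(dfc, grid)
            matrices.append(dfc)
    ref = ts_list[0]
    return assemble_dfc_array(
        matrices,
        ref.roi_labels,
        ref.rsn_labels,
        subject_ids=[ts.subject_id for ts in ts_list],
        method_ids=list(methods),
    )
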