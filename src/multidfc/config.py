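"""Run configuration: the hyperparameters of every estimator plus seed.

Defaults mirror the common practice for resting-state dFC at TR = 0.72 s:
a 60-TR rectangular window tapered with a 3-TR Gaussian stepping by 30
TRs, 101 wavelet scales with cone-of-influence masking, 12 FC states, 20
subject-level clusters, and a 16/24 observation-to-state ratio for the
discrete HMM.  The seed is recorded in every output artifact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .containers import METHOD_IDS
from .errors import ParameterError


@dataclass
class RunConfig:
    methods: tuple[str, ...] = METHOD_IDS
    tr_seconds: float = 0.72
    window_len_tr: int = 60          # nominal rectangle length (44 s at this TR)
    step_tr: int = 30
    taper_sigma_tr: float = 3.0
    n_scales: int = 101
    coi_mask: bool = True
    n_states: int = 12
    n_subject_clusters: int = 20
    obs_to_state_ratio: float = 16.0 / 24.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("window_len_tr", "step_tr", "n_scales", "n_states",
                     "n_subject_clusters"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.obs_to_state_ratio <= 0:
            raise ParameterError("obs_to_state_ratio must be positive")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if self.taper_sigma_tr < 0:
            raise ParameterError("taper_sigma_tr must be nonnegative")
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - set(METHOD_IDS)
        if unknown:
            raise ParameterError(
                f"unknown method(s) {sorted(unknown)}; valid: {list(METHOD_IDS)}"
            )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())
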