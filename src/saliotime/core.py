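"""Core data containers shared across the pipeline.

Trial-level metadata travels as a pandas DataFrame (the "trial table",
one row per trial with columns ``participant, block, trial, scene,
duration_s`` and, once simulated or measured, ``report_s``). Time-series
and derived per-TR quantities are small dataclasses keyed by
(participant, trial, hierarchy, layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

TRIAL_COLUMNS = ["participant", "block", "trial", "scene", "duration_s"]


@dataclass
class LayerTimeSeries:
    """Channel activity over time for one trial and one hierarchy layer.

    ``values`` has shape (n_trs, n_channels): row ``t`` is the activity
    pattern at sampling interval (TR) ``t``. Channels stand in for voxels
    of an ROI or nodes of a network layer.
    """

    values: np.ndarray
    tr_seconds: float
    hierarchy: str
    layer: int
    participant: int
    trial: int
    scene: str
    duration_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_trs, n_channels) array")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def key(self) -> tuple:
        return (self.participant, self.trial, self.hierarchy, self.layer)


@dataclass
class ChangeSeries:
    """Per-TR scalar change of one layer's activity within one trial.

    ``delta[t]`` summarises the change from TR t-1 to TR t; the first TR
    of the trial has no predecessor, so ``valid[0]`` is always False and
    ``delta[0]`` is NaN. ``metric`` records which summary produced it:
    ``"l1"`` (sum of absolute channel differences) or ``"signed"``
    (plain sum of channel differences).
    """

    delta: np.ndarray
    valid: np.ndarray
    metric: str
    standardized: bool
    tr_seconds: float
    hierarchy: str
    layer: int
    participant: int
    trial: int
    scene: str
    duration_s: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.delta.shape != self.valid.shape:
            raise ValueError("delta and valid must have the same shape")
        if self.metric not in ("l1", "signed"):
            raise ValueError(f"unknown change metric {self.metric!r}")

    @property
    def key(self) -> tuple:
        return (self.participant, self.trial, self.hierarchy, self.layer)

    def with_delta(self, delta: np.ndarray, *, standardized: bool) -> "ChangeSeries":
        return replace(self, delta=np.asarray(delta, float), standardized=standardized)


@dataclass
class EventRecord:
    """Salience classification of one ChangeSeries.

    ``salient`` flags the TRs whose standardized change met the decaying
    criterion; ``threshold`` stores the criterion value actually compared
    at each TR (NaN where no comparison took place); ``excluded`` flags
    TRs gated out as artifacts. ``count`` is the trial x layer total that
    the accumulator consumes.
    """

    salient: np.ndarray
    threshold: np.ndarray
    excluded: np.ndarray
    count: int
    hierarchy: str
    layer: int
    participant: int
    trial: int
    scene: str
    duration_s: float

    def __post_init__(self) -> None:
        self.salient = np.asarray(self.salient, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        self.threshold = np.asarray(self.threshold, dtype=float)
        if int(self.salient.sum()) != self.count:
            raise ValueError("count must equal the number of salient flags")
        if np.any(self.salient & self.excluded):
            raise ValueError("excluded TRs can never be salient")

    @property
    def key(self) -> tuple:
        return (self.participant, self.trial, self.hierarchy, self.layer)


@dataclass
class InferenceResult:
    """Summary of one fitted model or test.

    Only the fields relevant to the producing analysis are populated;
    the rest stay None.
    """

    analysis: str = ""
    estimate: Optional[float] = None
    se: Optional[float] = None
    stat: Optional[float] = None
    stat_name: Optional[str] = None
    df: Optional[float] = None
    p: Optional[float] = None
    sidedness: str = "two-sided"
    d: Optional[float] = None
    ci: Optional[tuple] = None
    bf: Optional[float] = None
    bf_rr: Optional[tuple] = None
    llf: Optional[float] = None
    llf_reduced: Optional[float] = None
    aic: Optional[float] = None
    aic_reduced: Optional[float] = None
    n_obs: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if k == "extra":
                out.update({f"extra_{ek}": ev for ek, ev in v.items()})
            elif v is not None:
                out[k] = list(v) if isinstance(v, tuple) else v
        return out
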