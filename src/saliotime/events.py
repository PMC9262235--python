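"""Salient-event classification against a decaying criterion, and accumulation.

A standardized change value z_TR is classified as a *salient event* when
it meets or exceeds an attention criterion that decays exponentially
from a conservative starting point towards a floor:

    theta(k) = theta_min + (theta_max - theta_min) * exp(-k / tau) + eps,
    eps ~ N(0, noise_sd^2)

where k counts TRs since the last reset (k = 1 at the first comparison).
The criterion resets to its maximal point after every salient event and
at the end of every trial; nothing carries over across trials. Values
beyond an artifact cutoff (default 2.5 SD, the head-motion gate) are
excluded: they neither trigger events nor, by default, advance the decay
clock. Counting the salient flags per trial and layer gives the
accumulated-event table that the duration mapping consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import ChangeSeries, EventRecord


@dataclass
class ThresholdParams:
    """Decaying-criterion parameters, in z units of the standardized change.

    ``theta_max`` is the criterion's most conservative (starting) point,
    ``theta_min`` the floor approached by the decay, ``tau`` the decay
    time constant in TRs. ``artifact_two_sided=None`` infers the gate
    sidedness from the metric: two-sided for the signed metric, one-sided
    for the (non-negative) L1 metric.
    """

    theta_max: float = 1.0
    theta_min: float = 0.0
    tau: float = 1.0
    noise_sd: float = 0.05
    artifact_cutoff: float = 2.5
    artifact_two_sided: Optional[bool] = None
    freeze_on_exclude: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_max < self.theta_min:
            raise ValueError("theta_max must be >= theta_min")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.artifact_cutoff <= 0:
            raise ValueError("artifact_cutoff must be positive")


def detect_salient_events(z: ChangeSeries, p: ThresholdParams) -> EventRecord:
    """Walk one trial TR-by-TR and flag salient events.

    The RNG for the criterion noise is seeded from ``(p.seed,
    participant, trial, layer)`` so detection is reproducible and
    independent of processing order.
    """
    if not z.standardized:
        raise ValueError("detect_salient_events requires standardized change values")
    zz = z.delta
    if not np.all(np.isfinite(zz[z.valid])):
        raise ValueError("non-finite standardized change values")

    two_sided = p.artifact_two_sided
    if two_sided is None:
        two_sided = z.metric == "signed"

    rng = np.random.default_rng(
        np.random.SeedSequence(
            [p.seed, int(z.participant), int(z.trial), int(z.layer)]
        )
    )
    n = zz.shape[0]
    salient = np.zeros(n, dtype=bool)
    excluded = np.zeros(n, dtype=bool)
    threshold = np.full(n, np.nan)
    span = p.theta_max - p.theta_min
    k = 0
    for t in range(n):
        if not z.valid[t]:
            continue
        v = zz[t]
        if (abs(v) if two_sided else v) > p.artifact_cutoff:
            excluded[t] = True
            if not p.freeze_on_exclude:
                k += 1
            continue
        k += 1
        eps = rng.normal(0.0, p.noise_sd) if p.noise_sd else 0.0
        th = p.theta_min + span * math.exp(-k / p.tau) + eps
        threshold[t] = th
        if v >= th:
            salient[t] = True
            k = 0
    return EventRecord(
        salient=salient,
        threshold=threshold,
        excluded=excluded,
        count=int(salient.sum()),
        hierarchy=z.hierarchy,
        layer=z.layer,
        participant=z.participant,
        trial=z.trial,
        scene=z.scene,
        duration_s=z.duration_s,
    )


def detect_all(
    series: Iterable[ChangeSeries], params_by_layer: dict[int, ThresholdParams]
) -> list[EventRecord]:
    """Detect events for every series using its layer's parameters."""
    out = []
    for z in series:
        try:
            p = params_by_layer[z.layer]
        except KeyError:
            raise ValueError(f"no ThresholdParams for layer {z.layer}") from None
        out.append(detect_salient_events(z, p))
    return out


def accumulate_events(records: Iterable[EventRecord]) -> pd.DataFrame:
    """Pivot per-TR salience flags into a trial x layer count table.

    One row per (participant, trial) with columns ``layer0..layerL``,
    plus carried-through ``scene`` and ``duration_s``. Raises if any
    trial x layer cell is missing so downstream mapping never silently
    sees an incomplete design.
    """
    records = list(records)
    if not records:
        raise ValueError("no event records")
    rows = [
        {
            "participant": r.participant,
            "trial": r.trial,
            "scene": r.scene,
            "duration_s": r.duration_s,
            "layer": r.layer,
            "n_events": r.count,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    wide = df.pivot_table(
        index=["participant", "trial", "scene", "duration_s"],
        columns="layer",
        values="n_events",
        aggfunc="first",
    )
    if wide.isna().any().any():
        missing = [
            (idx[0], idx[1], int(col))
            for col in wide.columns
            for idx in wide.index[wide[col].isna()]
        ]
        raise ValueError(f"missing trial x layer cells: {missing[:20]}")
    wide = wide.astype(int)
    wide.columns = [f"layer{c}" for c in wide.columns]
    return wide.reset_index()
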