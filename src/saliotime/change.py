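"""TR-to-TR change of layer activity and within-participant standardization.

Two summaries of how much a layer's activity pattern moved between
successive TRs:

* L1 change: sum over channels of the absolute difference,
  ``delta_TR = sum_v |X[TR, v] - X[TR-1, v]|`` (non-negative; the
  confirmatory metric),
* signed change: plain sum of differences,
  ``delta'_TR = sum_v (X[TR, v] - X[TR-1, v])`` (the exploratory metric,
  closer to a prediction-error reading of the signal).

Changes are never computed across trial boundaries; the first TR of each
trial carries no change value. Before thresholding, the change series
are z-scored pooling all of a participant's valid TRs within each
hierarchy layer, so the salience criterion has units of SDs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .core import ChangeSeries, LayerTimeSeries

logger = logging.getLogger(__name__)

#: ddof used in the z-scoring step (sample standard deviation).
STANDARDIZE_DDOF = 1


def _diff(x: LayerTimeSeries) -> np.ndarray:
    if x.n_trs < 2:
        raise ValueError(
            f"trial ({x.participant},{x.trial}) layer {x.layer} has {x.n_trs} TR(s); "
            "change needs at least 2"
        )
    return np.diff(x.values, axis=0)


def _wrap(x: LayerTimeSeries, per_tr: np.ndarray, metric: str) -> ChangeSeries:
    delta = np.full(x.n_trs, np.nan)
    delta[1:] = per_tr
    valid = np.zeros(x.n_trs, dtype=bool)
    valid[1:] = True
    return ChangeSeries(
        delta=delta,
        valid=valid,
        metric=metric,
        standardized=False,
        tr_seconds=x.tr_seconds,
        hierarchy=x.hierarchy,
        layer=x.layer,
        participant=x.participant,
        trial=x.trial,
        scene=x.scene,
        duration_s=x.duration_s,
    )


def l1_change(x: LayerTimeSeries) -> ChangeSeries:
    """Sum of absolute channel differences at each TR (always >= 0)."""
    return _wrap(x, np.abs(_diff(x)).sum(axis=1), "l1")


def signed_change(x: LayerTimeSeries) -> ChangeSeries:
    """Sum of raw channel differences at each TR (can be negative)."""
    return _wrap(x, _diff(x).sum(axis=1), "signed")


_METRICS = {"l1": l1_change, "signed": signed_change}


def compute_changes(
    series: Iterable[LayerTimeSeries], metric: str
) -> list[ChangeSeries]:
    """Apply one change metric to a batch, dropping non-finite trials.

    Trials containing any non-finite activity are dropped with a logged
    warning rather than imputed.
    """
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown change metric {metric!r}") from None
    out = []
    for x in series:
        if not np.all(np.isfinite(x.values)):
            logger.warning(
                "dropping trial (%s,%s) %s layer %d: non-finite activity",
                x.participant,
                x.trial,
                x.hierarchy,
                x.layer,
            )
            continue
        out.append(fn(x))
    return out


def standardize(series: Sequence[ChangeSeries]) -> list[ChangeSeries]:
    """Z-score change values pooled within participant x hierarchy x layer.

    All valid TRs of all of a participant's trials in a layer form one
    pool; after standardization that pool has mean 0 and sd 1 (ddof 1),
    so a cross-trial threshold expressed in z units is meaningful.
    Invalid flags are preserved.
    """
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(series):
        groups.setdefault((s.participant, s.hierarchy, s.layer), []).append(i)

    out: list[ChangeSeries] = list(series)
    for key, idxs in groups.items():
        pooled = np.concatenate([series[i].delta[series[i].valid] for i in idxs])
        if pooled.size < 2:
            raise ValueError(f"group {key} has fewer than 2 valid change values")
        mean = pooled.mean()
        sd = pooled.std(ddof=STANDARDIZE_DDOF)
        if sd == 0:
            raise ValueError(
                f"group (participant, hierarchy, layer) = {key} has zero variance"
            )
        for i in idxs:
            z = (series[i].delta - mean) / sd
            z[~series[i].valid] = np.nan
            out[i] = series[i].with_delta(z, standardized=True)
    return out
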