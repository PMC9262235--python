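"""Synthetic behavioral and neural data with the structure the analysis assumes.

The generator emulates a duration-judgement study: participants watch
short naturalistic scenes (quiet office vs. busy city) of 8-24 s and
report the duration on a 0-40 s scale while layered sensory activity is
sampled every TR. Three things are produced:

* a balanced trial design (``make_design``),
* human-like duration reports with central-tendency compression and a
  small scene bias (``simulate_reports``),
* per-trial channel x TR activity for layered hierarchies, driven by
  latent Poisson "salient change" events convolved with a hemodynamic
  response (``simulate_hierarchy_activity``).

Latent event times are returned alongside the activity so detector
recovery can be tested against ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import LayerTimeSeries

logger = logging.getLogger(__name__)

#: Response scale of the duration report slider, in seconds.
REPORT_SCALE_MAX = 40.0


class DesignError(ValueError):
    """Raised when a trial design cannot be balanced."""


@dataclass
class DesignSpec:
    """Factorial design: durations x scenes, balanced within block."""

    n_participants: int = 40
    blocks_per_participant: int = 3
    trials_per_block: int = 20
    durations: Sequence[float] = (8.0, 12.0, 16.0, 20.0, 24.0)
    scenes: Sequence[str] = ("office", "city")
    tr_seconds: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations):
            raise DesignError("all durations must be positive")
        n_cells = len(self.durations) * len(self.scenes)
        if self.trials_per_block % n_cells:
            raise DesignError(
                f"trials_per_block={self.trials_per_block} is not divisible by "
                f"|durations| x |scenes| = {len(self.durations)} x {len(self.scenes)} "
                f"= {n_cells}; the within-block design cannot be balanced"
            )
        if self.tr_seconds <= 0:
            raise DesignError("tr_seconds must be positive")


@dataclass
class ReportModelParams:
    """Affine regression-to-the-mean report model with multiplicative noise.

    ``report = (intercept + slope * duration) * scene_factor * gain * noise``
    where scene_factor is ``1 + scene_bias_pct/100`` for city scenes and 1
    for office scenes, ``gain`` is a per-participant lognormal response
    gain, and ``noise`` is Gaussian with coefficient of variation
    ``cv_noise``. slope < 1 with a positive intercept gives the
    over-short / under-long central-tendency pattern.
    """

    slope: float = 0.75
    intercept: float = 3.0
    scene_bias_pct: float = 5.0
    cv_noise: float = 0.15
    participant_gain_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.slope <= 1:
            raise ValueError("slope must be in (0, 1]")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be non-negative")
        if self.participant_gain_sd < 0:
            raise ValueError("participant_gain_sd must be non-negative")


@dataclass
class ActivityParams:
    """Forward model for one layered hierarchy's activity.

    ``event_rate`` maps scene label -> latent salient-event rate in
    events/s (a scalar applied to every layer, or one rate per layer).
    Each latent event deposits ``event_amplitude`` on a random subset of
    channels; the impulse train is convolved with a canonical
    double-gamma hemodynamic response sampled at the TR, then slow drift,
    white noise and occasional global artifact spikes are added.
    """

    hierarchy: str = "visual"
    n_layers: int = 3
    channels_per_layer: Sequence[int] = (40, 40, 40)
    event_rate: Mapping[str, object] = field(
        default_factory=lambda: {"office": 0.25, "city": 0.5}
    )
    event_amplitude: float = 1.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    channel_fraction: float = 0.5
    drift_sd: float = 0.1
    noise_sd: float = 0.1
    artifact_rate: float = 0.0
    artifact_amplitude: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if len(self.channels_per_layer) != self.n_layers:
            raise ValueError("channels_per_layer must list one count per layer")
        for name in ("event_amplitude", "drift_sd", "noise_sd", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def layer_rate(self, scene: str, layer: int) -> float:
        try:
            rate = self.event_rate[scene]
        except KeyError:
            raise ValueError(f"no event rate defined for scene {scene!r}") from None
        if np.isscalar(rate):
            return float(rate)
        return float(rate[layer])


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Build a balanced, seed-shuffled trial table (no reports yet)."""
    rng = np.random.default_rng(spec.seed)
    reps = spec.trials_per_block // (len(spec.durations) * len(spec.scenes))
    cell = [
        (scene, float(dur))
        for dur in spec.durations
        for scene in spec.scenes
        for _ in range(reps)
    ]
    rows = []
    for p in range(spec.n_participants):
        trial_idx = 0
        for b in range(spec.blocks_per_participant):
            order = rng.permutation(len(cell))
            for i in order:
                scene, dur = cell[i]
                rows.append((p, b, trial_idx, scene, dur))
                trial_idx += 1
    table = pd.DataFrame(
        rows, columns=["participant", "block", "trial", "scene", "duration_s"]
    )
    table.attrs["tr_seconds"] = float(spec.tr_seconds)
    return table


def simulate_reports(trials: pd.DataFrame, params: ReportModelParams) -> pd.DataFrame:
    """Attach a ``report_s`` column of human-like duration reports."""
    if (trials["duration_s"] <= 0).any():
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(params.seed)
    out = trials.copy()

    participants = np.sort(out["participant"].unique())
    gains = dict(
        zip(
            participants,
            np.exp(rng.normal(0.0, params.participant_gain_sd, len(participants))),
        )
    )
    base = params.intercept + params.slope * out["duration_s"].to_numpy()
    scene_factor = np.where(
        out["scene"].to_numpy() == "city", 1.0 + params.scene_bias_pct / 100.0, 1.0
    )
    gain = out["participant"].map(gains).to_numpy()
    noise = rng.normal(1.0, params.cv_noise, len(out)) if params.cv_noise else 1.0
    report = base * scene_factor * gain * noise

    n_trunc = int(np.sum((report < 0) | (report > REPORT_SCALE_MAX)))
    if n_trunc:
        logger.warning(
            "truncated %d report(s) to the [0, %g] s response scale",
            n_trunc,
            REPORT_SCALE_MAX,
        )
    out["report_s"] = np.clip(report, 0.0, REPORT_SCALE_MAX)
    return out


def hrf_kernel(tr_seconds: float, params: ActivityParams, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR."""
    t = np.arange(0, length_s, tr_seconds)
    peak = gamma_dist.pdf(t, params.hrf_peak_s)
    under = gamma_dist.pdf(t, params.hrf_undershoot_s)
    h = peak - params.hrf_undershoot_ratio * under
    return h / h.max()


def simulate_hierarchy_activity(
    trials: pd.DataFrame, params: ActivityParams
) -> tuple[list[LayerTimeSeries], pd.DataFrame]:
    """Simulate channel x TR activity for every trial and layer.

    Returns the list of :class:`LayerTimeSeries` and a latent-event table
    (participant, trial, layer, time_s) holding the ground-truth event
    times that drove the activity.
    """
    spec_tr = trials.attrs.get("tr_seconds", 0.8)
    rng = np.random.default_rng(params.seed)
    hrf = hrf_kernel(spec_tr, params)
    series: list[LayerTimeSeries] = []
    latent_rows = []

    for row in trials.itertuples(index=False):
        duration = float(row.duration_s)
        n_tr = math.ceil(duration / spec_tr)
        if n_tr < 1:
            raise ValueError(
                f"trial ({row.participant},{row.trial}) shorter than one TR"
            )
        for layer in range(params.n_layers):
            n_ch = int(params.channels_per_layer[layer])
            rate = params.layer_rate(row.scene, layer)
            n_events = rng.poisson(rate * duration)
            times = np.sort(rng.uniform(0.0, duration, n_events))
            impulses = np.zeros((n_tr, n_ch))
            n_hit = max(1, int(round(params.channel_fraction * n_ch)))
            for t_ev in times:
                tr_idx = min(int(t_ev / spec_tr), n_tr - 1)
                hit = rng.choice(n_ch, size=n_hit, replace=False)
                impulses[tr_idx, hit] += params.event_amplitude
                latent_rows.append((row.participant, row.trial, layer, float(t_ev)))
            # convolve each channel's impulse train with the HRF
            if impulses.any():
                conv = np.apply_along_axis(
                    lambda c: np.convolve(c, hrf)[:n_tr], 0, impulses
                )
            else:
                conv = impulses
            x = conv
            if params.drift_sd:
                steps = rng.normal(0.0, 1.0, (n_tr, n_ch))
                x = x + params.drift_sd * np.cumsum(steps, axis=0) / math.sqrt(n_tr)
            if params.noise_sd:
                x = x + rng.normal(0.0, params.noise_sd, (n_tr, n_ch))
            if params.artifact_rate:
                spikes = rng.random(n_tr) < params.artifact_rate
                if spikes.any():
                    # global (all-channel) spikes emulating head motion
                    x = x + np.outer(
                        spikes * params.artifact_amplitude, np.ones(n_ch)
                    )
            series.append(
                LayerTimeSeries(
                    values=x,
                    tr_seconds=spec_tr,
                    hierarchy=params.hierarchy,
                    layer=layer,
                    participant=int(row.participant),
                    trial=int(row.trial),
                    scene=str(row.scene),
                    duration_s=duration,
                )
            )
    latent = pd.DataFrame(
        latent_rows, columns=["participant", "trial", "layer", "time_s"]
    )
    return series, latent


def latent_event_counts(
    trials: pd.DataFrame, latent: pd.DataFrame, n_layers: int
) -> pd.DataFrame:
    """Ground-truth event counts per trial x layer, zero-filled."""
    idx = pd.MultiIndex.from_frame(trials[["participant", "trial"]])
    counts = (
        latent.groupby(["participant", "trial", "layer"])
        .size()
        .unstack("layer", fill_value=0)
        .reindex(idx, fill_value=0)
        .reindex(columns=range(n_layers), fill_value=0)
    )
    counts.columns = [f"layer{i}" for i in counts.columns]
    return counts.reset_index()
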