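"""End-to-end orchestration of the two named analyses, plus ROI extraction.

The *confirmatory* analysis uses the L1 change metric, pools behavior
into a super-subject, and tests the human-model bias association with
the 10,000-shuffle bootstrap slope test. The *exploratory* analysis uses
the signed change metric, keeps bias within-participant, and tests
associations with random-intercept linear mixed models compared by
likelihood-ratio chi-squared tests and AIC. Model predictions are always
generated from pooled accumulated events (single trials are too few per
participant for a within-participant fit).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .change import compute_changes, standardize
from .core import InferenceResult, LayerTimeSeries
from .events import ThresholdParams, accumulate_events, detect_all
from .mapping import MappingConfig, fit_predict_cv, fit_predict_ols
from .synthetic import (
    ActivityParams,
    DesignSpec,
    ReportModelParams,
    make_design,
    simulate_hierarchy_activity,
    simulate_reports,
)

logger = logging.getLogger(__name__)

#: Default per-layer criterion starting points: more conservative higher
#: in the hierarchy. Configuration defaults, not empirical claims.
DEFAULT_THETA_MAX = (1.0, 1.5, 2.0)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    preset: str = "confirmatory"  # 'confirmatory' | 'exploratory' | 'custom'
    metric: str = "l1"
    bias_grouping: str = "super_subject"  # or 'per_participant'
    thresholds: dict = field(default_factory=dict)  # hierarchy -> {layer: ThresholdParams}
    mapping: MappingConfig = field(default_factory=MappingConfig)
    n_boot: int = 10_000
    seed: int = 0
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if self.preset == "confirmatory":
            if self.metric != "l1" or self.bias_grouping != "super_subject":
                raise ValueError(
                    "confirmatory preset requires metric='l1' and "
                    "bias_grouping='super_subject'"
                )
        elif self.preset == "exploratory":
            if self.metric != "signed" or self.bias_grouping != "per_participant":
                raise ValueError(
                    "exploratory preset requires metric='signed' and "
                    "bias_grouping='per_participant'"
                )
        elif self.preset != "custom":
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.metric not in ("l1", "signed"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.bias_grouping not in ("super_subject", "per_participant"):
            raise ValueError(f"unknown bias grouping {self.bias_grouping!r}")


def confirmatory_config(seed: int = 0, **kwargs) -> PipelineConfig:
    return PipelineConfig(
        preset="confirmatory",
        metric="l1",
        bias_grouping="super_subject",
        seed=seed,
        **kwargs,
    )


def exploratory_config(seed: int = 0, **kwargs) -> PipelineConfig:
    return PipelineConfig(
        preset="exploratory",
        metric="signed",
        bias_grouping="per_participant",
        seed=seed,
        **kwargs,
    )


def default_thresholds(seed: int = 0, metric: str = "l1") -> dict[int, ThresholdParams]:
    return {
        layer: ThresholdParams(theta_max=tm, theta_min=0.0, seed=seed)
        for layer, tm in enumerate(DEFAULT_THETA_MAX)
    }


@dataclass
class HierarchyReport:
    counts: pd.DataFrame
    predictions: pd.DataFrame
    bias: pd.DataFrame  # per-trial human and model bias, merged
    results: dict[str, InferenceResult]
    r_pooled: float
    r_mean: float


@dataclass
class PipelineReport:
    hierarchies: dict[str, HierarchyReport]
    human_bias: pd.DataFrame
    comparison: pd.DataFrame
    manifest: dict

    def summary(self) -> dict:
        out = {"manifest": self.manifest, "hierarchies": {}}
        for name, h in self.hierarchies.items():
            out["hierarchies"][name] = {
                "r_pooled": h.r_pooled,
                "r_mean": h.r_mean,
                "results": {k: r.to_dict() for k, r in h.results.items()},
            }
        out["comparison"] = self.comparison.to_dict(orient="records")
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), sort_keys=True, indent=2, default=float)


def run_pipeline(
    config: PipelineConfig,
    trials: pd.DataFrame,
    series: Sequence[LayerTimeSeries],
) -> PipelineReport:
    """Run one named analysis end to end on a trial table plus time series."""
    config.validate()
    hierarchies = sorted({s.hierarchy for s in series})
    if not hierarchies:
        raise ValueError("no time series supplied")
    for h in hierarchies:
        if config.thresholds and h not in config.thresholds:
            raise ValueError(f"no thresholds configured for hierarchy {h!r}")

    # human bias
    if config.bias_grouping == "super_subject":
        human = st.pool_super_subject(trials)
    else:
        human = st.per_participant_bias(trials)
    hb = human[["participant", "trial", "scene", "duration_s", "bias"]].rename(
        columns={"bias": "bias_human"}
    )

    reports: dict[str, HierarchyReport] = {}
    compare_inputs: dict[str, InferenceResult] = {}
    for h in hierarchies:
        sub = [s for s in series if s.hierarchy == h]
        z = standardize(compute_changes(sub, config.metric))
        params = config.thresholds.get(h) if config.thresholds else None
        if params is None:
            params = default_thresholds(seed=config.seed, metric=config.metric)
        records = detect_all(z, params)
        counts = accumulate_events(records)
        if config.mapping.method == "svr":
            mres = fit_predict_cv(counts, counts["duration_s"], config.mapping)
        else:
            mres = fit_predict_ols(counts, counts["duration_s"])
        pred = mres.predictions.copy()
        pred["bias_model"] = st.normalized_bias(
            pred["predicted_s"].to_numpy(), pred["duration_s"].to_numpy()
        )
        merged = pred.merge(
            hb[["participant", "trial", "bias_human"]],
            on=["participant", "trial"],
            how="inner",
        )

        results: dict[str, InferenceResult] = {}
        if config.preset in ("confirmatory", "custom"):
            results["bootstrap_slope"] = st.bootstrap_slope_test(
                merged["bias_human"],
                merged["bias_model"],
                n_boot=config.n_boot,
                seed=config.seed,
            )
            results["ols_slope"] = st.ols_slope_test(
                merged["bias_human"], merged["bias_model"]
            )
            results["scene_contrast_model"] = st.scene_contrast(
                merged["bias_model"], merged["scene"], unit="trial"
            )
            compare_inputs[h] = _ols_with_reduced(
                merged["bias_human"], merged["bias_model"]
            )
        if config.preset == "exploratory":
            results["lmm_human_on_model"] = st.lmm_lr_test(
                merged, "bias_human", "bias_model"
            )
            results["lmm_model_on_scene"] = st.lmm_lr_test(
                merged, "bias_model", "scene"
            )
            compare_inputs[h] = results["lmm_human_on_model"]

        reports[h] = HierarchyReport(
            counts=counts,
            predictions=pred,
            bias=merged,
            results=results,
            r_pooled=mres.r_pooled,
            r_mean=mres.r_mean,
        )

    comparison = st.compare_models(compare_inputs)

    manifest = {
        "preset": config.preset,
        "metric": config.metric,
        "bias_grouping": config.bias_grouping,
        "mapping": vars(config.mapping),
        "n_boot": config.n_boot,
        "seed": config.seed,
        "hierarchies": hierarchies,
        "thresholds": {
            h: {
                int(l): {
                    k: v
                    for k, v in vars(p).items()
                }
                for l, p in (
                    config.thresholds.get(h)
                    if config.thresholds
                    else default_thresholds(seed=config.seed, metric=config.metric)
                ).items()
            }
            for h in hierarchies
        },
        "n_trials": int(trials.shape[0]),
    }
    report = PipelineReport(
        hierarchies=reports, human_bias=human, comparison=comparison, manifest=manifest
    )
    if config.output_dir:
        _write_outputs(report, Path(config.output_dir))
    return report


def _ols_with_reduced(y, x) -> InferenceResult:
    """OLS of y on x plus the intercept-only fit, for model comparison."""
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(x, float)
    full = sm.OLS(y, sm.add_constant(x)).fit()
    reduced = sm.OLS(y, np.ones((len(y), 1))).fit()
    return InferenceResult(
        analysis="ols_vs_null",
        estimate=float(full.params[1]),
        se=float(full.bse[1]),
        llf=float(full.llf),
        llf_reduced=float(reduced.llf),
        aic=float(full.aic),
        aic_reduced=float(reduced.aic),
        n_obs=int(full.nobs),
    )


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(report.summary_json())
    report.human_bias.to_csv(outdir / "human_bias.csv", index=False)
    report.comparison.to_csv(outdir / "model_comparison.csv", index=False)
    for name, h in report.hierarchies.items():
        h.counts.to_csv(outdir / f"{name}_events.csv", index=False)
        h.predictions.to_csv(outdir / f"{name}_predictions.csv", index=False)
        h.bias.to_csv(outdir / f"{name}_bias.csv", index=False)
    logger.info("pipeline outputs written to %s", outdir)


# ---------------------------------------------------------------------------
# synthetic study bundle
# ---------------------------------------------------------------------------


def simulate_dataset(
    design: DesignSpec | None = None,
    report_params: ReportModelParams | None = None,
    activity: Sequence[ActivityParams] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[LayerTimeSeries], pd.DataFrame]:
    """Generate a full study bundle: trials+reports, activity, latent events.

    By default three 3-layer hierarchies are simulated: a "visual"
    hierarchy whose latent event rate depends on scene (city busier than
    office) and two scene-indifferent control hierarchies ("auditory",
    "somatosensory").
    """
    design = design or DesignSpec(seed=seed)
    report_params = report_params or ReportModelParams(seed=seed + 1)
    if activity is None:
        activity = [
            ActivityParams(
                hierarchy="visual",
                event_rate={"office": 0.25, "city": 0.5},
                seed=seed + 2,
            ),
            ActivityParams(
                hierarchy="auditory",
                event_rate={"office": 0.35, "city": 0.35},
                seed=seed + 3,
            ),
            ActivityParams(
                hierarchy="somatosensory",
                event_rate={"office": 0.35, "city": 0.35},
                seed=seed + 4,
            ),
        ]
    trials = simulate_reports(make_design(design), report_params)
    all_series: list[LayerTimeSeries] = []
    latents = []
    for params in activity:
        s, latent = simulate_hierarchy_activity(trials, params)
        all_series.extend(s)
        latent = latent.copy()
        latent["hierarchy"] = params.hierarchy
        latents.append(latent)
    return trials, all_series, pd.concat(latents, ignore_index=True)


# ---------------------------------------------------------------------------
# ROI extraction from 4-D images
# ---------------------------------------------------------------------------


def extract_roi_timeseries(
    volume_path: str,
    mask_paths: dict[int, str],
    events: pd.DataFrame,
    hierarchy: str,
    participant: int,
    tr_seconds: float,
) -> list[LayerTimeSeries]:
    """Cut per-trial, per-layer voxel x TR matrices out of a 4-D image.

    ``mask_paths`` maps layer index -> label image (non-zero = in mask).
    ``events`` is BIDS-style with one row per trial: ``onset`` (s),
    ``duration`` (s), ``trial`` and ``scene`` columns. Trial windows are
    0-based, half-open TR intervals [onset_tr, onset_tr +
    ceil(duration / TR)).
    """
    import nibabel as nib

    img = nib.load(volume_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("volume must be 4-D")
    out: list[LayerTimeSeries] = []
    for layer, mpath in sorted(mask_paths.items()):
        mask = np.asarray(nib.load(mpath).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask {mpath} grid {mask.shape} does not match volume "
                f"{data.shape[:3]}"
            )
        if not mask.any():
            raise ValueError(f"mask {mpath} is empty")
        vox = data[mask]  # (n_voxels, n_volumes)
        for row in events.itertuples(index=False):
            onset_tr = int(round(float(row.onset) / tr_seconds))
            n_tr = math.ceil(float(row.duration) / tr_seconds)
            stop = onset_tr + n_tr
            if stop > vox.shape[1]:
                raise ValueError(
                    f"trial window [{onset_tr}, {stop}) exceeds scan length "
                    f"{vox.shape[1]}"
                )
            out.append(
                LayerTimeSeries(
                    values=vox[:, onset_tr:stop].T,
                    tr_seconds=tr_seconds,
                    hierarchy=hierarchy,
                    layer=layer,
                    participant=participant,
                    trial=int(row.trial),
                    scene=str(getattr(row, "scene", "")),
                    duration_s=float(row.duration),
                )
            )
    return out
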