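"""Robustness grid scan over criterion bounds (p-value heat maps).

Re-runs detect -> accumulate -> map -> bias -> slope-test over a grid of
(theta_min, theta_max) values for layer 1, with fixed additive offsets
for the higher layers, and records the one-tailed p-value and slope of
the human-bias ~ model-bias regression in each cell. The analytic OLS
test is used per cell (a bootstrap over thousands of cells would buy
nothing); cells that fail (e.g. zero events everywhere) are recorded as
NaN, not fatal. Each cell's RNG stream is derived from (seed, i, j) so
results are independent of evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ChangeSeries
from .events import ThresholdParams, accumulate_events, detect_all
from .mapping import MappingConfig, fit_predict_cv, fit_predict_ols
from .stats import normalized_bias, ols_slope_test

logger = logging.getLogger(__name__)


@dataclass
class GridSpec:
    """Grid of layer-1 criterion bounds; higher layers are offset copies."""

    n_min_values: int = 50
    n_max_values: int = 50
    theta_min_range: tuple[float, float] = (-3.0, 0.0)
    theta_max_range: tuple[float, float] = (0.0, 2.5)
    layer_offsets: Sequence[float] = (0.0, 0.5, 1.0)
    tau: float = 1.0
    noise_sd: float = 0.05
    artifact_cutoff: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_min_range[0] > self.theta_min_range[1]:
            raise ValueError("theta_min_range must be ordered")
        if self.theta_max_range[0] > self.theta_max_range[1]:
            raise ValueError("theta_max_range must be ordered")
        if self.n_min_values < 1 or self.n_max_values < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def theta_min_values(self) -> np.ndarray:
        return np.linspace(*self.theta_min_range, self.n_min_values)

    @property
    def theta_max_values(self) -> np.ndarray:
        return np.linspace(*self.theta_max_range, self.n_max_values)


@dataclass
class ScanResult:
    """p-value and slope matrices indexed by the layer-1 bounds."""

    p: pd.DataFrame  # index: theta_min, columns: theta_max
    slope: pd.DataFrame
    grid: GridSpec
    hierarchy: str = ""
    n_failed: int = 0

    def significance_mask(self, alpha: float = 0.05) -> pd.DataFrame:
        """True where the association is non-significant or negative
        (the cells drawn dark in the heat map)."""
        return (self.p >= alpha) | (self.slope <= 0) | self.p.isna()


def _cell_seed(seed: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31))


def grid_scan(
    z_series: Sequence[ChangeSeries],
    human_bias: pd.DataFrame,
    grid: GridSpec,
    mapping: MappingConfig | None = None,
) -> ScanResult:
    """Run the full event->duration->bias pipeline in every grid cell.

    ``z_series`` are standardized change series for one hierarchy;
    ``human_bias`` has one row per (participant, trial) with a ``bias``
    column. Returns p-value and slope matrices (rows = theta_min values,
    columns = theta_max values).
    """
    mapping = mapping or MappingConfig()
    layers = sorted({z.layer for z in z_series})
    if len(grid.layer_offsets) < len(layers):
        raise ValueError("layer_offsets must cover every layer present")
    hierarchy = z_series[0].hierarchy if z_series else ""
    hb = human_bias[["participant", "trial", "bias"]].rename(
        columns={"bias": "bias_human"}
    )

    tmin_vals = grid.theta_min_values
    tmax_vals = grid.theta_max_values
    p_mat = np.full((len(tmin_vals), len(tmax_vals)), np.nan)
    b_mat = np.full_like(p_mat, np.nan)
    n_failed = 0

    for i, tmin in enumerate(tmin_vals):
        for j, tmax in enumerate(tmax_vals):
            seed_ij = _cell_seed(grid.seed, i, j)
            try:
                params = {
                    l: ThresholdParams(
                        theta_max=tmax + grid.layer_offsets[l],
                        theta_min=tmin + grid.layer_offsets[l],
                        tau=grid.tau,
                        noise_sd=grid.noise_sd,
                        artifact_cutoff=grid.artifact_cutoff,
                        seed=seed_ij,
                    )
                    for l in layers
                }
                counts = accumulate_events(detect_all(z_series, params))
                cfg = MappingConfig(
                    method=mapping.method,
                    n_folds=mapping.n_folds,
                    svr_c=mapping.svr_c,
                    svr_epsilon=mapping.svr_epsilon,
                    kernel=mapping.kernel,
                    feature_scaling=mapping.feature_scaling,
                    seed=seed_ij,
                )
                if cfg.method == "svr":
                    res = fit_predict_cv(counts, counts["duration_s"], cfg)
                else:
                    res = fit_predict_ols(counts, counts["duration_s"])
                pred = res.predictions.copy()
                pred["bias_model"] = normalized_bias(
                    pred["predicted_s"].to_numpy(), pred["duration_s"].to_numpy()
                )
                merged = pred.merge(hb, on=["participant", "trial"], how="inner")
                test = ols_slope_test(merged["bias_human"], merged["bias_model"])
                p_mat[i, j] = test.p
                b_mat[i, j] = test.estimate
            except Exception as exc:  # cell failure is recorded, not fatal
                n_failed += 1
                logger.warning(
                    "grid cell (theta_min=%.3f, theta_max=%.3f) failed: %s",
                    tmin,
                    tmax,
                    exc,
                )
    idx = pd.Index(np.round(tmin_vals, 6), name="theta_min")
    cols = pd.Index(np.round(tmax_vals, 6), name="theta_max")
    return ScanResult(
        p=pd.DataFrame(p_mat, index=idx, columns=cols),
        slope=pd.DataFrame(b_mat, index=idx, columns=cols),
        grid=grid,
        hierarchy=hierarchy,
        n_failed=n_failed,
    )


def plot_scan(result: ScanResult, path: str, alpha: float = 0.05) -> None:
    """Render the p-value heat map; masked cells (non-significant or
    negative association) are drawn dark."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = result.p.to_numpy()
    mask = result.significance_mask(alpha).to_numpy()
    shown = np.where(mask, np.nan, p)
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    im = ax.imshow(
        shown,
        origin="lower",
        aspect="auto",
        cmap=cmap,
        extent=[
            result.grid.theta_max_range[0],
            result.grid.theta_max_range[1],
            result.grid.theta_min_range[0],
            result.grid.theta_min_range[1],
        ],
    )
    ax.set_xlabel("criterion maximum (z)")
    ax.set_ylabel("criterion minimum (z)")
    ax.set_title(f"{result.hierarchy}: one-tailed p for slope (dark = n.s./negative)")
    fig.colorbar(im, ax=ax, label="p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
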