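"""Normalized-bias psychophysics statistics and the inferential battery.

The behavioral currency throughout is *normalized bias*: for trial k of
duration category t,

    bias_tk = (x_tk - mean_t) / mean_t

the fractional deviation of a report from the typical report for that
duration (within a participant, or within the pooled "super-subject").
By construction it is independent of clock time, so it isolates the
subjective component of duration judgements. On top of it sit the
study's tests: scene contrasts (paired / two-sample t), the bootstrap
slope test linking human and model bias, random-intercept linear mixed
models with likelihood-ratio chi-squared tests, AIC / log-likelihood
model comparison, and Dienes-style Bayes factors with robustness
regions.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import integrate, stats

from .core import InferenceResult

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# normalized bias and the super-subject
# ---------------------------------------------------------------------------


def normalized_bias(
    reports: Sequence[float],
    durations: Sequence[float],
    groups: Optional[Sequence] = None,
) -> np.ndarray:
    """Per-trial normalized bias, as a fraction.

    Grouping cells are duration categories, optionally crossed with a
    grouping factor (typically participant). Within each cell the bias
    is (report - cell mean) / cell mean; its cell mean is exactly zero.
    """
    reports = np.asarray(reports, float)
    durations = np.asarray(durations, float)
    if reports.shape != durations.shape:
        raise ValueError("reports and durations must have equal length")
    if groups is None:
        keys = pd.Series(durations)
    else:
        keys = pd.Series(list(zip(np.asarray(groups), durations)))
    means = pd.Series(reports).groupby(keys).transform("mean").to_numpy()
    bad = means <= 0
    if bad.any():
        offending = sorted(set(keys[bad]))
        raise ValueError(f"non-positive mean report in cell(s) {offending[:5]}")
    return (reports - means) / means


def pool_super_subject(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool participants into one behavioral "super-subject".

    Reports are z-scored within participant (removing idiosyncratic
    response scale and offset), then re-anchored onto the grand mean and
    SD of all reports so the pooled series lives on the original
    positive seconds scale, and normalized bias is recomputed per
    duration on the pooled data. With a single participant this
    round-trips to the original reports exactly.

    Returns a copy of ``trials`` with ``report_z``, ``report_pooled_s``
    and ``bias`` columns.
    """
    out = trials.copy()
    grp = out.groupby("participant")["report_s"]
    mean = grp.transform("mean")
    sd = grp.transform("std")
    if (sd == 0).any() or sd.isna().any():
        bad = sorted(
            int(p) for p in out.loc[(sd == 0) | sd.isna(), "participant"].unique()
        )
        raise ValueError(f"constant or single report for participant(s) {bad}")
    out["report_z"] = (out["report_s"] - mean) / sd
    grand_mean = out["report_s"].mean()
    grand_sd = out["report_s"].std()
    out["report_pooled_s"] = out["report_z"] * grand_sd + grand_mean
    out["bias"] = normalized_bias(
        out["report_pooled_s"].to_numpy(), out["duration_s"].to_numpy()
    )
    return out


def per_participant_bias(trials: pd.DataFrame, report_col: str = "report_s") -> pd.DataFrame:
    """Normalized bias computed within participant x duration cells."""
    out = trials.copy()
    out["bias"] = normalized_bias(
        out[report_col].to_numpy(),
        out["duration_s"].to_numpy(),
        groups=out["participant"].to_numpy(),
    )
    return out


# ---------------------------------------------------------------------------
# scene contrasts
# ---------------------------------------------------------------------------


def scene_contrast(
    bias: Sequence[float],
    scenes: Sequence[str],
    participants: Optional[Sequence] = None,
    unit: str = "participant",
    scene_order: tuple[str, str] = ("city", "office"),
) -> InferenceResult:
    """Test whether bias differs between scene types (city minus office).

    ``unit='participant'``: paired t-test on per-participant scene means,
    with Cohen's d = mean difference / SD of differences.
    ``unit='trial'``: two-sample t-test with pooled variance and
    pooled-SD Cohen's d.
    """
    bias = np.asarray(bias, float)
    scenes = np.asarray(scenes)
    a_label, b_label = scene_order
    if unit == "participant":
        if participants is None:
            raise ValueError("participant mode needs participant labels")
        df = pd.DataFrame(
            {"bias": bias, "scene": scenes, "participant": np.asarray(participants)}
        )
        cell = df.groupby(["participant", "scene"])["bias"].mean().unstack("scene")
        if cell.isna().any().any() or not {a_label, b_label} <= set(cell.columns):
            missing = cell.index[cell.isna().any(axis=1)].tolist()
            raise ValueError(f"missing scene cell for participant(s) {missing[:10]}")
        diffs = (cell[a_label] - cell[b_label]).to_numpy()
        n = len(diffs)
        mean = diffs.mean()
        sd = diffs.std(ddof=1)
        se = sd / np.sqrt(n)
        t = mean / se if se > 0 else 0.0
        dof = n - 1
        p = 2 * stats.t.sf(abs(t), dof)
        d = mean / sd if sd > 0 else 0.0
        crit = stats.t.ppf(0.975, dof)
        return InferenceResult(
            analysis="scene_contrast_participant",
            estimate=mean,
            se=se,
            stat=t,
            stat_name="t",
            df=dof,
            p=p,
            d=d,
            ci=(mean - crit * se, mean + crit * se),
            n_obs=n,
        )
    elif unit == "trial":
        a = bias[scenes == a_label]
        b = bias[scenes == b_label]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 trials per scene")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        n1, n2 = len(a), len(b)
        dof = n1 + n2 - 2
        sp = np.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / dof
        )
        mean = a.mean() - b.mean()
        se = sp * np.sqrt(1 / n1 + 1 / n2)
        d = mean / sp if sp > 0 else 0.0
        crit = stats.t.ppf(0.975, dof)
        return InferenceResult(
            analysis="scene_contrast_trial",
            estimate=mean,
            se=se,
            stat=float(t),
            stat_name="t",
            df=dof,
            p=float(p),
            d=d,
            ci=(mean - crit * se, mean + crit * se),
            n_obs=n1 + n2,
        )
    raise ValueError(f"unknown unit {unit!r}")


def contrast_from_summary(mean_diff: float, se: float, n: int) -> InferenceResult:
    """One-sample t-test reconstructed from a printed mean and SE."""
    if se <= 0 or n < 2:
        raise ValueError("se must be positive and n >= 2")
    dof = n - 1
    t = mean_diff / se
    p = 2 * stats.t.sf(abs(t), dof)
    crit = stats.t.ppf(0.975, dof)
    return InferenceResult(
        analysis="contrast_from_summary",
        estimate=mean_diff,
        se=se,
        stat=t,
        stat_name="t",
        df=dof,
        p=p,
        d=t / np.sqrt(n),
        ci=(mean_diff - crit * se, mean_diff + crit * se),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# bootstrap slope test (human bias ~ model bias)
# ---------------------------------------------------------------------------


def bootstrap_slope_test(
    bias_human: Sequence[float],
    bias_model: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> InferenceResult:
    """One-tailed permutation test of the slope of human on model bias.

    Fits ``bias_human = b0 + b1 * bias_model`` by least squares, then
    shuffles the human (outcome) vector ``n_boot`` times and refits; the
    one-tailed p-value is (1 + #{b1_shuffled >= b1_observed}) /
    (n_boot + 1), so it is never exactly zero.
    """
    y = np.asarray(bias_human, float)
    x = np.asarray(bias_model, float)
    if y.shape != x.shape:
        raise ValueError("bias vectors must have equal length")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    xc = x - x.mean()
    var = float(xc @ xc)
    if var == 0:
        raise ValueError("model bias is constant; slope undefined")
    slope = float(xc @ (y - y.mean())) / var
    intercept = float(y.mean() - slope * x.mean())

    rng = np.random.default_rng(seed)
    # vectorized permutation slopes: b1 = xc . y_perm / (xc . xc)
    exceed = 0
    block = 2000
    done = 0
    while done < n_boot:
        b = min(block, n_boot - done)
        perms = np.empty((b, len(y)))
        for i in range(b):
            perms[i] = rng.permutation(y)
        slopes = (perms - perms.mean(axis=1, keepdims=True)) @ xc / var
        exceed += int(np.sum(slopes >= slope))
        done += b
    p = (1 + exceed) / (n_boot + 1)
    return InferenceResult(
        analysis="bootstrap_slope",
        estimate=slope,
        stat=slope,
        stat_name="beta1",
        df=len(y) - 2,
        p=p,
        sidedness="one-tailed (positive)",
        n_obs=len(y),
        extra={"intercept": intercept, "n_boot": n_boot},
    )


def ols_slope_test(
    bias_human: Sequence[float], bias_model: Sequence[float]
) -> InferenceResult:
    """Analytic one-tailed OLS test of the same slope (used by the grid scan)."""
    y = np.asarray(bias_human, float)
    x = np.asarray(bias_model, float)
    if np.std(x) == 0:
        raise ValueError("model bias is constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    t = float(fit.tvalues[1])
    p_one = float(stats.t.sf(t, fit.df_resid))
    return InferenceResult(
        analysis="ols_slope",
        estimate=slope,
        se=float(fit.bse[1]),
        stat=t,
        stat_name="t",
        df=float(fit.df_resid),
        p=p_one,
        sidedness="one-tailed (positive)",
        llf=float(fit.llf),
        aic=float(fit.aic),
        n_obs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------


def lmm_lr_test(
    data: pd.DataFrame,
    outcome: str,
    fixed: Optional[str],
    groups: str = "participant",
    reml: bool = False,
) -> InferenceResult:
    """Random-intercept LMM with a likelihood-ratio chi-squared test.

    Fits ``outcome ~ 1 + fixed + (1 | groups)`` and the intercept-only
    reduced model by maximum likelihood (REML would make the
    log-likelihoods incomparable across fixed-effect structures), and
    reports the fixed-effect estimate, chi2(1) = 2 * (ll_full -
    ll_reduced), its p-value, and both AICs.
    """
    if data[groups].nunique() < 2:
        raise ValueError("need at least 2 grouping units")
    formula_full = f"{outcome} ~ 1" + (f" + {fixed}" if fixed else "")

    def _fit(formula: str, name: str):
        model = smf.mixedlm(formula, data, groups=data[groups])
        last = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("bfgs", "lbfgs", "cg", "powell"):
                last = model.fit(reml=reml, method=method)
                if last.converged:
                    return last
                # A random-intercept variance pinned at zero is a boundary
                # solution, not a failure: accept it if the fit is otherwise
                # finite, as lmer's "singular fit" does.
                boundary = float(np.asarray(last.cov_re).ravel()[0]) < 1e-6
                finite = np.all(np.isfinite(last.fe_params)) and np.isfinite(
                    last.llf
                )
                if boundary and finite:
                    logger.warning(
                        "%s LMM converged on the boundary (singular random-"
                        "intercept variance)",
                        name,
                    )
                    return last
        raise RuntimeError(f"{name} LMM did not converge: {last.summary()}")

    full = _fit(formula_full, "full")
    reduced = _fit(f"{outcome} ~ 1", "reduced")

    def _aic(fit) -> float:
        # fixed effects + random-intercept variance + residual variance
        k = len(fit.fe_params) + 2
        return 2 * k - 2 * fit.llf

    lr = max(0.0, 2 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(lr, 1)) if fixed else 1.0
    est = se = None
    ci = None
    if fixed:
        names = [n for n in full.fe_params.index if n != "Intercept"]
        est = float(full.fe_params[names[0]])
        se = float(full.bse[names[0]])
        ci = (est - 1.96 * se, est + 1.96 * se)
    return InferenceResult(
        analysis="lmm_lr",
        estimate=est,
        se=se,
        stat=lr,
        stat_name="chi2",
        df=1,
        p=p,
        ci=ci,
        llf=float(full.llf),
        llf_reduced=float(reduced.llf),
        aic=_aic(full),
        aic_reduced=_aic(reduced),
        n_obs=len(data),
        extra={"formula": formula_full},
    )


def compare_models(results: dict[str, InferenceResult]) -> pd.DataFrame:
    """Rank fitted models by likelihood-ratio vs. their reduced model and AIC.

    All results must have been fitted on the same outcome data
    (checked via n_obs). Returns a table with log-likelihood ratio,
    delta-AIC relative to the best model, and a ``best`` flag.
    """
    if not results:
        raise ValueError("no results to compare")
    n = {r.n_obs for r in results.values()}
    if len(n) != 1:
        raise ValueError(f"results fitted on different outcome sizes: {sorted(n)}")
    rows = []
    for name, r in results.items():
        llr = None
        if r.llf is not None and r.llf_reduced is not None:
            llr = 2 * (r.llf - r.llf_reduced)
        rows.append(
            {"model": name, "llf": r.llf, "llr_vs_reduced": llr, "aic": r.aic}
        )
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["best"] = out["aic"] == out["aic"].min()
    return out.sort_values("aic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bayes factors (normal likelihood, Dienes-style)
# ---------------------------------------------------------------------------


def _likelihood(mean_diff: float, se: float, df: Optional[int]):
    if df is None:
        return lambda theta: stats.norm.pdf(mean_diff, theta, se)
    return lambda theta: stats.t.pdf((mean_diff - theta) / se, df) / se


def bayes_factor(
    mean_diff: float,
    se: float,
    prior: str = "half_normal",
    prior_scale: float = 1.0,
    likelihood_df: Optional[int] = None,
    robustness: bool = True,
) -> InferenceResult:
    """BF10 for a summary effect under a directional prior.

    BF10 = integral of likelihood(theta) * prior(theta) d theta, divided
    by likelihood(0). ``prior='half_normal'`` uses HalfNormal(0,
    prior_scale); ``prior='uniform'`` uses Uniform(0, prior_scale). The
    likelihood is normal in the observed mean with SD ``se`` (or scaled
    t with ``likelihood_df`` degrees of freedom). The robustness region
    is the contiguous range of prior scales, scanned on a log grid, over
    which the qualitative conclusion (BF > 3, BF < 1/3, or insensitive)
    is unchanged.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_scale <= 0:
        raise ValueError("prior scale must be positive")
    if prior not in ("half_normal", "uniform"):
        raise ValueError(f"unknown prior {prior!r}")

    lik = _likelihood(mean_diff, se, likelihood_df)

    def _bf(scale: float) -> float:
        if prior == "half_normal":
            # substitute theta = scale * u so the integrand stays O(1)-wide
            # even for prior scales far narrower than the likelihood
            f = lambda u: lik(scale * u) * stats.halfnorm.pdf(u)
            num, _ = integrate.quad(f, 0, np.inf, limit=200)
        else:
            f = lambda u: lik(scale * u)
            num, _ = integrate.quad(f, 0, 1, limit=200)
        return num / lik(0.0)

    bf = _bf(prior_scale)
    rr = None
    if robustness:
        rr = _robustness_region(_bf, prior_scale, bf)
    return InferenceResult(
        analysis=f"bayes_factor_{prior}",
        estimate=mean_diff,
        se=se,
        bf=bf,
        bf_rr=rr,
        extra={"prior_scale": prior_scale, "likelihood_df": likelihood_df},
    )


def _category(bf: float) -> str:
    if bf > 3:
        return "H1"
    if bf < 1 / 3:
        return "H0"
    return "insensitive"


def _robustness_region(
    bf_fn, scale: float, bf_at_scale: float, n_grid: int = 200
) -> tuple[float, float]:
    """Largest contiguous log-grid interval of prior scales keeping the
    qualitative conclusion of ``bf_at_scale``."""
    cat = _category(bf_at_scale)
    lo_exp, hi_exp = np.log10(scale) - 3, np.log10(scale) + 3
    grid = np.logspace(lo_exp, hi_exp, n_grid)
    cats = [_category(bf_fn(s)) for s in grid]
    i0 = int(np.argmin(np.abs(np.log10(grid) - np.log10(scale))))
    lo_i = i0
    while lo_i > 0 and cats[lo_i - 1] == cat:
        lo_i -= 1
    hi_i = i0
    while hi_i < n_grid - 1 and cats[hi_i + 1] == cat:
        hi_i += 1
    lo = 0.0 if lo_i == 0 else float(grid[lo_i])
    hi = np.inf if hi_i == n_grid - 1 else float(grid[hi_i])
    return (lo, hi)
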