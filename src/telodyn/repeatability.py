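"""Variance-component repeatability (intraclass correlation).

Repeatability R of a grouped measurement is the fraction of total variance
attributable to the grouping factor,

    R = sigma2_group / (sigma2_group + sigma2_resid),

estimated from a one-way random-intercept model fitted by restricted maximum
likelihood (REML), with a parametric-bootstrap confidence interval.  The
one-way REML criterion depends on the data only through per-group sizes,
means and the pooled within-group sum of squares, so each fit — and therefore
each bootstrap refit — costs O(#groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .lmm import ModelFit, ModelSpec, fit_lmm

__all__ = [
    "RepeatabilityResult",
    "icc",
    "adjusted_individual_repeatability",
    "within_individual_regression",
]


@dataclass
class RepeatabilityResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_groups: int
    n_obs: int
    grouping: str = ""
    adjusted_for: list = field(default_factory=list)
    var_group: float = float("nan")
    var_resid: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError("repeatability estimate must lie in [0, 1]")


def _group_stats(values: np.ndarray, codes: np.ndarray, k: int):
    n_i = np.bincount(codes, minlength=k).astype(float)
    sum_i = np.bincount(codes, weights=values, minlength=k)
    mean_i = sum_i / n_i
    ssw = float(np.sum((values - mean_i[codes]) ** 2))
    return n_i, mean_i, ssw


def _neg_reml(ratio: float, n_i, mean_i, ssw, N, k):
    """-2 * REML profile log-likelihood in theta = sigma2_a / sigma2_e.

    sigma2_e is profiled out in closed form given the ratio.
    """
    d = 1.0 + n_i * ratio
    w = n_i / d
    mu = np.sum(w * mean_i) / np.sum(w)
    q = ssw + float(np.sum(n_i * (mean_i - mu) ** 2 / d))
    sigma2_e = q / (N - 1)
    val = (
        (N - k) * np.log(sigma2_e)
        + float(np.sum(np.log(sigma2_e * d)))
        + np.log(float(np.sum(w)) / sigma2_e)
        + q / sigma2_e
    )
    return val


def _fit_oneway_reml(values: np.ndarray, codes: np.ndarray, k: int):
    """REML variance components (sigma2_group, sigma2_resid) of a one-way model."""
    N = len(values)
    n_i, mean_i, ssw = _group_stats(values, codes, k)
    if np.all(n_i <= 1):
        raise ValueError("degenerate grouping: all groups are singletons")

    def obj(log_ratio):
        return _neg_reml(np.exp(log_ratio), n_i, mean_i, ssw, N, k)

    res = minimize_scalar(obj, bounds=(-18.0, 22.0), method="bounded",
                          options={"xatol": 1e-10})
    ratio = float(np.exp(res.x))
    # compare against the boundary (no group variance)
    if _neg_reml(1e-14, n_i, mean_i, ssw, N, k) <= res.fun:
        ratio = 0.0
    d = 1.0 + n_i * ratio
    w = n_i / d
    mu = np.sum(w * mean_i) / np.sum(w)
    q = ssw + float(np.sum(n_i * (mean_i - mu) ** 2 / d))
    sigma2_e = q / (N - 1)
    return max(ratio * sigma2_e, 0.0), sigma2_e, n_i, mu


def icc(
    values,
    groups,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityResult:
    """Agreement repeatability of ``values`` grouped by ``groups``.

    Point estimate from one-way REML variance components (negative component
    estimates truncated at zero before forming the ratio, estimate clipped to
    [0, 1]); CI from a seeded parametric bootstrap with ``n_boot`` resamples
    of the fitted model.
    """
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    k = int(codes.max()) + 1
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 groups with at least 2 observations")

    var_a, var_e, n_i, mu = _fit_oneway_reml(values, codes, k)
    est = float(np.clip(var_a / (var_a + var_e), 0.0, 1.0))

    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_boot)
        sd_a, sd_e = np.sqrt(var_a), np.sqrt(var_e)
        N = len(values)
        for b in range(n_boot):
            a = rng.normal(0.0, sd_a, k)
            y = mu + a[codes] + rng.normal(0.0, sd_e, N)
            va, ve, _, _ = _fit_oneway_reml(y, codes, k)
            sims[b] = va / (va + ve)
        lo, hi = np.percentile(sims, [2.5, 97.5])
        lo, hi = float(min(lo, est)), float(max(hi, est))

    return RepeatabilityResult(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        n_groups=k,
        n_obs=len(values),
        var_group=var_a,
        var_resid=var_e,
    )


def adjusted_individual_repeatability(
    samples: pd.DataFrame, min_birds: int = 30
) -> RepeatabilityResult:
    """Within-individual repeatability of sqrt-RTL, adjusted for age and cohort.

    Fits ``sqrt_rtl ~ log(age) + cohort`` with a random intercept per bird and
    returns sigma2_bird / (sigma2_bird + sigma2_resid).
    """
    n_multi = (samples.groupby("bird_id").size() >= 2).sum()
    if n_multi < min_birds:
        raise ValueError(
            f"need >=2 samples for >= {min_birds} birds (have {n_multi})"
        )
    spec = ModelSpec(
        response="sqrt_rtl", fixed_terms=["age_log", "cohort"], random_terms=["bird_id"]
    )
    fit = fit_lmm(spec, samples, criterion="REML")
    if not fit.converged:
        raise RuntimeError(f"mixed model did not converge: {fit.diagnostics}")
    var_id = fit.variance_components.get("bird_id", 0.0)
    total = var_id + sum(
        v for k_, v in fit.variance_components.items() if k_ != "bird_id"
    ) + fit.resid_var
    est = float(np.clip(var_id / total, 0.0, 1.0))
    return RepeatabilityResult(
        estimate=est,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_groups=samples["bird_id"].nunique(),
        n_obs=len(samples),
        grouping="bird_id",
        adjusted_for=["age_log", "cohort"],
        var_group=var_id,
        var_resid=fit.resid_var,
    )


def within_individual_regression(samples: pd.DataFrame) -> ModelFit:
    """Regression of RTL at the next sampling on RTL at the current sampling.

    Consecutive sample pairs within birds; fixed effects are RTL(t) and age(t),
    random intercepts for bird and cohort.  The fitted object's ``estimates``
    carry the RTL(t) slope with its Wald interval; the marginal R-squared can
    be computed with :func:`telodyn.env_model.r2_nakagawa`.
    """
    s = samples.sort_values(["bird_id", "age_years"], kind="mergesort")
    g = s.groupby("bird_id")
    pairs = pd.DataFrame(
        {
            "bird_id": s["bird_id"],
            "cohort": s["cohort"] if "cohort" in s.columns else 0,
            "rtl_next": g["rtl"].shift(-1),
            "rtl_now": s["rtl"],
            "age_now": s["age_years"],
        }
    ).dropna(subset=["rtl_next"])
    if pairs.empty:
        raise ValueError("no birds with >= 2 samples")
    spec = ModelSpec(
        response="rtl_next",
        fixed_terms=["rtl_now", "age_now"],
        random_terms=["bird_id", "cohort"],
    )
    return fit_lmm(spec, pairs, criterion="REML")
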