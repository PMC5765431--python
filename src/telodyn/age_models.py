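"""Age/cohort trajectory model sets, AICc ranking, within-subject centring.

The cross-sectional candidate set compares linear, quadratic, loglinear and
factor codings of age, each with and without hatch-year cohort, against a
null model, all sharing crossed random intercepts for bird, catch year and
qPCR plate.  The longitudinal set decomposes age into a per-bird mean
(between-individual axis) and deviations from it (delta-age, the
within-individual axis), dropping the plate random effect because consecutive
samples of a bird are assayed on separate plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import ModelFit, ModelSpec, fit_lmm, prepare_model_columns

__all__ = [
    "aicc",
    "ModelRanking",
    "rank_models",
    "build_cross_sectional_set",
    "build_longitudinal_set",
    "within_subject_centre",
    "within_between_contrast",
]


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``-2*loglik + 2k + 2k(k+1)/(n - k - 1)``; ``k`` counts all estimated
    parameters (fixed coefficients, variance components and the residual).
    """
    if k > 0 and n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    correction = 2.0 * k * (k + 1) / (n - k - 1) if k > 0 else 0.0
    return -2.0 * loglik + 2.0 * k + correction


@dataclass
class ModelRanking:
    """Models ordered by AICc with deltas and Akaike weights."""

    entries: list  # of (spec, aicc, delta, weight)

    def __post_init__(self):
        deltas = [e[2] for e in self.entries]
        if any(d < 0 for d in deltas) or any(
            b < a for a, b in zip(deltas, deltas[1:])
        ):
            raise ValueError("deltas must be nonnegative and nondecreasing")
        if abs(sum(e[3] for e in self.entries) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def best(self) -> ModelSpec:
        return self.entries[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": s.name,
                    "df": None,
                    "aicc": a,
                    "delta_aicc": d,
                    "weight": w,
                }
                for s, a, d, w in self.entries
            ]
        )


def rank_models(fits: list[ModelFit], allow_flagged: bool = False) -> ModelRanking:
    """Rank fitted models by AICc; ties broken by fewer parameters, then input order."""
    if not fits:
        raise ValueError("no fits to rank")
    crit = {f.fit_criterion for f in fits}
    if len(crit) > 1:
        raise ValueError(f"mixed fit criteria: {sorted(crit)}")
    ns = {f.n_obs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits use differing n_obs: {sorted(ns)}")
    if not allow_flagged:
        bad = [f.spec.name for f in fits if not f.converged]
        if bad:
            raise ValueError(f"refusing non-converged fits: {bad}")

    order = sorted(
        range(len(fits)), key=lambda i: (fits[i].aicc, fits[i].k_params, i)
    )
    best = fits[order[0]].aicc
    deltas = [fits[i].aicc - best for i in order]
    raw = np.exp(-0.5 * np.asarray(deltas))
    weights = raw / raw.sum()
    entries = [
        (fits[i].spec, fits[i].aicc, d, float(w))
        for i, d, w in zip(order, deltas, weights)
    ]
    return ModelRanking(entries)


_CROSS_RANDOMS = ("bird_id", "catch_year", "plate_id")

#: the ten ranked cross-sectional model structures, plus the age x cohort
#: interaction follow-up used to test cohort-varying slopes
_CROSS_FIXED = [
    (("cohort", "age_log"), "Cohort + Age (log)"),
    (("age_quadratic", "age_linear", "cohort"), "Age (quadratic) + Age (linear) + Cohort"),
    (("age_linear", "cohort"), "Age (linear) + Cohort"),
    (("age_log",), "Age (log)"),
    (("cohort", "age_factor"), "Cohort + Age (factor)"),
    (("age_quadratic", "age_linear"), "Age (quadratic) + Age (linear)"),
    (("age_linear",), "Age (linear)"),
    (("age_factor",), "Age (factor)"),
    (("cohort",), "Cohort"),
    ((), "Null model"),
    (("cohort", "age_log", "age_log_x_cohort"), "Cohort x Age (log) interaction"),
]


def build_cross_sectional_set(data: pd.DataFrame, response: str = "sqrt_rtl") -> list[ModelSpec]:
    """The cross-sectional age/cohort candidate set (10 ranked models plus the
    log-age x cohort interaction follow-up), each with bird, catch-year and
    plate random intercepts."""
    for col in ("age_years", "cohort"):
        if col not in data.columns:
            raise ValueError(f"data lacks {col!r}")
    specs = []
    for fixed, name in _CROSS_FIXED:
        # quadratic term must follow its linear term for spec validity
        ordered = tuple(sorted(fixed, key=lambda t: t == "age_quadratic"))
        specs.append(
            ModelSpec(response, ordered, _CROSS_RANDOMS, name=name)
        )
    return specs


def within_subject_centre(
    data: pd.DataFrame, term: str = "age_log", group: str = "bird_id"
) -> pd.DataFrame:
    """Within-subject centring of age for the longitudinal model set.

    Keeps only birds with >= 2 samples, and adds per-bird mean and deviation
    columns: ``mean_age``/``delta_age`` (linear years), ``mean_log_age``/
    ``delta_log_age`` and ``delta_age_sq`` (deviation of squared age).
    Per-bird deviations sum to zero exactly.
    """
    out = prepare_model_columns(data)
    counts = out.groupby(group)["sample_id"].size() if "sample_id" in out.columns else out.groupby(group).size()
    multi = counts[counts >= 2].index
    out = out[out[group].isin(multi)].copy()
    g = out.groupby(group)
    for src, mean_col, delta_col in (
        ("age_years", "mean_age", "delta_age"),
        ("log_age", "mean_log_age", "delta_log_age"),
        ("age_years_sq", "mean_age_sq", "delta_age_sq"),
    ):
        m = g[src].transform("mean")
        out[mean_col] = m
        out[delta_col] = out[src] - m
    return out


_LONG_RANDOMS = ("bird_id", "catch_year")

_LONG_FIXED = [
    (("delta_age_log", "mean_age"), "Delta age (log) + Mean age"),
    (("delta_age_linear", "mean_age"), "Delta age (linear) + Mean age"),
    (("cohort", "delta_age_log", "mean_age"), "Cohort + Delta age (log) + Mean age"),
    (
        ("delta_age_linear", "delta_age_quadratic", "mean_age"),
        "Delta age (linear) + Delta age (quadratic) + Mean age",
    ),
    (("cohort", "delta_age_linear", "mean_age"), "Cohort + Delta age (linear) + Mean age"),
    (("mean_age",), "Mean age"),
    (
        ("cohort", "delta_age_linear", "delta_age_quadratic", "mean_age"),
        "Cohort + Delta age (linear) + Delta age (quadratic) + Mean age",
    ),
    (("cohort", "mean_age"), "Cohort + Mean age"),
]


def build_longitudinal_set(data: pd.DataFrame, response: str = "sqrt_rtl") -> list[ModelSpec]:
    """The eight longitudinal (within-subject centred) models; random
    intercepts for bird and catch year only — consecutive samples of a bird
    are run on separate plates, so a plate effect cannot be separated from
    residual error here."""
    needed = {"delta_log_age", "delta_age", "mean_age"}
    if needed - set(data.columns):
        raise ValueError("centred columns missing; run within_subject_centre first")
    return [
        ModelSpec(response, fixed, _LONG_RANDOMS, name=name)
        for fixed, name in _LONG_FIXED
    ]


def within_between_contrast(
    data: pd.DataFrame,
    response: str = "sqrt_rtl",
    criterion: str = "REML",
    randoms=_LONG_RANDOMS,
) -> tuple[float, tuple[float, float], ModelFit]:
    """Difference between between- and within-individual log-age slopes.

    Fits ``response ~ log_age + mean_log_age`` with bird and catch-year random
    intercepts; in this raw-plus-mean parameterisation the mean-age
    coefficient is exactly (between slope) - (within slope), so its Wald
    interval tests whether cross-sectional and longitudinal telomere
    shortening differ.  Returns (contrast, (ci_low, ci_high), fit).
    """
    if "mean_log_age" not in data.columns:
        data = within_subject_centre(data)
    spec = ModelSpec(
        response, ("age_log", "mean_age_log"), randoms, name="raw + mean age (log)"
    )
    fit = fit_lmm(spec, data, criterion=criterion)
    est = fit.coef("mean_log_age")
    return est, fit.ci("mean_log_age"), fit
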