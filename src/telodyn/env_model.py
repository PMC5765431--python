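"""Environmental/social models of telomere length and change.

The full model regresses sqrt-RTL on log age, morphometrics (tarsus, mass),
sex and four environment/social covariates (seasonal insect abundance,
territory quality, island-wide population density, group size, helpers), with
random intercepts for bird, qPCR plate and cohort plus a random log-age slope
among cohorts.  Continuous covariates are centred and scaled to unit SD so
zero-substitution model averaging and per-term relative importances are
comparable across terms.  Variance explained is summarised with marginal and
conditional R-squared for mixed models (fixed-effects variance over total,
and fixed-plus-random over total, with random-slope models contributing their
observation-averaged random-effect variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from patsy import dmatrix

from .lmm import FIXED_TERMS, RANDOM_TERMS, ModelFit, ModelSpec, fit_lmm, prepare_model_columns
from .age_models import rank_models

__all__ = [
    "AveragingResult",
    "R2Result",
    "standardize_covariates",
    "fit_full_rtl_model",
    "sex_tarsus_interaction",
    "fit_delta_rtl_model",
    "model_average",
    "r2_nakagawa",
    "FULL_MODEL_TERMS",
]

#: the nine fixed terms of the full RTL model
FULL_MODEL_TERMS = (
    "age_log",
    "tarsus",
    "mass",
    "sex",
    "insect",
    "territory_quality",
    "density",
    "group_size",
    "helpers",
)

_FULL_RANDOMS = ("bird_id", "plate_id", "cohort", "age_log|cohort")

_CONTINUOUS = (
    "tarsus_mm",
    "mass_g",
    "insect_abundance",
    "territory_quality",
    "density",
    "group_size",
    "helpers",
)


@dataclass
class R2Result:
    marginal: float
    conditional: float

    def __post_init__(self):
        if self.conditional < self.marginal - 1e-9:
            raise ValueError("conditional R2 cannot be below marginal R2")


@dataclass
class AveragingResult:
    top_set: list  # (spec, aicc, delta, weight) with delta <= threshold
    averaged_coefs: dict  # term -> (coef, ci_low, ci_high), zero-substitution
    conditional_coefs: dict  # term -> (coef, ci_low, ci_high), natural averaging
    relative_importance: dict  # term -> [0, 1]
    n_candidates: int
    n_dropped: int


def standardize_covariates(data: pd.DataFrame, columns=_CONTINUOUS) -> pd.DataFrame:
    """Centre continuous covariates and scale them to unit SD.

    Territory quality missing for a territory-year is first imputed with the
    territory's across-year mean.
    """
    out = prepare_model_columns(data)
    if "territory_quality" in out.columns and out["territory_quality"].isna().any():
        if "territory" in out.columns:
            fill = out.groupby("territory")["territory_quality"].transform("mean")
            out["territory_quality"] = out["territory_quality"].fillna(fill)
    for col in columns:
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        sd = x.std(ddof=0)
        out[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def _check_covariates(data: pd.DataFrame, terms) -> None:
    from .lmm import required_columns

    missing = sorted(
        required_columns(ModelSpec("sqrt_rtl", terms)) - set(data.columns) - {"sqrt_rtl"}
    )
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")


def fit_full_rtl_model(
    samples: pd.DataFrame, criterion: str = "REML", randoms=_FULL_RANDOMS
) -> ModelFit:
    """Fit the full environmental/social model of sqrt-RTL."""
    data = standardize_covariates(samples)
    _check_covariates(data, FULL_MODEL_TERMS)
    spec = ModelSpec("sqrt_rtl", FULL_MODEL_TERMS, randoms, name="full RTL model")
    return fit_lmm(spec, data, criterion=criterion)


def sex_tarsus_interaction(
    samples: pd.DataFrame, criterion: str = "REML", randoms=_FULL_RANDOMS
) -> ModelFit:
    """Full model plus the sex x tarsus interaction (hierarchy enforced)."""
    data = standardize_covariates(samples)
    terms = FULL_MODEL_TERMS + ("sex_x_tarsus",)
    spec = ModelSpec("sqrt_rtl", terms, randoms, name="full + sex x tarsus")
    return fit_lmm(spec, data, criterion=criterion)


def fit_delta_rtl_model(
    deltas: pd.DataFrame, samples: pd.DataFrame, criterion: str = "REML"
) -> ModelFit:
    """Environmental model of within-individual RTL change.

    ``deltas`` (from :func:`telodyn.elongation.pair_individual_deltas`) are
    joined to the covariates of the *first* sample of each pair; the fixed
    terms match the full model with age entering as log age at the first
    sample, and the only random term is bird identity.
    """
    cov_cols = [
        c
        for c in (
            "sample_id",
            "sex",
            "tarsus_mm",
            "mass_g",
            "insect_abundance",
            "territory_quality",
            "territory",
            "density",
            "group_size",
            "helpers",
            "cohort",
        )
        if c in samples.columns
    ]
    d = deltas.merge(
        samples[cov_cols], left_on="sample_id_first", right_on="sample_id", how="left"
    )
    d["age_years"] = d["age_first"]
    d = standardize_covariates(d)
    d = d.rename(columns={"unit_id": "bird_id"})
    _check_covariates(d.assign(sqrt_rtl=0.0), FULL_MODEL_TERMS)
    spec = ModelSpec(
        "delta_rtl", FULL_MODEL_TERMS, ("bird_id",), name="delta-RTL environment model"
    )
    return fit_lmm(spec, d, criterion=criterion)


def model_average(
    response: str,
    terms,
    randoms,
    data: pd.DataFrame,
    delta_threshold: float = 6.0,
    criterion: str = "ML",
) -> AveragingResult:
    """All-subsets AICc model averaging with a fixed random structure.

    Every subset of ``terms`` (2^k candidates; interaction hierarchy enforced
    by :class:`ModelSpec`) is fitted, ranked by AICc, and the top set (delta
    <= ``delta_threshold``, inclusive) retained.  Reports full-model
    ("zero-substitution") averaged coefficients and unconditional intervals,
    natural (conditional) averages over models containing each term, and
    per-term relative importance (sum of renormalised top-set weights of the
    models containing the term).
    """
    terms = tuple(terms)
    if len(terms) > 12:
        raise ValueError("all-subsets enumeration limited to 12 terms")
    data = prepare_model_columns(data)
    fits, dropped = [], 0
    for r in range(len(terms) + 1):
        for subset in combinations(terms, r):
            try:
                spec = ModelSpec(response, subset, randoms)
            except ValueError:
                continue  # violates term hierarchy
            fit = fit_lmm(spec, data, criterion=criterion)
            if fit.converged:
                fits.append(fit)
            else:
                dropped += 1
    if not fits:
        raise RuntimeError("no candidate model converged")
    ranking = rank_models(fits)
    fit_by_name = {f.spec.name: f for f in fits}
    top = [(s, a, d, w) for s, a, d, w in ranking.entries if d <= delta_threshold]
    wsum = sum(w for *_, w in top)
    top = [(s, a, d, w / wsum) for s, a, d, w in top]

    averaged, conditional, importance = {}, {}, {}
    for term in terms:
        coef_name_candidates = _term_coef_names(term, data)
        rows = []
        for s, _, _, w in top:
            contains = term in s.fixed_terms
            fit = fit_by_name[s.name]
            if contains:
                name = next(n for n in coef_name_candidates if n in fit.estimates)
                b, lo, hi = fit.estimates[name]
                se = (hi - b) / 1.96
            else:
                b, se = 0.0, 0.0
            rows.append((w, contains, b, se))
        importance[term] = sum(w for w, c, *_ in rows if c)
        averaged[term] = _pool(rows)
        cond_rows = [(w, c, b, se) for w, c, b, se in rows if c]
        if cond_rows:
            cw = sum(w for w, *_ in cond_rows)
            conditional[term] = _pool([(w / cw, c, b, se) for w, c, b, se in cond_rows])
        else:
            conditional[term] = (float("nan"),) * 3
    return AveragingResult(
        top_set=top,
        averaged_coefs=averaged,
        conditional_coefs=conditional,
        relative_importance=importance,
        n_candidates=2 ** len(terms),
        n_dropped=dropped,
    )


def _term_coef_names(term: str, data: pd.DataFrame) -> list[str]:
    frag = FIXED_TERMS[term]
    if "C(sex)" in frag:
        levels = sorted(pd.unique(data["sex"].dropna()))
        dummies = [f"C(sex)[T.{lv}]" for lv in levels[1:]]
        if term == "sex_x_tarsus":
            return [f"{d}:tarsus_mm" for d in dummies]
        return dummies
    return [frag]


def _pool(rows) -> tuple[float, float, float]:
    """Burnham-Anderson model-averaged estimate with unconditional SE."""
    bbar = sum(w * b for w, _, b, _ in rows)
    se = sum(w * np.sqrt(se_m**2 + (b - bbar) ** 2) for w, _, b, se_m in rows)
    return float(bbar), float(bbar - 1.96 * se), float(bbar + 1.96 * se)


def r2_nakagawa(fit: ModelFit, data: pd.DataFrame) -> R2Result:
    """Marginal and conditional R-squared of a fitted mixed model.

    marginal = var_fixed / (var_fixed + sum(random variances) + residual);
    conditional adds the random variances to the numerator.  Each random
    term's observation-level variance is its component times the mean row sum
    of squares of its design — 1 for intercept terms, mean(x^2) for a random
    slope — so random-slope models use the observation-averaged random-effect
    variance.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    data = prepare_model_columns(data)
    X = dmatrix(fit.spec.fixed_formula.split("~", 1)[1], data, return_type="dataframe")
    X = X[fit.fixed_names]
    pred = X.to_numpy() @ fit.fixed_params
    var_f = float(np.var(pred))

    var_r = 0.0
    for term, v in fit.variance_components.items():
        if v < -1e-10:
            raise ValueError(f"negative variance component for {term}")
        Z = np.asarray(dmatrix(RANDOM_TERMS[term], data))
        var_r += max(v, 0.0) * float(np.mean(np.sum(Z**2, axis=1)))
    total = var_f + var_r + fit.resid_var
    return R2Result(marginal=var_f / total, conditional=(var_f + var_r) / total)
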