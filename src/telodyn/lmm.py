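"""Linear mixed-model fitting from declarative model specifications.

A :class:`ModelSpec` names a response, an ordered list of fixed-effect terms
and a list of random terms from a fixed registry (bird, catch year, qPCR
plate, cohort intercepts, and a random log-age slope among cohorts).  Fitting
is delegated to :class:`statsmodels` ``MixedLM``: a single random intercept
uses the grouped formulation, crossed random structures use variance
components over a single all-encompassing group.  Fits with no random terms
fall back to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["ModelSpec", "ModelFit", "fit_lmm", "FIXED_TERMS", "RANDOM_TERMS"]

#: fixed-effect term name -> patsy formula fragment
FIXED_TERMS = {
    "age_linear": "age_years",
    "age_quadratic": "age_years_sq",
    "age_log": "log_age",
    "age_factor": "C(age_years)",
    "cohort": "C(cohort)",
    "age_log_x_cohort": "log_age:C(cohort)",
    "delta_age_log": "delta_log_age",
    "delta_age_linear": "delta_age",
    "delta_age_quadratic": "delta_age_sq",
    "mean_age": "mean_age",
    "mean_age_log": "mean_log_age",
    # environmental / social covariates (standardised upstream where relevant)
    "tarsus": "tarsus_mm",
    "mass": "mass_g",
    "sex": "C(sex)",
    "insect": "insect_abundance",
    "territory_quality": "territory_quality",
    "density": "density",
    "group_size": "group_size",
    "helpers": "helpers",
    "sex_x_tarsus": "C(sex):tarsus_mm",
    # direct passthrough terms used by auxiliary models
    "rtl_now": "rtl_now",
    "age_now": "age_now",
}

#: random term name -> variance-component formula (0 + indicator design)
RANDOM_TERMS = {
    "bird_id": "0 + C(bird_id)",
    "catch_year": "0 + C(catch_year)",
    "plate_id": "0 + C(plate_id)",
    "cohort": "0 + C(cohort)",
    "age_log|cohort": "0 + C(cohort):log_age",
}

#: data columns the vc formula of each random term needs
_RANDOM_COLS = {
    "bird_id": ["bird_id"],
    "catch_year": ["catch_year"],
    "plate_id": ["plate_id"],
    "cohort": ["cohort"],
    "age_log|cohort": ["cohort", "log_age"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification."""

    response: str
    fixed_terms: tuple = ()
    random_terms: tuple = ()
    name: str = ""

    def __init__(self, response, fixed_terms=(), random_terms=(), name=""):
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed_terms", tuple(fixed_terms))
        object.__setattr__(self, "random_terms", tuple(random_terms))
        object.__setattr__(self, "name", name or self._default_name())
        self._check()

    def _default_name(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "null"

    def _check(self) -> None:
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate random terms")
        if "age_quadratic" in self.fixed_terms and "age_linear" not in self.fixed_terms:
            raise ValueError("quadratic age requires the linear age term")
        if (
            "delta_age_quadratic" in self.fixed_terms
            and "delta_age_linear" not in self.fixed_terms
        ):
            raise ValueError("quadratic delta-age requires the linear delta-age term")
        if "sex_x_tarsus" in self.fixed_terms and not (
            "sex" in self.fixed_terms and "tarsus" in self.fixed_terms
        ):
            raise ValueError("sex x tarsus interaction requires both main effects")

    @property
    def fixed_formula(self) -> str:
        rhs = " + ".join(FIXED_TERMS[t] for t in self.fixed_terms) or "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """A fitted mixed (or degenerate fixed-effects) model."""

    spec: ModelSpec
    estimates: dict  # coefficient name -> (estimate, ci_low, ci_high)
    variance_components: dict  # random term -> variance
    resid_var: float
    loglik: float
    n_obs: int
    k_params: int
    aicc: float
    converged: bool
    singular: bool = False
    fit_criterion: str = "REML"
    diagnostics: str = ""
    fixed_params: np.ndarray | None = None
    fixed_names: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.estimates[name][0]

    def ci(self, name: str) -> tuple[float, float]:
        return self.estimates[name][1:]


def required_columns(spec: ModelSpec) -> set:
    import re

    cols = {spec.response}
    for t in spec.fixed_terms:
        frag = FIXED_TERMS[t]
        cols |= set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", frag)) - {"C", "I", "np"}
    for t in spec.random_terms:
        cols |= set(_RANDOM_COLS[t])
    return cols


def prepare_model_columns(data: pd.DataFrame) -> pd.DataFrame:
    """Add derived model columns (log_age, age_years_sq) where inputs exist."""
    out = data.copy()
    if "age_years" in out.columns:
        out["log_age"] = np.log(out["age_years"].astype(float))
        out["age_years_sq"] = out["age_years"].astype(float) ** 2
    return out


def _from_ols(spec: ModelSpec, data: pd.DataFrame, criterion: str) -> ModelFit:
    res = smf.ols(spec.fixed_formula, data=data).fit()
    ci = res.conf_int()
    estimates = {
        name: (float(res.params[name]), float(ci.loc[name, 0]), float(ci.loc[name, 1]))
        for name in res.params.index
    }
    k = len(res.params) + 1  # + residual variance
    from .age_models import aicc as _aicc

    return ModelFit(
        spec=spec,
        estimates=estimates,
        variance_components={},
        resid_var=float(res.scale),
        loglik=float(res.llf),
        n_obs=int(res.nobs),
        k_params=k,
        aicc=_aicc(float(res.llf), k, int(res.nobs)),
        converged=True,
        fit_criterion=criterion,
        fixed_params=np.asarray(res.params),
        fixed_names=list(res.params.index),
    )


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, criterion: str = "REML") -> ModelFit:
    """Fit ``spec`` to ``data`` by ML or REML.

    Point estimates carry 95% Wald intervals (estimate +/- 1.96 SE).  The fit
    is deterministic given the data.  Non-convergence and boundary (singular)
    fits are flagged on the returned object rather than raised; downstream
    ranking refuses flagged fits unless overridden.
    """
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    missing = required_columns(spec) - set(data.columns)
    derivable = {"log_age", "age_years_sq"} & missing
    if derivable and "age_years" in data.columns:
        data = prepare_model_columns(data)
        missing -= derivable
    if missing:
        raise ValueError(f"data lacks required columns: {sorted(missing)}")
    n = len(data)
    if n == 0:
        raise ValueError("empty data")

    if not spec.random_terms:
        return _from_ols(spec, data, criterion)

    reml = criterion == "REML"
    single_intercept = (
        len(spec.random_terms) == 1 and spec.random_terms[0] != "age_log|cohort"
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if single_intercept:
            term = spec.random_terms[0]
            model = smf.mixedlm(
                spec.fixed_formula, data, groups=data[_RANDOM_COLS[term][0]]
            )
        else:
            vcf = {t: RANDOM_TERMS[t] for t in spec.random_terms}
            model = smf.mixedlm(
                spec.fixed_formula,
                data,
                groups=np.ones(n),
                vc_formula=vcf,
                re_formula="0",
            )
        try:
            try:
                res = model.fit(reml=reml, maxiter=200)
            except np.linalg.LinAlgError:
                res = model.fit(reml=reml, method="cg", maxiter=300)
            converged = bool(res.converged)
        except Exception as exc:  # noqa: BLE001 - surfaced via the fit object
            return ModelFit(
                spec=spec,
                estimates={},
                variance_components={},
                resid_var=float("nan"),
                loglik=float("nan"),
                n_obs=n,
                k_params=0,
                aicc=float("nan"),
                converged=False,
                fit_criterion=criterion,
                diagnostics=f"fit failed: {exc}",
            )
    messages = "; ".join(str(w.message) for w in caught)

    fe_names = list(res.fe_params.index)
    bse = res.bse_fe
    estimates = {}
    for name in fe_names:
        b = float(res.fe_params[name])
        se = float(bse[name])
        estimates[name] = (b, b - 1.96 * se, b + 1.96 * se)

    vcomp = {}
    if single_intercept:
        vcomp[spec.random_terms[0]] = float(np.asarray(res.cov_re)[0, 0])
    else:
        for i, t in enumerate(model.exog_vc.names):
            vcomp[t] = float(res.vcomp[i])
    resid_var = float(res.scale)
    singular = any(v < 1e-8 * (resid_var + 1e-12) for v in vcomp.values())

    k = len(fe_names) + len(vcomp) + 1
    from .age_models import aicc as _aicc

    return ModelFit(
        spec=spec,
        estimates=estimates,
        variance_components=vcomp,
        resid_var=resid_var,
        loglik=float(res.llf),
        n_obs=n,
        k_params=k,
        aicc=_aicc(float(res.llf), k, n),
        converged=converged,
        singular=singular,
        fit_criterion=criterion,
        diagnostics=messages,
        fixed_params=np.asarray(res.fe_params),
        fixed_names=fe_names,
    )
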