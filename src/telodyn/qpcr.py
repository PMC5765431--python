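"""qPCR relative telomere length: quantification, QC filtering, sample summaries.

Relative telomere length (RTL) is the telomere qPCR signal normalised to a
single-copy control gene (GAPDH) and a reference sample, computed with the
two-efficiency relative-quantification formula

    RTL = E_T^(refCq_T - Cq_T) / E_G^(refCq_G - Cq_G)

where E is the per-cycle amplification efficiency of each reaction (ideally 2)
and refCq the quantification cycle of the plate's reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QcThresholds",
    "qc_filter",
    "compute_rtl",
    "summarize_samples",
    "storage_time_diagnostic",
]

#: covariate columns carried through from measurements to sample summaries
SAMPLE_COVARIATES = [
    "catch_date",
    "age_class",
    "cohort",
    "catch_year",
    "sex",
    "tarsus_mm",
    "mass_g",
    "territory",
    "territory_quality",
    "group_size",
    "helpers",
    "density",
    "insect_abundance",
    "storage_years",
]


@dataclass
class QcThresholds:
    """Pre-analysis sample inclusion thresholds.

    Defaults: DNA concentration at least 15 ng/ul (mean of three reads),
    260/280 absorbance within [1.8, 2.0] inclusive, 260/230 strictly above
    1.8, and Cq outlier exclusion (telomere Cq > 25 or GAPDH Cq > 26 treated
    as failed reactions).
    """

    min_conc: float = 15.0
    ratio_260_280: tuple[float, float] = (1.8, 2.0)
    min_260_230: float = 1.8
    max_cq_tel: float = 25.0
    max_cq_gapdh: float = 26.0

    def validate(self) -> None:
        lo, hi = self.ratio_260_280
        if lo > hi:
            raise ValueError("260/280 interval lower bound exceeds upper bound")
        for name in ("min_conc", "min_260_230", "max_cq_tel", "max_cq_gapdh"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# fixed check order: first failing reason is reported
_QC_CHECKS = ("conc", "260/280", "260/230", "cq_tel", "cq_gapdh")


def qc_filter(
    records: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition measurement records into (kept, excluded-with-reason).

    A record is kept iff conc >= min_conc, 260/280 inside the closed interval,
    260/230 > min_260_230, Cq_tel <= max_cq_tel and Cq_gapdh <= max_cq_gapdh.
    Records with missing QC fields are excluded with reason ``missing_qc``.
    Cq checks are skipped (vacuously passed) when the table carries
    precomputed RTL and no Cq values at all.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()

    conc = pd.to_numeric(records.get("dna_conc_ng_ul"), errors="coerce")
    r280 = pd.to_numeric(records.get("a260_280"), errors="coerce")
    r230 = pd.to_numeric(records.get("a260_230"), errors="coerce")
    missing = conc.isna() | r280.isna() | r230.isna()

    lo, hi = thresholds.ratio_260_280
    fails = {
        "conc": conc < thresholds.min_conc,
        "260/280": (r280 < lo) | (r280 > hi),
        "260/230": r230 <= thresholds.min_260_230,
    }
    for col, name, mx in (
        ("cq_tel", "cq_tel", thresholds.max_cq_tel),
        ("cq_gapdh", "cq_gapdh", thresholds.max_cq_gapdh),
    ):
        if col in records.columns and records[col].notna().any():
            cq = pd.to_numeric(records[col], errors="coerce")
            if "rtl" not in records.columns or records["rtl"].isna().any():
                missing = missing | cq.isna()
            fails[name] = cq > mx
        else:
            if "rtl" not in records.columns:
                raise ValueError("records must carry a Cq pair or a precomputed rtl column")
            fails[name] = pd.Series(False, index=records.index)

    reason = pd.Series(pd.NA, index=records.index, dtype="object")
    for name in reversed(_QC_CHECKS):
        reason = reason.mask(fails[name].fillna(False), name)
    reason = reason.mask(missing, "missing_qc")

    excluded_mask = reason.notna()
    kept = records.loc[~excluded_mask].copy()
    excluded = records.loc[excluded_mask].copy()
    excluded["qc_reason"] = reason.loc[excluded_mask]
    return kept, excluded


def compute_rtl(
    cq_tel,
    cq_gapdh,
    ref_cq_tel: float,
    ref_cq_gapdh: float,
    eff_tel: float = 1.78,
    eff_gapdh: float = 1.92,
):
    """Two-efficiency relative quantification of telomere signal.

    Returns ``eff_tel**(ref_cq_tel - cq_tel) / eff_gapdh**(ref_cq_gapdh - cq_gapdh)``;
    strictly decreasing in ``cq_tel`` and increasing in ``cq_gapdh``.
    Accepts scalars or arrays.
    """
    for e in (eff_tel, eff_gapdh):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiencies must lie in (1, 2]")
    cq_tel = np.asarray(cq_tel, dtype=float)
    cq_gapdh = np.asarray(cq_gapdh, dtype=float)
    if not (
        np.all(np.isfinite(cq_tel))
        and np.all(np.isfinite(cq_gapdh))
        and np.isfinite(ref_cq_tel)
        and np.isfinite(ref_cq_gapdh)
    ):
        raise ValueError("Cq inputs must be finite")
    out = eff_tel ** (ref_cq_tel - cq_tel) / eff_gapdh ** (ref_cq_gapdh - cq_gapdh)
    return out.item() if out.ndim == 0 else out


def summarize_samples(kept: pd.DataFrame) -> pd.DataFrame:
    """Collapse measurements to one row per sample.

    ``rtl`` is the arithmetic mean of the measurement RTLs (replicate
    averaging on the RTL scale), ``sqrt_rtl`` the square root of that mean.
    Covariates are carried through unchanged; conflicting covariate values
    within a sample raise an error naming the sample.  Output is ordered by
    (bird, age, sample).
    """
    if "rtl" not in kept.columns or kept["rtl"].isna().any():
        raise ValueError("every record needs an rtl value (given or computed)")

    sort_cols = ["sample_id"] + [c for c in ("run_index", "plate_id") if c in kept.columns]
    kept = kept.sort_values(sort_cols, kind="mergesort")

    cov_cols = [c for c in SAMPLE_COVARIATES if c in kept.columns]
    for col in ["bird_id", "age_years"] + cov_cols:
        n_distinct = kept.groupby("sample_id")[col].nunique(dropna=False)
        bad = n_distinct[n_distinct > 1]
        if len(bad):
            raise ValueError(
                f"conflicting values of {col!r} within sample(s): {list(bad.index[:5])}"
            )

    g = kept.groupby("sample_id", sort=False)
    out = g.agg(
        bird_id=("bird_id", "first"),
        age_years=("age_years", "first"),
        rtl=("rtl", "mean"),
        n_measurements=("rtl", "size"),
        **{c: (c, "first") for c in cov_cols},
    )
    out["sqrt_rtl"] = np.sqrt(out["rtl"])
    out["plate_ids"] = g["plate_id"].agg(lambda s: tuple(sorted(set(s))))
    out["plate_id"] = g["plate_id"].first()  # representative plate for random-effect use
    out = out.reset_index()
    cols = [
        "bird_id", "sample_id", "age_years", "rtl", "sqrt_rtl",
        "n_measurements", "plate_ids", "plate_id",
    ]
    out = out[cols + cov_cols]
    return out.sort_values(["bird_id", "age_years", "sample_id"], kind="mergesort").reset_index(
        drop=True
    )


def storage_time_diagnostic(samples: pd.DataFrame):
    """Slope of sqrt-RTL on sample storage time (years), adults only.

    A simple linear regression on samples from birds older than 1 year checks
    that telomere estimates do not drift with time in storage.  Returns
    ``(slope, (ci_low, ci_high))`` from the OLS fit.
    """
    adults = samples.loc[samples["age_years"] > 1.0]
    if "storage_years" not in adults.columns or adults["storage_years"].isna().all():
        raise ValueError("storage_years column required")
    if len(adults) < 3:
        raise ValueError("need at least 3 adult samples for the storage diagnostic")
    X = sm.add_constant(adults["storage_years"].to_numpy(float))
    fit = sm.OLS(adults["sqrt_rtl"].to_numpy(float), X).fit()
    lo, hi = fit.conf_int()[1]
    return float(fit.params[1]), (float(lo), float(hi))
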