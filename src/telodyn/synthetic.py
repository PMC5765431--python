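"""Synthetic longitudinal telomere studies with known generative truth.

The generator emulates the structure of a long-term cooperative-breeder field
study: birds hatch in annual cohorts, are blood-sampled repeatedly over life at
ages recorded on a discrete rounding grid (nestling = 1 month, fledgling = 6
months, subadult = 10 months, adults to the nearest year), and each sample is
assayed for relative telomere length (RTL) by qPCR on randomly assigned plates,
a fraction of samples being re-run on a second plate.

Truth is defined on the sqrt-RTL scale, the scale on which the downstream
models operate, so simulated effect sizes are directly comparable to fitted
coefficients.  The true sqrt-RTL of bird *i* from cohort *c* at age *t* is

    u = alpha + a_c + (beta + b_c) * log(t) + ind_i + sum_k gamma_k x_k + J_i(t)

with cohort intercepts ``a_c ~ N(0, sigma_cohort^2)``, cohort slopes
``b_c ~ N(0, sigma_slope^2)``, individual intercepts ``ind_i ~ N(0, sigma_id^2)``
and ``J_i`` a nondecreasing jump process: on each inter-sample interval, with
probability ``p_elong`` an Exponential(mean ``elongation_mean``) elongation bout
is added.  Each qPCR run observes ``u + p_r + eps`` with a shared plate effect
``p_r ~ N(0, sigma_plate^2)`` and run noise ``eps ~ N(0, sigma_meas^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimTruth", "SyntheticStudy", "simulate_study", "emit_cq", "AGE_GRID_JUVENILE"]

#: juvenile rounding grid (years): nestling, fledgling, subadult
AGE_GRID_JUVENILE = (1.0 / 12.0, 0.5, 10.0 / 12.0)


def _default_covariate_effects() -> dict:
    # effects per unit z-score (continuous) or for males vs females (sex),
    # on the sqrt-RTL scale; insect abundance positive, tarsus negative
    return {"insect_abundance": 0.02, "tarsus_mm": -0.01, "sex": 0.01}


@dataclass
class SimTruth:
    """Generative parameters of a synthetic study.

    Defaults emulate the study design the analysis targets: 22 hatch-year
    cohorts, ~1,000 birds, ~1,700 samples with repeated sampling, a loglinear
    age decline of -0.07 per log-year on the sqrt-RTL scale, cohort-varying
    intercepts and slopes, sporadic elongation bouts, and a two-level qPCR
    observation model (plate effects plus run noise) producing inter-plate
    repeatability near 0.68 and intra-plate repeatability near 0.73-0.74.
    """

    n_cohorts: int = 22
    birds_per_cohort: int = 46
    baseline_sqrt_rtl: float = 1.0
    log_age_slope: float = -0.07
    cohort_intercept_sd: float = 0.015
    cohort_slope_sd: float = 0.02
    individual_sd: float = 0.03
    plate_sd: float = 0.035
    replicate_sd: float = 0.073
    elongation_prob: float = 0.5
    elongation_mean: float = 0.1225
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    samples_per_bird_mean: float = 1.65
    replicate_fraction: float = 0.25
    seed: int = 0
    first_cohort_year: int = 1993
    sqrt_rtl_floor: float = 0.05
    runs_per_plate: int = 30

    def validate(self) -> None:
        if self.n_cohorts < 1 or self.birds_per_cohort < 1:
            raise ValueError("n_cohorts and birds_per_cohort must be >= 1")
        for name in ("cohort_intercept_sd", "cohort_slope_sd", "individual_sd",
                     "plate_sd", "replicate_sd", "elongation_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("elongation_prob", "replicate_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.samples_per_bird_mean < 1.0:
            raise ValueError("samples_per_bird_mean must be >= 1")
        if self.sqrt_rtl_floor <= 0:
            raise ValueError("sqrt_rtl_floor must be positive")

    def with_(self, **kwargs) -> "SimTruth":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SyntheticStudy:
    """A simulated study: per-run measurement table plus retained truth."""

    measurements: pd.DataFrame
    truth: SimTruth
    true_trajectories: pd.DataFrame

    def __post_init__(self):
        m = self.measurements
        if len(m) and m.groupby("sample_id").size().min() < 1:
            raise ValueError("every sample needs at least one measurement")


def error_only_truth(**overrides) -> SimTruth:
    """A truth with no true within-individual change: flat age trajectory, no
    elongation, no cohort slopes and no covariate effects.  Under this regime
    within-individual and within-sample RTL differences are identically
    distributed, which is the null the elongation test battery calibrates
    against."""
    base = SimTruth(
        log_age_slope=0.0,
        cohort_slope_sd=0.0,
        elongation_prob=0.0,
        covariate_effects={},
    )
    return base.with_(**overrides)


def _segmented_cumsum(values: np.ndarray, first_of_group: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at rows flagged as the first of their group.

    Requires values[first_of_group] == 0 so the group offset is exact.
    """
    cs = np.cumsum(values)
    offsets = np.where(first_of_group, cs, 0.0)
    np.maximum.accumulate(offsets, out=offsets)
    return cs - offsets


def _age_class(age: np.ndarray) -> np.ndarray:
    out = np.full(age.shape, "adult", dtype=object)
    out[np.isclose(age, AGE_GRID_JUVENILE[0])] = "nestling"
    out[np.isclose(age, AGE_GRID_JUVENILE[1])] = "fledgling"
    out[np.isclose(age, AGE_GRID_JUVENILE[2])] = "subadult"
    return out


def simulate_study(truth: SimTruth) -> SyntheticStudy:
    """Generate a complete synthetic study from a :class:`SimTruth`.

    Fully determined by ``truth`` (including ``truth.seed``).  Returns a
    :class:`SyntheticStudy` whose ``measurements`` table has one row per qPCR
    run in the long-format study schema (Cq columns left empty; see
    :func:`emit_cq`), and whose ``true_trajectories`` table records the
    noise-free sqrt-RTL per sample.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)

    n_birds = truth.n_cohorts * truth.birds_per_cohort
    cohort_idx = np.repeat(np.arange(truth.n_cohorts), truth.birds_per_cohort)
    cohort_year = truth.first_cohort_year + cohort_idx

    # --- per-cohort and per-bird latent effects -------------------------------
    a_c = rng.normal(0.0, truth.cohort_intercept_sd, truth.n_cohorts)
    b_c = rng.normal(0.0, truth.cohort_slope_sd, truth.n_cohorts)
    ind = rng.normal(0.0, truth.individual_sd, n_birds)
    sex = rng.choice(["F", "M"], n_birds)
    tarsus = rng.normal(25.5, 0.8, n_birds)
    territory = rng.integers(0, 110, n_birds)

    # --- sampling schedule ----------------------------------------------------
    n_samples = 1 + rng.poisson(truth.samples_per_bird_mean - 1.0, n_birds)
    n_samples = np.minimum(n_samples, 5)
    total = int(n_samples.sum())
    bird_row = np.repeat(np.arange(n_birds), n_samples)
    within_k = np.concatenate([np.arange(k) for k in n_samples])
    first_row = within_k == 0

    # first capture: mostly juveniles, some adults (grid per the ageing rules)
    first_ages = np.array(AGE_GRID_JUVENILE + (1.0, 2.0, 3.0, 4.0, 5.0))
    first_p = np.array([0.20, 0.28, 0.14, 0.10, 0.10, 0.08, 0.06, 0.04])
    first_age = rng.choice(first_ages, n_birds, p=first_p / first_p.sum())

    gaps = rng.choice([1.0, 2.0, 3.0], total, p=[0.55, 0.30, 0.15])
    gaps[first_row] = 0.0
    cum_gap = _segmented_cumsum(gaps, first_row)
    # later captures fall on whole adult years: a juvenile first caught on the
    # sub-year grid is next seen at age gap_1 (>= 1), an adult at first_age + gap_1
    start = np.where(first_age < 1.0, 0.0, first_age)
    age = np.where(first_row, first_age[bird_row], start[bird_row] + cum_gap)

    # --- true trajectories ----------------------------------------------------
    jump_hit = rng.random(total) < truth.elongation_prob
    jump_size = rng.exponential(truth.elongation_mean, total) if truth.elongation_mean > 0 else np.zeros(total)
    jumps = np.where(jump_hit & ~first_row, jump_size, 0.0)
    jumps[first_row] = 0.0
    J = _segmented_cumsum(jumps, first_row)

    coh_row = cohort_idx[bird_row]
    log_age = np.log(age)
    u = (
        truth.baseline_sqrt_rtl
        + a_c[coh_row]
        + (truth.log_age_slope + b_c[coh_row]) * log_age
        + ind[bird_row]
        + J
    )

    # --- covariates -----------------------------------------------------------
    catch_year = cohort_year[bird_row] + np.where(age < 0.75, 0, np.round(age)).astype(int)
    years = np.arange(catch_year.min(), catch_year.max() + 1)
    insect_by_year = rng.lognormal(0.7, 0.35, len(years))
    density_by_year = rng.normal(320.0, 25.0, len(years))
    yi = catch_year - years[0]
    insect = insect_by_year[yi]
    density = density_by_year[yi]
    tq = rng.lognormal(0.0, 0.5, total)  # territory quality per territory-year
    group_size = 2 + rng.poisson(0.6, total)
    helpers = np.minimum(rng.poisson(0.3, total), group_size - 2)
    mass = 15.0 + 0.5 * (tarsus[bird_row] - 25.5) + rng.normal(0.0, 0.8, total)

    sample_cov = {
        "insect_abundance": insect,
        "territory_quality": tq,
        "density": density.astype(float),
        "group_size": group_size.astype(float),
        "helpers": helpers.astype(float),
        "tarsus_mm": tarsus[bird_row],
        "mass_g": mass,
    }
    sex_row = sex[bird_row]
    for name, gamma in truth.covariate_effects.items():
        if gamma == 0.0:
            continue
        if name == "sex":
            u = u + gamma * (sex_row == "M").astype(float)
        elif name in sample_cov:
            x = sample_cov[name]
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            u = u + gamma * z
        else:
            raise ValueError(f"unknown covariate effect: {name!r}")

    # --- per-sample bookkeeping ----------------------------------------------
    bird_id = np.array([f"B{i:04d}" for i in range(n_birds)])
    sample_id = np.array([f"B{b:04d}_s{k}" for b, k in zip(bird_row, within_k)])
    dna_conc = np.maximum(rng.normal(60.0, 25.0, total), 0.5)
    a260_280 = rng.normal(1.90, 0.04, total)
    a260_230 = rng.normal(2.10, 0.15, total)
    storage_years = rng.uniform(0.0, 6.0, total)
    month = rng.integers(6, 10, total)  # main breeding season
    day = rng.integers(1, 29, total)
    catch_date = pd.to_datetime(
        pd.DataFrame({"year": catch_year, "month": month, "day": day})
    ).dt.strftime("%Y-%m-%d")

    # --- qPCR runs: every sample once, a fraction re-run on a second plate ----
    is_rep = rng.random(total) < truth.replicate_fraction
    run_sample = np.concatenate([np.arange(total), np.flatnonzero(is_rep)])
    run_index = np.concatenate([np.zeros(total, int), np.ones(int(is_rep.sum()), int)])
    n_runs = len(run_sample)
    n_plates = max(2, int(round(n_runs / truth.runs_per_plate)))
    plate = rng.integers(0, n_plates, n_runs)
    # force replicate runs onto a different plate than the first run
    rep_rows = np.flatnonzero(run_index == 1)
    same = plate[rep_rows] == plate[run_sample[rep_rows]]
    plate[rep_rows[same]] = (plate[rep_rows[same]] + 1 + rng.integers(0, n_plates - 1, int(same.sum()))) % n_plates

    plate_eff = rng.normal(0.0, truth.plate_sd, n_plates)
    eps = rng.normal(0.0, truth.replicate_sd, n_runs)
    obs_sqrt = u[run_sample] + plate_eff[plate] + eps
    floored = obs_sqrt < truth.sqrt_rtl_floor
    obs_sqrt = np.maximum(obs_sqrt, truth.sqrt_rtl_floor)

    s = run_sample  # sample row backing each run
    measurements = pd.DataFrame(
        {
            "bird_id": bird_id[bird_row[s]],
            "sample_id": sample_id[s],
            "plate_id": np.array([f"P{p:03d}" for p in plate]),
            "run_index": run_index,
            "catch_date": catch_date.to_numpy()[s],
            "age_years": age[s],
            "age_class": _age_class(age[s]),
            "cohort": cohort_year[bird_row[s]],
            "catch_year": catch_year[s],
            "sex": sex_row[s],
            "rtl": obs_sqrt**2,
            "cq_tel": np.nan,
            "cq_gapdh": np.nan,
            "dna_conc_ng_ul": dna_conc[s],
            "a260_280": a260_280[s],
            "a260_230": a260_230[s],
            "tarsus_mm": sample_cov["tarsus_mm"][s],
            "mass_g": mass[s],
            "territory": territory[bird_row[s]],
            "territory_quality": tq[s],
            "group_size": group_size[s].astype(float),
            "helpers": helpers[s].astype(float),
            "density": density[s],
            "insect_abundance": insect[s],
            "storage_years": storage_years[s],
            "floored": floored,
        }
    )
    measurements = measurements.sort_values(
        ["bird_id", "age_years", "sample_id", "run_index"], kind="mergesort"
    ).reset_index(drop=True)

    true_traj = pd.DataFrame(
        {
            "bird_id": bird_id[bird_row],
            "sample_id": sample_id,
            "age_years": age,
            "true_sqrt_rtl": u,
        }
    )
    return SyntheticStudy(measurements=measurements, truth=truth, true_trajectories=true_traj)


def emit_cq(
    study: SyntheticStudy,
    efficiencies: tuple[float, float] = (1.78, 1.92),
    reference_cqs: tuple[float, float] = (14.0, 16.0),
    gapdh_cq_sd: float = 0.8,
) -> pd.DataFrame:
    """Fill Cq columns consistent with each run's observed RTL.

    The GAPDH Cq is drawn near its plate-reference value (template-amount
    variation), and the telomere Cq is then solved from the two-efficiency
    relative-quantification identity so that quantification of the emitted Cq
    pair reproduces the observed RTL exactly:

        RTL = E_T^(refT - CqT) / E_G^(refG - CqG)

    Returns a copy of the measurement table with ``cq_tel``/``cq_gapdh`` set.
    """
    e_tel, e_gapdh = efficiencies
    ref_tel, ref_gapdh = reference_cqs
    for e in (e_tel, e_gapdh):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiencies must lie in (1, 2]")
    m = study.measurements.copy()
    rtl = m["rtl"].to_numpy(float)
    if np.any(~np.isfinite(rtl)) or np.any(rtl <= 0):
        raise ValueError("observed RTL must be positive and finite")
    rng = np.random.default_rng(np.random.SeedSequence([study.truth.seed, 0x5C9]))
    cq_gapdh = ref_gapdh + rng.normal(0.0, gapdh_cq_sd, len(m))
    # solve E_T^(refT - CqT) = RTL * E_G^(refG - CqG) for CqT
    delta_tel = (np.log(rtl) + (ref_gapdh - cq_gapdh) * np.log(e_gapdh)) / np.log(e_tel)
    m["cq_tel"] = ref_tel - delta_tel
    m["cq_gapdh"] = cq_gapdh
    return m
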