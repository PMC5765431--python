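"""Within-individual telomere change versus qPCR measurement error.

Two empirical change distributions are contrasted: delta-RTL_individual, the
change in replicate-averaged RTL between consecutive samples of the same
bird, and delta-RTL_sample, the change between independent qPCR runs of the
*same* sample on separate plates — a pure measurement-error distribution.  If
apparent telomere lengthening were nothing but error, the two distributions
would coincide; the battery tests this with a Brown-Forsythe variance-equality
test, signed-split rank-sum comparisons of the negative and positive tails, a
binomial mixed model for the probability of lengthening with age, and a
per-bird consistency test comparing lifetime RTL gains against residual
scatter around each bird's own age trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import BinomialGlmmFit, fit_binomial_glmm

__all__ = [
    "ElongationReport",
    "pair_individual_deltas",
    "pair_sample_deltas",
    "variance_equality_test",
    "signed_split_test",
    "lengthening_probability_model",
    "simons_consistency_test",
    "build_report",
]


@dataclass
class ElongationReport:
    n_individual: int
    n_sample: int
    prop_lengthening: float
    levene_F: float
    levene_p: float
    wilcoxon_decrease_p: float
    wilcoxon_increase_p: float
    simons_p: float
    simons_reverse_p: float
    simons_direction: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pair_individual_deltas(samples: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-sample RTL changes within birds (later minus earlier).

    One row per adjacent pair in each bird's age-ordered sampling sequence;
    delta count equals sum over birds of (n_samples - 1).
    """
    s = samples.sort_values(["bird_id", "age_years"], kind="mergesort")
    dup = s.duplicated(subset=["bird_id", "age_years"], keep=False)
    if dup.any():
        birds = s.loc[dup, "bird_id"].unique()
        raise ValueError(f"duplicate sampling ages within bird(s): {list(birds[:5])}")
    g = s.groupby("bird_id")
    out = pd.DataFrame(
        {
            "unit_id": s["bird_id"],
            "sample_id_first": s["sample_id"],
            "delta_rtl": g["rtl"].shift(-1) - s["rtl"],
            "age_first": s["age_years"],
            "interval_years": g["age_years"].shift(-1) - s["age_years"],
            "kind": "individual",
        }
    ).dropna(subset=["delta_rtl"])
    return out.reset_index(drop=True)


def pair_sample_deltas(measurements: pd.DataFrame) -> pd.DataFrame:
    """Within-sample RTL changes between qPCR runs on distinct plates.

    One delta per consecutive run pair per sample (run order as recorded);
    pairs whose two runs share a plate are skipped — the measurement-error
    null needs fully independent reactions.
    """
    sort_cols = [c for c in ("sample_id", "run_index", "plate_id") if c in measurements.columns]
    m = measurements.sort_values(sort_cols, kind="mergesort")
    g = m.groupby("sample_id")
    pairs = pd.DataFrame(
        {
            "unit_id": m["sample_id"],
            "bird_id": m["bird_id"],
            "delta_rtl": g["rtl"].shift(-1) - m["rtl"],
            "plate_a": m["plate_id"],
            "plate_b": g["plate_id"].shift(-1),
            "age_first": m["age_years"],
        }
    ).dropna(subset=["delta_rtl"])
    same_plate = pairs["plate_a"] == pairs["plate_b"]
    if same_plate.any():
        import warnings

        warnings.warn(
            f"skipping {int(same_plate.sum())} replicate pair(s) run on a single plate",
            stacklevel=2,
        )
        pairs = pairs[~same_plate]
    pairs["interval_years"] = 0.0
    pairs["kind"] = "sample"
    return pairs.drop(columns=["plate_a", "plate_b"]).reset_index(drop=True)


def variance_equality_test(individual, sample, center: str = "median") -> tuple[float, float]:
    """Brown-Forsythe (median-centred Levene) test of equal variance between
    the within-individual and within-sample delta distributions.

    Returns (F, p) with F on (1, n-2) degrees of freedom; ``center="mean"``
    gives the classical Levene variant.
    """
    x = np.asarray(individual, dtype=float)
    y = np.asarray(sample, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both delta vectors need length >= 2")
    zx = np.abs(x - (np.median(x) if center == "median" else np.mean(x)))
    zy = np.abs(y - (np.median(y) if center == "median" else np.mean(y)))
    if np.ptp(zx) == 0 and np.ptp(zy) == 0 and np.mean(zx) == np.mean(zy):
        return 0.0, 1.0
    F, p = stats.levene(x, y, center=center)
    return float(F), float(p)


def _rank_sum_p(a: np.ndarray, b: np.ndarray, exact_max: int = 12) -> float:
    """Two-sided two-sample rank-sum p-value.

    Exact null enumeration when both groups are small and tie-free; otherwise
    the normal approximation with tie correction (and continuity correction).
    """
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= exact_max and len(b) <= exact_max and not ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def signed_split_test(individual, sample) -> tuple[float, float]:
    """Compare the decrease and increase tails of the two delta distributions.

    Splits each distribution at zero (exact zeros excluded) and runs a
    rank-sum test within each sign class: negative individual deltas against
    negative sample deltas, and positive against positive.  Returns
    ``(decrease_p, increase_p)``; a side with an empty subgroup is reported
    as NaN (not applicable) rather than fabricated.
    """
    x = np.asarray(individual, dtype=float)
    y = np.asarray(sample, dtype=float)
    ps = []
    for sign in (-1, 1):
        xa = x[x * sign > 0]
        ya = y[y * sign > 0]
        if len(xa) == 0 or len(ya) == 0:
            ps.append(float("nan"))
        else:
            ps.append(_rank_sum_p(xa, ya))
    return ps[0], ps[1]


def lengthening_probability_model(
    deltas: pd.DataFrame, max_interval_years: float = 2.0, min_pairs: int = 30
) -> BinomialGlmmFit:
    """Binomial GLMM for the probability that RTL lengthened between samples.

    Restricted to pairs taken within ``max_interval_years`` of each other;
    response is 1{delta > 0}, fixed effect is log age at the first sample,
    random intercept per bird, Laplace-approximate likelihood.
    """
    d = deltas.loc[deltas["interval_years"] <= max_interval_years].copy()
    if len(d) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs within {max_interval_years} years")
    y = (d["delta_rtl"] > 0).to_numpy(int)
    X = np.column_stack([np.ones(len(d)), np.log(d["age_first"].to_numpy(float))])
    return fit_binomial_glmm(y, X, d["unit_id"].to_numpy(), names=["intercept", "log_age"])


def simons_consistency_test(
    samples: pd.DataFrame, min_measurements: int = 3, min_birds: int = 10
) -> tuple[float, str, pd.DataFrame]:
    """Per-bird consistency test of lifetime telomere gain against residual error.

    For every bird with at least ``min_measurements`` samples at >= 3 distinct
    ages, an ordinary least-squares line of RTL on age yields a residual
    standard deviation s_i; d_i is the overall change RTL_last - RTL_first.
    Among birds that gained (d_i > 0), a one-sided Wilcoxon signed-rank test
    asks whether gains exceed the residual-error prediction for a first-to-last
    difference, sqrt(2) * s_i — under pure measurement error
    Var(RTL_last - RTL_first) = 2 sigma_i^2, so exceeding that scale signals
    consistent lengthening.  The reverse direction (error prediction exceeds
    gains, i.e. increases look like error) is also tested.  Returns
    ``(p_lengthening, direction, per_bird_table)`` where the table carries
    d_i, s_i and the squared-scale residual variance.
    """
    s = samples.sort_values(["bird_id", "age_years"], kind="mergesort")
    rows = []
    for bird, grp in s.groupby("bird_id"):
        if len(grp) < min_measurements or grp["age_years"].nunique() < 3:
            continue
        x = grp["age_years"].to_numpy(float)
        y = grp["rtl"].to_numpy(float)
        beta, alpha = np.polyfit(x, y, 1)
        resid = y - (alpha + beta * x)
        dof = len(y) - 2
        s_i = math.sqrt(float(np.sum(resid**2)) / dof)
        rows.append(
            {
                "bird_id": bird,
                "n": len(y),
                "d_i": float(y[-1] - y[0]),
                "resid_sd": s_i,
                "resid_var": s_i**2,
            }
        )
    per_bird = pd.DataFrame(rows)
    if len(per_bird) < min_birds:
        raise ValueError(
            f"need >= {min_birds} birds with >= {min_measurements} measurements"
        )
    gained = per_bird.loc[per_bird["d_i"] > 0]
    if gained.empty:
        return float("nan"), "no_gains", per_bird
    diff = gained["d_i"].to_numpy() - math.sqrt(2.0) * gained["resid_sd"].to_numpy()
    if np.all(diff == 0):
        return 1.0, "none", per_bird
    p_len = float(stats.wilcoxon(diff, alternative="greater").pvalue)
    p_rev = float(stats.wilcoxon(diff, alternative="less").pvalue)
    if p_len < 0.05:
        direction = "lengthening"
    elif p_rev < 0.05:
        direction = "error_dominates"
    else:
        direction = "none"
    per_bird.attrs["p_lengthening"] = p_len
    per_bird.attrs["p_reverse"] = p_rev
    return p_len, direction, per_bird


def build_report(
    samples: pd.DataFrame, measurements: pd.DataFrame, min_simons_birds: int = 10
) -> ElongationReport:
    """Run the full battery and assemble an :class:`ElongationReport`."""
    ind = pair_individual_deltas(samples)
    samp = pair_sample_deltas(measurements)
    di = ind["delta_rtl"].to_numpy()
    ds = samp["delta_rtl"].to_numpy()
    F, p = variance_equality_test(di, ds)
    dec_p, inc_p = signed_split_test(di, ds)
    nonzero = di[di != 0]
    prop = float((nonzero > 0).mean()) if len(nonzero) else float("nan")
    try:
        simons_p, direction, per_bird = simons_consistency_test(
            samples, min_birds=min_simons_birds
        )
        rev_p = float(per_bird.attrs.get("p_reverse", float("nan")))
    except ValueError:
        simons_p, rev_p, direction = float("nan"), float("nan"), "insufficient_data"
    return ElongationReport(
        n_individual=len(ind),
        n_sample=len(samp),
        prop_lengthening=prop,
        levene_F=F,
        levene_p=p,
        wilcoxon_decrease_p=dec_p,
        wilcoxon_increase_p=inc_p,
        simons_p=simons_p,
        simons_reverse_p=rev_p,
        simons_direction=direction,
    )
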