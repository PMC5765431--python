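"""Study-table schema, validated readers/writers, and the pipeline driver.

One long-format CSV in, tidy CSV/JSON out.  Every output table begins with
provenance header comments (config hash, seed, stage) on ``#`` lines, which
:func:`pandas.read_csv` skips with ``comment="#"``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AGE_GRID_JUVENILE

__all__ = ["STUDY_SCHEMA", "read_study_table", "write_table", "run_pipeline"]

log = logging.getLogger("telodyn")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[telodyn:%(levelname)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

#: required column -> dtype kind ('s' string, 'f' float, 'i' int)
STUDY_SCHEMA = {
    "bird_id": "s",
    "sample_id": "s",
    "plate_id": "s",
    "catch_date": "s",
    "age_years": "f",
    "age_class": "s",
    "cohort": "i",
    "sex": "s",
    "dna_conc_ng_ul": "f",
    "a260_280": "f",
    "a260_230": "f",
    "tarsus_mm": "f",
    "mass_g": "f",
    "territory_quality": "f",
    "group_size": "f",
    "helpers": "f",
    "density": "f",
    "insect_abundance": "f",
}

_AGE_CLASS_RULE = {
    "nestling": AGE_GRID_JUVENILE[0],
    "fledgling": AGE_GRID_JUVENILE[1],
    "subadult": AGE_GRID_JUVENILE[2],
}


def read_study_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format study CSV.

    All validation failures are collected and reported together with row
    numbers.  Either a Cq pair (``cq_tel`` + ``cq_gapdh``) or a precomputed
    ``rtl`` column must be present.  Dates must parse as ISO-8601.
    """
    schema = schema or STUDY_SCHEMA
    df = pd.read_csv(path, comment="#")
    missing = sorted(set(schema) - set(df.columns))
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    has_cq = "cq_tel" in df.columns and df["cq_tel"].notna().any()
    has_rtl = "rtl" in df.columns and df["rtl"].notna().any()
    if not (has_cq or has_rtl):
        raise ValueError("table must carry either Cq columns (cq_tel, cq_gapdh) or rtl")

    problems: list[str] = []
    for col, kind in schema.items():
        if kind in ("f", "i"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            for i in bad[:20]:
                problems.append(f"row {i}: column {col!r} not numeric: {df.at[i, col]!r}")
            df[col] = coerced
    dates = pd.to_datetime(df["catch_date"], format="%Y-%m-%d", errors="coerce")
    for i in df.index[dates.isna()][:20]:
        problems.append(f"row {i}: catch_date not ISO-8601: {df.at[i, 'catch_date']!r}")

    nonpos = df.index[~(df["age_years"] > 0)]
    for i in nonpos[:20]:
        problems.append(f"row {i}: age_years must be positive")

    # age_class must agree with the rounding grid
    for cls, grid_age in _AGE_CLASS_RULE.items():
        wrong = df.index[(df["age_class"] == cls) & ~np.isclose(df["age_years"], grid_age)]
        for i in wrong[:20]:
            problems.append(
                f"row {i}: age_class {cls!r} inconsistent with age_years {df.at[i, 'age_years']}"
            )
    wrong_adult = df.index[(df["age_class"] == "adult") & (df["age_years"] < 1.0)]
    for i in wrong_adult[:20]:
        problems.append(f"row {i}: age_class 'adult' with age_years < 1")

    bad_cohort = df.index[df["cohort"] > dates.dt.year.fillna(9999)]
    for i in bad_cohort[:20]:
        problems.append(f"row {i}: cohort year after catch date")

    if problems:
        raise ValueError("study table validation failed:\n  " + "\n  ".join(problems))
    df["cohort"] = df["cohort"].astype(int)
    if "catch_year" not in df.columns:
        df["catch_year"] = dates.dt.year
    return df


def _provenance(stage: str, seed, config_hash: str) -> str:
    return (
        f"# telodyn stage={stage}\n# seed={seed}\n# config_hash={config_hash}\n"
    )


def write_table(df: pd.DataFrame, path, stage: str, seed, config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(stage, seed, config_hash))
        df.to_csv(fh, index=False)


def config_hash(config: dict) -> str:
    """Hash of the analytic configuration (output location excluded)."""
    cfg = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis pipeline from a configuration mapping.

    Stages: simulate/load -> qc -> quantify -> summarize -> repeatability ->
    age models -> elongation battery -> environment models.  Each stage
    writes its artifacts under ``output_dir`` and logs input/output row
    counts; identical config + seed give identical outputs.  A stage failure
    raises with the stage name; artifacts written so far are kept.
    """
    from . import (
        QcThresholds,
        adjusted_individual_repeatability,
        build_cross_sectional_set,
        build_longitudinal_set,
        compute_rtl,
        emit_cq,
        fit_full_rtl_model,
        fit_lmm,
        icc,
        qc_filter,
        rank_models,
        simulate_study,
        summarize_samples,
        within_between_contrast,
        within_subject_centre,
    )
    from .elongation import build_report, pair_sample_deltas
    from .env_model import r2_nakagawa
    from .synthetic import SimTruth

    out_dir = Path(config.get("output_dir", "telodyn_out"))
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    stages = config.get("stages", {})

    def enabled(name: str) -> bool:
        return bool(stages.get(name, True))

    results: dict = {"config_hash": chash, "seed": seed}
    stage = "input"
    try:
        if "input" in config and config["input"]:
            measurements = read_study_table(config["input"])
        else:
            sim_cfg = dict(config.get("simulation", {}))
            sim_cfg.setdefault("seed", seed)
            truth = SimTruth(**sim_cfg)
            study = simulate_study(truth)
            measurements = emit_cq(study)
            write_table(measurements, out_dir / "study.csv", "simulate", seed, chash)
            write_table(
                study.true_trajectories, out_dir / "truth.csv", "simulate", seed, chash
            )
        log.info("input: %d measurement rows", len(measurements))

        stage = "qc"
        if enabled("qc"):
            kept, excluded = qc_filter(measurements, QcThresholds(**config.get("qc", {})))
            report = pd.concat(
                [
                    kept[["sample_id"]].assign(kept=True, reason=""),
                    excluded[["sample_id"]].assign(kept=False, reason=excluded["qc_reason"]),
                ]
            )
            write_table(report, out_dir / "qc_report.csv", "qc", seed, chash)
            log.info("qc: kept %d / %d rows", len(kept), len(measurements))
        else:
            kept = measurements
            log.info("qc: disabled, passing through %d rows", len(kept))

        stage = "quantify"
        if enabled("quantify") and kept["rtl"].isna().any():
            q = config.get("quantification", {})
            kept = kept.copy()
            kept["rtl"] = compute_rtl(
                kept["cq_tel"],
                kept["cq_gapdh"],
                q.get("ref_cq_tel", 14.0),
                q.get("ref_cq_gapdh", 16.0),
                q.get("eff_tel", 1.78),
                q.get("eff_gapdh", 1.92),
            )
        stage = "summarize"
        samples = summarize_samples(kept)
        write_table(samples, out_dir / "samples.csv", "summarize", seed, chash)
        log.info("summarize: %d samples from %d rows", len(samples), len(kept))

        if enabled("repeatability"):
            stage = "repeatability"
            rep_rows = []
            multi = samples.loc[samples["n_measurements"] >= 2, "sample_id"]
            inter = kept[kept["sample_id"].isin(multi)]
            r = icc(inter["rtl"], inter["sample_id"], n_boot=config.get("n_boot", 1000), seed=seed)
            rep_rows.append(("inter_plate_rtl", r))
            results["inter_plate_icc"] = r.estimate
            radj = adjusted_individual_repeatability(samples)
            rep_rows.append(("individual_adjusted", radj))
            results["individual_repeatability"] = radj.estimate
            rep = pd.DataFrame(
                [
                    {
                        "level": name,
                        "estimate": rr.estimate,
                        "ci_low": rr.ci_low,
                        "ci_high": rr.ci_high,
                        "n_groups": rr.n_groups,
                        "n_obs": rr.n_obs,
                    }
                    for name, rr in rep_rows
                ]
            )
            write_table(rep, out_dir / "repeatability.csv", "repeatability", seed, chash)
            log.info("repeatability: %d levels", len(rep))

        if enabled("age_models"):
            stage = "age_models"
            fits = [
                fit_lmm(s, samples, criterion="ML")
                for s in build_cross_sectional_set(samples)[:10]
            ]
            ranking = rank_models(fits, allow_flagged=True)
            tbl = ranking.to_frame()
            write_table(tbl, out_dir / "age_models_cross.csv", "age_models", seed, chash)
            results["top_cross_sectional_model"] = ranking.best.name
            centred = within_subject_centre(samples)
            lfits = [
                fit_lmm(s, centred, criterion="ML") for s in build_longitudinal_set(centred)
            ]
            lrank = rank_models(lfits, allow_flagged=True)
            write_table(lrank.to_frame(), out_dir / "age_models_long.csv", "age_models", seed, chash)
            results["top_longitudinal_model"] = lrank.best.name
            contrast, ci, _ = within_between_contrast(centred)
            results["within_between_contrast"] = contrast
            log.info("age_models: top cross-sectional model %r", ranking.best.name)

        if enabled("elongation"):
            stage = "elongation"
            report = build_report(samples, kept)
            results["elongation"] = report.to_dict()
            (out_dir / "elongation.json").parent.mkdir(parents=True, exist_ok=True)
            with open(out_dir / "elongation.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            log.info(
                "elongation: %d individual vs %d sample deltas",
                report.n_individual,
                report.n_sample,
            )

        if enabled("env_models"):
            stage = "env_models"
            # the random slope among cohorts can fail to converge on small or
            # weakly structured data; fall back to progressively simpler
            # random structures so the stage still reports coefficients
            fit = fit_full_rtl_model(samples)
            if not fit.converged:
                for randoms in (("bird_id", "plate_id", "cohort"), ("bird_id",)):
                    fit = fit_full_rtl_model(samples, randoms=randoms)
                    if fit.converged:
                        log.info("env_models: random structure reduced to %s", randoms)
                        break
            coefs = pd.DataFrame(
                [
                    {"term": k, "estimate": b, "ci_low": lo, "ci_high": hi}
                    for k, (b, lo, hi) in fit.estimates.items()
                ]
            )
            write_table(coefs, out_dir / "env_full_model.csv", "env_models", seed, chash)
            from .env_model import standardize_covariates

            if fit.converged:
                r2 = r2_nakagawa(fit, standardize_covariates(samples))
                results["env_marginal_r2"] = r2.marginal
                results["env_conditional_r2"] = r2.conditional
                log.info("env_models: marginal R2 %.3f", r2.marginal)
            else:
                log.warning("env_models: no converged fit; R2 not computed")

        with open(out_dir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=float)
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
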