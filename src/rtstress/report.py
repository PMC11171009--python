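"""Cohort-level summaries and end-to-end pipeline orchestration.

Reporting mirrors the tables a clinical stress study prints: the
frequency distribution of the quantized stress-score bins, stress-case
counts by day and sex, per-day male/female comparisons with
nonparametric tests, model evaluation grids and the stress vs
respiratory-irregularity association.  ``run_pipeline`` wires every
stage together from one config dict and writes all artifacts as CSV /
JSON, logging attrition (masked segments, dropped intervals, excluded
cases) along the way.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import predict as predict_mod
from . import resp as resp_mod
from . import synth
from .config import default_config
from .types import CaseRecord

__all__ = [
    "summarize_distribution",
    "day_sex_comparisons",
    "run_pipeline",
]

log = logging.getLogger("rtstress")


def summarize_distribution(cases: Sequence[CaseRecord]) -> dict:
    """Frequency table of stress-score bins plus day/sex stress counts.

    Returns a dict with ``bins`` (one row per occupied score bin:
    count and percentage of all cases to 2 decimals), ``by_day`` and
    ``by_sex`` stressed-case counts, and headline shares: percentage
    of cases with any stress (score > 0) and above the 50% threshold.
    """
    if not cases:
        raise ValueError("need at least one case")
    scores = np.array([c.assessment.score for c in cases])
    stressed = np.array([c.assessment.stressed for c in cases])
    n = scores.size
    bins_order = sorted(set(scores.tolist()))
    bins = pd.DataFrame(
        {
            "score": bins_order,
            "count": [int(np.sum(scores == b)) for b in bins_order],
        }
    )
    bins["pct"] = (100.0 * bins["count"] / n).round(2)

    by_day = (
        pd.DataFrame(
            {
                "day": [c.day for c in cases],
                "stressed": stressed,
            }
        )
        .groupby("day")["stressed"]
        .agg(cases="size", stressed="sum")
        .reset_index()
    )
    by_sex = (
        pd.DataFrame(
            {
                "sex": [c.sex for c in cases],
                "stressed": stressed,
            }
        )
        .groupby("sex")["stressed"]
        .agg(cases="size", stressed="sum")
        .reset_index()
    )
    return {
        "n_cases": int(n),
        "bins": bins,
        "by_day": by_day,
        "by_sex": by_sex,
        "pct_nonzero": round(100.0 * float(np.mean(scores > 0)), 2),
        "pct_above_threshold": round(100.0 * float(np.mean(stressed)), 2),
    }


def day_sex_comparisons(
    cases: Sequence[CaseRecord], days: Sequence[int] = (1, 2, 3, 4)
) -> dict:
    """Per-day male/female stress-score means +- sd with tests.

    For each day a two-sided Mann-Whitney U test (exact on small
    samples) compares male vs female scores; a Friedman test across
    the listed days (patients with complete data) probes a trend, per
    sex and overall.  Cells without data are NaN / marked unavailable.
    """
    df = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "sex": [c.sex for c in cases],
            "day": [c.day for c in cases],
            "score": [c.assessment.score for c in cases],
        }
    )
    means = pd.DataFrame(index=["M", "F"], columns=list(days), dtype=float)
    sds = pd.DataFrame(index=["M", "F"], columns=list(days), dtype=float)
    pvals: dict[int, float] = {}
    for day in days:
        sub = df[df["day"] == day]
        groups = {}
        for sex in ("M", "F"):
            vals = sub.loc[sub["sex"] == sex, "score"].to_numpy()
            groups[sex] = vals
            if vals.size:
                means.loc[sex, day] = float(np.mean(vals))
                sds.loc[sex, day] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if groups["M"].size >= 2 and groups["F"].size >= 2:
            method = "exact" if (groups["M"].size < 20 and groups["F"].size < 20
                                 and not _has_ties(groups)) else "asymptotic"
            pvals[day] = float(
                stats.mannwhitneyu(
                    groups["M"], groups["F"], alternative="two-sided",
                    method=method,
                ).pvalue
            )
        else:
            pvals[day] = float("nan")

    friedman = {}
    for label, sexes in (("all", ("M", "F")), ("M", ("M",)), ("F", ("F",))):
        sub = df[df["sex"].isin(sexes) & df["day"].isin(days)]
        wide = sub.pivot_table(
            index="patient_id", columns="day", values="score"
        ).dropna()
        if wide.shape[0] >= 2 and wide.shape[1] == len(days):
            cols = [wide[d].to_numpy() for d in days]
            if np.ptp(np.concatenate(cols)) == 0:
                friedman[label] = {"statistic": float("nan"),
                                   "p": float("nan"),
                                   "note": "no-variation"}
            else:
                try:
                    res = stats.friedmanchisquare(*cols)
                    friedman[label] = {
                        "statistic": float(res.statistic),
                        "p": float(res.pvalue),
                    }
                except ValueError:  # zero variance across all days
                    friedman[label] = {"statistic": float("nan"),
                                       "p": float("nan"),
                                       "note": "no-variation"}
        else:
            friedman[label] = {"statistic": float("nan"), "p": float("nan"),
                               "note": "insufficient data"}

    formatted = pd.DataFrame(index=["Male", "Female", "p-value"],
                             columns=[f"Day {d}" for d in days], dtype=object)
    for day in days:
        for sex, rowname in (("M", "Male"), ("F", "Female")):
            m, s = means.loc[sex, day], sds.loc[sex, day]
            formatted.loc[rowname, f"Day {day}"] = (
                "n/a" if pd.isna(m) else f"{m:.2f} ± {s:.2f}%"
            )
        p = pvals[day]
        formatted.loc["p-value", f"Day {day}"] = (
            "n/a" if np.isnan(p) else f"{p:.4f}"
        )
    return {
        "means": means, "sds": sds, "p_values": pvals,
        "friedman": friedman, "table": formatted,
    }


def _has_ties(groups: dict) -> bool:
    pooled = np.concatenate([groups["M"], groups["F"]])
    return np.unique(pooled).size < pooled.size


def run_pipeline(config: Optional[dict] = None, outdir: str | Path = "out"):
    """Synthetic cohort end-to-end: generate, score, summarize,
    cross-validate, associate; write every artifact under ``outdir``.

    Deterministic under a fixed config seed: rerunning writes
    byte-identical CSV outputs.  Returns a dict of in-memory results.
    """
    cfg = config or default_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cc = cfg["cohort"]
    cohort_cfg = synth.CohortConfig(
        n_patients=cc["n_patients"],
        days_per_patient=tuple(cc["days_per_patient"]),
        sex_ratio=cc["sex_ratio"],
        age_range=tuple(cc["age_range"]),
        p_stress=cc["p_stress"],
        shift_magnitude=cc["shift_magnitude"],
        resp_slope=cc["resp_slope"],
        resp_intercept=cc["resp_intercept"],
        patient_sd=cc["patient_sd"],
        noise_sd=cc["noise_sd"],
        seed=cfg["seed"],
    )
    cases = synth.generate_cohort(cohort_cfg)
    log.info("generated %d cases from %d patients",
             len(cases), cohort_cfg.n_patients)

    table = synth.case_table(cases)
    table.to_csv(outdir / "cases.csv", index=False)

    summary = summarize_distribution(cases)
    summary["bins"].to_csv(outdir / "score_distribution.csv", index=False)
    summary["by_day"].to_csv(outdir / "stress_by_day.csv", index=False)
    summary["by_sex"].to_csv(outdir / "stress_by_sex.csv", index=False)

    comparisons = day_sex_comparisons(cases)
    comparisons["table"].to_csv(outdir / "day_sex_table.csv")

    pc = cfg["predict"]
    dataset = predict_mod.build_dataset(cases, pc["dataset_type"])
    ml_report, bin_report = predict_mod.crossvalidate(
        dataset, pc["model"], k=pc["folds"], seed=cfg["seed"],
        grouped=pc["grouped"],
    )
    metrics = {
        "dataset_type": pc["dataset_type"],
        "model": pc["model"],
        "multilabel": {
            m: getattr(ml_report, m)
            for m in ("emr", "accuracy", "recall", "precision", "f1")
        },
        "binary": {
            m: getattr(bin_report, m)
            for m in ("accuracy", "recall", "precision", "f1")
        },
    }

    associations = []
    for outcome in ("phase", "amplitude"):
        for kind in ("score10", "binary"):
            r = resp_mod.associate(cases, predictor_kind=kind, outcome=outcome)
            associations.append(
                {
                    "irregularity": outcome, "predictor": kind,
                    "beta": r.beta, "lcl": r.lcl, "ucl": r.ucl,
                    "p_value": r.p_value,
                }
            )
    assoc_df = pd.DataFrame(associations)
    assoc_df.to_csv(outdir / "associations.csv", index=False,
                    float_format="%.6g")

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    (outdir / "config_echo.json").write_text(
        json.dumps(cfg, indent=1, default=str)
    )
    return {
        "cases": cases, "case_table": table, "summary": summary,
        "comparisons": comparisons, "metrics": metrics,
        "associations": assoc_df,
    }
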