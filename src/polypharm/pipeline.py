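"""End-to-end orchestration: inputs -> diaries -> counts -> reports.

The pipeline loads (or simulates) the three archives, restricts to
patients with at least one dispensing in the observation year, builds the
shifted supply diaries, applies each polypharmacy definition over each
time window, and produces four delimited reports:

* ``prevalence.csv`` — patients per polypharmacy class bin (with the
  >=5 / >=10 summary rows), per definition and window;
* ``characteristics.csv`` — the on-polypharmacy cohort profile (size,
  % female, age, drug count, prior hospitalization, outcome);
* ``associations.csv`` — crude and adjusted odds ratios for the >=5-drug
  flag;
* ``class_associations.csv`` — per-class-bin odds ratios (reference 1-4).

Every reported number is recomputable by calling the module functions
directly with the same configuration; reports carry no private logic.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._calendar import year_length
from .association import assemble_cohort, fit_models, long_stay_filter
from .config import RunConfig
from .definitions import DEFAULT_DEFINITIONS, annual_ddd_totals, filter_segments
from .io import read_discharges, read_refills, read_registry
from .supply_diary import build_segments
from .synthetic_claims import generate_population
from .windows import (
    CLASS_BINS,
    WindowScheme,
    count_no_coverage,
    count_table,
    percent,
    summarize_table,
)

logger = logging.getLogger("polypharm")

__all__ = ["load_inputs", "analyze", "run_pipeline"]


def load_inputs(cfg: RunConfig):
    """Load the three archives from disk, or simulate them."""
    if cfg.simulate is not None:
        sim = generate_population(cfg.simulate)
        registry, refills, discharges = sim.registry, sim.refills, sim.discharges
        dates = pd.to_datetime(refills["dispense_date"])
        refills = refills.assign(
            dispense_date=dates,
            dispense_day=(
                dates - pd.Timestamp(dt.date(cfg.observation_year, 1, 1))
            ).dt.days.astype(int),
            record_id=np.arange(len(refills)),
        )
        registry = registry.assign(
            birth_date=pd.to_datetime(registry["birth_date"]),
            death_date=pd.to_datetime(registry["death_date"].replace("", pd.NaT)),
        )
        discharges = discharges.assign(
            admission_date=pd.to_datetime(discharges["admission_date"]),
            discharge_date=pd.to_datetime(discharges["discharge_date"]),
        )
        return registry, refills, discharges
    return (
        read_registry(cfg.registry_path, cfg.delimiter),
        read_refills(cfg.refills_path, cfg.observation_year, cfg.delimiter),
        read_discharges(cfg.discharges_path, cfg.delimiter),
    )


def analyze(registry: pd.DataFrame, refills: pd.DataFrame,
            discharges: pd.DataFrame, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured definition x window and return the report tables."""
    year = cfg.observation_year
    n_days = year_length(year)

    in_year = refills["dispense_day"].between(0, n_days - 1)
    cohort = pd.Index(sorted(refills.loc[in_year, "patient_id"].unique()),
                      name="patient_id")
    logger.info("cohort: %d patients with >=1 dispensing in %d", len(cohort), year)

    segments = build_segments(refills, rounding=cfg.rounding)
    totals = annual_ddd_totals(refills, segments, (0, n_days),
                               attribution=cfg.ddd_attribution)
    seg_year = segments.copy()
    seg_year["start_day"] = seg_year["start_day"].clip(lower=0)
    seg_year["end_day"] = seg_year["end_day"].clip(upper=n_days)
    seg_year = seg_year[seg_year["end_day"] > seg_year["start_day"]]
    logger.info("diary: %d segments, %d within %d", len(segments),
                len(seg_year), year)

    if cfg.min_stay_days is not None:
        discharges = long_stay_filter(discharges, cfg.min_stay_days)
        logger.info("long-stay filter (> %d days): %d discharge records kept",
                    cfg.min_stay_days, len(discharges))

    outcome_window = None
    if cfg.outcome_start is not None and cfg.outcome_end is not None:
        outcome_window = (cfg.outcome_start, cfg.outcome_end)

    prev_rows, char_rows, assoc_rows, class_rows = [], [], [], []
    for dname in cfg.definitions:
        spec = DEFAULT_DEFINITIONS[dname]
        segs_d = filter_segments(seg_year, spec, totals)
        for gran in cfg.granularities:
            scheme = WindowScheme(gran, cfg.aggregation, cfg.covered_fraction)
            if cfg.counting_mode == "dispensing":
                counts = count_no_coverage(
                    refills[in_year], gran, year, patients=cohort
                )
                if spec.excluded_atc_prefixes or spec.annual_ddd_threshold:
                    kept = filter_segments(
                        seg_year.assign(), spec, totals
                    )[["patient_id", "atc4"]].drop_duplicates()
                    df = refills[in_year].copy()
                    df["atc4"] = df["atc_code"].astype(str).str[:5]
                    df = df.merge(kept, on=["patient_id", "atc4"])
                    counts = count_no_coverage(df, gran, year, patients=cohort)
            else:
                counts = count_table(segs_d, gran, year, patients=cohort)
            summary = summarize_table(counts, scheme)

            n = len(summary)
            for b in CLASS_BINS:
                k = int((summary["class_bin"] == b).sum())
                prev_rows.append((dname, gran, b, k, percent(k, n)))
            for flag in ("poly5", "poly10"):
                k = int(summary[flag].sum())
                prev_rows.append((dname, gran, flag, k, percent(k, n)))

            rows = assemble_cohort(registry, discharges, summary,
                                   observation_year=year,
                                   outcome_window=outcome_window)
            poly = rows[rows["poly5"]]
            poly_kept = poly[~poly["excluded"]]
            char_rows.append(
                (
                    dname, gran, len(poly),
                    percent(int((poly["sex"] == "F").sum()), max(len(poly), 1)),
                    round(float(poly["summary_count"].mean()), 2)
                    if len(poly) else float("nan"),
                    round(float(poly["summary_count"].std(ddof=1)), 2)
                    if len(poly) > 1 else float("nan"),
                    round(float(poly["age_years"].mean()), 1)
                    if len(poly) else float("nan"),
                    round(float(poly["age_years"].std(ddof=1)), 1)
                    if len(poly) > 1 else float("nan"),
                    percent(int((poly["prior_hospitalizations"] > 0).sum()),
                            max(len(poly), 1)),
                    percent(int(poly_kept["outcome"].sum()), max(len(poly_kept), 1)),
                )
            )
            logger.info("%s/%s: %d on polypharmacy, %d excluded rows",
                        dname, gran, len(poly), int(rows["excluded"].sum()))

            label = f"{dname}/{gran}"
            for est in fit_models(rows, "poly5", label=label):
                assoc_rows.append(
                    (dname, gran, "adjusted" if est.adjusted else "crude",
                     est.term, est.or_value, est.lcl, est.ucl, est.converged)
                )
            for est in fit_models(rows, "class_bin", label=label):
                class_rows.append(
                    (dname, gran, "adjusted" if est.adjusted else "crude",
                     est.term, est.or_value, est.lcl, est.ucl, est.converged)
                )

    return {
        "prevalence": pd.DataFrame(
            prev_rows,
            columns=["definition", "window", "class_bin", "n", "percent"],
        ),
        "characteristics": pd.DataFrame(
            char_rows,
            columns=["definition", "window", "n_poly", "pct_female",
                     "drugs_mean", "drugs_sd", "age_mean", "age_sd",
                     "pct_prior_hospitalization", "pct_outcome"],
        ),
        "associations": pd.DataFrame(
            assoc_rows,
            columns=["definition", "window", "model", "term", "or_value",
                     "lcl", "ucl", "converged"],
        ),
        "class_associations": pd.DataFrame(
            class_rows,
            columns=["definition", "window", "model", "term", "or_value",
                     "lcl", "ucl", "converged"],
        ),
    }


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle.

    All tables are computed before anything is written, so a failure never
    leaves a partial bundle behind.
    """
    logging.basicConfig(level=cfg.log_level)
    registry, refills, discharges = load_inputs(cfg)
    results = analyze(registry, refills, discharges, cfg)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    import yaml

    provenance = {"polypharm_version": __version__, "config": cfg.resolved()}
    (out / "run_config.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))
    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)
    logger.info("wrote %d report files to %s", len(results) + 1, out)
    return results
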