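"""End-to-end analysis: detections in, summary/overlap/CCF reports out.

``run_all`` wires the modules together: read and validate the detection
and site tables, collapse grouped taxa, apply the 1-h independence
filter, attach sun times and solar offsets to every event, then produce

* a detection summary by species and season,
* per-species diel classification and seasonal offset ANOVA (+ Tukey),
* per-pair activity overlap with bootstrap CIs, and
* per-pair circular cross-correlation functions with significant lag
  ranges and peak lags,

each as a tidy DataFrame, optionally written as CSV.  Given the same
inputs and seed the report files are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from camtrapdiel import records_io
from camtrapdiel.activity import bin_hourly, classify_diel, times_to_radians
from camtrapdiel.ccf_analysis import circular_ccf, critical_t, summarise_ccf, t_statistic
from camtrapdiel.overlap_analysis import DEFAULT_BOOTSTRAP_REPS, estimate_overlap
from camtrapdiel.seasonal_stats import anova_offsets
from camtrapdiel.solar import SEASONS, offset_from_sun, season_of, sun_times
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_all"]

#: Predator-prey pairs analysed by default (grouped taxa).
DEFAULT_PAIRS = [
    ("fox", "hare"),
    ("fox", "rabbit"),
    ("fox", "wood_mouse"),
    ("pine_marten", "squirrel"),
    ("pine_marten", "wood_mouse"),
]

#: Grouped taxa: congeneric species pooled under one analysis label.
DEFAULT_SPECIES_GROUPS = {
    "hare": ["irish_hare", "european_hare"],
    "squirrel": ["grey_squirrel", "red_squirrel"],
}

#: Fewer events than this in a species-season and the pair analysis for
#: that season is skipped (mirrors sparse-winter gaps in real surveys).
MIN_EVENTS_PER_GROUP = 10


@dataclass
class AnalysisConfig:
    """Everything run_all needs; loadable from a flat YAML file."""

    detections_path: str | Path
    sites_path: str | Path
    output_dir: str | Path | None = None
    independence_hours: float = 1.0
    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    species_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SPECIES_GROUPS.items()}
    )
    estimator: str = "auto"
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    seed: int = 0
    tails: int = 1
    location_key: str = "site_id"
    adjust: float = 1.0
    schema: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairs" in raw:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        return cls(**raw)


def _apply_groups(df: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    mapping = {member: group for group, members in groups.items() for member in members}
    out = df.copy()
    out["species"] = out["species"].map(lambda s: mapping.get(s, s))
    return out


def _solar_day_lookup(df: pd.DataFrame, sites: pd.DataFrame):
    site_info = sites.set_index("site_id")
    cache: dict = {}

    def lookup(site_id: str, d):
        key = (site_id, d)
        if key not in cache:
            row = site_info.loc[site_id]
            cache[key] = sun_times(d, row["latitude"], row["longitude"], row["utc_offset"])
        return cache[key]

    return lookup


def _stars(p: float) -> str:
    if p <= 0.0001:
        return "***"
    if p <= 0.001:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def run_all(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns (and optionally writes) the reports."""
    try:
        detections = records_io.read_detections(config.detections_path, config.schema)
        sites = records_io.read_sites(config.sites_path)
    except Exception as exc:
        raise RuntimeError(f"stage=read: {exc}") from exc

    detections = _apply_groups(detections, config.species_groups)
    stream = records_io.filter_independent(
        detections, timedelta(hours=config.independence_hours)
    )
    events = stream.records

    missing = [
        sp
        for pair in config.pairs
        for sp in pair
        if sp not in set(events["species"])
    ]
    for sp in missing:
        logger.warning("configured pair species %r not present in data", sp)

    try:
        lookup = _solar_day_lookup(events, sites)
        solar_days = [
            lookup(site, ts.date()) for site, ts in zip(events["site_id"], events["timestamp"])
        ]
        events = events.assign(
            season=[season_of(ts.date()) for ts in events["timestamp"]],
            offset_hours=[
                offset_from_sun(ts.to_pydatetime(), sd).hours
                for ts, sd in zip(events["timestamp"], solar_days)
            ],
        )
    except Exception as exc:
        raise RuntimeError(f"stage=solar: {exc}") from exc

    solar_by_index = dict(zip(events.index, solar_days))

    # --- detection summary (species x season counts) -------------------
    summary = (
        events.pivot_table(
            index="species", columns="season", values="timestamp", aggfunc="count", fill_value=0
        )
        .reindex(columns=list(SEASONS), fill_value=0)
        .astype(int)
    )
    summary["total"] = summary.sum(axis=1)
    summary = summary.reset_index().rename_axis(None, axis=1)

    # --- diel classification + seasonal ANOVA per species --------------
    class_rows, anova_rows, tukey_rows = [], [], []
    for sp, grp in events.groupby("species"):
        label = classify_diel(
            grp["timestamp"].tolist(), [solar_by_index[i] for i in grp.index]
        )
        class_rows.append({"species": sp, "diel_class": label, "n_events": len(grp)})
        by_season = {
            season: g["offset_hours"].to_numpy() for season, g in grp.groupby("season")
        }
        try:
            test = anova_offsets(by_season, species=sp)
        except ValueError as exc:
            logger.warning("ANOVA skipped for %s: %s", sp, exc)
            continue
        anova_rows.append(
            {
                "species": sp,
                "F": round(test.F, 4),
                "df_between": test.df_between,
                "df_within": test.df_within,
                "p": float(f"{test.p:.4g}"),
            }
        )
        for _, row in test.tukey.iterrows():
            tukey_rows.append({"species": sp, **row.to_dict()})

    classification = pd.DataFrame(class_rows)
    anova = pd.DataFrame(anova_rows)
    tukey = pd.DataFrame(tukey_rows)

    # --- pairwise overlap and CCF --------------------------------------
    rng = np.random.default_rng(config.seed)
    overlap_rows, ccf_rows = [], []
    t_crit = critical_t(0.05, 22, tails=config.tails)
    for predator, prey in config.pairs:
        present = set(events["species"])
        if predator not in present or prey not in present:
            continue
        try:
            shared_events, shared = records_io.restrict_to_cooccurrence(
                events, predator, prey, config.location_key
            )
        except ValueError as exc:
            logger.warning("pair (%s, %s) skipped: %s", predator, prey, exc)
            continue
        for season in ["annual", *SEASONS]:
            sub = (
                shared_events
                if season == "annual"
                else shared_events[shared_events["season"] == season]
            )
            ta = sub.loc[sub["species"] == predator, "timestamp"]
            tb = sub.loc[sub["species"] == prey, "timestamp"]
            if len(ta) < MIN_EVENTS_PER_GROUP or len(tb) < MIN_EVENTS_PER_GROUP:
                logger.info(
                    "pair (%s, %s) %s skipped: %d vs %d events",
                    predator, prey, season, len(ta), len(tb),
                )
                continue
            res = estimate_overlap(
                times_to_radians(ta),
                times_to_radians(tb),
                pair=(predator, prey),
                season=season,
                reps=config.bootstrap_reps,
                seed=rng,
                estimator=config.estimator,
                adjust=config.adjust,
            )
            overlap_rows.append(
                {
                    "predator": predator,
                    "prey": prey,
                    "season": season,
                    "delta_pct": round(100.0 * res.delta),
                    "ci_low_pct": round(100.0 * res.ci95[0]),
                    "ci_high_pct": round(100.0 * res.ci95[1]),
                    "delta": round(res.delta, 4),
                    "category": res.category,
                    "estimator": res.estimator,
                    "n_predator": res.n_a,
                    "n_prey": res.n_b,
                }
            )

            px = bin_hourly(ta, predator, season)
            py = bin_hourly(tb, prey, season)
            try:
                lags, r = circular_ccf(px.counts, py.counts)
            except ValueError as exc:
                logger.warning("CCF skipped for (%s, %s) %s: %s", predator, prey, season, exc)
                continue
            ccf = summarise_ccf(lags, r, n=24, t_crit=t_crit, pair=(predator, prey), season=season)
            if not ccf.significant_ranges:
                ccf_rows.append(
                    {
                        "predator": predator,
                        "prey": prey,
                        "season": season,
                        "from_lag": "",
                        "to_lag": "",
                        "peak_lag": "",
                        "t": "",
                        "r": "",
                        "significance": "",
                    }
                )
                continue
            for lo, hi in ccf.significant_ranges:
                in_range = (ccf.lags >= lo) & (ccf.lags <= hi)
                cand = sorted(
                    zip(ccf.lags[in_range], ccf.r[in_range]),
                    key=lambda lr: (-abs(lr[1]), abs(lr[0]), lr[0]),
                )
                pk_lag, pk_r = int(cand[0][0]), float(cand[0][1])
                pk_t = abs(t_statistic(pk_r, 24))
                p_one = float(stats.t.sf(pk_t, 22))
                ccf_rows.append(
                    {
                        "predator": predator,
                        "prey": prey,
                        "season": season,
                        "from_lag": lo,
                        "to_lag": hi,
                        "peak_lag": pk_lag,
                        "t": round(pk_t, 2),
                        "r": round(pk_r, 3),
                        "significance": _stars(p_one),
                    }
                )

    overlap = pd.DataFrame(overlap_rows)
    ccf_report = pd.DataFrame(ccf_rows)

    reports = {
        "summary": summary,
        "classification": classification,
        "anova": anova,
        "tukey": tukey,
        "overlap": overlap,
        "ccf": ccf_report,
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in reports.items():
            df.to_csv(out / f"{name}.csv", index=False)
        logger.info("reports written to %s", out)
    return reports
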