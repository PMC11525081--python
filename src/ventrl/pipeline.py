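"""Flag-driven time-varying discretization of irregular ventilation records.

Raw long-format events become per-patient step tables: trajectories are cut
on a 4-hour grid, cut again wherever a deterioration flag fires (SpO2
dropping under 90%, PaO2 under 60 mm Hg, or pH leaving [7.25, 7.45]),
sub-hour fragments are merged away, values are time-weighted-averaged
within each step under last-observation-carried-forward, missing steps are
imputed from the nearest earlier (then next) step, and features are
normalized to (0, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    DYNAMIC_VARIABLES,
    FLAG_VARIABLES,
    SETTING_VARIABLES,
    STATIC_VARIABLES,
    FeatureSchema,
)
from .simulator import RawEventTable

logger = logging.getLogger(__name__)

_KNOWN_VARIABLES = set(DYNAMIC_VARIABLES) | set(STATIC_VARIABLES) | set(SETTING_VARIABLES) | {
    "icu_stay_number"
}

_EPS = 1e-9


@dataclass(frozen=True)
class FlagRuleSet:
    """Thresholds that define acute-deterioration flags."""

    spo2_floor: float = 90.0
    pao2_floor: float = 60.0
    ph_low: float = 7.25
    ph_high: float = 7.45

    def __post_init__(self) -> None:
        if self.ph_low >= self.ph_high:
            raise ValueError("ph_low must be below ph_high")
        if min(self.spo2_floor, self.pao2_floor) <= 0:
            raise ValueError("flag floors must be positive")

    def violates(self, variable: str, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if variable == "spo2":
            return values < self.spo2_floor
        if variable == "pao2":
            return values < self.pao2_floor
        if variable == "ph":
            return (values < self.ph_low) | (values > self.ph_high)
        raise KeyError(variable)


@dataclass(frozen=True)
class SegmentationConfig:
    """Step-grid parameters: 4-h base steps, 1-h minimum, 48-h horizon."""

    base_step_h: float = 4.0
    min_step_h: float = 1.0
    horizon_h: float = 48.0

    def __post_init__(self) -> None:
        if not 0 < self.min_step_h <= self.base_step_h <= self.horizon_h:
            raise ValueError("require 0 < min_step_h <= base_step_h <= horizon_h")


@dataclass(frozen=True)
class CohortFilterConfig:
    """Inclusion criteria applied before any discretization."""

    min_age: float = 16.0
    min_vent_h: float = 24.0
    max_vent_h: float = 14 * 24.0
    first_icu_stay_only: bool = True


def _vent_duration(events: pd.DataFrame, outcomes: pd.DataFrame) -> pd.Series:
    """Ventilation duration per patient: wean time if weaned, else last event time."""
    last_obs = events.groupby("patient_id")["time_h"].max()
    wean = outcomes.set_index("patient_id")["wean_time_h"]
    dur = wean.reindex(last_obs.index)
    return dur.fillna(last_obs)


def _static_value(events: pd.DataFrame, variable: str) -> pd.Series:
    sub = events[events["variable"] == variable]
    return sub.groupby("patient_id")["value"].first()


def apply_cohort_filters(
    table: RawEventTable,
    filters: CohortFilterConfig | None = None,
) -> tuple[RawEventTable, dict]:
    """Apply the cohort inclusion criteria in fixed order.

    Order: age >= 16; first ICU stay; ventilation >= 24 h; ventilation
    <= 14 days; mortality/height/sex present; at least one recorded value
    for each ventilator setting. Returns the filtered table and the
    per-criterion exclusion counts.
    """
    filters = filters or CohortFilterConfig()
    events, outcomes = table.events, table.outcomes
    alive = pd.Index(outcomes["patient_id"].unique())
    report: dict[str, int] = {}

    def drop(name: str, excluded: pd.Index) -> None:
        nonlocal alive
        excluded = excluded.intersection(alive)
        report[name] = len(excluded)
        alive = alive.difference(excluded)

    age = _static_value(events, "age")
    drop("age_under_16", alive[(age.reindex(alive) < filters.min_age).fillna(False)])

    if filters.first_icu_stay_only:
        stay = _static_value(events, "icu_stay_number")
        drop("not_first_icu_stay", alive[(stay.reindex(alive) > 1).fillna(False)])
    else:
        report["not_first_icu_stay"] = 0

    dur = _vent_duration(events, outcomes).reindex(alive)
    drop("ventilation_under_24h", alive[(dur < filters.min_vent_h).fillna(True)])
    dur = dur.reindex(alive)
    drop("ventilation_over_14d", alive[(dur > filters.max_vent_h).fillna(True)])

    mort = outcomes.set_index("patient_id")["hospital_mortality"].reindex(alive)
    height = _static_value(events, "height").reindex(alive)
    sex = _static_value(events, "sex").reindex(alive)
    drop(
        "missing_mortality_height_or_sex",
        alive[mort.isna() | height.isna() | sex.isna()],
    )

    have_settings = (
        events[events["variable"].isin(SETTING_VARIABLES)]
        .groupby("patient_id")["variable"]
        .nunique()
        .reindex(alive)
        .fillna(0)
    )
    drop("missing_ventilator_settings", alive[have_settings < len(SETTING_VARIABLES)])

    kept = RawEventTable(
        events[events["patient_id"].isin(alive)].reset_index(drop=True),
        outcomes[outcomes["patient_id"].isin(alive)].reset_index(drop=True),
    )
    report["retained"] = len(alive)
    return kept, report


def detect_flags(
    events: pd.DataFrame,
    rules: FlagRuleSet | None = None,
) -> dict[str, np.ndarray]:
    """Per-patient sorted times at which a deterioration flag fires.

    A flag fires at a violating observation whose immediately preceding
    observation of the same variable (if any) did not violate — i.e. at
    crossings into the abnormal range, so a sustained excursion raises one
    flag, not one per observation.
    """
    rules = rules or FlagRuleSet()
    unknown = set(events["variable"].unique()) - _KNOWN_VARIABLES
    if unknown:
        logger.warning("ignoring unknown variables: %s", sorted(unknown))

    out: dict[str, list[float]] = {}
    flagged = events[events["variable"].isin(FLAG_VARIABLES)]
    for (pid, var), grp in flagged.groupby(["patient_id", "variable"], sort=False):
        grp = grp.sort_values("time_h", kind="stable")
        bad = rules.violates(var, grp["value"].to_numpy())
        crossing = bad & np.r_[True, ~bad[:-1]]
        times = grp["time_h"].to_numpy()[crossing]
        if len(times):
            out.setdefault(pid, []).extend(times.tolist())
    return {pid: np.unique(np.asarray(t)) for pid, t in out.items()}


def segment_trajectory(
    flag_times: np.ndarray,
    cfg: SegmentationConfig,
    wean_time_h: float | None = None,
) -> np.ndarray:
    """Interval boundaries for one patient.

    The 4-hour grid anchored at ventilation onset is unioned with the flag
    times and truncated at min(horizon, wean time); fragments shorter than
    the 1-hour minimum are merged into their successor (the last fragment
    into its predecessor).
    """
    end = cfg.horizon_h
    if wean_time_h is not None and not np.isnan(wean_time_h):
        end = min(end, float(wean_time_h))
    if end <= 0:
        return np.array([])

    grid = np.arange(0.0, end + _EPS, cfg.base_step_h)
    flags = np.asarray(flag_times, dtype=float)
    flags = flags[(flags > _EPS) & (flags < end - _EPS)]
    bounds = np.unique(np.r_[grid, flags, end])
    # drop near-duplicate boundary points
    keep = np.r_[True, np.diff(bounds) > _EPS]
    bounds = bounds[keep]

    changed = True
    while changed and len(bounds) > 2:
        changed = False
        lengths = np.diff(bounds)
        for i, ln in enumerate(lengths):
            if ln < cfg.min_step_h - _EPS:
                # merge into successor; last interval merges into predecessor
                j = i + 1 if i + 1 < len(lengths) else i
                bounds = np.delete(bounds, j)
                changed = True
                break
    return bounds


def segment_cohort(
    table: RawEventTable,
    rules: FlagRuleSet | None = None,
    cfg: SegmentationConfig | None = None,
) -> dict[str, np.ndarray]:
    """Boundaries for every patient in a filtered event table."""
    cfg = cfg or SegmentationConfig()
    flags = detect_flags(table.events, rules)
    wean = table.outcomes.set_index("patient_id")["wean_time_h"]
    out = {}
    for pid in table.outcomes["patient_id"]:
        ft = flags.get(pid, np.array([]))
        out[pid] = segment_trajectory(ft, cfg, wean.get(pid, np.nan))
    return out


def _step_segments(
    times: np.ndarray, values: np.ndarray, start: float, end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant (value, duration) segments over [start, end) under LOCF."""
    i0 = np.searchsorted(times, start + _EPS)  # observations strictly inside
    inside_t = times[i0:]
    inside_t = inside_t[inside_t < end - _EPS]
    inside_v = values[i0 : i0 + len(inside_t)]
    # value holding at the interval start (last observation at or before start)
    j = np.searchsorted(times, start + _EPS)
    head_v = values[j - 1] if j > 0 else np.nan

    knots = np.r_[start, inside_t, end]
    vals = np.r_[head_v, inside_v]
    durs = np.diff(knots)
    ok = ~np.isnan(vals)
    return vals[ok], durs[ok]


def _step_average(times: np.ndarray, values: np.ndarray, start: float, end: float) -> float:
    """Duration-weighted LOCF average of one variable over [start, end)."""
    vals, durs = _step_segments(times, values, start, end)
    if not len(vals):
        return np.nan
    return float(np.sum(vals * durs) / np.sum(durs))


def _step_median(times: np.ndarray, values: np.ndarray, start: float, end: float) -> float:
    """Duration-weighted LOCF median over [start, end).

    Used for ventilator settings: when a setting changes inside a step, the
    median returns the value in force for most of the interval instead of a
    blend of levels that was never administered.
    """
    vals, durs = _step_segments(times, values, start, end)
    if not len(vals):
        return np.nan
    order = np.argsort(vals)
    cum = np.cumsum(durs[order])
    k = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(vals[order][min(k, len(vals) - 1)])


def aggregate_steps(
    table: RawEventTable,
    boundaries: dict[str, np.ndarray],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Time-weighted step averages for every schema feature and setting.

    Within each interval every observation holds until the next one (or
    the interval end); a value carried in from before the interval covers
    the head. Intervals with no observation before or inside get NaN.
    """
    variables = list(schema.names) + list(SETTING_VARIABLES)
    ev = table.events[table.events["variable"].isin(variables)]
    by_patient: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (pid, var), grp in ev.groupby(["patient_id", "variable"], sort=False):
        grp = grp.sort_values("time_h", kind="stable")
        by_patient.setdefault(pid, {})[var] = (
            grp["time_h"].to_numpy(float),
            grp["value"].to_numpy(float),
        )

    records = []
    for pid, bounds in boundaries.items():
        if len(bounds) < 2:
            continue
        series = by_patient.get(pid, {})
        n_steps = len(bounds) - 1
        for k in range(n_steps):
            start, end = float(bounds[k]), float(bounds[k + 1])
            rec = {
                "patient_id": pid,
                "step_index": k,
                "start_h": start,
                "end_h": end,
                "is_terminal": int(k == n_steps - 1),
            }
            for var in variables:
                if var in series:
                    t, v = series[var]
                    agg = _step_median if var in SETTING_VARIABLES else _step_average
                    rec[var] = agg(t, v, start, end)
                else:
                    rec[var] = np.nan
            records.append(rec)
    return pd.DataFrame(records)


def impute_steps(
    steps: pd.DataFrame,
    schema: FeatureSchema,
) -> tuple[pd.DataFrame, dict]:
    """Nearest-before / next-step imputation, with population fallbacks.

    Per patient and feature: missing step values take the nearest earlier
    step's value, then any still-missing take the next observed step's
    value; features missing for the entire trajectory fall back to the
    schema's population default. Patients with any ventilator setting
    missing at every step are removed. Idempotent. Returns the imputed
    table and a report with per-patient imputed-cell fractions and the
    removed patient ids.
    """
    feature_cols = list(schema.names)
    setting_cols = list(SETTING_VARIABLES)
    steps = steps.sort_values(["patient_id", "step_index"], kind="stable").reset_index(drop=True)

    all_missing_setting = (
        steps.groupby("patient_id")[setting_cols].agg(lambda c: c.isna().all()).any(axis=1)
    )
    removed = list(all_missing_setting[all_missing_setting].index)
    steps = steps[~steps["patient_id"].isin(removed)].reset_index(drop=True)

    cols = feature_cols + setting_cols
    missing_before = steps[feature_cols].isna()
    if len(steps):
        grouped = steps.groupby("patient_id", sort=False)
        steps[cols] = grouped[cols].transform(lambda c: c.ffill().bfill())

    for name in feature_cols:
        if steps[name].isna().any():
            spec = schema[name]
            if spec.default is None:
                raise ValueError(
                    f"feature {name!r} missing for an entire trajectory and the "
                    "schema has no population default; fit the schema first"
                )
            steps[name] = steps[name].fillna(spec.default)

    frac = missing_before.groupby(steps["patient_id"]).mean().mean(axis=1)
    report = {
        "removed_patients": removed,
        "imputed_fraction": {str(k): float(v) for k, v in frac.items()},
    }
    return steps, report


def normalize_features(steps: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Map schema features to [0, 1] per their normalization contracts.

    Setting columns are left on their raw scales (they feed action
    discretization, not the state).
    """
    out = steps.copy()
    for spec in schema.features:
        if spec.name not in out.columns:
            raise KeyError(f"step table lacks schema feature {spec.name!r}")
        if out[spec.name].isna().any():
            raise ValueError(f"feature {spec.name!r} still has missing values; impute first")
        out[spec.name] = spec.normalize(out[spec.name].to_numpy(float))
    return out


def preprocess_cohort(
    table: RawEventTable,
    schema: FeatureSchema,
    rules: FlagRuleSet | None = None,
    seg_cfg: SegmentationConfig | None = None,
    filters: CohortFilterConfig | None = None,
    fit_schema: bool = True,
) -> tuple[pd.DataFrame, FeatureSchema, dict]:
    """Full pipeline: filters -> flags -> segmentation -> aggregation -> imputation.

    Returns the imputed raw-scale step table (normalization is applied by
    the MDP builder through the returned, possibly refitted, schema), the
    schema, and a report combining exclusion counts and imputation stats.
    """
    filtered, excl = apply_cohort_filters(table, filters)
    bounds = segment_cohort(filtered, rules, seg_cfg)
    steps = aggregate_steps(filtered, bounds, schema)
    if fit_schema:
        schema = schema.fit(steps)
    steps, imp = impute_steps(steps, schema)
    report = {"exclusions": excl, "imputation": imp, "n_steps": int(len(steps))}
    return steps, schema, report
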