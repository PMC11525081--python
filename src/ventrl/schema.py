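"""State feature schema: the 40 physiological features that make up a patient state.

The state vector combines 12 time-varying variables (vital signs, blood gas
values, selected labs and vasopressor dose) with 28 per-patient static
features (demographics, admission labs and comorbidity indicators).
Continuous features are min-max normalized to (0, 1), optionally on a log
scale for right-skewed labs; binary features map to {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: ventilator-setting variables (the action dimensions, never state features)
SETTING_VARIABLES = ("peep", "fio2", "tidal_volume")

#: time-varying state variables emitted by monitors / labs
DYNAMIC_VARIABLES = (
    "spo2",
    "pao2",
    "ph",
    "mbp",
    "heart_rate",
    "resp_rate",
    "temperature",
    "lactate",
    "creatinine",
    "wbc",
    "glucose",
    "vasopressor_dose",
)

#: static per-patient variables, recorded once at ventilation onset
STATIC_VARIABLES = (
    "age",
    "sex",
    "height",
    "weight",
    "bmi",
    "elixhauser",
    "sofa",
    "sirs",
    "gcs",
    "hemoglobin",
    "platelets",
    "sodium",
    "potassium",
    "bicarbonate",
    "bun",
    "bilirubin",
    "albumin",
    "pf_ratio",
    "comorb_chf",
    "comorb_copd",
    "comorb_ckd",
    "comorb_diabetes",
    "comorb_liver",
    "comorb_cancer",
    "comorb_stroke",
    "comorb_cad",
    "comorb_immunosup",
    "comorb_obesity",
)

#: variables scanned for deterioration flags
FLAG_VARIABLES = ("spo2", "pao2", "ph")


@dataclass(frozen=True)
class FeatureSpec:
    """One state feature: name, kind and normalization contract."""

    name: str
    kind: str = "continuous"  # "continuous" | "binary"
    normalization: str = "minmax"  # "minmax" | "log-minmax"
    lower: float = 0.0
    upper: float = 1.0
    default: float | None = None  # population fallback for all-missing patients

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.normalization not in ("minmax", "log-minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.kind == "continuous" and not self.lower < self.upper:
            raise ValueError(
                f"feature {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )
        if self.normalization == "log-minmax" and self.lower <= 0:
            raise ValueError(f"feature {self.name!r}: log normalization needs lower > 0")

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Map raw values to [0, 1] per the feature's contract (clipping)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "binary":
            return np.clip(np.rint(x), 0.0, 1.0)
        if self.normalization == "log-minmax":
            lo, hi = math.log(self.lower), math.log(self.upper)
            z = (np.log(np.clip(x, self.lower, None)) - lo) / (hi - lo)
        else:
            z = (x - self.lower) / (self.upper - self.lower)
        return np.clip(z, 0.0, 1.0)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of exactly ``n_features`` state features."""

    features: tuple[FeatureSpec, ...]
    n_features: int = 40

    def __post_init__(self) -> None:
        if len(self.features) != self.n_features:
            raise ValueError(
                f"schema must define exactly {self.n_features} features, "
                f"got {len(self.features)}"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def fit(
        self,
        steps: pd.DataFrame,
        lower_q: float = 0.01,
        upper_q: float = 0.99,
    ) -> "FeatureSchema":
        """Refit continuous normalization bounds and population defaults.

        Bounds are per-feature empirical quantiles of the (training) step
        table; degenerate columns keep their prior physiological bounds.
        Defaults are medians, used for patients missing a feature entirely.
        """
        fitted = []
        for f in self.features:
            spec = f
            if f.name in steps.columns:
                col = pd.to_numeric(steps[f.name], errors="coerce").dropna()
                if len(col):
                    if f.kind == "continuous":
                        lo, hi = float(col.quantile(lower_q)), float(col.quantile(upper_q))
                        if f.normalization == "log-minmax":
                            lo = max(lo, 1e-6)
                            hi = max(hi, lo * 1.0001)
                        if lo < hi:
                            spec = replace(spec, lower=lo, upper=hi)
                    spec = replace(spec, default=float(col.median()))
            fitted.append(spec)
        return FeatureSchema(tuple(fitted), self.n_features)


def _c(name, lower, upper, norm="minmax", default=None):
    return FeatureSpec(name, "continuous", norm, lower, upper, default)


def _b(name, default=0.0):
    return FeatureSpec(name, "binary", "minmax", 0.0, 1.0, default)


def default_schema() -> FeatureSchema:
    """The shipped 40-feature schema with physiological normalization bounds.

    Bounds are broad reference ranges; :meth:`FeatureSchema.fit` tightens
    them to 1st/99th training percentiles.
    """
    specs = (
        # dynamic
        _c("spo2", 70, 100, default=96.0),
        _c("pao2", 30, 300, default=90.0),
        _c("ph", 6.8, 7.8, default=7.40),
        _c("mbp", 30, 150, default=78.0),
        _c("heart_rate", 30, 180, default=85.0),
        _c("resp_rate", 5, 50, default=18.0),
        _c("temperature", 33, 41, default=37.0),
        _c("lactate", 0.3, 20, "log-minmax", default=1.5),
        _c("creatinine", 0.2, 15, "log-minmax", default=1.0),
        _c("wbc", 1, 50, "log-minmax", default=10.0),
        _c("glucose", 40, 500, "log-minmax", default=130.0),
        _c("vasopressor_dose", 0.0, 2.0, default=0.0),
        # static continuous
        _c("age", 16, 100, default=64.0),
        _b("sex"),
        _c("height", 120, 210, default=170.0),
        _c("weight", 30, 200, default=80.0),
        _c("bmi", 10, 60, default=27.0),
        _c("elixhauser", -10, 30, default=4.0),
        _c("sofa", 0, 24, default=4.0),
        _c("sirs", 0, 4, default=2.0),
        _c("gcs", 3, 15, default=10.0),
        _c("hemoglobin", 4, 20, default=10.5),
        _c("platelets", 10, 1000, "log-minmax", default=200.0),
        _c("sodium", 110, 170, default=139.0),
        _c("potassium", 2, 8, default=4.1),
        _c("bicarbonate", 5, 50, default=24.0),
        _c("bun", 2, 150, "log-minmax", default=22.0),
        _c("bilirubin", 0.1, 30, "log-minmax", default=0.8),
        _c("albumin", 1, 6, default=3.2),
        _c("pf_ratio", 40, 600, default=250.0),
        # comorbidity indicators
        _b("comorb_chf"),
        _b("comorb_copd"),
        _b("comorb_ckd"),
        _b("comorb_diabetes"),
        _b("comorb_liver"),
        _b("comorb_cancer"),
        _b("comorb_stroke"),
        _b("comorb_cad"),
        _b("comorb_immunosup"),
        _b("comorb_obesity"),
    )
    return FeatureSchema(specs)
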