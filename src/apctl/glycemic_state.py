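"""Daily glycaemic state featurisation and local cost.

A day of CGM data is reduced to a two-dimensional Markov-decision-process
state ``x = [x1, x2]``: the normalised mean hyperglycaemia error and the
normalised mean hypoglycaemia error.  A scalar local cost ``c = a_h*x1 +
a_l*x2`` weights the two excursion types, with hypoglycaemia penalised an
order of magnitude more heavily than hyperglycaemia by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseTrace",
    "GlycemicThresholds",
    "FeatureScale",
    "StateFeatures",
    "CostWeights",
    "glucose_error",
    "daily_features",
    "local_cost",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class GlycemicThresholds:
    """Hyper-/hypoglycaemia bounds in mg/dl (normoglycaemia is 70-180)."""

    hyper_bound: float = 180.0
    hypo_bound: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.hypo_bound < self.hyper_bound):
            raise ValueError("require 0 < hypo_bound < hyper_bound")


@dataclass(frozen=True)
class FeatureScale:
    """Normalisation scales mapping 'severe' excursions to feature ~1.

    ``hyper_scale`` = 300-180 mg/dl and ``hypo_scale`` = 70-40 mg/dl by
    default, so a day pinned at the severe-hyperglycaemia bound (300 mg/dl)
    or the severe-hypoglycaemia bound (40 mg/dl) yields a feature of 1.
    Patient-independent by design.
    """

    hyper_scale: float = 120.0
    hypo_scale: float = 30.0

    def __post_init__(self) -> None:
        if self.hyper_scale <= 0 or self.hypo_scale <= 0:
            raise ValueError("normalisation scales must be positive")


@dataclass(frozen=True)
class CostWeights:
    """Local-cost weights; hypoglycaemia avoidance has priority (a_l >> a_h)."""

    a_h: float = 1.0
    a_l: float = 10.0

    def __post_init__(self) -> None:
        if self.a_h < 0 or self.a_l < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass(frozen=True)
class StateFeatures:
    """MDP state: normalised daily hyper (x1) and hypo (x2) error, each in [0,1]."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 <= 1.0 and 0.0 <= self.x2 <= 1.0):
            raise ValueError("features must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)

    @property
    def norm(self) -> float:
        return float(np.hypot(self.x1, self.x2))


@dataclass(frozen=True)
class GlucoseTrace:
    """Uniformly sampled glucose time series (mg/dl), typically on a 5-min CGM grid."""

    values: np.ndarray
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2000-01-01 00:00")
    )
    sampling_interval: float = 5.0  # minutes

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if self.values.size == 0:
            raise ValueError("glucose trace must be non-empty")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("glucose values must be finite and strictly positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def samples_per_day(self) -> int:
        per_day = MINUTES_PER_DAY / self.sampling_interval
        if abs(per_day - round(per_day)) > 1e-9:
            raise ValueError("sampling interval must divide 24 h evenly")
        return int(round(per_day))

    @property
    def n_days(self) -> int:
        per_day = self.samples_per_day
        if len(self) % per_day:
            raise ValueError("trace length does not cover an integer number of days")
        return len(self) // per_day

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.sampling_interval, unit="min"
        )

    def split_days(self) -> list["GlucoseTrace"]:
        """Split a multi-day trace into per-day traces at midnight boundaries."""
        per_day = self.samples_per_day
        n = self.n_days
        return [
            GlucoseTrace(
                self.values[d * per_day : (d + 1) * per_day],
                start_time=self.start_time + pd.Timedelta(days=d),
                sampling_interval=self.sampling_interval,
            )
            for d in range(n)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_iso8601": self.times(), "glucose_mgdl": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GlucoseTrace":
        df = pd.read_csv(path, parse_dates=["time_iso8601"])
        t = pd.DatetimeIndex(df["time_iso8601"])
        if len(t) < 2:
            raise ValueError("need at least two samples to infer the grid")
        steps = np.diff(t.view("int64")) / 60e9
        if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise ValueError("time column must be strictly increasing on a fixed grid")
        return cls(
            df["glucose_mgdl"].to_numpy(float),
            start_time=t[0],
            sampling_interval=float(steps[0]),
        )


def glucose_error(
    trace: GlucoseTrace, thresholds: GlycemicThresholds = GlycemicThresholds()
) -> np.ndarray:
    """Signed per-sample excursion outside the normoglycaemic band, mg/dl.

    EG(t) = G-hyper_bound above the band, G-hypo_bound below it, 0 inside.
    """
    g = trace.values
    eg = np.zeros_like(g)
    hyper = g > thresholds.hyper_bound
    hypo = g < thresholds.hypo_bound
    eg[hyper] = g[hyper] - thresholds.hyper_bound
    eg[hypo] = g[hypo] - thresholds.hypo_bound
    return eg


def daily_features(
    trace: GlucoseTrace,
    thresholds: GlycemicThresholds = GlycemicThresholds(),
    normalisation: FeatureScale = FeatureScale(),
    *,
    indicator_mean: bool = False,
) -> StateFeatures:
    """Reduce one day of glucose data to the state ``x = [x1, x2]``.

    The raw statistics are the mean excursion magnitude over the samples
    above (x1) or below (x2) the band, each 0 when no such samples exist,
    then divided by the configured scale and clipped to [0, 1].

    ``indicator_mean=True`` switches to averaging the Heaviside indicator
    of the excursion (identically 1 over excursion samples, so each raw
    feature is then simply 0 or 1) — retained only for fidelity
    experiments against the literal printed formula.
    """
    if trace.n_days != 1:
        raise ValueError("daily_features expects a trace spanning exactly one day")
    eg = glucose_error(trace, thresholds)
    hyper = eg[eg > 0]
    hypo = -eg[eg < 0]
    if indicator_mean:
        raw1 = 1.0 if hyper.size else 0.0
        raw2 = 1.0 if hypo.size else 0.0
        return StateFeatures(min(raw1, 1.0), min(raw2, 1.0))
    raw1 = float(hyper.mean()) if hyper.size else 0.0
    raw2 = float(hypo.mean()) if hypo.size else 0.0
    x1 = min(max(raw1 / normalisation.hyper_scale, 0.0), 1.0)
    x2 = min(max(raw2 / normalisation.hypo_scale, 0.0), 1.0)
    return StateFeatures(x1, x2)


def local_cost(state: StateFeatures, weights: CostWeights = CostWeights()) -> float:
    """Scalar daily cost c = a_h*x1 + a_l*x2 driving the learning signal."""
    return weights.a_h * state.x1 + weights.a_l * state.x2
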