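"""Automatic policy initialisation from insulin-to-glucose transfer entropy.

Four days of CGM and pump data are reduced to a single patient-specific
number: the transfer entropy (TE) from the active-insulin signal to the
glucose signal, estimated by the histogram (fixed-partition) plug-in with a
physiological insulin-absorption delay.  TE is magnitude-free, so — at a
given total daily insulin — a lower TE flags lower insulin sensitivity and
hence larger required fractional regimen updates; the policy vector is
therefore initialised inversely proportional to TE:

    theta_0 = [W_h / TE, W_l / TE],   W_h = 0.1, W_l = -0.2.

TE is reported in bits (base-2 logarithm); histogram bins are right-open and
anchored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actor import PolicyParameters
from .glycemic_state import GlucoseTrace

__all__ = [
    "PumpRecord",
    "ActiveInsulinTrace",
    "TEConfig",
    "ThetaInitWeights",
    "insulin_on_board",
    "active_insulin",
    "transfer_entropy",
    "initialize_theta",
    "te_window_stability",
]

TE_FLOOR_BITS = 1e-3


@dataclass(frozen=True)
class TEConfig:
    """Knobs of the TE estimator and the insulin-on-board model.

    delay_d is the insulin absorption delay applied as an index shift
    (default 20 min, the average sc absorption delay of rapid-acting
    analogues); bins are the fixed-partition widths for glucose (mg/dl)
    and active insulin (U).
    """

    delay_d: float = 20.0  # min
    glucose_bin: float = 10.0  # mg/dl
    insulin_bin: float = 1.0  # U
    window_days: int = 4
    iob_duration: float = 4.0  # hours of insulin action
    iob_curve: str = "linear"  # or "biexponential"
    basal_mode: str = "microbolus"  # or "instantaneous"

    def __post_init__(self) -> None:
        if self.delay_d < 0 or self.glucose_bin <= 0 or self.insulin_bin <= 0:
            raise ValueError("delay and bin widths must be positive")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.iob_duration <= 0:
            raise ValueError("iob_duration must be positive")
        if self.iob_curve not in ("linear", "biexponential"):
            raise ValueError("iob_curve must be 'linear' or 'biexponential'")
        if self.basal_mode not in ("microbolus", "instantaneous"):
            raise ValueError("basal_mode must be 'microbolus' or 'instantaneous'")


@dataclass(frozen=True)
class ThetaInitWeights:
    """Numerators of the TE-based initialisation; hypo weight is larger in magnitude."""

    w_h: float = 0.1
    w_l: float = -0.2


@dataclass(frozen=True)
class PumpRecord:
    """Insulin pump history on the CGM grid: basal series (U/h) and bolus events."""

    basal_series: np.ndarray
    bolus_events: tuple = ()  # (time_min_from_start, units_U) pairs
    sampling_interval: float = 5.0  # minutes
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2000-01-01 00:00")
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "basal_series", np.asarray(self.basal_series, dtype=float).ravel()
        )
        object.__setattr__(self, "bolus_events", tuple(self.bolus_events))
        if np.any(self.basal_series < 0):
            raise ValueError("basal rates must be non-negative")
        if any(u < 0 for _, u in self.bolus_events):
            raise ValueError("bolus units must be non-negative")

    def __len__(self) -> int:
        return int(self.basal_series.size)

    def bolus_on_grid(self) -> np.ndarray:
        """Bolus units accumulated onto the sampling grid (nearest earlier sample)."""
        doses = np.zeros(len(self))
        for t_min, units in self.bolus_events:
            idx = int(t_min // self.sampling_interval)
            if not (0 <= idx < len(self)):
                raise ValueError("bolus event outside the record span")
            doses[idx] += units
        return doses

    def to_frame(self) -> pd.DataFrame:
        times = self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.sampling_interval, unit="min"
        )
        return pd.DataFrame(
            {
                "time_iso8601": times,
                "basal_rate_Uph": self.basal_series,
                "bolus_U": self.bolus_on_grid(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PumpRecord":
        df = pd.read_csv(path, parse_dates=["time_iso8601"])
        t = pd.DatetimeIndex(df["time_iso8601"])
        steps = np.diff(t.view("int64")) / 60e9
        if len(t) < 2 or np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise ValueError("time column must be strictly increasing on a fixed grid")
        interval = float(steps[0])
        bolus = df["bolus_U"].to_numpy(float)
        events = tuple(
            (i * interval, u) for i, u in enumerate(bolus) if u > 0
        )
        return cls(
            df["basal_rate_Uph"].to_numpy(float),
            bolus_events=events,
            sampling_interval=interval,
            start_time=t[0],
        )


@dataclass(frozen=True)
class ActiveInsulinTrace:
    """Active insulin IA(t) in U on the glucose sampling grid."""

    values: np.ndarray
    sampling_interval: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if np.any(self.values < -1e-12):
            raise ValueError("active insulin must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


def _remaining_fraction(elapsed_min: np.ndarray, cfg: TEConfig) -> np.ndarray:
    """Fraction of a bolus still active after ``elapsed_min`` minutes.

    Monotone from 1 at injection to 0 at iob_duration.  The default is a
    linear decay; the bi-exponential alternative uses the normalised curve
    (1 + t/tau) * exp(-t/tau) with tau = duration/5, truncated to zero at
    the end of the action window.
    """
    tau_total = cfg.iob_duration * 60.0
    t = np.asarray(elapsed_min, dtype=float)
    if cfg.iob_curve == "linear":
        frac = 1.0 - t / tau_total
    else:
        tau = tau_total / 5.0
        frac = (1.0 + t / tau) * np.exp(-t / tau)
    frac = np.where((t < 0) | (t >= tau_total), 0.0, frac)
    return np.clip(frac, 0.0, 1.0)


def insulin_on_board(
    bolus_events, t: float, cfg: TEConfig = TEConfig()
) -> float:
    """Remaining active bolus insulin (U) at time ``t`` minutes from record start."""
    total = 0.0
    for t_ev, units in bolus_events:
        total += units * float(_remaining_fraction(np.array(t - t_ev), cfg))
    return total


def active_insulin(
    pump: PumpRecord, trace: GlucoseTrace, cfg: TEConfig = TEConfig()
) -> ActiveInsulinTrace:
    """Active insulin IA(t) = bolus IOB + basal contribution, on the CGM grid.

    The default basal convention treats the basal infusion as a train of
    per-sample micro-boluses decayed through the same IOB curve, so IA
    carries the full on-board insulin mass; the infusion is assumed to have
    been running at its initial rate before the record starts, so a
    constant basal yields a constant IA.  The 'instantaneous' mode adds
    only the insulin delivered at the current sample (rate x interval).
    """
    if len(pump) != len(trace) or pump.sampling_interval != trace.sampling_interval:
        raise ValueError("pump record and glucose trace must share the sampling grid")
    dt = trace.sampling_interval
    if cfg.basal_mode == "microbolus":
        kernel = _remaining_fraction(np.arange(len(pump)) * dt, cfg)
        pad = kernel.size
        delivery = np.concatenate(
            [
                np.full(pad, pump.basal_series[0] * dt / 60.0),
                pump.bolus_on_grid() + pump.basal_series * dt / 60.0,
            ]
        )
        ia = np.convolve(delivery, kernel)[pad : pad + len(pump)]
    else:
        kernel = _remaining_fraction(np.arange(len(pump)) * dt, cfg)
        ia = np.convolve(pump.bolus_on_grid(), kernel)[: len(pump)]
        ia = ia + pump.basal_series * dt / 60.0
    return ActiveInsulinTrace(ia, sampling_interval=dt)


def _bin_index(x: np.ndarray, width: float) -> np.ndarray:
    """Fixed-width, right-open bins anchored at 0: value v -> floor(v/width)."""
    return np.floor(np.asarray(x, dtype=float) / width).astype(np.int64)


def transfer_entropy(
    glucose: GlucoseTrace | np.ndarray,
    ia: ActiveInsulinTrace | np.ndarray,
    cfg: TEConfig = TEConfig(),
) -> float:
    """Plug-in transfer entropy from active insulin to glucose, in bits.

    TE = sum p(G_t, G_{t-1}, IA_{t-d}) * log2[ p(G_t | G_{t-1}, IA_{t-d})
    / p(G_t | G_{t-1}) ], with probabilities estimated from fixed-width
    histograms and the delay d applied as an index shift.  The estimate is
    clipped at zero (the plug-in can go slightly negative under sampling
    noise).  A glucose series confined to a single bin is degenerate and
    returns 0 with a warning.
    """
    g = glucose.values if isinstance(glucose, GlucoseTrace) else np.asarray(glucose)
    i = ia.values if isinstance(ia, ActiveInsulinTrace) else np.asarray(ia)
    if g.size != i.size:
        raise ValueError("glucose and insulin series must have equal length")
    interval = (
        glucose.sampling_interval if isinstance(glucose, GlucoseTrace) else 5.0
    )
    shift = int(round(cfg.delay_d / interval))
    if abs(shift * interval - cfg.delay_d) > 1e-9:
        raise ValueError("delay_d must be a multiple of the sampling interval")
    gi = _bin_index(g, cfg.glucose_bin)
    ii = _bin_index(i, cfg.insulin_bin)
    lag = max(shift, 1)
    g_t = gi[lag:]
    g_tm1 = gi[lag - 1 : -1]
    ia_tmd = ii[lag - shift : gi.size - shift]
    if g_t.size < 2:
        raise ValueError("series too short for the configured delay")
    if np.unique(gi).size < 2:
        warnings.warn("degenerate single-bin glucose series; TE = 0", stacklevel=2)
        return 0.0

    triples = np.stack([g_t, g_tm1, ia_tmd], axis=1)
    _, inv, c_xyz = np.unique(
        triples, axis=0, return_inverse=True, return_counts=True
    )
    n = g_t.size
    # marginal counts sharing the same sample multiset
    def counts_of(cols: np.ndarray) -> np.ndarray:
        _, inv_c, cnt = np.unique(cols, axis=0, return_inverse=True, return_counts=True)
        return cnt[inv_c]

    n_xyz = c_xyz[inv]  # per-sample joint count
    n_yz = counts_of(np.stack([g_tm1, ia_tmd], axis=1))
    n_xy = counts_of(np.stack([g_t, g_tm1], axis=1))
    n_y = counts_of(g_tm1[:, None])
    # sum over samples = sum over cells weighted by joint probability
    te = float(np.mean(np.log2(n_xyz * n_y / (n_yz * n_xy))))
    return max(te, 0.0)


def initialize_theta(
    te: float,
    weights: ThetaInitWeights = ThetaInitWeights(),
    *,
    te_floor: float = TE_FLOOR_BITS,
) -> PolicyParameters:
    """Policy initialisation theta_0 = [w_h/TE, w_l/TE].

    Lower TE (lower effective insulin sensitivity) yields larger initial
    fractional updates.  Below ``te_floor`` the estimate is unreliable and
    would explode the ratio, so the initialisation falls back to zeros (the
    manual mode) with a warning.
    """
    if te <= te_floor:
        warnings.warn(
            f"TE {te:.4g} at or below floor {te_floor:g}; "
            "falling back to zero initialisation",
            stacklevel=2,
        )
        return PolicyParameters.zeros()
    return PolicyParameters(np.array([weights.w_h, weights.w_l]) / te)


def te_window_stability(
    glucose_series: list,
    ia_series: list,
    cfg: TEConfig,
    lengths: list[int],
) -> pd.DataFrame:
    """Cohort-wise stability of TE across data-window lengths (days).

    For each subject, TE is computed on the first ``L`` days for each L in
    ``lengths``; the Pearson correlation of the subject-wise TE vectors is
    reported for each successive pair of lengths.  Requires >= 3 subjects.
    """
    if len(glucose_series) != len(ia_series):
        raise ValueError("need one insulin series per glucose series")
    if len(glucose_series) < 3:
        raise ValueError("cohort correlation needs at least 3 subjects")
    lengths = sorted(lengths)
    te_by_len = {}
    for L in lengths:
        vals = []
        for g, i in zip(glucose_series, ia_series):
            per_day = g.samples_per_day
            if len(g) < L * per_day:
                raise ValueError(f"subject series shorter than {L} days")
            g_sub = GlucoseTrace(
                g.values[: L * per_day],
                start_time=g.start_time,
                sampling_interval=g.sampling_interval,
            )
            i_sub = ActiveInsulinTrace(
                (i.values if isinstance(i, ActiveInsulinTrace) else np.asarray(i))[
                    : L * per_day
                ],
                sampling_interval=g.sampling_interval,
            )
            vals.append(transfer_entropy(g_sub, i_sub, cfg))
        te_by_len[L] = np.array(vals)
    rows = []
    for l1, l2 in zip(lengths[:-1], lengths[1:]):
        a, b = te_by_len[l1], te_by_len[l2]
        rows.append(
            {
                "days_a": l1,
                "days_b": l2,
                "correlation": float(np.corrcoef(a, b)[0, 1]),
            }
        )
    return pd.DataFrame(rows)
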