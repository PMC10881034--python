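"""Plate-reader fitness and expression metrics.

Growth assays compare induced versus uninduced cultures of the same clone.
Each signal (OD600 and fluorescence channels) is summarized as the
background-subtracted area under the curve (AUC) over a common time
window, bounded by the first time any monitored signal reaches the
detector ceiling. Metrics:

* Growth Fitness   — AUC_OD(induced) / AUC_OD(uninduced)
* Co-Expression Fitness — same ratio for the constitutive reporter channel
  (YFP), probing how much host translational capacity the overexpressed
  gene consumes
* Expression Level — induced AUC of the overexpressed protein's channel

AUC aggregates lag, rate and carrying-capacity differences without fitting
a growth model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ChannelError(KeyError):
    """Requested signal channel is not present in the time series."""


@dataclass
class PlateTimeseries:
    """Time-resolved signals for one well/condition.

    ``background`` holds per-channel scalar blanks (subtracted before
    integration, clipped at zero); ``upper_limit`` per-channel detector
    ceilings used to bound the analysis window.
    """

    time: np.ndarray
    signals: dict[str, np.ndarray]
    condition: str = "induced"
    background: Mapping[str, float] = field(default_factory=dict)
    upper_limit: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        for ch, y in self.signals.items():
            if y.shape != self.time.shape:
                raise ValueError(f"channel {ch!r} length mismatch")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.signals[name]
        except KeyError:
            raise ChannelError(
                f"channel {name!r} absent; have {sorted(self.signals)}"
            ) from None

    def first_ceiling_time(self) -> float:
        """Earliest time any channel reaches its detector ceiling (∞ if none)."""
        t_hit = np.inf
        for ch, ceiling in self.upper_limit.items():
            if ch not in self.signals:
                continue
            above = self.signals[ch] >= ceiling
            if above.any():
                t_hit = min(t_hit, float(self.time[int(np.argmax(above))]))
        return t_hit


@dataclass(frozen=True)
class FitnessSummary:
    """Derived metrics for one induced/uninduced pair."""

    growth_fitness: float
    coexpression_fitness: float
    expression_level: float
    auc_window_end: float
    uninduced_expression_auc: float = float("nan")


def auc_signal(ts: PlateTimeseries, channel: str, window_end: float) -> float:
    """Trapezoidal AUC of the background-subtracted signal on [0, window_end].

    The blank is the channel's entry in ``ts.background`` (default: the
    signal's first value); the subtracted signal is clipped at zero. If
    ``window_end`` falls between samples the boundary value is linearly
    interpolated, making the integral exactly additive over adjacent
    windows.
    """
    y = ts.channel(channel)
    t = ts.time
    if window_end > t[-1] + 1e-9:
        raise ValueError(
            f"window_end {window_end} beyond last time point {t[-1]}"
        )
    blank = ts.background.get(channel, float(y[0]))
    y = np.clip(y - blank, 0.0, None)
    t0 = float(t[0])
    if window_end <= t0:
        return 0.0
    mask = t <= window_end
    tt = t[mask]
    yy = y[mask]
    if tt[-1] < window_end:
        y_end = float(np.interp(window_end, t, y))
        tt = np.append(tt, window_end)
        yy = np.append(yy, y_end)
    return float(np.trapezoid(yy, tt))


def common_window(*series: PlateTimeseries, fixed_end: float | None = None) -> float:
    """Analysis-window end shared by all series.

    Default: min over series of (first ceiling-crossing time, last time
    point) — the window is bounded by the time it takes any sample to
    saturate the detector. A ``fixed_end`` overrides the ceiling rule.
    """
    last_common = min(float(ts.time[-1]) for ts in series)
    if fixed_end is not None:
        if fixed_end > last_common:
            raise ValueError("fixed window end beyond common data range")
        return fixed_end
    return min(last_common, min(ts.first_ceiling_time() for ts in series))


def fitness_summary(
    induced: PlateTimeseries,
    uninduced: PlateTimeseries,
    *,
    od_channel: str = "OD600",
    reporter_channel: str = "YFP",
    expression_channel: str = "CFP",
    fixed_window_end: float | None = None,
) -> FitnessSummary:
    """Growth Fitness, Co-Expression Fitness and Expression Level.

    All AUCs use one common truncated window. Fitness ratios are reported
    as-is (not clamped to [0, 1]); a zero uninduced AUC makes the ratio
    undefined and raises.
    """
    end = common_window(induced, uninduced, fixed_end=fixed_window_end)
    def ratio(channel: str) -> float:
        denom = auc_signal(uninduced, channel, end)
        if denom == 0:
            raise ZeroDivisionError(
                f"uninduced {channel} AUC is zero; fitness ratio undefined"
            )
        return auc_signal(induced, channel, end) / denom

    return FitnessSummary(
        growth_fitness=ratio(od_channel),
        coexpression_fitness=ratio(reporter_channel),
        expression_level=auc_signal(induced, expression_channel, end),
        auc_window_end=end,
        uninduced_expression_auc=auc_signal(uninduced, expression_channel, end),
    )


def fold_change_summary(
    samples: Sequence[FitnessSummary],
    control: Sequence[FitnessSummary],
) -> dict[str, float]:
    """Per-metric fold change of replicate means relative to a control.

    Replicate means are taken *before* the ratio (ratio of means, not mean
    of ratios).
    """
    if not samples or not control:
        raise ValueError("need at least one replicate on each side")
    out = {}
    for metric in ("growth_fitness", "coexpression_fitness", "expression_level"):
        s = float(np.mean([getattr(r, metric) for r in samples]))
        c = float(np.mean([getattr(r, metric) for r in control]))
        if c == 0:
            raise ZeroDivisionError(f"control mean for {metric} is zero")
        out[metric] = s / c
    return out
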