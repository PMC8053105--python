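"""Fluorescence onset timing, delay statistics and slope regression.

Onset is the earliest sampled time at which the background-subtracted
signal stays above ``m * background_sd`` for a given number of
consecutive samples; with the default multiplier m = 0 this is literally
"rose above the background value".  Delays are red (REase) minus green
(MTase) onsets per subject; groups are compared with a two-tailed
unpaired Student's t-test (Welch optional).

Steady-state expression levels from a growing culture are quantified as
the slope of background-subtracted fluorescence versus OD600, via the
statsmodels OLS machinery (:class:`FluorescenceSlopeModel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorTrace",
    "BackgroundModel",
    "OnsetRecord",
    "DelayStats",
    "detect_onset",
    "detect_onsets",
    "delays",
    "compare_groups",
    "FluorescenceSlopeModel",
    "relative_fluorescence_slope",
]


@dataclass(frozen=True)
class FluorTrace:
    """One channel's time course for one subject (a cell or "bulk")."""

    subject_id: str
    channel: str  # green | red
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray
    od600: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.subject_id}/{self.channel}: times must increase")
        if len(t) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if self.od600 is not None and len(self.od600) != len(t):
            raise ValueError("od600 must pair 1:1 with times")


@dataclass(frozen=True)
class BackgroundModel:
    """Negative-control background statistics for one channel.

    ``threshold_multiplier`` m sets the detection threshold at
    mean + m*sd; m = 0 detects any excursion above the background mean.
    """

    channel: str
    mean: float
    sd: float = 0.0
    threshold_multiplier: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("background sd must be >= 0")

    @classmethod
    def from_trace(
        cls, trace: FluorTrace, threshold_multiplier: float = 0.0
    ) -> "BackgroundModel":
        """Estimate background mean/sd from a negative-control trace."""
        return cls(
            channel=trace.channel,
            mean=float(np.mean(trace.intensities)),
            sd=float(np.std(trace.intensities, ddof=1)) if len(trace.intensities) > 1 else 0.0,
            threshold_multiplier=threshold_multiplier,
        )


@dataclass(frozen=True)
class OnsetRecord:
    subject_id: str
    t_green: float | None
    t_red: float | None

    @property
    def delay(self) -> float | None:
        """Red-minus-green onset difference, minutes; None if either absent."""
        if self.t_green is None or self.t_red is None:
            return None
        return self.t_red - self.t_green


def detect_onset(
    trace: FluorTrace, bg: BackgroundModel, consecutive: int = 2
) -> float | None:
    """Earliest sampled time from which the signal exceeds threshold for
    ``consecutive`` consecutive samples; None if never.

    The threshold is ``bg.mean + bg.threshold_multiplier * bg.sd``; the
    onset reported is the first time point of the qualifying run, so it
    always lies on the sampling grid.
    """
    if bg.channel != trace.channel:
        raise ValueError(
            f"background channel {bg.channel!r} does not match trace channel "
            f"{trace.channel!r}"
        )
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    if len(trace.times) < consecutive:
        raise ValueError("trace shorter than the required consecutive run")
    above = (
        np.asarray(trace.intensities, dtype=float) - bg.mean
        > bg.threshold_multiplier * bg.sd
    )
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run == consecutive:
            return float(trace.times[i - consecutive + 1])
    return None


def detect_onsets(
    traces: pd.DataFrame,
    backgrounds: dict[str, BackgroundModel],
    consecutive: int = 2,
) -> pd.DataFrame:
    """Per-subject green/red onset table from a long-format trace table.

    ``traces`` needs columns cell_id, t_min, channel, intensity (the
    layout written by :func:`rmdynamics.simulate.simulate_expression`).
    Returns columns subject_id, t_green_min, t_red_min, delay_min with
    NaN where no onset was found.
    """
    rows = []
    for sid, sub in traces.groupby("cell_id", sort=False):
        rec = {}
        for channel in ("green", "red"):
            ch = sub[sub["channel"] == channel].sort_values("t_min")
            if ch.empty:
                rec[channel] = None
                continue
            trace = FluorTrace(
                subject_id=str(sid),
                channel=channel,
                times=ch["t_min"].to_numpy(),
                intensities=ch["intensity"].to_numpy(),
            )
            rec[channel] = detect_onset(trace, backgrounds[channel], consecutive)
        delay = (
            rec["red"] - rec["green"]
            if rec["green"] is not None and rec["red"] is not None
            else np.nan
        )
        rows.append(
            {
                "subject_id": sid,
                "t_green_min": np.nan if rec["green"] is None else rec["green"],
                "t_red_min": np.nan if rec["red"] is None else rec["red"],
                "delay_min": delay,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DelayStats:
    """Summary of red-minus-green delays over cells with both onsets."""

    n: int
    mean: float
    sd: float
    fraction_nonnegative: float  # percent
    fraction_nonpositive: float  # percent
    normal_mu: float
    normal_sigma: float


def delays(onsets: pd.DataFrame) -> DelayStats:
    """Delay statistics from an onset table (see :func:`detect_onsets`).

    Only records with both onsets contribute.  The normal fit is by
    moments, matching the roughly normal spread such data show.
    """
    d = pd.to_numeric(onsets["delay_min"], errors="coerce").dropna().to_numpy()
    if d.size < 2:
        raise ValueError("need at least 2 records with both onsets")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return DelayStats(
        n=int(d.size),
        mean=mean,
        sd=sd,
        fraction_nonnegative=float((d >= 0).mean() * 100.0),
        fraction_nonpositive=float((d <= 0).mean() * 100.0),
        normal_mu=mean,
        normal_sigma=sd,
    )


def compare_groups(
    delays_a: np.ndarray, delays_b: np.ndarray, method: str = "student"
) -> tuple[float, float]:
    """Two-tailed unpaired t-test between two delay samples.

    Returns (t statistic, p value).  ``method`` is "student" (pooled
    variance, the default) or "welch".  Two identical zero-variance
    samples are reported as p = 1 by convention.
    """
    a = np.asarray(delays_a, dtype=float)
    b = np.asarray(delays_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if method not in {"student", "welch"}:
        raise ValueError("method must be 'student' or 'welch'")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    return float(res.statistic), float(res.pvalue)


class FluorescenceSlopeModel:
    """OLS of background-subtracted fluorescence against culture density.

    The slope of (F - background) versus OD600 is the steady-state
    relative expression level in arbitrary units; it is insensitive to
    the sampling times as long as the culture stays in balanced growth.
    """

    def __init__(self, trace: FluorTrace, bg: BackgroundModel):
        if trace.od600 is None:
            raise ValueError("trace lacks od600 values")
        if len(trace.times) < 3:
            raise ValueError("need >= 3 paired (fluorescence, OD) points")
        od = np.asarray(trace.od600, dtype=float)
        if np.any(od <= 0):
            raise ValueError("OD values must be positive")
        self.od = od
        self.signal = np.asarray(trace.intensities, dtype=float) - bg.mean

    def fit(self) -> "FluorescenceSlopeResults":
        import statsmodels.api as sm

        X = sm.add_constant(self.od)
        ols = sm.OLS(self.signal, X).fit()
        return FluorescenceSlopeResults(
            slope=float(ols.params[1]),
            stderr=float(ols.bse[1]),
            intercept=float(ols.params[0]),
            r_squared=float(ols.rsquared),
            per_od=self.signal / self.od,
        )


@dataclass(frozen=True)
class FluorescenceSlopeResults:
    slope: float
    stderr: float
    intercept: float
    r_squared: float
    per_od: np.ndarray  # per-point (F - bg)/OD

    def summary(self) -> str:
        return (
            "Fluorescence-vs-OD slope (arbitrary units)\n"
            f"slope:     {self.slope:.4g} +/- {self.stderr:.2g}\n"
            f"intercept: {self.intercept:.4g}\n"
            f"R-squared: {self.r_squared:.4f}"
        )


def relative_fluorescence_slope(
    trace: FluorTrace, bg: BackgroundModel
) -> FluorescenceSlopeResults:
    """Functional wrapper: ``FluorescenceSlopeModel(trace, bg).fit()``."""
    return FluorescenceSlopeModel(trace, bg).fit()
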