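"""Predicted-minus-observed EBCM residuals and C-peptide alignment.

For every autopsy record the residual ``delta = EBCM_pred(age) -
EBCM_obs`` measures departure from the age-expected beta cell loss at the
time of death: positive deltas mean fewer insulin-deficient islets than the
age-matched expectation (recovery of mass after onset), negative deltas a
further decline.  Because C-peptide studies report cohort aggregates at
fixed times while autopsies are single deaths at scattered times, the
residual series is smoothed with a nine-point moving average (and moving
SD) over the time-ordered records, and the smoothed series is interpolated
at each C-peptide timepoint to form the paired observations fed to the
weighted Bayesian regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fitting import AutopsyRecord
from .physiology import PhysiologyModel

__all__ = [
    "ResidualPoint",
    "SmoothedSeries",
    "CpeptideAggregate",
    "PairedObservation",
    "residual_series",
    "moving_average",
    "align_with_cpeptide",
    "WEEKS_PER_MONTH",
]

logger = logging.getLogger(__name__)

#: conversion used when inputs arrive in weeks
WEEKS_PER_MONTH = 4.345


@dataclass(frozen=True)
class ResidualPoint:
    """Predicted minus observed EBCM for one patient."""

    time_since_diagnosis: float  # months
    delta_ebcm: float
    patient_id: str

    def __post_init__(self) -> None:
        if self.time_since_diagnosis < 0:
            raise ValueError("time_since_diagnosis must be >= 0")
        if not np.isfinite(self.delta_ebcm):
            raise ValueError("delta_ebcm must be finite")


@dataclass(frozen=True)
class CpeptideAggregate:
    """One study-level C-peptide timepoint (mean +/- SE over n patients)."""

    study: str
    time_since_diagnosis: float  # months
    mean: float  # nmol/L
    se: float  # nmol/L
    n: int
    stratum: str = "mixed"  # {AA+, AA-, mixed}
    sampling: str = "fasting"  # {fasting, random}

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.time_since_diagnosis < 0:
            raise ValueError("time_since_diagnosis must be >= 0")


@dataclass(frozen=True)
class PairedObservation:
    """Smoothed delta-EBCM paired with a C-peptide aggregate at one time."""

    x: float  # smoothed delta EBCM
    x_sd: float
    y: float  # C-peptide mean, nmol/L
    y_se: float
    weight: float  # study sample size
    time_since_diagnosis: float = float("nan")
    study: str = ""

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("weight (sample size) must be >= 1")


@dataclass(frozen=True)
class SmoothedSeries:
    """Centered moving average/SD of the residual series (full windows only).

    For ``n`` input points and window ``w`` there are exactly ``n - w + 1``
    windows; each window's time is the time of its middle record.
    """

    times: np.ndarray  # months, window centers
    means: np.ndarray
    sds: np.ndarray
    window: int

    def interpolate(self, t, mode: str = "linear") -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (mean, sd) at times ``t`` inside the center range."""
        t = np.asarray(t, dtype=float)
        if mode == "linear":
            return np.interp(t, self.times, self.means), np.interp(
                t, self.times, self.sds
            )
        if mode == "nearest":
            idx = np.abs(self.times[None, :] - t[..., None]).argmin(axis=-1)
            return self.means[idx], self.sds[idx]
        raise ValueError(f"unknown interpolation mode {mode!r}")


def residual_series(
    records: Iterable[AutopsyRecord], model: PhysiologyModel
) -> list[ResidualPoint]:
    """Model-predicted minus observed EBCM per record, sorted by time.

    Ties in time since diagnosis are broken by patient id so the ordering
    (and hence the moving-average windows) is deterministic.
    """
    points = [
        ResidualPoint(
            time_since_diagnosis=r.time_since_diagnosis,
            delta_ebcm=model.excess_bcm(r.age).ebcm - r.observed_ebcm,
            patient_id=r.patient_id,
        )
        for r in records
    ]
    points.sort(key=lambda p: (p.time_since_diagnosis, p.patient_id))
    return points


def moving_average(
    points: Sequence[ResidualPoint] | np.ndarray,
    window: int = 9,
    times: np.ndarray | None = None,
) -> SmoothedSeries:
    """Centered moving average and sample SD over the ordered residuals.

    ``points`` is either a time-ordered sequence of :class:`ResidualPoint`
    or a plain value array (then ``times`` supplies the matching time
    stamps).  Only full windows are formed; the window time is the time of
    the middle (e.g. 5th of 9) record.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd count, got {window}")
    if len(points) and isinstance(points[0], ResidualPoint):
        values = np.array([p.delta_ebcm for p in points], dtype=float)
        times = np.array([p.time_since_diagnosis for p in points], dtype=float)
    else:
        values = np.asarray(points, dtype=float)
        if times is None:
            times = np.arange(values.size, dtype=float)
        times = np.asarray(times, dtype=float)
    n = values.size
    if n < window:
        raise ValueError(
            f"need at least window={window} points for one full window, got {n}; "
            "reduce the window or supply more records"
        )
    win = np.lib.stride_tricks.sliding_window_view(values, window)
    means = win.mean(axis=1)
    sds = win.std(axis=1, ddof=1) if window > 1 else np.zeros(n)
    centers = times[window // 2 : n - window // 2]
    return SmoothedSeries(times=centers, means=means, sds=sds, window=window)


def align_with_cpeptide(
    smoothed: SmoothedSeries,
    aggregates: Iterable[CpeptideAggregate],
    mode: str = "linear",
) -> list[PairedObservation]:
    """Pair each C-peptide timepoint with the smoothed delta-EBCM there.

    Timepoints outside the span of window centers are excluded (logged as
    warnings) rather than extrapolated.
    """
    if smoothed.times.size == 0:
        raise ValueError("smoothed series is empty")
    lo, hi = float(smoothed.times[0]), float(smoothed.times[-1])
    pairs: list[PairedObservation] = []
    for agg in aggregates:
        t = agg.time_since_diagnosis
        if t < lo or t > hi:
            logger.warning(
                "C-peptide timepoint %s @ %.2f mo outside smoothed range "
                "[%.2f, %.2f]; excluded",
                agg.study,
                t,
                lo,
                hi,
            )
            continue
        x, x_sd = smoothed.interpolate(np.array([t]), mode=mode)
        pairs.append(
            PairedObservation(
                x=float(x[0]),
                x_sd=float(x_sd[0]),
                y=agg.mean,
                y_se=agg.se,
                weight=float(agg.n),
                time_since_diagnosis=t,
                study=agg.study,
            )
        )
    if not pairs:
        raise ValueError(
            "no C-peptide timepoints fall inside the smoothed residual range"
        )
    return pairs
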