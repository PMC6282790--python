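"""Retention analysis: chromatograms -> retention factors -> log P_mw.

For a binding solute the retention factor follows

    k' = k'0 / (1 + K_AM * C_M)

so 1/k' is linear in the micellar concentration C_M with intercept
1/k'0 and slope K_AM/k'0.  The micelle-water association constant is
K_AM = slope/intercept and the partition coefficient is
log P_mw = log10(K_AM).  Antibinding solutes (retention increasing with
C_M) give a negative slope of the reciprocal line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "Chromatogram",
    "DeadTimeEstimate",
    "BindingSeries",
    "BindingFit",
    "RetentionError",
    "detect_apex",
    "estimate_dead_time",
    "retention_factor",
    "fit_binding_model",
    "logpmw_table",
    "series_from_table",
]

Convention = Literal["slope_over_intercept", "intercept_over_slope"]


class RetentionError(ValueError):
    """Invalid chromatographic input or non-physical fit."""


@dataclass(frozen=True)
class Chromatogram:
    """A uniformly sampled detector trace.

    time is in minutes and strictly increasing; signal is arbitrary
    absorbance units of the same length (>= 50 samples).
    """

    time: np.ndarray
    signal: np.ndarray
    drug: str = ""
    total_surfactant: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or len(t) != len(s):
            raise RetentionError("time and signal must be 1-D and equal length")
        if len(t) < 50:
            raise RetentionError("chromatogram needs at least 50 samples")
        if not np.all(np.diff(t) > 0):
            raise RetentionError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class DeadTimeEstimate:
    """Mean solvent-front time t0 over replicate recordings."""

    replicate_times: tuple[float, ...]
    t0: float
    n: int
    sd: float


@dataclass(frozen=True)
class BindingSeries:
    """Per-drug (C_M, k') observations, optionally with replicates.

    ``points`` maps each micellar concentration (M) to either a single
    retention factor or a sequence of replicate retention factors; the
    replicate mean is the regression observation.
    """

    drug: str
    points: Mapping[float, float | Sequence[float]]

    def mean_points(self) -> tuple[np.ndarray, np.ndarray]:
        cm, kp = [], []
        for c, k in sorted(self.points.items()):
            arr = np.atleast_1d(np.asarray(k, dtype=float))
            cm.append(float(c))
            kp.append(float(arr.mean()))
        return np.array(cm), np.array(kp)


@dataclass(frozen=True)
class BindingFit:
    """OLS fit of 1/k' on C_M and derived partition quantities."""

    drug: str
    slope: float
    intercept: float
    k_am: float
    log_pmw: float
    binding_class: str  # binding | antibinding | none
    r_squared: float
    slope_p_value: float
    convention: Convention


def detect_apex(
    chrom: Chromatogram,
    smoothing_window: int = 5,
    *,
    multipeak: bool = False,
    prominence_factor: float = 5.0,
) -> float | list[float]:
    """Apex time of the dominant peak (or all peaks in multipeak mode).

    The signal is smoothed with a centred moving average of
    ``smoothing_window`` samples, then the time of the global maximum is
    returned.  In multipeak mode all local maxima whose prominence
    exceeds ``prominence_factor`` times the baseline noise SD (median
    absolute deviation of the first 5% of samples) are returned sorted
    by time.  Raises if the trace is flat relative to that noise floor.
    """
    if smoothing_window < 1 or smoothing_window >= len(chrom.signal):
        raise RetentionError("smoothing_window must be >= 1 and shorter than trace")
    if smoothing_window % 2 == 0:
        raise RetentionError("smoothing_window must be odd")
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(chrom.signal, kernel, mode="same")

    n_base = max(5, len(smooth) // 20)
    noise_sd = stats.median_abs_deviation(chrom.signal[:n_base], scale="normal")
    floor = max(prominence_factor * noise_sd, 1e-12 * max(1.0, np.abs(smooth).max()))
    if smooth.max() - smooth.min() <= floor:
        raise RetentionError(f"no peak detected in trace for {chrom.drug!r}")

    if not multipeak:
        return float(chrom.time[int(np.argmax(smooth))])
    idx, _ = sps.find_peaks(smooth, prominence=floor)
    if len(idx) == 0:
        raise RetentionError(f"no peak detected in trace for {chrom.drug!r}")
    return [float(t) for t in chrom.time[idx]]


def estimate_dead_time(replicate_times: Iterable[float]) -> DeadTimeEstimate:
    """Dead time t0 as the mean of replicate solvent-front times.

    Protocol calls for at least 10 recordings; fewer produce a warning,
    not an error.
    """
    times = tuple(float(t) for t in replicate_times)
    if not times:
        raise RetentionError("no replicate times given")
    if any(t <= 0 for t in times):
        raise RetentionError(f"non-positive solvent-front time in {times}")
    if len(times) < 10:
        warnings.warn(
            f"dead time from only {len(times)} recordings; protocol uses >= 10",
            UserWarning,
            stacklevel=2,
        )
    arr = np.array(times)
    sd = float(arr.std(ddof=1)) if len(times) > 1 else 0.0
    return DeadTimeEstimate(times, float(arr.mean()), len(times), sd)


def retention_factor(retention_time: float, t0: float) -> float:
    """k' = (retention_time - t0) / t0."""
    if t0 <= 0:
        raise RetentionError("dead time must be positive")
    if retention_time < t0:
        raise RetentionError(
            f"retention time {retention_time} min before solvent front {t0} min"
        )
    return (retention_time - t0) / t0


def fit_binding_model(
    series: BindingSeries,
    *,
    alpha: float = 0.05,
    convention: Convention = "slope_over_intercept",
) -> BindingFit:
    """Fit the reciprocal retention line and extract K_AM and log P_mw.

    Ordinary least squares of mean 1/k' on C_M.  The default convention
    takes K_AM = slope/intercept, the standard micellar-partitioning
    relation; ``convention="intercept_over_slope"`` computes the literal
    intercept/slope ratio instead, and the fit records which was used.
    Binding class is decided by a two-sided t test on the slope at
    ``alpha``.
    """
    cm, kp = series.mean_points()
    if len(cm) < 3:
        raise RetentionError(
            f"{series.drug!r}: need >= 3 distinct C_M levels, got {len(cm)}"
        )
    if np.any(cm < 0):
        raise RetentionError(f"{series.drug!r}: negative C_M")
    if np.any(kp <= 0):
        raise RetentionError(f"{series.drug!r}: non-positive k'; cannot take 1/k'")

    y = 1.0 / kp
    res = stats.linregress(cm, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r_squared = float(res.rvalue**2)
    p_slope = float(res.pvalue)

    scale = max(abs(y).max(), 1e-300)
    if abs(slope) < 1e-12 * scale / max(cm.max(), 1e-300) and abs(intercept) < 1e-12 * scale:
        raise RetentionError(f"{series.drug!r}: slope and intercept both ~0")
    if intercept <= 0:
        raise RetentionError(
            f"{series.drug!r}: non-physical fit (intercept {intercept:.3g} <= 0)"
        )

    if p_slope < alpha and slope > 0:
        binding_class = "binding"
    elif p_slope < alpha and slope < 0:
        binding_class = "antibinding"
    else:
        binding_class = "none"

    if binding_class != "binding":
        k_am = math.nan
        log_pmw = math.nan
    else:
        ratio = slope / intercept if convention == "slope_over_intercept" else intercept / slope
        k_am = ratio
        log_pmw = math.log10(k_am) if k_am > 0 else math.nan

    return BindingFit(
        drug=series.drug,
        slope=slope,
        intercept=intercept,
        k_am=k_am,
        log_pmw=log_pmw,
        binding_class=binding_class,
        r_squared=r_squared,
        slope_p_value=p_slope,
        convention=convention,
    )


def series_from_table(
    table: pd.DataFrame, t0: float, cmc: float
) -> list[BindingSeries]:
    """Build per-drug binding series from a long retention table.

    Expects columns drug, total_conc_M, replicate, retention_time_min.
    C_M = total_conc_M - cmc; k' = (retention_time - t0)/t0, replicates
    kept per concentration level.  Drug order follows first appearance.
    """
    required = {"drug", "total_conc_M", "retention_time_min"}
    missing = required - set(table.columns)
    if missing:
        raise RetentionError(f"retention table missing columns {sorted(missing)}")
    out = []
    for drug in table["drug"].drop_duplicates():
        sub = table[table["drug"] == drug]
        points: dict[float, list[float]] = {}
        for _, row in sub.iterrows():
            cm = float(row["total_conc_M"]) - cmc
            if cm < 0:
                raise RetentionError(
                    f"{drug!r}: total concentration {row['total_conc_M']} M below CMC {cmc} M"
                )
            points.setdefault(round(cm, 12), []).append(
                retention_factor(float(row["retention_time_min"]), t0)
            )
        out.append(BindingSeries(drug=str(drug), points=points))
    return out


def logpmw_table(
    series_collection: Iterable[BindingSeries],
    *,
    alpha: float = 0.05,
    convention: Convention = "slope_over_intercept",
) -> pd.DataFrame:
    """One row per drug: slope, intercept, K_AM, log P_mw, fit quality.

    Drugs whose fit fails are kept with null numeric fields and the
    failure reason; other drugs are unaffected.
    """
    rows = []
    for series in series_collection:
        try:
            fit = fit_binding_model(series, alpha=alpha, convention=convention)
            reason = ""
            if fit.binding_class != "binding":
                reason = f"no log P_mw: binding class is {fit.binding_class}"
            rows.append(
                {
                    "drug": fit.drug,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "k_am": fit.k_am,
                    "log_pmw": fit.log_pmw,
                    "r_squared": fit.r_squared,
                    "binding_class": fit.binding_class,
                    "convention": fit.convention,
                    "reason": reason,
                }
            )
        except RetentionError as exc:
            rows.append(
                {
                    "drug": series.drug,
                    "slope": math.nan,
                    "intercept": math.nan,
                    "k_am": math.nan,
                    "log_pmw": math.nan,
                    "r_squared": math.nan,
                    "binding_class": "error",
                    "convention": convention,
                    "reason": str(exc),
                }
            )
    columns = [
        "drug", "slope", "intercept", "k_am", "log_pmw",
        "r_squared", "binding_class", "convention", "reason",
    ]
    return pd.DataFrame(rows, columns=columns)
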