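"""Normalization, pooling and cohort statistics of heat-evoked currents.

Normalization of a cell's initial heat response subtracts the current at
26 °C (the 26.0-26.25 °C bin of the same sweep) and divides by the maximum
of the subtracted values, mapping every curve onto [0, 1].  Normalized
curves are pooled per 0.25 °C grid point over 26-64 °C as mean ± SEM across
the cells contributing to that point (grid points a cell never visited are
masked, not zero-filled).

Cohort statistics are thin wrappers over scipy: Student's t tests (paired
or independent), one-way ANOVA with Dunnett's post hoc against a control
group, and the Pearson correlation between realized ramp speed and apparent
Q10.  Reports carry medians and quartiles, which is how skewed Q10
distributions are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .arrhenius import (
    ArrheniusFit,
    BinnedIV,
    NoLinearSegmentError,
    InsufficientDataError,
    arrhenius_points,
    bin_currents,
    detect_max_q10_segment,
    low_range_q10,
)
from .gating_sim import CurrentTrace
from .trace_io import extract_rising_phase

__all__ = [
    "GRID_LO",
    "GRID_HI",
    "PooledResponse",
    "DegenerateCurveError",
    "fit_sweep",
    "binned_rising_phase",
    "normalize_response",
    "pool_cohort",
    "cohort_compare",
    "cohort_anova",
    "speed_q10_correlation",
]

GRID_LO = 26.0
GRID_HI = 64.0
GRID_STEP = 0.25


class DegenerateCurveError(ValueError):
    """Normalization impossible: no current above the 26 °C reference."""


def binned_rising_phase(trace: CurrentTrace, bin_width: float = 0.25) -> BinnedIV:
    """Rising-phase window of a sweep, pooled into temperature bins."""
    w = extract_rising_phase(trace)
    sl = w.rising_slice
    return bin_currents(trace.temp[sl], trace.current[sl], bin_width)


def fit_sweep(
    trace: CurrentTrace, r2_min: float = 0.98, min_bins: int = 8
) -> ArrheniusFit:
    """Full per-sweep pipeline: rising phase -> bins -> maximal-Q10 segment."""
    x, y = arrhenius_points(binned_rising_phase(trace))
    return detect_max_q10_segment(x, y, r2_min=r2_min, min_bins=min_bins)


def sweep_low_range_q10(trace: CurrentTrace, T_range=(26.0, 34.0)) -> float:
    """Fixed low-temperature-range regression Q10 of one sweep."""
    x, y = arrhenius_points(binned_rising_phase(trace))
    return low_range_q10(x, y, T_range).Q10


@dataclass
class PooledResponse:
    """Mean ± SEM normalized current-temperature relationship of a cohort."""

    temp_grid: np.ndarray  # °C bin centers, 26-64 at 0.25 °C pitch
    mean_norm: np.ndarray  # masked with NaN where n_cells == 0
    sem_norm: np.ndarray
    n_cells: np.ndarray


def normalize_response(binned: BinnedIV):
    """Normalize a binned heat response onto [0, 1].

    ``y(T) = (|I|(T) - |I|(26 °C)) / max_T(|I|(T) - |I|(26 °C))``, clipped
    at zero.  The 26 °C reference is the mean of the 26.0-26.25 °C bin of
    the same sweep.

    Returns ``(temps, y)``.

    Raises
    ------
    InsufficientDataError
        If the sweep has no bin at or below 26.25 °C.
    DegenerateCurveError
        If the subtracted curve has no positive values (e.g. constant
        current).
    """
    centers = binned.bin_centers
    below = centers <= GRID_LO + GRID_STEP
    if not below.any():
        raise InsufficientDataError("no bin at or below 26.25 °C for the reference")
    mag = np.abs(binned.mean_current)  # sign convention of stored currents is moot
    ref = mag[below][-1]  # bin closest to 26 °C from below
    sub = mag - ref
    peak = sub.max()
    if peak <= 0:
        raise DegenerateCurveError("no current above the 26 °C reference")
    return centers, np.clip(sub / peak, 0.0, None)


def pool_cohort(curves) -> PooledResponse:
    """Pool normalized curves across cells onto the fixed 26-64 °C grid.

    ``curves`` is an iterable of ``(temps, y)`` pairs as returned by
    :func:`normalize_response`.  Each grid point averages the cells that
    have data there; SEM uses the n-1 sample standard deviation; points no
    cell visited are NaN with ``n_cells = 0``.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to pool")
    grid = np.arange(GRID_LO + GRID_STEP / 2, GRID_HI, GRID_STEP)
    n = np.zeros(grid.size, dtype=int)
    ssum = np.zeros(grid.size)
    ssq = np.zeros(grid.size)
    for temps, y in curves:
        idx = np.round((np.asarray(temps) - grid[0]) / GRID_STEP).astype(int)
        ok = (idx >= 0) & (idx < grid.size)
        np.add.at(n, idx[ok], 1)
        np.add.at(ssum, idx[ok], np.asarray(y)[ok])
        np.add.at(ssq, idx[ok], np.asarray(y)[ok] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, ssum / np.maximum(n, 1), np.nan)
        var = np.where(
            n > 1, (ssq - n * mean**2) / np.maximum(n - 1, 1), np.nan
        )
        sem = np.where(n > 1, np.sqrt(np.maximum(var, 0.0) / n), np.nan)
    return PooledResponse(grid, mean, sem, n)


@dataclass
class CompareReport:
    """Two-group comparison of Q10 (or threshold) values."""

    test: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    quartiles_a: tuple
    quartiles_b: tuple
    n_a: int
    n_b: int


def _q10s(fits):
    return np.asarray(
        [f.Q10 if isinstance(f, ArrheniusFit) else float(f) for f in fits]
    )


def cohort_compare(fits_a, fits_b, paired: bool = False) -> CompareReport:
    """Student's t comparison of two cohorts of Q10 values (or fits).

    Skewed Q10 distributions are compared on a log scale (a Q10 ratio test),
    which is the natural scale for the exponential Arrhenius coefficient;
    medians and quartiles are reported untransformed.
    """
    a, b = _q10s(fits_a), _q10s(fits_b)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal group sizes")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations per group")
    la, lb = np.log(a), np.log(b)
    if paired:
        if np.allclose(la, lb):
            # zero difference everywhere: no effect, p = 1 by convention
            res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            res = stats.ttest_rel(la, lb)
        name = "paired t-test (log Q10)"
    else:
        res = stats.ttest_ind(la, lb)
        name = "t-test (log Q10)"
    return CompareReport(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        quartiles_a=tuple(np.percentile(a, [25, 75])),
        quartiles_b=tuple(np.percentile(b, [25, 75])),
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class AnovaReport:
    f_statistic: float
    p_value: float
    dunnett_p: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)
    quartiles: dict = field(default_factory=dict)


def cohort_anova(groups: dict, control: str) -> AnovaReport:
    """One-way ANOVA across named groups + Dunnett's post hoc vs control."""
    if control not in groups:
        raise KeyError(f"control group {control!r} not in groups")
    if len(groups) < 3:
        raise ValueError("ANOVA needs at least 3 groups")
    arrays = {k: _q10s(v) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*arrays.values())
    others = [k for k in arrays if k != control]
    dn = stats.dunnett(*(arrays[k] for k in others), control=arrays[control])
    return AnovaReport(
        f_statistic=float(f),
        p_value=float(p),
        dunnett_p={k: float(pv) for k, pv in zip(others, dn.pvalue)},
        medians={k: float(np.median(v)) for k, v in arrays.items()},
        quartiles={k: tuple(np.percentile(v, [25, 75])) for k, v in arrays.items()},
    )


def speed_q10_correlation(speeds, q10s):
    """Pearson correlation between realized max ramp speed and apparent Q10."""
    speeds = np.asarray(speeds, float)
    q10s = np.asarray(q10s, float)
    if len(speeds) != len(q10s) or len(speeds) < 3:
        raise ValueError("need matched arrays of length >= 3")
    r, p = stats.pearsonr(speeds, q10s)
    return float(r), float(p)
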