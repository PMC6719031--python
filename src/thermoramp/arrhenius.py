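"""Arrhenius analysis of heat-evoked whole-cell currents.

The estimation procedure used throughout this package:

1. Currents sampled during the rising phase of a temperature ramp are
   pooled (averaged) into 0.25 °C temperature bins.
2. The absolute value of the binned inward current is plotted on a natural-log
   scale against the reciprocal of the absolute temperature (Arrhenius plot).
3. The maximal apparent temperature coefficient ``Q10`` and the thermal
   threshold are read off the steepest contiguous stretch of the plot that is
   still acceptably straight: among all contiguous bin windows of at least
   ``min_bins`` points whose linear-regression ``r² >= r2_min`` (default
   0.98), the window maximizing ``|slope|`` is reported.  The apparent
   activation energy is ``Ea = -slope * R`` and

       Q10 = exp(dT * Ea / (R * T1 * T2)),   dT = 10 K,

   with ``T1``/``T2`` the absolute temperatures bounding the window.  The
   thermal threshold is defined as the lower temperature limit ``T1`` of this
   maximal-Q10 segment.
4. A fixed-range, search-free regression Q10 over ~26-34 °C characterises the
   weak sub-threshold temperature dependence.

The exhaustive all-windows search is cheap at the bin counts that occur in
practice (a 25->60 °C ramp gives ~140 bins) and is deterministic: ties on
|slope| are broken toward the wider window, then toward the higher lower
temperature limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_GAS",
    "ZERO_C",
    "BinnedIV",
    "ArrheniusFit",
    "InsufficientDataError",
    "NoLinearSegmentError",
    "bin_currents",
    "arrhenius_points",
    "detect_max_q10_segment",
    "q10_from_slope",
    "q10_from_points",
    "low_range_q10",
    "threshold_of",
]

#: molar gas constant, J/(mol K)
R_GAS = 8.314
#: 0 °C in kelvin
ZERO_C = 273.15
#: ΔT of the Q10 definition, kelvin
DELTA_T = 10.0


class InsufficientDataError(ValueError):
    """Raised when a temperature range holds too few bins for a fit."""


class NoLinearSegmentError(ValueError):
    """Raised when no contiguous window satisfies the r² criterion.

    Carries the best attained r² in :attr:`best_r2` for diagnostics.
    """

    def __init__(self, message: str, best_r2: float = np.nan):
        super().__init__(message)
        self.best_r2 = best_r2


@dataclass(frozen=True)
class BinnedIV:
    """Mean absolute current per 0.25 °C temperature bin.

    Bins are half-open ``[T, T + width)``; ``bin_centers`` are the midpoints
    of the occupied bins only (empty bins are dropped).
    """

    bin_centers: np.ndarray  # °C
    mean_current: np.ndarray  # pA, absolute value
    n_samples: np.ndarray
    bin_width: float = 0.25

    def __post_init__(self):
        if not (len(self.bin_centers) == len(self.mean_current) == len(self.n_samples)):
            raise ValueError("binned arrays must have equal length")


@dataclass(frozen=True)
class ArrheniusFit:
    """Linear-segment fit of an Arrhenius plot.

    ``slope`` is d ln|I| / d(1/T) in kelvin; negative for heat-activated
    currents.  ``Ea`` (kJ/mol) and ``Q10`` follow from the slope and the
    segment's temperature limits.
    """

    T_low: float  # °C, lower limit == thermal threshold
    T_high: float  # °C
    slope: float  # K
    Ea: float  # kJ/mol
    Q10: float
    r2: float
    n_bins: int

    def __post_init__(self):
        if self.T_low >= self.T_high:
            raise ValueError("T_low must be below T_high")


def bin_currents(temp_C, current_pA, bin_width: float = 0.25) -> BinnedIV:
    """Pool current samples into fixed-width temperature bins.

    Parameters
    ----------
    temp_C, current_pA : array-like
        Paired temperature (°C) and current (pA) samples from the rising
        phase of one sweep.  The absolute value of the current is averaged.
    bin_width : float
        Bin pitch in °C; bins are half-open ``[k*w, (k+1)*w)`` anchored at
        0 °C.

    Returns
    -------
    BinnedIV
        Occupied bins only, sorted by temperature.

    Raises
    ------
    InsufficientDataError
        If fewer than 8 bins are occupied (< 2 °C span at the default pitch).
    """
    temp_C = np.asarray(temp_C, dtype=float)
    current = np.abs(np.asarray(current_pA, dtype=float))
    if temp_C.size == 0:
        raise InsufficientDataError("empty rising-phase window")
    idx = np.floor(temp_C / bin_width).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    cur_sorted = current[order]
    uniq, start = np.unique(idx_sorted, return_index=True)
    sums = np.add.reduceat(cur_sorted, start)
    counts = np.diff(np.append(start, idx_sorted.size))
    centers = (uniq + 0.5) * bin_width
    binned = BinnedIV(centers, sums / counts, counts, bin_width)
    if len(uniq) < 8:
        raise InsufficientDataError(
            f"insufficient temperature span: only {len(uniq)} non-empty bins (need >= 8)"
        )
    return binned


def arrhenius_points(binned: BinnedIV):
    """Transform binned currents to Arrhenius coordinates.

    Returns ``(x, y)`` with ``x = 1/T`` in 1/K (strictly decreasing as
    temperature rises) and ``y = ln |I|``.  Bins with non-positive mean
    current carry no information on a log scale and are excluded.
    """
    mask = binned.mean_current > 0
    T_K = binned.bin_centers[mask] + ZERO_C
    x = 1.0 / T_K
    y = np.log(binned.mean_current[mask])
    return x, y


def _window_stats(x, y):
    """Slope and r² of OLS y~x for every contiguous window, via prefix sums.

    Returns (slope, r2) as (n, n) upper-triangular-ish arrays where entry
    [i, j] describes the window covering points i..j inclusive.  O(n²) memory;
    fine for the few hundred bins a ramp produces.
    """
    n = len(x)
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = (j - i + 1).astype(float)  # window length
    Sx = cx[j + 1] - cx[i]
    Sy = cy[j + 1] - cy[i]
    Sxx = cxx[j + 1] - cxx[i]
    Syy = cyy[j + 1] - cyy[i]
    Sxy = cxy[j + 1] - cxy[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = Sxx - Sx * Sx / m
        vy = Syy - Sy * Sy / m
        cov = Sxy - Sx * Sy / m
        slope = cov / vx
        r2 = np.where(vy > 0, cov * cov / (vx * vy), 1.0)
    return slope, r2, m


def q10_from_slope(Ea_kJ: float, T1_K: float, T2_K: float) -> float:
    """Temperature coefficient from apparent activation energy.

    ``Q10 = exp(dT * Ea / (R * T1 * T2))`` with ``dT = 10 K``, ``Ea`` in
    kJ/mol converted to J/mol, and ``T1 < T2`` the absolute temperature
    limits of the fitted segment.
    """
    if T1_K <= 0 or T2_K <= 0:
        raise ValueError("absolute temperatures must be positive")
    if T1_K >= T2_K:
        raise ValueError("T1 must be below T2")
    return float(np.exp(DELTA_T * Ea_kJ * 1e3 / (R_GAS * T1_K * T2_K)))


def _fit_from_window(x, y, lo: int, hi: int, slope: float, r2: float) -> ArrheniusFit:
    # x = 1/T is decreasing, so the window's last point is the hottest
    T_high_K = 1.0 / x[hi]
    T_low_K = 1.0 / x[lo]
    Ea_kJ = -slope * R_GAS / 1e3
    return ArrheniusFit(
        T_low=T_low_K - ZERO_C,
        T_high=T_high_K - ZERO_C,
        slope=slope,
        Ea=Ea_kJ,
        Q10=q10_from_slope(Ea_kJ, T_low_K, T_high_K),
        r2=r2,
        n_bins=hi - lo + 1,
    )


def detect_max_q10_segment(
    x, y, r2_min: float = 0.98, min_bins: int = 8
) -> ArrheniusFit:
    """Find the steepest acceptably linear segment of an Arrhenius plot.

    Among all contiguous windows of >= ``min_bins`` points with regression
    ``r² >= r2_min``, return the fit of the window maximizing ``|slope|``
    (i.e. maximal Q10).  Ties break toward the wider window, then toward the
    higher lower-temperature limit.

    ``x`` must be strictly decreasing (1/T ordering of rising temperature).

    Raises
    ------
    NoLinearSegmentError
        If no window qualifies; the best attained r² among windows of
        sufficient width is attached.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < min_bins:
        raise InsufficientDataError(f"need at least {min_bins} points, got {n}")
    if np.any(np.diff(x) >= 0):
        raise ValueError("x (=1/T) must be strictly decreasing")
    slope, r2, m = _window_stats(x, y)
    valid = (m >= min_bins) & (np.arange(n)[:, None] <= np.arange(n)[None, :])
    ok = valid & (r2 >= r2_min)
    if not ok.any():
        best = float(np.nanmax(np.where(valid, r2, np.nan)))
        raise NoLinearSegmentError(
            f"no linear segment at r2_min={r2_min:g}; best attained r²={best:.4f}",
            best_r2=best,
        )
    absl = np.where(ok, np.abs(slope), -np.inf)
    # lexicographic argmax: |slope|, then window width, then higher T_low
    # (x = 1/T decreases with index, so index 0 is the coldest bin and a
    # higher T_low means a larger start index i).  Slopes within a relative
    # 1e-9 are treated as tied so that exactly collinear data returns the
    # widest window rather than an arbitrary float-jitter winner.
    best_val = absl.max()
    tol = 1e-9 * abs(best_val)
    ii2, jj2 = np.nonzero(absl >= best_val - tol)
    widths = jj2 - ii2 + 1
    wmax = widths.max()
    sel = widths == wmax
    ii3, jj3 = ii2[sel], jj2[sel]
    k = np.argmax(ii3)  # highest T_low
    lo, hi = int(ii3[k]), int(jj3[k])
    return _fit_from_window(x, y, lo, hi, float(slope[lo, hi]), float(r2[lo, hi]))


def q10_from_points(x, y) -> ArrheniusFit:
    """Single regression Q10 over a fixed window (no segment search)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 points for a regression")
    vx = x - x.mean()
    vy = y - y.mean()
    sxx = float(vx @ vx)
    syy = float(vy @ vy)
    sxy = float(vx @ vy)
    slope = sxy / sxx
    r2 = 1.0 if syy == 0 else sxy * sxy / (sxx * syy)
    order = np.argsort(x)
    return _fit_from_window(x[order][::-1], y[order][::-1], 0, len(x) - 1, slope, r2)


def low_range_q10(x, y, T_range=(26.0, 34.0)) -> ArrheniusFit:
    """Regression Q10 over a fixed low-temperature range (default 26-34 °C).

    Characterises the weak temperature dependence below the activation
    threshold (leak plus sub-threshold gating).  No segment search: all bins
    whose centers fall inside ``T_range`` enter one regression.

    Raises
    ------
    InsufficientDataError
        If fewer than 5 bins fall in the range.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    T_C = 1.0 / x - ZERO_C
    mask = (T_C >= T_range[0]) & (T_C <= T_range[1])
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} bins in {T_range[0]:g}-{T_range[1]:g} °C (need >= 5)"
        )
    return q10_from_points(x[mask], y[mask])


def threshold_of(fit: ArrheniusFit) -> float:
    """Thermal activation threshold: lower limit of the maximal-Q10 segment, °C."""
    return fit.T_low
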