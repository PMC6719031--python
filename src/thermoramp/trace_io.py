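"""CSV interchange of current traces and rising-phase segmentation.

The interchange format is a plain UTF-8 CSV with '.' decimal and a required
header ``cell_id,sweep,t_s,temp_C,current_pA,vhold_mV,agonist`` — one row
per sample, one (cell_id, sweep) pair per trace.  The Arrhenius analysis
consumes only the samples acquired during the *rising phase* of each
temperature ramp; :func:`extract_rising_phase` locates that window with a
stated convention: the ramp onset is the first sample of the sustained
stretch with smoothed dT/dt > 1 °C/s that ends at the sweep's temperature
peak (temperature smoothed by a centered 5-ms moving average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating_sim import CurrentTrace

__all__ = [
    "COLUMNS",
    "SweepWindow",
    "TraceFormatError",
    "NoRampError",
    "load_traces",
    "write_traces",
    "traces_to_frame",
    "extract_rising_phase",
]

COLUMNS = ["cell_id", "sweep", "t_s", "temp_C", "current_pA", "vhold_mV", "agonist"]

#: dT/dt that counts as active heating, °C/s
ONSET_SLOPE = 1.0


class TraceFormatError(ValueError):
    """Malformed trace CSV (missing column, bad ordering, mixed vhold)."""


class NoRampError(ValueError):
    """Sweep contains no rising temperature phase."""


@dataclass(frozen=True)
class SweepWindow:
    """Rising-phase window of one sweep."""

    cell_id: str
    sweep: int
    rising_slice: slice
    peak_T: float      # °C
    max_speed: float   # °C/s, max smoothed dT/dt inside the window


def traces_to_frame(traces) -> pd.DataFrame:
    """Concatenate traces into one tidy DataFrame in the interchange schema."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "sweep": tr.sweep,
                    "t_s": tr.t,
                    "temp_C": tr.temp,
                    "current_pA": tr.current,
                    "vhold_mV": tr.vhold,
                    "agonist": tr.agonist,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(parts, ignore_index=True)[COLUMNS]


def write_traces(traces, path) -> None:
    """Write traces to the interchange CSV (UTF-8, '.' decimal)."""
    traces_to_frame(traces).to_csv(path, index=False)


def load_traces(path) -> list[CurrentTrace]:
    """Load traces from the interchange CSV.

    Rows are sorted by (cell_id, sweep, t_s), so shuffled files load to the
    same traces.  Round-trips with :func:`write_traces` bit-exactly (Python's
    shortest-repr float formatting).

    Raises
    ------
    TraceFormatError
        On a missing column, non-monotone time within a sweep (after
        sorting: duplicate timestamps), or mixed holding potential within a
        sweep; the message names the offending column or row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"missing column {col}")
    df = df.sort_values(["cell_id", "sweep", "t_s"], kind="stable")
    traces = []
    for (cell, sweep), g in df.groupby(["cell_id", "sweep"], sort=True):
        t = g["t_s"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = g.index[bad[0] + 1]
            raise TraceFormatError(
                f"non-monotone time in cell {cell} sweep {sweep} at row {row}"
            )
        vh = g["vhold_mV"].to_numpy(float)
        if np.unique(vh).size > 1:
            raise TraceFormatError(
                f"mixed vhold_mV within cell {cell} sweep {sweep}"
            )
        ag = g["agonist"].to_numpy()
        traces.append(
            CurrentTrace(
                cell_id=str(cell),
                sweep=int(sweep),
                t=t,
                temp=g["temp_C"].to_numpy(float),
                current=g["current_pA"].to_numpy(float),
                vhold=float(vh[0]),
                agonist=bool(ag[0]),
            )
        )
    return traces


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation."""
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def extract_rising_phase(trace: CurrentTrace, smooth_ms: float = 5.0) -> SweepWindow:
    """Locate the rising-phase window of one sweep.

    Temperature is smoothed with a centered ``smooth_ms`` moving average;
    the window runs from the onset of sustained heating (dT/dt >
    ``ONSET_SLOPE``) to the sweep's peak temperature.

    Raises
    ------
    NoRampError
        If the sweep never heats faster than the onset slope before its
        temperature maximum (flat or cooling-only trace).
    """
    t, temp = trace.t, trace.temp
    if len(t) < 3:
        raise NoRampError("trace too short")
    dt_med = float(np.median(np.diff(t)))
    width = max(1, int(round(smooth_ms / 1e3 / dt_med)))
    sm = _smooth(temp, width)
    slope = np.gradient(sm, t)
    peak = int(np.argmax(temp))  # raw peak; smoothing is for the derivative only
    heating = slope > ONSET_SLOPE
    runs = np.nonzero(heating[: peak + 1])[0]
    if peak == 0 or runs.size == 0:
        raise NoRampError("no ramp detected (no sustained heating before peak)")
    # onset: start of the last contiguous heating run before the peak (the
    # smoothed slope may dip below threshold a few samples short of the raw
    # temperature maximum)
    last_heat = int(runs[-1])
    onset = last_heat
    while onset > 0 and heating[onset - 1]:
        onset -= 1
    window = slice(onset, peak + 1)
    return SweepWindow(
        cell_id=trace.cell_id,
        sweep=trace.sweep,
        rising_slice=window,
        peak_T=float(temp[peak]),
        max_speed=float(slope[onset : last_heat + 1].max()),
    )
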