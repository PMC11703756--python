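"""Fluorescence- and area-based quantification of ionophore-mediated transport.

Implements the standard normalizations used for GUV metal-transport assays
with the Rhod2 reporter:

* per-GUV transport (quench readout for Ni²⁺/Cu²⁺):
  ``(I_initial − I_final) / I_mean × 100`` with I_mean the initial mean
  intensity over all analysed GUVs in the sample;
* per-GUV relative transport (gain readout for Ca²⁺):
  ``(I_final − I_initial) / ΔI_ref × 100`` where ΔI_ref is the mean
  intensity change of the reference condition (cognate ionophore alone),
  defining 100 %;
* plate-reader transport efficiency:
  ``(I_initial − I_x)/(I_initial − I_min) × 100`` (quench) and
  ``(I_x − I_initial)/(I_max − I_initial) × 100`` (gain), with I_min/I_max
  the extremes within one experiment set;
* dye (sulfo-Cy5) retention: ``I_t / I_0 × 100`` with the 0-min baseline set
  to 100 %;
* lysis calls from GUV area traces (median-smoothed area falling below a
  fraction of the initial area and staying there).

Negative percentages are reported rather than clipped — a noisy
non-transporting GUV can undershoot — and a QC flag marks values outside
[−5, 105].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "GUVFluorescenceTrace",
    "SampleContext",
    "PlateReaderSeries",
    "GUVAreaTrace",
    "percent_transport_quench",
    "percent_relative_transport_ca",
    "compute_delta_i_ref",
    "platereader_percent_transport",
    "leakage_percent",
    "detect_lysis",
    "fluorescence_traces_from_dataframe",
    "area_traces_from_dataframe",
]

QC_BOUNDS = (-5.0, 105.0)


@dataclass
class GUVFluorescenceTrace:
    """Per-GUV, per-channel intensity vs time with addition timestamps."""

    guv_id: int
    channel: str
    times: np.ndarray  # min
    intensities: np.ndarray  # a.u.
    additions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class SampleContext:
    """Sample-level normalizers shared across the GUVs of one experiment."""

    i_mean: float | None = None  # initial mean intensity of analysed GUVs
    delta_i_ref: float | None = None  # reference-condition mean ΔI (gain mode)


@dataclass
class PlateReaderSeries:
    """One well's intensity series plus the experiment-set extremes."""

    well_id: str
    times: np.ndarray
    intensities: np.ndarray
    i_initial: float | None = None  # defaults to the first sample
    i_min: float | None = None
    i_max: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.i_initial is None:
            self.i_initial = float(self.intensities[0])


@dataclass
class GUVAreaTrace:
    """GUV cross-sectional area (µm²) vs time (min)."""

    guv_id: int
    times: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if np.any(self.areas < 0):
            raise ValueError("areas must be >= 0")


def _window_means(
    trace: GUVFluorescenceTrace, addition_label: str, window: int
) -> tuple[float, float]:
    """(I_initial, I_final): means of the pre-addition and terminal windows."""
    if addition_label not in trace.additions:
        raise ValueError(
            f"trace {trace.guv_id} has no addition event {addition_label!r}"
        )
    t_add = trace.additions[addition_label]
    pre = np.flatnonzero(trace.times < t_add)
    post = np.flatnonzero(trace.times >= t_add)
    if pre.size == 0 or post.size == 0:
        raise ValueError("trace needs samples both before and after the addition")
    i_initial = float(trace.intensities[pre[-window:]].mean())
    i_final = float(trace.intensities[post[-window:]].mean())
    return i_initial, i_final


def percent_transport_quench(
    trace: GUVFluorescenceTrace,
    context: SampleContext,
    addition_label: str = "ionophore",
    window: int = 3,
) -> float:
    """Quench-mode per-GUV transport percentage, (I_init − I_final)/I_mean·100.

    I_initial/I_final are window means (default 3 samples) around the
    addition; the result may be negative for non-transporting GUVs.
    """
    if context.i_mean is None or context.i_mean <= 0:
        raise ValueError("SampleContext.i_mean must be positive for quench mode")
    i_initial, i_final = _window_means(trace, addition_label, window)
    return (i_initial - i_final) / context.i_mean * 100.0


def compute_delta_i_ref(
    reference_traces: Iterable[GUVFluorescenceTrace],
    addition_label: str = "ionophore",
    window: int = 3,
) -> float:
    """Mean (I_final − I_initial) over the reference-condition GUV set."""
    deltas = []
    for tr in reference_traces:
        i_initial, i_final = _window_means(tr, addition_label, window)
        deltas.append(i_final - i_initial)
    if not deltas:
        raise ValueError("reference set is empty")
    return float(np.mean(deltas))


def percent_relative_transport_ca(
    trace: GUVFluorescenceTrace,
    context: SampleContext,
    addition_label: str = "ionophore",
    window: int = 3,
) -> float:
    """Gain-mode relative transport: (I_final − I_initial)/ΔI_ref × 100."""
    if context.delta_i_ref is None or context.delta_i_ref == 0:
        raise ValueError("SampleContext.delta_i_ref must be non-zero")
    i_initial, i_final = _window_means(trace, addition_label, window)
    return (i_final - i_initial) / context.delta_i_ref * 100.0


def platereader_percent_transport(
    series: PlateReaderSeries,
    direction: Literal["quench", "gain"],
) -> pd.DataFrame:
    """Per-timepoint plate-reader transport percentage with QC flags.

    Quench: (I_initial − I_x)/(I_initial − I_min)·100; gain:
    (I_x − I_initial)/(I_max − I_initial)·100.  Values outside [−5, 105] are
    flagged, not clipped.
    """
    i0 = series.i_initial
    if direction == "quench":
        if series.i_min is None:
            raise ValueError("quench normalization needs i_min")
        denom = i0 - series.i_min
        if denom == 0:
            raise ValueError("degenerate normalizer: i_initial == i_min")
        pct = (i0 - series.intensities) / denom * 100.0
    elif direction == "gain":
        if series.i_max is None:
            raise ValueError("gain normalization needs i_max")
        denom = series.i_max - i0
        if denom == 0:
            raise ValueError("degenerate normalizer: i_max == i_initial")
        pct = (series.intensities - i0) / denom * 100.0
    else:
        raise ValueError(f"direction must be 'quench' or 'gain', got {direction!r}")
    return pd.DataFrame(
        {
            "time_min": series.times,
            "percent_transport": pct,
            "qc_out_of_range": (pct < QC_BOUNDS[0]) | (pct > QC_BOUNDS[1]),
        }
    )


def leakage_percent(
    trace: GUVFluorescenceTrace,
    timepoints: Sequence[float] = (20.0, 40.0, 60.0),
    tolerance: float | None = None,
) -> dict[float, float]:
    """Dye retention I_t/I_0 × 100 at the requested timepoints.

    The intensity at t = 0 (nearest sample) is the 100 % baseline.
    Timepoints are matched to the nearest sample within ``tolerance``
    (default: the maximum sampling interval).
    """
    if tolerance is None:
        tolerance = float(np.max(np.diff(trace.times))) if len(trace.times) > 1 else 0.0
    i0 = trace.intensities[int(np.argmin(np.abs(trace.times - 0.0)))]
    if i0 <= 0:
        raise ValueError("baseline intensity at t=0 must be positive")
    out = {}
    for t in timepoints:
        k = int(np.argmin(np.abs(trace.times - t)))
        if abs(trace.times[k] - t) > tolerance:
            raise ValueError(f"timepoint {t} min outside the trace (±{tolerance} min)")
        out[float(t)] = float(trace.intensities[k] / i0 * 100.0)
    return out


def detect_lysis(
    area_trace: GUVAreaTrace,
    fraction_threshold: float = 0.5,
    smooth_window: int = 3,
) -> tuple[bool, float | None]:
    """Call lysis when the smoothed area falls below a fraction of initial
    and stays below until the end; returns (lysed, onset_time_min)."""
    if len(area_trace.times) < 2:
        raise ValueError("need at least 2 samples for a lysis call")
    smoothed = medfilt(area_trace.areas, kernel_size=smooth_window)
    initial = smoothed[0] if smoothed[0] > 0 else float(np.max(smoothed))
    below = smoothed < fraction_threshold * initial
    if not below.any():
        return False, None
    # first index from which the area never recovers
    above = np.flatnonzero(~below)
    start = above[-1] + 1 if above.size else 0
    if start >= len(below):
        return False, None
    return True, float(area_trace.times[start])


# ---------------------------------------------------------------------------
# CSV interchange (time_min, guv_id, channel, intensity) / (time_min, guv_id,
# area_um2)


def fluorescence_traces_from_dataframe(
    df: pd.DataFrame, additions: dict[str, float] | None = None
) -> list[GUVFluorescenceTrace]:
    required = {"time_min", "guv_id", "channel", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"fluorescence table needs columns {sorted(required)}")
    traces = []
    for (guv, channel), grp in df.groupby(["guv_id", "channel"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            GUVFluorescenceTrace(
                guv_id=int(guv),
                channel=str(channel),
                times=grp["time_min"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                additions=dict(additions or {}),
            )
        )
    return traces


def area_traces_from_dataframe(df: pd.DataFrame) -> list[GUVAreaTrace]:
    required = {"time_min", "guv_id", "area_um2"}
    if not required.issubset(df.columns):
        raise ValueError(f"area table needs columns {sorted(required)}")
    traces = []
    for guv, grp in df.groupby("guv_id", sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            GUVAreaTrace(
                guv_id=int(guv),
                times=grp["time_min"].to_numpy(),
                areas=grp["area_um2"].to_numpy(),
            )
        )
    return traces
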