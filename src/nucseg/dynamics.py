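"""Single-cell signaling-trace quantification.

Time-lapse segmentation yields, per tracked cell, a time series of mean
intensities (e.g. nuclear NF-kB reporter signal).  This module implements
the downstream quantification chain: mean imputation of timepoints whose
mask was missing, resampling to a common 7-minute grid by linear
interpolation, two normalisation schemes, a Euclidean trace-dissimilarity
measure, and surface-marker (Ly6C / CD115) status calls from thresholds
computed on the pre-stimulation baseline.

Normalisations
--------------
* ``normalize_baseline_minmax`` (tracking experiments): each cell's trace is
  divided by its mean value before stimulation (pre-stimulus level becomes
  1), then all traces of an experiment are jointly min-max rescaled to
  [0, 1].
* ``normalize_nuc_over_cell`` (confocal experiments): the nuclear trace is
  divided pointwise by the whole-cell trace, then baseline-normalised the
  same way; the output's pre-stimulation mean is exactly 1.

Both baseline normalisations are invariant to rescaling the raw
intensities, so they are comparable across acquisition settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class TraceError(ValueError):
    pass


@dataclass
class Trace:
    """Per-cell intensity time series with missing-value flags.

    times are minutes, strictly increasing; ``missing[i]`` marks timepoints
    whose value came from a missing mask; ``stim_time`` is the stimulation
    time in minutes and must lie within the observed window.
    """

    times: np.ndarray
    values: np.ndarray
    stim_time: float
    missing: np.ndarray | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.missing)):
            raise TraceError("times/values/missing lengths differ")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise TraceError("times must be strictly increasing")
        if len(self.times) and not (self.times[0] <= self.stim_time <= self.times[-1]):
            raise TraceError("stim_time outside the observed window")

    @property
    def pre_mask(self) -> np.ndarray:
        return self.times < self.stim_time

    @property
    def post_mask(self) -> np.ndarray:
        return self.times >= self.stim_time


@dataclass
class NormalizedTrace:
    times: np.ndarray
    values: np.ndarray
    stim_time: float
    normalization_kind: str = "baseline_minmax"
    cell_id: str = ""


def impute_missing(trace: Trace, method: str = "trace_mean") -> Trace:
    """Replace missing values; flags are retained for provenance.

    ``trace_mean`` (default) substitutes the mean of observed values;
    ``neighbor`` linearly interpolates between observed neighbours
    (end gaps take the nearest observed value).
    """
    obs = ~trace.missing
    if not obs.any():
        raise TraceError(f"trace {trace.cell_id!r} has no observed values")
    values = trace.values.copy()
    if method == "trace_mean":
        values[trace.missing] = values[obs].mean()
    elif method == "neighbor":
        values[trace.missing] = np.interp(
            trace.times[trace.missing], trace.times[obs], values[obs]
        )
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return replace(trace, values=values)


def resample(trace: Trace, interval: float = 7.0) -> Trace:
    """Linear-interpolation resampling onto a uniform grid.

    Grid starts at the first timepoint with the given step and never
    extrapolates beyond the last observation.
    """
    if len(trace.times) < 2:
        raise TraceError("resampling needs at least two timepoints")
    if trace.missing.any() and np.isnan(trace.values).any():
        raise TraceError("impute before resampling")
    t0, t1 = trace.times[0], trace.times[-1]
    n_steps = int(np.floor((t1 - t0) / interval * (1 + 1e-12) + 1e-12))
    grid = np.minimum(t0 + interval * np.arange(n_steps + 1), t1)
    values = np.interp(grid, trace.times, trace.values)
    return Trace(
        times=grid, values=values, stim_time=trace.stim_time,
        missing=np.zeros(len(grid), dtype=bool), cell_id=trace.cell_id,
    )


def _baseline(trace: Trace) -> float:
    pre = trace.values[trace.pre_mask]
    if len(pre) < 1:
        raise TraceError(f"trace {trace.cell_id!r} has no pre-stimulation points")
    base = pre.mean()
    if base == 0:
        raise TraceError(f"trace {trace.cell_id!r} has zero pre-stimulation mean")
    return float(base)


def normalize_baseline_minmax(traces: list[Trace]) -> list[NormalizedTrace]:
    """Cell-wise baseline division, then experiment-wise min-max to [0, 1]."""
    if not traces:
        raise TraceError("empty experiment")
    based = []
    for tr in traces:
        based.append(tr.values / _baseline(tr))
    lo = min(v.min() for v in based)
    hi = max(v.max() for v in based)
    if hi == lo:
        raise TraceError("degenerate experiment: min equals max after baseline division")
    return [
        NormalizedTrace(
            times=tr.times.copy(), values=(v - lo) / (hi - lo),
            stim_time=tr.stim_time, normalization_kind="baseline_minmax",
            cell_id=tr.cell_id,
        )
        for tr, v in zip(traces, based)
    ]


def normalize_nuc_over_cell(nuclear: Trace, wholecell: Trace) -> NormalizedTrace:
    """Nuclear/whole-cell ratio, then baseline division (pre-stim mean = 1)."""
    if len(nuclear.times) != len(wholecell.times) or np.any(
        nuclear.times != wholecell.times
    ):
        raise TraceError("nuclear and whole-cell traces must share a time grid")
    if np.any(wholecell.values == 0):
        raise TraceError("whole-cell trace contains zero values")
    ratio = nuclear.values / wholecell.values
    ratio_trace = Trace(
        times=nuclear.times, values=ratio, stim_time=nuclear.stim_time,
        missing=np.zeros(len(ratio), dtype=bool), cell_id=nuclear.cell_id,
    )
    base = _baseline(ratio_trace)
    return NormalizedTrace(
        times=nuclear.times.copy(), values=ratio / base,
        stim_time=nuclear.stim_time, normalization_kind="nuc_over_cell_baseline",
        cell_id=nuclear.cell_id,
    )


def trace_distance(a: NormalizedTrace, b: NormalizedTrace) -> float:
    """Euclidean dissimilarity D over the common time grid (0 = identical)."""
    if a.normalization_kind != b.normalization_kind:
        raise TraceError("cannot compare traces with different normalizations")
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if len(common) == 0:
        raise TraceError("no common timepoints")
    return float(np.linalg.norm(a.values[ia] - b.values[ib]))


MARKER_RULES = {
    "Ly6C": lambda mean, sd: mean + 5.0 * sd,
    "CD115": lambda mean, sd: 3.0 * mean,
}


def marker_status(
    trace: Trace, marker: str, sd_ddof: int = 1
) -> tuple[str, float]:
    """Positive/negative surface-marker call from a baseline threshold.

    The trace is the baseline-normalised whole-cell marker intensity.
    Thresholds: Ly6C = pre-stim mean + 5 sd; CD115 = 3 x pre-stim mean.
    The s.d. defaults to the sample convention (ddof=1, as in R's ``sd``,
    the environment these calls were originally made in); ``sd_ddof=0``
    selects the population convention.  The cell is positive iff any
    post-stimulation value exceeds the threshold; the threshold is returned
    for audit.
    """
    if marker not in MARKER_RULES:
        raise ValueError(f"unknown marker {marker!r}")
    pre = trace.values[trace.pre_mask]
    if len(pre) < 2:
        raise TraceError("need >= 2 pre-stimulation points")
    thr = MARKER_RULES[marker](float(pre.mean()), float(pre.std(ddof=sd_ddof)))
    post = trace.values[trace.post_mask]
    status = "positive" if len(post) and post.max() > thr else "negative"
    return status, thr


# ---------------------------------------------------------------------------
# Long-format CSV interchange
# ---------------------------------------------------------------------------

def traces_from_frame(df: pd.DataFrame) -> dict[str, list[Trace]]:
    """Build per-experiment trace lists from a long-format frame.

    Columns: cell_id, time_min, value, missing, stim_time, experiment_id.
    """
    out: dict[str, list[Trace]] = {}
    for (exp, cell), grp in df.groupby(["experiment_id", "cell_id"], sort=True):
        grp = grp.sort_values("time_min")
        tr = Trace(
            times=grp["time_min"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            missing=grp["missing"].to_numpy(dtype=bool)
            if "missing" in grp
            else None,
            stim_time=float(grp["stim_time"].iloc[0]),
            cell_id=str(cell),
        )
        out.setdefault(str(exp), []).append(tr)
    return out


def read_traces_csv(path) -> dict[str, list[Trace]]:
    return traces_from_frame(pd.read_csv(path))


def traces_to_frame(traces: dict[str, list[Trace]]) -> pd.DataFrame:
    rows = []
    for exp, trs in traces.items():
        for tr in trs:
            for t, v, m in zip(tr.times, tr.values, tr.missing):
                rows.append(
                    {
                        "experiment_id": exp, "cell_id": tr.cell_id,
                        "time_min": t, "value": v, "missing": bool(m),
                        "stim_time": tr.stim_time,
                    }
                )
    return pd.DataFrame(rows)
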