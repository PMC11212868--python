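"""Sarcomere-nuclear strain coupling analysis.

Turns per-cell length time series into strains relative to the diastolic
baseline, delimits pacing cycles into contraction (systolic) and
re-lengthening (diastolic) limbs, builds the cycle-averaged strain coupling
map (nuclear-length strain versus sarcomere strain), and quantifies:

* systolic dampening  — area between the contraction limb and the lossless
  identity line ``eps_n = eps_s`` (percent-squared units);
* diastolic dampening — area between the re-lengthening limb and a
  unit-slope reference line anchored at the end-systolic point (hysteresis);
* integrated nuclear strain — time integral of |nuclear strain| over one
  pacing period (percent-seconds), a cumulative nuclear load metric.

Compressive strain is negative internally; peak metrics are reported as
positive magnitudes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._baseline import baseline_window
from .errors import InsufficientDataError, NoContractionDetected
from .traces import ContractionTrace

DEFAULT_ONSET_THRESHOLD = 0.5   # percent strain
PATH_GRID_POINTS = 200          # resampling grid per limb for cycle averaging


@dataclass
class StrainTrace:
    """Strain (percent) versions of a contraction trace."""

    time: np.ndarray
    sarcomere_strain: np.ndarray
    nuclear_length_strain: np.ndarray
    nuclear_width_strain: np.ndarray
    baselines: dict          # {"SL0", "NL0", "NW0"} in um
    pacing_frequency: float
    cell_id: str = ""
    genotype_label: str = ""


@dataclass
class CyclePhases:
    """Per-cycle sample indices: onset, peak systole, relaxation end."""

    onset: np.ndarray
    peak: np.ndarray
    end: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.onset)


@dataclass
class CouplingPath:
    """Cycle-averaged (eps_s, eps_n) path: contraction then relaxation limb.

    ``peak_index`` marks the end-systolic sample shared by both limbs.
    """

    eps_s: np.ndarray
    eps_n: np.ndarray
    peak_index: int

    def contraction_limb(self):
        return self.eps_s[: self.peak_index + 1], self.eps_n[: self.peak_index + 1]

    def relaxation_limb(self):
        return self.eps_s[self.peak_index:], self.eps_n[self.peak_index:]


@dataclass
class CouplingResult:
    """Per-cell coupling metrics (peaks as positive magnitudes)."""

    cell_id: str
    genotype_label: str
    peak_sarcomere_compression: float   # %
    peak_nuclear_compression: float     # %
    peak_width_expansion: float         # %
    systolic_dampening: float           # %^2
    diastolic_dampening: float          # %^2
    integrated_nuclear_strain: float    # % * s
    path: CouplingPath | None = None


def compute_strain(trace: ContractionTrace, baseline_rule: str = "pre_onset_mean",
                   onset_threshold: float = DEFAULT_ONSET_THRESHOLD) -> StrainTrace:
    """Strains in percent relative to the diastolic baseline.

    ``baseline_rule`` is either ``first_sample`` or ``pre_onset_mean`` (mean
    of the 5 samples preceding contraction onset; falls back to the first
    sample when the onset is in the first 5 frames or no onset is found).
    """
    if baseline_rule not in ("first_sample", "pre_onset_mean"):
        raise ValueError(f"unknown baseline_rule {baseline_rule!r}")

    # provisional strain against the series median: the median of a mostly
    # diastolic trace sits at the baseline and is robust to frame noise
    ref = float(np.median(trace.sarcomere_length))
    prov = 100.0 * (trace.sarcomere_length - ref) / ref
    dt = float(trace.time[1] - trace.time[0])
    window = baseline_window(prov, onset_threshold, dt=dt)

    def baseline(series):
        if baseline_rule == "first_sample":
            return series[0]
        return float(np.mean(series[window]))

    out = {}
    for key, series in (("sarcomere", trace.sarcomere_length),
                        ("nuclear_length", trace.nuclear_length),
                        ("nuclear_width", trace.nuclear_width)):
        b = baseline(series)
        if b <= 0:
            raise ValueError(f"non-positive {key} baseline")
        out[key] = (100.0 * (series - b) / b, b)

    return StrainTrace(
        time=trace.time,
        sarcomere_strain=out["sarcomere"][0],
        nuclear_length_strain=out["nuclear_length"][0],
        nuclear_width_strain=out["nuclear_width"][0],
        baselines={"SL0": out["sarcomere"][1], "NL0": out["nuclear_length"][1],
                   "NW0": out["nuclear_width"][1]},
        pacing_frequency=trace.pacing_frequency,
        cell_id=trace.cell_id,
        genotype_label=trace.genotype_label,
    )


def segment_cycles(strain: StrainTrace, pacing_frequency: float | None = None,
                   onset_threshold: float = DEFAULT_ONSET_THRESHOLD) -> CyclePhases:
    """Delimit each pacing period into onset / peak-systole / relaxation-end.

    Onset is the first crossing of |eps_s| above the threshold inside the
    period, the peak is the extremum of eps_s within the period, and the
    relaxation end is the first return of |eps_s| below the threshold after
    the peak (or the period end).
    """
    f = pacing_frequency or strain.pacing_frequency
    T = 1.0 / f
    t = strain.time
    eps = strain.sarcomere_strain
    dt = t[1] - t[0]
    n_cycles = max(1, int(np.floor((t[-1] - t[0] + dt) / T + 1e-9)))
    onsets, peaks, ends = [], [], []
    for k in range(n_cycles):
        lo = np.searchsorted(t, t[0] + k * T)
        hi = np.searchsorted(t, t[0] + (k + 1) * T)
        if hi - lo < 3:
            continue
        window = np.abs(eps[lo:hi])
        above = np.flatnonzero(window > onset_threshold)
        if len(above) == 0:
            continue
        onset = lo + above[0]
        peak = lo + int(np.argmax(window))
        below_after = np.flatnonzero(window[peak - lo:] < onset_threshold)
        end = peak + below_after[0] if len(below_after) else hi - 1
        if not onset < peak:
            continue
        onsets.append(onset)
        peaks.append(peak)
        ends.append(min(end, hi - 1))
    if not onsets:
        raise NoContractionDetected(
            f"no |sarcomere strain| crossing above {onset_threshold}%")
    return CyclePhases(np.array(onsets), np.array(peaks), np.array(ends))


def _resample_limb(eps_s, eps_n, grid):
    """Interpolate eps_n onto a monotone eps_s grid along one limb."""
    order = np.argsort(eps_s, kind="stable")
    xs, yn = eps_s[order], eps_n[order]
    # collapse duplicate abscissae from noise
    xs, idx = np.unique(xs, return_index=True)
    return np.interp(grid, xs, yn[idx])


def coupling_path(strain: StrainTrace, phases: CyclePhases,
                  n_grid: int = PATH_GRID_POINTS) -> CouplingPath:
    """Cycle-averaged closed coupling path from onset to relaxation end.

    Each cycle's contraction and relaxation limbs are resampled onto a
    uniform sarcomere-strain grid before averaging, so the path depends only
    on the traversed geometry, not the time parameterization.
    """
    s, n = strain.sarcomere_strain, strain.nuclear_length_strain
    # extend limbs a few frames past the threshold crossings so the path
    # starts and ends at the quiescent strain level regardless of the
    # sampling rate (the crossing itself sits ~one frame into the rise)
    dt = float(strain.time[1] - strain.time[0])
    ext = max(2, int(round(0.044 / dt)))
    onsets = np.maximum(phases.onset - ext, 0)
    ends = np.minimum(phases.end + ext, len(s) - 1)
    start = float(np.mean([s[i] for i in onsets]))
    peak = float(np.mean([s[i] for i in phases.peak]))
    end = float(np.mean([s[i] for i in ends]))
    grid_con = np.linspace(start, peak, n_grid)
    grid_rel = np.linspace(peak, end, n_grid)

    con_acc = np.zeros(n_grid)
    rel_acc = np.zeros(n_grid)
    for o, p, e in zip(onsets, phases.peak, ends):
        if p - o < 1 or e - p < 1:
            raise InsufficientDataError("cycle limb shorter than 2 samples")
        con_acc += _resample_limb(s[o:p + 1], n[o:p + 1], grid_con)
        rel_acc += _resample_limb(s[p:e + 1], n[p:e + 1], grid_rel)
    con_acc /= phases.n_cycles
    rel_acc /= phases.n_cycles

    eps_s = np.concatenate([grid_con, grid_rel[1:]])
    eps_n = np.concatenate([con_acc, rel_acc[1:]])
    return CouplingPath(eps_s=eps_s, eps_n=eps_n, peak_index=n_grid - 1)


def systolic_dampening(path: CouplingPath) -> float:
    """|integral of (eps_n - eps_s) d eps_s| over the contraction limb (%^2).

    Zero iff the coupling is lossless (path on the identity line).
    """
    xs, yn = path.contraction_limb()
    if len(xs) < 3:
        raise InsufficientDataError("contraction limb shorter than 3 samples")
    return float(abs(np.trapezoid(yn - xs, xs)))


def diastolic_dampening(path: CouplingPath, reference: str = "shifted") -> float:
    """Hysteresis area of the re-lengthening limb (%^2).

    ``shifted`` (default): unit-slope line through the end-systolic point
    ``(eps_s*, eps_n*)``, i.e. ``ref(eps_s) = eps_s + (eps_n* - eps_s*)``.
    ``chord``: line through the origin and the end-systolic point.
    """
    xs, yn = path.relaxation_limb()
    if len(xs) < 3:
        raise InsufficientDataError("relaxation limb shorter than 3 samples")
    s_star, n_star = xs[0], yn[0]
    if reference == "shifted":
        ref = xs + (n_star - s_star)
    elif reference == "chord":
        if s_star == 0:
            raise InsufficientDataError("degenerate end-systolic point for chord reference")
        ref = (n_star / s_star) * xs
    else:
        raise ValueError(f"unknown diastolic reference {reference!r}")
    return float(abs(np.trapezoid(yn - ref, xs)))


def integrated_nuclear_strain(strain: StrainTrace, phases: CyclePhases) -> float:
    """Time integral of |nuclear-length strain| over one pacing period (%*s).

    Averaged across the available complete cycles.
    """
    T = 1.0 / strain.pacing_frequency
    t = strain.time
    eps = np.abs(strain.nuclear_length_strain)
    totals = []
    for k in range(phases.n_cycles):
        lo = np.searchsorted(t, t[0] + k * T)
        hi = min(np.searchsorted(t, t[0] + (k + 1) * T), len(t)) - 1
        if hi - lo < 2:
            continue
        total = np.trapezoid(eps[lo:hi + 1], t[lo:hi + 1])
        # close the period: the last sampled frame sits dt short of the
        # cycle end, so extend with the final value to the full period
        tail = (t[lo] + T) - t[hi]
        if tail > 0:
            total += eps[hi] * tail
        totals.append(total)
    return float(np.mean(totals)) if totals else 0.0


def analyze_trace(trace: ContractionTrace, baseline_rule: str = "pre_onset_mean",
                  onset_threshold: float = DEFAULT_ONSET_THRESHOLD,
                  diastolic_reference: str = "shifted") -> CouplingResult:
    """Full per-cell coupling analysis: strains, phases, path, metrics."""
    strain = compute_strain(trace, baseline_rule, onset_threshold)
    phases = segment_cycles(strain, onset_threshold=onset_threshold)
    path = coupling_path(strain, phases)
    return CouplingResult(
        cell_id=trace.cell_id,
        genotype_label=trace.genotype_label,
        peak_sarcomere_compression=float(np.max(np.abs(strain.sarcomere_strain))),
        peak_nuclear_compression=float(np.max(np.abs(
            np.minimum(strain.nuclear_length_strain, 0.0)))),
        peak_width_expansion=float(np.max(np.maximum(
            strain.nuclear_width_strain, 0.0))),
        systolic_dampening=systolic_dampening(path),
        diastolic_dampening=diastolic_dampening(path, diastolic_reference),
        integrated_nuclear_strain=integrated_nuclear_strain(strain, phases),
        path=path,
    )


METRIC_COLUMNS = ("peak_sarcomere_compression", "peak_nuclear_compression",
                  "peak_width_expansion", "systolic_dampening",
                  "diastolic_dampening", "integrated_nuclear_strain")


def results_frame(results) -> pd.DataFrame:
    rows = [{"cell_id": r.cell_id, "genotype": r.genotype_label,
             **{m: getattr(r, m) for m in METRIC_COLUMNS}} for r in results]
    return pd.DataFrame(rows)


def summarize_group(results, grouping=None) -> pd.DataFrame:
    """Mean +- SE and n per metric per group (no inferential tests)."""
    df = results_frame(results)
    if grouping is not None:
        df = df.assign(genotype=list(grouping))
    counts = df.groupby("genotype").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups need >= 2 cells: {bad}")
    agg = df.groupby("genotype")[list(METRIC_COLUMNS)].agg(["mean", "sem", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
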