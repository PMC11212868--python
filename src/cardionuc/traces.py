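"""Synthetic contraction traces for paced cardiomyocytes.

Generates per-cell time series of sarcomere length, nuclear length and
nuclear width during steady-state electrical pacing (default 1 Hz sampled at
90 frames/s).  The sarcomere strain waveform is a raised-cosine shortening
followed by an exponential re-lengthening; the nuclear response is a
first-order linear lag of the sarcomere strain with gain ``nuclear_gain``
and time constant ``nuclear_time_constant``, which reproduces both the
dampened amplitude and the diastolic hysteresis seen in strain-coupling
maps.  Nuclear width moves opposite to nuclear length through a negative
``width_gain``.

The generator is run at periodic steady state, so noiseless traces are
exactly periodic across cycles, and the nuclear gain is calibrated
internally so the realized peak nuclear strain matches a preset target.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import rng_from
from .errors import CalibrationError

GENOTYPE_LABELS = (
    "WT_rat", "AdV_empty", "AdV_DNKASH", "DMSO", "colch",
    "WT_mouse", "csDNKASH", "N195K", "N195K_csDNKASH",
)

GAIN_CEILING = 1.5
#: nuclear-gain calibration tolerance, percentage points of strain
CALIBRATION_TOL = 5e-3


@dataclass
class TraceParams:
    """Parameters of the paced-contraction trace generator.

    Lengths are in micrometres, times in seconds, strains in percent
    (negative = compression along the contractile axis).
    """

    pacing_frequency: float = 1.0          # Hz
    sampling_rate: float = 90.0            # frames / s
    n_cycles: int = 3
    baseline_sarcomere_length: float = 1.80
    baseline_nuclear_length: float = 12.4
    baseline_nuclear_width: float = 5.6
    peak_sarcomere_strain: float = -11.4   # % at peak systole
    contraction_time_constant: float = 1.0 / 6.0  # raised-cosine rise time, s
    relaxation_time_constant: float = 0.20  # exponential re-lengthening, s
    nuclear_gain: float = 0.8              # dimensionless, 0..1.5
    nuclear_time_constant: float = 0.12    # s, first-order lag
    width_gain: float = -0.35              # width strain per length strain
    noise_sd: float = 0.0                  # um, additive on every series
    genotype_label: str = "WT_rat"
    seed: int = 0
    onset_time: float = 0.10               # s after cycle start
    #: if set, calibrate nuclear_gain so the realized peak nuclear-length
    #: strain equals this magnitude target (percent, negative).
    target_peak_nuclear_strain: float | None = None

    def validate(self) -> None:
        period = 1.0 / self.pacing_frequency
        if not period > self.contraction_time_constant + self.relaxation_time_constant:
            raise ValueError("pacing period must exceed contraction + relaxation time constants")
        if self.sampling_rate < 2 * self.pacing_frequency:
            raise ValueError("sampling_rate must be at least twice the pacing frequency")
        for name in ("baseline_sarcomere_length", "baseline_nuclear_length",
                     "baseline_nuclear_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.genotype_label not in GENOTYPE_LABELS:
            raise ValueError(f"unknown genotype_label {self.genotype_label!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 <= self.nuclear_gain <= GAIN_CEILING:
            raise ValueError("nuclear_gain outside [0, 1.5]")


@dataclass
class ContractionTrace:
    """One cell's time series of sarcomere and nuclear dimensions (um)."""

    time: np.ndarray
    sarcomere_length: np.ndarray
    nuclear_length: np.ndarray
    nuclear_width: np.ndarray
    cell_id: str
    genotype_label: str
    pacing_frequency: float
    params: TraceParams | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.time)
        for name in ("sarcomere_length", "nuclear_length", "nuclear_width"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")
        if np.any(self.sarcomere_length <= 0) or np.any(self.nuclear_length <= 0) \
                or np.any(self.nuclear_width <= 0):
            raise ValueError("lengths must be positive")


def sarcomere_strain_waveform(t_phase: np.ndarray, params: TraceParams) -> np.ndarray:
    """Sarcomere strain (percent, <= 0) as a function of phase time in [0, T).

    Raised-cosine shortening of duration ``contraction_time_constant``
    starting at ``onset_time``, then an exponential re-lengthening shifted to
    return exactly to zero at the end of the cycle (so noiseless traces are
    periodic without a step at cycle boundaries).
    """
    T = 1.0 / params.pacing_frequency
    t_on = params.onset_time
    Tc = params.contraction_time_constant
    tau_r = params.relaxation_time_constant
    t = np.asarray(t_phase, dtype=float)
    shape = np.zeros_like(t)

    rise = (t >= t_on) & (t < t_on + Tc)
    shape[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t_on) / Tc))

    decay = t >= t_on + Tc
    t_rem = T - t_on - Tc                      # time available for relaxation
    x = t[decay] - (t_on + Tc)
    e_end = np.exp(-t_rem / tau_r)
    shape[decay] = (np.exp(-x / tau_r) - e_end) / (1.0 - e_end)
    return params.peak_sarcomere_strain * shape


def waveform_events(params: TraceParams) -> dict:
    """Analytic event times of one cycle: onset, peak systole, cycle period."""
    return {
        "t_onset": params.onset_time,
        "t_peak": params.onset_time + params.contraction_time_constant,
        "period": 1.0 / params.pacing_frequency,
    }


def _lag_response_period(params: TraceParams, gain: float, n_fine: int = 20000):
    """Periodic steady-state nuclear strain over one cycle on a fine grid.

    Exact exponential-integrator recursion for piecewise-constant input; the
    periodic initial condition is obtained in closed form from the linearity
    of the lag (one pass gives the affine cycle map a -> A + k a).
    """
    T = 1.0 / params.pacing_frequency
    tau = params.nuclear_time_constant
    t_fine = np.linspace(0.0, T, n_fine + 1)
    s = sarcomere_strain_waveform(t_fine % T, params)
    if tau <= 1e-6:
        return t_fine, gain * s
    dt = T / n_fine
    decay = np.exp(-dt / tau)
    # midpoint input over each substep (trapezoid-equivalent for smooth input)
    drive = gain * 0.5 * (s[:-1] + s[1:]) * (1.0 - decay)
    # one pass from a0 = 0 gives the inhomogeneous part A; map is a_T = A + k a0
    a = np.empty(n_fine + 1)
    a[0] = 0.0
    for i in range(n_fine):
        a[i + 1] = a[i] * decay + drive[i]
    k = decay ** n_fine
    a0_star = a[-1] / (1.0 - k)
    a += a0_star * decay ** np.arange(n_fine + 1)
    return t_fine, a


def _noiseless_series(params: TraceParams, gain: float):
    """Strain series (percent) at the sampling grid for all cycles."""
    T = 1.0 / params.pacing_frequency
    n_frames = int(round(params.n_cycles * T * params.sampling_rate))
    t = np.arange(n_frames) / params.sampling_rate
    phase = t % T
    eps_s = sarcomere_strain_waveform(phase, params)
    if params.nuclear_time_constant <= 1e-6:
        eps_n = gain * eps_s
    else:
        t_fine, a = _lag_response_period(params, gain)
        eps_n = np.interp(phase, t_fine, a)
    return t, eps_s, eps_n


def _realized_peak_nuclear_strain(params: TraceParams, gain: float) -> float:
    """Peak nuclear-length compression (percent, >0) measured exactly the
    way the strain pipeline measures it, by running the pipeline's own
    strain computation on a noiseless single-cycle trace."""
    from .coupling import compute_strain   # deferred: avoids an import cycle
    t, eps_s, eps_n = _noiseless_series(replace(params, n_cycles=1), gain)
    trace = ContractionTrace(
        time=t,
        sarcomere_length=params.baseline_sarcomere_length * (1.0 + eps_s / 100.0),
        nuclear_length=params.baseline_nuclear_length * (1.0 + eps_n / 100.0),
        nuclear_width=np.full_like(t, params.baseline_nuclear_width),
        cell_id="_calibration", genotype_label=params.genotype_label,
        pacing_frequency=params.pacing_frequency)
    strain = compute_strain(trace)
    return float(np.max(np.abs(np.minimum(strain.nuclear_length_strain, 0.0))))


def calibrate_gain(params: TraceParams) -> float:
    """Calibrate nuclear_gain so the realized peak nuclear strain hits the
    preset target.  Raises CalibrationError if the target needs gain > 1.5."""
    target = abs(params.target_peak_nuclear_strain)
    if target == 0.0:
        return 0.0
    gain = min(max(params.nuclear_gain, 0.1), GAIN_CEILING)
    for _ in range(6):
        realized = _realized_peak_nuclear_strain(params, gain)
        if realized == 0.0:
            raise CalibrationError("waveform produces no nuclear strain to calibrate")
        gain *= target / realized
        if gain > GAIN_CEILING * (1 + 1e-9):
            raise CalibrationError(
                f"target nuclear strain {target}% needs gain {gain:.3f} "
                f"> ceiling {GAIN_CEILING}")
        if abs(realized - target) <= CALIBRATION_TOL / 10:
            break
    realized = _realized_peak_nuclear_strain(params, gain)
    if abs(realized - target) > CALIBRATION_TOL:
        raise CalibrationError(
            f"gain calibration did not converge: realized {realized:.4f}% "
            f"vs target {target:.4f}%")
    return float(gain)


def resolved_gain(params: TraceParams) -> float:
    """Nuclear gain actually used: calibrated when a target is set."""
    if params.target_peak_nuclear_strain is not None:
        return calibrate_gain(params)
    return params.nuclear_gain


def generate_traces(params: TraceParams, n_cells: int = 1) -> list[ContractionTrace]:
    """Generate ``n_cells`` paced-contraction traces with independent noise.

    With ``noise_sd == 0`` and an identical seed the output is
    bit-reproducible.  Each cell derives its own RNG stream from
    ``params.seed`` so cohorts are order-independent.
    """
    params.validate()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    gain = resolved_gain(params)
    t, eps_s, eps_n = _noiseless_series(params, gain)
    eps_w = params.width_gain * eps_n

    sl0 = params.baseline_sarcomere_length
    nl0 = params.baseline_nuclear_length
    nw0 = params.baseline_nuclear_width
    sl = sl0 * (1.0 + eps_s / 100.0)
    nl = nl0 * (1.0 + eps_n / 100.0)
    nw = nw0 * (1.0 + eps_w / 100.0)

    traces = []
    for i in range(n_cells):
        rng = rng_from(params.seed, "trace", i)
        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=(3, len(t)))
        else:
            noise = np.zeros((3, len(t)))
        traces.append(ContractionTrace(
            time=t.copy(),
            sarcomere_length=sl + noise[0],
            nuclear_length=nl + noise[1],
            nuclear_width=nw + noise[2],
            cell_id=f"{params.genotype_label}_{i:03d}",
            genotype_label=params.genotype_label,
            pacing_frequency=params.pacing_frequency,
            params=params,
        ))
    return traces
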