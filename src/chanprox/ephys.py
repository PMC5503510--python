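"""Voltage-clamp activation analysis and single-channel NPo.

Covers the standard whole-cell workflow for voltage-gated channels:

* Nernst reversal potentials from ionic concentrations,
* conductance from current, ``G(V) = I / (V - E_rev)``,
* single-Boltzmann fits to G-V curves,
  ``G/Gmax = 1 / (1 + exp(-(V - Vmid)/slope))``,
* the "activation threshold", defined as the voltage at which the fitted
  Boltzmann reaches a small fraction (default 5%) of maximal conductance,
* blocker-subtraction trace arithmetic,
* single-exponential activation kinetics,
* NPo (number of channels x open probability) from idealized
  single-channel records.

Units: voltages in mV, currents in pA, conductances in nS, time in ms,
temperatures in K, concentrations in mol/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

GAS_CONSTANT = 8.31446261815324       # J / (mol K)
FARADAY = 96485.33212                 # C / mol


class FitError(RuntimeError):
    """Raised when a curve fit fails or lands on an invalid optimum."""


@dataclass
class IVSeries:
    """A voltage-clamp current-voltage series.

    ``currents_pA`` holds peak inward currents for calcium channels or
    steady-state outward currents for potassium channels.
    """

    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    capacitance_pF: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        if self.voltages_mV.shape != self.currents_pA.shape:
            raise ValueError("voltages and currents must have equal length")
        if np.any(np.diff(self.voltages_mV) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class GVPoints:
    """Conductance-voltage points derived from an I-V series."""

    voltages_mV: np.ndarray
    conductance_nS: np.ndarray
    excluded_voltages_mV: list = field(default_factory=list)


@dataclass
class BoltzmannFit:
    """Fitted single-Boltzmann activation parameters."""

    vmid_mV: float
    slope_mV: float
    gmax: float
    residual_sum: float
    cov: np.ndarray | None = None

    def __post_init__(self):
        if self.slope_mV <= 0:
            raise FitError(f"activation slope must be > 0, got {self.slope_mV}")
        if self.gmax <= 0:
            raise FitError(f"gmax must be > 0, got {self.gmax}")

    def __call__(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        return self.gmax / (1.0 + np.exp(-(v - self.vmid_mV) / self.slope_mV))


@dataclass
class ExponentialFit:
    """Mono-exponential activation fit: ``baseline + A*(1 - exp(-(t-t0)/tau))``."""

    tau_ms: float
    amplitude: float
    baseline: float
    t0_ms: float

    def __post_init__(self):
        if self.tau_ms <= 0:
            raise FitError(f"tau must be > 0, got {self.tau_ms}")

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return self.baseline + self.amplitude * (1.0 - np.exp(-(t - self.t0_ms) / self.tau_ms))


@dataclass
class SingleChannelTrace:
    """Current samples at a fixed sampling interval, with optional idealization.

    ``idealization`` gives the number of simultaneously open channels per
    sample (non-negative integers, same length as the trace).
    """

    samples_pA: np.ndarray
    dt_ms: float = 0.1
    holding_mV: float | None = None
    step_mV: float | None = None
    idealization: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if self.idealization is not None:
            self.idealization = np.asarray(self.idealization)
            if self.idealization.shape != self.samples_pA.shape:
                raise ValueError("idealization must match trace length")
            if np.any(self.idealization < 0):
                raise ValueError("idealization level counts must be >= 0")

    @property
    def duration_ms(self) -> float:
        return len(self.samples_pA) * self.dt_ms


def nernst_potential(
    z: int, c_out: float, c_in: float, temperature_K: float = 295.15
) -> float:
    """Equilibrium (reversal) potential from the Nernst equation, in mV.

    ``E = (R*T / (z*F)) * ln(c_out / c_in)``.  Concentrations may be in
    any common unit as only their ratio matters.  The default temperature
    is 295.15 K (22 degC, room-temperature recording).
    """
    if z == 0:
        raise ValueError("valence z must be nonzero")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be > 0")
    return 1000.0 * GAS_CONSTANT * temperature_K / (z * FARADAY) * np.log(c_out / c_in)


def conductance_from_iv(series: IVSeries, erev_mV: float) -> GVPoints:
    """Convert currents to chord conductances, ``G = I / (V - E_rev)``.

    With I in pA and V in mV the result is in nS.  Test potentials equal
    to the reversal potential are excluded (the quotient is undefined)
    and recorded in ``excluded_voltages_mV``.
    """
    v = series.voltages_mV
    i = series.currents_pA
    at_rev = np.isclose(v, erev_mV)
    excluded = list(v[at_rev])
    if excluded:
        warnings.warn(
            f"dropping {len(excluded)} point(s) at the reversal potential "
            f"{erev_mV} mV", stacklevel=2,
        )
    v = v[~at_rev]
    i = i[~at_rev]
    return GVPoints(v, i / (v - erev_mV), excluded)


def _boltzmann(v, gmax, vmid, slope):
    return gmax / (1.0 + np.exp(-(v - vmid) / slope))


def fit_boltzmann(gv, conductance=None) -> BoltzmannFit:
    """Least-squares single-Boltzmann fit to G-V points.

    ``gv`` may be a :class:`GVPoints` or a voltage array (with the
    conductances passed separately).  Initialization: ``vmid`` at the
    voltage nearest half-max, ``slope`` from the 25-75% voltage span.
    """
    if isinstance(gv, GVPoints):
        v, g = gv.voltages_mV, gv.conductance_nS
    else:
        v = np.asarray(gv, dtype=float)
        g = np.asarray(conductance, dtype=float)
    if len(v) < 4:
        raise FitError("need at least 4 G-V points spanning the transition")
    gmax0 = float(g.max())
    if gmax0 <= 0:
        raise FitError("all conductances are <= 0")
    order = np.argsort(v)
    vs, gs = v[order], g[order]
    vmid0 = float(vs[np.argmin(np.abs(gs - gmax0 / 2))])

    def _crossing(level):
        idx = np.nonzero(gs >= level * gmax0)[0]
        if idx.size == 0 or idx[0] == 0:
            return None
        i = idx[0]
        return float(np.interp(level * gmax0, [gs[i - 1], gs[i]], [vs[i - 1], vs[i]]))

    v25, v75 = _crossing(0.25), _crossing(0.75)
    if v25 is not None and v75 is not None and v75 > v25:
        slope0 = (v75 - v25) / (2.0 * np.log(3.0))
    else:
        slope0 = max(np.ptp(vs) / 10.0, 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _boltzmann, v, g, p0=[gmax0, vmid0, slope0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    gmax, vmid, slope = (float(x) for x in popt)
    resid = float(np.sum((g - _boltzmann(v, *popt)) ** 2))
    if slope <= 0:
        raise FitError(
            f"fit converged to non-positive slope {slope:.3g} mV "
            f"(vmid={vmid:.3g}, gmax={gmax:.3g}, residual={resid:.3g})"
        )
    return BoltzmannFit(vmid_mV=vmid, slope_mV=slope, gmax=gmax,
                        residual_sum=resid, cov=pcov)


def activation_threshold(fit, level: float = 0.05) -> float:
    """Voltage at which the fitted Boltzmann reaches ``level`` of Gmax.

    Closed form: ``V = Vmid + slope * ln(level / (1 - level))``.  At
    ``level=0.5`` this is exactly ``Vmid``.  ``fit`` may be a
    :class:`BoltzmannFit` or a ``(vmid_mV, slope_mV)`` pair.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if isinstance(fit, BoltzmannFit):
        vmid, slope = fit.vmid_mV, fit.slope_mV
    else:
        vmid, slope = fit
    return float(vmid + slope * np.log(level / (1.0 - level)))


def subtract_traces(before, after) -> np.ndarray:
    """Pointwise blocker subtraction: ``before - after``."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError(f"trace length mismatch: {b.shape} vs {a.shape}")
    return b - a


def fit_activation_tau(
    time_ms,
    current,
    window: tuple[float, float] | None = None,
    t0_ms: float | None = None,
) -> ExponentialFit:
    """Fit a rising mono-exponential to an activation time course.

    Model: ``I(t) = baseline + A * (1 - exp(-(t - t0)/tau))``.  ``window``
    restricts the fit to ``t in [w0, w1]``; ``t0`` defaults to the window
    start and is held fixed (it marks the step onset).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current, dtype=float)
    if t.shape != i.shape:
        raise ValueError("time and current must have equal length")
    if window is not None:
        w0, w1 = window
        if w0 < t[0] - 1e-12 or w1 > t[-1] + 1e-12:
            raise ValueError("fit window extends outside the trace")
        sel = (t >= w0) & (t <= w1)
        t, i = t[sel], i[sel]
    if len(t) < 4:
        raise FitError("too few samples in the fit window")
    t0 = float(t[0]) if t0_ms is None else float(t0_ms)

    def model(tt, amp, tau, baseline):
        return baseline + amp * (1.0 - np.exp(-(tt - t0) / tau))

    amp0 = float(i[-1] - i[0])
    tau0 = max((t[-1] - t0) / 5.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            model, t, i, p0=[amp0 if amp0 != 0 else 1.0, tau0, float(i[0])],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    amp, tau, baseline = (float(x) for x in popt)
    if tau <= 0:
        raise FitError(f"fit converged to non-positive tau {tau:.3g} ms")
    return ExponentialFit(tau_ms=tau, amplitude=amp, baseline=baseline, t0_ms=t0)


@dataclass
class NPoResult:
    """Idealization summary: NPo and per-level time fractions."""

    npo: float
    idealization: np.ndarray
    level_time_fractions: np.ndarray   # index k = fraction of time at level k


def idealize_trace(
    trace: SingleChannelTrace, unitary_pA: float, baseline_pA: float = 0.0
) -> np.ndarray:
    """Half-amplitude multi-level idealization.

    A sample is assigned level k (k open channels) when it lies in
    ``[(k - 1/2)*u, (k + 1/2)*u)`` above baseline; levels below zero are
    clipped to zero.
    """
    if unitary_pA <= 0:
        raise ValueError("unitary_pA must be > 0")
    lv = np.floor((trace.samples_pA - baseline_pA) / unitary_pA + 0.5).astype(np.int64)
    return np.clip(lv, 0, None)


def compute_npo(
    trace: SingleChannelTrace,
    unitary_pA: float,
    baseline_pA: float = 0.0,
    noise_sd_pA: float | None = None,
    strict: bool = True,
) -> NPoResult:
    """NPo = sum_k k * t_k / T from a half-amplitude idealization.

    NPo is invariant to the baseline offset and to a joint rescaling of
    the trace and the unitary amplitude.  When ``noise_sd_pA`` is given
    and the unitary amplitude is smaller than twice the noise, levels are
    not separable: a warning is issued and, with ``strict=True``, an
    error is raised.
    """
    if noise_sd_pA is not None and unitary_pA < 2.0 * noise_sd_pA:
        msg = (f"unitary amplitude {unitary_pA:g} pA < 2x noise sd "
               f"{noise_sd_pA:g} pA: idealization unreliable")
        warnings.warn(msg, stacklevel=2)
        if strict:
            raise ValueError(msg)
    lv = idealize_trace(trace, unitary_pA, baseline_pA)
    n = len(lv)
    if n == 0:
        raise ValueError("empty trace")
    fractions = np.bincount(lv) / n
    npo = float(np.sum(np.arange(len(fractions)) * fractions))
    return NPoResult(npo=npo, idealization=lv, level_time_fractions=fractions)
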