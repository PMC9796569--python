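"""Response-shape statistics of dim-flash photocurrents.

The standard descriptors of a dim flash response ``r(t)``:

* ``r_peak`` -- maximal suppression (pA), ``t_p`` its time (ms);
* integration time ``T_i`` -- integral of the response divided by its peak;
* recovery time constant ``tau_rec`` -- from ``A*exp(-t/tau)`` fitted to the
  falling phase between the first crossings of 80% and 20% of the peak;
* rising slope -- ordinary least squares over the rising phase between 20%
  and 60% of the peak, usable when Pearson ``r^2 > 0.8``;
* ``i_half`` -- flash strength of half-maximal response from the saturating
  exponential ``r/r_max = 1 - exp(-k i)``, ``i_half = ln 2 / k``;
* effective delay -- time to reach 5% of peak (convention).

Crossing times are located by linear interpolation between samples so the
metrics are grid-independent to discretization accuracy.  Traces are
baseline-corrected (pre-flash mean) before extraction when pre-flash
samples are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .trace import ResponseTrace


class MetricWindowError(ValueError):
    """The trace does not traverse the window a metric requires."""


@dataclass(frozen=True)
class ResponseMetrics:
    r_peak: float            # pA
    t_p: float               # ms
    T_i: float               # ms
    tau_rec: float | None    # ms
    rising_slope: float | None   # pA/ms
    rising_fit_r2: float | None
    rising_fit_usable: bool
    effective_delay: float | None  # ms, time to 5% of peak
    i_half: float | None = None    # photons/um^2 (from a separate fit)


def _prepare(trace: ResponseTrace) -> ResponseTrace:
    return trace.baseline_corrected().post_flash()


def _first_crossing(t, r, level, start=0, direction="up"):
    """Time of the first linear-interpolated crossing of ``level`` at or
    after sample ``start``; None if never crossed."""
    r = np.asarray(r)
    for i in range(start, len(r) - 1):
        a, b = r[i], r[i + 1]
        hit = (a < level <= b) if direction == "up" else (a > level >= b)
        if hit:
            w = (level - a) / (b - a)
            return t[i] + w * (t[i + 1] - t[i]), i
    if direction == "up" and r[start] >= level:
        return t[start], start
    if direction == "down" and len(r) and r[start] <= level:
        return t[start], start
    return None, None


def time_to_peak(trace: ResponseTrace) -> float:
    """Time (ms) of the global maximum; earliest sample on ties."""
    tr = _prepare(trace)
    if np.all(tr.r <= 0):
        raise MetricWindowError("trace has no positive response")
    return float(tr.t[int(np.argmax(tr.r))])


def peak_amplitude(trace: ResponseTrace) -> float:
    tr = _prepare(trace)
    return float(np.max(tr.r))


def integration_time(trace: ResponseTrace) -> float:
    """Trapezoidal integral of the response divided by its peak (ms)."""
    tr = _prepare(trace)
    peak = np.max(tr.r)
    if peak <= 0:
        raise MetricWindowError("zero peak; integration time undefined")
    return float(np.trapezoid(tr.r, tr.t) / peak)


def effective_delay(trace: ResponseTrace, level: float = 0.05) -> float | None:
    tr = _prepare(trace)
    peak = np.max(tr.r)
    if peak <= 0:
        return None
    t5, _ = _first_crossing(tr.t, tr.r, level * peak)
    return t5


def fit_recovery_tau(trace: ResponseTrace) -> tuple[float, float]:
    """Fit ``r = A exp(-t/tau)`` to the falling phase, 80% -> 20% of peak.

    The window runs from the first post-peak crossing of ``0.8 r_peak`` to
    the first subsequent crossing of ``0.2 r_peak``.  Returns ``(A, tau)``.
    """
    tr = _prepare(trace)
    peak = np.max(tr.r)
    if peak <= 0:
        raise MetricWindowError("zero peak")
    ipk = int(np.argmax(tr.r))
    t80, i80 = _first_crossing(tr.t, tr.r, 0.8 * peak, start=ipk, direction="down")
    if t80 is None:
        raise MetricWindowError("trace never recovers through 80% of peak")
    t20, i20 = _first_crossing(tr.t, tr.r, 0.2 * peak, start=i80, direction="down")
    if t20 is None:
        raise MetricWindowError("trace never recovers through 20% of peak (truncated)")
    sel = (tr.t >= t80) & (tr.t <= t20) & (tr.r > 0)
    t_w = np.concatenate([[t80], tr.t[sel], [t20]])
    r_w = np.concatenate([[0.8 * peak], tr.r[sel], [0.2 * peak]])
    # log-linear initialization, then nonlinear least squares
    coef = np.polyfit(t_w, np.log(r_w), 1)
    tau0 = -1.0 / coef[0] if coef[0] < 0 else (t20 - t80)
    A0 = float(np.exp(coef[1]))
    popt, _ = optimize.curve_fit(
        lambda t, A, tau: A * np.exp(-t / tau),
        t_w,
        r_w,
        p0=[A0, tau0],
        maxfev=10_000,
    )
    return float(popt[0]), float(popt[1])


def fit_rising_slope(trace: ResponseTrace) -> tuple[float, float, bool]:
    """OLS slope of the rising phase between 20% and 60% of peak.

    Returns ``(slope pA/ms, pearson r^2, usable)`` where ``usable`` is the
    ``r^2 > 0.8`` linearity gate.
    """
    tr = _prepare(trace)
    peak = np.max(tr.r)
    if peak <= 0:
        raise MetricWindowError("zero peak")
    t20, i20 = _first_crossing(tr.t, tr.r, 0.2 * peak)
    if t20 is None:
        raise MetricWindowError("rise never reaches 20% of peak")
    t60, i60 = _first_crossing(tr.t, tr.r, 0.6 * peak, start=i20)
    if t60 is None:
        raise MetricWindowError("rise never reaches 60% of peak")
    sel = (tr.t >= t20) & (tr.t <= t60)
    t_w = np.concatenate([[t20], tr.t[sel], [t60]])
    r_w = np.concatenate([[0.2 * peak], tr.r[sel], [0.6 * peak]])
    res = stats.linregress(t_w, r_w)
    r2 = float(res.rvalue**2)
    return float(res.slope), r2, r2 > 0.8


def fit_sensitivity(flash_strengths, amplitudes) -> tuple[float, float]:
    """Fit ``r/r_max = 1 - exp(-k i)`` to amplitude-vs-flash data.

    Returns ``(i_half, r_max)`` with ``i_half = ln 2 / k`` in the units of
    ``flash_strengths`` (photons/um^2).  Requires at least three flash
    strengths including a near-saturating one.
    """
    i = np.asarray(flash_strengths, dtype=float)
    r = np.asarray(amplitudes, dtype=float)
    if len(i) < 3:
        raise MetricWindowError("need at least three flash strengths")
    if np.max(r) <= 0:
        raise MetricWindowError("no positive amplitudes to fit")
    r_max0 = float(np.max(r))
    k0 = np.log(2.0) / np.median(i)
    popt, _ = optimize.curve_fit(
        lambda x, rm, k: rm * (1.0 - np.exp(-k * x)),
        i,
        r,
        p0=[r_max0, k0],
        maxfev=20_000,
    )
    r_max, k = popt
    if k <= 0:
        raise MetricWindowError("ill-conditioned sensitivity fit (k <= 0)")
    if np.max(r) < 0.75 * r_max:
        import warnings

        warnings.warn(
            "largest response is far from saturation; i_half is poorly "
            "constrained",
            RuntimeWarning,
        )
    return float(np.log(2.0) / k), float(r_max)


def percent_change(cond1_value: float, cond2_value: float) -> float:
    """``100 * cond1 / cond2`` (the per-cell percent-change convention)."""
    if cond2_value == 0:
        raise ZeroDivisionError("condition-2 value is zero")
    return 100.0 * cond1_value / cond2_value


def paired_percent_change(cond1_values, cond2_values) -> tuple[float, float]:
    """Per-cell percent changes averaged across cells: (mean, SEM)."""
    c1 = np.asarray(cond1_values, dtype=float)
    c2 = np.asarray(cond2_values, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("paired conditions must have equal length")
    pc = 100.0 * c1 / c2
    sem = float(np.std(pc, ddof=1) / np.sqrt(len(pc))) if len(pc) > 1 else 0.0
    return float(np.mean(pc)), sem


def compute_metrics(trace: ResponseTrace) -> ResponseMetrics:
    """All shape metrics of one trace (None where a window is unreachable)."""
    peak = peak_amplitude(trace)
    t_p = time_to_peak(trace)
    T_i = integration_time(trace)
    try:
        _, tau = fit_recovery_tau(trace)
    except (MetricWindowError, RuntimeError):
        tau = None
    try:
        slope, r2, usable = fit_rising_slope(trace)
    except MetricWindowError:
        slope, r2, usable = None, None, False
    return ResponseMetrics(
        r_peak=peak,
        t_p=t_p,
        T_i=T_i,
        tau_rec=tau,
        rising_slope=slope,
        rising_fit_r2=r2,
        rising_fit_usable=usable,
        effective_delay=effective_delay(trace),
    )


def metrics_table(traces: dict[str, ResponseTrace]):
    """One-row-per-trace tabular summary (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for label, tr in traces.items():
        m = compute_metrics(tr)
        rows.append({"label": label, **m.__dict__})
    return pd.DataFrame(rows)
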