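"""Synthetic dim-flash experiments with the structure the analysis assumes.

Emulates suction-electrode recording of dim-flash trials: per trial a
Poisson number of photoisomerizations, each scaling a single photon
response template with trial-to-trial amplitude spread; plus low-pass
filtered recording noise and optional baseline drift.  Slit optics restrict
where on the outer segment the photoisomerizations land (edge vs middle of
the disk; axial base vs tip), matching how position-resolved stimulation is
done experimentally.  Every generated quantity is logged in a ground-truth
ledger so downstream estimators can be validated end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cascade import PhotoisomerizationEvent
from .geometry import GeometryError, ROSGeometry
from .trace import ResponseTrace


class SlitError(ValueError):
    pass


@dataclass(frozen=True)
class SlitConfig:
    """Slit-shaped flash aperture projected onto the outer segment.

    ``orientation='parallel'`` runs along the ROS axis; ``position`` is then
    'edge' or 'middle' (resolved to radial offsets), and the slit band is
    centred halfway between base and tip.  ``orientation='perpendicular'``
    crosses the ROS at axial offset ``position`` (um from base).
    """

    orientation: str = "parallel"
    position: str | float = "middle"
    slit_length: float = 4.0   # um
    slit_width: float = 1.0    # um

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "perpendicular"):
            raise SlitError("orientation must be 'parallel' or 'perpendicular'")
        if self.orientation == "parallel" and self.position not in ("edge", "middle"):
            raise SlitError("parallel slit position must be 'edge' or 'middle'")
        if self.slit_length <= 0 or self.slit_width <= 0:
            raise SlitError("slit dimensions must be positive")


def sample_slit_positions(
    slit: SlitConfig,
    geom: ROSGeometry,
    n: int,
    seed: int | np.random.Generator,
) -> list[PhotoisomerizationEvent]:
    """Sample photoisomerization positions uniformly over the slit/ROS overlap.

    Edge slits restrict radial positions to within ``slit_width`` of the
    rim; middle slits produce random radial distances with the density of a
    uniform draw over the central chord band.  Proximity to an incisure is
    never controlled.  Perpendicular slits fix a narrow axial band and
    randomize ``(r, phi)`` over the full disk.
    """
    if slit.slit_width >= geom.diameter and slit.orientation == "parallel":
        raise SlitError("slit wider than the outer segment")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = geom.radius
    events = []
    if slit.orientation == "parallel":
        z_lo = 0.5 * geom.length - 0.5 * slit.slit_length
        z_hi = z_lo + slit.slit_length
        if slit.position == "edge":
            x_lo, x_hi = R - slit.slit_width, R
        else:
            x_lo, x_hi = -0.5 * slit.slit_width, 0.5 * slit.slit_width
        while len(events) < n:
            x = rng.uniform(x_lo, x_hi)
            y = rng.uniform(-R, R)
            if x * x + y * y > R * R:
                continue
            z = rng.uniform(z_lo, z_hi)
            events.append(
                PhotoisomerizationEvent(
                    disk_index=geom.disk_index_at(z),
                    radial_position=math.hypot(x, y),
                    angular_position=math.atan2(y, x) % (2 * math.pi),
                )
            )
    else:
        z0 = float(slit.position)
        if not 0.0 <= z0 <= geom.length:
            raise SlitError("perpendicular slit misses the outer segment")
        half = 0.5 * slit.slit_width
        z_lo, z_hi = max(0.0, z0 - half), min(geom.length, z0 + half)
        for _ in range(n):
            # uniform over the disk: area-weighted radius
            r = R * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2 * math.pi)
            z = rng.uniform(z_lo, z_hi)
            events.append(
                PhotoisomerizationEvent(
                    disk_index=geom.disk_index_at(z),
                    radial_position=r,
                    angular_position=phi,
                )
            )
    return events


def middle_slit_radial_density(r, R: float, width: float):
    """Analytic radial density of a uniform draw over the central chord band
    (slit of full chord length, half-width w/2): the arc of radius ``r``
    inside the band has length ``2 pi r`` for ``r <= w/2`` and
    ``4 r asin(w / 2r)`` beyond; normalized over the band area."""
    r = np.asarray(r, dtype=float)
    w2 = 0.5 * width
    area = 2.0 * (
        w2 * np.sqrt(R**2 - w2**2) + R**2 * np.arcsin(min(1.0, w2 / R))
    )
    dens = np.where(r <= w2, 2.0 * np.pi * r, 4.0 * r * np.arcsin(np.minimum(1.0, w2 / np.maximum(r, 1e-300))))
    return dens / area


# ---------------------------------------------------------------------------
# recording chain
# ---------------------------------------------------------------------------

def design_recording_filter(filter_cutoff: float, sample_rate: float, order: int = 4):
    """Causal low-pass (Bessel-type) filter of the recording chain.

    ``filter_cutoff`` is the -3 dB point in Hz, ``sample_rate`` in Hz.
    Returns ``(b, a, group_delay_ms)`` with the passband group delay
    evaluated at DC.
    """
    if sample_rate <= 2.0 * filter_cutoff:
        raise ValueError("sample rate must exceed twice the filter cutoff")
    b, a = signal.bessel(order, filter_cutoff, fs=sample_rate, norm="mag")
    w, gd = signal.group_delay((b, a), w=[1e-4], fs=sample_rate)
    gd_ms = float(gd[0]) / sample_rate * 1000.0
    return b, a, gd_ms


def noise_bandwidth_factor(b, a, sample_rate: float) -> float:
    """SD ratio (filtered/unfiltered) for white input: sqrt of the filter's
    power gain integrated over the Nyquist band."""
    w, h = signal.freqz(b, a, worN=4096, fs=sample_rate)
    return float(np.sqrt(np.trapezoid(np.abs(h) ** 2, w) / (0.5 * sample_rate)))


def apply_recording_chain(
    trace: ResponseTrace,
    filter_cutoff: float = 20.0,
    sample_rate: float = 400.0,
    order: int = 4,
) -> ResponseTrace:
    """Low-pass filter a trace and resample it to the acquisition rate.

    The input must be sampled at least at ``sample_rate``; the output grid
    is uniform at ``1000 / sample_rate`` ms.  The filter's group delay (ms)
    is recorded in the metadata (recordings are conventionally shifted by
    it when kinetics are read off).
    """
    dt_in = trace.dt
    fs_in = 1000.0 / dt_in
    if fs_in < 2.0 * filter_cutoff:
        raise ValueError("input sampling too slow for the requested cutoff (aliasing)")
    b, a, gd_ms = design_recording_filter(filter_cutoff, fs_in, order)
    y = signal.lfilter(b, a, trace.r)
    dt_out = 1000.0 / sample_rate
    t_out = np.arange(trace.t[0], trace.t[-1] + 0.5 * dt_out, dt_out)
    r_out = np.interp(t_out, trace.t, y)
    meta = dict(trace.meta)
    meta.update({"filter_cutoff_hz": filter_cutoff, "group_delay_ms": gd_ms})
    return ResponseTrace(t_out, r_out, trace.j_dark, meta)


# ---------------------------------------------------------------------------
# trial ensembles
# ---------------------------------------------------------------------------

def parametric_spr_template(
    t, t_peak: float = 1000.0, power: float = 3.0
):
    """Solver-free SPR shape ``(t/tr)^n exp(-t/tr)`` normalized to unit peak,
    with ``tr = t_peak / n``; zero before the flash."""
    t = np.asarray(t, dtype=float)
    tr = t_peak / power
    x = np.clip(t, 0.0, None) / tr
    y = x**power * np.exp(-x)
    y /= power**power * np.exp(-power)
    return np.where(t < 0, 0.0, y)


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of one synthetic dim-flash experiment.

    ``mean_photoisoms`` is the Poisson mean per trial; each event adds
    ``a + N(0, sigma1)`` times the unit-peak template, with
    ``sigma1 = amplitude_cv * a``.  ``baseline_sd`` is the effective
    amplitude-domain noise SD: the injected filtered noise is scaled so
    that the template-projection amplitude of a pure-noise trial has this
    SD, matching how histogram noise is quantified.
    """

    n_trials: int = 60
    mean_photoisoms: float = 0.8
    spr_amplitude: float = 0.7        # pA
    amplitude_cv: float = 0.2
    baseline_sd: float = 0.1          # pA (amplitude-domain)
    drift_slope: float = 0.0          # pA/s, per-trial linear drift
    filter_cutoff: float = 20.0       # Hz
    sample_rate: float = 400.0        # Hz
    t_pre: float = 500.0              # ms of pre-flash baseline
    t_post: float = 5000.0            # ms after the flash
    t_peak: float = 1000.0            # ms, template peak time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.amplitude_cv < 0 or self.baseline_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.sample_rate <= 2.0 * self.filter_cutoff:
            raise ValueError("sample rate must exceed twice the filter cutoff")


@dataclass
class EnsembleTruth:
    """Ground-truth ledger of a generated ensemble."""

    k_per_trial: np.ndarray
    event_amplitudes: list[np.ndarray]
    sigma0: float
    sigma1: float
    a: float
    m: float

    def trial_amplitude(self, i: int) -> float:
        return float(np.sum(self.event_amplitudes[i]))


def _noise_gain(template: np.ndarray, b, a, n_samples: int, rng) -> float:
    """Amplitude-domain SD of unit-SD filtered noise as seen by the trial
    amplitude estimator (pre-flash baseline subtraction, then template
    projection), estimated once per ensemble from 600 noise realizations."""
    e = signal.lfilter(b, a, rng.normal(size=(600, n_samples)), axis=1)
    n_pre = n_samples - len(template)
    if n_pre > 0:
        e_post = e[:, n_pre:] - e[:, :n_pre].mean(axis=1, keepdims=True)
    else:
        e_post = e[:, -len(template):]
    denom = float(template @ template)
    s = (e_post @ template) / denom * float(np.max(template))
    return float(np.std(s))


def generate_trial_ensemble(
    spec: EnsembleSpec,
    template: ResponseTrace | None = None,
) -> tuple[list[ResponseTrace], EnsembleTruth]:
    """Generate a dim-flash trial ensemble plus its ground-truth ledger.

    Trials share a time grid from ``-t_pre`` to ``t_post`` at the
    acquisition rate.  The SPR template defaults to the parametric shape;
    pass a simulated trace (e.g. from the solver) to use it instead.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.sample_rate
    t = np.arange(-spec.t_pre, spec.t_post + 0.5 * dt, dt)
    if template is None:
        tmpl = parametric_spr_template(t, spec.t_peak)
    else:
        tmpl = np.interp(t, template.t, template.r, left=0.0)
        peak = float(np.max(tmpl))
        if peak <= 0:
            raise ValueError("template trace has no positive peak")
        tmpl = tmpl / peak

    b, a, _ = design_recording_filter(spec.filter_cutoff, spec.sample_rate)
    post = t >= 0
    gain = _noise_gain(tmpl[post], b, a, len(t), np.random.default_rng(spec.seed + 1))
    noise_scale = spec.baseline_sd / gain if gain > 0 else 0.0

    sigma1 = spec.amplitude_cv * spec.spr_amplitude
    k = rng.poisson(spec.mean_photoisoms, size=spec.n_trials)
    traces: list[ResponseTrace] = []
    event_amps: list[np.ndarray] = []
    for i in range(spec.n_trials):
        amps = spec.spr_amplitude + rng.normal(0.0, sigma1, size=k[i])
        event_amps.append(amps)
        clean = float(np.sum(amps)) * tmpl
        noise = signal.lfilter(b, a, rng.normal(size=len(t))) * noise_scale
        drift = spec.drift_slope * (t - t[0]) / 1000.0
        traces.append(
            ResponseTrace(
                t,
                clean + noise + drift,
                meta={"trial": i, "k": int(k[i])},
            )
        )
    truth = EnsembleTruth(
        k_per_trial=k,
        event_amplitudes=event_amps,
        sigma0=spec.baseline_sd,
        sigma1=sigma1,
        a=spec.spr_amplitude,
        m=spec.mean_photoisoms,
    )
    return traces, truth


def write_ensemble(traces: list[ResponseTrace], truth: EnsembleTruth, path) -> None:
    """Multi-column tabular file (time + one column per trial) and a
    JSON ground-truth sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    data = np.column_stack([traces[0].t] + [tr.r for tr in traces])
    header = "time_ms " + " ".join(f"trial_{i}" for i in range(len(traces)))
    np.savetxt(path, data, header=header, fmt="%.6g")
    ledger = {
        "k_per_trial": truth.k_per_trial.tolist(),
        "event_amplitudes": [a.tolist() for a in truth.event_amplitudes],
        "sigma0": truth.sigma0,
        "sigma1": truth.sigma1,
        "a": truth.a,
        "m": truth.m,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(ledger, indent=1))
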