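"""End-to-end simulation studies: the named comparisons of the analysis.

Each function runs the full pipeline (presets -> scenario -> solver ->
metrics, or sampler -> fit -> test) at survey-quality problem sizes and
returns a flat dict of the headline quantities.  These are the routines
behind ``scripts/acceptance.py`` and the acceptance test suite.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .cascade import PhotoisomerizationEvent
from .geometry import MeshResolution
from .metrics import compute_metrics, fit_recovery_tau
from .presets import species_preset
from .scenarios import apply_scenario, load_scenario
from .solver import SimulationConfig, SPRSolver, dark_steady_state
from .spr_stats import (
    AmplitudeModelParams,
    AmplitudeSample,
    fit_amplitude_histogram,
    monte_carlo_ks_pvalue,
    sample_eq1,
)
from .synthetic import SlitConfig, sample_slit_positions
from .trace import mean_trace

#: survey resolutions: fine enough for stable shape metrics, small enough
#: that one deterministic SPR runs in tens of seconds on one CPU
SALAMANDER_RES = MeshResolution(n_radial=8, n_angular=46, n_axial=12)
TOAD_RES = MeshResolution(n_radial=8, n_angular=32, n_axial=24)


def bicarbonate_study(scenario: str = "bicarb_salamander_calibrated") -> dict:
    """Salamander bicarbonate effect: dark-current and recovery-tau change.

    One dark steady-state solve per condition and two deterministic SPR
    runs (center event).  The default scenario carries the cyclase
    multipliers calibrated against the recorded bicarbonate effects; the
    printed-variant scenarios can be passed instead.
    """
    geom, p = species_preset("salamander")
    pb, _ = apply_scenario(p, load_scenario(scenario))
    cfg = SimulationConfig(dt=5.0, t_end=8000.0)
    ev = PhotoisomerizationEvent(geom.n_disks // 2, 0.0, 0.0)
    out = {}
    s0 = SPRSolver(geom, p, SALAMANDER_RES)
    s1 = SPRSolver(geom, pb, SALAMANDER_RES)
    m0 = compute_metrics(s0.run(cfg, ev))
    m1 = compute_metrics(s1.run(cfg, ev))
    out["j_dark_ringers_pa"] = s0.dark.j_dark
    out["j_dark_change_pct"] = 100.0 * (s1.dark.j_dark / s0.dark.j_dark - 1.0)
    out["tau_ringers_ms"] = m0.tau_rec
    out["tau_change_pct"] = 100.0 * (m1.tau_rec / m0.tau_rec - 1.0)
    out["integration_time_change_pct"] = 100.0 * (m1.T_i / m0.T_i - 1.0)
    out["spr_peak_pa"] = m0.r_peak
    return out


def radial_position_study(n_trials: int = 20, seed: int = 0) -> dict:
    """Edge vs random-radial-position kinetics in a salamander rod.

    One deterministic edge event (disk rim, halfway between incisures)
    against the average of ``n_trials`` deterministic runs whose positions
    are sampled through the middle-slit optics.  All runs share the
    deterministic (mean) R* time course so position is the only varied
    quantity.  Slopes are measured on peak-normalized traces.
    """
    geom, p = species_preset("salamander")
    s = SPRSolver(geom, p, SALAMANDER_RES)
    cfg = SimulationConfig(dt=5.0, t_end=2800.0)
    mid = geom.n_disks // 2

    edge = PhotoisomerizationEvent(mid, geom.radius, math.pi / geom.n_incisures)
    tr_edge = s.run(cfg, edge)
    me = compute_metrics(tr_edge.normalized())

    events = sample_slit_positions(SlitConfig(position="middle"), geom, n_trials, seed)
    trials = []
    for ev in events:
        ev = replace(ev, disk_index=mid)  # shared activated plane
        trials.append(s.run(cfg, ev))
    avg = mean_trace(trials)
    mr = compute_metrics(avg.normalized())
    return {
        "edge_tp_ms": me.t_p,
        "random_avg_tp_ms": mr.t_p,
        "edge_tp_advance_ms": mr.t_p - me.t_p,
        "edge_slope_gain_pct": 100.0 * (me.rising_slope / mr.rising_slope - 1.0),
        "edge_delay_advance_ms": mr.effective_delay - me.effective_delay,
        "n_random_trials": n_trials,
    }


def axial_study() -> dict:
    """Toad rod-b vs rod-t (homogeneous base/tip surrogates), Ringer's and
    bicarbonate: four deterministic runs."""
    geom, base = species_preset("toad")
    cfg = SimulationConfig(dt=5.0, t_end=6500.0)
    ev = PhotoisomerizationEvent(geom.n_disks // 2, 0.0, 0.0)
    res = {}
    for name in ("rod_b_ringers", "rod_t_ringers", "rod_b_bicarb", "rod_t_bicarb"):
        prm, _ = apply_scenario(base, load_scenario(name))
        s = SPRSolver(geom, prm, TOAD_RES)
        res[name] = (s.dark, compute_metrics(s.run(cfg, ev)))
    (db, mb), (dt_, mt) = res["rod_b_ringers"], res["rod_t_ringers"]
    (dbb, mbb), (dtb, mtb) = res["rod_b_bicarb"], res["rod_t_bicarb"]
    return {
        "ringers_slope_diff_pct": 100.0 * (mb.rising_slope / mt.rising_slope - 1.0),
        "ringers_tp_diff_pct": 100.0 * (mb.t_p / mt.t_p - 1.0),
        "ringers_tau_diff_ms": mb.tau_rec - mt.tau_rec,
        "bicarb_tau_diff_ms": mbb.tau_rec - mtb.tau_rec,
        "rod_b_dark_current_change_pct": 100.0 * (dbb.j_dark / db.j_dark - 1.0),
        "rod_t_dark_current_change_pct": 100.0 * (dtb.j_dark / dt_.j_dark - 1.0),
        "rod_b_ti_change_pct": 100.0 * (mbb.T_i / mb.T_i - 1.0),
        "rod_t_ti_change_pct": 100.0 * (mtb.T_i / mt.T_i - 1.0),
        "rod_b_peak_pa": mb.r_peak,
        "rod_t_peak_pa": mt.r_peak,
        "ringers_dark_ca_ratio": dt_.ca0 / db.ca0,
    }


def amplitude_recovery_study(
    n: int = 500, n_replicates: int = 50, seed: int = 0
) -> dict:
    """Mixture-fit parameter recovery: median relative error of each of
    (sigma0, m, sigma1, a) over replicate fits of n draws."""
    truth = AmplitudeModelParams(sigma0=0.2, m=0.8, sigma1=0.2, a=0.7)
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_replicates):
        x = sample_eq1(truth, n, rng)
        p, _ = fit_amplitude_histogram(AmplitudeSample(x), n_restarts=1)
        est.append([p.sigma0, p.m, p.sigma1, p.a])
    med = np.median(np.asarray(est), axis=0)
    names = ("sigma0", "m", "sigma1", "a")
    true_vals = (truth.sigma0, truth.m, truth.sigma1, truth.a)
    out = {
        f"recovery_err_{k}_pct": 100.0 * abs(m_ - t_) / t_
        for k, m_, t_ in zip(names, med, true_vals)
    }
    out["recovery_n"] = n
    out["recovery_replicates"] = n_replicates
    return out


def ks_calibration_study(
    n_datasets: int = 300, n_per_set: int = 60, n_mc: int = 1000, seed: int = 0
) -> dict:
    """Type-I error of the fixed-parameter Monte-Carlo KS test: fraction
    of model-generated datasets rejected at p < 0.05."""
    p = AmplitudeModelParams(sigma0=0.2, m=1.0, sigma1=0.2, a=1.0)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_datasets):
        x = sample_eq1(p, n_per_set, rng)
        res = monte_carlo_ks_pvalue(x, p, n_mc=n_mc, seed=int(rng.integers(2**31)))
        rej += res.p_value < 0.05
    return {
        "ks_type1_rejection_pct": 100.0 * rej / n_datasets,
        "ks_n_datasets": n_datasets,
    }
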