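"""Bundled species parameter sets.

Geometry follows the recorded cells: salamander rod outer segments are
large in diameter (disk diameter 11 um, i.e. radius 5.5 um) with 23 evenly
spaced radial incisures, and roughly half as long as toad outer segments.
Cascade constants follow the amphibian space-resolved model family (rates,
diffusivities and channel/exchanger constants in their reported ranges),
with the operating point adjusted so the dark current, SPR amplitude and
dim-flash kinetics land where recordings of each species put them
(salamander: ~25 pA dark current, SPR ~0.7 pA, time to peak near 1 s;
toad: ~10 pA dark current, slower and more sensitive).
"""

from __future__ import annotations

from .geometry import ROSGeometry, evenly_spaced_incisures
from .params import CascadeParams, RStarParams


_DISK_PITCH = 0.028   # um axial repeat: 14 nm disk + 14 nm interdiskal gap


def salamander_geometry() -> ROSGeometry:
    length = 25.0
    return ROSGeometry(
        radius=5.5,
        length=length,
        disk_thickness=0.014,
        interdisk_gap=0.014,
        n_disks=round(length / _DISK_PITCH),
        incisures=evenly_spaced_incisures(23, depth=3.0, width=0.05),
        species_tag="salamander",
        shell_thickness=0.015,
    )


def toad_geometry() -> ROSGeometry:
    length = 50.0
    return ROSGeometry(
        radius=3.0,
        length=length,
        disk_thickness=0.014,
        interdisk_gap=0.014,
        n_disks=round(length / _DISK_PITCH),
        incisures=evenly_spaced_incisures(16, depth=1.0, width=0.05),
        species_tag="toad",
        shell_thickness=0.015,
    )


def salamander_params() -> CascadeParams:
    """Salamander operating point.

    Constructed so the uniform dark state sits at cg0 = 3 uM, Ca0 = 0.5 uM
    and J_dark = 25 pA, with a small dark cyclase reserve (Ca0 well above
    K_cyc) and a slow dark cGMP turnover; R*/PDE* shutoff is fast relative
    to the turnover, which gives the fast-rising, slow-recovering dim-flash
    shape of recorded salamander rods (t_p ~ 1 s, T_i ~ 2 s).
    """
    return CascadeParams(
        D_cG=0.08,
        D_Ca=0.25,
        beta_dark=0.45e-3,
        alpha_min=1.2002e-3,
        alpha_max=7.2014e-3,
        K_cyc=0.08,
        m_cyc=2.0,
        J_cng_sat=694.4,
        K_cg=16.0,
        m_cg=2.0,
        f_Ca=0.12,
        J_ex_sat=5.660,
        K_ex=1.5,
        B_Ca=20.0,
        nu_RG=0.30,
        k_E=1.0 / 400.0,
        k_hyd=1.4e-3,
        D_E=1.2e-3,
        rstar=RStarParams(
            phosphorylation_rates=tuple([1.0 / 120.0] * 6),
            arrestin_capping_rates=tuple([0.0] * 5 + [1.0 / 30.0]),
        ),
    )


def toad_params() -> CascadeParams:
    """Toad (rod-b, Ringer's) operating point.

    Dark state at cg0 = 3 uM, Ca0 = 0.45 uM and J_dark = 10.1 pA; faster
    dark turnover than salamander but slower front-end shutoff, and a
    stronger hydrolysis capacity so the SPR is a larger fraction of the
    dark current, as in toad recordings.
    """
    return CascadeParams(
        D_cG=0.08,
        D_Ca=0.25,
        beta_dark=0.75e-3,
        alpha_min=2.1380e-3,
        alpha_max=8.5519e-3,
        K_cyc=0.06,
        m_cyc=2.0,
        J_cng_sat=280.55,
        K_cg=16.0,
        m_cg=2.0,
        f_Ca=0.12,
        J_ex_sat=2.4774,
        K_ex=1.5,
        B_Ca=20.0,
        nu_RG=0.30,
        k_E=1.0 / 500.0,
        k_hyd=4.0e-3,
        D_E=1.2e-3,
        rstar=RStarParams(
            phosphorylation_rates=tuple([1.0 / 140.0] * 6),
            arrestin_capping_rates=tuple([0.0] * 5 + [1.0 / 35.0]),
        ),
    )


def species_preset(tag: str) -> tuple[ROSGeometry, CascadeParams]:
    """Geometry and cascade parameters for a bundled species."""
    if tag == "salamander":
        return salamander_geometry(), salamander_params()
    if tag == "toad":
        return toad_geometry(), toad_params()
    raise KeyError(f"unknown species preset '{tag}' (use 'salamander' or 'toad')")
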