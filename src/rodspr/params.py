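"""Kinetic and transport parameters of the transduction cascade.

Units: um, ms, uM, pA (see :mod:`rodspr.units`).  Values for the bundled
species presets live in :mod:`rodspr.presets`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field, fields

import numpy as np


class ParameterError(ValueError):
    """Inconsistent or out-of-range cascade parameters."""


@dataclass(frozen=True)
class RStarParams:
    """Stepwise shutoff of photoexcited rhodopsin (R*).

    R* is quenched by sequential phosphorylation through
    ``n_phospho_states`` states, each reducing its catalytic activity, and
    is finally capped by arrestin.  ``activity_per_state[i]`` is the
    catalytic weight while ``i``-fold phosphorylated (non-increasing,
    ``activity_per_state[0] = 1``).
    """

    n_phospho_states: int = 6
    phosphorylation_rates: tuple[float, ...] = ()   # 1/ms, state i -> i+1
    arrestin_capping_rates: tuple[float, ...] = ()  # 1/ms, state i -> capped
    activity_per_state: tuple[float, ...] = ()      # dimensionless

    def __post_init__(self) -> None:
        n = self.n_phospho_states
        if n < 1:
            raise ParameterError("need at least one R* state")
        phos = self.phosphorylation_rates or tuple([1.0 / 200.0] * n)
        cap = self.arrestin_capping_rates or tuple([0.0] * (n - 1) + [1.0 / 50.0])
        act = self.activity_per_state or tuple(0.5**i for i in range(n))
        if not (len(phos) == len(cap) == len(act) == n):
            raise ParameterError("per-state rate arrays must have length n_phospho_states")
        if any(r < 0 for r in phos + cap):
            raise ParameterError("rates must be non-negative")
        if any(b > a + 1e-12 for a, b in zip(act, act[1:])):
            raise ParameterError("activity weights must be non-increasing")
        object.__setattr__(self, "phosphorylation_rates", tuple(phos))
        object.__setattr__(self, "arrestin_capping_rates", tuple(cap))
        object.__setattr__(self, "activity_per_state", tuple(act))
        # from the final phospho-state the only exit is arrestin capping
        if cap[-1] <= 0 and phos[-1] <= 0 and all(r == 0 for r in phos + cap):
            pass  # fully frozen chain is allowed; sampling warns

    def mean_integrated_activity(self) -> float:
        """E[ integral of activity dt ] by first-step analysis of the chain.

        The chain visits state ``i`` with probability
        ``prod_{j<i} p_j / (p_j + c_j)`` and dwells ``1/(p_i + c_i)`` there
        on average; the last state exits only by capping.
        """
        total = 0.0
        reach = 1.0
        n = self.n_phospho_states
        for i in range(n):
            p = self.phosphorylation_rates[i] if i < n - 1 else 0.0
            c = self.arrestin_capping_rates[i]
            lam = p + c
            if lam <= 0:
                return float("inf")
            total += reach * self.activity_per_state[i] / lam
            reach *= p / lam
        return total


@dataclass(frozen=True)
class ActivationParams:
    """Transducin/PDE activation on the photoisomerized disk.

    ``nu_RG`` activated effectors produced per ms per unit R* activity;
    ``k_E`` first-order PDE* shutoff; ``D_E`` lateral diffusivity of the
    activated effector on the disk membrane; ``k_hyd`` cGMP hydrolysis
    capacity per PDE* (um^3/ms).
    """

    nu_RG: float
    k_E: float
    D_E: float
    k_hyd: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class CascadeParams:
    """All kinetic/transport constants of the cGMP/Ca2+ transduction model.

    Attributes
    ----------
    D_cG, D_Ca : float
        Cytosolic diffusivities, um^2/ms.  ``D_Ca`` is the free-ion value;
        buffering divides the effective mobility by ``B_Ca``.
    beta_dark : float
        Dark (spontaneous) PDE hydrolysis rate, 1/ms.
    alpha_min, alpha_max : float
        Guanylate cyclase cGMP synthesis rate at saturating-high and
        vanishing Ca2+, uM/ms.
    K_cyc, m_cyc : float
        Ca2+ half-inhibition constant (uM) and Hill coefficient of cyclase.
    J_cng_sat : float
        Whole-cell CNG current at saturating cGMP, pA.
    K_cg, m_cg : float
        cGMP half-activation (uM) and Hill coefficient (> 1) of the channel.
    f_Ca : float
        Fraction of the CNG current carried by Ca2+.
    J_ex_sat, K_ex : float
        Saturated whole-cell exchanger current (pA) and its Ca2+ constant (uM).
    B_Ca : float
        Fast-buffer capacity factor scaling Ca2+ accumulation.
    nu_RG, k_E, k_hyd, D_E : float
        Activation-chain constants, see :class:`ActivationParams`.
    """

    D_cG: float = 0.15
    D_Ca: float = 0.25
    beta_dark: float = 1.0e-3
    alpha_min: float = 0.7e-3
    alpha_max: float = 10.0e-3
    K_cyc: float = 0.23
    m_cyc: float = 2.0
    J_cng_sat: float = 2700.0
    K_cg: float = 20.0
    m_cg: float = 2.5
    f_Ca: float = 0.12
    J_ex_sat: float = 7.0
    K_ex: float = 1.5
    B_Ca: float = 20.0
    nu_RG: float = 0.30
    k_E: float = 1.0 / 600.0
    k_hyd: float = 1.0e-3
    D_E: float = 1.2e-3
    rstar: RStarParams = field(default_factory=RStarParams)

    def __post_init__(self) -> None:
        positive = (
            "D_cG D_Ca beta_dark alpha_min alpha_max K_cyc m_cyc J_cng_sat "
            "K_cg m_cg J_ex_sat K_ex B_Ca"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 < self.f_Ca < 1.0):
            raise ParameterError("f_Ca must lie in (0, 1)")
        if self.m_cg <= 1.0:
            raise ParameterError("CNG channel Hill coefficient must exceed 1")
        if self.alpha_max < self.alpha_min:
            raise ParameterError("alpha_max must be >= alpha_min")
        for name in ("nu_RG", "k_E", "k_hyd", "D_E"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    # -- derived pieces -------------------------------------------------
    def activation(self) -> ActivationParams:
        return ActivationParams(
            nu_RG=self.nu_RG, k_E=self.k_E, D_E=self.D_E, k_hyd=self.k_hyd
        )

    def cyclase_rate(self, ca):
        """Ca2+-inhibited cyclase synthesis rate alpha(ca), uM/ms."""
        ca = np.asarray(ca, dtype=float)
        return self.alpha_min + (self.alpha_max - self.alpha_min) / (
            1.0 + (ca / self.K_cyc) ** self.m_cyc
        )

    def cng_open_fraction(self, cg):
        """Fraction of saturated CNG current at cGMP level ``cg``."""
        cg = np.asarray(cg, dtype=float)
        x = (cg / self.K_cg) ** self.m_cg
        return x / (1.0 + x)

    def exchanger_saturation(self, ca):
        ca = np.asarray(ca, dtype=float)
        return ca / (ca + self.K_ex)

    def with_updates(self, **kwargs) -> "CascadeParams":
        return replace(self, **kwargs)
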