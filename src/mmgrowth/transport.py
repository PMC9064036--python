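"""Diffusive transport-limitation bounds for cell-filled growth channels.

Cells packed in a microchannel consume nutrient faster than diffusion can
replenish it once the inlet concentration is low enough.  From the prior
monolayer-chamber characterization (penetration depth l_g, half-saturation
g-bar) this module derives the per-cell uptake rate, the colony volumetric
uptake, the steady-state concentration profile along a channel open at both
ends, and the critical inlet concentration below which the channel center is
substantially depleted.

All computation is in SI units; concentrations are exposed in mmol/L at the
interface (1 mol m^-3 == 1 mmol/L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransportParams",
    "single_cell_uptake",
    "volumetric_uptake",
    "concentration_profile",
    "critical_concentration",
    "transport_report",
]


@dataclass(frozen=True)
class TransportParams:
    """Geometry and transport constants of the device, SI units.

    Defaults are the characterization values for PCA and *C. glutamicum*:
    diffusivity D of PCA in water, fitted half-saturation ``g_bar``
    (19.9 umol/L = 0.0199 mol m^-3) and penetration depth ``l_g`` (3.78 um)
    from the prior study's Monod fit, areal cell density ``rho``
    (0.66 um^-2), chamber height ``h`` (0.8 um), and growth-channel length
    ``l`` (~20 um).
    """

    D: float = 2.8e-10  # m^2/s
    g_bar: float = 0.0199  # mol/m^3
    l_g: float = 3.78e-6  # m
    rho: float = 0.66e12  # m^-2
    h: float = 0.8e-6  # m
    l: float = 20e-6  # m

    def __post_init__(self) -> None:
        for name in ("D", "g_bar", "l_g", "rho", "h", "l"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.l <= self.l_g:
            warnings.warn(
                f"channel length l = {self.l:g} m does not exceed the "
                f"penetration depth l_g = {self.l_g:g} m; the depletion "
                "estimate assumes l > l_g",
                stacklevel=2,
            )


def single_cell_uptake(params: TransportParams) -> float:
    """Per-cell nutrient uptake rate in mol/s.

    Inverts the penetration-depth relation ``l_g^2 = D * g_bar * h / (rho * u)``
    for the uptake rate:  ``u = D * g_bar * h / (rho * l_g^2)``.
    """
    return params.D * params.g_bar * params.h / (params.rho * params.l_g**2)


def volumetric_uptake(u: float, rho: float, h: float) -> float:
    """Colony volume-related uptake in mol s^-1 m^-3.

    Per-cell rate times cells per area, divided by the monolayer height:
    ``U_hat = u * rho / h``.
    """
    for name, value in (("u", u), ("rho", rho), ("h", h)):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    return u * rho / h


def concentration_profile(x, c_in: float, U_hat: float, D: float, l: float):
    """Steady-state concentration along a channel open at both ends, mol/m^3.

    With zeroth-order (saturated) uptake U_hat the diffusion equation gives a
    parabola pinned to the inlet concentration at both openings:

        c(x) = c_in - U_hat * x * (l - x) / (2 D),   clipped at 0.

    Symmetric about l/2; the center drop is ``U_hat * l^2 / (8 D)``.
    """
    if not (D > 0 and l > 0 and U_hat >= 0 and c_in >= 0):
        raise ValueError("require D > 0, l > 0, U_hat >= 0, c_in >= 0")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > l):
        raise ValueError(f"x must lie in [0, {l:g}] m")
    c = c_in - U_hat * x_arr * (l - x_arr) / (2.0 * D)
    c = np.clip(c, 0.0, None)
    return c if c.ndim else float(c)


def critical_concentration(
    U_hat: float, D: float, l: float, convention: str = "half_center"
) -> float:
    """Critical inlet concentration in mmol/L below which the channel center
    is diffusion-limited.

    Conventions
    -----------
    ``"half_center"`` (default)
        Inlet concentration at which the center of the channel sits at half
        the inlet value: solving ``c_in - U_hat l^2 / (8D) = c_in / 2`` gives
        ``c_crit = U_hat * l^2 / (4 D)``.
    ``"center_drop"``
        The absolute center drop itself, ``U_hat * l^2 / (8 D)`` — the inlet
        concentration at which the center reaches exactly zero.
    """
    for name, value in (("U_hat", U_hat), ("D", D), ("l", l)):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    drop = U_hat * l**2 / (8.0 * D)
    if convention == "half_center":
        c_crit = 2.0 * drop
    elif convention == "center_drop":
        c_crit = drop
    else:
        raise ValueError(
            f"unknown convention {convention!r}; use 'half_center' or 'center_drop'"
        )
    return c_crit * 1.0  # mol/m^3 == mmol/L


def transport_report(
    params: TransportParams | None = None,
    n_profile: int = 21,
    convention: str = "half_center",
) -> dict:
    """Assemble the full transport-limitation report as a JSON-ready dict."""
    if params is None:
        params = TransportParams()
    u = single_cell_uptake(params)
    U_hat = volumetric_uptake(u, params.rho, params.h)
    c_crit = critical_concentration(U_hat, params.D, params.l, convention=convention)
    x = np.linspace(0.0, params.l, n_profile)
    profile = concentration_profile(x, c_crit, U_hat, params.D, params.l)
    return {
        "u_mol_per_s": u,
        "U_hat_mol_per_s_m3": U_hat,
        "c_crit_mmol_per_L": c_crit,
        "c_crit_convention": convention,
        "profile": [
            {"x_m": float(xi), "c_mmol_per_L": float(ci)}
            for xi, ci in zip(x, profile)
        ],
        "params": {
            "D_m2_per_s": params.D,
            "g_bar_mol_per_m3": params.g_bar,
            "l_g_m": params.l_g,
            "rho_per_m2": params.rho,
            "h_m": params.h,
            "l_m": params.l,
        },
    }
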