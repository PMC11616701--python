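"""Carreau shear-thinning viscosity and channel-flow dimensionless numbers.

The viscoelastic carrier fluid (PEO dissolved in PBS) is shear-thinning; its
steady viscosity is described by the Carreau model

    eta(gdot) = eta_inf + (eta0 - eta_inf) * [1 + (lambda_c * gdot)^2]^((n-1)/2)

with zero-shear viscosity eta0, infinite-shear viscosity eta_inf, relaxation
time constant lambda_c and power-law index n (n = 1 recovers a Newtonian
fluid; 0 < n < 1 is shear-thinning).

Focusing/deformation conditions are characterized by the Reynolds and
Weissenberg numbers.  With U the mean velocity, H the channel size, rho the
fluid density (1080 kg/m³ by default) and lambda the fluid relaxation time,
the conventions used here are

    Re = rho * U * H / eta,   Wi = lambda * U / H,   El = Wi / Re

i.e. the characteristic shear rate is U/H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CarreauParams",
    "FlowCondition",
    "carreau_viscosity",
    "fit_carreau",
    "dimensionless_numbers",
]


@dataclass(frozen=True)
class CarreauParams:
    """Carreau model parameters (SI units)."""

    eta0: float
    eta_inf: float
    lambda_c: float
    n_exp: float

    def __post_init__(self) -> None:
        if not self.eta0 >= self.eta_inf >= 0:
            raise ValueError("require eta0 >= eta_inf >= 0")
        if self.lambda_c < 0:
            raise ValueError("lambda_c must be >= 0")
        if not 0 < self.n_exp <= 1:
            raise ValueError("0 < n_exp <= 1 for shear-thinning fluids")


@dataclass(frozen=True)
class FlowCondition:
    """Flow state used for Re/Wi/El computation."""

    mean_velocity_mps: float
    channel_size_m: float
    relaxation_time_s: float = 0.0
    density_kgm3: float = 1080.0

    def __post_init__(self) -> None:
        if self.mean_velocity_mps <= 0 or self.channel_size_m <= 0:
            raise ValueError("velocity and channel size must be positive")
        if self.relaxation_time_s < 0 or self.density_kgm3 <= 0:
            raise ValueError("relaxation time must be >= 0 and density > 0")


def carreau_viscosity(shear_rate, params: CarreauParams):
    """Carreau viscosity (Pa·s) at the given shear rate(s) (1/s)."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear_rate must be >= 0")
    eta = params.eta_inf + (params.eta0 - params.eta_inf) * (
        1.0 + (params.lambda_c * g) ** 2
    ) ** ((params.n_exp - 1.0) / 2.0)
    return eta if eta.ndim else float(eta)


def fit_carreau(shear_rates, viscosities) -> tuple[CarreauParams, dict]:
    """Least-squares Carreau fit in log-viscosity space.

    Requires at least 6 points spanning two decades of shear rate.  Returns
    the fitted parameters plus diagnostics (residual RMS in log space,
    covariance diagonal).  Raises ``RuntimeError`` with diagnostics if the
    optimizer does not converge.
    """
    g = np.asarray(shear_rates, dtype=float)
    eta = np.asarray(viscosities, dtype=float)
    if len(g) != len(eta):
        raise ValueError("shear_rates and viscosities must have equal length")
    if len(g) < 6:
        raise ValueError("need at least 6 (shear rate, viscosity) points")
    if np.any(g <= 0) or np.any(eta <= 0):
        raise ValueError("shear rates and viscosities must be positive")
    if np.log10(g.max() / g.min()) < 2.0:
        raise ValueError("shear rates must span at least 2 decades")

    def model_log(gdot, eta0, eta_inf, lam, n):
        e = eta_inf + (eta0 - eta_inf) * (1.0 + (lam * gdot) ** 2) ** ((n - 1.0) / 2.0)
        return np.log(e)

    eta_max, eta_min = float(eta.max()), float(eta.min())
    p0 = [eta_max, max(0.5 * eta_min, 1e-8), 1.0 / float(np.median(g)), 0.6]
    bounds = (
        [1e-12, 0.0, 1e-12, 0.01],
        [1e3, eta_max, 1e6, 1.0],
    )
    try:
        popt, pcov = curve_fit(
            model_log, g, np.log(eta), p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Carreau fit did not converge: {exc}") from exc
    eta0, eta_inf, lam, n = (float(v) for v in popt)
    eta_inf = min(eta_inf, eta0)
    params = CarreauParams(eta0=eta0, eta_inf=eta_inf, lambda_c=lam, n_exp=min(n, 1.0))
    resid = model_log(g, *popt) - np.log(eta)
    diagnostics = {
        "rms_log_residual": float(np.sqrt(np.mean(resid**2))),
        "param_variance": [float(v) for v in np.diag(pcov)],
        "n_points": len(g),
    }
    return params, diagnostics


def dimensionless_numbers(
    cond: FlowCondition, viscosity: float
) -> tuple[float, float, float]:
    """(Re, Wi, El) for a flow condition at the given viscosity (Pa·s)."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    re = cond.density_kgm3 * cond.mean_velocity_mps * cond.channel_size_m / viscosity
    wi = cond.relaxation_time_s * cond.mean_velocity_mps / cond.channel_size_m
    el = wi / re if re > 0 else 0.0
    return re, wi, el
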