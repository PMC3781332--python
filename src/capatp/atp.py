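"""Plasma ATP transport along each vessel.

The plasma ATP concentration A(y) (carried internally in mol/cm^3,
reported in mol/L) obeys a convection equation with saturation-dependent
erythrocyte release and endothelial degradation:

    (1 - H_T) dA/dt = -u (1 - H_D) dA/dy + H_T C0 (1 - C1 S) - (2/R) k_d A,

with A(0) = 0 at the entrance. Nothing in the oxygen problem depends on A,
so the steady profile is computed after the SO2 field has converged; the
implicit upwind march used for that shares the exact fixed point of the
explicit pseudo-time update.

For constant saturation the steady profile is the closed form

    A(y) = A_inf (1 - exp(-y / lambda)),
    A_inf = H_T C0 (1 - C1 S) R / (2 k_d),   lambda = u (1 - H_D) R / (2 k_d),

used as the test oracle.
"""

from __future__ import annotations


import numpy as np

from .errors import StabilityError
from .geometry import NetworkGeometry
from .oxygen import get_coupling
from .params import AtpParams, TransportParams, MOL_PER_CM3_TO_MOLAR


def atp_equilibrium(S, radius_cm, params: TransportParams,
                    atp_params: AtpParams):
    """Plateau concentration (mol/cm^3) balancing release and degradation.

    A_inf = H_T C0 (1 - C1 S) R / (2 k_d); strictly decreasing in S and
    linear in the vessel radius.
    """
    S = np.asarray(S, dtype=float)
    out = (params.H_T * atp_params.C0 * (1.0 - atp_params.C1 * S)
           * np.asarray(radius_cm) / (2.0 * atp_params.k_d))
    return out if out.ndim else float(out)


def atp_decay_length_cm(radius_cm, velocity_cm_s, params: TransportParams,
                        atp_params: AtpParams):
    """Axial relaxation length lambda = u (1 - H_D) R / (2 k_d)."""
    return velocity_cm_s * (1.0 - params.H_D) * radius_cm / (2.0 * atp_params.k_d)


def atp_step(A: np.ndarray, S: np.ndarray, geometry: NetworkGeometry,
             params: TransportParams, atp_params: AtpParams,
             dt: float) -> np.ndarray:
    """One explicit upwind pseudo-time update of A (mol/cm^3) per vessel."""
    coup = get_coupling(geometry)
    dy = geometry.dy_cm
    A_prev = np.concatenate([np.zeros((A.shape[0], 1)), A[:, :-1]], axis=1)
    release = params.H_T * atp_params.C0 * (1.0 - atp_params.C1 * S)
    degr = (2.0 / coup.radius_cm[:, None]) * atp_params.k_d * A
    adv = -coup.velocity[:, None] * (1.0 - params.H_D) * (A - A_prev) / dy
    A_new = A + dt * (adv + release - degr) / (1.0 - params.H_T)
    if not np.all(np.isfinite(A_new)) or A_new.min() < -1e-25:
        raise StabilityError(f"ATP update unstable at dt={dt:g}", dt=dt)
    return np.clip(A_new, 0.0, None)


def atp_steady(S: np.ndarray, geometry: NetworkGeometry,
               params: TransportParams, atp_params: AtpParams) -> np.ndarray:
    """Steady upwind profile A (mol/cm^3) for a frozen saturation field.

    Implicit march in y; identical to the fixed point of :func:`atp_step`.
    """
    coup = get_coupling(geometry)
    dy = geometry.dy_cm
    nv, nseg = S.shape
    uy = coup.velocity * (1.0 - params.H_D) / dy           # (nv,)
    dcoef = 2.0 * atp_params.k_d / coup.radius_cm          # (nv,)
    release = params.H_T * atp_params.C0 * (1.0 - atp_params.C1 * S)
    A = np.empty_like(S)
    prev = np.zeros(nv)
    for i in range(nseg):
        A[:, i] = (uy * prev + release[:, i]) / (uy + dcoef)
        prev = A[:, i]
    return A


def atp_profile_oracle(y_cm, S_const: float, radius_cm: float,
                       velocity_cm_s: float, params: TransportParams,
                       atp_params: AtpParams):
    """Closed-form steady profile at constant saturation (mol/cm^3)."""
    a_inf = atp_equilibrium(S_const, radius_cm, params, atp_params)
    lam = atp_decay_length_cm(radius_cm, velocity_cm_s, params, atp_params)
    return a_inf * (1.0 - np.exp(-np.asarray(y_cm, dtype=float) / lam))


def to_molar(A_mol_per_cm3):
    """Convert an internal mol/cm^3 concentration to mol/L."""
    return np.asarray(A_mol_per_cm3) * MOL_PER_CM3_TO_MOLAR
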