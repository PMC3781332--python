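"""Oxygen transport: kinetics, tissue reaction-diffusion, capillary SO2.

Tissue PO2 obeys a reaction-diffusion equation with Michaelis-Menten
consumption and myoglobin-facilitated diffusion,

    dP/dt = [1 + (c_Mb/alpha) S_Mb'(P)]^-1
            { D lap(P) - M(P)/alpha
              + (D_Mb c_Mb / alpha) div(S_Mb'(P) grad P) } + wall sources,

while each vessel carries a convective saturation balance

    (C + alpha_b dPb/dS) dS/dt =
        -u (C~ + alpha~_b dPb/dS) dS/dy - (2/R) j,      j = kappa (P_b - P_w),

with first-order upwind differencing on 50 axial segments and blood PO2
P_b tied to S through the Hill curve. Positive j moves O2 from blood to
tissue and desaturates the blood.

This module holds the pointwise kinetics, the explicit pseudo-time update
operators (used by the time-marching driver and by the tests), the steady
upwind vessel march used by the accelerated elliptic solver, and the
precomputed vessel-grid coupling arrays shared by both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, StabilityError
from .geometry import NetworkGeometry
from .params import TransportParams

__all__ = [
    "hill_saturation", "hill_inverse", "hill_inverse_slope",
    "mb_saturation", "mb_saturation_deriv", "consumption", "wall_flux",
    "SimulationState", "Coupling", "get_coupling", "kappa_effective",
    "tissue_step", "capillary_step", "march_vessels_steady",
    "sample_wall_po2", "stable_dt",
]


# ---------------------------------------------------------------------------
# pointwise kinetics
# ---------------------------------------------------------------------------

def hill_saturation(P, params: TransportParams):
    """Oxyhemoglobin saturation S(P) = P^n / (P^n + P50^n)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise DomainError("PO2 must be non-negative")
    r = (P / params.P50) ** params.n_hill
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def hill_inverse(S, params: TransportParams):
    """Blood PO2 at saturation S: P = P50 (S/(1-S))^(1/n)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0) or np.any(S >= 1):
        raise DomainError("saturation must lie in [0, 1); S = 1 needs infinite PO2")
    out = params.P50 * (S / (1.0 - S)) ** (1.0 / params.n_hill)
    return out if out.ndim else float(out)


def _hill_inv_raw(S, params):
    return params.P50 * (S / (1.0 - S)) ** (1.0 / params.n_hill)


def hill_inverse_slope(S, params: TransportParams):
    """dP_b/dS along the Hill curve, dP/dS = P / (n S (1 - S))."""
    S = np.asarray(S, dtype=float)
    Sc = np.clip(S, 1e-9, 1.0 - 1e-12)
    out = _hill_inv_raw(Sc, params) / (params.n_hill * Sc * (1.0 - Sc))
    return out if out.ndim else float(out)


def mb_saturation(P, params: TransportParams):
    """Myoglobin saturation S_Mb(P) = P / (P + P50_Mb)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise DomainError("PO2 must be non-negative")
    out = P / (P + params.P50_Mb)
    return out if out.ndim else float(out)


def mb_saturation_deriv(P, params: TransportParams):
    """dS_Mb/dP = P50_Mb / (P + P50_Mb)^2 (positive, max 1/P50_Mb at P=0)."""
    P = np.asarray(P, dtype=float)
    out = params.P50_Mb / (P + params.P50_Mb) ** 2
    return out if out.ndim else float(out)


def consumption(P, params: TransportParams):
    """Michaelis-Menten O2 consumption M(P) = M0 P / (P + P_cr)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise DomainError("PO2 must be non-negative")
    out = params.M0 * P / (P + params.P_cr)
    return out if out.ndim else float(out)


def wall_flux(S_seg, P_wall_mean, params: TransportParams, kappa=None):
    """Trans-wall flux j = kappa (P_b(S) - P_w); positive out of the blood."""
    k = params.kappa if kappa is None else kappa
    return k * (hill_inverse(S_seg, params) - np.asarray(P_wall_mean, dtype=float))


# ---------------------------------------------------------------------------
# state and coupling arrays
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Tissue PO2 field plus per-vessel axial saturation."""

    P: np.ndarray           # (Nx, Ny, Nz), mmHg
    S: np.ndarray           # (n_vessels, n_segments)
    t: float = 0.0
    j: Optional[np.ndarray] = None  # last wall flux per (vessel, segment)

    def blood_po2(self, params: TransportParams) -> np.ndarray:
        return _hill_inv_raw(np.clip(self.S, 1e-12, 1 - 1e-12), params)

    def copy(self) -> "SimulationState":
        return SimulationState(P=self.P.copy(), S=self.S.copy(), t=self.t,
                               j=None if self.j is None else self.j.copy())


@dataclass
class Coupling:
    """Flattened wall maps of a network plus per-vessel constants."""

    node_index: np.ndarray      # (n,) flat node indices
    seg_global: np.ndarray      # (n,) vessel*n_seg + segment
    area_cm2: np.ndarray        # (n,) wall-area weights
    seg_area_cm2: np.ndarray    # (nv*nseg,) total wall area per segment
    radius_cm: np.ndarray       # (nv,)
    velocity: np.ndarray        # (nv,) cm/s
    S_in: np.ndarray            # (nv,)
    consuming: np.ndarray       # (Nx,Ny,Nz) bool, tissue (non-lumen) nodes
    volumes: np.ndarray         # (Nx,Ny,Nz) control volumes, cm^3


def get_coupling(geometry: NetworkGeometry) -> Coupling:
    """Build (and cache on the geometry) the flattened coupling arrays."""
    cached = getattr(geometry, "_coupling", None)
    if cached is not None:
        return cached
    nseg = geometry.n_segments
    idx, seg, area = [], [], []
    for v_pos, wm in enumerate(geometry.wall_maps):
        idx.append(wm.node_index)
        seg.append(wm.segment.astype(np.int64) + v_pos * nseg)
        area.append(wm.area_cm2)
    nv = geometry.n_vessels
    if nv:
        node_index = np.concatenate(idx)
        seg_global = np.concatenate(seg)
        area_cm2 = np.concatenate(area)
    else:
        node_index = np.zeros(0, dtype=np.int64)
        seg_global = np.zeros(0, dtype=np.int64)
        area_cm2 = np.zeros(0)
    seg_area = np.bincount(seg_global, weights=area_cm2, minlength=nv * nseg)
    coup = Coupling(
        node_index=node_index, seg_global=seg_global, area_cm2=area_cm2,
        seg_area_cm2=seg_area,
        radius_cm=np.array([v.radius_cm for v in geometry.vessels]),
        velocity=np.array([v.velocity_cm_s for v in geometry.vessels]),
        S_in=np.array([v.S_in for v in geometry.vessels]),
        consuming=~geometry.lumen_mask(),
        volumes=geometry.grid.node_volumes_cm3(),
    )
    geometry._coupling = coup
    return coup


def kappa_effective(geometry: NetworkGeometry, params: TransportParams,
                    correction: bool = True) -> np.ndarray:
    """Per-vessel numerical mass-transfer coefficient.

    Folds the annulus between the physical wall radius R and the discrete
    sampling radius r_eff of the regularized wall source into kappa
    (series resistance), so the exchange is nearly independent of grid
    spacing even when R is below the spacing:

        kappa_num = kappa / (1 + kappa R ln(r_eff / R) / (D alpha))
    """
    from .geometry import effective_coupling_radius_um
    h = geometry.grid.h_um
    out = np.empty(geometry.n_vessels)
    for i, v in enumerate(geometry.vessels):
        if not correction:
            out[i] = params.kappa
            continue
        r_eff = effective_coupling_radius_um(round(v.radius_um, 6), round(h, 6))
        denom = 1.0 + params.kappa * v.radius_cm * np.log(r_eff / v.radius_um) \
            / (params.D * params.alpha)
        out[i] = params.kappa / max(denom, 0.05)
    return out


def sample_wall_po2(P: np.ndarray, coup: Coupling, n_vessels: int,
                    n_segments: int) -> np.ndarray:
    """Area-weighted mean tissue PO2 over each segment's wall nodes."""
    flat = P.reshape(-1)
    acc = np.bincount(coup.seg_global, weights=coup.area_cm2 * flat[coup.node_index],
                      minlength=n_vessels * n_segments)
    with np.errstate(invalid="ignore"):
        mean = acc / coup.seg_area_cm2
    return mean.reshape(n_vessels, n_segments)


# ---------------------------------------------------------------------------
# explicit pseudo-time operators
# ---------------------------------------------------------------------------

def stable_dt(geometry: NetworkGeometry, params: TransportParams,
              safety: float = 0.2) -> float:
    """Explicit diffusion stability bound for the tissue update."""
    d_fac = params.D_Mb * params.c_Mb / (params.alpha * params.P50_Mb)
    d_max = params.D + d_fac  # max facilitated diffusivity (S_Mb' max at P=0)
    h = geometry.grid.h_cm
    return safety * h * h / (6.0 * d_max)


def _div_facilitated_flux(P: np.ndarray, gamma: np.ndarray, h_cm: float):
    """div(gamma grad P) with mirror (zero-flux) conditions on all faces."""
    Pp = np.pad(P, 1, mode="reflect")
    Gp = np.pad(gamma, 1, mode="reflect")
    out = np.zeros_like(P)
    inv_h2 = 1.0 / (h_cm * h_cm)
    core = (slice(1, -1),) * 3
    for ax in range(3):
        up = tuple(slice(2, None) if a == ax else slice(1, -1) for a in range(3))
        dn = tuple(slice(0, -2) if a == ax else slice(1, -1) for a in range(3))
        g_up = 0.5 * (Gp[up] + gamma)
        g_dn = 0.5 * (Gp[dn] + gamma)
        out += (g_up * (Pp[up] - P) - g_dn * (P - Pp[dn])) * inv_h2
    return out


def tissue_step(state: SimulationState, geometry: NetworkGeometry,
                params: TransportParams, chamber, dt: float,
                kappa_eff: Optional[np.ndarray] = None) -> SimulationState:
    """One explicit pseudo-time update of the tissue PO2 field.

    Wall fluxes are evaluated from the current state (j = kappa (P_b - P_w))
    and deposited on the wall-map nodes; chamber nodes are re-clamped after
    the update. Raises :class:`StabilityError` on NaN or negative PO2.
    """
    coup = get_coupling(geometry)
    nv, nseg = geometry.n_vessels, geometry.n_segments
    if kappa_eff is None:
        kappa_eff = kappa_effective(geometry, params)
    P = state.P
    smb_p = mb_saturation_deriv(P, params)
    gamma = params.D + (params.D_Mb * params.c_Mb / params.alpha) * smb_p
    div = _div_facilitated_flux(P, gamma, geometry.grid.h_cm)
    sink = np.where(coup.consuming, params.M0 * P / (P + params.P_cr), 0.0)
    q = np.zeros(P.size)
    j = None
    if nv:
        Pw = sample_wall_po2(P, coup, nv, nseg)
        Pb = state.blood_po2(params)
        j = kappa_eff[:, None] * (Pb - Pw)            # ml O2 cm^-2 s^-1
        np.add.at(q, coup.node_index,
                  j.reshape(-1)[coup.seg_global] * coup.area_cm2)
    q = q.reshape(P.shape) / coup.volumes
    fac = 1.0 + (params.c_Mb / params.alpha) * smb_p
    P_new = P + dt * (div + (q - sink) / params.alpha) / fac
    if chamber is not None and not chamber.is_control:
        P_new[:, :, 0][chamber.mask(geometry.grid)] = chamber.outlet_po2
    if not np.all(np.isfinite(P_new)) or P_new.min() < -1e-9:
        bad = np.argwhere(~np.isfinite(P_new) | (P_new < -1e-9))
        raise StabilityError(
            f"tissue update unstable at dt={dt:g}", dt=dt,
            location=tuple(bad[0]) if len(bad) else None)
    return SimulationState(P=P_new, S=state.S.copy(), t=state.t + dt, j=j)


def capillary_step(state: SimulationState, geometry: NetworkGeometry,
                   params: TransportParams, dt: float,
                   kappa_eff: Optional[np.ndarray] = None) -> SimulationState:
    """One explicit upwind update of every vessel's saturation profile."""
    coup = get_coupling(geometry)
    nv, nseg = geometry.n_vessels, geometry.n_segments
    if kappa_eff is None:
        kappa_eff = kappa_effective(geometry, params)
    dy = geometry.dy_cm
    S = state.S
    Sc = np.clip(S, 1e-12, 1.0 - 1e-12)
    Pb = _hill_inv_raw(Sc, params)
    slope = hill_inverse_slope(Sc, params)
    Pw = sample_wall_po2(state.P, coup, nv, nseg)
    j = kappa_eff[:, None] * (Pb - Pw)
    S_prev = np.concatenate([coup.S_in[:, None], S[:, :-1]], axis=1)
    adv = -coup.velocity[:, None] * (params.C_tilde
                                     + params.alpha_b_tilde * slope) \
        * (S - S_prev) / dy
    sink = (2.0 / coup.radius_cm[:, None]) * j
    dS = dt * (adv - sink) / (params.C + params.alpha_b * slope)
    S_new = S + dS
    if not np.all(np.isfinite(S_new)) or S_new.min() < -1e-9 or S_new.max() > 1.0:
        raise StabilityError(f"capillary update unstable at dt={dt:g}", dt=dt)
    return SimulationState(P=state.P, S=np.clip(S_new, 0.0, 1.0 - 1e-12),
                           t=state.t, j=j)


# ---------------------------------------------------------------------------
# steady upwind vessel march (accelerated mode)
# ---------------------------------------------------------------------------

def march_vessels_steady(Pw: np.ndarray, geometry: NetworkGeometry,
                         params: TransportParams,
                         kappa_eff: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady state of the upwind vessel balance for a frozen wall PO2.

    Solves, segment by segment in the flow direction, the nonlinear
    fixed-point equation of the explicit upwind update

        u (C~ + a~_b Pb'(S_i)) (S_i - S_{i-1})/dy + (2 kappa / R)(Pb(S_i) - Pw_i) = 0

    by vectorized bisection (monotone in S_i), so the accelerated solver
    shares the exact discrete fixed point of :func:`capillary_step`.

    Returns (S, Pb, j) with shapes (n_vessels, n_segments).
    """
    nv, nseg = Pw.shape
    dy = geometry.dy_cm
    coup = get_coupling(geometry)
    u = coup.velocity
    R = coup.radius_cm
    S = np.empty((nv, nseg))
    S_prev = coup.S_in.copy()

    def g(Si, Sprev, Pwi):
        Sc = np.clip(Si, 1e-12, 1 - 1e-12)
        slope = _hill_inv_raw(Sc, params) / (params.n_hill * Sc * (1 - Sc))
        return (u * (params.C_tilde + params.alpha_b_tilde * slope)
                * (Si - Sprev) / dy
                + (2.0 * kappa_eff / R) * (_hill_inv_raw(Sc, params) - Pwi))

    for i in range(nseg):
        lo = np.full(nv, 1e-9)
        hi = np.full(nv, 1.0 - 1e-9)
        g_lo = g(lo, S_prev, Pw[:, i])
        # root is bracketed: g(0+) < 0 (advection of any positive inlet plus
        # O2 uptake), g(1-) -> +inf (blood PO2 diverges)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            g_mid = g(mid, S_prev, Pw[:, i])
            take_lo = (g_mid > 0) == (g_lo > 0)
            lo = np.where(take_lo, mid, lo)
            g_lo = np.where(take_lo, g_mid, g_lo)
            hi = np.where(take_lo, hi, mid)
        S[:, i] = 0.5 * (lo + hi)
        S_prev = S[:, i]
    Sc = np.clip(S, 1e-12, 1 - 1e-12)
    Pb = _hill_inv_raw(Sc, params)
    j = kappa_eff[:, None] * (Pb - Pw)
    return S, Pb, j
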