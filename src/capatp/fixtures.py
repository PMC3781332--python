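"""Reduced geometries and analytic oracles for fast validation.

Every solver path in the package is exercisable in seconds through these
fixtures; the oracles are closed forms (slab with zero-order consumption,
Krogh-Erlang annulus, exponential ATP relaxation), entirely independent of
the finite-volume solvers they check. The model is deterministic, so the
fixtures carry no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .chamber import ChamberCondition
from .errors import DomainError
from .geometry import (GridSpec, LayoutSpec, NetworkGeometry, TissueGrid,
                       Vessel)
from .params import AtpParams, TransportParams, CM_PER_UM
from .atp import atp_profile_oracle


@dataclass
class FixtureSpec:
    """A runnable reduced configuration plus its oracle."""

    name: str
    geometry: NetworkGeometry
    params: TransportParams
    chamber: ChamberCondition
    oracle: Optional[Callable] = None
    oracle_kind: str = "closed form"
    notes: str = ""


def make_slab_oracle(P0: float = 50.0, M0: Optional[float] = None,
                     L_um: float = 60.0, h_um: float = 2.0,
                     params: Optional[TransportParams] = None) -> FixtureSpec:
    """1D consuming slab: z = 0 clamped at P0, far face zero-flux.

    With myoglobin off and P >> P_cr the steady profile is the parabola
    P(z) = P0 - (M0/(D alpha)) (L z - z^2/2). Errors out if the slab would
    go anoxic (caller should shrink L).
    """
    params = (params or TransportParams()).replace(c_Mb=0.0)
    if M0 is not None:
        params = params.replace(M0=M0)
    k = params.M0 / (params.D * params.alpha)
    L_cm = L_um * CM_PER_UM
    p_min = P0 - 0.5 * k * L_cm ** 2
    if p_min < 5.0 * params.P_cr:
        raise DomainError(
            f"slab goes (nearly) anoxic (min P = {p_min:.2f} mmHg); "
            "shrink L or M0")
    grid = TissueGrid(Lx_um=4 * h_um, Ly_um=4 * h_um, Lz_um=L_um, h_um=h_um)
    geom = NetworkGeometry(grid, [])
    chamber = ChamberCondition(shape="full", outlet_po2=P0)

    def oracle(z_um):
        z = np.asarray(z_um, dtype=float) * CM_PER_UM
        return P0 - k * (L_cm * z - 0.5 * z ** 2)

    return FixtureSpec(name="slab", geometry=geom, params=params,
                       chamber=chamber, oracle=oracle,
                       notes=f"parabolic profile, min P {p_min:.2f} mmHg")


def make_single_capillary_fixture(box_um: float = 60.0, L_um: float = 100.0,
                                  R_um: float = 6.0, h_um: float = 2.0,
                                  M0: float = 3.0e-3,
                                  S_in: float = 0.8,
                                  kappa: float = 1.0e-3) -> FixtureSpec:
    """Single centered capillary: Krogh-Erlang validation limit.

    Myoglobin is off and consumption is strong enough that the radial drop
    is well above discretization noise; the large kappa and a high blood
    velocity pin the wall PO2 near blood PO2 and keep the axial SO2 drop
    small, as the Krogh picture assumes. A square box cannot reproduce the
    annulus exactly (corner tissue consumes too), so the oracle uses the
    equal-cross-sectional-area Krogh radius R_t = s/sqrt(pi) and is meant
    for comparison at radii inside the inscribed region, anchored at the
    first resolved radius.
    """
    params = TransportParams().replace(c_Mb=0.0, M0=M0, kappa=kappa,
                                       S_in=S_in, R_cap_um=R_um,
                                       v_rbc=0.2)
    grid = TissueGrid(Lx_um=box_um, Ly_um=L_um, Lz_um=box_um, h_um=h_um)
    vessel = Vessel(id=1, kind="capillary", radius_um=R_um,
                    x_um=box_um / 2, z_um=box_um / 2,
                    velocity_cm_s=params.v_rbc, S_in=S_in)
    geom = NetworkGeometry(grid, [vessel])
    chamber = ChamberCondition(shape="none", outlet_po2=None)
    R_cm = R_um * CM_PER_UM
    Rt_cm = (box_um / np.sqrt(np.pi)) * CM_PER_UM
    k = M0 / (params.D * params.alpha)

    def oracle(r_um, r_anchor_um, P_anchor):
        """Krogh-Erlang profile anchored at (r_anchor, P_anchor)."""
        r = np.asarray(r_um, dtype=float) * CM_PER_UM
        ra = r_anchor_um * CM_PER_UM

        def prof(rr):
            return k * (rr ** 2 - R_cm ** 2) / 4.0 \
                - k * Rt_cm ** 2 / 2.0 * np.log(rr / R_cm)
        anoxic_min = P_anchor + (prof(Rt_cm) - prof(ra))
        if anoxic_min < 0:
            raise DomainError("Krogh annulus goes anoxic; reduce M0 or box")
        return P_anchor + (prof(r) - prof(ra))

    return FixtureSpec(name="krogh", geometry=geom, params=params,
                       chamber=chamber, oracle=oracle,
                       notes=f"equal-area Krogh radius {Rt_cm / CM_PER_UM:.1f} um")


def make_atp_profile_oracle(S_const: float = 0.65, R_um: float = 2.0,
                            params: Optional[TransportParams] = None,
                            atp_params: Optional[AtpParams] = None):
    """Closed-form steady ATP profile for a constant-saturation vessel.

    Returns (oracle(y_um) -> mol/cm^3, A_inf, lambda_um).
    """
    if not 0 <= S_const <= 1:
        raise DomainError("saturation must lie in [0, 1]")
    params = params or TransportParams()
    atp_params = atp_params or AtpParams()
    R_cm = R_um * CM_PER_UM
    from .atp import atp_decay_length_cm, atp_equilibrium
    a_inf = atp_equilibrium(S_const, R_cm, params, atp_params)
    lam_um = atp_decay_length_cm(R_cm, params.v_rbc, params, atp_params) \
        / CM_PER_UM

    def oracle(y_um):
        return atp_profile_oracle(np.asarray(y_um) * CM_PER_UM, S_const,
                                  R_cm, params.v_rbc, params, atp_params)

    return oracle, a_inf, lam_um


# ---------------------------------------------------------------------------
# reduced network fixtures
# ---------------------------------------------------------------------------

def mini_layout() -> LayoutSpec:
    """One 12-capillary double row (16/33 um depths) across a 108 um width."""
    return LayoutSpec(n_double_rows=1, per_subrow=6, x_pitch_um=18.0,
                      x0_shallow_um=4.5, x0_deep_um=13.5)


def mini_grid(h_um: float = 4.0) -> GridSpec:
    return GridSpec(Lx_um=108.0, Ly_um=266.0, Lz_um=100.0, h_um=h_um)


def make_mini_network(h_um: float = 4.0, params: Optional[TransportParams] = None
                      ) -> NetworkGeometry:
    """Reduced network keeping the surface-vs-depth contrast at ~1% of full cost."""
    from .geometry import build_capillary_array
    return build_capillary_array(mini_grid(h_um), mini_layout(), params)


def make_tiny_network(h_um: float = 4.0, params: Optional[TransportParams] = None
                      ) -> NetworkGeometry:
    """4 capillaries in a small box; cheap enough for pseudo-time marching."""
    from .geometry import build_capillary_array
    layout = LayoutSpec(n_double_rows=1, per_subrow=2, x_pitch_um=18.0,
                        x0_shallow_um=9.0, x0_deep_um=18.0)
    grid = GridSpec(Lx_um=44.0, Ly_um=120.0, Lz_um=60.0, h_um=h_um)
    return build_capillary_array(grid, layout, params)


def reference_grid(h_um: float = 2.0) -> GridSpec:
    """The full published tissue box (7,304,853 nodes at h = 2 um)."""
    return GridSpec(Lx_um=216.0, Ly_um=532.0, Lz_um=500.0, h_um=h_um)


FIXTURES = {
    "slab": lambda: make_slab_oracle(),
    "krogh": lambda: make_single_capillary_fixture(),
    "mini": lambda: FixtureSpec(
        name="mini", geometry=make_mini_network(),
        params=TransportParams(),
        chamber=ChamberCondition(shape="none", outlet_po2=None),
        notes="12-capillary reduced network, zero-flux control"),
    "tiny": lambda: FixtureSpec(
        name="tiny", geometry=make_tiny_network(),
        params=TransportParams(),
        chamber=ChamberCondition(shape="none", outlet_po2=None),
        notes="4-capillary box for pseudo-time cross-checks"),
}
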