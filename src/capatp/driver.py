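"""Run coupled O2 + ATP solves to steady state and manage run matrices.

Two routes to the steady state are provided and share one discrete fixed
point: the accelerated elliptic Picard solver (default, used for
production grids) and explicit pseudo-time marching (the literal
time-dependent scheme; practical for reduced fixtures and used to
cross-check the accelerated mode). ATP is solved after the oxygen field
has converged — nothing in the O2 problem depends on ATP, so the
sequential solve is exact at steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .atp import atp_steady
from .chamber import ChamberCondition
from .errors import ConvergenceError
from .geometry import NetworkGeometry
from .elliptic import SteadyOxygenSolver, o2_balance
from .oxygen import (SimulationState, capillary_step, get_coupling,
                     kappa_effective, stable_dt, tissue_step)
from .params import AtpParams, TransportParams

logger = logging.getLogger("capatp")


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical controls for the steady-state drivers."""

    method: str = "elliptic"        # "elliptic" | "pseudo_time"
    tol_P: float = 1.0e-3           # mmHg, max field change per outer pass / 1 s
    tol_S: float = 1.0e-5           # max saturation change
    tol_integral: float = 1.0e-4    # relative change of monitored integrals
    max_outer: int = 300            # elliptic Picard iterations
    cg_rtol: float = 1.0e-7
    cg_maxiter: int = 2000
    preconditioner: str = "dct"     # "dct" | "jacobi" | "none"
    relax: float = 1.0              # Picard mixing parameter (Anderson beta)
    anderson_memory: int = 4        # 0 disables Anderson acceleration
    dt_safety: float = 0.2          # explicit stability safety factor
    max_time_s: float = 400.0       # pseudo-time budget (simulated seconds)
    check_window_s: float = 1.0     # pseudo-time convergence window
    wall_index_correction: bool = True

    def replace(self, **kw) -> "NumericsConfig":
        return replace(self, **kw)


@dataclass
class SteadyStateResult:
    """Converged oxygen + ATP state with provenance metadata."""

    geometry: NetworkGeometry
    params: TransportParams
    atp_params: AtpParams
    chamber: ChamberCondition
    state: SimulationState
    atp: np.ndarray               # (n_vessels, n_segments), mol/cm^3
    residual_log: list
    converged: bool
    meta: dict = field(default_factory=dict)

    @property
    def P(self) -> np.ndarray:
        return self.state.P

    @property
    def S(self) -> np.ndarray:
        return self.state.S

    def blood_po2(self) -> np.ndarray:
        return self.state.blood_po2(self.params)

    def o2_balance(self) -> dict:
        return o2_balance(self.geometry, self.params, self.chamber, self.state)


def _atp_probe(geometry, params, atp_params):
    coup = get_coupling(geometry)
    seg_vol = np.pi * coup.radius_cm[:, None] ** 2 * geometry.dy_cm

    def probe(S):
        return float(np.sum(atp_steady(S, geometry, params, atp_params)
                            * seg_vol))
    return probe


def run_steady_state(geometry: NetworkGeometry, params: TransportParams,
                     chamber: ChamberCondition,
                     numerics: Optional[NumericsConfig] = None,
                     atp_params: Optional[AtpParams] = None,
                     initial: Optional[SimulationState] = None) -> SteadyStateResult:
    """Solve the coupled O2 problem to steady state, then the ATP profiles.

    Raises :class:`ConvergenceError` (carrying the residual trace) if the
    iteration budget is exhausted.
    """
    numerics = numerics or NumericsConfig()
    atp_params = atp_params or AtpParams()
    probe = _atp_probe(geometry, params, atp_params)
    if numerics.method == "elliptic":
        solver = SteadyOxygenSolver(geometry, params, chamber, numerics)
        state, log = solver.solve(init=initial, atp_probe=probe)
    elif numerics.method == "pseudo_time":
        state, log = _run_pseudo_time(geometry, params, chamber, numerics,
                                      atp_params, initial)
    else:
        raise ValueError(f"unknown method {numerics.method!r}")
    atp = atp_steady(state.S, geometry, params, atp_params)
    result = SteadyStateResult(
        geometry=geometry, params=params, atp_params=atp_params,
        chamber=chamber, state=state, atp=atp, residual_log=log,
        converged=True,
        meta={"geometry": geometry.fingerprint(),
              "chamber": chamber.describe(),
              "method": numerics.method})
    if geometry.n_vessels:
        logger.info("steady state (%s): exit SO2 range %.3f-%.3f",
                    chamber.describe(), state.S[:, -1].min(),
                    state.S[:, -1].max())
    return result


def _run_pseudo_time(geometry, params, chamber, numerics, atp_params, initial):
    """Explicit marching of the literal time-dependent equations."""
    g = geometry.grid
    coup = get_coupling(geometry)
    keff = kappa_effective(geometry, params,
                           correction=numerics.wall_index_correction)
    dt = stable_dt(geometry, params, numerics.dt_safety)
    nseg = geometry.n_segments
    S0 = (np.tile(coup.S_in[:, None], (1, nseg))
          if geometry.n_vessels else np.zeros((0, nseg)))
    if initial is not None:
        S_init = initial.S.copy() if initial.S.shape == S0.shape else S0
        state = SimulationState(P=initial.P.copy(), S=S_init)
    else:
        state = SimulationState(P=np.full(g.shape, 25.0), S=S0)
    if chamber is not None and not chamber.is_control:
        state.P[:, :, 0][chamber.mask(g)] = chamber.outlet_po2
    log = []
    window = max(int(np.ceil(numerics.check_window_s / dt)), 1)
    probe = _atp_probe(geometry, params, atp_params)
    P_ref = state.P.copy()
    S_ref = state.S.copy()
    int_ref = None
    n_steps = int(np.ceil(numerics.max_time_s / dt))
    for step in range(1, n_steps + 1):
        state = tissue_step(state, geometry, params, chamber, dt,
                            kappa_eff=keff)
        if geometry.n_vessels:
            state = capillary_step(state, geometry, params, dt,
                                   kappa_eff=keff)
        if step % window == 0:
            dP = float(np.max(np.abs(state.P - P_ref)))
            dS = float(np.max(np.abs(state.S - S_ref))) \
                if geometry.n_vessels else 0.0
            cons = float(np.sum(
                np.where(coup.consuming,
                         params.M0 * state.P / (state.P + params.P_cr), 0.0)
                * coup.volumes))
            atp_tot = probe(state.S) if geometry.n_vessels else 0.0
            integrals = np.array([cons, atp_tot])
            if int_ref is not None:
                dint = float(np.max(np.abs(integrals - int_ref)
                                    / np.maximum(np.abs(int_ref), 1e-300)))
            else:
                dint = np.inf
            log.append({"t": state.t, "dP": dP, "dS": dS, "dint": dint,
                        "consumption": cons, "atp_total": atp_tot})
            logger.debug("pseudo-time t=%.2f s dP=%.3g dS=%.3g", state.t, dP, dS)
            if dP < numerics.tol_P and dS < numerics.tol_S \
                    and dint < numerics.tol_integral:
                return state, log
            P_ref = state.P.copy()
            S_ref = state.S.copy()
            int_ref = integrals
    raise ConvergenceError(
        f"pseudo-time march did not settle within {numerics.max_time_s:g} "
        f"simulated seconds", residual_log=log)


def run_condition_matrix(geometry: NetworkGeometry, params: TransportParams,
                         conditions: Sequence[ChamberCondition],
                         numerics: Optional[NumericsConfig] = None,
                         atp_params: Optional[AtpParams] = None) -> list:
    """Run the control plus every perturbed condition.

    The first condition must be the zero-flux control; perturbed runs are
    warm-started from the control state (the fixed point is unique per
    condition, so run order does not affect results). Per-run failures are
    recorded without aborting the matrix; failed cells carry the exception
    in place of a result.
    """
    if not conditions or not conditions[0].is_control:
        raise ValueError("the first condition must be the zero-flux control")
    results = []
    control = run_steady_state(geometry, params, conditions[0],
                               numerics, atp_params)
    results.append(control)
    for cond in conditions[1:]:
        try:
            results.append(run_steady_state(
                geometry, params, cond, numerics, atp_params,
                initial=control.state))
        except Exception as exc:  # propagate per-run errors as cells
            logger.warning("condition %s failed: %s", cond.describe(), exc)
            results.append(exc)
    return results


def calibrate_kappa(geometry: NetworkGeometry, params: TransportParams,
                    target_surface_so2: float = 0.50,
                    surface_depth_um: float = 16.0,
                    bounds: tuple[float, float] = (1.0e-5, 6.0e-5),
                    tol_so2: float = 0.005, max_runs: int = 8,
                    numerics: Optional[NumericsConfig] = None):
    """Adjust kappa so the zero-flux control reproduces the target exit SO2.

    Mean venular-end SO2 of the surface capillaries decreases monotonically
    in kappa (stronger exchange desaturates faster), so a bracketing secant
    search suffices. Returns (kappa, log of (kappa, surface SO2) pairs).
    """
    control = ChamberCondition(shape="none", outlet_po2=None)
    surf = [geometry.vessel_pos(i)
            for i in geometry.vessels_at_depth(surface_depth_um)]
    if not surf:
        raise ValueError("no vessels at the requested surface depth")
    log = []
    state = None

    def evaluate(kappa):
        nonlocal state
        p = params.replace(kappa=kappa)
        res = run_steady_state(geometry, p, control, numerics,
                               initial=state)
        state = res.state
        so2 = float(np.mean(res.S[surf, -1]))
        log.append((kappa, so2))
        logger.info("calibrate kappa=%.3e -> surface exit SO2 %.4f", kappa, so2)
        return so2

    lo, hi = bounds
    f_lo = evaluate(lo) - target_surface_so2
    if abs(f_lo) < tol_so2:
        return lo, log
    f_hi = evaluate(hi) - target_surface_so2
    if abs(f_hi) < tol_so2:
        return hi, log
    if f_lo * f_hi > 0:
        # target not bracketed: return the closer endpoint
        return (lo if abs(f_lo) < abs(f_hi) else hi), log
    a, b, fa, fb = lo, hi, f_lo, f_hi
    for _ in range(max_runs - 2):
        m = a - fa * (b - a) / (fb - fa)  # secant within the bracket
        m = min(max(m, a + 0.05 * (b - a)), b - 0.05 * (b - a))
        fm = evaluate(m) - target_surface_so2
        if abs(fm) < tol_so2:
            return m, log
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    best = min(log, key=lambda kv: abs(kv[1] - target_surface_so2))
    return best[0], log
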