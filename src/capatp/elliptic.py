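"""Accelerated steady-state oxygen solver.

Instead of marching the parabolic problem to its fixed point, this solver
iterates a Picard/Gauss-Seidel loop on the nonlinear elliptic system:

1. freeze the tissue field, march every vessel's steady upwind SO2 balance
   (shared discrete fixed point with the explicit scheme);
2. freeze the Michaelis-Menten rate (as a positive linear sink
   M0 P / (P_prev + P_cr)), the myoglobin facilitation coefficient and the
   blood PO2, and solve the resulting symmetric positive-definite
   finite-volume system for the tissue PO2 with preconditioned conjugate
   gradients (warm-started from the previous iterate);
3. repeat until field, saturation and integral (consumption / wall flux /
   ATP) changes fall below the configured tolerances.

The linearization keeps the system an M-matrix, so tissue PO2 stays
non-negative throughout, including anoxic regions. The preconditioner is
an FFT (DCT-II) inverse of the constant-coefficient Neumann Laplacian plus
the mean sink — exact for the dominant part of the operator, so CG
typically converges in a few tens of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sfft
from scipy.sparse.linalg import LinearOperator, cg

from .errors import ConvergenceError
from .geometry import NetworkGeometry
from .oxygen import (SimulationState, get_coupling, kappa_effective,
                     march_vessels_steady, mb_saturation_deriv,
                     sample_wall_po2)
from .params import TransportParams


def _gamma_abs(P, params):
    """Facilitated conductivity alpha*D + D_Mb c_Mb S_Mb'(P)."""
    return (params.alpha * params.D
            + params.D_Mb * params.c_Mb * mb_saturation_deriv(P, params))


class SteadyOxygenSolver:
    """Picard/CG solver for the steady tissue-vessel oxygen problem."""

    def __init__(self, geometry: NetworkGeometry, params: TransportParams,
                 chamber, numerics=None):
        from .driver import NumericsConfig
        self.geometry = geometry
        self.params = params
        self.chamber = chamber
        self.numerics = numerics or NumericsConfig()
        self.coup = get_coupling(geometry)
        self.kappa_eff = kappa_effective(
            geometry, params, correction=self.numerics.wall_index_correction)
        g = geometry.grid
        self.h = g.h_cm
        self.wx = g.node_widths_cm("x")
        self.wy = g.node_widths_cm("y")
        self.wz = g.node_widths_cm("z")
        self.V = self.coup.volumes
        # Dirichlet chamber nodes on the z = 0 face
        self.dir_mask = np.zeros(g.shape, dtype=bool)
        if chamber is not None and not chamber.is_control:
            self.dir_mask[:, :, 0] = chamber.mask(g)
        self.free = ~self.dir_mask
        nv, nseg = geometry.n_vessels, geometry.n_segments
        self.nv, self.nseg = nv, nseg
        if nv:
            self.entry_kappa = self.kappa_eff[self.coup.seg_global // nseg]
        # vessel diagonal (kappa * area scattered to nodes) is P-independent
        self.vessel_diag = np.zeros(g.n_nodes)
        if nv:
            np.add.at(self.vessel_diag, self.coup.node_index,
                      self.entry_kappa * self.coup.area_cm2)
        self.vessel_diag = self.vessel_diag.reshape(g.shape)

    # -- operator pieces ---------------------------------------------------
    def _face_conductances(self, P):
        gam = _gamma_abs(P, self.params)
        ayz = self.wy[None, :, None] * self.wz[None, None, :]
        axz = self.wx[:, None, None] * self.wz[None, None, :]
        axy = self.wx[:, None, None] * self.wy[None, :, None]
        gx = 0.5 * (gam[:-1] + gam[1:]) * ayz / self.h
        gy = 0.5 * (gam[:, :-1] + gam[:, 1:]) * axz / self.h
        gz = 0.5 * (gam[:, :, :-1] + gam[:, :, 1:]) * axy / self.h
        return gx, gy, gz

    def _sink_diag(self, P):
        p = self.params
        mlin = np.where(self.coup.consuming, p.M0 / (P + p.P_cr), 0.0) * self.V
        return mlin + self.vessel_diag

    def _apply(self, v, gx, gy, gz, diag):
        y = diag * v
        dx = gx * (v[:-1] - v[1:])
        y[:-1] += dx
        y[1:] -= dx
        dy = gy * (v[:, :-1] - v[:, 1:])
        y[:, :-1] += dy
        y[:, 1:] -= dy
        dz = gz * (v[:, :, :-1] - v[:, :, 1:])
        y[:, :, :-1] += dz
        y[:, :, 1:] -= dz
        return y

    def _make_preconditioner(self, gx, gy, gz, diag):
        shape = self.geometry.grid.shape
        # mean per-face conductance (interior faces have unit-area h*gamma)
        gm = (float(np.mean(gx)) + float(np.mean(gy)) + float(np.mean(gz))) / 3.0
        lam = []
        for n in shape:
            lam.append(2.0 * (1.0 - np.cos(np.pi * np.arange(n) / n)))
        lam3 = (lam[0][:, None, None] + lam[1][None, :, None]
                + lam[2][None, None, :]) * gm
        sigma = max(float(np.mean(diag[self.free])), 0.0) + 1e-30
        denom = lam3 + sigma
        free = self.free

        def apply_m(r):
            r3 = r.reshape(shape).copy()
            r3[~free] = 0.0
            x = sfft.idctn(sfft.dctn(r3, type=2, norm="ortho") / denom,
                           type=2, norm="ortho")
            x[~free] = 0.0
            return x.reshape(-1)

        return apply_m

    # -- one linear solve --------------------------------------------------
    @staticmethod
    def _mix(p, r, hist_p, hist_r, memory, beta):
        """Anderson(m) mixing step for the fixed-point iteration P -> G(P)."""
        hist_p.append(p.copy())
        hist_r.append(r.copy())
        if len(hist_p) > memory + 1:
            hist_p.pop(0)
            hist_r.pop(0)
        m = len(hist_p) - 1
        if m == 0 or memory == 0:
            return p + beta * r
        dR = np.stack([hist_r[i + 1] - hist_r[i] for i in range(m)], axis=1)
        dP = np.stack([hist_p[i + 1] - hist_p[i] for i in range(m)], axis=1)
        gamma, *_ = np.linalg.lstsq(dR, r, rcond=1e-10)
        return p + beta * r - (dP + beta * dR) @ gamma

    def _blood_sensitivity(self, S):
        """Local d(blood PO2)/d(wall PO2) per segment, in (0, 1).

        From the steady upwind segment balance with the upstream state
        frozen; used to make the linear solve semi-implicit in the blood
        (same fixed point, much faster outer convergence where the blood
        locally equilibrates with the tissue).
        """
        from .oxygen import hill_inverse_slope
        p = self.params
        slope = hill_inverse_slope(S, p)
        coup = self.coup
        dy = self.geometry.dy_cm
        adv = coup.velocity[:, None] * (p.C_tilde
                                        + p.alpha_b_tilde * slope) / dy
        exch = (2.0 * self.kappa_eff[:, None] / coup.radius_cm[:, None]) * slope
        return exch / (adv + exch)

    def solve_linear(self, P_old, Pb, rtol, lam=None, Pw_frozen=None):
        """Solve the frozen-coefficient system; returns the new field.

        ``lam``/``Pw_frozen`` enable the semi-implicit blood correction:
        the wall source becomes kappa*w*(Pb + lam*(Pw - Pw_frozen) - P),
        a symmetric positive-semidefinite rank-one term per segment.
        """
        shape = self.geometry.grid.shape
        gx, gy, gz = self._face_conductances(P_old)
        diag = self._sink_diag(P_old)
        coup = self.coup
        use_lam = lam is not None and self.nv
        if use_lam:
            lam_entry = lam.reshape(-1)[coup.seg_global]
            kw_lam = self.entry_kappa * coup.area_cm2 * lam_entry
            inv_area = 1.0 / coup.seg_area_cm2

            def lam_term(vflat):
                seg_mean = np.bincount(
                    coup.seg_global, weights=coup.area_cm2 * vflat[coup.node_index],
                    minlength=self.nv * self.nseg) * inv_area
                out = np.zeros(vflat.size)
                np.add.at(out, coup.node_index,
                          kw_lam * seg_mean[coup.seg_global])
                return out
        b = np.zeros(P_old.size)
        if self.nv:
            rhs_seg = Pb - (lam * Pw_frozen if use_lam else 0.0)
            np.add.at(b, self.coup.node_index,
                      self.entry_kappa * self.coup.area_cm2
                      * rhs_seg.reshape(-1)[self.coup.seg_global])
        b = b.reshape(shape)
        # fold Dirichlet values into the RHS and project
        x_dir = np.zeros(shape)
        if self.dir_mask.any():
            x_dir[self.dir_mask] = self.chamber.outlet_po2
            b = b - self._apply(x_dir, gx, gy, gz, diag)
            if use_lam:
                b = b + lam_term(x_dir.reshape(-1)).reshape(shape)
        b[self.dir_mask] = 0.0
        free = self.free

        def matvec(v):
            v3 = v.reshape(shape).copy()
            v3[~free] = 0.0
            y = self._apply(v3, gx, gy, gz, diag)
            if use_lam:
                y -= lam_term(v3.reshape(-1)).reshape(shape)
            y[~free] = 0.0
            return y.reshape(-1)

        n = P_old.size
        A = LinearOperator((n, n), matvec=matvec, dtype=float)
        if self.numerics.preconditioner == "dct":
            M = LinearOperator((n, n), matvec=self._make_preconditioner(
                gx, gy, gz, diag), dtype=float)
        elif self.numerics.preconditioner == "jacobi":
            jd = diag.copy()
            jd[:-1] += gx
            jd[1:] += gx
            jd[:, :-1] += gy
            jd[:, 1:] += gy
            jd[:, :, :-1] += gz
            jd[:, :, 1:] += gz
            inv = 1.0 / np.maximum(jd, 1e-300)
            inv[~free] = 0.0
            M = LinearOperator((n, n), matvec=lambda r: (r.reshape(shape)
                                                         * inv).reshape(-1),
                               dtype=float)
        else:
            M = None
        x0 = P_old.copy()
        x0[self.dir_mask] = 0.0
        x, info = cg(A, b.reshape(-1), x0=x0.reshape(-1), rtol=rtol,
                     atol=0.0, maxiter=self.numerics.cg_maxiter, M=M)
        P_new = x.reshape(shape)
        P_new[self.dir_mask] = 0.0
        P_new = P_new + x_dir
        np.maximum(P_new, 0.0, out=P_new)
        return P_new

    # -- outer loop --------------------------------------------------------
    def solve(self, init: Optional[SimulationState] = None,
              atp_probe=None):
        """Run the Picard loop; returns (state, residual_log).

        ``atp_probe(S) -> float`` optionally supplies the total-ATP integral
        monitored as one of the convergence criteria.
        """
        num = self.numerics
        g = self.geometry.grid
        S_default = np.tile(self.coup.S_in[:, None], (1, self.nseg)) \
            if self.nv else np.zeros((0, self.nseg))
        if init is not None:
            P = init.P.copy()
            # a warm start from another vessel network keeps only the field
            S = init.S.copy() if init.S.shape == S_default.shape else S_default
        else:
            P = np.full(g.shape, 25.0)
            S = S_default
        if self.dir_mask.any():
            P[self.dir_mask] = self.chamber.outlet_po2
        log = []
        prev_integrals = None
        j = np.zeros_like(S)
        hist_p: list[np.ndarray] = []   # Anderson history of iterates
        hist_r: list[np.ndarray] = []   # ... and fixed-point residuals
        for it in range(num.max_outer):
            if self.nv:
                Pw = sample_wall_po2(P, self.coup, self.nv, self.nseg)
                S_new, Pb, j = march_vessels_steady(
                    Pw, self.geometry, self.params, self.kappa_eff)
                lam = self._blood_sensitivity(S_new)
            else:
                S_new = S
                Pb = np.zeros_like(S)
                lam = None
                Pw = None
            rtol = num.cg_rtol if it else min(num.cg_rtol * 100, 1e-4)
            P_star = self.solve_linear(P, Pb, rtol=rtol, lam=lam,
                                       Pw_frozen=Pw)
            r = (P_star - P).reshape(-1)
            P_new = self._mix(P.reshape(-1), r, hist_p, hist_r,
                              num.anderson_memory,
                              num.relax).reshape(P.shape)
            np.maximum(P_new, 0.0, out=P_new)
            if self.dir_mask.any():
                P_new[self.dir_mask] = self.chamber.outlet_po2
            dP = float(np.max(np.abs(P_new - P)))
            dS = float(np.max(np.abs(S_new - S))) if self.nv else 0.0
            p = self.params
            cons = float(np.sum(np.where(self.coup.consuming,
                                         p.M0 * P_new / (P_new + p.P_cr), 0.0)
                                * self.V))
            wall = float(np.sum(j * self.coup.seg_area_cm2.reshape(
                self.nv, self.nseg))) if self.nv else 0.0
            atp_tot = float(atp_probe(S_new)) if atp_probe else 0.0
            integrals = np.array([cons, wall, atp_tot])
            if prev_integrals is not None:
                scale = np.maximum(np.abs(prev_integrals), 1e-300)
                dint = float(np.max(np.abs(integrals - prev_integrals) / scale))
            else:
                dint = np.inf
            log.append({"iter": it, "dP": dP, "dS": dS, "dint": dint,
                        "consumption": cons, "wall_flux": wall,
                        "atp_total": atp_tot})
            P, S = P_new, S_new
            prev_integrals = integrals
            if (dP < num.tol_P and dS < num.tol_S and dint < num.tol_integral
                    and it >= 1):
                state = SimulationState(P=P, S=S, t=float(it), j=j)
                return state, log
        raise ConvergenceError(
            f"steady-state Picard iteration did not converge in "
            f"{num.max_outer} iterations (dP={log[-1]['dP']:.3g}, "
            f"dS={log[-1]['dS']:.3g})", residual_log=log)


def o2_balance(geometry: NetworkGeometry, params: TransportParams, chamber,
               state: SimulationState, numerics=None) -> dict:
    """Discrete O2 bookkeeping of a converged state.

    Returns total consumption, total vessel wall flux, and net chamber
    influx (all ml O2/s); at steady state wall + chamber = consumption.
    """
    solver = SteadyOxygenSolver(geometry, params, chamber, numerics)
    P = state.P
    coup = solver.coup
    cons = float(np.sum(np.where(coup.consuming,
                                 params.M0 * P / (P + params.P_cr), 0.0)
                        * solver.V))
    nv, nseg = solver.nv, solver.nseg
    wall = 0.0
    if nv:
        Pw = sample_wall_po2(P, coup, nv, nseg)
        Pb = state.blood_po2(params)
        jmat = solver.kappa_eff[:, None] * (Pb - Pw)
        wall = float(np.sum(jmat * coup.seg_area_cm2.reshape(nv, nseg)))
    chamber_in = 0.0
    if solver.dir_mask.any():
        gx, gy, gz = solver._face_conductances(P)
        diag = solver._sink_diag(P)
        resid = solver._apply(P, gx, gy, gz, diag)
        src = np.zeros(P.size)
        if nv:
            np.add.at(src, coup.node_index,
                      solver.entry_kappa * coup.area_cm2
                      * Pb.reshape(-1)[coup.seg_global])
        resid -= src.reshape(P.shape)
        # at clamped nodes the imbalance is supplied by the chamber; the
        # frozen-M linearization at the converged P equals M(P) exactly
        chamber_in = float(np.sum(resid[solver.dir_mask]))
    return {"consumption": cons, "wall_flux": wall, "chamber_influx": chamber_in,
            "residual": cons - wall - chamber_in}
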