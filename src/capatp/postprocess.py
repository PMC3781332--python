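"""Derived metrics: exit values, ATP magnitudes, penetration depths.

All percent changes are relative changes versus the zero-flux control,
100*(test - control)/control (negative = decrease); absolute
percentage-point changes of SO2 are reported alongside since narrative
"dropped by X%" phrasing can be read either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atp import to_molar
from .driver import SteadyStateResult
from .errors import CapatpError
from .oxygen import get_coupling


def percent_change_vs_control(test_value, control_value):
    """Relative percent change 100*(test - control)/control."""
    control_value = np.asarray(control_value, dtype=float)
    if np.any(control_value == 0):
        raise CapatpError("percent change undefined for a zero control value")
    out = 100.0 * (np.asarray(test_value, dtype=float) - control_value) \
        / control_value
    return out if out.ndim else float(out)


def exit_values(result: SteadyStateResult,
                vessel_ids: Optional[Sequence[int]] = None,
                control: Optional[SteadyStateResult] = None) -> pd.DataFrame:
    """Venular-end SO2 and [ATP] per vessel (plus changes vs. a control)."""
    geom = result.geometry
    ids = list(vessel_ids) if vessel_ids is not None \
        else [v.id for v in geom.vessels]
    rows = []
    for vid in ids:
        pos = geom.vessel_pos(vid)
        v = geom.vessels[pos]
        row = {
            "vessel_id": vid, "kind": v.kind, "depth_um": v.depth_um,
            "exit_so2": float(result.S[pos, -1]),
            "exit_atp_molar": float(to_molar(result.atp[pos, -1])),
        }
        if control is not None:
            cpos = control.geometry.vessel_pos(vid)
            c_so2 = float(control.S[cpos, -1])
            c_atp = float(to_molar(control.atp[cpos, -1]))
            row["pct_change_so2"] = percent_change_vs_control(
                row["exit_so2"], c_so2)
            row["pct_change_atp"] = percent_change_vs_control(
                row["exit_atp_molar"], c_atp)
            row["delta_so2_points"] = 100.0 * (row["exit_so2"] - c_so2)
        rows.append(row)
    return pd.DataFrame(rows)


def total_atp_magnitude(result: SteadyStateResult,
                        vessel_subset: Optional[Sequence[int]] = None) -> float:
    """Lumen-integrated ATP content (moles) over the selected vessels."""
    geom = result.geometry
    if vessel_subset is None:
        positions = range(geom.n_vessels)
    else:
        subset = list(vessel_subset)
        if not subset:
            raise CapatpError("empty vessel subset")
        positions = [geom.vessel_pos(i) for i in subset]
    coup = get_coupling(geom)
    dy = geom.dy_cm
    total = 0.0
    for pos in positions:
        seg_vol = np.pi * coup.radius_cm[pos] ** 2 * dy      # cm^3
        total += float(np.sum(result.atp[pos] * seg_vol))    # mol
    return total


def penetration_depth(P_test: np.ndarray, P_control: np.ndarray, chamber,
                      grid, threshold_mmhg: float = 1.0):
    """Radial and axial reach (um) of a chamber perturbation.

    Both are measured in the width-depth cross-section through the outlet
    center — the plane the published 3D profiles are sliced on. Measuring
    there isolates diffusive spread; elsewhere the desaturated blood
    convects the perturbation far downstream of the outlet. Radial:
    largest lateral (x) distance from the outlet edge, on the exposed
    face, at which |P_test - P_control| >= threshold. Axial: largest
    depth above the outlet center at which the same holds. Returns (0, 0)
    when the fields differ nowhere above threshold.
    """
    if P_test.shape != P_control.shape:
        raise CapatpError("fields must share one grid")
    if threshold_mmhg <= 0:
        raise CapatpError("threshold must be positive")
    mask = chamber.mask(grid)
    if not mask.any():
        return 0.0, 0.0
    diff = np.abs(P_test - P_control)
    h = grid.h_um
    xc, yc = chamber.resolve_center(grid)
    ix = min(int(round(xc / h)), grid.Nx - 1)
    iy = min(int(round(yc / h)), grid.Ny - 1)
    # lateral spread along the surface line (y = yc, z = 0)
    row_mask = mask[:, iy]
    row_diff = diff[:, iy, 0]
    radial = 0.0
    if row_mask.any() and not row_mask.all():
        x = grid.axis_coords_um("x")
        edge_lo = x[row_mask].min()
        edge_hi = x[row_mask].max()
        lateral = np.maximum(edge_lo - x, x - edge_hi)  # <0 inside footprint
        outside = (~row_mask) & (row_diff >= threshold_mmhg) & (lateral > 0)
        if outside.any():
            radial = float(lateral[outside].max())
    # axial: column above the outlet center
    col = diff[ix, iy, :]
    above = np.nonzero(col >= threshold_mmhg)[0]
    axial = float(above.max() * h) if above.size else 0.0
    return radial, axial


@dataclass
class MetricsReport:
    """Per-vessel exit metrics plus network-level ATP magnitudes."""

    exit_table: pd.DataFrame
    atp_total_mol: float
    atp_total_control_mol: float
    atp_total_pct_change: float
    atp_arteriole_mol: Optional[float] = None
    atp_arteriole_frac_of_control: Optional[float] = None
    penetration_radial_um: Optional[float] = None
    penetration_axial_um: Optional[float] = None
    penetration_threshold_mmhg: float = 1.0

    def to_dict(self) -> dict:
        d = {
            "atp_total_mol": self.atp_total_mol,
            "atp_total_control_mol": self.atp_total_control_mol,
            "atp_total_pct_change": self.atp_total_pct_change,
            "atp_arteriole_mol": self.atp_arteriole_mol,
            "atp_arteriole_frac_of_control": self.atp_arteriole_frac_of_control,
            "penetration_radial_um": self.penetration_radial_um,
            "penetration_axial_um": self.penetration_axial_um,
            "penetration_threshold_mmhg": self.penetration_threshold_mmhg,
            "vessels": self.exit_table.to_dict(orient="records"),
        }
        return d


def matrix_summary(results, labeled_ids: Sequence[int],
                   threshold_mmhg: float = 1.0) -> pd.DataFrame:
    """Condition-by-vessel summary table for a run matrix.

    ``results`` is the output of :func:`capatp.run_condition_matrix`
    (control first; failed cells are skipped). One row per condition and
    labeled vessel: exit SO2, relative SO2/[ATP] changes, and the
    network ATPtot percent change.
    """
    control = results[0]
    rows = []
    for res in results:
        if isinstance(res, Exception):
            continue
        tab = exit_values(res, labeled_ids, control=control)
        tot_pct = percent_change_vs_control(
            total_atp_magnitude(res), total_atp_magnitude(control))
        for _, r in tab.iterrows():
            rows.append({
                "condition": res.chamber.describe(),
                "vessel_id": int(r.vessel_id),
                "exit_so2": r.exit_so2,
                "pct_change_so2": r.pct_change_so2,
                "pct_change_atp": r.pct_change_atp,
                "atp_total_pct_change": tot_pct,
            })
    return pd.DataFrame(rows)


def build_metrics(result: SteadyStateResult, control: SteadyStateResult,
                  vessel_ids: Optional[Sequence[int]] = None,
                  threshold_mmhg: float = 1.0) -> MetricsReport:
    """Assemble the standard report for one run against its control."""
    geom = result.geometry
    table = exit_values(result, vessel_ids, control=control)
    tot = total_atp_magnitude(result)
    tot_c = total_atp_magnitude(control)
    art_ids = [v.id for v in geom.vessels if v.kind == "arteriole"]
    art = total_atp_magnitude(result, art_ids) if art_ids else None
    rad = ax = None
    if not result.chamber.is_control:
        rad, ax = penetration_depth(result.P, control.P, result.chamber,
                                    geom.grid, threshold_mmhg)
    return MetricsReport(
        exit_table=table,
        atp_total_mol=tot,
        atp_total_control_mol=tot_c,
        atp_total_pct_change=percent_change_vs_control(tot, tot_c),
        atp_arteriole_mol=art,
        atp_arteriole_frac_of_control=(100.0 * art / tot_c
                                       if art is not None else None),
        penetration_radial_um=rad,
        penetration_axial_um=ax,
        penetration_threshold_mmhg=threshold_mmhg,
    )
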