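"""File output: vessel tables/profiles (CSV), PO2 fields (legacy VTK),
geometry and result containers (HDF5 + JSON summary)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .atp import to_molar
from .geometry import NetworkGeometry, TissueGrid, Vessel


def vessel_table(geometry: NetworkGeometry) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": v.id, "kind": v.kind, "x_um": v.x_um, "z_um": v.z_um,
         "radius_um": v.radius_um, "depth_um": v.depth_um,
         "velocity_cm_s": v.velocity_cm_s, "entrance_so2": v.S_in}
        for v in geometry.vessels])


def write_vessel_table(geometry: NetworkGeometry, path):
    vessel_table(geometry).to_csv(path, index=False)


def vessel_profiles(result) -> pd.DataFrame:
    """Per-segment axial profiles: SO2, blood PO2, wall flux, [ATP]."""
    geom = result.geometry
    dy_um = geom.grid.Ly_um / geom.n_segments
    Pb = result.blood_po2()
    j = result.state.j
    rows = []
    for pos, v in enumerate(geom.vessels):
        for s in range(geom.n_segments):
            rows.append({
                "vessel_id": v.id, "segment": s,
                "y_um": (s + 0.5) * dy_um,
                "SO2": float(result.S[pos, s]),
                "Pb_mmHg": float(Pb[pos, s]),
                "flux_mlO2_cm2_s": float(j[pos, s]) if j is not None else np.nan,
                "ATP_molar": float(to_molar(result.atp[pos, s])),
            })
    return pd.DataFrame(rows)


def write_vessel_profiles(result, path):
    vessel_profiles(result).to_csv(path, index=False)


def write_field_vtk(path, grid: TissueGrid, fields: dict):
    """ASCII legacy VTK STRUCTURED_POINTS file of node-centered scalars."""
    path = Path(path)
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("capatp steady-state field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {grid.Nx} {grid.Ny} {grid.Nz}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {grid.h_um} {grid.h_um} {grid.h_um}\n")
        f.write(f"POINT_DATA {grid.n_nodes}\n")
        for name, arr in fields.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; our arrays are (x, y, z) C-order
            flat = np.asarray(arr).transpose(2, 1, 0).reshape(-1)
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")


def save_geometry(geometry: NetworkGeometry, h5_path, json_path=None):
    """Self-describing container: /grid attrs, /vessels table, /wall_map."""
    g = geometry.grid
    with h5py.File(h5_path, "w") as f:
        gr = f.create_group("grid")
        for k, v in (("Lx_um", g.Lx_um), ("Ly_um", g.Ly_um),
                     ("Lz_um", g.Lz_um), ("h_um", g.h_um)):
            gr.attrs[k] = v
        tab = vessel_table(geometry)
        vg = f.create_group("vessels")
        for col in tab.columns:
            data = tab[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            vg.create_dataset(col, data=data)
        wm = f.create_group("wall_map")
        for pos, m in enumerate(geometry.wall_maps):
            sg = wm.create_group(str(geometry.vessels[pos].id))
            sg.create_dataset("node_index", data=m.node_index)
            sg.create_dataset("segment", data=m.segment)
            sg.create_dataset("area_cm2", data=m.area_cm2)
    if json_path:
        summary = {
            "grid": {"Lx_um": g.Lx_um, "Ly_um": g.Ly_um, "Lz_um": g.Lz_um,
                     "h_um": g.h_um, "nodes": g.n_nodes},
            "n_vessels": geometry.n_vessels,
            "fingerprint": geometry.fingerprint(),
            "vessels": vessel_table(geometry).to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(summary, indent=1))


def load_geometry(h5_path) -> NetworkGeometry:
    with h5py.File(h5_path, "r") as f:
        gr = f["grid"].attrs
        grid = TissueGrid(float(gr["Lx_um"]), float(gr["Ly_um"]),
                          float(gr["Lz_um"]), float(gr["h_um"]))
        vg = f["vessels"]
        n = vg["id"].shape[0]
        vessels = []
        for i in range(n):
            vessels.append(Vessel(
                id=int(vg["id"][i]),
                kind=vg["kind"][i].decode()
                if isinstance(vg["kind"][i], bytes) else str(vg["kind"][i]),
                radius_um=float(vg["radius_um"][i]),
                x_um=float(vg["x_um"][i]), z_um=float(vg["z_um"][i]),
                velocity_cm_s=float(vg["velocity_cm_s"][i]),
                S_in=float(vg["entrance_so2"][i])))
    return NetworkGeometry(grid, vessels)


def write_metrics_json(report, path):
    Path(path).write_text(json.dumps(report.to_dict(), indent=1, default=float))
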