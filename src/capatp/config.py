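"""YAML run configuration.

A config file mirrors the model's parameter names directly, e.g.::

    geometry:
      variant: array          # array | arteriole
      h_um: 4.0
    params:
      alpha: 3.89e-5
      M0: 1.5e-4
      kappa: 2.5e-5
    atp:
      C0: 1.4e-9
      C1: 0.891
      k_d: 2.0e-4
    arteriole:
      S_in: 0.65
    chamber:
      shape: circle           # none | full | circle | square | rectangle
      outlet_po2: 15
    numerics:
      method: elliptic
      tol_P: 1.0e-3
    output:
      directory: runs/circle15

Unknown keys raise, so typos in parameter names fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .chamber import make_chamber
from .driver import NumericsConfig
from .geometry import (ArterioleSpec, GridSpec, LayoutSpec,
                       build_arteriole_variant, build_capillary_array)
from .params import AtpParams, TransportParams


def _build(cls, section: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise KeyError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path, h_override=None):
    """Parse a YAML config into a run specification dict."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_config(raw, h_override=h_override)


def parse_config(raw: dict, h_override=None) -> dict:
    geo = dict(raw.get("geometry", {}))
    variant = geo.pop("variant", "array")
    h_um = geo.pop("h_um", None)
    if h_override is not None:
        h_um = h_override
    grid_kw = {k: geo.pop(k) for k in list(geo)
               if k in ("Lx_um", "Ly_um", "Lz_um")}
    if h_um is not None:
        grid_kw["h_um"] = h_um
    grid_spec = _build(GridSpec, grid_kw, "grid")
    layout_spec = _build(LayoutSpec, geo.pop("layout", {}), "layout")
    if geo:
        raise KeyError(f"unknown geometry keys: {sorted(geo)}")
    params = _build(TransportParams, raw.get("params", {}), "transport")
    atp_params = _build(AtpParams, raw.get("atp", {}), "ATP")
    cham = dict(raw.get("chamber", {"shape": "none"}))
    shape = cham.pop("shape", "none")
    outlet = cham.pop("outlet_po2", None)
    center = cham.pop("center_um", None)
    chamber = make_chamber(shape, outlet, center, **cham)
    numerics = _build(NumericsConfig, raw.get("numerics", {}), "numerics")
    art = _build(ArterioleSpec, raw.get("arteriole", {}), "arteriole")
    if variant == "array":
        geometry = build_capillary_array(grid_spec, layout_spec, params)
    elif variant == "arteriole":
        geometry = build_arteriole_variant(grid_spec, layout_spec, art, params)
    else:
        raise KeyError(f"unknown geometry variant {variant!r}")
    return {
        "geometry": geometry, "params": params, "atp_params": atp_params,
        "chamber": chamber, "numerics": numerics,
        "output": dict(raw.get("output", {})),
    }
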