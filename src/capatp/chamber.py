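"""Gas-exchange chamber boundary conditions on the bottom tissue face.

The chamber clamps PO2 on a shaped subset of the z = 0 face (full face,
circular micro-outlet, square micro-slit, or rectangular micro-slit);
everywhere else that face — like all other tissue faces — is zero-flux.
``shape="none"`` is the zero-flux control. A rectangular slit wider than
the tissue is clipped, so the default 1000 um-wide slit becomes a
full-width band 200 um long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError
from .geometry import TissueGrid

SUPPORTED_PO2_LEVELS = (15.0, 40.0, 150.0)

_DEFAULT_DIMS = {
    "circle": {"diameter_um": 100.0},
    "square": {"width_um": 200.0, "length_um": 200.0},
    "rectangle": {"width_um": 1000.0, "length_um": 200.0},
}


@dataclass(frozen=True)
class ChamberCondition:
    """Fixed-PO2 mask on the z = 0 face (or the zero-flux control)."""

    shape: str                      # none | full | circle | square | rectangle
    outlet_po2: Optional[float]     # mmHg; None for the zero-flux control
    center_um: Optional[tuple[float, float]] = None  # (x, y); None -> face midpoint
    diameter_um: float = 100.0
    width_um: float = 200.0         # x extent for square/rectangle
    length_um: float = 200.0        # y extent for square/rectangle

    @property
    def is_control(self) -> bool:
        return self.shape == "none"

    def describe(self) -> str:
        if self.is_control:
            return "zero-flux control"
        where = {"full": "full surface",
                 "circle": f"circle d={self.diameter_um:g} um",
                 "square": f"square {self.width_um:g}x{self.length_um:g} um",
                 "rectangle": f"rectangle {self.width_um:g}x{self.length_um:g} um",
                 }[self.shape]
        return f"{where} @ {self.outlet_po2:g} mmHg"

    def resolve_center(self, grid: TissueGrid) -> tuple[float, float]:
        if self.center_um is not None:
            return self.center_um
        return (grid.Lx_um / 2.0, grid.Ly_um / 2.0)

    def mask(self, grid: TissueGrid) -> np.ndarray:
        """Boolean (Nx, Ny) mask of clamped nodes on the z = 0 face."""
        if self.is_control:
            return np.zeros((grid.Nx, grid.Ny), dtype=bool)
        if self.shape == "full":
            return np.ones((grid.Nx, grid.Ny), dtype=bool)
        xc, yc = self.resolve_center(grid)
        x = grid.axis_coords_um("x")
        y = grid.axis_coords_um("y")
        if self.shape == "circle":
            r = self.diameter_um / 2.0
            if (xc + r < 0 or xc - r > grid.Lx_um
                    or yc + r < 0 or yc - r > grid.Ly_um):
                raise GeometryError("chamber outlet lies entirely outside the face")
            m = ((x[:, None] - xc) ** 2 + (y[None, :] - yc) ** 2) <= r * r
        elif self.shape in ("square", "rectangle"):
            hx = self.width_um / 2.0
            hy = self.length_um / 2.0
            if (xc + hx < 0 or xc - hx > grid.Lx_um
                    or yc + hy < 0 or yc - hy > grid.Ly_um):
                raise GeometryError("chamber outlet lies entirely outside the face")
            m = ((np.abs(x[:, None] - xc) <= hx)
                 & (np.abs(y[None, :] - yc) <= hy))
        else:
            raise GeometryError(f"unknown chamber shape {self.shape!r}")
        # a footprint that captures no nodes behaves as the zero-flux control
        return m


def make_chamber(shape: str, outlet_po2=None,
                 center_um: Optional[tuple[float, float]] = None,
                 **dims) -> ChamberCondition:
    """Build a chamber condition.

    ``outlet_po2=None`` (or ``shape="none"``) gives the zero-flux control.
    Unusual PO2 levels only warn — the levels are config-extensible.
    """
    shape = shape.lower()
    if shape not in ("none", "full", "circle", "square", "rectangle"):
        raise GeometryError(f"unknown chamber shape {shape!r}")
    if shape == "none" or outlet_po2 is None:
        return ChamberCondition(shape="none", outlet_po2=None)
    outlet_po2 = float(outlet_po2)
    if outlet_po2 < 0:
        raise GeometryError("outlet PO2 must be non-negative")
    if outlet_po2 not in SUPPORTED_PO2_LEVELS:
        warnings.warn(
            f"outlet PO2 {outlet_po2:g} mmHg is outside the standard levels "
            f"{SUPPORTED_PO2_LEVELS}", stacklevel=2)
    kw = dict(_DEFAULT_DIMS.get(shape, {}))
    kw.update(dims)
    return ChamberCondition(shape=shape, outlet_po2=outlet_po2,
                            center_um=center_um, **kw)
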