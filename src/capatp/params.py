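"""Physical parameters of the oxygen and ATP transport model.

All defaults are the rat extensor digitorum longus (EDL) values used
throughout the package: tissue solubility/diffusivity, Michaelis-Menten
consumption, myoglobin facilitation, the Hill oxyhemoglobin curve,
hematocrit-weighted blood capacities, and the erythrocyte ATP release /
endothelial degradation constants.

Unit conventions
----------------
* lengths in cm inside the solvers (geometry is specified in um),
* PO2 in mmHg, saturations as fractions in [0, 1],
* O2 amounts in ml O2, so solubilities are ml O2 ml^-1 mmHg^-1,
* ATP concentrations in mol/cm^3 internally, reported as mol/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


def _check_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class TransportParams:
    """Oxygen transport parameters (tissue + blood).

    The default mass-transfer coefficient ``kappa`` is the value calibrated
    so that the zero-flux control run of the full 72-capillary array
    reproduces venular-end saturations of ~50% for surface capillaries and
    ~40% for capillaries deeper than 100 um.
    """

    alpha: float = 3.89e-5      # tissue O2 solubility, ml O2 ml^-1 mmHg^-1
    D: float = 2.41e-5          # tissue O2 diffusivity, cm^2 s^-1
    M0: float = 1.5e-4          # maximal O2 consumption, ml O2 ml^-1 s^-1
    P_cr: float = 0.5           # Michaelis constant, mmHg
    c_Mb: float = 1.02e-2       # myoglobin O2-binding content, ml O2 ml^-1
    D_Mb: float = 3e-7          # myoglobin diffusivity, cm^2 s^-1
    P50_Mb: float = 5.3         # myoglobin half-saturation PO2, mmHg
    P50: float = 37.0           # hemoglobin half-saturation PO2, mmHg
    n_hill: float = 2.7         # Hill exponent
    C_Hb: float = 0.52          # hemoglobin O2 binding capacity, ml O2 ml^-1
    v_rbc: float = 1.45e-2      # mean capillary blood velocity, cm s^-1
    H_T: float = 0.19           # tube (volume-weighted) hematocrit
    H_D: float = 0.20           # discharge (flow-weighted) hematocrit
    alpha_cell: float = 3.38e-5  # erythrocyte O2 solubility
    alpha_pl: float = 2.82e-5    # plasma O2 solubility
    kappa: float = 2.5e-5       # wall mass-transfer coeff, ml O2 cm^-2 s^-1 mmHg^-1
    S_in: float = 0.65          # capillary entrance SO2 (fraction)
    # Capillary radius is not tabulated; the default is calibrated (once,
    # against the zero-flux control exit saturations ~50%/~40%) because it
    # sets the per-vessel O2 carrying capacity pi R^2 u C~. See docs/methods.
    R_cap_um: float = 2.9

    def __post_init__(self):
        _check_positive(self, ["alpha", "D", "P_cr", "D_Mb", "P50_Mb", "P50",
                               "C_Hb", "v_rbc", "alpha_cell", "alpha_pl",
                               "kappa", "R_cap_um"])
        if self.M0 < 0 or self.c_Mb < 0:
            raise ValueError("M0 and c_Mb must be non-negative")
        if not 0 < self.H_T < 1 or not 0 < self.H_D < 1:
            raise ValueError("hematocrits must lie in (0, 1)")
        if not self.n_hill > 1:
            raise ValueError("Hill exponent must exceed 1")
        if not 0 <= self.S_in < 1:
            raise ValueError("entrance SO2 must lie in [0, 1)")

    # Hematocrit-weighted blood capacities and solubilities.
    @property
    def C(self) -> float:
        """Volume-weighted blood O2 binding capacity H_T * C_Hb."""
        return self.H_T * self.C_Hb

    @property
    def C_tilde(self) -> float:
        """Flow-weighted blood O2 binding capacity H_D * C_Hb."""
        return self.H_D * self.C_Hb

    @property
    def alpha_b(self) -> float:
        """Volume-weighted blood O2 solubility."""
        return self.H_T * self.alpha_cell + (1.0 - self.H_T) * self.alpha_pl

    @property
    def alpha_b_tilde(self) -> float:
        """Flow-weighted blood O2 solubility."""
        return self.H_D * self.alpha_cell + (1.0 - self.H_D) * self.alpha_pl

    def replace(self, **kw) -> "TransportParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AtpParams:
    """Plasma ATP release/degradation parameters.

    Release from erythrocytes is linear in saturation, H_T*C0*(1 - C1*S);
    C1 < 1 keeps the release positive even at full saturation. Degradation
    by the endothelium acts as a wall sink of velocity k_d.
    """

    C0: float = 1.4e-9   # maximal release rate scale, mol s^-1 cm^-3
    C1: float = 0.891    # saturation dependence coefficient, dimensionless
    k_d: float = 2.0e-4  # endothelial degradation velocity, cm s^-1

    def __post_init__(self):
        _check_positive(self, ["C0", "C1", "k_d"])
        if not self.C1 < 1:
            raise ValueError("C1 must be < 1 so release stays positive at S = 1")

    def replace(self, **kw) -> "AtpParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


UM_PER_CM = 1.0e4
CM_PER_UM = 1.0e-4
MOL_PER_CM3_TO_MOLAR = 1.0e3  # mol/cm^3 -> mol/L
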