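"""Areal kelp-carbon export estimate.

Converts per-kelp detrital production into carbon exported past the shelf
edge per hectare of kelp forest per year:

    export = production [g FW / kelp / day]
             x density [kelp / m^2]
             x FW-to-DW ratio x carbon fraction of DW
             x 365 day/yr x 10^4 m^2/ha x exported fraction
             / 10^6 g/Mg                       [Mg C / ha / yr]

With the default parameters (2.15 g FW/kelp/day, 6.3 kelp/m^2, FW:DW 0.20,
30% carbon) and exported fractions of 0.17-0.29, the estimate spans
0.50-0.86 Mg C/ha/yr.  The estimate is linear in every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CarbonParams", "areal_carbon_export"]


@dataclass(frozen=True)
class CarbonParams:
    """Parameters of the areal carbon-export arithmetic."""

    production_g_fw_per_kelp_day: float = 2.15
    kelp_per_m2: float = 6.3
    fw_to_dw: float = 0.20
    carbon_fraction_dw: float = 0.30
    exported_fraction: float = 0.21
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if (self.production_g_fw_per_kelp_day <= 0 or self.kelp_per_m2 <= 0
                or self.days_per_year <= 0):
            raise ValueError("production, density and days/year must be positive")
        for name in ("fw_to_dw", "carbon_fraction_dw"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.exported_fraction < 0:
            raise ValueError("exported fraction must be >= 0")


def areal_carbon_export(params: CarbonParams = CarbonParams()) -> float:
    """Carbon exported per hectare of kelp forest per year (Mg C/ha/yr)."""
    g_c_per_m2_year = (params.production_g_fw_per_kelp_day
                       * params.kelp_per_m2
                       * params.fw_to_dw
                       * params.carbon_fraction_dw
                       * params.days_per_year)
    m2_per_ha = 1e4
    g_per_mg = 1e6
    return g_c_per_m2_year * m2_per_ha / g_per_mg * params.exported_fraction
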