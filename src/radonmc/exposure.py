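"""Radon exposure bookkeeping: working level (WL) and WL-month (WLM).

1 WL = 20.8 uJ/m^3 of potential alpha energy; 1 WLM is exposure to 1 WL
for a 170 h working month (3.54e-3 J h/m^3).  The mapping between the
simulation's alpha-emission density (emissions per 5 um^3 mucous section,
i.e. per um^2 of mucous footprint) and WLM is anchored to the reported
mine-exposure correspondence: 0.74 emissions per um^2 after 8 h under
5.7 WL.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExposureConversion:
    wl_uj_m3: float = 20.8
    hours_per_wlm: float = 170.0
    anchor_wl: float = 5.7
    anchor_hours: float = 8.0
    anchor_density: float = 0.74
    anchor_dose_gy: float = 5.29

    @property
    def wlm_j_h_m3(self) -> float:
        """1 WLM in J h/m^3 (= WL x 170 h)."""
        return self.wl_uj_m3 * 1e-6 * self.hours_per_wlm

    @property
    def wlm_per_unit_density(self) -> float:
        return (self.anchor_wl * self.anchor_hours / self.hours_per_wlm
                / self.anchor_density)


DEFAULT_CONVERSION = ExposureConversion()


def density_to_wlm(density: float,
                   conv: ExposureConversion = DEFAULT_CONVERSION) -> float:
    """WLM exposure producing the given alpha-emission density."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return conv.wlm_per_unit_density * density


def wlm_to_density(wlm: float,
                   conv: ExposureConversion = DEFAULT_CONVERSION) -> float:
    if wlm < 0:
        raise ValueError("exposure must be non-negative")
    return wlm / conv.wlm_per_unit_density


def density_to_dose(density: float, slope_gy_per_density: float) -> float:
    """Tissue dose from the fitted linear dose-density response."""
    return slope_gy_per_density * density
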