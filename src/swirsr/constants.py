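"""Wavelength bands, channel mapping, probe geometry, and water-absorption constants.

All lengths are in cm and all attenuation coefficients in cm^-1 throughout
the package.  The probe measures diffuse reflectance at two SWIR wavelengths
(1450 nm, 1650 nm) and two source-detector separations (0.45 cm, 0.70 cm)
through a 4 mm circular collection aperture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import DomainError, MissingConstantError

#: LED center wavelengths in nm.
WAVELENGTH_1450 = 1450
WAVELENGTH_1650 = 1650
WAVELENGTHS = (WAVELENGTH_1450, WAVELENGTH_1650)

#: Source-detector separations in cm.
RHO_CLOSE_CM = 0.45
RHO_FAR_CM = 0.70
SEPARATIONS: Mapping[str, float] = {"close": RHO_CLOSE_CM, "far": RHO_FAR_CM}

#: Physical channel wiring: channel id -> (wavelength nm, separation label).
#: Note the quirk: CH2 is the *far* 1650 nm channel and CH3 the far 1450 nm
#: channel, matching the physical LED placement around the aperture.
CHANNEL_MAP: Mapping[str, tuple[int, str]] = {
    "CH1": (WAVELENGTH_1450, "close"),
    "CH2": (WAVELENGTH_1650, "far"),
    "CH3": (WAVELENGTH_1450, "far"),
    "CH4": (WAVELENGTH_1650, "close"),
}


def channel_for(wavelength: int, separation: str,
                channel_map: Mapping[str, tuple[int, str]] = CHANNEL_MAP) -> str:
    """Return the channel id carrying (wavelength, separation)."""
    for ch, (wl, sep) in channel_map.items():
        if wl == wavelength and sep == separation:
            return ch
    raise MissingConstantError(f"no channel for ({wavelength} nm, {separation})")


@dataclass(frozen=True)
class ProbeGeometry:
    """Geometry of the contact probe and the simulated slab phantom.

    The acceptance half-angle of the collection tunnel is either given
    explicitly (degrees) or derived from the cylindrical tunnel geometry as
    ``atan(aperture_radius / tunnel_length)``.
    """

    rho_c: float = RHO_CLOSE_CM
    rho_f: float = RHO_FAR_CM
    aperture_diameter: float = 0.4
    tunnel_length: float = 0.5
    acceptance_half_angle_deg: float | None = None
    led_emitter_side: float = 0.1
    slab_x: float = 3.5
    slab_y: float = 3.5
    slab_z: float = 1.2
    n_medium: float = 1.33
    n_outside: float = 1.0

    def __post_init__(self):
        if self.rho_f <= self.rho_c:
            raise DomainError("rho_f must exceed rho_c")
        if self.aperture_diameter < 0:
            raise DomainError("aperture_diameter must be >= 0")
        if min(self.slab_x, self.slab_y, self.slab_z) <= 0:
            raise DomainError("slab dimensions must be positive")
        if self.n_medium < 1 or self.n_outside < 1:
            raise DomainError("refractive indices must be >= 1")
        half = self.acceptance_half_angle_rad
        if not (0 < half <= math.pi / 2):
            raise DomainError("acceptance half-angle must be in (0, 90] degrees")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def acceptance_half_angle_rad(self) -> float:
        if self.acceptance_half_angle_deg is not None:
            return math.radians(self.acceptance_half_angle_deg)
        if self.tunnel_length <= 0:
            return math.pi / 2
        return math.atan2(self.aperture_radius, self.tunnel_length)

    def rho(self, separation: str) -> float:
        try:
            return {"close": self.rho_c, "far": self.rho_f}[separation]
        except KeyError as exc:
            raise MissingConstantError(f"unknown separation {separation!r}") from exc


class WaterAbsorptionTable:
    """Tabulated liquid-water absorption coefficients, cm^-1, by wavelength (nm).

    Lookups are exact: asking for an untabulated wavelength raises
    :class:`MissingConstantError` rather than silently interpolating.
    """

    def __init__(self, entries: Mapping[float, float]):
        if not entries:
            raise DomainError("water absorption table is empty")
        for wl, mua in entries.items():
            if mua <= 0:
                raise DomainError(f"mu_a_water({wl}) must be positive, got {mua}")
        self._entries = dict(entries)
        if WAVELENGTH_1450 in self._entries and WAVELENGTH_1650 in self._entries:
            if self._entries[WAVELENGTH_1450] <= self._entries[WAVELENGTH_1650]:
                raise DomainError("expected mu_a_water(1450) > mu_a_water(1650)")

    @classmethod
    def from_packaged(cls) -> "WaterAbsorptionTable":
        with resources.files("swirsr.data").joinpath("water_absorption.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        return cls({int(r.wavelength_nm): float(r.mu_a_water_cm1) for r in df.itertuples()})

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted(self._entries))

    def mu_a(self, wavelength: float) -> float:
        try:
            return self._entries[wavelength]
        except KeyError:
            raise MissingConstantError(
                f"no tabulated water absorption at {wavelength} nm "
                f"(tabulated: {sorted(self._entries)})"
            ) from None


_DEFAULT_TABLE: WaterAbsorptionTable | None = None


def default_water_table() -> WaterAbsorptionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = WaterAbsorptionTable.from_packaged()
    return _DEFAULT_TABLE


def water_absorption(wavelength: float,
                     table: WaterAbsorptionTable | None = None) -> float:
    """Tabulated mu_a of liquid water at ``wavelength`` nm (cm^-1)."""
    table = table if table is not None else default_water_table()
    return table.mu_a(wavelength)


def assign_absorption(f_w: float, wavelength: float,
                      table: WaterAbsorptionTable | None = None) -> float:
    """Water-dominant absorption assignment: mu_a = f_w * mu_a_water(wavelength)."""
    if not 0.0 <= f_w <= 1.0:
        raise DomainError(f"water fraction must lie in [0, 1], got {f_w}")
    return f_w * water_absorption(wavelength, table)


def mus_from_musp(mu_s_prime: float, g: float) -> float:
    """Scattering coefficient from reduced scattering: mu_s = mu_s' / (1 - g)."""
    if not 0.0 <= g < 1.0:
        raise DomainError(f"anisotropy must lie in [0, 1), got {g}")
    if mu_s_prime < 0:
        raise DomainError(f"mu_s_prime must be >= 0, got {mu_s_prime}")
    return mu_s_prime / (1.0 - g)
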