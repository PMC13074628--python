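"""Synthetic measurement frames with known ground truth, plus packaged
fixtures of the phantom recipe and validation tables.

Frames emulate the acquisition model: per-channel gains, dark offsets, and
multiplicative/additive noise around a forward-model signal (diffusion
dipole by default, Monte Carlo optionally).  The reference frame sees a flat
unit "PTFE" signal through the same gains, with an optional per-channel
mismatch factor for systematic-bias studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import diffusion, mc, recipes
from .constants import (CHANNEL_MAP, ProbeGeometry, SEPARATIONS,
                        WaterAbsorptionTable, assign_absorption)
from .errors import DomainError
from .signals import ChannelReading, MeasurementFrame


@dataclass(frozen=True)
class SyntheticScenario:
    f_w_true: float
    mu_s_prime_true: dict[int, float]  # wavelength -> cm^-1
    channel_gains: dict[str, float] = field(default_factory=dict)
    dark_offsets: dict[str, float] = field(default_factory=dict)
    ref_mismatch: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.0
    additive_noise_v: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_w_true <= 1.0:
            raise DomainError("f_w_true must lie in [0, 1]")
        if self.noise_cv < 0 or self.additive_noise_v < 0:
            raise DomainError("noise levels must be >= 0")
        if any(g <= 0 for g in self.channel_gains.values()):
            raise DomainError("channel gains must be positive")

    def gain(self, ch: str) -> float:
        return self.channel_gains.get(ch, 1.0)

    def offset(self, ch: str) -> float:
        return self.dark_offsets.get(ch, 0.0)

    def mismatch(self, ch: str) -> float:
        return self.ref_mismatch.get(ch, 1.0)


def forward_signal(scenario: SyntheticScenario, wavelength: int, rho: float,
                   geometry: ProbeGeometry,
                   water_table: WaterAbsorptionTable | None = None,
                   forward: str = "diffusion", n_photons: int = 200_000,
                   mc_seed: int = 0, g: float = 0.9) -> float:
    """Noise-free detector signal for one (wavelength, separation) channel."""
    mu_a = assign_absorption(scenario.f_w_true, wavelength, water_table)
    musp = scenario.mu_s_prime_true[wavelength]
    if forward == "diffusion":
        n = geometry.n_medium / geometry.n_outside
        return diffusion.fluence_at(mu_a, musp, n, rho)
    if forward == "mc":
        props = mc.OpticalProperties.from_musp(mu_a, musp, g=g, n=geometry.n_medium)
        source = mc.SourceModel(center_offset=rho,
                                emitter_side=geometry.led_emitter_side)
        res = mc.simulate_channel(props, geometry, source, n_photons, seed=mc_seed)
        return res.p_det
    raise DomainError(f"unknown forward model {forward!r}")


def generate_frame(scenario: SyntheticScenario,
                   geometry: ProbeGeometry | None = None,
                   water_table: WaterAbsorptionTable | None = None,
                   forward: str = "diffusion",
                   **forward_kwargs) -> tuple[MeasurementFrame, MeasurementFrame]:
    """Generate paired (sample, reference) frames.  Deterministic per seed."""
    geometry = geometry or ProbeGeometry()
    rng = np.random.default_rng(scenario.seed)
    sample_readings: dict[str, ChannelReading] = {}
    ref_readings: dict[str, ChannelReading] = {}
    for ch, (wl, sep_label) in CHANNEL_MAP.items():
        rho = geometry.rho(sep_label)
        sig = forward_signal(scenario, wl, rho, geometry, water_table,
                             forward=forward, **forward_kwargs)
        gain = scenario.gain(ch)
        off = scenario.offset(ch)

        def noisy_on(level: float) -> ChannelReading:
            mult = 1.0 + scenario.noise_cv * rng.standard_normal()
            v_on = gain * level * mult + off \
                + scenario.additive_noise_v * rng.standard_normal()
            v_dark = off + scenario.additive_noise_v * rng.standard_normal()
            return ChannelReading(v_on=v_on, v_dark=v_dark)

        sample_readings[ch] = noisy_on(sig)
        ref_readings[ch] = noisy_on(1.0 * scenario.mismatch(ch))
    return (MeasurementFrame(role="sample", readings=sample_readings),
            MeasurementFrame(role="reference", readings=ref_readings))


def table1_fixture() -> list[recipes.PhantomRecipe]:
    """The eight packaged phantom recipes (verbatim masses)."""
    return recipes.packaged_recipes()


def table3_fixture() -> pd.DataFrame:
    """The eight packaged validation rows: per-gel Intralipid loading,
    LUT-inverted scattering, reference and recovered water fractions, and
    printed absolute percent error."""
    with resources.files("swirsr.data").joinpath("validation_results.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def table3_pairs() -> tuple[list[tuple[float, float]], list[int]]:
    """(f_w_true, f_w_hat) pairs and Intralipid-group labels, in table order."""
    df = table3_fixture()
    pairs = list(zip(df["f_w_true"].astype(float), df["f_w_hat"].astype(float)))
    return pairs, df["il_pct"].astype(int).tolist()
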