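"""Lookup tables mapping reduced scattering to detected fractions and
far/close spatial ratios, conditional on an assigned absorption.

A LUT is a list of :class:`LutEntry` records, one per (wavelength,
separation, mu_s') condition.  Ratio curves pair far and close entries at
the same grid point; starved pairs are dropped.  Inversion is log-domain
linear interpolation between bracketing grid nodes, with no extrapolation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import diffusion
from .constants import (ProbeGeometry, SEPARATIONS, WAVELENGTHS,
                        WaterAbsorptionTable, assign_absorption)
from .errors import DomainError, LowSNRError, MonotonicityError, OutOfRangeError
from .mc import (DEFAULT_MIN_COUNTS, OpticalProperties, SourceModel,
                 simulate_channel)

MU_S_PRIME_MIN = 0.05
MU_S_PRIME_MAX = 30.0


def default_grid(n: int = 40, lo: float = MU_S_PRIME_MIN,
                 hi: float = MU_S_PRIME_MAX) -> np.ndarray:
    """Log-spaced mu_s' grid over the sweep range [0.05, 30] cm^-1."""
    if not (MU_S_PRIME_MIN <= lo < hi <= MU_S_PRIME_MAX):
        raise DomainError(f"grid bounds must satisfy {MU_S_PRIME_MIN} <= lo < hi <= {MU_S_PRIME_MAX}")
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class LutEntry:
    wavelength: int
    rho: float
    mu_a_assigned: float
    mu_s_prime: float
    p_det: float
    detected_count: int
    launched: int
    starved: bool


@dataclass
class RatioCurve:
    """Far/close ratio versus mu_s' at one wavelength and assigned mu_a.

    ``ratio_se`` is a per-point relative-count standard-error estimate used
    by the noise-tolerant monotonicity check; it may be None for analytic
    (noise-free) curves.
    """

    wavelength: int
    mu_a_assigned: float
    mu_s_prime: np.ndarray
    ratio: np.ndarray
    ratio_se: np.ndarray | None = None
    dropped: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.mu_s_prime.size != self.ratio.size:
            raise DomainError("grid and ratio arrays must have equal length")
        if np.any(np.diff(self.mu_s_prime) <= 0):
            raise DomainError("mu_s_prime grid must be strictly ascending")
        if np.any(self.ratio <= 0):
            raise DomainError("ratio curve must be strictly positive")

    @property
    def dynamic_range(self) -> float:
        return float(self.ratio.max() - self.ratio.min())


def build_lut(fw_nominal: float, wavelengths: Sequence[int] = WAVELENGTHS,
              mu_s_prime_grid: np.ndarray | None = None,
              geometry: ProbeGeometry | None = None,
              n_photons: int = 1_000_000, seed: int = 0, g: float = 0.9,
              min_counts: int = DEFAULT_MIN_COUNTS,
              divergence_exponent: float = 1.0,
              water_table: WaterAbsorptionTable | None = None) -> list[LutEntry]:
    """Monte Carlo LUT: one entry per (wavelength, separation, mu_s').

    Absorption is held fixed per wavelength at mu_a = fw_nominal *
    mu_a_water(wavelength) while mu_s' is swept.  Each condition runs on an
    independent substream spawned from ``seed``.
    """
    geometry = geometry or ProbeGeometry()
    grid = np.asarray(default_grid() if mu_s_prime_grid is None else mu_s_prime_grid,
                      dtype=float)
    if np.any(grid < MU_S_PRIME_MIN) or np.any(grid > MU_S_PRIME_MAX):
        raise DomainError(f"grid must lie within [{MU_S_PRIME_MIN}, {MU_S_PRIME_MAX}]")
    conditions = [(wl, label) for wl in wavelengths for label in ("far", "close")]
    seeds = np.random.SeedSequence(seed).spawn(len(conditions) * grid.size)
    entries: list[LutEntry] = []
    k = 0
    for wl, label in conditions:
        mu_a = assign_absorption(fw_nominal, wl, water_table)
        rho = geometry.rho(label)
        for musp in grid:
            props = OpticalProperties.from_musp(mu_a, float(musp), g=g,
                                                n=geometry.n_medium)
            source = SourceModel(center_offset=rho,
                                 emitter_side=geometry.led_emitter_side,
                                 divergence_exponent=divergence_exponent)
            sub_seed = int(seeds[k].generate_state(1)[0])
            k += 1
            res = simulate_channel(props, geometry, source, n_photons,
                                   seed=sub_seed, min_counts=min_counts)
            entries.append(LutEntry(
                wavelength=wl, rho=rho, mu_a_assigned=mu_a,
                mu_s_prime=float(musp), p_det=res.p_det,
                detected_count=res.detected_count, launched=res.launched,
                starved=res.starved,
            ))
    return entries


def ratio_curve(entries: Iterable[LutEntry], wavelength: int,
                geometry: ProbeGeometry | None = None) -> RatioCurve:
    """Pair far/close entries at one wavelength into a ratio curve.

    Starved pairs (or pairs with a zero close signal) are dropped and
    reported via ``curve.dropped``.
    """
    geometry = geometry or ProbeGeometry()
    far = {e.mu_s_prime: e for e in entries
           if e.wavelength == wavelength and math.isclose(e.rho, geometry.rho_f)}
    close = {e.mu_s_prime: e for e in entries
             if e.wavelength == wavelength and math.isclose(e.rho, geometry.rho_c)}
    grid = sorted(set(far) & set(close))
    if not grid:
        raise DomainError(f"no paired far/close entries at {wavelength} nm")
    mu_a = next(iter(far.values())).mu_a_assigned
    kept_mu, ratios, ses, dropped = [], [], [], []
    for musp in grid:
        ef, ec = far[musp], close[musp]
        if ef.starved or ec.starved or ec.p_det <= 0 or ef.p_det <= 0:
            dropped.append(musp)
            continue
        r = ef.p_det / ec.p_det
        # relative SE from detected counts (Poisson-like approximation)
        se = r * math.sqrt(1.0 / max(ef.detected_count, 1)
                           + 1.0 / max(ec.detected_count, 1))
        kept_mu.append(musp)
        ratios.append(r)
        ses.append(se)
    if not kept_mu:
        raise DomainError(f"all {wavelength} nm LUT pairs starved")
    return RatioCurve(wavelength=wavelength, mu_a_assigned=mu_a,
                      mu_s_prime=np.array(kept_mu), ratio=np.array(ratios),
                      ratio_se=np.array(ses), dropped=dropped)


def ratio_curve_from_diffusion(fw_nominal: float, wavelength: int,
                               mu_s_prime_grid: np.ndarray,
                               geometry: ProbeGeometry | None = None,
                               water_table: WaterAbsorptionTable | None = None
                               ) -> RatioCurve:
    """Analytic ratio curve from the dipole forward model (noise-free).

    Useful as a fast LUT substitute in closed-loop tests and for the
    fixed-nominal sensitivity mode.
    """
    geometry = geometry or ProbeGeometry()
    grid = np.asarray(mu_s_prime_grid, dtype=float)
    mu_a = assign_absorption(fw_nominal, wavelength, water_table)
    ratios = np.array([
        diffusion.model_ratio(fw_nominal, m, wavelength, geometry, water_table)
        for m in grid
    ])
    return RatioCurve(wavelength=wavelength, mu_a_assigned=mu_a,
                      mu_s_prime=grid, ratio=ratios, ratio_se=None)


def _pava(y: np.ndarray, increasing: bool) -> np.ndarray:
    """Pool-adjacent-violators projection onto monotonic sequences."""
    y = y.copy() if increasing else -y.copy()
    n = y.size
    level = y.astype(float)
    weight = np.ones(n)
    # block-merge implementation
    values, weights, sizes = [], [], []
    for v in level:
        values.append(v)
        weights.append(1.0)
        sizes.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            w = weights[-2] + weights[-1]
            v_new = (values[-2] * weights[-2] + values[-1] * weights[-1]) / w
            values[-2:] = [v_new]
            weights[-2:] = [w]
            sizes[-2:] = [sizes[-2] + sizes[-1]]
    out = np.concatenate([np.full(s, v) for v, s in zip(values, sizes)])
    return out if increasing else -out


def check_monotonic(curve: RatioCurve, se_factor: float = 2.0) -> RatioCurve:
    """Validate (and, within noise tolerance, repair) curve monotonicity.

    The trend direction is chosen by the better-fitting isotonic projection.
    If every adjustment the projection makes is within ``se_factor`` standard
    errors of the raw point, the smoothed curve is returned; otherwise
    :class:`MonotonicityError` is raised.  Noise-free curves must be strictly
    monotonic as-is.
    """
    r = curve.ratio
    if r.size < 2:
        raise MonotonicityError("need at least two points to assess monotonicity")
    diffs = np.diff(r)
    if np.all(diffs > 0) or np.all(diffs < 0):
        return curve
    if curve.ratio_se is None:
        raise MonotonicityError(f"{curve.wavelength} nm ratio curve is non-monotonic")
    fits = {direction: _pava(r, increasing=direction) for direction in (True, False)}
    direction = min(fits, key=lambda d: float(np.sum((fits[d] - r) ** 2)))
    fit = fits[direction]
    adjust = np.abs(fit - r)
    tol = se_factor * curve.ratio_se
    if np.any(adjust > tol):
        worst = float(np.max(adjust / np.maximum(curve.ratio_se, 1e-300)))
        raise MonotonicityError(
            f"{curve.wavelength} nm ratio curve violates monotonicity beyond "
            f"{se_factor} standard errors (worst {worst:.1f} SE)")
    return RatioCurve(wavelength=curve.wavelength, mu_a_assigned=curve.mu_a_assigned,
                      mu_s_prime=curve.mu_s_prime, ratio=fit,
                      ratio_se=curve.ratio_se, dropped=list(curve.dropped))


def invert_ratio(curve: RatioCurve, r_corr: float) -> float:
    """Log-domain interpolation inversion of a monotonic ratio curve.

    Exact at grid nodes; ties (a ratio equal to two nodes) resolve to the
    lower mu_s'.  Out-of-range ratios raise (no extrapolation); non-positive
    ratios are a low-SNR exclusion.
    """
    if r_corr <= 0:
        raise LowSNRError(f"non-positive corrected ratio {r_corr}; excluded")
    mu = curve.mu_s_prime
    r = curve.ratio
    # exact node hits, lower-mu_s' tie break
    hits = np.nonzero(r == r_corr)[0]
    if hits.size:
        return float(mu[hits[0]])
    increasing = r[-1] > r[0]
    r_sorted = r if increasing else r[::-1]
    mu_sorted = mu if increasing else mu[::-1]
    if not (r_sorted[0] < r_corr < r_sorted[-1]):
        raise OutOfRangeError(
            f"ratio {r_corr:.6g} outside LUT range "
            f"[{r.min():.6g}, {r.max():.6g}] at {curve.wavelength} nm")
    i = int(np.searchsorted(r_sorted, r_corr))
    mu1, mu2 = mu_sorted[i - 1], mu_sorted[i]
    r1, r2 = r_sorted[i - 1], r_sorted[i]
    t = (math.log(r_corr) - math.log(r1)) / (math.log(r2) - math.log(r1))
    return float(mu1 + (mu2 - mu1) * t)


# ---------------------------------------------------------------------------
# Persistence: CSV table + JSON sidecar with provenance

_LUT_COLUMNS = ["wavelength_nm", "rho_cm", "mu_a_cm-1", "mu_s_prime_cm-1",
                "p_det", "detected_count", "launched", "starved"]


def write_lut(entries: Sequence[LutEntry], path: str | Path, *,
              fw_nominal: float, seed: int, config: dict | None = None) -> Path:
    """Write entries to CSV plus a JSON sidecar with config hash and seed."""
    path = Path(path)
    df = pd.DataFrame([{
        "wavelength_nm": e.wavelength, "rho_cm": e.rho,
        "mu_a_cm-1": e.mu_a_assigned, "mu_s_prime_cm-1": e.mu_s_prime,
        "p_det": e.p_det, "detected_count": e.detected_count,
        "launched": e.launched, "starved": e.starved,
    } for e in entries], columns=_LUT_COLUMNS)
    df.to_csv(path, index=False)
    config = dict(config or {})
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    sidecar = {"fw_nominal": fw_nominal, "seed": seed,
               "config": config, "config_sha256": config_hash}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_lut(path: str | Path) -> tuple[list[LutEntry], dict]:
    """Read a LUT CSV (and its JSON sidecar, if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    entries = [LutEntry(
        wavelength=int(r["wavelength_nm"]), rho=float(r["rho_cm"]),
        mu_a_assigned=float(r["mu_a_cm-1"]), mu_s_prime=float(r["mu_s_prime_cm-1"]),
        p_det=float(r["p_det"]), detected_count=int(r["detected_count"]),
        launched=int(r["launched"]), starved=bool(r["starved"]),
    ) for _, r in df.iterrows()]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return entries, sidecar
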