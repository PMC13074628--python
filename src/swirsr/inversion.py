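"""Water-fraction recovery: LUT-inverted scattering plus a bounded
diffusion-model sweep minimizing a log-domain ratio error, and the
agreement metrics used to compare recovered against recipe-defined values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from . import diffusion, lut, signals
from .constants import ProbeGeometry, WAVELENGTHS, WaterAbsorptionTable
from .errors import DomainError, LowSNRError, OutOfRangeError, PipelineError


@dataclass(frozen=True)
class InversionConfig:
    feasible_lo: float = 0.5
    feasible_hi: float = 0.95
    sweep_step: float = 0.001
    wavelengths: tuple[int, ...] = WAVELENGTHS
    fw_nominal_for_lut: float | None = None  # recorded provenance

    def __post_init__(self):
        if not (0.0 <= self.feasible_lo <= self.feasible_hi <= 1.0):
            raise DomainError("feasible set must be an interval within [0, 1]")
        if self.sweep_step <= 0:
            raise DomainError("sweep_step must be positive")

    def grid(self) -> np.ndarray:
        n = int(round((self.feasible_hi - self.feasible_lo) / self.sweep_step)) + 1
        return self.feasible_lo + self.sweep_step * np.arange(n)


@dataclass
class InversionResult:
    mu_s_prime_hat: dict[int, float]
    f_w_hat: float
    error_curve: list[tuple[float, float]]
    flags: list[str] = field(default_factory=list)
    lut_mode: str = "absorption-consistent"
    r_corr: dict[int, float] = field(default_factory=dict)


def objective(f_w: float, r_corr_by_wavelength: Mapping[int, float],
              mu_s_prime_hat_by_wavelength: Mapping[int, float],
              geometry: ProbeGeometry | None = None,
              water_table: WaterAbsorptionTable | None = None) -> float:
    """Log-domain squared error E(f_w) = sum_k [ln r_corr,k - ln r_model,k(f_w)]^2."""
    if not r_corr_by_wavelength:
        raise DomainError("objective needs at least one ratio term")
    total = 0.0
    for wl, r_corr in r_corr_by_wavelength.items():
        if r_corr <= 0:
            raise LowSNRError(f"non-positive corrected ratio at {wl} nm")
        r_model = diffusion.model_ratio(f_w, mu_s_prime_hat_by_wavelength[wl],
                                        wl, geometry, water_table)
        total += (math.log(r_corr) - math.log(r_model)) ** 2
    return total


def sweep_fw(config: InversionConfig, r_corr_by_wavelength: Mapping[int, float],
             mu_s_prime_hat_by_wavelength: Mapping[int, float],
             geometry: ProbeGeometry | None = None,
             water_table: WaterAbsorptionTable | None = None) -> InversionResult:
    """Dense-grid argmin of the objective over the feasible interval.

    Ties break toward lower f_w (the grid scan keeps the first minimum).
    """
    grid = config.grid()
    errors = np.array([
        objective(fw, r_corr_by_wavelength, mu_s_prime_hat_by_wavelength,
                  geometry, water_table)
        for fw in grid
    ])
    idx = int(np.argmin(errors))  # first occurrence -> lower f_w on ties
    flags = []
    if np.allclose(errors, errors[0]):
        flags.append("degenerate-objective: error curve is flat")
    return InversionResult(
        mu_s_prime_hat=dict(mu_s_prime_hat_by_wavelength),
        f_w_hat=float(grid[idx]),
        error_curve=list(zip(grid.tolist(), errors.tolist())),
        flags=flags,
        r_corr=dict(r_corr_by_wavelength),
    )


def run_pipeline(frame_sample: signals.MeasurementFrame,
                 frame_reference: signals.MeasurementFrame,
                 curves_by_wavelength: Mapping[int, lut.RatioCurve],
                 config: InversionConfig | None = None,
                 geometry: ProbeGeometry | None = None,
                 water_table: WaterAbsorptionTable | None = None,
                 lut_mode: str = "absorption-consistent") -> InversionResult:
    """Full chain: corrected ratios -> LUT scattering inversion per wavelength
    -> bounded water-fraction sweep.

    Wavelengths excluded upstream (low SNR, out-of-LUT-range) are dropped
    with flags; if none survive, :class:`PipelineError` lists the reasons.
    """
    config = config or InversionConfig()
    ratios = signals.corrected_ratios(frame_sample, frame_reference,
                                      wavelengths=config.wavelengths)
    reasons: dict[int, str] = dict(ratios.excluded)
    r_by_wl: dict[int, float] = {}
    musp_by_wl: dict[int, float] = {}
    for wl, r_corr in ratios.r_corr.items():
        try:
            musp_by_wl[wl] = lut.invert_ratio(curves_by_wavelength[wl], r_corr)
            r_by_wl[wl] = r_corr
        except (LowSNRError, OutOfRangeError, KeyError) as exc:
            reasons[wl] = str(exc)
    if not r_by_wl:
        raise PipelineError("all wavelengths excluded from inversion",
                            reasons={str(k): v for k, v in reasons.items()})
    result = sweep_fw(config, r_by_wl, musp_by_wl, geometry, water_table)
    result.lut_mode = lut_mode
    result.flags.extend(f"{wl} nm excluded: {msg}" for wl, msg in reasons.items())
    return result


# ---------------------------------------------------------------------------
# Agreement metrics

def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, matching printed-table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def abs_percent_error(f_w_true: float, f_w_hat: float) -> float:
    """|f_w_hat - f_w_true| / f_w_true * 100."""
    if f_w_true == 0:
        raise DomainError("percent error undefined for f_w_true = 0")
    return abs(f_w_hat - f_w_true) / f_w_true * 100.0


def agreement_metrics(pairs: Sequence[tuple[float, float]],
                      groups: Sequence | None = None) -> dict:
    """Summary agreement statistics over (f_w_true, f_w_hat) pairs.

    Returns per-pair absolute percent errors (None where undefined), overall
    mean/max percent error, per-group mean percent errors when ``groups``
    labels are supplied, and bias / MAE / RMSE in absolute water-fraction
    units.
    """
    if len(pairs) < 1:
        raise DomainError("need at least one (true, hat) pair")
    if groups is not None and len(groups) != len(pairs):
        raise DomainError("groups must align with pairs")
    per_pair: list[float | None] = []
    for true, hat in pairs:
        per_pair.append(None if true == 0 else abs_percent_error(true, hat))
    defined = [e for e in per_pair if e is not None]
    diffs = np.array([hat - true for true, hat in pairs])
    metrics = {
        "per_pair_abs_pct_error": per_pair,
        "mean_abs_pct_error": float(np.mean(defined)) if defined else None,
        "max_abs_pct_error": float(np.max(defined)) if defined else None,
        "bias": float(np.mean(diffs)),
        "mae": float(np.mean(np.abs(diffs))),
        "rmse": float(np.sqrt(np.mean(diffs**2))),
        "n": len(pairs),
        "n_undefined": len(per_pair) - len(defined),
    }
    if groups is not None:
        group_means = {}
        for label in dict.fromkeys(groups):  # preserve order
            errs = [e for e, grp in zip(per_pair, groups)
                    if grp == label and e is not None]
            group_means[label] = float(np.mean(errs)) if errs else None
        metrics["group_mean_abs_pct_error"] = group_means
    return metrics
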