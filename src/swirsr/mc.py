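"""Monte Carlo photon transport in a homogeneous slab with probe-emulated
finite LED source, absorbing top mask with circular aperture, and
acceptance-cone-limited detection.

Transport uses continuous absorption weighting (implicit capture),
Henyey-Greenstein scattering, Fresnel reflection at the index-mismatched top
surface, and Russian roulette below a weight threshold.  The slab sides and
bottom are absorbing; the top surface outside the aperture is covered by an
optically black mask.  Geometry is handled analytically (no voxel grid): for
a uniform slab, analytic boundaries are exact.

Conventions: the sample occupies 0 <= z <= slab_z with +z pointing into the
medium; the detector/aperture axis is at x = y = 0 and the LED center sits
at (rho, 0) on the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import ProbeGeometry, mus_from_musp
from .errors import DomainError

WEIGHT_MIN = 1e-4
ROULETTE_SURVIVE = 0.1
DEFAULT_MIN_COUNTS = 100

_BIG = 1e12


@dataclass(frozen=True)
class OpticalProperties:
    mu_a: float   # cm^-1
    mu_s: float   # cm^-1
    g: float
    n: float = 1.33

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise DomainError("mu_a and mu_s must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise DomainError("anisotropy must lie in (-1, 1)")
        if self.n < 1.0:
            raise DomainError("refractive index must be >= 1")

    @classmethod
    def from_musp(cls, mu_a: float, mu_s_prime: float, g: float = 0.9,
                  n: float = 1.33) -> "OpticalProperties":
        return cls(mu_a=mu_a, mu_s=mus_from_musp(mu_s_prime, g), g=g, n=n)

    @property
    def mu_s_prime(self) -> float:
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class SourceModel:
    """Finite-area LED source with generalized Lambertian divergence.

    Launch positions are uniform over a square of side ``emitter_side``
    centered at lateral offset ``center_offset`` from the detector axis;
    launch directions follow p(theta) proportional to cos^m(theta).
    """

    center_offset: float
    emitter_side: float = 0.1
    divergence_exponent: float = 1.0

    def __post_init__(self):
        if self.emitter_side <= 0:
            raise DomainError("emitter_side must be positive")
        if self.divergence_exponent < 1:
            raise DomainError("divergence_exponent must be >= 1")


@dataclass(frozen=True)
class DetectionResult:
    p_det: float
    detected_count: int
    launched: int
    starved: bool
    detected_weight: float
    mask_weight: float
    escaped_weight: float
    absorbed_weight: float
    roulette_weight: float

    @property
    def weight_balance(self) -> float:
        """Total tallied weight; equals ``launched`` up to float rounding."""
        return (self.detected_weight + self.mask_weight + self.escaped_weight
                + self.absorbed_weight + self.roulette_weight)


@njit(cache=True)
def _fresnel_reflectance(n_rel: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for internal incidence with relative
    index n_rel = n_in/n_out; returns 1.0 beyond the critical angle."""
    if cos_i >= 1.0:
        r = (n_rel - 1.0) / (n_rel + 1.0)
        return r * r
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _hg_cosine(g: float, xi: float) -> float:
    """Henyey-Greenstein scattering cosine from a uniform deviate."""
    if abs(g) < 1e-8:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _lambertian_cosine(m: float, xi: float) -> float:
    """Polar cosine for generalized Lambertian emission, p(theta) ~ cos^m."""
    return xi ** (1.0 / (m + 1.0))


@njit(cache=True, inline="always")
def _rng_next(state):
    """xorshift128+ step; returns a uniform double in (0, 1]."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    u = (s0 + s1) >> np.uint64(11)
    return (np.float64(u) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _rng_init(seed):
    """Seed two xorshift128+ words via splitmix64."""
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = t ^ (t >> np.uint64(31))
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, fastmath=True)
def _mc_kernel(n_photons, seed, mu_a, mu_s, g, n_rel,
               src_x, emitter_side, m_div,
               half_x, half_y, depth, aperture_r2, cos_accept):
    rng = _rng_init(seed)
    mu_t = mu_a + mu_s
    det_w = 0.0
    det_n = 0
    mask_w = 0.0
    esc_w = 0.0
    abs_w = 0.0
    rr_w = 0.0
    for _ in range(n_photons):
        x = src_x + (_rng_next(rng) - 0.5) * emitter_side
        y = (_rng_next(rng) - 0.5) * emitter_side
        z = 0.0
        cost = _lambertian_cosine(m_div, _rng_next(rng))
        sint = math.sqrt(max(0.0, 1.0 - cost * cost))
        phi = 2.0 * math.pi * _rng_next(rng)
        ux = sint * math.cos(phi)
        uy = sint * math.sin(phi)
        uz = cost  # into the medium
        w = 1.0
        alive = True
        while alive:
            if mu_t > 0.0:
                s = -math.log(_rng_next(rng)) / mu_t
            else:
                s = _BIG
            # propagate, handling boundary crossings within the step
            while s > 0.0:
                d_top = _BIG
                d_bot = _BIG
                d_x = _BIG
                d_y = _BIG
                if uz < 0.0:
                    d_top = -z / uz
                elif uz > 0.0:
                    d_bot = (depth - z) / uz
                if ux > 0.0:
                    d_x = (half_x - x) / ux
                elif ux < 0.0:
                    d_x = (-half_x - x) / ux
                if uy > 0.0:
                    d_y = (half_y - y) / uy
                elif uy < 0.0:
                    d_y = (-half_y - y) / uy
                d_min = d_top
                which = 0  # 0 top, 1 bottom, 2 side
                if d_bot < d_min:
                    d_min = d_bot
                    which = 1
                if d_x < d_min:
                    d_min = d_x
                    which = 2
                if d_y < d_min:
                    d_min = d_y
                    which = 2
                if s < d_min:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    s = 0.0
                    break
                # move to the boundary
                x += ux * d_min
                y += uy * d_min
                z += uz * d_min
                s -= d_min
                if which == 0:
                    z = 0.0
                    cos_i = -uz
                    refl = _fresnel_reflectance(n_rel, cos_i)
                    if _rng_next(rng) < refl:
                        uz = -uz  # internal reflection, keep remaining step
                        continue
                    # transmitted through the top surface
                    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                    sin_t = n_rel * sin_i
                    cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                    if (x * x + y * y) <= aperture_r2 and cos_t >= cos_accept:
                        det_w += w
                        det_n += 1
                    else:
                        mask_w += w
                    alive = False
                    break
                else:
                    # sides and bottom are absorbing terminations
                    esc_w += w
                    alive = False
                    break
            if not alive:
                break
            if mu_t <= 0.0:
                # ballistic photon never interacted yet failed to exit: lost
                esc_w += w
                break
            # interaction: continuous absorption weighting
            abs_w += w * (mu_a / mu_t)
            w *= mu_s / mu_t
            if w <= 0.0:
                alive = False
                break
            # Henyey-Greenstein direction update; azimuth via the double-angle
            # disk-rejection trick (no per-event trig)
            ct = _hg_cosine(g, _rng_next(rng))
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            while True:
                va = 2.0 * _rng_next(rng) - 1.0
                vb = 2.0 * _rng_next(rng) - 1.0
                rr = va * va + vb * vb
                if 0.0 < rr <= 1.0:
                    break
            cp = (va * va - vb * vb) / rr
            sp = 2.0 * va * vb / rr
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                tmp = math.sqrt(1.0 - uz * uz)
                uxn = st * (ux * uz * cp - uy * sp) / tmp + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) / tmp + uy * ct
                uzn = -st * cp * tmp + uz * ct
                norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm
            # Russian roulette
            if w < WEIGHT_MIN:
                if _rng_next(rng) < ROULETTE_SURVIVE:
                    rr_w -= w * (1.0 / ROULETTE_SURVIVE - 1.0)
                    w /= ROULETTE_SURVIVE
                else:
                    rr_w += w
                    alive = False
    return det_w, det_n, mask_w, esc_w, abs_w, rr_w


def simulate_channel(props: OpticalProperties, geometry: ProbeGeometry,
                     source: SourceModel, n_photons: int, seed: int,
                     min_counts: int = DEFAULT_MIN_COUNTS) -> DetectionResult:
    """Run one probe-emulated channel simulation and return the detected
    photon fraction with weight-conservation tallies.

    Deterministic for a fixed seed.  ``starved`` is set when fewer than
    ``min_counts`` photons reached the detector.
    """
    if n_photons <= 0:
        raise DomainError(f"n_photons must be >= 1, got {n_photons}")
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1, dtype=np.uint64)[0]
                      & np.uint64(2**63 - 1))
    det_w, det_n, mask_w, esc_w, abs_w, rr_w = _mc_kernel(
        int(n_photons), kernel_seed,
        float(props.mu_a), float(props.mu_s), float(props.g),
        float(props.n / geometry.n_outside),
        float(source.center_offset), float(source.emitter_side),
        float(source.divergence_exponent),
        geometry.slab_x / 2.0, geometry.slab_y / 2.0, geometry.slab_z,
        geometry.aperture_radius ** 2,
        math.cos(geometry.acceptance_half_angle_rad),
    )
    return DetectionResult(
        p_det=det_w / n_photons,
        detected_count=int(det_n),
        launched=int(n_photons),
        starved=det_n < min_counts,
        detected_weight=det_w,
        mask_weight=mask_w,
        escaped_weight=esc_w,
        absorbed_weight=abs_w,
        roulette_weight=rr_w,
    )


# ---------------------------------------------------------------------------
# Python-level sampling helpers (same formulas as the kernel; unit-testable)

def launch_photon(source: SourceModel, rng: np.random.Generator):
    """Sample one launch (position, direction) at the sample surface."""
    x = source.center_offset + (rng.random() - 0.5) * source.emitter_side
    y = (rng.random() - 0.5) * source.emitter_side
    cost = _lambertian_cosine(source.divergence_exponent, rng.random())
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * rng.random()
    pos = np.array([x, y, 0.0])
    direction = np.array([sint * math.cos(phi), sint * math.sin(phi), cost])
    return pos, direction


def sample_hg_cosines(g: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` Henyey-Greenstein scattering cosines."""
    xi = rng.random(n)
    return np.array([_hg_cosine(g, x) for x in xi])


def sample_lambertian_cosines(m: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` generalized-Lambertian polar cosines."""
    return rng.random(n) ** (1.0 / (m + 1.0))


def fresnel_reflectance(n_in: float, n_out: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance at internal incidence cosine cos_i."""
    return float(_fresnel_reflectance(n_in / n_out, cos_i))


def propagate_step(position: np.ndarray, direction: np.ndarray,
                   props: OpticalProperties, weight: float,
                   rng: np.random.Generator):
    """One free-flight + interaction update (reference implementation).

    Returns (position, direction, weight, absorbed).  Mirrors the kernel's
    physics without boundary handling; used for distribution-level testing.
    """
    if weight <= 0:
        raise DomainError("weight must be positive")
    mu_t = props.mu_a + props.mu_s
    if mu_t <= 0:
        return position + _BIG * direction, direction, weight, 0.0
    s = -math.log(1.0 - rng.random()) / mu_t
    position = position + s * direction
    absorbed = weight * props.mu_a / mu_t
    weight = weight * props.mu_s / mu_t
    ct = _hg_cosine(props.g, rng.random())
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    psi = 2.0 * math.pi * rng.random()
    ux, uy, uz = direction
    if abs(uz) > 0.99999:
        direction = np.array([st * math.cos(psi), st * math.sin(psi),
                              ct if uz > 0 else -ct])
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        uxn = st * (ux * uz * math.cos(psi) - uy * math.sin(psi)) / tmp + ux * ct
        uyn = st * (uy * uz * math.cos(psi) + ux * math.sin(psi)) / tmp + uy * ct
        uzn = -st * math.cos(psi) * tmp + uz * ct
        direction = np.array([uxn, uyn, uzn])
        direction /= np.linalg.norm(direction)
    if weight < WEIGHT_MIN:
        if rng.random() < ROULETTE_SURVIVE:
            weight /= ROULETTE_SURVIVE
        else:
            weight = 0.0
    if not (np.all(np.isfinite(position)) and np.all(np.isfinite(direction))):
        raise RuntimeError("non-finite photon state")
    return position, direction, weight, absorbed
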