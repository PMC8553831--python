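"""Trait-based types and per-link rate computations for the food-web model.

Every species carries three heritable traits: a body mass ``m`` placing it
on a (log10) body-size axis, a feeding centre ``f`` and a feeding range
``s``.  The pair (f, s) defines a Gaussian feeding kernel over log10 body
mass: a consumer attacks any resource in proportion to the kernel value at
the resource's log-mass.  Because the kernel is normalised, narrow kernels
(specialists) buy a higher peak attack rate at the price of breadth — the
efficiency/generalism trade-off is built into the attack-rate equation.

This module is pure computation: kernels, attack rates, Holling type-II
consumption, allometric handling time and metabolic loss, and interference
competition derived from the overlap integral of two feeding kernels.  The
dynamics and metrics layers consume these functions (and their vectorised
matrix forms) without adding model content of their own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Parameters",
    "Species",
    "CommunityState",
    "feeding_kernel",
    "attack_rate",
    "max_attack_rate",
    "handling_time",
    "metabolic_loss",
    "consumption_rate",
    "competition_overlap",
    "competition_coefficient",
    "attack_matrix",
    "competition_matrix",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class Parameters:
    """Model constants and evolutionary-rule settings.

    The defaults define the reference study conditions.  Units are set by
    the basal-resource influx rate ``n0 = 1``: all other rates (and hence
    species lifespans) are relative to it.

    Notes on the allometric exponents: attack rate scales as ``m^0.75``
    and metabolic loss as ``m^-0.25``.  The handling-time exponent default
    is ``-0.75`` so that the saturated mass-specific intake
    ``e / (m_i h_i)`` scales as ``m^-0.25`` — the same allometry as
    metabolic loss.  This is the classic bioenergetic formulation with a
    mass-independent maximum consumption-to-metabolism ratio
    ``y = 1/(h_coeff * x_coeff) ≈ 8``; any other pairing of exponents
    makes consumers beyond some fixed body mass energetically inviable
    regardless of prey availability (with ``-0.25`` the cutoff sits near
    m = 50, below the m = 100 ancestor that seeds every community).
    """

    n0: float = 1.0            # basal resource input rate (sets the time scale)
    l: float = 0.5             # basal resource loss (outflow) rate
    m0: float = 1.0            # basal resource body mass (trait floor for m)
    e: float = 0.85            # assimilation efficiency
    c0: float = 0.05           # interference-competition strength
    h_coeff: float = 0.4       # handling-time coefficient
    h_exp: float = -0.75       # handling-time body-mass exponent (see class notes)
    x_coeff: float = 0.3       # metabolic-loss coefficient
    x_exp: float = -0.25       # metabolic-loss body-mass exponent
    a_exp: float = 0.75        # attack-rate body-mass exponent
    p: float = 0.2             # probability an introduction is an invader
    z_mutant: float = 0.1      # trait-draw SD for mutants
    z_invader: float = 0.1     # trait-draw SD for invaders ("strangeness")
    eps: float = 1e-8          # extinction threshold = introduction biomass
    s_floor: float = 0.3       # minimum feeding range
    intro_interval: float = 100.0   # time between species introductions
    horizon: float = 25_000_000.0   # total simulated time
    include_cannibalism: bool = True  # count own biomass among potential prey
    mutate_log_scale: bool = True     # m and f mutate on log10 scale, s linear
    reject_floors: bool = True        # enforce trait floors by redraw (else clamp)

    def __post_init__(self) -> None:
        for name in ("n0", "l", "m0", "e", "c0", "h_coeff", "x_coeff",
                     "z_mutant", "z_invader", "eps", "s_floor",
                     "intro_interval", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Parameters.{name} must be strictly positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("Parameters.p must lie in [0, 1]")
        if self.z_invader < self.z_mutant:
            warnings.warn(
                "z_invader < z_mutant: invaders will be *less* novel than "
                "mutants, which inverts the intended strangeness contrast",
                stacklevel=2,
            )

    def with_z(self, z: float) -> "Parameters":
        """Copy with a new invader strangeness value (the sweep variable)."""
        return replace(self, z_invader=z)


@dataclass
class Species:
    """One species: heritable traits plus ledger bookkeeping.

    Traits are fixed for the species' whole lifespan; only its biomass
    (held in :class:`CommunityState`) changes through time.
    """

    id: int
    m: float                     # body mass, >= resource body mass m0
    f: float                     # feeding centre, on the mass scale
    s: float                     # feeding range, SD of the kernel in log10-mass units
    origin: str = "ancestor"     # ancestor | mutant | invader
    parent_id: int | None = None
    birth_time: float = 0.0
    death_time: float | None = None

    def __post_init__(self) -> None:
        if self.m <= 0 or self.f <= 0 or self.s <= 0:
            raise ValueError("Species traits m, f, s must be strictly positive")
        if self.origin not in ("ancestor", "mutant", "invader"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.death_time is not None and self.death_time <= self.birth_time:
            raise ValueError("death_time must exceed birth_time")

    @property
    def lifespan(self) -> float | None:
        """Time from introduction to removal; None while extant/censored."""
        if self.death_time is None:
            return None
        return self.death_time - self.birth_time


@dataclass
class CommunityState:
    """Biomass densities of the basal resource and all extant species at time t."""

    t: float
    B0: float
    species: list[Species] = field(default_factory=list)
    B: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if len(self.species) != self.B.size:
            raise ValueError("species list and biomass vector lengths differ")
        if not np.isfinite(self.B0) or self.B0 < 0:
            raise ValueError("B0 must be finite and non-negative")
        if self.B.size and (not np.all(np.isfinite(self.B)) or np.any(self.B < 0)):
            raise ValueError("biomasses must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.species)

    def masses(self) -> np.ndarray:
        return np.array([sp.m for sp in self.species])

    def copy(self) -> "CommunityState":
        return CommunityState(self.t, self.B0, list(self.species), self.B.copy())


# ---------------------------------------------------------------------------
# Per-link rates
# ---------------------------------------------------------------------------

def feeding_kernel(f_i: float, s_i: float, m_j: float) -> float:
    """Gaussian feeding kernel N_ij evaluated at resource mass ``m_j``.

    The kernel is a normalised Gaussian over *log10* body mass centred at
    log10(f_i) with SD s_i, so it integrates to 1 along the log-mass axis
    and peaks at 1/(s_i sqrt(2 pi)) when m_j equals the feeding centre.
    """
    if f_i <= 0 or s_i <= 0 or m_j <= 0:
        raise ValueError("feeding_kernel requires f_i, s_i, m_j > 0")
    d = math.log10(f_i) - math.log10(m_j)
    return math.exp(-(d * d) / (2.0 * s_i * s_i)) / (s_i * _SQRT_2PI)


def attack_rate(consumer: Species, m_j: float, params: Parameters) -> float:
    """Mass-specific attack rate a_ij = m_i^a_exp * N_ij."""
    return consumer.m ** params.a_exp * feeding_kernel(consumer.f, consumer.s, m_j)


def max_attack_rate(consumer: Species, params: Parameters) -> float:
    """Attack rate on an ideal prey sitting exactly at the feeding centre."""
    return consumer.m ** params.a_exp / (consumer.s * _SQRT_2PI)


def handling_time(m_i: float, params: Parameters) -> float:
    """Allometric handling time h_i = h_coeff * m_i^h_exp."""
    if m_i <= 0:
        raise ValueError("handling_time requires m_i > 0")
    return params.h_coeff * m_i ** params.h_exp


def metabolic_loss(m_i: float, params: Parameters) -> float:
    """Allometric respiration/mortality loss x_i = x_coeff * m_i^x_exp."""
    if m_i <= 0:
        raise ValueError("metabolic_loss requires m_i > 0")
    return params.x_coeff * m_i ** params.x_exp


def _prey_masses_biomasses(
    consumer: Species, state: CommunityState, params: Parameters
) -> tuple[np.ndarray, np.ndarray]:
    """Masses and biomasses of every potential prey of ``consumer``.

    Prey are the basal resource plus all extant species; the consumer's own
    biomass is included unless cannibalism is switched off.
    """
    ms = [params.m0]
    bs = [state.B0]
    for sp, b in zip(state.species, state.B):
        if not params.include_cannibalism and sp.id == consumer.id:
            continue
        ms.append(sp.m)
        bs.append(b)
    return np.array(ms), np.array(bs)


def consumption_rate(
    consumer: Species, j: int, state: CommunityState, params: Parameters
) -> float:
    """Holling type-II mass-specific consumption rate g_ij.

    ``j = 0`` addresses the basal resource; ``j >= 1`` addresses
    ``state.species[j-1]``.  The half-saturation denominator sums handling
    over *all* potential prey of the consumer, so g_ij depends on the whole
    community, not just the focal link.
    """
    if j < 0 or j > state.n:
        raise ValueError(f"resource index {j} out of range for community of size {state.n}")
    m_j = params.m0 if j == 0 else state.species[j - 1].m
    if (not params.include_cannibalism and j >= 1
            and state.species[j - 1].id == consumer.id):
        return 0.0
    a_ij = attack_rate(consumer, m_j, params)
    prey_m, prey_b = _prey_masses_biomasses(consumer, state, params)
    h_i = handling_time(consumer.m, params)
    a_ik = consumer.m ** params.a_exp * np.array(
        [feeding_kernel(consumer.f, consumer.s, mk) for mk in prey_m]
    )
    denom = 1.0 + h_i * float(a_ik @ prey_b)
    return a_ij / (consumer.m * denom)


def competition_overlap(i: Species, j: Species) -> float:
    """Overlap integral I_ij of two feeding kernels over the log10-mass line.

    The product of two normalised Gaussians integrates in closed form:
    I_ij = exp(-(log10 f_i - log10 f_j)^2 / (2 (s_i^2 + s_j^2)))
           / sqrt(2 pi (s_i^2 + s_j^2)).
    Symmetric in (i, j); the self-overlap is I_ii = 1/(2 s_i sqrt(pi)).
    """
    var = i.s * i.s + j.s * j.s
    d = math.log10(i.f) - math.log10(j.f)
    return math.exp(-(d * d) / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def competition_coefficient(i: Species, j: Species, params: Parameters) -> float:
    """Interference competition c_ij = c0 * I_ij / I_ii, defined for i != j.

    Normalisation by the focal species' self-overlap makes the coefficient
    asymmetric in general and exactly c0 for identical kernels.
    """
    if i.id == j.id:
        raise ValueError("competition_coefficient is defined only for distinct species")
    return params.c0 * competition_overlap(i, j) / competition_overlap(i, i)


# ---------------------------------------------------------------------------
# Vectorised matrix forms (consumed by the dynamics layer)
# ---------------------------------------------------------------------------

def attack_matrix(species: list[Species], params: Parameters) -> np.ndarray:
    """Attack rates of every consumer on every potential prey.

    Returns an (n, n+1) array: row i is consumer ``species[i]``, column 0 the
    basal resource and column j+1 species j.  The diagonal (cannibalism) is
    zeroed when ``include_cannibalism`` is off.
    """
    n = len(species)
    if n == 0:
        return np.zeros((0, 1))
    f = np.array([sp.f for sp in species])
    s = np.array([sp.s for sp in species])
    m = np.array([sp.m for sp in species])
    log_prey = np.concatenate(([math.log10(params.m0)], np.log10(m)))
    d = np.log10(f)[:, None] - log_prey[None, :]
    kern = np.exp(-(d * d) / (2.0 * s * s)[:, None]) / (s * _SQRT_2PI)[:, None]
    A = (m ** params.a_exp)[:, None] * kern
    if not params.include_cannibalism:
        A[np.arange(n), np.arange(n) + 1] = 0.0
    return A


def competition_matrix(species: list[Species], params: Parameters) -> np.ndarray:
    """Pairwise interference coefficients c_ij with a zero diagonal."""
    n = len(species)
    if n == 0:
        return np.zeros((0, 0))
    f = np.log10(np.array([sp.f for sp in species]))
    s = np.array([sp.s for sp in species])
    var = s[:, None] ** 2 + s[None, :] ** 2
    d = f[:, None] - f[None, :]
    overlap = np.exp(-(d * d) / (2.0 * var)) / np.sqrt(2.0 * math.pi * var)
    self_overlap = 1.0 / (2.0 * s * math.sqrt(math.pi))
    C = params.c0 * overlap / self_overlap[:, None]
    np.fill_diagonal(C, 0.0)
    return C
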