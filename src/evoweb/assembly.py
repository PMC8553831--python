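"""Evolutionary layer: scheduled species introductions.

Every ``intro_interval`` time units one new species enters the community,
either as a *mutant* (probability 1 - p) or an *invader* (probability p).
Mutant parents are chosen in proportion to individual density B_i / m_i;
invader parents uniformly at random.  Child traits are Gaussian draws
around the parent's traits with SD ``z`` — z_mutant (0.1) for mutants and
the experiment's strangeness parameter z_invader for invaders — so larger
z_invader makes invaders increasingly novel relative to the resident
community.  Body mass and feeding centre mutate on the log10 scale (the
scale on which the feeding kernel lives), the feeding range linearly; the
trait floors m >= m0 and s >= s_floor are enforced by redraw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CommunityState, Parameters, Species

__all__ = [
    "CommunityCollapse",
    "IntroductionEvent",
    "choose_kind",
    "select_parent",
    "draw_traits",
    "introduce",
    "init_community",
]

_MAX_REDRAWS = 10_000

ANCESTOR_TRAITS = (100.0, 1.0, 0.4)  # body mass, feeding centre, feeding range


class CommunityCollapse(RuntimeError):
    """All consumers are extinct: the run cannot continue and must restart."""


@dataclass(frozen=True)
class IntroductionEvent:
    """Record of one introduction: when, what kind, from whom, with which SD."""

    t: float
    kind: str                 # "mutant" | "invader"
    parent_id: int
    child: Species
    z_used: float


def choose_kind(rng: np.random.Generator, params: Parameters) -> str:
    """Invader with probability p, mutant otherwise."""
    return "invader" if rng.random() < params.p else "mutant"


def select_parent(state: CommunityState, kind: str, rng: np.random.Generator) -> Species:
    """Pick the parent of the next introduction from the extant community.

    Mutant parents are drawn with probability proportional to individual
    density B_i / m_i (denser populations mutate more often); invader
    parents uniformly.  The basal resource is never a parent.
    """
    if state.n == 0:
        raise CommunityCollapse("no extant species to parent an introduction")
    if kind == "mutant":
        w = state.B / state.masses()
        total = w.sum()
        if total <= 0:  # all-zero biomass community: fall back to uniform
            idx = rng.integers(state.n)
        else:
            idx = rng.choice(state.n, p=w / total)
    elif kind == "invader":
        idx = rng.integers(state.n)
    else:
        raise ValueError(f"unknown introduction kind {kind!r}")
    return state.species[int(idx)]


def _draw_floored(rng, mean: float, sd: float, floor: float, log_scale: bool,
                  reject: bool) -> float:
    for _ in range(_MAX_REDRAWS):
        val = rng.normal(mean, sd)
        if log_scale:
            val = 10.0 ** val
        if val >= floor:
            return val
        if not reject:
            return floor
    raise RuntimeError(
        f"trait draw rejected {_MAX_REDRAWS} times (mean={mean}, sd={sd}, floor={floor})"
    )


def draw_traits(
    parent: Species, z: float, rng: np.random.Generator, params: Parameters
) -> tuple[float, float, float]:
    """Draw child traits (m, f, s) independently around the parent's.

    log10(m) and log10(f) are Normal(parent log-trait, z); s is
    Normal(parent s, z) on the linear scale.  m and s are redrawn until
    they respect their floors (rejection keeps the distributions free of
    boundary atoms; set ``reject_floors=False`` to clamp instead).
    """
    if z <= 0:
        raise ValueError("trait SD z must be strictly positive")
    log = params.mutate_log_scale
    m = _draw_floored(rng, np.log10(parent.m) if log else parent.m, z,
                      params.m0, log, params.reject_floors)
    f = rng.normal(np.log10(parent.f), z) if log else rng.normal(parent.f, z)
    f = 10.0 ** f if log else f
    if not log:
        # linear-scale mutation can cross zero; the feeding centre must stay positive
        while f <= 0:
            f = rng.normal(parent.f, z)
    s = _draw_floored(rng, parent.s, z, params.s_floor, False, params.reject_floors)
    return m, f, s


def introduce(
    state: CommunityState,
    kind: str,
    rng: np.random.Generator,
    params: Parameters,
    t: float,
    child_id: int,
    parent_rng: np.random.Generator | None = None,
) -> tuple[CommunityState, IntroductionEvent]:
    """Add one new species at the extinction-threshold biomass eps.

    A mutant's seed biomass is transferred out of its parent population
    (total biomass unchanged); an invader's is injected from outside (total
    biomass rises by eps).  Separate generators for parent selection and
    trait draws keep the two sources of randomness independently testable.
    """
    parent = select_parent(state, kind, parent_rng if parent_rng is not None else rng)
    z = params.z_mutant if kind == "mutant" else params.z_invader
    m, f, s = draw_traits(parent, z, rng, params)
    child = Species(id=child_id, m=m, f=f, s=s, origin=kind,
                    parent_id=parent.id, birth_time=t)
    B = np.append(state.B, params.eps)
    if kind == "mutant":
        idx = state.species.index(parent)
        B[idx] = max(B[idx] - params.eps, 0.0)
    new_state = CommunityState(t, state.B0, state.species + [child], B)
    return new_state, IntroductionEvent(t, kind, parent.id, child, z)


def init_community(params: Parameters) -> CommunityState:
    """Initial two-node system: basal resource at its consumer-free
    equilibrium n0/l and a single ancestor (m=100, f=1, s=0.4) at biomass eps."""
    ancestor = Species(id=0, m=ANCESTOR_TRAITS[0], f=ANCESTOR_TRAITS[1],
                       s=ANCESTOR_TRAITS[2], origin="ancestor", birth_time=0.0)
    return CommunityState(0.0, params.n0 / params.l, [ancestor],
                          np.array([params.eps]))
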