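"""Coupled biomass dynamics: assemble the ODE right-hand side, integrate
between evolutionary events, and cull species below the extinction threshold.

The state vector is ``[B0, B_1 .. B_n]`` (basal resource first).  Between
introductions the traits of all species are fixed, so the attack-rate and
competition matrices are precomputed once per chunk and the right-hand side
reduces to dense O(n^2) linear algebra.  Chunks are advanced with an
adaptive embedded Runge-Kutta-Fehlberg 4(5) stepper compiled with numba;
the pure-numpy :func:`rhs` is the readable reference form and also returns
the per-link flux ledger used for conservation checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import (
    CommunityState,
    Parameters,
    attack_matrix,
    competition_matrix,
    handling_time,
    metabolic_loss,
)

__all__ = [
    "RhsEvaluation",
    "IntegrationFailure",
    "rhs",
    "integrate",
    "cull_extinct",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-12


class IntegrationFailure(RuntimeError):
    """Raised when the adaptive stepper cannot advance the state.

    The experiment driver treats this as a failed run and restarts with a
    fresh seed rather than silently continuing from a corrupt state.
    """


@dataclass
class RhsEvaluation:
    """One right-hand-side evaluation with optional per-link diagnostics.

    ``flux[i, j]`` is the biomass flow g_ij * B_i * B_j from prey j (column
    0 = basal resource) into consumer i, *before* assimilation losses; the
    consumer banks e times this amount.
    """

    dB0: float
    dB: np.ndarray
    flux: np.ndarray | None = None


def _rate_arrays(state: CommunityState, params: Parameters):
    m = state.masses()
    A = attack_matrix(state.species, params)
    C = competition_matrix(state.species, params)
    h = np.array([handling_time(mi, params) for mi in m])
    x = np.array([metabolic_loss(mi, params) for mi in m])
    return m, A, C, h, x


def rhs(state: CommunityState, params: Parameters, with_flux: bool = False) -> RhsEvaluation:
    """Time derivatives of all biomasses (reference numpy implementation).

    Consumers gain ``e * g_ij * B_i * B_j`` summed over prey (basal resource
    plus every extant species), lose to predation by every other consumer,
    to interference competition against all distinct consumers, and to
    metabolism.  The basal resource has constant inflow n0, linear outflow
    l*B0, and consumption losses.
    """
    if not (np.isfinite(state.B0) and np.all(np.isfinite(state.B))):
        raise IntegrationFailure("non-finite biomass in state")
    n = state.n
    y = np.concatenate(([state.B0], state.B))
    if n == 0:
        dB0 = params.n0 - params.l * state.B0
        return RhsEvaluation(dB0, np.empty(0), np.zeros((0, 1)) if with_flux else None)
    m, A, C, h, x = _rate_arrays(state, params)
    W = A @ y                              # per-consumer handled-prey biomass
    denom = 1.0 + h * W
    q = state.B / (m * denom)              # B_i * (per-attack g scale)
    flux = A * q[:, None] * y[None, :]     # g_ij B_i B_j
    gain = params.e * flux.sum(axis=1)
    pred = A.T @ q                         # summed g over consumers, per prey column
    dB = gain - state.B * pred[1:] - state.B * (C @ state.B) - x * state.B
    dB0 = params.n0 - params.l * state.B0 - state.B0 * pred[0]
    return RhsEvaluation(dB0, dB, flux if with_flux else None)


# ---------------------------------------------------------------------------
# Runge-Kutta-Fehlberg 4(5) core
# ---------------------------------------------------------------------------
# Classic Fehlberg tableau; the 5th-order solution is propagated and the
# 4th/5th difference drives the step-size controller.

@njit(cache=True)
def _deriv(y, A, C, h, x, m, e, n0, l, out):
    n = A.shape[0]
    out[0] = n0 - l * y[0]
    pred = np.zeros(n + 1)
    for i in range(n):
        W = 0.0
        for j in range(n + 1):
            W += A[i, j] * y[j]
        q = y[i + 1] / (m[i] * (1.0 + h[i] * W))
        comp = 0.0
        for j in range(n):
            comp += C[i, j] * y[j + 1]
        out[i + 1] = e * q * W - (comp + x[i]) * y[i + 1]
        for j in range(n + 1):
            pred[j] += A[i, j] * q
    out[0] -= pred[0] * y[0]
    for i in range(n):
        out[i + 1] -= pred[i + 1] * y[i + 1]


@njit(cache=True)
def _rkf45(y, A, C, hvec, xvec, mvec, e, n0, l, span, rtol, atol, max_steps):
    """Advance y over `span` time units in place. Returns a status code:
    0 = ok, 1 = non-finite state, 2 = step-size underflow, 3 = step budget."""
    ndim = y.shape[0]
    k1 = np.empty(ndim); k2 = np.empty(ndim); k3 = np.empty(ndim)
    k4 = np.empty(ndim); k5 = np.empty(ndim); k6 = np.empty(ndim)
    ytmp = np.empty(ndim)
    y5 = np.empty(ndim)
    t = 0.0
    dt = min(1.0, span)
    steps = 0
    while t < span:
        if steps >= max_steps:
            return 3
        if dt > span - t:
            dt = span - t
        _deriv(y, A, C, hvec, xvec, mvec, e, n0, l, k1)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * 0.25 * k1[i]
        _deriv(ytmp, A, C, hvec, xvec, mvec, e, n0, l, k2)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * (3.0 / 32.0 * k1[i] + 9.0 / 32.0 * k2[i])
        _deriv(ytmp, A, C, hvec, xvec, mvec, e, n0, l, k3)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * (1932.0 / 2197.0 * k1[i]
                                   - 7200.0 / 2197.0 * k2[i]
                                   + 7296.0 / 2197.0 * k3[i])
        _deriv(ytmp, A, C, hvec, xvec, mvec, e, n0, l, k4)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * (439.0 / 216.0 * k1[i] - 8.0 * k2[i]
                                   + 3680.0 / 513.0 * k3[i]
                                   - 845.0 / 4104.0 * k4[i])
        _deriv(ytmp, A, C, hvec, xvec, mvec, e, n0, l, k5)
        for i in range(ndim):
            ytmp[i] = y[i] + dt * (-8.0 / 27.0 * k1[i] + 2.0 * k2[i]
                                   - 3544.0 / 2565.0 * k3[i]
                                   + 1859.0 / 4104.0 * k4[i]
                                   - 11.0 / 40.0 * k5[i])
        _deriv(ytmp, A, C, hvec, xvec, mvec, e, n0, l, k6)
        err = 0.0
        ok = True
        for i in range(ndim):
            y5[i] = y[i] + dt * (16.0 / 135.0 * k1[i]
                                 + 6656.0 / 12825.0 * k3[i]
                                 + 28561.0 / 56430.0 * k4[i]
                                 - 9.0 / 50.0 * k5[i]
                                 + 2.0 / 55.0 * k6[i])
            y4 = y[i] + dt * (25.0 / 216.0 * k1[i]
                              + 1408.0 / 2565.0 * k3[i]
                              + 2197.0 / 4104.0 * k4[i]
                              - 0.2 * k5[i])
            if not np.isfinite(y5[i]):
                ok = False
                break
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            d = (y5[i] - y4) / sc
            err += d * d
        steps += 1
        if ok:
            err = math.sqrt(err / ndim)
        if ok and err <= 1.0:
            t += dt
            for i in range(ndim):
                # negative excursions are integration noise at the atol
                # scale; biomass is clamped to the physical domain
                y[i] = y5[i] if y5[i] > 0.0 else 0.0
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            dt *= fac
        else:
            dt *= 0.2 if not ok else max(0.2, 0.9 * err ** -0.2)
        if dt < 1e-12:
            return 2
        if not np.isfinite(y).all():
            return 1
    return 0


def integrate(
    state: CommunityState,
    t_span: float,
    params: Parameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = 10_000_000,
) -> CommunityState:
    """Advance the community by ``t_span`` time units.

    Deterministic given (state, params, tolerances).  A zero span returns a
    copy unchanged; a failed step (blow-up or step underflow) raises
    :class:`IntegrationFailure` for the caller's restart policy.
    """
    if t_span < 0:
        raise ValueError("t_span must be non-negative")
    if t_span == 0:
        return state.copy()
    m, A, C, h, x = _rate_arrays(state, params)
    y = np.concatenate(([state.B0], state.B))
    status = _rkf45(y, A, C, h, x, m, params.e, params.n0, params.l,
                    float(t_span), rtol, atol, max_steps)
    if status != 0:
        reasons = {1: "non-finite state", 2: "step-size underflow", 3: "step budget exhausted"}
        raise IntegrationFailure(f"RKF45 failed at t={state.t}: {reasons[status]}")
    return CommunityState(state.t + t_span, float(y[0]), list(state.species), y[1:])


def cull_extinct(
    state: CommunityState, params: Parameters, t_now: float | None = None
) -> tuple[CommunityState, list]:
    """Remove every species whose biomass fell strictly below eps.

    A biomass of exactly eps survives: species are *introduced* at eps, and
    removal applies only once a population has fallen below the threshold.
    The basal resource is never removed.  Removed species get their
    death_time stamped.
    """
    t = state.t if t_now is None else t_now
    keep = state.B >= params.eps
    removed = [sp for sp, k in zip(state.species, keep) if not k]
    for sp in removed:
        sp.death_time = t
    survivors = [sp for sp, k in zip(state.species, keep) if k]
    return CommunityState(t, state.B0, survivors, state.B[keep]), removed
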