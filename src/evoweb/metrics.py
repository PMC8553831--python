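"""Disturbance, generalism and persistence metrics for simulation records.

Three groups of statistics summarise one run:

* disturbance — standard deviation of the basal-resource and community
  biomass series, and mean species turnover (Jaccard dissimilarity of
  consecutive composition snapshots);
* generalism — mean/median fundamental feeding range of viable mutants,
  and the realized feeding range: the fraction of the community a consumer
  attacks at >= 10% of its own maximum attack rate;
* persistence — the lifespan-vs-feeding-range regression slope (gamma GLM,
  log link) and mean lifespans of specialist (s <= 0.32) and generalist
  (s >= 0.39) bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .model_core import Parameters
from .stats import glm_fit

__all__ = [
    "UndefinedMetric",
    "SimMetrics",
    "sd_resource",
    "sd_community",
    "turnover_series",
    "mean_turnover",
    "mutant_range_summary",
    "realized_range",
    "mean_realized_range",
    "lifespan_slope",
    "binned_persistence",
    "compute_metrics",
    "metrics_table",
    "REALIZED_THRESHOLD",
    "SPECIALIST_MAX",
    "GENERALIST_MIN",
]

REALIZED_THRESHOLD = 0.1
SPECIALIST_MAX = 0.32
GENERALIST_MIN = 0.39
DEFAULT_BURN_IN = 50_000.0
MIN_SURVIVAL = 100.0


class UndefinedMetric(ValueError):
    """The metric is not defined for this record (too few points / empty filter)."""


@dataclass
class SimMetrics:
    """Per-simulation metric row for the z-sweep analysis."""

    z: float
    seed: int
    sd_resource: float
    sd_community: float
    mean_turnover: float
    mean_mutant_s: float
    median_mutant_s: float
    mean_realized_range: float
    lifespan_slope: float
    mean_lifespan_generalist: float
    mean_lifespan_specialist: float


def _series_sd(values: np.ndarray, what: str) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedMetric(f"{what} SD needs at least 2 output points, got {values.size}")
    return float(np.std(values, ddof=1))


def sd_resource(record) -> float:
    """Sample SD of the basal-resource biomass series (time 0 excluded)."""
    return _series_sd(record.resource_series["B0"].to_numpy(), "resource")


def sd_community(record) -> float:
    """Sample SD of the summed community biomass series."""
    return _series_sd(record.community_series["biomass"].to_numpy(), "community")


def turnover_series(record) -> np.ndarray:
    """Jaccard dissimilarity of consecutive extant-species sets.

    For snapshots A then B: (|A \\ B| + |B \\ A|) / |A u B|, in [0, 1];
    0 for identical sets, 1 for disjoint ones, 0 by convention when both
    are empty.
    """
    snaps = record.composition_snapshots
    if len(snaps) < 2:
        raise UndefinedMetric("turnover needs at least 2 composition snapshots")
    out = []
    for (_, a), (_, b) in zip(snaps, snaps[1:]):
        union = a | b
        out.append(0.0 if not union else (len(a - b) + len(b - a)) / len(union))
    return np.array(out)


def mean_turnover(record) -> float:
    return float(turnover_series(record).mean())


def _ledger_frame(ledger) -> pd.DataFrame:
    return ledger if isinstance(ledger, pd.DataFrame) else ledger.to_frame()


def mutant_range_summary(
    ledger,
    burn_in: float = DEFAULT_BURN_IN,
    min_survival: float = MIN_SURVIVAL,
) -> tuple[float, float]:
    """Mean and median feeding range of viable mutants.

    Keeps mutant-origin species born after the burn-in that survived at
    least ``min_survival`` time units (censored species count as surviving).
    Mutants only: invader traits are manipulated directly by the experiment
    and would contaminate an evolved-generalism signal.
    """
    df = _ledger_frame(ledger)
    survived = df["censored"] | (df["lifespan"] >= min_survival)
    keep = (df["origin"] == "mutant") & survived & (df["birth_time"] >= burn_in)
    if not keep.any():
        raise UndefinedMetric("no viable mutants after filtering")
    s = df.loc[keep, "s"]
    return float(s.mean()), float(s.median())


def realized_range(
    consumer_traits: tuple[float, float, float],
    community_traits: list[tuple[float, float, float]],
    params: Parameters,
    threshold: float = REALIZED_THRESHOLD,
) -> float:
    """Fraction of community entities attacked at >= ``threshold`` of the
    consumer's maximum attack rate.

    Entities are the basal resource plus every extant species *including
    the focal consumer itself*.  The ratio attack/max-attack reduces to
    exp(-(log10 f - log10 m_j)^2 / (2 s^2)), so an entity passes exactly
    when |log10 f - log10 m_j| <= s * sqrt(-2 ln(threshold)).
    """
    _, f, s = consumer_traits
    masses = [params.m0] + [m for m, _, _ in community_traits]
    log_f = math.log10(f)
    # boundary-inclusive at float precision: a prey sitting exactly on the
    # threshold locus |dlog10| = s*sqrt(-2 ln threshold) must count
    cut = threshold * (1.0 - 1e-12)
    hits = sum(
        1 for m in masses
        if math.exp(-((log_f - math.log10(m)) ** 2) / (2 * s * s)) >= cut
    )
    return hits / len(masses)


def mean_realized_range(record, threshold: float = REALIZED_THRESHOLD) -> float:
    """Mean realized feeding range over all consumers at all community
    snapshots (species introduced at a snapshot time are excluded)."""
    traits = record.traits()
    params = record.config.params
    vals = []
    for _, ids in record.community_snapshots:
        community = [traits[i] for i in sorted(ids)]
        for tr in community:
            vals.append(realized_range(tr, community, params, threshold))
    if not vals:
        raise UndefinedMetric("no community snapshots for realized range")
    return float(np.mean(vals))


def lifespan_slope(ledger, min_rows: int = 10) -> float:
    """Slope of species lifespan on log10 feeding range.

    Gamma-family GLM with log link on uncensored species; positive slopes
    mean generalists outlive specialists.  The fit is flagged undefined for
    degenerate designs (too few species or constant s).
    """
    df = _ledger_frame(ledger)
    df = df[~df["censored"] & (df["lifespan"] > 0)]
    if len(df) < min_rows:
        raise UndefinedMetric(f"lifespan slope needs >= {min_rows} uncensored species")
    x = np.log10(df["s"].to_numpy())
    if np.ptp(x) < 1e-12:
        raise UndefinedMetric("feeding range constant across species: slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    fit = glm_fit(df["lifespan"].to_numpy(), X, family="gamma", link="log")
    if not fit.converged:
        raise UndefinedMetric("lifespan GLM did not converge")
    return float(fit.coefficients[1])


def binned_persistence(
    ledger,
    specialist_max: float = SPECIALIST_MAX,
    generalist_min: float = GENERALIST_MIN,
) -> tuple[float, float]:
    """Mean uncensored lifespan of specialist (s <= 0.32) and generalist
    (s >= 0.39) species; intermediate feeding ranges are excluded.

    Returns (specialist_mean, generalist_mean); an empty bin yields NaN.
    """
    df = _ledger_frame(ledger)
    df = df[~df["censored"]]
    spec = df.loc[df["s"] <= specialist_max, "lifespan"]
    gen = df.loc[df["s"] >= generalist_min, "lifespan"]
    return (
        float(spec.mean()) if len(spec) else float("nan"),
        float(gen.mean()) if len(gen) else float("nan"),
    )


def _maybe(fn, *args, **kw) -> float:
    try:
        return fn(*args, **kw)
    except UndefinedMetric:
        return float("nan")


def compute_metrics(record, burn_in: float = DEFAULT_BURN_IN) -> SimMetrics:
    """All per-simulation metrics for one record; undefined ones become NaN."""
    ledger = record.ledger.to_frame()
    mean_s, median_s = (float("nan"), float("nan"))
    try:
        mean_s, median_s = mutant_range_summary(ledger, burn_in=burn_in)
    except UndefinedMetric:
        pass
    spec_mean, gen_mean = binned_persistence(ledger)
    return SimMetrics(
        z=record.z,
        seed=record.seed,
        sd_resource=_maybe(sd_resource, record),
        sd_community=_maybe(sd_community, record),
        mean_turnover=_maybe(mean_turnover, record),
        mean_mutant_s=mean_s,
        median_mutant_s=median_s,
        mean_realized_range=_maybe(mean_realized_range, record),
        lifespan_slope=_maybe(lifespan_slope, ledger),
        mean_lifespan_generalist=gen_mean,
        mean_lifespan_specialist=spec_mean,
    )


def metrics_table(records, burn_in: float = DEFAULT_BURN_IN) -> pd.DataFrame:
    """One SimMetrics row per record, as a DataFrame."""
    rows = [compute_metrics(r, burn_in=burn_in) for r in records]
    return pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(SimMetrics)}
                         for r in rows])
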