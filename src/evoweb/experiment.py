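"""Orchestration of whole simulations and the invader-strangeness sweep.

A run starts from the two-node ancestor system and repeats the assembly
cycle — integrate the ODEs for one introduction interval, cull species
below the extinction threshold, introduce one new species, record any due
outputs — until the horizon.  Output cadence follows the three-interval
design: the species ledger tracks every introduction and removal (the
100-step granularity), community and resource biomass are sampled at the
community-output interval, and species-composition snapshots at the
turnover interval.  A community-level extinction or integrator failure
triggers a restart with a fresh seed; the restart count is kept.

``run_sweep`` runs one simulation per (z, replicate) cell over a grid of
invader-strangeness values, the experiment that probes how invader novelty
disturbs the community and reshapes diet-breadth evolution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly
from .assembly import CommunityCollapse, init_community, introduce, choose_kind
from .dynamics import DEFAULT_ATOL, DEFAULT_RTOL, IntegrationFailure, cull_extinct, integrate
from .model_core import CommunityState, Parameters, Species, attack_matrix

__all__ = [
    "RunConfig",
    "SpeciesLedger",
    "SimulationRecord",
    "introduction_times",
    "run_simulation",
    "run_sweep",
    "default_z_grid",
    "desk_config",
    "write_record",
    "load_ledger",
    "snapshot_edges",
    "export_graphml",
]

logger = logging.getLogger("evoweb")


@dataclass(frozen=True)
class RunConfig:
    """One simulation's full configuration: model parameters plus recording
    cadence, integrator tolerances and the restart policy.

    Production-scale defaults match the reference study design (horizon
    2.5e7 inside ``params``, community output every 50,000, turnover every
    10,000).  ``desk_config`` builds the scaled-down profile used for
    desk-scale experiments.
    """

    params: Parameters = field(default_factory=Parameters)
    community_interval: float = 50_000.0
    turnover_interval: float = 10_000.0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    max_restarts: int = 20
    cull_substeps: int = 1   # culling checks per introduction interval

    def __post_init__(self) -> None:
        dt = self.params.intro_interval
        for name in ("community_interval", "turnover_interval"):
            if getattr(self, name) % dt != 0:
                raise ValueError(f"{name} must be a multiple of the introduction interval")
        if self.cull_substeps < 1:
            raise ValueError("cull_substeps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = Parameters(**d["params"])
        return cls(**d)


class SpeciesLedger:
    """Append-only record of every species ever introduced in one run."""

    def __init__(self) -> None:
        self._species: list[Species] = []

    def append(self, sp: Species) -> None:
        self._species.append(sp)

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self):
        return iter(self._species)

    def to_frame(self) -> pd.DataFrame:
        """One row per species; extant-at-horizon species are censored."""
        rows = []
        for sp in self._species:
            rows.append({
                "id": sp.id,
                "origin": sp.origin,
                "parent_id": -1 if sp.parent_id is None else sp.parent_id,
                "m": sp.m,
                "f": sp.f,
                "s": sp.s,
                "birth_time": sp.birth_time,
                "death_time": np.nan if sp.death_time is None else sp.death_time,
                "censored": sp.death_time is None,
            })
        df = pd.DataFrame(rows)
        df["lifespan"] = df["death_time"] - df["birth_time"]
        return df


@dataclass
class SimulationRecord:
    """All outputs of one completed run."""

    config: RunConfig
    seed: int
    attempts: int
    ledger: SpeciesLedger
    resource_series: pd.DataFrame     # columns t, B0
    community_series: pd.DataFrame    # columns t, biomass
    composition_snapshots: list       # (t, frozenset of extant ids), turnover cadence
    community_snapshots: list         # (t, frozenset of extant ids), community cadence
    final_state: CommunityState

    @property
    def z(self) -> float:
        return self.config.params.z_invader

    @property
    def status(self) -> str:
        return "completed" if self.attempts == 1 else f"restarted({self.attempts - 1})"

    def traits(self) -> dict[int, tuple[float, float, float]]:
        """Map species id -> (m, f, s) for snapshot-based metrics."""
        return {sp.id: (sp.m, sp.f, sp.s) for sp in self.ledger}


def introduction_times(horizon: float, intro_interval: float) -> np.ndarray:
    """Scheduled introduction times: every interval from the first up to and
    including the horizon — floor(horizon / interval) events in total."""
    k = int(np.floor(horizon / intro_interval))
    return np.arange(1, k + 1) * intro_interval


def _run_once(config: RunConfig, seed_seq: np.random.SeedSequence) -> dict:
    params = config.params
    kind_rng, parent_rng, trait_rng = (np.random.default_rng(s) for s in seed_seq.spawn(3))

    state = init_community(params)
    ledger = SpeciesLedger()
    ledger.append(state.species[0])
    next_id = 1

    dt = params.intro_interval
    n_events = int(np.floor(params.horizon / dt))
    comm_every = int(round(config.community_interval / dt))
    turn_every = int(round(config.turnover_interval / dt))

    resource_rows, community_rows = [], []
    composition, community_snaps = [], []

    sub = config.cull_substeps
    for k in range(1, n_events + 1):
        t = k * dt
        for j in range(sub):
            state = integrate(state, dt / sub, params, config.rtol, config.atol)
            state.t = (k - 1) * dt + (j + 1) * dt / sub  # exact time, no float drift
            state, _ = cull_extinct(state, params, state.t)
        state.t = t
        if state.n == 0:
            raise CommunityCollapse(f"community extinct at t={t}")
        kind = choose_kind(kind_rng, params)
        state, event = introduce(state, kind, trait_rng, params, t, next_id,
                                 parent_rng=parent_rng)
        ledger.append(event.child)
        next_id += 1
        # recording excludes the species introduced at this very time step
        if k % comm_every == 0:
            resident = np.array([sp.birth_time < t for sp in state.species])
            resource_rows.append((t, state.B0))
            community_rows.append((t, float(state.B[resident].sum())))
            community_snaps.append(
                (t, frozenset(sp.id for sp, r in zip(state.species, resident) if r)))
        if k % turn_every == 0:
            composition.append(
                (t, frozenset(sp.id for sp in state.species if sp.birth_time < t)))
        if k % 100 == 0:
            logger.debug("t=%g richness=%d B0=%.4f", t, state.n, state.B0)

    return {
        "ledger": ledger,
        "resource_series": pd.DataFrame(resource_rows, columns=["t", "B0"]),
        "community_series": pd.DataFrame(community_rows, columns=["t", "biomass"]),
        "composition_snapshots": composition,
        "community_snapshots": community_snaps,
        "final_state": state,
    }


def run_simulation(config: RunConfig, seed: int) -> SimulationRecord:
    """Run one simulation to the horizon, restarting with a fresh sub-seed
    after a community collapse or integration failure.

    Deterministic given (config, seed).  Raises after ``max_restarts``
    consecutive failures rather than dropping the run silently.
    """
    last_err: Exception | None = None
    for attempt in range(config.max_restarts + 1):
        try:
            out = _run_once(config, np.random.SeedSequence([seed, attempt]))
        except (CommunityCollapse, IntegrationFailure) as err:
            logger.warning("run seed=%d attempt=%d failed: %s", seed, attempt, err)
            last_err = err
            continue
        return SimulationRecord(config=config, seed=seed, attempts=attempt + 1, **out)
    raise RuntimeError(
        f"simulation failed {config.max_restarts + 1} times (seed={seed}): {last_err}")


def default_z_grid(n: int = 50, lo: float = 0.1, hi: float = 5.0) -> np.ndarray:
    """Evenly spaced invader-strangeness values, production default 50 on [0.1, 5]."""
    return np.linspace(lo, hi, n)


def desk_config(z: float, horizon: float = 200_000.0) -> RunConfig:
    """Scaled-down profile for desk-scale sweeps.

    Shrinks only the horizon and the community-output interval (2,000 time
    units, so the biomass SDs rest on ~100 samples instead of the 4 that
    the production 50,000 cadence would leave at this horizon); every model
    parameter, the turnover interval and the burn-in keep their reference
    values.
    """
    return RunConfig(
        params=Parameters(z_invader=z, horizon=horizon),
        community_interval=2_000.0,
        turnover_interval=10_000.0,
    )


def run_sweep(
    z_grid,
    replicates: int,
    base_config: RunConfig | None = None,
    base_seed: int = 0,
    config_factory=None,
    progress: bool = False,
) -> list[SimulationRecord]:
    """One simulation per (z, replicate) cell.

    ``config_factory(z) -> RunConfig`` overrides ``base_config`` when the
    per-z configuration is not a plain parameter substitution.  Run seeds
    are derived deterministically from ``base_seed`` and the cell index.
    """
    z_grid = np.asarray(list(z_grid), dtype=float)
    if z_grid.size == 0:
        raise ValueError("z grid must be non-empty")
    records = []
    for i, z in enumerate(z_grid):
        for r in range(replicates):
            if config_factory is not None:
                cfg = config_factory(z)
            else:
                base = base_config if base_config is not None else RunConfig()
                cfg = dataclasses.replace(base, params=base.params.with_z(z))
            seed = int(np.random.SeedSequence([base_seed, i, r]).generate_state(1)[0]
                       % (2 ** 31))
            rec = run_simulation(cfg, seed)
            if progress:
                logger.info("z=%.3g replicate=%d done (%s, richness=%d)",
                            z, r, rec.status, rec.final_state.n)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_record(record: SimulationRecord, outdir: str | Path) -> Path:
    """Write one run's outputs as TSV tables plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record.ledger.to_frame().to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    record.resource_series.to_csv(outdir / "resource_series.tsv", sep="\t", index=False)
    record.community_series.to_csv(outdir / "community_series.tsv", sep="\t", index=False)
    for name, snaps in (("composition.tsv", record.composition_snapshots),
                        ("community_snapshots.tsv", record.community_snapshots)):
        df = pd.DataFrame(
            [(t, " ".join(str(i) for i in sorted(ids))) for t, ids in snaps],
            columns=["t", "extant_ids"],
        )
        df.to_csv(outdir / name, sep="\t", index=False)
    manifest = {
        "config": record.config.to_dict(),
        "seed": record.seed,
        "status": record.status,
        "attempts": record.attempts,
        "z": record.z,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_ledger(outdir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "ledger.tsv", sep="\t")


def snapshot_edges(state: CommunityState, params: Parameters) -> pd.DataFrame:
    """Edge list (consumer_id, resource_id, attack_rate) of the current
    network; resource_id 0 denotes the basal resource pool."""
    A = attack_matrix(state.species, params)
    ids = [sp.id for sp in state.species]
    rows = [
        (ids[i], 0 if j == 0 else ids[j - 1], A[i, j])
        for i in range(len(ids))
        for j in range(A.shape[1])
        if A[i, j] > 0
    ]
    return pd.DataFrame(rows, columns=["consumer_id", "resource_id", "attack_rate"])


def export_graphml(state: CommunityState, params: Parameters, path: str | Path) -> None:
    """Write the snapshot network (attack-rate weighted digraph) as GraphML."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_node(0, kind="basal", m=params.m0)
    for sp, b in zip(state.species, state.B):
        g.add_node(sp.id, kind=sp.origin, m=sp.m, f=sp.f, s=sp.s, biomass=float(b))
    for row in snapshot_edges(state, params).itertuples(index=False):
        g.add_edge(int(row.consumer_id), int(row.resource_id),
                   attack_rate=float(row.attack_rate))
    nx.write_graphml(g, str(path))
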