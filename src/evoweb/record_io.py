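"""Read stored run outputs back into metric-ready records.

`experiment.write_record` serialises one run as TSV tables plus a JSON
manifest; :func:`load_record` reconstructs an object with the same metric
surface (ledger, series, snapshots, traits) without re-running dynamics.
The final biomass state is not round-tripped — loaded records serve the
metrics and report stages, not simulation resumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .experiment import RunConfig

__all__ = ["LoadedRecord", "load_record"]


class _FrameLedger:
    """Ledger facade over a stored data frame."""

    def __init__(self, frame: pd.DataFrame) -> None:
        self._frame = frame

    def to_frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)


@dataclass
class LoadedRecord:
    config: RunConfig
    seed: int
    attempts: int
    ledger: _FrameLedger
    resource_series: pd.DataFrame
    community_series: pd.DataFrame
    composition_snapshots: list
    community_snapshots: list

    @property
    def z(self) -> float:
        return self.config.params.z_invader

    def traits(self) -> dict[int, tuple[float, float, float]]:
        df = self.ledger.to_frame()
        return {int(r.id): (r.m, r.f, r.s) for r in df.itertuples(index=False)}


def _read_snapshots(path: Path) -> list:
    if not path.exists():
        return []
    df = pd.read_csv(path, sep="\t", dtype={"extant_ids": str})
    out = []
    for row in df.itertuples(index=False):
        ids = frozenset() if pd.isna(row.extant_ids) or not str(row.extant_ids).strip() \
            else frozenset(int(i) for i in str(row.extant_ids).split())
        out.append((float(row.t), ids))
    return out


def load_record(outdir: str | Path) -> LoadedRecord:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "run_manifest.json").read_text())
    ledger = pd.read_csv(outdir / "ledger.tsv", sep="\t")
    ledger["censored"] = ledger["censored"].astype(bool)
    return LoadedRecord(
        config=RunConfig.from_dict(manifest["config"]),
        seed=int(manifest["seed"]),
        attempts=int(manifest["attempts"]),
        ledger=_FrameLedger(ledger),
        resource_series=pd.read_csv(outdir / "resource_series.tsv", sep="\t"),
        community_series=pd.read_csv(outdir / "community_series.tsv", sep="\t"),
        composition_snapshots=_read_snapshots(outdir / "composition.tsv"),
        community_snapshots=_read_snapshots(outdir / "community_snapshots.tsv"),
    )
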