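"""Curation of odor-threshold records.

Odor thresholds (OT, in nmol) for the same compound are often reported by
more than one literature source.  Curation reconciles those records: the
response is modeled as log10(OT); concordant sources are averaged on the
log scale, discordant compounds are dropped, and every decision is logged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "CompoundRecord",
    "CuratedDataset",
    "log_transform",
    "merge_sources",
    "read_compound_table",
    "write_curated",
]


class CurationError(ValueError):
    """Raised for invalid threshold values or malformed compound tables."""


@dataclass
class CompoundRecord:
    """One odorant with per-source threshold values.

    ``ot_by_source`` maps a source label to an odor threshold in nmol
    (strictly positive).  ``log_ot`` is set once the record is curated.
    """

    id: str
    name: str = ""
    smiles: Optional[str] = None
    ot_by_source: dict[str, float] = field(default_factory=dict)
    log_ot: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CurationError("compound id must be non-empty")
        for source, value in self.ot_by_source.items():
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise CurationError(
                    f"compound {self.id!r}: threshold from source {source!r} "
                    f"must be a positive finite number, got {value!r}"
                )
        if self.log_ot is not None and not math.isfinite(self.log_ot):
            raise CurationError(f"compound {self.id!r}: log_ot must be finite")


@dataclass
class CuratedDataset:
    """Curated records (each with one log_ot) plus the removal log."""

    records: list[CompoundRecord]
    removed: list[tuple[str, str]]
    provenance: list[dict] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "name": [r.name for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "log_ot": [r.log_ot for r in self.records],
            }
        )


def log_transform(ot_nmol: float, compound: str = "?") -> float:
    """Base-10 log of an odor threshold in nmol.

    Raises a domain error naming the compound for non-positive or
    non-finite input.
    """
    if not (isinstance(ot_nmol, (int, float)) and math.isfinite(ot_nmol) and ot_nmol > 0):
        raise CurationError(
            f"compound {compound!r}: odor threshold must be positive and finite, got {ot_nmol!r}"
        )
    return math.log10(ot_nmol)


def merge_sources(records: list[CompoundRecord], delta_max: float = 1.0) -> CuratedDataset:
    """Reconcile per-source thresholds into one log(OT) per compound.

    A compound reported by a single source is kept as-is.  For several
    sources, if the spread between the largest and smallest log10
    threshold is at most ``delta_max`` log-units the values are averaged
    (arithmetic mean on the log scale); otherwise the compound is removed
    as discordant.  Every decision is recorded in the provenance log.
    """
    if delta_max <= 0:
        raise CurationError("delta_max must be positive")
    seen: dict[str, CompoundRecord] = {}
    for rec in records:
        if not rec.ot_by_source:
            raise CurationError(f"compound {rec.id!r} has no source values")
        if rec.id in seen:
            merged = seen[rec.id]
            for source, value in rec.ot_by_source.items():
                if source in merged.ot_by_source:
                    raise CurationError(f"duplicate (id, source) pair: ({rec.id!r}, {source!r})")
                merged.ot_by_source[source] = value
        else:
            seen[rec.id] = CompoundRecord(
                id=rec.id, name=rec.name, smiles=rec.smiles,
                ot_by_source=dict(rec.ot_by_source),
            )

    kept: list[CompoundRecord] = []
    removed: list[tuple[str, str]] = []
    provenance: list[dict] = []
    for rec in seen.values():
        logs = {s: log_transform(v, rec.id) for s, v in sorted(rec.ot_by_source.items())}
        values = list(logs.values())
        spread = max(values) - min(values)
        if len(values) == 1 or spread <= delta_max:
            rec.log_ot = sum(values) / len(values)
            kept.append(rec)
            provenance.append(
                {
                    "id": rec.id,
                    "decision": "kept",
                    "n_sources": len(values),
                    "log_values": logs,
                    "spread": spread,
                    "log_ot": rec.log_ot,
                }
            )
        else:
            removed.append((rec.id, "discordant sources"))
            provenance.append(
                {
                    "id": rec.id,
                    "decision": "removed",
                    "reason": "discordant sources",
                    "n_sources": len(values),
                    "log_values": logs,
                    "spread": spread,
                    "delta_max": delta_max,
                }
            )
    return CuratedDataset(records=kept, removed=removed, provenance=provenance)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table in long or wide CSV dialect.

    Long format: ``id,name,smiles,source,ot_nmol`` (one row per source
    record).  Wide format: ``id,name,smiles,log_ot`` for pre-curated
    data.  The ``smiles`` column may be absent in either dialect.
    """
    df = pd.read_csv(path, dtype={"id": str})
    cols = set(df.columns)
    if {"id", "source", "ot_nmol"} <= cols:
        records = []
        for _, row in df.iterrows():
            records.append(
                CompoundRecord(
                    id=str(row["id"]),
                    name=str(row.get("name", "")),
                    smiles=(str(row["smiles"]) if "smiles" in cols and pd.notna(row["smiles"]) else None),
                    ot_by_source={str(row["source"]): float(row["ot_nmol"])},
                )
            )
        return records
    if {"id", "log_ot"} <= cols:
        records = []
        for _, row in df.iterrows():
            rec = CompoundRecord(
                id=str(row["id"]),
                name=str(row.get("name", "")),
                smiles=(str(row["smiles"]) if "smiles" in cols and pd.notna(row["smiles"]) else None),
            )
            rec.log_ot = float(row["log_ot"])
            if not math.isfinite(rec.log_ot):
                raise CurationError(f"compound {rec.id!r}: log_ot must be finite")
            records.append(rec)
        return records
    raise CurationError(
        "compound table must have columns id,source,ot_nmol (long) or id,log_ot (wide); "
        f"got {sorted(cols)}"
    )


def write_curated(dataset: CuratedDataset, csv_path: str | Path,
                  provenance_path: str | Path | None = None) -> None:
    """Write the curated CSV and, optionally, the JSON provenance log."""
    dataset.to_frame().to_csv(csv_path, index=False)
    if provenance_path is not None:
        with open(provenance_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"removed": [list(t) for t in dataset.removed], "log": dataset.provenance},
                fh, indent=2,
            )
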