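"""Cross-platform nomenclature harmonization and coverage set logic.

Vendors name metabolites idiosyncratically; overlap between platforms can
only be counted after mapping raw names to a shared vocabulary (HMDB IDs).
Names that cannot be mapped stay as *platform-scoped* keys — they count
toward their own platform's coverage but can never inflate an intersection,
so the overlap estimate degrades honestly when nomenclature is
irreconcilable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .io import MeasurementTable

__all__ = [
    "CoverageSet",
    "harmonize",
    "coverage_sets",
    "coverage_overlap",
    "shipment_consistent_classes",
    "coverage_change",
]

UNMAPPED = "unmapped"


@dataclasses.dataclass
class CoverageSet:
    """Harmonized metabolite keys covered by one platform (optionally one shipment)."""

    platform: str
    ids: frozenset[str]
    shipment: int | None = None
    unmapped_count: int = 0


def _scoped_key(platform: str, raw_name: str, hmdb_id: str | None) -> str:
    if hmdb_id:
        return hmdb_id
    return f"{platform}::{raw_name}"


def harmonize(
    table: MeasurementTable, mapping: pd.DataFrame
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Annotate measurements with HMDB IDs and class labels.

    Returns the annotated table (columns ``hmdb_id``, ``class_label``,
    ``harmonized_key`` added) and an unmapped report listing, per platform,
    every raw name absent from the map or mapped without an HMDB ID.
    Unmapped names are a reported state, never an error, and are never
    dropped: precision statistics run on raw (platform-scoped) keys.
    """
    df = table.df.copy()
    m = mapping[["platform", "raw_name", "hmdb_id", "class_label"]].rename(
        columns={"raw_name": "metabolite"}
    )
    df = df.merge(m, on=["platform", "metabolite"], how="left")
    df["class_label"] = df["class_label"].fillna(UNMAPPED)
    df["hmdb_id"] = df["hmdb_id"].where(df["hmdb_id"].notna(), None)
    df["harmonized_key"] = [
        _scoped_key(p, n, h) for p, n, h in zip(df["platform"], df["metabolite"], df["hmdb_id"])
    ]
    unmapped = (
        df.loc[df["hmdb_id"].isna(), ["platform", "metabolite"]]
        .drop_duplicates()
        .sort_values(["platform", "metabolite"])
        .reset_index(drop=True)
    )
    out = MeasurementTable(df, validate=False)
    return out, unmapped


def coverage_sets(
    table: MeasurementTable, per_shipment: bool = False
) -> list[CoverageSet]:
    """Coverage set per platform (requires a harmonized table).

    A metabolite is covered if it has at least one non-missing measurement.
    """
    df = table.df
    if "harmonized_key" not in df.columns:
        raise ValueError("table must be harmonized first (no harmonized_key column)")
    obs = df[~df["missing"]]
    keys = ["platform", "shipment"] if per_shipment else ["platform"]
    sets = []
    for name, sub in obs.groupby(keys):
        platform = name[0] if isinstance(name, tuple) else name
        shipment = int(name[1]) if per_shipment else None
        ids = frozenset(sub["harmonized_key"])
        unmapped_count = int(sub.loc[sub["hmdb_id"].isna(), "harmonized_key"].nunique())
        sets.append(CoverageSet(platform=platform, ids=ids, shipment=shipment, unmapped_count=unmapped_count))
    return sets


def coverage_overlap(sets: Sequence[CoverageSet]) -> dict:
    """Region counts and memberships for every Venn region of 2–5 platforms.

    Regions are keyed by bitmask over the input order (bit *i* set ⇔ the key
    is present in ``sets[i]``); all ``2^k − 1`` non-empty-mask regions are
    reported, and the counts sum to the size of the union.
    """
    k = len(sets)
    if not 2 <= k <= 5:
        raise ValueError(f"need between 2 and 5 coverage sets, got {k}")
    universe = set().union(*(s.ids for s in sets))
    regions: dict[int, list[str]] = {mask: [] for mask in range(1, 2**k)}
    for key in universe:
        mask = 0
        for i, s in enumerate(sets):
            if key in s.ids:
                mask |= 1 << i
        regions[mask].append(key)
    return {
        "platforms": [s.platform for s in sets],
        "regions": {mask: sorted(members) for mask, members in regions.items()},
        "counts": {mask: len(members) for mask, members in regions.items()},
        "union_size": len(universe),
    }


def shipment_consistent_classes(table: MeasurementTable) -> pd.DataFrame:
    """Per platform, the metabolite classes observed in *both* shipments.

    A class is kept for a platform iff at least one metabolite of that class
    has a non-missing value in shipment 1 AND in shipment 2; classes seen in
    only one shipment reflect unstable coverage and are dropped.
    """
    df = table.df
    if "class_label" not in df.columns:
        raise ValueError("table must be harmonized first (no class_label column)")
    present = set(df["shipment"].unique())
    for s in (1, 2):
        if s not in present:
            raise ValueError(f"table lacks shipment {s}; both shipments are required")
    obs = df[~df["missing"]]
    seen = obs.groupby(["platform", "class_label"])["shipment"].agg(lambda s: set(s))
    rows = [
        {"platform": p, "class_label": c, "consistent": {1, 2} <= ships}
        for (p, c), ships in seen.items()
    ]
    return pd.DataFrame(rows).sort_values(["platform", "class_label"]).reset_index(drop=True)


def coverage_change(n1: int, n2: int) -> float:
    """Signed percent change in metabolite count between shipments, 100·(n2−n1)/n1."""
    if n1 <= 0:
        raise ValueError("shipment-1 count must be positive")
    return round(100.0 * (n2 - n1) / n1, 1)
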