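"""Technical-replicate precision: intra- and inter-assay CV%.

Duplicate aliquots of each parent sample travel in both of two identical
shipments.  Within a shipment the duplicates (a₁, b₁) measure *intra-assay*
precision; matching the same aliquot slot across shipments (a₁ ↔ a₂)
measures *inter-assay* precision, i.e. run-to-run drift over the weeks
separating the two analyses.

For a duplicate pair the CV% is 100·s/m with m the pair mean and s the
two-point sample standard deviation (n−1 denominator), so s = |a−b|/√2.
Metabolite-level CV% is the unweighted mean over complete pairs; pairs with
a missing member are skipped, never imputed.  Because the two-point sample
SD is a biased estimator of σ (E[s] = √(2/π)·σ), a root-mean-square
aggregate is also carried (``cv_pct_rms``): squared CVs estimate variances,
which pool linearly, so the RMS is the right scale on which to recover a
generative noise parameter (see the synthetic-data module).

Class summaries report the unweighted mean over the metabolites of a class
with an n−1 SD, count and min–max range, and a traffic-light category:
high ≤ 10%, moderate strictly between 10 and 20%, low ≥ 20%.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MeasurementTable

__all__ = [
    "HIGH",
    "MODERATE",
    "LOW",
    "PrecisionSummary",
    "pair_cv",
    "categorize_cv",
    "intra_assay_cv",
    "inter_assay_cv",
    "class_summary",
]

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"


@dataclasses.dataclass(frozen=True)
class PrecisionSummary:
    """Class-level CV% summary for one (platform, class, group)."""

    platform: str
    class_label: str
    group: str
    mean_cv_pct: float
    sd_cv_pct: float | None  # None ("NA") when a single metabolite is in the class
    count: int
    min_cv: float
    max_cv: float
    category: str


def pair_cv(a: float, b: float, *, ddof: int = 1) -> float:
    """CV% of a duplicate pair: 100 · s / mean.

    With ``ddof=1`` (default, the duplicate-CV convention) s = |a−b|/√2;
    ``ddof=0`` gives the population-SD variant s = |a−b|/2.
    """
    if a < 0 or b < 0:
        raise ValueError("pair members must be non-negative")
    m = (a + b) / 2.0
    if m == 0:
        raise ValueError("pair mean is zero; CV undefined")
    s = abs(a - b) / math.sqrt(2.0) if ddof == 1 else abs(a - b) / 2.0
    return 100.0 * s / m


def categorize_cv(cv: float) -> str:
    """Traffic-light precision band: HIGH ≤ 10 < MODERATE < 20 ≤ LOW."""
    if cv < 0 or not np.isfinite(cv):
        raise ValueError(f"CV% must be a finite non-negative number, got {cv}")
    if cv <= 10.0:
        return HIGH
    if cv < 20.0:
        return MODERATE
    return LOW


def _per_metabolite(pairs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate pair CVs to metabolite level (mean, RMS, pair count)."""
    agg = (
        pairs.groupby(["platform", "metabolite"], sort=True)["pair_cv"]
        .agg(
            cv_pct="mean",
            cv_pct_rms=lambda c: float(np.sqrt(np.mean(np.square(c)))),
            n_pairs="size",
        )
        .reset_index()
    )
    return agg


def intra_assay_cv(
    table: MeasurementTable, shipment: int, group: str, *, ddof: int = 1
) -> pd.DataFrame:
    """Metabolite-level intra-assay CV% from within-shipment duplicates.

    For each parent sample the CV of its duplicate aliquots is computed;
    the metabolite CV is the unweighted mean over parent samples with both
    members observed.  Metabolites with zero complete pairs are reported
    with ``n_pairs=0`` and ``cv_pct=NaN`` (not assessable).
    """
    df = table.df
    if group not in set(df["group"]):
        raise ValueError(f"group {group!r} absent from table")
    sub = df[(df["group"] == group) & (df["shipment"] == shipment)]
    obs = sub[~sub["missing"]]
    g = obs.groupby(["platform", "metabolite", "parent_sample_id"])["value"]
    sd = "std" if ddof == 1 else (lambda v: v.std(ddof=ddof))
    stats = g.agg(n="size", mean="mean", sd=sd).reset_index()
    complete = stats[(stats["n"] >= 2) & (stats["mean"] > 0)].copy()
    complete["pair_cv"] = 100.0 * complete["sd"] / complete["mean"]
    pairs = complete[["platform", "metabolite", "pair_cv"]]
    out = _per_metabolite(pairs) if len(pairs) else pd.DataFrame(
        columns=["platform", "metabolite", "cv_pct", "cv_pct_rms", "n_pairs"]
    )
    # metabolites present in the data but with no complete pair → not assessable
    all_mets = sub[["platform", "metabolite"]].drop_duplicates()
    out = all_mets.merge(out, on=["platform", "metabolite"], how="left")
    out["n_pairs"] = pd.to_numeric(out["n_pairs"]).fillna(0).astype(int)
    return out.sort_values(["platform", "metabolite"]).reset_index(drop=True)


def inter_assay_cv(table: MeasurementTable, group: str, *, ddof: int = 1) -> pd.DataFrame:
    """Metabolite-level inter-assay CV% across the two shipments.

    Pairs match the same (parent sample, replicate slot) between shipment 1
    and shipment 2 (a₁↔a₂, b₁↔b₂); the metabolite CV is the unweighted mean
    over all matched pairs with both members observed.
    """
    df = table.df
    if group not in set(df["group"]):
        raise ValueError(f"group {group!r} absent from table")
    shipments = set(df["shipment"].unique())
    if not {1, 2} <= shipments:
        raise ValueError("both shipments are required for inter-assay CV")
    sub = df[df["group"] == group]
    obs = sub[~sub["missing"]]
    wide = obs.pivot_table(
        index=["platform", "metabolite", "parent_sample_id", "replicate_slot"],
        columns="shipment",
        values="value",
        aggfunc="first",
    )
    both = wide.dropna(subset=[1, 2]) if {1, 2} <= set(wide.columns) else wide.iloc[0:0]
    both = both[(both[1] + both[2]) > 0] if len(both) else both
    if len(both):
        a, b = both[1].to_numpy(float), both[2].to_numpy(float)
        denom = math.sqrt(2.0) if ddof == 1 else 2.0
        cv = 100.0 * (np.abs(a - b) / denom) / ((a + b) / 2.0)
        pairs = pd.DataFrame(
            {
                "platform": both.index.get_level_values("platform"),
                "metabolite": both.index.get_level_values("metabolite"),
                "pair_cv": cv,
            }
        )
    else:
        pairs = pd.DataFrame(columns=["platform", "metabolite", "pair_cv"])
    out = _per_metabolite(pairs) if len(pairs) else pd.DataFrame(
        columns=["platform", "metabolite", "cv_pct", "cv_pct_rms", "n_pairs"]
    )
    all_mets = sub[["platform", "metabolite"]].drop_duplicates()
    out = all_mets.merge(out, on=["platform", "metabolite"], how="left")
    out["n_pairs"] = pd.to_numeric(out["n_pairs"]).fillna(0).astype(int)
    return out.sort_values(["platform", "metabolite"]).reset_index(drop=True)


def class_summary(
    metabolite_cvs: pd.DataFrame,
    class_map: Mapping[tuple[str, str], str] | pd.DataFrame,
    group: str | None = None,
) -> pd.DataFrame:
    """Aggregate metabolite CVs to (platform, class[, group]) summaries.

    ``class_map`` is either a {(platform, raw_name): class_label} mapping or
    a harmonization-map frame with platform/raw_name/class_label columns.
    Metabolites without a class label fall into class "unmapped".  The SD is
    the n−1 standard deviation across the metabolites of the class and is
    reported as NA (None) for singleton classes; the category bands the
    class mean CV.
    """
    cvs = metabolite_cvs.dropna(subset=["cv_pct"]).copy()
    if isinstance(class_map, pd.DataFrame):
        lookup = {
            (p, n): c
            for p, n, c in zip(class_map["platform"], class_map["raw_name"], class_map["class_label"])
        }
    else:
        lookup = dict(class_map)
    cvs["class_label"] = [
        lookup.get((p, m), "unmapped") for p, m in zip(cvs["platform"], cvs["metabolite"])
    ]
    group_keys = ["platform", "class_label"] + (["group"] if "group" in cvs.columns else [])
    rows = []
    for keys, sub in cvs.groupby(group_keys, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        c = sub["cv_pct"].to_numpy(float)
        rec = dict(zip(group_keys, keys))
        if group is not None and "group" not in rec:
            rec["group"] = group
        rec.update(
            mean_cv_pct=float(c.mean()),
            sd_cv_pct=float(c.std(ddof=1)) if len(c) > 1 else None,
            count=int(len(c)),
            min_cv=float(c.min()),
            max_cv=float(c.max()),
        )
        rec["category"] = categorize_cv(rec["mean_cv_pct"])
        rows.append(rec)
    cols = ["platform", "class_label", "group", "mean_cv_pct", "sd_cv_pct", "count", "min_cv", "max_cv", "category"]
    out = pd.DataFrame(rows)
    for c in cols:
        if c not in out.columns:
            out[c] = None
    return out[cols]
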