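"""Missingness profiling and the modified 80% rule.

No substitution, ever: a below-threshold or absent measurement stays absent,
because the source of missingness differs between analytical platforms and
imputation would distort distributions and deflate group standard
deviations.  Instead, metabolites whose non-missing proportion falls below
80% in *any* biological group are excluded outright before any summary
statistic is computed.  Vendor-imputed cells (flagged upstream) count as
observed — vendor handling of missing data is passed through unmodified.
"""

from __future__ import annotations

import pandas as pd

from .io import BIOLOGICAL_GROUPS, MeasurementTable

__all__ = ["missingness_profile", "apply_80_rule"]

MIN_PRESENT_FRACTION = 0.80


def missingness_profile(
    table: MeasurementTable, groups: tuple[str, ...] = BIOLOGICAL_GROUPS
) -> pd.DataFrame:
    """Non-missing fraction per (platform, metabolite, group).

    Each replicate aliquot counts as one data element; fractions are in
    [0, 1] over all aliquots shipped for the group.
    """
    df = table.df[table.df["group"].isin(groups)]
    prof = (
        df.groupby(["platform", "metabolite", "group"], sort=True)
        .agg(n_total=("missing", "size"), n_present=("missing", lambda m: int((~m).sum())))
        .reset_index()
    )
    prof["fraction"] = prof["n_present"] / prof["n_total"]
    return prof


def apply_80_rule(
    table: MeasurementTable,
    groups: tuple[str, ...] = BIOLOGICAL_GROUPS,
    *,
    per_shipment: bool = False,
    min_fraction: float = MIN_PRESENT_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain a metabolite iff its non-missing fraction is ≥ 80% in every group.

    The boundary is inclusive: exactly 80% present is retained (only *less
    than* 80% excludes).  Reference (NIST) samples are never a filtering
    group.  By default fractions pool both shipments; ``per_shipment=True``
    requires the threshold within each shipment separately.

    Returns
    -------
    retained:
        Frame (platform, metabolite) of metabolites that survive.
    report:
        Per (platform, metabolite, group[, shipment]) fractions with the
        per-row and overall decision, for the exclusion report.
    """
    if not groups:
        raise ValueError("at least one biological group is required")
    df = table.df
    for g in groups:
        if g not in set(df["group"]):
            raise ValueError(f"group {g!r} absent from table")
    sub = df[df["group"].isin(groups)]
    keys = ["platform", "metabolite", "group"] + (["shipment"] if per_shipment else [])
    prof = (
        sub.groupby(keys, sort=True)
        .agg(n_total=("missing", "size"), n_present=("missing", lambda m: int((~m).sum())))
        .reset_index()
    )
    prof["fraction"] = prof["n_present"] / prof["n_total"]
    prof["passes"] = prof["fraction"] >= min_fraction
    decision = prof.groupby(["platform", "metabolite"])["passes"].all().rename("retained")
    report = prof.merge(decision.reset_index(), on=["platform", "metabolite"])
    report["decision"] = report["retained"].map({True: "retained", False: "excluded"})
    retained = (
        decision[decision]
        .reset_index()[["platform", "metabolite"]]
        .sort_values(["platform", "metabolite"])
        .reset_index(drop=True)
    )
    return retained, report.drop(columns=["retained"])
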