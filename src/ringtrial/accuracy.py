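"""Accuracy against certified reference plasma and dilution linearity.

Accuracy: for every analyte with a certified concentration in the NIST
SRM 1950 Certificate of Analysis, the signed percent difference
100·(reported − COA)/COA is computed from shipment-1 reference-plasma
measurements; a negative value means the platform reports below the
certified concentration.  Only absolute-unit (µM) platforms are scored —
relative-unit platforms have no comparable scale.  The same traffic-light
bands as for precision apply to |percent difference|.

Linearity: the reference plasma is also shipped diluted with saline to 80,
60 and 40% of full strength.  A zero-intercept line is fitted to measured
value vs nominal fraction; R² uses the uncentered (about-zero) total sum of
squares, the standard definition for through-origin regression.  If any of
the four design points is missing, linearity is not assessed for that
metabolite on that platform.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ABSOLUTE_UM, CONTROL, DILUTION_FRACTIONS, NIST, NIST_DILUTION, MeasurementTable, ReferenceCOA
from .precision import categorize_cv

__all__ = [
    "AccuracyRecord",
    "LinearityRecord",
    "percent_accuracy",
    "accuracy_table",
    "fit_zero_intercept",
    "linearity_table",
    "platform_profile",
]


@dataclasses.dataclass(frozen=True)
class AccuracyRecord:
    """Reported-vs-certified concentration comparison for one analyte/platform."""

    analyte: str
    platform: str
    reported: float  # µM
    coa_value: float  # µM
    percent_diff: float  # signed %
    category: str


@dataclasses.dataclass(frozen=True)
class LinearityRecord:
    """Zero-intercept dilution-curve fit for one metabolite/platform."""

    metabolite: str
    platform: str
    slope: float | None
    r_squared: float | None
    n_points: int
    assessed: bool


def percent_accuracy(reported: float, coa: float) -> float:
    """Signed percent deviation from the certified value: 100·(reported−coa)/coa."""
    if coa <= 0:
        raise ValueError("certified reference value must be positive")
    return 100.0 * (reported - coa) / coa


def accuracy_table(
    table: MeasurementTable,
    coa: Sequence[ReferenceCOA],
    shipment: int = 1,
    *,
    nist_stat: str = "mean",
) -> tuple[list[AccuracyRecord], pd.DataFrame]:
    """Score each absolute-unit platform's reference-plasma values against the COA.

    The reported value per analyte is the mean over the shipment's undiluted
    reference aliquots (``nist_stat="first"`` selects a single designated
    aliquot instead).  Relative-unit platforms are excluded; analytes absent
    from the COA are skipped.  Both exclusions are listed in the returned
    skip report.
    """
    df = table.df
    nist = df[(df["group"] == NIST) & (df["shipment"] == shipment) & ~df["missing"]]
    if nist.empty:
        raise ValueError(f"no reference (NIST) samples in shipment {shipment}")
    by_name = {c.analyte: c for c in coa}
    by_hmdb = {c.hmdb_id: c for c in coa if c.hmdb_id}

    records: list[AccuracyRecord] = []
    skipped: list[dict] = []
    for (platform, met), sub in nist.groupby(["platform", "metabolite"], sort=True):
        if (sub["unit_kind"] != ABSOLUTE_UM).any():
            skipped.append({"platform": platform, "metabolite": met, "reason": "relative units"})
            continue
        ref = by_name.get(met)
        if ref is None and "hmdb_id" in sub.columns:
            ids = sub["hmdb_id"].dropna().unique()
            if len(ids):
                ref = by_hmdb.get(ids[0])
        if ref is None:
            skipped.append({"platform": platform, "metabolite": met, "reason": "not in COA"})
            continue
        vals = sub["value"].to_numpy(float)
        reported = float(vals[0]) if nist_stat == "first" else float(vals.mean())
        pct = percent_accuracy(reported, ref.coa_value)
        records.append(
            AccuracyRecord(
                analyte=ref.analyte,
                platform=platform,
                reported=reported,
                coa_value=ref.coa_value,
                percent_diff=pct,
                category=categorize_cv(abs(pct)),
            )
        )
    skip_report = pd.DataFrame(skipped, columns=["platform", "metabolite", "reason"])
    return records, skip_report


def fit_zero_intercept(
    fractions: Sequence[float],
    values: Sequence[float | None],
    *,
    metabolite: str = "",
    platform: str = "",
    design: Sequence[float] = DILUTION_FRACTIONS,
) -> LinearityRecord:
    """Through-origin fit of measured value on nominal dilution fraction.

    Requires a value at every design point (100/80/60/40%); otherwise the
    curve is not assessed.  The slope solves the normal equation Σxy/Σx²
    (computed via OLS without a constant); R² = 1 − Σ(y−ŷ)²/Σy², clipped to
    [0, 1] and snapped to exactly 1.0 when residuals vanish to machine
    precision.
    """
    pts = {
        round(float(f), 6): v
        for f, v in zip(fractions, values)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    }
    needed = [round(f, 6) for f in design]
    if any(f not in pts for f in needed):
        return LinearityRecord(metabolite, platform, None, None, len(pts), False)
    x = np.array(needed, float)
    y = np.array([pts[f] for f in needed], float)
    fit = sm.OLS(y, x[:, None]).fit()
    slope = float(fit.params[0])
    tss = float(np.sum(y**2))
    ssr = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - ssr / tss if tss > 0 else 0.0
    if ssr <= 1e-24 * max(tss, 1.0):  # numerically exact fit
        r2 = 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return LinearityRecord(metabolite, platform, slope, r2, len(needed), True)


def linearity_table(table: MeasurementTable, shipment: int = 1) -> list[LinearityRecord]:
    """Fit the dilution curve for every metabolite on every platform.

    The 100% point is the undiluted reference aliquot (mean over aliquots if
    several); diluted points come from the dilution-series samples of the
    given shipment.
    """
    df = table.df
    nist = df[df["group"].isin([NIST, NIST_DILUTION]) & (df["shipment"] == shipment)]
    records = []
    for (platform, met), sub in nist.groupby(["platform", "metabolite"], sort=True):
        obs = sub[~sub["missing"]]
        frac = obs["dilution_fraction"].fillna(1.0).round(6)
        mean_by_frac = obs.groupby(frac)["value"].mean()
        n_design_obs = sub["dilution_fraction"].fillna(1.0).round(6).nunique()
        rec = fit_zero_intercept(
            mean_by_frac.index.to_list(),
            mean_by_frac.to_list(),
            metabolite=met,
            platform=platform,
        )
        if not rec.assessed:
            rec = dataclasses.replace(rec, n_points=min(n_design_obs, len(mean_by_frac)))
        records.append(rec)
    return records


def platform_profile(table: MeasurementTable, group: str = CONTROL) -> pd.DataFrame:
    """Mean ± SEM of natural-log values per (platform, metabolite) in a group.

    Only absolute-unit platforms are meaningful here (log µM); zero or
    negative values cannot be log-transformed and are excluded with a count.
    """
    df = table.df
    sub = df[(df["group"] == group) & (df["unit_kind"] == ABSOLUTE_UM) & ~df["missing"]]
    rows = []
    for (platform, met), vals in sub.groupby(["platform", "metabolite"], sort=True)["value"]:
        v = vals.to_numpy(float)
        pos = v[v > 0]
        n_excluded = int(len(v) - len(pos))
        if len(pos) == 0:
            rows.append(
                {"platform": platform, "metabolite": met, "log_mean": None, "log_sem": None,
                 "n": 0, "n_excluded": n_excluded, "assessable": False}
            )
            continue
        logs = np.log(pos)
        sem = float(logs.std(ddof=1) / np.sqrt(len(logs))) if len(logs) > 1 else 0.0
        rows.append(
            {"platform": platform, "metabolite": met, "log_mean": float(logs.mean()),
             "log_sem": sem, "n": int(len(logs)), "n_excluded": n_excluded, "assessable": True}
        )
    return pd.DataFrame(
        rows, columns=["platform", "metabolite", "log_mean", "log_sem", "n", "n_excluded", "assessable"]
    )
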