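"""Model/Results interface over the ring-trial QC pipeline.

:class:`RingTrialEvaluation` is built from a measurement table plus the
optional side inputs (harmonization map, certificate of analysis); its
:meth:`~RingTrialEvaluation.fit` runs the full stage order —
harmonize → 80% rule → precision (intra per shipment, inter) → accuracy →
linearity → coverage — and returns a :class:`RingTrialResults` carrying
every stage's tables, the exclusion log, and a text ``summary()``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .accuracy import AccuracyRecord, LinearityRecord, accuracy_table, linearity_table, platform_profile
from .filtering import apply_80_rule
from .harmonization import coverage_change, coverage_overlap, coverage_sets, harmonize, shipment_consistent_classes
from .io import (
    BIOLOGICAL_GROUPS,
    NIST,
    NIST_DILUTION,
    MeasurementTable,
    ReferenceCOA,
    read_coa,
    read_harmonization_map,
    read_measurements,
    write_table,
)
from .precision import class_summary, inter_assay_cv, intra_assay_cv

__all__ = ["PipelineError", "RingTrialEvaluation", "RingTrialResults"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


class RingTrialEvaluation:
    """Cross-platform ring-trial QC evaluation of a measurement table.

    Parameters
    ----------
    table:
        Validated long-format replicate-level measurements.
    harmonization_map:
        Optional raw-name→HMDB-ID→class map frame; without it every
        metabolite is class "unmapped" and keys stay platform-scoped.
    coa:
        Optional certified reference concentrations; defaults to the
        packaged SRM 1950 certificate when reference samples are present.
    groups:
        Biological groups used for filtering and precision (reference
        samples are never a filtering group).
    min_present_fraction:
        The modified 80% rule threshold (inclusive).
    per_shipment_filter:
        Apply the missingness rule within each shipment instead of pooled.
    nist_stat:
        "mean" over reference aliquots (default) or "first" designated one.
    cv_ddof:
        1 (default) for the sample-SD duplicate CV convention |a−b|/√2;
        0 for the population-SD variant.
    """

    def __init__(
        self,
        table: MeasurementTable,
        harmonization_map: pd.DataFrame | None = None,
        coa: Sequence[ReferenceCOA] | None = None,
        *,
        groups: tuple[str, ...] = BIOLOGICAL_GROUPS,
        min_present_fraction: float = 0.80,
        per_shipment_filter: bool = False,
        nist_stat: str = "mean",
        cv_ddof: int = 1,
    ):
        self.table = table
        self.harmonization_map = harmonization_map
        self.coa = list(coa) if coa is not None else None
        self.groups = tuple(groups)
        self.min_present_fraction = min_present_fraction
        self.per_shipment_filter = per_shipment_filter
        self.nist_stat = nist_stat
        self.cv_ddof = cv_ddof

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "RingTrialEvaluation":
        return cls(MeasurementTable(df), **kw)

    @classmethod
    def from_csv(cls, path, dialect=None, harmonization_map_path=None, coa_path=None, **kw):
        table = read_measurements(path, dialect=dialect)
        hmap = read_harmonization_map(harmonization_map_path) if harmonization_map_path else None
        coa = read_coa(coa_path) if coa_path else None
        return cls(table, harmonization_map=hmap, coa=coa, **kw)

    def fit(self) -> "RingTrialResults":
        log: list[str] = []

        def stage(name, fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # abort with stage name and context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        # --- harmonize ---------------------------------------------------
        if self.harmonization_map is not None:
            table, unmapped = stage("harmonize", harmonize, self.table, self.harmonization_map)
            log.append(f"harmonize: {len(unmapped)} unmapped (platform, raw name) pairs")
        else:
            df = self.table.df.copy()
            df["hmdb_id"] = None
            df["class_label"] = "unmapped"
            df["harmonized_key"] = df["platform"] + "::" + df["metabolite"]
            table = MeasurementTable(df, validate=False)
            unmapped = df[["platform", "metabolite"]].drop_duplicates().reset_index(drop=True)
            log.append("harmonize: no map supplied; all metabolites platform-scoped")
        class_map = {
            (p, m): c
            for p, m, c in zip(table.df["platform"], table.df["metabolite"], table.df["class_label"])
        }

        # --- 80% rule ----------------------------------------------------
        retained, exclusion_report = stage(
            "80% rule",
            apply_80_rule,
            table,
            self.groups,
            per_shipment=self.per_shipment_filter,
            min_fraction=self.min_present_fraction,
        )
        n_excl = exclusion_report.loc[exclusion_report["decision"] == "excluded", ["platform", "metabolite"]].drop_duplicates()
        log.append(f"80% rule: retained {len(retained)} (platform, metabolite); excluded {len(n_excl)}")
        keep = set(map(tuple, retained[["platform", "metabolite"]].to_numpy()))
        in_keep = np.array(
            [(p, m) in keep for p, m in zip(table.df["platform"], table.df["metabolite"])], dtype=bool
        )
        kept_df = table.df[in_keep | table.df["group"].isin([NIST, NIST_DILUTION]).to_numpy()]
        kept = MeasurementTable(kept_df, validate=False)

        # --- precision ---------------------------------------------------
        shipments = kept.shipments
        intra_frames = []
        for s in shipments:
            for g in self.groups:
                f = stage("intra-assay CV", intra_assay_cv, kept, s, g, ddof=self.cv_ddof)
                f.insert(0, "shipment", s)
                f.insert(1, "group", g)
                intra_frames.append(f)
        intra_cv = pd.concat(intra_frames, ignore_index=True)

        if set(shipments) >= {1, 2}:
            inter_frames = []
            for g in self.groups:
                f = stage("inter-assay CV", inter_assay_cv, kept, g, ddof=self.cv_ddof)
                f.insert(0, "group", g)
                inter_frames.append(f)
            inter_cv = pd.concat(inter_frames, ignore_index=True)
        else:
            warnings.warn("single shipment: inter-assay stage skipped", stacklevel=2)
            log.append("inter-assay CV: skipped (single shipment)")
            inter_cv = None

        summ_intra_parts = []
        for s in shipments:
            part = class_summary(intra_cv[intra_cv["shipment"] == s], class_map)
            part.insert(0, "shipment", s)
            summ_intra_parts.append(part)
        class_summary_intra = pd.concat(summ_intra_parts, ignore_index=True)
        class_summary_intra = _add_pooled_range(class_summary_intra, extra_keys=["shipment"])
        class_summary_inter = None
        if inter_cv is not None:
            class_summary_inter = _add_pooled_range(class_summary(inter_cv, class_map), extra_keys=[])

        # --- accuracy ----------------------------------------------------
        accuracy: list[AccuracyRecord] = []
        accuracy_skips = pd.DataFrame(columns=["platform", "metabolite", "reason"])
        has_nist = (table.df["group"] == NIST).any()
        if has_nist:
            coa = self.coa if self.coa is not None else read_coa()
            accuracy, accuracy_skips = stage(
                "accuracy", accuracy_table, table, coa, 1 if 1 in shipments else shipments[0],
                nist_stat=self.nist_stat,
            )
            log.append(f"accuracy: {len(accuracy)} analytes scored, {len(accuracy_skips)} skipped")
        else:
            log.append("accuracy: skipped (no reference samples)")

        # --- linearity ---------------------------------------------------
        linearity: list[LinearityRecord] = []
        if (table.df["group"] == NIST_DILUTION).any():
            linearity = stage("linearity", linearity_table, table, 1 if 1 in shipments else shipments[0])
            n_ok = sum(r.assessed for r in linearity)
            log.append(f"linearity: {n_ok}/{len(linearity)} dilution curves assessed")
        else:
            log.append("linearity: skipped (no dilution series)")

        # --- coverage ----------------------------------------------------
        sets = stage("coverage", coverage_sets, table)
        coverage = coverage_overlap(sets) if len(sets) >= 2 else None
        per_ship = stage("coverage", coverage_sets, table, per_shipment=True)
        drift_rows = []
        by_platform: dict[str, dict[int, int]] = {}
        for s in per_ship:
            by_platform.setdefault(s.platform, {})[s.shipment] = len(s.ids)
        for p, counts in sorted(by_platform.items()):
            if {1, 2} <= set(counts):
                drift_rows.append(
                    {"platform": p, "n_shipment1": counts[1], "n_shipment2": counts[2],
                     "percent_change": coverage_change(counts[1], counts[2])}
                )
        coverage_drift = pd.DataFrame(drift_rows, columns=["platform", "n_shipment1", "n_shipment2", "percent_change"])
        consistent = None
        if set(shipments) >= {1, 2}:
            consistent = stage("coverage", shipment_consistent_classes, table)
        profile = stage("profile", platform_profile, table)

        return RingTrialResults(
            model=self,
            table=table,
            unmapped=unmapped,
            retained=retained,
            exclusion_report=exclusion_report,
            intra_cv=intra_cv,
            inter_cv=inter_cv,
            class_summary_intra=class_summary_intra,
            class_summary_inter=class_summary_inter,
            accuracy=accuracy,
            accuracy_skips=accuracy_skips,
            linearity=linearity,
            coverage=coverage,
            coverage_drift=coverage_drift,
            consistent_classes=consistent,
            profile=profile,
            log=log,
        )


def _add_pooled_range(summary: pd.DataFrame, extra_keys: list[str]) -> pd.DataFrame:
    """Add both-group pooled min/max CV alongside the per-group ranges."""
    keys = extra_keys + ["platform", "class_label"]
    pooled = summary.groupby(keys).agg(pooled_min_cv=("min_cv", "min"), pooled_max_cv=("max_cv", "max")).reset_index()
    return summary.merge(pooled, on=keys)


@dataclasses.dataclass
class RingTrialResults:
    """Fitted ring-trial QC results: one attribute per pipeline stage."""

    model: RingTrialEvaluation
    table: MeasurementTable
    unmapped: pd.DataFrame
    retained: pd.DataFrame
    exclusion_report: pd.DataFrame
    intra_cv: pd.DataFrame
    inter_cv: pd.DataFrame | None
    class_summary_intra: pd.DataFrame
    class_summary_inter: pd.DataFrame | None
    accuracy: list[AccuracyRecord]
    accuracy_skips: pd.DataFrame
    linearity: list[LinearityRecord]
    coverage: dict | None
    coverage_drift: pd.DataFrame
    consistent_classes: pd.DataFrame | None
    profile: pd.DataFrame
    log: list[str]

    @property
    def accuracy_frame(self) -> pd.DataFrame:
        cols = ["analyte", "platform", "reported", "coa_value", "percent_diff", "category"]
        return pd.DataFrame([dataclasses.asdict(r) for r in self.accuracy], columns=cols)

    @property
    def linearity_frame(self) -> pd.DataFrame:
        cols = ["metabolite", "platform", "slope", "r_squared", "n_points", "assessed"]
        return pd.DataFrame([dataclasses.asdict(r) for r in self.linearity], columns=cols)

    def summary(self) -> str:
        """Human-readable overview of all fitted stages."""
        lines = ["Ring-trial QC evaluation", "=" * 24]
        df = self.table.df
        lines.append(
            f"platforms: {', '.join(self.table.platforms)}; shipments: {self.table.shipments}; "
            f"{df['metabolite'].nunique()} metabolites; {len(df)} measurements"
        )
        lines.append(f"retained after 80% rule: {len(self.retained)} (platform, metabolite) series")
        for label, cs in (("intra-assay", self.class_summary_intra), ("inter-assay", self.class_summary_inter)):
            if cs is None or cs.empty:
                continue
            counts = cs["category"].value_counts()
            mean_cv = cs["mean_cv_pct"].mean()
            lines.append(
                f"{label} CV: {len(cs)} class summaries, grand mean {mean_cv:.2f}% "
                f"(HIGH {counts.get('HIGH', 0)} / MODERATE {counts.get('MODERATE', 0)} / LOW {counts.get('LOW', 0)})"
            )
        if self.accuracy:
            af = self.accuracy_frame
            lines.append(
                f"accuracy vs certificate: {len(af)} analyte×platform records, "
                f"median |percent diff| {af['percent_diff'].abs().median():.2f}%"
            )
        if self.linearity:
            lf = self.linearity_frame
            ok = lf[lf["assessed"]]
            if len(ok):
                lines.append(
                    f"dilution linearity: {len(ok)}/{len(lf)} curves assessed, median R² {ok['r_squared'].median():.4f}"
                )
        if self.coverage is not None:
            lines.append(
                f"coverage: union {self.coverage['union_size']} harmonized keys over "
                f"{len(self.coverage['platforms'])} platforms ({len(self.coverage['counts'])} Venn regions)"
            )
        if not self.coverage_drift.empty:
            drift = ", ".join(
                f"{r.platform}: {r.percent_change:+.1f}%" for r in self.coverage_drift.itertuples()
            )
            lines.append(f"shipment coverage change: {drift}")
        return "\n".join(lines)

    def save(self, outdir: str | Path, seed: int | None = None) -> Path:
        """Write every report file plus a run manifest to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.intra_cv.to_csv(outdir / "metabolite_cvs_intra.csv", index=False)
        if self.inter_cv is not None:
            self.inter_cv.to_csv(outdir / "metabolite_cvs_inter.csv", index=False)
        self.class_summary_intra.to_csv(outdir / "class_summary_intra.csv", index=False)
        if self.class_summary_inter is not None:
            self.class_summary_inter.to_csv(outdir / "class_summary_inter.csv", index=False)
        write_table(self.accuracy_frame, outdir / "accuracy.csv", columns=["analyte", "platform", "reported", "coa_value", "percent_diff", "category"])
        write_table(self.linearity_frame, outdir / "linearity.csv", columns=["metabolite", "platform", "slope", "r_squared", "n_points", "assessed"])
        self.exclusion_report.to_csv(outdir / "exclusions.csv", index=False)
        cov = {
            "overlap": None
            if self.coverage is None
            else {
                "platforms": self.coverage["platforms"],
                "counts": {str(k): v for k, v in self.coverage["counts"].items()},
                "regions": {str(k): v for k, v in self.coverage["regions"].items()},
                "union_size": self.coverage["union_size"],
            },
            "drift": self.coverage_drift.to_dict(orient="records"),
            "consistent_classes": None
            if self.consistent_classes is None
            else self.consistent_classes.to_dict(orient="records"),
        }
        (outdir / "coverage.json").write_text(json.dumps(cov, indent=1, sort_keys=True))
        manifest = {
            "version": _version,
            "seed": seed,
            "stages": self.log,
            "conventions": {
                "cv": "100·s/m, s the n−1 (sample) SD of the duplicate pair, |a−b|/√2"
                if self.model.cv_ddof == 1
                else "100·s/m, population (n) SD of the duplicate pair, |a−b|/2",
                "r_squared": "uncentered (through-origin): 1 − Σ(y−ŷ)²/Σy², clipped to [0,1]",
                "categories": "HIGH ≤ 10% < MODERATE < 20% ≤ LOW (accuracy bands on |percent diff|)",
                "missingness": "no substitution; 80% rule threshold "
                + f"{self.model.min_present_fraction:.2f} (inclusive), pooled"
                + ("" if not self.model.per_shipment_filter else " per shipment"),
            },
        }
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")
        return outdir
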