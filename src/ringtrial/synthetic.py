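"""Synthetic ring-trial data with known variance components.

The generator emulates the evaluated study design: two identical blinded
plasma shipments to each platform, duplicate aliquots of 6 PTSD and 6
control parent samples, plus pooled reference plasma and its saline
dilution series (100/80/60/40%).  Run order is block-randomized within
25-sample shipment boxes, identically across platforms.

Measurement model (multiplicative lognormal — CV-based reporting and
non-negative concentrations make it the natural error model, and it gives
closed-form CV targets):

    y = c · bias(platform, class) · exp(u + e)

with ``u ~ N(0, σ_between²)`` drawn once per (platform, metabolite,
shipment) — a class-specific run-to-run drift random effect — and
``e ~ N(0, σ_within²)`` per aliquot.  ``c`` is the parent sample's true
concentration (a per-parent biological factor around the metabolite's
population level); dilution samples scale the reference concentration by
the nominal fraction *before* noise.  Values below a platform's detection
limit are left-censored (set missing); further cells are removed completely
at random at ``mcar_rate``.

Expected CVs under this model are closed-form:
intra-assay 100·√(exp(σ_within²)−1), inter-assay
100·√(exp(σ_within²+σ_between²)−1); ``recover_parameters`` checks that the
analysis pipeline recovers them.  All synthetic harmonized IDs carry a
``SYNHMDB`` prefix — they are generated, not real database accessions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import (
    ABSOLUTE_UM,
    CONTROL,
    DILUTION_FRACTIONS,
    NIST,
    NIST_DILUTION,
    PTSD,
    RELATIVE,
    MeasurementTable,
    ReferenceCOA,
)

__all__ = [
    "PlatformSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "demo_config",
    "generate",
    "synthetic_harmonization_map",
    "truth_coa",
    "expected_intra_cv",
    "expected_inter_cv",
    "recover_parameters",
]

ParamMap = float | dict[str, float]


def _resolve(param: ParamMap, platform: str, class_label: str, default: float) -> float:
    """Resolve a (platform, class)-keyed parameter with ``|``-joined wildcard keys."""
    if isinstance(param, (int, float)):
        return float(param)
    for key in (f"{platform}|{class_label}", f"{platform}|*", f"*|{class_label}", "*|*"):
        if key in param:
            return float(param[key])
    return default


class PlatformSpec(BaseModel):
    """One simulated analytical platform."""

    name: str
    unit_kind: str = ABSOLUTE_UM
    lod: float = Field(0.0, ge=0.0)  # µM; 0 disables left-censoring


class SyntheticConfig(BaseModel):
    """Generator settings; defaults mirror the emulated two-shipment design."""

    platforms: list[PlatformSpec]
    n_metabolites_per_class: dict[str, int]
    n_parent_samples_per_group: int = Field(6, ge=1)
    n_nist_replicates: int = Field(2, ge=1)
    sigma_within: ParamMap = 0.07  # log-scale within-run SD
    sigma_between: ParamMap = 0.10  # log-scale between-shipment SD
    sigma_biological: float = Field(0.30, ge=0.0)  # parent-to-parent spread
    bias: ParamMap = 1.0  # multiplicative platform bias, > 0
    mcar_rate: float = Field(0.02, ge=0.0, lt=1.0)
    unmapped_fraction: float = Field(0.10, ge=0.0, le=1.0)
    dilution_fractions: tuple[float, ...] = DILUTION_FRACTIONS
    box_size: int = Field(25, ge=1)  # block-randomization box (5 × 5 samples)
    seed: int = 0

    @field_validator("sigma_within", "sigma_between", "bias")
    @classmethod
    def _non_negative(cls, v, info):
        vals = [v] if isinstance(v, (int, float)) else list(v.values())
        for x in vals:
            if info.field_name == "bias":
                if x <= 0:
                    raise ValueError("bias factors must be positive")
            elif x < 0:
                raise ValueError(f"{info.field_name} must be non-negative")
        return v


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth needed for recovery tests; reproducible from (config, seed)."""

    config: SyntheticConfig
    true_concentration: dict[str, float]  # metabolite → population µM
    metabolite_class: dict[str, str]
    bias_factors: dict[tuple[str, str], float]  # (platform, class) → factor
    sigma_within: dict[tuple[str, str], float]
    sigma_between: dict[tuple[str, str], float]


def expected_intra_cv(sigma_within: float) -> float:
    """Closed-form lognormal CV%: 100·√(exp(σ²)−1)."""
    return 100.0 * math.sqrt(math.expm1(sigma_within**2))

def expected_inter_cv(sigma_within: float, sigma_between: float) -> float:
    """Closed-form CV% with shipment drift: variances add on the log scale."""
    return 100.0 * math.sqrt(math.expm1(sigma_within**2 + sigma_between**2))


def demo_config(seed: int = 0) -> SyntheticConfig:
    """Five-platform demo emulating the evaluated vendor mix.

    Four absolute-unit platforms and one relative-unit discovery platform;
    class noise levels chosen so amino acids are tight, lipid classes are
    noisier, and glycerophospholipids / organooxygen compounds carry the
    largest between-shipment drift.
    """
    return SyntheticConfig(
        platforms=[
            PlatformSpec(name="NMR-A", unit_kind=ABSOLUTE_UM, lod=5.0),
            PlatformSpec(name="LCMS-T", unit_kind=ABSOLUTE_UM, lod=0.05),
            PlatformSpec(name="FIA-L", unit_kind=ABSOLUTE_UM, lod=0.1),
            PlatformSpec(name="CEMS", unit_kind=ABSOLUTE_UM, lod=0.2),
            PlatformSpec(name="LCMS-D", unit_kind=RELATIVE, lod=0.0),
        ],
        n_metabolites_per_class={
            "Amino Acids": 15,
            "Fatty Acids": 10,
            "Glycerophospholipids": 15,
            "Sphingomyelins": 8,
            "Triglycerides": 12,
            "Organooxygen compounds": 5,
        },
        sigma_within={
            "*|Amino Acids": 0.04,
            "*|Sphingomyelins": 0.05,
            "*|Fatty Acids": 0.09,
            "*|*": 0.07,
        },
        sigma_between={
            "*|Glycerophospholipids": 0.20,
            "*|Organooxygen compounds": 0.18,
            "*|Fatty Acids": 0.15,
            "*|*": 0.08,
        },
        bias={
            "FIA-L|Fatty Acids": 0.80,   # systematically low lipid reporting
            "CEMS|Amino Acids": 0.85,
            "LCMS-D|*": 1000.0,          # arbitrary relative scale
            "*|*": 1.0,
        },
        mcar_rate=0.02,
        seed=seed,
    )


def _metabolites(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Deterministic (metabolite, class) roster."""
    out = []
    for class_label in sorted(config.n_metabolites_per_class):
        abbr = "".join(w[0] for w in class_label.split()).upper()
        for k in range(config.n_metabolites_per_class[class_label]):
            out.append((f"{abbr}_{k:03d}", class_label))
    return out


def _sample_plan(config: SyntheticConfig) -> list[dict]:
    """One shipment's sample manifest (before box randomization)."""
    plan = []
    for group, prefix in ((PTSD, "P"), (CONTROL, "C")):
        for i in range(1, config.n_parent_samples_per_group + 1):
            for slot in ("a", "b"):
                plan.append(
                    {"parent_sample_id": f"{prefix}{i:02d}", "replicate_slot": slot,
                     "group": group, "dilution_fraction": np.nan}
                )
    for slot in "abcdefgh"[: config.n_nist_replicates]:
        plan.append(
            {"parent_sample_id": "NIST", "replicate_slot": slot, "group": NIST,
             "dilution_fraction": 1.0}
        )
    for frac in config.dilution_fractions:
        if round(frac, 6) == 1.0:
            continue
        plan.append(
            {"parent_sample_id": "NIST", "replicate_slot": "a", "group": NIST_DILUTION,
             "dilution_fraction": float(frac)}
        )
    return plan


def generate(config: SyntheticConfig) -> tuple[MeasurementTable, SyntheticTruth]:
    """Simulate the full two-shipment, multi-platform measurement table.

    Randomness is organized as named substreams keyed on (seed, purpose,
    platform index, shipment), so adding a platform never perturbs the draws
    of existing ones.  Identical (config, seed) give byte-identical tables.
    """
    mets = _metabolites(config)
    met_names = [m for m, _ in mets]
    met_class = dict(mets)
    n_met = len(mets)

    rng_conc = np.random.default_rng([config.seed, 101])
    # population levels spread over ~3 decades of µM, as plasma panels are
    conc = 10.0 ** rng_conc.uniform(-0.3, 2.7, size=n_met)
    true_conc = dict(zip(met_names, conc))

    rng_bio = np.random.default_rng([config.seed, 102])
    parents = sorted({p["parent_sample_id"] for p in _sample_plan(config)} - {"NIST"})
    bio = {
        (m, p): math.exp(rng_bio.normal(0.0, config.sigma_biological))
        for m in met_names
        for p in parents
    }

    truth = SyntheticTruth(
        config=config,
        true_concentration=true_conc,
        metabolite_class=met_class,
        bias_factors={
            (ps.name, c): _resolve(config.bias, ps.name, c, 1.0)
            for ps in config.platforms
            for c in config.n_metabolites_per_class
        },
        sigma_within={
            (ps.name, c): _resolve(config.sigma_within, ps.name, c, 0.0)
            for ps in config.platforms
            for c in config.n_metabolites_per_class
        },
        sigma_between={
            (ps.name, c): _resolve(config.sigma_between, ps.name, c, 0.0)
            for ps in config.platforms
            for c in config.n_metabolites_per_class
        },
    )

    frames = []
    for shipment in (1, 2):
        plan = _sample_plan(config)
        # block randomization within 25-sample boxes, shared across platforms
        rng_box = np.random.default_rng([config.seed, 103, shipment])
        order = []
        for start in range(0, len(plan), config.box_size):
            box = list(range(start, min(start + config.box_size, len(plan))))
            order.extend(rng_box.permutation(box).tolist())
        plan = [plan[i] for i in order]
        for pi, ps in enumerate(config.platforms):
            rng = np.random.default_rng([config.seed, 104, pi, shipment])
            sw = np.array([truth.sigma_within[(ps.name, met_class[m])] for m in met_names])
            sb = np.array([truth.sigma_between[(ps.name, met_class[m])] for m in met_names])
            bias = np.array([truth.bias_factors[(ps.name, met_class[m])] for m in met_names])
            u = rng.normal(0.0, 1.0, size=n_met) * sb  # per-metabolite shipment drift
            for si, s in enumerate(plan):
                if s["group"] in (NIST, NIST_DILUTION):
                    base = conc * (s["dilution_fraction"] if s["group"] == NIST_DILUTION else 1.0)
                else:
                    base = conc * np.array([bio[(m, s["parent_sample_id"])] for m in met_names])
                e = rng.normal(0.0, 1.0, size=n_met) * sw
                y = base * bias * np.exp(u + e)
                censored = (ps.lod > 0) & (y < ps.lod) & (ps.unit_kind == ABSOLUTE_UM)
                mcar = rng.random(n_met) < config.mcar_rate
                miss = censored | mcar
                frames.append(
                    pd.DataFrame(
                        {
                            "platform": ps.name,
                            "shipment": shipment,
                            "sample_id": f"S{shipment}-{si:02d}-{s['parent_sample_id']}{s['replicate_slot']}"
                            + ("" if s["group"] not in (NIST, NIST_DILUTION)
                               else f"-{int(round((s['dilution_fraction'] or 1.0) * 100))}"),
                            "parent_sample_id": s["parent_sample_id"],
                            "replicate_slot": s["replicate_slot"],
                            "group": s["group"],
                            "dilution_fraction": s["dilution_fraction"],
                            "metabolite": met_names,
                            "value": np.where(miss, np.nan, y),
                            "unit_kind": ps.unit_kind,
                            "imputed_by_vendor": False,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return MeasurementTable(df), truth


def synthetic_harmonization_map(config: SyntheticConfig) -> pd.DataFrame:
    """Harmonization map for generated tables (synthetic SYNHMDB accessions).

    A deterministic ``unmapped_fraction`` of each platform's metabolites is
    left without an ID, emulating nomenclature that cannot be reconciled
    across vendors.
    """
    mets = _metabolites(config)
    rows = []
    for pi, ps in enumerate(config.platforms):
        rng = np.random.default_rng([config.seed, 105, pi])
        drop = rng.random(len(mets)) < config.unmapped_fraction
        for (m, c), unmapped in zip(mets, drop):
            rows.append(
                {
                    "platform": ps.name,
                    "raw_name": m,
                    "hmdb_id": None if unmapped else f"SYNHMDB{hash_id(m):05d}",
                    "class_label": c,
                }
            )
    df = pd.DataFrame(rows)
    df["mapped"] = df["hmdb_id"].notna()
    return df


def hash_id(name: str) -> int:
    """Deterministic small integer for a metabolite name (stable across runs)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 99991
    return h


def truth_coa(truth: SyntheticTruth) -> list[ReferenceCOA]:
    """A certificate of analysis equal to the generator's reference truth."""
    return [
        ReferenceCOA(analyte=m, coa_value=float(c))
        for m, c in sorted(truth.true_concentration.items())
    ]


def recover_parameters(table: MeasurementTable, truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Re-estimate the generator's noise and bias parameters from its output.

    Runs the precision pipeline on the synthetic table and compares, per
    (platform, class), the recovered CV to the closed-form lognormal
    expectation.  Recovery uses the root-mean-square of pair CVs (squared
    CVs estimate variances, which pool linearly), so the two-point
    sample-SD bias does not enter; the unweighted mean-of-pair-CVs, the
    convention used in the report tables, is also returned.  Platform bias
    is recovered as the mean reported/true ratio over reference aliquots.
    """
    from .precision import inter_assay_cv, intra_assay_cv

    table_mets = set(table.df["metabolite"].unique())
    if table_mets != set(truth.true_concentration):
        raise ValueError("table and truth describe different metabolite rosters")
    met_class = truth.metabolite_class

    def classed(cvs: pd.DataFrame) -> pd.DataFrame:
        cvs = cvs.dropna(subset=["cv_pct"]).copy()
        cvs["class_label"] = cvs["metabolite"].map(met_class)
        return cvs

    intra = pd.concat(
        [classed(intra_assay_cv(table, shipment=s, group=g)) for s in table.shipments for g in (PTSD, CONTROL)],
        ignore_index=True,
    )
    inter = pd.concat(
        [classed(inter_assay_cv(table, group=g)) for g in (PTSD, CONTROL)],
        ignore_index=True,
    ) if set(table.shipments) >= {1, 2} else pd.DataFrame(
        columns=["platform", "metabolite", "cv_pct", "cv_pct_rms", "n_pairs", "class_label"]
    )

    def agg(cvs: pd.DataFrame, sigma_true: Mapping, which: str) -> pd.DataFrame:
        rows = []
        for (p, c), sub in cvs.groupby(["platform", "class_label"], sort=True):
            est_rms = float(np.sqrt(np.mean(np.square(sub["cv_pct_rms"]))))
            est_mean = float(np.mean(sub["cv_pct"]))
            sw = truth.sigma_within[(p, c)]
            sb = truth.sigma_between[(p, c)]
            true_cv = expected_intra_cv(sw) if which == "intra" else expected_inter_cv(sw, sb)
            rows.append(
                {"platform": p, "class_label": c, "context": which,
                 "cv_recovered": est_rms, "cv_mean": est_mean, "cv_true": true_cv,
                 "abs_error": abs(est_rms - true_cv), "n_metabolites": sub["metabolite"].nunique()}
            )
        return pd.DataFrame(rows)

    precision_report = pd.concat(
        [agg(intra, truth.sigma_within, "intra"), agg(inter, truth.sigma_between, "inter")],
        ignore_index=True,
    )

    nist = table.df[(table.df["group"] == NIST) & ~table.df["missing"]]
    bias_rows = []
    for (p, m), sub in nist.groupby(["platform", "metabolite"], sort=True):
        ratio = float(sub["value"].mean() / truth.true_concentration[m])
        bias_rows.append({"platform": p, "class_label": met_class[m], "metabolite": m, "ratio": ratio})
    bias_df = pd.DataFrame(bias_rows)
    if len(bias_df):
        bias_report = (
            bias_df.groupby(["platform", "class_label"], sort=True)["ratio"].mean().reset_index()
        )
        bias_report["bias_true"] = [
            truth.bias_factors[(p, c)] for p, c in zip(bias_report["platform"], bias_report["class_label"])
        ]
        bias_report["abs_error"] = (bias_report["ratio"] - bias_report["bias_true"]).abs()
    else:
        bias_report = pd.DataFrame(columns=["platform", "class_label", "ratio", "bias_true", "abs_error"])
    return {"precision": precision_report, "bias": bias_report}
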