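"""Pipeline orchestration from a config file and markdown report rendering."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .accuracy import percent_accuracy
from .io import read_coa, read_harmonization_map, read_measurements, packaged_reported_path
from .model import RingTrialEvaluation
from .precision import categorize_cv
from .synthetic import SyntheticConfig, demo_config, generate, synthetic_harmonization_map, truth_coa

__all__ = ["run_pipeline", "render_summary", "published_accuracy", "write_synthetic_inputs"]

log = logging.getLogger("ringtrial")


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    return yaml.safe_load(Path(config).read_text()) or {}


def write_synthetic_inputs(outdir: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Generate a synthetic dataset and write every pipeline input to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = generate(config)
    paths = {
        "measurements": outdir / "measurements.csv",
        "harmonization_map": outdir / "harmonization_map.tsv",
        "coa": outdir / "coa.csv",
        "truth": outdir / "truth.json",
    }
    table.to_csv(paths["measurements"])
    synthetic_harmonization_map(config).to_csv(paths["harmonization_map"], sep="\t", index=False)
    pd.DataFrame(
        [{"analyte": c.analyte, "coa_uM": c.coa_value} for c in truth_coa(truth)]
    ).to_csv(paths["coa"], index=False)
    paths["truth"].write_text(
        json.dumps(
            {
                "config": config.model_dump(),
                "true_concentration": truth.true_concentration,
                "metabolite_class": truth.metabolite_class,
                "bias_factors": {f"{p}|{c}": v for (p, c), v in truth.bias_factors.items()},
                "sigma_within": {f"{p}|{c}": v for (p, c), v in truth.sigma_within.items()},
                "sigma_between": {f"{p}|{c}": v for (p, c), v in truth.sigma_between.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )
    return paths


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None, seed: int | None = None) -> Path:
    """Run harmonize → filter → precision → accuracy → linearity → coverage.

    ``config`` is a YAML path or dict with keys ``measurements`` (path) or
    ``simulate`` (synthetic generator settings / true for the demo),
    optional ``harmonization_map``, ``coa`` (path or "packaged"),
    ``output_dir`` and ``options`` (model keyword arguments).  The same
    inputs and config always produce identical outputs.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("output_dir", "ringtrial_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else cfg.get("seed")

    if cfg.get("measurements"):
        table = read_measurements(cfg["measurements"], dialect=cfg.get("dialect"))
        hmap = read_harmonization_map(cfg["harmonization_map"]) if cfg.get("harmonization_map") else None
        coa_cfg = cfg.get("coa")
        coa = read_coa(None if coa_cfg in (None, "packaged") else coa_cfg) if coa_cfg else None
    elif "simulate" in cfg:
        sim = cfg["simulate"]
        syn = demo_config(seed or 0) if sim in (True, None, {}) else SyntheticConfig(**{**sim, **({"seed": seed} if seed is not None else {})})
        log.info("simulating inputs (seed=%s)", syn.seed)
        paths = write_synthetic_inputs(outdir / "inputs", syn)
        table = read_measurements(paths["measurements"])
        hmap = read_harmonization_map(paths["harmonization_map"])
        coa = read_coa(paths["coa"])
    else:
        raise ValueError("config needs either 'measurements' or 'simulate'")

    model = RingTrialEvaluation(table, harmonization_map=hmap, coa=coa, **cfg.get("options", {}))
    results = model.fit()
    for line in results.log:
        log.info(line)
    results.save(outdir, seed=seed)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest_path = outdir / "run_manifest.json"
    manifest = json.loads(manifest_path.read_text())
    manifest["config_sha256"] = cfg_hash
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    render_summary(outdir)
    return outdir


def _md_table(df: pd.DataFrame, float_fmt: str = "{:.2f}") -> list[str]:
    if df is None or df.empty:
        return ["*(no rows)*", ""]
    show = df.copy()
    for c in show.columns:
        if pd.api.types.is_float_dtype(show[c]):
            show[c] = show[c].map(lambda v: "NA" if pd.isna(v) else float_fmt.format(v))
    lines = ["| " + " | ".join(map(str, show.columns)) + " |",
             "|" + "---|" * len(show.columns)]
    for row in show.itertuples(index=False):
        lines.append("| " + " | ".join("NA" if v is None else str(v) for v in row) + " |")
    lines.append("")
    return lines


def render_summary(outdir: str | Path) -> str:
    """Render a deterministic markdown report from saved pipeline outputs.

    Traffic-light colors are encoded as text labels (HIGH/MODERATE/LOW);
    class tables are sorted by class label.  A missing required output file
    raises with its name.
    """
    outdir = Path(outdir)
    required = ["class_summary_intra.csv", "accuracy.csv", "linearity.csv", "coverage.json", "run.log"]
    for name in required:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"pipeline output missing: {outdir / name}")

    lines = ["# Ring-trial QC report", ""]
    lines += ["## Run log", ""]
    lines += [f"- {l}" for l in (outdir / "run.log").read_text().splitlines()] + [""]
    lines += ["Legend: HIGH ≤ 10% < MODERATE < 20% ≤ LOW (CV% bands; accuracy bands use |percent difference|).", ""]

    intra = pd.read_csv(outdir / "class_summary_intra.csv")
    lines += ["## Intra-assay precision by class", ""]
    lines += _md_table(intra.sort_values(["class_label", "platform"] if not intra.empty else intra.columns.tolist()[:1]))
    inter_path = outdir / "class_summary_inter.csv"
    lines += ["## Inter-assay precision by class", ""]
    if inter_path.exists():
        inter = pd.read_csv(inter_path)
        lines += _md_table(inter.sort_values(["class_label", "platform"] if not inter.empty else inter.columns.tolist()[:1]))
    else:
        lines += ["*(not computed: single shipment)*", ""]

    lines += ["## Accuracy vs certified reference", ""]
    lines += _md_table(pd.read_csv(outdir / "accuracy.csv"))
    lines += ["## Dilution linearity", ""]
    lines += _md_table(pd.read_csv(outdir / "linearity.csv"), float_fmt="{:.4f}")

    cov = json.loads((outdir / "coverage.json").read_text())
    lines += ["## Coverage", ""]
    if cov.get("overlap"):
        ov = cov["overlap"]
        platforms = ov["platforms"]
        lines.append(f"Union of harmonized keys: {ov['union_size']} across {', '.join(platforms)}.")
        lines.append("")
        lines.append("| region | platforms | count |")
        lines.append("|---|---|---|")
        for mask_str in sorted(ov["counts"], key=int):
            mask = int(mask_str)
            members = [p for i, p in enumerate(platforms) if mask & (1 << i)]
            lines.append(f"| {mask} | {'∩'.join(members)} | {ov['counts'][mask_str]} |")
        lines.append("")
    else:
        lines += ["*(fewer than two platforms; no overlap computed)*", ""]
    if cov.get("drift"):
        lines += ["### Shipment-to-shipment coverage change", ""]
        lines += _md_table(pd.DataFrame(cov["drift"]), float_fmt="{:+.1f}")

    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text


def published_accuracy() -> pd.DataFrame:
    """Score the packaged published reported values against the packaged COA.

    Recomputes the signed percent difference for every analyte × platform in
    the packaged SRM 1950 fixture and compares it (at two decimals,
    half-even) to the percent printed alongside the reported value —
    a worked-example check of the accuracy arithmetic.  Platforms whose
    integer-rounded reported values cannot reproduce their printed percent
    are visible here as ``matches_printed=False`` rows.
    """
    reported = pd.read_csv(packaged_reported_path())
    coa = {c.analyte: c.coa_value for c in read_coa()}
    rows = []
    for r in reported.itertuples(index=False):
        pct = percent_accuracy(r.reported_uM, coa[r.analyte])
        pct2 = float(pd.Series([pct]).round(2).iloc[0])
        rows.append(
            {
                "analyte": r.analyte,
                "platform": r.platform,
                "reported": r.reported_uM,
                "coa_value": coa[r.analyte],
                "percent_diff": pct,
                "printed_percent_diff": r.printed_percent_diff,
                "matches_printed": abs(pct2 - r.printed_percent_diff) < 0.005,
                "category": categorize_cv(abs(pct)),
            }
        )
    return pd.DataFrame(rows)
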