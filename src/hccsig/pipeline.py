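"""End-to-end orchestration: config -> preprocess -> screen -> validate -> report.

A run is driven by a YAML/JSON config (or a :class:`RunConfig` built in
code), executes deterministically under its seed, writes every stage
output as TSV/JSON into the output directory and records a manifest of
paths plus a full parameter echo.  Identical config + seed reproduces
every output byte for byte (the manifest carries no timestamps; wall-
clock detail goes to run.log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as hio
from .cohort import CohortConfig, simulate_counts, simulate_expression
from .diffexp import DiffExpThresholds
from .models import PairedValidation, SignatureScreen
from .signature import SignatureThresholds

log = logging.getLogger("hccsig")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed for one end-to-end run."""

    output_dir: str
    seed: int = 0
    synthetic: CohortConfig | None = None
    synthetic_counts: dict[str, Any] | None = None  # {n_patients, dispersion}
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    probe_map_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    diff_thresholds: DiffExpThresholds = field(default_factory=DiffExpThresholds)
    sig_thresholds: SignatureThresholds = field(default_factory=SignatureThresholds)
    fdr_max: float = 0.05
    min_mean_count: float = 5.0
    stratify_etiologies: bool = True
    validation_setting: str = "HCC"
    #: None = auto: synthetic cohorts are generated on a common scale and
    #: are treated as already normalized; file inputs are normalized.
    assume_normalized: bool | None = None

    def validate(self) -> None:
        file_inputs = (self.expression_path, self.sample_sheet_path, self.probe_map_path)
        if self.synthetic is None and not all(file_inputs):
            raise ConfigError(
                "config needs either a 'synthetic' cohort spec or all of "
                "expression/sample_sheet/probe_map paths"
            )
        if self.synthetic is not None and any(file_inputs):
            raise ConfigError("config must not mix 'synthetic' with file inputs")
        for name in ("expression_path", "sample_sheet_path", "probe_map_path",
                     "counts_path", "design_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        if not 0 < self.fdr_max < 1:
            raise ConfigError(f"fdr_max must be in (0, 1), got {self.fdr_max}")
        try:
            self.diff_thresholds.validate()
            self.sig_thresholds.validate()
            if self.synthetic is not None:
                self.synthetic.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {
            "output_dir", "seed", "synthetic", "inputs", "diffexp", "signature",
            "fdr_max", "min_mean_count", "stratify_etiologies", "validation_setting",
            "assume_normalized",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError(f"{path}: config requires output_dir")

        def build(cls_, section, label):
            section = dict(section or {})
            names = {f.name for f in dataclasses.fields(cls_)}
            bad = set(section) - names
            if bad:
                raise ConfigError(f"{path}: unknown {label} keys {sorted(bad)}")
            try:
                return cls_(**section)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: invalid {label} section: {exc}") from exc

        synthetic = None
        synthetic_counts = None
        if raw.get("synthetic") is not None:
            synth_raw = dict(raw["synthetic"])
            synthetic_counts = synth_raw.pop("counts", None)
            if "probes_per_gene_range" in synth_raw:
                synth_raw["probes_per_gene_range"] = tuple(synth_raw["probes_per_gene_range"])
            synthetic = build(CohortConfig, synth_raw, "synthetic")
        inputs = dict(raw.get("inputs") or {})
        cfg = cls(
            output_dir=str(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            synthetic=synthetic,
            synthetic_counts=synthetic_counts,
            expression_path=inputs.get("expression"),
            sample_sheet_path=inputs.get("sample_sheet"),
            probe_map_path=inputs.get("probe_map"),
            counts_path=inputs.get("counts"),
            design_path=inputs.get("design"),
            diff_thresholds=build(DiffExpThresholds, raw.get("diffexp"), "diffexp"),
            sig_thresholds=build(SignatureThresholds, raw.get("signature"), "signature"),
            fdr_max=float(raw.get("fdr_max", 0.05)),
            min_mean_count=float(raw.get("min_mean_count", 5.0)),
            stratify_etiologies=bool(raw.get("stratify_etiologies", True)),
            validation_setting=str(raw.get("validation_setting", "HCC")),
            assume_normalized=raw.get("assume_normalized"),
        )
        cfg.validate()
        return cfg

    def echo(self) -> dict[str, Any]:
        """Parameter echo for the manifest (JSON-serializable)."""
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["n_planted_per_class"] = dict(self.synthetic.n_planted_per_class)
            d["synthetic"]["probes_per_gene_range"] = list(self.synthetic.probes_per_gene_range)
        return d


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    from . import __version__ as version

    manifest: dict[str, Any] = {
        "version": version,
        "parameters": config.echo(),
        "outputs": {},
        "funnels": {},
        "completed_stages": [],
        "failed_stage": None,
    }
    manifest_path = outdir / "manifest.json"

    try:
        stage = "inputs"
        truth = None
        if config.synthetic is not None:
            synth = dataclasses.replace(config.synthetic, seed=config.seed)
            expr, sheet, probe_map, truth = simulate_expression(synth)
            fixdir = outdir / "inputs"
            fixdir.mkdir(exist_ok=True)
            hio.write_expression(expr, fixdir / "expression.tsv")
            hio.write_sample_sheet(sheet, fixdir / "sample_sheet.tsv")
            hio.write_probe_map(probe_map, fixdir / "probe_map.tsv")
            hio.write_truth(truth, fixdir / "truth.tsv")
            manifest["outputs"]["inputs"] = {
                "expression": str(fixdir / "expression.tsv"),
                "sample_sheet": str(fixdir / "sample_sheet.tsv"),
                "probe_map": str(fixdir / "probe_map.tsv"),
                "truth": str(fixdir / "truth.tsv"),
            }
            log.info("simulated cohort: %d probes x %d samples", *expr.shape)
        else:
            expr = hio.read_expression(config.expression_path)
            sheet = hio.read_sample_sheet(config.sample_sheet_path, expr)
            probe_map = hio.read_probe_map(config.probe_map_path, expr)
            log.info("loaded cohort: %d probes x %d samples", *expr.shape)
        manifest["completed_stages"].append(stage)

        stage = "screen"
        normalized = (
            config.assume_normalized
            if config.assume_normalized is not None
            else config.synthetic is not None
        )
        screen = SignatureScreen(expr, sheet, probe_map, normalized=normalized)
        if config.stratify_etiologies:
            strat = screen.fit_stratified(config.diff_thresholds, config.sig_thresholds)
            results = strat.results
        else:
            res = screen.fit(config.diff_thresholds, config.sig_thresholds)
            strat = None
            results = {res.setting: res}
        for name, res in results.items():
            res.de_table.to_csv(outdir / f"diffexp_{name}.tsv", sep="\t", index_label="probe_id")
            res.to_frame().to_csv(outdir / f"signature_{name}.tsv", sep="\t", index=False)
            _write_json(
                {
                    "setting": name,
                    "funnel": res.funnel,
                    "liver_specific": sorted(res.signature_set.liver_specific),
                    "tumor_associated": sorted(res.signature_set.tumor_associated),
                    "tumor_specific": sorted(res.signature_set.tumor_specific),
                },
                outdir / f"signature_{name}.json",
            )
            manifest["outputs"][f"diffexp_{name}"] = str(outdir / f"diffexp_{name}.tsv")
            manifest["outputs"][f"signature_{name}"] = str(outdir / f"signature_{name}.tsv")
            manifest["outputs"][f"signature_{name}_json"] = str(outdir / f"signature_{name}.json")
            manifest["funnels"][name] = res.funnel
            log.info("setting %s: %s", name,
                     {k: v for k, v in res.funnel.items() if k.startswith("n_tumor")})
        manifest["completed_stages"].append(stage)

        if strat is not None:
            stage = "overlap"
            overlap = strat.overlap("tumor_specific")
            overlap.to_csv(outdir / "overlap_tumor_specific.tsv", sep="\t", index=False)
            manifest["outputs"]["overlap_tumor_specific"] = str(
                outdir / "overlap_tumor_specific.tsv"
            )
            manifest["completed_stages"].append(stage)

        want_validation = (
            (config.synthetic is not None and config.synthetic_counts is not None)
            or (config.counts_path and config.design_path)
        )
        if want_validation:
            stage = "validation"
            if config.synthetic is not None:
                cc = dict(config.synthetic_counts or {})
                counts, design = simulate_counts(
                    config.synthetic,
                    truth,
                    n_patients=int(cc.get("n_patients", 9)),
                    dispersion=float(cc.get("dispersion", 0.1)),
                    seed=config.seed + 1,
                )
                fixdir = outdir / "inputs"
                hio.write_counts(counts, fixdir / "counts.tsv")
                hio.write_design(design, fixdir / "design.tsv")
                manifest["outputs"]["inputs"]["counts"] = str(fixdir / "counts.tsv")
                manifest["outputs"]["inputs"]["design"] = str(fixdir / "design.tsv")
            else:
                counts = hio.read_counts(config.counts_path)
                design = hio.read_design(config.design_path)
            if config.validation_setting not in results:
                raise ValueError(
                    f"validation_setting {config.validation_setting!r} not among "
                    f"fitted settings {sorted(results)}"
                )
            res = results[config.validation_setting]
            val = PairedValidation(counts, design).fit(
                res.gene_log2fc,
                res.signature_set.tumor_specific,
                fdr_max=config.fdr_max,
                min_mean_count=config.min_mean_count,
            )
            val.records.to_csv(outdir / "validation.tsv", sep="\t", index_label="gene")
            _write_json(
                {"setting": config.validation_setting, **val.concordance.to_dict()},
                outdir / "validation_summary.json",
            )
            manifest["outputs"]["validation"] = str(outdir / "validation.tsv")
            manifest["outputs"]["validation_summary"] = str(outdir / "validation_summary.json")
            manifest["completed_stages"].append(stage)
            log.info("validation: %s", val.concordance.to_dict())
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(manifest, manifest_path)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    manifest["outputs"]["manifest"] = str(manifest_path)
    _write_json(manifest, manifest_path)
    return manifest


def _recount_tsv(path: str) -> int:
    return len(pd.read_csv(path, sep="\t"))


def render_report(manifest: dict[str, Any] | str | Path) -> str:
    """Render a human-readable run report (markdown) from a manifest.

    Counts in the report are re-derived from the written TSVs, so the
    report doubles as an internal-consistency check.  Raises
    :class:`StageError` if manifest entries required for a completed
    stage are missing.
    """
    if not isinstance(manifest, dict):
        with open(manifest, encoding="utf-8") as fh:
            manifest = json.load(fh)
    outputs = manifest.get("outputs", {})
    lines = ["# Signature screen run report", ""]
    if manifest.get("failed_stage"):
        lines.append(f"**Run failed at stage: {manifest['failed_stage']}**")
        lines.append("")

    funnels = manifest.get("funnels", {})
    if not funnels and "screen" in manifest.get("completed_stages", []):
        raise StageError("report", "manifest lacks funnels for completed screen stage")
    for setting, funnel in funnels.items():
        sig_path = outputs.get(f"signature_{setting}")
        if sig_path is None:
            raise StageError("report", f"manifest lacks signature output for {setting}")
        sig = pd.read_csv(sig_path, sep="\t") if _recount_tsv(sig_path) else pd.DataFrame(
            columns=["category"]
        )
        counts_by_cat = sig["category"].value_counts().to_dict() if len(sig) else {}
        lines += [
            f"## Setting {setting}",
            "",
            "| gate | count |",
            "|---|---|",
            f"| probes in | {funnel['n_probes']} |",
            f"| dropped (missing) | {funnel['n_dropped_missing']} |",
            f"| untestable | {funnel['n_untestable']} |",
            f"| up probes | {funnel['n_up_probes']} |",
            f"| down probes | {funnel['n_down_probes']} |",
            f"| failing gates | {funnel['n_fail']} |",
            f"| up genes (unique) | {funnel['n_up_genes']} |",
            f"| liver_specific | {counts_by_cat.get('liver_specific', 0)} |",
            f"| tumor_associated | {counts_by_cat.get('tumor_associated', 0)} |",
            f"| tumor_specific | {counts_by_cat.get('tumor_specific', 0)} |",
            "",
        ]
        checks = [
            ("liver_specific", "n_liver_specific"),
            ("tumor_associated", "n_tumor_associated"),
            ("tumor_specific", "n_tumor_specific"),
        ]
        for cat, key in checks:
            if counts_by_cat.get(cat, 0) != funnel[key]:
                raise StageError(
                    "report",
                    f"funnel/{setting}: {key}={funnel[key]} but signature TSV has "
                    f"{counts_by_cat.get(cat, 0)} {cat} rows",
                )

    if "overlap_tumor_specific" in outputs:
        overlap = pd.read_csv(outputs["overlap_tumor_specific"], sep="\t")
        lines += ["## Tumor-specific overlap across settings", ""]
        lines += ["| cell | n |", "|---|---|"]
        setting_cols = [c for c in overlap.columns if c not in ("n", "members")]
        for _, row in overlap.iterrows():
            cell = "&".join(s for s in setting_cols if row[s]) or "-"
            lines.append(f"| {cell} | {row['n']} |")
        lines.append("")

    lines.append("## Validation")
    lines.append("")
    if "validation_summary" in outputs:
        with open(outputs["validation_summary"], encoding="utf-8") as fh:
            vs = json.load(fh)
        lines += [f"- {k}: {v}" for k, v in sorted(vs.items())]
    else:
        lines.append("- not run")
    lines.append("")
    return "\n".join(lines)
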