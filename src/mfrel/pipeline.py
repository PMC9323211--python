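"""Pipeline orchestration: config, I/O and the end-to-end analysis.

One config drives the whole chain — formulation QC and selection, model
fitting of release curves, fractality estimation with drug ordering,
and HET-CAM scoring — each stage either loading delimited-text inputs
or generating seeded synthetic ones.  Stages are run sequentially and
communicate only through the package's declared types; a stage failure
is recorded in the report and later independent stages still run.

All randomness derives from the single config seed through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`` so reruns
with the same config are byte-identical (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, colloid_qc, fractality, hetcam, release_models, synth

#: fixed per-stage spawn keys for seed derivation
_STAGE_KEYS = {"release": 1, "hetcam": 2, "panel": 101}


class ConfigError(ValueError):
    """Raised when a pipeline config violates the schema."""


@dataclass
class AnalysisReport:
    qc: pd.DataFrame | None = None
    selected_formulation: str | None = None
    model_fits: pd.DataFrame | None = None
    fractality: pd.DataFrame | None = None
    fractality_ordering: list[tuple[str, float]] | None = None
    hetcam_scores: pd.DataFrame | None = None
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the config seed."""
    key = _STAGE_KEYS.get(stage, sum(stage.encode()))
    state = np.random.SeedSequence(entropy=base_seed, spawn_key=(key,)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


# ---------------------------------------------------------------- I/O


def write_release_csv(curve: release_models.ReleaseCurve, path) -> None:
    """Write a release curve with its metadata sidecar block."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# drug: {curve.drug}\n")
        fh.write(f"# units: {curve.units}\n")
        fh.write("time_min,mean,sd,n\n")
        sd = curve.sd_release if curve.sd_release is not None else np.zeros(len(curve.times_min))
        for t, m, s in zip(curve.times_min, curve.mean_release, sd):
            fh.write(f"{float(t)!r},{float(m)!r},{float(s)!r},{curve.n_replicates}\n")


def read_release_csv(path) -> release_models.ReleaseCurve:
    """Read a release-curve CSV (``time_min,mean,sd[,n]`` + sidecar)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = parts
                if header[:2] != ["time_min", "mean"]:
                    raise ValueError(f"{path}:{lineno}: expected header time_min,mean,sd[,n]")
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                rows.append([float(p) for p in parts[: len(header)]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    has_sd = len(header) >= 3
    n = int(arr[0, 3]) if len(header) >= 4 else 1
    return release_models.ReleaseCurve(
        drug=meta.get("drug", path.stem),
        times_min=arr[:, 0],
        mean_release=arr[:, 1],
        sd_release=arr[:, 2] if has_sd else None,
        n_replicates=n,
        units=meta.get("units", "fraction"),
    )


def read_hetcam_csv(path) -> pd.DataFrame:
    """Read HET-CAM observations: ``sample,h_s,l_s,c_s``."""
    df = pd.read_csv(path)
    expected = {"sample", "h_s", "l_s", "c_s"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    return df


# ----------------------------------------------------------- config


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Schema-check a pipeline config; returns a normalised copy."""
    cfg = dict(config)
    any_synth = False
    for stream in ("release", "hetcam"):
        block = cfg.get(stream, {})
        has_path = bool(block.get("paths") or block.get("path"))
        has_synth = bool(block.get("synthetic"))
        if has_path and has_synth:
            raise ConfigError(f"{stream}: give either file inputs or a synthetic spec, not both")
        any_synth = any_synth or has_synth
    if any_synth and cfg.get("seed") is None:
        raise ConfigError("seed is required when any synthetic stream is configured")
    if "seed" in cfg and cfg["seed"] is not None:
        cfg["seed"] = int(cfg["seed"])
    models = cfg.get("models", list(release_models.MODEL_NAMES))
    for m in models:
        if m not in release_models.MODEL_NAMES:
            raise ConfigError(f"unknown model {m!r}")
    cfg["models"] = list(models)
    return cfg


def demo_config(seed: int) -> dict[str, Any]:
    """All-synthetic demo config: packaged formulation table, three-drug
    synthetic panel, one synthetic non-irritant HET-CAM observation."""
    return {
        "seed": seed,
        "formulations": {"packaged": True},
        "release": {"synthetic": {"panel": True}},
        "hetcam": {"synthetic": {"categories": ["non-irritant"]}},
        "models": list(release_models.MODEL_NAMES),
        "fractality": {"estimator": "boxcount", "k_max": 8},
    }


# -------------------------------------------------------------- run


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: Mapping[str, Any]) -> AnalysisReport:
    """Run the full analysis described by a validated config."""
    cfg = validate_config(config)
    report = AnalysisReport(
        provenance={
            "config_sha256": _config_hash(cfg),
            "seed": cfg.get("seed"),
            "tool_version": __version__,
        }
    )

    # --- formulation QC and selection
    try:
        fblock = cfg.get("formulations")
        if fblock:
            if fblock.get("packaged"):
                records = colloid_qc.load_pre_emulsion_table()
            else:
                records = colloid_qc.read_formulation_table(fblock["path"])
            thr = colloid_qc.StabilityThresholds(**cfg.get("qc", {}))
            rows = []
            for rec in records:
                res = colloid_qc.stability_screen(rec, thr)
                rows.append(
                    {
                        "label": rec.label,
                        "size_nm": rec.mean_size_nm,
                        "pdi": rec.pdi,
                        "zeta_mV": rec.zeta_mV,
                        "passed": res.passed,
                        "violations": ";".join(v.rule for v in res.violations),
                    }
                )
            report.qc = pd.DataFrame(rows)
            report.selected_formulation = colloid_qc.select_formulation(records)
    except Exception as exc:  # noqa: BLE001 - stage isolation by contract
        report.errors["formulations"] = str(exc)

    # --- release curves: load or generate
    curves: list[release_models.ReleaseCurve] = []
    try:
        rblock = cfg.get("release", {})
        if rblock.get("paths"):
            curves = [read_release_csv(p) for p in rblock["paths"]]
        elif rblock.get("synthetic"):
            sblock = rblock["synthetic"]
            if sblock.get("panel"):
                curves = synth.gen_drug_panel(cfg["seed"])
            else:
                spec = synth.SyntheticSpec(
                    seed=stage_seed(cfg["seed"], "release"), **sblock.get("spec", {})
                )
                curves = [synth.gen_release_curve(spec)]
    except Exception as exc:  # noqa: BLE001
        report.errors["release_input"] = str(exc)

    # --- model fitting
    if curves:
        try:
            rows = []
            for curve in curves:
                for rank, fit in enumerate(
                    release_models.fit_all_models(curve, cfg["models"]), start=1
                ):
                    rows.append(
                        {
                            "drug": curve.drug,
                            "rank": rank,
                            "model": fit.model_name,
                            "aicc": fit.aicc,
                            "r_squared": fit.r_squared,
                            "rss": fit.rss,
                            "converged": fit.converged,
                            **{f"param_{k}": v for k, v in fit.params.items()},
                        }
                    )
            report.model_fits = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            report.errors["model_fits"] = str(exc)

        try:
            fcfg = cfg.get("fractality", {})
            results = [
                fractality.estimate_both(c, k_max=fcfg.get("k_max", 8)) for c in curves
            ]
            report.fractality = pd.DataFrame(
                {
                    "drug": [r.drug for r in results],
                    "dim_boxcount": [r.dimension_boxcount for r in results],
                    "dim_higuchi": [r.dimension_higuchi for r in results],
                    "r2": [r.r_squared_loglog for r in results],
                    "scale_lo": [r.scale_range[0] for r in results],
                    "scale_hi": [r.scale_range[1] for r in results],
                }
            )
            if len(results) >= 2:
                report.fractality_ordering = fractality.drug_ordering(
                    results, estimator=fcfg.get("estimator", "boxcount")
                )
        except Exception as exc:  # noqa: BLE001
            report.errors["fractality"] = str(exc)

    # --- HET-CAM scoring
    try:
        hblock = cfg.get("hetcam", {})
        obs_rows: list[dict[str, Any]] = []
        if hblock.get("path"):
            df = read_hetcam_csv(hblock["path"])
            for row in df.itertuples(index=False):
                obs = hetcam.HetcamObservation(float(row.h_s), float(row.l_s), float(row.c_s))
                obs_rows.append({"sample": row.sample, "obs": obs})
        elif hblock.get("synthetic"):
            cats = hblock["synthetic"].get("categories", ["non-irritant"])
            base = stage_seed(cfg["seed"], "hetcam")
            for i, cat in enumerate(cats):
                obs = synth.gen_hetcam_observation(cat, seed=base + i)
                obs_rows.append({"sample": f"synthetic-{cat}", "obs": obs})
        if obs_rows:
            rows = []
            for entry in obs_rows:
                res = hetcam.score_observation(entry["obs"])
                rows.append(
                    {
                        "sample": entry["sample"],
                        "h_s": entry["obs"].hemorrhage_onset_s,
                        "l_s": entry["obs"].lysis_onset_s,
                        "c_s": entry["obs"].coagulation_onset_s,
                        "score": res.score,
                        "category": res.category,
                    }
                )
            report.hetcam_scores = pd.DataFrame(rows)
    except Exception as exc:  # noqa: BLE001
        report.errors["hetcam"] = str(exc)

    return report


def write_report(report: AnalysisReport, outdir) -> list[Path]:
    """Write the report tables as CSV plus a JSON summary; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "formulation_qc.csv": report.qc,
        "model_fits.csv": report.model_fits,
        "fractality.csv": report.fractality,
        "hetcam_scores.csv": report.hetcam_scores,
    }
    for name, df in tables.items():
        if df is not None:
            p = outdir / name
            df.to_csv(p, index=False)
            written.append(p)
    summary = {
        "provenance": report.provenance,
        "selected_formulation": report.selected_formulation,
        "fractality_ordering": report.fractality_ordering,
        "errors": report.errors,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(p)
    return written
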