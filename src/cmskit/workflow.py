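"""End-to-end orchestration: filter -> preprocess -> select -> score -> cluster.

Every stage writes its artifact into the output directory, and a run
manifest records the tool version, input digests, the fully resolved
configuration (all defaults materialized), the seed, and per-artifact
digests — replaying the manifest on identical inputs reproduces all
outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .clustering import (
    ClusterConfig,
    SeverityAssignment,
    ThresholdSet,
    assign_severity,
    group_distribution,
    run_severity_clustering,
)
from .io import (
    FilterReport,
    ParameterSpec,
    filter_parameters,
    read_parameter_specs,
    read_parameter_table,
)
from .preprocess import PreprocessManifest, apply_preprocess, fit_preprocess
from .score import CompositeScores, build_composite
from .selection import (
    ResampleConfig,
    SelectionConfig,
    StabilitySelectionResult,
    run_stability_selection,
    spearman_correlation_matrix,
)

DEFAULT_CONFIG = {
    "seed": 42,
    "filter": {"max_missing_fraction": 0.20},
    "preprocess": {"boxcox": True, "impute": "column_mean"},
    "select": {
        "n_runs": 100,
        "train_fraction": 0.80,
        "top_k": 4,
        "component": "auto",
        "n_selected": 4,
        "stratify_by_group": False,
    },
    "cluster": {"k": 3, "n_runs": 100, "train_fraction": 0.80, "n_init": 10},
}


def resolve_config(overrides: dict | None = None, seed: int | None = None) -> dict:
    """Merge user overrides onto the defaults (one level of nesting)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one pipeline run."""

    filter_report: FilterReport
    scaled_manifest: PreprocessManifest
    selection: StabilitySelectionResult
    scores: CompositeScores
    thresholds: ThresholdSet
    assignment: SeverityAssignment
    group_dist: "object"
    outdir: Path
    manifest: dict


def run_pipeline(
    table_path,
    specs_path,
    outdir,
    config: dict | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full composite-measure-scheme construction workflow.

    Writes: filtered.csv, filter_report.json, correlation.csv, scaled.csv,
    preprocess_manifest.json, selection.json, scores.csv, severity.json,
    levels.csv, group_distribution.csv, cms_model.json, summary.txt,
    run_manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = resolve_config(config, seed)
    started = datetime.now(timezone.utc).isoformat()

    table = read_parameter_table(table_path)
    specs = read_parameter_specs(specs_path)
    spec_by_name = {s.name: s for s in specs}

    # 1. parameter funnel
    filtered, report = filter_parameters(
        table, specs, cfg["filter"]["max_missing_fraction"]
    )
    filtered.write_csv(outdir / "filtered.csv", float_format="%.10g")
    report.write(outdir / "filter_report.json")

    # 2. exploratory correlation structure (raw retained parameters)
    corr = spearman_correlation_matrix(filtered)
    corr.to_csv(outdir / "correlation.csv", float_format="%.6f")

    # 3. normalize + standardize (+ impute)
    scaled = fit_preprocess(
        filtered,
        boxcox=cfg["preprocess"]["boxcox"],
        impute=cfg["preprocess"]["impute"],
    )
    scaled.values.to_csv(outdir / "scaled.csv", float_format="%.10g")
    scaled.manifest.write(outdir / "preprocess_manifest.json")

    # 4. resampled-PCA stability selection
    sel_cfg = cfg["select"]
    rconf = ResampleConfig(
        n_runs=sel_cfg["n_runs"],
        train_fraction=sel_cfg["train_fraction"],
        seed=cfg["seed"],
        stratify_by_group=sel_cfg["stratify_by_group"],
    )
    component = sel_cfg["component"]
    sconf = SelectionConfig(
        top_k=sel_cfg["top_k"],
        component=component if component == "auto" else int(component),
        n_selected=sel_cfg["n_selected"],
    )
    selection = run_stability_selection(scaled, rconf, sconf, keep_runs=False)
    with open(outdir / "selection.json", "w") as fh:
        json.dump(selection.to_dict(), fh, indent=2)

    # 5. composite score
    scores = build_composite(scaled, selection.selected, specs)
    scores.write_csv(outdir / "scores.csv")

    # 6. severity clustering + thresholds
    clu = cfg["cluster"]
    cconf = ClusterConfig(
        k=clu["k"], n_runs=clu["n_runs"], train_fraction=clu["train_fraction"],
        seed=cfg["seed"], n_init=clu["n_init"],
    )
    thresholds, memberships = run_severity_clustering(scores, cconf)
    thresholds.write(outdir / "severity.json")

    # 7. per-animal levels + per-group distributions
    assignment = assign_severity(scores, thresholds, memberships)
    assignment.write_csv(outdir / "levels.csv")
    gdist = group_distribution(memberships, scores.frame["model"], scores.frame["group"], clu["k"])
    gdist.to_csv(outdir / "group_distribution.csv", index=False, float_format="%.4f")

    # 8. frozen model bundle for cross-study application
    frozen = {
        "selected": selection.selected,
        "parameters": {
            p: {
                "lambda": scaled.manifest.lambdas.get(p),
                "offset": scaled.manifest.offsets.get(p),
                "mean": scaled.manifest.means[p],
                "sd": scaled.manifest.sds[p],
                "direction": spec_by_name[p].direction,
            }
            for p in selection.selected
        },
        "boxcox": scaled.manifest.boxcox,
        "thresholds": [float(t) for t in thresholds.mean],
    }
    with open(outdir / "cms_model.json", "w") as fh:
        json.dump(frozen, fh, indent=2)

    _write_summary(outdir / "summary.txt", report, selection, thresholds, gdist, cfg)

    artifacts = [
        "filtered.csv", "filter_report.json", "correlation.csv", "scaled.csv",
        "preprocess_manifest.json", "selection.json", "scores.csv", "severity.json",
        "levels.csv", "group_distribution.csv", "cms_model.json", "summary.txt",
    ]
    manifest = {
        "tool": "cmskit",
        "version": __version__,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "table": {"path": str(table_path), "sha256": _sha256(table_path)},
            "specs": {"path": str(specs_path), "sha256": _sha256(specs_path)},
        },
        "config": cfg,
        "artifacts": {a: _sha256(outdir / a) for a in artifacts},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        filter_report=report,
        scaled_manifest=scaled.manifest,
        selection=selection,
        scores=scores,
        thresholds=thresholds,
        assignment=assignment,
        group_dist=gdist,
        outdir=outdir,
        manifest=manifest,
    )


def _write_summary(path, report, selection, thresholds, gdist, cfg) -> None:
    lines = ["Composite measure scheme — pipeline summary", ""]
    lines.append("Parameter funnel:")
    lines.append(f"  input parameters:          {report.n_input_parameters}")
    lines.append(
        f"  removed by missingness:    {len(report.removed_by_missingness)}"
        f"  ({', '.join(report.removed_by_missingness) or '-'})"
    )
    lines.append(
        f"  removed by exclusion:      {len(report.removed_by_exclusion)}"
        f"  ({', '.join(report.removed_by_exclusion) or '-'})"
    )
    lines.append(f"  retained:                  {len(report.retained)}")
    lines.append("")
    lines.append("Stability selection (top-k loading frequency across runs):")
    for p, f in selection.frequency.sort_values(ascending=False).items():
        mark = " *" if p in selection.selected else ""
        lines.append(f"  {p:<22s} {int(f):>4d}{mark}")
    lines.append("  (* = selected)")
    lines.append("")
    lines.append("Explained variance (mean ± SD across runs):")
    for comp, row in selection.mean_explained_variance.head(4).iterrows():
        lines.append(f"  {comp}: {row['mean'] * 100:.2f}% ± {row['sd'] * 100:.2f}%")
    lines.append("")
    lines.append("Severity thresholds (composite-score scale, worst -> best):")
    k = thresholds.k
    for i, (m, lo, hi) in enumerate(
        zip(thresholds.mean, thresholds.ci_low, thresholds.ci_high)
    ):
        lines.append(f"  {k - i} to {k - i - 1}: {m:.2f} (95% CI: {lo:.2f} - {hi:.2f})")
    lines.append("")
    lines.append("Severity distribution per (model, group): mean % of animals (SD)")
    for (mod, grp), sub in gdist.groupby(["model", "group"], sort=True):
        cells = ", ".join(
            f"L{int(r.severity_level)}: {r.mean_pct:.1f}% ({r.sd_pct:.1f})"
            for r in sub.itertuples()
        )
        lines.append(f"  {mod}/{grp}: {cells}")
    lines.append("")
    lines.append(
        "Note: these severity levels support comparative assessment between "
        "models/interventions; they do not translate directly to EU Directive "
        "2010/63 severity categories without further processing and "
        "considerations."
    )
    Path(path).write_text("\n".join(lines) + "\n")


def apply_frozen_cms(table_path, model_path, thresholds_path=None, out_path=None):
    """Score and classify new animals with a frozen CMS — no refitting.

    ``model_path`` is a cms_model.json bundle (selected parameters with
    frozen lambda/offset/mean/SD/direction). Thresholds come from the
    bundle itself, or from ``thresholds_path`` (a severity.json file) if
    given. Returns the per-animal assignment frame.
    """
    import numpy as np
    import pandas as pd
    from scipy import special

    from .clustering import assign_levels

    with open(model_path) as fh:
        model = json.load(fh)
    table = read_parameter_table(table_path)
    selected = model["selected"]
    missing = [p for p in selected if p not in table.parameters]
    if missing:
        raise ValueError(f"input table lacks required parameter column(s): {missing}")
    if thresholds_path is not None:
        thr = ThresholdSet.read(thresholds_path).mean
    else:
        thr = np.asarray(model["thresholds"], dtype=float)

    z = pd.DataFrame(index=table.animal_ids)
    for p in selected:
        blk = model["parameters"][p]
        col = table.values[p].to_numpy(dtype=float)
        if model.get("boxcox") and blk.get("lambda") is not None:
            obs = ~np.isnan(col)
            out = np.full_like(col, np.nan)
            out[obs] = special.boxcox(col[obs] + blk["offset"], blk["lambda"])
            col = out
        zcol = (col - blk["mean"]) / blk["sd"]
        z[p] = np.where(np.isnan(zcol), 0.0, zcol) * blk["direction"]
    score = z.sum(axis=1)
    n_missing = table.values[selected].isna().sum(axis=1)
    frame = pd.DataFrame(
        {
            "group": table.groups,
            "model": table.models,
            "score": score,
            "n_contributing": len(selected) - n_missing,
            "severity_level": assign_levels(score.to_numpy(), thr),
        },
        index=table.animal_ids,
    )
    if out_path is not None:
        out = frame.copy()
        out.index.name = "animal_id"
        out.to_csv(out_path)
    return frame
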