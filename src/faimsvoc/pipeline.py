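"""Run orchestration: config, end-to-end analysis, and report rendering.

The library entry points are :func:`classify` (one comparison, one
classifier) and :func:`analyze` (every comparison x family x k, as in the
study).  ``cmd_simulate`` / ``cmd_analyze`` / ``cmd_report`` back the CLI
subcommands and work purely through files: a YAML run config in, CSV/JSON/
TSV/PNG reports out, with the archived config and seeds beside them so a
run can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from faimsvoc import comparisons as comp_mod
from faimsvoc.crossval import (
    CLASSIFIER_FAMILIES,
    ClassifierSpec,
    CrossValResult,
    make_folds,
    run_cv,
)
from faimsvoc.io import (
    CohortMetadata,
    FaimsSample,
    InstrumentRun,
    read_metadata,
    read_scan,
    select_replicate,
)
from faimsvoc.layout import Geometry, POLARITIES
from faimsvoc.performance import (
    PerformanceReport,
    build_report,
    plot_roc,
    roc_auc,
    round_half_up,
)
from faimsvoc.preprocess import FeatureVector, apply_mask, combine_polarities, fit_background_mask
from faimsvoc.select import feature_map_coordinates, plot_feature_map, write_feature_map
from faimsvoc.simulate import CohortConfig, SyntheticConfig, simulate_cohort, write_cohort


@dataclass
class RunConfig:
    """Declarative description of one analysis run (YAML-serialisable)."""

    input_dir: str | None = None
    simulate: dict | None = None  # SyntheticConfig overrides; used if no input_dir
    replicate: int = 2
    mask_statistic: str = "sd"
    mask_quantile: float = 0.5
    ks: tuple[int, ...] = (100, 50, 20)
    families: tuple[str, ...] = CLASSIFIER_FAMILIES
    comparisons: tuple[str, ...] = ()  # empty = all builtin
    n_folds: int = 10
    n_boot: int = 2000
    n_perm: int = 10000
    seed: int = 0
    output_dir: str = "faimsvoc_run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("ks", "families", "comparisons"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def synthetic_config_from_dict(d: dict | None, seed: int = 0) -> SyntheticConfig:
    """Build a SyntheticConfig from a flat override dict (YAML-friendly)."""
    d = dict(d or {})
    kwargs: dict = {"seed": d.pop("seed", seed)}
    if "geometry" in d:
        kwargs["geometry"] = Geometry(*d.pop("geometry"))
    if "cohort" in d:
        kwargs["cohort"] = CohortConfig(**d.pop("cohort"))
    if d.pop("null", False):
        kwargs["class_effects"] = ()
    for key in (
        "background_amplitude",
        "noise_sd",
        "gain_jitter",
        "n_replicates",
        "ground_truth_rel_threshold",
    ):
        if key in d:
            kwargs[key] = d.pop(key)
    if d:
        raise ValueError(f"unknown simulate keys: {sorted(d)}")
    return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# loading and vectorisation


def load_cohort(indir, replicate: int = 2) -> tuple[list[FaimsSample], CohortMetadata]:
    """Read a cohort written in the package dialects (see simulate.write_cohort)."""
    indir = Path(indir)
    metadata = read_metadata(indir / "metadata.csv")
    scans_dir = indir / "scans"
    samples = []
    for sid in metadata.sample_ids:
        runs = []
        for rep_path in sorted(scans_dir.glob(f"{sid}_r*_positive.csv")):
            rep = int(rep_path.stem.split("_r")[1].split("_")[0])
            pos = read_scan(rep_path, "positive")
            neg = read_scan(scans_dir / f"{sid}_r{rep}_negative.csv", "negative")
            runs.append(InstrumentRun(sid, rep, pos, neg))
        if not runs:
            raise FileNotFoundError(f"no scans found for sample {sid} under {scans_dir}")
        samples.append(
            FaimsSample(
                sample_id=sid,
                selected_run=select_replicate(runs, replicate),
                metadata=metadata.row(sid),
                replicate_choice=replicate,
            )
        )
    return samples, metadata


def sample_vectors(samples: list[FaimsSample]) -> dict[str, FeatureVector]:
    """Combine each sample's selected run into its flat feature vector."""
    return {s.sample_id: combine_polarities(s.selected_run) for s in samples}


def classify(
    vectors: list[FeatureVector],
    labels,
    family: str = "sparse_logistic_regression",
    k: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    mask_statistic: str = "sd",
    mask_quantile: float = 0.5,
    in_fold_selection: bool = True,
    comparison_id: str = "",
) -> CrossValResult:
    """Full single-comparison pipeline on in-memory vectors.

    Background masking (label-blind, fitted once on all vectors), then
    tenfold CV with in-fold rank-sum selection of the top ``k`` features
    and the requested classifier family.  ``in_fold_selection=False`` is
    the deliberately leaky variant kept to demonstrate selection bias.
    """
    mask = fit_background_mask(vectors, statistic=mask_statistic, quantile=mask_quantile)
    masked = [apply_mask(v, mask) for v in vectors] if len(mask) else vectors
    y = np.asarray(labels).astype(bool)
    folds = make_folds(y, n_folds=min(n_folds, y.size), seed=seed)
    return run_cv(
        masked,
        y,
        ClassifierSpec(family, seed=seed),
        k=k,
        folds=folds,
        comparison_id=comparison_id,
        in_fold_selection=in_fold_selection,
    )


@dataclass
class AnalysisOutput:
    reports: list[PerformanceReport]
    results: list[CrossValResult]
    log: list[str] = field(default_factory=list)

    def best_per_comparison(self) -> dict[str, PerformanceReport]:
        return {r.comparison_id: r for r in self.reports if r.best}


def analyze(
    vectors_by_id: dict[str, FeatureVector],
    metadata: CohortMetadata,
    config: RunConfig,
) -> AnalysisOutput:
    """Run every requested comparison x classifier family x k.

    Flags the best performer per comparison by highest AUC.  Comparisons
    with an empty arm on this cohort are skipped with a log entry.
    """
    specs = comp_mod.builtin_comparisons()
    if config.comparisons:
        by_id = {s.id: s for s in specs}
        unknown = set(config.comparisons) - set(by_id)
        if unknown:
            raise ValueError(f"unknown comparison ids: {sorted(unknown)}")
        specs = [by_id[c] for c in config.comparisons]
    log: list[str] = []
    reports: list[PerformanceReport] = []
    results: list[CrossValResult] = []
    for spec in specs:
        try:
            res = comp_mod.resolve(spec, metadata)
        except ValueError as e:
            log.append(f"skipped {spec.id}: {e}")
            continue
        if res.excluded_ids:
            log.append(f"{spec.id}: excluded {len(res.excluded_ids)} subjects")
        ids = res.arm_a_ids + res.arm_b_ids
        vecs = [vectors_by_id[i] for i in ids]
        y = np.array([True] * len(res.arm_a_ids) + [False] * len(res.arm_b_ids))
        comp_reports = []
        for family in config.families:
            for k in config.ks:
                result = classify(
                    vecs,
                    y,
                    family=family,
                    k=k,
                    n_folds=config.n_folds,
                    seed=config.seed,
                    mask_statistic=config.mask_statistic,
                    mask_quantile=config.mask_quantile,
                    comparison_id=spec.id,
                )
                results.append(result)
                try:
                    comp_reports.append(
                        build_report(
                            result,
                            n_boot=config.n_boot,
                            n_perm=config.n_perm,
                            seed=config.seed,
                            positive_class=spec.arm_a_name,
                        )
                    )
                except ValueError as e:  # e.g. every fold failed on a tiny arm
                    log.append(f"skipped {spec.id} ({family}, k={k}): {e}")
        if comp_reports:
            best = max(comp_reports, key=lambda r: r.auc)
            best.best = True
        reports.extend(comp_reports)
    return AnalysisOutput(reports=reports, results=results, log=log)


# ---------------------------------------------------------------------------
# CLI-facing commands


def cmd_simulate(config: RunConfig, force: bool = False) -> Path:
    """Generate a synthetic cohort on disk."""
    outdir = Path(config.output_dir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use --force)")
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_config_from_dict(config.simulate, seed=config.seed)
    cohort = simulate_cohort(cfg)
    write_cohort(cohort, outdir)
    (outdir / "ground_truth.json").write_text(
        json.dumps({k: v.tolist() for k, v in cohort.ground_truth.items()})
    )
    config.to_yaml(outdir / "config.yaml")
    return outdir


def cmd_analyze(config: RunConfig) -> Path:
    """Run the analysis described by a config; write reports to disk."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_dir:
        samples, metadata = load_cohort(config.input_dir, replicate=config.replicate)
    else:
        cohort = simulate_cohort(
            synthetic_config_from_dict(config.simulate, seed=config.seed)
        )
        samples, metadata = cohort.samples, cohort.metadata
    vectors = sample_vectors(samples)
    out = analyze(vectors, metadata, config)

    rows = [r.to_dict() for r in out.reports]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "reports.csv", index=False)
    payload = {
        "reports": rows,
        "log": out.log,
        "seed": config.seed,
        "scores": {},
    }
    geom = next(iter(vectors.values())).geometry
    for res in out.results:
        key = f"{res.comparison_id}/{res.family}/k{res.k}"
        payload["scores"][key] = {
            "sample_ids": res.sample_ids,
            "scores": [None if np.isnan(s) else float(s) for s in res.scores],
            "labels": res.labels.astype(int).tolist(),
            "fold_id": res.fold_id.tolist(),
        }
    (outdir / "reports.json").write_text(json.dumps(payload, indent=1))
    config.to_yaml(outdir / "config.yaml")

    # feature maps for each comparison's best model
    best_keys = {
        (r.comparison_id, r.family, r.k) for r in out.reports if r.best
    }
    for res in out.results:
        if (res.comparison_id, res.family, res.k) in best_keys:
            sel = np.unique(np.concatenate(list(res.selected_per_fold.values())))
            coords = feature_map_coordinates(sel, geom)
            write_feature_map(outdir / f"features_{res.comparison_id}.tsv", coords)
            try:
                plot_feature_map(coords, outdir / f"features_{res.comparison_id}.png")
            except Exception as e:  # plotting must never sink a run
                warnings.warn(f"feature-map plot failed: {e}", stacklevel=2)
    return outdir


def cmd_report(run_dir) -> Path:
    """Render a completed run as a markdown summary table + ROC images."""
    run_dir = Path(run_dir)
    payload = json.loads((run_dir / "reports.json").read_text())
    lines = [
        "| Comparison | Best performing algorithm | Features (number) | AUC (95% CI) | P | "
        "Sensitivity | Specificity | PPV | NPV |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    spec_labels = {s.id: s.label for s in comp_mod.builtin_comparisons()}
    reports = payload["reports"]
    seen = set()
    for r in reports:
        if not r["best"]:
            continue
        seen.add(r["comparison_id"])
        lo, hi = r["auc_ci_95"]
        f2 = round_half_up
        lines.append(
            f"| {spec_labels.get(r['comparison_id'], r['comparison_id'])} "
            f"| {r['family'].replace('_', ' ')} | {r['k']} "
            f"| {f2(r['auc'])} ({f2(lo)}-{f2(hi)}) | {r['p_value']:.3g} "
            f"| {f2(r['sensitivity'])} | {f2(r['specificity'])} "
            f"| {f2(r['ppv'])} | {f2(r['npv'])} |"
        )
        key = f"{r['comparison_id']}/{r['family']}/k{r['k']}"
        sc = payload["scores"][key]
        scores = np.array([np.nan if s is None else s for s in sc["scores"]])
        labels = np.array(sc["labels"], dtype=bool)
        ok = ~np.isnan(scores)
        if labels[ok].any() and (~labels[ok]).any():
            curve, auc = roc_auc(scores[ok], labels[ok])
            plot_roc(
                curve,
                auc,
                spec_labels.get(r["comparison_id"], r["comparison_id"]),
                run_dir / f"roc_{r['comparison_id']}.png",
            )
    for entry in payload.get("log", []):
        if entry.startswith("skipped"):
            lines.append(f"| {entry.split()[1].rstrip(':')} | skipped | | | | | | | |")
    md = run_dir / "report.md"
    md.write_text("\n".join(lines) + "\n")
    return md
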