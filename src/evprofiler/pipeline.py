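"""End-to-end orchestration: reduction -> selection -> comparison -> ROC.

The pipeline consumes a cohort manifest plus per-sample event tables,
reduces every sample to its variable profile, runs the two-level
regression-tree selection against the CD-RISC score for the requested
analysis mode(s) (baseline D0 profiles and/or D3 - D0 change scores),
compares each candidate variable between the resilience groups with
normality-routed tests, and evaluates the diagnostic accuracy of every
significant candidate with a ROC analysis.  Biomarker and NTA panels, when
provided, additionally get paired baseline-to-peak-stress tests.

The report is a plain dict (JSON-serializable); identical inputs, config
and seed produce byte-identical report files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as evio
from .cart import CartConfig
from .cohort import CohortManifest, TIMEPOINTS
from .manifest import FeatureManifest, default_manifest
from .reduction import change_scores, reduce_sample
from .roc import roc_analysis
from .selection import select_features
from .stats import compare_groups, paired_change_test

log = logging.getLogger(__name__)

MODES = ("baseline", "change", "both")


@dataclass
class PipelineConfig:
    feature_manifest: FeatureManifest = field(default_factory=default_manifest)
    cart: CartConfig = field(default_factory=CartConfig)
    alpha: float = 0.05
    mode: str = "change"
    level1_scope: str = "all_splitters"
    equal_var: bool = True
    outdir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "feature_manifest": self.feature_manifest.to_dict(),
            "cart": {"min_terminal": self.cart.min_terminal,
                     "min_parent": self.cart.min_parent,
                     "max_depth": self.cart.max_depth,
                     "min_improvement": self.cart.min_improvement},
            "alpha": self.alpha, "mode": self.mode,
            "level1_scope": self.level1_scope, "equal_var": self.equal_var,
            "seed": self.seed,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def reduce_cohort(manifest: CohortManifest, fm: FeatureManifest,
                  tables: dict[tuple[str, str], pd.DataFrame] | None = None
                  ) -> dict[tuple[str, str], pd.Series]:
    """Per-sample profiles for every (subject, timepoint) with a table.

    ``tables`` supplies in-memory event tables (samples absent from it are
    skipped); without it, tables are read from the manifest's paths.  Stage
    errors are re-raised with the sample identity attached.
    """
    profiles: dict[tuple[str, str], pd.Series] = {}
    for rec in manifest.subjects:
        for tp in TIMEPOINTS:
            key = (rec.subject_id, tp)
            if tables is not None:
                if key not in tables:
                    continue
                table = tables[key]
            elif rec.event_tables.get(tp):
                table = evio.read_event_table(rec.event_tables[tp], fm)
            else:
                continue
            try:
                profiles[key] = reduce_sample(table, fm)
            except Exception as err:
                raise RuntimeError(
                    f"reduction failed for sample {rec.subject_id}/{tp}: {err}"
                ) from err
    return profiles


def analysis_frame(manifest: CohortManifest,
                   profiles: dict[tuple[str, str], pd.Series],
                   mode: str) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """(subjects x variables frame, scores, groups) for one analysis mode."""
    rows, scores, groups, index = [], [], [], []
    for rec in manifest.subjects:
        if mode == "baseline":
            if (rec.subject_id, "D0") not in profiles:
                continue
            rows.append(profiles[(rec.subject_id, "D0")])
        else:
            if any((rec.subject_id, tp) not in profiles for tp in TIMEPOINTS):
                continue  # change scores need both timepoints
            rows.append(change_scores(profiles[(rec.subject_id, "D0")],
                                      profiles[(rec.subject_id, "D3")]))
        scores.append(rec.cdrisc)
        groups.append(rec.group)
        index.append(rec.subject_id)
    frame = pd.DataFrame(rows, index=index)
    return frame, np.asarray(scores, dtype=float), groups


def _run_analysis(frame: pd.DataFrame, scores: np.ndarray, groups: list[str],
                  config: PipelineConfig) -> dict:
    sel = select_features(frame, scores, config.cart,
                          manifest=config.feature_manifest,
                          level1_scope=config.level1_scope)
    is_high = np.asarray([g == "high" for g in groups])
    comparisons, rocs = [], []
    for vid in sel.candidates:
        vals = frame[vid].to_numpy(dtype=float)
        cmp_ = compare_groups(vals[is_high], vals[~is_high],
                              alpha=config.alpha, variable=vid,
                              equal_var=config.equal_var)
        comparisons.append(cmp_.to_dict())
        if cmp_.p < config.alpha and not cmp_.degenerate:
            rocs.append(roc_analysis(vals, is_high, positive=True,
                                     variable=vid).to_dict())
    return {
        "n_subjects": int(len(frame)),
        "selection": sel.to_dict(include_trees=False),
        "candidates": sel.candidates,
        "n_candidates": len(sel.candidates),
        "comparisons": comparisons,
        "roc": rocs,
        "trees": {k: t.to_dict() for k, t in sel.trees.items()},
    }


def _stress_effects(panel: pd.DataFrame | None, value_cols: list[str],
                    key_col: str | None, alpha: float) -> dict:
    """Paired D0 vs D3 tests across all subjects for panel measurements."""
    if panel is None or panel.empty:
        return {}
    out: dict[str, dict] = {}
    groups = panel.groupby(key_col) if key_col else [(None, panel)]
    for name, sub in groups:
        wide = sub.pivot_table(index="subject_id", columns="timepoint",
                               values=value_cols, aggfunc="first")
        for col in value_cols:
            if ("D0" not in wide[col] or "D3" not in wide[col]):
                continue
            paired = wide[col].dropna(subset=["D0", "D3"])
            if len(paired) < 3:
                continue
            res = paired_change_test(paired["D0"].to_numpy(),
                                     paired["D3"].to_numpy(), alpha=alpha)
            label = str(name) if name is not None else col
            if key_col and len(value_cols) > 1:
                label = f"{name}/{col}"
            out[label] = res.to_dict()
    return out


def run_pipeline(manifest: CohortManifest, config: PipelineConfig | None = None,
                 tables: dict[tuple[str, str], pd.DataFrame] | None = None,
                 biomarkers: pd.DataFrame | None = None,
                 nta: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline and (optionally) write the report files.

    Returns the report dict; when ``config.outdir`` is set, also writes
    ``variables.tsv``, ``selection.json``, ``comparisons.tsv``, ``roc.tsv``
    and ``report.json`` there.
    """
    config = config or PipelineConfig()
    fm = config.feature_manifest
    warnings = manifest.validate()
    for w in warnings:
        log.warning("cohort: %s", w)

    profiles = reduce_cohort(manifest, fm, tables)
    modes = ("baseline", "change") if config.mode == "both" else (config.mode,)

    report: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_high": manifest.n_high,
        "n_low": manifest.n_low,
        "cohort_warnings": warnings,
        "n_samples_reduced": len(profiles),
        "analyses": {},
    }
    for mode in modes:
        frame, scores, groups = analysis_frame(manifest, profiles, mode)
        if len(frame) == 0:
            report["analyses"][mode] = {"error": "no eligible subjects"}
            continue
        report["analyses"][mode] = _run_analysis(frame, scores, groups, config)

    stress: dict = {}
    if biomarkers is not None:
        stress.update(_stress_effects(biomarkers, ["value"], "analyte",
                                      config.alpha))
    if nta is not None:
        stress.update(_stress_effects(nta, ["concentration_e10", "mean_size_nm"],
                                      None, config.alpha))
    report["stress_effects"] = stress

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        evio.write_variables_table(profiles,
                                   os.path.join(config.outdir, "variables.tsv"))
        selection_doc = {m: report["analyses"][m].get("selection")
                         for m in report["analyses"]}
        evio.write_json(selection_doc, os.path.join(config.outdir, "selection.json"))
        all_cmp = [c for m in report["analyses"]
                   for c in report["analyses"][m].get("comparisons", [])]
        evio.write_comparisons_tsv(all_cmp,
                                   os.path.join(config.outdir, "comparisons.tsv"))
        all_roc = [r for m in report["analyses"]
                   for r in report["analyses"][m].get("roc", [])]
        evio.write_roc_tsv(all_roc, os.path.join(config.outdir, "roc.tsv"))
        slim = {k: v for k, v in report.items()}
        slim["analyses"] = {
            m: {k: v for k, v in a.items() if k != "trees"}
            for m, a in report["analyses"].items()}
        evio.write_json(slim, os.path.join(config.outdir, "report.json"))
    return report


#: backwards-compatible private alias
_analysis_frame = analysis_frame
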