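"""Readers and writers for event tables, cohort manifests and reports.

Event tables are the per-object CSV exports of the vendor analysis software
(header row + numeric rows); the column spellings vary by export template,
so headers are resolved through the feature manifest's alias map.  Cohort
manifests are tidy TSV (subject_id, group, cdrisc, timepoint, path) or a
YAML equivalent.  Pipeline outputs are tidy TSV tables plus one JSON
summary; all JSON is written with sorted keys so identical inputs produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd
import yaml

from .cohort import TIMEPOINTS, CohortManifest, SubjectRecord
from .manifest import FeatureManifest, parse_variable_id

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def read_event_table(path, manifest: FeatureManifest) -> pd.DataFrame:
    """Read one per-sample event CSV into canonical column names.

    Headers are resolved through the manifest alias map; unresolvable extra
    columns are dropped with a logged warning; missing required columns or
    non-numeric cells in feature columns raise.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    raw.columns = [manifest.resolve_column(c) for c in raw.columns]

    required = manifest.required_columns()
    if "Area_BF" not in raw.columns:
        raise ValueError(f"{path}: no resolvable brightfield area column "
                         "(required feature absent)")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: required feature absent: {missing}")

    known = set(required) | {
        c for f in manifest.excluded_features for c in f.columns(manifest.channels)}
    extra = [c for c in raw.columns if c not in known]
    if extra:
        log.warning("%s: ignoring %d unresolvable columns: %s",
                    path, len(extra), extra[:8])
    out = raw[[c for c in raw.columns if c in known]]
    try:
        out = out.apply(pd.to_numeric)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric cell in a feature column: {err}") from err
    return out


def write_event_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

def read_cohort_manifest(path) -> CohortManifest:
    """Read a cohort manifest (tidy TSV or YAML) and validate it.

    Group/score consistency violations are logged as warnings (not fatal);
    duplicate subject ids, unknown group labels or out-of-range scores raise.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty cohort manifest")
    base = os.path.dirname(os.path.abspath(path))

    if str(path).endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not doc or "subjects" not in doc:
            raise ValueError(f"{path}: no subjects in manifest")
        records = []
        for s in doc["subjects"]:
            tables = {tp: (os.path.join(base, p) if p else None)
                      for tp, p in (s.get("tables") or {}).items()}
            records.append(SubjectRecord(str(s["subject_id"]), s["group"],
                                         float(s["cdrisc"]), tables))
    else:
        df = pd.read_csv(path, sep="\t")
        needed = {"subject_id", "group", "cdrisc", "timepoint", "path"}
        if not needed <= set(df.columns):
            raise ValueError(f"{path}: manifest needs columns {sorted(needed)}")
        records = []
        for sid, sub in df.groupby("subject_id", sort=False):
            groups = sub["group"].unique()
            scores = sub["cdrisc"].unique()
            if len(groups) > 1 or len(scores) > 1:
                raise ValueError(f"{path}: inconsistent rows for subject {sid}")
            tables = {row.timepoint: os.path.join(base, row.path)
                      for row in sub.itertuples() if isinstance(row.path, str)}
            records.append(SubjectRecord(str(sid), groups[0], float(scores[0]), tables))

    manifest = CohortManifest(subjects=records)
    for w in manifest.validate():
        log.warning("cohort manifest: %s", w)
    return manifest


def write_cohort_manifest(manifest: CohortManifest, path) -> None:
    rows = [(s.subject_id, s.group, s.cdrisc, tp, s.event_tables.get(tp))
            for s in manifest.subjects for tp in TIMEPOINTS
            if s.event_tables.get(tp) is not None]
    pd.DataFrame(rows, columns=["subject_id", "group", "cdrisc",
                                "timepoint", "path"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variables tables
# ---------------------------------------------------------------------------

def variables_to_tidy(profiles: dict[tuple[str, str], pd.Series]) -> pd.DataFrame:
    """Long-format variables table: one row per (sample, variable)."""
    rows = []
    for (sid, tp), prof in profiles.items():
        for vid, value in prof.items():
            feature, channel, stratum, statistic = parse_variable_id(vid)
            rows.append((sid, tp, feature, channel, stratum, statistic, value))
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", "feature",
                                       "channel", "stratum", "statistic", "value"])


def write_variables_table(profiles: dict[tuple[str, str], pd.Series], path) -> None:
    variables_to_tidy(profiles).to_csv(path, sep="\t", index=False)


def read_variables_table(path) -> dict[tuple[str, str], pd.Series]:
    """Inverse of :func:`write_variables_table` (round-trips profiles)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"subject_id": str, "timepoint": str})
    out: dict[tuple[str, str], pd.Series] = {}
    vid = (df["feature"] + "|" + df["channel"] + "|" + df["stratum"]
           + "|" + df["statistic"])
    df = df.assign(variable_id=vid)
    for (sid, tp), sub in df.groupby(["subject_id", "timepoint"], sort=False):
        out[(sid, tp)] = pd.Series(sub["value"].to_numpy(),
                                   index=sub["variable_id"].to_numpy(),
                                   dtype=float, name="value")
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default,
                  allow_nan=True)
        fh.write("\n")


def write_comparisons_tsv(comparisons: list[dict], path) -> None:
    rows = []
    for c in comparisons:
        eff = c.get("effect") or {}
        hi, lo = c["summaries"].get("high", {}), c["summaries"].get("low", {})
        rows.append({
            "variable": c["variable"], "test": c["test"],
            "statistic": c["statistic"], "p": c["p"],
            "high_mean": hi.get("mean"), "high_sd": hi.get("sd"),
            "high_median": hi.get("median"), "high_iqr": hi.get("iqr"),
            "low_mean": lo.get("mean"), "low_sd": lo.get("sd"),
            "low_median": lo.get("median"), "low_iqr": lo.get("iqr"),
            "hedges_g": eff.get("g"), "g_ci_low": eff.get("ci_low"),
            "g_ci_high": eff.get("ci_high"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_roc_tsv(rocs: list[dict], path) -> None:
    rows = []
    for r in rocs:
        rows.append({
            "variable": r["variable"], "auc": r["auc"],
            "auc_ci_low": r["auc_ci"][0], "auc_ci_high": r["auc_ci"][1],
            "p": r["p"], "cutoff": r["cutoff"], "direction": r["direction"],
            "sensitivity": r["sensitivity"],
            "sens_ci_low": r["sensitivity_ci"][0],
            "sens_ci_high": r["sensitivity_ci"][1],
            "specificity": r["specificity"],
            "spec_ci_low": r["specificity_ci"][0],
            "spec_ci_high": r["specificity_ci"][1],
            "youden_j": r["j"], "lr_plus": r["lr_plus"],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
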