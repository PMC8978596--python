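"""Per-event data reduction: filter, derive, stratify, summarize, change scores.

The reduction turns one event table (rows = detected objects) into a single
per-sample profile: events saturating any fluorescence channel are removed as
debris/aggregates, a pixel-range feature is derived per channel, events are
stratified by brightfield area into small / medium / large vesicles, and the
mean (AVG), median (MED) and sample standard deviation (SD) of every active
feature are computed per channel within each stratum and over the whole
sample.  Change scores are elementwise D3 - D0 differences of two profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .manifest import STRATA, FeatureManifest, make_variable_id

log = logging.getLogger(__name__)


def filter_events(table: pd.DataFrame, manifest: FeatureManifest) -> pd.DataFrame:
    """Remove saturated events and excluded-feature columns.

    An object with a saturation count >= 1 in any fluorescence channel is
    treated as possible debris or a fluorochrome aggregate and removed.
    Columns of manifest-excluded features are dropped.  Removal counts are
    logged; a sample losing all its events is flagged with a warning.
    """
    sat_cols = [f"SaturationCount_{ch}" for ch in manifest.channels]
    missing = [c for c in sat_cols if c not in table.columns]
    if missing:
        raise ValueError(f"saturation-count columns absent: {missing}")
    keep = (table[sat_cols].to_numpy() == 0).all(axis=1)
    out = table.loc[keep]
    n_removed = len(table) - len(out)
    log.info("filter_events: retained %d / %d events (%d saturated removed)",
             len(out), len(table), n_removed)
    drop = [c for f in manifest.excluded_features
            for c in f.columns(manifest.channels) if c in out.columns]
    out = out.drop(columns=drop)
    if len(table) and not len(out):
        log.warning("filter_events: all %d events removed; sample is empty", len(table))
    return out.reset_index(drop=True)


def derive_pixel_range(table: pd.DataFrame, manifest: FeatureManifest) -> pd.DataFrame:
    """Add per-channel PixelRange = RawMaxPixel - RawMinPixel.

    Raises if any event has RawMaxPixel < RawMinPixel (an invalid export).
    """
    out = table.copy()
    for ch in manifest.channels:
        hi, lo = f"RawMaxPixel_{ch}", f"RawMinPixel_{ch}"
        if hi not in out.columns or lo not in out.columns:
            raise ValueError(f"raw pixel columns absent for channel {ch}")
        rng = out[hi].to_numpy() - out[lo].to_numpy()
        if (rng < 0).any():
            raise ValueError(f"RawMaxPixel < RawMinPixel in channel {ch}")
        out[f"PixelRange_{ch}"] = rng
    return out


def stratify(area, manifest: FeatureManifest):
    """Map brightfield area (um^2) to a size stratum.

    small if area < cutoff_small; medium if cutoff_small <= area <= cutoff_large
    (both boundaries inclusive on the medium side); large if area > cutoff_large.
    Accepts a scalar or an array; areas must be strictly positive.
    """
    arr = np.asarray(area, dtype=float)
    if (arr <= 0).any():
        raise ValueError("non-positive brightfield area")
    labels = np.where(arr < manifest.cutoff_small, "small",
                      np.where(arr > manifest.cutoff_large, "large", "medium"))
    if np.isscalar(area) or arr.ndim == 0:
        return str(labels)
    return labels


def _stratum_masks(areas: np.ndarray, manifest: FeatureManifest) -> dict[str, np.ndarray]:
    small = areas < manifest.cutoff_small
    large = areas > manifest.cutoff_large
    medium = ~small & ~large
    return {"small": small, "medium": medium, "large": large,
            "total": np.ones_like(small, dtype=bool)}


def _stats_by_stratum(values: np.ndarray, masks: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for stratum, mask in masks.items():
        v = values[mask]
        n = v.size
        if n == 0:
            avg = med = sd = np.nan
        else:
            avg = float(v.mean())
            med = float(np.median(v))
            sd = float(v.std(ddof=1)) if n >= 2 else np.nan
        out[(stratum, "AVG")] = avg
        out[(stratum, "MED")] = med
        out[(stratum, "SD")] = sd
    return out


def summarize_sample(table: pd.DataFrame, manifest: FeatureManifest) -> pd.Series:
    """Reduce a filtered, derived event table to the per-sample profile.

    Returns a float Series indexed by variable id (feature|channel|stratum|
    statistic) in canonical manifest order.  Strata with zero events yield
    missing AVG/MED; strata with fewer than two events yield missing SD.
    Missingness is data, not an error.

    When a per-channel positivity gate is configured, each channel's
    summaries (for every feature, including channel-agnostic ones) are
    computed over the events exceeding that channel's intensity threshold;
    by default no gate is applied and channel-agnostic features are
    identical across the antibody dimension.
    """
    if "Area_BF" not in table.columns:
        raise ValueError("required feature absent: Area_BF")
    areas = table["Area_BF"].to_numpy(dtype=float)
    gates = manifest.positivity_thresholds or {}

    all_masks = _stratum_masks(areas, manifest) if len(table) else {
        s: np.zeros(0, dtype=bool) for s in STRATA}
    masks_by_channel: dict[str, dict[str, np.ndarray]] = {}
    for ch in manifest.channels:
        if ch in gates:
            pos = table[f"Intensity_{ch}"].to_numpy(dtype=float) > gates[ch]
            masks_by_channel[ch] = {s: m & pos for s, m in all_masks.items()}
        else:
            masks_by_channel[ch] = all_masks

    # cache per (column, channel-mask identity) so channel-agnostic columns
    # are summarized once when ungated
    cache: dict[tuple[str, int], dict[tuple[str, str], float]] = {}
    values: dict[str, float] = {}
    for feat in manifest.active_features:
        for ch in manifest.channels:
            col = feat.column_for(ch)
            if col not in table.columns:
                raise ValueError(f"required feature absent: {col}")
            key = (col, id(masks_by_channel[ch]))
            if key not in cache:
                cache[key] = _stats_by_stratum(
                    table[col].to_numpy(dtype=float), masks_by_channel[ch])
            stats = cache[key]
            for stratum in STRATA:
                for stat in manifest.statistics:
                    values[make_variable_id(feat.name, ch, stratum, stat)] = \
                        stats[(stratum, stat)]

    ids = manifest.variable_ids()
    return pd.Series([values[i] for i in ids], index=ids, dtype=float, name="value")


def reduce_sample(table: pd.DataFrame, manifest: FeatureManifest) -> pd.Series:
    """filter -> derive -> summarize, the full per-sample reduction."""
    return summarize_sample(
        derive_pixel_range(filter_events(table, manifest), manifest), manifest)


def change_scores(d0: pd.Series, d3: pd.Series) -> pd.Series:
    """Elementwise stress-response change profile, D3 - D0.

    Both profiles must cover the same variable ids; the result is missing
    wherever either input is missing.
    """
    if set(d0.index) != set(d3.index):
        raise ValueError("variable-id sets differ between D0 and D3 profiles")
    return (d3 - d0.reindex(d3.index)).rename("change")
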