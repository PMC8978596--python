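"""Data-reduction unit and property tests: filtering, derivation,
stratification, per-sample summarization and change scores."""

import numpy as np
import pandas as pd
import pytest

from evprofiler.manifest import STRATA, default_manifest, make_variable_id, parse_variable_id
from evprofiler.reduction import (change_scores, derive_pixel_range,
                                  filter_events, reduce_sample, stratify,
                                  summarize_sample)

from oracles import brute_force_summaries


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("area, expected", [
    (0.02, "small"),
    (0.031416, "medium"),     # lower boundary is inclusive on the medium side
    (0.5, "medium"),
    (0.785398, "medium"),     # upper boundary is inclusive on the medium side
    (0.8, "large"),
])
def test_stratify_boundaries(fm, area, expected):
    assert stratify(area, fm) == expected


def test_stratify_rejects_nonpositive_area(fm):
    with pytest.raises(ValueError):
        stratify(0.0, fm)
    with pytest.raises(ValueError):
        stratify(np.array([0.1, -1.0]), fm)


def test_default_cutoffs_are_circular_areas(fm):
    # areas of 200 nm and 1000 nm diameter circles, the conventional
    # exosome / microvesicle / apoptotic-body size boundaries
    assert fm.cutoff_small == pytest.approx(np.pi * 0.1 ** 2, abs=5e-7)
    assert fm.cutoff_large == pytest.approx(np.pi * 0.5 ** 2, abs=5e-7)


# ---------------------------------------------------------------------------
# saturation filter
# ---------------------------------------------------------------------------

def test_filter_removes_any_saturated_channel(fm, event_table):
    table = event_table.copy()
    out = filter_events(table, fm)
    sat_cols = [f"SaturationCount_{ch}" for ch in fm.channels]
    # row-scan oracle for the retained count
    expected = sum(1 for _, row in table.iterrows()
                   if all(row[c] == 0 for c in sat_cols))
    assert len(out) == expected
    assert 0 < len(out) < len(table)  # the fixture contains saturated events
    # saturation counters are themselves excluded features, hence dropped
    assert not any(c in out.columns for c in sat_cols)


def test_filter_single_saturated_event(fm, event_table):
    table = event_table.copy()
    table[[f"SaturationCount_{ch}" for ch in fm.channels]] = 0.0
    table.loc[3, "SaturationCount_CD63"] = 1.0
    out = filter_events(table, fm)
    assert len(out) == len(table) - 1


def test_filter_drops_excluded_feature_columns(fm, event_table):
    out = filter_events(event_table, fm)
    assert "ObjectNumber" not in out.columns


def test_adding_saturated_event_never_changes_profile(fm, event_table):
    """Monotone filtering: a saturated event is invisible to the profile."""
    base = reduce_sample(event_table, fm)
    extra = event_table.iloc[[0]].copy()
    extra["SaturationCount_THSD1"] = 2.0
    extra["Area_BF"] = 99.0  # would land in 'large' if it were kept
    augmented = pd.concat([event_table, extra], ignore_index=True)
    pd.testing.assert_series_equal(base, reduce_sample(augmented, fm))


# ---------------------------------------------------------------------------
# pixel range
# ---------------------------------------------------------------------------

def test_pixel_range_matches_elementwise_subtraction(fm, event_table):
    out = derive_pixel_range(event_table, fm)
    for ch in fm.channels:
        expected = (event_table[f"RawMaxPixel_{ch}"].to_numpy()
                    - event_table[f"RawMinPixel_{ch}"].to_numpy())
        np.testing.assert_allclose(out[f"PixelRange_{ch}"].to_numpy(), expected)
        assert (out[f"PixelRange_{ch}"] >= 0).all()


def test_pixel_range_simple_values(fm):
    table = pd.DataFrame({"RawMaxPixel_CD63": [100.0, 7.0],
                          "RawMinPixel_CD63": [40.0, 7.0]})
    for ch in ("VAMP3", "THSD1"):
        table[f"RawMaxPixel_{ch}"] = 1.0
        table[f"RawMinPixel_{ch}"] = 0.0
    out = derive_pixel_range(table, fm)
    assert out["PixelRange_CD63"].tolist() == [60.0, 0.0]


def test_pixel_range_rejects_inverted_pixels(fm):
    table = pd.DataFrame({f"Raw{side}Pixel_{ch}": [1.0]
                          for ch in fm.channels for side in ("Max", "Min")})
    table["RawMaxPixel_CD63"] = 0.5
    table["RawMinPixel_CD63"] = 1.0
    with pytest.raises(ValueError, match="RawMaxPixel < RawMinPixel"):
        derive_pixel_range(table, fm)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def test_profile_has_1116_variables(fm, event_table):
    prof = reduce_sample(event_table, fm)
    assert len(prof) == 1116
    stats = [parse_variable_id(v)[3] for v in prof.index]
    assert stats.count("AVG") == stats.count("MED") == stats.count("SD") == 372


def test_constant_feature_summaries(fm, event_table):
    table = derive_pixel_range(filter_events(event_table, fm), fm)
    table["Intensity_CD63"] = 7.5
    prof = summarize_sample(table, fm)
    for stratum in STRATA:
        n = (stratify(table["Area_BF"].to_numpy(), fm) == stratum).sum() \
            if stratum != "total" else len(table)
        if n >= 1:
            assert prof[make_variable_id("Intensity", "CD63", stratum, "AVG")] == 7.5
            assert prof[make_variable_id("Intensity", "CD63", stratum, "MED")] == 7.5
        if n >= 2:
            assert prof[make_variable_id("Intensity", "CD63", stratum, "SD")] == 0.0


def test_summaries_match_row_scan_oracle(fm):
    """30 spot-checked variables equal an independently coded summarizer."""
    rng = np.random.default_rng(23)
    from conftest import neutral_params
    from evprofiler.synthetic import generate_event_sample
    table = generate_event_sample(neutral_params(p_sat=0.0), 500, rng)
    table = derive_pixel_range(table, fm)
    prof = summarize_sample(table, fm)
    oracle = brute_force_summaries(table, fm)
    picked = rng.choice(prof.index.to_numpy(), size=30, replace=False)
    for vid in picked:
        a, b = prof[vid], oracle[vid]
        if np.isnan(a) or np.isnan(b):
            assert np.isnan(a) and np.isnan(b)
        else:
            assert a == pytest.approx(b, rel=1e-9), vid


def test_stratum_counts_partition_total(fm, event_table):
    labels = stratify(event_table["Area_BF"].to_numpy(), fm)
    counts = {s: int((labels == s).sum()) for s in ("small", "medium", "large")}
    assert sum(counts.values()) == len(event_table)


def test_total_mean_is_weighted_stratum_mean(fm, event_table):
    """Exact identity: total AVG = event-count-weighted mean of stratum AVGs."""
    table = derive_pixel_range(filter_events(event_table, fm), fm)
    prof = summarize_sample(table, fm)
    labels = stratify(table["Area_BF"].to_numpy(), fm)
    for col, feat, ch in [("Intensity_THSD1", "Intensity", "THSD1"),
                          ("Area_BF", "Area_BF", "CD63")]:
        weighted, n_tot = 0.0, 0
        for s in ("small", "medium", "large"):
            n = int((labels == s).sum())
            if n:
                weighted += n * prof[make_variable_id(feat, ch, s, "AVG")]
                n_tot += n
        assert prof[make_variable_id(feat, ch, "total", "AVG")] == \
            pytest.approx(weighted / n_tot, rel=1e-12)


def test_sparse_strata_yield_missing_not_error(fm, event_table):
    table = derive_pixel_range(filter_events(event_table, fm), fm).copy()
    table["Area_BF"] = 0.01  # everything small
    single = table.iloc[:1].copy()
    prof = summarize_sample(single, fm)
    assert np.isnan(prof[make_variable_id("Intensity", "CD63", "large", "AVG")])
    assert np.isnan(prof[make_variable_id("Intensity", "CD63", "small", "SD")])
    assert prof[make_variable_id("Intensity", "CD63", "small", "AVG")] == \
        single["Intensity_CD63"].iloc[0]


def test_sd_uses_sample_denominator(fm, event_table):
    table = derive_pixel_range(filter_events(event_table, fm), fm)
    prof = summarize_sample(table, fm)
    vid = make_variable_id("Intensity", "VAMP3", "total", "SD")
    assert prof[vid] == pytest.approx(table["Intensity_VAMP3"].std(ddof=1), rel=1e-12)


# ---------------------------------------------------------------------------
# change scores
# ---------------------------------------------------------------------------

def test_change_scores_zero_for_identical_profiles(fm, event_table):
    prof = reduce_sample(event_table, fm)
    delta = change_scores(prof, prof)
    assert (delta.dropna() == 0).all()


def test_change_scores_match_subtraction_and_propagate_missing(fm):
    ids = ["A|CD63|small|AVG", "B|CD63|small|AVG", "C|CD63|small|AVG"]
    d0 = pd.Series([1.0, np.nan, 3.0], index=ids)
    d3 = pd.Series([4.0, 5.0, np.nan], index=ids)
    delta = change_scores(d0, d3)
    assert delta[ids[0]] == 3.0
    assert np.isnan(delta[ids[1]]) and np.isnan(delta[ids[2]])


def test_change_scores_reject_mismatched_ids():
    d0 = pd.Series([1.0], index=["A|CD63|small|AVG"])
    d3 = pd.Series([1.0], index=["B|CD63|small|AVG"])
    with pytest.raises(ValueError):
        change_scores(d0, d3)
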