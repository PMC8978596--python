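"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates per-event imaging-flow-cytometry feature tables, a neuroendocrine
biomarker panel and a nanoparticle-tracking (NTA) summary for a two-group
resilience cohort, with implantable group-by-timepoint effects so every
downstream stage is testable without any experimental data:

* CD-RISC scores are drawn from truncated normals matching the study groups
  (high: 94.90 +/- 3.04 on (90, 100]; low: 70.00 +/- 5.89 on [0, 79]).
* Event areas follow a three-component lognormal mixture (one component per
  intended size stratum); fluorescence intensities are lognormal with a
  subject-level random effect on the log-mean plus a smaller visit-level
  effect, the standard shape of cytometry intensity data.
* Effect A multiplies the within-sample spread (log-sd) of the THSD1
  bright-detail intensity among large-stratum events at D3, per group.
* Effect B shifts the minimum side-scatter pixel of medium-stratum events
  at D3, per group.
* Biomarker baselines are lognormals moment-matched to the study's printed
  group means/SDs, with proportional D3 declines per analyte
  (IGF-I -13.5%, alpha-Klotho -8.9%, NPY -17.2%, BDNF and cortisol flat).

Effects default to D3 only: the emulated study found group differences in
stress-response change scores, not at baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import TIMEPOINTS, CohortManifest, SubjectRecord
from .manifest import CUTOFF_LARGE, CUTOFF_SMALL, FeatureManifest, default_manifest

ANALYTES = ("alpha-Klotho", "BDNF", "NPY", "IGF-I", "Cortisol")

#: baseline (D0) biomarker concentrations per group, (mean, SD), and the
#: proportional decline from baseline to peak stress
BIOMARKER_PARAMS: dict[str, dict] = {
    "alpha-Klotho": {"low": (1013.69, 332.89), "high": (956.37, 341.04),
                     "decline": -0.089, "unit": "pg/ml"},
    "BDNF": {"low": (5595.60, 6548.55), "high": (6273.00, 4592.35),
             "decline": 0.0, "unit": "pg/ml"},
    "NPY": {"low": (2210.53, 993.55), "high": (3594.32, 2496.45),
            "decline": -0.172, "unit": "pg/ml"},
    "IGF-I": {"low": (273.57, 64.37), "high": (293.05, 91.62),
              "decline": -0.135, "unit": "ng/ml"},
    "Cortisol": {"low": (26.15, 11.63), "high": (28.21, 9.57),
                 "decline": 0.0, "unit": "ug/dl"},
}

#: NTA concentration (x 10^10 nanoparticles/ml) and mean size (nm) per group
NTA_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "concentration_e10": {"low": (2.78, 1.81), "high": (2.60, 1.67)},
    "mean_size_nm": {"low": (112.63, 24.86), "high": (97.68, 18.96)},
}


@dataclass
class CohortSpec:
    """Cohort design: group sizes, CD-RISC distributions, events per sample."""

    n_high: int = 10
    n_low: int = 10
    # (mean, sd, lower bound, upper bound); high truncated to (90, 100],
    # low to [0, 79], matching the tertile selection rule
    cdrisc_high: tuple[float, float, float, float] = (94.90, 3.04, 90.0, 100.0)
    cdrisc_low: tuple[float, float, float, float] = (70.00, 5.89, 0.0, 79.0)
    events_min: int = 2000
    events_max: int = 10000

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("need at least one subject per group")
        if not 1 <= self.events_min <= self.events_max:
            raise ValueError("require 1 <= events_min <= events_max")


@dataclass
class EventModel:
    """Distributions of the per-event features.

    Areas (um^2) are a lognormal mixture whose components roughly occupy the
    small / medium / large strata; intensities are lognormal with sd
    ``subject_sd`` subject effects and ``visit_sd`` visit effects on the
    log-mean; raw pixel maxima are built as minimum + positive range so the
    RawMax >= RawMin invariant holds by construction; a fraction ``p_sat``
    of events is injected with a positive saturation count in one
    fluorescence channel.
    """

    area_medians: tuple[float, float, float] = (0.015, 0.15, 1.5)
    area_sigmas: tuple[float, float, float] = (0.5, 0.7, 0.5)
    area_weights: tuple[float, float, float] = (0.50, 0.35, 0.15)
    channel_log_intensity: dict[str, float] = field(
        default_factory=lambda: {"CD63": 3.0, "VAMP3": 2.6, "THSD1": 2.2})
    channel_log_bdi: dict[str, float] = field(
        default_factory=lambda: {"CD63": 3.2, "VAMP3": 3.0, "THSD1": 3.9})
    intensity_sigma: float = 0.8
    bdi_sigma: float = 0.8
    subject_sd: float = 0.4
    visit_sd: float = 0.1
    ssc_log_intensity: float = 8.0
    ssc_sigma: float = 0.9
    ssc_min_shape: float = 2.0
    ssc_min_scale: float = 0.5
    ssc_min_subject_sd: float = 0.15
    p_sat: float = 0.02
    cutoff_small: float = CUTOFF_SMALL
    cutoff_large: float = CUTOFF_LARGE

    def __post_init__(self) -> None:
        w = np.asarray(self.area_weights, dtype=float)
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("area mixture weights must be nonnegative and sum to 1")
        if not 0 <= self.p_sat <= 1:
            raise ValueError("p_sat must lie in [0, 1]")


@dataclass
class EffectSpec:
    """Group-by-timepoint effects implanted at D3.

    ``bdi_sd_factor_*`` multiplies the log-sd of the THSD1 bright-detail
    intensity of large-stratum events (effect A); ``ssc_min_shift_*`` adds to
    the minimum side-scatter pixel of medium-stratum events (effect B);
    ``biomarker_declines`` are proportional D0->D3 mean changes per analyte.
    """

    bdi_sd_factor_high: float = 2.0
    bdi_sd_factor_low: float = 1.0
    ssc_min_shift_high: float = -0.4
    ssc_min_shift_low: float = 0.0
    biomarker_declines: dict[str, float] = field(
        default_factory=lambda: {a: BIOMARKER_PARAMS[a]["decline"] for a in ANALYTES})

    def __post_init__(self) -> None:
        if self.bdi_sd_factor_high <= 0 or self.bdi_sd_factor_low <= 0:
            raise ValueError("spread factors must be positive")
        for a, d in self.biomarker_declines.items():
            if not -1 < d < 1:
                raise ValueError(f"decline for {a} must lie in (-1, 1)")

    @classmethod
    def neutral(cls) -> "EffectSpec":
        """No implanted effects: D0 and D3 share one distribution."""
        return cls(bdi_sd_factor_high=1.0, bdi_sd_factor_low=1.0,
                   ssc_min_shift_high=0.0, ssc_min_shift_low=0.0,
                   biomarker_declines={a: 0.0 for a in ANALYTES})


@dataclass
class SubjectVisitParams:
    """Latent parameters for one subject at one timepoint."""

    log_intensity_offset: dict[str, float]
    log_bdi_offset: dict[str, float]
    ssc_offset: float
    ssc_min_scale_mult: float
    bdi_sigma_factor: dict[str, float]   # per channel; applied to large events
    ssc_min_shift: float                 # applied to medium events
    p_sat: float


def _truncnorm_rvs(mean: float, sd: float, lo: float, hi: float, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if not a < b or sps.norm.cdf(b) - sps.norm.cdf(a) < 1e-12:
        raise ValueError(f"infeasible truncation: N({mean}, {sd}) on [{lo}, {hi}]")
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


def generate_event_sample(params: SubjectVisitParams, n_events: int,
                          rng: np.random.Generator,
                          model: EventModel | None = None) -> pd.DataFrame:
    """One per-event feature table (rows = detected objects).

    Exactly ``n_events`` rows before any filtering; roughly ``p_sat`` of
    events carry a saturation count >= 1 in one fluorescence channel.  All
    event invariants (positive area, aspect ratio in (0, 1], RawMax >=
    RawMin >= 0) hold by construction.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    model = model or EventModel()
    n = n_events
    channels = tuple(model.channel_log_intensity)

    comp = rng.choice(3, size=n, p=model.area_weights)
    mu_area = np.log(np.asarray(model.area_medians))[comp]
    sd_area = np.asarray(model.area_sigmas)[comp]
    area = np.exp(rng.normal(mu_area, sd_area))
    large = area > model.cutoff_large
    medium = (area >= model.cutoff_small) & ~large

    diameter = 2.0 * np.sqrt(area / math.pi)
    cols: dict[str, np.ndarray] = {
        "ObjectNumber": np.arange(n, dtype=float),
        "Area_BF": area,
        "Diameter_BF": diameter * (1 + rng.normal(0, 0.02, n)).clip(0.5),
        "MajorAxis_BF": diameter * (1 + np.abs(rng.normal(0, 0.10, n))),
        "MinorAxis_BF": diameter * (1 - np.abs(rng.normal(0, 0.10, n))).clip(0.2),
        "Perimeter_BF": math.pi * diameter * (1 + rng.normal(0, 0.05, n)).clip(0.5),
        "AspectRatio_SSC": np.clip(1.0 - rng.beta(2.0, 8.0, n), 1e-6, 1.0),
        "RawMinPixel_BF": np.abs(rng.normal(10.0, 3.0, n)),
        "Intensity_SSC": np.exp(rng.normal(model.ssc_log_intensity + params.ssc_offset,
                                           model.ssc_sigma, n)),
    }
    cols["Length_BF"] = cols["MajorAxis_BF"] * (1 + np.abs(rng.normal(0, 0.05, n)))
    cols["Width_BF"] = cols["MinorAxis_BF"] * (1 - np.abs(rng.normal(0, 0.05, n))).clip(0.2)
    cols["Height_BF"] = cols["Width_BF"] * (1 + rng.normal(0, 0.05, n)).clip(0.5)
    cols["RawMaxPixel_BF"] = cols["RawMinPixel_BF"] + np.exp(rng.normal(3.0, 0.5, n))

    ssc_min = rng.gamma(model.ssc_min_shape,
                        model.ssc_min_scale * params.ssc_min_scale_mult, n)
    ssc_min = ssc_min + np.where(medium, params.ssc_min_shift, 0.0)
    cols["RawMinPixel_SSC"] = ssc_min.clip(0.0)
    cols["RawMaxPixel_SSC"] = cols["RawMinPixel_SSC"] + np.exp(rng.normal(1.0, 0.5, n))

    for ch in channels:
        mu = model.channel_log_intensity[ch] + params.log_intensity_offset[ch]
        inten = np.exp(rng.normal(mu, model.intensity_sigma, n))
        cols[f"Intensity_{ch}"] = inten
        cols[f"RawIntensity_{ch}"] = inten * (1 + rng.normal(0, 0.05, n)).clip(0.1)
        mean_px = inten / 50.0 * (1 + rng.normal(0, 0.05, n)).clip(0.1)
        cols[f"MeanPixel_{ch}"] = mean_px
        cols[f"MedianPixel_{ch}"] = mean_px * (1 - np.abs(rng.normal(0, 0.05, n)))
        cols[f"MinPixel_{ch}"] = mean_px * rng.uniform(0.0, 0.5, n)
        cols[f"MaxPixel_{ch}"] = mean_px * (1.5 + rng.gamma(2.0, 0.5, n))
        raw_min = np.abs(rng.normal(5.0, 2.0, n))
        cols[f"RawMinPixel_{ch}"] = raw_min
        cols[f"RawMaxPixel_{ch}"] = raw_min + inten * (0.5 + rng.uniform(0, 1, n))
        cols[f"BkgdMean_{ch}"] = rng.normal(20.0, 2.0, n)
        cols[f"BkgdStdDev_{ch}"] = np.abs(rng.normal(3.0, 0.5, n))

        # bright-detail intensity: spread widened for large events when the
        # implanted effect applies to this channel
        sigma = np.full(n, model.bdi_sigma)
        sigma[large] *= params.bdi_sigma_factor.get(ch, 1.0)
        mu_bdi = model.channel_log_bdi[ch] + params.log_bdi_offset[ch]
        cols[f"BrightDetailIntensity_{ch}"] = np.exp(mu_bdi + sigma * rng.normal(0, 1, n))

        cols[f"Contrast_{ch}"] = np.abs(rng.normal(0.5, 0.15, n))
        cols[f"Modulation_{ch}"] = rng.beta(2.0, 2.0, n)
        cols[f"StdDev_{ch}"] = inten / 30.0 * (1 + np.abs(rng.normal(0, 0.1, n)))
        grms = np.abs(rng.normal(10.0, 3.0, n))
        cols[f"GradientRMS_{ch}"] = grms
        cols[f"GradientMax_{ch}"] = grms * (1.5 + rng.gamma(2.0, 0.5, n))
        cols[f"SaturationCount_{ch}"] = np.zeros(n)

    if params.p_sat > 0:
        sat = rng.random(n) < params.p_sat
        sat_ch = rng.integers(0, len(channels), n)
        sat_count = 1 + rng.poisson(1.0, n)
        for k, ch in enumerate(channels):
            mask = sat & (sat_ch == k)
            cols[f"SaturationCount_{ch}"][mask] = sat_count[mask]

    # single-block frame: much cheaper than per-column consolidation
    return pd.DataFrame(np.column_stack(list(cols.values())),
                        columns=list(cols))


@dataclass
class SyntheticCohort:
    """A generated cohort: manifest, per-sample event tables, and panels."""

    manifest: CohortManifest
    tables: dict[tuple[str, str], pd.DataFrame]   # (subject_id, timepoint) -> events
    biomarkers: pd.DataFrame                      # subject, group, analyte, timepoint, value
    nta: pd.DataFrame                             # subject, group, timepoint, concentration, size
    seed: int


def _subject_visit_params(model: EventModel, effects: EffectSpec, group: str,
                          timepoint: str, visit_rng: np.random.Generator,
                          subject_latents: dict) -> SubjectVisitParams:
    channels = tuple(model.channel_log_intensity)
    visit_int = {ch: float(visit_rng.normal(0, model.visit_sd)) for ch in channels}
    visit_bdi = {ch: float(visit_rng.normal(0, model.visit_sd)) for ch in channels}
    visit_ssc = float(visit_rng.normal(0, model.visit_sd))
    at_d3 = timepoint == "D3"
    bdi_factor = {ch: 1.0 for ch in channels}
    ssc_shift = 0.0
    if at_d3:
        bdi_factor["THSD1"] = (effects.bdi_sd_factor_high if group == "high"
                               else effects.bdi_sd_factor_low)
        ssc_shift = (effects.ssc_min_shift_high if group == "high"
                     else effects.ssc_min_shift_low)
    return SubjectVisitParams(
        log_intensity_offset={ch: subject_latents["intensity"][ch] + visit_int[ch]
                              for ch in channels},
        log_bdi_offset={ch: subject_latents["bdi"][ch] + visit_bdi[ch]
                        for ch in channels},
        ssc_offset=subject_latents["ssc"] + visit_ssc,
        ssc_min_scale_mult=subject_latents["ssc_min_scale"],
        bdi_sigma_factor=bdi_factor,
        ssc_min_shift=ssc_shift,
        p_sat=model.p_sat,
    )


def generate_biomarkers(subjects: list[tuple[str, str]], rng: np.random.Generator,
                        declines: dict[str, float] | None = None,
                        params: dict | None = None, rho: float = 0.8) -> pd.DataFrame:
    """Biomarker panel: per subject, analyte and timepoint concentrations.

    Baselines are lognormals moment-matched to the per-group (mean, SD);
    peak-stress values scale the mean by (1 + decline) with the SD scaled by
    the same factor, correlated within subject (``rho`` on the latent log
    scale) so paired tests see realistic within-subject coupling.
    """
    declines = declines if declines is not None else \
        {a: BIOMARKER_PARAMS[a]["decline"] for a in ANALYTES}
    params = params or BIOMARKER_PARAMS
    for a, d in declines.items():
        if d <= -1:
            raise ValueError(f"decline for {a} must exceed -1")
    rows = []
    for subject_id, group in subjects:
        for analyte in params:
            mean0, sd0 = params[analyte][group]
            mu0, s0 = _lognormal_params(mean0, sd0)
            factor = 1.0 + declines.get(analyte, 0.0)
            mu3, s3 = _lognormal_params(mean0 * factor, sd0 * factor)
            u = rng.normal()
            e0, e3 = rng.normal(size=2)
            z0 = rho * u + math.sqrt(1 - rho ** 2) * e0
            z3 = rho * u + math.sqrt(1 - rho ** 2) * e3
            rows.append((subject_id, group, analyte, "D0", math.exp(mu0 + s0 * z0)))
            rows.append((subject_id, group, analyte, "D3", math.exp(mu3 + s3 * z3)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "analyte",
                                       "timepoint", "value"])


def generate_nta(subjects: list[tuple[str, str]], rng: np.random.Generator,
                 rho: float = 0.8) -> pd.DataFrame:
    """NTA panel: particle concentration and mean size per subject/timepoint.

    Marginals match the per-group baseline summaries at both timepoints
    (the emulated study saw no systematic stress change in either)."""
    rows = []
    for subject_id, group in subjects:
        vals = {}
        for metric, by_group in NTA_PARAMS.items():
            mu, s = _lognormal_params(*by_group[group])
            u = rng.normal()
            e0, e3 = rng.normal(size=2)
            vals[metric] = (
                math.exp(mu + s * (rho * u + math.sqrt(1 - rho ** 2) * e0)),
                math.exp(mu + s * (rho * u + math.sqrt(1 - rho ** 2) * e3)))
        for i, tp in enumerate(TIMEPOINTS):
            rows.append((subject_id, group, tp,
                         vals["concentration_e10"][i], vals["mean_size_nm"][i]))
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint",
                                       "concentration_e10", "mean_size_nm"])


def generate_cohort(spec: CohortSpec | None = None,
                    model: EventModel | None = None,
                    effects: EffectSpec | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a full cohort, reproducible from ``seed``.

    Every subject receives D0 and D3 event tables; effects are implanted at
    D3 only, per group.  Subject-level latents are shared across timepoints
    so change scores carry realistic within-subject coupling.
    """
    spec = spec or CohortSpec()
    model = model or EventModel()
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    channels = tuple(model.channel_log_intensity)

    scores_high = _truncnorm_rvs(*spec.cdrisc_high, spec.n_high, rng)
    scores_low = _truncnorm_rvs(*spec.cdrisc_low, spec.n_low, rng)
    subjects: list[SubjectRecord] = []
    for i, sc in enumerate(scores_high):
        subjects.append(SubjectRecord(f"H{i + 1:02d}", "high", float(sc), {}))
    for i, sc in enumerate(scores_low):
        subjects.append(SubjectRecord(f"L{i + 1:02d}", "low", float(sc), {}))

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for rec in subjects:
        latents = {
            "intensity": {ch: float(rng.normal(0, model.subject_sd)) for ch in channels},
            "bdi": {ch: float(rng.normal(0, model.subject_sd)) for ch in channels},
            "ssc": float(rng.normal(0, model.subject_sd)),
            "ssc_min_scale": float(np.exp(rng.normal(0, model.ssc_min_subject_sd))),
        }
        for tp in TIMEPOINTS:
            params = _subject_visit_params(model, effects, rec.group, tp,
                                           rng, latents)
            n_events = int(rng.integers(spec.events_min, spec.events_max + 1))
            tables[(rec.subject_id, tp)] = generate_event_sample(
                params, n_events, rng, model)
            rec.event_tables[tp] = f"{rec.subject_id}_{tp}.csv"

    pairs = [(s.subject_id, s.group) for s in subjects]
    biomarkers = generate_biomarkers(pairs, rng, declines=effects.biomarker_declines)
    nta = generate_nta(pairs, rng)
    return SyntheticCohort(manifest=CohortManifest(subjects=subjects),
                           tables=tables, biomarkers=biomarkers, nta=nta,
                           seed=seed)


def small_cohort_spec(n_high: int = 5, n_low: int = 5,
                      events: tuple[int, int] = (300, 600)) -> CohortSpec:
    """A desk-scale cohort for simulation sweeps (smaller n, fewer events)."""
    return CohortSpec(n_high=n_high, n_low=n_low,
                      events_min=events[0], events_max=events[1])


def neutral_effects() -> EffectSpec:
    return EffectSpec.neutral()


def default_event_model() -> EventModel:
    return EventModel()


#: variable id of the implanted effect-A target in the default manifest
EFFECT_A_TARGET = "BrightDetailIntensity|THSD1|large|SD"
#: variable id of the implanted effect-B target
EFFECT_B_TARGET = "RawMinPixel_SSC|CD63|medium|AVG"


def write_cohort(cohort: SyntheticCohort, outdir,
                 feature_manifest: FeatureManifest | None = None) -> None:
    """Write a cohort to disk in the formats the readers consume.

    Layout: one ``<subject>_<tp>.csv`` per sample, ``cohort.tsv`` manifest,
    ``biomarkers.tsv``, ``nta.tsv``, and the feature manifest as YAML.
    """
    from . import io as evio  # local import to avoid a cycle
    import os

    os.makedirs(outdir, exist_ok=True)
    for (sid, tp), table in cohort.tables.items():
        table.to_csv(os.path.join(outdir, f"{sid}_{tp}.csv"), index=False)
    evio.write_cohort_manifest(cohort.manifest, os.path.join(outdir, "cohort.tsv"))
    cohort.biomarkers.to_csv(os.path.join(outdir, "biomarkers.tsv"),
                             sep="\t", index=False)
    cohort.nta.to_csv(os.path.join(outdir, "nta.tsv"), sep="\t", index=False)
    (feature_manifest or default_manifest()).to_yaml(
        os.path.join(outdir, "features.yaml"))
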