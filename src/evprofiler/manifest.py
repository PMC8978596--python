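"""Feature manifest: the catalogue of per-event image features kept for profiling.

Imaging flow cytometers export one row per detected object with tens of
quantitative image features per spectral channel, grouped by the vendor into
four categories: size, shape, texture, and signal strength.  The manifest
records which features survive data reduction, which channel(s) each feature
is measured in, and the brightfield-area cutoffs used to stratify events into
small / medium / large vesicle subpopulations.

Under the default manifest the per-sample profile has

    (8 size + 1 shape + 6 texture + 16 signal-strength) active features
      x 3 antibody channels (CD63, VAMP3, THSD1)
      x 4 strata (small, medium, large, total)
      x 3 statistics (AVG, MED, SD)
    = 1116 variables,

i.e. 372 variables per statistic split 96 / 12 / 72 / 192 across the four
categories.  The two area cutoffs are the circular areas of 200 nm and
1000 nm diameter particles (pi * 0.1^2 and pi * 0.5^2 um^2), the diameters
conventionally separating exosomes, microvesicles and apoptotic bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

CHANNELS: tuple[str, ...] = ("CD63", "VAMP3", "THSD1")
STRATA: tuple[str, ...] = ("small", "medium", "large", "total")
STATISTICS: tuple[str, ...] = ("AVG", "MED", "SD")
CATEGORIES: tuple[str, ...] = ("size", "shape", "texture", "signal_strength")

#: default stratum cutoffs in um^2 (areas of 200 nm and 1000 nm circles)
CUTOFF_SMALL = 0.031416
CUTOFF_LARGE = 0.785398

SEP = "|"


def make_variable_id(feature: str, channel: str, stratum: str, statistic: str) -> str:
    """Canonical variable id ``feature|channel|stratum|statistic``."""
    return SEP.join((feature, channel, stratum, statistic))


def parse_variable_id(variable_id: str) -> tuple[str, str, str, str]:
    parts = tuple(variable_id.split(SEP))
    if len(parts) != 4:
        raise ValueError(f"malformed variable id: {variable_id!r}")
    return parts  # type: ignore[return-value]


@dataclass(frozen=True)
class Feature:
    """One exported image feature.

    ``per_channel`` features are measured once per fluorescence channel and
    resolve to columns ``<name>_<channel>``; channel-agnostic features (the
    brightfield and side-scatter measurements, whose names carry a ``_BF`` or
    ``_SSC`` suffix) resolve to a single column and are replicated across the
    antibody dimension of the profile.  ``derived`` features are computed
    during reduction rather than read from the export.  ``excluded`` carries
    the removal reason (``"redundant"`` or ``"irrelevant"``) for features that
    are dropped during reduction.
    """

    name: str
    category: str
    per_channel: bool = False
    derived: bool = False
    excluded: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name!r}")
        if self.excluded not in (None, "redundant", "irrelevant"):
            raise ValueError(f"bad exclusion reason {self.excluded!r} for {self.name!r}")

    def columns(self, channels: tuple[str, ...] = CHANNELS) -> list[str]:
        if self.per_channel:
            return [f"{self.name}_{ch}" for ch in channels]
        return [self.name]

    def column_for(self, channel: str) -> str:
        return f"{self.name}_{channel}" if self.per_channel else self.name


def _default_features() -> list[Feature]:
    size = [Feature(n, "size") for n in (
        "Area_BF", "Diameter_BF", "Length_BF", "Width_BF",
        "Height_BF", "Perimeter_BF", "MajorAxis_BF", "MinorAxis_BF",
    )]
    shape = [Feature("AspectRatio_SSC", "shape")]
    texture = [Feature(n, "texture", per_channel=True) for n in (
        "BrightDetailIntensity", "Contrast", "GradientMax",
        "GradientRMS", "Modulation", "StdDev",
    )]
    signal = [Feature(n, "signal_strength", per_channel=True) for n in (
        "Intensity", "RawIntensity", "MeanPixel", "MedianPixel",
        "MaxPixel", "MinPixel", "RawMaxPixel", "RawMinPixel",
        "BkgdMean", "BkgdStdDev",
    )]
    signal.append(Feature("PixelRange", "signal_strength", per_channel=True, derived=True))
    signal += [Feature(n, "signal_strength") for n in (
        "RawMaxPixel_BF", "RawMinPixel_BF",
        "Intensity_SSC", "RawMaxPixel_SSC", "RawMinPixel_SSC",
    )]
    excluded = [
        Feature("RawMeanPixel", "signal_strength", per_channel=True, excluded="redundant"),
        Feature("RawMedianPixel", "signal_strength", per_channel=True, excluded="redundant"),
        Feature("Diameter_SSC", "size", excluded="redundant"),
        Feature("SaturationCount", "signal_strength", per_channel=True, excluded="irrelevant"),
        Feature("SaturationPercent", "signal_strength", per_channel=True, excluded="irrelevant"),
        Feature("ObjectNumber", "size", excluded="irrelevant"),
        Feature("Time", "size", excluded="irrelevant"),
        Feature("FlowSpeed", "size", excluded="irrelevant"),
    ]
    return size + shape + texture + signal + excluded


@dataclass
class FeatureManifest:
    """Active feature list, channel order, stratum cutoffs and column aliases."""

    features: list[Feature] = field(default_factory=_default_features)
    channels: tuple[str, ...] = CHANNELS
    statistics: tuple[str, ...] = STATISTICS
    cutoff_small: float = CUTOFF_SMALL
    cutoff_large: float = CUTOFF_LARGE
    #: map from external CSV header spellings to canonical column names
    aliases: dict[str, str] = field(default_factory=dict)
    #: optional per-channel intensity gate; events with Intensity_<ch> <= gate
    #: are excluded from that channel's summaries (default: no gate)
    positivity_thresholds: dict[str, float] | None = None

    # -- validation ---------------------------------------------------------
    def __post_init__(self) -> None:
        if not self.cutoff_small < self.cutoff_large:
            raise ValueError("cutoff_small must be < cutoff_large")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in manifest")

    # -- feature access -----------------------------------------------------
    @property
    def active_features(self) -> list[Feature]:
        return [f for f in self.features if f.excluded is None]

    @property
    def excluded_features(self) -> list[Feature]:
        return [f for f in self.features if f.excluded is not None]

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def category_of(self, feature_name: str) -> str:
        return self.feature(feature_name).category

    def counts_per_category(self) -> dict[str, int]:
        """Variables per category per statistic (feature x channel x stratum)."""
        out = {c: 0 for c in CATEGORIES}
        for f in self.active_features:
            out[f.category] += len(self.channels) * len(STRATA)
        return out

    def n_variables(self) -> int:
        return (len(self.active_features) * len(self.channels)
                * len(STRATA) * len(self.statistics))

    def variable_ids(self) -> list[str]:
        """All variable ids in canonical (feature, channel, stratum, statistic) order."""
        return [
            make_variable_id(f.name, ch, stratum, stat)
            for f in self.active_features
            for ch in self.channels
            for stratum in STRATA
            for stat in self.statistics
        ]

    # -- columns ------------------------------------------------------------
    def required_columns(self) -> list[str]:
        """Columns an event table must provide (non-derived active + saturation)."""
        cols: list[str] = []
        for f in self.active_features:
            if not f.derived:
                cols.extend(f.columns(self.channels))
        cols.extend(f"SaturationCount_{ch}" for ch in self.channels)
        # deduplicate, preserve order
        seen: set[str] = set()
        return [c for c in cols if not (c in seen or seen.add(c))]

    def resolve_column(self, raw: str) -> str:
        """Map an external header to its canonical name (alias map, then strip)."""
        raw = raw.strip()
        return self.aliases.get(raw, raw)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "statistics": list(self.statistics),
            "cutoff_small": self.cutoff_small,
            "cutoff_large": self.cutoff_large,
            "aliases": dict(self.aliases),
            "positivity_thresholds": self.positivity_thresholds,
            "features": [
                {"name": f.name, "category": f.category, "per_channel": f.per_channel,
                 "derived": f.derived, "excluded": f.excluded}
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureManifest":
        feats = [Feature(**fd) for fd in d.get("features", [])] or _default_features()
        return cls(
            features=feats,
            channels=tuple(d.get("channels", CHANNELS)),
            statistics=tuple(d.get("statistics", STATISTICS)),
            cutoff_small=float(d.get("cutoff_small", CUTOFF_SMALL)),
            cutoff_large=float(d.get("cutoff_large", CUTOFF_LARGE)),
            aliases=dict(d.get("aliases", {})),
            positivity_thresholds=d.get("positivity_thresholds"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_cutoffs(self, small: float, large: float) -> "FeatureManifest":
        return replace(self, cutoff_small=small, cutoff_large=large)


def default_manifest() -> FeatureManifest:
    return FeatureManifest()
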