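"""Channel layout, frequency bands, and the feature-name grid.

The recording montage is four single-wire electrodes in the nucleus
accumbens: shell left (SL), shell right (SR), core left (CL), core
right (CR).  Features are band power per channel and magnitude-squared
coherence per channel pair, summarized in six canonical bands.  Short
feature names follow the field convention: ``SLa`` is shell-left alpha
power, ``SLCRhg`` is shell-left/core-right high-gamma coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

__all__ = [
    "Band",
    "ChannelLayout",
    "FeatureSpec",
    "DEFAULT_BANDS",
    "DEFAULT_LAYOUT",
    "DEFAULT_EXCLUSIONS",
    "BAND_CODES",
]

#: short band codes used in feature names
BAND_CODES = {
    "delta": "d",
    "theta": "t",
    "alpha": "a",
    "beta": "b",
    "low_gamma": "lg",
    "high_gamma": "hg",
}


@dataclass(frozen=True)
class Band:
    """A named frequency band [lo_hz, hi_hz]."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo_hz must be < hi_hz")

    @property
    def code(self) -> str:
        return BAND_CODES.get(self.name, self.name)

    @property
    def width_hz(self) -> float:
        return self.hi_hz - self.lo_hz


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 5.0, 10.0),
    Band("alpha", 11.0, 14.0),
    Band("beta", 15.0, 20.0),
    Band("low_gamma", 45.0, 65.0),
    Band("high_gamma", 70.0, 90.0),
)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channels and the derived unordered channel pairs."""

    channels: tuple[str, ...] = ("SL", "SR", "CL", "CR")

    def __post_init__(self) -> None:
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("duplicate channel names")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(combinations(self.channels, 2))

    @property
    def n_channels(self) -> int:
        return len(self.channels)


DEFAULT_LAYOUT = ChannelLayout()

# Two coherence features dropped from modeling by default: theta
# coherences on the shell-left wire, the chewing-artifact screen's
# prime suspects (see whole_session.chewing_artifact_screen).
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset({"SLCLt", "SLCRt"})


@dataclass(frozen=True)
class FeatureSpec:
    """Defines the per-bin feature vector: which channels, bands, and bin size.

    With the default 4-channel layout and 6 bands the full grid is
    4*6 = 24 power features plus C(4,2)*6 = 36 coherence features (60
    total); the default exclusion list of two artifact-flagged
    coherence features leaves the 58 used for modeling.
    """

    layout: ChannelLayout = DEFAULT_LAYOUT
    bands: tuple[Band, ...] = DEFAULT_BANDS
    exclusions: frozenset[str] = frozenset()
    bin_length_s: float = 5.0

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.lo_hz)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo_hz < a.hi_hz:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
        if self.bin_length_s <= 0:
            raise ValueError("bin_length_s must be positive")

    # -- feature naming -------------------------------------------------
    def power_names(self) -> list[str]:
        return [f"{ch}{b.code}" for ch in self.layout.channels for b in self.bands]

    def coherence_names(self) -> list[str]:
        return [f"{c1}{c2}{b.code}" for c1, c2 in self.layout.pairs for b in self.bands]

    def all_names(self) -> list[str]:
        """Full grid, channels-then-pairs outer order, bands inner."""
        return self.power_names() + self.coherence_names()

    def feature_names(self) -> list[str]:
        """Modeling features: full grid minus exclusions, order preserved."""
        return [n for n in self.all_names() if n not in self.exclusions]

    @property
    def n_features(self) -> int:
        return len(self.feature_names())

    def band_of(self, feature: str) -> Band:
        """Band a feature name belongs to (longest code match wins)."""
        best = None
        for b in self.bands:
            if feature.endswith(b.code) and (best is None or len(b.code) > len(best.code)):
                best = b
        if best is None:
            raise KeyError(f"no band code matches feature {feature!r}")
        return best

    def is_power(self, feature: str) -> bool:
        return feature in set(self.power_names())

    def channels_of(self, feature: str) -> tuple[str, ...]:
        """Channel(s) a feature involves, e.g. SLa -> (SL,), SLCRhg -> (SL, CR)."""
        code = self.band_of(feature).code
        head = feature[: -len(code)]
        for ch in self.layout.channels:
            if head == ch:
                return (ch,)
        for c1, c2 in self.layout.pairs:
            if head == c1 + c2:
                return (c1, c2)
        raise KeyError(f"cannot parse channels from feature {feature!r}")


#: spec with the study's default modeling exclusions (58 features)
STUDY_SPEC = FeatureSpec(exclusions=DEFAULT_EXCLUSIONS)
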