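"""Frontal electrode montage, frequency bands, and the feature-name grammar.

Feature names follow ``<SET>_<KIND>_<LOC>_<BAND>`` where SET is one of
RST/PRE/PST/DIF, KIND one of power/wPLI/MI, LOC an electrode, a hyphenated
electrode pair, or a region tag, and BAND a canonical band name or a
phase-amplitude coupling tag (``thetagamma``, ``alphagamma``).
"""
from __future__ import annotations

from dataclasses import dataclass

#: The 17 frontal 10-10 electrodes the analysis is confined to.  This is the
#: smallest standard frontal set of size 17 containing every electrode that
#: appears in the discriminative features (AFz, AF3, F4, F5, F6, F8).
FRONTAL_17: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
)

#: Left-DLPFC electrodes used for phase-amplitude coupling.
DLPFC_CHANNELS: tuple[str, ...] = ("F3", "F5", "AF3")

FEATURE_SETS: tuple[str, ...] = ("RST", "PRE", "PST", "DIF")


@dataclass(frozen=True)
class BandDef:
    """A named frequency band in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: Canonical analysis bands.
BANDS: tuple[BandDef, ...] = (
    BandDef("theta", 4.0, 7.0),
    BandDef("alpha", 8.0, 13.0),
    BandDef("beta", 14.0, 30.0),
    BandDef("gamma", 30.0, 45.0),
)

BAND_MAP: dict[str, BandDef] = {b.name: b for b in BANDS}

#: Phase-amplitude couplings: tag -> (phase band, amplitude band).
COUPLINGS: dict[str, tuple[str, str]] = {
    "thetagamma": ("theta", "gamma"),
    "alphagamma": ("alpha", "gamma"),
}


def pair_name(ch_a: str, ch_b: str) -> str:
    """Hyphenated channel-pair location tag (order as given)."""
    return f"{ch_a}-{ch_b}"


_CH_ORDER = {ch: i for i, ch in enumerate(FRONTAL_17)}


def canonical_pair(ch_a: str, ch_b: str) -> str:
    """Pair tag in montage order (alphabetical for unknown electrodes)."""
    key = _CH_ORDER.get
    a, b = sorted((ch_a, ch_b), key=lambda c: (key(c, len(_CH_ORDER)), c))
    return pair_name(a, b)


def canonicalize_feature_name(name: str) -> str:
    """Rewrite a feature name so channel pairs are in montage order
    (wPLI is symmetric, so ``RST_wPLI_F6-F4_gamma`` and
    ``RST_wPLI_F4-F6_gamma`` denote the same feature)."""
    set_tag, kind, loc, band = parse_feature_name(name)
    if kind == "wPLI" and "-" in loc:
        loc = canonical_pair(*loc.split("-"))
    return feature_name(set_tag, kind, loc, band)


def feature_name(set_tag: str, kind: str, loc: str, band: str) -> str:
    return f"{set_tag}_{kind}_{loc}_{band}"


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    """Split a feature name into (SET, KIND, LOC, BAND).

    Raises ValueError if the name does not follow the grammar.
    """
    parts = name.split("_")
    if len(parts) != 4:
        raise ValueError(f"feature name {name!r} does not parse into 4 fields")
    set_tag, kind, loc, band = parts
    if set_tag not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_tag!r} in {name!r}")
    if kind not in ("power", "wPLI", "MI"):
        raise ValueError(f"unknown feature kind {kind!r} in {name!r}")
    if band not in BAND_MAP and band not in COUPLINGS:
        raise ValueError(f"unknown band tag {band!r} in {name!r}")
    return set_tag, kind, loc, band
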