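"""Isobaric-tag plex definitions: channel labels and reporter-ion m/z values.

A *plex* is a set of isobaric labels mixed in one experiment; each label
releases a low-mass reporter ion in MS2 whose intensity encodes one sample
channel.  Reporter m/z values below are the singly-protonated monoisotopic
masses commonly tabulated for the iTRAQ and TMT reagent families.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelDefinition:
    """One reporter channel: its label (e.g. ``"127N"``) and reporter m/z in Th."""

    label: str
    reporter_mz: float

    def __post_init__(self) -> None:
        if self.reporter_mz <= 0:
            raise ValueError(f"reporter_mz must be positive, got {self.reporter_mz}")


_TMT_MZ = {
    "126": 126.12773,
    "127N": 127.12476,
    "127C": 127.13108,
    "128N": 128.12812,
    "128C": 128.13444,
    "129N": 129.13147,
    "129C": 129.13779,
    "130N": 130.13483,
    "130C": 130.14115,
    "131": 131.13818,
}

_ITRAQ_MZ = {
    "113": 113.10787,
    "114": 114.11068,
    "115": 115.10715,
    "116": 116.11162,
    "117": 117.11497,
    "118": 118.11144,
    "119": 119.11479,
    "121": 121.12152,
}

# TMT-6 uses the C-form channels plus 126/127N-style naming collapsed to the
# nominal mass; labels follow the vendor convention for each kit size.
PLEXES: dict[str, tuple[ChannelDefinition, ...]] = {
    "iTRAQ-4": tuple(
        ChannelDefinition(l, _ITRAQ_MZ[l]) for l in ("114", "115", "116", "117")
    ),
    "iTRAQ-8": tuple(
        ChannelDefinition(l, _ITRAQ_MZ[l])
        for l in ("113", "114", "115", "116", "117", "118", "119", "121")
    ),
    "TMT-6": (
        ChannelDefinition("126", _TMT_MZ["126"]),
        ChannelDefinition("127", _TMT_MZ["127N"]),
        ChannelDefinition("128", _TMT_MZ["128C"]),
        ChannelDefinition("129", _TMT_MZ["129N"]),
        ChannelDefinition("130", _TMT_MZ["130C"]),
        ChannelDefinition("131", _TMT_MZ["131"]),
    ),
    "TMT-8": (
        ChannelDefinition("126", _TMT_MZ["126"]),
        ChannelDefinition("127N", _TMT_MZ["127N"]),
        ChannelDefinition("127C", _TMT_MZ["127C"]),
        ChannelDefinition("128C", _TMT_MZ["128C"]),
        ChannelDefinition("129N", _TMT_MZ["129N"]),
        ChannelDefinition("129C", _TMT_MZ["129C"]),
        ChannelDefinition("130C", _TMT_MZ["130C"]),
        ChannelDefinition("131", _TMT_MZ["131"]),
    ),
    "TMT-10": tuple(
        ChannelDefinition(l, _TMT_MZ[l])
        for l in (
            "126", "127N", "127C", "128N", "128C",
            "129N", "129C", "130N", "130C", "131",
        )
    ),
}


def plex_channels(plex_name: str) -> tuple[ChannelDefinition, ...]:
    """Return the ordered channel definitions of a preset plex.

    Raises ``KeyError`` with the list of known presets for unknown names.
    """
    try:
        return PLEXES[plex_name]
    except KeyError:
        raise KeyError(
            f"unknown plex {plex_name!r}; presets: {', '.join(sorted(PLEXES))}"
        ) from None


def check_window_overlap(channels: tuple[ChannelDefinition, ...], tol: float) -> None:
    """Ensure extraction windows of ±tol around reporter m/z values do not overlap."""
    mzs = sorted(c.reporter_mz for c in channels)
    for lo, hi in zip(mzs, mzs[1:]):
        if hi - lo < 2 * tol:
            raise ValueError(
                f"reporter tolerance {tol} Th overlaps channels at "
                f"{lo:.5f} and {hi:.5f} Th (spacing {hi - lo:.5f})"
            )
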