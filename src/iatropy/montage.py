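"""Electrode layout, scalp regions and task conditions.

The analysis montage covers 14 midline/para-midline electrodes grouped into
five scalp regions (frontal, fronto-central, central, centro-parietal,
parietal).  Regional feature values are means over the electrodes of a
region.  The four task conditions cross IAT type (affective / instrumental)
with block type (compatible / incompatible).
"""

from __future__ import annotations

REGION_MAP: dict[str, tuple[str, ...]] = {
    "frontal": ("Fz", "F1", "F2"),
    "fronto_central": ("FCz", "FC1", "FC2"),
    "central": ("Cz", "C1", "C2"),
    "centro_parietal": ("CP1", "CP2"),
    "parietal": ("Pz", "P3", "P4"),
}

REGIONS: tuple[str, ...] = tuple(REGION_MAP)

CHANNELS: tuple[str, ...] = tuple(ch for chs in REGION_MAP.values() for ch in chs)

IAT_TYPES: tuple[str, ...] = ("affective", "instrumental")

BLOCKS: tuple[str, ...] = ("compatible", "incompatible")

#: condition label -> (iat_type, block)
CONDITION_PARTS: dict[str, tuple[str, str]] = {
    f"{iat}_{block}": (iat, block) for iat in IAT_TYPES for block in BLOCKS
}

CONDITIONS: tuple[str, ...] = tuple(CONDITION_PARTS)

REGION_ABBR: dict[str, str] = {
    "frontal": "F",
    "fronto_central": "FC",
    "central": "C",
    "centro_parietal": "CP",
    "parietal": "P",
}

IAT_ABBR: dict[str, str] = {"affective": "A", "instrumental": "I"}

BLOCK_ABBR: dict[str, str] = {"compatible": "C", "incompatible": "IC"}


def condition_abbr(condition: str) -> str:
    """Short label for a condition, e.g. ``affective_incompatible -> A_IC``."""
    iat, block = CONDITION_PARTS[condition]
    return f"{IAT_ABBR[iat]}_{BLOCK_ABBR[block]}"


def region_of(channel: str) -> str:
    for region, chs in REGION_MAP.items():
        if channel in chs:
            return region
    raise KeyError(f"channel {channel!r} not in the analysis montage")
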