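"""Marker vocabulary for the lumbar flexion-extension protocol.

Spine markers sit on the spinous processes of C7, T10 and L1..S1; lateral
lumbar markers flank L2 and L4 at the same mediolateral width as the PSIS
markers; the pelvis carries bilateral PSIS, ASIS and iliac-crest (TIP)
markers which define the anatomical frame and the sagittal plane.
"""

from __future__ import annotations

SPINE_LABELS: tuple[str, ...] = ("C7", "T10", "L1", "L2", "L3", "L4", "L5", "S1")
LUMBAR_LABELS: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5")
PELVIS_LABELS: tuple[str, ...] = ("LPSIS", "RPSIS", "LASIS", "RASIS", "LTIP", "RTIP")
LATERAL_LABELS: tuple[str, ...] = ("LL2", "RL2", "LL4", "RL4")

ALL_LABELS: tuple[str, ...] = SPINE_LABELS + PELVIS_LABELS + LATERAL_LABELS

#: Labels that must survive preprocessing for every analyzed capture
#: (all four segment models plus the torso-angle computation).
MODEL_REQUIRED_LABELS: tuple[str, ...] = ("C7", "T10", "L1", "L2", "L3", "L4", "L5", "S1")

#: Plug-in-Gait and common Nexus label dialects mapped onto the canonical names.
LABEL_ALIASES: dict[str, str] = {
    "RPSI": "RPSIS",
    "LPSI": "LPSIS",
    "RASI": "RASIS",
    "LASI": "LASIS",
    "RILC": "RTIP",
    "LILC": "LTIP",
    "SACR": "S1",
    "T10S": "T10",
    "C7S": "C7",
}

#: Which lateral pair reconstructs which lumbar marker.  L3 is bracketed by
#: both pairs; it is assigned to the L2 pair for determinism.
LATERAL_DONORS: dict[str, tuple[str, str]] = {
    "L1": ("LL2", "RL2"),
    "L2": ("LL2", "RL2"),
    "L3": ("LL2", "RL2"),
    "L4": ("LL4", "RL4"),
    "L5": ("LL4", "RL4"),
}

EXERCISES: tuple[str, ...] = ("STA", "FE", "F", "COB", "SHO", "CUP")
STATIC_EXERCISES: tuple[str, ...] = ("STA", "COB", "SHO", "CUP")
DYNAMIC_EXERCISES: tuple[str, ...] = ("FE", "F")


def normalize_label(label: str, extra_map: dict[str, str] | None = None) -> str:
    """Map a raw file label onto the canonical vocabulary.

    Subject prefixes in the Nexus style (``"P01:L3"``) are stripped before
    alias lookup.  Unknown labels are returned stripped but otherwise
    untouched; callers decide whether that is an error.
    """
    name = label.strip()
    if ":" in name:
        name = name.split(":", 1)[1].strip()
    name = name.upper()
    if extra_map and name in extra_map:
        return extra_map[name]
    return LABEL_ALIASES.get(name, name)
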