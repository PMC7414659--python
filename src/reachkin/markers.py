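"""Canonical upper-body marker set.

Twenty reflective markers: four on the trunk midline/torso (7th cervical
vertebra spinous process, 10th thoracic vertebra spinous process,
suprasternal notch, xiphoid process) and eight per side (acromion, upper
arm, lateral humeral epicondyle, forearm, radial styloid, ulnar styloid,
first metacarpal head, second metacarpal head).

Coordinate convention used throughout: right-handed, +Z vertical (up),
+Y anterior (toward the target panel), +X toward the subject's right.
All positions in cm, time in seconds.
"""

from __future__ import annotations

TRUNK_MARKERS = ("C7", "T10", "CLAV", "STRN")

#: per-side marker suffixes; prefixed with "R" or "L"
SIDE_MARKERS = ("SHO", "UPA", "ELB", "FRA", "WRA", "WRB", "FIN1", "FIN2")

MARKER_SET = TRUNK_MARKERS + tuple(
    side + name for side in ("R", "L") for name in SIDE_MARKERS
)

#: the endpoint marker (second metacarpal head), per side
ENDPOINT_MARKER = "FIN2"

#: markers the analysis requires downstream (right-arm canonical form)
REQUIRED_MARKERS = TRUNK_MARKERS + tuple(
    "R" + name for name in ("SHO", "ELB", "WRA", "WRB", "FIN2")
) + ("LSHO",)

#: label aliases accepted on file ingestion (anatomical name -> canonical)
MARKER_ALIASES = {
    "suprasternal_notch": "CLAV",
    "sternal_notch": "CLAV",
    "clavicle": "CLAV",
    "xiphoid": "STRN",
    "xiphoid_process": "STRN",
    "sternum": "STRN",
    "c7": "C7",
    "t10": "T10",
    "r_acromion": "RSHO",
    "l_acromion": "LSHO",
    "r_lat_epicondyle": "RELB",
    "l_lat_epicondyle": "LELB",
    "r_radial_styloid": "RWRA",
    "l_radial_styloid": "LWRA",
    "r_ulnar_styloid": "RWRB",
    "l_ulnar_styloid": "LWRB",
    "r_metacarpal_1": "RFIN1",
    "l_metacarpal_1": "LFIN1",
    "r_metacarpal_2": "RFIN2",
    "l_metacarpal_2": "LFIN2",
    "index_metacarpal_head": "RFIN2",
}


def canonical_label(label: str) -> str:
    """Map a marker label (canonical or anatomical alias) to canonical form."""
    lab = label.strip()
    if lab in MARKER_SET:
        return lab
    return MARKER_ALIASES.get(lab.lower(), lab)


def endpoint_label(side: str) -> str:
    """Endpoint marker label for a given side ('right'/'left')."""
    return ("R" if side == "right" else "L") + ENDPOINT_MARKER
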