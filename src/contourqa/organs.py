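"""Canonical organ-at-risk labels and ROI-name alias handling.

The QA pipeline targets the five thoracic organs at risk whose contours are
reviewed in lung-cancer trial submissions: heart, esophagus, spinal cord and
the two lungs.  Multicenter structure sets name these ROIs inconsistently
("SpinalCord", "Cord", "Lung_L", ...), so mapping to canonical labels goes
through a user-editable alias table with sensible defaults.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

ORGANS: tuple[str, ...] = (
    "heart",
    "esophagus",
    "spinal_cord",
    "lung_left",
    "lung_right",
)

#: Default ROI-name aliases.  Matching is done on a normalized form (lower
#: case, alphanumeric only); an ROI maps to an organ when its normalized name
#: equals an alias or contains it as a substring.  Longer aliases are tried
#: first so "leftlung" wins over "lung".
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "heart": ("heart", "coeur"),
    "esophagus": ("esophagus", "oesophagus", "esophag"),
    "spinal_cord": ("spinalcord", "spinal_cord", "cord", "myelon"),
    "lung_left": ("lungleft", "leftlung", "lungl", "llung", "lt lung", "lunglt"),
    "lung_right": ("lungright", "rightlung", "lungr", "rlung", "rt lung", "lungrt"),
}


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def match_roi_name(
    roi_name: str, aliases: Mapping[str, Iterable[str]] | None = None
) -> str | None:
    """Map an ROI name to a canonical organ label, or ``None`` if unmapped.

    Exact (normalized) matches are preferred; otherwise the longest alias
    contained in the name wins, which resolves names like "Esophagus_avoid".
    """
    table = aliases if aliases is not None else DEFAULT_ALIASES
    norm = _normalize(roi_name)
    candidates: list[tuple[int, str]] = []
    for organ, organ_aliases in table.items():
        for alias in organ_aliases:
            alias_norm = _normalize(alias)
            if not alias_norm:
                continue
            if norm == alias_norm:
                return organ
            if alias_norm in norm:
                candidates.append((len(alias_norm), organ))
    if candidates:
        return max(candidates)[1]
    return None
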