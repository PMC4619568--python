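"""Partition numbered chains into FW1-4 / CDR1-3 under Kabat boundaries.

Kabat CDR boundaries (heavy: 31-35, 50-65, 95-102; lambda: 24-34, 50-56,
89-97) are hard-coded here but exposed for audit; insertion-lettered codes
inherit the region of their base number, so 35B belongs to CDR1 and 100C to
CDR3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .kabat_numbering import KabatCode, NumberedChain

REGION_ORDER = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3", "FW4")

#: region -> (first, last) Kabat number, inclusive.
KABAT_BOUNDARIES: dict[str, dict[str, tuple[int, int]]] = {
    "heavy": {
        "FW1": (1, 30), "CDR1": (31, 35), "FW2": (36, 49), "CDR2": (50, 65),
        "FW3": (66, 94), "CDR3": (95, 102), "FW4": (103, 113),
    },
    "lambda": {
        "FW1": (1, 23), "CDR1": (24, 34), "FW2": (35, 49), "CDR2": (50, 56),
        "FW3": (57, 88), "CDR3": (89, 97), "FW4": (98, 108),
    },
}

#: Names the per-chain CDR ids used throughout reports (H1..H3, L1..L3).
CDR_IDS = {"heavy": ("H1", "H2", "H3"), "lambda": ("L1", "L2", "L3")}


@dataclass
class RegionAnnotation:
    """Region partition of one numbered chain plus its CDR lengths."""

    chain_type: str
    region_map: dict[str, list[tuple[KabatCode, str]]]
    cdr_lengths: dict[str, int] = field(default_factory=dict)


def region_of(code: KabatCode, chain_type: str) -> str:
    """Region id a Kabat code belongs to (insertions follow their base)."""
    bounds = KABAT_BOUNDARIES[chain_type]
    for region in REGION_ORDER:
        lo, hi = bounds[region]
        if lo <= code.number <= hi:
            return region
    # overflow past the profile's FW4 end (custom profiles only)
    return "FW4"


def annotate_regions(nc: NumberedChain) -> RegionAnnotation:
    """Assign every residue of a numbered chain to exactly one region."""
    region_map: dict[str, list[tuple[KabatCode, str]]] = {
        r: [] for r in REGION_ORDER}
    for code, aa in nc.residues:
        region_map[region_of(code, nc.chain_type)].append((code, aa))
    empty = [r for r in REGION_ORDER if not region_map[r]]
    if empty:
        warnings.warn(
            f"{nc.chain_type} chain has empty region(s) {empty}", stacklevel=2)
    prefix = "H" if nc.chain_type == "heavy" else "L"
    cdr_lengths = {f"{prefix}{i}": len(region_map[f"CDR{i}"])
                   for i in (1, 2, 3)}
    return RegionAnnotation(nc.chain_type, region_map, cdr_lengths)


def cdr_length(ra: RegionAnnotation, cdr: str) -> int:
    """Residue count of one CDR ('CDR1'..'CDR3' or 'H1'..'L3').

    Only residues actually present count: Kabat numbers absent from the
    chain (deletions) contribute nothing.
    """
    cdr = cdr.upper()
    if cdr in ra.cdr_lengths:
        return ra.cdr_lengths[cdr]
    if cdr in ("CDR1", "CDR2", "CDR3"):
        return len(ra.region_map[cdr])
    raise ValueError(f"unknown CDR id {cdr!r}")
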