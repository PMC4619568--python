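"""Shared plumbing: number, annotate and classify whole clone sets once.

Statistics modules accept precomputed per-clone numbering so a repertoire
is aligned a single time per analysis run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .canonical_classifier import (CanonicalAssignment, CanonicalTemplate,
                                   assign_canonical, canonical_combination,
                                   load_templates)
from .kabat_numbering import KabatNumberingError, NumberedChain, number_chain
from .region_annotation import RegionAnnotation, annotate_regions
from .sequence_io import CloneSet

log = logging.getLogger(__name__)


@dataclass
class NumberedCloneSet:
    """Per-clone numbering/annotation/classification for one chain type."""

    chain_type: str
    numbered: dict[str, NumberedChain] = field(default_factory=dict)
    annotations: dict[str, RegionAnnotation] = field(default_factory=dict)
    assignments: dict[str, CanonicalAssignment] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def number_clone_set(cs: CloneSet, chain_type: str, *,
                     templates: tuple[CanonicalTemplate, ...] | None = None,
                     classify: bool = True,
                     collapse_unmatched: bool = False) -> NumberedCloneSet:
    """Number (and optionally annotate + classify) every clone carrying the
    requested chain. Per-clone failures are recorded, never silently
    dropped."""
    if templates is None and classify:
        templates = load_templates()
    out = NumberedCloneSet(chain_type)
    for clone in cs.with_chain(chain_type):
        try:
            nc = number_chain(clone.chain(chain_type), chain_type)
        except KabatNumberingError as exc:
            log.warning("clone %s (%s): %s", clone.clone_id, chain_type, exc)
            out.failures[clone.clone_id] = str(exc)
            continue
        out.numbered[clone.clone_id] = nc
        out.annotations[clone.clone_id] = annotate_regions(nc)
        if classify:
            out.assignments[clone.clone_id] = assign_canonical(
                nc, out.annotations[clone.clone_id], templates,
                collapse_unmatched=collapse_unmatched)
    return out


def combinations(heavy: NumberedCloneSet | None,
                 light: NumberedCloneSet | None) -> dict[str, tuple[str, str]]:
    """Per-clone (h1-h2, l1-l2-l3) combination strings."""
    ids = set()
    if heavy:
        ids |= set(heavy.assignments)
    if light:
        ids |= set(light.assignments)
    out = {}
    for cid in sorted(ids):
        ha = heavy.assignments.get(cid) if heavy else None
        la = light.assignments.get(cid) if light else None
        out[cid] = canonical_combination(ha, la)
    return out
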