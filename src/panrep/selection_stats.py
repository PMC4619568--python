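"""Frequency tables for CDR lengths and canonical combinations, pre/post
enrichment comparison, and the chi-square goodness-of-fit test for
canonical-class uniformity."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .canonical_classifier import CanonicalTemplate
from .pipeline import NumberedCloneSet, combinations, number_clone_set
from .region_annotation import CDR_IDS
from .sequence_io import CloneSet

CDR_CHAIN = {"H1": "heavy", "H2": "heavy", "H3": "heavy",
             "L1": "lambda", "L2": "lambda", "L3": "lambda"}


@dataclass
class FrequencyTable:
    """Category counts with percents; categories sorted by descending count,
    ties broken by category."""

    grouping: str
    rows: list[tuple[str, int, float]] = field(default_factory=list)
    n_total: int = 0

    @classmethod
    def from_counts(cls, counts: dict, grouping: str) -> "FrequencyTable":
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"{grouping}: empty frequency table")
        rows = sorted(((str(cat), n, 100.0 * n / total)
                       for cat, n in counts.items()),
                      key=lambda r: (-r[1], r[0]))
        return cls(grouping, rows, total)

    @property
    def counts(self) -> dict[str, int]:
        return {cat: n for cat, n, _ in self.rows}

    @property
    def percents(self) -> dict[str, float]:
        return {cat: p for cat, _, p in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"category": c, "count": n, "percent": p}
             for c, n, p in self.rows])


def _dedupe(cs: CloneSet) -> CloneSet:
    """Collapse clones with identical amino-acid sequences (post-selection
    convention: copies of one founder count once). First occurrence wins."""
    seen: set[tuple[str, str]] = set()
    keep = []
    for clone in cs:
        key = (clone.heavy_seq, clone.light_seq)
        if key not in seen:
            seen.add(key)
            keep.append(clone)
    return CloneSet(keep, provenance=cs.provenance + " (deduplicated)")


def length_frequency_table(cs: CloneSet, cdr: str, *,
                           dedupe: bool = False,
                           numbered: NumberedCloneSet | None = None
                           ) -> FrequencyTable:
    """Distribution of one CDR's lengths over a clone set."""
    cdr = cdr.upper()
    if cdr not in CDR_CHAIN:
        raise ValueError(f"unknown CDR id {cdr!r}")
    if len(cs) == 0:
        raise ValueError("empty CloneSet")
    if dedupe:
        cs, numbered = _dedupe(cs), None
    chain = CDR_CHAIN[cdr]
    ncs = numbered or number_clone_set(cs, chain, classify=False)
    counts: dict[int, int] = {}
    for ra in ncs.annotations.values():
        n = ra.cdr_lengths[cdr]
        counts[n] = counts.get(n, 0) + 1
    if not counts:
        raise ValueError(f"no {chain} chains available for {cdr}")
    return FrequencyTable.from_counts(counts, grouping=f"CDR {cdr} length")


def canonical_frequency_table(cs: CloneSet, which: str, *,
                              dedupe: bool = False,
                              templates: tuple[CanonicalTemplate, ...] | None = None,
                              collapse_unmatched: bool = False,
                              numbered: dict[str, NumberedCloneSet] | None = None
                              ) -> FrequencyTable:
    """Distribution of canonical combinations ("heavy_pair" -> h1-h2,
    "light_triple" -> l1-l2-l3)."""
    if which not in ("heavy_pair", "light_triple"):
        raise ValueError(f"which must be heavy_pair/light_triple, got {which!r}")
    if len(cs) == 0:
        raise ValueError("empty CloneSet")
    if dedupe:
        cs, numbered = _dedupe(cs), None
    chain = "heavy" if which == "heavy_pair" else "lambda"
    ncs = (numbered or {}).get(chain) or number_clone_set(
        cs, chain, templates=templates, collapse_unmatched=collapse_unmatched)
    combos = combinations(ncs if chain == "heavy" else None,
                          ncs if chain == "lambda" else None)
    counts: dict[str, int] = {}
    for cid, (h, l) in combos.items():
        combo = h if chain == "heavy" else l
        counts[combo] = counts.get(combo, 0) + 1
    return FrequencyTable.from_counts(counts, grouping=which)


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit against a uniform null over the observed
    categories."""

    statistic: float
    df: int
    p_value: float
    k: int


def chi_square_gof(counts: list[int]) -> GofResult:
    """Chi-square goodness of fit of category counts to a uniform null.

    statistic = sum (obs - exp)^2 / exp with exp = total / k and
    df = k - 1; the p-value is the upper tail of the chi-square
    distribution.
    """
    if any(c < 0 for c in counts):
        raise ValueError("negative counts are not valid frequencies")
    if len(counts) < 2:
        raise ValueError("need at least two categories")
    if sum(counts) == 0:
        raise ValueError("total count must be positive")
    statistic, p_value = stats.chisquare(counts)
    return GofResult(float(statistic), len(counts) - 1, float(p_value),
                     len(counts))


def pre_post_enrichment(pre_table: FrequencyTable,
                        post_table: FrequencyTable) -> pd.DataFrame:
    """Per-category pre/post percent comparison with fold change of percent.

    Categories absent pre-selection are flagged "novel" with an undefined
    fold change (NaN). Fold changes use unrounded percents.
    """
    if pre_table.grouping != post_table.grouping:
        raise ValueError(
            f"grouping mismatch: {pre_table.grouping!r} vs "
            f"{post_table.grouping!r}")
    pre_p, post_p = pre_table.percents, post_table.percents
    rows = []
    for cat in sorted(set(pre_p) | set(post_p),
                      key=lambda c: (-post_p.get(c, 0.0), c)):
        pre_v, post_v = pre_p.get(cat), post_p.get(cat, 0.0)
        novel = pre_v is None
        fold = math.nan if novel else (post_v / pre_v if pre_v else math.nan)
        rows.append({"category": cat,
                     "pre_percent": math.nan if novel else pre_v,
                     "post_percent": post_v,
                     "fold_change": fold,
                     "novel": novel})
    return pd.DataFrame(rows)
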