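"""Per-position variability profiling and pre/post conserved-site analysis.

Variability at a Kabat position is 100 x (1 - modal-residue frequency),
binned into five classes; conservative substitutions are judged by a
seven-group biophysical partition of the amino acids. A position counts as
conserved in a test repertoire when every chain carries a residue there and
each residue either equals the reference (pre-selection) consensus or
shares its biophysical group.
"""

from __future__ import annotations

import functools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .kabat_numbering import KabatCode
from .pipeline import NumberedCloneSet, number_clone_set
from .region_annotation import REGION_ORDER, region_of
from .sequence_io import AMINO_ACIDS, CloneSet

#: Variability bin edges (percent): bin 1 = [0,10), ... bin 5 = [75,100].
DEFAULT_BIN_EDGES = (10.0, 25.0, 50.0, 75.0)

#: Positions observed in fewer chains than this are flagged, not binned.
DEFAULT_COVERAGE_FLOOR = 5

UNGROUPABLE = "ungroupable"


class SchemeError(ValueError):
    """Malformed biophysical grouping scheme."""


@dataclass(frozen=True)
class BiophysicalScheme:
    """Partition of the 20 standard amino acids into exactly seven groups."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.groups) != 7:
            raise SchemeError(f"expected 7 groups, got {len(self.groups)}")
        union: set[str] = set()
        for name, members in self.groups.items():
            if union & members:
                raise SchemeError(f"group {name} overlaps another group")
            union |= members
        if union != AMINO_ACIDS:
            raise SchemeError("groups do not partition the 20-letter alphabet")

    @functools.cached_property
    def _by_residue(self) -> dict[str, str]:
        return {aa: name for name, members in self.groups.items()
                for aa in members}

    def group_of(self, aa: str) -> str:
        return self._by_residue.get(aa.upper(), UNGROUPABLE)

    def same_group(self, a: str, b: str) -> bool:
        ga, gb = self.group_of(a), self.group_of(b)
        return ga == gb and ga != UNGROUPABLE


def load_scheme(path: str | Path | None = None) -> BiophysicalScheme:
    """Load the grouping scheme (built-in seven-group partition by default)."""
    if path is None:
        text = resources.files("panrep.data").joinpath(
            "biophysical_groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    groups = {str(name): frozenset(str(members).upper())
              for name, members in doc["groups"].items()}
    return BiophysicalScheme(groups)


def biophysical_group(aa: str, scheme: BiophysicalScheme | None = None) -> str:
    """Group id of one amino acid ('ungroupable' for X/non-standard)."""
    if scheme is None:
        scheme = load_scheme()
    return scheme.group_of(aa)


@dataclass
class VariabilityProfile:
    """Per-position variability and bin plus per-region bin summaries."""

    chain_type: str
    positions: pd.DataFrame          # index: Kabat code str
    region_summary: pd.DataFrame     # index: region, columns: bin 1..5
    fw_cdr_summary: pd.DataFrame     # index: FW/CDR, columns: bin 1..5
    coverage_floor: int
    bin_edges: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return self.positions.reset_index(names="position")


def _bin_of(variability: float, edges: tuple[float, ...]) -> int:
    for i, edge in enumerate(edges, start=1):
        if variability < edge:
            return i
    return len(edges) + 1


def _numbered(cs: CloneSet, chain_type: str,
              numbered: NumberedCloneSet | None) -> NumberedCloneSet:
    if numbered is not None:
        return numbered
    return number_clone_set(cs, chain_type, classify=False)


def _position_counts(ncs: NumberedCloneSet
                     ) -> dict[KabatCode, Counter]:
    counts: dict[KabatCode, Counter] = {}
    for nc in ncs.numbered.values():
        for code, aa in nc.residues:
            counts.setdefault(code, Counter())[aa] += 1
    return counts


def variability_profile(cs: CloneSet, chain_type: str, *,
                        numbered: NumberedCloneSet | None = None,
                        coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
                        bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
                        ) -> VariabilityProfile:
    """Per-Kabat-position variability profile of one chain of a repertoire.

    variability = 100 x (1 - modal_count / coverage); bins follow
    ``bin_edges`` (defaults: <10, <25, <50, <75, >=75 percent). Positions
    covered by fewer than ``coverage_floor`` chains are flagged
    ``insufficient`` and left unbinned. Region summaries report the percent
    of binnable positions per bin, per region and for FW vs CDR overall.
    """
    if len(cs) == 0:
        raise ValueError("empty CloneSet")
    ncs = _numbered(cs, chain_type, numbered)
    if not ncs.numbered:
        raise ValueError(f"no {chain_type} chains could be numbered")
    counts = _position_counts(ncs)
    rows = []
    for code in sorted(counts):
        counter = counts[code]
        coverage = sum(counter.values())
        modal_residue, modal_count = min(
            counter.items(), key=lambda kv: (-kv[1], kv[0]))
        variability = 100.0 * (1.0 - modal_count / coverage)
        sufficient = coverage >= coverage_floor
        rows.append({
            "position": str(code),
            "region": region_of(code, chain_type),
            "coverage": coverage,
            "modal_residue": modal_residue,
            "modal_count": modal_count,
            "variability": variability,
            "bin": _bin_of(variability, bin_edges) if sufficient else pd.NA,
            "insufficient": not sufficient,
        })
    positions = pd.DataFrame(rows).set_index("position")
    positions["bin"] = positions["bin"].astype("Int64")

    n_bins = len(bin_edges) + 1
    bin_cols = list(range(1, n_bins + 1))

    def summary(frame: pd.DataFrame, groups: dict[str, pd.DataFrame]
                ) -> pd.DataFrame:
        out = {}
        for name, sub in groups.items():
            binned = sub.dropna(subset=["bin"])
            if len(binned):
                pct = (binned["bin"].value_counts(normalize=True) * 100.0)
                out[name] = [float(pct.get(b, 0.0)) for b in bin_cols]
            else:
                out[name] = [float("nan")] * n_bins
        return pd.DataFrame.from_dict(
            out, orient="index",
            columns=[f"bin{b}_percent" for b in bin_cols])

    region_summary = summary(positions, {
        r: positions[positions["region"] == r] for r in REGION_ORDER})
    fw_cdr_summary = summary(positions, {
        "FW": positions[positions["region"].str.startswith("FW")],
        "CDR": positions[positions["region"].str.startswith("CDR")]})
    return VariabilityProfile(chain_type, positions, region_summary,
                              fw_cdr_summary, coverage_floor, bin_edges)


def consensus(cs: CloneSet, chain_type: str, *,
              numbered: NumberedCloneSet | None = None
              ) -> dict[KabatCode, str]:
    """Modal residue per Kabat position (alphabetical tie-break)."""
    if len(cs) == 0:
        raise ValueError("empty CloneSet")
    ncs = _numbered(cs, chain_type, numbered)
    counts = _position_counts(ncs)
    return {code: min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            for code, counter in sorted(counts.items())}


def conserved_positions(test_set: CloneSet,
                        reference_consensus: dict[KabatCode, str],
                        scheme: BiophysicalScheme | None = None, *,
                        chain_type: str,
                        numbered: NumberedCloneSet | None = None,
                        reference_residues: dict[KabatCode, set[str]] | None = None
                        ) -> set[KabatCode]:
    """Kabat positions conserved across every chain of a test repertoire.

    A position is conserved iff every test chain carries a residue there
    and each residue either equals the reference consensus or shares its
    biophysical group. Passing ``reference_residues`` (position -> set of
    residues seen in the reference repertoire) switches to the laxer
    reading in which matching *any* reference residue, or its group,
    suffices.
    """
    if scheme is None:
        scheme = load_scheme()
    ncs = _numbered(test_set, chain_type, numbered)
    if not ncs.numbered:
        raise ValueError(f"no {chain_type} chains in the test set")
    maps = [nc.position_map() for nc in ncs.numbered.values()]
    observed: set[KabatCode] = set()
    for m in maps:
        observed |= set(m)
    skipped = sorted(str(c) for c in observed - set(reference_consensus))
    if skipped:
        warnings.warn(
            f"{len(skipped)} position(s) absent from the reference consensus "
            f"excluded: {skipped[:10]}", stacklevel=2)

    def ok(aa: str, code: KabatCode) -> bool:
        if reference_residues is not None:
            refs = reference_residues.get(code, set())
            return any(aa == r or scheme.same_group(aa, r) for r in refs)
        ref = reference_consensus[code]
        return aa == ref or scheme.same_group(aa, ref)

    conserved = set()
    for code in reference_consensus:
        residues = [m.get(code) for m in maps]
        if all(aa is not None and ok(aa, code) for aa in residues):
            conserved.add(code)
    return conserved


@dataclass
class ConservationReport:
    """Conserved-site comparison of a pre vs post repertoire (per chain and
    region, with self-consistent totals)."""

    positions: dict[tuple[str, str, str], list[str]] = field(
        default_factory=dict)  # (phase, chain, region) -> sorted codes

    def count(self, phase: str, chain: str, region: str) -> int:
        return len(self.positions.get((phase, chain, region), []))

    def total(self, phase: str, chain: str, which: str = "chain") -> int:
        regions = {"FWs": [r for r in REGION_ORDER if r.startswith("FW")],
                   "CDRs": [r for r in REGION_ORDER if r.startswith("CDR")],
                   "chain": list(REGION_ORDER)}[which]
        return sum(self.count(phase, chain, r) for r in regions)

    def grand_total(self, phase: str) -> int:
        return sum(self.total(phase, chain) for chain in ("heavy", "lambda"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        row_order = (["FW1", "FW2", "FW3", "FW4", "Total (FWs)",
                      "CDR1", "CDR2", "CDR3", "Total (CDRs)",
                      "Total (chain)"])
        for label in row_order:
            row = {"region": label}
            for phase in ("pre", "post"):
                for chain in ("heavy", "lambda"):
                    col = f"{phase}_{chain}"
                    if label.startswith("Total"):
                        which = label.split("(")[1].rstrip(")")
                        row[col] = self.total(phase, chain, which)
                        row[f"{col}_positions"] = ""
                    else:
                        codes = self.positions.get((phase, chain, label), [])
                        row[col] = len(codes)
                        row[f"{col}_positions"] = ",".join(codes)
            rows.append(row)
        grand = {"region": "Grand total"}
        for phase in ("pre", "post"):
            for chain in ("heavy", "lambda"):
                grand[f"{phase}_{chain}"] = self.total(phase, chain)
                grand[f"{phase}_{chain}_positions"] = ""
        grand["region"] = "Grand total"
        rows.append(grand)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "positions": {f"{p}/{c}/{r}": codes
                          for (p, c, r), codes in sorted(self.positions.items())},
            "totals": {p: {c: self.total(p, c) for c in ("heavy", "lambda")}
                       for p in ("pre", "post")},
            "grand_totals": {p: self.grand_total(p) for p in ("pre", "post")},
        }


def conservation_report(pre: CloneSet, post: CloneSet,
                        scheme: BiophysicalScheme | None = None, *,
                        chains: tuple[str, ...] = ("heavy", "lambda"),
                        numbered_pre: dict[str, NumberedCloneSet] | None = None,
                        numbered_post: dict[str, NumberedCloneSet] | None = None,
                        reference_any_residue: bool = False
                        ) -> ConservationReport:
    """Conserved positions of the pre and post sets, both judged against the
    pre-selection consensus, organised per chain and region.

    ``reference_any_residue`` switches the conservation rule to accept any
    residue observed in the pre set at a position (not just its consensus).
    """
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("pre and post CloneSets must be non-empty")
    if scheme is None:
        scheme = load_scheme()
    report = ConservationReport()
    for chain in chains:
        ncs_pre = (numbered_pre or {}).get(chain) or number_clone_set(
            pre, chain, classify=False)
        ncs_post = (numbered_post or {}).get(chain) or number_clone_set(
            post, chain, classify=False)
        cons = consensus(pre, chain, numbered=ncs_pre)
        ref_residues = None
        if reference_any_residue:
            ref_residues = {
                code: set(counter)
                for code, counter in _position_counts(ncs_pre).items()}
        for phase, cs, ncs in (("pre", pre, ncs_pre),
                               ("post", post, ncs_post)):
            conserved = conserved_positions(
                cs, cons, scheme, chain_type=chain, numbered=ncs,
                reference_residues=ref_residues)
            by_region: dict[str, list[KabatCode]] = {}
            for code in conserved:
                by_region.setdefault(region_of(code, chain), []).append(code)
            for region in REGION_ORDER:
                codes = sorted(by_region.get(region, []))
                report.positions[(phase, chain, region)] = [
                    str(c) for c in codes]
    return report
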