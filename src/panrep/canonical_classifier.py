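"""Canonical structure assignment by strict Chothia-SDR template matching.

A loop's canonical class is determined by its length over a Chothia-style
loop window (expressed in Kabat codes; distinct from the Kabat CDR
boundaries used for length tables) plus a set of key residues. Matching is
strict: one violated key residue disqualifies a template. Loops whose
window length matches no known template are labelled "X"; loops with a
length-compatible template but violated key residues are labelled
"unmatched" (optionally collapsed into "X").

CDR H3 is deliberately not classified.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .kabat_numbering import KabatCode, NumberedChain
from .region_annotation import RegionAnnotation

#: Loops classified per chain type (H3 is excluded by design).
CANONICAL_LOOPS = {"heavy": ("H1", "H2"), "lambda": ("L1", "L2", "L3")}

CLASS_X = "X"
CLASS_UNMATCHED = "unmatched"


class TemplateError(ValueError):
    """Malformed or ambiguous canonical template set."""


@dataclass(frozen=True)
class CanonicalTemplate:
    """Loop-length plus key-residue rule for one canonical class."""

    chain_type: str
    loop: str
    class_label: str
    window: tuple[int, int]          # inclusive Kabat numbers
    loop_length: int
    key_residues: tuple[tuple[KabatCode, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if self.loop_length < 1:
            raise TemplateError(f"{self.loop} class {self.class_label}: "
                                "loop_length must be >= 1")
        for code, allowed in self.key_residues:
            if not allowed:
                raise TemplateError(f"{self.loop} class {self.class_label}: "
                                    f"empty allowed set at {code}")


@dataclass
class LoopEvidence:
    """Why a loop received its label."""

    observed_length: int
    length_compatible: list[str] = field(default_factory=list)
    matched: list[str] = field(default_factory=list)
    violations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class CanonicalAssignment:
    """Per-loop canonical class labels for one chain."""

    chain_type: str
    labels: dict[str, str]
    evidence: dict[str, LoopEvidence]


def _parse_template(rec: dict) -> CanonicalTemplate:
    try:
        keys = tuple(
            (KabatCode.parse(k["code"]), frozenset(str(k["allowed"]).upper()))
            for k in rec.get("keys", []))
        return CanonicalTemplate(
            chain_type=str(rec["chain"]),
            loop=str(rec["loop"]).upper(),
            class_label=str(rec["class"]),
            window=(int(rec["window"][0]), int(rec["window"][1])),
            loop_length=int(rec["length"]),
            key_residues=keys,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise TemplateError(f"malformed template record {rec!r}: {exc}") from exc


@functools.lru_cache(maxsize=None)
def _builtin_templates() -> tuple[CanonicalTemplate, ...]:
    text = resources.files("panrep.data").joinpath(
        "canonical_templates.yaml").read_text()
    return _load_from_text(text)


def _load_from_text(text: str) -> tuple[CanonicalTemplate, ...]:
    doc = yaml.safe_load(text)
    templates = tuple(_parse_template(rec) for rec in doc["templates"])
    seen = set()
    windows: dict[tuple[str, str], tuple[int, int]] = {}
    for t in templates:
        key = (t.chain_type, t.loop, t.class_label)
        if key in seen:
            raise TemplateError(f"duplicate template {key}")
        seen.add(key)
        w = windows.setdefault((t.chain_type, t.loop), t.window)
        if w != t.window:
            raise TemplateError(
                f"inconsistent windows for {t.chain_type} {t.loop}")
    return templates


def load_templates(path: str | Path | None = "builtin"
                   ) -> tuple[CanonicalTemplate, ...]:
    """Load canonical templates from a YAML file or the built-in set."""
    if path is None or path == "builtin":
        return _builtin_templates()
    return _load_from_text(Path(path).read_text())


def loop_window(templates: tuple[CanonicalTemplate, ...], chain_type: str,
                loop: str) -> tuple[int, int]:
    for t in templates:
        if t.chain_type == chain_type and t.loop == loop:
            return t.window
    raise TemplateError(f"no templates define a window for {chain_type} {loop}")


def measure_loop_length(nc: NumberedChain, window: tuple[int, int]) -> int:
    """Residues present whose Kabat number lies inside the loop window."""
    lo, hi = window
    return sum(1 for code, _ in nc.residues if lo <= code.number <= hi)


def assign_canonical(nc: NumberedChain,
                     ra: RegionAnnotation | None = None,
                     templates: tuple[CanonicalTemplate, ...] | None = None,
                     *, collapse_unmatched: bool = False
                     ) -> CanonicalAssignment:
    """Assign a canonical class (or "X"/"unmatched") to every loop.

    ``ra`` is accepted for pipeline symmetry; loop lengths are measured
    directly over the template windows. With ``collapse_unmatched`` the
    "unmatched" label is reported as "X" (the convention of publications
    that lump both kinds of non-classified loops together).
    """
    if templates is None:
        templates = load_templates()
    position = nc.position_map()
    labels: dict[str, str] = {}
    evidence: dict[str, LoopEvidence] = {}
    for loop in CANONICAL_LOOPS[nc.chain_type]:
        window = loop_window(templates, nc.chain_type, loop)
        observed = measure_loop_length(nc, window)
        candidates = [t for t in templates
                      if t.chain_type == nc.chain_type and t.loop == loop
                      and t.loop_length == observed]
        ev = LoopEvidence(observed_length=observed,
                          length_compatible=[t.class_label for t in candidates])
        if not candidates:
            labels[loop] = CLASS_X
            evidence[loop] = ev
            continue
        matched = []
        for t in candidates:
            violated = [(str(code), position.get(code) or "-")
                        for code, allowed in t.key_residues
                        if position.get(code) not in allowed]
            if violated:
                ev.violations[t.class_label] = violated
            else:
                matched.append(t.class_label)
        ev.matched = matched
        if len(matched) > 1:
            raise TemplateError(
                f"ambiguous template set for {nc.chain_type} {loop} length "
                f"{observed}: classes {matched} all match")
        if matched:
            labels[loop] = matched[0]
        else:
            labels[loop] = CLASS_X if collapse_unmatched else CLASS_UNMATCHED
        evidence[loop] = ev
    return CanonicalAssignment(nc.chain_type, labels, evidence)


def canonical_combination(ca_heavy: CanonicalAssignment | None,
                          ca_light: CanonicalAssignment | None
                          ) -> tuple[str, str]:
    """Combination strings ("h1-h2", "l1-l2-l3"); empty string if a chain
    is absent."""
    heavy = ""
    if ca_heavy is not None:
        heavy = "-".join(ca_heavy.labels[l] for l in CANONICAL_LOOPS["heavy"])
    light = ""
    if ca_light is not None:
        light = "-".join(ca_light.labels[l] for l in CANONICAL_LOOPS["lambda"])
    return heavy, light
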