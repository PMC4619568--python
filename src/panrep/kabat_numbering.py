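"""Kabat numbering of antibody variable domains by profile alignment.

Each query sequence is globally aligned (affine gaps, BLOSUM62) against an
embedded position-annotated reference profile for its chain type. Residues
matched to the reference inherit its Kabat codes; insertions relative to the
reference receive letter suffixes at the nearest permitted insertion anchor
(heavy: 35, 52, 82, 100; lambda: 27, 95, 106); deletions leave Kabat numbers
unassigned. Insertion lettering is a numbering convention, not an alignment
artefact: an inserted run is always attached immediately after its anchor
code, so codes within a chain are strictly increasing and concatenating the
numbered residues reproduces the input exactly.
"""

from __future__ import annotations

import functools
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

#: Kabat positions at which insertion letters may be attached.
INSERTION_ANCHORS = {
    "heavy": (35, 52, 82, 100),
    "lambda": (27, 95, 106),
}

#: Maximum distance (in Kabat numbers) between an inserted run's flanking
#: matched codes and the nearest anchor before numbering is refused; wide
#: enough that any run inside a Kabat CDR reaches that CDR's anchor
#: (CDR H2 spans 50-65 with its anchor at 52).
ANCHOR_WINDOW = 14

#: Variable domains fall in this length range; anything else is rejected
#: before alignment.
MIN_DOMAIN_LENGTH, MAX_DOMAIN_LENGTH = 80, 150

#: Default floor on the raw alignment score below which the input is deemed
#: not to be an antibody variable domain.
DEFAULT_MIN_SCORE = 50.0

_CODE_RE = re.compile(r"^(\d+)([A-Za-z]?)$")


class KabatNumberingError(ValueError):
    """Sequence could not be numbered under the Kabat scheme."""


@functools.total_ordering
@dataclass(frozen=True)
class KabatCode:
    """A Kabat position: integer number plus optional insertion letter.

    Ordering is lexicographic by (number, insertion) with the empty
    insertion sorting before 'A', so 82 < 82A < 82B < 83.
    """

    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"Kabat number must be >= 1, got {self.number}")
        if self.insertion and self.insertion not in string.ascii_uppercase:
            raise ValueError(f"bad insertion letter {self.insertion!r}")

    @classmethod
    def parse(cls, text: str) -> "KabatCode":
        m = _CODE_RE.match(str(text).strip())
        if not m:
            raise ValueError(f"cannot parse Kabat code {text!r}")
        return cls(int(m.group(1)), m.group(2).upper())

    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion)

    def __lt__(self, other: "KabatCode") -> bool:
        return self.key() < other.key()

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"


@dataclass(frozen=True)
class ReferenceProfile:
    """Position-annotated reference sequence for one chain type."""

    chain_type: str
    codes: tuple[KabatCode, ...]
    residues: str
    anchors: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.residues):
            raise ValueError("reference codes and residues differ in length")
        if list(self.codes) != sorted(self.codes):
            raise ValueError("reference codes are not strictly increasing")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class NumberedChain:
    """A variable-domain sequence with a Kabat code on every residue."""

    chain_type: str
    residues: tuple[tuple[KabatCode, str], ...]
    alignment_score: float = 0.0

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def codes(self) -> tuple[KabatCode, ...]:
        return tuple(code for code, _ in self.residues)

    def position_map(self) -> dict[KabatCode, str]:
        return {code: aa for code, aa in self.residues}

    def residue_at(self, code: KabatCode | str) -> str | None:
        if isinstance(code, str):
            code = KabatCode.parse(code)
        return self.position_map().get(code)


def _read_profile(text: str, chain_type: str) -> ReferenceProfile:
    codes, residues = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code_s, aa = line.split()
        codes.append(KabatCode.parse(code_s))
        residues.append(aa.upper())
    return ReferenceProfile(chain_type, tuple(codes), "".join(residues),
                            INSERTION_ANCHORS[chain_type])


@functools.lru_cache(maxsize=None)
def load_reference(chain_type: str,
                   path: str | None = None) -> ReferenceProfile:
    """Load the reference profile for a chain type.

    With ``path`` omitted the embedded sheep-consensus-like profile is used;
    the data format is two whitespace-separated columns (Kabat code,
    residue) with '#' comments.
    """
    if chain_type not in INSERTION_ANCHORS:
        raise ValueError(f"unknown chain type {chain_type!r}")
    if path is None:
        fname = {"heavy": "heavy_reference.tsv",
                 "lambda": "lambda_reference.tsv"}[chain_type]
        text = resources.files("panrep.data").joinpath(fname).read_text()
    else:
        text = Path(path).read_text()
    return _read_profile(text, chain_type)


@functools.lru_cache(maxsize=None)
def _aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _next_letters(start_after: str, k: int) -> list[str]:
    letters = string.ascii_uppercase
    i = letters.index(start_after) + 1 if start_after else 0
    if i + k > len(letters):
        raise KabatNumberingError("more than 26 insertions at one anchor")
    return list(letters[i:i + k])


def number_chain(seq: str, chain_type: str, *,
                 profile: ReferenceProfile | None = None,
                 open_gap: float = -10.0, extend_gap: float = -1.0,
                 min_score: float = DEFAULT_MIN_SCORE) -> NumberedChain:
    """Assign a Kabat code to every residue of a variable-domain sequence.

    Raises :class:`KabatNumberingError` when the sequence does not look like
    a variable domain (length outside 80-150, alignment score below
    ``min_score``) or when an inserted run falls outside every anchor
    window.
    """
    seq = seq.upper()
    if not (MIN_DOMAIN_LENGTH <= len(seq) <= MAX_DOMAIN_LENGTH):
        raise KabatNumberingError(
            f"sequence length {len(seq)} outside the variable-domain range "
            f"[{MIN_DOMAIN_LENGTH}, {MAX_DOMAIN_LENGTH}]")
    if profile is None:
        profile = load_reference(chain_type)
    alignment = _aligner(open_gap, extend_gap).align(profile.residues, seq)[0]
    if alignment.score < min_score:
        raise KabatNumberingError(
            f"not an antibody variable domain (alignment score "
            f"{alignment.score:.1f} < {min_score:.1f})")

    ref_for_query: list[int | None] = [None] * len(seq)
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for k in range(qe - qs):
            ref_for_query[qs + k] = rs + k

    matched = [r for r in ref_for_query if r is not None]

    # Attach every inserted run to its nearest permitted anchor.
    insert_counts: dict[int, int] = {}
    i = 0
    while i < len(seq):
        if ref_for_query[i] is not None:
            i += 1
            continue
        j = i
        while j < len(seq) and ref_for_query[j] is None:
            j += 1
        left = next((ref_for_query[k] for k in range(i - 1, -1, -1)
                     if ref_for_query[k] is not None), None)
        right = next((ref_for_query[k] for k in range(j, len(seq))
                      if ref_for_query[k] is not None), None)
        if left is None or right is None:
            raise KabatNumberingError(
                f"inserted residues at query position {i + 1} fall outside "
                "the reference (terminal overhang)")
        lnum = profile.codes[left].number
        rnum = profile.codes[right].number

        def distance(a: int) -> int:
            if lnum <= a < rnum:
                return 0
            return min(abs(a - lnum), abs(a - rnum))

        anchor = min(profile.anchors, key=lambda a: (distance(a), a))
        if distance(anchor) > ANCHOR_WINDOW:
            raise KabatNumberingError(
                f"insertion at query position {i + 1} (between Kabat "
                f"{lnum} and {rnum}) falls outside every anchor window")
        insert_counts[anchor] = insert_counts.get(anchor, 0) + (j - i)
        i = j

    # Splice insertion codes immediately after their anchor code.
    matched_codes = [profile.codes[r] for r in matched]
    final_codes: list[KabatCode] = []
    pending = dict(insert_counts)
    for idx, code in enumerate(matched_codes):
        final_codes.append(code)
        nxt = matched_codes[idx + 1] if idx + 1 < len(matched_codes) else None
        for anchor in sorted(pending):
            # splice after the last matched code numbered <= anchor
            if code.number <= anchor and (nxt is None or nxt.number > anchor):
                last_letter = code.insertion if code.number == anchor else ""
                for letter in _next_letters(last_letter,
                                            pending.pop(anchor)):
                    final_codes.append(KabatCode(anchor, letter))
    if pending:
        raise KabatNumberingError(
            f"could not place insertions at anchors {sorted(pending)} "
            "(anchor region deleted)")
    if len(final_codes) != len(seq):
        raise KabatNumberingError("internal error: code/residue count mismatch")
    residues = tuple(zip(final_codes, seq))
    nc = NumberedChain(chain_type, residues, float(alignment.score))
    problems = validate_numbering(nc, profile=profile)
    if problems:
        raise KabatNumberingError("; ".join(problems))
    return nc


def validate_numbering(nc: NumberedChain, *,
                       profile: ReferenceProfile | None = None
                       ) -> list[str]:
    """Diagnostics for a NumberedChain; an empty list means valid.

    Checks strict code ordering, anchor-only insertion letters (letters
    present in the reference itself, e.g. heavy 82A-82C, are permitted),
    and contiguous lettering at each anchor.
    """
    if profile is None:
        profile = load_reference(nc.chain_type)
    diagnostics: list[str] = []
    codes = nc.codes
    for a, b in zip(codes, codes[1:]):
        if not a < b:
            diagnostics.append(f"codes not strictly increasing at {a} >= {b}")
    reference_inserts = {c for c in profile.codes if c.insertion}
    anchors = set(profile.anchors)
    by_number: dict[int, list[str]] = {}
    for code in codes:
        if code.insertion:
            by_number.setdefault(code.number, []).append(code.insertion)
            if code.number not in anchors and code not in reference_inserts:
                diagnostics.append(
                    f"insertion letter at non-anchor position {code}")
    reference_numbers = {c.number for c in reference_inserts}
    for number, letters in by_number.items():
        if number in reference_numbers:
            continue  # reference-borne letters may be partially deleted
        expected = list(string.ascii_uppercase[:len(letters)])
        if sorted(letters) != expected:
            diagnostics.append(
                f"non-contiguous insertion letters at {number}: {letters}")
    seen = set()
    for code in codes:
        if code in seen:
            diagnostics.append(f"duplicate code {code}")
        seen.add(code)
    return diagnostics
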