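"""Reading and writing scFv clone sequences, metadata and tabular reports.

The unit of analysis is a :class:`Clone` (heavy and/or lambda variable
domain plus library/phase/target metadata) collected into a
:class:`CloneSet`. scFv constructs are split into VH / linker / VL around
the 15-residue EGKSSGASGESKVDD linker.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: scFv inter-domain linker joining VH to VL.
SCFV_LINKER = "EGKSSGASGESKVDD"

#: Minimum ungapped identity (over the 15-residue window) accepted when the
#: linker is not found verbatim.
FUZZY_LINKER_IDENTITY = 0.80

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated in inputs (ambiguous residue) but never emitted.
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}

METADATA_COLUMNS = ["clone_id", "library_id", "phase", "target",
                    "light_isotype", "chain_format"]


class SequenceIOError(ValueError):
    """Malformed input sequence, metadata or scFv construct."""


@dataclass(frozen=True)
class Clone:
    """One antibody clone: VH and/or VL sequence plus sample metadata."""

    clone_id: str
    library_id: str = ""
    phase: str = "pre"              # "pre" | "post"
    target: str = ""                # hapten id, non-empty iff phase == "post"
    heavy_seq: str = ""
    light_seq: str = ""
    light_isotype: str = "lambda"   # "lambda" | "kappa"

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise SequenceIOError(f"{self.clone_id}: phase must be pre/post")
        if self.phase == "post" and not self.target:
            raise SequenceIOError(
                f"{self.clone_id}: post-selection clone requires a target")
        if self.light_isotype not in ("lambda", "kappa"):
            raise SequenceIOError(
                f"{self.clone_id}: light_isotype must be lambda/kappa")
        for name, seq in (("heavy", self.heavy_seq), ("light", self.light_seq)):
            bad = set(seq) - EXTENDED_ALPHABET
            if bad:
                raise SequenceIOError(
                    f"{self.clone_id}: non-amino-acid characters in "
                    f"{name} chain: {sorted(bad)}")

    def chain(self, chain_type: str) -> str:
        """Sequence of one chain; chain_type is 'heavy' or 'lambda'/'light'."""
        if chain_type == "heavy":
            return self.heavy_seq
        if chain_type in ("lambda", "light", "kappa"):
            return self.light_seq
        raise ValueError(f"unknown chain type {chain_type!r}")


@dataclass
class CloneSet:
    """Ordered collection of clones sharing a provenance description."""

    clones: list[Clone] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceIOError(f"duplicate clone ids: {dupes}")

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self) -> Iterator[Clone]:
        return iter(self.clones)

    def __getitem__(self, i: int) -> Clone:
        return self.clones[i]

    def with_chain(self, chain_type: str) -> list[Clone]:
        """Clones that actually carry the requested chain."""
        return [c for c in self.clones if c.chain(chain_type)]

    def subset(self, *, phase: str | None = None, target: str | None = None,
               library_id: str | None = None) -> "CloneSet":
        keep = [c for c in self.clones
                if (phase is None or c.phase == phase)
                and (target is None or c.target == target)
                and (library_id is None or c.library_id == library_id)]
        return CloneSet(keep, provenance=self.provenance)


def split_scfv(seq: str) -> tuple[str, str, str]:
    """Split an scFv construct into (heavy, linker, light).

    The linker is located by exact match to :data:`SCFV_LINKER`; failing
    that, by the best ungapped 15-residue window with >= 80 % identity
    (leftmost best window wins ties). Raises :class:`SequenceIOError` when
    the construct is ambiguous (two exact matches) or the linker cannot be
    found.
    """
    if len(seq) <= 200:
        raise SequenceIOError(
            f"sequence too short for an scFv construct ({len(seq)} aa)")
    n_exact = seq.count(SCFV_LINKER)
    if n_exact > 1:
        raise SequenceIOError("ambiguous construct: multiple exact linker matches")
    if n_exact == 1:
        i = seq.index(SCFV_LINKER)
        return seq[:i], SCFV_LINKER, seq[i + len(SCFV_LINKER):]
    # fuzzy search: best ungapped window
    k = len(SCFV_LINKER)
    best_i, best_m = -1, 0
    for i in range(len(seq) - k + 1):
        m = sum(a == b for a, b in zip(seq[i:i + k], SCFV_LINKER))
        if m > best_m:
            best_i, best_m = i, m
    if best_m / k < FUZZY_LINKER_IDENTITY:
        raise SequenceIOError(
            f"linker not found (best window identity {best_m}/{k})")
    log.warning("linker located by fuzzy match (%d/%d identity) at %d",
                best_m, k, best_i)
    return seq[:best_i], seq[best_i:best_i + k], seq[best_i + k:]


def _parse_header_tokens(description: str) -> dict[str, str]:
    """Parse ``key=value`` tokens (';'-separated) from a FASTA description."""
    meta: dict[str, str] = {}
    for token in description.replace(",", ";").split():
        for part in token.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                meta[k.strip().lower()] = v.strip()
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar metadata TSV, keyed by clone_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "clone_id" not in df.columns:
        raise SequenceIOError(f"{path}: metadata lacks a clone_id column")
    if df["clone_id"].duplicated().any():
        dupes = sorted(df.loc[df["clone_id"].duplicated(), "clone_id"])
        raise SequenceIOError(f"{path}: duplicate metadata ids {dupes}")
    return df.set_index("clone_id")


def read_repertoire(fasta_path: str | Path,
                    metadata_path: str | Path | None = None) -> CloneSet:
    """Read a repertoire FASTA (scFv constructs or single chains) into a
    :class:`CloneSet`.

    Per-record metadata comes from the sidecar TSV when given, else from
    ``key=value`` tokens in the FASTA header (``lib=...;phase=...;
    target=...;isotype=...;format=...``). Records without metadata default
    to phase=pre with a logged warning. Records with a non-amino-acid
    alphabet are rejected individually with a diagnostic.
    """
    meta = read_metadata(metadata_path) if metadata_path else None
    clones: list[Clone] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - EXTENDED_ALPHABET
        if bad:
            log.warning("record %s rejected: non-amino-acid alphabet %s",
                        rec.id, sorted(bad))
            continue
        if meta is not None and rec.id in meta.index:
            row = meta.loc[rec.id]
            get = lambda k, d="": (str(row[k]) if k in row.index else d)
        else:
            tokens = _parse_header_tokens(rec.description)
            if meta is not None and rec.id not in meta.index and not tokens:
                log.warning("record %s lacks metadata; defaulting to phase=pre",
                            rec.id)
            row = {"library_id": tokens.get("lib", ""),
                   "phase": tokens.get("phase", "pre") or "pre",
                   "target": tokens.get("target", ""),
                   "light_isotype": tokens.get("isotype", "lambda") or "lambda",
                   "chain_format": tokens.get("format", "")}
            get = lambda k, d="": (row.get(k) or d)
        fmt = get("chain_format")
        if not fmt:
            fmt = "scfv" if len(seq) > 200 else "heavy"
        if fmt == "scfv":
            heavy, _linker, light = split_scfv(seq)
        elif fmt == "heavy":
            heavy, light = seq, ""
        elif fmt in ("lambda", "kappa", "light"):
            heavy, light = "", seq
        else:
            raise SequenceIOError(f"record {rec.id}: unknown chain format {fmt!r}")
        clones.append(Clone(
            clone_id=rec.id,
            library_id=get("library_id"),
            phase=get("phase", "pre") or "pre",
            target=get("target"),
            heavy_seq=heavy,
            light_seq=light,
            light_isotype=get("light_isotype", "lambda") or "lambda",
        ))
    return CloneSet(clones, provenance=str(fasta_path))


def write_repertoire(cs: CloneSet, fasta_path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    """Write a CloneSet as FASTA plus a metadata TSV.

    Paired clones are emitted as one scFv record (VH + linker + VL); single
    chains as one record with their chain format in the metadata. A
    read -> write -> read round trip preserves every clone field.
    """
    records, rows = [], []
    for c in cs:
        if c.heavy_seq and c.light_seq:
            seq, fmt = c.heavy_seq + SCFV_LINKER + c.light_seq, "scfv"
        elif c.heavy_seq:
            seq, fmt = c.heavy_seq, "heavy"
        elif c.light_seq:
            seq, fmt = c.light_seq, c.light_isotype
        else:
            raise SequenceIOError(f"{c.clone_id}: clone has no sequence")
        records.append(SeqRecord(Seq(seq), id=c.clone_id, description=""))
        rows.append({"clone_id": c.clone_id, "library_id": c.library_id,
                     "phase": c.phase, "target": c.target,
                     "light_isotype": c.light_isotype, "chain_format": fmt})
    SeqIO.write(records, str(fasta_path), "fasta")
    if metadata_path is not None:
        pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
            metadata_path, sep="\t", index=False)


def _as_frame(table) -> pd.DataFrame:
    """Coerce any report object to a DataFrame (duck-typed via to_frame)."""
    if isinstance(table, pd.DataFrame):
        return table
    if hasattr(table, "to_frame"):
        return table.to_frame()
    if isinstance(table, Mapping):
        return pd.DataFrame(table)
    raise TypeError(f"cannot serialize report of type {type(table).__name__}")


def write_report(table, path: str | Path, format: str = "tsv") -> None:
    """Write a report table as TSV or JSON.

    Column order is deterministic; percentage columns are rendered with one
    decimal place. Empty tables produce a header-only file plus a warning.
    """
    path = Path(path)
    if format == "json":
        if hasattr(table, "to_json_dict"):
            payload = table.to_json_dict()
        else:
            frame = _as_frame(table)
            payload = frame.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    frame = _as_frame(table).copy()
    if frame.empty:
        warnings.warn(f"writing empty report to {path}", stacklevel=2)
    for col in frame.columns:
        if "percent" in str(col) or "variability" in str(col):
            frame[col] = frame[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.1f}")
    frame.to_csv(path, sep="\t", index=False)
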