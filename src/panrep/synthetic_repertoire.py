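"""Synthetic sheep-like scFv repertoires with known ground truth.

The generator emulates the design of an immunized-sheep phage-display
experiment: three heavy+lambda pre-selection libraries whose canonical-class
mixtures and CDR-length distributions are configurable, followed by a
panning step that contracts each library to a handful of founder clones
replicated several times. Planted "conserved" positions give the
conservation analysis an exact ground truth to recover.

Scaffolds are synthetic consensus-like sequences derived from the embedded
numbering references (no real germline database entries); substitutions are
uniform over the 19 alternatives except at canonical key residues, which
mutate only within their class-allowed set so that planted class labels
survive mutagenesis exactly.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .canonical_classifier import (CanonicalTemplate, load_templates,
                                   loop_window)
from .diversity_conservation import BiophysicalScheme, consensus, load_scheme
from .kabat_numbering import KabatCode, NumberedChain, load_reference
from .pipeline import number_clone_set
from .region_annotation import region_of
from .sequence_io import Clone, CloneSet

#: Residues used to fill loop positions created by resizing.
LOOP_FILLER = "ADGNSY"

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Loop id -> (canonical window anchor used for resizing).
RESIZE_ANCHORS = {"H1": 35, "H2": 52, "H3": 100, "L1": 27, "L3": 95}

#: Kabat windows over which non-canonical loops are resized.
H3_WINDOW = (95, 102)


class SyntheticConfigError(ValueError):
    """Inconsistent synthetic-repertoire configuration."""


def _check_distribution(name: str, dist: dict) -> dict:
    if not dist:
        raise SyntheticConfigError(f"{name}: empty distribution")
    total = sum(dist.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise SyntheticConfigError(f"{name}: probabilities sum to {total}")
    if any(p < 0 for p in dist.values()):
        raise SyntheticConfigError(f"{name}: negative probability")
    return dist


@dataclass
class SyntheticConfig:
    """Full description of one synthetic library + panning run.

    Defaults reproduce library 1 of the built-in three-library study design
    (110 heavy + 80 lambda pre-selection sequences, six post-selection
    clones in three copies each).
    """

    seed: int
    library_id: str = "lib1"
    n_pre_heavy: int = 110
    n_pre_lambda: int = 80
    heavy_mixture: dict[str, float] = field(default_factory=lambda: {
        "1-1": 0.973, "2-4": 0.010, "1-4": 0.010, "2-1": 0.007})
    lambda_mixture: dict[str, float] = field(default_factory=lambda: {
        "6-1-X": 0.513, "2-1-5": 0.112, "6-1-5": 0.112, "2-1-X": 0.100,
        "5-1-X": 0.080, "5-1-5": 0.053, "5-1-4": 0.030})
    h3_lengths: dict[int, float] = field(default_factory=lambda: {
        9: 0.025, 10: 0.20, 11: 0.15, 12: 0.10, 13: 0.118, 14: 0.145,
        15: 0.12, 16: 0.092, 17: 0.05})
    l3_x_lengths: dict[int, float] = field(default_factory=lambda: {
        10: 0.85, 12: 0.10, 13: 0.05})
    mutation_rate_fw: float = 0.01
    mutation_rate_cdr: float = 0.15
    n_post_clones: int = 6
    post_copies: int = 3
    post_target: str = "SQA"
    planted_conserved: dict[str, list[str]] = field(default_factory=dict)
    planted_mode: str = "identical"   # "identical" | "group"

    def validate(self, templates: tuple[CanonicalTemplate, ...]) -> None:
        if self.seed is None:
            raise SyntheticConfigError("an explicit seed is required")
        _check_distribution("heavy_mixture", self.heavy_mixture)
        _check_distribution("lambda_mixture", self.lambda_mixture)
        _check_distribution("h3_lengths", self.h3_lengths)
        _check_distribution("l3_x_lengths", self.l3_x_lengths)
        if self.planted_mode not in ("identical", "group"):
            raise SyntheticConfigError(
                f"planted_mode must be identical/group, got {self.planted_mode!r}")
        by_loop: dict[tuple[str, str], dict[str, CanonicalTemplate]] = {}
        for t in templates:
            by_loop.setdefault((t.chain_type, t.loop), {})[t.class_label] = t
        for combo in self.heavy_mixture:
            h1, h2 = combo.split("-")
            for loop, label in (("H1", h1), ("H2", h2)):
                if label != "X" and label not in by_loop[("heavy", loop)]:
                    raise SyntheticConfigError(
                        f"no template for heavy {loop} class {label}")
        for combo in self.lambda_mixture:
            l1, l2, l3 = combo.split("-")
            for loop, label in (("L1", l1), ("L2", l2), ("L3", l3)):
                if label != "X" and label not in by_loop[("lambda", loop)]:
                    raise SyntheticConfigError(
                        f"no template for lambda {loop} class {label}")
                if label == "X" and loop != "L3":
                    raise SyntheticConfigError(
                        f"class X only supported for L3, got {loop}")
        l3_lengths = {t.loop_length for t in templates
                      if t.chain_type == "lambda" and t.loop == "L3"}
        clash = l3_lengths & set(self.l3_x_lengths)
        if clash:
            raise SyntheticConfigError(
                f"l3_x_lengths collide with template lengths {sorted(clash)}")

    @classmethod
    def from_dict(cls, doc: dict, *, seed: int) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        payload = {k: v for k, v in doc.items() if k in known and k != "seed"}
        for key in ("h3_lengths", "l3_x_lengths"):
            if key in payload:
                payload[key] = {int(k): float(v)
                                for k, v in payload[key].items()}
        return cls(seed=seed, **payload)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    clones: dict[str, dict] = field(default_factory=dict)
    planted_conserved: dict[str, dict[str, str]] = field(default_factory=dict)
    founders: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"clones": self.clones,
                "planted_conserved": self.planted_conserved,
                "founders": self.founders}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), indent=2) + "\n")


def _template_index(templates: tuple[CanonicalTemplate, ...]
                    ) -> dict[tuple[str, str, str], CanonicalTemplate]:
    return {(t.chain_type, t.loop, t.class_label): t for t in templates}


def _resize_loop(residues: list[tuple[KabatCode, str]],
                 window: tuple[int, int], anchor: int, target: int) -> None:
    """Resize a loop window (in place) to ``target`` residues.

    Extra residues are inserted as lettered codes immediately after the
    anchor; deletions remove lettered codes first, then base codes just
    after the anchor.
    """
    lo, hi = window
    idxs = [i for i, (c, _) in enumerate(residues)
            if lo <= c.number <= hi]
    if not idxs:
        raise SyntheticConfigError(f"empty loop window {window}")
    current = len(idxs)
    if target == current:
        return
    if target > current:
        k = target - current
        anchor_idxs = [i for i in idxs if residues[i][0].number == anchor]
        if not anchor_idxs:
            raise SyntheticConfigError(
                f"anchor {anchor} absent from loop window {window}")
        at = anchor_idxs[-1]
        last_letter = residues[at][0].insertion
        start = string.ascii_uppercase.index(last_letter) + 1 if last_letter else 0
        letters = string.ascii_uppercase[start:start + k]
        if len(letters) < k:
            raise SyntheticConfigError("too many insertions requested")
        for offset, letter in enumerate(letters, start=1):
            # deterministic filler: scaffold construction carries no noise,
            # all stochasticity lives in the mutation model
            aa = LOOP_FILLER[(anchor + offset) % len(LOOP_FILLER)]
            residues.insert(at + offset, (KabatCode(anchor, letter), aa))
    else:
        k = current - target
        lettered = [i for i in idxs if residues[i][0].insertion
                    and residues[i][0].number == anchor]
        after_anchor = [i for i in idxs
                        if not residues[i][0].insertion
                        and residues[i][0].number > anchor]
        order = list(reversed(lettered)) + after_anchor
        if len(order) < k:
            raise SyntheticConfigError(
                f"cannot shorten window {window} to {target} residues")
        for i in sorted(order[:k], reverse=True):
            del residues[i]


def build_variable_domain(chain_type: str, classes: dict[str, str], *,
                          h3_length: int | None = None,
                          x_lengths: dict[str, int] | None = None,
                          rng: np.random.Generator | None = None,
                          templates: tuple[CanonicalTemplate, ...] | None = None,
                          mutation_rate_fw: float = 0.0,
                          mutation_rate_cdr: float = 0.0
                          ) -> tuple[str, dict]:
    """Build one variable-domain sequence on the reference scaffold.

    ``classes`` maps loop ids to canonical class labels ("X" allowed for
    L3, with its length in ``x_lengths``); heavy chains additionally take
    an ``h3_length``. Scaffold construction (loop resizing, key residues)
    is deterministic; the ``rng`` drives only the per-site mutation model,
    so zero mutation rates yield the bare scaffold. Returns (sequence,
    info) where info records classes, loop lengths and the mutation count.
    """
    if templates is None:
        templates = load_templates()
    index = _template_index(templates)
    profile = load_reference(chain_type)
    residues: list[tuple[KabatCode, str]] = list(
        zip(profile.codes, profile.residues))
    protected: dict[KabatCode, frozenset[str]] = {}
    x_lengths = x_lengths or {}

    for loop, label in sorted(classes.items()):
        if label == "X":
            if loop not in x_lengths:
                raise SyntheticConfigError(
                    f"class X for {loop} requires an entry in x_lengths")
            window = loop_window(templates, chain_type, loop)
            target = x_lengths[loop]
            if any(t.loop_length == target for t in templates
                   if t.chain_type == chain_type and t.loop == loop):
                raise SyntheticConfigError(
                    f"{loop} length {target} belongs to a known class; "
                    "not a valid X length")
        else:
            t = index.get((chain_type, loop, label))
            if t is None:
                raise SyntheticConfigError(
                    f"no template for {chain_type} {loop} class {label}")
            window, target = t.window, t.loop_length
        anchor = RESIZE_ANCHORS.get(loop)
        lo, hi = window
        current = sum(1 for c, _ in residues if lo <= c.number <= hi)
        if target != current:
            if anchor is None:
                raise SyntheticConfigError(
                    f"{loop} has no insertion anchor; cannot resize "
                    f"{current} -> {target}")
            _resize_loop(residues, window, anchor, target)
        if label != "X":
            pos = {c: i for i, (c, _) in enumerate(residues)}
            for code, allowed in t.key_residues:
                if code not in pos:
                    raise SyntheticConfigError(
                        f"key residue {code} absent from scaffold")
                protected[code] = allowed
                if residues[pos[code]][1] not in allowed:
                    residues[pos[code]] = (code, sorted(allowed)[0])

    if chain_type == "heavy":
        if h3_length is None:
            raise SyntheticConfigError("heavy chains require an h3_length")
        _resize_loop(residues, H3_WINDOW, RESIZE_ANCHORS["H3"], h3_length)

    n_mut = 0
    if rng is not None and (mutation_rate_fw > 0 or mutation_rate_cdr > 0):
        for i, (code, aa) in enumerate(residues):
            region = region_of(code, chain_type)
            rate = (mutation_rate_cdr if region.startswith("CDR")
                    else mutation_rate_fw)
            if rate <= 0 or rng.random() >= rate:
                continue
            if code in protected:
                options = sorted(protected[code] - {aa})
                if not options:
                    continue
            else:
                options = [x for x in _AA if x != aa]
            residues[i] = (code, options[rng.integers(len(options))])
            n_mut += 1

    seq = "".join(aa for _, aa in residues)
    lengths = {}
    for loop in classes:
        window = loop_window(templates, chain_type, loop)
        lo, hi = window
        lengths[loop] = sum(1 for c, _ in residues if lo <= c.number <= hi)
    if chain_type == "heavy":
        lengths["H3"] = sum(1 for c, _ in residues
                            if H3_WINDOW[0] <= c.number <= H3_WINDOW[1])
    info = {"classes": dict(classes), "loop_lengths": lengths,
            "n_mutations": n_mut}
    return seq, info


def _draw(rng: np.random.Generator, dist: dict) -> object:
    cats = sorted(dist)
    probs = np.array([dist[c] for c in cats], dtype=float)
    probs /= probs.sum()
    return cats[rng.choice(len(cats), p=probs)]


def generate_pre_library(cfg: SyntheticConfig, *,
                         templates: tuple[CanonicalTemplate, ...] | None = None
                         ) -> tuple[CloneSet, GroundTruth]:
    """Generate one pre-selection library per the configured mixtures.

    The first min(n_pre_heavy, n_pre_lambda) clones carry both chains; the
    remainder carry only the more numerous chain (pre-selection heavy and
    lambda pools need not be paired). Fixed seed implies byte-identical
    output.
    """
    if templates is None:
        templates = load_templates()
    cfg.validate(templates)
    rng = np.random.default_rng(cfg.seed)
    clones: list[Clone] = []
    truth = GroundTruth(planted_conserved={
        chain: {} for chain in cfg.planted_conserved})
    n = max(cfg.n_pre_heavy, cfg.n_pre_lambda)
    for i in range(n):
        cid = f"{cfg.library_id}-pre-{i + 1:04d}"
        record: dict = {}
        heavy_seq = light_seq = ""
        if i < cfg.n_pre_heavy:
            h1, h2 = str(_draw(rng, cfg.heavy_mixture)).split("-")
            h3_len = int(_draw(rng, cfg.h3_lengths))
            heavy_seq, info = build_variable_domain(
                "heavy", {"H1": h1, "H2": h2}, h3_length=h3_len, rng=rng,
                templates=templates, mutation_rate_fw=cfg.mutation_rate_fw,
                mutation_rate_cdr=cfg.mutation_rate_cdr)
            record["heavy"] = info
        if i < cfg.n_pre_lambda:
            l1, l2, l3 = str(_draw(rng, cfg.lambda_mixture)).split("-")
            x_lengths = {}
            if l3 == "X":
                x_lengths["L3"] = int(_draw(rng, cfg.l3_x_lengths))
            light_seq, info = build_variable_domain(
                "lambda", {"L1": l1, "L2": l2, "L3": l3},
                x_lengths=x_lengths, rng=rng, templates=templates,
                mutation_rate_fw=cfg.mutation_rate_fw,
                mutation_rate_cdr=cfg.mutation_rate_cdr)
            record["lambda"] = info
        clones.append(Clone(clone_id=cid, library_id=cfg.library_id,
                            phase="pre", heavy_seq=heavy_seq,
                            light_seq=light_seq))
        truth.clones[cid] = record
    cs = CloneSet(clones, provenance=(
        f"synthetic pre-selection library {cfg.library_id} (seed {cfg.seed})"))
    return cs, truth


def simulate_selection(pre: CloneSet, cfg: SyntheticConfig, *,
                       scheme: BiophysicalScheme | None = None
                       ) -> tuple[CloneSet, GroundTruth]:
    """Contract a pre-selection library into a panned post-selection panel.

    ``n_post_clones`` founders are sampled without replacement from the
    clones carrying both chains, weighted toward scaffold-faithful
    sequences (weight 1/(1 + Hamming distance to the pre consensus)).
    Positions listed in ``planted_conserved`` are overwritten with the pre
    consensus residue ("identical" mode) or a random residue from its
    biophysical group ("group" mode); founders are then replicated
    ``post_copies`` times without further mutation.
    """
    if len(pre) == 0:
        raise ValueError("pre CloneSet is empty")
    templates = load_templates()
    cfg.validate(templates)
    if scheme is None:
        scheme = load_scheme()
    rng_select = np.random.default_rng([cfg.seed, 1])
    rng_plant = np.random.default_rng([cfg.seed, 2])

    numbered = {chain: number_clone_set(pre, chain, classify=False)
                for chain in ("heavy", "lambda")}
    cons = {chain: consensus(pre, chain, numbered=numbered[chain])
            for chain in ("heavy", "lambda")}

    candidates = [c for c in pre
                  if c.heavy_seq and c.light_seq
                  and c.clone_id in numbered["heavy"].numbered
                  and c.clone_id in numbered["lambda"].numbered]
    if cfg.n_post_clones > len(candidates):
        raise SyntheticConfigError(
            f"n_post_clones={cfg.n_post_clones} exceeds the "
            f"{len(candidates)} distinct two-chain founders available")

    def distance(clone: Clone) -> int:
        d = 0
        for chain in ("heavy", "lambda"):
            pm = numbered[chain].numbered[clone.clone_id].position_map()
            d += sum(1 for code, aa in pm.items()
                     if cons[chain].get(code) not in (None, aa))
        return d

    weights = np.array([1.0 / (1.0 + distance(c)) for c in candidates])
    weights /= weights.sum()
    founder_idx = rng_select.choice(len(candidates), size=cfg.n_post_clones,
                                    replace=False, p=weights)
    founders = [candidates[int(i)] for i in sorted(founder_idx)]

    planted: dict[str, dict[str, str]] = {}
    post_clones: list[Clone] = []
    truth = GroundTruth(founders=[f.clone_id for f in founders])
    for founder in founders:
        new_seq = {}
        for chain in ("heavy", "lambda"):
            nc = numbered[chain].numbered[founder.clone_id]
            residues = list(nc.residues)
            pos = {c: i for i, (c, _) in enumerate(residues)}
            for code_s in cfg.planted_conserved.get(chain, []):
                code = KabatCode.parse(code_s)
                if code not in pos:
                    raise SyntheticConfigError(
                        f"planted position {code_s} absent from "
                        f"{founder.clone_id} ({chain})")
                ref = cons[chain][code]
                if cfg.planted_mode == "identical":
                    aa = ref
                else:
                    group = sorted(
                        scheme.groups[scheme.group_of(ref)])
                    aa = group[rng_plant.integers(len(group))]
                residues[pos[code]] = (code, aa)
                planted.setdefault(chain, {})[code_s] = cfg.planted_mode
            new_seq[chain] = "".join(aa for _, aa in residues)
        for copy in range(1, cfg.post_copies + 1):
            cid = (f"{cfg.library_id}-{cfg.post_target}-"
                   f"{founder.clone_id.rsplit('-', 1)[-1]}-r{copy}")
            post_clones.append(Clone(
                clone_id=cid, library_id=cfg.library_id, phase="post",
                target=cfg.post_target, heavy_seq=new_seq["heavy"],
                light_seq=new_seq["lambda"]))
            truth.clones[cid] = {"founder": founder.clone_id}
    truth.planted_conserved = planted
    cs = CloneSet(post_clones, provenance=(
        f"synthetic post-selection panel {cfg.library_id}/{cfg.post_target} "
        f"(seed {cfg.seed})"))
    return cs, truth


def load_study_config(path: str | Path | None = None) -> list[dict]:
    """Parse the multi-library study design YAML (built-in three-library
    design by default). Returns the raw per-library dictionaries."""
    if path is None:
        text = resources.files("panrep.data").joinpath(
            "table1_emulation.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return list(doc["libraries"])


def emulate_study(seed: int, path: str | Path | None = None
                  ) -> list[dict]:
    """Generate every library and panel of the study design.

    Returns one dict per library: ``{"config", "pre", "pre_truth",
    "panels": [{"target", "post", "truth"}, ...]}``. Per-library and
    per-panel seeds are derived from ``seed`` so the whole study is
    reproducible from a single integer.
    """
    if seed is None:
        raise SyntheticConfigError("an explicit seed is required")
    results = []
    for lib_i, doc in enumerate(load_study_config(path)):
        panels = doc.get("panels", [])
        base = SyntheticConfig.from_dict(
            {k: v for k, v in doc.items() if k != "panels"},
            seed=int((seed * 1009 + lib_i) % (2**31)))
        pre, pre_truth = generate_pre_library(base)
        lib_out = {"config": base, "pre": pre, "pre_truth": pre_truth,
                   "panels": []}
        for panel_i, panel in enumerate(panels):
            pcfg = dataclasses.replace(
                base,
                seed=int((seed * 1009 + lib_i * 31 + panel_i + 7) % (2**31)),
                post_target=str(panel["target"]),
                n_post_clones=int(panel["n_post_clones"]),
                post_copies=int(panel.get("post_copies", 3)))
            post, post_truth = simulate_selection(pre, pcfg)
            lib_out["panels"].append(
                {"target": pcfg.post_target, "config": pcfg,
                 "post": post, "truth": post_truth})
        results.append(lib_out)
    return results
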