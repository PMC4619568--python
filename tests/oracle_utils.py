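"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: numbering is scored by
exhaustive enumeration of anchor placements instead of pairwise alignment,
and canonical assignment is a direct template scan over explicitly filtered
codes.
"""

import string
from itertools import product

from Bio.Align import substitution_matrices

from panrep.kabat_numbering import KabatCode, load_reference

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _compositions(k, n):
    """All ways to distribute k insertions over n anchors."""
    if n == 1:
        yield (k,)
        return
    for i in range(k + 1):
        for rest in _compositions(k - i, n - 1):
            yield (i,) + rest


def _codes_for_placement(profile, counts):
    """Code list implied by placing counts[anchor] insertions after each
    anchor; matched entries carry their reference index, insertions None."""
    codes, ref_idx = [], []
    for idx, code in enumerate(profile.codes):
        codes.append(code)
        ref_idx.append(idx)
        nxt = profile.codes[idx + 1] if idx + 1 < len(profile.codes) else None
        for anchor in profile.anchors:
            m = counts.get(anchor, 0)
            if m and code.number <= anchor and (
                    nxt is None or nxt.number > anchor):
                last = code.insertion if code.number == anchor else ""
                start = string.ascii_uppercase.index(last) + 1 if last else 0
                for letter in string.ascii_uppercase[start:start + m]:
                    codes.append(KabatCode(anchor, letter))
                    ref_idx.append(None)
    return codes, ref_idx


def brute_force_number(seq, chain_type, open_gap=-10.0, extend_gap=-1.0):
    """Exhaustively score every legal anchor placement of the insertions a
    query carries relative to the reference (no-deletion queries only) and
    return the best-scoring Kabat code list."""
    profile = load_reference(chain_type)
    k = len(seq) - len(profile)
    assert 0 <= k <= 6, "oracle handles insertion-only queries up to +6"
    best_score, best_codes = None, None
    for comp in _compositions(k, len(profile.anchors)):
        counts = dict(zip(profile.anchors, comp))
        codes, ref_idx = _codes_for_placement(profile, counts)
        score = sum(
            _BLOSUM[profile.residues[r], seq[qi]]
            for qi, r in enumerate(ref_idx) if r is not None)
        score += sum(open_gap + extend_gap * (m - 1)
                     for m in counts.values() if m)
        if best_score is None or score > best_score:
            best_score, best_codes = score, codes
    return best_codes


def brute_force_assign(nc, templates):
    """Direct template scan: observed window length by explicit filtering,
    then strict key-residue evaluation of every template."""
    labels = {}
    loops = sorted({t.loop for t in templates if t.chain_type == nc.chain_type})
    residues = dict(nc.residues)
    for loop in loops:
        window = next(t.window for t in templates
                      if t.chain_type == nc.chain_type and t.loop == loop)
        observed = len([c for c in residues
                        if window[0] <= c.number <= window[1]])
        matching = []
        for t in templates:
            if (t.chain_type, t.loop) != (nc.chain_type, loop):
                continue
            if t.loop_length != observed:
                continue
            if all(residues.get(code) in allowed
                   for code, allowed in t.key_residues):
                matching.append(t.class_label)
        if not any(t.loop_length == observed for t in templates
                   if (t.chain_type, t.loop) == (nc.chain_type, loop)):
            labels[loop] = "X"
        elif len(matching) == 1:
            labels[loop] = matching[0]
        elif not matching:
            labels[loop] = "unmatched"
        else:
            raise AssertionError(f"ambiguous oracle match {matching}")
    return labels
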