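import dataclasses

import pytest

from panrep import (Clone, CloneSet, KabatCode, biophysical_group, consensus,
                    conservation_report, conserved_positions, load_scheme,
                    simulate_selection, variability_profile)
from panrep.diversity_conservation import UNGROUPABLE
from panrep.sequence_io import AMINO_ACIDS
from panrep.synthetic_repertoire import build_variable_domain


def _clone_set(seqs, chain="lambda"):
    clones = []
    for i, s in enumerate(seqs):
        kwargs = {"heavy_seq": s} if chain == "heavy" else {"light_seq": s}
        clones.append(Clone(clone_id=f"c{i}", **kwargs))
    return CloneSet(clones)


class TestBiophysicalScheme:
    def test_partition_covers_all_twenty(self, scheme):
        assert len(scheme.groups) == 7
        grouped = {aa for members in scheme.groups.values() for aa in members}
        assert grouped == AMINO_ACIDS

    def test_acidic_pair_same_group(self, scheme):
        assert biophysical_group("D", scheme) == biophysical_group("E", scheme)

    def test_aromatic_vs_acidic_differ(self, scheme):
        assert biophysical_group("F", scheme) != biophysical_group("D", scheme)

    def test_x_is_ungroupable(self, scheme):
        assert biophysical_group("X", scheme) == UNGROUPABLE


class TestVariabilityProfile:
    def test_invariant_position_is_bin_1(self):
        seq, _ = build_variable_domain("lambda",
                                       {"L1": "6", "L2": "1", "L3": "5"})
        cs = _clone_set([seq] * 6)
        vp = variability_profile(cs, "lambda")
        assert (vp.positions["variability"] == 0).all()
        assert (vp.positions["bin"] == 1).all()

    def test_modal_4_of_10_is_60_percent_bin_4(self, lambda_ref):
        """10 chains with modal count 4: variability 100x(1-4/10)=60, bin 4."""
        base = lambda_ref.residues
        variants = []
        for aa, n in (("A", 4), ("S", 3), ("T", 2), ("V", 1)):
            variants += [base[:30] + aa + base[31:]] * n
        vp = variability_profile(_clone_set(variants), "lambda")
        row = vp.positions.loc["31"]
        assert row["coverage"] == 10
        assert row["modal_residue"] == "A"
        assert row["variability"] == pytest.approx(60.0)
        assert row["bin"] == 4

    def test_bin_edges(self, lambda_ref):
        from panrep.diversity_conservation import _bin_of
        edges = (10.0, 25.0, 50.0, 75.0)
        assert [_bin_of(v, edges) for v in (0, 9.9, 10, 24.9, 25, 49.9,
                                            50, 74.9, 75, 100)] == \
            [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_coverage_floor_flags_not_bins(self, lambda_ref):
        cs = _clone_set([lambda_ref.residues] * 3)
        vp = variability_profile(cs, "lambda", coverage_floor=5)
        assert vp.positions["insufficient"].all()
        assert vp.positions["bin"].isna().all()

    def test_low_fw_mutation_rate_keeps_fw_conserved(self, pre_small):
        """With a 1 % per-site FW mutation rate most framework positions sit
        in the lowest variability bin (<10 %)."""
        vp = variability_profile(pre_small, "heavy")
        fw = vp.positions[vp.positions["region"].str.startswith("FW")]
        frac_bin1 = (fw["bin"] == 1).mean()
        assert frac_bin1 >= 0.70
        cdr = vp.positions[vp.positions["region"].str.startswith("CDR")]
        assert cdr["variability"].mean() > fw["variability"].mean()

    def test_variability_bounds(self, pre_small):
        vp = variability_profile(pre_small, "lambda")
        assert ((vp.positions["variability"] >= 0)
                & (vp.positions["variability"] <= 100)).all()

    def test_empty_set_rejected(self):
        with pytest.raises(Exception):
            variability_profile(CloneSet([]), "lambda")


class TestConsensus:
    def test_single_clone_is_its_own_consensus(self, lambda_ref):
        cs = _clone_set([lambda_ref.residues])
        cons = consensus(cs, "lambda")
        assert "".join(cons[c] for c in sorted(cons)) == lambda_ref.residues

    def test_majority_wins(self, lambda_ref):
        base = lambda_ref.residues
        cs = _clone_set([base[:30] + "A" + base[31:],
                         base[:30] + "A" + base[31:],
                         base[:30] + "S" + base[31:]])
        assert consensus(cs, "lambda")[KabatCode(31)] == "A"

    def test_tie_breaks_alphabetically(self, lambda_ref):
        base = lambda_ref.residues
        cs = _clone_set([base[:30] + "S" + base[31:],
                         base[:30] + "A" + base[31:]])
        assert consensus(cs, "lambda")[KabatCode(31)] == "A"


class TestConservedPositions:
    def test_identical_residue_conserved(self, lambda_ref, scheme):
        cs = _clone_set([lambda_ref.residues] * 3)
        cons = consensus(cs, "lambda")
        conserved = conserved_positions(cs, cons, scheme, chain_type="lambda")
        assert conserved == set(cons)

    def test_same_group_substitution_conserved(self, lambda_ref, scheme):
        base = lambda_ref.residues
        i = base.index("GVPDRF") + 3  # position 60, D in the reference
        cs_ref = _clone_set([base] * 3)
        cons = consensus(cs_ref, "lambda")
        test = _clone_set([base, base[:i] + "E" + base[i + 1:]])
        conserved = conserved_positions(test, cons, scheme,
                                        chain_type="lambda")
        assert KabatCode(60) in conserved

    def test_cross_group_substitution_not_conserved(self, lambda_ref, scheme):
        base = lambda_ref.residues
        i = base.index("GVPDRF") + 3
        cons = consensus(_clone_set([base] * 3), "lambda")
        test = _clone_set([base, base[:i] + "K" + base[i + 1:]])
        conserved = conserved_positions(test, cons, scheme,
                                        chain_type="lambda")
        assert KabatCode(60) not in conserved

    def test_position_missing_in_one_clone_not_conserved(self, lambda_ref,
                                                         scheme):
        base = lambda_ref.residues
        i = base.index("SGSSSNIGNNY")
        short = base[:i + 4] + base[i + 6:]  # L1 deletion
        cons = consensus(_clone_set([base] * 3), "lambda")
        conserved = conserved_positions(_clone_set([base, short]), cons,
                                        scheme, chain_type="lambda")
        missing = {KabatCode(28), KabatCode(29)}
        assert not (missing & conserved)

    def test_any_reference_residue_reading_is_laxer(self, lambda_ref, scheme):
        base = lambda_ref.residues
        i = base.index("GVPDRF") + 3  # position 60: consensus D, minority K
        pre = _clone_set([base, base, base[:i] + "K" + base[i + 1:]])
        cons = consensus(pre, "lambda")
        refs = {KabatCode(60): {"D", "K"}}
        test = _clone_set([base[:i] + "K" + base[i + 1:]])
        strict = conserved_positions(test, cons, scheme, chain_type="lambda")
        lax = conserved_positions(test, cons, scheme, chain_type="lambda",
                                  reference_residues={**{c: {r} for c, r in
                                                         cons.items()}, **refs})
        assert KabatCode(60) not in strict
        assert KabatCode(60) in lax

    def test_monotonicity_adding_clones_never_enlarges(self, pre_small,
                                                       post_small, scheme):
        cons = consensus(pre_small, "lambda")
        clones = list(post_small)
        previous = None
        for n in (3, 6, len(clones)):
            subset = CloneSet(clones[:n])
            conserved = conserved_positions(subset, cons, scheme,
                                            chain_type="lambda")
            if previous is not None:
                assert conserved <= previous
            previous = conserved


class TestConservationReport:
    def test_pre_as_post_gives_identical_sets(self, pre_small, scheme):
        report = conservation_report(pre_small, pre_small, scheme)
        for chain in ("heavy", "lambda"):
            for region in ("FW1", "FW3", "CDR3"):
                assert report.positions[("pre", chain, region)] == \
                    report.positions[("post", chain, region)]

    def test_clonal_post_set_conserves_every_covered_position(
            self, pre_small, scheme):
        """Three identical clones judged against their own single-clone
        reference: every covered position is conserved and the total equals
        the number of covered positions."""
        founder = pre_small[0]
        reference = CloneSet([founder])
        copies = CloneSet([dataclasses.replace(founder, clone_id=f"cp{i}")
                           for i in range(3)])
        for chain in ("heavy", "lambda"):
            cons = consensus(reference, chain)
            conserved = conserved_positions(copies, cons, scheme,
                                            chain_type=chain)
            assert conserved == set(cons)

    def test_totals_are_self_consistent(self, pre_small, post_small, scheme):
        report = conservation_report(pre_small, post_small, scheme)
        for phase in ("pre", "post"):
            for chain in ("heavy", "lambda"):
                fw = sum(report.count(phase, chain, f"FW{i}")
                         for i in (1, 2, 3, 4))
                cdr = sum(report.count(phase, chain, f"CDR{i}")
                          for i in (1, 2, 3))
                assert report.total(phase, chain, "FWs") == fw
                assert report.total(phase, chain, "CDRs") == cdr
                assert report.total(phase, chain) == fw + cdr
            assert report.grand_total(phase) == \
                report.total(phase, "heavy") + report.total(phase, "lambda")

    def test_post_panning_contraction_conserves_more(self, pre_small,
                                                     post_small, scheme):
        """Panning collapses the repertoire to a few founders, so the post
        set shows more conserved sites than the diverse pre set."""
        report = conservation_report(pre_small, post_small, scheme)
        assert report.grand_total("post") > report.grand_total("pre")

    def test_empty_input_rejected(self, pre_small, scheme):
        with pytest.raises(ValueError):
            conservation_report(CloneSet([]), pre_small, scheme)
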