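import dataclasses
from collections import Counter

import numpy as np
import pytest

from panrep import (canonical_frequency_table, consensus,
                    conserved_positions, generate_pre_library, KabatCode,
                    number_clone_set, simulate_selection, variability_profile)
from panrep.synthetic_repertoire import (SyntheticConfig,
                                         SyntheticConfigError,
                                         build_variable_domain, emulate_study)


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        cfg = SyntheticConfig(seed=1, heavy_mixture={"1-1": 0.5})
        with pytest.raises(SyntheticConfigError, match="sum"):
            generate_pre_library(cfg)

    def test_unknown_class_rejected(self):
        cfg = SyntheticConfig(seed=1, heavy_mixture={"9-1": 1.0})
        with pytest.raises(SyntheticConfigError, match="no template"):
            generate_pre_library(cfg)

    def test_x_length_colliding_with_template_rejected(self):
        cfg = SyntheticConfig(seed=1, l3_x_lengths={11: 1.0})
        with pytest.raises(SyntheticConfigError, match="collide"):
            generate_pre_library(cfg)


class TestZeroNoiseLimit:
    def test_zero_rates_single_scaffold_identical_clones(self):
        cfg = SyntheticConfig(
            seed=3, n_pre_heavy=5, n_pre_lambda=5,
            heavy_mixture={"1-1": 1.0}, lambda_mixture={"6-1-5": 1.0},
            h3_lengths={12: 1.0}, mutation_rate_fw=0.0, mutation_rate_cdr=0.0)
        cs, _ = generate_pre_library(cfg)
        heavies = {c.heavy_seq for c in cs}
        lights = {c.light_seq for c in cs}
        assert len(heavies) == 1 and len(lights) == 1


class TestDeterminism:
    def test_same_seed_identical_output(self, small_cfg):
        a, _ = generate_pre_library(small_cfg)
        b, _ = generate_pre_library(small_cfg)
        assert [(c.heavy_seq, c.light_seq) for c in a] == \
            [(c.heavy_seq, c.light_seq) for c in b]

    def test_different_seed_differs(self, small_cfg):
        a, _ = generate_pre_library(small_cfg)
        b, _ = generate_pre_library(dataclasses.replace(small_cfg, seed=12))
        assert [(c.heavy_seq, c.light_seq) for c in a] != \
            [(c.heavy_seq, c.light_seq) for c in b]


class TestGroundTruthConsistency:
    def test_classifier_recovers_planted_classes_exactly(self, pre_small,
                                                         small_library,
                                                         templates):
        _, truth = small_library
        for chain, which in (("heavy", "heavy_pair"),
                             ("lambda", "light_triple")):
            ncs = number_clone_set(pre_small, chain, templates=templates)
            assert not ncs.failures
            for cid, ca in ncs.assignments.items():
                planted = truth.clones[cid][chain]["classes"]
                assert ca.labels == planted, cid

    def test_ground_truth_lengths_match_annotation(self, pre_small,
                                                   small_library):
        _, truth = small_library
        ncs = number_clone_set(pre_small, "heavy", classify=False)
        for cid, ra in ncs.annotations.items():
            assert ra.cdr_lengths["H3"] == \
                truth.clones[cid]["heavy"]["loop_lengths"]["H3"]


class TestMixtureRecovery:
    def test_canonical_mixture_recovered_within_binomial_bounds(self):
        mixture = {"1-1": 0.97, "2-4": 0.03}
        cfg = SyntheticConfig(seed=5, n_pre_heavy=200, n_pre_lambda=0,
                              heavy_mixture=mixture)
        cs, _ = generate_pre_library(cfg)
        table = canonical_frequency_table(cs, "heavy_pair")
        n = table.n_total
        for combo, p in mixture.items():
            se = np.sqrt(p * (1 - p) / n)
            observed = table.percents.get(combo, 0.0) / 100.0
            assert abs(observed - p) <= 1.96 * se + 1e-9, combo


class TestSimulateSelection:
    def test_too_many_founders_requested(self, pre_small, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_post_clones=1000)
        with pytest.raises(SyntheticConfigError, match="exceeds"):
            simulate_selection(pre_small, cfg)

    def test_post_metadata(self, post_small, small_cfg):
        assert len(post_small) == small_cfg.n_post_clones * \
            small_cfg.post_copies
        assert all(c.phase == "post" and c.target == "SQA"
                   for c in post_small)

    def test_planted_identical_recovered_and_baseline_subtraction(
            self, pre_small, small_cfg, scheme):
        """In "identical" mode every planted position is conserved, and the
        planted run equals the unplanted control plus the planted set."""
        control_cfg = dataclasses.replace(small_cfg, planted_conserved={})
        control, _ = simulate_selection(pre_small, control_cfg)
        planted_run, truth = simulate_selection(pre_small, small_cfg)
        for chain in ("heavy", "lambda"):
            cons = consensus(pre_small, chain)
            planted = {KabatCode.parse(c)
                       for c in small_cfg.planted_conserved[chain]}
            conserved = conserved_positions(planted_run, cons, scheme,
                                            chain_type=chain)
            baseline = conserved_positions(control, cons, scheme,
                                           chain_type=chain)
            assert planted <= conserved
            assert conserved == baseline | planted
            assert set(truth.planted_conserved[chain]) == \
                {str(c) for c in planted}

    def test_group_mode_conserved_but_variable(self, pre_small, small_cfg,
                                               scheme):
        """Group-conserving planting at an acidic position keeps the site
        conserved under the seven-group rule while allowing variability."""
        cfg = dataclasses.replace(
            small_cfg, planted_conserved={"lambda": ["60"]},
            planted_mode="group", n_post_clones=8, post_copies=1)
        post, _ = simulate_selection(pre_small, cfg)
        cons = consensus(pre_small, "lambda")
        assert cons[KabatCode(60)] in "DE"
        conserved = conserved_positions(post, cons, scheme,
                                        chain_type="lambda")
        assert KabatCode(60) in conserved
        residues = {c.light_seq for c in post}
        vp = variability_profile(post, "lambda", coverage_floor=1)
        assert set(vp.positions.loc["60", "modal_residue"]) <= set("DE")


class TestStudyEmulation:
    def test_unpaired_chains_allowed(self):
        cfg = SyntheticConfig(seed=2, n_pre_heavy=6, n_pre_lambda=3)
        cs, _ = generate_pre_library(cfg)
        assert len(cs.with_chain("heavy")) == 6
        assert len(cs.with_chain("lambda")) == 3
        assert sum(1 for c in cs if c.heavy_seq and c.light_seq) == 3

    def test_seed_required(self):
        with pytest.raises(SyntheticConfigError, match="seed"):
            emulate_study(None)
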