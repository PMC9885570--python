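"""Synthetic landscape generator: determinism, planted-truth recovery,
degree-law realization and enrichment planting."""

import math

import numpy as np
import pytest
from scipy import special, stats

from dgnet.enrichment import hypergeometric_ora
from dgnet.network import build_layer, compute_gene_scores, merge_layers, partition_genes
from dgnet.signatures import SignatureCallingConfig, call_signatures
from dgnet.synthetic import (
    SyntheticSpec,
    generate_annotation_library,
    generate_signature_tables,
    generate_target_table,
    landscape_plan,
    sample_zeta,
    write_synthetic_inputs,
)

SMALL = dict(n_drugs=20, n_genes=300, n_target_genes=40, n_sensitive_genes=280,
             n_null_per_drug=25)


class TestSampleZeta:
    def test_matches_zeta_ccdf(self):
        rng = np.random.default_rng(4)
        alpha = 2.0
        sample = sample_zeta(alpha, 20000, rng)
        norm = special.zeta(alpha, 1)
        for k in (1, 2, 5, 10):
            expected = float(special.zeta(alpha, k) / norm)
            observed = float(np.mean(sample >= k))
            se = math.sqrt(expected * (1 - expected) / sample.size)
            assert abs(observed - expected) <= 4 * se + 1e-9

    def test_truncation_respected(self, rng):
        sample = sample_zeta(1.5, 5000, rng, kmax=30)
        assert sample.max() <= 30 and sample.min() >= 1

    def test_xmin_shifts_support(self, rng):
        sample = sample_zeta(2.5, 1000, rng, xmin=4)
        assert sample.min() >= 4

    def test_invalid_alpha(self, rng):
        with pytest.raises(ValueError):
            sample_zeta(1.0, 10, rng)


class TestTargetTable:
    def test_recomputed_degrees_equal_planted(self):
        spec = SyntheticSpec(seed=5, **SMALL)
        table, planted = generate_target_table(spec)
        net = build_layer(table.pairs, "target")
        scores = compute_gene_scores(net)
        assert {g: k for g, k in scores.kdtn.items()} == planted

    def test_single_gene_covers_all_drugs(self):
        spec = SyntheticSpec(
            seed=2, n_drugs=7, n_genes=1, n_target_genes=1,
            n_sensitive_genes=1, overlap_fraction=1.0,
        )
        table, _ = generate_target_table(spec)
        assert table.drugs == {f"D{i:04d}" for i in range(1, 8)}
        assert len(table.genes) == 1

    def test_every_drug_has_a_target(self):
        spec = SyntheticSpec(seed=9, **SMALL)
        table, _ = generate_target_table(spec)
        assert len(table.drugs) == spec.n_drugs

    def test_same_seed_identical(self):
        spec = SyntheticSpec(seed=3, **SMALL)
        assert generate_target_table(spec)[0] == generate_target_table(spec)[0]


class TestSignatureTables:
    def test_clean_mode_calls_recovered_exactly(self):
        spec = SyntheticSpec(seed=8, **SMALL)
        table, planted = generate_signature_tables(spec)
        got = call_signatures(table, SignatureCallingConfig(adjust_method="none"))
        assert got.pairs == planted.pairs

    def test_zero_overlap_gives_empty_dtsg(self):
        small = dict(SMALL, n_sensitive_genes=260)
        spec = SyntheticSpec(seed=8, overlap_fraction=0.0, **small)
        plan = landscape_plan(spec)
        targets, _ = generate_target_table(spec, plan)
        sigs, calls = generate_signature_tables(spec, plan)
        merged = merge_layers(
            build_layer(targets.pairs, "target"), build_layer(calls.pairs, "sensitive")
        )
        part = partition_genes(compute_gene_scores(merged))
        assert len(part.dtsg) == 0

    def test_anti_correlation_rank_reversal(self):
        # heavy tails (few ties at degree 1) expose the reversal coupling
        spec = SyntheticSpec(
            seed=12, n_drugs=400, n_genes=1000, n_target_genes=150,
            n_sensitive_genes=800, overlap_fraction=0.8,
            target_degree_alpha=1.5, sensitive_degree_alpha=1.5,
            anti_correlation=-1.0,
        )
        plan = landscape_plan(spec)
        shared = plan.shared_genes
        assert len(shared) >= 100
        rho = stats.spearmanr(
            [plan.kdtn[g] for g in shared], [plan.kdsn[g] for g in shared]
        ).statistic
        assert rho <= -0.8

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(
                n_genes=100, n_target_genes=80, n_sensitive_genes=10,
                overlap_fraction=1.0,
            )

    def test_planted_partition_sizes_reproduced(self):
        spec = SyntheticSpec(seed=21, **SMALL)
        plan = landscape_plan(spec)
        targets, _ = generate_target_table(spec, plan)
        sigs, calls = generate_signature_tables(spec, plan)
        merged = merge_layers(
            build_layer(targets.pairs, "target"), build_layer(calls.pairs, "sensitive")
        )
        part = partition_genes(compute_gene_scores(merged))
        assert part.sizes() == plan.partition_sizes()


class TestAnnotationLibrary:
    def test_zero_term_size_rejected(self):
        spec = SyntheticSpec(seed=1, **SMALL)
        with pytest.raises(ValueError):
            generate_annotation_library([(0, "DTG", 2.0)], spec)

    def test_effect_below_one_rejected(self):
        spec = SyntheticSpec(seed=1, **SMALL)
        with pytest.raises(ValueError):
            generate_annotation_library([(10, "DTG", 0.5)], spec)

    def test_planted_term_detected(self):
        # strong planted enrichment recovered at FDR < 0.05 in most replicates
        hits = 0
        n_rep = 20
        small = dict(SMALL, n_sensitive_genes=260)
        for seed in range(n_rep):
            spec = SyntheticSpec(seed=seed, overlap_fraction=0.3, **small)
            plan = landscape_plan(spec)
            lib = generate_annotation_library(
                [(50, "DTG", 6.0)], spec, plan=plan, n_background_terms=10
            )
            shared = set(plan.shared_genes)
            dtg = set(plan.target_genes) - shared
            universe = set(plan.genes)
            res = hypergeometric_ora(dtg, universe, lib, fdr_threshold=0.05)
            hits += any(r.term.startswith("PLANTED") for r in res)
        assert hits >= int(0.9 * n_rep)

    def test_null_effect_is_calibrated(self):
        # effect 1.0 plants nothing: uniform sampling, ORA p approximately uniform
        spec = SyntheticSpec(seed=40, **SMALL)
        plan = landscape_plan(spec)
        lib = generate_annotation_library(
            [(30, "DTG", 1.0)], spec, plan=plan, n_background_terms=0
        )
        shared = set(plan.shared_genes)
        dtg = set(plan.target_genes) - shared
        res = hypergeometric_ora(dtg, set(plan.genes), lib, fdr_threshold=1.0)
        if res:
            assert res[0].p > 1e-4  # no spurious extreme enrichment


class TestBundle:
    def test_byte_identical_under_same_seed(self, tmp_path):
        spec = SyntheticSpec(seed=13, **SMALL)
        p1 = write_synthetic_inputs(spec, tmp_path / "a")
        p2 = write_synthetic_inputs(spec, tmp_path / "b")
        from pathlib import Path

        for key in p1:
            assert Path(p1[key]).read_bytes() == Path(p2[key]).read_bytes(), key

    def test_different_seed_different_tables(self, tmp_path):
        from pathlib import Path

        p1 = write_synthetic_inputs(SyntheticSpec(seed=1, **SMALL), tmp_path / "a")
        p2 = write_synthetic_inputs(SyntheticSpec(seed=2, **SMALL), tmp_path / "b")
        assert Path(p1["targets"]).read_bytes() != Path(p2["targets"]).read_bytes()
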