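import numpy as np
import pytest

from cilioprior.consensus import consensus_merge
from cilioprior.de import DeThresholds, apply_thresholds, concordant_probes, fit_moderated_t
from cilioprior.intervals import IntervalConfig, build_blocks
from cilioprior.io import write_snp_bed
from cilioprior.simulate import (
    SimConfig, gen_expression_pair, gen_reviewer_labels, gen_snp_panel,
    gen_true_classes, write_simulated_inputs,
)

SMALL = SimConfig(seed=7, cluster_sizes=(3, 2, 1, 1, 1), n_indels=2,
                  n_probes=300, dataset_sizes=((5, 5), (6, 4)),
                  n_target_specific=5)


class TestSnpPanel:
    def test_block_builder_recovers_planted_partition(self):
        snps, partition = gen_snp_panel(SMALL)
        blocks = build_blocks(snps, IntervalConfig())
        assert len(blocks) == len(partition) == 5
        got = {frozenset(b.member_snps) for b in blocks}
        assert got == {frozenset(c) for c in partition}

    def test_default_config_mirrors_the_study_panel(self):
        cfg = SimConfig(seed=0)
        snps, partition = gen_snp_panel(cfg)
        assert len(snps) == 76
        assert len(partition) == 54
        assert sum(r.vclass == "indel" for r in snps) == 6
        assert sum(r.vclass == "substitution" for r in snps) == 70
        assert len(build_blocks(snps)) == 54

    def test_single_snp_panel(self):
        snps, partition = gen_snp_panel(SimConfig(seed=1, cluster_sizes=(1,), n_indels=0))
        assert len(snps) == 1 and partition == [[snps.records[0].rsid]]

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        for i, sub in enumerate(("a", "b")):
            snps, _ = gen_snp_panel(SimConfig(seed=5))
            write_snp_bed(snps, tmp_path / f"{sub}.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_infeasible_cluster_spec_rejected(self):
        cfg = SimConfig(seed=0, cluster_sizes=(500,),
                        chrom_lengths={"chr1": 10_000_000})
        with pytest.raises(ValueError, match="infeasible"):
            gen_snp_panel(cfg)


class TestExpressionPair:
    def test_shapes_and_groups_mirror_config(self):
        datasets, annot, truth = gen_expression_pair(SMALL)
        assert [(d.n_fte, d.n_hgsoc) for d in datasets] == [(5, 5), (6, 4)]
        assert len(annot) == 300
        assert len(truth["de_signs"]) == 15  # 5% of 300

    def test_same_seed_reproduces_matrices_exactly(self):
        a, _, _ = gen_expression_pair(SMALL)
        b, _, _ = gen_expression_pair(SMALL)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.matrix.to_numpy(), db.matrix.to_numpy())

    def test_planted_fraction_of_de_genes_lands_inside_blocks(self):
        snps, _ = gen_snp_panel(SMALL)
        blocks = build_blocks(snps)
        _, annot, truth = gen_expression_pair(SMALL, blocks)
        by_label = {b.label: b for b in blocks}
        ann = annot.frame.set_index("probe_id")
        n_de = len(truth["de_signs"])
        assert len(truth["de_in_blocks"]) == round(SMALL.frac_de_in_blocks * n_de)
        for probe in truth["de_in_blocks"]:
            row = ann.loc[probe]
            assert any(b.chrom == row["chrom"]
                       and max(b.start, row["gene_start"]) <= min(b.end, row["gene_end"])
                       for b in by_label.values())
        # non-planted genes never touch a block
        outside = set(ann.index) - set(truth["de_in_blocks"])
        for probe in sorted(outside)[:50]:
            row = ann.loc[probe]
            assert not any(b.chrom == row["chrom"]
                           and max(b.start, row["gene_start"]) <= min(b.end, row["gene_end"])
                           for b in by_label.values())

    def test_null_simulation_controls_retained_fraction(self):
        cfg = SimConfig(seed=11, n_probes=1000, frac_de=0.0, dataset_sizes=((10, 10),))
        (ds,), _, _ = gen_expression_pair(cfg)
        sig = apply_thresholds(fit_moderated_t(ds).table, DeThresholds())
        # BH at 5% on a global null: retained fraction should be tiny
        assert len(sig) / cfg.n_probes <= 0.01

    def test_power_simulation_reaches_high_sensitivity(self):
        cfg = SimConfig(seed=12, n_probes=1000, frac_de=0.05, logfc_effect=3.0)
        datasets, _, truth = gen_expression_pair(cfg)
        planted = set(truth["de_signs"])
        for ds in datasets:
            sig = apply_thresholds(fit_moderated_t(ds).table, DeThresholds())
            assert len(planted & set(sig.index)) / len(planted) >= 0.9

    def test_planted_signs_agree_across_datasets(self):
        datasets, _, truth = gen_expression_pair(SMALL)
        sigs = []
        for ds in datasets:
            res = fit_moderated_t(ds)
            sigs.append(np.sign(res.table.loc[list(truth["de_signs"])]["logFC"]))
        for probe, sign in truth["de_signs"].items():
            assert sigs[0][probe] == sigs[1][probe] == sign


class TestReviewerLabels:
    def test_zero_discordance_reproduces_truth(self):
        truth = gen_true_classes(SMALL, [f"G{i}" for i in range(30)])
        a, b, adj = gen_reviewer_labels(SimConfig(seed=3, discordance_rate=0.0), truth)
        assert a == b == truth and adj == {}

    def test_full_discordance_recovers_truth_via_adjudication(self):
        truth = gen_true_classes(SMALL, [f"G{i}" for i in range(30)])
        a, b, adj = gen_reviewer_labels(SimConfig(seed=3, discordance_rate=1.0), truth)
        assert set(adj) == set(truth)
        records, unresolved = consensus_merge(a, b, adj)
        assert unresolved == []
        assert all(r.adjudicated for r in records)
        assert {r.gene_symbol: r.cls for r in records} == truth

    def test_partial_discordance_consensus_equals_truth_and_is_reproducible(self):
        genes = [f"G{i}" for i in range(100)]
        truth = gen_true_classes(SMALL, genes)
        cfg = SimConfig(seed=21, discordance_rate=0.3)
        a, b, adj = gen_reviewer_labels(cfg, truth)
        records, unresolved = consensus_merge(a, b, adj)
        assert unresolved == []
        assert {r.gene_symbol: r.cls for r in records} == truth
        a2, b2, adj2 = gen_reviewer_labels(cfg, truth)
        assert (a, b, adj) == (a2, b2, adj2)
        assert 0 < len(adj) < len(genes)  # some but not all flipped at rate 0.3


class TestWriteSimulatedInputs:
    def test_emits_complete_consistent_input_set(self, tmp_path):
        manifest = write_simulated_inputs(SMALL, tmp_path)
        for key in ("snps", "annotation", "tissue_a", "tissue_b", "ihc_labels", "tissues"):
            assert (tmp_path / manifest["paths"][key].split("/")[-1]).exists()
        truth = manifest["truth"]
        assert truth["n_clusters"] == 5
        # planted tissue-specific genes come from the DE-inside-blocks pool
        _, annot, expr_truth = gen_expression_pair(
            SMALL, build_blocks(gen_snp_panel(SMALL)[0]))
        in_block_genes = {expr_truth["probe_to_gene"][p] for p in expr_truth["de_in_blocks"]}
        spec = set(truth["specific_genes"])
        assert spec  # non-empty at these settings
        assert spec <= in_block_genes
        assert spec <= set(truth["true_classes"])
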