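import numpy as np
import pandas as pd
import pytest

from bivalency.qpcr import bound_unbound_ratio
from bivalency.quantify import promoter_quant
from bivalency.states import STATE_ORDER, ChromatinState, classify_threshold_table
from bivalency.synthetic_data import (
    SyntheticConfig,
    generate_annotation,
    simulate_expression,
    simulate_qpcr,
    simulate_tags,
    simulate_truth,
)


class TestAnnotation:
    def test_spacing_and_uniqueness(self):
        cfg = SyntheticConfig(n_genes=100, chrom_len=1_000_000, seed=1)
        tss, sizes, gene_sets = generate_annotation(cfg)
        positions = sorted(r.tss for r in tss)
        assert len(tss) == 100
        assert len({r.gene_id for r in tss}) == 100
        assert min(b - a for a, b in zip(positions, positions[1:])) >= 8000
        assert positions[0] >= cfg.flank and positions[-1] <= 1_000_000 - cfg.flank
        assert not (gene_sets["testis_specific"].members & gene_sets["ovary_specific"].members)

    def test_same_seed_reproduces(self):
        cfg = SyntheticConfig(n_genes=50, chrom_len=1_000_000, seed=9)
        a, _, sets_a = generate_annotation(cfg)
        b, _, sets_b = generate_annotation(cfg)
        assert [(r.tss, r.strand) for r in a] == [(r.tss, r.strand) for r in b]
        assert sets_a["testis_specific"].members == sets_b["testis_specific"].members

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(SyntheticConfig(n_genes=10_000, chrom_len=1_000_000))


class TestTags:
    def test_zero_background_confines_tags_to_window(self):
        cfg = SyntheticConfig(
            n_genes=1, chrom_len=100_000, background_rate=0.0, seed=2
        )
        tss, _, _ = generate_annotation(cfg)
        truth = simulate_truth(cfg, [r.gene_id for r in tss])
        truth.state_t0[tss[0].gene_id] = ChromatinState.BIVALENT
        libs = simulate_tags(truth, tss, cfg)
        window = (tss[0].tss - 2000, tss[0].tss + 2000)
        for lib in libs.values():
            pos = lib.tags["pos"].to_numpy()
            assert np.all((pos >= window[0]) & (pos < window[1]))

    def test_determinism(self):
        cfg = SyntheticConfig(n_genes=20, chrom_len=1_000_000, seed=5)
        tss, _, _ = generate_annotation(cfg)
        truth = simulate_truth(cfg, [r.gene_id for r in tss])
        a = simulate_tags(truth, tss, cfg)
        b = simulate_tags(truth, tss, cfg)
        for mark in a:
            assert np.array_equal(a[mark].tags["pos"].to_numpy(), b[mark].tags["pos"].to_numpy())

    def test_deeper_libraries_do_not_hurt_recovery(self):
        """Doubling all rates (a paired-seed comparison in a low-depth
        regime) does not reduce classification accuracy."""
        correct = {1.0: 0, 2.0: 0}
        total = 0
        for seed in range(10):
            for scale in (1.0, 2.0):
                cfg = SyntheticConfig(
                    n_genes=60,
                    chrom_len=15_000_000,
                    lambda_h3=7.5 * scale,
                    background_rate=0.002 * scale,
                    seed=seed,
                )
                tss, sizes, _ = generate_annotation(cfg)
                truth = simulate_truth(cfg, [r.gene_id for r in tss])
                libs = simulate_tags(truth, tss, cfg)
                quant = promoter_quant(
                    tss, libs["H3K4me3"], libs["H3K27me3"], libs["H3"], chrom_sizes=sizes
                )
                table = classify_threshold_table(quant, "t0")
                correct[scale] += sum(
                    table.states[g] is truth.state_t0[g] for g in truth.genes
                )
            total += 60
        assert correct[2.0] >= correct[1.0]

    def test_overdispersed_counts_have_extra_variance(self):
        cfg = SyntheticConfig(
            n_genes=200, chrom_len=20_000_000, background_rate=0.0, overdispersion=2.0, seed=3
        )
        tss, _, _ = generate_annotation(cfg)
        truth = simulate_truth(cfg, [r.gene_id for r in tss])
        truth.state_t0 = {g: ChromatinState.NEITHER for g in truth.genes}
        libs = simulate_tags(truth, tss, cfg)
        # H3 per-window mean 30; NB with shape 2 has variance 30 + 450
        h3_counts = [
            np.sum((libs["H3"].tags["pos"].to_numpy() >= r.tss - 2000)
                   & (libs["H3"].tags["pos"].to_numpy() < r.tss + 2000))
            for r in tss
        ]
        assert np.var(h3_counts) > 2 * np.mean(h3_counts)


class TestExpression:
    def test_zero_sd_hits_state_means(self):
        cfg = SyntheticConfig(n_genes=40, chrom_len=2_000_000, expression_sd=0.0, seed=4)
        tss, _, _ = generate_annotation(cfg)
        truth = simulate_truth(cfg, [r.gene_id for r in tss])
        expr = simulate_expression(truth, cfg)
        for gene, value in zip(expr["gene_id"], expr["value"]):
            assert value == cfg.expression_means[truth.state_t0[gene]]

    def test_determinism(self):
        cfg = SyntheticConfig(n_genes=30, chrom_len=2_000_000, seed=6)
        tss, _, _ = generate_annotation(cfg)
        truth = simulate_truth(cfg, [r.gene_id for r in tss])
        pd.testing.assert_frame_equal(
            simulate_expression(truth, cfg), simulate_expression(truth, cfg)
        )


class TestQpcrSimulation:
    def test_noiseless_inverse_is_exact(self):
        plate = simulate_qpcr({"Sox9": 0.5, "Wnt4": 2.0}, noise_sd_ct=0.0, n_replicates=2)
        for row in plate.itertuples(index=False):
            truth = {"Sox9": 0.5, "Wnt4": 2.0}[row.target]
            assert bound_unbound_ratio(row.ct_bound, row.ct_unbound) == pytest.approx(truth)

    def test_noisy_mean_near_truth(self):
        plate = simulate_qpcr({"Sox9": 0.5}, noise_sd_ct=0.2, n_replicates=30, seed=1)
        ratios = [
            bound_unbound_ratio(b, u)
            for b, u in zip(plate["ct_bound"], plate["ct_unbound"])
        ]
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.5) <= 3 * sem

    def test_fixed_seed_reproduces_csv_bytes(self, tmp_path):
        a = simulate_qpcr({"Sox9": 0.5}, noise_sd_ct=0.3, seed=12)
        b = simulate_qpcr({"Sox9": 0.5}, noise_sd_ct=0.3, seed=12)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()


class TestConfigValidation:
    def test_proportions_and_matrix_checked(self):
        with pytest.raises(ValueError):
            SyntheticConfig(state_proportions={s: 0.3 for s in STATE_ORDER})
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError):
            SyntheticConfig(transition_matrix=bad)
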