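import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from markdyn.consensus import call_consensus, filter_by_qvalue
from markdyn.diffbind import count_fragments
from markdyn.intervals import GenomicInterval, any_overlap_flags
from markdyn.motifs import gc_content
from markdyn.simulate import (
    SimulationConfig,
    simulate_count_benchmark,
    simulate_genome,
    simulate_motif_sequences,
    simulate_study,
    simulate_tissue_matrix,
    toy_pwms,
)


class TestConfig:
    def test_probability_validation(self):
        with pytest.raises(ValueError, match="probabilities"):
            SimulationConfig(peak_dropout_prob=1.4)

    def test_corr_fractions_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(corr_class_fractions=(0.6, 0.6, 0.2))

    def test_occupancy_rates_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            SimulationConfig(occupancy_rates=(0.7, 0.5, 0.5, 0.5))

    def test_yaml_roundtrip_rejects_unknown_keys(self, tmp_path):
        cfg = small_config(seed=3)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg
        path.write_text(path.read_text() + "bogus_knob: 1\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            SimulationConfig.from_yaml(path)


class TestGenome:
    def test_same_seed_identical_fasta(self):
        cfg = small_config(seed=9)
        g1, genes1 = simulate_genome(cfg)
        g2, genes2 = simulate_genome(cfg)
        assert g1 == g2
        assert genes1 == genes2

    def test_promoter_gc_concentrates_at_target(self):
        cfg = SimulationConfig(seed=2)  # default size: 400 genes
        genome, genes = simulate_genome(cfg)
        seqs = []
        for g in genes:
            win = g.promoter()
            seqs.append(genome[g.chrom][win.start : win.end])
        pooled, _ = gc_content(seqs)
        assert abs(pooled - cfg.promoter_gc) < 0.03

    def test_both_strands_represented_and_no_overlap(self):
        _, genes = simulate_genome(small_config(seed=4))
        assert {g.strand for g in genes} == {"+", "-"}
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError, match="enlarge"):
            simulate_genome(SimulationConfig(n_genes=1000, chrom_length=50_000))


class TestPeaks:
    def test_noiseless_limit_consensus_equals_truth(self, noiseless_study):
        st = noiseless_study
        gene_idx = {g.gene_id: i for i, g in enumerate(st.genes)}
        for ti, tp in enumerate(st.config.timepoints):
            cs = call_consensus(
                [filter_by_qvalue(r) for r in st.replicate_peaks[("H3K18La", tp)]],
                2,
            )
            truth = sorted(
                (r.chrom, r.start, r.end)
                for r in st.truth.peak_table.itertuples()
                if st.truth.occupancy[gene_idx[r.gene_id], ti, 0]
            )
            got = sorted(
                (p.interval.chrom, p.interval.start, p.interval.end)
                for p in cs.peaks
            )
            assert got == truth

    def test_dropout_support_arithmetic(self):
        # P(>=2 of 3 replicates survive dropout p=0.1) = 1 - 3 p^2 (1-p) - p^3
        st = simulate_study(SimulationConfig(seed=21))
        gene_idx = {g.gene_id: i for i, g in enumerate(st.genes)}
        fracs = []
        for ti, tp in enumerate(st.config.timepoints):
            cs = call_consensus(
                [filter_by_qvalue(r) for r in st.replicate_peaks[("H3K18La", tp)]],
                2,
            )
            truth_ivs = [
                GenomicInterval(r.chrom, r.start, r.end)
                for r in st.truth.peak_table.itertuples()
                if st.truth.occupancy[gene_idx[r.gene_id], ti, 0]
            ]
            flags = any_overlap_flags(truth_ivs, cs.intervals)
            fracs.append(np.mean(flags))
        assert abs(np.mean(fracs) - 0.972) < 0.02

    def test_noise_singletons_never_reach_consensus(self, small_study):
        st = small_study
        gene_idx = {g.gene_id: i for i, g in enumerate(st.genes)}
        for ti, tp in enumerate(st.config.timepoints):
            cs = call_consensus(
                [filter_by_qvalue(r) for r in st.replicate_peaks[("H3K18La", tp)]],
                2,
            )
            truth_ivs = [
                GenomicInterval(r.chrom, r.start, r.end)
                for r in st.truth.peak_table.itertuples()
                if st.truth.occupancy[gene_idx[r.gene_id], ti, 0]
            ]
            # every consensus peak overlaps a true locus
            assert all(any_overlap_flags(cs.intervals, truth_ivs))

    def test_qvalues_split_at_threshold(self, small_study):
        for reps in small_study.replicate_peaks.values():
            for peaks in reps:
                qs = np.array([p.neglog10_q for p in peaks])
                assert ((qs > 6.0) | (qs < 6.0)).all()


class TestCounts:
    def test_same_seed_identical_counts(self):
        cfg = small_config(seed=13)
        a = simulate_study(cfg).counts.counts
        b = simulate_study(cfg).counts.counts
        assert (a.values == b.values).all()

    def test_fragments_reproduce_the_count_matrix(self, small_study):
        st = small_study
        cm = count_fragments(st.fragments(), st.merged_peaks,
                             dict(st.counts.conditions))
        assert (cm.counts.values == st.counts.counts.loc[cm.counts.index].values).all()
        assert (cm.library_sizes == st.counts.library_sizes[cm.samples]).all()

    def test_poisson_limit_variance_matches_mean(self):
        cm, _ = simulate_count_benchmark(
            3000, 10, phi=0.0, library_factor_sd=0.0, seed=1
        )
        y = cm.counts.values
        ratio = y.var(axis=1, ddof=1) / np.maximum(y.mean(axis=1), 1e-9)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_planted_db_benchmark_recovered(self):
        from markdyn.diffbind import differential_binding

        cm, is_db = simulate_count_benchmark(
            1000, 3, phi=0.1, fold_change=4.0, db_fraction=0.2, seed=2
        )
        res = differential_binding(cm, "A", "B")
        assert (res.fdr[is_db] < 0.01).mean() >= 0.8


class TestExpression:
    def test_noiseless_positive_class_correlates_exactly(self):
        cfg = small_config(seed=7, expression_noise_sd=0.0)
        st = simulate_study(cfg)
        tab = st.truth.gene_table
        ramp = np.log(cfg.corr_fold ** (np.arange(len(cfg.timepoints)) /
                                        (len(cfg.timepoints) - 1)))
        for rec in tab[tab.corr_class == "positive"].itertuples():
            e = np.log(st.expression.loc[rec.gene_id].values)
            assert np.corrcoef(ramp, e)[0, 1] == pytest.approx(1.0)
        for rec in tab[tab.corr_class == "negative"].itertuples():
            e = np.log(st.expression.loc[rec.gene_id].values)
            assert np.corrcoef(ramp, e)[0, 1] == pytest.approx(-1.0)

    def test_same_seed_identical_expression(self):
        cfg = small_config(seed=8)
        assert simulate_study(cfg).expression.equals(simulate_study(cfg).expression)


class TestFootprintsAndMotifs:
    def test_every_footprint_inside_its_parent_promoter(self, small_study):
        st = small_study
        promoters = {g.gene_id: g.promoter() for g in st.genes}
        for r in st.footprints.itertuples():
            win = promoters[r.gene_id]
            assert win.start <= r.start < r.end <= win.end

    def test_planted_instances_present_in_genome(self, small_study):
        st = small_study
        pwm = [p for p in toy_pwms() if p.motif_id == "GCBOX_TOY"][0]
        from markdyn.motifs import pwm_threshold, scan_region

        thr = pwm_threshold(pwm, 1e-3)
        planted = st.footprints[st.footprints.motif_planted]
        assert len(planted) > 0
        hit = sum(
            bool(scan_region(st.genome[r.chrom][r.start : r.end], pwm, thr))
            for r in planted.itertuples()
        )
        # instances are sampled from the PWM; most match near-consensus
        assert hit / len(planted) > 0.5

    def test_extreme_plant_rates_give_extreme_tables(self):
        from markdyn.motifs import enrich_motifs

        fg, bg, fg_flags, bg_flags = simulate_motif_sequences(
            60, 60, plant_rate_fg=1.0, plant_rate_bg=0.0, rng=3
        )
        assert fg_flags.all() and not bg_flags.any()
        res = enrich_motifs(fg, bg, toy_pwms())
        assert res.motif_id.iloc[0] == "GCBOX_TOY"
        assert res.fisher_p.iloc[0] < 1e-10


class TestTissueMatrix:
    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=14)
        a, _ = simulate_tissue_matrix(cfg)
        b, _ = simulate_tissue_matrix(cfg)
        assert a.equals(b)

    def test_within_block_phi_exceeds_between_block_without_noise(self):
        from markdyn.tissues import phi_matrix

        occ, blocks = simulate_tissue_matrix(
            SimulationConfig(seed=15, tissue_noise_flip=0.0)
        )
        phi = phi_matrix(occ)
        within, between = [], []
        for a in occ.columns:
            for b in occ.columns:
                if a >= b:
                    continue
                (within if blocks[a] == blocks[b] else between).append(phi.loc[a, b])
        assert min(within) > max(between)


def test_full_study_regeneration_is_identical():
    cfg = small_config(seed=30)
    a, b = simulate_study(cfg), simulate_study(cfg)
    assert a.genome == b.genome
    assert a.truth.gene_table.equals(b.truth.gene_table)
    assert a.truth.peak_table.equals(b.truth.peak_table)
    assert np.array_equal(a.truth.occupancy, b.truth.occupancy)
    for key in a.replicate_peaks:
        assert a.replicate_peaks[key] == b.replicate_peaks[key]
    assert a.footprints.equals(b.footprints)
    assert a.tissue_occupancy.equals(b.tissue_occupancy)
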