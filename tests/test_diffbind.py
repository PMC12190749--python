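import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from markdyn.consensus import MergedPeak
from markdyn.diffbind import (
    CountMatrix,
    bh_adjust,
    bin_counts,
    bin_tmm_factors,
    common_dispersion_mle,
    count_fragments,
    differential_binding,
    estimate_dispersion,
    nb_lrt_test,
    pca_peaks,
    tmm_norm_factors,
)
from markdyn.intervals import GenomicInterval


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def mp(start, end, chrom="chr1"):
    return MergedPeak(GenomicInterval(chrom, start, end), ("c",))


def make_cm(counts, conditions, lib=None):
    df = pd.DataFrame(
        counts, index=[f"pk{i}" for i in range(len(counts))],
        columns=list(conditions),
    )
    lib = lib or {s: 1e6 for s in conditions}
    return CountMatrix(df, pd.Series(lib), pd.Series(conditions))


class TestCountFragments:
    def test_midpoint_membership_and_library_size(self):
        frags = {
            "s1": [gi(100, 200), gi(120, 220), gi(150, 250),  # mids in peak
                   gi(900, 1000), gi(2000, 2100)]             # mids outside
        }
        cm = count_fragments(frags, [mp(100, 300)])
        assert cm.counts.loc["chr1:100-300", "s1"] == 3
        assert cm.library_sizes["s1"] == 5

    def test_no_peaks_empty_matrix_keeps_library_sizes(self):
        cm = count_fragments({"s1": [gi(0, 100)]}, [])
        assert cm.counts.shape == (0, 1)
        assert cm.library_sizes["s1"] == 1

    def test_midpoint_at_peak_end_not_counted(self):
        # fragment [90, 110) has midpoint 100 = peak end (half-open)
        cm = count_fragments({"s1": [gi(90, 110)]}, [mp(0, 100)])
        assert cm.counts.values.sum() == 0

    def test_zero_fragment_sample_rejected(self):
        with pytest.raises(ValueError, match="zero fragments"):
            count_fragments({"s1": []}, [mp(0, 100)])

    def test_fragment_conservation(self, small_study):
        frags = small_study.fragments()
        cm = count_fragments(frags, small_study.merged_peaks)
        for s in cm.samples:
            assert cm.counts[s].sum() <= cm.library_sizes[s]


def tmm_oracle(counts, lib, m_trim=0.30, a_trim=0.05):
    """Independent scalar reimplementation of the trimmed-mean recipe."""
    counts = np.asarray(counts, float)
    lib = np.asarray(lib, float)
    ref = int(np.argmin(np.abs(np.log(lib) - np.log(lib).mean())))
    raw = []
    for s in range(counts.shape[1]):
        if s == ref:
            raw.append(1.0)
            continue
        M, A, W = [], [], []
        for y_s, y_r in zip(counts[:, s], counts[:, ref]):
            if y_s > 0 and y_r > 0:
                ps, pr = y_s / lib[s], y_r / lib[ref]
                M.append(np.log2(ps / pr))
                A.append(0.5 * np.log2(ps * pr))
                W.append(
                    1.0
                    / (
                        (lib[s] - y_s) / (lib[s] * y_s)
                        + (lib[ref] - y_r) / (lib[ref] * y_r)
                    )
                )
        M, A, W = map(np.array, (M, A, W))
        keep = np.ones(len(M), bool)
        for v, trim in ((M, m_trim), (A, a_trim)):
            lo, hi = np.quantile(v, [trim, 1 - trim])
            keep &= (v >= lo) & (v <= hi)
        raw.append(2 ** (np.sum(W[keep] * M[keep]) / np.sum(W[keep])))
    raw = np.array(raw)
    return raw / np.exp(np.mean(np.log(raw)))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        y = np.tile(np.arange(1, 101)[:, None], (1, 2))
        f = tmm_norm_factors(y, [y[:, 0].sum()] * 2)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 200) + 1
        y = np.stack([a, 2 * a], axis=1)
        f = tmm_norm_factors(y, [a.sum(), 2 * a.sum()])
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_composition_biased_sample_matches_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(80, 300) + 1
        y = np.stack([base, base, base.copy()], axis=1).astype(float)
        y[:30, 2] *= 20  # 10% of bins grab extra signal in sample 3
        lib = y.sum(axis=0)
        got = tmm_norm_factors(y, lib)
        want = tmm_oracle(y, lib)
        assert np.allclose(got, want, rtol=1e-10)
        assert got[2] < 1.0  # composition bias pushes its factor down

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            tmm_norm_factors(np.ones((10, 1)), [100.0])

    def test_bin_factors_on_fragments(self, small_study):
        frags = small_study.fragments()
        sizes = {c: len(s) for c, s in small_study.genome.items()}
        f = bin_tmm_factors(frags, sizes, 10_000)
        assert np.isclose(np.exp(np.mean(np.log(f.values))), 1.0)
        bc = bin_counts(frags, sizes, 10_000)
        assert bc.values.sum() == sum(len(v) for v in frags.values())


class TestDispersion:
    def test_poisson_counts_hit_the_floor_region(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(100, size=(2000, 6))
        cm = make_cm(y, {f"s{i}": "A" if i < 3 else "B" for i in range(6)})
        phi = estimate_dispersion(cm)
        assert np.median(phi) < 0.02

    def test_constant_counts_floor(self):
        y = np.full((5, 4), 7)
        cm = make_cm(y, {f"s{i}": "A" for i in range(4)})
        phi = estimate_dispersion(cm, shrink=0.0)
        assert np.allclose(phi, 1e-4)

    def test_parameter_recovery_phi_02(self):
        rng = np.random.default_rng(3)
        r = 1 / 0.2
        mu = 100.0
        y = rng.negative_binomial(r, r / (r + mu), size=(2000, 20))
        cm = make_cm(y, {f"s{i}": "A" if i < 10 else "B" for i in range(20)})
        phi = estimate_dispersion(cm, shrink=0.0)
        assert 0.1 <= np.median(phi) <= 0.3

    def test_common_mle_recovers_truth(self):
        from markdyn.simulate import simulate_count_benchmark

        cm, _ = simulate_count_benchmark(2000, 3, phi=0.1, seed=9)
        est = common_dispersion_mle(cm)
        assert 0.07 <= est <= 0.13


class TestNbLrt:
    def test_identical_groups_give_p_one(self):
        y = np.tile([[10, 10, 10, 10]], (5, 1))
        cm = make_cm(y, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = nb_lrt_test(cm, "A", "B", np.full(5, 0.1))
        assert np.allclose(res.p_value, 1.0)
        assert np.allclose(res.log2_fold_change, 0.0)

    def test_all_zero_peak_flagged(self):
        y = np.array([[0, 0, 0, 0], [5, 6, 50, 60]])
        cm = make_cm(y, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = nb_lrt_test(cm, "A", "B", np.full(2, 0.1))
        assert res.all_zero.iloc[0]
        assert res.p_value.iloc[0] == 1.0 and res.log2_fold_change.iloc[0] == 0.0

    def test_planted_eightfold_shift_detected(self):
        # 500 independent simulated peaks in one vectorized fit
        rng = np.random.default_rng(4)
        phi = 0.05
        r = 1 / phi
        mu_a, mu_b = 50.0, 400.0
        y = np.hstack(
            [
                rng.negative_binomial(r, r / (r + mu_a), size=(500, 3)),
                rng.negative_binomial(r, r / (r + mu_b), size=(500, 3)),
            ]
        )
        cm = make_cm(y, {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)})
        res = nb_lrt_test(cm, "A", "B", np.full(500, phi))
        assert (res.p_value < 1e-3).mean() >= 0.95
        assert np.median(res.log2_fold_change) == pytest.approx(3.0, abs=0.3)

    def test_group_relabel_flips_lfc_and_keeps_p(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(40, size=(50, 6))
        cm = make_cm(y, {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)})
        ab = nb_lrt_test(cm, "A", "B", np.full(50, 0.1))
        ba = nb_lrt_test(cm, "B", "A", np.full(50, 0.1))
        assert np.allclose(ab.p_value, ba.p_value, rtol=1e-6, atol=1e-12)
        assert np.allclose(ab.log2_fold_change, -ba.log2_fold_change, atol=1e-6)

    def test_offsets_absorb_depth(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(100, size=(100, 3))
        y = np.hstack([base, 4 * base])  # sample depth x4, no real change
        lib = {f"a{i}": 1e6 for i in range(3)} | {f"b{i}": 4e6 for i in range(3)}
        cm = make_cm(
            y,
            {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)},
            lib=lib,
        )
        res = nb_lrt_test(cm, "A", "B", np.full(100, 0.1))
        assert np.abs(np.median(res.log2_fold_change)) < 0.1


class TestBH:
    def test_textbook_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def bh_oracle(self, p):
        # exhaustive definition: q_i = min over j with p_j >= p_i of p_j * n / rank_j
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(n)
        for pos, i in enumerate(order):
            candidates = [
                p[order[k]] * n / (k + 1) for k in range(pos, n)
            ]
            q[i] = min(1.0, min(candidates))
        return q

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_exhaustive_definition_and_statsmodels(self, p):
        got = bh_adjust(p)
        assert np.allclose(got, self.bh_oracle(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(got, q_sm, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPCA:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(7)
        y = rng.poisson(50, size=(200, 2))
        y = np.hstack([y, y[:, [0]]])  # third sample duplicates the first
        cm = make_cm(y, {"s1": "A", "s2": "B", "s3": "A"})
        scores, varexp = pca_peaks(cm)
        assert np.allclose(scores.loc["s1"], scores.loc["s3"], atol=1e-8)
        assert np.all(varexp >= 0) and varexp.sum() <= 1 + 1e-9

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(8)
        a = rng.poisson(20, size=(300, 3))
        b = rng.poisson(20, size=(300, 3)) + np.tile(
            rng.poisson(60, size=(300, 1)), (1, 3)
        )
        cm = make_cm(
            np.hstack([a, b]),
            {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)},
        )
        scores, _ = pca_peaks(cm)
        pc1 = scores.PC1.values
        assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:])) or (
            np.sign(pc1[:3]).tolist() != np.sign(pc1[3:]).tolist()
        )
        assert (np.sign(pc1[:3]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[3:]) == np.sign(pc1[3])).all()
        assert np.sign(pc1[0]) != np.sign(pc1[3])

    def test_constant_matrix_rejected(self):
        y = np.full((10, 3), 5)
        cm = make_cm(y, {"s1": "A", "s2": "A", "s3": "B"})
        with pytest.raises(ValueError, match="variance"):
            pca_peaks(cm)

    def test_needs_three_samples(self):
        y = np.ones((10, 2), dtype=int)
        cm = make_cm(y, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError):
            pca_peaks(cm)


def test_differential_binding_auto_uses_common_dispersion_smoothly():
    from markdyn.simulate import simulate_count_benchmark

    cm, is_db = simulate_count_benchmark(
        500, 3, phi=0.1, fold_change=4.0, db_fraction=0.2, seed=10
    )
    res = differential_binding(cm, "A", "B")
    assert (res.loc[is_db, "fdr"] < 0.01).mean() > 0.7
    assert (res.loc[~is_db, "p_value"] < 0.05).mean() < 0.12
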