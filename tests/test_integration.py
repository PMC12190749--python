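import math

import numpy as np
import pandas as pd
import pytest

from markdyn.genes import FeatureAssignment, FeatureClass, GeneModel
from markdyn.integration import (
    OccupancyLedger,
    build_occupancy_ledger,
    colocalization_fraction,
    cooccupancy_fractions,
    correlate_binding_expression,
    geneset_enrichment,
    transition_flows,
)
from markdyn.intervals import GenomicInterval


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def make_partition(binding_rows, expr_rows, timepoints=("t1", "t2", "t3")):
    binding = pd.DataFrame(binding_rows, columns=list(timepoints)).rename(
        index=lambda i: f"pk{i}"
    )
    expr = pd.DataFrame(expr_rows, columns=list(timepoints)).rename(
        index=lambda i: f"g{i}"
    )
    pm = pd.DataFrame(
        {
            "peak_id": binding.index,
            "gene_id": expr.index[: len(binding)],
            "start": range(len(binding)),
        }
    )
    return correlate_binding_expression(binding, expr, pm)


class TestCorrelationPartition:
    def test_exact_linear_relations(self):
        part = make_partition([[1, 2, 3], [3, 2, 1]], [[10, 20, 30], [10, 20, 30]])
        assert list(part.pairs.corr_class) == ["positive", "negative"]
        assert part.pairs.pearson_r.iloc[0] == pytest.approx(1.0)
        assert part.pairs.pearson_r.iloc[1] == pytest.approx(-1.0)

    def test_hand_computed_three_point_r(self):
        # r((1,2,3),(1,2,2)) = 1/sqrt(4/3) = 0.866..., above the 0.8 threshold
        part = make_partition([[1, 2, 3]], [[1, 2, 2]])
        assert part.pairs.pearson_r.iloc[0] == pytest.approx(math.sqrt(3) / 2)
        assert part.pairs.corr_class.iloc[0] == "positive"

    def test_constant_vector_flagged_neutral(self):
        part = make_partition([[5, 5, 5]], [[1, 2, 3]])
        assert part.pairs.flagged.iloc[0]
        assert part.pairs.corr_class.iloc[0] == "neutral"
        assert np.isnan(part.pairs.pearson_r.iloc[0])

    def test_gene_representative_is_max_abs_r_with_coordinate_tiebreak(self):
        binding = pd.DataFrame(
            [[1, 2, 3], [1, 2, 4], [3, 2, 1]],
            columns=["t1", "t2", "t3"],
            index=["pkA", "pkB", "pkC"],
        )
        expr = pd.DataFrame([[1, 2, 3]], columns=["t1", "t2", "t3"], index=["g1"])
        pm = pd.DataFrame(
            {
                "peak_id": ["pkA", "pkB", "pkC"],
                "gene_id": ["g1", "g1", "g1"],
                "start": [500, 100, 900],
            }
        )
        part = correlate_binding_expression(binding, expr, pm)
        rep = part.genes.set_index("gene_id").loc["g1"]
        # pkA (r=1) and pkC (r=-1) tie on |r|; lower start wins -> pkA
        assert rep.peak_id == "pkA"
        assert rep.corr_class == "positive"

    def test_requires_three_shared_timepoints(self):
        binding = pd.DataFrame([[1, 2]], columns=["t1", "t2"], index=["pk0"])
        expr = pd.DataFrame([[1, 2]], columns=["t1", "t2"], index=["g0"])
        pm = pd.DataFrame({"peak_id": ["pk0"], "gene_id": ["g0"]})
        with pytest.raises(ValueError, match="shared timepoints"):
            correlate_binding_expression(binding, expr, pm)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        b = rng.random(5)
        e = rng.random(5)
        cols = [f"t{i}" for i in range(5)]
        r0 = make_r(b, e, cols)
        assert make_r(3 * b + 7, e, cols) == pytest.approx(r0)
        assert make_r(b, 0.5 * e + 2, cols) == pytest.approx(r0)
        assert make_r(-b, e, cols) == pytest.approx(-r0)


def make_r(b, e, cols):
    binding = pd.DataFrame([b], columns=cols, index=["pk0"])
    expr = pd.DataFrame([e], columns=cols, index=["g0"])
    pm = pd.DataFrame({"peak_id": ["pk0"], "gene_id": ["g0"]})
    return correlate_binding_expression(binding, expr, pm).pairs.pearson_r.iloc[0]


GENES = [
    GeneModel("g1", "chr1", "+", 10_000, 12_000),
    GeneModel("g2", "chr1", "+", 50_000, 52_000),
    GeneModel("g3", "chr1", "-", 90_000, 92_000, biotype="lincRNA"),
]


class TestOccupancyLedger:
    def test_full_interval_overlap_detection(self):
        sets = {
            ("m1", "t1"): [gi(8_990, 10_600)],  # spans g1's promoter window
            ("m1", "t2"): [],
        }
        ledger = build_occupancy_ledger(sets, GENES, timepoints=["t1", "t2"])
        assert ledger.gene_ids == ["g1", "g2"]  # lincRNA excluded
        df = ledger.slice("m1")
        assert bool(df.loc["g1", "t1"]) and not bool(df.loc["g1", "t2"])
        assert not df.loc["g2"].any()

    def test_incomplete_grid_raises_with_missing_cells(self):
        with pytest.raises(ValueError, match="missing cells"):
            build_occupancy_ledger(
                {("m1", "t1"): []},
                GENES,
                marks=["m1", "m2"],
                timepoints=["t1"],
            )

    def test_ledger_matches_planted_truth_in_noiseless_limit(self, noiseless_study):
        st = noiseless_study
        from markdyn.consensus import call_consensus, filter_by_qvalue

        sets = {}
        for (mark, tp), reps in st.replicate_peaks.items():
            cs = call_consensus([filter_by_qvalue(r) for r in reps], 2)
            sets[(mark, tp)] = cs.intervals
        ledger = build_occupancy_ledger(
            sets,
            st.genes,
            marks=list(st.config.marks),
            timepoints=list(st.config.timepoints),
            biotype=None,
        )
        order = {g: i for i, g in enumerate(r.gene_id for r in st.genes)}
        truth_rows = [order[g] for g in ledger.gene_ids]
        assert np.array_equal(ledger.values, st.truth.occupancy[truth_rows])


class TestCooccupancy:
    def _ledger(self, values, marks=("anchor", "m2", "m3"), tps=("t1",)):
        genes = [f"g{i}" for i in range(len(values))]
        return OccupancyLedger(np.array(values, dtype=bool), genes, list(tps), list(marks))

    def test_direct_tally_of_combinations(self):
        # anchor-positive genes with other-mark patterns (1,1), (1,0), (0,0)
        values = [
            [[True, True, True]],
            [[True, True, False]],
            [[True, False, False]],
        ]
        fr = cooccupancy_fractions(self._ledger(values), "anchor")
        both = fr[(fr.combination == "m2+m3")].fraction.iloc[0]
        assert both == pytest.approx(1 / 3)
        assert fr.groupby("timepoint").fraction.sum().iloc[0] == pytest.approx(1.0)

    def test_all_marks_everywhere(self):
        values = [[[True, True, True]]] * 4
        fr = cooccupancy_fractions(self._ledger(values), "anchor")
        assert fr[(fr.combination == "m2+m3")].fraction.iloc[0] == 1.0

    def test_no_anchor_genes_undefined(self):
        values = [[[False, True, True]]]
        fr = cooccupancy_fractions(self._ledger(values), "anchor")
        assert fr.fraction.isna().all()

    def test_unknown_anchor_rejected(self):
        with pytest.raises(ValueError):
            cooccupancy_fractions(self._ledger([[[True, True, True]]]), "nope")


class TestTransitionFlows:
    def test_static_ledger_only_diagonal(self):
        values = np.zeros((3, 2, 2), dtype=bool)
        values[0, :, 0] = True
        ledger = OccupancyLedger(values, ["g0", "g1", "g2"], ["t1", "t2"], ["a", "b"])
        flows = transition_flows(ledger)
        assert (flows.state_from == flows.state_to).all()
        assert flows.gene_count.sum() == 3

    def test_single_gain_is_one_off_diagonal_flow(self):
        values = np.zeros((2, 2, 1), dtype=bool)
        values[0, 1, 0] = True  # g0 gains the mark at t2
        ledger = OccupancyLedger(values, ["g0", "g1"], ["t1", "t2"], ["a"])
        flows = transition_flows(ledger)
        off = flows[flows.state_from != flows.state_to]
        assert len(off) == 1
        assert off.iloc[0].state_from == "none" and off.iloc[0].state_to == "a"
        assert off.iloc[0].gene_count == 1

    def test_flows_conserve_genes_between_timepoints(self, small_study):
        st = small_study
        ledger = OccupancyLedger(
            st.truth.occupancy,
            list(st.truth.gene_table.gene_id),
            list(st.config.timepoints),
            list(st.config.marks),
        )
        flows = transition_flows(ledger)
        n_genes = len(ledger.gene_ids)
        for trans, sub in flows.groupby("transition"):
            assert sub.gene_count.sum() == n_genes

    def test_needs_two_timepoints(self):
        ledger = OccupancyLedger(
            np.zeros((1, 1, 1), dtype=bool), ["g0"], ["t1"], ["a"]
        )
        with pytest.raises(ValueError):
            transition_flows(ledger)

    def test_flow_marginals_match_cooccupancy_tallies(self, small_study):
        """State counts derived from flows equal direct ledger tallies."""
        st = small_study
        ledger = OccupancyLedger(
            st.truth.occupancy,
            list(st.truth.gene_table.gene_id),
            list(st.config.timepoints),
            list(st.config.marks),
        )
        flows = transition_flows(ledger)
        from markdyn.integration import combination_label

        t0, t1 = ledger.timepoints[0], ledger.timepoints[1]
        sub = flows[flows.transition == f"{t0}->{t1}"]
        out_marginal = sub.groupby("state_from").gene_count.sum()
        direct = pd.Series(
            [
                combination_label(ledger.marks, ledger.values[g, 0, :])
                for g in range(len(ledger.gene_ids))
            ]
        ).value_counts()
        assert out_marginal.sort_index().equals(direct.sort_index())


class TestColocalization:
    def _annot(self, peaks, cls=FeatureClass.PROMOTER):
        return [FeatureAssignment(p, cls, None, 0) for p in peaks]

    def test_half_overlap_is_fifty_percent(self):
        q = [gi(0, 100), gi(200, 300)]
        rep = colocalization_fraction(q, [gi(50, 150)], self._annot(q))
        assert rep["overall"]["fraction"] == pytest.approx(0.5)

    def test_reference_superset_is_full(self):
        q = [gi(0, 100), gi(200, 300)]
        rep = colocalization_fraction(q, [gi(0, 1000)], self._annot(q))
        assert rep["overall"]["fraction"] == 1.0

    def test_disjoint_sets_are_zero_and_empty_reference_is_zero(self):
        q = [gi(0, 100)]
        assert (
            colocalization_fraction(q, [gi(500, 600)], self._annot(q))["overall"][
                "fraction"
            ]
            == 0.0
        )
        assert (
            colocalization_fraction(q, [], self._annot(q))["overall"]["fraction"]
            == 0.0
        )

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            colocalization_fraction([], [gi(0, 10)], [])

    def test_per_class_split(self):
        q = [gi(0, 100), gi(200, 300)]
        annots = [
            FeatureAssignment(q[0], FeatureClass.PROMOTER, "g1", 0),
            FeatureAssignment(q[1], FeatureClass.DISTAL, None, None),
        ]
        rep = colocalization_fraction(q, [gi(50, 150)], annots)
        assert rep["by_class"]["promoter"]["fraction"] == 1.0
        assert rep["by_class"]["distal"]["fraction"] == 0.0


class TestGenesetEnrichment:
    def test_exact_tail_enumeration_by_hand(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = {"S": universe[:5]}
        query = universe[:4] + [universe[10]]
        res = geneset_enrichment(query, universe, gene_set)
        assert res.p_value.iloc[0] == pytest.approx(76 / 15504)

    def test_disjoint_set_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        res = geneset_enrichment(universe[:3], universe, {"S": universe[5:]})
        assert res.p_value.iloc[0] == pytest.approx(1.0)

    def test_proportional_overlap_not_significant(self):
        universe = [f"u{i}" for i in range(100)]
        # query 20 of 100, set 50: expected overlap 10; observe exactly 10
        query = universe[:10] + universe[50:60]
        res = geneset_enrichment(query, universe, {"S": universe[:50]})
        assert res.p_value.iloc[0] > 0.5

    def test_matches_exact_enumeration_small_universes(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            M = int(rng.integers(5, 26))
            universe = [f"u{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            gene_set = {"S": list(rng.choice(universe, K, replace=False))}
            query = list(rng.choice(universe, n, replace=False))
            res = geneset_enrichment(query, universe, gene_set)
            k = len(set(query) & set(gene_set["S"]))
            p_exact = sum(
                math.comb(K, x) * math.comb(M - K, n - x)
                for x in range(k, min(K, n) + 1)
                if n - x <= M - K
            ) / math.comb(M, n)
            assert res.p_value.iloc[0] == pytest.approx(p_exact, rel=1e-9)

    def test_query_must_be_subset_of_universe(self):
        with pytest.raises(ValueError):
            geneset_enrichment(["x"], ["a", "b"], {"S": ["a"]})
        with pytest.raises(ValueError):
            geneset_enrichment([], ["a"], {"S": ["a"]})

    def test_bh_across_collection_and_sorting(self):
        universe = [f"u{i}" for i in range(30)]
        sets = {
            "hit": universe[:6],
            "miss": universe[20:26],
            "part": universe[:3] + universe[10:13],
        }
        res = geneset_enrichment(universe[:6], universe, sets)
        assert list(res.p_value) == sorted(res.p_value)
        assert (res.bh_q >= res.p_value - 1e-12).all()
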