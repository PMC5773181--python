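"""Contingency classification, likelihood ratio and Fisher's exact test."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import chromoreg as cr
from chromoreg.errors import UndefinedStatisticError, ValidationError
from chromoreg.segments import ClusterCall
from helpers import brute_force_fisher_p, make_annotation

TABLE1 = cr.ContingencyTable2x2(24, 49, 245, 723)


class TestClassification:
    @pytest.mark.parametrize(
        "pair,expected",
        [(("U", "U"), "UU"), (("D", "D"), "DD"), (("O", "U"), "UO"),
         (("O", "D"), "DO"), (("D", "U"), "UD"), (("O", "O"), "OO")],
    )
    def test_joint_states_are_unordered(self, pair, expected):
        assert cr.joint_state(*pair) == expected
        assert cr.joint_state(*reversed(pair)) == expected

    def test_hand_classified_pairs(self):
        ann = make_annotation(
            {
                "chr1": [("a", "-"), ("b", "+")],   # RF
                "chr2": [("c", "+"), ("d", "+")],   # FF
                "chr3": [("e", "+"), ("f", "-")],   # FR
            }
        )
        states = {"a": "U", "b": "U", "c": "U", "d": "O", "e": "O", "f": "O"}
        table, n_excluded = cr.classify_pairs(cr.adjacent_pairs(ann), states)
        assert table == cr.ContingencyTable2x2(a=1, b=0, c=0, d=1)
        assert n_excluded == 1

    def test_all_constitutive_pairs_excluded(self):
        ann = make_annotation({"chr1": [("a", "+"), ("b", "+"), ("c", "+")]})
        table, n_excluded = cr.classify_pairs(
            cr.adjacent_pairs(ann), {"a": "O", "b": "O", "c": "O"}
        )
        assert table.total == 0
        assert n_excluded == 2

    def test_missing_state_raises(self):
        ann = make_annotation({"chr1": [("a", "+"), ("b", "+")]})
        with pytest.raises(ValidationError, match="b"):
            cr.classify_pairs(cr.adjacent_pairs(ann), {"a": "U"})

    def test_counts_partition_all_pairs(self, small_bundle):
        pairs = cr.adjacent_pairs(small_bundle.annotation)
        table, n_excluded = cr.classify_pairs(pairs, small_bundle.truth.states)
        assert table.total + n_excluded == len(pairs)


class TestLikelihoodRatio:
    def test_printed_contingency_value(self):
        assert cr.likelihood_ratio(TABLE1) == pytest.approx(1.41, abs=0.005)

    def test_symmetric_table_gives_unity(self):
        assert cr.likelihood_ratio(cr.ContingencyTable2x2(7, 7, 13, 13)) == 1.0

    def test_hand_arithmetic(self):
        assert cr.likelihood_ratio(cr.ContingencyTable2x2(10, 5, 0, 5)) == 2.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            cr.likelihood_ratio(cr.ContingencyTable2x2(5, 0, 3, 7))


class TestFisher:
    def test_printed_contingency_values(self):
        res = cr.fisher_exact(TABLE1)
        assert res.odds_ratio == pytest.approx(1.44, abs=0.005)
        assert res.p_two_sided == pytest.approx(0.166, abs=0.0005)

    def test_balanced_table(self):
        res = cr.fisher_exact(cr.ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_two_sided == 1.0

    def test_two_table_enumeration(self):
        """For margins (1,1)x(1,1) both tables are equally likely: p = 1."""
        res = cr.fisher_exact(cr.ContingencyTable2x2(1, 0, 0, 1))
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(brute_force_fisher_p(1, 0, 0, 1))

    def test_degenerate_margin(self):
        res = cr.fisher_exact(cr.ContingencyTable2x2(0, 0, 5, 5))
        assert res.p_two_sided == 1.0
        assert math.isnan(res.odds_ratio)

    def test_agrees_with_hypergeometric_enumeration(self):
        """p matches full enumeration over tables with fixed margins for a
        sweep of tables with total <= 40."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 60:
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d > 40 or (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            got = cr.fisher_exact(cr.ContingencyTable2x2(a, b, c, d)).p_two_sided
            assert got == pytest.approx(brute_force_fisher_p(a, b, c, d), rel=1e-8)
            checked += 1

    def test_invariant_to_swapping_pair_sides(self):
        """Swapping left/right genes within pairs changes nothing: the table
        is built from unordered joint states and orientation is a property
        of the pair, so L and Fisher p are reproduced."""
        ann = make_annotation(
            {"chr1": [("a", "-"), ("b", "+"), ("c", "+"), ("d", "-"), ("e", "+")]}
        )
        states = {"a": "U", "b": "U", "c": "D", "d": "O", "e": "U"}
        pairs = cr.adjacent_pairs(ann)
        table, _ = cr.classify_pairs(pairs, states)
        swapped_states = dict(states)  # joint_state(x, y) == joint_state(y, x)
        for p in pairs:
            assert cr.joint_state(states[p.left.id], states[p.right.id]) == (
                cr.joint_state(swapped_states[p.right.id], swapped_states[p.left.id])
            )

    def test_uniform_p_when_orientation_independent_of_state(self):
        """Fisher p over replicate genomes with orientation independent of
        expression state is consistent with uniformity."""
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(200):
            cfg = cr.SimConfig(
                n_chromosomes=1,
                genes_per_chromosome=300,
                state_frequencies=(0.15, 0.12),
                p_forward=0.5,
                with_sequence=False,
                seed=int(rng.integers(2**31)),
            )
            bundle = cr.generate(cfg)
            res = cr.fisher_exact(bundle.truth.contingency)
            pvals.append(res.p_two_sided)
        # Fisher p is discrete and conservative; one-sided check against
        # super-uniformity would always pass, so bound the KS statistic for
        # the anti-conservative direction only
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01


class TestRfCounts:
    @pytest.mark.parametrize("n,expected", [(1041, 260.25), (0, 0.0), (4, 1.0)])
    def test_expected_rf_count(self, n, expected):
        assert cr.expected_rf_count(n) == expected


class TestClusterRfExplained:
    def _cluster(self, gene_ids, direction="up"):
        return ClusterCall(
            chromosome="chr1", gene_ids=list(gene_ids), span=(0, 1),
            direction=direction, n_concordant=len(gene_ids),
        )

    def test_inulinase_like_cluster(self):
        """Six concordant genes with two internal RF pairs: 4/6 explained."""
        ann = make_annotation(
            {"chr1": [("g1", "-"), ("g2", "+"), ("g3", "+"),
                      ("g4", "-"), ("g5", "+"), ("g6", "+")]}
        )  # RF pairs: (g1,g2) and (g4,g5)
        states = {g: "U" for g in "g1 g2 g3 g4 g5 g6".split()}
        frac = cr.cluster_rf_explained_fraction(
            self._cluster(states), cr.adjacent_pairs(ann), states
        )
        assert frac == pytest.approx(4 / 6)

    def test_half_explained_cluster(self):
        """Four concordant genes, one shared intergenic region: 2/4."""
        ann = make_annotation(
            {"chr1": [("g1", "+"), ("g2", "-"), ("g3", "+"), ("g4", "+")]}
        )  # RF pair: (g2,g3)
        states = {g: "U" for g in "g1 g2 g3 g4".split()}
        frac = cr.cluster_rf_explained_fraction(
            self._cluster(states), cr.adjacent_pairs(ann), states
        )
        assert frac == 0.5

    def test_tandem_cluster_unexplained(self):
        """All-tandem orientation (no shared intergenic region): 0."""
        ann = make_annotation(
            {"chr1": [(f"g{i}", "+") for i in range(1, 5)]}
        )
        states = {f"g{i}": "U" for i in range(1, 5)}
        frac = cr.cluster_rf_explained_fraction(
            self._cluster(states), cr.adjacent_pairs(ann), states
        )
        assert frac == 0.0

    def test_rf_partner_outside_cluster_does_not_count(self):
        ann = make_annotation({"chr1": [("g1", "-"), ("g2", "+")]})
        states = {"g1": "O", "g2": "U"}
        frac = cr.cluster_rf_explained_fraction(
            self._cluster(["g2"]), cr.adjacent_pairs(ann), states
        )
        assert frac == 0.0
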