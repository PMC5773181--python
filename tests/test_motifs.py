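"""Pattern compilation, reverse complementation and sequence scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromoreg as cr
from chromoreg.errors import ConfigError
from chromoreg.motifs import REGISTRY, MotifHit
from helpers import brute_force_motif_scan, make_annotation


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCompile:
    def test_core_pattern_positions(self):
        p = cr.compile_pattern("mig1_core", "[GC][TC]GG[GA]G")
        assert p.n_fixed == 6
        assert p.spacer is None
        assert p.positions[0] == frozenset("GC")
        assert p.positions[2] == frozenset("G")

    def test_inline_spacer(self):
        p = cr.compile_pattern("dimer", "C[CT]CC[GA][TCA]N{2-36}[TGA][TC]GG[AG]G")
        assert p.n_fixed == 12
        assert p.spacer == (6, 2, 36)
        assert (p.min_len, p.max_len) == (14, 48)

    def test_spacer_spec_argument(self):
        p = cr.compile_pattern(
            "dimer2", "C[CT]CC[GA][TCA]", spacer_spec=(2, 36)
        )
        assert p.spacer == (6, 2, 36)

    def test_n_position_matches_any_base(self):
        p = cr.compile_pattern("x", "ANT")
        assert p.positions[1] == frozenset("ACGT")

    @pytest.mark.parametrize(
        "bad", ["[]", "A[", "AXG", "A N", "N{5-2}A", "AN{1-2}GN{1-2}C"]
    )
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(ConfigError):
            cr.compile_pattern("bad", bad)

    def test_class_string_round_trip(self):
        for p in REGISTRY.values():
            again = cr.compile_pattern(p.name, p.class_string())
            assert again.positions == p.positions
            assert again.spacer == p.spacer


class TestReverseComplement:
    def test_combined_mig1_reverse_matches_printed_form(self):
        """The reverse complement of the combined AT box + GC box model is
        the independently printed reverse pattern."""
        fwd = REGISTRY["mig1_atgc"]
        printed_reverse = cr.compile_pattern(
            "mig1_atgc_rev", "CCCC[GA][GC]N[TAC][AT][AT][AT][CAT]"
        )
        rev = cr.reverse_complement_pattern(fwd)
        assert rev.positions == printed_reverse.positions

    def test_adr1_dimer_is_its_own_reverse_complement(self):
        p = REGISTRY["adr1_dimer"]
        rc = cr.reverse_complement_pattern(p)
        assert rc.positions == p.positions
        assert rc.spacer == p.spacer
        assert p.is_self_reverse_complement

    @given(
        st.lists(
            st.sets(st.sampled_from("ACGT"), min_size=1, max_size=4),
            min_size=1, max_size=12,
        ),
        st.one_of(st.none(), st.tuples(st.integers(0, 3), st.integers(4, 9))),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_revcomp_is_an_involution(self, sets, spacer_bounds):
        p = cr.MotifPattern(
            name="rand",
            positions=tuple(frozenset(s) for s in sets),
            spacer=(len(sets) // 2,) + spacer_bounds if spacer_bounds else None,
        )
        assert cr.reverse_complement_pattern(cr.reverse_complement_pattern(p)) == p


class TestScan:
    def test_both_printed_promoter_sequences_match_combined_model(self):
        p = REGISTRY["mig1_atgc"]
        for s in ("TTAAATCCGGGG", "TTTTTCCTGGGG"):
            hits = cr.scan(s, p, strands="forward")
            assert [(h.start, h.end) for h in hits] == [(0, 12)]

    def test_dimeric_hit_with_shortest_spacer(self):
        hits = cr.scan("CCCCGTAATTGGAG", REGISTRY["adr1_dimer"], strands="forward")
        assert [(h.start, h.end, h.spacer_length) for h in hits] == [(0, 14, 2)]

    def test_empty_sequence(self):
        assert cr.scan("", REGISTRY["mig1_core"]) == []

    def test_n_in_sequence_never_matches(self):
        p = REGISTRY["mig1_core"]
        assert cr.scan("GCGGGG", p, strands="forward")
        assert cr.scan("GNGGGG", p, strands="forward") == []

    def test_gc_free_sequence_has_no_registry_hits(self):
        """Every registry model contains a G-rich core, so an AT-only
        sequence can never match on either strand."""
        seq = random_seq(3000, 5).translate(str.maketrans("GC", "AT"))
        for p in REGISTRY.values():
            assert cr.scan(seq, p, strands="both") == []

    def test_reverse_strand_coordinates_mirror_forward(self):
        """Forward hits of the reverse-complement pattern coincide with
        reverse-strand hits of the pattern itself."""
        seq = random_seq(4000, 9)
        for p in (REGISTRY["mig1_core"], REGISTRY["mig1_atgc"]):
            rev_hits = [
                (h.start, h.end)
                for h in cr.scan(seq, p, strands="reverse")
            ]
            fwd_of_rc = [
                (h.start, h.end)
                for h in cr.scan(seq, cr.reverse_complement_pattern(p),
                                 strands="forward")
            ]
            assert sorted(rev_hits) == sorted(fwd_of_rc)

    def test_palindrome_hits_deduplicated(self):
        """A self-reverse-complementary dimer site is reported once, on the
        forward strand, when both strands are scanned."""
        seq = "TT" + "CCCCGTAATTGGAG" + "TT"
        hits = cr.scan(seq, REGISTRY["adr1_dimer"], strands="both")
        assert [(h.start, h.end, h.strand) for h in hits] == [(2, 16, "+")]

    def test_matches_brute_force_oracle(self):
        """Optimised scanning (regex, shortest-spacer selection) agrees
        exactly with naive all-starts/all-spacers enumeration on random
        sequence, for every registry pattern and both strands."""
        for rep in range(6):
            seq = random_seq(2000, 100 + rep)
            rc = cr.reverse_complement(seq)
            for p in REGISTRY.values():
                got = {
                    (h.start, h.end, h.strand, h.spacer_length)
                    for h in cr.scan(seq, p, strands="both", spacer_policy="all")
                }
                n = len(seq)
                expected = {
                    (s, e, "+", g) for s, e, g in brute_force_motif_scan(seq, p)
                } | {
                    (n - e, n - s, "-", g)
                    for s, e, g in brute_force_motif_scan(rc, p)
                }
                if p.is_self_reverse_complement:
                    collapsed = {}
                    for s, e, strand, g in sorted(expected):
                        collapsed.setdefault((s, e, g), strand)
                    expected = {
                        (s, e, strand, g)
                        for (s, e, g), strand in collapsed.items()
                    }
                assert got == expected, p.name

    def test_shortest_spacer_policy_is_min_over_all(self):
        seq = random_seq(5000, 77)
        p = REGISTRY["adr1_dimer"]
        all_hits = cr.scan(seq, p, strands="forward", spacer_policy="all")
        shortest = cr.scan(seq, p, strands="forward", spacer_policy="shortest")
        by_anchor = {}
        for h in all_hits:
            by_anchor.setdefault(h.start, []).append(h.spacer_length)
        assert {(h.start, h.spacer_length) for h in shortest} == {
            (s, min(gaps)) for s, gaps in by_anchor.items()
        }


class TestPlantedRecovery:
    def test_planted_motifs_recovered_at_exact_coordinates(self):
        cfg = cr.SimConfig(
            n_chromosomes=1,
            genes_per_chromosome=10,
            planted_motifs=[
                cr.PlantedMotif("mig1_atgc", 0, pair_index=2),
                cr.PlantedMotif("aft1_strict", 0, pair_index=5),
            ],
            seed=42,
        )
        bundle = cr.generate(cfg)
        seq = bundle.sequences["chr1"]
        for planted in bundle.truth.motif_coords:
            hits = cr.scan(seq, REGISTRY[planted["pattern"]], strands="both",
                           chromosome="chr1")
            assert any(
                h.start == planted["start"] and h.end == planted["end"]
                for h in hits
            ), planted

    def test_false_positive_rate_matches_analytic_probability(self):
        """On i.i.d. uniform sequence the per-position match probability of
        the Mig1 core is the product of class sizes / 4: 2^-9 per strand."""
        n, L = 60, 4000  # 240 kb total
        per_strand = (2 / 4) ** 3 * (1 / 4) ** 3
        count = 0
        positions = 0
        p = REGISTRY["mig1_core"]
        for i in range(n):
            seq = random_seq(L, 900 + i)
            count += len(cr.scan(seq, p, strands="both"))
            positions += 2 * (L - p.n_fixed + 1)
        expected = positions * per_strand
        sd = np.sqrt(positions * per_strand * (1 - per_strand))
        assert abs(count - expected) <= 3 * sd


class TestContext:
    def _annotation(self):
        return make_annotation(
            {
                "chr1": [
                    ("left", "+", 1000, 2000, "gene"),
                    ("mid", "+", 3000, 4000, "gene"),
                    ("right", "-", 5000, 6000, "gene"),
                ]
            }
        )

    def _hit(self, start, end):
        return MotifHit(
            pattern_name="x", chromosome="chr1", start=start, end=end,
            strand="+", matched_sequence="A" * (end - start),
        )

    def test_hit_inside_gene(self):
        (h,) = cr.assign_context([self._hit(3500, 3510)], self._annotation())
        assert h.context.kind == "inside"
        assert h.context.gene_ids == ("mid",)

    def test_upstream_of_forward_gene(self):
        (h,) = cr.assign_context([self._hit(2790, 2800)], self._annotation())
        assert h.context.kind == "upstream-of"
        assert h.context.gene_ids == ("mid",)
        assert h.context.distance == 200

    def test_shared_intergenic_region_of_rf_like_gap(self):
        """Between an RF-oriented flank (left reverse, right forward) within
        both upstream windows: both genes are listed."""
        ann = make_annotation(
            {"chr1": [("a", "-", 1000, 2000, "gene"),
                      ("b", "+", 2500, 3500, "gene")]}
        )
        (h,) = cr.assign_context([self._hit(2200, 2210)], ann)
        assert h.context.kind == "intergenic"
        assert set(h.context.gene_ids) == {"a", "b"}

    def test_downstream_when_no_promoter_faces_hit(self):
        """Between a forward left gene and reverse right gene (convergent
        pair) the gap holds only 3' ends."""
        ann = make_annotation(
            {"chr1": [("a", "+", 1000, 2000, "gene"),
                      ("b", "-", 2500, 3500, "gene")]}
        )
        (h,) = cr.assign_context([self._hit(2100, 2110)], ann)
        assert h.context.kind == "downstream-of"
        assert h.context.gene_ids == ("a",)

    def test_upstream_window_truncation(self):
        """A hit farther than the window from the start is not upstream."""
        (h,) = cr.assign_context(
            [self._hit(2100, 2110)], self._annotation(), upstream_window=500
        )
        assert h.context.kind != "upstream-of" or h.context.gene_ids != ("mid",)

    def test_unknown_chromosome_raises(self):
        bad = MotifHit("x", "chrZ", 0, 5, "+", "AAAAA")
        with pytest.raises(Exception, match="chrZ"):
            cr.assign_context([bad], self._annotation())
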