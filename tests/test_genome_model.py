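import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subtelo.genome_model import (
    AnnotatedGenome,
    Chromosome,
    Gene,
    GenomeModelError,
    LiftBlock,
    LiftoverMap,
    MethylationDomain,
    POSITION_DEPENDENT,
    POSITION_INDEPENDENT,
    Rearrangement,
    TruthParams,
    apply_rearrangement,
    apply_rearrangements,
    distance_to_repeat_capped_end,
    reevaluate_methylation,
)

from conftest import label_bases


# ---------------------------------------------------------------------------
# apply_rearrangement
# ---------------------------------------------------------------------------


class TestReciprocalToy:
    """Spec toy: chrA=10 kb, chrB=20 kb, exchange at A:6000 / B:12000."""

    @pytest.fixture(autouse=True)
    def _apply(self, toy_genome):
        self.r = Rearrangement("reciprocal_translocation", donor="chrA",
                               acceptor="chrB", segment=(6_000, 10_000),
                               insertion_point=12_000)
        self.derived, self.lift = apply_rearrangement(toy_genome, self.r)

    def test_lengths(self):
        assert self.derived.length("chrA") == 14_000
        assert self.derived.length("chrB") == 16_000

    def test_gene_position_matches_label_oracle(self):
        # Independent oracle: move labeled bases by explicit list slicing.
        A = label_bases("chrA", 10_000)
        B = label_bases("chrB", 20_000)
        newB = B[:12_000] + A[6_000:]
        expect_start = newB.index(("chrA", 7_000))
        expect_end = newB.index(("chrA", 7_499)) + 1
        assert (expect_start, expect_end) == (13_000, 13_500)
        gene = next(g for g in self.derived.genes if g.gene_id == "gA1")
        assert (gene.chrom, gene.start, gene.end) == ("chrB", 13_000, 13_500)

    def test_total_length_conserved(self):
        assert self.derived.total_length == 30_000

    def test_telomeres_travel_with_arms(self):
        assert self.derived.telomeres["chrA"] == (20, 20)
        assert self.derived.telomeres["chrB"] == (20, 20)


def test_insertional_length_change():
    # 1.88 Mb of a large donor inserted distally into an acceptor.
    genome = AnnotatedGenome(
        chromosomes=[Chromosome("chr5", 9_000_000), Chromosome("chr6", 5_000_000)],
        telomeres={"chr5": (20, 20), "chr6": (20, 20)},
    )
    r = Rearrangement("insertional_translocation", donor="chr5", acceptor="chr6",
                      segment=(3_000_000, 4_880_000), insertion_point=4_700_000)
    derived, _ = apply_rearrangement(genome, r)
    assert derived.length("chr6") == 5_000_000 + 1_880_000
    assert derived.length("chr5") == 9_000_000 - 1_880_000
    assert derived.total_length == genome.total_length


def test_empty_rearrangement_is_identity(toy_genome):
    r = Rearrangement("insertion_at_locus", acceptor="chrA", insertion_point=5_000)
    derived, lift = apply_rearrangement(toy_genome, r)
    assert derived.chrom_lengths == toy_genome.chrom_lengths
    assert derived.genes == toy_genome.genes
    assert derived.domains == toy_genome.domains
    for pos in (0, 5_000, 9_999):
        assert lift.lift_position("chrA", pos) == ("chrA", pos, 1)


def test_inverted_segment_label_oracle(toy_genome):
    r = Rearrangement("insertional_translocation", donor="chrA", acceptor="chrB",
                      segment=(6_500, 8_000), insertion_point=2_000,
                      orientation=-1)
    derived, lift = apply_rearrangement(toy_genome, r)
    A = label_bases("chrA", 10_000)
    B = label_bases("chrB", 20_000)
    seg = A[6_500:8_000][::-1]  # inversion of the moved block
    newB = B[:2_000] + seg + B[2_000:]
    gene = next(g for g in derived.genes if g.gene_id == "gA1")
    expect_start = newB.index(("chrA", 7_499))
    assert gene.chrom == "chrB"
    assert gene.start == expect_start
    assert gene.end == expect_start + 500
    assert gene.strand == "-"  # flipped by the inversion


def test_quasiterminal_transfers_telomere_and_heals():
    genome = AnnotatedGenome(
        chromosomes=[Chromosome("chrA", 1_000_000), Chromosome("chrB", 2_000_000)],
        telomeres={"chrA": (20, 30), "chrB": (20, 25)},
    )
    r = Rearrangement("quasiterminal_translocation", donor="chrA",
                      acceptor="chrB", segment=(600_000, 1_000_000),
                      heal_repeats=20)
    derived, lift = apply_rearrangement(genome, r)
    # Donor end array transfers; acceptor's old right array is trimmed out.
    assert derived.telomeres["chrB"] == (20, 30)
    assert derived.telomeres["chrA"] == (20, 20)
    assert ("chrA", "right") in derived.new_capped_ends
    assert derived.length("chrB") == 2_000_000 - 6 * 25 + 400_000
    assert derived.length("chrA") == 600_000 + 6 * 20
    # old acceptor telomere bases are deleted
    assert lift.lift_interval("chrB", 2_000_000 - 6 * 25, 2_000_000) == []


def test_deletion_drops_annotations(toy_genome):
    r = Rearrangement("deletion", donor="chrA", segment=(100, 2_000))
    derived, lift = apply_rearrangement(toy_genome, r)
    assert derived.length("chrA") == 10_000 - 1_900
    # the chrA domain [200, 1200) was inside the deletion
    assert all(d.chrom != "chrA" for d in derived.domains)
    assert lift.lift_interval("chrA", 300, 400) == []


def test_terminal_deletion_heals_new_end(toy_genome):
    r = Rearrangement("deletion", donor="chrA", segment=(8_000, 10_000),
                      heal_repeats=15)
    derived, _ = apply_rearrangement(toy_genome, r)
    assert derived.telomeres["chrA"] == (20, 15)
    assert ("chrA", "right") in derived.new_capped_ends
    assert derived.length("chrA") == 8_000 + 6 * 15


def test_circularize(toy_genome):
    r = Rearrangement("circularize", donor="chrA")
    derived, lift = apply_rearrangement(toy_genome, r)
    c = derived.chrom("chrA")
    assert c.circular
    assert derived.telomeres["chrA"] == (0, 0)
    assert c.length == 10_000 - 2 * 120
    assert derived.circular_junctions["chrA"] == {"trim_left": 120,
                                                  "trim_right": 120}
    with pytest.raises(GenomeModelError):
        apply_rearrangement(derived, r)


def test_duplication_copies_annotations(toy_genome):
    r = Rearrangement("insertion_at_locus", donor="chrA", acceptor="chrB",
                      segment=(100, 1_500), insertion_point=15_000,
                      duplicate=True)
    derived, _ = apply_rearrangement(toy_genome, r)
    assert derived.length("chrB") == 20_000 + 1_400
    assert derived.length("chrA") == 10_000
    doms_b = [d for d in derived.domains if d.chrom == "chrB"
              and 15_000 <= d.start < 16_400]
    assert len(doms_b) == 1  # copy of chrA [200,1200) domain
    assert doms_b[0].start == 15_000 + 100 and doms_b[0].end == 15_000 + 1_100
    # native copy untouched
    assert any(d.chrom == "chrA" and d.start == 200 for d in derived.domains)


def test_telomere_insertion_records_interstitial(toy_genome):
    r = Rearrangement("insertion_at_locus", acceptor="chrB",
                      insertion_point=10_000, novel_repeats=17)
    derived, _ = apply_rearrangement(toy_genome, r)
    assert derived.length("chrB") == 20_000 + 102
    (ir,) = derived.interstitial_repeats
    assert (ir.chrom, ir.pos, ir.n) == ("chrB", 10_000, 17)


class TestRearrangementErrors:
    def test_segment_out_of_bounds(self, toy_genome):
        r = Rearrangement("insertional_translocation", donor="chrA",
                          acceptor="chrB", segment=(9_000, 11_000),
                          insertion_point=100)
        with pytest.raises(GenomeModelError):
            apply_rearrangement(toy_genome, r)

    def test_insertion_inside_segment(self, toy_genome):
        r = Rearrangement("insertional_translocation", donor="chrA",
                          acceptor="chrA", segment=(2_000, 4_000),
                          insertion_point=3_000)
        with pytest.raises(GenomeModelError):
            apply_rearrangement(toy_genome, r)

    def test_unknown_kind(self):
        with pytest.raises(GenomeModelError):
            Rearrangement("inversion")

    def test_bad_orientation(self):
        with pytest.raises(GenomeModelError):
            Rearrangement("deletion", donor="chrA", segment=(0, 10), orientation=2)


# ---------------------------------------------------------------------------
# lift_interval
# ---------------------------------------------------------------------------


def test_lift_identity(toy_genome):
    lift = LiftoverMap.identity(toy_genome)
    assert lift.lift_interval("chrA", 100, 200) == [("chrA", 100, 200, 1)]


def test_lift_spanning_breakpoint_per_base_oracle(toy_genome):
    r = Rearrangement("insertional_translocation", donor="chrA", acceptor="chrB",
                      segment=(4_000, 6_000), insertion_point=1_000)
    derived, lift = apply_rearrangement(toy_genome, r)
    # chrA interval spanning the excision point 4000
    pieces = lift.lift_interval("chrA", 3_900, 4_100)
    assert len(pieces) == 2
    assert sum(e - s for _, s, e, _ in pieces) == 200
    # per-base oracle
    A = label_bases("chrA", 10_000)
    B = label_bases("chrB", 20_000)
    newA = A[:4_000] + A[6_000:]
    newB = B[:1_000] + A[4_000:6_000] + B[1_000:]
    layout = {"chrA": newA, "chrB": newB}
    for base in [("chrA", i) for i in range(3_900, 4_100)]:
        found = False
        for piece in pieces:
            chrom, s, e, _ = piece
            seq = layout[chrom]
            if base in seq[s:e]:
                found = True
        assert found, base


def test_lift_deleted_interval_empty(toy_genome):
    r = Rearrangement("deletion", donor="chrA", segment=(2_000, 3_000))
    _, lift = apply_rearrangement(toy_genome, r)
    assert lift.lift_interval("chrA", 2_100, 2_900) == []


def test_lift_unknown_chromosome(toy_genome):
    lift = LiftoverMap.identity(toy_genome)
    with pytest.raises(GenomeModelError):
        lift.lift_interval("chrZ", 0, 10)


def test_block_length_mismatch_rejected():
    with pytest.raises(GenomeModelError):
        LiftBlock("a", 0, 10, "b", 0, 11, 1)


@settings(max_examples=25, deadline=None)
@given(pos=st.integers(min_value=0, max_value=9_999), seed=st.integers(0, 50))
def test_liftover_round_trip(pos, seed):
    """inverse(forward(x)) == x for every non-deleted base."""
    genome = AnnotatedGenome(
        chromosomes=[Chromosome("chrA", 10_000), Chromosome("chrB", 20_000)],
        telomeres={"chrA": (5, 5), "chrB": (5, 5)},
    )
    rng = np.random.default_rng(seed)
    s = int(rng.integers(1_000, 5_000))
    e = s + int(rng.integers(100, 3_000))
    p = int(rng.integers(0, 15_000))
    orient = 1 if rng.random() < 0.5 else -1
    r = Rearrangement("insertional_translocation", donor="chrA", acceptor="chrB",
                      segment=(s, e), insertion_point=p, orientation=orient)
    _, lift = apply_rearrangement(genome, r)
    fwd = lift.lift_position("chrA", pos)
    assert fwd is not None
    chrom2, pos2, _ = fwd
    back = lift.inverse().lift_position(chrom2, pos2)
    assert back is not None
    assert (back[0], back[1]) == ("chrA", pos)


def test_compose_liftover_matches_sequential(toy_genome):
    r1 = Rearrangement("insertional_translocation", donor="chrA", acceptor="chrB",
                       segment=(4_000, 6_000), insertion_point=1_000)
    r2 = Rearrangement("deletion", donor="chrB", segment=(500, 1_500))
    derived, composed = apply_rearrangements(toy_genome, [r1, r2])
    g1, l1 = apply_rearrangement(toy_genome, r1)
    g2, l2 = apply_rearrangement(g1, r2)
    for pos in range(0, 10_000, 37):
        step1 = l1.lift_position("chrA", pos)
        expect = None
        if step1 is not None:
            expect = l2.lift_position(step1[0], step1[1])
        got = composed.lift_position("chrA", pos)
        if expect is None:
            assert got is None
        else:
            assert got[:2] == expect[:2]


# ---------------------------------------------------------------------------
# distance_to_repeat_capped_end
# ---------------------------------------------------------------------------


def test_distance_both_ends_capped():
    g = AnnotatedGenome(chromosomes=[Chromosome("c", 1_000_000)],
                        telomeres={"c": (20, 20)})
    assert distance_to_repeat_capped_end(g, "c", 10_000) == 10_000


def test_distance_circular_infinite():
    g = AnnotatedGenome(chromosomes=[Chromosome("c", 1_000_000, circular=True)],
                        telomeres={"c": (0, 0)})
    assert distance_to_repeat_capped_end(g, "c", 123) == math.inf


def test_distance_only_left_capped():
    # Oracle: enumerate both ends, keep the capped one.
    L = 50_000
    g = AnnotatedGenome(chromosomes=[Chromosome("c", L)], telomeres={"c": (20, 0)})
    pos = L - 1
    capped = [(0, pos), ]  # (end, distance): only left end qualifies
    expect = min(d for _, d in capped)
    assert distance_to_repeat_capped_end(g, "c", pos) == expect == L - 1


def test_distance_uncapped_linear_infinite():
    g = AnnotatedGenome(chromosomes=[Chromosome("c", 1_000)], telomeres={"c": (0, 0)})
    assert distance_to_repeat_capped_end(g, "c", 10) == math.inf


def test_distance_errors():
    g = AnnotatedGenome(chromosomes=[Chromosome("c", 1_000)])
    with pytest.raises(GenomeModelError):
        distance_to_repeat_capped_end(g, "nope", 0)
    with pytest.raises(GenomeModelError):
        distance_to_repeat_capped_end(g, "c", 1_000)


# ---------------------------------------------------------------------------
# reevaluate_methylation
# ---------------------------------------------------------------------------


def _genome(domains, length=6_000_000, tel=(20, 20), circular=False,
            new_ends=(), interstitial=()):
    from subtelo.genome_model import InterstitialRepeat

    return AnnotatedGenome(
        chromosomes=[Chromosome("c", length, circular=circular)],
        telomeres={"c": (0, 0) if circular else tel},
        domains=list(domains),
        new_capped_ends=list(new_ends),
        interstitial_repeats=[InterstitialRepeat("c", p, n) for p, n in interstitial],
    )


def test_position_dependent_internal_removed():
    # Moved ~4.5 Mb internal: way beyond D_tel.
    g = _genome([MethylationDomain("c", 4_500_000, 4_550_000, POSITION_DEPENDENT)])
    assert reevaluate_methylation(g, TruthParams()) == []


def test_position_independent_internal_retained():
    d = MethylationDomain("c", 3_000_000, 3_050_000, POSITION_INDEPENDENT)
    assert reevaluate_methylation(_genome([d]), TruthParams()) == [d]


def test_subtelomeric_position_dependent_kept():
    d = MethylationDomain("c", 500, 40_000, POSITION_DEPENDENT)
    assert reevaluate_methylation(_genome([d]), TruthParams()) == [d]


def test_zero_domains_zero_output():
    assert reevaluate_methylation(_genome([]), TruthParams()) == []


def test_circular_loses_position_dependent_keeps_independent():
    doms = [
        MethylationDomain("c", 500, 40_000, POSITION_DEPENDENT),
        MethylationDomain("c", 3_000_000, 3_050_000, POSITION_INDEPENDENT),
    ]
    g = _genome(doms, circular=True)
    out = reevaluate_methylation(g, TruthParams())
    assert out == [doms[1]]


def test_new_end_nucleates_domain():
    g = _genome([], new_ends=[("c", "right")])
    tp = TruthParams(seed=7)
    out = reevaluate_methylation(g, tp)
    assert len(out) == 1
    d = out[0]
    assert d.klass == POSITION_DEPENDENT
    assert d.end == 6_000_000 - 120  # inside the telomere array
    ext = d.end - d.start
    assert tp.end_ext_min <= ext <= tp.d_tel


def test_interstitial_array_induces_split_domain():
    pos = 3_000_000
    g = _genome([], interstitial=[(pos, 17)])
    tp = TruthParams(seed=3)
    out = reevaluate_methylation(g, tp)
    assert len(out) == 1
    d = out[0]
    span = d.length
    assert 150_000 < span < 350_000
    left = pos - d.start
    right = d.end - (pos + 102)
    big, small = max(left, right), min(left, right)
    assert big / span == pytest.approx(tp.interstitial_split, rel=0.01)
    assert small > 0


def test_small_interstitial_array_not_inducing():
    g = _genome([], interstitial=[(3_000_000, 4)])
    assert reevaluate_methylation(g, TruthParams()) == []


def test_reevaluate_idempotent():
    g = _genome(
        [MethylationDomain("c", 500, 40_000, POSITION_DEPENDENT),
         MethylationDomain("c", 2_000_000, 2_040_000, POSITION_INDEPENDENT)],
        new_ends=[("c", "right")], interstitial=[(3_000_000, 17)],
    )
    tp = TruthParams(seed=9)
    once = reevaluate_methylation(g, tp)
    g2 = dataclasses.replace(g, domains=once)
    assert reevaluate_methylation(g2, tp) == once


@pytest.mark.parametrize("d_small,d_large", [(100_000, 250_000),
                                             (250_000, 400_000)])
def test_dtel_monotonicity(d_small, d_large):
    rng = np.random.default_rng(0)
    doms = [
        MethylationDomain("c", int(s), int(s) + 20_000, POSITION_DEPENDENT)
        for s in rng.integers(0, 5_000_000, size=30)
    ]
    g = _genome([], length=6_000_000)
    surv_small = {
        (d.start, d.end)
        for dom in doms
        for d in reevaluate_methylation(dataclasses.replace(g, domains=[dom]),
                                        TruthParams(d_tel=d_small))
    }
    surv_large = {
        (d.start, d.end)
        for dom in doms
        for d in reevaluate_methylation(dataclasses.replace(g, domains=[dom]),
                                        TruthParams(d_tel=d_large))
    }
    assert surv_small <= surv_large


def test_missing_class_tag_rejected():
    with pytest.raises(GenomeModelError):
        MethylationDomain("c", 0, 10, "mystery")


# ---------------------------------------------------------------------------
# validation invariants
# ---------------------------------------------------------------------------


def test_validate_rejects_overlapping_domains():
    g = _genome([MethylationDomain("c", 0, 100, POSITION_DEPENDENT)])
    g.domains.append(MethylationDomain("c", 50, 150, POSITION_DEPENDENT))
    with pytest.raises(GenomeModelError):
        g.validate()


def test_validate_rejects_circular_with_telomeres():
    with pytest.raises(GenomeModelError):
        AnnotatedGenome(
            chromosomes=[Chromosome("c", 100, circular=True)],
            telomeres={"c": (5, 0)},
        ).validate()
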