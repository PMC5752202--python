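import dataclasses

import numpy as np
import pytest
from scipy import stats

from subtelo.genome_model import POSITION_DEPENDENT, POSITION_INDEPENDENT, TruthParams
from subtelo.synthetic_data import (
    GeneratorParams,
    ReadSimParams,
    RnaSimParams,
    build_scenario,
    generate_snpome,
    generate_wt_genome,
    genome_digest,
    genome_manifest,
    methylated_gene_ids,
    read_sequences,
    simulate_chip_reads,
    simulate_paired_reads,
    simulate_rna_counts,
    truth_enrichment_track,
)


# ---------------------------------------------------------------------------
# generate_wt_genome
# ---------------------------------------------------------------------------


class TestGenerator:
    def test_default_targets(self, default_wt):
        g = default_wt
        frac = sum(d.length for d in g.domains) / g.total_length
        assert 0.06 <= frac <= 0.08
        assert len(g.domains) > 200
        assert all(500 <= d.length <= 107_000 for d in g.domains)

    def test_passes_model_invariants(self, default_wt):
        default_wt.validate()

    def test_every_end_capped(self, default_wt):
        assert all(v == (20, 20) for v in default_wt.telomeres.values())

    def test_domain_count_zero(self):
        g = generate_wt_genome(GeneratorParams(domain_count=0, seed=1))
        assert g.domains == []

    def test_same_seed_identical(self):
        p = GeneratorParams(n_chromosomes=2,
                            chrom_length_range=(500_000, 800_000),
                            domain_count=20, seed=42, with_sequence=True)
        assert genome_digest(generate_wt_genome(p)) == \
            genome_digest(generate_wt_genome(p))

    def test_different_seed_differs(self):
        p1 = GeneratorParams(seed=1)
        p2 = GeneratorParams(seed=2)
        assert genome_digest(generate_wt_genome(p1)) != \
            genome_digest(generate_wt_genome(p2))

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            generate_wt_genome(GeneratorParams(
                domain_count=3, target_fraction=0.5, seed=0))

    def test_manifest_records_stats(self, default_wt):
        m = genome_manifest(default_wt, GeneratorParams(seed=5))
        assert m["n_domains"] == len(default_wt.domains)
        assert m["seed"] == 5
        assert 0.06 < m["methylated_fraction"] < 0.08

    def test_class_tagging(self, default_wt):
        # default: internal (position-independent) domains start >= 100 kb
        # from the nearest end
        for d in default_wt.domains:
            L = default_wt.length(d.chrom)
            if d.klass == POSITION_INDEPENDENT:
                assert min(d.start, L - d.end) >= 100_000

    def test_gene_density(self, default_wt):
        per_bp = len(default_wt.genes) / default_wt.total_length
        assert per_bp == pytest.approx(1 / 7_500, rel=0.15)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            generate_wt_genome(GeneratorParams(subtel_weight=1.5))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


class TestScenarios:
    def test_tert_all_circular_no_position_dependent(self, small_wt):
        sc = build_scenario("tert", small_wt, seed=1)
        assert all(c.circular for c in sc.derived.chromosomes)
        assert all(d.klass != POSITION_DEPENDENT for d in sc.derived.domains)
        # internal position-independent domains unchanged in number
        n_pi_wt = sum(d.klass == POSITION_INDEPENDENT for d in small_wt.domains)
        assert len(sc.derived.domains) == n_pi_wt

    def test_telomere_insertion_17_truth(self, small_wt):
        sc = build_scenario("telomere_insertion_17", small_wt, seed=2)
        chrom, pos, k = sc.meta["insertion"]
        assert k == 17
        induced = [d for d in sc.derived.domains
                   if d.chrom == chrom and d.start <= pos < d.end]
        assert len(induced) == 1
        assert induced[0].klass == POSITION_DEPENDENT
        assert 150_000 < induced[0].length < 350_000

    def test_telomere_insertion_small_array(self, small_wt):
        sc = build_scenario("telomere_insertion_8", small_wt, seed=2)
        chrom, pos, _ = sc.meta["insertion"]
        induced = [d for d in sc.derived.domains
                   if d.chrom == chrom and d.start <= pos < d.end]
        assert len(induced) == 1
        assert induced[0].length < 50_000  # "some local" methylation only

    def test_segmental_duplication_two_copies(self, small_wt):
        sc = build_scenario("segmental_duplication", small_wt, seed=1)
        donor, s, e = sc.meta["native_segment"]
        dup_chrom, dup_pos = sc.meta["duplicate_at"]
        # native copy domain retained (still subtelomeric)
        native = [d for d in sc.derived.domains
                  if d.chrom == donor and s <= d.start and d.end <= e]
        assert native
        # duplicate copy lost its (position-dependent) domain: internal now
        dup = [d for d in sc.derived.domains
               if d.chrom == dup_chrom and dup_pos <= d.start < dup_pos + (e - s)]
        assert dup == []

    def test_quasiterminal_new_end(self, small_wt):
        sc = build_scenario("quasiterminal", small_wt, seed=4)
        assert sc.meta["new_end"] in sc.derived.new_capped_ends
        chrom, side = sc.meta["new_end"]
        # a de novo domain should sit at the healed end
        L = sc.derived.length(chrom)
        near = [d for d in sc.derived.domains
                if d.chrom == chrom and L - d.end <= 200]
        assert len(near) == 1

    def test_truth_consistent_with_model(self, small_wt):
        from subtelo.genome_model import reevaluate_methylation

        for name in ("insertional", "reciprocal", "terminal_shift"):
            sc = build_scenario(name, small_wt, seed=6)
            sc.derived.validate()
            assert reevaluate_methylation(sc.derived, sc.truth_params) \
                == sc.derived.domains

    def test_unknown_name(self, small_wt):
        with pytest.raises(ValueError):
            build_scenario("mystery", small_wt, seed=0)

    def test_deterministic(self, small_wt):
        a = build_scenario("reciprocal", small_wt, seed=9)
        b = build_scenario("reciprocal", small_wt, seed=9)
        assert a.rearrangements == b.rearrangements
        assert a.derived.domains == b.derived.domains


# ---------------------------------------------------------------------------
# ChIP read simulation
# ---------------------------------------------------------------------------


class TestChipReads:
    def test_depth_conserved(self, small_wt):
        rsp = ReadSimParams(depth=2.0, seed=1)
        reads = simulate_chip_reads(small_wt, rsp, "input")
        expect = small_wt.total_length * 2.0 / 75
        assert abs(reads.n_reads - expect) / expect < 0.01

    def test_enrichment_ratio(self, small_wt):
        # compare empirical start-rate in/out of the sampler's domain
        # start-space (domain intervals extended read_length-1 leftward)
        rsp = ReadSimParams(depth=8.0, enrichment=8.0, seed=2)
        reads = simulate_chip_reads(small_wt, rsp, "chip")
        rl = rsp.read_length
        by_chrom = {}
        for d in small_wt.domains:
            by_chrom.setdefault(d.chrom, []).append((d.start - rl + 1, d.end))
        for chrom, starts in reads.starts.items():
            ivs = np.array(sorted(by_chrom[chrom]))
            idx = np.searchsorted(ivs[:, 0], starts, side="right") - 1
            idx0 = np.clip(idx, 0, len(ivs) - 1)
            inside = (idx >= 0) & (starts < ivs[idx0, 1])
            dom_space = int((ivs[:, 1] - ivs[:, 0]).sum())
            out_space = small_wt.length(chrom) - dom_space
            rate_ratio = (inside.sum() / dom_space) / \
                ((~inside).sum() / out_space)
            assert rate_ratio == pytest.approx(8.0, rel=0.10)

    def test_e1_indistinguishable_from_input(self, small_wt):
        rsp = dataclasses.replace(ReadSimParams(depth=5.0, seed=3), enrichment=1.0)
        chip = simulate_chip_reads(small_wt, rsp, "chip")
        inp = simulate_chip_reads(small_wt, dataclasses.replace(rsp, seed=4),
                                  "input")
        from subtelo.coverage_norm import window_coverage

        t1 = window_coverage(chip, small_wt.chrom_lengths)
        t2 = window_coverage(inp, small_wt.chrom_lengths)
        v1 = np.concatenate(list(t1.values.values()))
        v2 = np.concatenate(list(t2.values.values()))
        assert len(v1) >= 10_000
        _stat, p = stats.ks_2samp(v1, v2)
        assert p > 0.01

    def test_fixed_seed_identical(self, small_wt):
        rsp = ReadSimParams(depth=1.0, seed=7)
        a = simulate_chip_reads(small_wt, rsp, "chip")
        b = simulate_chip_reads(small_wt, rsp, "chip")
        for chrom in a.starts:
            np.testing.assert_array_equal(a.starts[chrom], b.starts[chrom])

    def test_chrom_restriction_consistent(self, small_wt):
        rsp = ReadSimParams(depth=1.0, seed=8)
        full = simulate_chip_reads(small_wt, rsp, "chip")
        name = small_wt.chromosomes[1].name
        only = simulate_chip_reads(small_wt, rsp, "chip", chroms=[name])
        np.testing.assert_array_equal(full.starts[name], only.starts[name])

    def test_zero_depth_rejected(self, small_wt):
        with pytest.raises(ValueError):
            simulate_chip_reads(small_wt, ReadSimParams(depth=0), "chip")

    def test_bad_channel(self, small_wt):
        with pytest.raises(ValueError):
            simulate_chip_reads(small_wt, ReadSimParams(), "rna")


# ---------------------------------------------------------------------------
# SNPome
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def seq_genome():
    return generate_wt_genome(GeneratorParams(
        n_chromosomes=1, chrom_length_range=(1_000_000, 1_000_000),
        domain_count=5, seed=3, with_sequence=True))


class TestSnpome:

    def test_snp_count_binomial(self, seq_genome):
        snpome, _ = generate_snpome(seq_genome, 0.002, seed=1)
        n_sites = 1_000_000 - 2 * (120 + 70)
        expect = n_sites * 0.002
        sd = np.sqrt(n_sites * 0.002 * 0.998)
        assert abs(len(snpome) - expect) <= 3 * sd

    def test_variant_differs_exactly_at_snps(self, seq_genome):
        snpome, variant = generate_snpome(seq_genome, 0.0005, seed=2)
        chrom = seq_genome.chromosomes[0].name
        a = np.frombuffer(seq_genome.sequences[chrom].encode(), dtype=np.uint8)
        b = np.frombuffer(variant.sequences[chrom].encode(), dtype=np.uint8)
        diff = set(np.nonzero(a != b)[0].tolist())
        assert diff == set(snpome.pos)
        assert len(snpome) > 0

    def test_same_seed_identical(self, seq_genome):
        s1, _ = generate_snpome(seq_genome, 0.001, seed=9)
        s2, _ = generate_snpome(seq_genome, 0.001, seed=9)
        assert s1.pos == s2.pos and s1.allele_b == s2.allele_b

    def test_requires_sequence(self, small_wt):
        with pytest.raises(Exception):
            generate_snpome(small_wt, 0.001, seed=0)

    def test_rate_bounds(self, seq_genome):
        with pytest.raises(ValueError):
            generate_snpome(seq_genome, 0.2, seed=0)


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


class TestRnaCounts:
    def test_repression_ratio(self, dense_wt):
        counts = simulate_rna_counts(dense_wt, dense_wt.domains,
                                     RnaSimParams(repression=0.1, seed=1))
        meth = set(methylated_gene_ids(dense_wt, dense_wt.domains))
        assert len(meth) >= 500
        v = counts.iloc[:, 0]
        ratio = v[v.index.isin(meth)].mean() / v[~v.index.isin(meth)].mean()
        assert ratio == pytest.approx(0.1, rel=0.2)

    def test_rho_one_indistinguishable(self, dense_wt):
        counts = simulate_rna_counts(dense_wt, dense_wt.domains,
                                     RnaSimParams(repression=1.0, seed=2))
        meth = set(methylated_gene_ids(dense_wt, dense_wt.domains))
        v = counts.iloc[:, 0]
        a = v[v.index.isin(meth)]
        b = v[~v.index.isin(meth)]
        assert len(a) >= 500
        _s, p = stats.mannwhitneyu(a, b)
        assert p > 0.01

    def test_zero_genes_empty(self):
        g = generate_wt_genome(GeneratorParams(
            n_chromosomes=1, chrom_length_range=(200_000, 200_000),
            domain_count=0, gene_spacing_range=(300_000, 300_001), seed=0))
        assert len(g.genes) == 0
        table = simulate_rna_counts(g, [], RnaSimParams())
        assert table.empty

    def test_invalid_rho(self, small_wt):
        with pytest.raises(ValueError):
            simulate_rna_counts(small_wt, [], RnaSimParams(repression=0.0))

    def test_monotone_repression(self, default_wt):
        meth = set(methylated_gene_ids(default_wt, default_wt.domains))
        medians = []
        for rho in (0.05, 0.2, 0.8):
            c = simulate_rna_counts(default_wt, default_wt.domains,
                                    RnaSimParams(repression=rho, seed=3))
            v = c.iloc[:, 0]
            medians.append(v[v.index.isin(meth)].mean())
        assert medians[0] < medians[1] < medians[2]


# ---------------------------------------------------------------------------
# paired reads / read sequences
# ---------------------------------------------------------------------------


def test_paired_reads_deterministic(small_wt):
    sc = build_scenario("insertional", small_wt, seed=5)
    rsp = ReadSimParams(depth=2.0, paired=True, seed=6)
    a = simulate_paired_reads(sc.derived, sc.liftover, rsp)
    b = simulate_paired_reads(sc.derived, sc.liftover, rsp)
    np.testing.assert_array_equal(a.pos1, b.pos1)
    np.testing.assert_array_equal(a.pos2, b.pos2)
    assert a.n_pairs > 0


def test_read_sequences_match_genome():
    g = generate_wt_genome(GeneratorParams(
        n_chromosomes=1, chrom_length_range=(50_000, 50_000),
        domain_count=0, seed=4, with_sequence=True))
    reads = simulate_chip_reads(g, ReadSimParams(depth=0.5, seed=1), "input")
    chrom = g.chromosomes[0].name
    seq = g.sequences[chrom]
    from subtelo._util import revcomp

    n = 0
    for (name, rseq), start, strand in zip(
            read_sequences(g, reads), reads.starts[chrom], reads.strands[chrom]):
        expect = seq[start:start + 75]
        if strand < 0:
            expect = revcomp(expect)
        assert rseq == expect
        n += 1
    assert n == reads.n_reads


def test_truth_track_values(small_wt):
    t = truth_enrichment_track(small_wt, enrichment=8.0)
    chrom = small_wt.chromosomes[0].name
    d = next(d for d in small_wt.domains if d.chrom == chrom)
    mid_idx = (d.start + d.length // 2) // 50
    if d.length >= 300:
        assert t.values[chrom][mid_idx] == pytest.approx(8.0)
    far_idx = 0 if d.start > 10_000 else len(t.values[chrom]) - 1
    assert t.values[chrom][far_idx] >= 1.0
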