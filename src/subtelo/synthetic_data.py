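"""Synthetic genomes, strain scenarios, reads, SNPomes and expression counts.

Every generator is a pure function of its parameters and seed; identical
inputs give identical outputs (per-chromosome RNG streams are keyed so that
restricting simulation to a subset of chromosomes does not change results on
the rest).

Wild-type defaults mirror the architecture the analysis assumes: a
multi-chromosome genome whose linear ends carry (TTAGGG)_20 arrays, >200
methylation domains of 0.5-107 kb covering ~7% of the genome with a
subtelomere-enriched placement mixture, subtelomeric domains tagged
position-dependent and internal domains position-independent.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import keyed_rng, random_dna
from .alignments import PairedAlignmentSet, ReadAlignmentSet, SplitAlignment
from .genome_model import (
    AnnotatedGenome,
    Chromosome,
    Gene,
    GenomeModelError,
    LiftoverMap,
    MethylationDomain,
    POSITION_DEPENDENT,
    POSITION_INDEPENDENT,
    Rearrangement,
    TELOMERE_UNIT,
    TELOMERE_UNIT_RC,
    TruthParams,
    apply_rearrangements,
    reevaluate_methylation,
)
from .snp_parse import SNPome

SCENARIO_NAMES = (
    "insertional",
    "reciprocal",
    "quasiterminal",
    "insertional_to_mid",
    "terminal_shift",
    "tert",
    "segmental_duplication",
)  # plus "telomere_insertion_<k>"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    n_chromosomes: int = 7
    chrom_length_range: Tuple[int, int] = (4_000_000, 10_000_000)
    telomere_repeats: int = 20
    gene_length_range: Tuple[int, int] = (1_000, 3_000)
    gene_spacing_range: Tuple[int, int] = (3_500, 7_500)  # mean pitch 7.5 kb
    domain_count: int = 230
    domain_size_range: Tuple[int, int] = (500, 107_000)
    target_fraction: float = 0.07
    subtel_weight: float = 0.35
    subtel_window: int = 100_000
    frac_subtel_position_dependent: float = 1.0
    frac_internal_position_independent: float = 1.0
    domain_min_gap: int = 20_000
    with_sequence: bool = False
    seed: int = 0

    def validate(self) -> None:
        for f in (self.target_fraction, self.subtel_weight,
                  self.frac_subtel_position_dependent,
                  self.frac_internal_position_independent):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.domain_size_range[0] <= 0 or self.chrom_length_range[0] <= 0:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 75
    paired: bool = False
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    depth: float = 1.0
    enrichment: float = 8.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must lie in [0, 1)")
        if min(self.read_length, self.fragment_mean, self.fragment_sd) <= 0:
            raise ValueError("read/fragment parameters must be positive")


@dataclass(frozen=True)
class RnaSimParams:
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    repression: float = 0.1  # rho: mean multiplier for fully methylated genes
    seed: int = 0


# ---------------------------------------------------------------------------
# Wild-type genome
# ---------------------------------------------------------------------------


def generate_wt_genome(params: GeneratorParams = GeneratorParams()) -> AnnotatedGenome:
    """Simulated wild-type genome meeting the params' targets in expectation."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tel_bp = 6 * params.telomere_repeats

    lo, hi = params.chrom_length_range
    lengths = rng.integers(lo, hi + 1, size=params.n_chromosomes)
    names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    chroms = [Chromosome(n, int(L)) for n, L in zip(names, lengths)]
    total = int(lengths.sum())

    smin, smax = params.domain_size_range
    if params.domain_count > 0 and \
            params.domain_count * smax < params.target_fraction * total:
        raise ValueError("infeasible targets: fraction unreachable at this count")

    telomeres = {n: (params.telomere_repeats, params.telomere_repeats) for n in names}

    genes = _place_genes(rng, names, lengths, params, tel_bp)
    domains = _place_domains(rng, names, lengths, params, tel_bp, total)

    sequences = None
    if params.with_sequence:
        sequences = {}
        for n, L in zip(names, lengths):
            core = random_dna(rng, int(L) - 2 * tel_bp)
            core = _guard_core(core)
            sequences[n] = TELOMERE_UNIT_RC * params.telomere_repeats + core + \
                TELOMERE_UNIT * params.telomere_repeats

    genome = AnnotatedGenome(
        chromosomes=chroms, telomeres=telomeres, genes=genes,
        domains=domains, sequences=sequences,
    )
    genome.validate()
    return genome


def _guard_core(core: str) -> str:
    # Keep the bases flanking the terminal arrays from extending them.
    if core[:6] == TELOMERE_UNIT_RC or core[:6] == TELOMERE_UNIT:
        core = "ACACAC" + core[6:]
    if core[-6:] == TELOMERE_UNIT or core[-6:] == TELOMERE_UNIT_RC:
        core = core[:-6] + "ACACAC"
    return core


def _place_genes(rng, names, lengths, params, tel_bp) -> List[Gene]:
    genes = []
    glo, ghi = params.gene_length_range
    plo, phi = params.gene_spacing_range
    idx = 0
    for n, L in zip(names, lengths):
        pos = tel_bp + int(rng.integers(plo, phi + 1))
        while True:
            glen = int(rng.integers(glo, ghi + 1))
            if pos + glen > int(L) - tel_bp:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(n, pos, pos + glen, strand, f"gene_{idx:05d}"))
            idx += 1
            pos += glen + int(rng.integers(plo, phi + 1))
    return genes


def _place_domains(rng, names, lengths, params, tel_bp, total) -> List[MethylationDomain]:
    if params.domain_count <= 0:
        return []
    smin, smax = params.domain_size_range
    sizes = np.exp(rng.uniform(np.log(smin), np.log(smax), size=params.domain_count))
    scale = params.target_fraction * total / sizes.sum()
    sizes = np.clip(np.round(sizes * scale).astype(np.int64), smin, smax)

    lengths = np.asarray(lengths, dtype=np.int64)
    placed: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}

    def fits(chrom, start, end):
        if start < 0 or end > int(lengths[names.index(chrom)]):
            return False
        for s, e in placed[chrom]:
            if start < e + params.domain_min_gap and s < end + params.domain_min_gap:
                return False
        return True

    domains = []
    length_w = lengths / lengths.sum()
    for size in sizes:
        size = int(size)
        subtel = rng.random() < params.subtel_weight
        done = False
        if subtel:
            for _ in range(30):
                ci = int(rng.integers(0, len(names)))
                chrom, L = names[ci], int(lengths[ci])
                left = rng.random() < 0.5
                if left:
                    start = tel_bp + int(rng.integers(0, params.subtel_window))
                    end = start + size
                else:
                    end = L - tel_bp - int(rng.integers(0, params.subtel_window))
                    start = end - size
                if fits(chrom, start, end):
                    pd_tag = rng.random() < params.frac_subtel_position_dependent
                    klass = POSITION_DEPENDENT if pd_tag else POSITION_INDEPENDENT
                    placed[chrom].append((start, end))
                    domains.append(MethylationDomain(chrom, start, end, klass))
                    done = True
                    break
        if not done:
            for _ in range(200):
                ci = int(rng.choice(len(names), p=length_w))
                chrom, L = names[ci], int(lengths[ci])
                lo = tel_bp + params.subtel_window
                hi = L - tel_bp - params.subtel_window - size
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + size
                if fits(chrom, start, end):
                    pi_tag = rng.random() < params.frac_internal_position_independent
                    klass = POSITION_INDEPENDENT if pi_tag else POSITION_DEPENDENT
                    placed[chrom].append((start, end))
                    domains.append(MethylationDomain(chrom, start, end, klass))
                    done = True
                    break
        # a domain that cannot be placed anywhere is dropped (counted in the
        # manifest; does not happen at default parameters)
    domains.sort(key=lambda d: (d.chrom, d.start))
    return domains


def genome_manifest(genome: AnnotatedGenome, params: GeneratorParams) -> dict:
    """Realized statistics of a generated genome (JSON-serializable)."""
    dom_bp = sum(d.length for d in genome.domains)
    sizes = [d.length for d in genome.domains]
    return {
        "params": asdict(params),
        "seed": params.seed,
        "n_chromosomes": len(genome.chromosomes),
        "genome_bp": genome.total_length,
        "n_genes": len(genome.genes),
        "n_domains": len(genome.domains),
        "domain_bp": dom_bp,
        "methylated_fraction": dom_bp / genome.total_length,
        "domain_size_min": min(sizes) if sizes else None,
        "domain_size_max": max(sizes) if sizes else None,
        "digest": genome_digest(genome),
    }


def genome_digest(genome: AnnotatedGenome) -> str:
    """Stable content digest of a genome's annotations (and sequence)."""
    h = hashlib.sha256()
    for c in genome.chromosomes:
        h.update(f"{c.name}:{c.length}:{c.circular}".encode())
        h.update(str(genome.telomeres[c.name]).encode())
    for g in genome.genes:
        h.update(f"{g.chrom}:{g.start}:{g.end}:{g.strand}:{g.gene_id}".encode())
    for d in genome.domains:
        h.update(f"{d.chrom}:{d.start}:{d.end}:{d.klass}".encode())
    if genome.sequences is not None:
        for c in genome.chromosomes:
            h.update(genome.sequences[c.name].encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Strain scenarios
# ---------------------------------------------------------------------------


@dataclass
class StrainScenario:
    """A named rearrangement scenario with full simulated truth."""

    name: str
    base: AnnotatedGenome
    rearrangements: List[Rearrangement]
    derived: AnnotatedGenome  # carries truth post-rearrangement domains
    liftover: LiftoverMap
    truth_breakpoints: List[Tuple[Tuple[str, int], Tuple[str, int]]]
    truth_params: TruthParams
    meta: dict = field(default_factory=dict)


def build_scenario(name: str, genome: AnnotatedGenome, seed: int = 0,
                   truth_params: Optional[TruthParams] = None) -> StrainScenario:
    """Construct one of the named strain scenarios from a wild-type genome."""
    tp = truth_params or TruthParams(seed=seed)
    rng = keyed_rng(seed, "scenario", name)
    tel_bp = {c.name: 6 * genome.telomeres[c.name][1] for c in genome.chromosomes}
    names = [c.name for c in genome.chromosomes]

    meta: dict = {}
    if name == "insertional":
        donor, acceptor = _pick_two(rng, genome)
        L = genome.length(donor)
        seg_len = min(1_880_000, L // 3)
        s = (L - seg_len) // 2
        p = genome.length(acceptor) - tel_bp[acceptor] - 300_000
        rs = [Rearrangement("insertional_translocation", donor=donor,
                            acceptor=acceptor, segment=(s, s + seg_len),
                            insertion_point=p)]
    elif name == "insertional_to_mid":
        donor, acceptor = _pick_two(rng, genome)
        L = genome.length(donor)
        seg_len = min(1_000_000, L // 4)
        s = (L - seg_len) // 2
        p = genome.length(acceptor) // 2
        rs = [Rearrangement("insertional_translocation", donor=donor,
                            acceptor=acceptor, segment=(s, s + seg_len),
                            insertion_point=p)]
    elif name == "reciprocal":
        donor, acceptor, a = _pick_distal_breakpoint(rng, genome)
        b = genome.length(acceptor) // 2
        rs = [Rearrangement("reciprocal_translocation", donor=donor,
                            acceptor=acceptor,
                            segment=(a, genome.length(donor)),
                            insertion_point=b)]
        meta["donor_breakpoint"] = (donor, a)
    elif name == "quasiterminal":
        donor, acceptor = _pick_two(rng, genome)
        L = genome.length(donor)
        seg_len = int(rng.integers(400_000, 800_000))
        rs = [Rearrangement("quasiterminal_translocation", donor=donor,
                            acceptor=acceptor, segment=(L - seg_len, L))]
        meta["new_end"] = (donor, "right")
    elif name == "terminal_shift":
        chrom = names[int(rng.integers(0, len(names)))]
        L = genome.length(chrom)
        del_len = int(rng.integers(300_000, 600_000))
        rs = [Rearrangement("deletion", donor=chrom, segment=(L - del_len, L))]
        meta["new_end"] = (chrom, "right")
    elif name == "tert":
        rs = [Rearrangement("circularize", donor=c.name)
              for c in genome.chromosomes if not c.circular]
    elif name.startswith("telomere_insertion_"):
        k = int(name.rsplit("_", 1)[1])
        chrom, p = _pick_clear_locus(rng, genome, clearance=350_000)
        rs = [Rearrangement("insertion_at_locus", acceptor=chrom,
                            insertion_point=p, novel_repeats=k)]
        meta["insertion"] = (chrom, p, k)
    elif name == "segmental_duplication":
        donor, seg, acceptor, p = _pick_duplication(rng, genome)
        rs = [Rearrangement("insertion_at_locus", donor=donor, acceptor=acceptor,
                            insertion_point=p, segment=seg, duplicate=True)]
        meta["native_segment"] = (donor, *seg)
        meta["duplicate_at"] = (acceptor, p)
    else:
        raise ValueError(f"unknown scenario name {name!r}")

    derived, lift = apply_rearrangements(genome, rs)
    derived.domains = reevaluate_methylation(derived, tp)
    derived.validate()
    breakpoints = truth_junctions(lift)
    return StrainScenario(name, genome, rs, derived, lift, breakpoints, tp, meta)


def _pick_two(rng, genome):
    names = [c.name for c in genome.chromosomes]
    if len(names) < 2:
        raise GenomeModelError("scenario needs at least two chromosomes")
    i, j = rng.choice(len(names), size=2, replace=False)
    return names[int(i)], names[int(j)]


def _pick_distal_breakpoint(rng, genome):
    """Chromosome with a right-subtelomeric position-dependent domain, plus a
    breakpoint between that domain and the telomere (so the exchange shifts
    the domain internal)."""
    candidates = []
    for c in genome.chromosomes:
        tel_r = 6 * genome.telomeres[c.name][1]
        for d in genome.domains:
            if d.chrom == c.name and d.klass == POSITION_DEPENDENT:
                dist = c.length - tel_r - d.end
                if 0 < dist < 150_000:
                    candidates.append((c.name, d.end + min(dist // 2, 5_000)))
    if not candidates:
        raise GenomeModelError("no right-subtelomeric domain available")
    donor, a = candidates[int(rng.integers(0, len(candidates)))]
    others = [c.name for c in genome.chromosomes if c.name != donor]
    acceptor = others[int(rng.integers(0, len(others)))]
    return donor, acceptor, a


def _pick_clear_locus(rng, genome, clearance: int):
    """Internal position with no truth domain within ``clearance`` bp.

    On small or dense genomes the clearance requirement is relaxed stepwise
    (down to ``clearance / 8``) before giving up.
    """
    for clear_bp in (clearance, clearance // 2, clearance // 4, clearance // 8):
        for _ in range(500):
            c = genome.chromosomes[int(rng.integers(0, len(genome.chromosomes)))]
            margin = 6 * max(genome.telomeres[c.name]) + \
                min(450_000, c.length // 3)
            if c.length <= 2 * margin:
                continue
            p = int(rng.integers(margin, c.length - margin))
            clear = all(
                not (d.chrom == c.name and d.start - clear_bp < p < d.end + clear_bp)
                for d in genome.domains
            )
            if clear:
                return c.name, p
    raise GenomeModelError("could not find a clear internal locus")


def _pick_duplication(rng, genome):
    """A segment covering a right-subtelomeric domain, plus an internal
    insertion locus on another chromosome."""
    flank = 25_000
    candidates = []
    for c in genome.chromosomes:
        tel_r = 6 * genome.telomeres[c.name][1]
        for d in genome.domains:
            if (d.chrom == c.name and d.klass == POSITION_DEPENDENT
                    and c.length - tel_r - d.end < 120_000
                    and d.start - flank > 0):
                seg = (max(d.start - flank, 0), min(d.end + flank, c.length - tel_r))
                candidates.append((c.name, seg))
    if not candidates:
        raise GenomeModelError("no subtelomeric domain to duplicate")
    donor, seg = candidates[int(rng.integers(0, len(candidates)))]
    for clearance in (300_000, 150_000, 75_000):
        for _ in range(500):
            others = [c for c in genome.chromosomes if c.name != donor]
            c = others[int(rng.integers(0, len(others)))]
            margin = min(500_000, c.length // 3)
            p = int(rng.integers(margin, c.length - margin))
            clear = all(
                not (d.chrom == c.name and d.start - clearance < p < d.end + clearance)
                for d in genome.domains
            )
            if clear:
                return donor, seg, c.name, p
    raise GenomeModelError("could not place duplication")


def truth_junctions(lift: LiftoverMap):
    """Source-coordinate locus pairs of every novel adjacency in the map."""
    by_tgt: Dict[str, list] = {}
    for b in lift.blocks:
        by_tgt.setdefault(b.tgt_chrom, []).append(b)
    junctions = []
    for chrom, blocks in by_tgt.items():
        blocks.sort(key=lambda b: b.tgt_start)
        for left, right in zip(blocks, blocks[1:]):
            if left.tgt_end != right.tgt_start:
                continue  # novel material (e.g. healed telomere) intervenes
            contiguous = (
                left.src_chrom == right.src_chrom
                and left.orient == right.orient == 1
                and left.src_end == right.src_start
            ) or (
                left.src_chrom == right.src_chrom
                and left.orient == right.orient == -1
                and right.src_end == left.src_start
            )
            if contiguous:
                continue
            locus1 = (left.src_chrom,
                      left.src_end if left.orient == 1 else left.src_start)
            locus2 = (right.src_chrom,
                      right.src_start if right.orient == 1 else right.src_end)
            pair = (locus1, locus2) if locus1 <= locus2 else (locus2, locus1)
            # the two products of a reciprocal exchange share one source
            # locus pair; aligned evidence cannot distinguish them
            if pair not in junctions:
                junctions.append(pair)
    return junctions


# ---------------------------------------------------------------------------
# ChIP / input read sampling
# ---------------------------------------------------------------------------


def simulate_chip_reads(genome: AnnotatedGenome, rsp: ReadSimParams,
                        channel: str = "chip",
                        chroms: Optional[Sequence[str]] = None) -> ReadAlignmentSet:
    """Sample single-end truth alignments.

    ``input`` reads start uniformly; ``chip`` read starts are drawn with
    relative rate ``enrichment`` inside the genome's (truth) methylation
    domains and 1 outside. Read count per chromosome is
    ``round(depth * length / read_length)``; per-chromosome RNG streams are
    keyed by (seed, channel, chrom).
    """
    rsp.validate()
    if channel not in ("chip", "input"):
        raise ValueError("channel must be 'chip' or 'input'")
    use = [c for c in genome.chromosomes if chroms is None or c.name in chroms]
    starts: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}
    rl = rsp.read_length
    for c in use:
        rng = keyed_rng(rsp.seed, "chip_reads", channel, c.name)
        span = c.length - rl + 1
        if span <= 0:
            continue
        n = int(round(rsp.depth * c.length / rl))
        if n == 0:
            continue
        e = rsp.enrichment if channel == "chip" else 1.0
        doms = [(max(d.start - rl + 1, 0), min(d.end, span))
                for d in genome.domains if d.chrom == c.name]
        doms = [(s, t) for s, t in doms if t > s]
        if e == 1.0 or not doms:
            pos = rng.integers(0, span, size=n)
        else:
            dom_lens = np.array([t - s for s, t in doms], dtype=np.int64)
            D = int(dom_lens.sum())
            p_in = e * D / (e * D + (span - D))
            n_in = rng.binomial(n, p_in)
            off = rng.integers(0, D, size=n_in)
            cum = np.concatenate(([0], np.cumsum(dom_lens)))
            di = np.searchsorted(cum, off, side="right") - 1
            pos_in = np.array([s for s, _ in doms], dtype=np.int64)[di] + (off - cum[di])
            pos_out = _sample_complement(rng, span, doms, n - n_in)
            pos = np.concatenate([pos_in, pos_out])
        pos.sort()
        starts[c.name] = pos.astype(np.int64)
        strands[c.name] = rng.choice(np.array([1, -1], dtype=np.int8), size=len(pos))
    lengths = {c.name: c.length for c in use}
    return ReadAlignmentSet(lengths, rl, starts, strands)


def _sample_complement(rng, span, doms, n):
    """Uniform positions in [0, span) excluding the given intervals."""
    gaps = []
    prev = 0
    for s, t in sorted(doms):
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, t)
    if prev < span:
        gaps.append((prev, span))
    gap_lens = np.array([t - s for s, t in gaps], dtype=np.int64)
    total = int(gap_lens.sum())
    off = rng.integers(0, total, size=n)
    cum = np.concatenate(([0], np.cumsum(gap_lens)))
    gi = np.searchsorted(cum, off, side="right") - 1
    return np.array([s for s, _ in gaps], dtype=np.int64)[gi] + (off - cum[gi])


def read_sequences(genome: AnnotatedGenome, reads: ReadAlignmentSet,
                   error_rate: float = 0.0, seed: int = 0):
    """Yield ``(name, sequence)`` for each alignment (sequence-mode genome).

    Reverse-strand reads are reverse-complemented; optional uniform
    substitution errors.
    """
    from ._util import revcomp

    if genome.sequences is None:
        raise GenomeModelError("read sequences require a sequence-mode genome")
    rng = np.random.default_rng(seed) if error_rate > 0 else None
    i = 0
    for chrom in reads.starts:
        seq = genome.sequences[chrom]
        strands = reads.strands.get(chrom)
        for j, s in enumerate(reads.starts[chrom]):
            s = int(s)
            frag = seq[s:s + reads.read_length]
            if strands is not None and strands[j] < 0:
                frag = revcomp(frag)
            if rng is not None:
                frag = _mutate(rng, frag, error_rate)
            yield f"read_{chrom}_{i}", frag
            i += 1


def _mutate(rng, seq, rate):
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq.encode())
    for p in rng.choice(len(seq), size=n_err, replace=False):
        cur = chr(arr[p])
        alts = [b for b in "ACGT" if b != cur]
        arr[p] = ord(alts[int(rng.integers(0, 3))])
    return arr.decode()


# ---------------------------------------------------------------------------
# Paired reads mapped back through a liftover (breakpoint evidence source)
# ---------------------------------------------------------------------------


def simulate_paired_reads(derived: AnnotatedGenome, lift: LiftoverMap,
                          rsp: ReadSimParams,
                          chroms: Optional[Sequence[str]] = None) -> PairedAlignmentSet:
    """Sample read pairs from the derived genome and report their alignments
    in source-genome coordinates (what aligning strain reads to the reference
    would produce).

    Mates falling entirely in unmapped (novel) material are dropped; mates
    spanning a junction yield split alignments.
    """
    rsp.validate()
    inv = lift.inverse()
    rl = rsp.read_length
    use = [c for c in derived.chromosomes if chroms is None or c.name in chroms]
    all_c1, all_p1, all_s1 = [], [], []
    all_c2, all_p2, all_s2 = [], [], []
    splits: List[SplitAlignment] = []
    for c in use:
        blocks = sorted(
            (b for b in inv.blocks if b.src_chrom == c.name),
            key=lambda b: b.src_start,
        )
        if not blocks:
            continue
        bs = np.array([b.src_start for b in blocks], dtype=np.int64)
        be = np.array([b.src_end for b in blocks], dtype=np.int64)
        ts = np.array([b.tgt_start for b in blocks], dtype=np.int64)
        orient = np.array([b.orient for b in blocks], dtype=np.int64)
        tchrom = np.array([b.tgt_chrom for b in blocks], dtype=object)

        rng = keyed_rng(rsp.seed, "paired_reads", c.name)
        n = int(round(rsp.depth * c.length / (2 * rl)))
        if n == 0:
            continue
        flen = np.maximum(
            rng.normal(rsp.fragment_mean, rsp.fragment_sd, size=n), 2 * rl
        ).astype(np.int64)
        flen = np.minimum(flen, c.length)
        fstart = rng.integers(0, np.maximum(c.length - flen + 1, 1))

        mapped = []
        slow = np.zeros(n, dtype=bool)
        for mate, mstrand in ((0, 1), (1, -1)):
            s_arr = fstart if mate == 0 else fstart + flen - rl
            e_arr = s_arr + rl
            idx = np.searchsorted(bs, s_arr, side="right") - 1
            safe = idx >= 0
            idx0 = np.where(safe, idx, 0)
            clean = safe & (e_arr <= be[idx0]) & (s_arr >= bs[idx0])
            pos = np.where(
                orient[idx0] == 1,
                ts[idx0] + (s_arr - bs[idx0]),
                ts[idx0] + (be[idx0] - e_arr),
            )
            mapped.append((clean, tchrom[idx0], pos, mstrand * orient[idx0]))
            slow |= ~clean
        clean_both = ~slow
        c1, p1, s1 = (mapped[0][1][clean_both], mapped[0][2][clean_both],
                      mapped[0][3][clean_both])
        c2, p2, s2 = (mapped[1][1][clean_both], mapped[1][2][clean_both],
                      mapped[1][3][clean_both])
        all_c1.append(c1); all_p1.append(p1); all_s1.append(s1.astype(np.int8))
        all_c2.append(c2); all_p2.append(p2); all_s2.append(s2.astype(np.int8))

        # Slow path: junction-spanning or unmapped mates.
        for i in np.nonzero(slow)[0]:
            s, fl = int(fstart[i]), int(flen[i])
            name = f"frag_{c.name}_{i}"
            m1 = _map_read(inv, c.name, s, s + rl, +1, splits, name)
            m2 = _map_read(inv, c.name, s + fl - rl, s + fl, -1, splits, name)
            if m1 is not None and m2 is not None:
                all_c1.append(np.array([m1[0]], dtype=object))
                all_p1.append(np.array([m1[1]], dtype=np.int64))
                all_s1.append(np.array([m1[2]], dtype=np.int8))
                all_c2.append(np.array([m2[0]], dtype=object))
                all_p2.append(np.array([m2[1]], dtype=np.int64))
                all_s2.append(np.array([m2[2]], dtype=np.int8))

    out = PairedAlignmentSet({c.name: c.length for c in derived.chromosomes}, rl)
    if all_p1:
        out.chrom1 = np.concatenate(all_c1)
        out.pos1 = np.concatenate(all_p1)
        out.strand1 = np.concatenate(all_s1)
        out.chrom2 = np.concatenate(all_c2)
        out.pos2 = np.concatenate(all_p2)
        out.strand2 = np.concatenate(all_s2)
    out.splits = splits
    return out


def _map_read(inv, chrom, s, e, strand, splits, name):
    pieces = inv.lift_interval(chrom, s, e)
    if not pieces:
        return None
    if len(pieces) >= 2:
        a, b = pieces[0], pieces[1]
        splits.append(SplitAlignment(
            name,
            a[0], a[2] if a[3] == 1 else a[1],
            b[0], b[1] if b[3] == 1 else b[2],
            e - s,
        ))
    c2, s2, e2, o = max(pieces, key=lambda x: x[2] - x[1])
    return c2, s2, strand * o


# ---------------------------------------------------------------------------
# SNPome
# ---------------------------------------------------------------------------


def generate_snpome(genome: AnnotatedGenome, snp_rate: float, seed: int = 0,
                    flank: int = 70,
                    parents: Tuple[str, str] = ("OR", "MV")):
    """Biallelic substitutions at sampled positions; returns
    ``(snpome, variant_genome)``.

    SNPs avoid terminal repeat arrays and a ``flank``-bp margin at
    chromosome ends so every SNP has full read-length context.
    """
    if genome.sequences is None:
        raise GenomeModelError("SNPome generation requires sequence")
    if not 0.0 < snp_rate <= 0.05:
        raise ValueError("snp_rate must lie in (0, 0.05]")
    rng = np.random.default_rng(seed)
    chroms, positions, ref, alt = [], [], [], []
    variant_seqs = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in genome.chromosomes:
        seq = genome.sequences[c.name]
        tel_l, tel_r = genome.telomeres[c.name]
        lo = 6 * tel_l + flank
        hi = c.length - 6 * tel_r - flank
        arr = bytearray(seq.encode())
        if hi > lo:
            n = rng.binomial(hi - lo, snp_rate)
            pos = np.sort(rng.choice(hi - lo, size=n, replace=False)) + lo
            for p in pos:
                p = int(p)
                cur = seq[p]
                choices = [b for b in "ACGT" if b != cur]
                nb = choices[int(rng.integers(0, 3))]
                chroms.append(c.name)
                positions.append(p)
                ref.append(cur)
                alt.append(nb)
                arr[p] = ord(nb)
        variant_seqs[c.name] = arr.decode()
    snpome = SNPome(
        chrom=chroms, pos=positions, allele_a=ref, allele_b=alt,
        parents=parents, flank=flank,
    )
    variant = AnnotatedGenome(
        chromosomes=list(genome.chromosomes),
        telomeres=dict(genome.telomeres),
        genes=list(genome.genes),
        domains=list(genome.domains),
        sequences=variant_seqs,
        interstitial_repeats=list(genome.interstitial_repeats),
        new_capped_ends=list(genome.new_capped_ends),
        circular_junctions=dict(genome.circular_junctions),
    )
    return snpome, variant


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


def simulate_rna_counts(genome: AnnotatedGenome,
                        domains: Sequence[MethylationDomain],
                        params: RnaSimParams = RnaSimParams(),
                        sample: str = "sample") -> pd.DataFrame:
    """Negative-binomial per-gene counts with methylation repression.

    A gene fully covered by a truth domain has its mean multiplied by the
    repression factor rho; partial overlap interpolates linearly in the
    covered fraction.
    """
    if params.repression <= 0:
        raise ValueError("repression factor rho must be > 0")
    rng = np.random.default_rng(params.seed)
    ivs: Dict[str, List[Tuple[int, int]]] = {}
    for d in domains:
        ivs.setdefault(d.chrom, []).append((d.start, d.end))
    counts = {}
    r = 1.0 / params.dispersion
    for g in genome.genes:
        cov = 0
        for s, e in ivs.get(g.chrom, ()):
            cov += max(0, min(e, g.end) - max(s, g.start))
        frac = cov / (g.end - g.start) if g.end > g.start else 0.0
        mean = params.baseline_mean * ((1 - frac) + frac * params.repression)
        p = r / (r + mean)
        counts[g.gene_id] = int(rng.negative_binomial(r, p))
    return pd.DataFrame({sample: pd.Series(counts, dtype=np.int64)})


def methylated_gene_ids(genome: AnnotatedGenome,
                        domains: Sequence[MethylationDomain]) -> List[str]:
    """Genes fully covered by a domain (the transcriptionally repressed set)."""
    out = []
    for g in genome.genes:
        for d in domains:
            if d.chrom == g.chrom and d.start <= g.start and g.end <= d.end:
                out.append(g.gene_id)
                break
    return out


# ---------------------------------------------------------------------------
# Truth (noise-free) tracks
# ---------------------------------------------------------------------------


def truth_enrichment_track(genome: AnnotatedGenome, enrichment: float = 8.0,
                           window: int = 100, step: int = 50):
    """Noise-free per-window track: 1 + (e-1) * fraction of window inside a
    truth domain. Returned as a :class:`~subtelo.coverage_norm.CoverageTrack`."""
    from .coverage_norm import CoverageTrack

    values = {}
    for c in genome.chromosomes:
        n = CoverageTrack.n_windows(c.length, window, step)
        v = np.ones(n)
        starts = np.arange(n, dtype=np.int64) * step
        for d in genome.domains:
            if d.chrom != c.name:
                continue
            ov = (np.minimum(d.end, starts + window)
                  - np.maximum(d.start, starts)).clip(0)
            v += (enrichment - 1.0) * ov / window
        values[c.name] = v
    return CoverageTrack(genome.chrom_lengths, window, step, values)
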