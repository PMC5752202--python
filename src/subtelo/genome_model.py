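"""Genome data model: chromosomes, rearrangements, liftover and truth methylation.

Coordinates are 0-based, half-open throughout. A chromosome end is
"repeat-capped" when it carries a non-zero telomere-repeat array; circular
chromosomes carry no terminal arrays. Methylation domains are tagged either
``position_dependent`` (maintained only near telomere repeats) or
``position_independent`` (retained wherever they lie), and
:func:`reevaluate_methylation` computes the ground-truth domain set of a
rearranged genome from those tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from scipy.stats import truncnorm

from ._util import interval_gap, keyed_rng, merge_intervals, revcomp

TELOMERE_UNIT = "TTAGGG"
TELOMERE_UNIT_RC = "CCCTAA"

POSITION_DEPENDENT = "position_dependent"
POSITION_INDEPENDENT = "position_independent"

REARRANGEMENT_KINDS = (
    "insertional_translocation",
    "reciprocal_translocation",
    "quasiterminal_translocation",
    "deletion",
    "insertion_at_locus",
    "circularize",
)


class GenomeModelError(ValueError):
    """Raised on invalid genomes, rearrangements or liftover queries."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    circular: bool = False


@dataclass(frozen=True)
class Gene:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str


@dataclass(frozen=True)
class MethylationDomain:
    chrom: str
    start: int
    end: int
    klass: str

    def __post_init__(self):
        if self.end <= self.start:
            raise GenomeModelError(
                f"domain {self.chrom}:{self.start}-{self.end} has end <= start"
            )
        if self.klass not in (POSITION_DEPENDENT, POSITION_INDEPENDENT):
            raise GenomeModelError(f"unknown domain class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InterstitialRepeat:
    """An internal (TTAGGG)_n array, e.g. from targeted insertion."""

    chrom: str
    pos: int
    n: int

    @property
    def end(self) -> int:
        return self.pos + 6 * self.n


@dataclass(frozen=True)
class Rearrangement:
    """One of the six modeled rearrangement classes.

    ``segment`` is the moved/deleted donor interval (half-open);
    ``insertion_point`` the acceptor coordinate receiving material (or the
    acceptor breakpoint for a reciprocal exchange). ``orientation`` is +1 or
    -1 for the moved segment. ``novel_repeats`` > 0 turns an
    ``insertion_at_locus`` into a telomere-repeat insertion;
    ``duplicate=True`` leaves the donor segment in place and inserts a copy.
    ``heal_repeats`` is the array length used for de-novo telomere healing of
    ends created by quasiterminal translocation or terminal deletion.
    """

    kind: str
    donor: Optional[str] = None
    acceptor: Optional[str] = None
    segment: Optional[Tuple[int, int]] = None
    insertion_point: Optional[int] = None
    orientation: int = 1
    novel_repeats: int = 0
    duplicate: bool = False
    heal_repeats: int = 20

    def __post_init__(self):
        if self.kind not in REARRANGEMENT_KINDS:
            raise GenomeModelError(f"unknown rearrangement kind {self.kind!r}")
        if self.orientation not in (1, -1):
            raise GenomeModelError("orientation must be +1 or -1")


@dataclass(frozen=True)
class LiftBlock:
    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orient: int

    def __post_init__(self):
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise GenomeModelError("liftover block source/target lengths differ")


class LiftoverMap:
    """Invertible piecewise map between source and derived coordinates."""

    def __init__(self, blocks: Sequence[LiftBlock], deleted=()):
        self.blocks = list(blocks)
        self.deleted = [(c, int(s), int(e)) for c, s, e in deleted]
        self._by_src: Dict[str, List[LiftBlock]] = {}
        for b in self.blocks:
            self._by_src.setdefault(b.src_chrom, []).append(b)
        for lst in self._by_src.values():
            lst.sort(key=lambda b: b.src_start)
            for a, b in zip(lst, lst[1:]):
                if b.src_start < a.src_end:
                    raise GenomeModelError("liftover blocks overlap on source")

    @classmethod
    def identity(cls, genome: "AnnotatedGenome") -> "LiftoverMap":
        blocks = [
            LiftBlock(c.name, 0, c.length, c.name, 0, c.length, 1)
            for c in genome.chromosomes
        ]
        return cls(blocks)

    def source_chromosomes(self):
        return set(self._by_src)

    def lift_interval(self, chrom: str, start: int, end: int):
        """Map a source interval; returns ``[(chrom, start, end, orient), ...]``.

        Pieces are ordered along the source interval. Deleted bases simply do
        not appear; an interval entirely within a deleted segment yields ``[]``.
        """
        if chrom not in self._by_src and not any(c == chrom for c, _, _ in self.deleted):
            raise GenomeModelError(f"unknown source chromosome {chrom!r}")
        out = []
        for b in self._by_src.get(chrom, ()):
            a = max(start, b.src_start)
            z = min(end, b.src_end)
            if a >= z:
                continue
            if b.orient == 1:
                t0 = b.tgt_start + (a - b.src_start)
                out.append((b.tgt_chrom, t0, t0 + (z - a), 1))
            else:
                t0 = b.tgt_start + (b.src_end - z)
                out.append((b.tgt_chrom, t0, t0 + (z - a), -1))
        return out

    def lift_position(self, chrom: str, pos: int):
        """Map one base; ``None`` if deleted."""
        res = self.lift_interval(chrom, pos, pos + 1)
        if not res:
            return None
        c, s, e, o = res[0]
        return (c, s, o)

    def inverse(self) -> "LiftoverMap":
        blocks = [
            LiftBlock(
                b.tgt_chrom, b.tgt_start, b.tgt_end,
                b.src_chrom, b.src_start, b.src_end, b.orient,
            )
            for b in self.blocks
        ]
        return LiftoverMap(blocks)


@dataclass
class AnnotatedGenome:
    """Chromosomes plus telomere arrays, genes, truth domains and (optionally)
    sequence.

    ``telomeres`` maps chromosome name to ``(left_n, right_n)`` repeat counts.
    ``new_capped_ends`` lists ``(chrom, side)`` ends created by de-novo
    telomere healing (these nucleate truth methylation on re-evaluation).
    ``circular_junctions`` records, per circularized chromosome, how many bp
    of terminal repeat array were trimmed at each former end.
    """

    chromosomes: List[Chromosome]
    telomeres: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    genes: List[Gene] = field(default_factory=list)
    domains: List[MethylationDomain] = field(default_factory=list)
    sequences: Optional[Dict[str, str]] = None
    interstitial_repeats: List[InterstitialRepeat] = field(default_factory=list)
    new_capped_ends: List[Tuple[str, str]] = field(default_factory=list)
    circular_junctions: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        self._index = {c.name: c for c in self.chromosomes}
        if len(self._index) != len(self.chromosomes):
            raise GenomeModelError("duplicate chromosome names")
        for c in self.chromosomes:
            self.telomeres.setdefault(c.name, (0, 0))

    def chrom(self, name: str) -> Chromosome:
        try:
            return self._index[name]
        except KeyError:
            raise GenomeModelError(f"unknown chromosome {name!r}") from None

    def length(self, name: str) -> int:
        return self.chrom(name).length

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def validate(self) -> None:
        for g in self.genes:
            c = self.chrom(g.chrom)
            if not (0 <= g.start <= g.end <= c.length):
                raise GenomeModelError(f"gene {g.gene_id} out of bounds")
        per_chrom: Dict[str, list] = {}
        for d in self.domains:
            c = self.chrom(d.chrom)
            if not (0 <= d.start < d.end <= c.length):
                raise GenomeModelError(f"domain {d} out of bounds")
            per_chrom.setdefault(d.chrom, []).append((d.start, d.end))
        for name, ivs in per_chrom.items():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                if b[0] < a[1]:
                    raise GenomeModelError(f"overlapping domains on {name}")
        for c in self.chromosomes:
            ln, rn = self.telomeres[c.name]
            if c.circular and (ln or rn):
                raise GenomeModelError(
                    f"circular chromosome {c.name} has terminal repeats"
                )
            if min(ln, rn) < 0:
                raise GenomeModelError("negative telomere repeat count")
        if self.sequences is not None:
            for c in self.chromosomes:
                if len(self.sequences[c.name]) != c.length:
                    raise GenomeModelError(f"sequence length mismatch on {c.name}")


# ---------------------------------------------------------------------------
# Rearrangement application
# ---------------------------------------------------------------------------

# Internal layout pieces:
#   ("src", chrom, start, end, orient)    mapped material (enters liftover)
#   ("tel", n, side)                      de-novo telomere repeats (novel)
#   ("dup", chrom, start, end, orient)    duplicated copy (novel; annotations
#                                         are copied, coordinates not mapped)


def _piece_len(p) -> int:
    if p[0] == "tel":
        return 6 * p[1]
    return p[3] - p[2] if p[0] == "src" else p[3] - p[2]


def _check_segment(genome, chrom, seg):
    L = genome.length(chrom)
    s, e = seg
    if not (0 <= s <= e <= L):
        raise GenomeModelError(f"segment {seg} out of bounds on {chrom}")


def apply_rearrangement(genome: AnnotatedGenome, r: Rearrangement):
    """Apply one rearrangement; returns ``(derived_genome, liftover_map)``.

    Telomere arrays travel with chromosome ends; genes and domains are lifted
    through the map (a feature split by a junction keeps its largest piece for
    genes, and every piece for domains). Duplicated segments are annotated in
    place but, to keep the map one-to-one, only the native copy is mapped.
    """
    kind = r.kind
    if kind == "insertional_translocation":
        return _apply_insertional(genome, r)
    if kind == "reciprocal_translocation":
        return _apply_reciprocal(genome, r)
    if kind == "quasiterminal_translocation":
        return _apply_quasiterminal(genome, r)
    if kind == "deletion":
        return _apply_deletion(genome, r)
    if kind == "insertion_at_locus":
        return _apply_insertion_at_locus(genome, r)
    if kind == "circularize":
        return _apply_circularize(genome, r)
    raise GenomeModelError(f"unknown rearrangement kind {kind!r}")


def _apply_insertional(genome, r):
    donor, acceptor = r.donor, r.acceptor
    s, e = r.segment
    p = r.insertion_point
    _check_segment(genome, donor, (s, e))
    M = genome.length(acceptor)
    if not (0 <= p <= M):
        raise GenomeModelError("insertion point out of bounds")
    if donor == acceptor and s <= p < e and e > s:
        raise GenomeModelError("insertion point inside the moved segment")
    if e == s:  # empty move: identity
        return _assemble(genome, {}, {})
    layout = {}
    if donor == acceptor:
        L = genome.length(donor)
        if p <= s:
            pieces = [
                ("src", donor, 0, p, 1),
                ("src", donor, s, e, r.orientation),
                ("src", donor, p, s, 1),
                ("src", donor, e, L, 1),
            ]
        else:  # p >= e
            pieces = [
                ("src", donor, 0, s, 1),
                ("src", donor, e, p, 1),
                ("src", donor, s, e, r.orientation),
                ("src", donor, p, L, 1),
            ]
        layout[donor] = pieces
    else:
        L = genome.length(donor)
        layout[donor] = [("src", donor, 0, s, 1), ("src", donor, e, L, 1)]
        layout[acceptor] = [
            ("src", acceptor, 0, p, 1),
            ("src", donor, s, e, r.orientation),
            ("src", acceptor, p, M, 1),
        ]
    return _assemble(genome, layout, {})


def _apply_reciprocal(genome, r):
    donor, acceptor = r.donor, r.acceptor
    if donor == acceptor:
        raise GenomeModelError("reciprocal translocation needs two chromosomes")
    a = r.segment[0]
    b = r.insertion_point
    L, M = genome.length(donor), genome.length(acceptor)
    if r.segment[1] != L:
        raise GenomeModelError("reciprocal exchange segment must reach the donor end")
    if not (0 < a < L and 0 < b < M):
        raise GenomeModelError("reciprocal breakpoints out of bounds")
    layout = {
        donor: [("src", donor, 0, a, 1), ("src", acceptor, b, M, 1)],
        acceptor: [("src", acceptor, 0, b, 1), ("src", donor, a, L, 1)],
    }
    tel = {
        donor: (genome.telomeres[donor][0], genome.telomeres[acceptor][1]),
        acceptor: (genome.telomeres[acceptor][0], genome.telomeres[donor][1]),
    }
    return _assemble(genome, layout, tel)


def _apply_quasiterminal(genome, r):
    donor, acceptor = r.donor, r.acceptor
    if donor == acceptor:
        raise GenomeModelError("quasiterminal translocation needs two chromosomes")
    s, e = r.segment
    L, M = genome.length(donor), genome.length(acceptor)
    if e != L:
        raise GenomeModelError("quasiterminal segment must be terminal on the donor")
    _check_segment(genome, donor, (s, e))
    acc_tel_r = genome.telomeres[acceptor][1]
    trim = 6 * acc_tel_r
    layout = {
        donor: [("src", donor, 0, s, 1), ("tel", r.heal_repeats, "right")],
        acceptor: [("src", acceptor, 0, M - trim, 1), ("src", donor, s, L, 1)],
    }
    tel = {
        donor: (genome.telomeres[donor][0], r.heal_repeats),
        acceptor: (genome.telomeres[acceptor][0], genome.telomeres[donor][1]),
    }
    deleted = [(acceptor, M - trim, M)] if trim else []
    new_ends = [(donor, "right")] if r.heal_repeats > 0 else []
    return _assemble(genome, layout, tel, deleted=deleted, new_ends=new_ends)


def _apply_deletion(genome, r):
    chrom = r.donor
    s, e = r.segment
    _check_segment(genome, chrom, (s, e))
    L = genome.length(chrom)
    if e == s:
        return _assemble(genome, {}, {})
    tel_l, tel_r = genome.telomeres[chrom]
    deleted = [(chrom, s, e)]
    new_ends = []
    if e == L:  # terminal deletion on the right: heal
        layout = {chrom: [("src", chrom, 0, s, 1), ("tel", r.heal_repeats, "right")]}
        tel = {chrom: (tel_l, r.heal_repeats)}
        if r.heal_repeats > 0:
            new_ends.append((chrom, "right"))
    elif s == 0:  # terminal deletion on the left: heal
        layout = {chrom: [("tel", r.heal_repeats, "left"), ("src", chrom, e, L, 1)]}
        tel = {chrom: (r.heal_repeats, tel_r)}
        if r.heal_repeats > 0:
            new_ends.append((chrom, "left"))
    else:
        layout = {chrom: [("src", chrom, 0, s, 1), ("src", chrom, e, L, 1)]}
        tel = {chrom: (tel_l, tel_r)}
    return _assemble(genome, layout, tel, deleted=deleted, new_ends=new_ends)


def _apply_insertion_at_locus(genome, r):
    acceptor = r.acceptor
    p = r.insertion_point
    M = genome.length(acceptor)
    if not (0 <= p <= M):
        raise GenomeModelError("insertion point out of bounds")
    if r.novel_repeats > 0:
        mid = ("tel", r.novel_repeats, "right")
        extra_repeats = [InterstitialRepeat(acceptor, p, r.novel_repeats)]
    elif r.duplicate and r.segment is not None and r.donor is not None:
        _check_segment(genome, r.donor, r.segment)
        if r.donor == acceptor and r.segment[0] <= p < r.segment[1]:
            raise GenomeModelError("insertion point inside the duplicated segment")
        mid = ("dup", r.donor, r.segment[0], r.segment[1], r.orientation)
        extra_repeats = []
    else:
        return _assemble(genome, {}, {})  # zero-length: identity
    layout = {
        acceptor: [("src", acceptor, 0, p, 1), mid, ("src", acceptor, p, M, 1)]
    }
    return _assemble(genome, layout, {}, extra_repeats=extra_repeats)


def _apply_circularize(genome, r):
    chrom = r.donor if r.donor is not None else r.acceptor
    c = genome.chrom(chrom)
    if c.circular:
        raise GenomeModelError(f"{chrom} is already circular")
    tel_l, tel_r = genome.telomeres[chrom]
    trim_l, trim_r = 6 * tel_l, 6 * tel_r
    layout = {chrom: [("src", chrom, trim_l, c.length - trim_r, 1)]}
    deleted = []
    if trim_l:
        deleted.append((chrom, 0, trim_l))
    if trim_r:
        deleted.append((chrom, c.length - trim_r, c.length))
    return _assemble(
        genome, layout, {chrom: (0, 0)},
        deleted=deleted, circular={chrom},
        junctions={chrom: {"trim_left": trim_l, "trim_right": trim_r}},
    )


def _assemble(genome, layout, telomeres, deleted=(), new_ends=(),
              circular=frozenset(), extra_repeats=(), junctions=None):
    """Build the derived genome + liftover from per-chromosome piece layouts.

    Chromosomes absent from ``layout`` pass through unchanged (identity
    blocks), preserving genome order.
    """
    full_layout = {}
    for c in genome.chromosomes:
        full_layout[c.name] = layout.get(
            c.name, [("src", c.name, 0, c.length, 1)]
        )

    blocks = []
    dup_pieces = []  # (tgt_chrom, tgt_start, src_chrom, s, e, orient)
    new_chroms = []
    for c in genome.chromosomes:
        offset = 0
        for p in full_layout[c.name]:
            plen = _piece_len(p)
            if p[0] == "src":
                _, sc, s, e, o = p
                if plen:
                    blocks.append(LiftBlock(sc, s, e, c.name, offset, offset + plen, o))
            elif p[0] == "dup":
                _, sc, s, e, o = p
                dup_pieces.append((c.name, offset, sc, s, e, o))
            offset += plen
        new_chroms.append(Chromosome(c.name, offset, circular=c.name in circular or genome.chrom(c.name).circular))

    lift = LiftoverMap(blocks, deleted=deleted)

    # Genes: keep the largest lifted piece; strand flips under orient -1.
    new_genes = []
    for g in genome.genes:
        pieces = lift.lift_interval(g.chrom, g.start, g.end)
        if not pieces:
            continue
        c2, s2, e2, o = max(pieces, key=lambda x: x[2] - x[1])
        strand = g.strand if o == 1 else ("-" if g.strand == "+" else "+")
        new_genes.append(Gene(c2, s2, e2, strand, g.gene_id))

    # Domains: every lifted piece survives with its class tag.
    new_domains = []
    for d in genome.domains:
        for c2, s2, e2, _ in lift.lift_interval(d.chrom, d.start, d.end):
            new_domains.append(MethylationDomain(c2, s2, e2, d.klass))

    # Interstitial repeat arrays lift as points.
    new_repeats = []
    for ir in genome.interstitial_repeats:
        res = lift.lift_interval(ir.chrom, ir.pos, ir.end)
        if res:
            c2, s2, e2, _ = max(res, key=lambda x: x[2] - x[1])
            if e2 - s2 == 6 * ir.n:
                new_repeats.append(InterstitialRepeat(c2, s2, ir.n))
    new_repeats.extend(extra_repeats)

    # Copy annotations into duplicated segments.
    for tgt_chrom, tgt_off, sc, s, e, o in dup_pieces:
        seg_len = e - s
        for g in genome.genes:
            if g.chrom == sc and g.start >= s and g.end <= e:
                if o == 1:
                    ns, ne = tgt_off + (g.start - s), tgt_off + (g.end - s)
                    strand = g.strand
                else:
                    ns, ne = tgt_off + (e - g.end), tgt_off + (e - g.start)
                    strand = "-" if g.strand == "+" else "+"
                new_genes.append(Gene(tgt_chrom, ns, ne, strand, g.gene_id + "_dup"))
        for d in genome.domains:
            if d.chrom == sc:
                a, z = max(d.start, s), min(d.end, e)
                if a < z:
                    if o == 1:
                        ns, ne = tgt_off + (a - s), tgt_off + (z - s)
                    else:
                        ns, ne = tgt_off + (e - z), tgt_off + (e - a)
                    new_domains.append(MethylationDomain(tgt_chrom, ns, ne, d.klass))

    new_tel = dict(genome.telomeres)
    new_tel.update(telomeres)
    for name in circular:
        new_tel[name] = (0, 0)

    new_junctions = dict(genome.circular_junctions)
    if junctions:
        new_junctions.update(junctions)

    # Carry forward previously recorded de-novo ends that still exist.
    carried_ends = [
        (c, side) for (c, side) in genome.new_capped_ends
        if new_tel.get(c, (0, 0))[0 if side == "left" else 1] > 0
    ]
    all_new_ends = carried_ends + [x for x in new_ends if x not in carried_ends]

    sequences = None
    if genome.sequences is not None:
        sequences = {}
        for c in genome.chromosomes:
            parts = []
            for p in full_layout[c.name]:
                if p[0] == "tel":
                    unit = TELOMERE_UNIT_RC if p[2] == "left" else TELOMERE_UNIT
                    parts.append(unit * p[1])
                else:
                    _, sc, s, e, o = p
                    frag = genome.sequences[sc][s:e]
                    parts.append(frag if o == 1 else revcomp(frag))
            sequences[c.name] = "".join(parts)

    derived = AnnotatedGenome(
        chromosomes=new_chroms,
        telomeres=new_tel,
        genes=new_genes,
        domains=_merge_domains(new_domains),
        sequences=sequences,
        interstitial_repeats=new_repeats,
        new_capped_ends=all_new_ends,
        circular_junctions=new_junctions,
    )
    return derived, lift


def _merge_domains(domains: List[MethylationDomain]) -> List[MethylationDomain]:
    """Sort and merge overlapping domains per chromosome.

    Overlaps between classes (rare; e.g. an induced domain engulfing a
    position-independent one) merge to ``position_dependent``.
    """
    by_chrom: Dict[str, List[MethylationDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    out = []
    for chrom in by_chrom:
        ds = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        cur = None
        for d in ds:
            if cur is None:
                cur = [d.start, d.end, d.klass]
            elif d.start <= cur[1]:
                cur[1] = max(cur[1], d.end)
                if d.klass != cur[2]:
                    cur[2] = POSITION_DEPENDENT
            else:
                out.append(MethylationDomain(chrom, cur[0], cur[1], cur[2]))
                cur = [d.start, d.end, d.klass]
        if cur is not None:
            out.append(MethylationDomain(chrom, cur[0], cur[1], cur[2]))
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def apply_rearrangements(genome: AnnotatedGenome, rearrangements):
    """Apply a sequence of rearrangements, composing the liftover maps."""
    current = genome
    composed = LiftoverMap.identity(genome)
    for r in rearrangements:
        current, lift = apply_rearrangement(current, r)
        composed = compose_liftover(composed, lift)
    return current, composed


def compose_liftover(first: LiftoverMap, second: LiftoverMap) -> LiftoverMap:
    """Map composition: source of ``first`` to target of ``second``."""
    blocks = []
    for b in first.blocks:
        for b2 in second.blocks:
            if b2.src_chrom != b.tgt_chrom:
                continue
            a = max(b.tgt_start, b2.src_start)
            z = min(b.tgt_end, b2.src_end)
            if a >= z:
                continue
            if b.orient == 1:
                ss = b.src_start + (a - b.tgt_start)
            else:
                ss = b.src_start + (b.tgt_end - z)
            if b2.orient == 1:
                ts = b2.tgt_start + (a - b2.src_start)
            else:
                ts = b2.tgt_start + (b2.src_end - z)
            blocks.append(
                LiftBlock(b.src_chrom, ss, ss + (z - a),
                          b2.tgt_chrom, ts, ts + (z - a), b.orient * b2.orient)
            )
    deleted = list(first.deleted)
    # Bases deleted in the second step map back through the first.
    inv_first = first.inverse()
    for c, s, e in second.deleted:
        if c in inv_first.source_chromosomes():
            for ci, si, ei, _ in inv_first.lift_interval(c, s, e):
                deleted.append((ci, si, ei))
    return LiftoverMap(blocks, deleted=deleted)


# ---------------------------------------------------------------------------
# Telomere distance and truth methylation
# ---------------------------------------------------------------------------


def distance_to_repeat_capped_end(genome: AnnotatedGenome, chrom: str, pos: int) -> float:
    """Distance (bp) from ``pos`` to the nearest repeat-capped chromosome end.

    Returns ``inf`` on circular chromosomes or when neither end carries
    repeats.
    """
    c = genome.chrom(chrom)
    if not (0 <= pos < c.length):
        raise GenomeModelError(f"position {pos} outside {chrom}")
    if c.circular:
        return math.inf
    left_n, right_n = genome.telomeres[chrom]
    best = math.inf
    if left_n > 0:
        best = min(best, pos)
    if right_n > 0:
        best = min(best, c.length - 1 - pos)
    return best


@dataclass(frozen=True)
class TruthParams:
    """Parameters of the ground-truth methylation rule.

    ``d_tel`` is the sharp telomere-influence distance; position-dependent
    domains farther than this from every maintaining repeat anchor are lost.
    New repeat-capped ends nucleate de-novo domains with inward extension
    drawn from a truncated normal (mean/sd/bounds below). Interstitial arrays
    of >= ``min_inducing_repeats`` units induce a domain whose total span is
    drawn from the large- or small-array normal depending on repeat count,
    split ``interstitial_split`` / (1 - split) around the insertion point.
    """

    d_tel: int = 250_000
    min_inducing_repeats: int = 5
    end_ext_mean: float = 180_000.0
    end_ext_sd: float = 40_000.0
    end_ext_min: float = 30_000.0
    large_array_repeats: int = 10
    interstitial_span_large: Tuple[float, float] = (225_000.0, 25_000.0)
    interstitial_span_small: Tuple[float, float] = (20_000.0, 5_000.0)
    interstitial_split: float = 0.75
    seed: int = 0


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    if sd <= 0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _maintenance_distance(genome, params, chrom, start, end) -> float:
    """Nearest-edge distance from [start, end) to any maintaining repeat
    anchor (capped linear end or inducing interstitial array) on ``chrom``."""
    c = genome.chrom(chrom)
    best = math.inf
    if not c.circular:
        left_n, right_n = genome.telomeres[chrom]
        if left_n > 0:
            best = min(best, start)
        if right_n > 0:
            best = min(best, c.length - end)
    for ir in genome.interstitial_repeats:
        if ir.chrom == chrom and ir.n >= params.min_inducing_repeats:
            best = min(best, interval_gap(start, end, ir.pos, ir.end))
    return best


def reevaluate_methylation(genome: AnnotatedGenome,
                           params: TruthParams = TruthParams()):
    """Ground-truth post-rearrangement methylation domain set.

    Rules: (i) position-dependent domains survive only within ``d_tel`` of a
    maintaining repeat anchor; (ii) position-independent domains survive
    anywhere; (iii) de-novo healed ends and inducing interstitial arrays
    nucleate new position-dependent domains with sampled extents; (iv)
    circular chromosomes have no telomere-proximal domains. Deterministic in
    (genome, params): extension draws are keyed by chromosome/end identity,
    so re-evaluation is idempotent.
    """
    for d in genome.domains:
        if d.klass not in (POSITION_DEPENDENT, POSITION_INDEPENDENT):
            raise GenomeModelError("domain missing class tag")

    kept = []
    for d in genome.domains:
        if d.klass == POSITION_INDEPENDENT:
            kept.append(d)
            continue
        dist = _maintenance_distance(genome, params, d.chrom, d.start, d.end)
        if dist <= params.d_tel:
            kept.append(d)

    # De-novo domains at healed ends.
    for chrom, side in genome.new_capped_ends:
        c = genome.chrom(chrom)
        if c.circular:
            continue
        left_n, right_n = genome.telomeres[chrom]
        n = left_n if side == "left" else right_n
        if n <= 0:
            continue
        rng = keyed_rng(params.seed, "end", chrom, side)
        ext = int(_trunc_normal(rng, params.end_ext_mean, params.end_ext_sd,
                                params.end_ext_min, params.d_tel))
        tel_bp = 6 * n
        if side == "left":
            s, e = tel_bp, min(tel_bp + ext, c.length)
        else:
            s, e = max(c.length - tel_bp - ext, 0), c.length - tel_bp
        if e > s:
            kept.append(MethylationDomain(chrom, s, e, POSITION_DEPENDENT))

    # Induction by interstitial arrays.
    for ir in genome.interstitial_repeats:
        if ir.n < params.min_inducing_repeats:
            continue
        c = genome.chrom(ir.chrom)
        mean, sd = (params.interstitial_span_large
                    if ir.n >= params.large_array_repeats
                    else params.interstitial_span_small)
        rng = keyed_rng(params.seed, "interstitial", ir.chrom, ir.pos, ir.n)
        span = _trunc_normal(rng, mean, sd, 1_000.0, 2 * params.d_tel)
        big = span * params.interstitial_split
        small = span - big
        left_first = bool(rng.integers(0, 2))
        left_span, right_span = (big, small) if left_first else (small, big)
        s = max(int(ir.pos - left_span), 0)
        e = min(int(ir.end + right_span), c.length)
        if e > s:
            kept.append(MethylationDomain(ir.chrom, s, e, POSITION_DEPENDENT))

    return _merge_domains(kept)


def with_truth_methylation(genome: AnnotatedGenome,
                           params: TruthParams = TruthParams()) -> AnnotatedGenome:
    """Return a copy of ``genome`` whose domains are re-evaluated truth."""
    return replace(genome, domains=reevaluate_methylation(genome, params))
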