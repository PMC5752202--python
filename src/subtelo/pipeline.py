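"""End-to-end seeded pipeline runs: simulate, analyze, write artifacts.

A :class:`RunConfig` fully determines a run; identical config + seeds give
byte-identical manifests (every output file is recorded with a sha256
digest). Read simulation can be restricted to the chromosomes a scenario
touches, which keeps desk-scale runtime without changing results elsewhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

from . import io as sio
from .breakpoints import cluster_and_call, collect_evidence, fusion_junction_test, match_truth
from .coverage_norm import normalize_track, scaling_factor, window_coverage
from .domain_analysis import (
    GAINED,
    INVARIANT,
    LOST,
    anchored_span_and_genes,
    call_domains,
    classify_differential,
    subtelomeric_extension,
)
from .expression_stats import log2_ratio_by_class
from .genome_model import TruthParams
from .synthetic_data import (
    GeneratorParams,
    ReadSimParams,
    RnaSimParams,
    StrainScenario,
    build_scenario,
    generate_wt_genome,
    genome_manifest,
    simulate_chip_reads,
    simulate_paired_reads,
    simulate_rna_counts,
)

log = logging.getLogger("subtelo.pipeline")


@dataclass
class CallerParams:
    T: float = 2.0
    G: int = 10_000
    S: int = 500
    min_overlap: float = 0.5
    window: int = 100
    step: int = 50


@dataclass
class BreakpointParams:
    cluster_dist: int = 500
    min_weight: int = 5
    depth: float = 30.0


@dataclass
class RunConfig:
    scenarios: List[str] = field(default_factory=list)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    reads: ReadSimParams = field(default_factory=lambda: ReadSimParams(depth=20.0))
    truth: TruthParams = field(default_factory=TruthParams)
    caller: CallerParams = field(default_factory=CallerParams)
    bp: BreakpointParams = field(default_factory=BreakpointParams)
    rna: RnaSimParams = field(default_factory=RnaSimParams)
    seed: int = 0
    outdir: str = "run"
    restrict_chroms: bool = True
    run_breakpoints: bool = True
    run_expression: bool = True

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if os.path.exists(str(source)):
            with open(source) as fh:
                d = json.load(fh)
        else:
            d = json.loads(source)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, key):
            sub = d.get(key, {})
            fields = {f.name for f in dataclasses.fields(klass)}
            sub = {k: v for k, v in sub.items() if k in fields}
            for k, v in list(sub.items()):
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return klass(**sub)

        return cls(
            scenarios=list(d.get("scenarios", [])),
            generator=build(GeneratorParams, "generator"),
            reads=build(ReadSimParams, "reads"),
            truth=build(TruthParams, "truth"),
            caller=build(CallerParams, "caller"),
            bp=build(BreakpointParams, "bp"),
            rna=build(RnaSimParams, "rna"),
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir", "run"),
            restrict_chroms=bool(d.get("restrict_chroms", True)),
            run_breakpoints=bool(d.get("run_breakpoints", True)),
            run_expression=bool(d.get("run_expression", True)),
        )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _affected_chroms(scenario: StrainScenario) -> List[str]:
    names = set()
    for r in scenario.rearrangements:
        for c in (r.donor, r.acceptor):
            if c is not None:
                names.add(c)
    return sorted(names) if names else [c.name for c in scenario.derived.chromosomes]


def scenario_tracks(scenario: StrainScenario, reads: ReadSimParams,
                    caller: CallerParams, chroms: Optional[List[str]] = None):
    """Simulate chip/input on the derived genome and return normalized
    chip track plus input track (scaling factor = mapped-read ratio)."""
    chip = simulate_chip_reads(scenario.derived, reads, "chip", chroms=chroms)
    inp = simulate_chip_reads(scenario.derived, reads, "input", chroms=chroms)
    lengths = {c: scenario.derived.length(c)
               for c in (chroms or [x.name for x in scenario.derived.chromosomes])}
    chip_t = window_coverage(chip, lengths, caller.window, caller.step)
    inp_t = window_coverage(inp, lengths, caller.window, caller.step)
    sf = scaling_factor(max(chip.n_reads, 1), max(inp.n_reads, 1))
    chip_t = normalize_track(chip_t, sf, reference_id="input")
    return chip_t, inp_t


def run_scenario(config: RunConfig, genome, wt_calls, name: str,
                 outdir: str) -> dict:
    """One scenario end to end; returns its metrics dict."""
    log.info("[%s] building scenario", name)
    truth = dataclasses.replace(config.truth, seed=config.seed)
    scenario = build_scenario(name, genome, seed=config.seed, truth_params=truth)
    os.makedirs(outdir, exist_ok=True)
    files = sio.save_genome(scenario.derived, outdir)
    sio.write_liftover_tsv(scenario.liftover, os.path.join(outdir, "liftover.tsv"))
    files["liftover"] = os.path.join(outdir, "liftover.tsv")

    chroms = _affected_chroms(scenario) if config.restrict_chroms else None
    log.info("[%s] simulating reads on %s", name, chroms or "all chromosomes")
    chip_t, inp_t = scenario_tracks(scenario, config.reads, config.caller, chroms)
    chip_bg = os.path.join(outdir, "chip.bedgraph")
    chip_t.to_bedgraph(chip_bg)
    files["chip_bedgraph"] = chip_bg

    calls = call_domains(chip_t, inp_t, config.caller.T, config.caller.G,
                         config.caller.S)
    calls.to_bed(os.path.join(outdir, "calls.bed"))
    files["calls_bed"] = os.path.join(outdir, "calls.bed")

    # Differential classification against wild-type calls on those chroms.
    diff = classify_differential(wt_calls, calls, scenario.liftover,
                                 min_overlap=config.caller.min_overlap)
    restrict = None if chroms is None else set(chroms)
    if restrict is not None:
        diff.calls = [c for c in diff.calls if c.chrom in restrict]
    diff.to_bed(os.path.join(outdir, "differential.bed"))
    files["differential_bed"] = os.path.join(outdir, "differential.bed")

    metrics: dict = {
        "n_calls": len(calls),
        "labels": {
            lab: sum(1 for c in diff if c.label == lab)
            for lab in (GAINED, LOST, INVARIANT)
        },
    }

    for chrom, side in scenario.derived.new_capped_ends:
        if restrict is None or chrom in restrict:
            ext = subtelomeric_extension(calls, chrom,
                                         scenario.derived.length(chrom),
                                         side=side, G=config.caller.G)
            metrics.setdefault("new_end_extension_bp", {})[f"{chrom}:{side}"] = ext

    if "insertion" in scenario.meta:
        chrom, pos, k = scenario.meta["insertion"]
        span, far, n_genes = anchored_span_and_genes(
            calls, chrom, pos, scenario.derived.genes,
            chrom_length=scenario.derived.length(chrom), G=config.caller.G)
        metrics["anchored"] = {"span_bp": span, "farthest_bp": far,
                               "n_genes": n_genes, "repeats": k}

    if config.run_breakpoints and scenario.truth_breakpoints:
        rsp = dataclasses.replace(config.reads, depth=config.bp.depth,
                                  paired=True)
        pairs = simulate_paired_reads(scenario.derived, scenario.liftover, rsp,
                                      chroms=chroms)
        ev = collect_evidence(pairs, rsp.fragment_mean, rsp.fragment_sd)
        bcalls = cluster_and_call(ev, config.bp.cluster_dist, config.bp.min_weight)
        tp, fp, fn = match_truth(bcalls, scenario.truth_breakpoints)
        metrics["breakpoints"] = {"n_calls": len(bcalls), "tp": tp, "fp": fp,
                                  "fn": fn}

    if name == "tert":
        metrics["fusion_test"] = fusion_junction_test(scenario.derived)

    if config.run_expression:
        rna = dataclasses.replace(config.rna, seed=config.seed)
        wt_counts = simulate_rna_counts(genome, genome.domains, rna, sample="wt")
        # strain counts simulated on derived genes/domains, indexed by gene id
        strain_counts = simulate_rna_counts(
            scenario.derived, scenario.derived.domains,
            dataclasses.replace(rna, seed=rna.seed + 1), sample=name)
        table = wt_counts.join(strain_counts, how="inner")
        if len(table) and table.sum().min() > 0 and len(diff.calls):
            values, summaries = log2_ratio_by_class(
                table, name, "wt", diff, scenario.derived.genes)
            metrics["expression"] = {
                k: (s["median"] if s else None) for k, s in summaries.items()
            }
        table.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
        files["expression"] = os.path.join(outdir, "expression.tsv")

    return {"metrics": metrics,
            "files": {k: {"path": os.path.relpath(p, start=os.path.dirname(outdir)),
                          "sha256": _digest(p)} for k, p in files.items()}}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured scenario; returns (and writes) the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    gen = dataclasses.replace(config.generator, seed=config.seed)
    genome = generate_wt_genome(gen)
    manifest: dict = {
        "config": json.loads(config.to_json()),
        "wt": genome_manifest(genome, gen),
        "scenarios": {},
    }
    wt_dir = os.path.join(config.outdir, "wt")
    sio.save_genome(genome, wt_dir)

    # Wild-type calls reused as the differential reference.
    wt_chip = simulate_chip_reads(genome, config.reads, "chip")
    wt_inp = simulate_chip_reads(genome, config.reads, "input")
    lengths = genome.chrom_lengths
    chip_t = window_coverage(wt_chip, lengths, config.caller.window, config.caller.step)
    inp_t = window_coverage(wt_inp, lengths, config.caller.window, config.caller.step)
    chip_t = normalize_track(chip_t, scaling_factor(wt_chip.n_reads, wt_inp.n_reads),
                             "input")
    wt_calls = call_domains(chip_t, inp_t, config.caller.T, config.caller.G,
                            config.caller.S)
    wt_calls.to_bed(os.path.join(wt_dir, "calls.bed"))
    manifest["wt"]["n_calls"] = len(wt_calls)

    for name in config.scenarios:
        outdir = os.path.join(config.outdir, name)
        try:
            manifest["scenarios"][name] = run_scenario(
                config, genome, wt_calls, name, outdir)
        except Exception as exc:
            log.error("[%s] stage failed: %s", name, exc)
            raise RuntimeError(f"scenario {name!r} failed: {exc}") from exc

    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
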