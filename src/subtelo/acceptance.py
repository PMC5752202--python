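"""Recomputes the headline quantities of the analysis from scratch.

Each target is measured by actually running the pipeline on freshly
simulated data (no cached numbers): statistics reproduction (t1-t2), repeat
arithmetic (t3-t4, t11), generator fidelity (t5-t6) and parameter-recovery
experiments in which simulated ChIP-seq is pushed through coverage
normalization and domain calling and the recovered geometry is measured
(t7-t10). Values are reported on the scale the quantities are usually
printed on (percent, kb, counts).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List

import numpy as np

from ._util import random_dna
from .domain_analysis import anchored_span_and_genes, call_domains, subtelomeric_extension
from .coverage_norm import normalize_track, scaling_factor, window_coverage
from .expression_stats import summary_from_stats
from .genome_model import TruthParams
from .pipeline import CallerParams, scenario_tracks
from .synthetic_data import (
    GeneratorParams,
    ReadSimParams,
    build_scenario,
    generate_wt_genome,
)
from .telomere_repeats import find_repeat_arrays, terminal_repeat_counts

# Published qPCR summary statistics the CI computation must reproduce
# (wild-type and 17-repeat strains, n=3 biological replicates).
QPCR_WT = (3.05970, 0.64784, 3)
QPCR_17 = (52.78110, 14.35716, 3)


def _repeat_array_length(n_units: int, seed: int) -> int:
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 500) + "TTAGGG" * n_units + random_dna(rng, 500)
    arrays = [a for a in find_repeat_arrays(seq) if a.n == n_units]
    assert len(arrays) == 1, "expected exactly one full-length array"
    return arrays[0].end - arrays[0].start


def _insertion_recovery(seed: int, n_seeds: int) -> Dict[str, float]:
    caller = CallerParams()
    spans, fars, genes = [], [], []
    for s in range(seed, seed + n_seeds):
        genome = generate_wt_genome(GeneratorParams(seed=s))
        sc = build_scenario("telomere_insertion_17", genome, seed=s,
                            truth_params=TruthParams(seed=s))
        chrom, pos, _k = sc.meta["insertion"]
        chip_t, inp_t = scenario_tracks(
            sc, ReadSimParams(depth=20.0, enrichment=8.0, seed=s),
            caller, chroms=[chrom])
        calls = call_domains(chip_t, inp_t, caller.T, caller.G, caller.S)
        span, far, n_genes = anchored_span_and_genes(
            calls, chrom, pos, sc.derived.genes,
            chrom_length=sc.derived.length(chrom), G=caller.G)
        spans.append(span)
        fars.append(far)
        genes.append(n_genes)
    return {
        "span_kb": float(np.mean(spans)) / 1000.0,
        "farthest_kb": float(np.mean(fars)) / 1000.0,
        "n_genes": float(np.mean(genes)),
        "n": n_seeds,
    }


def _new_end_extension(seed: int, n_seeds: int, n_scenarios: int = 7) -> Dict[str, float]:
    caller = CallerParams()
    exts: List[float] = []
    names = ["quasiterminal", "terminal_shift"]
    for s in range(seed, seed + n_seeds):
        genome = generate_wt_genome(GeneratorParams(seed=s))
        for j in range(n_scenarios):
            sub_seed = s * 1000 + j
            sc = build_scenario(names[j % 2], genome, seed=sub_seed,
                                truth_params=TruthParams(seed=sub_seed))
            for chrom, side in sc.derived.new_capped_ends:
                chip_t, inp_t = scenario_tracks(
                    sc, ReadSimParams(depth=20.0, enrichment=8.0, seed=sub_seed),
                    caller, chroms=[chrom])
                calls = call_domains(chip_t, inp_t, caller.T, caller.G, caller.S)
                exts.append(subtelomeric_extension(
                    calls, chrom, sc.derived.length(chrom), side=side,
                    G=caller.G))
    return {"mean_kb": float(np.mean(exts)) / 1000.0, "n": len(exts)}


def run_acceptance(seed: int = 1, fast: bool = False) -> dict:
    """Compute every acceptance target; returns ``{id: {value, n}, ...}``."""
    n_seeds = 2 if fast else 10
    report: dict = {}

    report["t1"] = {"value": summary_from_stats(*QPCR_WT).ci_lo, "n": QPCR_WT[2]}
    report["t2"] = {"value": summary_from_stats(*QPCR_17).ci_hi, "n": QPCR_17[2]}

    report["t3"] = {"value": _repeat_array_length(17, seed), "n": 17}
    report["t4"] = {"value": _repeat_array_length(8, seed), "n": 8}

    fracs = []
    counts = []
    for s in range(seed, seed + n_seeds):
        g = generate_wt_genome(GeneratorParams(seed=s))
        fracs.append(sum(d.length for d in g.domains) / g.total_length)
        counts.append(len(g.domains))
    report["t5"] = {"value": 100.0 * float(np.mean(fracs)), "n": n_seeds}
    report["t6"] = {"value": int(counts[0]), "n": 1}

    rec = _insertion_recovery(seed, n_seeds)
    report["t7"] = {"value": rec["span_kb"], "n": rec["n"]}
    report["t8"] = {"value": rec["n_genes"], "n": rec["n"]}
    report["t9"] = {"value": rec["farthest_kb"], "n": rec["n"]}

    ext = _new_end_extension(seed, n_seeds)
    report["t10"] = {"value": ext["mean_kb"], "n": ext["n"]}

    g = generate_wt_genome(GeneratorParams(seed=seed, with_sequence=True))
    counts_per_end = terminal_repeat_counts(g)
    flat = [n for pair in counts_per_end.values() for n in pair]
    assert len(set(flat)) == 1, f"non-uniform terminal counts: {counts_per_end}"
    report["t11"] = {"value": int(flat[0]), "n": len(flat)}

    return report
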