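"""Canned planted-truth simulation experiments.

These run the pipeline's components against the synthetic generator's
recorded ground truth and report recovery / calibration metrics: useful
both as validation of an installation and as a template for power
analyses at other coverages and effect sizes.
"""

from __future__ import annotations

import numpy as np

from . import methylation_core
from .dmr_caller import DmrParams, annotate_dmrs, collect_dmgs, find_dmrs
from .functional_profiles import derive_elements
from .synthetic_data import (
    SimulationConfig,
    plant_dmrs,
    simulate_counts,
    simulate_genome,
    simulate_true_methylome,
)


def recovery_metrics(dmrs, planted_regions, min_recovered_fraction: float = 0.5) -> dict:
    """Sensitivity and false-discovery proportion of a DMR call set.

    A planted region counts as recovered when called DMRs cover at least
    ``min_recovered_fraction`` of its length; a called DMR is a false
    discovery when it overlaps no planted region at all.
    """
    n_hit = 0
    for chrom, start, end, _, _ in planted_regions:
        covered = 0
        for row in dmrs.itertuples():
            if row.chrom == chrom and row.start <= end and start <= row.end:
                covered += min(end, row.end) - max(start, row.start) + 1
        if covered >= min_recovered_fraction * (end - start + 1):
            n_hit += 1
    n_fp = sum(
        1
        for row in dmrs.itertuples()
        if not any(
            row.chrom == chrom and row.start <= end and start <= row.end
            for chrom, start, end, _, _ in planted_regions
        )
    )
    return {
        "n_planted": len(planted_regions),
        "n_recovered": n_hit,
        "n_dmrs": len(dmrs),
        "n_false": n_fp,
        "sensitivity": n_hit / len(planted_regions) if planted_regions else float("nan"),
        "fdp": n_fp / len(dmrs) if len(dmrs) else 0.0,
    }


def planted_dmr_recovery(
    config: SimulationConfig | None = None,
    n_replicates: int = 5,
    params: DmrParams | None = None,
) -> dict:
    """Recover planted regions over replicate read-samplings of one genome.

    The genome, truth and planted regions are fixed by ``config``; each
    replicate redraws treatment and control read counts (a fresh
    sequencing run of the same material) and re-calls DMRs in the planted
    context.  Metrics are pooled across replicates.
    """
    config = config or SimulationConfig()
    params = params or DmrParams()
    genome = simulate_genome(config)
    truth = simulate_true_methylome(genome, config)
    arm = plant_dmrs(truth, config, genome=genome)
    lengths = {c: genome.length(c) for c in genome.chrom_names}
    totals = {"n_planted": 0, "n_recovered": 0, "n_dmrs": 0, "n_false": 0}
    for rep in range(n_replicates):
        treat = simulate_counts(arm, config, f"treat-{rep}")
        ctrl = simulate_counts(truth, config, f"ctrl-{rep}")
        dmrs = find_dmrs(treat, ctrl, params, contexts=(config.dmr_context,),
                         chrom_lengths=lengths)
        m = recovery_metrics(dmrs, arm.planted_regions)
        for k in totals:
            totals[k] += m[k]
    return {
        **totals,
        "n_replicates": n_replicates,
        "sensitivity": totals["n_recovered"] / totals["n_planted"],
        "fdp": totals["n_false"] / totals["n_dmrs"] if totals["n_dmrs"] else 0.0,
    }


def null_dmr_calibration(
    config: SimulationConfig | None = None,
    n_replicates: int = 20,
    params: DmrParams | None = None,
) -> dict:
    """DMR counts when treatment and control are drawn from the same truth."""
    config = config or SimulationConfig()
    params = params or DmrParams()
    genome = simulate_genome(config)
    truth = simulate_true_methylome(genome, config)
    lengths = {c: genome.length(c) for c in genome.chrom_names}
    counts = []
    for rep in range(n_replicates):
        treat = simulate_counts(truth, config, f"null-treat-{rep}")
        ctrl = simulate_counts(truth, config, f"null-ctrl-{rep}")
        dmrs = find_dmrs(treat, ctrl, params, contexts=(config.dmr_context,),
                         chrom_lengths=lengths)
        counts.append(len(dmrs))
    counts = np.asarray(counts)
    return {
        "dmr_counts": counts.tolist(),
        "n_replicates": n_replicates,
        "fraction_zero": float((counts == 0).mean()),
    }


def nonconversion_recovery(seed: int = 0, p_true: float = 0.2, r: float = 0.006,
                           coverage: float = 30.0, chrom_length: int = 100_000) -> dict:
    """Flat-truth check of the non-conversion estimate and ML correction.

    Every non-control cytosine gets the same true level ``p_true``; the
    pooled raw ML should sit at p + (1-p)r and the corrected ML back at
    p, within binomial standard error; the lambda estimate should match r.
    """
    config = SimulationConfig(
        seed=seed, chrom_lengths=(chrom_length,),
        base_levels={"CG": p_true, "CHG": p_true, "CHH": p_true},
        level_dispersion=None, coverage_mean=coverage, nonconversion_rate=r,
    )
    genome = simulate_genome(config)
    truth = simulate_true_methylome(genome, config)
    sample = simulate_counts(truth, config, "flat")
    r_hat = methylation_core.estimate_nonconversion(sample, genome)
    body = sample.sites[sample.sites["chrom"] != genome.control_chrom]
    n_reads = int((body["count_meth"] + body["count_unmeth"]).sum())
    ml_raw = float(body["count_meth"].sum()) / n_reads
    ml_corrected = float(methylation_core.correct_ml(ml_raw, r_hat))
    q = p_true + (1 - p_true) * r
    se = float(np.sqrt(q * (1 - q) / n_reads))
    return {
        "ml_raw": ml_raw, "ml_corrected": ml_corrected, "r_hat": r_hat,
        "expected_raw": q, "expected_corrected": p_true, "true_r": r,
        "se": se, "n_reads": n_reads,
    }


def dmr_dmg_counts(treat, ctrl, genes, genome, params: DmrParams) -> tuple[int, int]:
    """DMR and DMG counts for one contrast at the given thresholds."""
    lengths = {c: genome.length(c) for c in genome.chrom_names}
    dmrs, shared = find_dmrs(treat, ctrl, params, chrom_lengths=lengths, return_shared=True)
    dmrs = annotate_dmrs(dmrs, derive_elements(genes, genome))
    dmgs = collect_dmgs(dmrs, shared)
    return len(dmrs), len(dmgs)
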