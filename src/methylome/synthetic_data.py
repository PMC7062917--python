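"""Seeded generator for every input the pipeline consumes.

The generator emulates the study conditions end to end: a multi-chromosome
toy genome plus an unmethylated lambda spike-in chromosome, context-
dependent true methylation (CG high, CHG intermediate, CHH low), planted
differential regions with recorded coordinates, binomial read counts with
a non-conversion error process (an unmethylated cytosine escapes
conversion with probability r and reads as methylated), and median-effect
dose-response growth tables.  Everything is a pure function of
:class:`SimulationConfig`; per-sample streams are derived by hashing the
master seed with the sample id so samples are independent yet reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io_formats, methylation_core, synergy_ci
from .functional_profiles import GeneModel

LAMBDA_NAME = "lambda"

# rng stream salts (second word of the seed sequence)
_S_GENOME, _S_TRUTH, _S_REGIONS, _S_GENES, _S_TERMS, _S_ARMS, _S_DOSE = range(7)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Context base levels default to CG 0.24 / CHG 0.10 / CHH 0.04 so the
    realised per-context ordering is CG > CHG > CHH; the non-conversion
    rate defaults to 0.004 (conversion efficiency > 99.5%); coverage is
    30x; planted differential regions default to 20 CG regions of 2 kb
    with delta +0.4 on a 1-Mb two-chromosome genome.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (600_000, 400_000)
    gc_fraction: float = 0.36
    base_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.10, "CHH": 0.04}
    )
    level_dispersion: float | None = 20.0  # Beta concentration; None = no site-to-site spread
    coverage_mean: float = 30.0
    nonconversion_rate: float = 0.004
    lambda_length: int = 48_502
    n_dmrs: int = 20
    dmr_length: int = 2_000
    dmr_delta: float = 0.4
    dmr_context: str = "CG"

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0 <= self.nonconversion_rate < 1:
            raise ValueError("nonconversion_rate must be in [0, 1)")
        if self.lambda_length <= 0:
            raise ValueError("lambda_length must be positive")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chrom_lengths": list(self.chrom_lengths),
            "gc_fraction": self.gc_fraction,
            "base_levels": dict(self.base_levels),
            "level_dispersion": self.level_dispersion,
            "coverage_mean": self.coverage_mean,
            "nonconversion_rate": self.nonconversion_rate,
            "lambda_length": self.lambda_length,
            "n_dmrs": self.n_dmrs,
            "dmr_length": self.dmr_length,
            "dmr_delta": self.dmr_delta,
            "dmr_context": self.dmr_context,
        }


@dataclass
class TrueMethylome:
    """Ground-truth per-site methylation probabilities.

    ``sites``: chrom, pos, strand, context, trinucleotide, p_true for every
    classifiable cytosine of the genome (p_true = 0 on the control
    chromosome).  ``planted_regions``: (chrom, start, end, context, delta)
    of each planted differential region.
    """

    sites: pd.DataFrame
    planted_regions: list[tuple[str, int, int, str, float]] = field(default_factory=list)


def _sample_stream(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def simulate_genome(config: SimulationConfig) -> io_formats.GenomeSequence:
    """i.i.d. bases at the requested GC fraction plus a ~50% GC lambda control."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_GENOME])
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    g = config.gc_fraction
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    sequences: dict[str, str] = {}
    for i, length in enumerate(config.chrom_lengths, 1):
        seq = rng.choice(bases, size=length, p=probs)
        sequences[f"Chr{i}"] = seq.tobytes().decode()
    lam = rng.choice(bases, size=config.lambda_length, p=[0.25, 0.25, 0.25, 0.25])
    sequences[LAMBDA_NAME] = lam.tobytes().decode()
    return io_formats.GenomeSequence(sequences, control_chrom=LAMBDA_NAME)


def simulate_true_methylome(genome: io_formats.GenomeSequence, config: SimulationConfig) -> TrueMethylome:
    """Per-cytosine p_true from a context-mean Beta; control chromosome fixed at 0."""
    if genome.control_chrom is None:
        raise ValueError("genome must carry a control chromosome")
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_TRUTH])
    sites = methylation_core.scan_cytosines(genome)
    p = np.zeros(len(sites))
    c = config.level_dispersion
    for ctx, mean in config.base_levels.items():
        mask = (sites["context"] == ctx).to_numpy() & (sites["chrom"] != genome.control_chrom).to_numpy()
        n = int(mask.sum())
        if n == 0 or mean == 0:
            continue
        if c is None or not np.isfinite(c):
            p[mask] = mean
        else:
            p[mask] = rng.beta(mean * c, (1 - mean) * c, size=n)
    sites = sites.copy()
    sites["p_true"] = p
    return TrueMethylome(sites)


def sample_dmr_regions(
    genome: io_formats.GenomeSequence, config: SimulationConfig
) -> list[tuple[str, int, int, str, float]]:
    """Non-overlapping planted-region coordinates on the non-control chromosomes."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_REGIONS])
    chroms = [c for c in genome.chrom_names if c != genome.control_chrom]
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: list[tuple[str, int, int, str, float]] = []
    attempts = 0
    while len(placed) < config.n_dmrs:
        attempts += 1
        if attempts > 1000 * max(config.n_dmrs, 1):
            raise ValueError("could not place the requested regions without overlap")
        ci = rng.choice(len(chroms), p=weights)
        chrom, chrom_len = chroms[ci], int(lengths[ci])
        if chrom_len < config.dmr_length:
            continue
        start = int(rng.integers(1, chrom_len - config.dmr_length + 2))
        end = start + config.dmr_length - 1
        if any(c == chrom and s <= end and start <= e for c, s, e, _, _ in placed):
            continue
        placed.append((chrom, start, end, config.dmr_context, config.dmr_delta))
    return sorted(placed)


def plant_dmrs(
    truth: TrueMethylome,
    config: SimulationConfig,
    genome: io_formats.GenomeSequence | None = None,
    regions: list[tuple[str, int, int, str, float]] | None = None,
) -> TrueMethylome:
    """Treatment-arm copy of the truth with p_true shifted by delta in each region.

    Only sites matching the region's context are shifted; values are
    clamped to [0, 1].  Regions must be non-overlapping.
    """
    if regions is None:
        if genome is None:
            raise ValueError("pass a genome to sample regions, or pass regions explicitly")
        regions = sample_dmr_regions(genome, config)
    regions = sorted(regions)
    for (c1, s1, e1, _, _), (c2, s2, e2, _, _) in zip(regions, regions[1:]):
        if c1 == c2 and s2 <= e1:
            raise ValueError(f"planted regions overlap: {c1}:{s1}-{e1} and {c2}:{s2}-{e2}")
    sites = truth.sites.copy()
    p = sites["p_true"].to_numpy().copy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for chrom, start, end, ctx, delta in regions:
        mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end) & (ctx_arr == ctx)
        p[mask] = np.clip(p[mask] + delta, 0.0, 1.0)
    sites["p_true"] = p
    return TrueMethylome(sites, planted_regions=list(regions))


def simulate_counts(
    truth: TrueMethylome, config: SimulationConfig, sample_id: str
) -> io_formats.SampleMethylome:
    """Binomial read counts with the non-conversion error process.

    Per site: coverage ~ Poisson(coverage_mean) and count_meth ~
    Binomial(coverage, q) with q = p_true + (1 - p_true) * r — unconverted
    unmethylated cytosines read as methylated.  Deterministic given the
    master seed and sample id.
    """
    rng = _sample_stream(config.seed, sample_id)
    sites = truth.sites
    n = len(sites)
    cov = rng.poisson(config.coverage_mean, size=n)
    p = sites["p_true"].to_numpy()
    q = p + (1.0 - p) * config.nonconversion_rate
    meth = rng.binomial(cov, q)
    df = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "pos": sites["pos"].to_numpy(),
        "strand": sites["strand"].to_numpy(),
        "count_meth": meth,
        "count_unmeth": cov - meth,
        "context": sites["context"].to_numpy(),
        "trinucleotide": sites["trinucleotide"].to_numpy(),
    })
    return io_formats.SampleMethylome(sample_id, df)


def simulate_gene_models(genome: io_formats.GenomeSequence, config: SimulationConfig) -> list[GeneModel]:
    """Random non-overlapping gene models with exons, introns and UTRs."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_GENES])
    genes: list[GeneModel] = []
    for chrom in genome.chrom_names:
        if chrom == genome.control_chrom:
            continue
        chrom_len = genome.length(chrom)
        pos = 2501  # leave room for the first promoter
        i = 0
        while True:
            gene_len = int(rng.integers(1000, 3001))
            if pos + gene_len - 1 > chrom_len - 100:
                break
            i += 1
            start, end = pos, pos + gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            n_seg = 2 * n_exons - 1
            extra = rng.multinomial(gene_len - 50 * n_seg, np.full(n_seg, 1.0 / n_seg))
            seg_len = 50 + extra
            bounds = start + np.concatenate([[0], np.cumsum(seg_len)])
            exons = [(int(bounds[k]), int(bounds[k + 1] - 1)) for k in range(0, n_seg, 2)]
            first, last = exons[0], exons[-1]
            utr_a = (first[0], min(first[1], first[0] + 149))
            utr_b = (max(last[0], last[1] - 149), last[1])
            utr5, utr3 = ([utr_a], [utr_b]) if strand == "+" else ([utr_b], [utr_a])
            genes.append(GeneModel(
                gene_id=f"{chrom}g{i:04d}", chrom=chrom, strand=strand,
                start=start, end=end, exons=exons, utr5=utr5, utr3=utr3,
            ))
            pos = end + 1 + int(rng.integers(1500, 4001))
    return genes


def simulate_term_map(gene_ids: list[str], config: SimulationConfig, n_terms: int = 40):
    """Random term -> gene-set map over the simulated genes."""
    from .enrichment import TermMap

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_TERMS])
    background = sorted(gene_ids)
    terms, descriptions = {}, {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(5, min(41, max(6, len(background)))))
        members = rng.choice(len(background), size=min(size, len(background)), replace=False)
        tid = f"TERM:{i:04d}"
        terms[tid] = frozenset(background[j] for j in members)
        descriptions[tid] = f"synthetic term {i}"
    return TermMap(terms=terms, background=frozenset(background), descriptions=descriptions)


# ---------------------------------------------------------------------------
# dose-response growth tables
# ---------------------------------------------------------------------------

#: median-effect parameters (m, Dm in uM) emulating the study's agents;
#: azacitidine's Dm of 10 uM realises its GI50, and the single doses used
#: in combinations are RAP 5 uM, AZD 1 uM, azacitidine 10 uM.
DEFAULT_AGENTS: dict[str, tuple[float, float]] = {
    "azacitidine": (1.8, 10.0),
    "AZD": (1.5, 1.0),
    "RAP": (1.2, 5.0),
}

DEFAULT_COMBOS: list[tuple[str, float, str, float]] = [
    ("RAP", 5.0, "azacitidine", 10.0),
    ("AZD", 1.0, "azacitidine", 10.0),
]


def median_effect_fa(dose, m: float, dm: float):
    """Noise-free fraction affected: Fa = (D/Dm)^m / (1 + (D/Dm)^m)."""
    ratio = (np.asarray(dose, dtype=float) / dm) ** m
    return (ratio / (1.0 + ratio))[()]


def simulate_dose_response(
    m: float, dm: float, doses, cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Dose -> Fa table from the median-effect model with lognormal noise.

    Fa(D) = (D/Dm)^m / (1 + (D/Dm)^m), multiplied by lognormal noise of
    coefficient ``cv`` and clamped into the open unit interval.
    """
    doses = np.asarray(doses, dtype=float)
    if dm <= 0 or m <= 0:
        raise ValueError("require Dm > 0 and m > 0")
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    fa = np.asarray(median_effect_fa(doses, m, dm), dtype=float)
    if cv > 0:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, _S_DOSE])
        sigma = np.sqrt(np.log(1.0 + cv**2))
        fa = fa * rng.lognormal(-sigma**2 / 2.0, sigma, size=fa.shape)
    fa = np.clip(fa, synergy_ci.FA_MIN, synergy_ci.FA_MAX)
    return pd.DataFrame({"dose_uM": doses, "fa": fa})


def _combo_fa_for_ci(d1, m1, dm1, d2, m2, dm2, ci_target: float) -> float:
    """Fa at which the two-term combination index equals ``ci_target``."""

    def g(fa):
        dx1 = dm1 * (fa / (1 - fa)) ** (1.0 / m1)
        dx2 = dm2 * (fa / (1 - fa)) ** (1.0 / m2)
        return d1 / dx1 + d2 / dx2 - ci_target

    return brentq(g, 1e-9, 1 - 1e-9)


def simulate_growth_tables(
    config: SimulationConfig,
    agents: dict[str, tuple[float, float]] | None = None,
    combos: list[tuple[str, float, str, float]] | None = None,
    ci_true: float = 0.5,
    cv: float = 0.05,
    n_replicates: int = 3,
    control_weight_mg: float = 100.0,
    dose_scales=(0.25, 0.5, 1.0, 2.0, 4.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fresh-weight growth tables for single agents and fixed-dose combinations.

    Single-agent doses span Dm x dose_scales; combination Fa values are
    chosen so the true (exclusive) combination index equals ``ci_true``
    (default 0.5, a strong synergy), then replicate fresh weights get
    lognormal noise of coefficient ``cv``.
    """
    agents = DEFAULT_AGENTS if agents is None else agents
    combos = DEFAULT_COMBOS if combos is None else combos
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_DOSE])
    sigma = np.sqrt(np.log(1.0 + cv**2)) if cv > 0 else 0.0

    def noisy(weight):
        if sigma == 0:
            return float(weight)
        return float(weight * rng.lognormal(-sigma**2 / 2.0, sigma))

    growth_rows = []
    for rep in range(1, n_replicates + 1):
        growth_rows.append(("DMSO", 0.0, rep, noisy(control_weight_mg)))
    for agent, (m, dm) in agents.items():
        for scale in dose_scales:
            dose = dm * scale
            fa = float(median_effect_fa(dose, m, dm))
            for rep in range(1, n_replicates + 1):
                growth_rows.append((agent, dose, rep, noisy(control_weight_mg * (1 - fa))))
    growth = pd.DataFrame(growth_rows, columns=["agent", "dose_uM", "replicate", "fresh_weight_mg"])

    combo_rows = []
    for a1, d1, a2, d2 in combos:
        m1, dm1 = agents[a1]
        m2, dm2 = agents[a2]
        for scale in dose_scales:
            fa = _combo_fa_for_ci(d1 * scale, m1, dm1, d2 * scale, m2, dm2, ci_true)
            for rep in range(1, n_replicates + 1):
                combo_rows.append(
                    (a1, d1 * scale, a2, d2 * scale, rep, noisy(control_weight_mg * (1 - fa)))
                )
    combo = pd.DataFrame(
        combo_rows,
        columns=["agent1", "dose1_uM", "agent2", "dose2_uM", "replicate", "fresh_weight_mg"],
    )
    return growth, combo


# ---------------------------------------------------------------------------
# planted-region truth files and the full input bundle
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["chrom", "start", "end", "context", "delta"]


def write_regions_tsv(regions, path) -> Path:
    df = pd.DataFrame(regions, columns=REGION_COLUMNS)
    return io_formats.write_tsv(df, path)


def read_regions_tsv(path) -> list[tuple[str, int, int, str, float]]:
    df = io_formats.read_tsv(path)
    return [
        (str(r.chrom), int(r.start), int(r.end), str(r.context), float(r.delta))
        for r in df.itertuples()
    ]


def write_input_bundle(
    config: SimulationConfig,
    outdir,
    arms: list[str] = ("AZD", "RAP", "AZD+RAP"),
    control: str = "DMSO",
    arm_keep_prob: float = 0.7,
) -> dict:
    """Generate and write the complete input bundle; returns a path manifest.

    Each treatment arm receives a per-arm random subset (probability
    ``arm_keep_prob``) of one master list of planted regions, so arm DMG
    sets overlap partially, as in a multi-treatment contrast design.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    truth = simulate_true_methylome(genome, config)
    genes = simulate_gene_models(genome, config)
    master_regions = sample_dmr_regions(genome, config)
    arm_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, _S_ARMS])

    paths: dict = {"samples": {}, "truth": {}}
    paths["genome"] = str(io_formats.write_genome_fasta(genome, outdir / "genome.fa"))
    paths["genes"] = str(io_formats.write_gene_models_gff3(genes, outdir / "genes.gff3"))

    ctrl_sample = simulate_counts(truth, config, control)
    paths["samples"][control] = str(io_formats.write_cx_report(ctrl_sample, outdir / f"{control}.cx.tsv"))
    for arm in arms:
        keep = arm_rng.random(len(master_regions)) < arm_keep_prob
        if not keep.any():
            keep[0] = True
        regions = [r for r, k in zip(master_regions, keep) if k]
        arm_truth = plant_dmrs(truth, config, regions=regions)
        sample = simulate_counts(arm_truth, config, arm)
        paths["samples"][arm] = str(io_formats.write_cx_report(sample, outdir / f"{arm}.cx.tsv"))
        paths["truth"][arm] = str(write_regions_tsv(regions, outdir / f"planted_regions.{arm}.tsv"))

    term_map = simulate_term_map([g.gene_id for g in genes], config)
    term_rows = [(tid, gid) for tid in sorted(term_map.terms) for gid in sorted(term_map.terms[tid])]
    paths["terms"] = str(io_formats.write_tsv(
        pd.DataFrame(term_rows, columns=["term_id", "gene_id"]), outdir / "terms.tsv"
    ))
    paths["term_descriptions"] = str(io_formats.write_tsv(
        pd.DataFrame(sorted(term_map.descriptions.items()), columns=["term_id", "description"]),
        outdir / "term_descriptions.tsv",
    ))

    growth, combo = simulate_growth_tables(config)
    paths["growth"] = str(io_formats.write_tsv(growth, outdir / "growth.tsv"))
    paths["combos"] = str(io_formats.write_tsv(combo, outdir / "combos.tsv"))

    with open(outdir / "simulation.json", "w") as fh:
        json.dump({"config": config.to_dict(), "control": control, "arms": list(arms),
                   "arm_keep_prob": arm_keep_prob}, fh, indent=2, sort_keys=True)
    paths["config"] = str(outdir / "simulation.json")
    return paths
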