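"""Orchestration: simulate -> summarize -> profile -> dmr -> enrich -> synergy.

A run is a pure function of its :class:`RunConfig`: the same seed and
thresholds produce byte-identical outputs (fixed float formats, sorted
manifests, no timestamps).  Stages write under the output directory and
the manifest records the config hash, seed, per-stage row counts and the
sha256 of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dmr_caller, enrichment, functional_profiles, io_formats, methylation_core, synergy_ci
from .synthetic_data import LAMBDA_NAME, SimulationConfig, write_input_bundle

log = logging.getLogger("methylome")

DEFAULT_CONTRASTS = (("AZD", "DMSO"), ("RAP", "DMSO"), ("AZD+RAP", "DMSO"))


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    outdir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    dmr: dmr_caller.DmrParams = field(default_factory=dmr_caller.DmrParams)
    arm_keep_prob: float = 0.7
    window: int = 3000
    step: int = 600
    bin_size: int = 10000
    min_coverage: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.contrasts = tuple((str(t), str(c)) for t, c in self.contrasts)
        controls = {c for _, c in self.contrasts}
        for treat, ctrl in self.contrasts:
            if treat == ctrl:
                raise ValueError(f"contrast {treat} vs {ctrl}: treatment equals control")
        if len(controls) != 1:
            raise ValueError("exactly one control sample across contrasts is expected")

    @property
    def control(self) -> str:
        return self.contrasts[0][1]

    @property
    def arms(self) -> list[str]:
        return [t for t, _ in self.contrasts]

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "sim": self.sim.to_dict(),
            "contrasts": [list(c) for c in self.contrasts],
            "dmr": self.dmr.to_dict(),
            "arm_keep_prob": self.arm_keep_prob,
            "window": self.window, "step": self.step, "bin_size": self.bin_size,
            "min_coverage": self.min_coverage, "alpha": self.alpha,
        }

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = SimulationConfig(**raw.pop("sim", {})) if not isinstance(raw.get("sim"), SimulationConfig) \
            else raw.pop("sim")
        dmr = raw.pop("dmr", {})
        if not isinstance(dmr, dmr_caller.DmrParams):
            dmr = dmr_caller.DmrParams(**dmr)
        contrasts = tuple(tuple(c) for c in raw.pop("contrasts", DEFAULT_CONTRASTS))
        return cls(sim=sim, dmr=dmr, contrasts=contrasts, **raw)


def small_run_config(outdir, seed: int = 0) -> RunConfig:
    """Scaled-down study profile for quick end-to-end runs and determinism checks."""
    sim = SimulationConfig(
        seed=seed, chrom_lengths=(150_000, 100_000), lambda_length=20_000, n_dmrs=8
    )
    return RunConfig(outdir=Path(outdir), sim=sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    # outdir is a location, not an analysis parameter
    d = config.to_dict()
    d.pop("outdir")
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_inputs(indir) -> dict:
    """Read the input bundle back from disk into domain objects."""
    indir = Path(indir)
    with open(indir / "simulation.json") as fh:
        meta = json.load(fh)
    genome = io_formats.read_genome_fasta(indir / "genome.fa", control_chrom=LAMBDA_NAME)
    genes = io_formats.read_gene_models(indir / "genes.gff3")
    samples = {}
    for name in [meta["control"], *meta["arms"]]:
        samples[name] = io_formats.read_cx_report(indir / f"{name}.cx.tsv", sample_id=name)
        samples[name].validate_against(genome)
    term_map = enrichment.read_term_map(
        indir / "terms.tsv", indir / "term_descriptions.tsv",
        background=[g.gene_id for g in genes],
    )
    return {"meta": meta, "genome": genome, "genes": genes, "samples": samples, "term_map": term_map}


def summarize_stage(samples, genome, outdir, window=3000, step=600, bin_size=10000,
                    min_coverage=5, alpha=0.05) -> dict:
    """Non-conversion rates, window/bin MLs and context summaries per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    rate_rows = []
    for name in sorted(samples):
        sample = samples[name]
        r = methylation_core.estimate_nonconversion(sample, genome)
        rate_rows.append({"sample": name, "nonconversion_rate": r})
        frames = []
        for ctx in (None, "CG", "CHG", "CHH"):
            win = methylation_core.sliding_window_ml(sample, genome, window, step, ctx)
            win["ml_corrected"] = methylation_core.correct_ml(win["ml"].to_numpy(), r) if len(win) else []
            frames.append(win)
        windows = pd.concat(frames, ignore_index=True)
        io_formats.write_tsv(windows, outdir / f"windows.{name}.tsv")
        bins = methylation_core.bin_profile(sample, genome, bin_size)
        bins["ml_corrected"] = methylation_core.correct_ml(bins["ml"].to_numpy(), r) if len(bins) else []
        io_formats.write_tsv(bins, outdir / f"bins.{name}.tsv")
        calls = methylation_core.call_methylated_sites(sample, r, min_coverage, alpha)
        summary = methylation_core.context_proportions(calls)
        srows = [{"scope": summary.scope, "pct_mCG": summary.pct_mcg, "pct_mCHG": summary.pct_mchg,
                  "pct_mCHH": summary.pct_mchh, "pct_total_mCX": summary.pct_total}]
        for chrom in genome.chrom_names:
            if chrom == genome.control_chrom:
                continue
            cs = methylation_core.context_proportions(calls, chrom)
            srows.append({"scope": cs.scope, "pct_mCG": cs.pct_mcg, "pct_mCHG": cs.pct_mchg,
                          "pct_mCHH": cs.pct_mchh, "pct_total_mCX": cs.pct_total})
        io_formats.write_tsv(pd.DataFrame(srows), outdir / f"context_summary.{name}.tsv")
        shares = methylation_core.chromosome_context_shares(calls[calls["chrom"] != genome.control_chrom])
        io_formats.write_tsv(shares, outdir / f"context_shares.{name}.tsv")
        counts[name] = {"windows": len(windows), "bins": len(bins), "sites": len(sample)}
    io_formats.write_tsv(pd.DataFrame(rate_rows), outdir / "nonconversion.tsv")
    return counts


def profile_stage(samples, genes, genome, outdir, n_bins=20) -> dict:
    """20-bin metaprofiles per sample, element type and context."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    elements = functional_profiles.derive_elements(genes, genome)
    io_formats.write_tsv(elements, outdir / "elements.tsv")
    counts = {"elements": len(elements)}
    present = [t for t in functional_profiles.ELEMENT_TYPES if (elements["element_type"] == t).any()]
    for name in sorted(samples):
        frames = []
        for etype in present:
            for ctx in dmr_caller.CONTEXTS:
                prof = functional_profiles.metaprofile(samples[name], elements, etype, ctx, n_bins)
                frames.append(prof.to_frame())
        df = pd.concat(frames, ignore_index=True)
        io_formats.write_tsv(df, outdir / f"metaprofile.{name}.tsv")
        counts[name] = len(df)
    return counts


def dmr_stage(samples, genes, genome, contrasts, params, outdir) -> dict:
    """Per-contrast DMR calling, annotation, DMGs, Venn and clustering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    elements = functional_profiles.derive_elements(genes, genome)
    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    counts: dict = {}
    dmg_sets: dict[str, set] = {}
    gene_intervals: dict[str, set] = {}
    for treat_name, ctrl_name in contrasts:
        label = f"{treat_name}_vs_{ctrl_name}"
        dmrs, shared_tables = dmr_caller.find_dmrs(
            samples[treat_name], samples[ctrl_name], params,
            chrom_lengths=chrom_lengths, return_shared=True,
        )
        dmrs = dmr_caller.annotate_dmrs(dmrs, elements)
        io_formats.write_dmr_outputs(dmrs, outdir / f"dmrs.{label}")
        dmgs = dmr_caller.collect_dmgs(dmrs, shared_tables)
        io_formats.write_tsv(dmgs, outdir / f"dmgs.{label}.tsv")
        dmg_sets[treat_name] = set(dmgs["gene_id"])
        for row in dmrs.itertuples():
            if not row.gene_ids:
                continue
            for gid in row.gene_ids.split(","):
                gene_intervals.setdefault(gid, set()).add((row.context, row.chrom, row.start, row.end))
        counts[label] = {"dmrs": len(dmrs), "dmgs": len(dmgs)}
        log.info("%s: %d DMRs, %d DMGs", label, len(dmrs), len(dmgs))

    if len(dmg_sets) in (2, 3):
        venn = dmr_caller.venn_overlap(dmg_sets)
        io_formats.write_tsv(
            pd.DataFrame(sorted(venn.items()), columns=["region", "n_genes"]),
            outdir / "venn.tsv",
        )
        counts["venn_regions"] = len(venn)

    matrix = _dmg_ml_matrix(gene_intervals, samples)
    if len(matrix) >= 2:
        result = dmr_caller.cluster_dmgs(matrix)
        (outdir / "dendrogram.nwk").write_text(result.newick + "\n")
        io_formats.write_tsv(
            pd.DataFrame({"leaf_rank": range(1, len(result.leaf_order) + 1),
                          "gene_id": result.leaf_order}),
            outdir / "leaf_order.tsv",
        )
        io_formats.write_tsv(matrix.reset_index(), outdir / "dmg_ml_matrix.tsv")
        counts["clustered_genes"] = len(result.leaf_order)
    return counts


def _dmg_ml_matrix(gene_intervals: dict[str, set], samples) -> pd.DataFrame:
    """Genes x samples pooled ML over each gene's union of DMR intervals."""
    sample_names = sorted(samples)
    rows = {}
    for gid in sorted(gene_intervals):
        vals = {}
        ok = True
        for name in sample_names:
            sites = samples[name].sites
            seen: set = set()
            meth = unmeth = 0
            for ctx, chrom, start, end in sorted(gene_intervals[gid]):
                sub = sites[(sites["chrom"] == chrom) & (sites["context"] == ctx)
                            & (sites["pos"] >= start) & (sites["pos"] <= end)]
                for t in sub.itertuples():
                    key = (t.chrom, t.pos, t.strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    meth += t.count_meth
                    unmeth += t.count_unmeth
            if meth + unmeth == 0:
                ok = False
                break
            vals[name] = meth / (meth + unmeth)
        if ok:
            rows[gid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_names).rename_axis("gene_id")


def enrich_stage(dmg_dir, term_map, contrasts, outdir) -> dict:
    """Over-representation of each contrast's DMG set against the term map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for treat_name, ctrl_name in contrasts:
        label = f"{treat_name}_vs_{ctrl_name}"
        dmgs = io_formats.read_tsv(Path(dmg_dir) / f"dmgs.{label}.tsv")
        hits = set(dmgs["gene_id"].astype(str)) & term_map.background
        result = enrichment.enrich_terms(hits, term_map)
        io_formats.write_tsv(result, outdir / f"enrichment.{label}.tsv")
        counts[label] = {"hits": len(hits), "terms_tested": len(result),
                         "significant": int((result["q"] < 0.05).sum()) if len(result) else 0}
    return counts


def synergy_stage(growth: pd.DataFrame, combos: pd.DataFrame, outdir,
                  control_label: str = "DMSO") -> dict:
    """Median-effect fits per agent and the Fa-CI curve per combination pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    responses = synergy_ci.dose_responses_from_growth(growth, control_label)
    fits = {a: synergy_ci.fit_median_effect(dr) for a, dr in sorted(responses.items())}
    io_formats.write_tsv(
        pd.DataFrame([{"agent": f.agent, "m": f.m, "Dm_uM": f.dm, "gi50_uM": f.dm, "r2": f.r2}
                      for f in fits.values()]),
        outdir / "median_effect_fits.tsv",
    )
    w_ctrl = float(growth.loc[growth["agent"] == control_label, "fresh_weight_mg"].mean())
    combo_fa = synergy_ci.combo_fa_from_growth(combos, w_ctrl)
    frames = []
    for (a1, a2), grp in combo_fa.groupby(["agent1", "agent2"], sort=True):
        curve = synergy_ci.fa_ci_curve(
            list(zip(grp["dose1_uM"], grp["dose2_uM"], grp["fa"])), fits[a1], fits[a2]
        )
        curve.insert(0, "agent1", a1)
        curve.insert(2, "agent2", a2)
        frames.append(curve)
    fa_ci = pd.concat(frames, ignore_index=True)
    io_formats.write_tsv(fa_ci, outdir / "fa_ci.tsv")
    return {"agents_fit": len(fits), "combinations": len(fa_ci),
            "all_synergistic": bool((fa_ci["ci"] < 1).all())}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write a deterministic manifest; returns it."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.sim.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }
    stage = "simulate"
    try:
        write_input_bundle(config.sim, out / "inputs", arms=config.arms,
                           control=config.control, arm_keep_prob=config.arm_keep_prob)
        data = load_inputs(out / "inputs")
        manifest["stages"]["simulate"] = {
            "samples": len(data["samples"]), "genes": len(data["genes"]),
            "chromosomes": len(data["genome"].chrom_names),
        }
        stage = "summarize"
        manifest["stages"]["summarize"] = summarize_stage(
            data["samples"], data["genome"], out / "summaries",
            config.window, config.step, config.bin_size, config.min_coverage, config.alpha,
        )
        stage = "profile"
        manifest["stages"]["profile"] = profile_stage(
            data["samples"], data["genes"], data["genome"], out / "profiles"
        )
        stage = "dmr"
        manifest["stages"]["dmr"] = dmr_stage(
            data["samples"], data["genes"], data["genome"], config.contrasts,
            config.dmr, out / "dmr",
        )
        stage = "enrich"
        manifest["stages"]["enrich"] = enrich_stage(
            out / "dmr", data["term_map"], config.contrasts, out / "enrichment"
        )
        stage = "synergy"
        growth = synergy_ci.read_growth_table(out / "inputs" / "growth.tsv")
        combos = synergy_ci.read_combo_table(out / "inputs" / "combos.tsv")
        manifest["stages"]["synergy"] = synergy_stage(growth, combos, out / "synergy")
    except Exception:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.exception("pipeline aborted in stage %s", stage)
        raise
    manifest["outputs"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
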