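"""Sliding-window Fisher's-exact DMR calling and downstream gene summaries.

The procedure slides a 1000-bp window in 100-bp steps over the shared
covered cytosines of a treatment/control pair, pools read counts per
window, applies the filter cascade (|diff| > 0.1, fold change > 2, > 10
cytosines), tests each candidate with a two-sided Fisher's exact test on
the pooled 2x2 count table, controls the FDR with Benjamini-Hochberg,
merges overlapping significant windows of the same sign into maximal
runs, and recomputes pooled statistics on each merged region.  DMRs are
then annotated to promoter/UTR/exon/intron intervals and collapsed to
differentially methylated genes (DMGs) with a treatment/control
methylation ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .functional_profiles import ELEMENT_TYPES
from .io_formats import SampleMethylome

FOLD_EPS = 0.01  # floor on the smaller ML in the symmetric fold change
RATIO_EPS = 0.01  # floor on the control ML in the DMG methylation ratio

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class DmrParams:
    """Filter cascade and test thresholds for DMR identification."""

    window_bp: int = 1000
    step_bp: int = 100
    min_site_coverage: int = 5
    min_diff: float = 0.1
    min_fold_change: float = 2.0
    min_cytosines: int = 10  # strict: a window needs > 10 shared covered cytosines
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.window_bp < self.step_bp or self.step_bp < 1:
            raise ValueError("require window_bp >= step_bp >= 1")
        for name in ("min_site_coverage", "min_diff", "min_fold_change", "min_cytosines",
                     "p_threshold", "fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "window_bp": self.window_bp, "step_bp": self.step_bp,
            "min_site_coverage": self.min_site_coverage, "min_diff": self.min_diff,
            "min_fold_change": self.min_fold_change, "min_cytosines": self.min_cytosines,
            "p_threshold": self.p_threshold, "fdr_threshold": self.fdr_threshold,
        }


def fisher_exact_p(meth_t: int, unmeth_t: int, meth_c: int, unmeth_c: int) -> float:
    """Two-sided Fisher's exact p for [[meth_t, unmeth_t], [meth_c, unmeth_c]].

    The two-sided p is the sum of hypergeometric probabilities of all
    tables with the same margins whose point probability does not exceed
    that of the observed table.
    """
    return float(stats.fisher_exact([[meth_t, unmeth_t], [meth_c, unmeth_c]])[1])


def shared_sites(
    treat: SampleMethylome, ctrl: SampleMethylome, params: DmrParams, context: str
) -> pd.DataFrame:
    """Cytosines of ``context`` covered >= min_site_coverage in BOTH samples.

    Returns columns ``chrom, pos, strand, meth_t, unmeth_t, meth_c, unmeth_c``.
    """
    cols = ["chrom", "pos", "strand", "count_meth", "count_unmeth"]
    t = treat.sites.loc[treat.sites["context"] == context, cols]
    c = ctrl.sites.loc[ctrl.sites["context"] == context, cols]
    merged = t.merge(c, on=["chrom", "pos", "strand"], suffixes=("_t", "_c"))
    cov_t = merged["count_meth_t"] + merged["count_unmeth_t"]
    cov_c = merged["count_meth_c"] + merged["count_unmeth_c"]
    merged = merged[(cov_t >= params.min_site_coverage) & (cov_c >= params.min_site_coverage)]
    return merged.rename(columns={
        "count_meth_t": "meth_t", "count_unmeth_t": "unmeth_t",
        "count_meth_c": "meth_c", "count_unmeth_c": "unmeth_c",
    }).reset_index(drop=True)


WINDOW_COLUMNS = [
    "chrom", "start", "end", "context", "n_cytosines",
    "meth_t", "unmeth_t", "meth_c", "unmeth_c",
    "ml_treat", "ml_ctrl", "diff", "fold_change",
]


def window_scan(
    shared: pd.DataFrame, params: DmrParams, context: str,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pool shared-site counts into sliding windows and evaluate diff/fold change.

    Windows start at 1, 1+step, ...; windows with zero shared covered
    cytosines are skipped.
    """
    frames = []
    w, s = params.window_bp, params.step_bp
    n_overlap = -(-w // s)
    for chrom, grp in shared.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        chrom_len = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        n_win = (chrom_len - 1) // s + 1
        sums = {k: np.zeros(n_win, dtype=np.int64) for k in ("meth_t", "unmeth_t", "meth_c", "unmeth_c")}
        nsites = np.zeros(n_win, dtype=np.int64)
        arrays = {k: grp[k].to_numpy() for k in sums}
        k_hi = (pos - 1) // s
        for off in range(n_overlap):
            k = k_hi - off
            valid = (k >= 0) & (pos <= k * s + w)
            kk = k[valid]
            np.add.at(nsites, kk, 1)
            for name, acc in sums.items():
                np.add.at(acc, kk, arrays[name][valid])
        kidx = np.flatnonzero(nsites > 0)
        start = kidx * s + 1
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": start, "end": np.minimum(start + w - 1, chrom_len),
            "context": context, "n_cytosines": nsites[kidx],
            **{name: acc[kidx] for name, acc in sums.items()},
        }))
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    win = pd.concat(frames, ignore_index=True)
    return _evaluate(win)


def _evaluate(win: pd.DataFrame) -> pd.DataFrame:
    """Add ml_treat, ml_ctrl, diff and the symmetric fold change."""
    ml_t = win["meth_t"] / (win["meth_t"] + win["unmeth_t"])
    ml_c = win["meth_c"] / (win["meth_c"] + win["unmeth_c"])
    win = win.copy()
    win["ml_treat"] = ml_t
    win["ml_ctrl"] = ml_c
    win["diff"] = ml_t - ml_c
    hi = np.maximum(ml_t, ml_c)
    lo = np.maximum(np.minimum(ml_t, ml_c), FOLD_EPS)
    win["fold_change"] = hi / lo
    return win[WINDOW_COLUMNS]


def test_window(meth_t: int, unmeth_t: int, meth_c: int, unmeth_c: int) -> dict:
    """Single-window statistics: MLs, diff, symmetric fold change, Fisher p."""
    cov_t, cov_c = meth_t + unmeth_t, meth_c + unmeth_c
    if cov_t == 0 or cov_c == 0:
        raise ValueError("window has zero pooled coverage in one sample")
    ml_t, ml_c = meth_t / cov_t, meth_c / cov_c
    return {
        "ml_treat": ml_t,
        "ml_ctrl": ml_c,
        "diff": ml_t - ml_c,
        "fold_change": max(ml_t, ml_c) / max(min(ml_t, ml_c), FOLD_EPS),
        "p": fisher_exact_p(meth_t, unmeth_t, meth_c, unmeth_c),
    }


test_window.__test__ = False  # a library operation, not a pytest case


DMR_CORE_COLUMNS = [
    "chrom", "start", "end", "context", "status", "ml_treat", "ml_ctrl",
    "diff", "fold_change", "n_cytosines", "p", "q",
]


def call_dmrs(windows: pd.DataFrame, shared: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Filter cascade -> Fisher test -> BH -> merge -> recompute.

    1. pre-filter: |diff| > min_diff AND fold_change > min_fold_change AND
       n_cytosines > min_cytosines (strict);
    2. Fisher p < p_threshold;
    3. BH across all windows passing (1); keep q < fdr_threshold;
    4. merge overlapping or book-ended surviving windows of identical
       diff sign into maximal runs;
    5. recompute pooled statistics and Fisher p on each merged interval;
       q by BH across the merged regions; status from the merged diff sign.
    """
    empty = pd.DataFrame(columns=DMR_CORE_COLUMNS)
    if windows.empty:
        return empty
    pre = windows[
        (windows["diff"].abs() > params.min_diff)
        & (windows["fold_change"] > params.min_fold_change)
        & (windows["n_cytosines"] > params.min_cytosines)
    ].copy()
    if pre.empty:
        return empty
    pre["p"] = [
        fisher_exact_p(r.meth_t, r.unmeth_t, r.meth_c, r.unmeth_c) for r in pre.itertuples()
    ]
    pre["q"] = stats.false_discovery_control(pre["p"].to_numpy())
    sig = pre[(pre["p"] < params.p_threshold) & (pre["q"] < params.fdr_threshold)]
    if sig.empty:
        return empty

    runs = []
    for row in sig.sort_values(["chrom", "start"]).itertuples():
        sign = 1 if row.diff > 0 else -1
        if runs and runs[-1]["chrom"] == row.chrom and runs[-1]["sign"] == sign \
                and row.start <= runs[-1]["end"] + 1:
            runs[-1]["end"] = max(runs[-1]["end"], row.end)
        else:
            runs.append({"chrom": row.chrom, "start": row.start, "end": row.end,
                         "sign": sign, "context": row.context})

    out = []
    for run in runs:
        in_run = shared[
            (shared["chrom"] == run["chrom"])
            & (shared["pos"] >= run["start"])
            & (shared["pos"] <= run["end"])
        ]
        m_t, u_t = int(in_run["meth_t"].sum()), int(in_run["unmeth_t"].sum())
        m_c, u_c = int(in_run["meth_c"].sum()), int(in_run["unmeth_c"].sum())
        s = test_window(m_t, u_t, m_c, u_c)
        out.append({
            "chrom": run["chrom"], "start": run["start"], "end": run["end"],
            "context": run["context"],
            "status": "hyper" if s["diff"] > 0 else "hypo",
            "ml_treat": s["ml_treat"], "ml_ctrl": s["ml_ctrl"], "diff": s["diff"],
            "fold_change": s["fold_change"], "n_cytosines": len(in_run), "p": s["p"],
        })
    dmrs = pd.DataFrame(out)
    dmrs["q"] = stats.false_discovery_control(dmrs["p"].to_numpy())
    return dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)[DMR_CORE_COLUMNS]


def find_dmrs(
    treat: SampleMethylome,
    ctrl: SampleMethylome,
    params: DmrParams | None = None,
    contexts=CONTEXTS,
    chrom_lengths: dict[str, int] | None = None,
    return_shared: bool = False,
):
    """Full per-context DMR scan for one treatment/control contrast."""
    params = params or DmrParams()
    frames, shared_tables = [], {}
    for ctx in contexts:
        sh = shared_sites(treat, ctrl, params, ctx)
        shared_tables[ctx] = sh
        win = window_scan(sh, params, ctx, chrom_lengths)
        frames.append(call_dmrs(win, sh, params))
    frames = [f for f in frames if len(f)]
    dmrs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=DMR_CORE_COLUMNS)
    dmrs = dmrs.sort_values(["chrom", "start", "context"]).reset_index(drop=True)
    if return_shared:
        return dmrs, shared_tables
    return dmrs


# ---------------------------------------------------------------------------
# annotation, DMGs, Venn, clustering
# ---------------------------------------------------------------------------

def annotate_dmrs(dmrs: pd.DataFrame, elements: pd.DataFrame) -> pd.DataFrame:
    """Record every element type a DMR overlaps by >= 1 bp and every owning gene.

    ``element_hits`` joins the hit types in canonical order (e.g.
    "exon,intron"); intergenic DMRs get empty strings.
    """
    trees: dict[str, IntervalTree] = {}
    for el in elements.itertuples():
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end + 1, (el.element_type, el.gene_id))
    hits_col, genes_col = [], []
    for row in dmrs.itertuples():
        tree = trees.get(row.chrom)
        found = tree.overlap(row.start, row.end + 1) if tree is not None else ()
        types = {iv.data[0] for iv in found}
        genes = sorted({iv.data[1] for iv in found})
        hits_col.append(",".join(t for t in ELEMENT_TYPES if t in types))
        genes_col.append(",".join(genes))
    out = dmrs.copy()
    out["element_hits"] = hits_col
    out["gene_ids"] = genes_col
    return out


DMG_COLUMNS = [
    "gene_id", "n_dmrs", "contexts", "regions",
    "ml_treat", "ml_ctrl", "methylation_ratio", "ratio_status",
]


def collect_dmgs(
    dmrs: pd.DataFrame,
    shared_tables: dict[str, pd.DataFrame],
    hyper_ratio: float = 1.5,
) -> pd.DataFrame:
    """One DMG per gene carrying >= 1 DMR, with a pooled methylation ratio.

    The ratio is pooled treatment ML over pooled control ML across the
    union of the gene's DMR intervals (per DMR context; duplicate sites
    counted once), with an epsilon floor of 0.01 on the denominator.
    Status: hyper if ratio >= 1.5, hypo if ratio <= 1/1.5, else unchanged;
    a gene with zero pooled coverage is flagged degenerate.
    """
    per_gene: dict[str, list] = {}
    for row in dmrs.itertuples():
        if not row.gene_ids:
            continue
        for gid in row.gene_ids.split(","):
            per_gene.setdefault(gid, []).append(row)
    out = []
    for gid in sorted(per_gene):
        rows = per_gene[gid]
        pieces = []
        for row in rows:
            sh = shared_tables.get(row.context)
            if sh is None or sh.empty:
                continue
            sub = sh[(sh["chrom"] == row.chrom) & (sh["pos"] >= row.start) & (sh["pos"] <= row.end)]
            pieces.append(sub.assign(context=row.context))
        if pieces:
            pool = pd.concat(pieces).drop_duplicates(subset=["chrom", "pos", "strand", "context"])
        else:
            pool = pd.DataFrame(columns=["meth_t", "unmeth_t", "meth_c", "unmeth_c"])
        cov_t = pool["meth_t"].sum() + pool["unmeth_t"].sum()
        cov_c = pool["meth_c"].sum() + pool["unmeth_c"].sum()
        if cov_t == 0 or cov_c == 0:
            ml_t = ml_c = ratio = float("nan")
            status = "degenerate"
        else:
            ml_t = pool["meth_t"].sum() / cov_t
            ml_c = pool["meth_c"].sum() / cov_c
            ratio = ml_t / max(ml_c, RATIO_EPS)
            if ratio >= hyper_ratio:
                status = "hyper"
            elif ratio <= 1.0 / hyper_ratio:
                status = "hypo"
            else:
                status = "unchanged"
        regions = sorted({t for row in rows for t in row.element_hits.split(",") if t})
        out.append({
            "gene_id": gid, "n_dmrs": len(rows),
            "contexts": ",".join(sorted({row.context for row in rows})),
            "regions": ",".join(t for t in ELEMENT_TYPES if t in regions),
            "ml_treat": ml_t, "ml_ctrl": ml_c,
            "methylation_ratio": ratio, "ratio_status": status,
        })
    return pd.DataFrame(out, columns=DMG_COLUMNS)


def venn_overlap(dmg_sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts of a 2- or 3-set Venn diagram.

    Keys are '&'-joined set names in the given order; every gene is
    counted in exactly one region, so per-set totals match cardinalities.
    """
    names = list(dmg_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_overlap supports 2 or 3 sets")
    out: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(set(dmg_sets[n]) for n in inside))
        for n in outside:
            region -= set(dmg_sets[n])
        out["&".join(inside)] = len(region)
    return out


@dataclass
class ClusterResult:
    gene_ids: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def cluster_dmgs(ml_matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of genes with distance 1 - Pearson r.

    Rows are genes, columns samples.  Constant rows are dropped with a
    warning (Pearson undefined); missing values are an error.  Rows are
    pre-sorted by gene id so tied merges resolve deterministically.
    """
    if ml_matrix.isna().any().any():
        raise ValueError("matrix contains missing values: impute or drop those genes first")
    if ml_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = ml_matrix.sort_index()
    const = mat.std(axis=1, ddof=0) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant gene rows (Pearson undefined)")
        mat = mat[~const]
    if len(mat) < 2:
        raise ValueError("need at least 2 non-constant genes")
    dist = pdist(mat.to_numpy(dtype=float), metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    order = [mat.index[i] for i in hierarchy.leaves_list(link)]
    tree = hierarchy.to_tree(link)

    def _newick(node, parent_dist):
        bl = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{mat.index[node.id]}:{bl:.6g}"
        left = _newick(node.left, node.dist)
        right = _newick(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    newick = f"({_newick(tree.left, tree.dist)},{_newick(tree.right, tree.dist)});"
    return ClusterResult(list(mat.index), link, order, newick)
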