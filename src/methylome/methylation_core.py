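"""Context calling and methylation-level estimation.

The per-site methylation level (ML) is mC/(mC+C), the fraction of reads
supporting methylation.  Because a fraction r of unmethylated cytosines
escapes bisulfite conversion and reads as methylated, the apparent level
is q = p + (1-p)r; ``correct_ml`` inverts this with the lambda-spike-in
estimate of r.  Genome summaries use a sliding-window pooling of read
counts (default 3000 bp window, 600 bp step) and per-context percentages
of binomially-called methylated sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, SampleMethylome

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "trinucleotide"]


def classify_context(genome: GenomeSequence, chrom: str, pos: int, strand: str):
    """Classify one cytosine as CG / CHG / CHH; returns (context, trinucleotide).

    Returns None when the context is undefined (fewer than two downstream
    bases before the chromosome edge, or a downstream N); such sites are
    excluded from all analyses.  Raises if the base at (chrom, pos) is not
    a cytosine on the requested strand.
    """
    seq = genome.sequences[chrom]
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside {chrom} (length {n})")
    if strand == "+":
        if seq[pos - 1] != "C":
            raise ValueError(f"{chrom}:{pos}:+ is {seq[pos - 1]!r}, not C")
        if pos + 2 > n:
            return None
        tri = seq[pos - 1 : pos + 2]
    elif strand == "-":
        if seq[pos - 1] != "G":
            raise ValueError(f"{chrom}:{pos}:- is {seq[pos - 1]!r}, not C on the minus strand")
        if pos - 2 < 1:
            return None
        tri = seq[pos - 3 : pos].encode().translate(_COMPLEMENT)[::-1].decode()
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if "N" in tri[1:]:
        return None
    if tri[1] == "G":
        return "CG", tri
    if tri[2] == "G":
        return "CHG", tri
    return "CHH", tri


def scan_cytosines(genome: GenomeSequence, include_control: bool = True) -> pd.DataFrame:
    """Vectorised both-strand scan of every classifiable cytosine.

    Returns columns ``chrom, pos, strand, context, trinucleotide`` sorted
    by position within each chromosome.  Edge cytosines and cytosines
    with a downstream N are excluded (context undefined).
    """
    frames = []
    for chrom in genome.chrom_names:
        if not include_control and chrom == genome.control_chrom:
            continue
        raw = genome.sequences[chrom].encode()
        arr = np.frombuffer(raw, dtype="S1")
        n = len(arr)
        # plus strand: need two downstream bases at pos+1, pos+2
        idx = np.flatnonzero(arr == b"C")
        idx = idx[idx <= n - 3]
        if idx.size:
            b1, b2 = arr[idx + 1], arr[idx + 2]
            ok = (b1 != b"N") & (b2 != b"N")
            idx, b1, b2 = idx[ok], b1[ok], b2[ok]
        if idx.size:
            ctx = np.where(b1 == b"G", "CG", np.where(b2 == b"G", "CHG", "CHH"))
            tri = np.char.add(np.char.add("C", b1.astype("U1")), b2.astype("U1"))
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": idx + 1, "strand": "+", "context": ctx, "trinucleotide": tri,
            }))
        # minus strand: a C on '-' is a G on '+'; downstream = lower coordinates
        gidx = np.flatnonzero(arr == b"G")
        gidx = gidx[gidx >= 2]
        if gidx.size:
            u1, u2 = arr[gidx - 1], arr[gidx - 2]
            ok = (u1 != b"N") & (u2 != b"N")
            gidx, u1, u2 = gidx[ok], u1[ok], u2[ok]
        if gidx.size:
            ctx = np.where(u1 == b"C", "CG", np.where(u2 == b"C", "CHG", "CHH"))
            c1 = np.frombuffer(u1.tobytes().translate(_COMPLEMENT), dtype="S1").astype("U1")
            c2 = np.frombuffer(u2.tobytes().translate(_COMPLEMENT), dtype="S1").astype("U1")
            tri = np.char.add(np.char.add("C", c1), c2)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": gidx + 1, "strand": "-", "context": ctx, "trinucleotide": tri,
            }))
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def site_ml(count_meth: int, count_unmeth: int) -> float:
    """ML = mC/(mC+C).  Zero coverage is undefined: the site is missing, never 0."""
    cov = count_meth + count_unmeth
    if cov == 0:
        raise ValueError("site has zero coverage; ML undefined (treat as missing)")
    if count_meth < 0 or count_unmeth < 0:
        raise ValueError("read counts must be non-negative")
    return count_meth / cov


def estimate_nonconversion(methylome: SampleMethylome, genome: GenomeSequence) -> float:
    """Pooled non-conversion rate from the unmethylated control chromosome.

    r = sum(count_meth) / sum(count_meth + count_unmeth) over all covered
    control-chromosome sites; stored on the methylome and returned.
    """
    if genome.control_chrom is None:
        raise ValueError("genome has no control chromosome; supply r explicitly")
    ctrl = methylome.sites[methylome.sites["chrom"] == genome.control_chrom]
    total = int(ctrl["count_meth"].sum() + ctrl["count_unmeth"].sum())
    if total == 0:
        raise ValueError(
            "no covered sites on the control chromosome; supply the non-conversion rate explicitly"
        )
    r = float(ctrl["count_meth"].sum()) / total
    methylome.nonconversion_rate = r
    return r


def correct_ml(ml_raw, r: float):
    """Invert the non-conversion error model: ml_corrected = max(0, (ml-r)/(1-r)).

    Accepts scalars or arrays.  The apparent level of a site with true
    level p is q = p + (1-p)r, so this is the exact inverse, clamped at 0.
    """
    if r >= 1 or r < 0:
        raise ValueError("non-conversion rate must be in [0, 1)")
    return np.maximum(0.0, (np.asarray(ml_raw, dtype=float) - r) / (1.0 - r))[()]


def methylated_site_pvalue(count_meth, coverage, r: float):
    """One-sided exact binomial tail P[X >= count_meth | Binomial(coverage, r)]."""
    k = np.asarray(count_meth)
    n = np.asarray(coverage)
    return stats.binom.sf(k - 1, n, r)[()]


def call_methylated_site(count_meth: int, coverage: int, r: float, alpha: float = 0.05):
    """Single-site methylation call: (methylated, p).

    Genome-wide calling applies BH within each context stratum via
    :func:`call_methylated_sites`; this single-site form compares the raw
    binomial p to ``alpha``.
    """
    p = float(methylated_site_pvalue(count_meth, coverage, r))
    return p < alpha, p


def call_methylated_sites(
    methylome: SampleMethylome,
    r: float | None = None,
    min_coverage: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site methylation calls with BH correction per context stratum.

    Sites with coverage below ``min_coverage`` are untestable (excluded
    from numerator and denominator of downstream percentages).  Returns
    the site table with ``testable, p, q, methylated`` columns added.
    """
    if r is None:
        r = methylome.nonconversion_rate
    if r is None:
        raise ValueError("non-conversion rate unknown: call estimate_nonconversion first or pass r")
    df = methylome.sites.copy()
    cov = df["count_meth"] + df["count_unmeth"]
    df["coverage"] = cov
    df["testable"] = cov >= min_coverage
    df["p"] = np.nan
    df["q"] = np.nan
    df["methylated"] = False
    for ctx in ("CG", "CHG", "CHH"):
        mask = df["testable"] & (df["context"] == ctx)
        if not mask.any():
            continue
        p = methylated_site_pvalue(df.loc[mask, "count_meth"].to_numpy(), cov[mask].to_numpy(), r)
        q = stats.false_discovery_control(p)
        df.loc[mask, "p"] = p
        df.loc[mask, "q"] = q
        df.loc[mask, "methylated"] = q < alpha
    return df


@dataclass
class ContextSummary:
    """Percentage of called-methylated sites per context among all testable cytosines."""

    scope: str
    pct_mcg: float
    pct_mchg: float
    pct_mchh: float

    @property
    def pct_total(self) -> float:
        return self.pct_mcg + self.pct_mchg + self.pct_mchh


def context_proportions(calls: pd.DataFrame, scope: str | None = None) -> ContextSummary:
    """Genome or per-chromosome context percentages from per-site calls.

    pct for context c = 100 * (# called-methylated sites of context c in
    scope) / (# testable cytosines of all contexts in scope).
    """
    sub = calls if scope is None else calls[calls["chrom"] == scope]
    n_testable = int(sub["testable"].sum())
    if n_testable == 0:
        raise ValueError(f"scope {scope or 'genome'!r} has no testable cytosines")
    pct = {}
    for ctx in ("CG", "CHG", "CHH"):
        n_meth = int((sub["methylated"] & (sub["context"] == ctx)).sum())
        pct[ctx] = 100.0 * n_meth / n_testable
    return ContextSummary(scope or "genome", pct["CG"], pct["CHG"], pct["CHH"])


def chromosome_context_shares(calls: pd.DataFrame) -> pd.DataFrame:
    """Among called-methylated sites of each chromosome, the fraction per context.

    Shares sum to 1 per chromosome with at least one methylated site.
    """
    meth = calls[calls["methylated"]]
    rows = []
    for chrom, grp in meth.groupby("chrom", sort=True):
        total = len(grp)
        counts = grp["context"].value_counts()
        rows.append({
            "chrom": chrom,
            "share_mCG": counts.get("CG", 0) / total,
            "share_mCHG": counts.get("CHG", 0) / total,
            "share_mCHH": counts.get("CHH", 0) / total,
        })
    return pd.DataFrame(rows, columns=["chrom", "share_mCG", "share_mCHG", "share_mCHH"])


def sliding_window_ml(
    methylome: SampleMethylome,
    genome: GenomeSequence | None = None,
    window: int = 3000,
    step: int = 600,
    context: str | None = None,
) -> pd.DataFrame:
    """Pooled per-window methylation levels.

    Windows start at 1, 1+step, ...; the last window is truncated at the
    chromosome end.  Counts are pooled over covered sites of the requested
    context (both strands); windows with zero covered sites are omitted.
    ``context=None`` pools all three contexts ("combined").
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    sites = methylome.sites
    if context is not None:
        sites = sites[sites["context"] == context]
    label = context if context is not None else "combined"
    frames = []
    n_overlap = -(-window // step)  # windows covering any one position
    for chrom, grp in sites.groupby("chrom", sort=False):
        cov = (grp["count_meth"] + grp["count_unmeth"]).to_numpy()
        keep = cov > 0
        if not keep.any():
            continue
        pos = grp["pos"].to_numpy()[keep]
        m = grp["count_meth"].to_numpy()[keep]
        u = grp["count_unmeth"].to_numpy()[keep]
        chrom_len = genome.length(chrom) if genome is not None else int(pos.max())
        n_win = (chrom_len - 1) // step + 1
        msum = np.zeros(n_win, dtype=np.int64)
        usum = np.zeros(n_win, dtype=np.int64)
        nsites = np.zeros(n_win, dtype=np.int64)
        k_hi = (pos - 1) // step
        for off in range(n_overlap):
            k = k_hi - off
            valid = (k >= 0) & (pos <= k * step + window)
            kk = k[valid]
            np.add.at(msum, kk, m[valid])
            np.add.at(usum, kk, u[valid])
            np.add.at(nsites, kk, 1)
        kidx = np.flatnonzero(nsites > 0)
        start = kidx * step + 1
        tot = msum[kidx] + usum[kidx]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": start,
            "end": np.minimum(start + window - 1, chrom_len),
            "context": label,
            "n_sites": nsites[kidx],
            "sum_meth": msum[kidx],
            "sum_unmeth": usum[kidx],
            "ml": msum[kidx] / tot,
        }))
    cols = ["chrom", "start", "end", "context", "n_sites", "sum_meth", "sum_unmeth", "ml"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def bin_profile(
    methylome: SampleMethylome,
    genome: GenomeSequence | None = None,
    bin_size: int = 10000,
    context: str | None = None,
) -> pd.DataFrame:
    """Non-overlapping tiling-bin MLs (window = step = bin_size); empty bins omitted."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    return sliding_window_ml(methylome, genome, window=bin_size, step=bin_size, context=context)
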