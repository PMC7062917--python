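"""Functional-element intervals and 20-bin methylation metaprofiles.

Gene models are decomposed into promoter / 5'UTR / exon / intron / 3'UTR
intervals and, for each element type and cytosine context, an average
metaprofile is computed by splitting every element into ``n_bins`` equal
fractional bins (5'->3' in gene orientation) and pooling methylated /
unmethylated read counts per bin across all elements of the type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical ordering of element types, used for stable output
ELEMENT_TYPES = ("promoter", "utr5", "exon", "intron", "utr3")

PROMOTER_BP = 2000


@dataclass
class GeneModel:
    """One gene collapsed to a single (longest-span) transcript.

    Coordinates are 1-based inclusive.  The TSS is the span start on the
    plus strand and the span end on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if b < a:
                raise ValueError(f"gene {self.gene_id}: exon end < start")
            if a < self.start or b > self.end:
                raise ValueError(f"gene {self.gene_id}: exon {a}-{b} outside gene span")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur[0] <= prev[1]:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start - a_end > 1
        ]


@dataclass
class MetaProfile:
    """Pooled per-bin counts and mean ML for one element type and context."""

    element_type: str
    context: str
    n_bins: int
    bin_meth: np.ndarray
    bin_unmeth: np.ndarray

    @property
    def bin_means(self) -> np.ndarray:
        """Pooled ML per bin; NaN where a bin received no reads."""
        tot = self.bin_meth + self.bin_unmeth
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.bin_meth / np.maximum(tot, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_type": self.element_type,
                "context": self.context,
                "bin": np.arange(1, self.n_bins + 1),
                "sum_meth": self.bin_meth,
                "sum_unmeth": self.bin_unmeth,
                "ml": self.bin_means,
            }
        )


ELEMENT_COLUMNS = ["gene_id", "element_type", "chrom", "start", "end", "strand"]


def derive_elements(gene_models, genome) -> pd.DataFrame:
    """Decompose gene models into element intervals.

    Promoters are the 2 kb strand-aware upstream of the TSS, truncated at
    chromosome bounds; introns are the gaps between consecutive exons;
    UTRs are passed through from the annotation.  Returns a DataFrame with
    columns ``gene_id, element_type, chrom, start, end, strand``.
    """
    rows = []
    for g in gene_models:
        chrom_len = genome.length(g.chrom)
        if g.strand == "+":
            p_start, p_end = g.tss - PROMOTER_BP, g.tss - 1
            p_start = max(1, p_start)
        else:
            p_start, p_end = g.tss + 1, g.tss + PROMOTER_BP
            p_end = min(chrom_len, p_end)
        if p_end < p_start or p_end < 1 or p_start > chrom_len:
            warnings.warn(f"gene {g.gene_id}: promoter falls entirely off-chromosome; omitted")
        else:
            rows.append((g.gene_id, "promoter", g.chrom, p_start, p_end, g.strand))
        for a, b in g.utr5:
            rows.append((g.gene_id, "utr5", g.chrom, a, b, g.strand))
        for a, b in g.exons:
            rows.append((g.gene_id, "exon", g.chrom, a, b, g.strand))
        for a, b in g.introns:
            rows.append((g.gene_id, "intron", g.chrom, a, b, g.strand))
        for a, b in g.utr3:
            rows.append((g.gene_id, "utr3", g.chrom, a, b, g.strand))
    df = pd.DataFrame(rows, columns=ELEMENT_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "gene_id", "element_type"]).reset_index(drop=True)


def metaprofile(methylome, elements: pd.DataFrame, element_type: str, context: str, n_bins: int = 20) -> MetaProfile:
    """Pooled ``n_bins``-bin profile over all elements of one type.

    Bin ``k`` (0-based) of an element of length ``L`` covers offsets
    ``[floor(k*L/n), floor((k+1)*L/n))`` from the element's biological 5'
    end: minus-strand elements are traversed 3'->5' in genome coordinates
    so bin 1 is always 5'.  Each covered site lands in exactly one bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    els = elements[elements["element_type"] == element_type]
    if els.empty:
        raise ValueError(f"no elements of type {element_type!r}")
    sites = methylome.sites
    sites = sites[(sites["context"] == context) & (sites["count_meth"] + sites["count_unmeth"] > 0)]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        by_chrom[chrom] = (
            grp["pos"].to_numpy()[order],
            grp["count_meth"].to_numpy()[order],
            grp["count_unmeth"].to_numpy()[order],
        )
    bin_m = np.zeros(n_bins, dtype=np.int64)
    bin_u = np.zeros(n_bins, dtype=np.int64)
    for el in els.itertuples():
        if el.chrom not in by_chrom:
            continue
        pos, m, u = by_chrom[el.chrom]
        i0 = np.searchsorted(pos, el.start, side="left")
        i1 = np.searchsorted(pos, el.end, side="right")
        if i0 == i1:
            continue
        p = pos[i0:i1]
        length = el.end - el.start + 1
        offset = (p - el.start) if el.strand == "+" else (el.end - p)
        bounds = (np.arange(1, n_bins + 1, dtype=np.int64) * length) // n_bins
        b = np.searchsorted(bounds, offset, side="right")
        np.add.at(bin_m, b, m[i0:i1])
        np.add.at(bin_u, b, u[i0:i1])
    return MetaProfile(element_type, context, n_bins, bin_m, bin_u)
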