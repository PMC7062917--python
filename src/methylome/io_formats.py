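"""Readers and writers for every on-disk format the pipeline touches.

All in-memory coordinates are 1-based inclusive (the per-cytosine report
convention); BED output alone is 0-based half-open.  Every TSV written by
this package carries a single header line beginning ``#``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .functional_profiles import GeneModel

VALID_CONTEXTS = ("CG", "CHG", "CHH")
GENOME_ALPHABET = frozenset("ACGTN")

CX_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]


@dataclass
class GenomeSequence:
    """An ordered set of chromosomes plus an optional unmethylated spike-in.

    ``sequences`` maps chromosome name -> uppercase sequence over A,C,G,T,N.
    ``control_chrom`` names the unmethylated control (lambda) chromosome
    used to estimate the bisulfite non-conversion rate.
    """

    sequences: dict[str, str]
    control_chrom: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            if len(seq) < 1:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - GENOME_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA characters {sorted(bad)!r}"
                )
        if self.control_chrom is not None and self.control_chrom not in self.sequences:
            raise ValueError(f"control chromosome {self.control_chrom!r} not in genome")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass
class SampleMethylome:
    """Per-cytosine counts for one sample.

    ``sites`` is a DataFrame with columns ``chrom, pos, strand, count_meth,
    count_unmeth, context, trinucleotide``, unique on (chrom, pos, strand)
    and sorted by that key.  ``nonconversion_rate`` is the lambda-estimated
    fraction of unmethylated cytosines read as methylated, or None.
    """

    sample_id: str
    sites: pd.DataFrame
    nonconversion_rate: float | None = None

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in CX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sites table missing columns {missing}")
        df = df[CX_COLUMNS].copy()
        if len(df):
            bad_strand = ~df["strand"].isin(["+", "-"])
            if bad_strand.any():
                raise ValueError("strand must be '+' or '-'")
            bad_ctx = ~df["context"].isin(VALID_CONTEXTS)
            if bad_ctx.any():
                raise ValueError(f"context must be one of {VALID_CONTEXTS}")
            if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
                raise ValueError("read counts must be non-negative")
            df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "pos", "strand"])
            if dup.any():
                row = df[dup].iloc[0]
                raise ValueError(
                    f"duplicate site ({row.chrom}, {row.pos}, {row.strand}) in sample {self.sample_id}"
                )
        self.sites = df
        if self.nonconversion_rate is not None and not 0 <= self.nonconversion_rate <= 1:
            raise ValueError("nonconversion_rate must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.sites)

    def validate_against(self, genome: GenomeSequence) -> None:
        unknown = set(self.sites["chrom"]) - set(genome.chrom_names)
        if unknown:
            raise ValueError(f"sample {self.sample_id}: unknown chromosomes {sorted(unknown)}")


# ---------------------------------------------------------------------------
# CX report (7-column per-cytosine TSV)
# ---------------------------------------------------------------------------

def read_cx_report(path, sample_id: str | None = None) -> SampleMethylome:
    """Parse a tab-separated per-cytosine report into a :class:`SampleMethylome`.

    Columns: chrom, pos, strand, count_meth, count_unmeth, context,
    trinucleotide.  Lines starting with ``#`` and blank lines are ignored.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, m_s, u_s, context, tri = parts
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer position or count") from None
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: position must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}")
            if m < 0 or u < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            if context not in VALID_CONTEXTS:
                raise ValueError(f"{path}: line {lineno}: context must be one of {VALID_CONTEXTS}, got {context!r}")
            rows.append((chrom, pos, strand, m, u, context, tri))
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    if not len(df):
        df = df.astype({"pos": "int64", "count_meth": "int64", "count_unmeth": "int64"})
    return SampleMethylome(sample_id, df)


def write_cx_report(methylome: SampleMethylome, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CX_COLUMNS) + "\n")
        methylome.sites.to_csv(fh, sep="\t", header=False, index=False)
    return path


# ---------------------------------------------------------------------------
# FASTA genome
# ---------------------------------------------------------------------------

def read_genome_fasta(path, control_chrom: str | None = None) -> GenomeSequence:
    """Read a DNA FASTA; sequences are uppercased and validated (A,C,G,T,N only)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty FASTA record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    if control_chrom is not None and control_chrom not in sequences:
        raise ValueError(f"{path}: control chromosome {control_chrom!r} not present")
    return GenomeSequence(sequences, control_chrom)


def write_genome_fasta(genome: GenomeSequence, path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Load gene models from GFF3, collapsing each gene to its longest-span transcript.

    Genes without exons are skipped with a warning; an exon outside its
    gene span raises a validation error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = list(db.children(g, featuretype=("mRNA", "transcript"), level=1))
        if transcripts:
            tx = sorted(transcripts, key=lambda t: (-(t.end - t.start), t.id))[0]
            parent = tx
        else:
            parent = g
        exons = sorted(db.children(parent, featuretype="exon"), key=lambda e: e.start)
        if not exons:
            warnings.warn(f"gene {g.id} has no exons; skipped")
            continue
        for e in exons:
            if e.start < g.start or e.end > g.end:
                raise ValueError(f"gene {g.id}: exon {e.start}-{e.end} outside gene span {g.start}-{g.end}")
        utr5 = sorted(db.children(parent, featuretype="five_prime_UTR"), key=lambda u: u.start)
        utr3 = sorted(db.children(parent, featuretype="three_prime_UTR"), key=lambda u: u.start)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exons=[(e.start, e.end) for e in exons],
                utr5=[(u.start, u.end) for u in utr5],
                utr3=[(u.start, u.end) for u in utr3],
            )
        )
    return genes


def write_gene_models_gff3(genes: list[GeneModel], path) -> Path:
    """Write gene models as GFF3 (gene / mRNA / exon / UTR features)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
            base = f"{g.chrom}\tmethylome\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(base + f"gene\t{g.start}\t{g.end}" + tail + f"\tID={g.gene_id}\n")
            tx_id = f"{g.gene_id}.1"
            fh.write(base + f"mRNA\t{g.start}\t{g.end}" + tail + f"\tID={tx_id};Parent={g.gene_id}\n")
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(base + f"exon\t{a}\t{b}" + tail + f"\tID={tx_id}.exon{i};Parent={tx_id}\n")
            for i, (a, b) in enumerate(g.utr5, 1):
                fh.write(base + f"five_prime_UTR\t{a}\t{b}" + tail + f"\tID={tx_id}.utr5.{i};Parent={tx_id}\n")
            for i, (a, b) in enumerate(g.utr3, 1):
                fh.write(base + f"three_prime_UTR\t{a}\t{b}" + tail + f"\tID={tx_id}.utr3.{i};Parent={tx_id}\n")
    return path


# ---------------------------------------------------------------------------
# DMR outputs
# ---------------------------------------------------------------------------

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "status", "ml_treat", "ml_ctrl",
    "diff", "fold_change", "n_cytosines", "p", "q", "element_hits", "gene_ids",
]


def bed_score(q: float) -> int:
    """-10*log10(q) rounded, capped at 1000 (q=1 -> 0; q=0 -> 1000)."""
    if q <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(q))))


def write_dmr_outputs(dmrs: pd.DataFrame, path_prefix) -> tuple[Path, Path]:
    """Write DMRs as BED6 (0-based half-open) plus a full TSV.

    Byte-identical across repeated runs on identical input: fixed column
    order and a fixed ``%.6g`` float format.
    """
    prefix = Path(path_prefix)
    bed_path = Path(str(prefix) + ".bed")
    tsv_path = Path(str(prefix) + ".tsv")
    cols = [c for c in DMR_COLUMNS if c in dmrs.columns]
    with open(bed_path, "w") as fh:
        for row in dmrs.itertuples():
            name = f"{row.context}:{row.status}"
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{name}\t{bed_score(row.q)}\t.\n")
    with open(tsv_path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        dmrs[cols].to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
    return bed_path, tsv_path


def read_tsv(path) -> pd.DataFrame:
    """Read a ``#``-headed TSV written by this package."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        names = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=names)


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
    return path
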