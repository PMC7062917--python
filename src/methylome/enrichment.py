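"""Hypergeometric over-representation test of gene sets against term maps.

Per term with K member genes in a background of N, a hit set of size n
containing k term genes scores the upper-tail p = P[X >= k] of the
hypergeometric distribution, followed by Benjamini-Hochberg adjustment
across all terms.  This is the generic form of a GO/KEGG enrichment step;
database retrieval and length-bias weighting are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .io_formats import read_tsv


@dataclass
class TermMap:
    """term_id -> member gene set, plus the background universe."""

    terms: dict[str, frozenset]
    background: frozenset
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            extra = set(genes) - self.background
            if extra:
                raise ValueError(f"term {tid}: genes outside the background: {sorted(extra)[:5]}")


def read_term_map(path, descriptions_path=None, background=None) -> TermMap:
    """Two-column TSV (term_id, gene_id); background defaults to the union."""
    df = read_tsv(path)
    if list(df.columns[:2]) != ["term_id", "gene_id"]:
        raise ValueError(f"{path}: expected columns term_id, gene_id")
    terms: dict[str, set] = {}
    for row in df.itertuples():
        terms.setdefault(str(row.term_id), set()).add(str(row.gene_id))
    all_genes = frozenset().union(*terms.values()) if terms else frozenset()
    bg = frozenset(background) if background is not None else all_genes
    descriptions = {}
    if descriptions_path is not None:
        ddf = read_tsv(descriptions_path)
        descriptions = dict(zip(ddf["term_id"].astype(str), ddf["description"].astype(str)))
    return TermMap({t: frozenset(g) for t, g in terms.items()}, bg, descriptions)


ENRICH_COLUMNS = ["term_id", "description", "k", "K", "n", "N", "p", "q"]


def enrich_terms(hits, term_map: TermMap) -> pd.DataFrame:
    """Per-term over-representation of ``hits``, sorted by (q, term_id).

    Raises if any hit gene is outside the background universe.
    """
    hits = set(hits)
    offenders = hits - term_map.background
    if offenders:
        raise ValueError(f"hit genes outside background: {sorted(offenders)}")
    n, N = len(hits), len(term_map.background)
    rows = []
    for tid in sorted(term_map.terms):
        genes = term_map.terms[tid]
        K = len(genes)
        if K < 1:
            continue
        k = len(hits & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": tid, "description": term_map.descriptions.get(tid, ""),
            "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "q"])
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"].to_numpy())
    else:
        df["q"] = []
    return df.sort_values(["q", "term_id"]).reset_index(drop=True)[ENRICH_COLUMNS]
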