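import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylome.io_formats import GenomeSequence
from methylome.methylation_core import (
    bin_profile,
    call_methylated_sites,
    chromosome_context_shares,
    classify_context,
    context_proportions,
    correct_ml,
    estimate_nonconversion,
    methylated_site_pvalue,
    scan_cytosines,
    site_ml,
    sliding_window_ml,
)

from conftest import make_methylome


# ---------------------------------------------------------------------------
# context calling
# ---------------------------------------------------------------------------

def _oracle_scan(seq):
    """Independent per-position 3-mer scan of both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    out = []
    n = len(seq)
    for i in range(n):  # 0-based
        if seq[i] == "C" and i + 2 < n:
            tri = seq[i : i + 3]
            if "N" not in tri[1:]:
                ctx = "CG" if tri[1] == "G" else ("CHG" if tri[2] == "G" else "CHH")
                out.append((i + 1, "+", ctx, tri))
        if seq[i] == "G" and i - 2 >= 0:
            tri = "".join(comp[b] for b in reversed(seq[i - 2 : i + 1]))
            if "N" not in tri[1:]:
                ctx = "CG" if tri[1] == "G" else ("CHG" if tri[2] == "G" else "CHH")
                out.append((i + 1, "-", ctx, tri))
    return sorted(out)


@pytest.mark.parametrize(
    "seq, pos, strand, expected",
    [
        ("ACGT", 2, "+", ("CG", "CGT")),
        ("TTGAA", 3, "-", ("CHH", "CAA")),
        ("ACAGT", 2, "+", ("CHG", "CAG")),
    ],
)
def test_classify_context_examples(seq, pos, strand, expected):
    g = GenomeSequence({"Chr1": seq})
    assert classify_context(g, "Chr1", pos, strand) == expected


def test_classify_context_errors_and_exclusions():
    g = GenomeSequence({"Chr1": "ACNGTC"})
    with pytest.raises(ValueError, match="not C"):
        classify_context(g, "Chr1", 1, "+")
    # chromosome edge: fewer than 2 downstream bases
    assert classify_context(g, "Chr1", 6, "+") is None
    # downstream N
    assert classify_context(g, "Chr1", 2, "+") is None


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
def test_scan_cytosines_matches_bruteforce(seq):
    g = GenomeSequence({"Chr1": seq})
    df = scan_cytosines(g)
    got = sorted(zip(df["pos"], df["strand"], df["context"], df["trinucleotide"]))
    assert got == _oracle_scan(seq)


def test_scan_cytosines_agrees_with_classify_context(small_genome):
    df = scan_cytosines(small_genome).head(500)
    for row in df.itertuples():
        assert classify_context(small_genome, row.chrom, row.pos, row.strand) == (
            row.context, row.trinucleotide,
        )


# ---------------------------------------------------------------------------
# ML, non-conversion, site calls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m, u, expected", [(3, 7, 0.3), (0, 10, 0.0), (10, 0, 1.0)])
def test_site_ml(m, u, expected):
    assert site_ml(m, u) == pytest.approx(expected)


def test_site_ml_zero_coverage_is_missing_not_zero():
    with pytest.raises(ValueError, match="missing"):
        site_ml(0, 0)


def test_estimate_nonconversion_pools_control_counts():
    g = GenomeSequence({"Chr1": "ACGT" * 10, "lambda": "ACGT" * 10}, control_chrom="lambda")
    m = make_methylome([
        ("Chr1", 2, "+", 50, 50, "CG", "CGA"),
        ("lambda", 2, "+", 2, 198, "CG", "CGA"),
        ("lambda", 6, "+", 0, 200, "CG", "CGA"),
    ])
    r = estimate_nonconversion(m, g)
    assert r == pytest.approx(2 / 400)
    assert m.nonconversion_rate == r
    # two equal sites pool identically
    m2 = make_methylome([
        ("lambda", 2, "+", 1, 99, "CG", "CGA"),
        ("lambda", 6, "+", 1, 99, "CG", "CGA"),
    ])
    assert estimate_nonconversion(m2, g) == pytest.approx(0.01)


def test_estimate_nonconversion_requires_covered_control_sites():
    g = GenomeSequence({"Chr1": "ACGT", "lambda": "ACGT"}, control_chrom="lambda")
    m = make_methylome([("Chr1", 2, "+", 1, 1, "CG", "CGA")])
    with pytest.raises(ValueError, match="explicitly"):
        estimate_nonconversion(m, g)


@pytest.mark.parametrize(
    "ml, r, expected",
    [(0.3, 0.005, (0.3 - 0.005) / 0.995), (0.004, 0.005, 0.0), (0.37, 0.0, 0.37)],
)
def test_correct_ml(ml, r, expected):
    assert correct_ml(ml, r) == pytest.approx(expected)


def test_correct_ml_rejects_full_nonconversion():
    with pytest.raises(ValueError):
        correct_ml(0.5, 1.0)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.floats(0, 1), st.floats(0, 0.5))
def test_correct_ml_bounds(ml, r):
    c = correct_ml(ml, r)
    assert 0.0 <= c <= ml + 1e-12


def _binom_tail_bruteforce(k, n, r):
    return sum(math.comb(n, j) * r**j * (1 - r) ** (n - j) for j in range(k, n + 1))


@pytest.mark.parametrize("k, n, r", [(5, 5, 0.005), (0, 10, 0.02), (2, 10, 0.005), (3, 12, 0.01)])
def test_methylated_site_pvalue_matches_bruteforce(k, n, r):
    assert methylated_site_pvalue(k, n, r) == pytest.approx(_binom_tail_bruteforce(k, n, r), rel=1e-10)
    # spot values forced by the formula
    assert methylated_site_pvalue(5, 5, 0.005) == pytest.approx(0.005**5)
    assert methylated_site_pvalue(0, 10, 0.1) == pytest.approx(1.0)


def test_call_methylated_sites_respects_coverage_floor():
    m = make_methylome([
        ("Chr1", 2, "+", 4, 0, "CG", "CGA"),   # below min coverage: untestable
        ("Chr1", 6, "+", 10, 0, "CG", "CGA"),  # clearly methylated
        ("Chr1", 10, "+", 0, 30, "CG", "CGA"),
    ])
    calls = call_methylated_sites(m, r=0.005, min_coverage=5, alpha=0.05)
    assert list(calls["testable"]) == [False, True, True]
    assert list(calls["methylated"]) == [False, True, False]
    assert np.isnan(calls["p"].iloc[0])


# ---------------------------------------------------------------------------
# windows and bins
# ---------------------------------------------------------------------------

def test_single_full_window_on_3000bp_chromosome():
    g = GenomeSequence({"Chr1": "A" * 3000})
    m = make_methylome([("Chr1", 100, "+", 4, 6, "CG", "CGA")])
    win = sliding_window_ml(m, g, window=3000, step=600)
    full = win[win["start"] == 1]
    assert len(full) == 1
    assert (full.iloc[0]["end"], full.iloc[0]["ml"], full.iloc[0]["n_sites"]) == (3000, 0.4, 1)


def test_window_step_arithmetic_3600bp():
    g = GenomeSequence({"Chr1": "A" * 3600})
    m = make_methylome([
        ("Chr1", 100, "+", 1, 1, "CG", "CGA"),
        ("Chr1", 3500, "+", 1, 1, "CG", "CGA"),
    ])
    win = sliding_window_ml(m, g, window=3000, step=600)
    spans = set(zip(win["start"], win["end"]))
    assert (1, 3000) in spans and (601, 3600) in spans
    # no window may extend past the chromosome end
    assert (win["end"] <= 3600).all()


def test_window_pooling_is_coverage_weighted_mean(small_samples):
    sample = small_samples["DMSO"]
    win = sliding_window_ml(sample, window=3000, step=3000, context="CG").head(10)
    sites = sample.sites[sample.sites["context"] == "CG"]
    for row in win.itertuples():
        sub = sites[(sites["chrom"] == row.chrom) & (sites["pos"] >= row.start) & (sites["pos"] <= row.end)]
        cov = sub["count_meth"] + sub["count_unmeth"]
        sub = sub[cov > 0]
        weighted = (sub["count_meth"]).sum() / (sub["count_meth"] + sub["count_unmeth"]).sum()
        assert row.ml == pytest.approx(weighted)
        assert row.n_sites == len(sub)


def test_bin_profile_equals_window_equals_step(small_samples):
    sample = small_samples["DMSO"]
    bins = bin_profile(sample, bin_size=10_000)
    win = sliding_window_ml(sample, window=10_000, step=10_000)
    pd.testing.assert_frame_equal(bins, win)


def test_bin_profile_degenerate_inputs():
    empty = make_methylome([])
    assert len(bin_profile(empty)) == 0
    single = make_methylome([("Chr1", 5, "+", 3, 1, "CHH", "CTA")])
    bins = bin_profile(single, bin_size=10_000)
    assert len(bins) == 1 and bins.iloc[0]["ml"] == pytest.approx(0.75)


def test_sliding_window_rejects_step_above_window():
    with pytest.raises(ValueError):
        sliding_window_ml(make_methylome([]), window=100, step=200)


# ---------------------------------------------------------------------------
# context proportions
# ---------------------------------------------------------------------------

def _calls_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "context", "testable", "methylated"])


def test_context_proportions_definition():
    rows = [("Chr1", "CG", True, True)] * 40 + [("Chr1", "CHG", True, False)] * 30 \
        + [("Chr1", "CHH", True, False)] * 30
    summary = context_proportions(_calls_frame(rows))
    assert summary.pct_mcg == pytest.approx(40.0)
    assert summary.pct_mchg == summary.pct_mchh == 0.0
    assert summary.pct_total == pytest.approx(40.0)


def test_context_proportions_additivity_and_shares(small_samples, small_genome):
    sample = small_samples["DMSO"]
    r = estimate_nonconversion(sample, small_genome)
    calls = call_methylated_sites(sample, r)
    s = context_proportions(calls)
    assert s.pct_total == pytest.approx(s.pct_mcg + s.pct_mchg + s.pct_mchh)
    shares = chromosome_context_shares(calls)
    for row in shares.itertuples():
        assert row.share_mCG + row.share_mCHG + row.share_mCHH == pytest.approx(1.0)


def test_context_proportions_empty_scope_rejected():
    with pytest.raises(ValueError, match="testable"):
        context_proportions(_calls_frame([("Chr1", "CG", False, False)]), "Chr1")
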