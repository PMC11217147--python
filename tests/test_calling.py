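"""Read filters, background estimation, binomial tail, and site calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ubscall as u
from ubscall.calling import binomial_pvalues, _cluster_discard, PRESETS

from conftest import make_read


# ---------------------------------------------------------------------------
# binomial tail
# ---------------------------------------------------------------------------

# exact values precomputed by rational-arithmetic direct summation
FROZEN_TAILS = [
    (5, 30, 0.02, 0.0003003305793665167),
    (3, 50, 0.006, 0.003430033668616655),
    (30, 100, 0.3, 0.5376602639846375),
    (10, 10, 0.01, 1.0e-20),
]


@pytest.mark.parametrize("k,n,p0,expected", FROZEN_TAILS)
def test_binomial_tail_matches_direct_summation(k, n, p0, expected):
    assert u.binomial_pvalue(k, n, p0) == pytest.approx(expected, rel=1e-10)


def test_binomial_tail_edge_cases():
    assert u.binomial_pvalue(0, 50, 0.01) == 1.0
    assert u.binomial_pvalue(0, 50, 0.0) == 1.0
    assert u.binomial_pvalue(5, 50, 0.0) == 0.0
    assert u.binomial_pvalue(5, 50, 1.0) == 1.0
    with pytest.raises(ValueError):
        u.binomial_pvalue(11, 10, 0.5)
    with pytest.raises(ValueError):
        u.binomial_pvalue(1, 10, 1.5)


@given(
    n=st.integers(1, 300),
    p0=st.floats(1e-4, 0.5),
    data=st.data(),
)
@settings(max_examples=60, deadline=None)
def test_binomial_tail_monotone_in_k(n, p0, data):
    k = data.draw(st.integers(1, n))
    assert u.binomial_pvalue(k, n, p0) >= u.binomial_pvalue(min(k + 1, n), n, p0) - 1e-15


def test_vectorized_tail_matches_scalar():
    rng = np.random.default_rng(0)
    n = rng.integers(1, 400, size=50)
    k = rng.integers(0, n + 1)
    vec = binomial_pvalues(k, n, 0.0123)
    for ki, ni, vi in zip(k, n, vec):
        assert vi == pytest.approx(u.binomial_pvalue(int(ki), int(ni), 0.0123), rel=1e-12)


# ---------------------------------------------------------------------------
# read filters
# ---------------------------------------------------------------------------


def test_cluster_filter_examples():
    # 4 unconverted among 20 covered C: discarded (more than three unconverted)
    kept, _ = u.filter_reads([make_read(4, 16)])
    assert kept == []
    # 2 unconverted of 3 covered C: discarded (more than one third of total)
    kept, _ = u.filter_reads([make_read(2, 1)])
    assert kept == []
    # fully converted read: retained
    kept, _ = u.filter_reads([make_read(0, 20)])
    assert len(kept) == 1


def test_filter_order_and_attrition_counts():
    reads = [
        make_read(0, 20, barcode="TTTTTT", rid="bad_bc"),
        make_read(0, 20, mismatches=10, rid="bad_mm"),
        make_read(4, 40, rid="cluster"),
        make_read(1, 20, rid="ok"),
    ]
    kept, counts = u.filter_reads(reads, expect_barcode="ATCACG")
    assert [r.id for r in kept] == ["ok"]
    assert counts == {
        "input": 4, "barcode_fail": 1, "mismatch_fail": 1,
        "cluster_fail": 1, "retained": 1,
    }


def _naive_filter(reads, rule):
    """Independent reference implementation of the read filters."""
    out = []
    for r in reads:
        if r.barcode != "ATCACG":
            continue
        if r.mismatches > 0.05 * r.length:
            continue
        nu, nc = r.n_unconverted(), r.n_converted()
        if nu > 3:
            continue
        if rule == "third" and nu > (nu + nc) / 3:
            continue
        if rule == "half" and nu > nc / 2:
            continue
        out.append(r.id)
    return out


@pytest.mark.parametrize("rule", ["third", "half"])
def test_filter_agrees_with_naive_reference(rule):
    rng = np.random.default_rng(7)
    reads = [
        make_read(
            int(rng.integers(0, 8)),
            int(rng.integers(0, 30)),
            mismatches=int(rng.integers(0, 8)),
            barcode="ATCACG" if rng.random() < 0.9 else "GGGGGG",
            rid=f"r{i}",
        )
        for i in range(2000)
    ]
    kept, _ = u.filter_reads(reads, expect_barcode="ATCACG", cluster_rule=rule)
    assert [r.id for r in kept] == _naive_filter(reads, rule)


# ---------------------------------------------------------------------------
# background + calling
# ---------------------------------------------------------------------------


def _site_df(rows):
    recs = []
    for ref, pos, k, cov in rows:
        recs.append((ref, pos, "+", "C", k, cov - k, cov, k / cov))
    return pd.DataFrame(
        recs,
        columns=["ref", "pos", "strand", "context", "n_unconverted",
                 "n_converted", "coverage", "ratio"],
    )


def test_background_pooled_estimator():
    df = _site_df([("a", 1, 1, 100), ("a", 2, 3, 100)])
    bg = u.estimate_background(df)
    assert bg.p0 == pytest.approx(0.02)
    assert bg.n_sites_used == 2
    all_converted = _site_df([("a", 1, 0, 50), ("a", 2, 0, 80)])
    assert u.estimate_background(all_converted).p0 == 0.0
    with pytest.raises(ValueError):
        u.estimate_background(df[df["coverage"] > 1000])


def test_call_sites_thresholds():
    bg = u.BackgroundModel(p0=0.005, n_sites_used=1, total_unconverted=1,
                           total_coverage=200)
    # truth-like site x=0.3 at coverage 100: strongly called
    df = _site_df([("a", 1, 30, 100)])
    out = u.call_sites(df, bg, min_cov=10)
    assert bool(out["called"].iloc[0])
    assert out["p_value"].iloc[0] < 1e-6
    # arbitrarily small P but ratio below the 5% cutoff: not called
    df = _site_df([("a", 1, 40, 1000)])
    out = u.call_sites(df, bg, min_cov=10)
    assert out["p_value"].iloc[0] < 1e-6
    assert not bool(out["called"].iloc[0])
    # below min coverage: not called
    df = _site_df([("a", 1, 5, 8)])
    assert not bool(u.call_sites(df, bg, min_cov=10)["called"].iloc[0])


def test_calling_monotone_in_k():
    bg = u.BackgroundModel(0.006, 1, 1, 100)
    n = 60
    called = [
        bool(u.call_sites(_site_df([("a", 1, k, n)]), bg, min_cov=10)["called"].iloc[0])
        for k in range(n + 1)
    ]
    # once called at k, called for all larger k
    first = called.index(True)
    assert all(called[first:])


def test_presets_match_figure_thresholds():
    df = _site_df([("a", 1, 2, 12)])  # ratio 0.167, cov 12
    out = u.call_sites(df, preset="dna-ed2a")
    assert bool(out["called"].iloc[0])  # >=10x and >10%
    out = u.call_sites(df, preset="dna-fig2c")
    assert not bool(out["called"].iloc[0])  # needs >25%


def test_model_results_summary_and_iterative_background():
    rng = np.random.default_rng(3)
    rows = [("a", i, int(rng.binomial(100, 0.006)), 100) for i in range(200)]
    rows += [("a", 900 + i, 40, 100) for i in range(3)]  # modified sites
    model = u.MethylationSiteModel(_site_df(rows))
    res = model.fit(min_cov=10)
    assert int(res.sites["called"].sum()) == 3
    assert "binomial background model" in res.summary()
    res_it = model.fit(min_cov=10, iterative=True)
    # excluding called sites lowers the background estimate
    assert res_it.background.p0 < res.background.p0


# ---------------------------------------------------------------------------
# motif classification
# ---------------------------------------------------------------------------


def test_motif_classification():
    seq = "G" * 10 + "CTCCA" + "G" * 10
    motif, window, truncated = u.classify_motif(seq, 10)
    assert motif == "CUCCA" and not truncated
    assert len(window) == 21
    motif, _, _ = u.classify_motif("GGGGGGGGGGCGGGAGGGGG", 10)
    assert motif == "non-CUCCA"
    # U and T are equivalent on transcripts
    assert u.classify_motif("CUCCAGGGGGGGGGGGGGGGGGGGG", 0)[0] == "CUCCA"


def test_motif_window_truncated_at_transcript_start():
    motif, window, truncated = u.classify_motif("CTCCA" + "G" * 20, 0)
    assert motif == "CUCCA" and truncated
    assert window.startswith("CTCCA")
    with pytest.raises(ValueError):
        u.classify_motif("AAAA", 1)
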