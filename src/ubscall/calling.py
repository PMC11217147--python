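"""Read filtering, background estimation, and binomial m5C/5mC site calling.

The null model: at an unmodified C, a read reports C (unconverted) with a
small per-library failure probability p0, estimated by pooling counts over
all C sites in the library.  At a site with coverage n and k unconverted
reads, the evidence against the null is the upper binomial tail
P = Pr(X >= k), X ~ Binomial(n, p0).  A site is called when P < alpha
(default 1e-6) AND its unconverted ratio is >= the minimum ratio (default
5%) AND coverage reaches the minimum.  The fixed small alpha deliberately
avoids a preference for low-coverage sites, where a single random error
perturbs the ratio the most; no multiple-testing correction is applied by
default (a Benjamini-Hochberg mode is available).

Read-level filters applied before counting (RNA branch): inline-barcode
check, a mismatch-rate filter (>5% non-conversion mismatches), and the
unconverted-cluster filter — discard reads with more than three unconverted
C, or more than one third of their covered C unconverted (default rule); an
alternative variant discards reads whose unconverted C exceed half of their
converted C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ubscall.align import CONVERTED, OTHER, UNCONVERTED, MappedRead

__all__ = [
    "BackgroundModel",
    "MethylationSiteModel",
    "SiteCallingResults",
    "PRESETS",
    "filter_reads",
    "estimate_background",
    "binomial_pvalue",
    "binomial_pvalues",
    "call_sites",
    "classify_motif",
]


#: figure-level calling presets: RNA uses the binomial test; the two DNA
#: presets are pure coverage/ratio thresholds
PRESETS = {
    "rna": dict(alpha=1e-6, min_ratio=0.05, min_cov=20, strict_ratio=False),
    "dna-ed2a": dict(alpha=None, min_ratio=0.10, min_cov=10, strict_ratio=True),
    "dna-fig2c": dict(alpha=None, min_ratio=0.25, min_cov=5, strict_ratio=True),
}


# ---------------------------------------------------------------------------
# read-level filters
# ---------------------------------------------------------------------------


def _cluster_discard(n_unconverted: int, n_converted: int, rule: str) -> bool:
    if rule == "third":
        total = n_unconverted + n_converted
        return n_unconverted > 3 or 3 * n_unconverted > total
    if rule == "half":
        return n_unconverted > 3 or 2 * n_unconverted > n_converted
    raise ValueError(f"unknown cluster rule {rule!r}")


def filter_reads(
    reads: Sequence[MappedRead],
    expect_barcode: str | None = None,
    max_mismatch_frac: float = 0.05,
    cluster_rule: str = "third",
) -> tuple[list[MappedRead], dict[str, int]]:
    """Apply barcode, mismatch-rate, and unconverted-cluster filters in order.

    Returns (retained reads, attrition counts).  The mismatch filter discards
    reads with more than ``max_mismatch_frac`` of their length in mismatches
    (C→T conversions excluded).  The cluster filter discards reads with more
    than three unconverted C, or — under the default 'third' rule — more than
    one third of their covered C unconverted ('half': unconverted exceeding
    half of the converted C).
    """
    counts = {
        "input": len(reads),
        "barcode_fail": 0,
        "mismatch_fail": 0,
        "cluster_fail": 0,
        "retained": 0,
    }
    kept: list[MappedRead] = []
    for r in reads:
        if expect_barcode is not None and r.barcode != expect_barcode:
            counts["barcode_fail"] += 1
            continue
        if r.mismatches > max_mismatch_frac * r.length:
            counts["mismatch_fail"] += 1
            continue
        if _cluster_discard(r.n_unconverted(), r.n_converted(), cluster_rule):
            counts["cluster_fail"] += 1
            continue
        kept.append(r)
    counts["retained"] = len(kept)
    return kept, counts


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Per-library conversion-failure rate pooled over all C sites."""

    p0: float
    n_sites_used: int
    total_unconverted: int
    total_coverage: int
    per_context: dict[str, float] | None = None

    @property
    def se(self) -> float:
        if self.total_coverage == 0:
            return float("nan")
        return math.sqrt(self.p0 * (1 - self.p0) / self.total_coverage)


def estimate_background(
    site_counts: pd.DataFrame,
    min_cov: int = 1,
    by_context: bool = False,
) -> BackgroundModel:
    """Pooled-count background estimate over all C sites in the library.

    Single pass, modified sites included: p0 = sum(unconverted) / sum(coverage)
    over sites with coverage >= min_cov.
    """
    df = site_counts[site_counts["coverage"] >= min_cov]
    if df.empty or df["coverage"].sum() == 0:
        raise ValueError("no sites with nonzero coverage for background estimation")
    total_u = int(df["n_unconverted"].sum())
    total_cov = int(df["coverage"].sum())
    per_context = None
    if by_context:
        g = df.groupby("context")
        per_context = (g["n_unconverted"].sum() / g["coverage"].sum()).to_dict()
    return BackgroundModel(
        p0=total_u / total_cov,
        n_sites_used=len(df),
        total_unconverted=total_u,
        total_coverage=total_cov,
        per_context=per_context,
    )


# ---------------------------------------------------------------------------
# binomial tail
# ---------------------------------------------------------------------------


def _log_tail(n: int, p0: float) -> np.ndarray:
    """log Pr(X >= k) for k = 0..n, computed by stable reverse accumulation."""
    i = np.arange(n + 1, dtype=float)
    log_terms = (
        gammaln(n + 1.0)
        - gammaln(i + 1.0)
        - gammaln(n - i + 1.0)
        + i * math.log(p0)
        + (n - i) * math.log1p(-p0)
    )
    return np.logaddexp.accumulate(log_terms[::-1])[::-1]


def binomial_pvalue(k: int, n: int, p0: float, log: bool = False) -> float:
    """Upper-tail binomial probability Pr(X >= k), X ~ Binomial(n, p0).

    Computed in log space (log-gamma terms, stable log-sum accumulation);
    inclusive tail, so k = 0 gives exactly 1.  ``log=True`` returns the
    natural log of the tail, useful far below float underflow.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 0 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k == 0 or p0 == 1.0:
        return 0.0 if log else 1.0
    if p0 == 0.0:
        return -math.inf if log else 0.0
    log_p = min(0.0, float(_log_tail(n, p0)[k]))
    return log_p if log else math.exp(log_p)


def binomial_pvalues(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized upper-tail p-values, grouped by coverage for efficiency."""
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    if np.any((k < 0) | (k > n)):
        raise ValueError("require 0 <= k <= n elementwise")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    out = np.ones(len(k), dtype=float)
    if p0 == 0.0:
        out[k > 0] = 0.0
        return out
    if p0 == 1.0:
        return out
    for nv in np.unique(n):
        mask = n == nv
        tail = np.exp(_log_tail(int(nv), p0))
        out[mask] = np.minimum(1.0, tail[k[mask]])
    return out


# ---------------------------------------------------------------------------
# site calling (model / results)
# ---------------------------------------------------------------------------


class MethylationSiteModel:
    """Binomial background model for methylation site detection.

    Parameters
    ----------
    site_counts : DataFrame
        Per-site counts with columns ref, pos, strand, context,
        n_unconverted, n_converted, coverage, ratio.
    background : BackgroundModel, optional
        Pre-estimated background; estimated from ``site_counts`` at fit time
        when omitted.
    """

    def __init__(
        self,
        site_counts: pd.DataFrame,
        background: BackgroundModel | None = None,
    ):
        required = {"ref", "pos", "strand", "n_unconverted", "n_converted", "coverage", "ratio"}
        missing = required - set(site_counts.columns)
        if missing:
            raise ValueError(f"site_counts missing columns: {sorted(missing)}")
        bad = site_counts["n_unconverted"] + site_counts["n_converted"] != site_counts["coverage"]
        if bad.any():
            raise ValueError("coverage must equal n_unconverted + n_converted")
        self.site_counts = site_counts.reset_index(drop=True)
        self.background = background

    @classmethod
    def from_reads(cls, reads, references, rna_mode=False):
        from ubscall.align import pileup

        return cls(pileup(reads, references, rna_mode=rna_mode))

    def fit(
        self,
        alpha: float | None = 1e-6,
        min_ratio: float = 0.05,
        min_cov: int = 10,
        strict_ratio: bool = False,
        preset: str | None = None,
        correction: str | None = None,
        iterative: bool = False,
    ) -> "SiteCallingResults":
        """Estimate the background (if needed) and test every site.

        ``preset`` overrides the thresholds ('rna', 'dna-ed2a', 'dna-fig2c');
        ``alpha=None`` disables the binomial test (threshold-only calling).
        ``iterative`` re-estimates p0 once excluding called sites (off by
        default: the background pools all C sites in a single pass).
        ``correction='bh'`` applies Benjamini-Hochberg to the p-values and
        tests the adjusted values against alpha.
        """
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}")
            cfg = PRESETS[preset]
            alpha, min_ratio = cfg["alpha"], cfg["min_ratio"]
            min_cov, strict_ratio = cfg["min_cov"], cfg["strict_ratio"]

        background = self.background or estimate_background(self.site_counts)
        sites = self._test(background, alpha, min_ratio, min_cov, strict_ratio, correction)
        if iterative and alpha is not None:
            rest = self.site_counts[~sites["called"].to_numpy()]
            background = estimate_background(rest)
            sites = self._test(background, alpha, min_ratio, min_cov, strict_ratio, correction)
        params = dict(
            alpha=alpha, min_ratio=min_ratio, min_cov=min_cov,
            strict_ratio=strict_ratio, correction=correction,
        )
        return SiteCallingResults(self, sites, background, params)

    def _test(self, background, alpha, min_ratio, min_cov, strict_ratio, correction):
        sites = self.site_counts.copy()
        k = sites["n_unconverted"].to_numpy()
        n = sites["coverage"].to_numpy()
        if alpha is not None:
            pvals = binomial_pvalues(k, n, background.p0)
            sites["p_value"] = pvals
            if correction == "bh":
                from statsmodels.stats.multitest import multipletests

                pvals = multipletests(pvals, method="fdr_bh")[1]
                sites["p_adjusted"] = pvals
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}")
            sites["passes_p"] = pvals < alpha
        else:
            sites["p_value"] = np.nan
            sites["passes_p"] = True
        ratio = sites["ratio"].to_numpy()
        sites["passes_ratio"] = (ratio > min_ratio) if strict_ratio else (ratio >= min_ratio)
        sites["passes_cov"] = n >= min_cov
        sites["called"] = sites["passes_p"] & sites["passes_ratio"] & sites["passes_cov"]
        return sites


class SiteCallingResults:
    """Results of a :class:`MethylationSiteModel` fit."""

    def __init__(self, model, sites, background, params):
        self.model = model
        self.sites = sites
        self.background = background
        self.params = params

    @property
    def called(self) -> pd.DataFrame:
        return self.sites[self.sites["called"]].reset_index(drop=True)

    def annotate_motifs(self, references: dict[str, str]) -> pd.DataFrame:
        """Add motif_class / flank / flank_truncated columns (RNA transcripts)."""
        cls, flanks, trunc = [], [], []
        for ref, pos in zip(self.sites["ref"], self.sites["pos"]):
            m, window, truncated = classify_motif(references[ref], int(pos))
            cls.append(m)
            flanks.append(window)
            trunc.append(truncated)
        self.sites["motif_class"] = cls
        self.sites["flank"] = flanks
        self.sites["flank_truncated"] = trunc
        return self.sites

    def summary(self) -> str:
        b = self.background
        n_called = int(self.sites["called"].sum())
        lines = [
            "Methylation site calling (binomial background model)",
            "=" * 54,
            f"sites tested            {len(self.sites):>12d}",
            f"background p0           {b.p0:>12.6f}  (se {b.se:.2e})",
            f"  pooled counts         {b.total_unconverted}/{b.total_coverage}"
            f" over {b.n_sites_used} sites",
            f"alpha                   {self.params['alpha']!r:>12}",
            f"min ratio               {self.params['min_ratio']:>12.3f}"
            + ("  (strict >)" if self.params["strict_ratio"] else "  (>=)"),
            f"min coverage            {self.params['min_cov']:>12d}",
            f"sites called            {n_called:>12d}",
        ]
        called = self.called
        if n_called:
            for thr in (0.05, 0.20, 0.33):
                lines.append(
                    f"  called with ratio >= {thr:.2f}  "
                    f"{int((called['ratio'] >= thr).sum()):>8d}"
                )
        return "\n".join(lines)


def call_sites(
    site_counts: pd.DataFrame,
    background: BackgroundModel | None = None,
    alpha: float | None = 1e-6,
    min_ratio: float = 0.05,
    min_cov: int = 10,
    strict_ratio: bool = False,
    preset: str | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit the site model and return the annotated table."""
    res = MethylationSiteModel(site_counts, background).fit(
        alpha=alpha,
        min_ratio=min_ratio,
        min_cov=min_cov,
        strict_ratio=strict_ratio,
        preset=preset,
        correction=correction,
    )
    return res.sites


# ---------------------------------------------------------------------------
# motif classification
# ---------------------------------------------------------------------------


def classify_motif(
    reference: str, pos: int, flank: int = 10
) -> tuple[str, str, bool]:
    """CUCCA / non-CUCCA classification of a called C on its transcript strand.

    A site is CUCCA when the methylated C begins the 5-mer C-U-C-C-A
    (register 1, the NSUN6 target register).  Returns
    (motif_class, +/-flank window, truncated_flag); the window is truncated
    and flagged at transcript ends.  U and T are equivalent.
    """
    seq = reference.upper().replace("U", "T")
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside transcript")
    if seq[pos] != "C":
        raise ValueError(f"position {pos} is not a C")
    motif = "CUCCA" if seq[pos : pos + 5] == "CTCCA" else "non-CUCCA"
    lo, hi = pos - flank, pos + flank + 1
    truncated = lo < 0 or hi > len(seq)
    window = seq[max(lo, 0) : min(hi, len(seq))]
    return motif, window, truncated
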