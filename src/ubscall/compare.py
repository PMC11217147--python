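"""Downstream comparative statistics for bisulfite methylomes.

Covers knockdown-response classification of called sites, cfDNA
differentially-methylated-region (DMR) detection in tiled 1 kb windows,
the closed-form degradation-bias curve, coverage-evenness summaries,
spike-in false-positive rates, and stoichiometry/region distribution
summaries of called sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialMethylationModel",
    "DMRResults",
    "knockdown_response",
    "dmr_detect",
    "degradation_bias_curve",
    "coverage_evenness",
    "spike_in_fp_rate",
    "background_fold_change",
    "distribution_summary",
]


# ---------------------------------------------------------------------------
# knockdown response
# ---------------------------------------------------------------------------


def knockdown_response(
    sites_ctrl: pd.DataFrame,
    sites_kd: pd.DataFrame,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Classify per-site methylation response to a writer knockdown.

    Sites are matched on (ref, pos, strand).  A site is 'decreased' when the
    knockdown fraction drops to at most one third of the control fraction
    (a more-than-two-thirds decrease), 'increased' at a threefold or greater
    rise, otherwise 'unchanged'.  Sites covered in the control but not called
    in the knockdown keep their observed knockdown ratio (not forced to 0).
    The classification is scale-consistent: both thresholds are ratios of
    the two fractions.
    """
    key = ["ref", "pos", "strand"]
    a = sites_ctrl[key + ["ratio", "coverage"]].rename(
        columns={"ratio": "fraction_ctrl", "coverage": "cov_ctrl"}
    )
    b = sites_kd[key + ["ratio", "coverage"]].rename(
        columns={"ratio": "fraction_kd", "coverage": "cov_kd"}
    )
    merged = a.merge(b, on=key, how="inner")
    merged = merged[merged["cov_ctrl"] >= min_cov].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no overlapping sites between the two libraries")
    ctrl = merged["fraction_ctrl"].to_numpy()
    kd = merged["fraction_kd"].to_numpy()
    # small relative tolerance so exact-boundary fractions classify stably
    decreased = kd <= (ctrl / 3) * (1 + 1e-9)
    increased = kd * (1 + 1e-9) >= 3 * ctrl
    both_zero = (ctrl == 0) & (kd == 0)
    cls = np.where(
        both_zero, "unchanged",
        np.where(decreased, "decreased", np.where(increased, "increased", "unchanged")),
    )
    merged["response"] = cls
    return merged


# ---------------------------------------------------------------------------
# DMR detection (model / results)
# ---------------------------------------------------------------------------


class DifferentialMethylationModel:
    """Two-group DMR detection over non-overlapping 1 kb windows.

    Per sample and window, methylation is the pooled unconverted/coverage
    over the window's CpG sites; windows with more than ``min_cpg`` CpG
    motifs are compared between groups with a Welch t-test.  Windows are
    tiled from position 0.

    Parameters
    ----------
    case, control : mappings of sample name -> site-count DataFrame
        (or plain sequences of DataFrames); at least two samples per group.
    window : window width in nt (default 1000).
    min_cpg : minimum CpG count, exclusive (default 20: windows need > 20).
    """

    def __init__(
        self,
        case: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
        control: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
        window: int = 1000,
        min_cpg: int = 20,
    ):
        self.case = self._as_dict(case, "case")
        self.control = self._as_dict(control, "ctrl")
        if len(self.case) < 2 or len(self.control) < 2:
            raise ValueError("need at least 2 samples per group")
        if window < 1:
            raise ValueError("window must be positive")
        self.window = window
        self.min_cpg = min_cpg

    @staticmethod
    def _as_dict(group, prefix):
        if isinstance(group, Mapping):
            return dict(group)
        return {f"{prefix}{i + 1}": df for i, df in enumerate(group)}

    def _window_matrix(self):
        """Per-(ref, window) pooled methylation per sample + CpG counts."""
        frames = []
        for name, df in {**self.control, **self.case}.items():
            cpg = df[df["context"] == "CpG"].copy()
            cpg["wstart"] = (cpg["pos"] // self.window) * self.window
            g = cpg.groupby(["ref", "wstart"])
            agg = pd.DataFrame(
                {
                    "meth": g["n_unconverted"].sum() / g["coverage"].sum(),
                    "n_cpg": g.size(),
                }
            )
            agg["sample"] = name
            frames.append(agg.reset_index())
        longf = pd.concat(frames, ignore_index=True)
        meth = longf.pivot_table(
            index=["ref", "wstart"], columns="sample", values="meth"
        )
        n_cpg = (
            longf.pivot_table(index=["ref", "wstart"], columns="sample", values="n_cpg")
            .min(axis=1)
            .astype(int)
        )
        return meth, n_cpg

    def fit(
        self,
        min_diff: float = 0.20,
        alpha: float = 0.001,
        correction: str | None = None,
    ) -> "DMRResults":
        """Test every eligible window; report DMRs passing both thresholds.

        A window is a DMR when |mean_case - mean_control| > ``min_diff`` and
        the Welch t-test p-value is below ``alpha`` (raw by default;
        ``correction='bh'`` tests Benjamini-Hochberg-adjusted p-values).
        """
        meth, n_cpg = self._window_matrix()
        case_cols = [c for c in meth.columns if c in self.case]
        ctrl_cols = [c for c in meth.columns if c in self.control]
        eligible = (n_cpg > self.min_cpg) & meth.notna().all(axis=1)
        meth = meth[eligible]
        n_cpg = n_cpg[eligible]

        rows = []
        for (ref, wstart), row in meth.iterrows():
            x = row[case_cols].to_numpy(dtype=float)
            y = row[ctrl_cols].to_numpy(dtype=float)
            t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append(
                (
                    ref, int(wstart), int(wstart) + self.window,
                    int(n_cpg.loc[(ref, wstart)]),
                    float(x.mean()), float(y.mean()),
                    float(x.mean() - y.mean()), float(p),
                )
            )
        windows = pd.DataFrame(
            rows,
            columns=[
                "ref", "start", "end", "n_cpg",
                "mean_case", "mean_control", "diff", "p_value",
            ],
        )
        pvals = windows["p_value"].to_numpy()
        if correction == "bh" and len(pvals):
            from statsmodels.stats.multitest import multipletests

            pvals = multipletests(pvals, method="fdr_bh")[1]
            windows["p_adjusted"] = pvals
        elif correction not in (None, "bh"):
            raise ValueError(f"unknown correction {correction!r}")
        windows["is_dmr"] = (np.abs(windows["diff"]) > min_diff) & (pvals < alpha)

        # z-scored per-sample window methylation matrix for clustering output
        mat = meth.to_numpy(dtype=float)
        sd = mat.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        zmat = pd.DataFrame(
            (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None],
            index=meth.index,
            columns=meth.columns,
        )
        params = dict(min_diff=min_diff, alpha=alpha, correction=correction)
        return DMRResults(self, windows, zmat, params)


class DMRResults:
    """Results of a :class:`DifferentialMethylationModel` fit."""

    def __init__(self, model, windows, zscore_matrix, params):
        self.model = model
        self.windows = windows
        self.zscore_matrix = zscore_matrix
        self.params = params

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.windows[self.windows["is_dmr"]].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Differential methylation (tiled windows, Welch t-test)",
            "=" * 54,
            f"window width            {self.model.window:>8d} nt",
            f"CpG minimum (exclusive) {self.model.min_cpg:>8d}",
            f"windows tested          {len(self.windows):>8d}",
            f"|diff| threshold        {self.params['min_diff']:>8.2f}",
            f"alpha                   {self.params['alpha']:>8.4g}",
            f"DMRs reported           {len(self.dmrs):>8d}",
        ]
        for _, r in self.dmrs.iterrows():
            lines.append(
                f"  {r['ref']}:{r['start']}-{r['end']}  n_cpg={r['n_cpg']}"
                f"  diff={r['diff']:+.3f}  p={r['p_value']:.2e}"
            )
        return "\n".join(lines)


def dmr_detect(
    case: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    control: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    window: int = 1000,
    min_cpg: int = 20,
    min_diff: float = 0.20,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Functional wrapper around :class:`DifferentialMethylationModel`."""
    res = DifferentialMethylationModel(case, control, window, min_cpg).fit(
        min_diff=min_diff, alpha=alpha
    )
    return res.dmrs


# ---------------------------------------------------------------------------
# degradation bias
# ---------------------------------------------------------------------------


def degradation_bias_curve(x, survival):
    """Expected observed methylation fraction under C-biased degradation.

    At a site with true stoichiometry x, unmethylated molecules carry one
    more converted C than methylated ones and survive bisulfite treatment
    with mean relative survival ``survival`` (S in (0, 1]); among surviving
    fragments the observed fraction is x / (x + (1 - x) * S).  The bias is
    zero at x = 0 and x = 1 and positive in between whenever S < 1 —
    partially methylated sites are over-estimated.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(survival, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must be in [0, 1]")
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("survival must be in (0, 1]")
    out = x / (x + (1 - x) * s)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# coverage evenness
# ---------------------------------------------------------------------------


def coverage_evenness(window_depths, z_outlier: float = 1.5) -> dict:
    """Evenness summary of per-window mean sequencing depths.

    Depths are scaled to z-scores over windows; reported are the IQR of the
    z-scores, the count of outlier windows at |z| > ``z_outlier``, and the
    raw-scale IQR with 1.5x-IQR whisker bounds.  Constant depth gives IQR 0
    and no outliers.
    """
    d = np.asarray(window_depths, dtype=float)
    if d.size < 2 or np.count_nonzero(d) < 2:
        raise ValueError("need at least two windows with nonzero depth")
    sd = d.std(ddof=1)
    z = np.zeros_like(d) if sd == 0 else (d - d.mean()) / sd
    q1, q3 = np.percentile(d, [25, 75])
    iqr_raw = q3 - q1
    zq1, zq3 = np.percentile(z, [25, 75])
    return {
        "z": z,
        "iqr_z": float(zq3 - zq1),
        "n_outliers": int(np.sum(np.abs(z) > z_outlier)),
        "iqr_raw": float(iqr_raw),
        "whisker_low": float(q1 - 1.5 * iqr_raw),
        "whisker_high": float(q3 + 1.5 * iqr_raw),
    }


# ---------------------------------------------------------------------------
# spike-in false positives
# ---------------------------------------------------------------------------


def spike_in_fp_rate(
    site_counts: pd.DataFrame,
    ratio_cutoff: float = 0.05,
    min_cov: int = 1,
) -> dict:
    """False-positive rate on a truth-unmodified spike-in sequence.

    FP rate = fraction of eligible sites (coverage >= min_cov) whose
    unconverted ratio reaches the cutoff; the pooled unconverted rate is the
    library's background estimate on the spike-in.
    """
    df = site_counts[site_counts["coverage"] >= min_cov]
    if df.empty:
        raise ValueError("no eligible spike-in sites")
    fp = float((df["ratio"] >= ratio_cutoff).mean())
    pooled = float(df["n_unconverted"].sum() / df["coverage"].sum())
    return {"fp_rate": fp, "n_eligible": len(df), "pooled_rate": pooled}


def background_fold_change(spike_a: pd.DataFrame, spike_b: pd.DataFrame) -> float:
    """Fold-ratio of pooled spike-in unconverted rates between two libraries."""
    ra = spike_in_fp_rate(spike_a, ratio_cutoff=0.0)["pooled_rate"]
    rb = spike_in_fp_rate(spike_b, ratio_cutoff=0.0)["pooled_rate"]
    if rb == 0:
        raise ValueError("second library has zero pooled unconverted rate")
    return ra / rb


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------


def distribution_summary(
    called_sites: pd.DataFrame,
    thresholds: Sequence[float] = (0.05, 0.20, 0.33),
    annotation: pd.DataFrame | None = None,
    n_bins: int = 100,
) -> dict:
    """Stoichiometry bins, sites-per-gene histogram, region assignment,
    and a gene-body metaprofile of called sites.

    ``annotation``: BED-like DataFrame with columns ref, start, end, gene,
    region (region in {"5UTR", "CDS", "3UTR"}); sites outside it are
    bucketed 'unannotated'.  The metaprofile concatenates ``n_bins`` scaled
    position bins per region (5UTR | CDS | 3UTR), normalized per gene before
    averaging.
    """
    out: dict = {}
    out["threshold_counts"] = {
        float(t): int((called_sites["ratio"] >= t).sum()) for t in thresholds
    }
    out["n_sites"] = len(called_sites)
    if annotation is None:
        return out

    region_order = ["5UTR", "CDS", "3UTR"]
    region_counts = {r: 0 for r in region_order}
    region_counts["unannotated"] = 0
    per_gene: dict[str, int] = {}
    # per gene+region scaled-position histograms
    profiles: dict[str, np.ndarray] = {}

    ann = annotation.reset_index(drop=True)
    for _, site in called_sites.iterrows():
        hit = ann[
            (ann["ref"] == site["ref"])
            & (ann["start"] <= site["pos"])
            & (site["pos"] < ann["end"])
        ]
        if hit.empty:
            region_counts["unannotated"] += 1
            continue
        row = hit.iloc[0]
        region_counts[row["region"]] += 1
        per_gene[row["gene"]] = per_gene.get(row["gene"], 0) + 1
        frac = (site["pos"] - row["start"]) / max(row["end"] - row["start"], 1)
        bin_idx = region_order.index(row["region"]) * n_bins + min(
            int(frac * n_bins), n_bins - 1
        )
        prof = profiles.setdefault(row["gene"], np.zeros(3 * n_bins))
        prof[bin_idx] += 1

    out["region_counts"] = region_counts
    out["sites_per_gene"] = per_gene
    hist: dict[int, int] = {}
    for count in per_gene.values():
        hist[count] = hist.get(count, 0) + 1
    out["sites_per_gene_hist"] = hist
    if profiles:
        normed = [p / p.sum() for p in profiles.values() if p.sum() > 0]
        out["metaprofile"] = np.mean(normed, axis=0)
    else:
        out["metaprofile"] = np.zeros(3 * n_bins)
    return out
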