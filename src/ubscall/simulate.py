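"""Ground-truthed synthetic bisulfite libraries (DNA and RNA modes).

The generator emulates the statistical structure of directional bisulfite
libraries: per-site modification stoichiometry ``x`` (each molecule is
independently methylated at a site with probability x), a per-library
incomplete-conversion background, clustered conversion failures inside
"structured" regions, and bisulfite-induced degradation in which a fragment's
survival decreases with the number of converted C it carries
(survival = s_c ** n_converted).  Because unmethylated molecules convert more
C, they are depleted, which inflates the observed methylation fraction at
partially methylated sites — the expected observed fraction is
``x / (x + (1-x) * S)`` with ``S`` the mean relative survival of unmethylated
molecules (see :func:`ubscall.compare.degradation_bias_curve`).

RNA-mode reads carry the library's inline barcode (ATCACG) and two 5-nt UMIs
flanking the insert, mirroring the small-RNA adapter design; an unmodified
spike-in sequence (lambda-DNA stand-in) is included for background estimation.
All randomness flows from explicit seeds; runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FastqRead",
    "SimParams",
    "REGIME_PRESETS",
    "INLINE_BARCODE",
    "revcomp",
    "simulate_reference",
    "simulate_bisulfite_reads",
    "simulate_cfdna_cohort",
]

INLINE_BARCODE = "ATCACG"
_QUAL_CHAR = chr(37 + 33)  # constant Phred 37

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRUTH_COLUMNS = ["ref", "pos", "strand", "mod_type", "x"]
SITECOUNT_COLUMNS = [
    "ref",
    "pos",
    "strand",
    "context",
    "n_unconverted",
    "n_converted",
    "coverage",
    "ratio",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqRead(NamedTuple):
    id: str
    sequence: str
    quality: str


@dataclass
class SimParams:
    """Parameters of one simulated bisulfite library.

    depth is the target mean fragment coverage per position before
    degradation losses; background_fail is the per-library probability that
    an unmodified C fails to convert; survival_coeff (s_c) is the per
    converted-C fragment survival multiplier; fourmC_convert is the
    probability that a 4mC deaminates (1.0 under ultrafast conditions,
    ~0.5 under conventional bisulfite, where 4mC reads ~1:1 C/T).
    """

    seed: int = 0
    depth: float = 50.0
    read_length: int = 100
    frag_mean: float = 150.0
    frag_sd: float = 30.0
    frag_min: int = 50
    background_fail: float = 0.006
    structured_regions: list[tuple[str, int, int]] = field(default_factory=list)
    structured_fail: float = 0.5
    survival_coeff: float = 1.0
    error_rate: float = 0.0
    fourmC_convert: float = 1.0
    directional: bool = True
    rna_mode: bool = False
    duplication_rate: float = 0.0
    barcode: str = INLINE_BARCODE

    def validate(self) -> None:
        for name in (
            "background_fail",
            "structured_fail",
            "error_rate",
            "fourmC_convert",
            "duplication_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.survival_coeff <= 1.0:
            raise ValueError("survival_coeff must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.frag_min < 1 or self.frag_mean < self.frag_min:
            raise ValueError("degenerate fragment length parameters")


#: Direction-encoding regime presets (magnitudes are not calibrated to any
#: particular kit; conventional bisulfite degrades more, converts 4mC
#: partially, and shows a higher, more clustered background).
REGIME_PRESETS = {
    "ubs": dict(
        background_fail=0.006, survival_coeff=0.98, fourmC_convert=1.0,
        structured_fail=0.05,
    ),
    "conventional": dict(
        background_fail=0.02, survival_coeff=0.85, fourmC_convert=0.5,
        structured_fail=0.5,
    ),
}


# ---------------------------------------------------------------------------
# reference + truth generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _bimodal_x(rng: np.random.Generator, size: int, modes=(0.05, 0.95), weight_high=0.5):
    """Mixture of two Beta laws with the requested modes (concentration 22)."""
    lo, hi = modes
    a_lo, b_lo = 1 + lo * 20, 1 + (1 - lo) * 20
    a_hi, b_hi = 1 + hi * 20, 1 + (1 - hi) * 20
    pick_hi = rng.random(size) < weight_high
    x = np.where(
        pick_hi,
        rng.beta(a_hi, b_hi, size=size),
        rng.beta(a_lo, b_lo, size=size),
    )
    return np.clip(x, 1e-4, 1.0)


def simulate_reference(
    seed: int,
    n_sequences: int = 2,
    lengths: int | Sequence[int] = 2000,
    gc_content: float = 0.45,
    spike_in: bool = True,
    spike_in_length: int = 1500,
    rna_mode: bool = False,
    cpg_modes: tuple[float, float] = (0.05, 0.95),
    cpg_weight_high: float = 0.5,
    noncpg_mod_rate: float = 0.01,
    fourmC_rate: float = 0.0,
    m5c_sites_per_seq: int = 10,
    m5c_stoichiometry: tuple[float, float] = (0.05, 0.95),
    cucca_fraction: float = 0.3,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate random reference sequences plus a per-C modification truth table.

    DNA mode: CpG cytosines (both strands of each CpG, symmetrically) draw
    stoichiometry from a bimodal distribution; a fraction ``noncpg_mod_rate``
    of non-CpG cytosines carry low-stoichiometry 5mC (or 4mC if
    ``fourmC_rate`` > 0); everything else is unmodified.  One designated
    spike-in sequence (named ``spike``) is fully unmodified.

    RNA mode: plus-strand transcripts; ``m5c_sites_per_seq`` random C
    positions per transcript become m5C with stoichiometry drawn uniformly
    between the given bounds; a fraction ``cucca_fraction`` of sites have the
    CUCCA motif planted at the site (methylated C in register 1).

    Deterministic for a fixed seed.  Returns (references, truth) where truth
    has one row per C position per strand: (ref, pos, strand, mod_type, x).
    """
    if gc_content <= 0.0 or gc_content >= 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    if isinstance(lengths, int):
        lengths = [lengths] * n_sequences
    lengths = list(lengths)
    if len(lengths) != n_sequences:
        raise ValueError("lengths must match n_sequences")
    if any(l < 20 for l in lengths):
        raise ValueError("reference sequences must be at least 20 nt")

    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    rows: list[tuple] = []

    for k in range(n_sequences):
        name = ("tx%03d" if rna_mode else "chr%d") % (k + 1)
        seq = _random_sequence(rng, lengths[k], gc_content)
        if rna_mode:
            seq, site_rows = _place_m5c_sites(
                rng, name, seq, m5c_sites_per_seq, m5c_stoichiometry, cucca_fraction
            )
            rows.extend(site_rows)
        else:
            rows.extend(
                _dna_truth_rows(
                    rng, name, seq, cpg_modes, cpg_weight_high, noncpg_mod_rate,
                    fourmC_rate,
                )
            )
        refs[name] = seq

    if spike_in:
        seq = _random_sequence(rng, spike_in_length, gc_content)
        refs["spike"] = seq
        strands = ("+",) if rna_mode else ("+", "-")
        for strand in strands:
            base = "C" if strand == "+" else "G"
            for i, b in enumerate(seq):
                if b == base:
                    rows.append(("spike", i, strand, "none", 0.0))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["ref", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )
    return refs, truth


def _dna_truth_rows(rng, name, seq, cpg_modes, cpg_weight_high, noncpg_mod_rate,
                    fourmC_rate):
    rows = []
    n = len(seq)
    # CpG dinucleotides: symmetric stoichiometry on both strands
    cpg_starts = [i for i in range(n - 1) if seq[i] == "C" and seq[i + 1] == "G"]
    x_cpg = _bimodal_x(rng, len(cpg_starts), cpg_modes, cpg_weight_high)
    cpg_fwd = set(cpg_starts)
    cpg_rev = {i + 1 for i in cpg_starts}
    for i, x in zip(cpg_starts, x_cpg):
        rows.append((name, i, "+", "5mC", float(x)))
        rows.append((name, i + 1, "-", "5mC", float(x)))
    # non-CpG cytosines on each strand
    for strand, base, taken in (("+", "C", cpg_fwd), ("-", "G", cpg_rev)):
        positions = [i for i, b in enumerate(seq) if b == base and i not in taken]
        for i in positions:
            u = rng.random()
            if u < noncpg_mod_rate * fourmC_rate:
                rows.append((name, i, strand, "4mC", float(rng.uniform(0.5, 1.0))))
            elif u < noncpg_mod_rate:
                x = float(np.clip(rng.beta(2, 20), 1e-4, 1.0))
                rows.append((name, i, strand, "5mC", x))
            else:
                rows.append((name, i, strand, "none", 0.0))
    return rows


def _place_m5c_sites(rng, name, seq, n_sites, stoich_bounds, cucca_fraction):
    seq_list = list(seq)
    c_positions = [i for i, b in enumerate(seq_list) if b == "C" and i + 5 <= len(seq_list)]
    n_sites = min(n_sites, len(c_positions))
    chosen = sorted(rng.choice(len(c_positions), size=n_sites, replace=False))
    sites = []
    used: set[int] = set()
    for idx in chosen:
        pos = c_positions[idx]
        if any(abs(pos - p) < 6 for p in used):
            continue
        if rng.random() < cucca_fraction:
            for off, b in enumerate("CTCCA"):  # CUCCA, U stored as T
                seq_list[pos + off] = b
        x = float(rng.uniform(*stoich_bounds))
        sites.append((pos, x))
        used.add(pos)
    seq = "".join(seq_list)
    site_pos = {p for p, _ in sites}
    rows = [(name, p, "+", "m5C", x) for p, x in sites]
    rows.extend(
        (name, i, "+", "none", 0.0)
        for i, b in enumerate(seq)
        if b == "C" and i not in site_pos
    )
    return seq, rows


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _truth_lookup(truth: pd.DataFrame):
    table: dict[tuple[str, str], dict[int, tuple[str, float]]] = {}
    for ref, pos, strand, mod, x in truth[TRUTH_COLUMNS].itertuples(index=False):
        table.setdefault((ref, strand), {})[int(pos)] = (mod, float(x))
    return table


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alt = "ACGT".replace(chars[i], "") if chars[i] in "ACGT" else "ACGT"
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def simulate_bisulfite_reads(
    references: dict[str, str],
    truth: pd.DataFrame,
    params: SimParams,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate a directional bisulfite library from a reference + truth table.

    Per fragment: each 5mC/m5C site is methylated on this molecule with
    probability x (methylated C resists conversion); 4mC converts with
    probability ``fourmC_convert``; unmodified C converts with probability
    1 - background_fail, except that within a structured region all the
    fragment's unmodified C fail together with probability
    ``structured_fail``.  The fragment survives bisulfite degradation with
    probability survival_coeff ** n_converted.  Sequencing errors are applied
    last.  Returns (reads, truth_alignment) where truth_alignment records the
    origin of every emitted read.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lookup = _truth_lookup(truth)

    reads: list[FastqRead] = []
    aln_rows: list[tuple] = []
    frag_id = 0

    for ref_name, ref_seq in references.items():
        L = len(ref_seq)
        n_frags = int(round(params.depth * L / params.frag_mean))
        regions = [
            (s, e) for (r, s, e) in params.structured_regions if r == ref_name
        ]
        for _ in range(n_frags):
            flen = int(
                np.clip(
                    rng.normal(params.frag_mean, params.frag_sd),
                    params.frag_min,
                    L,
                )
            )
            start = int(rng.integers(0, L - flen + 1))
            end = start + flen
            strand = "+" if (params.rna_mode or rng.random() < 0.5) else "-"
            frag = ref_seq[start:end] if strand == "+" else revcomp(ref_seq[start:end])
            site_truth = lookup.get((ref_name, strand), {})

            # cluster-failure state per overlapping structured region
            cluster_fail = [
                (s, e, rng.random() < params.structured_fail)
                for (s, e) in regions
                if s < end and e > start
            ]

            frag_chars = list(frag)
            n_conv = n_unconv = 0
            for i, b in enumerate(frag_chars):
                if b != "C":
                    continue
                ref_pos = start + i if strand == "+" else end - 1 - i
                mod, x = site_truth.get(ref_pos, ("none", 0.0))
                methylated = mod in ("5mC", "m5C") and rng.random() < x
                is_4mc = mod == "4mC" and rng.random() < x
                if methylated:
                    converts = False
                elif is_4mc:
                    converts = rng.random() < params.fourmC_convert
                else:
                    clustered = any(
                        fail and s <= ref_pos < e for (s, e, fail) in cluster_fail
                    )
                    if clustered:
                        converts = False
                    else:
                        converts = rng.random() >= params.background_fail
                if converts:
                    frag_chars[i] = "T"
                    n_conv += 1
                else:
                    n_unconv += 1

            if rng.random() >= params.survival_coeff**n_conv:
                continue  # fragment degraded

            converted = "".join(frag_chars)
            if params.rna_mode:
                umi5 = "".join(rng.choice(list("ACGT"), size=5))
                umi3 = "".join(rng.choice(list("ACGT"), size=5))
                payload = umi5 + converted + umi3 + params.barcode
                read_start, read_end = start, end
            else:
                payload = converted[: params.read_length]
                # the read covers the fragment's 5' end on its own strand
                if strand == "+" or len(payload) == flen:
                    read_start, read_end = start, start + len(payload)
                else:
                    read_start, read_end = end - len(payload), end

            n_copies = 1 + (rng.random() < params.duplication_rate)
            for copy in range(n_copies):
                rid = f"{ref_name}:frag{frag_id}" + (":dup" if copy else "")
                seq = _apply_errors(rng, payload, params.error_rate)
                reads.append(FastqRead(rid, seq, _QUAL_CHAR * len(seq)))
                aln_rows.append(
                    (rid, ref_name, start, end, read_start, read_end, strand,
                     frag_id, n_conv, n_unconv)
                )
            frag_id += 1

    truth_alignment = pd.DataFrame(
        aln_rows,
        columns=[
            "read_id", "ref", "start", "end", "read_start", "read_end", "strand",
            "frag_id", "n_converted", "n_unconverted",
        ],
    )
    return reads, truth_alignment


# ---------------------------------------------------------------------------
# cfDNA cohort simulation (site-count level)
# ---------------------------------------------------------------------------


def simulate_cfdna_cohort(
    seed: int,
    n_case: int = 6,
    n_control: int = 6,
    planted_dmrs: Sequence[tuple[int, float]] = (),
    n_windows: int = 50,
    window: int = 1000,
    cpg_per_window: float = 30.0,
    min_cpg: int = 22,
    depth: float = 50.0,
    concentration: float = 100.0,
    ref_name: str = "cf1",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample CpG methylation count tables for a case/control cohort.

    Control samples share a base methylome (bimodal CpG methylation); case
    samples shift the methylation of CpGs inside each planted window by the
    given signed effect (clipped to [0, 1]).  Between-sample variation is
    beta-binomial: per sample and CpG the success probability is drawn from a
    Beta with the site's mean and the given ``concentration`` (larger =
    less overdispersed), and counts are binomial at Poisson coverage.

    ``planted_dmrs`` is a sequence of ``(window_start, effect)`` pairs; window
    starts must be multiples of ``window`` and windows must not overlap.

    Returns (samples, cpg_truth): samples maps sample name ('case1'...,
    'ctrl1'...) to a site-count table; cpg_truth records per-CpG base and
    case means.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    starts = []
    for s, effect in planted_dmrs:
        if s % window or not 0 <= s < n_windows * window:
            raise ValueError(f"planted window start {s} not a tile of {window}")
        starts.append(s)
    if len(set(starts)) != len(starts):
        raise ValueError("overlapping planted windows rejected")
    planted = dict(planted_dmrs)

    rng = np.random.default_rng(seed)

    # CpG positions and base methylome
    pos_list: list[int] = []
    for w in range(n_windows):
        n_cpg = min_cpg + rng.poisson(max(cpg_per_window - min_cpg, 0.0))
        offsets = np.sort(rng.choice(window // 2, size=n_cpg, replace=False)) * 2
        pos_list.extend(w * window + offsets)
    pos = np.asarray(pos_list)
    n_sites = len(pos)

    kind = rng.random(n_sites)
    base = np.where(
        kind < 0.75,
        rng.beta(20, 2, n_sites),
        np.where(kind < 0.90, rng.beta(2, 20, n_sites), rng.beta(5, 5, n_sites)),
    )
    base = np.clip(base, 1e-3, 1 - 1e-3)

    # planted windows redraw their baseline with headroom for the shift:
    # a region that gains (loses) 0.30 methylation must start low (high)
    for s, effect in planted.items():
        mask = (pos >= s) & (pos < s + window)
        b = rng.beta(4, 12, mask.sum())
        if effect < 0:
            b = 1 - b
        base[mask] = np.clip(b, 1e-3 + max(-effect, 0), 1 - 1e-3 - max(effect, 0))

    case_mean = base.copy()
    for s, effect in planted.items():
        mask = (pos >= s) & (pos < s + window)
        case_mean[mask] = np.clip(base[mask] + effect, 1e-3, 1 - 1e-3)

    def _sample_table(mean: np.ndarray) -> pd.DataFrame:
        cov = rng.poisson(depth, n_sites).astype(int)
        cov = np.maximum(cov, 1)
        p = rng.beta(mean * concentration, (1 - mean) * concentration)
        k = rng.binomial(cov, p)
        return pd.DataFrame(
            {
                "ref": ref_name,
                "pos": pos,
                "strand": "+",
                "context": "CpG",
                "n_unconverted": k,
                "n_converted": cov - k,
                "coverage": cov,
                "ratio": k / cov,
            }
        )

    samples: dict[str, pd.DataFrame] = {}
    for i in range(n_control):
        samples[f"ctrl{i + 1}"] = _sample_table(base)
    for i in range(n_case):
        samples[f"case{i + 1}"] = _sample_table(case_mean)

    cpg_truth = pd.DataFrame(
        {
            "ref": ref_name,
            "pos": pos,
            "window_start": (pos // window) * window,
            "base_mean": base,
            "case_mean": case_mean,
        }
    )
    return samples, cpg_truth
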