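"""File formats and configuration.

Sequence formats go through Bio.SeqIO; tabular formats are TSV with a
versioned header comment.  Emitted TSV positions are 1-based (common
methylation-table convention); BED output is 0-based half-open per the BED
standard.  Site tables are validated on read: coverage and ratio must be
consistent with the counts, and malformed lines are reported with their
line number.
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ubscall.simulate import FastqRead, SITECOUNT_COLUMNS, TRUTH_COLUMNS

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_site_table",
    "write_site_table",
    "read_truth_table",
    "write_truth_table",
    "write_called_bed",
    "PipelineConfig",
    "load_config",
]

_SITE_HEADER = "#ubscall site-table v1: ref pos1 strand context unconverted converted coverage ratio"
_TRUTH_HEADER = "#ubscall truth-table v1: ref pos1 strand mod_type x"


class FormatError(ValueError):
    """Malformed record in an input file (message carries the line number)."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(references: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in references.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# site / truth tables
# ---------------------------------------------------------------------------


def write_site_table(df: pd.DataFrame, path) -> None:
    out = df[SITECOUNT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1  # 1-based in emitted TSV
    with open(path, "w") as fh:
        fh.write(_SITE_HEADER + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITECOUNT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=3):
        cov = row.n_unconverted + row.n_converted
        if cov != row.coverage or cov <= 0:
            raise FormatError(
                f"{path}:{i}: coverage {row.coverage} != "
                f"unconverted+converted ({cov})"
            )
        if abs(row.ratio - row.n_unconverted / cov) > 1e-6:
            raise FormatError(
                f"{path}:{i}: ratio {row.ratio} != unconverted/coverage"
            )
    df["pos"] = df["pos"] - 1
    return df


def write_truth_table(df: pd.DataFrame, path) -> None:
    out = df[TRUTH_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["pos"] = df["pos"] - 1
    return df


def write_called_bed(called: pd.DataFrame, path) -> None:
    """Called sites as BED6: name = motif class (or context), score = 1000*ratio."""
    with open(path, "w") as fh:
        for _, r in called.iterrows():
            name = r.get("motif_class") or r.get("context", "site")
            fh.write(
                f"{r['ref']}\t{int(r['pos'])}\t{int(r['pos']) + 1}\t{name}\t"
                f"{round(1000 * r['ratio'])}\t{r['strand']}\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "run": {"seed", "mode", "stages", "outdir"},
    "simulate": {
        "n_sequences", "lengths", "gc_content", "spike_in_length",
        "depth", "read_length", "frag_mean", "frag_sd", "frag_min",
        "background_fail", "survival_coeff", "error_rate", "fourmC_convert",
        "duplication_rate", "m5c_sites_per_seq", "cucca_fraction",
        "noncpg_mod_rate", "regime",
    },
    "call": {"alpha", "min_ratio", "min_cov", "preset", "cluster_rule"},
    "compare": {"spike_ref", "ratio_cutoff"},
}

_STAGE_ORDER = ["simulate", "map", "count", "call", "compare"]
_STAGE_REQUIRES = {"map": "simulate", "count": "map", "call": "count", "compare": "call"}


class PipelineConfig:
    """Validated pipeline configuration (plain-text INI, mandatory seed)."""

    def __init__(self, sections: dict[str, dict[str, str]]):
        for section, keys in sections.items():
            if section not in _KNOWN_KEYS:
                raise ValueError(f"unknown config section [{section}]")
            unknown = set(keys) - _KNOWN_KEYS[section]
            if unknown:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(unknown)}"
                )
        run = sections.get("run", {})
        if "seed" not in run:
            raise ValueError("config must set an explicit seed in [run]")
        self.seed = int(run["seed"])
        self.mode = run.get("mode", "rna")
        if self.mode not in ("rna", "dna"):
            raise ValueError(f"mode must be 'rna' or 'dna', got {self.mode!r}")
        self.stages = [
            s.strip() for s in run.get("stages", ",".join(_STAGE_ORDER)).split(",")
        ]
        for s in self.stages:
            if s not in _STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
            needs = _STAGE_REQUIRES.get(s)
            if needs is not None and needs not in self.stages:
                raise ValueError(f"stage {s!r} requires stage {needs!r} in the config")
        self.outdir = run.get("outdir", "ubscall_out")
        self.simulate = dict(sections.get("simulate", {}))
        self.call = dict(sections.get("call", {}))
        self.compare = dict(sections.get("compare", {}))


def load_config(path_or_text) -> PipelineConfig:
    parser = configparser.ConfigParser()
    text = (
        path_or_text
        if "\n" in str(path_or_text)
        else Path(path_or_text).read_text()
    )
    parser.read_string(text)
    sections = {s: dict(parser.items(s)) for s in parser.sections()}
    return PipelineConfig(sections)
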