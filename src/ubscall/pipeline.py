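"""Pipeline driver: simulate → map → dedup → (filter) → count → call → compare.

All randomness flows from the configured seed; running the same config twice
yields byte-identical tables.  Each stage logs record counts in and out, and
read attrition is bookkept exactly: reads_in = reads_out + per-filter
discards at every filtering stage.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

from ubscall import align, calling, compare as cmp_mod, io as uio, simulate as sim

__all__ = ["run_pipeline"]


def _log(fh, stage: str, records_in: int, records_out: int, detail: str = ""):
    line = f"{stage}\t{records_in}\t{records_out}\t{detail}"
    print(f"[ubscall] {line}", file=sys.stderr)
    fh.append((stage, records_in, records_out, detail))


def run_pipeline(config: "uio.PipelineConfig | str", outdir=None) -> dict:
    """Execute the configured stages; returns a summary dict of outputs.

    ``config`` may be a :class:`ubscall.io.PipelineConfig`, a path to an INI
    file, or the INI text itself.  Outputs (FASTA/FASTQ/TSV/BED and a
    run-summary TSV) are written under the configured output directory.
    """
    if not isinstance(config, uio.PipelineConfig):
        config = uio.load_config(config)
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rna = config.mode == "rna"
    log: list[tuple] = []
    result: dict = {"outdir": str(out)}

    sp = config.simulate
    regime = sp.get("regime")
    params = sim.SimParams(
        seed=config.seed,
        depth=float(sp.get("depth", 50)),
        read_length=int(sp.get("read_length", 100)),
        frag_mean=float(sp.get("frag_mean", 80 if rna else 150)),
        frag_sd=float(sp.get("frag_sd", 15 if rna else 30)),
        frag_min=int(sp.get("frag_min", 40)),
        background_fail=float(sp.get("background_fail", 0.006)),
        survival_coeff=float(sp.get("survival_coeff", 1.0)),
        error_rate=float(sp.get("error_rate", 0.0)),
        fourmC_convert=float(sp.get("fourmc_convert", 1.0)),
        duplication_rate=float(sp.get("duplication_rate", 0.0)),
        rna_mode=rna,
    )
    if regime:
        if regime not in sim.REGIME_PRESETS:
            raise ValueError(f"unknown regime {regime!r}")
        for key, val in sim.REGIME_PRESETS[regime].items():
            setattr(params, key, val)

    refs = truth = reads = None
    if "simulate" in config.stages:
        refs, truth = sim.simulate_reference(
            seed=config.seed,
            n_sequences=int(sp.get("n_sequences", 2)),
            lengths=int(sp.get("lengths", 2000)),
            gc_content=float(sp.get("gc_content", 0.45)),
            spike_in_length=int(sp.get("spike_in_length", 1000)),
            rna_mode=rna,
            m5c_sites_per_seq=int(sp.get("m5c_sites_per_seq", 10)),
            cucca_fraction=float(sp.get("cucca_fraction", 0.3)),
            noncpg_mod_rate=float(sp.get("noncpg_mod_rate", 0.01)),
        )
        reads, truth_aln = sim.simulate_bisulfite_reads(refs, truth, params)
        uio.write_fasta(refs, out / "reference.fa")
        uio.write_fastq(reads, out / "reads.fastq")
        uio.write_truth_table(truth, out / "truth.tsv")
        truth_aln.to_csv(out / "truth_alignment.tsv", sep="\t", index=False)
        _log(log, "simulate", len(truth), len(reads), f"refs={len(refs)}")
        result["n_reads"] = len(reads)

    mapped = None
    if "map" in config.stages:
        index = align.ReferenceIndex(refs)
        mapped = align.map_reads(reads, index, rna_mode=rna)
        n_mapped = len(mapped)
        deduped = align.dedup(mapped, mode="rna" if rna else "dna")
        _log(log, "map", len(reads), n_mapped, f"unmapped={len(reads) - n_mapped}")
        _log(log, "dedup", n_mapped, len(deduped),
             f"duplicates={n_mapped - len(deduped)}")
        if rna:
            cp = config.call
            filtered, fc = calling.filter_reads(
                deduped,
                expect_barcode=sim.INLINE_BARCODE,
                cluster_rule=cp.get("cluster_rule", "third"),
            )
            assert fc["input"] == fc["retained"] + fc["barcode_fail"] + \
                fc["mismatch_fail"] + fc["cluster_fail"]
            _log(log, "filter", fc["input"], fc["retained"],
                 f"barcode={fc['barcode_fail']} mismatch={fc['mismatch_fail']}"
                 f" cluster={fc['cluster_fail']}")
            mapped = filtered
        else:
            mapped = deduped
        result["n_usable_reads"] = len(mapped)

    counts = None
    if "count" in config.stages:
        counts = align.pileup(mapped, refs, rna_mode=rna)
        uio.write_site_table(counts, out / "site_counts.tsv")
        _log(log, "count", len(mapped), len(counts), "")
        result["site_counts"] = counts

    if "call" in config.stages:
        cp = config.call
        model = calling.MethylationSiteModel(counts)
        preset = cp.get("preset")
        if preset:
            res = model.fit(preset=preset)
        else:
            res = model.fit(
                alpha=float(cp.get("alpha", 1e-6)),
                min_ratio=float(cp.get("min_ratio", 0.05)),
                min_cov=int(cp.get("min_cov", 20 if rna else 10)),
            )
        if rna:
            res.annotate_motifs(refs)
        res.sites.to_csv(out / "called_sites.tsv", sep="\t", index=False)
        uio.write_called_bed(res.called, out / "called_sites.bed")
        (out / "call_summary.txt").write_text(res.summary() + "\n")
        _log(log, "call", len(counts), int(res.sites["called"].sum()),
             f"p0={res.background.p0:.5f}")
        result["calling"] = res

    if "compare" in config.stages:
        spike_name = config.compare.get("spike_ref", "spike")
        spike = counts[counts["ref"] == spike_name]
        report = cmp_mod.spike_in_fp_rate(
            spike,
            ratio_cutoff=float(config.compare.get("ratio_cutoff", 0.05)),
            min_cov=5,
        )
        pd.DataFrame([report]).to_csv(out / "spike_report.tsv", sep="\t", index=False)
        _log(log, "compare", len(spike), report["n_eligible"],
             f"fp_rate={report['fp_rate']:.4f} pooled={report['pooled_rate']:.5f}")
        result["spike_report"] = report

    pd.DataFrame(log, columns=["stage", "in", "out", "detail"]).to_csv(
        out / "run_summary.tsv", sep="\t", index=False
    )
    result["log"] = log
    return result
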