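"""Desk-scale three-base read mapping, deduplication, and per-site pileup.

Bisulfite conversion destroys the C/T distinction on the read's strand of
origin, so reads are aligned in a collapsed three-base space: the read's
C→T collapse against the C→T-collapsed forward reference (plus-strand
origins), and the reverse complement's G→A collapse against the
G→A-collapsed reference (minus-strand origins).  In a directional library,
read 1 always derives from the converted strand, so exactly these two
spaces are searched; reverse-directional (single-cell) libraries swap them.

Alignment is ungapped, seeded on exact k-mers with full-length extension;
ties between distinct best-scoring loci are discarded as unmapped (strict
multi-mapper policy, preventing methylation averaging across paralogs).
After placement, the C conversion state of every covered reference C on the
read's bisulfite strand is recorded, and mismatches are counted excluding
reference-C → read-T conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ubscall.simulate import (
    FastqRead,
    INLINE_BARCODE,
    SITECOUNT_COLUMNS,
    revcomp,
)

__all__ = [
    "ReferenceIndex",
    "MappedRead",
    "parse_rna_read",
    "map_read",
    "map_reads",
    "dedup",
    "pileup",
    "classify_context",
]

CONVERTED = "converted"
UNCONVERTED = "unconverted"
OTHER = "other"

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


@dataclass
class MappedRead:
    """A read placed on the reference with per-C conversion states."""

    id: str
    ref: str
    start: int  # 0-based, forward-strand coordinates
    strand: str
    length: int
    mismatches: int  # excludes reference-C -> read-T conversions
    c_states: list[tuple[int, str]] = field(default_factory=list)
    umi5: str = ""
    umi3: str = ""
    barcode: str = ""
    sequence: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length

    def n_unconverted(self) -> int:
        return sum(1 for _, s in self.c_states if s == UNCONVERTED)

    def n_converted(self) -> int:
        return sum(1 for _, s in self.c_states if s == CONVERTED)


class ReferenceIndex:
    """Exact k-mer seed index over the two collapsed reference spaces."""

    def __init__(self, references: dict[str, str], seed_length: int = 20):
        if seed_length < 8:
            raise ValueError("seed_length must be at least 8")
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.seed_length = seed_length
        self.ct = {n: s.translate(_CT) for n, s in self.references.items()}
        self.ga = {n: s.translate(_GA) for n, s in self.references.items()}
        self._seeds: dict[str, dict[str, list[tuple[str, int]]]] = {
            "CT": {}, "GA": {},
        }
        for space, collapsed in (("CT", self.ct), ("GA", self.ga)):
            table = self._seeds[space]
            for name, seq in collapsed.items():
                for i in range(len(seq) - seed_length + 1):
                    table.setdefault(seq[i : i + seed_length], []).append((name, i))


def parse_rna_read(sequence: str, barcode_length: int = len(INLINE_BARCODE)):
    """Split an RNA-mode read into (umi5, insert, umi3, barcode).

    Layout: 5-nt UMI | insert | 5-nt UMI | inline barcode.
    """
    if len(sequence) < 10 + barcode_length + 1:
        raise ValueError("read too short for the RNA adapter layout")
    umi5 = sequence[:5]
    barcode = sequence[-barcode_length:]
    umi3 = sequence[-barcode_length - 5 : -barcode_length]
    insert = sequence[5 : -barcode_length - 5]
    return umi5, insert, umi3, barcode


def _candidate_hits(index: ReferenceIndex, query: str, space: str, max_mm: int):
    """Best ungapped full-length placements of query in one collapsed space."""
    seqs = index.ct if space == "CT" else index.ga
    k = index.seed_length
    if len(query) < k:
        raise ValueError(f"read shorter than the seed length ({k})")
    hits: dict[tuple[str, int], int] = {}
    for offset in (0, k):
        if offset + k > len(query):
            break
        seed = query[offset : offset + k]
        for name, i in index._seeds[space].get(seed, ()):
            start = i - offset
            if start < 0 or start + len(query) > len(seqs[name]):
                continue
            key = (name, start)
            if key in hits:
                continue
            ref_seg = seqs[name][start : start + len(query)]
            mm = sum(a != b for a, b in zip(query, ref_seg))
            if mm <= max_mm:
                hits[key] = mm
    return hits


def _annotate(read_seq: str, ref_seq: str, start: int, strand: str):
    """Per-C conversion states and conversion-excluded mismatch count."""
    L = len(read_seq)
    seg = ref_seq[start : start + L]
    c_states: list[tuple[int, str]] = []
    mismatches = 0
    if strand == "+":
        walk = read_seq
        c_base = "C"
    else:
        walk = revcomp(read_seq)
        c_base = "G"  # a C on the minus strand is a G in forward coordinates
    for i, (r, q) in enumerate(zip(seg, walk)):
        pos = start + i
        if r == c_base:
            if strand == "+":
                state = UNCONVERTED if q == "C" else CONVERTED if q == "T" else OTHER
            else:
                state = UNCONVERTED if q == "G" else CONVERTED if q == "A" else OTHER
            c_states.append((pos, state))
            if state == OTHER:
                mismatches += 1
        elif q != r:
            mismatches += 1
    return c_states, mismatches


def map_read(
    read: FastqRead | str,
    index: ReferenceIndex,
    mode: str = "directional",
    max_mismatch_frac: float = 0.05,
) -> MappedRead | None:
    """Place one read; returns None for unmapped or ambiguous (tied) reads."""
    if mode not in ("directional", "directional-reverse"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    rid, seq = (read.id, read.sequence) if isinstance(read, FastqRead) else ("read", read)
    seq = seq.upper()
    if mode == "directional-reverse":
        # read 1 derives from the original strand: map its reverse complement
        # with the directional rule and flip the reported strand
        flipped = map_read(
            FastqRead(rid, revcomp(seq), ""), index, "directional", max_mismatch_frac
        )
        if flipped is None:
            return None
        flipped.strand = "+" if flipped.strand == "-" else "-"
        flipped.sequence = seq
        flipped.c_states, flipped.mismatches = _annotate(
            seq, index.references[flipped.ref], flipped.start, flipped.strand
        )
        return flipped

    max_mm = int(max_mismatch_frac * len(seq))
    hits: dict[tuple[str, int, str], int] = {}
    for strand, space, query in (
        ("+", "CT", seq.translate(_CT)),
        ("-", "GA", revcomp(seq).translate(_GA)),
    ):
        for (name, start), mm in _candidate_hits(index, query, space, max_mm).items():
            hits[(name, start, strand)] = mm
    if not hits:
        return None
    best = min(hits.values())
    best_keys = [k for k, v in hits.items() if v == best]
    if len(best_keys) > 1:
        return None  # ambiguous multi-mapper: strict discard
    name, start, strand = best_keys[0]
    c_states, mismatches = _annotate(seq, index.references[name], start, strand)
    return MappedRead(
        id=rid,
        ref=name,
        start=start,
        strand=strand,
        length=len(seq),
        mismatches=mismatches,
        c_states=c_states,
        sequence=seq,
    )


def map_reads(
    reads: Iterable[FastqRead],
    index: ReferenceIndex | Sequence[ReferenceIndex],
    mode: str = "directional",
    rna_mode: bool = False,
    max_mismatch_frac: float = 0.05,
) -> list[MappedRead]:
    """Map reads against one index or an ordered list of reference groups.

    With multiple indexes (e.g. rRNA/tRNA first, then the genome), a read is
    claimed by the first group in which it maps and is excluded from later
    groups.  In RNA mode the UMI/barcode layout is parsed off before mapping
    and stored on the result.
    """
    indexes = [index] if isinstance(index, ReferenceIndex) else list(index)
    out: list[MappedRead] = []
    for read in reads:
        umi5 = umi3 = barcode = ""
        target = read
        if rna_mode:
            umi5, insert, umi3, barcode = parse_rna_read(read.sequence)
            target = FastqRead(read.id, insert, "")
        for idx in indexes:
            m = map_read(target, idx, mode, max_mismatch_frac)
            if m is not None:
                m.umi5, m.umi3, m.barcode = umi5, umi3, barcode
                out.append(m)
                break
    return out


def dedup(reads: Sequence[MappedRead], mode: str = "dna") -> list[MappedRead]:
    """Remove PCR duplicates, keeping the first read per key.

    DNA keys: (ref, start, end, strand).  RNA keys: (umi5+umi3, ref, start) —
    fragments with identical placement but different UMI pairs are distinct
    molecules.
    """
    if mode not in ("dna", "rna"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    seen: set[tuple] = set()
    kept: list[MappedRead] = []
    for r in reads:
        if mode == "rna":
            if not (r.umi5 and r.umi3):
                raise ValueError("RNA-mode dedup requires UMIs on every read")
            key = (r.umi5 + r.umi3, r.ref, r.start)
        else:
            key = (r.ref, r.start, r.end, r.strand)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Cytosine context (CpG / CHG / CHH) from the two downstream bases.

    ``pos`` must be a C on the given strand (a G in forward coordinates for
    the minus strand).  Sites within 2 nt of the sequence end are
    'indeterminate'.
    """
    seq = reference
    if strand == "+":
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            raise ValueError(f"position {pos} is not a C on the + strand")
        if pos + 2 >= len(seq):
            return "indeterminate"
        d1, d2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if pos < 0 or pos >= len(seq) or seq[pos] != "G":
            raise ValueError(f"position {pos} is not a C on the - strand")
        if pos - 2 < 0:
            return "indeterminate"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        d1, d2 = comp.get(seq[pos - 1], "N"), comp.get(seq[pos - 2], "N")
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if d1 == "G":
        return "CpG"
    if d1 in "ACT" and d2 == "G":
        return "CHG"
    if d1 in "ACT" and d2 in "ACT":
        return "CHH"
    return "indeterminate"


def pileup(
    reads: Sequence[MappedRead],
    references: dict[str, str],
    rna_mode: bool = False,
) -> pd.DataFrame:
    """Per-site converted/unconverted counts over all covered reference C.

    Strand-aware: forward-strand C are interrogated by C→T reads, reverse
    strand C (G on the forward sequence) by G→A reads.  The methylation ratio
    is n_unconverted / (n_unconverted + n_converted); 'other' bases at C
    positions are excluded from both counts.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    for r in reads:
        for pos, state in r.c_states:
            if state == OTHER:
                continue
            key = (r.ref, pos, r.strand)
            c = counts.setdefault(key, [0, 0])
            c[0 if state == UNCONVERTED else 1] += 1
    rows = []
    for (ref, pos, strand), (u, c) in sorted(counts.items()):
        cov = u + c
        context = "C" if rna_mode else classify_context(references[ref], pos, strand)
        rows.append((ref, pos, strand, context, u, c, cov, u / cov))
    return pd.DataFrame(rows, columns=SITECOUNT_COLUMNS)
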