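import numpy as np
import pytest

import ubscall as u


@pytest.fixture(scope="session")
def dna_library():
    """Small DNA reference + truth + error-free simulated reads, mapped."""
    refs, truth = u.simulate_reference(seed=11, n_sequences=1, lengths=2000)
    params = u.SimParams(seed=12, depth=30)
    reads, aln = u.simulate_bisulfite_reads(refs, truth, params)
    index = u.ReferenceIndex(refs)
    mapped = u.map_reads(reads, index)
    return dict(refs=refs, truth=truth, params=params, reads=reads,
                truth_aln=aln, index=index, mapped=mapped)


@pytest.fixture(scope="session")
def rna_library():
    """RNA-mode library with UMIs/barcode and planted m5C sites."""
    refs, truth = u.simulate_reference(
        seed=21, n_sequences=2, lengths=1200, rna_mode=True,
        m5c_sites_per_seq=8,
    )
    params = u.SimParams(
        seed=22, depth=40, rna_mode=True, frag_mean=80, frag_sd=15,
        frag_min=40, duplication_rate=0.2,
    )
    reads, aln = u.simulate_bisulfite_reads(refs, truth, params)
    index = u.ReferenceIndex(refs)
    mapped = u.map_reads(reads, index, rna_mode=True)
    return dict(refs=refs, truth=truth, params=params, reads=reads,
                truth_aln=aln, index=index, mapped=mapped)


def make_read(n_unconverted, n_converted, mismatches=0, length=100,
              barcode="ATCACG", rid="r"):
    """Construct a MappedRead with the requested conversion profile."""
    from ubscall.align import CONVERTED, UNCONVERTED, MappedRead

    states = [(i, UNCONVERTED) for i in range(n_unconverted)]
    states += [(100 + i, CONVERTED) for i in range(n_converted)]
    return MappedRead(
        id=rid, ref="chr1", start=0, strand="+", length=length,
        mismatches=mismatches, c_states=states,
        umi5="AAAAA", umi3="CCCCC", barcode=barcode,
    )
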