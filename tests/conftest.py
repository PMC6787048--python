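import numpy as np
import pytest

import hapfish as hf


@pytest.fixture(scope="session")
def ref8k():
    """Small repeat-free random reference."""
    return hf.generate_reference(8_000, seed=3)


@pytest.fixture(scope="session")
def pair20k():
    """20-kb haplotype pair with SNPs, short indels and both PAV kinds."""
    ref = hf.generate_reference(20_000, seed=5)
    return hf.derive_haplotype(
        ref, snp_rate=0.01, indel_rate=1e-3,
        pav_specs=[(1000, "pav_deletion"), (800, "pav_insertion")], seed=6,
    )


@pytest.fixture(scope="session")
def pair1mb():
    """The 1-Mb study-condition haplotype pair used by the end-to-end and
    breakpoint-recovery checks."""
    ref = hf.generate_reference(1_000_000, seed=1)
    return hf.derive_haplotype(
        ref, snp_rate=0.01, indel_rate=1e-3,
        pav_specs=[(5000, "pav_deletion"), (4000, "pav_insertion"),
                   (3000, "pav_deletion")],
        seed=2,
    )


def brute_force_kmer_counts(seqs, k, canonical):
    """Dictionary k-mer counting oracle."""
    from collections import Counter

    comp = str.maketrans("ACGT", "TGCA")
    counts = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) - set("ACGT"):
                continue
            if canonical:
                kmer = min(kmer, kmer.translate(comp)[::-1])
            counts[kmer] += 1
    return counts


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
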