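"""Shared fixtures: a small simulated cohort and reusable brute-force
oracles kept independent of the library's search implementations."""
from __future__ import annotations

import numpy as np
import pytest

from falsitron import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def sim():
    """Default study conditions, seed 1: 10 genes, 5 planted artifact
    loci (repeat lengths 4/6/8/12/16), p_slip 0.3, depth 100."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cdna_reads(sim):
    reads, _ = simulate_reads(sim, "cDNA")
    return reads


@pytest.fixture(scope="session")
def drna_reads(sim):
    reads, _ = simulate_reads(sim, "dRNA")
    return reads


def brute_force_max_repeat(w5, w3, motif5, motif3, k_min=4, k_max=20):
    """Exhaustive substring enumeration: the largest k with a k-mer
    present in both windows, each occurrence overlapping >= 1 nt of its
    motif. Scans every k (no early exit) via set intersection."""
    best = 0
    for k in range(k_min, min(k_max, len(w5), len(w3)) + 1):
        kmers5 = {
            w5[i : i + k]
            for i in range(len(w5) - k + 1)
            if i < motif5[1] and i + k > motif5[0]
        }
        kmers3 = {
            w3[i : i + k]
            for i in range(len(w3) - k + 1)
            if i < motif3[1] and i + k > motif3[0]
        }
        if kmers5 & kmers3:
            best = k
    return best


def random_window_pair(rng: np.random.Generator, window: int = 40, shared=None):
    """A random window pair with centred dinucleotide motifs; optionally
    a shared k-mer planted across both motifs."""
    bases = np.array(list("ACGT"))
    w5 = "".join(bases[rng.integers(0, 4, window)])
    w3 = "".join(bases[rng.integers(0, 4, window)])
    half = window // 2
    motif5 = (half, half + 2)
    motif3 = (half - 2, half)
    if shared is not None:
        k = len(shared)
        i5 = int(rng.integers(max(0, motif5[0] - k + 1), min(motif5[1], window - k) + 1))
        i3 = int(rng.integers(max(0, motif3[0] - k + 1), min(motif3[1], window - k) + 1))
        w5 = w5[:i5] + shared + w5[i5 + k :]
        w3 = w3[:i3] + shared + w3[i3 + k :]
    return w5, w3, motif5, motif3
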