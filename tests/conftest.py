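import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kmerperiod as kp
from kmerperiod.io import GenomicInterval, write_fasta

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_seqs():
    """50 sequences of 300 bp with TT planted every 10 bp, no jitter."""
    seqs, truth = kp.make_periodic_sequences(
        50, 300, kp.PlantSpec("TT", 10), seed=1
    )
    return seqs, truth


@pytest.fixture(scope="session")
def random_seqs():
    """50 i.i.d.-uniform sequences of 300 bp."""
    return kp.make_random_sequences(50, 300, seed=7)


@pytest.fixture()
def tiny_genome(tmp_path):
    """10-kb single-chromosome genome with a 1-kb TT-periodic segment at 4000.

    Returns (fasta_path, planted_interval, matched_random_interval).
    """
    bg = kp.make_random_sequences(1, 10000, seed=11)[0]
    planted, _ = kp.make_periodic_sequences(1, 1000, kp.PlantSpec("TT", 10), seed=12)
    bases = bg.bases[:4000] + planted[0].bases + bg.bases[5000:]
    path = tmp_path / "genome.fa"
    write_fasta([kp.DnaSequence("chr1", bases)], path)
    return path, GenomicInterval("chr1", 4000, 5000), GenomicInterval("chr1", 7000, 8000)


def naive_dft_psd(signal):
    """O(L^2) direct-summation DFT power oracle on the k/L grid, DC excluded."""
    signal = np.asarray(signal, dtype=float)
    L = signal.size
    n = np.arange(L)
    psd = np.empty(L // 2)
    for k in range(1, L // 2 + 1):
        w = np.exp(-2j * np.pi * k * n / L)
        psd[k - 1] = np.abs(np.sum(signal * w)) ** 2 / L**2
    return psd
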