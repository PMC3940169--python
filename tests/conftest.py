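"""Shared fixtures: designed index sets, sample sheets, simulated runs.

Everything is generated programmatically with fixed seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

import hetspacer as hs
from hetspacer._seq import hamming


def random_index_pool(n: int, seed: int, min_pairwise: int = 3) -> list[str]:
    """n random 12-mers that are mutually >= min_pairwise apart."""
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    while len(pool) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(4, size=12))
        if all(hamming(cand, p) >= min_pairwise for p in pool):
            pool.append(cand)
    return pool


HOMOPOLYMERS = ["A" * 12, "C" * 12, "G" * 12, "T" * 12]


@pytest.fixture(scope="session")
def index_pool():
    return random_index_pool(40, seed=11)


@pytest.fixture(scope="session")
def spacers():
    return hs.design_spacer_set(range(8), hs.DEFAULT_PRIMER_FWD, seed=7)


@pytest.fixture(scope="session")
def sheet8(index_pool, spacers):
    """8 samples, one per spacer length, unique dual indices."""
    fwd = hs.design_index_set(index_pool[:16], k=8, min_hamming=3, seed=1)
    rev = hs.design_index_set(index_pool[16:32], k=8, min_hamming=3, seed=2)
    return hs.assign_samples(
        [f"S{i + 1:02d}" for i in range(8)], fwd, rev, spacers, seed=3
    )


@pytest.fixture(scope="session")
def templates():
    return hs.simulate_templates(
        5, 469, hs.DEFAULT_PRIMER_FWD, hs.DEFAULT_PRIMER_REV, seed=5
    )


@pytest.fixture(scope="session")
def clean_run_250(sheet8, templates):
    """Error-free, contaminant-free 250PE run with ground truth."""
    cfg = hs.SimConfig(
        seed=21,
        read_length=250,
        reads_per_sample=50,
        substitution_error_rate=0.0,
        contaminant_fraction=0.0,
    )
    pairs, truth = hs.simulate_run(sheet8, templates, cfg)
    return pairs, truth, cfg


@pytest.fixture(scope="session")
def noisy_run_250(sheet8, templates):
    """Default error model + 20% contaminant, 250PE."""
    cfg = hs.SimConfig(seed=22, read_length=250, reads_per_sample=50)
    pairs, truth = hs.simulate_run(sheet8, templates, cfg)
    return pairs, truth, cfg


@pytest.fixture(scope="session")
def clean_run_300(sheet8, templates):
    cfg = hs.SimConfig(
        seed=23,
        read_length=300,
        reads_per_sample=30,
        substitution_error_rate=0.0,
        contaminant_fraction=0.0,
    )
    pairs, truth = hs.simulate_run(sheet8, templates, cfg)
    return pairs, truth, cfg


def write_pairs(tmpdir, pairs, gzip_output=False):
    """Write ReadPairs to a FASTQ pair under tmpdir; returns the two paths."""
    ext = ".fastq.gz" if gzip_output else ".fastq"
    p1, p2 = tmpdir / f"reads_R1{ext}", tmpdir / f"reads_R2{ext}"
    with hs.FastqPairWriter(p1, p2) as w:
        for p in pairs:
            w.write(p)
    return p1, p2
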