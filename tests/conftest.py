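"""Shared fixtures: a small fast dataset for unit tests and the
default-scale dataset/pipeline run reused by the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

from seatlas import RunConfig, SimulationConfig, run_pipeline, simulate
from seatlas.core import GenomicInterval


@pytest.fixture(scope="session")
def small_dataset():
    """Quarter-scale dataset: 1 x 300-kb chromosome, 5 planted SEs."""
    config = SimulationConfig(
        seed=5,
        n_chromosomes=1,
        chromosome_length=300_000,
        n_genes=60,
        n_samples=3,
        n_planted_ses=5,
        n_background_acrs=60,
        n_insertion_loci=2,
        n_decoy_cns=5,
        n_decoy_loops=10,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    cfg = RunConfig(
        seed=5,
        se_length_threshold=1500,
        n_null_reps=30,
        tad_n_sets=100,
        n_resamples=100,
    )
    return run_pipeline(small_dataset, cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 2 x 1 Mb, 300 genes, 6 samples,
    20 planted SEs, 400 background ACRs."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_dataset):
    return run_pipeline(default_dataset, RunConfig(seed=1, se_length_threshold=1500))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_merge(intervals, max_gap):
    """O(n^2) transitive-closure chaining of intervals."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    out = [
        GenomicInterval(
            g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g)
        )
        for g in groups.values()
    ]
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def sw_local_score(q, t, match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-2.0):
    """Exhaustive Gotoh local-alignment score (affine gaps, one strand)."""
    n, m = len(q), len(t)
    NEG = -1e12
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            M[i, j] = max(
                0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            )
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


def random_intervals(rng, n, n_chroms=2, span=10_000, max_len=300):
    out = []
    for _ in range(n):
        chrom = f"c{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
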