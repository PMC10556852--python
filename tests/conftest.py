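"""Shared fixtures and independent brute-force oracles.

The oracles re-derive detector output by exhaustive enumeration and are kept
deliberately naive (plain loops over every window / every stretch) so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    SampleRecord,
)

H = HOM_A   # shorthand for building call vectors in tests
B = HOM_B
E = HET     # hEt
M = MISSING


def make_gm(rows, pos=None, chrom=1, sample_ids=None, groups=None,
            snps=None) -> GenotypeMatrix:
    """Build a one-chromosome (or custom-map) matrix from call-code rows."""
    calls = np.asarray(rows, dtype=np.uint8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n_samples, n_snps = calls.shape
    if snps is None:
        if pos is None:
            pos = (np.arange(n_snps) + 1) * 100_000  # 100 kb spacing
        snps = pd.DataFrame({
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos_bp": np.asarray(pos, dtype=np.int64),
        })
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if groups is None:
        groups = [None] * n_samples
    samples = [SampleRecord(sid, g) for sid, g in zip(sample_ids, groups)]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def brute_force_homozygous_runs(pos, calls, min_snp, min_length_bp, max_gap_bp):
    """Oracle: maximal all-homozygous stretches with gap/length/count filters.

    Valid only for het/missing budgets of zero.  Returns (start_idx, end_idx)
    inclusive SNP-index pairs.
    """
    pos = np.asarray(pos)
    calls = np.asarray(calls)
    n = len(pos)
    runs = []
    start = None
    for j in range(n):
        hom = calls[j] in (HOM_A, HOM_B)
        if not hom:
            if start is not None:
                runs.append((start, j - 1))
                start = None
            continue
        if start is None:
            start = j
        elif pos[j] - pos[j - 1] > max_gap_bp:
            runs.append((start, j - 1))
            start = j
    if start is not None:
        runs.append((start, n - 1))
    return [
        (s, e) for s, e in runs
        if e - s + 1 >= min_snp and pos[e] - pos[s] >= min_length_bp
    ]


def brute_force_window_support(calls, window_snp, max_het, max_missing):
    """Oracle: per-SNP support by explicit enumeration of every window."""
    calls = np.asarray(calls)
    n = len(calls)
    if n < window_snp:
        return np.zeros(n)
    qualifying = []
    for start in range(n - window_snp + 1):
        win = calls[start:start + window_snp]
        ok = (np.sum(win == HET) <= max_het) and (np.sum(win == MISSING) <= max_missing)
        qualifying.append(ok)
    support = np.zeros(n)
    for i in range(n):
        covering = [s for s in range(len(qualifying)) if s <= i <= s + window_snp - 1]
        support[i] = sum(qualifying[s] for s in covering) / len(covering)
    return support


def random_chromosome(rng, max_snps=60):
    """A random small chromosome: positions with occasional large gaps, and
    calls mixing homozygous/het/missing states."""
    n = int(rng.integers(1, max_snps + 1))
    gaps = rng.integers(10_000, 300_000, size=n)
    big = rng.random(n) < 0.08  # occasional gap-limit breakers
    gaps[big] = rng.integers(1_000_001, 3_000_000, size=int(big.sum()))
    pos = np.cumsum(gaps)
    calls = rng.choice(
        [HOM_A, HOM_B, HET, MISSING], size=n, p=[0.45, 0.30, 0.18, 0.07]
    ).astype(np.uint8)
    return pos.astype(np.int64), calls


@pytest.fixture
def toy_sim_params():
    """Small 2-chromosome simulation parameters used across tests."""
    from rohscan import SimParams

    return SimParams(
        n_samples=8,
        chrom_lengths_bp={1: 30_000_000, 2: 20_000_000},
        mean_spacing_bp=52_000,
        tracts_per_sample_mean=3.0,
        tract_length_range_bp=(1_000_000, 8_000_000),
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
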