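"""ROH calling by consecutive runs and by proportion-of-overlapping-windows.

Two detectors are implemented, mirroring the two families of SNP-array ROH
callers in routine use:

* **consecutive runs** -- a direct left-to-right scan per sample and
  chromosome that grows a candidate run and closes it when a
  heterozygous-call budget, missing-call budget, or inter-SNP gap limit is
  exceeded (the detectRUNS "consecutive" method);
* **sliding windows** -- each SNP's *support* is the fraction of fixed-size
  windows covering it that are (near-)homozygous; SNPs whose support clears a
  threshold are assembled into runs (the PLINK ``--homozyg`` / detectRUNS
  "sliding" method).

Both emit :class:`RohSegment` records with 1-based inclusive positions of the
first and last SNP in the run; run length is ``end_bp - start_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genotype_io import HET, MISSING, GenotypeMatrix

__all__ = [
    "ConsecutiveParams",
    "SlidingParams",
    "RohSegment",
    "detect_consecutive",
    "detect_sliding",
    "snp_window_support",
    "PRESETS",
    "get_preset",
]


@dataclass(frozen=True)
class ConsecutiveParams:
    """Consecutive-runs calling parameters.

    Defaults are the standard 50k-array settings: at least 20 SNPs and 250 kb
    per run, no heterozygous or missing calls tolerated, and runs split at
    inter-SNP gaps above 1 Mb.
    """

    min_snp: int = 20
    max_het: int = 0
    max_missing: int = 0
    min_length_bp: int = 250_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_snp < 2:
            raise ValueError("min_snp must be >= 2")
        if min(self.max_het, self.max_missing, self.min_length_bp, self.max_gap_bp) < 0:
            raise ValueError("parameters must be non-negative")


@dataclass(frozen=True)
class SlidingParams:
    """Sliding-window calling parameters.

    ``max_bp_per_snp`` is the minimum SNP density expressed as the largest
    tolerated mean bp per SNP inside a run: 1_000_000 reproduces the
    detectRUNS preset (1 SNP per 1 Mb), 60_000 the PLINK preset (1 SNP per
    60 kb).
    """

    window_snp: int = 20
    window_threshold: float = 0.05
    min_snp: int = 20
    window_max_het: int = 0
    window_max_missing: int = 0
    min_length_bp: int = 250_000
    max_gap_bp: int = 1_000_000
    max_bp_per_snp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_snp < 2:
            raise ValueError("window_snp must be >= 2")
        if not (0.0 < self.window_threshold <= 1.0):
            raise ValueError("window_threshold must be in (0, 1]")
        if self.min_snp < 2:
            raise ValueError("min_snp must be >= 2")


@dataclass(frozen=True)
class RohSegment:
    """One called run of homozygosity."""

    sample_id: str
    chrom: int | str
    start_bp: int
    end_bp: int
    n_snp: int
    n_het: int
    n_missing: int
    method: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def overlaps(self, other: "RohSegment") -> bool:
        return (self.sample_id == other.sample_id and self.chrom == other.chrom
                and self.start_bp < other.end_bp and other.start_bp < self.end_bp)


# Paper-style parameter bundles for the two software presets compared in
# cattle ROH studies: detectRUNS (consecutive + sliding) and PLINK --homozyg.
PRESETS: dict[str, ConsecutiveParams | SlidingParams] = {
    "consecutive-15": ConsecutiveParams(min_snp=15),
    "consecutive-20": ConsecutiveParams(min_snp=20),
    "sliding-15": SlidingParams(window_snp=15, min_snp=15, max_bp_per_snp=1_000_000),
    "sliding-20": SlidingParams(window_snp=20, min_snp=20, max_bp_per_snp=1_000_000),
    "plink-paper": SlidingParams(window_snp=20, min_snp=20, max_bp_per_snp=60_000),
}


def get_preset(name: str, **overrides) -> ConsecutiveParams | SlidingParams:
    """Return a named preset, optionally overriding individual fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


def _emit(sample_id, chrom, pos, calls, start, end, min_snp, min_length_bp, method, out):
    """Append run [start, end] (inclusive SNP indices) if it passes filters.

    Returns True iff the run was emitted.
    """
    n_snp = end - start + 1
    if n_snp < min_snp:
        return False
    length = int(pos[end] - pos[start])
    if length < min_length_bp:
        return False
    window = calls[start:end + 1]
    out.append(RohSegment(
        sample_id=sample_id,
        chrom=chrom,
        start_bp=int(pos[start]),
        end_bp=int(pos[end]),
        n_snp=n_snp,
        n_het=int(np.count_nonzero(window == HET)),
        n_missing=int(np.count_nonzero(window == MISSING)),
        method=method,
    ))
    return True


def _consecutive_scan_chrom(sample_id, chrom, pos, calls, p: ConsecutiveParams, out) -> None:
    n = len(pos)
    max_het, max_missing, max_gap = p.max_het, p.max_missing, p.max_gap_bp
    i = 0
    while i < n:
        n_het = n_miss = 0
        first_bad = None   # first het/missing counted into the candidate
        j = i
        end = None         # inclusive end of the closed candidate
        resume = None
        budget_closed = False
        while j < n:
            if j > i and pos[j] - pos[j - 1] > max_gap:
                end, resume = j - 1, j
                break
            c = calls[j]
            if c == HET:
                if n_het == max_het:
                    # budget violated: close before j, skip the violating call
                    end, resume, budget_closed = j - 1, j + 1, True
                    break
                n_het += 1
                if first_bad is None:
                    first_bad = j
            elif c == MISSING:
                if n_miss == max_missing:
                    end, resume, budget_closed = j - 1, j + 1, True
                    break
                n_miss += 1
                if first_bad is None:
                    first_bad = j
            j += 1
        if end is None:
            end, resume = n - 1, n
        emitted = False
        if end >= i:
            emitted = _emit(sample_id, chrom, pos, calls, i, end,
                            p.min_snp, p.min_length_bp, "consecutive", out)
        # A budget-closed candidate that was dropped must not shadow a
        # downstream run: rescan just past its first tolerated bad call
        # (which frees budget, so a longer passing run may exist there).
        # Gap/end closures cannot shadow -- any sub-candidate is a subset
        # and the filters are monotone in extent.
        if budget_closed and not emitted and first_bad is not None:
            resume = first_bad + 1
        i = resume


def detect_consecutive(gm: GenotypeMatrix, p: ConsecutiveParams) -> list[RohSegment]:
    """Call ROH by the consecutive-runs scan, per sample and chromosome.

    The scan grows a candidate run SNP by SNP and closes it when admitting
    the next SNP would exceed the heterozygous or missing budget, when the
    gap to the next SNP exceeds ``max_gap_bp``, or at the chromosome end.
    Closed candidates are kept iff they span at least ``min_snp`` SNPs and
    ``min_length_bp`` base pairs.  After an *emitted* budget closure the scan
    resumes just past the violating call (keeping reported runs disjoint);
    after a *dropped* budget closure it backtracks to just past the
    candidate's first tolerated het/missing call, so a failed candidate
    never shadows a downstream run.  With ``max_het = max_missing = 0`` the
    output is exactly the set of maximal all-homozygous stretches passing
    the gap/length/count filters.
    """
    gm.validate_sorted()
    out: list[RohSegment] = []
    for chrom, pos, idx in gm.chrom_slices():
        if len(idx) == 0:
            continue
        sub = gm.calls[:, idx]
        for i, sample in enumerate(gm.samples):
            _consecutive_scan_chrom(sample.sample_id, chrom, pos, sub[i], p, out)
    out.sort(key=lambda s: (s.sample_id, str(s.chrom), s.start_bp))
    return out


def snp_window_support(calls: np.ndarray, p: SlidingParams) -> np.ndarray:
    """Per-SNP support: fraction of covering windows that are near-homozygous.

    A window is ``window_snp`` consecutive SNPs, slid one SNP at a time; it
    qualifies iff it contains at most ``window_max_het`` HET and
    ``window_max_missing`` MISSING calls.  Edge SNPs are covered by fewer
    windows and are normalised by their own coverage (PLINK edge semantics).
    If the chromosome holds fewer SNPs than one window, support is 0
    everywhere.
    """
    calls = np.asarray(calls)
    n, w = len(calls), p.window_snp
    if n == 0:
        return np.zeros(0)
    if n < w:
        return np.zeros(n)
    is_het = (calls == HET).astype(np.int64)
    is_mis = (calls == MISSING).astype(np.int64)
    kernel = np.ones(w, dtype=np.int64)
    het_per_win = np.convolve(is_het, kernel, mode="valid")   # n - w + 1 windows
    mis_per_win = np.convolve(is_mis, kernel, mode="valid")
    qual = ((het_per_win <= p.window_max_het)
            & (mis_per_win <= p.window_max_missing)).astype(np.int64)
    # windows covering SNP i start in [i - w + 1, i] clipped to [0, n - w]
    cums = np.concatenate([[0], np.cumsum(qual)])
    i = np.arange(n)
    lo = np.clip(i - w + 1, 0, None)
    hi = np.minimum(i, n - w)
    n_qual = cums[hi + 1] - cums[lo]
    n_cover = hi - lo + 1
    return n_qual / n_cover


def _sliding_scan_chrom(sample_id, chrom, pos, calls, p: SlidingParams, out) -> None:
    support = snp_window_support(calls, p)
    marked = support >= p.window_threshold
    # a HET (resp. MISSING) call may sit inside a run only when the window
    # budget admits such calls at all
    if p.window_max_het == 0:
        marked &= calls != HET
    if p.window_max_missing == 0:
        marked &= calls != MISSING
    n = len(pos)
    i = 0
    while i < n:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and marked[j + 1]:
            j += 1
        # candidate [i, j]; split at over-long inter-SNP gaps
        start = i
        for k in range(i + 1, j + 1):
            if pos[k] - pos[k - 1] > p.max_gap_bp:
                _maybe_emit_sliding(sample_id, chrom, pos, calls, start, k - 1, p, out)
                start = k
        _maybe_emit_sliding(sample_id, chrom, pos, calls, start, j, p, out)
        i = j + 1


def _maybe_emit_sliding(sample_id, chrom, pos, calls, start, end, p: SlidingParams, out):
    n_snp = end - start + 1
    if n_snp < p.min_snp:
        return
    length = int(pos[end] - pos[start])
    if length < p.min_length_bp:
        return
    if length / n_snp > p.max_bp_per_snp:
        return
    _emit(sample_id, chrom, pos, calls, start, end, p.min_snp, p.min_length_bp,
          "sliding", out)


def detect_sliding(gm: GenotypeMatrix, p: SlidingParams) -> list[RohSegment]:
    """Call ROH by sliding-window support, per sample and chromosome.

    SNPs whose support reaches ``window_threshold`` are marked; maximal
    stretches of marked SNPs become candidate runs, which are split at
    inter-SNP gaps above ``max_gap_bp`` and then filtered on SNP count, bp
    length, and mean SNP density (``length_bp / n_snp <= max_bp_per_snp``).
    """
    gm.validate_sorted()
    out: list[RohSegment] = []
    for chrom, pos, idx in gm.chrom_slices():
        if len(idx) == 0:
            continue
        sub = gm.calls[:, idx]
        for i, sample in enumerate(gm.samples):
            _sliding_scan_chrom(sample.sample_id, chrom, pos, sub[i], p, out)
    out.sort(key=lambda s: (s.sample_id, str(s.chrom), s.start_bp))
    return out
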