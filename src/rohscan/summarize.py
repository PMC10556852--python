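"""Downstream ROH statistics: FROH, length classes, chromosome ranks,
group (herd) summaries with Welch t-tests, the het/missing sensitivity
sweep, and Spearman agreement between detection methods.

FROH, the genomic inbreeding coefficient, is the summed ROH length of an
individual divided by the autosome length covered by the SNP map; the
default denominator is 2,508,706,681 bp (2508.706681 Mb), the mapped-autosome
total of the BovineSNP50 panel this package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import (
    ConsecutiveParams,
    RohSegment,
    SlidingParams,
    detect_consecutive,
    detect_sliding,
)
from .genotype_io import GenotypeMatrix
from .simulate import AUTOSOME_TOTAL_BP

__all__ = [
    "FrohResult",
    "LengthClassCounts",
    "ChromRankRow",
    "GroupSummary",
    "SweepCell",
    "LENGTH_CLASSES",
    "compute_froh",
    "froh_per_sample",
    "classify_lengths",
    "rank_chromosomes",
    "summarize_groups",
    "sweep_het_missing",
    "compare_methods",
    "denominator_from_map",
]

#: The five tabulated length classes (Mb, left-closed right-open), plus the
#: sub-1 Mb bin kept separate because the minimum run length (250 kb) sits
#: below the smallest tabulated class.
LENGTH_CLASSES: tuple[str, ...] = ("<1Mb", "1-2Mb", "2-4Mb", "4-8Mb", "8-16Mb", ">16Mb")
_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class FrohResult:
    """Genomic inbreeding of one sample: summed ROH length / denominator."""

    sample_id: str
    sum_roh_bp: int
    denominator_bp: float
    froh: float


@dataclass
class LengthClassCounts:
    """Segment counts and relative frequencies per length class.

    ``frequencies`` are over the five classes from 1 Mb up; the ``<1Mb`` bin
    is counted but excluded from the five-class frequencies.
    """

    counts: dict[str, int]
    frequencies: dict[str, float]
    n_total: int
    n_sub_1mb: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "length_class": list(LENGTH_CLASSES),
            "n_roh": [self.counts[c] for c in LENGTH_CLASSES],
            "frequency": [self.frequencies.get(c, float("nan")) for c in LENGTH_CLASSES],
        })


@dataclass(frozen=True)
class ChromRankRow:
    """Per-chromosome ROH share normalised by genome-length share.

    ``score = (n_roh / total_roh) / (chrom_len / genome_len)``; rank 1 is the
    most ROH-enriched chromosome.
    """

    chrom: int | str
    n_roh: int
    prop_roh: float
    prop_len: float
    score: float
    rank: int


@dataclass
class GroupSummary:
    """Mean +/- SE of a per-sample statistic within one group (herd)."""

    group_id: str
    n: int
    mean: float
    se: float | None
    pairwise: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SweepCell:
    """One cell of the het x missing allowance grid."""

    max_het: int
    max_missing: int
    mean_roh_count: float
    mean_froh: float
    mean_sum_roh_bp: float


def _segment_length_class(length_bp: float) -> str:
    mb = length_bp / 1e6
    if mb < _CLASS_EDGES_MB[0]:
        return "<1Mb"
    for lo, hi in zip(_CLASS_EDGES_MB[:-1], _CLASS_EDGES_MB[1:]):
        if mb < hi:
            return f"{lo:.0f}-{hi:.0f}Mb"
    return ">16Mb"


def _check_non_overlapping(segments: Sequence[RohSegment]) -> None:
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sid, chrom), segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError(
                    f"overlapping ROH segments for sample {sid} chrom {chrom}: "
                    f"[{a.start_bp},{a.end_bp}] and [{b.start_bp},{b.end_bp}]"
                )


def compute_froh(
    segments_for_sample: Sequence[RohSegment],
    denominator_bp: float = AUTOSOME_TOTAL_BP,
    sample_id: str | None = None,
) -> FrohResult:
    """FROH for one sample: sum of its ROH lengths over the autosome denominator.

    Overlapping segments indicate a caller bug and raise rather than being
    silently merged.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    ids = {s.sample_id for s in segments_for_sample}
    if len(ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    _check_non_overlapping(segments_for_sample)
    total = int(sum(s.length_bp for s in segments_for_sample))
    return FrohResult(
        sample_id=sample_id,
        sum_roh_bp=total,
        denominator_bp=float(denominator_bp),
        froh=total / denominator_bp,
    )


def froh_per_sample(
    segments: Sequence[RohSegment],
    sample_ids: Sequence[str],
    denominator_bp: float = AUTOSOME_TOTAL_BP,
) -> list[FrohResult]:
    """FROH for every sample in ``sample_ids`` (zero for samples with no ROH)."""
    by_sample: dict[str, list[RohSegment]] = {sid: [] for sid in sample_ids}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    return [
        compute_froh(by_sample[sid], denominator_bp, sample_id=sid)
        for sid in sample_ids
    ]


def classify_lengths(segments: Sequence[RohSegment]) -> LengthClassCounts:
    """Tally segments into the standard length classes.

    Classes are left-closed, right-open ([1,2), [2,4), [4,8), [8,16) Mb and
    [16, inf)); a 2.0 Mb run falls in 2-4 Mb.  Runs below 1 Mb land in an
    explicit ``<1Mb`` bin that is excluded from the five-class frequencies.
    """
    counts = {c: 0 for c in LENGTH_CLASSES}
    for s in segments:
        counts[_segment_length_class(s.length_bp)] += 1
    n_total = len(segments)
    n_sub = counts["<1Mb"]
    n_tabulated = n_total - n_sub
    frequencies = {
        c: (counts[c] / n_tabulated) if n_tabulated else float("nan")
        for c in LENGTH_CLASSES if c != "<1Mb"
    }
    return LengthClassCounts(
        counts=counts, frequencies=frequencies, n_total=n_total, n_sub_1mb=n_sub
    )


def rank_chromosomes(
    segments: Sequence[RohSegment],
    chrom_lengths_bp: Mapping,
) -> list[ChromRankRow]:
    """Rank chromosomes by length-normalised ROH share.

    For each chromosome the proportion of all ROH segments lying on it is
    divided by the chromosome's share of the genome length; rank 1 is the
    largest score, ties broken by ascending chromosome number.  The weighted
    mean of scores (weights = length shares) is exactly 1.
    """
    total_roh = len(segments)
    if total_roh == 0:
        raise ValueError("cannot rank chromosomes with zero ROH segments")
    genome_len = float(sum(chrom_lengths_bp.values()))
    n_by_chrom: dict = {c: 0 for c in chrom_lengths_bp}
    for s in segments:
        if s.chrom not in n_by_chrom:
            raise ValueError(f"segment chromosome {s.chrom!r} absent from the length map")
        n_by_chrom[s.chrom] += 1

    rows = []
    for chrom in sorted(chrom_lengths_bp, key=lambda c: (isinstance(c, str), c)):
        prop_roh = n_by_chrom[chrom] / total_roh
        prop_len = chrom_lengths_bp[chrom] / genome_len
        rows.append((chrom, n_by_chrom[chrom], prop_roh, prop_len, prop_roh / prop_len))
    order = sorted(range(len(rows)), key=lambda i: (-rows[i][4], i))
    ranks = {i: r + 1 for r, i in enumerate(order)}
    return [
        ChromRankRow(chrom=c, n_roh=n, prop_roh=pr, prop_len=pl, score=sc, rank=ranks[i])
        for i, (c, n, pr, pl, sc) in enumerate(rows)
    ]


def summarize_groups(
    per_sample_values: Mapping[str, float],
    group_map: Mapping[str, str | None],
    exclude: Sequence[str] = (),
) -> list[GroupSummary]:
    """Group means with SE and pairwise Welch two-sided t-tests.

    ``SE = sd / sqrt(n)`` with the n-1 variance denominator; groups of one
    sample get no SE and take part in no test.  ``exclude`` names samples to
    leave out (the leave-one-out device used to probe single outlier
    animals).  Welch's unequal-variance form is used throughout because herd
    variances routinely differ; p-values are not multiplicity-corrected.
    """
    excluded = set(exclude)
    values_by_group: dict[str, list[float]] = {}
    for sid, val in per_sample_values.items():
        if sid in excluded:
            continue
        if sid not in group_map:
            raise KeyError(f"sample {sid!r} has no group assignment")
        gid = group_map[sid]
        if gid is None:
            raise KeyError(f"sample {sid!r} has no group assignment")
        values_by_group.setdefault(str(gid), []).append(float(val))

    out: list[GroupSummary] = []
    for gid in sorted(values_by_group):
        vals = np.asarray(values_by_group[gid], dtype=float)
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
        out.append(GroupSummary(group_id=gid, n=n, mean=float(vals.mean()), se=se))
    for a in out:
        for b in out:
            if a.group_id >= b.group_id or a.n < 2 or b.n < 2:
                continue
            t, p = stats.ttest_ind(
                values_by_group[a.group_id], values_by_group[b.group_id],
                equal_var=False,
            )
            a.pairwise[b.group_id] = (float(t), float(p))
            out[[g.group_id for g in out].index(b.group_id)].pairwise[a.group_id] = (
                float(-t), float(p)
            )
    return out


def sweep_het_missing(
    gm: GenotypeMatrix,
    base_params: ConsecutiveParams | SlidingParams,
    het_values: Sequence[int] = (0, 1, 2),
    missing_values: Sequence[int] = (0, 1, 2, 3, 4),
    denominator_bp: float = AUTOSOME_TOTAL_BP,
) -> list[SweepCell]:
    """Re-run a detector over the het x missing allowance grid.

    Each cell reruns detection with the heterozygous and missing budgets set
    to the cell's values (window budgets for the sliding method) and records
    the mean ROH count and mean FROH over samples.  This is the sensitivity
    analysis showing that ROH counts inflate sharply with the het allowance
    while missing allowances are inert on panels without missing calls.
    """
    sample_ids = gm.sample_ids
    cells: list[SweepCell] = []
    for h in het_values:
        for m in missing_values:
            if isinstance(base_params, ConsecutiveParams):
                p = replace(base_params, max_het=h, max_missing=m)
                segs = detect_consecutive(gm, p)
            else:
                p = replace(base_params, window_max_het=h, window_max_missing=m)
                segs = detect_sliding(gm, p)
            counts: dict[str, int] = {sid: 0 for sid in sample_ids}
            for s in segs:
                counts[s.sample_id] += 1
            froh = froh_per_sample(segs, sample_ids, denominator_bp)
            cells.append(SweepCell(
                max_het=h,
                max_missing=m,
                mean_roh_count=float(np.mean([counts[sid] for sid in sample_ids])),
                mean_froh=float(np.mean([f.froh for f in froh])),
                mean_sum_roh_bp=float(np.mean([f.sum_roh_bp for f in froh])),
            ))
    return cells


def compare_methods(
    rank_rows_a: Sequence[ChromRankRow],
    rank_rows_b: Sequence[ChromRankRow],
) -> tuple[float, float]:
    """Spearman rank correlation between two chromosome rankings.

    Ranks are aligned on the shared chromosome set (which must be identical)
    and correlated with average ranks for ties; the two-sided p-value comes
    from the t approximation, whose floor is 0 for a perfect correlation.
    """
    a = {r.chrom: r.rank for r in rank_rows_a}
    b = {r.chrom: r.rank for r in rank_rows_b}
    if set(a) != set(b):
        raise ValueError("rankings cover different chromosome sets")
    if len(a) < 3:
        raise ValueError("need at least 3 chromosomes for a rank correlation")
    chroms = sorted(a, key=lambda c: (isinstance(c, str), c))
    res = stats.spearmanr([a[c] for c in chroms], [b[c] for c in chroms])
    return float(res.statistic), float(res.pvalue)


def denominator_from_map(gm: GenotypeMatrix) -> float:
    """Sum of per-chromosome mapped extents (last - first SNP position).

    The alternative FROH denominator for panels (e.g. simulated toy genomes)
    where the fixed autosome total does not apply.
    """
    total = 0.0
    for _chrom, pos, _idx in gm.chrom_slices():
        if len(pos) >= 2:
            total += float(pos[-1] - pos[0])
    if total <= 0:
        raise ValueError("map has no extent")
    return total
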