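"""BovineSNP50-like genotype simulation with planted autozygous tracts.

The generator emulates a medium-density cattle array panel: 29 autosomes
whose lengths follow the real BTA proportions (rescaled so the genome totals
2,508,706,681 bp, the mapped-autosome denominator used for FROH), a jittered
SNP grid at ~52 kb mean spacing (~48k SNPs genome-wide), per-SNP allele
frequencies drawn uniformly, and background genotypes drawn per SNP from
Hardy-Weinberg proportions.  Autozygosity is planted as homozygous tracts of
configurable length; every SNP a tract spans is set homozygous (allele drawn
by its frequency) before genotyping error and missingness are injected.
Planted tracts are returned as ground truth so detector output can be scored
for recall, precision, and boundary accuracy.

The generator is a pure function of its parameters: RNG streams are derived
from ``(seed, stage, sample index)``, so the same seed is bit-reproducible
and adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, SampleRecord

__all__ = [
    "BTA_LENGTHS_BP",
    "AUTOSOME_TOTAL_BP",
    "SimParams",
    "TractTruth",
    "RecoveryReport",
    "simulate_panel",
    "inject_errors",
    "evaluate_detection",
    "extend_tracts_to_homozygous_span",
    "write_truth_table",
]

#: Total autosome length covered by the array map, in bp; the default FROH
#: denominator (2508.706681 Mb).
AUTOSOME_TOTAL_BP: int = 2_508_706_681

# ARS-UCD1.2 autosome lengths, used only as proportions.
_BTA_RAW = {
    1: 158_534_110, 2: 136_231_102, 3: 121_005_158, 4: 120_000_601,
    5: 120_089_316, 6: 117_806_340, 7: 110_682_743, 8: 113_319_770,
    9: 105_454_467, 10: 103_308_737, 11: 106_982_474, 12: 87_216_183,
    13: 83_472_345, 14: 82_403_003, 15: 85_007_780, 16: 81_013_979,
    17: 73_167_244, 18: 65_820_629, 19: 63_449_741, 20: 71_974_595,
    21: 69_862_954, 22: 60_773_035, 23: 52_498_615, 24: 62_317_253,
    25: 42_350_435, 26: 51_992_305, 27: 45_612_108, 28: 45_940_150,
    29: 51_098_607,
}


def _scaled_bta_lengths() -> dict[int, int]:
    total = sum(_BTA_RAW.values())
    scaled = {c: int(round(v * AUTOSOME_TOTAL_BP / total)) for c, v in _BTA_RAW.items()}
    # absorb rounding drift into BTA 1 so the genome sums exactly
    scaled[1] += AUTOSOME_TOTAL_BP - sum(scaled.values())
    return scaled


#: Default 29-autosome partition: real BTA proportions rescaled to sum to
#: exactly :data:`AUTOSOME_TOTAL_BP`.
BTA_LENGTHS_BP: dict[int, int] = _scaled_bta_lengths()

# RNG stage tags (second word of the seed tuple)
_STAGE_MAP = 0
_STAGE_GENO = 1
_STAGE_TRACT = 2
_STAGE_ERROR = 3


@dataclass(frozen=True)
class SimParams:
    """Panel-generator parameters.

    Defaults emulate the study panel: a BovineSNP50-class map (~48k autosomal
    SNPs at ~52 kb mean spacing over 2,508.7 Mb), uniform(0.05, 0.5) minor
    allele frequencies, log-uniform tract lengths on [250 kb, 20 Mb] with a
    Poisson(55) tract count per animal (planted autozygosity ~0.1 of the
    genome, the FROH level reported for commercial Holstein herds), and
    0.5% missingness (total genotyping rate > 0.99).
    """

    n_samples: int = 50
    chrom_lengths_bp: dict[int, int] = field(default_factory=lambda: dict(BTA_LENGTHS_BP))
    mean_spacing_bp: int = 52_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    tracts_per_sample_mean: float = 55.0
    tract_length_range_bp: tuple[int, int] = (250_000, 20_000_000)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.005
    group_sizes: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.genotype_error_rate, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(v <= 0 for v in self.chrom_lengths_bp.values()):
            raise ValueError("chromosome lengths must be positive")
        lo, hi = self.tract_length_range_bp
        if not (0 < lo <= hi):
            raise ValueError("invalid tract length range")
        if hi > max(self.chrom_lengths_bp.values()):
            raise ValueError(
                f"max tract length {hi} exceeds the longest chromosome "
                f"({max(self.chrom_lengths_bp.values())} bp)"
            )
        if self.group_sizes is not None and sum(self.group_sizes) != self.n_samples:
            raise ValueError("group_sizes must sum to n_samples")


@dataclass(frozen=True)
class TractTruth:
    """One planted autozygous interval (ground truth for recovery scoring)."""

    sample_id: str
    chrom: int | str
    start_bp: int
    end_bp: int
    n_snps_spanned: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class RecoveryReport:
    """Detector output scored against planted-tract truth.

    Undefined ratios (no truth tracts, or no called segments) are reported as
    ``None``, never as 0/0.
    """

    n_truth: int
    n_segments: int
    n_truth_matched: int
    n_segments_matched: int
    recall: float | None
    precision: float | None
    mean_boundary_error_bp: float | None
    per_class_recall: dict[str, float | None] = field(default_factory=dict)


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, int(index)]))


def _simulate_map(p: SimParams) -> pd.DataFrame:
    """Jittered SNP grid per chromosome at the requested mean spacing."""
    rng = _rng(p.seed, _STAGE_MAP)
    rows = []
    for chrom in sorted(p.chrom_lengths_bp):
        length = p.chrom_lengths_bp[chrom]
        n = max(2, int(round(length / p.mean_spacing_bp)))
        step = length / n
        jitter = rng.uniform(-0.4, 0.4, size=n) * step
        pos = (np.arange(n) + 0.5) * step + jitter
        pos = np.clip(np.round(pos).astype(np.int64), 1, length)
        pos = np.sort(pos)
        # de-duplicate while preserving order (grid jitter < step/2 keeps
        # collisions rare; nudging by +1 cannot overrun the neighbour's slot)
        for k in range(1, n):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        for k, bp in enumerate(pos):
            rows.append((f"snp_{chrom}_{k}", chrom, int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out: list[list[int]] = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def simulate_panel(p: SimParams) -> tuple[GenotypeMatrix, list[TractTruth]]:
    """Generate a panel plus its planted-tract ground truth.

    Background calls are drawn per SNP from HWE given its allele frequency;
    inside each planted tract every spanned SNP is set homozygous (HOM_A with
    probability equal to the A-allele frequency) *before* error/missingness
    injection.  Overlapping tracts within one sample+chromosome are merged,
    so the returned truth is canonical.
    """
    snps = _simulate_map(p)
    n_snps = len(snps)
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos_bp"].to_numpy()

    rng_map = _rng(p.seed, _STAGE_MAP, 1)
    freq_a = rng_map.uniform(p.maf_range[0], p.maf_range[1], size=n_snps)

    chroms = sorted(p.chrom_lengths_bp)
    chrom_len = np.array([p.chrom_lengths_bp[c] for c in chroms], dtype=float)
    chrom_prob = chrom_len / chrom_len.sum()
    chrom_index = {c: np.flatnonzero(chrom_arr == c) for c in chroms}

    # group (herd) labels
    if p.group_sizes is not None:
        labels = []
        for g, size in enumerate(p.group_sizes, start=1):
            labels.extend([f"herd{g}"] * size)
    else:
        labels = [None] * p.n_samples

    # fixed-width ids so growing n_samples never renames earlier samples
    samples = [
        SampleRecord(sample_id=f"s{i:04d}", group_id=labels[i])
        for i in range(p.n_samples)
    ]

    calls = np.empty((p.n_samples, n_snps), dtype=np.uint8)
    truth: list[TractTruth] = []
    lo, hi = p.tract_length_range_bp
    log_lo, log_hi = math.log(lo), math.log(hi)

    for i, sample in enumerate(samples):
        g = _rng(p.seed, _STAGE_GENO, i)
        u = g.random(n_snps)
        p_aa = freq_a ** 2
        p_het = 2 * freq_a * (1 - freq_a)
        row = np.where(u < p_aa, HOM_A, np.where(u < p_aa + p_het, HET, HOM_B)).astype(np.uint8)

        t = _rng(p.seed, _STAGE_TRACT, i)
        k = t.poisson(p.tracts_per_sample_mean)
        per_chrom: dict[int, list[tuple[int, int]]] = {}
        for _ in range(k):
            ci = t.choice(len(chroms), p=chrom_prob)
            chrom = chroms[ci]
            length = int(round(math.exp(t.uniform(log_lo, log_hi))))
            length = min(length, p.chrom_lengths_bp[chrom] - 1)
            start = int(t.integers(1, p.chrom_lengths_bp[chrom] - length + 1))
            per_chrom.setdefault(chrom, []).append((start, start + length))
        for chrom, intervals in sorted(per_chrom.items()):
            for s, e in _merge_intervals(intervals):
                idx = chrom_index[chrom]
                span = idx[(pos_arr[idx] >= s) & (pos_arr[idx] <= e)]
                hom = np.where(t.random(len(span)) < freq_a[span], HOM_A, HOM_B)
                row[span] = hom.astype(np.uint8)
                truth.append(TractTruth(
                    sample_id=sample.sample_id, chrom=chrom,
                    start_bp=s, end_bp=e, n_snps_spanned=len(span),
                ))
        calls[i] = row

    gm = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    if p.genotype_error_rate > 0 or p.missing_rate > 0:
        gm = inject_errors(gm, p.genotype_error_rate, p.missing_rate, seed=p.seed)
    truth.sort(key=lambda t: (t.sample_id, str(t.chrom), t.start_bp))
    return gm, truth


def inject_errors(
    gm: GenotypeMatrix,
    genotype_error_rate: float,
    missing_rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Return a copy with genotyping error and missingness injected.

    Each non-missing call is independently rendered HET with
    ``genotype_error_rate`` (the miscall mode that interrupts ROH; homozygote
    to homozygote miscalls are invisible to run detection and not modelled),
    then each call is independently set MISSING with ``missing_rate``.
    Streams are split per sample so the noise field is stable under sample
    addition.
    """
    for r in (genotype_error_rate, missing_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    calls = gm.calls.copy()
    n_snps = gm.n_snps
    for i in range(gm.n_samples):
        e = _rng(seed, _STAGE_ERROR, i)
        if genotype_error_rate > 0:
            flip = (e.random(n_snps) < genotype_error_rate) & (calls[i] != MISSING)
            calls[i, flip] = HET
        else:
            e.random(n_snps)  # keep the stream aligned across rate settings
        if missing_rate > 0:
            drop = e.random(n_snps) < missing_rate
            calls[i, drop] = MISSING
    return GenotypeMatrix(samples=list(gm.samples), snps=gm.snps.copy(), calls=calls)


def _length_class(length_bp: int) -> str:
    mb = length_bp / 1e6
    if mb < 1:
        return "<1Mb"
    for lo, hi in ((1, 2), (2, 4), (4, 8), (8, 16)):
        if mb < hi:
            return f"{lo}-{hi}Mb"
    return ">16Mb"


def evaluate_detection(
    truth: Sequence[TractTruth],
    segments: Sequence,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Score called segments against planted truth by reciprocal overlap.

    A truth tract is *matched* when some called segment on the same sample
    and chromosome overlaps it by at least ``min_reciprocal_overlap`` of both
    lengths.  Boundary error is the mean of ``|start diff| + |end diff|``
    over matched pairs (best-overlapping segment per tract).
    """
    if not (0.0 < min_reciprocal_overlap <= 1.0):
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    seg_by_key: dict[tuple, list] = {}
    for s in segments:
        seg_by_key.setdefault((s.sample_id, s.chrom), []).append(s)

    matched_truth = 0
    matched_seg_ids: set[int] = set()
    boundary_errors: list[float] = []
    class_total: dict[str, int] = {}
    class_hit: dict[str, int] = {}

    for t in truth:
        cls = _length_class(t.length_bp)
        class_total[cls] = class_total.get(cls, 0) + 1
        best = None
        best_recip = 0.0
        for s in seg_by_key.get((t.sample_id, t.chrom), ()):
            ov = min(t.end_bp, s.end_bp) - max(t.start_bp, s.start_bp)
            if ov <= 0:
                continue
            recip = min(ov / t.length_bp, ov / max(s.length_bp, 1))
            if recip >= min_reciprocal_overlap:
                matched_seg_ids.add(id(s))
                if recip > best_recip:
                    best, best_recip = s, recip
        if best is not None:
            matched_truth += 1
            class_hit[cls] = class_hit.get(cls, 0) + 1
            boundary_errors.append(
                abs(best.start_bp - t.start_bp) + abs(best.end_bp - t.end_bp)
            )

    # segments matched to any truth tract (for precision)
    n_seg_matched = 0
    truth_by_key: dict[tuple, list[TractTruth]] = {}
    for t in truth:
        truth_by_key.setdefault((t.sample_id, t.chrom), []).append(t)
    for s in segments:
        for t in truth_by_key.get((s.sample_id, s.chrom), ()):
            ov = min(t.end_bp, s.end_bp) - max(t.start_bp, s.start_bp)
            if ov > 0 and min(ov / t.length_bp, ov / max(s.length_bp, 1)) >= min_reciprocal_overlap:
                n_seg_matched += 1
                break

    per_class = {
        cls: (class_hit.get(cls, 0) / n if n else None)
        for cls, n in sorted(class_total.items())
    }
    return RecoveryReport(
        n_truth=len(truth),
        n_segments=len(segments),
        n_truth_matched=matched_truth,
        n_segments_matched=n_seg_matched,
        recall=(matched_truth / len(truth)) if truth else None,
        precision=(n_seg_matched / len(segments)) if segments else None,
        mean_boundary_error_bp=(float(np.mean(boundary_errors)) if boundary_errors else None),
        per_class_recall=per_class,
    )


def extend_tracts_to_homozygous_span(
    gm: GenotypeMatrix, truth: Sequence[TractTruth]
) -> list[TractTruth]:
    """Snap each planted tract to its observable homozygous SNP extent.

    A planted boundary falling between SNPs, or adjoining a stretch of
    background homozygosity, is not observable from genotypes: the maximal
    information the data carries about a tract is the maximal run of
    homozygous calls containing it.  This helper extends each tract outward
    over consecutive homozygous calls (stopping at HET or MISSING) and snaps
    the boundaries to the first/last SNP of that run, giving the reference
    against which detector boundary accuracy is meaningfully measured.
    """
    sample_row = {s.sample_id: i for i, s in enumerate(gm.samples)}
    chrom_pos = {c: (pos, idx) for c, pos, idx in gm.chrom_slices()}
    out: list[TractTruth] = []
    for t in truth:
        pos, idx = chrom_pos[t.chrom]
        row = gm.calls[sample_row[t.sample_id], idx]
        inside = np.flatnonzero((pos >= t.start_bp) & (pos <= t.end_bp))
        if len(inside) == 0:
            out.append(t)
            continue
        lo, hi = int(inside[0]), int(inside[-1])
        is_hom = (row == HOM_A) | (row == HOM_B)
        while lo > 0 and is_hom[lo - 1]:
            lo -= 1
        while hi + 1 < len(row) and is_hom[hi + 1]:
            hi += 1
        out.append(TractTruth(
            sample_id=t.sample_id, chrom=t.chrom,
            start_bp=int(pos[lo]), end_bp=int(pos[hi]),
            n_snps_spanned=hi - lo + 1,
        ))
    return out


def write_truth_table(truth: Iterable[TractTruth], path) -> None:
    """Write planted tracts as a BED-like TSV (sample, chrom, start, end, n_snps)."""
    df = pd.DataFrame(
        [(t.sample_id, t.chrom, t.start_bp, t.end_bp, t.n_snps_spanned) for t in truth],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps_spanned"],
    )
    df.to_csv(path, sep="\t", index=False)
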