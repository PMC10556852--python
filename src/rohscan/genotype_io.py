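"""PLINK text PED/MAP genotype input/output, the genotype matrix, and SNP QC.

Genotype calls are held as a dense ``samples x snps`` uint8 matrix over four
states (:data:`HOM_A`, :data:`HET`, :data:`HOM_B`, :data:`MISSING`).  ROH
detection only distinguishes homozygous / heterozygous / missing, so the
assignment of A vs B (lexicographically smaller observed allele = A) is
immaterial to every downstream statistic.

Coordinates are 1-based inclusive base pairs throughout the package, and the
length of an interval is ``end_bp - start_bp`` (the detectRUNS "to - from"
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HOM_A",
    "HET",
    "HOM_B",
    "MISSING",
    "SnpRecord",
    "SampleRecord",
    "GenotypeMatrix",
    "QcParams",
    "QcReport",
    "FormatError",
    "EmptyPanelError",
    "read_ped_map",
    "write_ped_map",
    "apply_qc",
    "write_roh_table",
    "read_roh_table",
]

# 4-state genotype coding
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = 3

_VALID_ALLELES = frozenset("ACGT12")

ROH_TABLE_COLUMNS = [
    "IID", "GROUP", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET", "NMISS", "METHOD",
]


class FormatError(ValueError):
    """Raised when a PED/MAP or ROH table does not parse."""


class EmptyPanelError(ValueError):
    """Raised when QC removes every SNP."""


@dataclass(frozen=True)
class SnpRecord:
    """One mapped SNP: identifier, chromosome label and 1-based bp position."""

    snp_id: str
    chrom: int | str
    pos_bp: int


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual, optionally assigned to a group (herd)."""

    sample_id: str
    group_id: str | None = None


def _chrom_sort_key(chrom: int | str) -> tuple[int, int, str]:
    """Sort integer chromosome labels numerically before string labels."""
    if isinstance(chrom, (int, np.integer)):
        return (0, int(chrom), "")
    return (1, 0, str(chrom))


def _parse_chrom(token: str) -> int | str:
    try:
        return int(token)
    except ValueError:
        return token


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls plus the SNP map and sample sheet.

    ``snps`` is a DataFrame with columns ``snp_id, chrom, pos_bp`` sorted by
    (chrom, pos_bp); ``calls`` is a uint8 matrix aligned to it row-per-sample.
    """

    samples: list[SampleRecord]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.calls.size and self.calls.max() > MISSING:
            raise ValueError("calls contain codes outside the 4-state alphabet")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_map(self) -> dict[str, str | None]:
        return {s.sample_id: s.group_id for s in self.samples}

    def chromosomes(self) -> list[int | str]:
        seen = self.snps["chrom"].unique().tolist()
        return sorted(seen, key=_chrom_sort_key)

    def sample_call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per sample."""
        with np.errstate(invalid="ignore"):
            rate = 1.0 - (self.calls == MISSING).mean(axis=1)
        return pd.Series(rate, index=self.sample_ids, name="call_rate")

    def total_genotyping_rate(self) -> float:
        return float(1.0 - (self.calls == MISSING).mean())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
        )

    def chrom_slices(self) -> list[tuple[int | str, np.ndarray, np.ndarray]]:
        """Yield (chrom, positions, column-index array) per chromosome, in order."""
        out = []
        chrom_col = self.snps["chrom"].to_numpy()
        pos_col = self.snps["pos_bp"].to_numpy()
        for chrom in self.chromosomes():
            idx = np.flatnonzero(chrom_col == chrom)
            out.append((chrom, pos_col[idx].astype(np.int64), idx))
        return out

    def validate_sorted(self) -> None:
        """Raise if the SNP map is not strictly sorted within chromosomes."""
        for chrom, pos, _ in self.chrom_slices():
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"SNP map not strictly increasing on chromosome {chrom}")


@dataclass(frozen=True)
class QcParams:
    """SNP-level quality-control thresholds.

    Defaults are the standard medium-density array filters: drop SNPs with
    more than 5% missing calls or minor allele frequency below 1%, and keep
    autosomes only (cattle BTA 1-29).
    """

    max_snp_missing_rate: float = 0.05
    min_maf: float = 0.01
    autosomes_only: bool = True
    autosome_labels: frozenset = frozenset(range(1, 30))

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_snp_missing_rate <= 1.0):
            raise ValueError("max_snp_missing_rate must be in [0, 1]")
        if not (0.0 <= self.min_maf <= 1.0):
            raise ValueError("min_maf must be in [0, 1]")


@dataclass
class QcReport:
    """Per-filter attrition bookkeeping; removals counted once, in filter order."""

    n_snps_in: int
    n_snps_out: int
    n_removed_nonautosomal: int
    n_removed_missing: int
    n_removed_maf: int
    removed_nonautosomal: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (self.n_removed_nonautosomal + self.n_removed_missing
                 + self.n_removed_maf + self.n_snps_out)
        if total != self.n_snps_in:
            raise ValueError("QC accounting does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("nonautosomal", s) for s in self.removed_nonautosomal]
            + [("missing_rate", s) for s in self.removed_missing]
            + [("maf", s) for s in self.removed_maf]
        )
        return pd.DataFrame(rows, columns=["filter", "snp_id"])


def _sort_map(snps: pd.DataFrame, calls: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    keys = [_chrom_sort_key(c) for c in snps["chrom"]]
    order = sorted(range(len(snps)), key=lambda i: (keys[i], int(snps["pos_bp"].iat[i])))
    order = np.asarray(order)
    return snps.iloc[order].reset_index(drop=True), calls[:, order]


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED + MAP into a :class:`GenotypeMatrix`.

    MAP rows are ``chrom snp_id cM pos_bp``; PED rows are the six standard
    leading columns followed by two allele columns per SNP.  Allele codes may
    be A/C/G/T or 1/2; ``0`` marks a missing allele.  The PED family ID is
    kept as the sample's group label, matching how herds are usually encoded.
    SNPs are returned sorted by (chrom, pos_bp).
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            map_rows.append((snp_id, _parse_chrom(chrom), int(pos)))
    snps = pd.DataFrame(map_rows, columns=["snp_id", "chrom", "pos_bp"])
    if snps.empty:
        raise FormatError(f"{map_path}: no SNPs")
    if snps["snp_id"].duplicated().any():
        dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{map_path}: duplicate snp_id {dup!r}")
    if (snps["pos_bp"] < 1).any():
        raise FormatError(f"{map_path}: positions must be >= 1")
    n_snps = len(snps)

    samples: list[SampleRecord] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} PED columns "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            samples.append(SampleRecord(sample_id=iid, group_id=fid if fid != "0" else None))
            alleles = np.array(parts[6:], dtype="U4")
            bad = ~np.isin(alleles, list(_VALID_ALLELES | {"0"}))
            if bad.any():
                raise FormatError(
                    f"{ped_path}:{ln}: invalid allele code {alleles[bad][0]!r}"
                )
            allele_rows.append(alleles)
    if not samples:
        raise FormatError(f"{ped_path}: no samples")

    a1 = np.stack([r[0::2] for r in allele_rows])  # samples x snps
    a2 = np.stack([r[1::2] for r in allele_rows])
    calls = np.full(a1.shape, MISSING, dtype=np.uint8)
    observed_missing = (a1 == "0") | (a2 == "0")
    # per-SNP lexicographically smallest observed allele is A
    for j in range(n_snps):
        col1, col2 = a1[:, j], a2[:, j]
        ok = ~observed_missing[:, j]
        if not ok.any():
            continue
        observed = np.unique(np.concatenate([col1[ok], col2[ok]]))
        allele_a = observed[0]  # np.unique output is sorted
        het = ok & (col1 != col2)
        hom_a = ok & ~het & (col1 == allele_a)
        hom_b = ok & ~het & (col1 != allele_a)
        calls[het, j] = HET
        calls[hom_a, j] = HOM_A
        calls[hom_b, j] = HOM_B

    snps, calls = _sort_map(snps, calls)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_ped_map(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a matrix as PLINK text PED/MAP.

    Allele letters are not retained by the 4-state coding, so genotypes are
    written with synthetic alleles ``1`` (A) and ``2`` (B); ``1`` sorts before
    ``2``, so a read-back reproduces the call matrix exactly.
    """
    with open(map_path, "w") as fh:
        for rec in gm.snps.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos_bp}\n")
    allele_text = {
        HOM_A: "1 1",
        HET: "1 2",
        HOM_B: "2 2",
        MISSING: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.samples):
            fid = s.group_id if s.group_id is not None else "0"
            lead = f"{fid} {s.sample_id} 0 0 0 -9"
            geno = " ".join(allele_text[int(c)] for c in gm.calls[i])
            fh.write(f"{lead} {geno}\n" if geno else f"{lead}\n")


def apply_qc(gm: GenotypeMatrix, qc: QcParams | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply SNP QC filters in a fixed order; samples are never dropped.

    Order: (1) drop non-autosomal SNPs, (2) drop SNPs whose missing fraction
    exceeds ``max_snp_missing_rate``, (3) drop SNPs with MAF below ``min_maf``
    (allele frequencies over non-missing calls; a SNP with zero non-missing
    calls has undefined MAF and is removed).
    """
    if qc is None:
        qc = QcParams()
    if gm.n_snps == 0:
        raise EmptyPanelError("input panel has no SNPs")

    snp_ids = gm.snps["snp_id"].to_numpy()
    alive = np.ones(gm.n_snps, dtype=bool)

    if qc.autosomes_only:
        autosomal = np.array(
            [isinstance(c, (int, np.integer)) and int(c) in qc.autosome_labels
             for c in gm.snps["chrom"]],
            dtype=bool,
        )
        removed_auto = np.flatnonzero(alive & ~autosomal)
        alive &= autosomal
    else:
        removed_auto = np.array([], dtype=int)

    miss_frac = (gm.calls == MISSING).mean(axis=0)
    fail_miss = miss_frac > qc.max_snp_missing_rate
    removed_miss = np.flatnonzero(alive & fail_miss)
    alive &= ~fail_miss

    n_a = (2 * (gm.calls == HOM_A) + (gm.calls == HET)).sum(axis=0)
    n_b = (2 * (gm.calls == HOM_B) + (gm.calls == HET)).sum(axis=0)
    n_tot = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n_tot > 0, np.minimum(n_a, n_b) / np.maximum(n_tot, 1), np.nan)
    fail_maf = np.isnan(maf) | (maf < qc.min_maf)
    removed_maf = np.flatnonzero(alive & fail_maf)
    alive &= ~fail_maf

    report = QcReport(
        n_snps_in=gm.n_snps,
        n_snps_out=int(alive.sum()),
        n_removed_nonautosomal=len(removed_auto),
        n_removed_missing=len(removed_miss),
        n_removed_maf=len(removed_maf),
        removed_nonautosomal=snp_ids[removed_auto].tolist(),
        removed_missing=snp_ids[removed_miss].tolist(),
        removed_maf=snp_ids[removed_maf].tolist(),
    )
    if report.n_snps_out == 0:
        raise EmptyPanelError("empty panel after QC: every SNP failed a filter")
    return gm.subset_snps(alive), report


def write_roh_table(segments: Iterable, path: str | Path, group_map: dict | None = None) -> None:
    """Write ROH segments as a PLINK ``.hom``-style TSV.

    One row per segment (IID, GROUP, CHR, POS1, POS2, KB, NSNP, NHET, NMISS,
    METHOD), ordered by (sample, chrom, start) so output is deterministic.
    """
    group_map = group_map or {}
    rows = []
    for seg in segments:
        rows.append({
            "IID": seg.sample_id,
            "GROUP": group_map.get(seg.sample_id) or "NA",
            "CHR": seg.chrom,
            "POS1": seg.start_bp,
            "POS2": seg.end_bp,
            "KB": (seg.end_bp - seg.start_bp) / 1000.0,
            "NSNP": seg.n_snp,
            "NHET": seg.n_het,
            "NMISS": seg.n_missing,
            "METHOD": seg.method,
        })
    df = pd.DataFrame(rows, columns=ROH_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["IID", "CHR", "POS1"],
            key=lambda col: col.map(_chrom_sort_key) if col.name == "CHR" else col,
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_roh_table(path: str | Path) -> list:
    """Parse a ``.hom``-style TSV written by :func:`write_roh_table`."""
    from .detect import RohSegment  # deferred: avoid circular import

    df = pd.read_csv(path, sep="\t", dtype={"IID": str, "GROUP": str, "METHOD": str})
    missing_cols = set(ROH_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    return [
        RohSegment(
            sample_id=row.IID,
            chrom=_parse_chrom(str(row.CHR)),
            start_bp=int(row.POS1),
            end_bp=int(row.POS2),
            n_snp=int(row.NSNP),
            n_het=int(row.NHET),
            n_missing=int(row.NMISS),
            method=row.METHOD,
        )
        for row in df.itertuples(index=False)
    ]
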