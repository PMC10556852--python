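"""One-command study orchestration.

``run_study`` drives the full analysis: ingest PED/MAP genotypes (or
simulate a panel with planted autozygous tracts), apply QC, call ROH with
every configured parameterization of both detectors, and emit the complete
table set -- QC report, per-method ``.hom`` tables, FROH per sample, group
summaries, length-class tables, chromosome ranks, the het/missing
sensitivity grid, method-agreement statistics, and (in simulation mode) a
recovery report against the planted truth.  Everything is deterministic
given the seed, and every stage logs record counts so attrition and yields
are auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import detect as _detect
from .detect import ConsecutiveParams, get_preset
from .genotype_io import (
    GenotypeMatrix,
    QcParams,
    apply_qc,
    read_ped_map,
    write_ped_map,
    write_roh_table,
)
from .simulate import (
    AUTOSOME_TOTAL_BP,
    SimParams,
    evaluate_detection,
    simulate_panel,
    write_truth_table,
)
from .summarize import (
    classify_lengths,
    compare_methods,
    denominator_from_map,
    froh_per_sample,
    rank_chromosomes,
    summarize_groups,
    sweep_het_missing,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "load_config", "save_config"]

log = logging.getLogger("rohscan")

_DEFAULT_DETECTORS = ("consecutive-20", "consecutive-15", "sliding-20", "plink-paper")


@dataclass
class StudyConfig:
    """Full study description; exactly one input mode (files or simulation)."""

    ped_path: str | None = None
    map_path: str | None = None
    sim: SimParams | None = None
    qc: QcParams = field(default_factory=QcParams)
    detectors: tuple[str, ...] = _DEFAULT_DETECTORS
    sweep_het: tuple[int, ...] = (0, 1, 2)
    sweep_missing: tuple[int, ...] = (0, 1, 2, 3, 4)
    sweep_detector: str = "consecutive-20"
    denominator_bp: float | str = AUTOSOME_TOTAL_BP  # number or "from-map"
    min_reciprocal_overlap: float = 0.5
    out_dir: str = "rohscan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        file_mode = self.ped_path is not None or self.map_path is not None
        sim_mode = self.sim is not None
        if file_mode == sim_mode:
            raise ValueError("exactly one input mode: ped/map paths OR a simulation block")
        if file_mode and (self.ped_path is None or self.map_path is None):
            raise ValueError("both ped_path and map_path are required in file mode")
        for name in self.detectors:
            get_preset(name)  # validates


@dataclass
class StudyResult:
    """In-memory bundle of everything ``run_study`` wrote to disk."""

    genotypes: GenotypeMatrix
    qc_report: Any
    segments: dict[str, list]
    froh: dict[str, pd.DataFrame]
    group_summaries: dict[str, pd.DataFrame]
    length_classes: dict[str, pd.DataFrame]
    chrom_ranks: dict[str, pd.DataFrame]
    rank_agreement: pd.DataFrame | None
    sweep: pd.DataFrame
    recovery: pd.DataFrame | None
    denominator_bp: float
    out_dir: Path


def _params_to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, frozenset):
            d[k] = sorted(v)
    return d


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    """Serialize a config to YAML (round-trips through :func:`load_config`)."""
    d: dict[str, Any] = {
        "ped_path": cfg.ped_path,
        "map_path": cfg.map_path,
        "qc": _params_to_dict(cfg.qc),
        "detectors": list(cfg.detectors),
        "sweep_het": list(cfg.sweep_het),
        "sweep_missing": list(cfg.sweep_missing),
        "sweep_detector": cfg.sweep_detector,
        "denominator_bp": cfg.denominator_bp,
        "min_reciprocal_overlap": cfg.min_reciprocal_overlap,
        "out_dir": str(cfg.out_dir),
        "seed": cfg.seed,
    }
    if cfg.sim is not None:
        sim = dataclasses.asdict(cfg.sim)
        sim["chrom_lengths_bp"] = {int(k): int(v) for k, v in sim["chrom_lengths_bp"].items()}
        sim["maf_range"] = list(sim["maf_range"])
        sim["tract_length_range_bp"] = list(sim["tract_length_range_bp"])
        if sim["group_sizes"] is not None:
            sim["group_sizes"] = list(sim["group_sizes"])
        d["sim"] = sim
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path: str | Path) -> StudyConfig:
    """Parse a YAML study config written by :func:`save_config` (or by hand)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    sim = None
    if d.get("sim") is not None:
        s = dict(d["sim"])
        if "chrom_lengths_bp" in s:
            s["chrom_lengths_bp"] = {int(k): int(v) for k, v in s["chrom_lengths_bp"].items()}
        for key in ("maf_range", "tract_length_range_bp", "group_sizes"):
            if s.get(key) is not None:
                s[key] = tuple(s[key])
        sim = SimParams(**s)
    qc = QcParams(**{**d.get("qc", {}),
                     **({"autosome_labels": frozenset(d["qc"]["autosome_labels"])}
                        if d.get("qc", {}).get("autosome_labels") is not None else {})})
    return StudyConfig(
        ped_path=d.get("ped_path"),
        map_path=d.get("map_path"),
        sim=sim,
        qc=qc,
        detectors=tuple(d.get("detectors", _DEFAULT_DETECTORS)),
        sweep_het=tuple(d.get("sweep_het", (0, 1, 2))),
        sweep_missing=tuple(d.get("sweep_missing", (0, 1, 2, 3, 4))),
        sweep_detector=d.get("sweep_detector", "consecutive-20"),
        denominator_bp=d.get("denominator_bp", AUTOSOME_TOTAL_BP),
        min_reciprocal_overlap=d.get("min_reciprocal_overlap", 0.5),
        out_dir=d.get("out_dir", "rohscan_out"),
        seed=int(d.get("seed", 0)),
    )


def _froh_frame(froh_results) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.sample_id, f.sum_roh_bp, f.denominator_bp, f.froh) for f in froh_results],
        columns=["sample_id", "sum_roh_bp", "denominator_bp", "froh"],
    )


def _groups_frame(summaries) -> pd.DataFrame:
    rows = []
    for g in summaries:
        for other, (t, p) in sorted(g.pairwise.items()):
            rows.append((g.group_id, g.n, g.mean, g.se, other, t, p))
        if not g.pairwise:
            rows.append((g.group_id, g.n, g.mean, g.se, None, None, None))
    return pd.DataFrame(
        rows, columns=["group", "n", "mean", "se", "vs_group", "welch_t", "welch_p"]
    )


def _ranks_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.n_roh, r.prop_roh, r.prop_len, r.score, r.rank) for r in rows],
        columns=["chrom", "n_roh", "prop_roh", "prop_len", "score", "rank"],
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full study and write all result tables under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ingest or simulate
    truth = None
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        gm, truth = simulate_panel(sim)
        log.info("simulated panel: %d samples x %d SNPs, %d planted tracts",
                 gm.n_samples, gm.n_snps, len(truth))
        write_ped_map(gm, out / "panel.ped", out / "panel.map")
        write_truth_table(truth, out / "truth_tracts.tsv")
    else:
        gm = read_ped_map(cfg.ped_path, cfg.map_path)
        log.info("read panel: %d samples x %d SNPs", gm.n_samples, gm.n_snps)

    gm_qc, qc_report = apply_qc(gm, cfg.qc)
    log.info("QC: %d -> %d SNPs (nonautosomal %d, missing %d, maf %d)",
             qc_report.n_snps_in, qc_report.n_snps_out,
             qc_report.n_removed_nonautosomal, qc_report.n_removed_missing,
             qc_report.n_removed_maf)
    qc_report.to_frame().to_csv(out / "qc_removed_snps.tsv", sep="\t", index=False)

    if cfg.denominator_bp == "from-map":
        denominator = denominator_from_map(gm_qc)
    else:
        denominator = float(cfg.denominator_bp)
    log.info("FROH denominator: %.0f bp", denominator)

    group_map = gm_qc.group_map()
    have_groups = any(v is not None for v in group_map.values())
    sample_ids = gm_qc.sample_ids

    segments: dict[str, list] = {}
    froh_frames: dict[str, pd.DataFrame] = {}
    group_frames: dict[str, pd.DataFrame] = {}
    class_frames: dict[str, pd.DataFrame] = {}
    rank_frames: dict[str, pd.DataFrame] = {}
    rank_rows_by_detector: dict[str, list] = {}
    recovery_rows = []

    chrom_lengths = (
        {c: int(v) for c, v in (cfg.sim.chrom_lengths_bp.items() if cfg.sim else [])}
        or {c: int(pos[-1]) for c, pos, _ in gm_qc.chrom_slices() if len(pos)}
    )

    for name in cfg.detectors:
        params = get_preset(name)
        if isinstance(params, ConsecutiveParams):
            segs = _detect.detect_consecutive(gm_qc, params)
        else:
            segs = _detect.detect_sliding(gm_qc, params)
        segments[name] = segs
        log.info("detector %s: %d segments", name, len(segs))
        write_roh_table(segs, out / f"roh_{name}.hom.tsv", group_map=group_map)

        froh = froh_per_sample(segs, sample_ids, denominator)
        froh_frames[name] = _froh_frame(froh)
        _write(froh_frames[name], out / f"froh_{name}.tsv")

        class_frames[name] = classify_lengths(segs).to_frame()
        _write(class_frames[name], out / f"length_classes_{name}.tsv")

        if segs:
            rows = rank_chromosomes(segs, chrom_lengths)
            rank_rows_by_detector[name] = rows
            rank_frames[name] = _ranks_frame(rows)
            _write(rank_frames[name], out / f"chrom_ranks_{name}.tsv")

        if have_groups:
            counts = {sid: 0 for sid in sample_ids}
            for s in segs:
                counts[s.sample_id] += 1
            gsum_counts = summarize_groups(counts, group_map)
            gsum_froh = summarize_groups({f.sample_id: f.froh for f in froh}, group_map)
            frame = pd.concat([
                _groups_frame(gsum_counts).assign(statistic="roh_count"),
                _groups_frame(gsum_froh).assign(statistic="froh"),
            ], ignore_index=True)
            group_frames[name] = frame
            _write(frame, out / f"group_summary_{name}.tsv")

        if truth is not None:
            rep = evaluate_detection(truth, segs, cfg.min_reciprocal_overlap)
            recovery_rows.append({
                "detector": name,
                "n_truth": rep.n_truth,
                "n_segments": rep.n_segments,
                "recall": rep.recall,
                "precision": rep.precision,
                "mean_boundary_error_bp": rep.mean_boundary_error_bp,
                **{f"recall_{cls}": v for cls, v in rep.per_class_recall.items()},
            })

    # method agreement on chromosome ranks
    rank_agreement = None
    named = [n for n in cfg.detectors if n in rank_rows_by_detector]
    if len(named) >= 2:
        rows = []
        for i, a in enumerate(named):
            for b in named[i + 1:]:
                try:
                    rho, p = compare_methods(rank_rows_by_detector[a], rank_rows_by_detector[b])
                except ValueError as err:
                    log.warning("rank agreement %s vs %s skipped: %s", a, b, err)
                    continue
                rows.append((a, b, rho, p))
        if rows:
            rank_agreement = pd.DataFrame(rows, columns=["method_a", "method_b", "spearman_rho", "p_value"])
            _write(rank_agreement, out / "rank_agreement.tsv")

    # het x missing sensitivity sweep
    sweep_cells = sweep_het_missing(
        gm_qc, get_preset(cfg.sweep_detector),
        het_values=cfg.sweep_het, missing_values=cfg.sweep_missing,
        denominator_bp=denominator,
    )
    sweep_df = pd.DataFrame(
        [(c.max_het, c.max_missing, c.mean_roh_count, c.mean_froh, c.mean_sum_roh_bp)
         for c in sweep_cells],
        columns=["max_het", "max_missing", "mean_roh_count", "mean_froh", "mean_sum_roh_bp"],
    )
    _write(sweep_df, out / "sweep_het_missing.tsv")
    log.info("sweep: %d cells (detector %s)", len(sweep_df), cfg.sweep_detector)

    recovery_df = None
    if recovery_rows:
        recovery_df = pd.DataFrame(recovery_rows)
        _write(recovery_df, out / "recovery.tsv")

    return StudyResult(
        genotypes=gm_qc,
        qc_report=qc_report,
        segments=segments,
        froh=froh_frames,
        group_summaries=group_frames,
        length_classes=class_frames,
        chrom_ranks=rank_frames,
        rank_agreement=rank_agreement,
        sweep=sweep_df,
        recovery=recovery_df,
        denominator_bp=denominator,
        out_dir=out,
    )
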